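"""Genome assembly description: ordered chromosomes and their lengths.

Every track, fragment set and annotation in this package is interpreted
against a :class:`GenomeAssembly`, which plays the role of the "whole
genome" averaging domain used by array scores and pooling windows.
Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = ["GenomeAssembly", "read_chrom_sizes"]


@dataclass(frozen=True)
class GenomeAssembly:
    """Ordered chromosome names and lengths in bp.

    Parameters
    ----------
    names
        Chromosome names, unique, in a fixed order.
    lengths
        Chromosome lengths in bp, positive, parallel to ``names``.
    fasta_path
        Optional path to the genome sequence (only needed for the
        dinucleotide-periodicity QC).
    """

    names: tuple[str, ...]
    lengths: tuple[int, ...]
    fasta_path: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if len(self.names) != len(self.lengths):
            raise ValueError("names and lengths must be parallel")
        if len(set(self.names)) != len(self.names):
            raise ValueError("chromosome names must be unique")
        if any(l <= 0 for l in self.lengths):
            raise ValueError("chromosome lengths must be positive")

    @property
    def sizes(self) -> dict[str, int]:
        return dict(zip(self.names, self.lengths))

    @property
    def total_length(self) -> int:
        """Effective genome size in bp (sum of chromosome lengths)."""
        return sum(self.lengths)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sizes

    def length_of(self, chrom: str) -> int:
        return self.sizes[chrom]


def read_chrom_sizes(path: str | Path, fasta_path: str | None = None) -> GenomeAssembly:
    """Read a two-column ``chrom.sizes`` TSV into a :class:`GenomeAssembly`."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "length"], dtype={"chrom": str})
    if df.empty:
        raise ValueError(f"no chromosomes in {path}")
    return GenomeAssembly(
        names=tuple(df["chrom"]),
        lengths=tuple(int(v) for v in df["length"]),
        fasta_path=fasta_path,
    )
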