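"""MNase-protected fragment sets and sequencing-coverage summaries.

Fragments are the raw evidence for everything downstream: each one is a
(chrom, start, end) interval in 0-based half-open coordinates, nominally
the template span of a paired-end read pair protected from micrococcal
nuclease by a nucleosome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GenomeAssembly

logger = logging.getLogger(__name__)

__all__ = ["FragmentSet", "CoverageSummary", "read_fragments", "compute_coverage"]


@dataclass
class FragmentSet:
    """Genomic intervals of MNase-protected fragments for one sample.

    ``df`` holds columns ``chrom`` (str), ``start``, ``end`` (int64,
    0-based half-open).  Invariant: 0 <= start < end <= chromosome length.
    """

    sample_id: str
    df: pd.DataFrame
    cell_type: str = ""
    treatment: str = ""
    dropped: int = field(default=0, compare=False)  # records dropped at read time

    def __len__(self) -> int:
        return len(self.df)

    @property
    def lengths(self) -> np.ndarray:
        """Fragment lengths in bp (end - start)."""
        return (self.df["end"] - self.df["start"]).to_numpy()

    def midpoints(self) -> np.ndarray:
        return ((self.df["start"] + self.df["end"]) // 2).to_numpy()


@dataclass(frozen=True)
class CoverageSummary:
    """Sequencing coverage: total fragment bases over effective genome size."""

    total_bases: int
    genome_size: int

    @property
    def fold(self) -> float:
        return self.total_bases / self.genome_size

    def to_dict(self) -> dict:
        return {"total_bases": self.total_bases, "genome_size": self.genome_size,
                "fold": self.fold}


def _read_bed_fragments(path: Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        usecols=[0, 1, 2], names=["chrom", "start", "end"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64},
    )
    return df


def _read_alignment_fragments(path: Path) -> pd.DataFrame:
    """Fragments from a coordinate-sorted paired-end SAM/BAM: template spans."""
    import pysam

    mode = "rb" if path.suffix == ".bam" else "r"
    chroms, starts, ends = [], [], []
    with pysam.AlignmentFile(str(path), mode) as af:
        for read in af:
            # one fragment per proper pair, taken from the leftmost mate
            if (read.is_unmapped or read.mate_is_unmapped or read.is_secondary
                    or read.is_supplementary or not read.is_paired):
                continue
            if read.template_length <= 0:
                continue
            chroms.append(read.reference_name)
            starts.append(read.reference_start)
            ends.append(read.reference_start + read.template_length)
    return pd.DataFrame({"chrom": chroms,
                         "start": np.asarray(starts, dtype=np.int64),
                         "end": np.asarray(ends, dtype=np.int64)})


def read_fragments(path: str | Path, assembly: GenomeAssembly,
                   sample_id: str | None = None, cell_type: str = "",
                   treatment: str = "") -> FragmentSet:
    """Read fragments from BED3+ or a paired-end SAM/BAM file.

    Records on chromosomes absent from ``assembly`` and records extending
    past a chromosome end are dropped (not clipped) with a logged count,
    so coverage is never silently distorted.

    Raises
    ------
    ValueError
        If the file is unreadable or no fragments survive filtering.
    """
    path = Path(path)
    if sample_id is None:
        sample_id = path.stem
    try:
        if path.suffix in {".sam", ".bam"}:
            df = _read_alignment_fragments(path)
        else:
            df = _read_bed_fragments(path)
    except Exception as exc:  # noqa: BLE001 - fatal per contract
        raise ValueError(f"unreadable fragment file {path}: {exc}") from exc

    n_in = len(df)
    sizes = assembly.sizes
    known = df["chrom"].map(sizes)
    ok = known.notna()
    ok &= df["start"] >= 0
    ok &= df["start"] < df["end"]
    ok &= df["end"] <= known.fillna(-1)
    dropped = int(n_in - ok.sum())
    if dropped:
        logger.warning("%s: dropped %d of %d records (unknown chromosome or "
                       "out-of-bounds)", path, dropped, n_in)
    df = df[ok].reset_index(drop=True)
    if df.empty:
        raise ValueError(f"no usable fragments in {path}")
    return FragmentSet(sample_id=sample_id, df=df, cell_type=cell_type,
                       treatment=treatment, dropped=dropped)


def compute_coverage(frags: FragmentSet, assembly: GenomeAssembly) -> CoverageSummary:
    """Fold coverage = (sum of fragment lengths) / (sum of chromosome lengths)."""
    if len(frags) == 0:
        raise ValueError("cannot compute coverage of an empty fragment set")
    return CoverageSummary(total_bases=int(frags.lengths.sum()),
                           genome_size=assembly.total_length)
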