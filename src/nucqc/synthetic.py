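"""Synthetic MNase-seq samples and TF-binding datasets with known ground truth.

The generator emulates the statistical structure the downstream features
assume: a nucleosome-free region at each synthetic TSS/DHS, a phased
nucleosome array downstream (both sides for DHSs) whose positions drift as
a random walk with configurable jitter, ~147 bp fragments centered on
nucleosome dyads, a uniform background fragment fraction, and (optionally)
AA dinucleotides planted at a 10 bp phase inside nucleosomal DNA so the
dinucleotide-periodicity QC has signal to find.

Everything is deterministic given the seed, and every output carries the
seed in its header.  Truth tables (dyad positions, site lists, expected
spacing) are sufficient to compute expected feature values independently
of the main code paths.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .fragments import FragmentSet
from .genome import GenomeAssembly
from .tracks import SignalTrack
from .tf import LabeledSite, extract_predictors

__all__ = ["SyntheticSpec", "BindingSpec", "SimulatedSample",
           "simulate_sample", "simulate_binding", "write_sample"]


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic MNase-seq sample.

    Defaults describe a deeply sequenced mononucleosomal library on a small
    genome: ~190 bp repeat length (a typical mammalian value), a 150 bp NFR
    at promoters, fragment lengths Normal(147, 15) truncated to [80, 250],
    and a 20% unpositioned background fraction.
    """

    chrom_length: int = 150_000
    n_chroms: int = 2
    n_tss: int = 15            # per chromosome
    n_dhs: int = 10            # per chromosome
    nfr_width: int = 250       # promoter NDR width; +1 dyad sits at nfr/2 + 73
    spacing: int = 190         # nucleosome repeat length, bp
    n_array_nucs: int = 5      # nucleosomes per downstream array
    n_upstream_nucs: int = 2   # nucleosomes upstream of each TSS
    jitter_sd: float = 0.0     # per-step random-walk jitter of array positions
    # per-fragment midpoint dispersion around the dyad: a rotational component
    # quantized to the helical repeat (nucleosomes slide in ~10 bp frames,
    # which preserves dinucleotide phase) plus a small continuous component
    frag_rot_jitter_sd: float = 10.0
    frag_jitter_sd: float = 2.5
    n_fragments: int = 60_000
    frag_len_mean: float = 147.0
    frag_len_sd: float = 15.0
    frag_len_min: int = 80
    frag_len_max: int = 250
    noise_fraction: float = 0.2
    dinucleotide_period: int | None = 10
    sample_id: str = "sim"
    cell_type: str = "simCell"
    treatment: str = "none"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spacing < 100:
            raise ValueError("nucleosome spacing < 100 bp is infeasible "
                             "(violates the position-merge distance)")
        if not 0.0 <= self.noise_fraction <= 1.0:
            raise ValueError("noise_fraction must be in [0, 1]")
        for name in ("chrom_length", "n_chroms", "nfr_width", "n_fragments"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SimulatedSample:
    spec: SyntheticSpec
    assembly: GenomeAssembly
    fragments: FragmentSet
    tss: pd.DataFrame            # chrom, start, end, name, score, strand
    dhs: pd.DataFrame            # chrom, start, end, name, score, strand, anchor
    dyads: pd.DataFrame          # chrom, pos, site, kind, index
    sequences: dict[str, str] = field(default_factory=dict)
    expected: dict = field(default_factory=dict)


def _site_grid(spec: SyntheticSpec, chrom_idx: int) -> tuple[list[int], list[int]]:
    """Deterministic interleaved TSS/DHS anchor positions with safe margins."""
    margin = 5000
    n_sites = spec.n_tss + spec.n_dhs
    usable = spec.chrom_length - 2 * margin
    step = usable // n_sites
    positions = [margin + step // 2 + i * step for i in range(n_sites)]
    tss = [p for i, p in enumerate(positions) if i % 2 == 0][: spec.n_tss]
    dhs = [p for i, p in enumerate(positions) if i % 2 == 1][: spec.n_dhs]
    # top up if the alternation ran short of either kind
    leftovers = [p for p in positions if p not in tss and p not in dhs]
    tss += leftovers[: spec.n_tss - len(tss)]
    dhs += [p for p in leftovers if p not in tss][: spec.n_dhs - len(dhs)]
    return sorted(tss), sorted(dhs)


def _array_dyads(anchor: int, direction: int, spec: SyntheticSpec,
                 rng: np.random.Generator, n: int) -> list[int]:
    """Random-walk array: each step is spacing + N(0, jitter_sd)."""
    pos = anchor + direction * (spec.nfr_width // 2 + 73)
    if spec.jitter_sd > 0:
        pos += int(round(rng.normal(0, spec.jitter_sd)))
    dyads = [pos]
    for _ in range(n - 1):
        step = spec.spacing
        if spec.jitter_sd > 0:
            step += rng.normal(0, spec.jitter_sd)
        pos = pos + direction * int(round(step))
        dyads.append(pos)
    return dyads


def simulate_sample(spec: SyntheticSpec) -> SimulatedSample:
    """Generate a fragment set, annotations, genome sequence and truth tables."""
    rng = np.random.default_rng(spec.seed)
    names = tuple(f"chr{i + 1}" for i in range(spec.n_chroms))
    assembly = GenomeAssembly(names=names,
                              lengths=(spec.chrom_length,) * spec.n_chroms)

    tss_rows, dhs_rows, dyad_rows = [], [], []
    for ci, chrom in enumerate(names):
        tss_pos, dhs_pos = _site_grid(spec, ci)
        for k, p in enumerate(tss_pos):
            strand = "+" if rng.random() < 0.5 else "-"
            sid = f"{chrom}_tss{k}"
            tss_rows.append({"chrom": chrom, "start": p, "end": p + 1,
                             "name": sid, "score": 0.0, "strand": strand})
            sgn = 1 if strand == "+" else -1
            for j, d in enumerate(_array_dyads(p, sgn, spec, rng,
                                               spec.n_array_nucs)):
                dyad_rows.append({"chrom": chrom, "pos": d, "site": sid,
                                  "kind": "tss_down", "index": j + 1})
            for j, d in enumerate(_array_dyads(p, -sgn, spec, rng,
                                               spec.n_upstream_nucs)):
                dyad_rows.append({"chrom": chrom, "pos": d, "site": sid,
                                  "kind": "tss_up", "index": -(j + 1)})
        for k, p in enumerate(dhs_pos):
            sid = f"{chrom}_dhs{k}"
            dhs_rows.append({"chrom": chrom, "start": p - 75, "end": p + 75,
                             "name": sid, "score": 0.0, "strand": ".",
                             "anchor": p})
            for direction, kind in ((1, "dhs_down"), (-1, "dhs_up")):
                for j, d in enumerate(_array_dyads(p, direction, spec, rng,
                                                   spec.n_array_nucs)):
                    dyad_rows.append({"chrom": chrom, "pos": d, "site": sid,
                                      "kind": kind,
                                      "index": direction * (j + 1)})

    dyads = pd.DataFrame(dyad_rows)
    dyads = dyads[(dyads["pos"] >= 200)
                  & (dyads["pos"] < spec.chrom_length - 200)].reset_index(drop=True)

    # fragments: positioned (on dyads) + uniform background
    n_bg = int(round(spec.noise_fraction * spec.n_fragments))
    n_pos = spec.n_fragments - n_bg
    lengths = rng.normal(spec.frag_len_mean, spec.frag_len_sd, spec.n_fragments)
    lengths = np.clip(np.round(lengths), spec.frag_len_min,
                      spec.frag_len_max).astype(np.int64)
    chroms = np.empty(spec.n_fragments, dtype=object)
    centers = np.empty(spec.n_fragments, dtype=np.int64)
    if n_pos:
        pick = rng.integers(0, len(dyads), n_pos)
        chroms[:n_pos] = dyads["chrom"].to_numpy()[pick]
        centers[:n_pos] = dyads["pos"].to_numpy()[pick]
        jitter = np.zeros(n_pos)
        if spec.frag_rot_jitter_sd > 0:
            step = spec.dinucleotide_period or 10
            jitter += step * np.round(
                rng.normal(0, spec.frag_rot_jitter_sd, n_pos) / step)
        if spec.frag_jitter_sd > 0:
            jitter += rng.normal(0, spec.frag_jitter_sd, n_pos)
        centers[:n_pos] += np.round(jitter).astype(np.int64)
    if n_bg:
        chroms[n_pos:] = np.asarray(names, dtype=object)[
            rng.integers(0, spec.n_chroms, n_bg)]
        centers[n_pos:] = rng.integers(200, spec.chrom_length - 200, n_bg)
    starts = centers - lengths // 2
    ends = starts + lengths
    ok = (starts >= 0) & (ends <= spec.chrom_length)
    frag_df = pd.DataFrame({"chrom": chroms[ok], "start": starts[ok],
                            "end": ends[ok]}).sort_values(
        ["chrom", "start"]).reset_index(drop=True)
    fragments = FragmentSet(sample_id=spec.sample_id, df=frag_df,
                            cell_type=spec.cell_type, treatment=spec.treatment)

    sequences = _simulate_sequences(spec, names, dyads, rng)

    expected = {
        "spacing": spec.spacing,
        "expected_linker_length": spec.spacing - 147,
        "expected_fuzziness_cv": 0.0 if spec.jitter_sd == 0 else None,
        "plus1_offset": spec.nfr_width // 2 + 73,
        "seed": spec.seed,
    }
    return SimulatedSample(spec=spec, assembly=assembly, fragments=fragments,
                           tss=pd.DataFrame(tss_rows), dhs=pd.DataFrame(dhs_rows),
                           dyads=dyads, sequences=sequences, expected=expected)


def _simulate_sequences(spec: SyntheticSpec, names: tuple[str, ...],
                        dyads: pd.DataFrame,
                        rng: np.random.Generator) -> dict[str, str]:
    """Random genome; AA planted at the helical phase inside nucleosomal DNA."""
    sequences = {}
    bases = np.frombuffer(b"ACGT", dtype="S1")
    for chrom in names:
        seq = bases[rng.integers(0, 4, spec.chrom_length)].copy()
        if spec.dinucleotide_period:
            offsets = np.arange(-73, 73, spec.dinucleotide_period)
            for pos in dyads.loc[dyads["chrom"] == chrom, "pos"]:
                idx = pos + offsets
                idx = idx[(idx >= 0) & (idx + 1 < spec.chrom_length)]
                seq[idx] = b"A"
                seq[idx + 1] = b"A"
        sequences[chrom] = seq.tobytes().decode()
    return sequences


def write_sample(sim: SimulatedSample, outdir: str | Path) -> dict[str, Path]:
    """Write BED/FASTA/chrom.sizes/truth files; returns the path map.

    The spec (including the seed) goes into ``spec.json``; the assembly's
    ``fasta_path`` is pointed at the written FASTA.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fragments": outdir / "fragments.bed",
        "chrom_sizes": outdir / "genome.chrom.sizes",
        "fasta": outdir / "genome.fa",
        "tss": outdir / "tss.bed",
        "dhs": outdir / "dhs.bed",
        "dyads": outdir / "truth_dyads.tsv",
        "spec": outdir / "spec.json",
    }
    sim.fragments.df.to_csv(paths["fragments"], sep="\t", header=False,
                            index=False)
    with open(paths["chrom_sizes"], "w") as fh:
        for name, length in zip(sim.assembly.names, sim.assembly.lengths):
            fh.write(f"{name}\t{length}\n")
    with open(paths["fasta"], "w") as fh:
        for name in sim.assembly.names:
            fh.write(f">{name} seed={sim.spec.seed}\n")
            seq = sim.sequences[name]
            for i in range(0, len(seq), 80):
                fh.write(seq[i: i + 80] + "\n")
    sim.tss[["chrom", "start", "end", "name", "score", "strand"]].to_csv(
        paths["tss"], sep="\t", header=False, index=False)
    sim.dhs[["chrom", "start", "end", "name", "score", "strand"]].to_csv(
        paths["dhs"], sep="\t", header=False, index=False)
    sim.dyads.to_csv(paths["dyads"], sep="\t", index=False)
    with open(paths["spec"], "w") as fh:
        json.dump(asdict(sim.spec), fh, indent=1, sort_keys=True)
    object.__setattr__(sim.assembly, "fasta_path", str(paths["fasta"]))
    return paths


# ---------------------------------------------------------------------------
# TF binding data

@dataclass
class BindingSpec:
    """Generative model for a synthetic TF-binding experiment.

    Binding labels are drawn Bernoulli(sigmoid(intercept + beta . x)) with
    predictors on their natural scales; a None intercept is auto-centered so
    classes are roughly balanced.
    """

    n_hits: int = 3000
    hit_width: int = 12
    motif_score_mean: float = 10.0
    motif_score_sd: float = 2.0
    beta_motif: float = 0.8
    beta_depletion: float = 0.0
    beta_occupancy: float = 0.0
    beta_array_up: float = 0.0
    beta_array_down: float = 0.0
    intercept: float | None = None
    frac_at_anchors: float = 0.5  # hits placed at NFR anchors vs uniform
    peak_halfwidth: int = 150
    seed: int = 0

    @property
    def betas(self) -> dict[str, float]:
        return {"motif_score": self.beta_motif,
                "depletion_level": self.beta_depletion,
                "occupancy": self.beta_occupancy,
                "array_score_up": self.beta_array_up,
                "array_score_down": self.beta_array_down}


def simulate_binding(bspec: BindingSpec, sim: SimulatedSample,
                     occ: SignalTrack, arr: SignalTrack
                     ) -> tuple[pd.DataFrame, pd.DataFrame, list[LabeledSite]]:
    """Draw motif hits, compute their predictors, and assign bound labels.

    Returns (hits BED frame, peaks BED frame, labeled sites carrying the
    true labels).  Peaks are +/- ``peak_halfwidth`` around bound hit
    centers, so running :func:`nucqc.tf.label_sites` on the written files
    reconstructs the labels up to rare adjacency collisions.
    """
    rng = np.random.default_rng(bspec.seed)
    spec = sim.spec
    anchors = pd.concat([
        sim.tss.rename(columns={"start": "pos"})[["chrom", "pos"]],
        sim.dhs.rename(columns={"anchor": "pos"})[["chrom", "pos"]],
    ], ignore_index=True)
    n_anchor = int(round(bspec.frac_at_anchors * bspec.n_hits))
    n_unif = bspec.n_hits - n_anchor
    chroms = np.empty(bspec.n_hits, dtype=object)
    centers = np.empty(bspec.n_hits, dtype=np.int64)
    if n_anchor:
        pick = rng.integers(0, len(anchors), n_anchor)
        chroms[:n_anchor] = anchors["chrom"].to_numpy()[pick]
        centers[:n_anchor] = (anchors["pos"].to_numpy()[pick]
                              + rng.integers(-30, 31, n_anchor))
    if n_unif:
        chroms[n_anchor:] = np.asarray(sim.assembly.names, dtype=object)[
            rng.integers(0, spec.n_chroms, n_unif)]
        centers[n_anchor:] = rng.integers(1500, spec.chrom_length - 1500, n_unif)
    scores = rng.normal(bspec.motif_score_mean, bspec.motif_score_sd,
                        bspec.n_hits)
    half = bspec.hit_width // 2
    sites = [LabeledSite(chrom=chroms[i], start=int(centers[i] - half),
                         end=int(centers[i] - half + bspec.hit_width),
                         strand="+", motif_score=float(scores[i]))
             for i in range(bspec.n_hits)]
    sites = extract_predictors(sites, occ, arr)

    X = np.array([s.predictor_vector() for s in sites])
    beta = np.array([bspec.betas[n] for n in
                     ("motif_score", "depletion_level", "occupancy",
                      "array_score_up", "array_score_down")])
    lin = X @ beta
    intercept = (-float(np.median(lin)) if bspec.intercept is None
                 else bspec.intercept)
    p = 1.0 / (1.0 + np.exp(-(intercept + lin)))
    bound = rng.random(len(sites)) < p
    for s, b in zip(sites, bound):
        s.bound = bool(b)

    hits = pd.DataFrame({
        "chrom": [s.chrom for s in sites],
        "start": [s.start for s in sites],
        "end": [s.end for s in sites],
        "name": [f"hit{i}" for i in range(len(sites))],
        "score": [s.motif_score for s in sites],
        "strand": ["+"] * len(sites),
    })
    peak_rows = []
    for s in sites:
        if s.bound:
            peak_rows.append({"chrom": s.chrom,
                              "start": max(0, s.center - bspec.peak_halfwidth),
                              "end": min(spec.chrom_length,
                                         s.center + bspec.peak_halfwidth)})
    peaks = pd.DataFrame(peak_rows).sort_values(
        ["chrom", "start"]).reset_index(drop=True)
    return hits, peaks, sites
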