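"""Six MNase-seq quality-control measurements, Pass/Fail labels and rank quantiles.

The measurements, per sample:

1. sequencing coverage — fold coverage (total fragment bases / genome size);
   the only metric without a Pass/Fail label.
2. AA/TT/AT dinucleotide periodicity — fraction of spectral power at the
   ~10 bp helical repeat in the positional dinucleotide frequency profile
   of footprint-centered 147 bp windows.
3. nucleosomal DNA length — mode of the fragment-length histogram; ranked
   by absolute deviation from 146 bp.
4. nucleosome depletion at TSSs — mean per-TSS depletion level.
5. nucleosome fuzziness downstream of TSSs — CV of the +1..+4 nucleosome
   spacings on the aggregate strand-aware TSS profile; Pass iff < 0.4.
6. enrichment of well-positioned nucleosome arrays at DHSs — mean array
   signal over DHS +/- 1 kb divided by the genome-wide mean.

Rank quantiles (1 = best) are computed per metric over a sample collection
with the metric-appropriate direction, for use by the landscape-selection
indicators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .features import call_positions_from_profile, depletion_level
from .fragments import FragmentSet, compute_coverage
from .genome import GenomeAssembly
from .tracks import SignalTrack

logger = logging.getLogger(__name__)

__all__ = ["SampleQC", "QCThresholds", "METRICS", "LABELED_METRICS",
           "qc_fragment_length", "qc_dinucleotide_periodicity",
           "qc_tss_depletion", "qc_tss_fuzziness", "qc_dhs_array_enrichment",
           "assign_labels", "rank_quantiles", "compute_sample_qc"]

METRICS = ("coverage_fold", "dinucleotide_periodicity", "fragment_length_bp",
           "tss_depletion", "tss_fuzziness", "dhs_array_enrichment")
#: every metric except sequencing coverage carries a Pass/Fail label
LABELED_METRICS = METRICS[1:]

#: ranking key per metric; smaller key = better rank
_RANK_KEYS = {
    "coverage_fold": lambda v: -v,
    "dinucleotide_periodicity": lambda v: -v,
    "fragment_length_bp": lambda v: abs(v - 146.0),
    "tss_depletion": lambda v: -v,
    "tss_fuzziness": lambda v: v,
    "dhs_array_enrichment": lambda v: -v,
}

FUZZINESS_PASS_BELOW = 0.4  # printed Pass rule; not configurable


@dataclass
class QCThresholds:
    """Pass thresholds for the four metrics whose printed rule is external.

    These defaults are package defaults, not published cutoffs, and reports
    label them as such.  The fuzziness rule (< 0.4) is fixed.
    """

    tss_depletion_min: float = 0.2
    dhs_array_enrichment_min: float = 1.2
    fragment_length_center: float = 146.0
    fragment_length_tol: float = 20.0
    # ~2x the flat-spectrum expectation of the 9-11 bp band power fraction
    dinucleotide_min: float = 0.08


@dataclass
class SampleQC:
    """QC values, labels and rank quantiles for one sample."""

    sample_id: str
    cell_type: str = ""
    treatment: str = ""
    coverage_fold: float = float("nan")
    values: dict = field(default_factory=dict)          # metric -> value (NaN = NA)
    labels: dict = field(default_factory=dict)          # labeled metric -> "Pass"/"Fail"
    quantiles: dict = field(default_factory=dict)       # metric -> [0, 1]
    low_confidence: bool = False

    @property
    def group(self) -> tuple[str, str]:
        return (self.cell_type, self.treatment)

    @property
    def n_pass(self) -> int:
        return sum(1 for m in LABELED_METRICS if self.labels.get(m) == "Pass")


# ---------------------------------------------------------------------------
# the six measurements

def qc_fragment_length(frags: FragmentSet) -> tuple[int, bool]:
    """Mode of the 1 bp fragment-length histogram; flags < 100 fragments."""
    lengths = frags.lengths
    low_confidence = lengths.size < 100
    if low_confidence:
        logger.warning("%s: only %d fragments; length mode is low-confidence",
                       frags.sample_id, lengths.size)
    counts = np.bincount(lengths)
    return int(counts.argmax()), low_confidence


_DINUC = {"AA", "TT", "AT"}


def qc_dinucleotide_periodicity(frags: FragmentSet, assembly: GenomeAssembly,
                                footprint: int = 147,
                                max_fragments: int = 20_000,
                                rng: np.random.Generator | None = None) -> float:
    """Spectral power fraction at the 9-11 bp period of the AA/TT/AT profile.

    The positional frequency of {AA, TT, AT} dinucleotide starts is
    accumulated over footprint-sized windows centered on fragment midpoints;
    the mean-subtracted profile's rfft power in the 9-11 bp period band is
    divided by the total (non-DC) power.  NaN when no genome FASTA is set.
    """
    if assembly.fasta_path is None:
        logger.warning("no genome FASTA: dinucleotide periodicity is NA")
        return float("nan")
    if len(frags) < 1000:
        logger.warning("%s: fewer than 1000 fragments for dinucleotide QC",
                       frags.sample_id)
    from pyfaidx import Fasta

    fasta = Fasta(assembly.fasta_path, as_raw=True, sequence_always_upper=True)
    half = footprint // 2
    df = frags.df
    if len(df) > max_fragments:
        rng = rng or np.random.default_rng(0)
        df = df.iloc[np.sort(rng.choice(len(df), max_fragments, replace=False))]
    counts = np.zeros(footprint, dtype=np.float64)
    n_windows = 0
    for chrom, sub in df.groupby("chrom", sort=False):
        if chrom not in fasta:
            continue
        seq = str(fasta[chrom][:])
        chrom_len = len(seq)
        mids = ((sub["start"].to_numpy() + sub["end"].to_numpy()) // 2)
        for mid in mids:
            s = mid - half
            if s < 0 or s + footprint + 1 > chrom_len:
                continue
            w = seq[s: s + footprint + 1]
            counts += np.fromiter(
                (w[i: i + 2] in _DINUC for i in range(footprint)),
                dtype=np.float64, count=footprint)
            n_windows += 1
    if n_windows == 0:
        return float("nan")
    profile = counts / n_windows
    x = profile - profile.mean()
    power = np.abs(np.fft.rfft(x)) ** 2
    total = power[1:].sum()
    if total <= 0:
        return 0.0
    freqs = np.fft.rfftfreq(footprint)  # cycles per bp
    band = (freqs >= 1 / 11.0) & (freqs <= 1 / 9.0)
    return float(power[band].sum() / total)


def qc_tss_depletion(occ: SignalTrack, tss: pd.DataFrame) -> float:
    """Mean depletion level over all usable TSSs."""
    vals = [depletion_level(occ, row.chrom, int(row.start))
            for row in tss.itertuples()]
    vals = [v for v in vals if v is not None]
    if not vals:
        raise ValueError("no TSS with a full depletion window on the genome")
    return float(np.mean(vals))


def aggregate_tss_profile(occ: SignalTrack, tss: pd.DataFrame,
                          span: int = 1500) -> np.ndarray:
    """Strand-aware mean occupancy over [TSS, TSS+span) (minus strand reversed)."""
    profiles = []
    for row in tss.itertuples():
        pos = int(row.start)
        strand = getattr(row, "strand", "+") or "+"
        if strand == "-":
            win = occ.window(row.chrom, pos - span, pos)
            if win is not None:
                profiles.append(win[::-1])
        else:
            win = occ.window(row.chrom, pos, pos + span)
            if win is not None:
                profiles.append(win)
    if not profiles:
        raise ValueError("no TSS window fits on the genome")
    return np.mean(profiles, axis=0)


def qc_tss_fuzziness(occ: SignalTrack, tss: pd.DataFrame, span: int = 1500,
                     smooth_window: int = 50) -> float:
    """CV of the +1..+4 nucleosome spacings on the aggregate TSS profile.

    Nucleosome positions are local maxima of the smoothed aggregate profile
    (same calling machinery as the per-locus features).  CV uses the
    population SD of the three adjacent spacings.  NaN (-> Fail) when fewer
    than four aggregate peaks are found.
    """
    profile = aggregate_tss_profile(occ, tss, span=span)
    calls = call_positions_from_profile(profile, smooth_window=smooth_window)
    if len(calls) < 4:
        logger.warning("fewer than 4 aggregate TSS peaks; fuzziness is NA")
        return float("nan")
    spacings = np.diff(calls.offsets[:4])
    return float(spacings.std(ddof=0) / spacings.mean())


def qc_dhs_array_enrichment(arr: SignalTrack, dhs: pd.DataFrame,
                            flank: int = 1000) -> float:
    """Mean array signal over DHS +/- 1 kb divided by the genome-wide mean."""
    genome_mean = arr.genome_mean()
    if genome_mean <= 0:
        raise ValueError("degenerate array track: genome-wide mean is zero")
    vals = []
    for row in dhs.itertuples():
        anchor = int(getattr(row, "anchor", (row.start + row.end) // 2))
        win = arr.window(row.chrom, anchor - flank, anchor + flank)
        if win is not None:
            vals.append(float(win.mean()))
    if not vals:
        raise ValueError("no DHS window fits on the genome")
    return float(np.mean(vals)) / genome_mean


# ---------------------------------------------------------------------------
# labels and ranking

def assign_labels(qc: SampleQC, thresholds: QCThresholds | None = None) -> SampleQC:
    """Assign the five Pass/Fail labels (coverage is unlabeled).

    The fuzziness rule is fixed at the printed < 0.4; the other four use the
    (overridable) package defaults.  An NA value fails conservatively.
    """
    t = thresholds or QCThresholds()
    v = qc.values

    def label(metric: str, ok: bool) -> None:
        val = v.get(metric, float("nan"))
        qc.labels[metric] = "Fail" if np.isnan(val) else ("Pass" if ok else "Fail")

    label("tss_fuzziness",
          v.get("tss_fuzziness", float("nan")) < FUZZINESS_PASS_BELOW)
    label("tss_depletion", v.get("tss_depletion", 0.0) >= t.tss_depletion_min)
    label("dhs_array_enrichment",
          v.get("dhs_array_enrichment", 0.0) >= t.dhs_array_enrichment_min)
    label("fragment_length_bp",
          abs(v.get("fragment_length_bp", float("nan")) - t.fragment_length_center)
          <= t.fragment_length_tol)
    label("dinucleotide_periodicity",
          v.get("dinucleotide_periodicity", 0.0) >= t.dinucleotide_min)
    return qc


def rank_quantiles(collection: list[SampleQC]) -> list[SampleQC]:
    """Per-metric rank quantiles over a collection (1 = best, in place).

    Ranks use average ranks for ties and the metric's printed direction
    (coverage, dinucleotide, depletion, array enrichment descending;
    fragment-length deviation from 146 bp and fuzziness ascending).
    quantile = 1 - (rank - 1)/(n - 1); a single ranked sample gets 1.0;
    NA values get quantile 0 and are excluded from the ranking.
    """
    if not collection:
        raise ValueError("empty sample collection")
    for metric in METRICS:
        key = _RANK_KEYS[metric]
        vals = np.array([key(s.values.get(metric, float("nan")))
                         for s in collection], dtype=float)
        ok = ~np.isnan(vals)
        n = int(ok.sum())
        ranks = np.full(len(collection), np.nan)
        if n:
            ranks[ok] = rankdata(vals[ok], method="average")
        for i, s in enumerate(collection):
            if not ok[i]:
                s.quantiles[metric] = 0.0
            elif n == 1:
                s.quantiles[metric] = 1.0
            else:
                s.quantiles[metric] = float(1.0 - (ranks[i] - 1.0) / (n - 1.0))
    return collection


# ---------------------------------------------------------------------------
# convenience driver

def compute_sample_qc(frags: FragmentSet, assembly: GenomeAssembly,
                      occ: SignalTrack, arr: SignalTrack,
                      tss: pd.DataFrame, dhs: pd.DataFrame,
                      thresholds: QCThresholds | None = None) -> SampleQC:
    """Run all six measurements for one sample and assign labels."""
    cov = compute_coverage(frags, assembly)
    length_mode, low_conf = qc_fragment_length(frags)
    qc = SampleQC(sample_id=frags.sample_id, cell_type=frags.cell_type,
                  treatment=frags.treatment, coverage_fold=cov.fold,
                  low_confidence=low_conf)
    qc.values = {
        "coverage_fold": cov.fold,
        "dinucleotide_periodicity": qc_dinucleotide_periodicity(frags, assembly),
        "fragment_length_bp": float(length_mode),
        "tss_depletion": qc_tss_depletion(occ, tss),
        "tss_fuzziness": qc_tss_fuzziness(occ, tss),
        "dhs_array_enrichment": qc_dhs_array_enrichment(arr, dhs),
    }
    return assign_labels(qc, thresholds)


def qc_table(collection: list[SampleQC]) -> pd.DataFrame:
    """One-row-per-sample report of values, labels and quantiles."""
    rows = []
    for s in collection:
        row = {"sample_id": s.sample_id, "cell_type": s.cell_type,
               "treatment": s.treatment}
        for m in METRICS:
            row[m] = s.values.get(m, float("nan"))
        for m in LABELED_METRICS:
            row[f"label_{m}"] = s.labels.get(m, "")
        for m in METRICS:
            row[f"quantile_{m}"] = s.quantiles.get(m, float("nan"))
        rows.append(row)
    return pd.DataFrame(rows)
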