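"""Per-locus nucleosome organization features at TSSs, DHSs and motif hits.

The feature set quantifies the canonical promoter chromatin architecture:
a nucleosome-free region (NFR) at the anchor, a well-positioned +1
nucleosome just downstream, and a phased array decaying away from it.

* depletion level — 1 - N_center/N_background with N_center the occupancy
  maximum in the central 200 bp bin and N_background the maximum over the
  two flanking 200 bp spans; clamped to 0 when the center exceeds the
  background, so the value lives in [0, 1).
* occupancy — mean normalized occupancy over the central 100 bp bin.
* array score — mean array-track signal over a strand-aware 1 kb window
  divided by the genome-wide mean array signal.
* nucleosome positions — local maxima of the smoothed occupancy profile
  over a 1 kb scan, merged so adjacent calls are never closer than 100 bp
  (the higher-occupancy call wins).
* linker statistics — mean adjacent spacing minus 147 bp of nucleosomal
  DNA, and the population SD of the spacings; undetectable quantities are
  stored as the sentinel -1 so they are easily recognized downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .tracks import SignalTrack

logger = logging.getLogger(__name__)

__all__ = [
    "NucleosomePositionList", "TssFeatureRecord", "DhsFeatureRecord",
    "depletion_level", "occupancy_at_site", "array_score", "call_positions",
    "call_positions_from_profile", "linker_stats", "tss_feature_table",
    "dhs_feature_table", "read_bed6", "read_dhs_bed",
    "NUCLEOSOME_BP", "MERGE_DIST",
]

NUCLEOSOME_BP = 147   # standardized nucleosomal DNA length subtracted from spacings
MERGE_DIST = 100      # adjacent position calls closer than this are merged


@dataclass
class NucleosomePositionList:
    """Ordered nucleosome positions as signed bp offsets from an anchor.

    Offsets are strictly increasing, downstream-positive on the anchor's
    strand, and adjacent offsets differ by at least the merge distance.
    """

    site_id: str
    chrom: str
    anchor: int
    strand: str
    offsets: list[int] = field(default_factory=list)
    heights: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.offsets)


@dataclass
class TssFeatureRecord:
    site_id: str
    chrom: str = ""
    position: int = -1
    strand: str = "+"
    array_score_down: float = float("nan")
    depletion_level: float = float("nan")
    occupancy: float = float("nan")
    plus1_position: int = -1
    linker_length: float = -1.0
    linker_sd: float = -1.0
    nucleosome_count: int = 0
    valid: bool = True  # False when windows leave the chromosome


@dataclass
class DhsFeatureRecord(TssFeatureRecord):
    """TSS record plus the mirrored upstream scan (DHSs have no strand)."""

    array_score_up: float = float("nan")
    minus1_position: int = -1
    up_linker_length: float = -1.0
    up_linker_sd: float = -1.0
    up_nucleosome_count: int = 0


# ---------------------------------------------------------------------------
# scalar features

def depletion_level(occ: SignalTrack, chrom: str, position: int) -> float | None:
    """Nucleosome depletion level at a site; None if the window is off-chromosome.

    N_center = max occupancy on [pos-100, pos+100); N_background = max over
    [pos-300, pos-100) and [pos+100, pos+300).  Returns 0 when N_center
    exceeds N_background or the background is empty, else 1 - N_center/N_background.
    """
    win = occ.window(chrom, position - 300, position + 300)
    if win is None:
        logger.debug("depletion window off-chromosome at %s:%d", chrom, position)
        return None
    n_center = float(win[200:400].max())
    n_background = float(max(win[:200].max(), win[400:].max()))
    if n_background == 0.0 or n_center > n_background:
        return 0.0
    return 1.0 - n_center / n_background


def occupancy_at_site(occ: SignalTrack, chrom: str, position: int) -> float | None:
    """Mean occupancy over the central 100 bp bin [pos-50, pos+50)."""
    win = occ.window(chrom, position - 50, position + 50)
    if win is None:
        return None
    return float(win.mean())


def array_score(arr: SignalTrack, chrom: str, position: int, side: str = "down",
                span: int = 1000, strand: str = "+",
                genome_mean: float | None = None) -> float | None:
    """Mean array signal over the strand-aware 1 kb window / genome mean.

    ``side="down"`` scans [pos, pos+span) on the plus strand and
    [pos-span, pos) on the minus strand; ``side="up"`` mirrors that.
    """
    if genome_mean is None:
        genome_mean = arr.genome_mean()
    if genome_mean <= 0:
        raise ValueError("genome-wide mean array signal is zero")
    downstream = (side == "down") == (strand != "-")
    if downstream:
        win = arr.window(chrom, position, position + span)
    else:
        win = arr.window(chrom, position - span, position)
    if win is None:
        return None
    return float(win.mean()) / genome_mean


# ---------------------------------------------------------------------------
# nucleosome position calling

def _smooth(profile: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with edge truncation (same length as input)."""
    if window <= 1:
        return profile.astype(float)
    kernel = np.ones(window)
    num = np.convolve(profile, kernel, mode="same")
    den = np.convolve(np.ones_like(profile, dtype=float), kernel, mode="same")
    return num / den


def _local_maxima(x: np.ndarray) -> list[int]:
    """Strict local maxima; a plateau yields its leftmost index."""
    peaks = []
    n = x.size
    i = 0
    while i < n:
        j = i
        while j + 1 < n and x[j + 1] == x[i]:
            j += 1
        left_ok = i == 0 or x[i - 1] < x[i]
        right_ok = j == n - 1 or x[j + 1] < x[i]
        if left_ok and right_ok:
            peaks.append(i)
        i = j + 1
    return peaks


def _merge_peaks(offsets: list[int], heights: list[float],
                 merge_dist: int) -> tuple[list[int], list[float]]:
    """Iteratively drop the globally lowest peak that sits closer than
    ``merge_dist`` to a neighbour; ties drop the peak farther from the anchor.
    Order-independent by construction."""
    offs = list(offsets)
    hts = list(heights)
    while True:
        victims = []
        for k in range(len(offs) - 1):
            if offs[k + 1] - offs[k] < merge_dist:
                if hts[k] < hts[k + 1]:
                    victims.append((hts[k], offs[k], k))
                elif hts[k + 1] < hts[k]:
                    victims.append((hts[k + 1], offs[k + 1], k + 1))
                else:  # equal heights: drop the one farther from the anchor
                    victims.append((hts[k + 1], offs[k + 1], k + 1))
        if not victims:
            return offs, hts
        _, _, idx = min(victims)
        del offs[idx], hts[idx]


def call_positions_from_profile(profile: np.ndarray, site_id: str = "",
                                chrom: str = "", anchor: int = 0,
                                strand: str = "+", smooth_window: int = 50,
                                merge_dist: int = MERGE_DIST,
                                min_offset: int = 1,
                                min_rel_height: float = 0.25) -> NucleosomePositionList:
    """Call nucleosome positions on a downstream-oriented occupancy profile.

    ``profile[k]`` is the occupancy ``k`` bp downstream of the anchor (on the
    anchor's strand).  A maximum at offset 0 is excluded: the +1 nucleosome
    search domain is strictly downstream.  Candidate maxima below
    ``min_rel_height`` times the tallest candidate are discarded before
    merging; background sampling noise otherwise produces spurious calls
    inside nucleosome-free regions.
    """
    result = NucleosomePositionList(site_id=site_id, chrom=chrom,
                                    anchor=anchor, strand=strand)
    if profile.size == 0:
        return result
    sm = _smooth(np.asarray(profile, dtype=float), smooth_window)
    idx = [i for i in _local_maxima(sm) if i >= min_offset]
    if idx and min_rel_height > 0:
        floor = min_rel_height * max(sm[i] for i in idx)
        idx = [i for i in idx if sm[i] >= floor]
    offs, hts = _merge_peaks(idx, [float(sm[i]) for i in idx], merge_dist)
    result.offsets = offs
    result.heights = hts
    return result


def call_positions(occ: SignalTrack, chrom: str, anchor: int, strand: str = "+",
                   direction: str = "down", span: int = 1000,
                   smooth_window: int = 50,
                   merge_dist: int = MERGE_DIST,
                   site_id: str = "") -> NucleosomePositionList:
    """Scan 1 kb of occupancy from the anchor and call nucleosome positions.

    ``direction="down"`` scans downstream on the anchor's strand;
    ``direction="up"`` scans upstream (offsets still reported as positive
    distances from the anchor along the scan).  Windows reaching past a
    chromosome end are clipped (logged).
    """
    downstream = (direction == "down") == (strand != "-")
    if chrom not in occ.data:
        return NucleosomePositionList(site_id, chrom, anchor, strand)
    v = occ.data[chrom]
    if downstream:
        s, e = anchor, min(anchor + span, v.size)
        if e < anchor + span:
            logger.debug("clipped scan at %s:%d", chrom, anchor)
        profile = v[max(s, 0):e]
    else:
        s, e = max(anchor - span, 0), anchor
        if s > anchor - span:
            logger.debug("clipped scan at %s:%d", chrom, anchor)
        profile = v[s:max(e, 0)][::-1]
    return call_positions_from_profile(profile, site_id=site_id, chrom=chrom,
                                       anchor=anchor, strand=strand,
                                       smooth_window=smooth_window,
                                       merge_dist=merge_dist)


def linker_stats(positions: NucleosomePositionList) -> tuple[int, float, float, int]:
    """(first-nucleosome offset, linker length, linker SD, count) with sentinels.

    linker length = mean adjacent spacing - 147; linker SD = population SD of
    the spacings.  Sentinels: no position -> all -1; count < 2 -> linker and
    SD -1; count < 3 -> SD -1.
    """
    count = len(positions)
    if count == 0:
        return -1, -1.0, -1.0, 0
    first = positions.offsets[0]
    if count < 2:
        return first, -1.0, -1.0, count
    spacings = np.diff(positions.offsets)
    linker = float(spacings.mean()) - NUCLEOSOME_BP
    if count < 3:
        return first, linker, -1.0, count
    return first, linker, float(spacings.std(ddof=0)), count


# ---------------------------------------------------------------------------
# per-site tables

def read_bed6(path: str | Path) -> pd.DataFrame:
    """Read BED3/BED6 sites; missing name/score/strand filled with defaults."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                rows.append({
                    "chrom": parts[0], "start": int(parts[1]), "end": int(parts[2]),
                    "name": parts[3] if len(parts) > 3 else f"site{lineno}",
                    "score": float(parts[4]) if len(parts) > 4 and parts[4] != "." else 0.0,
                    "strand": parts[5] if len(parts) > 5 else "+",
                })
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return pd.DataFrame(rows)


def read_dhs_bed(path: str | Path) -> pd.DataFrame:
    """Read DHS regions; a 10-column narrowPeak summit offset sets the anchor,
    otherwise the interval midpoint does."""
    df = read_bed6(path)
    anchors = []
    with open(path) as fh:
        raw = [l.split("\t") for l in fh
               if l.strip() and not l.startswith(("#", "track", "browser"))]
    for row, parts in zip(df.itertuples(), raw):
        summit = None
        if len(parts) >= 10:
            try:
                off = int(parts[9])
                if off >= 0:
                    summit = row.start + off
            except ValueError:
                summit = None
        anchors.append(summit if summit is not None else (row.start + row.end) // 2)
    df["anchor"] = anchors
    return df


def tss_feature_table(occ: SignalTrack, arr: SignalTrack, tss: pd.DataFrame,
                      span: int = 1000, smooth_window: int = 50) -> list[TssFeatureRecord]:
    """Per-TSS nucleosome feature bundle, strand-aware, in input order.

    ``tss`` needs columns chrom/start/strand (+ optional name); the TSS point
    is ``start``.
    """
    genome_mean = arr.genome_mean()
    records = []
    for row in tss.itertuples():
        name = getattr(row, "name", None) or f"tss_{row.Index}"
        pos = int(row.start)
        strand = getattr(row, "strand", "+") or "+"
        rec = TssFeatureRecord(site_id=name, chrom=row.chrom, position=pos,
                               strand=strand)
        dep = depletion_level(occ, row.chrom, pos)
        occ_val = occupancy_at_site(occ, row.chrom, pos)
        arr_val = array_score(arr, row.chrom, pos, side="down", span=span,
                              strand=strand, genome_mean=genome_mean)
        if dep is None or occ_val is None or arr_val is None:
            rec.valid = False
            logger.warning("site %s at %s:%d leaves the chromosome; record NA",
                           name, row.chrom, pos)
            records.append(rec)
            continue
        rec.depletion_level = dep
        rec.occupancy = occ_val
        rec.array_score_down = arr_val
        calls = call_positions(occ, row.chrom, pos, strand=strand,
                               direction="down", span=span,
                               smooth_window=smooth_window, site_id=name)
        rec.plus1_position, rec.linker_length, rec.linker_sd, rec.nucleosome_count = \
            linker_stats(calls)
        records.append(rec)
    return records


def dhs_feature_table(occ: SignalTrack, arr: SignalTrack, dhs: pd.DataFrame,
                      span: int = 1000, smooth_window: int = 50) -> list[DhsFeatureRecord]:
    """Per-DHS features: the TSS bundle downstream plus a mirrored upstream
    scan (-1 nucleosome, upstream count/linker stats and array score).
    DHSs are unstranded; scans use the reference orientation."""
    genome_mean = arr.genome_mean()
    records = []
    for row in dhs.itertuples():
        name = getattr(row, "name", None) or f"dhs_{row.Index}"
        anchor = int(getattr(row, "anchor", (row.start + row.end) // 2))
        rec = DhsFeatureRecord(site_id=name, chrom=row.chrom, position=anchor,
                               strand=".")
        dep = depletion_level(occ, row.chrom, anchor)
        occ_val = occupancy_at_site(occ, row.chrom, anchor)
        arr_down = array_score(arr, row.chrom, anchor, side="down", span=span,
                               strand="+", genome_mean=genome_mean)
        arr_up = array_score(arr, row.chrom, anchor, side="up", span=span,
                             strand="+", genome_mean=genome_mean)
        if dep is None or occ_val is None or arr_down is None or arr_up is None:
            rec.valid = False
            logger.warning("DHS %s at %s:%d leaves the chromosome; record NA",
                           name, row.chrom, anchor)
            records.append(rec)
            continue
        rec.depletion_level = dep
        rec.occupancy = occ_val
        rec.array_score_down = arr_down
        rec.array_score_up = arr_up
        down = call_positions(occ, row.chrom, anchor, strand="+",
                              direction="down", span=span,
                              smooth_window=smooth_window, site_id=name)
        rec.plus1_position, rec.linker_length, rec.linker_sd, rec.nucleosome_count = \
            linker_stats(down)
        up = call_positions(occ, row.chrom, anchor, strand="+",
                            direction="up", span=span,
                            smooth_window=smooth_window, site_id=name)
        (rec.minus1_position, rec.up_linker_length, rec.up_linker_sd,
         rec.up_nucleosome_count) = linker_stats(up)
        records.append(rec)
    return records


def feature_frame(records: list[TssFeatureRecord]) -> pd.DataFrame:
    """Records as a DataFrame with literal -1 sentinels and NA invalid rows."""
    rows = []
    for r in records:
        d = dict(r.__dict__)
        if not r.valid:
            for k in d:
                if k not in {"site_id", "chrom", "position", "strand", "valid"}:
                    d[k] = np.nan
        rows.append(d)
    return pd.DataFrame(rows)
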