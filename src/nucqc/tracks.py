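"""Nucleosome occupancy and array-regularity signal tracks.

Two track roles exist:

* ``occupancy`` — per-base count of nucleosome footprints (fragment
  midpoint +/- half a 147 bp footprint) covering each position, optionally
  normalized to genome-wide mean 1 so depletion ratios and cross-sample
  correlations are comparable between samples.
* ``array`` — per-position score in [0, 1] of local nucleosome-spacing
  regularity: the peak normalized autocorrelation of the mean-subtracted
  occupancy in a sliding window, over lags in the nucleosome-repeat range.

Tracks round-trip through bedGraph (always) and bigWig (when pyBigWig is
usable for writing).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .fragments import FragmentSet
from .genome import GenomeAssembly

__all__ = ["SignalTrack", "build_occupancy_track", "build_array_track",
           "write_bedgraph", "read_bedgraph", "write_bigwig"]


@dataclass
class SignalTrack:
    """Per-base numeric genome track at a fixed resolution.

    ``data`` maps chromosome name to a float vector of length
    ``ceil(chrom_length / resolution)``.
    """

    role: str  # "occupancy" | "array"
    data: dict[str, np.ndarray]
    resolution: int = 1
    normalized: bool = False
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def genome_mean(self) -> float:
        """Mean signal over every position of every chromosome."""
        total = sum(float(v.sum()) for v in self.data.values())
        n = sum(v.size for v in self.data.values())
        return total / n

    def window(self, chrom: str, start: int, end: int) -> np.ndarray | None:
        """Values on [start, end); None if the window leaves the chromosome."""
        if chrom not in self.data:
            return None
        v = self.data[chrom]
        if start < 0 or end > v.size or start >= end:
            return None
        return v[start:end]


def build_occupancy_track(frags: FragmentSet, assembly: GenomeAssembly,
                          footprint: int = 147, normalize: bool = True,
                          resolution: int = 1) -> SignalTrack:
    """Accumulate dyad-centered footprints into an occupancy track.

    Each fragment contributes a footprint [mid - half, mid + half) with
    ``half = footprint // 2``, centered on the fragment midpoint
    ``(start + end) // 2`` and clipped at chromosome ends.  With
    ``normalize`` the track is divided by its genome-wide mean so that the
    mean over all positions is exactly 1.
    """
    if len(frags) == 0:
        raise ValueError("empty fragment set")
    if footprint <= 0:
        raise ValueError("footprint must be positive")
    half = footprint // 2
    data: dict[str, np.ndarray] = {}
    for chrom, length in assembly.sizes.items():
        sub = frags.df[frags.df["chrom"] == chrom]
        diff = np.zeros(length + 1, dtype=np.float64)
        if len(sub):
            mids = ((sub["start"].to_numpy() + sub["end"].to_numpy()) // 2)
            s = np.clip(mids - half, 0, length)
            e = np.clip(mids + half, 0, length)
            np.add.at(diff, s, 1.0)
            np.add.at(diff, e, -1.0)
        occ = np.cumsum(diff[:-1])
        data[chrom] = occ
    track = SignalTrack(role="occupancy", data=data, resolution=1,
                        normalized=False, chrom_lengths=dict(assembly.sizes))
    if resolution > 1:
        track = _bin_track(track, resolution)
    if normalize:
        mean = track.genome_mean()
        if mean > 0:
            for v in track.data.values():
                v /= mean
        track.normalized = True
    return track


def _bin_track(track: SignalTrack, resolution: int) -> SignalTrack:
    """Average a 1 bp track into fixed-width bins (last bin may be partial)."""
    data = {}
    for chrom, v in track.data.items():
        nbins = -(-v.size // resolution)
        padded = np.full(nbins * resolution, np.nan)
        padded[: v.size] = v
        data[chrom] = np.nanmean(padded.reshape(nbins, resolution), axis=1)
    return SignalTrack(role=track.role, data=data, resolution=resolution,
                       normalized=track.normalized,
                       chrom_lengths=dict(track.chrom_lengths))


def build_array_track(occ: SignalTrack, window: int = 2000, step: int = 100,
                      lag_range: tuple[int, int] = (150, 220)) -> SignalTrack:
    """Windowed autocorrelation peak over the nucleosome-repeat lag range.

    For each ``step``-bp bin, a window of ``window`` bp centered on the bin
    is mean-subtracted and its normalized autocorrelation
    ``r(lag) = sum(x[t] x[t+lag]) / sum(x[t]^2)`` is maximized over
    ``lag_range``; the value, clipped to [0, 1], is assigned to every base
    of the bin.  Zero-variance (flat) windows score 0.  The statistic is
    invariant to positive scaling of the occupancy.
    """
    if occ.role != "occupancy":
        raise ValueError("array track must be built from an occupancy track")
    lag_lo, lag_hi = lag_range
    if window < 2 * lag_hi:
        raise ValueError(f"window {window} too short for max lag {lag_hi} "
                         "(autocorrelation undefined)")
    lags = np.arange(lag_lo, lag_hi + 1)
    data: dict[str, np.ndarray] = {}
    for chrom, v in occ.data.items():
        length = v.size
        out = np.zeros(length, dtype=np.float64)
        nbins = -(-length // step)
        for b in range(nbins):
            center = b * step + step // 2
            ws = max(0, center - window // 2)
            we = min(length, center + window // 2)
            x = v[ws:we]
            if x.size < 2 * lag_hi:
                continue
            scale = float(np.max(np.abs(x)))
            x = x - x.mean()
            denom = float(np.dot(x, x))
            # effectively-flat windows score 0 (guard against float dust)
            if scale == 0.0 or denom <= (1e-8 * scale) ** 2 * x.size:
                continue
            best = max(float(np.dot(x[:-lag], x[lag:])) for lag in lags)
            out[b * step: min((b + 1) * step, length)] = min(max(best / denom, 0.0), 1.0)
        data[chrom] = out
    return SignalTrack(role="array", data=data, resolution=occ.resolution,
                       normalized=False, chrom_lengths=dict(occ.chrom_lengths))


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    """Write a run-length-encoded bedGraph (zero runs included)."""
    with open(path, "w") as fh:
        for chrom, v in track.data.items():
            if v.size == 0:
                continue
            # run boundaries where the value changes
            change = np.flatnonzero(np.diff(v)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [v.size]))
            res = track.resolution
            for s, e in zip(starts, ends):
                fh.write(f"{chrom}\t{s * res}\t{min(e * res, track.chrom_lengths.get(chrom, e * res))}"
                         f"\t{v[s]:.6g}\n")


def read_bedgraph(path: str | Path, assembly: GenomeAssembly,
                  role: str = "occupancy") -> SignalTrack:
    """Read a bedGraph into a dense 1 bp track; overlapping intervals are fatal."""
    data = {c: np.zeros(l, dtype=np.float64) for c, l in assembly.sizes.items()}
    covered_to = {c: 0 for c in assembly.names}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 bedGraph columns")
            chrom, s, e, val = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            if chrom not in data:
                continue
            if s >= e or e > data[chrom].size:
                raise ValueError(f"{path}:{lineno}: bad interval [{s},{e})")
            if s < covered_to[chrom]:
                raise ValueError(f"{path}:{lineno}: overlapping bedGraph intervals")
            covered_to[chrom] = e
            data[chrom][s:e] = val
    return SignalTrack(role=role, data=data, resolution=1,
                       normalized=False, chrom_lengths=dict(assembly.sizes))


def write_bigwig(track: SignalTrack, path: str | Path) -> None:
    """Write the track to bigWig (requires pyBigWig built with write support)."""
    import pyBigWig

    bw = pyBigWig.open(str(path), "w")
    header = [(c, int(track.chrom_lengths.get(c, v.size * track.resolution)))
              for c, v in track.data.items()]
    bw.addHeader(header)
    res = track.resolution
    for chrom, v in track.data.items():
        change = np.flatnonzero(np.diff(v)) + 1
        starts = np.concatenate(([0], change)) * res
        ends = np.minimum(np.concatenate((change, [v.size])) * res,
                          track.chrom_lengths.get(chrom, v.size * res))
        bw.addEntries([chrom] * len(starts), [int(s) for s in starts],
                      ends=[int(e) for e in ends],
                      values=[float(v[s // res]) for s in starts])
    bw.close()
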