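"""Sample ranking, pooling and referenced-landscape selection.

Within a cell type / treatment group, samples are ordered by three summary
indicators computed from the six QC measurements:

* ``N_good`` — number of Pass labels (0-5; coverage carries no label),
* ``C_better`` — number of metrics (0-6) where the sample's rank quantile
  is strictly above its group's mean quantile for that metric,
* ``R_better`` — sum of the six rank quantiles (0-6),

compared lexicographically (N_good first), with residual ties broken by
coverage fold and then sample id so the ordering is total and
permutation-invariant.  The top sample is the "High Quality Sample".

Samples whose genome-wide occupancy (averaged in 1 kb windows) correlates
with Pearson r > 0.6 are pooled; pooling uses single-linkage connected
components of the r > 0.6 graph.  The High Quality Sample is the group's
referenced landscape unless it belongs to a pool, in which case the pooled
sample is.  Candidates below five-fold coverage are filtered out.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fragments import FragmentSet
from .qc import METRICS, SampleQC
from .tracks import SignalTrack

__all__ = ["RankingResult", "PoolPlan", "ReferenceSelection",
           "compute_indicators", "pool_samples", "select_reference",
           "POOL_R_MIN", "MIN_COVERAGE_FOLD"]

POOL_R_MIN = 0.6          # pool samples with Pearson r strictly above this
MIN_COVERAGE_FOLD = 5.0   # references below five-fold coverage are filtered out


@dataclass
class RankingResult:
    """Per-sample indicators and the final ordering (best first)."""

    table: pd.DataFrame  # sample_id, group, N_good, C_better, R_better, coverage_fold
    order: list[str]     # sample ids, rank 1 first

    def indicators(self, sample_id: str) -> tuple[int, int, float]:
        row = self.table.set_index("sample_id").loc[sample_id]
        return int(row["N_good"]), int(row["C_better"]), float(row["R_better"])


@dataclass
class PoolPlan:
    """Groups of sample ids to merge and the pairwise correlation matrix."""

    groups: list[list[str]]
    correlations: pd.DataFrame

    def pool_of(self, sample_id: str) -> list[str] | None:
        for g in self.groups:
            if sample_id in g:
                return g
        return None


@dataclass
class ReferenceSelection:
    group: tuple[str, str]
    reference_id: str | None
    provenance: str          # "high_quality" | "pooled" | "none"
    coverage_fold: float
    members: list[str] = field(default_factory=list)


def compute_indicators(collection: list[SampleQC],
                       coverages: dict[str, float] | None = None) -> RankingResult:
    """N_good / C_better / R_better and the lexicographic ordering.

    Quantiles must already be computed over the full collection
    (:func:`nucqc.qc.rank_quantiles`).  C_better compares each sample's
    quantile to the mean quantile of its own (cell type, treatment) group,
    sample included, with a strict inequality — a singleton group therefore
    scores C_better = 0.
    """
    if not collection:
        raise ValueError("empty collection")
    coverages = coverages or {s.sample_id: s.coverage_fold for s in collection}
    group_means: dict[tuple[str, str], dict[str, float]] = {}
    for s in collection:
        group_means.setdefault(s.group, {})
    for group in group_means:
        members = [s for s in collection if s.group == group]
        group_means[group] = {
            m: float(np.mean([s.quantiles[m] for s in members])) for m in METRICS
        }
    rows = []
    for s in collection:
        means = group_means[s.group]
        rows.append({
            "sample_id": s.sample_id,
            "cell_type": s.cell_type,
            "treatment": s.treatment,
            "N_good": s.n_pass,
            "C_better": sum(1 for m in METRICS if s.quantiles[m] > means[m]),
            "R_better": float(sum(s.quantiles[m] for m in METRICS)),
            "coverage_fold": float(coverages.get(s.sample_id, s.coverage_fold)),
        })
    table = pd.DataFrame(rows)
    ordered = table.sort_values(
        by=["N_good", "C_better", "R_better", "coverage_fold", "sample_id"],
        ascending=[False, False, False, False, True],
        kind="mergesort",
    )
    return RankingResult(table=table, order=list(ordered["sample_id"]))


def _window_means(track: SignalTrack, window: int) -> np.ndarray:
    """Occupancy averaged in non-overlapping windows, concatenated over chroms."""
    parts = []
    for chrom in sorted(track.data):
        v = track.data[chrom]
        n = v.size // window
        if n:
            parts.append(v[: n * window].reshape(n, window).mean(axis=1))
    if not parts:
        raise ValueError("tracks too short for the correlation window")
    return np.concatenate(parts)


def pool_samples(tracks: dict[str, SignalTrack], r_min: float = POOL_R_MIN,
                 window: int = 1000) -> PoolPlan:
    """Pool samples whose 1 kb-window occupancy correlates with r > r_min.

    Windows with zero occupancy in both members of a pair are excluded from
    that pair's correlation (they reflect unmappable genome, not agreement).
    Pools are connected components (single linkage) of the r > r_min graph
    with at least two members.
    """
    ids = sorted(tracks)
    if len(ids) < 2:
        return PoolPlan(groups=[], correlations=pd.DataFrame(index=ids, columns=ids,
                                                             dtype=float))
    sizes = {i: tuple(sorted(tracks[i].data)) for i in ids}
    if len(set(sizes.values())) != 1:
        raise ValueError("tracks are on different assemblies")
    vecs = {i: _window_means(tracks[i], window) for i in ids}
    corr = pd.DataFrame(np.eye(len(ids)), index=ids, columns=ids)
    parent = {i: i for i in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a_idx in range(len(ids)):
        for b_idx in range(a_idx + 1, len(ids)):
            a, b = ids[a_idx], ids[b_idx]
            va, vb = vecs[a], vecs[b]
            keep = (va != 0) | (vb != 0)
            if keep.sum() < 2 or va[keep].std() == 0 or vb[keep].std() == 0:
                r = float("nan")
            else:
                r = float(np.corrcoef(va[keep], vb[keep])[0, 1])
            corr.loc[a, b] = corr.loc[b, a] = r
            if r > r_min:
                parent[find(a)] = find(b)
    components: dict[str, list[str]] = {}
    for i in ids:
        components.setdefault(find(i), []).append(i)
    groups = sorted([sorted(g) for g in components.values() if len(g) >= 2])
    return PoolPlan(groups=groups, correlations=corr)


def pooled_fragments(frags: dict[str, FragmentSet], members: list[str],
                     pooled_id: str | None = None) -> FragmentSet:
    """Union of member fragment sets; the basis for the pooled track."""
    dfs = [frags[m].df for m in members]
    first = frags[members[0]]
    return FragmentSet(
        sample_id=pooled_id or "pooled:" + "+".join(sorted(members)),
        df=pd.concat(dfs, ignore_index=True),
        cell_type=first.cell_type, treatment=first.treatment,
    )


def select_reference(ranking: RankingResult, pools: PoolPlan,
                     coverages: dict[str, float],
                     group: tuple[str, str] = ("", ""),
                     min_fold: float = MIN_COVERAGE_FOLD) -> ReferenceSelection:
    """Pick the referenced landscape for one cell type / treatment group.

    The top-ranked (High Quality) sample is the reference, unless it is a
    member of a pool — then the pooled sample is (its coverage is the sum of
    the member folds, since pooling unions fragment sets on one genome).
    A candidate below ``min_fold`` coverage leaves the group unreferenced.
    """
    hq = ranking.order[0]
    members = pools.pool_of(hq)
    if members is not None:
        fold = float(sum(coverages[m] for m in members))
        ref_id = "pooled:" + "+".join(sorted(members))
        provenance = "pooled"
    else:
        fold = float(coverages[hq])
        ref_id = hq
        members = [hq]
        provenance = "high_quality"
    if fold < min_fold:
        return ReferenceSelection(group=group, reference_id=None,
                                  provenance="none", coverage_fold=fold,
                                  members=members)
    return ReferenceSelection(group=group, reference_id=ref_id,
                              provenance=provenance, coverage_fold=fold,
                              members=members)
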