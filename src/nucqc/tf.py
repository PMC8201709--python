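"""Nucleosome-feature-augmented transcription-factor binding-site prediction.

Motif hits overlapping a ChIP-seq peak are labeled bound (positive); hits
overlapping no peak are unbound (negative).  Two logistic regressions are
compared under identical stratified cross-validation folds:

* motif-only — predictor: motif score;
* full — motif score + nucleosome depletion level, occupancy, and
  upstream/downstream array scores at the hit center.

Performance is summarized as the AUC of pooled out-of-fold predicted
probabilities (a rank statistic, equivalent to trapezoidal ROC
integration), and the headline quantity is

    auc_improvement = AUC(full) - AUC(motif-only).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from .features import array_score, depletion_level, occupancy_at_site
from .tracks import SignalTrack

logger = logging.getLogger(__name__)

__all__ = ["LabeledSite", "TFModelResult", "label_sites", "extract_predictors",
           "fit_and_evaluate", "auc_improvement",
           "NUCLEOSOME_PREDICTORS", "PREDICTORS"]

NUCLEOSOME_PREDICTORS = ("depletion_level", "occupancy", "array_score_up",
                         "array_score_down")
PREDICTORS = ("motif_score",) + NUCLEOSOME_PREDICTORS


@dataclass
class LabeledSite:
    """A motif hit with its binding label and predictor vector."""

    chrom: str
    start: int
    end: int
    strand: str
    motif_score: float
    bound: bool | None = None
    depletion_level: float = float("nan")
    occupancy: float = float("nan")
    array_score_up: float = float("nan")
    array_score_down: float = float("nan")

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def predictor_vector(self, names: tuple[str, ...] = PREDICTORS) -> list[float]:
        return [getattr(self, n) for n in names]


@dataclass
class TFModelResult:
    auc_motif: float                  # pooled out-of-fold AUC, motif-only model
    auc_full: float                   # pooled out-of-fold AUC, full model
    fold_aucs_motif: list[float]
    fold_aucs_full: list[float]
    coefficients: dict = field(default_factory=dict)   # full model, with SEs
    metrics_motif: dict = field(default_factory=dict)  # at threshold 0.5
    metrics_full: dict = field(default_factory=dict)
    n_folds: int = 10
    n_sites: int = 0
    labels: np.ndarray | None = None        # 0/1 per site, input order
    oof_motif: np.ndarray | None = None     # pooled out-of-fold probabilities
    oof_full: np.ndarray | None = None

    @property
    def auc_improvement(self) -> float:
        return self.auc_full - self.auc_motif

    def to_dict(self) -> dict:
        return {
            "auc_motif": self.auc_motif, "auc_full": self.auc_full,
            "auc_improvement": self.auc_improvement,
            "fold_aucs_motif": self.fold_aucs_motif,
            "fold_aucs_full": self.fold_aucs_full,
            "mean_fold_auc_motif": float(np.mean(self.fold_aucs_motif)),
            "mean_fold_auc_full": float(np.mean(self.fold_aucs_full)),
            "coefficients": self.coefficients,
            "metrics_motif": self.metrics_motif,
            "metrics_full": self.metrics_full,
            "n_folds": self.n_folds, "n_sites": self.n_sites,
        }


def _merged_intervals(peaks: pd.DataFrame, chrom: str) -> tuple[np.ndarray, np.ndarray]:
    sub = peaks[peaks["chrom"] == chrom].sort_values("start")
    starts, ends = [], []
    for row in sub.itertuples():
        if starts and row.start <= ends[-1]:
            ends[-1] = max(ends[-1], row.end)
        else:
            starts.append(row.start)
            ends.append(row.end)
    return np.asarray(starts), np.asarray(ends)


def label_sites(hits: pd.DataFrame, peaks: pd.DataFrame) -> list[LabeledSite]:
    """Label motif hits bound iff they intersect >= 1 bp of any peak.

    ``hits`` needs chrom/start/end/score (+ optional strand); ``peaks``
    needs chrom/start/end.  Half-open intervals: touching is not overlap.
    """
    if hits.empty or peaks.empty:
        raise ValueError("empty motif hits or peaks: degenerate experiment")
    merged = {c: _merged_intervals(peaks, c) for c in peaks["chrom"].unique()}
    sites = []
    for row in hits.itertuples():
        bound = False
        if row.chrom in merged:
            starts, ends = merged[row.chrom]
            i = np.searchsorted(ends, row.start, side="right")
            bound = i < starts.size and starts[i] < row.end
        sites.append(LabeledSite(chrom=row.chrom, start=int(row.start),
                                 end=int(row.end),
                                 strand=getattr(row, "strand", "+") or "+",
                                 motif_score=float(row.score), bound=bool(bound)))
    return sites


def extract_predictors(sites: list[LabeledSite], occ: SignalTrack,
                       arr: SignalTrack) -> list[LabeledSite]:
    """Fill nucleosome predictors at each hit center (reference orientation).

    Delegates to the per-locus feature operations with the hit center as the
    site.  Hits whose windows leave the chromosome are dropped (logged).
    """
    genome_mean = arr.genome_mean()
    kept = []
    for s in sites:
        c = s.center
        dep = depletion_level(occ, s.chrom, c)
        occ_val = occupancy_at_site(occ, s.chrom, c)
        up = array_score(arr, s.chrom, c, side="up", strand="+",
                         genome_mean=genome_mean)
        down = array_score(arr, s.chrom, c, side="down", strand="+",
                           genome_mean=genome_mean)
        if dep is None or occ_val is None or up is None or down is None:
            logger.debug("dropping off-chromosome hit at %s:%d", s.chrom, c)
            continue
        s.depletion_level = dep
        s.occupancy = occ_val
        s.array_score_up = up
        s.array_score_down = down
        kept.append(s)
    if len(kept) < len(sites):
        logger.warning("dropped %d hits with off-chromosome windows",
                       len(sites) - len(kept))
    return kept


def _fit_logistic(X: np.ndarray, y: np.ndarray) -> LogisticRegression:
    """Maximum-likelihood fit; near-singular/separable data falls back to a
    weakly ridge-regularized fit."""
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        model = LogisticRegression(penalty=None, solver="lbfgs", max_iter=1000)
        model.fit(X, y)
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            logger.info("unpenalized fit did not converge (possible perfect "
                        "separation); refitting with a weak ridge penalty")
            model = LogisticRegression(penalty="l2", C=1e6, solver="lbfgs",
                                       max_iter=2000)
            model.fit(X, y)
    return model


def _threshold_metrics(y: np.ndarray, prob: np.ndarray,
                       threshold: float = 0.5) -> dict:
    pred = prob >= threshold
    tp = int(np.sum(pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    fp = int(np.sum(pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    prec = tp / (tp + fp) if tp + fp else float("nan")
    f1 = (2 * prec * sens / (prec + sens)
          if prec + sens and not np.isnan(prec + sens) else float("nan"))
    return {"sensitivity": sens, "specificity": spec, "precision": prec,
            "f1": f1, "fpr": 1 - spec if not np.isnan(spec) else float("nan")}


def _coefficients_with_se(X: np.ndarray, y: np.ndarray,
                          names: tuple[str, ...]) -> dict:
    """Full-data logistic coefficients with standard errors (statsmodels)."""
    import statsmodels.api as sm

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, sm.add_constant(X)).fit(disp=0, maxiter=200)
        params = np.asarray(res.params, dtype=float)
        ses = np.asarray(res.bse, dtype=float)
        if not (np.all(np.isfinite(params)) and np.all(np.isfinite(ses))):
            raise ValueError("non-finite estimates")
    except Exception:  # separation or singular Hessian
        logger.info("statsmodels Logit failed; reporting ridge coefficients "
                    "without standard errors")
        model = _fit_logistic(X, y)
        params = np.concatenate((model.intercept_, model.coef_[0]))
        ses = np.full(params.size, float("nan"))
    out = {"intercept": {"coef": float(params[0]), "se": float(ses[0])}}
    for i, n in enumerate(names):
        out[n] = {"coef": float(params[i + 1]), "se": float(ses[i + 1])}
    return out


def fit_and_evaluate(sites: list[LabeledSite], folds: int = 10,
                     seed: int = 1234) -> TFModelResult:
    """Cross-validated comparison of the motif-only and full models.

    Stratified k-fold CV with a fixed seed; both models are fitted on
    identical folds and their out-of-fold probabilities pooled for the AUC.
    Classification metrics are evaluated at probability 0.5.  The number of
    folds is reduced (logged) when a class has fewer members than folds.
    """
    y = np.array([1 if s.bound else 0 for s in sites])
    if len(np.unique(y)) < 2:
        raise ValueError("both bound and unbound sites are required")
    X_full = np.array([s.predictor_vector() for s in sites])
    if not np.all(np.isfinite(X_full)):
        raise ValueError("non-finite predictor values; run extract_predictors")
    X_motif = X_full[:, :1]
    min_class = int(min(np.sum(y == 1), np.sum(y == 0)))
    if min_class < folds:
        logger.warning("reducing folds from %d to %d (smallest class size)",
                       folds, max(2, min_class))
        folds = max(2, min_class)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    oof = {"motif": np.zeros(len(y)), "full": np.zeros(len(y))}
    fold_aucs: dict[str, list[float]] = {"motif": [], "full": []}
    for train, test in skf.split(X_full, y):
        for name, X in (("motif", X_motif), ("full", X_full)):
            model = _fit_logistic(X[train], y[train])
            p = model.predict_proba(X[test])[:, 1]
            oof[name][test] = p
            fold_aucs[name].append(float(roc_auc_score(y[test], p)))
    return TFModelResult(
        auc_motif=float(roc_auc_score(y, oof["motif"])),
        auc_full=float(roc_auc_score(y, oof["full"])),
        fold_aucs_motif=fold_aucs["motif"],
        fold_aucs_full=fold_aucs["full"],
        coefficients=_coefficients_with_se(X_full, y, PREDICTORS),
        metrics_motif=_threshold_metrics(y, oof["motif"]),
        metrics_full=_threshold_metrics(y, oof["full"]),
        n_folds=folds, n_sites=len(y),
        labels=y, oof_motif=oof["motif"], oof_full=oof["full"],
    )


def auc_improvement(result: TFModelResult) -> float:
    """AUC(motif + nucleosome features) - AUC(motif score)."""
    return result.auc_improvement


def roc_points(sites: list[LabeledSite], probabilities: np.ndarray) -> pd.DataFrame:
    """ROC curve points (FPR, TPR, threshold) for plotting or export."""
    y = np.array([1 if s.bound else 0 for s in sites])
    fpr, tpr, thr = roc_curve(y, probabilities)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
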