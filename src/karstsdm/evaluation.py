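"""Thresholding, discrimination metrics and spatial k-fold cross-validation.

Thresholds: the primary management threshold is the upper decile (top 10%)
of suitability over the analysis mask, cross-checked against the P10
(10th-percentile training presence) and MTP (minimum training presence)
rules.  Discrimination is summarized by the Mann-Whitney AUC and the True
Skill Statistic at the Youden threshold.  Spatial cross-validation clusters
presence and background coordinates with k-means so test points are
geographically separated from training points; the fold count adapts to the
number of presences.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.cluster import KMeans

from .model import RidgeLogit, SuitabilityMap
from .sampling import TrainingTable

# Score comparisons classify ties as positive: presence iff score >= threshold.


def auc(presence_scores, background_scores) -> float:
    """Mann-Whitney AUC: P(random presence scores above random background).

    Ties count one half: (wins + 0.5 * ties) / (nP * nB).
    """
    p = np.asarray(presence_scores, float)
    b = np.asarray(background_scores, float)
    if p.size == 0 or b.size == 0:
        raise ValueError("both score sets must be non-empty")
    ranks = rankdata(np.concatenate([p, b]))
    r_p = ranks[: p.size].sum()
    return float((r_p - p.size * (p.size + 1) / 2.0) / (p.size * b.size))


def confusion_metrics(presence_scores, background_scores, thr: float) -> tuple[float, float, float]:
    """(sensitivity, specificity, TSS) at a threshold, ties positive."""
    p = np.asarray(presence_scores, float)
    b = np.asarray(background_scores, float)
    if not np.isfinite(thr):
        raise ValueError("threshold must be finite")
    sens = float(np.mean(p >= thr)) if p.size else float("nan")
    spec = float(np.mean(b < thr)) if b.size else float("nan")
    return sens, spec, sens + spec - 1.0


def _candidate_thresholds(presence_scores, background_scores) -> np.ndarray:
    pooled = np.unique(np.concatenate([presence_scores, background_scores]))
    mids = (pooled[:-1] + pooled[1:]) / 2.0
    span = max(pooled[-1] - pooled[0], 1.0)
    below = pooled[0] - 0.01 * span
    above = pooled[-1] + 0.01 * span
    return np.concatenate([[below], mids, pooled, [above]])


def youden_threshold(presence_scores, background_scores) -> float:
    """Threshold maximizing TSS (sensitivity + specificity - 1); ties -> lowest."""
    p = np.asarray(presence_scores, float)
    b = np.asarray(background_scores, float)
    if p.size == 0 or b.size == 0:
        raise ValueError("both score sets must be non-empty")
    cands = np.sort(_candidate_thresholds(p, b))
    tss = np.array([confusion_metrics(p, b, t)[2] for t in cands])
    return float(cands[int(np.argmax(tss))])


def spec_sens_threshold(presence_scores, background_scores) -> float:
    """Threshold where sensitivity is closest to specificity; ties -> lowest."""
    p = np.asarray(presence_scores, float)
    b = np.asarray(background_scores, float)
    if p.size == 0 or b.size == 0:
        raise ValueError("both score sets must be non-empty")
    cands = np.sort(_candidate_thresholds(p, b))
    gap = np.array([abs(confusion_metrics(p, b, t)[0] - confusion_metrics(p, b, t)[1]) for t in cands])
    return float(cands[int(np.argmin(gap))])


# ---------------------------------------------------------------------------
# Threshold set


@dataclass(frozen=True)
class ThresholdSet:
    """Upper-decile / P10 / MTP thresholds with the final binarization rule."""

    top10_thr: float
    p10_thr: float
    mtp_thr: float
    final_thr: float
    coverage: float          # fraction of presences >= final threshold
    positive_fraction: float  # fraction of masked cells >= final threshold
    rule: str = "min-top10-p10"

    def __post_init__(self) -> None:
        if self.mtp_thr > self.p10_thr + 1e-12:
            raise ValueError("MTP cannot exceed the P10 threshold")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1))


THRESHOLD_RULES = ("min-top10-p10", "strict-mtp", "top10-only")


def threshold_set(
    suitability: "SuitabilityMap | np.ndarray",
    presence_scores,
    rule: str = "min-top10-p10",
) -> ThresholdSet:
    """Thresholds over the masked suitability surface.

    ``top10`` is the 90th percentile of masked suitability (an area-based
    management target selecting the top decile of cells); P10 and MTP come
    from the presence suitabilities.  The final threshold follows ``rule``:
    ``min-top10-p10`` (default), ``strict-mtp`` (guarantees full presence
    coverage) or ``top10-only``.
    """
    if isinstance(suitability, SuitabilityMap):
        masked = suitability.masked_values()
    else:
        masked = np.asarray(suitability, float)
    masked = masked[np.isfinite(masked)]
    p = np.asarray(presence_scores, float)
    if masked.size < 10:
        raise ValueError("need at least 10 masked suitability cells to threshold")
    if p.size < 1:
        raise ValueError("need at least one presence score")
    if np.ptp(masked) == 0:
        raise ValueError("suitability is constant over the mask; thresholding degenerate")
    if rule not in THRESHOLD_RULES:
        raise ValueError(f"unknown threshold rule {rule!r}")

    top10 = float(np.percentile(masked, 90))
    p10 = float(np.percentile(p, 10))
    mtp = float(np.min(p))
    if rule == "min-top10-p10":
        final = min(top10, p10)
    elif rule == "strict-mtp":
        final = min(top10, mtp)
    else:
        final = top10
    return ThresholdSet(
        top10_thr=top10,
        p10_thr=p10,
        mtp_thr=mtp,
        final_thr=final,
        coverage=float(np.mean(p >= final)),
        positive_fraction=float(np.mean(masked >= final)),
        rule=rule,
    )


def binary_map(suitability: SuitabilityMap, thr: float):
    """Uint8-style binary layer: 1 where suitability >= thr, 0 elsewhere on mask."""
    from .grids import CATEGORICAL, RasterLayer

    vals = np.full(suitability.layer.grid.shape, np.nan)
    cells = suitability.mask.cells
    vals[cells] = (suitability.layer.values[cells] >= thr).astype(float)
    return RasterLayer("binary_suitability", suitability.layer.grid, vals, kind=CATEGORICAL)


# ---------------------------------------------------------------------------
# Spatial cross-validation


def adaptive_k(n_presence: int) -> int:
    """Fold count min(5, max(2, floor(n_presence / 2)))."""
    if n_presence < 2:
        raise ValueError("cannot cross-validate with fewer than 2 presences")
    return int(min(5, max(2, n_presence // 2)))


def spatial_folds(coords: np.ndarray, k: int, seed: int = 0, n_restarts: int = 10) -> np.ndarray:
    """Fold assignment by seeded k-means on projected coordinates."""
    coords = np.asarray(coords, float)
    if k < 2:
        raise ValueError("need at least 2 folds")
    n_distinct = np.unique(coords, axis=0).shape[0]
    if n_distinct < k:
        raise ValueError(f"only {n_distinct} distinct coordinates for k={k} folds")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(coords)
    assert all(np.any(labels == f) for f in range(k)), "every fold must be non-empty"
    return labels


@dataclass
class FoldReport:
    """Per-fold spatial-CV metrics plus mean / sample-SD / median summaries."""

    folds: pd.DataFrame  # fold, auc, youden_thr, spec_sens_thr, tss, n_presence_test, n_background_test, sparse, note
    summary: dict

    def to_csv(self, path: str | Path) -> None:
        out = self.folds.rename(
            columns={
                "fold": "Fold", "auc": "AUC", "spec_sens_thr": "Thr_Spec_Sens",
                "tss": "TSS", "n_presence_test": "nP", "n_background_test": "nB",
            }
        )[["Fold", "AUC", "Thr_Spec_Sens", "TSS", "nP", "nB"]]
        summary_rows = pd.DataFrame(
            [
                {"Fold": "mean", "AUC": self.summary["auc"]["mean"], "TSS": self.summary["tss"]["mean"]},
                {"Fold": "sd", "AUC": self.summary["auc"]["sd"], "TSS": self.summary["tss"]["sd"]},
                {"Fold": "median", "AUC": self.summary["auc"]["median"], "TSS": self.summary["tss"]["median"]},
            ]
        )
        pd.concat([out, summary_rows], ignore_index=True).to_csv(path, index=False)


def summarize_cv(values: Sequence[float]) -> dict:
    """Mean, sample SD (n-1; None for a single value) and median of defined folds."""
    v = np.asarray([x for x in values if x is not None and np.isfinite(x)], float)
    if v.size == 0:
        raise ValueError("no defined fold values to summarize")
    return {
        "mean": float(np.mean(v)),
        "sd": float(np.std(v, ddof=1)) if v.size >= 2 else None,
        "median": float(np.median(v)),
        "n": int(v.size),
    }


def cross_validate(
    table: TrainingTable,
    seed: int = 0,
    lambda_: float | None = None,
    fit_kwargs: dict | None = None,
) -> FoldReport:
    """Spatial k-fold CV: k-means folds, per-fold refit and held-out metrics.

    Per fold the model is refitted on the training rows with class weights
    re-normalized to 0.5 : 0.5 within the subset, then test presences are
    scored against test background.  Folds whose training subset cannot
    support a refit (single class, or one presence with no fixed lambda) are
    recorded as undefined with a note, never silently dropped; test folds
    with fewer than 2 presences are flagged sparse.
    """
    fit_kwargs = dict(fit_kwargs or {})
    n_presence = table.n_presence
    k = adaptive_k(n_presence)
    labels = spatial_folds(table.coords, k, seed=seed)

    records = []
    for f in range(k):
        test = labels == f
        train = ~test
        y_test = table.y[test]
        nP = int((y_test == 1).sum())
        nB = int((y_test == 0).sum())
        rec = {
            "fold": f + 1, "auc": np.nan, "youden_thr": np.nan,
            "spec_sens_thr": np.nan, "tss": np.nan,
            "n_presence_test": nP, "n_background_test": nB,
            "sparse": nP < 2, "note": "",
        }
        train_table = table.subset(train)
        n_train_p = train_table.n_presence
        if n_train_p == 0 or train_table.n_background == 0:
            rec["note"] = "training subset single-class; fold undefined"
            records.append(rec)
            continue
        if nP == 0 or nB == 0:
            rec["note"] = "no test presences" if nP == 0 else "no test background"
            records.append(rec)
            continue
        model = RidgeLogit.from_training_table(train_table)
        if lambda_ is not None:
            res = model.fit(lambda_=lambda_, **fit_kwargs)
        elif n_train_p >= 2:
            kw = dict(fit_kwargs)
            kw.setdefault("cv_folds", min(5, n_train_p))
            res = model.fit(seed=seed + 1000 + f, **kw)
        else:
            rec["note"] = "single training presence and no fixed lambda; fold undefined"
            records.append(rec)
            continue
        scores = res.predict(table.X[test])
        p_scores = scores[y_test == 1]
        b_scores = scores[y_test == 0]
        thr = youden_threshold(p_scores, b_scores)
        rec.update(
            auc=auc(p_scores, b_scores),
            youden_thr=thr,
            spec_sens_thr=spec_sens_threshold(p_scores, b_scores),
            tss=confusion_metrics(p_scores, b_scores, thr)[2],
        )
        records.append(rec)

    folds = pd.DataFrame(records)

    def safe_summary(vals):
        try:
            return summarize_cv(vals)
        except ValueError:
            return {"mean": None, "sd": None, "median": None, "n": 0}

    summary = {
        "auc": safe_summary(folds["auc"].tolist()),
        "tss": safe_summary(folds["tss"].tolist()),
    }
    return FoldReport(folds=folds, summary=summary)
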