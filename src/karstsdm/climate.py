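"""Empirical quantile-mapping bias correction and annual climatologies.

Temperature and relative humidity are corrected additively on the empirical
quantiles; precipitation multiplicatively on wet-day totals so dry days stay
dry.  Corrections are interpolated linearly between probability knots and
held constant beyond the outermost knots (edge offset / edge ratio).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

ADDITIVE = "additive"
MULTIPLICATIVE = "multiplicative"

#: daily totals at or below this (mm) are treated as dry
WET_DAY_THRESHOLD_MM = 0.1


@dataclass
class QuantileMap:
    """Empirical quantiles of a raw and a reference series on a shared grid."""

    probs: np.ndarray
    q_ref: np.ndarray
    q_raw: np.ndarray
    mode: str = ADDITIVE
    wet_threshold: float = 0.0

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, float)
        self.q_ref = np.asarray(self.q_ref, float)
        self.q_raw = np.asarray(self.q_raw, float)
        if self.probs.size < 2:
            raise ValueError("quantile map needs at least 2 probability knots")
        for q in (self.q_ref, self.q_raw):
            if np.any(np.diff(q) < -1e-12):
                raise ValueError("quantile sequences must be non-decreasing")
        if self.mode not in (ADDITIVE, MULTIPLICATIVE):
            raise ValueError(f"unknown mode {self.mode!r}")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "probs": self.probs.tolist(),
                    "q_ref": self.q_ref.tolist(),
                    "q_raw": self.q_raw.tolist(),
                    "mode": self.mode,
                    "wet_threshold": self.wet_threshold,
                },
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "QuantileMap":
        d = json.loads(Path(path).read_text())
        return cls(
            probs=np.array(d["probs"]),
            q_ref=np.array(d["q_ref"]),
            q_raw=np.array(d["q_raw"]),
            mode=d["mode"],
            wet_threshold=d["wet_threshold"],
        )


def fit_quantile_map(
    raw_daily: np.ndarray,
    ref_daily: np.ndarray,
    n_quantiles: int = 99,
    mode: str = ADDITIVE,
) -> QuantileMap:
    """Fit an empirical quantile map between a raw and a reference series.

    In multiplicative mode only wet-day values (> ``WET_DAY_THRESHOLD_MM``)
    enter the quantile estimation, and the wet-day threshold is stored so
    application leaves dry days untouched.
    """
    raw = np.asarray(raw_daily, float)
    ref = np.asarray(ref_daily, float)
    raw = raw[np.isfinite(raw)]
    ref = ref[np.isfinite(ref)]
    wet_threshold = 0.0
    if mode == MULTIPLICATIVE:
        wet_threshold = WET_DAY_THRESHOLD_MM
        raw = raw[raw > wet_threshold]
        ref = ref[ref > wet_threshold]
        if raw.size == 0 or ref.size == 0:
            raise ValueError(
                "multiplicative quantile map needs wet days in both series"
            )
    if raw.size < n_quantiles or ref.size < n_quantiles:
        raise ValueError(
            f"series too short for {n_quantiles} quantiles "
            f"(raw {raw.size}, ref {ref.size} usable values)"
        )
    probs = np.arange(1, n_quantiles + 1) / (n_quantiles + 1)
    return QuantileMap(
        probs=probs,
        q_ref=np.quantile(ref, probs),
        q_raw=np.quantile(raw, probs),
        mode=mode,
        wet_threshold=wet_threshold,
    )


def apply_quantile_map(raw_daily: np.ndarray, qmap: QuantileMap) -> np.ndarray:
    """Bias-correct a series through a fitted quantile map.

    Additive: ``x -> x + (Q_ref - Q_raw)`` interpolated at x's position on
    the raw quantiles.  Multiplicative: wet values scaled by ``Q_ref/Q_raw``
    likewise interpolated; values at or below the wet threshold unchanged.
    Beyond the outermost knots the edge correction is held constant, and NaN
    passes through.
    """
    x = np.asarray(raw_daily, float)
    if qmap.mode == ADDITIVE:
        offset = np.interp(x, qmap.q_raw, qmap.q_ref - qmap.q_raw)
        return x + offset
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = qmap.q_ref / qmap.q_raw
    ratio = np.interp(x, qmap.q_raw, ratios)
    out = np.where(x > qmap.wet_threshold, x * ratio, x)
    out[np.isnan(x)] = np.nan
    return out


@dataclass
class Climatology:
    """Multi-year annual climate summaries used as SDM predictors."""

    tmean_ann: float      # mean over years of annual mean daily temperature, degC
    tmax_ann: float       # mean over years of the annual maximum daily tmax, degC
    precip_ann_mm: float  # mean annual precipitation total, mm
    rh_ann_pct: float     # mean over years of annual mean relative humidity, %
    n_years_used: int = 0
    years_dropped: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 <= self.rh_ann_pct <= 100.0:
            raise ValueError("rh_ann_pct must lie in [0, 100]")
        if self.precip_ann_mm < 0:
            raise ValueError("precip_ann_mm must be non-negative")
        if self.tmax_ann < self.tmean_ann:
            raise ValueError("tmax_ann cannot be below tmean_ann")


def derive_climatology(
    daily: pd.DataFrame,
    min_year_completeness: float = 0.95,
) -> Climatology:
    """Annual climatology from daily ``tmean``/``tmax``/``precip``/``rh`` columns.

    Quality control drops any calendar year with fewer than
    ``min_year_completeness`` of its days present and finite (logged); the
    remaining years are averaged.  ``tmax_ann`` is the mean over years of
    each year's maximum daily tmax.
    """
    required = {"tmean", "tmax", "precip", "rh"}
    missing = required - set(daily.columns)
    if missing:
        raise ValueError(f"daily table missing columns: {sorted(missing)}")
    if not isinstance(daily.index, pd.DatetimeIndex):
        raise ValueError("daily table must have a DatetimeIndex")

    rows = []
    dropped: list[int] = []
    for year, grp in daily.groupby(daily.index.year):
        n_expected = 366 if pd.Timestamp(f"{year}-12-31").is_leap_year else 365
        ok = np.isfinite(grp[list(required)].to_numpy()).all(axis=1)
        if ok.sum() < min_year_completeness * n_expected:
            dropped.append(int(year))
            log.warning(
                "dropping year %d: %d/%d complete days", year, int(ok.sum()), n_expected
            )
            continue
        g = grp[ok]
        rows.append(
            {
                "tmean": g["tmean"].mean(),
                "tmax_max": g["tmax"].max(),
                "precip_total": g["precip"].sum(),
                "rh": g["rh"].mean(),
            }
        )
    if not rows:
        raise ValueError("no usable years after quality control")
    ann = pd.DataFrame(rows)
    return Climatology(
        tmean_ann=float(ann["tmean"].mean()),
        tmax_ann=float(ann["tmax_max"].mean()),
        precip_ann_mm=float(ann["precip_total"].mean()),
        rh_ann_pct=float(ann["rh"].mean()),
        n_years_used=len(ann),
        years_dropped=dropped,
    )
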