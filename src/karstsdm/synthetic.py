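"""Seeded synthetic landscapes, occurrences and daily climate series.

Real inputs for this kind of analysis (a national DEM, gridded soil
fractions, daily gridded climate, and a handful of occurrence points on
limestone) are either licence-restricted or too large to ship, so the
package carries a generator producing fields with the same statistical
structure: a smooth ridge-bearing elevation surface, elevation-lapsed
temperature, orographic precipitation, compositional soil texture, a blobby
categorical limestone mask, and occurrences drawn from a known logistic
suitability surface restricted to that mask.  Every output is a pure
function of its configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit, softmax

from .grids import CATEGORICAL, CONTINUOUS, Grid, RasterLayer, RasterStack
from .points import OccurrenceSet


def _default_noise_sd() -> dict[str, float]:
    return {
        "tmean_ann": 0.3,   # degC
        "tmax_ann": 0.3,    # degC
        "precip_ann_mm": 60.0,
        "rh_ann_pct": 2.0,
        "soil": 1.0,        # logit-scale sd of the texture fields
    }


@dataclass
class LandscapeConfig:
    """Configuration of the synthetic landscape generator.

    Defaults emulate a mid-latitude montane limestone belt at ~90 m grid
    resolution: elevation 200-1600 m, a 6.5 degC/km lapse rate, and a
    limestone outcrop covering ~30% of the domain in contiguous blobs.
    """

    n_rows: int = 128
    n_cols: int = 128
    cell_size: float = 90.0
    seed: int = 0
    smoothness: float = 8.0           # Gaussian filter sigma, in cells
    lapse_rate: float = 0.0065        # degC per metre
    temp_at_sea_level: float = 14.0   # degC
    tmax_offset: float = 6.0          # degC added to tmean for tmax
    elev_range: tuple[float, float] = (200.0, 1600.0)
    precip_base_mm: float = 1100.0
    precip_orographic_mm_per_m: float = 0.35
    rh_base_pct: float = 62.0
    rh_orographic_pct_per_m: float = 0.008
    limestone_fraction: float = 0.3
    noise_sd: dict[str, float] = field(default_factory=_default_noise_sd)

    def __post_init__(self) -> None:
        if self.n_rows < 16 or self.n_cols < 16:
            raise ValueError("landscape must be at least 16x16 cells")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if not 0.0 < self.limestone_fraction < 1.0:
            raise ValueError("limestone_fraction must lie in (0, 1)")
        noise = _default_noise_sd()
        noise.update(self.noise_sd)
        self.noise_sd = noise


@dataclass
class TrueModel:
    """Generative logistic suitability surface on standardized predictors."""

    intercept: float
    coefficients: dict[str, float]


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    """Unit-variance Gaussian-filtered white noise."""
    f = gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")
    sd = f.std()
    return f / sd if sd > 0 else f


def generate_landscape(config: LandscapeConfig) -> RasterStack:
    """Generate the aligned predictor stack for one seeded landscape.

    Layers: ``elev_m``, ``tmean_ann``, ``tmax_ann`` (always >= tmean),
    ``precip_ann_mm`` (>= 0), ``rh_ann_pct`` (in [0, 100]), compositional
    ``SAND_05cm``/``SILT_05cm``/``CLAY_05cm`` summing to 100 per cell,
    ``CEC_05cm`` and ``SOC_05cm`` (>= 0), and categorical ``limestone_bin``.
    """
    rng = np.random.default_rng(config.seed)
    shape = (config.n_rows, config.n_cols)
    grid = Grid(
        origin_x=0.0,
        origin_y=config.n_rows * config.cell_size,
        cell_size=config.cell_size,
        n_rows=config.n_rows,
        n_cols=config.n_cols,
    )
    ns = config.noise_sd

    base = _smooth_field(rng, shape, config.smoothness)
    lo, hi = config.elev_range
    elev = lo + (hi - lo) * (base - base.min()) / (base.max() - base.min())

    tmean = (
        config.temp_at_sea_level
        - config.lapse_rate * elev
        + ns["tmean_ann"] * rng.standard_normal(shape)
    )
    tmax = tmean + np.abs(config.tmax_offset + ns["tmax_ann"] * rng.standard_normal(shape))
    precip = np.maximum(
        config.precip_base_mm
        + config.precip_orographic_mm_per_m * elev
        + ns["precip_ann_mm"] * rng.standard_normal(shape),
        0.0,
    )
    rh = np.clip(
        config.rh_base_pct
        + config.rh_orographic_pct_per_m * elev
        + ns["rh_ann_pct"] * rng.standard_normal(shape),
        0.0,
        100.0,
    )

    # Soil texture: softmax of three smooth logit fields -> closed composition.
    logits = np.stack(
        [ns["soil"] * _smooth_field(rng, shape, config.smoothness / 2) for _ in range(3)]
    )
    logits[0] += 0.4   # sand-rich bias typical of shallow rendzina-like soils
    frac = softmax(logits, axis=0) * 100.0
    sand, silt, clay = frac

    cec = 10.0 * np.exp(0.4 * _smooth_field(rng, shape, config.smoothness / 2))
    soc = 40.0 * np.exp(0.5 * _smooth_field(rng, shape, config.smoothness / 2))

    lime_field = _smooth_field(rng, shape, config.smoothness)
    thr = np.quantile(lime_field, 1.0 - config.limestone_fraction)
    limestone = (lime_field >= thr).astype(float)

    layers = [
        RasterLayer("elev_m", grid, elev),
        RasterLayer("tmean_ann", grid, tmean),
        RasterLayer("tmax_ann", grid, tmax),
        RasterLayer("precip_ann_mm", grid, precip),
        RasterLayer("rh_ann_pct", grid, rh),
        RasterLayer("SAND_05cm", grid, sand),
        RasterLayer("SILT_05cm", grid, silt),
        RasterLayer("CLAY_05cm", grid, clay),
        RasterLayer("CEC_05cm", grid, cec),
        RasterLayer("SOC_05cm", grid, soc),
        RasterLayer("limestone_bin", grid, limestone, kind=CATEGORICAL),
    ]
    return RasterStack(layers)


def generate_occurrences(
    stack: RasterStack, truth: TrueModel, n_presence: int, seed: int
) -> OccurrenceSet:
    """Draw presence cells from a logistic suitability surface on the mask.

    Suitability is ``expit(intercept + sum_j beta_j * z_j)`` where ``z_j`` is
    the predictor z-scored over limestone cells.  Distinct cells are sampled
    without replacement with probability proportional to suitability; points
    are placed at cell centres (one presence per cell).
    """
    if n_presence < 1:
        raise ValueError("n_presence must be >= 1")
    if "limestone_bin" not in stack:
        raise ValueError("stack has no limestone_bin layer")
    mask = stack["limestone_bin"].values == 1
    for name in truth.coefficients:
        if name not in stack:
            raise ValueError(f"TrueModel names unknown predictor {name!r}")
        mask &= np.isfinite(stack[name].values)
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("limestone mask is empty; cannot place occurrences")
    if n_presence > rows.size:
        raise ValueError(
            f"requested {n_presence} presences but only {rows.size} masked cells"
        )

    eta = np.full(rows.size, truth.intercept, dtype=float)
    for name, beta in truth.coefficients.items():
        v = stack[name].values[rows, cols]
        sd = v.std()
        z = (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)
        eta += beta * z
    p = expit(eta)
    p = p / p.sum()

    rng = np.random.default_rng(seed)
    chosen = rng.choice(rows.size, size=n_presence, replace=False, p=p)
    x, y = stack.grid.cell_center(rows[chosen], cols[chosen])
    data = pd.DataFrame(
        {"site_id": np.arange(1, n_presence + 1), "x": x, "y": y}
    )
    return OccurrenceSet(data)


def generate_daily_climate(
    n_days: int,
    seed: int,
    additive_bias: float = 0.0,
    scale_bias: float = 1.0,
    dry_day_prob: float = 0.6,
    precip_shape: float = 0.9,
    precip_scale_mm: float = 12.0,
    start: str = "2015-01-01",
) -> pd.DataFrame:
    """Paired raw/reference daily series for temperature, RH and precipitation.

    The reference series carry a sinusoidal seasonal cycle plus daily noise;
    the "raw" (to-be-corrected) series are the reference shifted by
    ``additive_bias`` (temperature, RH) or scaled by ``scale_bias`` on wet
    days (precipitation).  Wet days occur with probability
    ``1 - dry_day_prob``; wet-day totals are gamma distributed.
    """
    if n_days < 30:
        raise ValueError("need at least 30 days of daily data")
    if scale_bias <= 0:
        raise ValueError("scale_bias must be positive")
    rng = np.random.default_rng(seed)
    dates = pd.date_range(start, periods=n_days, freq="D")
    doy = dates.dayofyear.to_numpy()
    season = np.sin(2 * np.pi * (doy - 105) / 365.25)

    tmean_ref = 11.0 + 12.0 * season + 3.0 * rng.standard_normal(n_days)
    tmax_ref = tmean_ref + np.abs(5.0 + 1.5 * rng.standard_normal(n_days))
    rh_ref = np.clip(65.0 + 10.0 * season + 6.0 * rng.standard_normal(n_days), 0.0, 100.0)
    wet = rng.random(n_days) >= dry_day_prob
    precip_ref = np.where(
        wet, rng.gamma(precip_shape, precip_scale_mm, n_days), 0.0
    )

    return pd.DataFrame(
        {
            "tmean_ref": tmean_ref,
            "tmean_raw": tmean_ref + additive_bias,
            "tmax_ref": tmax_ref,
            "tmax_raw": tmax_ref + additive_bias,
            "rh_ref": rh_ref,
            "rh_raw": rh_ref + additive_bias,
            "precip_ref": precip_ref,
            "precip_raw": np.where(precip_ref > 0, precip_ref * scale_bias, 0.0),
        },
        index=dates,
    )
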