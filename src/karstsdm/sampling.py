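"""Collinearity filtering, stratified background sampling, training table.

Candidate predictors are screened on pairwise Spearman correlation with a
greedy removal rule that always retains protected predictors (elevation by
default).  Background (pseudo-absence) points are drawn uniformly over the
analysis mask, stratified between a survey buffer around the occurrences and
the whole mask, with the total adapted to the number of occurrences.  The
training table carries per-row weights normalizing presences and background
to equal total weight (0.5 : 0.5).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import rankdata

from .grids import RasterStack
from .masking import DomainMask
from .points import BackgroundSet, OccurrenceSet

log = logging.getLogger(__name__)

META_COLUMNS = ["x", "y", "stratum", "label", "weight"]


# ---------------------------------------------------------------------------
# Collinearity


def spearman_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman rank correlation (average ranks for ties).

    Constant columns get zero correlations with everything, a warning, and
    are listed in the result's ``attrs['degenerate']``.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 rows for a correlation matrix")
    cols = list(table.columns)
    ranks = np.column_stack([rankdata(table[c].to_numpy(float)) for c in cols])
    sds = ranks.std(axis=0)
    degenerate = [c for c, sd in zip(cols, sds) if sd == 0]
    if degenerate:
        warnings.warn(f"constant predictor columns (correlations set to 0): {degenerate}")
    safe = np.where(sds == 0, 1.0, sds)
    z = (ranks - ranks.mean(axis=0)) / safe
    rho = z.T @ z / len(table)
    for i, c in enumerate(cols):
        if c in degenerate:
            rho[i, :] = 0.0
            rho[:, i] = 0.0
    np.fill_diagonal(rho, 1.0)
    out = pd.DataFrame(rho, index=cols, columns=cols)
    out.attrs["degenerate"] = degenerate
    return out


@dataclass
class CollinearityReport:
    """Keep/drop decisions of the iterative Spearman filter."""

    kept: list[str]
    dropped: list[dict] = field(default_factory=list)  # {dropped, partner, abs_rho}
    threshold: float = 0.7
    protected: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "kept": self.kept,
                    "dropped": self.dropped,
                    "threshold": self.threshold,
                    "protected": self.protected,
                },
                indent=1,
            )
        )

    def to_text(self) -> str:
        lines = [f"Collinearity filter (|rho| > {self.threshold}):"]
        for d in self.dropped:
            lines.append(
                f"  drop {d['dropped']:<16s} (|rho| = {d['abs_rho']:.3f} with {d['partner']})"
            )
        lines.append("  kept: " + ", ".join(self.kept))
        return "\n".join(lines)


def filter_collinear(
    matrix: pd.DataFrame,
    threshold: float = 0.7,
    protected: Sequence[str] = ("elev_m",),
) -> CollinearityReport:
    """Iteratively drop predictors until no pair exceeds ``threshold``.

    At each step the currently worst (highest |rho|) offending pair is
    examined; the non-protected member with more offending partners is
    dropped (ties: the one later in the input ordering).  Two protected
    predictors exceeding the threshold with each other are both kept with a
    warning.
    """
    names = list(matrix.columns)
    protected = [p for p in protected if p in names]
    kept = list(names)
    dropped: list[dict] = []
    absrho = matrix.abs()

    for _ in range(len(names)):
        sub = absrho.loc[kept, kept]
        best: tuple[float, str, str] | None = None
        for i, a in enumerate(kept):
            for b in kept[i + 1 :]:
                r = float(sub.loc[a, b])
                if r > threshold and not (a in protected and b in protected):
                    if best is None or r > best[0]:
                        best = (r, a, b)
        if best is None:
            break
        r, a, b = best
        candidates = [v for v in (a, b) if v not in protected]
        if len(candidates) == 1:
            victim = candidates[0]
        else:
            # partner counts among currently kept predictors
            counts = {
                v: int((sub.loc[v, [k for k in kept if k != v]] > threshold).sum())
                for v in candidates
            }
            order = {n: i for i, n in enumerate(names)}
            victim = max(candidates, key=lambda v: (counts[v], order[v]))
        partner = b if victim == a else a
        dropped.append({"dropped": victim, "partner": partner, "abs_rho": r})
        kept.remove(victim)

    # report any protected-protected violations left in place
    for i, a in enumerate(protected):
        for b in protected[i + 1 :]:
            if float(absrho.loc[a, b]) > threshold:
                warnings.warn(
                    f"protected predictors {a!r} and {b!r} exceed |rho| > {threshold}; both kept"
                )
    return CollinearityReport(
        kept=kept, dropped=dropped, threshold=threshold, protected=list(protected)
    )


# ---------------------------------------------------------------------------
# Background sampling


def background_size(n_presence: int) -> int:
    """Adaptive background total: 5000 below 10 occurrences, else 10000."""
    if n_presence < 1:
        raise ValueError("n_presence must be >= 1")
    return 5000 if n_presence < 10 else 10000


def _sample_cells(
    rng: np.random.Generator,
    flat_indices: np.ndarray,
    n: int,
    replace: bool | None,
    stratum: str,
) -> np.ndarray:
    if flat_indices.size == 0:
        raise ValueError(f"no eligible cells in the {stratum} stratum")
    if flat_indices.size >= n and replace is not True:
        return rng.choice(flat_indices, size=n, replace=False)
    if replace is False:
        raise ValueError(
            f"{stratum} stratum has {flat_indices.size} cells but {n} requested; "
            "enable replacement or request fewer points"
        )
    if flat_indices.size < n:
        log.warning(
            "%s stratum has %d cells < %d requested; sampling with replacement",
            stratum, flat_indices.size, n,
        )
    return rng.choice(flat_indices, size=n, replace=True)


def sample_background(
    mask: DomainMask,
    occ: OccurrenceSet,
    buffer_km: float = 3.0,
    split: tuple[float, float] = (0.3, 0.7),
    seed: int = 0,
    n_total: int | None = None,
    replace: bool | None = None,
) -> BackgroundSet:
    """Stratified uniform background sample over the analysis mask.

    ``split`` fractions go to the survey-buffer stratum (mask cells within
    ``buffer_km`` of any occurrence) and the whole-mask stratum.  Cells are
    drawn uniformly, without replacement when enough cells are eligible
    (``replace=None`` auto-falls back with a warning; ``False`` errors
    instead).  Points are cell centres.
    """
    if abs(sum(split) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    if n_total is None:
        n_total = background_size(len(occ))
    rng = np.random.default_rng(seed)

    rows, cols = np.nonzero(mask.cells)
    x, y = mask.grid.cell_center(rows, cols)
    centres = np.column_stack([x, y])
    d = cdist(centres, occ.xy).min(axis=1)
    in_buffer = d <= buffer_km * 1000.0
    if not in_buffer.any():
        raise ValueError(
            f"no mask cell within {buffer_km} km of an occurrence; buffer stratum empty"
        )

    all_idx = np.arange(rows.size)
    n_buffer = int(round(split[0] * n_total))
    n_mask = n_total - n_buffer
    chosen_buffer = _sample_cells(rng, all_idx[in_buffer], n_buffer, replace, "buffer")
    chosen_mask = _sample_cells(rng, all_idx, n_mask, replace, "mask")

    idx = np.concatenate([chosen_buffer, chosen_mask])
    stratum = np.array(["buffer"] * n_buffer + ["mask"] * n_mask)
    data = pd.DataFrame({"x": centres[idx, 0], "y": centres[idx, 1], "stratum": stratum})
    return BackgroundSet(data=data, seed=seed)


# ---------------------------------------------------------------------------
# Training table


@dataclass
class TrainingTable:
    """Presence + background rows with standardized predictors and weights.

    Row order is presences first.  Presence weights sum to 0.5 and background
    weights to 0.5, giving the two classes equal total weight.
    """

    data: pd.DataFrame
    predictors: list[str]

    def __post_init__(self) -> None:
        missing = set(META_COLUMNS + self.predictors) - set(self.data.columns)
        if missing:
            raise ValueError(f"training table missing columns: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def X(self) -> np.ndarray:
        return self.data[self.predictors].to_numpy(float)

    @property
    def y(self) -> np.ndarray:
        return self.data["label"].to_numpy(int)

    @property
    def weights(self) -> np.ndarray:
        return self.data["weight"].to_numpy(float)

    @property
    def coords(self) -> np.ndarray:
        return self.data[["x", "y"]].to_numpy(float)

    @property
    def n_presence(self) -> int:
        return int((self.data["label"] == 1).sum())

    @property
    def n_background(self) -> int:
        return int((self.data["label"] == 0).sum())

    def subset(self, row_mask: np.ndarray, renormalize: bool = True) -> "TrainingTable":
        """Row subset; by default re-normalizes class weights to 0.5 : 0.5."""
        sub = self.data.loc[np.asarray(row_mask)].copy()
        if renormalize:
            for label in (0, 1):
                m = sub["label"] == label
                total = sub.loc[m, "weight"].sum()
                if total > 0:
                    sub.loc[m, "weight"] *= 0.5 / total
        return TrainingTable(sub.reset_index(drop=True), list(self.predictors))

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TrainingTable":
        data = pd.read_csv(path)
        predictors = [c for c in data.columns if c not in META_COLUMNS]
        return cls(data, predictors)


def assemble_training(
    stack_z: RasterStack,
    occ: OccurrenceSet,
    bg: BackgroundSet,
    report: CollinearityReport,
) -> TrainingTable:
    """Extract kept predictors at presence and background points, with weights.

    Rows with any nodata predictor are dropped (count logged).  Surviving
    presences get weight 0.5/nP each and background rows 0.5/nB.
    """
    kept = [k for k in report.kept if k != "limestone_bin"]
    frames = []
    for pts, label, stratum in ((occ.xy, 1, None), (bg.xy, 0, bg.data["stratum"].to_numpy())):
        vals = stack_z.extract(pts[:, 0], pts[:, 1], kept)
        df = pd.DataFrame(vals, columns=kept)
        df.insert(0, "x", pts[:, 0])
        df.insert(1, "y", pts[:, 1])
        df.insert(2, "stratum", stratum if stratum is not None else "presence")
        df.insert(3, "label", label)
        frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    complete = np.isfinite(table[kept].to_numpy(float)).all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        log.info("dropping %d rows with nodata predictor values", n_dropped)
    table = table.loc[complete].reset_index(drop=True)
    n_p = int((table["label"] == 1).sum())
    n_b = int((table["label"] == 0).sum())
    if n_p == 0:
        raise ValueError("no presence rows survive predictor extraction")
    if n_b == 0:
        raise ValueError("no background rows survive predictor extraction")
    table["weight"] = np.where(table["label"] == 1, 0.5 / n_p, 0.5 / n_b)
    table = table[["x", "y", "stratum", "label", "weight"] + kept]
    return TrainingTable(table, kept)
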