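"""Weighted ridge-penalized logistic regression for presence-background data.

The model contrasts presence rows against background rows with class weights
normalized to 0.5 : 0.5 and minimizes the penalized weighted negative
log-likelihood

    f(b0, b) = -sum_i w_i [y_i log p_i + (1 - y_i) log(1 - p_i)]
               + (lambda/2) ||b||^2,        p_i = expit(b0 + x_i' b),

with the intercept unpenalized, by damped Newton iterations (IRLS).  The
penalty strength is chosen on a log-spaced grid by internal cross-validation
minimizing mean held-out weighted deviance, then the model is refitted on
all rows at the selected lambda.  Predictors are expected on a common
z-score scale so one lambda penalizes all slopes comparably.

Usage follows the Model/Results convention::

    model = RidgeLogit.from_training_table(table)
    res = model.fit(cv_folds=5, seed=1)
    res.summary()
    smap = res.predict_suitability(stack_z, mask)
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .grids import Grid, RasterLayer, RasterStack
from .masking import DomainMask
from .sampling import TrainingTable

AT_BACKGROUND_MEAN = "at-background-mean"
BACKGROUND_AVERAGED = "background-averaged"

#: |slope| below this (z-score scale) is labelled a near-flat response
NEAR_FLAT_SLOPE = 0.05


class ConvergenceError(RuntimeError):
    pass


def _check_table(y: np.ndarray, w: np.ndarray) -> None:
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training data contain a single class; cannot fit")
    if np.any(w <= 0):
        raise ValueError("all row weights must be positive")


def _weighted_nll(y: np.ndarray, w: np.ndarray, eta: np.ndarray) -> float:
    # numerically stable -sum w [y log p + (1-y) log(1-p)]
    return float(np.sum(w * (np.logaddexp(0.0, eta) - y * eta)))


class RidgeLogit:
    """Weighted logistic regression with an L2 penalty on the slopes."""

    def __init__(
        self,
        endog: np.ndarray,
        exog: np.ndarray,
        weights: np.ndarray | None = None,
        exog_names: Sequence[str] | None = None,
        standardization=None,
    ):
        self.endog = np.asarray(endog, float)
        self.exog = np.atleast_2d(np.asarray(exog, float))
        n, k = self.exog.shape
        if weights is None:
            weights = np.full(n, 1.0 / n)
        self.weights = np.asarray(weights, float)
        if self.endog.shape != (n,) or self.weights.shape != (n,):
            raise ValueError("endog/weights length does not match exog rows")
        self.exog_names = list(exog_names) if exog_names is not None else [f"x{j}" for j in range(k)]
        if len(self.exog_names) != k:
            raise ValueError("exog_names length does not match exog columns")
        self.standardization = standardization
        _check_table(self.endog, self.weights)

    @classmethod
    def from_training_table(cls, table: TrainingTable, standardization=None) -> "RidgeLogit":
        if "limestone_bin" in table.predictors:
            raise ValueError("the mask variable limestone_bin must not be a predictor")
        return cls(
            endog=table.y,
            exog=table.X,
            weights=table.weights,
            exog_names=table.predictors,
            standardization=standardization,
        )

    # -- single-lambda Newton fit ------------------------------------------

    def _fit_one(
        self,
        lam: float,
        start: np.ndarray | None = None,
        tol: float = 1e-9,
        max_iter: int = 200,
    ) -> tuple[np.ndarray, bool, int, list[float]]:
        y, w = self.endog, self.weights
        X = np.column_stack([np.ones(len(y)), self.exog])
        k = X.shape[1]
        pen = np.full(k, lam)
        pen[0] = 0.0  # intercept unpenalized
        b = np.zeros(k) if start is None else start.copy()

        def objective(bvec: np.ndarray) -> float:
            return _weighted_nll(y, w, X @ bvec) + 0.5 * float(pen @ bvec**2)

        path = [objective(b)]
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            eta = X @ b
            p = expit(eta)
            grad = X.T @ (w * (p - y)) + pen * b
            s = np.maximum(w * p * (1.0 - p), 0.0)
            H = (X * s[:, None]).T @ X + np.diag(pen)
            try:
                step = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(H, grad, rcond=None)[0]
            # damped Newton: halve until the objective does not increase
            t = 1.0
            f_old = path[-1]
            for _ in range(60):
                cand = b - t * step
                f_new = objective(cand)
                if f_new <= f_old + 1e-14:
                    break
                t /= 2.0
            else:
                break
            b = cand
            path.append(f_new)
            if abs(f_old - f_new) <= tol * (abs(f_old) + 1e-12):
                converged = True
                break
        assert all(b2 <= b1 + 1e-12 for b1, b2 in zip(path, path[1:])), \
            "objective must not increase across Newton iterations"
        return b, converged, it, path

    # -- lambda grid and internal CV ---------------------------------------

    def default_lambda_grid(self, n_lambda: int = 60, ratio: float = 1e-5) -> np.ndarray:
        """Log-spaced grid descending from a data-driven lambda_max.

        lambda_max is the elastic-net software convention max_j |weighted null-model
        gradient_j| / 1e-3 (a pure ridge never zeroes slopes exactly, so the
        lasso annihilation point is inflated by the conventional 1/alpha_min
        factor).
        """
        y, w = self.endog, self.weights
        p0 = float(np.sum(w * y))  # weighted prevalence = null-model fit
        g = self.exog.T @ (w * (p0 - y))
        gmax = float(np.max(np.abs(g)))
        if gmax <= 0:
            gmax = 1.0
        lam_max = gmax / 1e-3
        return np.geomspace(lam_max, lam_max * ratio, n_lambda)

    def _cv_folds(self, k: int, seed: int) -> np.ndarray:
        """Stratified-by-class fold ids, seeded."""
        rng = np.random.default_rng(seed)
        fold = np.empty(len(self.endog), dtype=int)
        for label in (0, 1):
            idx = np.nonzero(self.endog == label)[0]
            idx = rng.permutation(idx)
            fold[idx] = np.arange(idx.size) % k
        return fold

    def fit(
        self,
        lambda_: float | None = None,
        lambda_grid: np.ndarray | None = None,
        n_lambda: int = 60,
        cv_folds: int | None = None,
        seed: int = 0,
        tol: float = 1e-9,
        max_iter: int = 200,
    ) -> "RidgeLogitResults":
        """Fit the model; select lambda by internal CV unless given.

        ``cv_folds`` defaults to ``min(5, n_presence)``; with fewer than two
        presences a fixed ``lambda_`` must be supplied.
        """
        if lambda_ is not None:
            b, conv, it, path = self._fit_one(lambda_, tol=tol, max_iter=max_iter)
            if not conv:
                raise ConvergenceError(f"no convergence at lambda={lambda_:g} after {it} iterations")
            return RidgeLogitResults(
                model=self, params=b, lambda_=float(lambda_),
                lambda_grid=np.array([lambda_]), cv_deviance=None,
                converged=conv, n_iter=it, objective_path=path,
            )

        grid = np.asarray(lambda_grid, float) if lambda_grid is not None else self.default_lambda_grid(n_lambda)
        if np.any(np.diff(grid) > 0):
            grid = np.sort(grid)[::-1]
        n_presence = int(np.sum(self.endog == 1))
        if cv_folds is None:
            cv_folds = min(5, n_presence)
        if cv_folds < 2:
            raise ValueError(
                "internal CV needs >= 2 presences; pass a fixed lambda_ instead"
            )
        fold = self._cv_folds(cv_folds, seed)

        deviance = np.zeros(grid.size)
        for f in range(cv_folds):
            test = fold == f
            train = ~test
            sub = RidgeLogit(
                self.endog[train], self.exog[train], self.weights[train],
                self.exog_names,
            )
            start = None
            for j, lam in enumerate(grid):
                b, conv, _, _ = sub._fit_one(lam, start=start, tol=tol, max_iter=max_iter)
                start = b
                eta = b[0] + self.exog[test] @ b[1:]
                deviance[j] += 2.0 * _weighted_nll(self.endog[test], self.weights[test], eta)
        deviance /= cv_folds

        best = int(np.argmin(deviance))
        lam_best = float(grid[best])

        # final path fit on all rows (warm-started) down to the chosen lambda
        start = None
        norms = []
        final = None
        for lam in grid:
            b, conv, it, path = self._fit_one(lam, start=start, tol=tol, max_iter=max_iter)
            start = b
            norms.append(float(np.linalg.norm(b[1:])))
            if lam == lam_best:
                final = (b, conv, it, path)
                break
        assert all(n2 >= n1 - 1e-8 for n1, n2 in zip(norms, norms[1:])), \
            "slope norm must be non-increasing in lambda along the path"
        b, conv, it, path = final
        if not conv:
            raise ConvergenceError(
                f"final refit did not converge at lambda={lam_best:g} ({it} iterations)"
            )
        return RidgeLogitResults(
            model=self, params=b, lambda_=lam_best, lambda_grid=grid,
            cv_deviance=deviance, converged=conv, n_iter=it, objective_path=path,
        )


@dataclass
class SuitabilityMap:
    """Predicted occurrence suitability over the analysis mask, in [0, 1]."""

    layer: RasterLayer
    mask: DomainMask

    @property
    def values(self) -> np.ndarray:
        return self.layer.values

    def masked_values(self) -> np.ndarray:
        return self.layer.values[self.mask.cells]


@dataclass
class ResponseCurve:
    """Partial-dependence curve of one predictor (suitability in [0, 1])."""

    predictor: str
    values: np.ndarray          # predictor grid, original units when known
    values_z: np.ndarray        # same grid on the standardized scale
    suitability: np.ndarray
    mode: str
    sign: str                   # "+", "-", or "near-flat"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {self.predictor: self.values, "z": self.values_z, "suitability": self.suitability}
        )


@dataclass
class RidgeLogitResults:
    """Fitted ridge logistic model: estimates, selection path, diagnostics."""

    model: RidgeLogit
    params: np.ndarray          # [intercept, slopes...]
    lambda_: float
    lambda_grid: np.ndarray
    cv_deviance: np.ndarray | None
    converged: bool
    n_iter: int
    objective_path: list[float] = field(default_factory=list)

    @property
    def intercept(self) -> float:
        return float(self.params[0])

    @property
    def coefficients(self) -> pd.Series:
        return pd.Series(self.params[1:], index=self.model.exog_names, name="coef")

    # -- prediction ---------------------------------------------------------

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        return self.intercept + np.asarray(X, float) @ self.params[1:]

    def predict(self, X: np.ndarray | pd.DataFrame) -> np.ndarray:
        """Suitability for rows of standardized predictor values."""
        if isinstance(X, pd.DataFrame):
            X = X[self.model.exog_names].to_numpy(float)
        return expit(self.linear_predictor(X))

    def predict_suitability(self, stack_z: RasterStack, mask: DomainMask) -> SuitabilityMap:
        """Suitability surface over the mask; nodata elsewhere."""
        for name in self.model.exog_names:
            if name not in stack_z:
                raise ValueError(f"standardized stack is missing predictor layer {name!r}")
        cells = mask.cells
        rows, cols = np.nonzero(cells)
        X = np.column_stack([stack_z[n].values[rows, cols] for n in self.model.exog_names])
        vals = np.full(mask.grid.shape, np.nan)
        vals[rows, cols] = self.predict(X)
        return SuitabilityMap(RasterLayer("suitability", mask.grid, vals), mask)

    # -- response curves ----------------------------------------------------

    def partial_dependence(
        self,
        table: TrainingTable,
        predictor: str,
        n_grid: int = 50,
        mode: str = AT_BACKGROUND_MEAN,
    ) -> ResponseCurve:
        """Response curve of one predictor over its background range.

        ``at-background-mean`` holds the other predictors at background-row
        means; ``background-averaged`` averages predictions over all
        background rows with the predictor substituted.
        """
        if predictor not in self.model.exog_names:
            raise ValueError(f"unknown predictor {predictor!r}")
        if mode not in (AT_BACKGROUND_MEAN, BACKGROUND_AVERAGED):
            raise ValueError(f"unknown partial-dependence mode {mode!r}")
        j = self.model.exog_names.index(predictor)
        bg = table.data[table.data["label"] == 0]
        Xbg = bg[self.model.exog_names].to_numpy(float)
        zgrid = np.linspace(Xbg[:, j].min(), Xbg[:, j].max(), n_grid)
        if mode == AT_BACKGROUND_MEAN:
            base = Xbg.mean(axis=0)
            Xg = np.tile(base, (n_grid, 1))
            Xg[:, j] = zgrid
            suit = self.predict(Xg)
        else:
            suit = np.empty(n_grid)
            Xwork = Xbg.copy()
            for i, v in enumerate(zgrid):
                Xwork[:, j] = v
                suit[i] = self.predict(Xwork).mean()
        slope = float(self.params[1 + j])
        sign = "near-flat" if abs(slope) < NEAR_FLAT_SLOPE else ("+" if slope > 0 else "-")
        std = self.model.standardization
        values = std.inverse(predictor, zgrid) if std is not None and predictor in std.means else zgrid
        return ResponseCurve(
            predictor=predictor, values=values, values_z=zgrid,
            suitability=suit, mode=mode, sign=sign,
        )

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        lines = [
            "Weighted ridge logistic regression (presence-background)",
            "=" * 58,
            f"n obs            {len(self.model.endog):>10d}"
            f"    presences {int(np.sum(self.model.endog == 1))}",
            f"lambda           {self.lambda_:>10.4g}"
            f"    grid size {self.lambda_grid.size}",
            f"converged        {str(self.converged):>10s}    iterations {self.n_iter}",
        ]
        if self.cv_deviance is not None:
            lines.append(f"min CV deviance  {float(np.min(self.cv_deviance)):>10.4f}")
        lines.append("-" * 58)
        lines.append(f"{'predictor':<20s}{'coef':>12s}")
        lines.append(f"{'(intercept)':<20s}{self.intercept:>12.4f}")
        for name, c in self.coefficients.items():
            lines.append(f"{name:<20s}{c:>12.4f}")
        lines.append("=" * 58)
        return "\n".join(lines)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "exog_names": self.model.exog_names,
            "intercept": self.intercept,
            "coefficients": self.coefficients.to_dict(),
            "lambda": self.lambda_,
            "lambda_grid": np.asarray(self.lambda_grid).tolist(),
            "cv_deviance": None if self.cv_deviance is None else np.asarray(self.cv_deviance).tolist(),
            "converged": self.converged,
            "n_iter": self.n_iter,
        }
        if self.model.standardization is not None:
            payload["standardization"] = {
                "means": self.model.standardization.means,
                "sds": self.model.standardization.sds,
            }
        Path(path).write_text(json.dumps(payload, indent=1))
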