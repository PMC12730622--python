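"""End-to-end pipeline: landscape -> mask -> filter -> sample -> fit -> maps.

A :class:`RunConfig` (YAML-loadable, unknown keys rejected) drives the whole
analysis: simulate or load the predictor stack and occurrences, derive
terrain predictors, build the limestone-and-elevation-band mask, filter
collinear predictors, sample stratified background, fit the weighted ridge
logistic model with internal lambda CV, predict the suitability surface,
threshold it, run spatial k-fold cross-validation, and write every artifact
with a checksummed manifest.  All randomness flows from the named stage
seeds, so a config reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import evaluation, masking, preprocess, sampling, synthetic
from .grids import RasterStack, read_stack, write_ascii_grid, write_stack
from .model import AT_BACKGROUND_MEAN, RidgeLogit
from .points import OccurrenceSet

log = logging.getLogger(__name__)


def _asdict_section(obj) -> dict:
    return {f.name: getattr(obj, f.name) for f in dataclasses.fields(obj)}


@dataclass
class Seeds:
    landscape: int = 0
    occurrences: int = 1
    background: int = 2
    model: int = 3
    cv: int = 4

    def offset(self, base: int) -> "Seeds":
        return Seeds(*(base + i for i in range(5)))


@dataclass
class RunConfig:
    """All tunables of one pipeline run, with field defaults."""

    outdir: str = "karstsdm_run"
    landscape: dict = field(default_factory=dict)     # LandscapeConfig overrides
    stack_dir: str | None = None                      # load stack instead of simulating
    occurrences_csv: str | None = None                # load occurrences instead of simulating
    truth_intercept: float = -1.0
    truth_coefficients: dict = field(
        default_factory=lambda: {"elev_m": 2.0, "tmean_ann": -1.5, "TPI_300m": 1.0}
    )
    n_presence: int = 6
    seeds: Seeds = field(default_factory=Seeds)
    tpi_radii_m: tuple = (300.0, 900.0)
    collinearity_threshold: float = 0.7
    protected: tuple = ("elev_m",)
    buffer_km: float = 3.0
    background_split: tuple = (0.3, 0.7)
    n_background: int | None = None                   # default: adaptive rule
    band_p_low: float = 5.0
    band_p_high: float = 95.0
    band_buffer_low: float = -100.0
    band_buffer_high: float = 200.0
    percentile_method: str = "linear"
    n_lambda: int = 60
    cv_folds: int | None = None                       # internal-CV folds; None = min(5, nP)
    threshold_rule: str = "min-top10-p10"
    pd_mode: str = AT_BACKGROUND_MEAN
    write_stack_layers: bool = False
    write_plots: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "seeds" in raw and isinstance(raw["seeds"], dict):
            seed_known = {f.name for f in dataclasses.fields(Seeds)}
            bad = set(raw["seeds"]) - seed_known
            if bad:
                raise ValueError(f"unknown seed keys: {sorted(bad)}")
            raw["seeds"] = Seeds(**raw["seeds"])
        for tup in ("tpi_radii_m", "protected", "background_split"):
            if tup in raw and isinstance(raw[tup], list):
                raw[tup] = tuple(raw[tup])
        return cls(**raw)

    def with_seed(self, base: int) -> "RunConfig":
        cfg = dataclasses.replace(self, seeds=self.seeds.offset(base))
        return cfg

    def to_yaml(self, path: str | Path, include_outdir: bool = True) -> None:
        d = dataclasses.asdict(self)
        if not include_outdir:
            del d["outdir"]
        d["seeds"] = dataclasses.asdict(self.seeds)
        d["tpi_radii_m"] = list(self.tpi_radii_m)
        d["protected"] = list(self.protected)
        d["background_split"] = list(self.background_split)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


@dataclass
class RunReport:
    """Everything a run produced, with a checksummed file manifest."""

    config: dict
    mask_diagnostics: dict
    collinearity: sampling.CollinearityReport
    model_summary: str
    coefficients: dict
    lambda_: float
    thresholds: evaluation.ThresholdSet
    fold_report: evaluation.FoldReport
    manifest: dict[str, str]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": self.config,
            "mask_diagnostics": self.mask_diagnostics,
            "collinearity": {
                "kept": self.collinearity.kept,
                "dropped": self.collinearity.dropped,
            },
            "coefficients": self.coefficients,
            "lambda": self.lambda_,
            "thresholds": self.thresholds.__dict__,
            "cv_summary": self.fold_report.summary,
            "manifest": self.manifest,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def build_stack(config: RunConfig) -> RasterStack:
    """Simulate (or load) the base stack and append terrain derivatives."""
    if config.stack_dir is not None:
        base = read_stack(config.stack_dir)
    else:
        overrides = {"seed": config.seeds.landscape, **config.landscape}
        lc = synthetic.LandscapeConfig(**overrides)
        base = synthetic.generate_landscape(lc)
    if "elev_m" not in base:
        raise ValueError("stack must contain an elev_m layer")
    terrain = preprocess.derive_terrain(base["elev_m"], config.tpi_radii_m)
    combined = RasterStack([base[n] for n in base.names])
    for name in terrain.names:
        if name not in combined and name != "aspect_deg":
            combined.add(terrain[name])
    return combined


def load_occurrences(config: RunConfig, stack: RasterStack) -> OccurrenceSet:
    if config.occurrences_csv is not None:
        path = Path(config.occurrences_csv)
        if not path.exists():
            raise FileNotFoundError(f"occurrence file not found: {path}")
        return OccurrenceSet.from_csv(path)
    truth = synthetic.TrueModel(config.truth_intercept, dict(config.truth_coefficients))
    return synthetic.generate_occurrences(
        stack, truth, config.n_presence, seed=config.seeds.occurrences
    )


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full analysis; see the module docstring for the stages."""
    t0 = time.perf_counter()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if config.occurrences_csv is not None and not Path(config.occurrences_csv).exists():
        raise FileNotFoundError(f"occurrence file not found: {config.occurrences_csv}")
    if config.stack_dir is not None and not Path(config.stack_dir).exists():
        raise FileNotFoundError(f"stack directory not found: {config.stack_dir}")

    def stage(name: str):
        log.info("stage %-12s t=%.2fs", name, time.perf_counter() - t0)

    stage("stack")
    stack = build_stack(config)
    stage("occurrences")
    occ = load_occurrences(config, stack)

    stage("mask")
    occ_elev = stack.extract(occ.xy[:, 0], occ.xy[:, 1], ["elev_m"])[:, 0]
    band = masking.elevation_band(
        occ_elev,
        p_low=config.band_p_low, p_high=config.band_p_high,
        buffer_low=config.band_buffer_low, buffer_high=config.band_buffer_high,
        method=config.percentile_method,
    )
    mask = masking.build_mask(stack, band)

    stage("standardize")
    stack_z, std_params = preprocess.standardize(stack, mask.cells)

    stage("filter")
    candidates = [n for n in stack.continuous_names() if n != "aspect_deg"]
    import pandas as pd

    env = pd.DataFrame(
        {n: stack[n].values[mask.cells] for n in candidates}
    )
    rho = sampling.spearman_matrix(env)
    collin = sampling.filter_collinear(
        rho, threshold=config.collinearity_threshold, protected=config.protected
    )

    stage("background")
    bg = sampling.sample_background(
        mask, occ,
        buffer_km=config.buffer_km, split=config.background_split,
        seed=config.seeds.background, n_total=config.n_background,
    )
    table = sampling.assemble_training(stack_z, occ, bg, collin)

    stage("fit")
    model = RidgeLogit.from_training_table(table, standardization=std_params)
    results = model.fit(
        n_lambda=config.n_lambda, cv_folds=config.cv_folds, seed=config.seeds.model
    )

    stage("predict")
    smap = results.predict_suitability(stack_z, mask)
    presence_scores = results.predict(table.X[table.y == 1])
    thresholds = evaluation.threshold_set(smap, presence_scores, rule=config.threshold_rule)
    binary = evaluation.binary_map(smap, thresholds.final_thr)

    stage("cv")
    fold_report = evaluation.cross_validate(table, seed=config.seeds.cv)

    stage("curves")
    curves = [
        results.partial_dependence(table, name, mode=config.pd_mode)
        for name in table.predictors
    ]

    stage("write")
    occ.to_csv(outdir / "occurrences.csv")
    occ.to_geojson(outdir / "occurrences.geojson")
    bg.to_csv(outdir / "background.csv")
    table.to_csv(outdir / "training.csv")
    collin.to_json(outdir / "collinearity.json")
    std_params.to_json(outdir / "standardization.json")
    results.to_json(outdir / "model.json")
    thresholds.to_json(outdir / "thresholds.json")
    fold_report.to_csv(outdir / "cv_folds.csv")
    mask.write(outdir / "domain_mask.asc")
    write_ascii_grid(smap.layer, outdir / "suitability.asc")
    write_ascii_grid(binary, outdir / "binary_suitability.asc")
    curve_dir = outdir / "response_curves"
    curve_dir.mkdir(exist_ok=True)
    for c in curves:
        c.to_frame().to_csv(curve_dir / f"{c.predictor}.csv", index=False)
    if config.write_plots:
        plot_response_curves(curves, outdir / "response_curves.png")
    if config.write_stack_layers:
        write_stack(stack, outdir / "stack")
    # echo without outdir so identical configs give identical artifacts
    config.to_yaml(outdir / "config_echo.yaml", include_outdir=False)

    manifest = {
        str(p.relative_to(outdir)): _sha256(p)
        for p in sorted(outdir.rglob("*"))
        if p.is_file() and p.name != "report.json"
    }
    report = RunReport(
        config=json.loads(json.dumps(dataclasses.asdict(config), default=list)),
        mask_diagnostics=mask.diagnostics,
        collinearity=collin,
        model_summary=results.summary(),
        coefficients=results.coefficients.to_dict(),
        lambda_=results.lambda_,
        thresholds=thresholds,
        fold_report=fold_report,
        manifest=manifest,
    )
    report.to_json(outdir / "report.json")
    stage("done")
    return report


def plot_response_curves(curves, path: str | Path) -> None:
    """Small-multiples PNG of all response curves."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(curves)
    ncols = 4
    nrows = -(-n // ncols)
    fig, axes = plt.subplots(nrows, ncols, figsize=(3.2 * ncols, 2.4 * nrows), squeeze=False)
    for ax, c in zip(axes.flat, curves):
        ax.plot(c.values, c.suitability)
        ax.set_title(f"{c.predictor} ({c.sign})", fontsize=9)
        ax.set_ylim(0, 1)
    for ax in axes.flat[n:]:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=100, metadata={"Software": "karstsdm"})
    plt.close(fig)
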