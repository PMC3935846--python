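"""End-to-end pipeline: simulate → fit → validate → map → stocks.

A single YAML config drives all stages.  Every stochastic stage draws its
own child seed from the root seed via ``numpy.random.SeedSequence.spawn``,
so enabling or disabling one stage never perturbs another's randomness and
the whole run is a pure function of (inputs, config).  Each stage reads and
writes serialized artifacts only, so any stage can be rerun alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .grids import (
    read_observations,
    read_raster,
    write_observations,
    write_raster,
    write_esri_ascii,
)
from .mapping import (
    DEFAULT_TAU_UPPER,
    habitat_suitability_map,
    minimum_positive_biomass,
    realized_stock,
)
from .regression import (
    QuantileFitGrid,
    TERMS,
    coefficient_paths,
    fit_quantile_grid,
)
from .synthetic import SyntheticTruth, generate_observations, generate_raster
from .validation import calibrate_grid

logger = logging.getLogger(__name__)

STAGES = ("simulate", "fit", "validate", "map", "stocks")


@dataclass
class PipelineConfig:
    """Validated pipeline configuration with defaults applied.

    Production defaults mirror the standard protocol: τ grid 0.01–0.99 in
    steps of 0.02, upper boundary τ = 0.975, 5000 bootstrap iterations,
    10 calibration classes, 5 stock simulations.
    """

    seed: int = 0
    output_dir: str = "qsdm_out"
    # input paths; None → the simulate stage generates them
    observations: str | None = None
    velocity_raster: str | None = None
    inundation_raster: str | None = None
    cell_area: float | None = None
    # synthetic-data stage
    synthetic: dict = field(default_factory=dict)
    # model
    formula: tuple[str, ...] = TERMS
    tau_min: float = 0.01
    tau_max: float = 0.99
    tau_step: float = 0.02
    tau_upper: float = DEFAULT_TAU_UPPER
    # validation
    n_iter: int = 5000
    n_classes: int = 10
    class_scheme: str = "frequency"
    validation_taus: tuple[float, ...] = (0.175, 0.375, 0.575, 0.775)
    # stocks
    n_sim: int = 5
    occurrence_basis: str = "sampled"
    tau_sampling: str = "continuous"
    report_tonnes: bool = False

    def tau_grid(self) -> np.ndarray:
        if not (0.0 < self.tau_min <= self.tau_max < 1.0):
            raise ValueError(
                f"tau grid bounds must satisfy 0 < min <= max < 1, got "
                f"[{self.tau_min}, {self.tau_max}]"
            )
        if self.tau_step <= 0:
            raise ValueError("tau_step must be positive")
        if self.tau_step > self.tau_max - self.tau_min and self.tau_min != self.tau_max:
            raise ValueError(
                f"tau_step {self.tau_step} exceeds the grid range "
                f"[{self.tau_min}, {self.tau_max}]"
            )
        n = int(np.floor((self.tau_max - self.tau_min) / self.tau_step + 1e-9)) + 1
        return self.tau_min + self.tau_step * np.arange(n)

    def validate(self) -> "PipelineConfig":
        if not 0.0 < self.tau_upper < 1.0:
            raise ValueError(f"tau_upper must lie strictly inside (0, 1), got {self.tau_upper}")
        self.tau_grid()
        for t in self.validation_taus:
            if not 0.0 < t < 1.0:
                raise ValueError(f"validation tau {t} must lie strictly inside (0, 1)")
        unknown = set(self.formula) - set(TERMS)
        if unknown:
            raise ValueError(f"unknown formula terms: {sorted(unknown)}")
        if self.n_iter < 1 or self.n_classes < 2 or self.n_sim < 1:
            raise ValueError("n_iter >= 1, n_classes >= 2 and n_sim >= 1 required")
        if self.class_scheme not in ("frequency", "width"):
            raise ValueError(f"invalid class_scheme {self.class_scheme!r}")
        if self.occurrence_basis not in ("sampled", "potential"):
            raise ValueError(f"invalid occurrence_basis {self.occurrence_basis!r}")
        if self.tau_sampling not in ("continuous", "discrete"):
            raise ValueError(f"invalid tau_sampling {self.tau_sampling!r}")
        return self


def parse_config(path: str | Path | None = None, overrides: dict | None = None) -> PipelineConfig:
    """Load and validate a YAML config; unknown keys are rejected.

    An empty (or absent) file yields all defaults.  ``overrides`` are
    applied on top (used by CLI flags).
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config must be a mapping, got {type(loaded).__name__}")
        raw = loaded
    if overrides:
        raw.update({k: v for k, v in overrides.items() if v is not None})
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for tup_key in ("formula", "validation_taus"):
        if tup_key in raw and isinstance(raw[tup_key], list):
            raw[tup_key] = tuple(raw[tup_key])
    return PipelineConfig(**raw).validate()


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _stage_seeds(seed: int) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(len(STAGES))
    return {
        stage: int(child.generate_state(1)[0] % (2**31))
        for stage, child in zip(STAGES, children)
    }


class PipelineRunner:
    """Executes pipeline stages against an output directory of artifacts."""

    def __init__(self, config: PipelineConfig):
        self.config = config.validate()
        self.outdir = Path(config.output_dir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.seeds = _stage_seeds(config.seed)

    # artifact paths -------------------------------------------------------
    @property
    def obs_path(self) -> Path:
        return Path(self.config.observations or self.outdir / "observations.csv")

    @property
    def velocity_path(self) -> Path:
        return Path(self.config.velocity_raster or self.outdir / "velocity.asc")

    @property
    def inundation_path(self) -> Path:
        return Path(self.config.inundation_raster or self.outdir / "inundation.asc")

    @property
    def fit_path(self) -> Path:
        return self.outdir / "fit.json"

    # stages ---------------------------------------------------------------
    def simulate(self) -> None:
        """Generate synthetic observations and rasters where inputs are absent."""
        cfg = self.config
        syn = dict(cfg.synthetic)
        truth = SyntheticTruth(
            beta=tuple(syn.get("beta", SyntheticTruth().beta)),
            p0=syn.get("p0", SyntheticTruth().p0),
            seed=self.seeds["simulate"],
        )
        shape = tuple(syn.get("shape", (80, 100)))
        n_obs = int(syn.get("n_obs", 3000))
        if cfg.velocity_raster is None or cfg.inundation_raster is None:
            raster = generate_raster(shape, truth, seed=self.seeds["simulate"])
            write_raster(raster, self.velocity_path, self.inundation_path)
        if cfg.observations is None:
            obs = generate_observations(n_obs, truth, seed=self.seeds["simulate"] + 1)
            write_observations(obs, self.obs_path)

    def fit(self) -> QuantileFitGrid:
        """Fit the τ grid (with τ_upper merged in) and export coefficient paths."""
        cfg = self.config
        data = read_observations(self.obs_path)
        taus = np.unique(np.append(cfg.tau_grid(), cfg.tau_upper))
        fit = fit_quantile_grid(data, terms=cfg.formula, taus=taus)
        fit.to_json(self.fit_path)
        coefficient_paths(fit).to_csv(self.outdir / "coefficient_paths.csv", index=False)
        return fit

    def validate_stage(self) -> list:
        cfg = self.config
        data = read_observations(self.obs_path)
        results = calibrate_grid(
            data,
            terms=cfg.formula,
            taus=cfg.validation_taus,
            n_iter=cfg.n_iter,
            n_classes=cfg.n_classes,
            seed=self.seeds["validate"],
            class_scheme=cfg.class_scheme,
        )
        summary = [r.summary() for r in results]
        (self.outdir / "calibration_summary.json").write_text(
            json.dumps(summary, indent=1)
        )
        for r in results:
            out = r.class_table.assign(tau=r.tau).rename(columns={"class_index": "class"})[
                ["tau", "class", "mean_predicted", "observed_quantile", "n", "all_zero"]
            ]
            out.to_csv(self.outdir / f"calibration_tau{r.tau:.3f}.csv", index=False)
        return results

    def map_stage(self) -> np.ndarray:
        cfg = self.config
        fit = QuantileFitGrid.from_json(self.fit_path)
        raster = read_raster(self.velocity_path, self.inundation_path, cfg.cell_area)
        suit = habitat_suitability_map(fit, raster, cfg.tau_upper)
        write_esri_ascii(
            self.outdir / "suitability.asc", suit, cellsize=float(np.sqrt(raster.cell_area))
        )
        return suit

    def stocks(self):
        cfg = self.config
        fit = QuantileFitGrid.from_json(self.fit_path)
        raster = read_raster(self.velocity_path, self.inundation_path, cfg.cell_area)
        data = read_observations(self.obs_path)
        threshold = minimum_positive_biomass(data)
        report = realized_stock(
            fit,
            raster,
            n_sim=cfg.n_sim,
            seed=self.seeds["stocks"],
            tau_upper=cfg.tau_upper,
            threshold=threshold,
            occurrence_basis=cfg.occurrence_basis,
            tau_sampling=cfg.tau_sampling,
            scenario_id=self.outdir.name,
        )
        report.to_json(self.outdir / "stock_report.json")
        return report

    def run(self) -> dict:
        """Run all stages; returns and writes the run manifest."""
        completed = []
        for stage, fn in (
            ("simulate", self.simulate),
            ("fit", self.fit),
            ("validate", self.validate_stage),
            ("map", self.map_stage),
            ("stocks", self.stocks),
        ):
            logger.info("running stage %s", stage)
            try:
                fn()
            except Exception as err:
                raise RuntimeError(f"stage {stage!r} failed: {err}") from err
            completed.append(stage)
        manifest = {
            "version": __version__,
            "stages": completed,
            "seed": self.config.seed,
            "stage_seeds": self.seeds,
            "tau_grid_levels": int(self.config.tau_grid().size),
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in asdict(self.config).items()
            },
            "input_digests": {
                "observations": _digest(self.obs_path),
                "velocity": _digest(self.velocity_path),
                "inundation": _digest(self.inundation_path),
            },
        }
        (self.outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        return manifest


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage end-to-end; returns the run manifest."""
    return PipelineRunner(config).run()
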