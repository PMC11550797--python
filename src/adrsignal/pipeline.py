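"""End-to-end orchestration: simulate/ingest -> curate -> fit -> classify -> report.

A single YAML configuration drives the run; every stage output is written
under the configured output directory and recorded, with its SHA-256 hash,
in a machine-readable run manifest.  Reruns with an identical configuration
and seed reproduce identical output hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from .cohort import DrugCatalog, RawCohort
from .curation import COVARIATE_NAMES, CurationConfig, curate
from .priors import HorseshoePrior, LaplacePrior
from .sampler import FitConfig, fit
from .signals import build_signal_table, forest_plot, summarize_posterior
from .synthetic import CohortSpec, build_drug_catalog, reference_fixture, \
    sample_cohort, assign_outcomes, TrueEffects, write_simulation

__all__ = ["RunManifest", "run_pipeline", "load_config", "DEFAULT_P0"]

def _pkg_version() -> str:
    from importlib.metadata import version
    try:
        return version("adrsignal")
    except Exception:
        return "unknown"


log = logging.getLogger("adrsignal")

#: default expected number of non-zero coefficients; a guess that should be
#: set explicitly from pharmacological expectation whenever possible
DEFAULT_P0 = 5.0

_REQUIRED_KEYS = ("seed", "output_dir", "outcome")
_PRIOR_NAMES = ("horseshoe", "lasso")


class ConfigError(ValueError):
    """Configuration does not match the documented schema."""


def load_config(path: str | Path) -> dict[str, Any]:
    """Load and validate a pipeline configuration file."""
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ConfigError("configuration must be a YAML mapping")
    for key in _REQUIRED_KEYS:
        if key not in cfg:
            raise ConfigError(f"missing required config key: {key!r}")
    if "simulate" not in cfg and "input" not in cfg:
        raise ConfigError("config needs a 'simulate' or 'input' section")
    model = cfg.get("model", {})
    for name in model.get("priors", ["horseshoe", "lasso"]):
        if name not in _PRIOR_NAMES:
            raise ConfigError(f"unknown prior {name!r} in model.priors")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Machine-readable record of one pipeline run."""

    config: dict[str, Any]
    seed: int
    versions: dict[str, str]
    outputs: dict[str, dict[str, str]] = field(default_factory=dict)
    curation_report: dict[str, Any] | None = None
    diagnostics: dict[str, list[str]] = field(default_factory=dict)

    def record(self, name: str, path: Path) -> None:
        self.outputs[name] = {"path": str(path), "sha256": _sha256(path)}

    @property
    def has_warnings(self) -> bool:
        return any(w for w in self.diagnostics.values())

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


def _simulate_stage(cfg: Mapping[str, Any], seed: int, out_dir: Path,
                    ) -> tuple[RawCohort, DrugCatalog, TrueEffects | None]:
    sim = cfg.get("simulate")
    if sim is not None:
        if sim.get("reference_fixture", False):
            cohort, effects, catalog = reference_fixture(
                seed=seed, outcome=cfg["outcome"])
        else:
            spec_kwargs = dict(sim.get("spec", {}))
            spec_kwargs.setdefault("seed", seed)
            spec = CohortSpec(**spec_kwargs)
            rng = spec.rng()
            catalog = build_drug_catalog(spec, rng)
            cohort = sample_cohort(spec, catalog, rng)
            effects = TrueEffects(
                intercept=float(sim.get("intercept", -2.5)),
                drug_effects={str(k): float(v)
                              for k, v in sim.get("drug_effects", {}).items()},
                covariate_effects={str(k): float(v)
                                   for k, v in sim.get("covariate_effects", {}).items()},
            )
            effects.validate_against(catalog)
            cohort = assign_outcomes(cohort, effects, rng)
        write_simulation(cohort, catalog, effects, out_dir / "simulated")
        log.info("stage=simulate event=done cases=%d catalog=%d",
                 len(cohort), len(catalog))
        return cohort, catalog, effects
    inp = cfg["input"]
    for key in ("cases", "exposures", "catalog"):
        if key not in inp:
            raise ConfigError(f"missing required config key: input.{key!r}")
        if not Path(inp[key]).exists():
            raise FileNotFoundError(f"input file not found: {inp[key]}")
    cohort = RawCohort.from_csv(inp["cases"], inp["exposures"])
    catalog = DrugCatalog.from_csv(inp["catalog"])
    log.info("stage=ingest event=done cases=%d catalog=%d",
             len(cohort), len(catalog))
    return cohort, catalog, None


def curation_config_from(catalog: DrugCatalog,
                         cfg: Mapping[str, Any] | None = None) -> CurationConfig:
    """Build a CurationConfig whose name lists and CYP table come from the catalog."""
    cfg = dict(cfg or {})
    return CurationConfig(
        min_count=cfg.get("min_count", 32),
        top_n=cfg.get("top_n", 100),
        keep_main_substance=cfg.get("keep_main_substance",
                                    CurationConfig().keep_main_substance),
        unspecific_names=frozenset(cfg.get("unspecific_names",
                                           catalog.unspecific_names())),
        supplement_names=frozenset(cfg.get("supplement_names",
                                           catalog.supplement_names())),
        cyp_table=catalog.cyp_table(),
    )


def _build_prior(name: str, model_cfg: Mapping[str, Any],
                 p: int, n: int, y: np.ndarray):
    if name == "horseshoe":
        p0 = model_cfg.get("p0")
        if p0 is None:
            p0 = DEFAULT_P0
            log.warning(
                "stage=fit event=default_p0 p0=%.0f -- expected non-zero "
                "coefficient count not set; using the package default. Set "
                "model.p0 from pharmacological expectation.", p0)
        return HorseshoePrior.calibrated(
            float(p0), p, n, y,
            slab_constant=model_cfg.get("slab_constant"),
            slab_df=float(model_cfg.get("slab_df", 4.0)))
    return LaplacePrior(
        scale=float(model_cfg.get("laplace_scale", 1.0)),
        learn_scale=bool(model_cfg.get("laplace_learn_scale", True)))


def run_pipeline(config_path: str | Path) -> RunManifest:
    """Execute the full pipeline described by a YAML configuration.

    Stages: simulate (or ingest) -> curate -> fit (each configured prior)
    -> classify -> report.  Returns the run manifest; convergence warnings
    are surfaced in ``manifest.diagnostics``.
    """
    cfg = load_config(config_path)
    seed = int(cfg["seed"])
    out_dir = Path(cfg["output_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)

    import arviz
    import matplotlib
    import scipy
    manifest = RunManifest(
        config=cfg, seed=seed,
        versions={"adrsignal": _pkg_version(), "numpy": np.__version__,
                  "scipy": scipy.__version__, "pandas": pd.__version__,
                  "arviz": arviz.__version__,
                  "matplotlib": matplotlib.__version__},
    )

    cohort, catalog, _effects = _simulate_stage(cfg, seed, out_dir)

    cur_cfg = curation_config_from(catalog, cfg.get("curation"))
    dm, report = curate(cohort, cur_cfg)
    dm_path = dm.to_csv(out_dir / "design_matrix.csv")
    rep_path = report.to_json(out_dir / "curation_report.json")
    manifest.record("design_matrix", dm_path)
    manifest.record("curation_report", rep_path)
    manifest.curation_report = dataclasses.asdict(report)
    log.info("stage=curate event=done n_final=%d n_cols=%d",
             report.n_final, dm.shape[1])

    model_cfg = dict(cfg.get("model", {}))
    classify_cfg = dict(cfg.get("classify", {}))
    level_light = float(classify_cfg.get("level_light", 0.5))
    level_strong = float(classify_cfg.get("level_strong", 0.9))
    fit_config = FitConfig(
        n_chains=int(model_cfg.get("n_chains", 2)),
        n_warmup=int(model_cfg.get("n_warmup", 500)),
        n_draws=int(model_cfg.get("n_draws", 500)),
        seed=seed,
        rhat_max=float(model_cfg.get("rhat_max", 1.01)),
        ess_min=int(model_cfg.get("ess_min", 400)),
    )

    X, y = dm.X, dm.y
    for name in model_cfg.get("priors", ["horseshoe", "lasso"]):
        prior = _build_prior(name, model_cfg, p=X.shape[1], n=X.shape[0], y=y)
        samples = fit(X, y, prior, fit_config,
                      predictor_names=dm.predictor_names)
        paths = samples.save(out_dir, stem=f"{name}_{cfg['outcome']}")
        for kind, p_ in paths.items():
            manifest.record(f"{name}_{kind}", p_)
        manifest.diagnostics[name] = list(samples.warnings)

        summaries = summarize_posterior(samples, level_light, level_strong)
        table = build_signal_table(summaries, covariate_names=COVARIATE_NAMES)
        csv_path = table.to_csv(out_dir / f"{name}_{cfg['outcome']}_signals.csv")
        json_path = table.to_json(out_dir / f"{name}_{cfg['outcome']}_signals.json")
        svg_path = forest_plot(summaries, f"{cfg['outcome']} ({name})",
                               out_dir / f"{name}_{cfg['outcome']}_forest.svg")
        manifest.record(f"{name}_signals_csv", csv_path)
        manifest.record(f"{name}_signals_json", json_path)
        manifest.record(f"{name}_forest", svg_path)
        log.info("stage=fit event=done prior=%s warnings=%d",
                 name, len(samples.warnings))

    manifest_path = manifest.to_json(out_dir / "manifest.json")
    log.info("stage=report event=done manifest=%s", manifest_path)
    return manifest
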