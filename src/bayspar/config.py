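"""Run configuration: YAML schema with strict key validation.

Unknown keys are errors — a typo in a prior setting must not silently fall
back to a default.  The effective configuration of every run is embedded
in its outputs for provenance.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .calibration import McmcSettings, PriorSpec
from .spatial import CorrelationModel

__all__ = ["RunConfig", "load_config"]

_SCHEMA: dict[str, set[str]] = {
    "": {"target_kind", "lat_cutoff_deg", "gamma", "matern", "grid", "priors",
         "mcmc", "extraction", "seed"},
    "gamma": {"shape_a", "scale_b"},
    "matern": {"phi", "jitter", "metric"},
    "grid": {"box_size_deg"},
    "extraction": {"method", "search_radius_cells"},
    "priors": {
        "mu_alpha_mean", "mu_alpha_sd", "mu_beta_mean", "mu_beta_sd",
        "tau2_shape", "tau2_scale", "sigma2_alpha_shape", "sigma2_alpha_scale",
        "sigma2_beta_shape", "sigma2_beta_scale", "phi_fixed", "phi_grid",
    },
    "mcmc": {"n_chains", "n_iter", "n_warmup", "thin", "rhat_warn"},
}


class ConfigError(ValueError):
    pass


def _check_keys(section: str, mapping: dict) -> None:
    allowed = _SCHEMA[section]
    unknown = set(mapping) - allowed
    if unknown:
        where = f"section '{section}'" if section else "top level"
        raise ConfigError(f"unknown config key(s) {sorted(unknown)} at {where}; "
                          f"allowed: {sorted(allowed)}")


@dataclass
class RunConfig:
    target_kind: str = "SST"
    lat_cutoff_deg: float = 70.0
    gamma_shape_a: float = 4.5
    gamma_scale_b: float = 15.0
    box_size_deg: float = 20.0
    extraction_method: str = "nearest"
    extraction_search_radius_cells: int = 3
    seed: int = 0
    correlation: CorrelationModel = field(default_factory=CorrelationModel)
    priors: PriorSpec = field(default_factory=PriorSpec)
    mcmc: McmcSettings = field(default_factory=McmcSettings)

    def to_json(self) -> str:
        d = {
            "target_kind": self.target_kind,
            "lat_cutoff_deg": self.lat_cutoff_deg,
            "gamma": {"shape_a": self.gamma_shape_a, "scale_b": self.gamma_scale_b},
            "grid": {"box_size_deg": self.box_size_deg},
            "matern": {"phi": self.correlation.phi, "jitter": self.correlation.jitter,
                       "metric": self.correlation.metric},
            "extraction": {"method": self.extraction_method,
                           "search_radius_cells": self.extraction_search_radius_cells},
            "mcmc": asdict(self.mcmc),
            "seed": self.seed,
        }
        return json.dumps(d, sort_keys=True)


def load_config(path=None) -> RunConfig:
    """Load a YAML run configuration; missing sections take defaults."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    _check_keys("", raw)
    for sec in ("gamma", "matern", "grid", "priors", "mcmc", "extraction"):
        if sec in raw:
            if not isinstance(raw[sec], dict):
                raise ConfigError(f"config section '{sec}' must be a mapping")
            _check_keys(sec, raw[sec])

    cfg = RunConfig()
    cfg.target_kind = str(raw.get("target_kind", cfg.target_kind))
    if cfg.target_kind not in ("SST", "SubT"):
        raise ConfigError(f"target_kind must be SST or SubT, got {cfg.target_kind!r}")
    cfg.lat_cutoff_deg = float(raw.get("lat_cutoff_deg", cfg.lat_cutoff_deg))
    cfg.seed = int(raw.get("seed", cfg.seed))
    g = raw.get("gamma", {})
    cfg.gamma_shape_a = float(g.get("shape_a", cfg.gamma_shape_a))
    cfg.gamma_scale_b = float(g.get("scale_b", cfg.gamma_scale_b))
    gr = raw.get("grid", {})
    cfg.box_size_deg = float(gr.get("box_size_deg", cfg.box_size_deg))
    m = raw.get("matern", {})
    cfg.correlation = CorrelationModel(
        phi=float(m.get("phi", cfg.correlation.phi)),
        jitter=float(m.get("jitter", cfg.correlation.jitter)),
        metric=str(m.get("metric", cfg.correlation.metric)),
    )
    e = raw.get("extraction", {})
    cfg.extraction_method = str(e.get("method", cfg.extraction_method))
    if cfg.extraction_method not in ("nearest", "bilinear"):
        raise ConfigError("extraction.method must be 'nearest' or 'bilinear'")
    cfg.extraction_search_radius_cells = int(
        e.get("search_radius_cells", cfg.extraction_search_radius_cells)
    )
    p = dict(raw.get("priors", {}))
    if p:
        cfg.priors = PriorSpec(**p)
    mc = dict(raw.get("mcmc", {}))
    if mc:
        cfg.mcmc = McmcSettings(**mc)
    return cfg
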