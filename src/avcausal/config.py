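"""Flat key-value configuration files (YAML) for models and experiments.

A config file is a single flat mapping; every key is optional and falls
back to the package default.  Recognized keys:

network:   n, angle_min, angle_max, m1, m2, sigma1, sigma2, mode,
           input_steps, max_steps, tol, threshold_frac, min_sep, assign_rule
stimulus:  m_v, m_a, sigma_v, sigma_a, sigma_vx, sigma_ax, s_v, s_a
bayes:     p_co, bayes_sigma_v, bayes_sigma_a, bayes_a
experiment: model, disparities, n_trials, base_seed, noiseless
"""

from __future__ import annotations

from pathlib import Path
from typing import Any, Mapping

import yaml

from .bayes import BayesParams
from .experiments import ExperimentConfig, NetworkModel
from .network import ConnectivityParams, build_geometry
from .stimulus import StimulusConfig

__all__ = [
    "load_config",
    "model_from_config",
    "stimulus_from_config",
    "bayes_from_config",
    "experiment_from_config",
    "KNOWN_KEYS",
]

_NETWORK_KEYS = {
    "n", "angle_min", "angle_max", "m1", "m2", "sigma1", "sigma2", "mode",
    "input_steps", "max_steps", "tol", "threshold_frac", "min_sep", "assign_rule",
}
_STIMULUS_KEYS = {"m_v", "m_a", "sigma_v", "sigma_a", "sigma_vx", "sigma_ax", "s_v", "s_a"}
_BAYES_KEYS = {"p_co", "bayes_sigma_v", "bayes_sigma_a", "bayes_a"}
_EXPERIMENT_KEYS = {"model", "disparities", "n_trials", "base_seed", "noiseless"}
KNOWN_KEYS = _NETWORK_KEYS | _STIMULUS_KEYS | _BAYES_KEYS | _EXPERIMENT_KEYS


def load_config(path: str | Path) -> dict[str, Any]:
    """Read a flat YAML mapping; unknown keys raise to catch typos early."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a flat key-value mapping")
    unknown = set(data) - KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return data


def _pick(cfg: Mapping[str, Any], keys: set[str]) -> dict[str, Any]:
    return {k: cfg[k] for k in keys if k in cfg}


def model_from_config(cfg: Mapping[str, Any]) -> NetworkModel:
    """Build a :class:`NetworkModel` from flat config values."""
    geom = build_geometry(
        n=int(cfg.get("n", 1000)),
        angle_min=float(cfg.get("angle_min", -50.0)),
        angle_max=float(cfg.get("angle_max", 50.0)),
    )
    conn = ConnectivityParams(
        m1=float(cfg.get("m1", 28.0)),
        m2=float(cfg.get("m2", 10.0)),
        sigma1=float(cfg.get("sigma1", 1.5)),
        sigma2=float(cfg.get("sigma2", 3.0)),
    )
    return NetworkModel(
        geom=geom,
        conn=conn,
        mode=cfg.get("mode", "linear"),
        input_steps=int(cfg.get("input_steps", 5)),
        max_steps=int(cfg.get("max_steps", 100)),
        tol=float(cfg.get("tol", 1e-9)),
        threshold_frac=float(cfg.get("threshold_frac", 0.1)),
        min_sep=float(cfg.get("min_sep", 3.0)),
        assign_rule=cfg.get("assign_rule", "nearest"),
    )


def stimulus_from_config(cfg: Mapping[str, Any]) -> StimulusConfig:
    kw = {k: float(v) for k, v in _pick(cfg, _STIMULUS_KEYS).items()}
    return StimulusConfig(**kw)


def bayes_from_config(cfg: Mapping[str, Any]) -> BayesParams:
    return BayesParams(
        p_co=float(cfg.get("p_co", 0.2)),
        sigma_v=float(cfg.get("bayes_sigma_v", 3.0)),
        sigma_a=float(cfg.get("bayes_sigma_a", 6.5)),
        a=float(cfg.get("bayes_a", 100.0)),
    )


def experiment_from_config(cfg: Mapping[str, Any], **overrides: Any) -> ExperimentConfig:
    """Build an :class:`ExperimentConfig`; keyword overrides (e.g. from CLI
    flags) take precedence over file values, which beat defaults."""
    merged: dict[str, Any] = _pick(cfg, _EXPERIMENT_KEYS)
    merged.update({k: v for k, v in overrides.items() if v is not None})
    kwargs: dict[str, Any] = {}
    if "disparities" in merged:
        kwargs["disparities"] = tuple(float(d) for d in merged["disparities"])
    for key, cast in (("n_trials", int), ("base_seed", int), ("model", str), ("noiseless", bool)):
        if key in merged:
            kwargs[key] = cast(merged[key])
    kwargs["stim"] = stimulus_from_config(cfg)
    kwargs["bayes_params"] = bayes_from_config(cfg)
    return ExperimentConfig(**kwargs)
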