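"""Plain-text (YAML) configuration for trajectories and study grids.

Recognised keys::

    visit_months:     [0, 6, 12, 18, 24, 36]
    placebo_means:    [1.5, 1.72, 2.0, 2.29, 2.67, 3.5]
    covariance:       [[...], ...]        # full matrix, same order as visits
    slowing_fraction: 0.20
    n_per_arm:        [200, 300, ...]     # scalar or list
    duration_months:  [18, 24, 36]        # scalar or list
    n_replicates:     200
    seed:             0

Any key may be omitted; packaged defaults fill the gaps, so a user who has
the true cohort trajectory and covariance can drop them in without code.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any, Mapping

import yaml

from .study import ScenarioGrid
from .trajectories import TrajectorySpec, TreatmentEffectSpec, default_trajectory


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, Mapping):
        raise ValueError("config file must contain a mapping of keys to values")
    return dict(cfg)


def trajectory_from_config(cfg: Mapping[str, Any]) -> TrajectorySpec:
    default = default_trajectory()
    visit_months = cfg.get("visit_months", default.visit_months)
    means = cfg.get("placebo_means", default.placebo_means)
    cov = cfg.get("covariance")
    if cov is None:
        if tuple(visit_months) != default.visit_months:
            raise ValueError("a covariance matrix is required for a custom visit schedule")
        cov = default.covariance
    return TrajectorySpec(visit_months, means, cov)


def effect_from_config(cfg: Mapping[str, Any]) -> TreatmentEffectSpec:
    return TreatmentEffectSpec(slowing_fraction=float(cfg.get("slowing_fraction", 0.20)))


def _as_tuple(value) -> tuple:
    if isinstance(value, (list, tuple)):
        return tuple(value)
    return (value,)


def grid_from_config(cfg: Mapping[str, Any]) -> ScenarioGrid:
    defaults = ScenarioGrid()
    return ScenarioGrid(
        n_per_arm=tuple(int(n) for n in _as_tuple(cfg.get("n_per_arm", defaults.n_per_arm))),
        durations=tuple(
            float(d) for d in _as_tuple(cfg.get("duration_months", defaults.durations))
        ),
        n_replicates=int(cfg.get("n_replicates", defaults.n_replicates)),
        master_seed=int(cfg.get("seed", defaults.master_seed)),
    )
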