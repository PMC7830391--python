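"""Desk-scale comparison and robustness experiments.

Reproduces the shape of the study's evaluations on synthetic phantoms:
method comparison (colony-tuned vs cross-validation vs an arbitrary
setting vs CGLS), a noise-level sweep, an angle-arrangement sweep, and
transfer of a trained configuration to a different phantom variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .aco import ColonyConfig, aco_tune, default_search_space
from .cv import cv_tune
from .geometry import (
    ImageVolume,
    ProjectionSet,
    ScanGeometry,
    fan_geometry,
    forward_project,
)
from .metrics import relative_error, uqi
from .phantoms import NoiseModel, add_ct_noise, render_phantom, thorax_like_spec
from .recon import AwpcsdParams, awpcsd, cgls, estimate_delta

__all__ = [
    "NOISE_CASES",
    "ANGLE_ARRANGEMENTS",
    "ARBITRARY_CONFIG",
    "ExperimentPlan",
    "simulate_case",
    "reconstruct_method",
    "run_comparison",
    "transfer_experiment",
]

# Noise cases: default plus the three elevated levels of the robustness
# sweep (max photon count, gaussian mean, gaussian sd).
NOISE_CASES: dict[str, tuple[float, float, float]] = {
    "default": (60_000.0, 0.0, 0.5),
    "noise1": (30_000.0, 0.0, 1.0),
    "noise2": (20_000.0, 0.0, 3.0),
    "noise3": (10_000.0, 0.0, 5.0),
}

# Angle arrangements: 50 views at each increment (degrees); the first two
# span a full turn region, the last two a half turn.
ANGLE_ARRANGEMENTS: dict[str, float] = {
    "360_7.2": 7.2,
    "360_7.0": 7.0,
    "360_5.9": 5.9,
    "180_3.6": 3.6,
    "180_3.52": 3.52,
}

# The naive user's setting used as a comparator.
ARBITRARY_CONFIG: dict[str, float] = {"epsilon": 700.0, "ng": 100.0}


@dataclass(frozen=True)
class ExperimentPlan:
    """Declarative description of a comparison run."""

    grid: int = 64
    n_views: int = 50
    phantom_variant: str = "train"
    noise_cases: tuple[str, ...] = ("default",)
    angle_cases: tuple[str, ...] = ("360_7.2",)
    methods: tuple[str, ...] = ("aco", "arbitrary", "cgls")
    seed: int = 0
    max_iter: int = 50
    cgls_iter: int = 15
    colony: ColonyConfig = field(
        default_factory=lambda: ColonyConfig(
            n_ants=20, max_generations=4, max_iterations=12, evaporation=1.0
        )
    )
    cv_trial_stride: int = 10
    cv_max_iter: int = 20

    def __post_init__(self) -> None:
        for c in self.noise_cases:
            if c not in NOISE_CASES:
                raise ValueError(f"unknown noise case {c!r}")
        for c in self.angle_cases:
            if c not in ANGLE_ARRANGEMENTS:
                raise ValueError(f"unknown angle case {c!r}")
        for m in self.methods:
            if m not in ("aco", "cv", "arbitrary", "cgls"):
                raise ValueError(f"unknown method {m!r}")


def _geometry_for(plan: ExperimentPlan, angle_case: str) -> ScanGeometry:
    inc = ANGLE_ARRANGEMENTS[angle_case]
    return fan_geometry(n=plan.grid, n_views=plan.n_views, span=inc * plan.n_views)


def simulate_case(
    plan: ExperimentPlan, angle_case: str, noise_case: str, seed: int
) -> tuple[ImageVolume, ScanGeometry, ProjectionSet]:
    """Phantom, geometry and noisy projections for one experimental case."""
    geom = _geometry_for(plan, angle_case)
    truth = render_phantom(
        thorax_like_spec((plan.grid, plan.grid), variant=plan.phantom_variant),
        voxel_size=geom.voxel_size,
    )
    clean = forward_project(truth, geom)
    i0, mean, sd = NOISE_CASES[noise_case]
    noisy = add_ct_noise(clean, NoiseModel(i0, mean, sd, seed=seed))
    return truth, geom, noisy


def _awpcsd_params(config: dict[str, float], delta: float, max_iter: int) -> AwpcsdParams:
    return AwpcsdParams(
        epsilon=float(config["epsilon"]),
        ng=int(config["ng"]),
        beta=float(config.get("beta", 1.0)),
        beta_red=float(config.get("beta_red", 0.99)),
        delta=float(config.get("delta", delta)),
        k=float(config.get("k", 1.0)),
        max_iter=max_iter,
    )


def reconstruct_method(
    method: str,
    config: dict[str, float] | None,
    b: ProjectionSet,
    geom: ScanGeometry,
    delta: float,
    plan: ExperimentPlan,
) -> ImageVolume:
    """Reconstruct one case with one method."""
    if method == "cgls":
        return cgls(b, geom, n_iter=plan.cgls_iter)
    assert config is not None
    params = _awpcsd_params(config, delta, plan.max_iter)
    return awpcsd(None, b, geom, params).image


def _resolve_configs(
    plan: ExperimentPlan,
    truth: ImageVolume,
    b: ProjectionSet,
    geom: ScanGeometry,
    delta: float,
) -> dict[str, dict[str, float] | None]:
    """Hyperparameter source per method (tuners run on the training case)."""
    space = default_search_space(delta=delta)
    configs: dict[str, dict[str, float] | None] = {}
    for method in plan.methods:
        if method == "aco":
            res = aco_tune(b, geom, truth, space, replace(plan.colony, seed=plan.seed))
            configs[method] = res.best_config
        elif method == "cv":
            res = cv_tune(
                b, geom, space, trial_stride=plan.cv_trial_stride, max_iter=plan.cv_max_iter
            )
            configs[method] = res.best_config
        elif method == "arbitrary":
            configs[method] = {**ARBITRARY_CONFIG, "delta": delta}
        else:
            configs[method] = None
    return configs


def _profile_row(img: ImageVolume) -> np.ndarray:
    """1-D profile through the volume centre (second axis varies)."""
    arr = img.values
    mid = tuple(s // 2 for s in arr.shape)
    if arr.ndim == 2:
        return arr[mid[0], :].copy()
    return arr[mid[0], :, mid[2]].copy()


def run_comparison(plan: ExperimentPlan) -> tuple[pd.DataFrame, dict]:
    """Execute the plan: every method on every (angle, noise) case.

    Hyperparameters are tuned once on the training case (first angle case,
    default noise, plan seed) and reused across cases, mirroring the
    train-once / test-everywhere protocol.  Returns the metric table
    (relative error in %, UQI) and a dict of artefacts (images, profiles,
    difference images, tuned configs).
    """
    truth0, geom0, b0 = simulate_case(plan, plan.angle_cases[0], "default", plan.seed)
    delta = estimate_delta(b0, geom0)
    configs = _resolve_configs(plan, truth0, b0, geom0, delta)

    rows = []
    artefacts: dict = {"configs": configs, "delta": delta, "images": {}, "profiles": {},
                       "difference_images": {}, "truth": {}}
    for angle_case in plan.angle_cases:
        for noise_case in plan.noise_cases:
            truth, geom, b = simulate_case(plan, angle_case, noise_case, plan.seed)
            artefacts["truth"][(angle_case, noise_case)] = truth
            for method in plan.methods:
                try:
                    img = reconstruct_method(method, configs[method], b, geom, delta, plan)
                    err = 100.0 * relative_error(img, truth)
                    q = uqi(img, truth)
                    rows.append(
                        {
                            "angle_case": angle_case,
                            "noise_case": noise_case,
                            "method": method,
                            "relative_error_pct": err,
                            "uqi": q,
                            "status": "ok",
                        }
                    )
                    key = (angle_case, noise_case, method)
                    artefacts["images"][key] = img
                    artefacts["profiles"][key] = _profile_row(img)
                    artefacts["difference_images"][key] = ImageVolume(
                        img.values - truth.values, img.voxel_size
                    )
                except Exception as exc:  # record the failure, keep going
                    rows.append(
                        {
                            "angle_case": angle_case,
                            "noise_case": noise_case,
                            "method": method,
                            "relative_error_pct": np.nan,
                            "uqi": np.nan,
                            "status": f"failed: {exc}",
                        }
                    )
    return pd.DataFrame(rows), artefacts


def transfer_experiment(
    trained_config: dict[str, float],
    new_phantom_variant: str,
    plan: ExperimentPlan | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Apply a trained configuration to a different phantom variant and
    compare it against direct tuning, the arbitrary setting and CGLS."""
    if plan is None:
        plan = ExperimentPlan()
    plan = replace(plan, phantom_variant=new_phantom_variant,
                   methods=("aco", "arbitrary", "cgls"))
    truth, geom, b = simulate_case(plan, plan.angle_cases[0], "default", plan.seed)
    delta = estimate_delta(b, geom)
    configs = _resolve_configs(plan, truth, b, geom, delta)
    configs["trained"] = dict(trained_config)

    rows = []
    artefacts: dict = {"configs": configs, "delta": delta, "images": {}, "truth": truth}
    for method in ("trained", "aco", "arbitrary", "cgls"):
        img = reconstruct_method(
            "cgls" if method == "cgls" else "awpcsd", configs.get(method), b, geom, delta, plan
        )
        rows.append(
            {
                "method": method,
                "relative_error_pct": 100.0 * relative_error(img, truth),
                "uqi": uqi(img, truth),
                "epsilon": None if method == "cgls" else configs[method]["epsilon"],
                "ng": None if method == "cgls" else configs[method]["ng"],
            }
        )
        artefacts["images"][method] = img
    return pd.DataFrame(rows), artefacts
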