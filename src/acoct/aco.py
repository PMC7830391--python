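"""Ant-colony search over the discrete hyperparameter grid.

A colony of ants repeatedly draws hyperparameter configurations from
per-value pheromone distributions, each ant advances the shared solver
state by exactly one outer iteration, and the correlation coefficient
against a reference image is its score.  Pheromones are kept per candidate
value per dimension (not per configuration); per-configuration summed
scores form the ledger from which the final best configuration is chosen.

Control flow per colony generation: sample and score ``n_ants`` ants from
the previous-iteration best image; update pheromones with the per-value
mean scores; if the generation's best score beats the previous
generation's best, advance an *iteration* (the winning image becomes the
new base), otherwise launch another generation, up to ``max_generations``
per iteration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .geometry import ImageVolume, ProjectionSet, ScanGeometry
from .metrics import correlation_coefficient
from .recon import AwpcsdParams, AwpcsdState, awpcsd

__all__ = [
    "SearchSpace",
    "PheromoneState",
    "ColonyConfig",
    "AntRecord",
    "GenerationRecord",
    "TuneResult",
    "default_search_space",
    "choice_probabilities",
    "sample_config",
    "score_ant",
    "update_pheromones",
    "aco_tune",
]

logger = logging.getLogger(__name__)

# Candidate grids for the two searched hyperparameters: 10 tolerance values
# and 15 TV sub-iteration counts (150 configurations in total); the other
# three hyperparameters are pinned.
EPSILON_GRID = (0.0, 50.0, 70.0, 100.0, 200.0, 500.0, 2e3, 1e4, 1e5, 5e5)
NG_GRID = tuple(range(2, 31, 2))
FIXED_DEFAULTS = {"beta": 1.0, "beta_red": 0.99, "delta": 0.0213}


@dataclass(frozen=True)
class SearchSpace:
    """Discrete search grid: ordered candidate lists per searched dimension
    plus pinned values for the remaining hyperparameters."""

    dimensions: tuple[tuple[str, tuple[float, ...]], ...]
    fixed: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        dims = tuple((str(n), tuple(float(v) for v in vals)) for n, vals in self.dimensions)
        object.__setattr__(self, "dimensions", dims)
        object.__setattr__(self, "fixed", tuple((str(n), float(v)) for n, v in self.fixed))
        for name, vals in self.dimensions:
            if len(vals) == 0:
                raise ValueError(f"dimension {name!r} has no candidate values")
            if len(set(vals)) != len(vals):
                raise ValueError(f"dimension {name!r} has duplicate values")

    @classmethod
    def from_mappings(cls, dimensions: dict, fixed: dict | None = None) -> "SearchSpace":
        return cls(
            dimensions=tuple((k, tuple(v)) for k, v in dimensions.items()),
            fixed=tuple((fixed or {}).items()),
        )

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.dimensions)

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(len(v) for _, v in self.dimensions)

    @property
    def n_configs(self) -> int:
        return int(np.prod(self.shape))

    def values(self, name: str) -> tuple[float, ...]:
        for n, vals in self.dimensions:
            if n == name:
                return vals
        raise KeyError(name)

    def config(self, indices: tuple[int, ...]) -> dict[str, float]:
        """Full hyperparameter mapping for one index tuple (searched values
        merged with the pinned ones)."""
        if len(indices) != len(self.dimensions):
            raise ValueError("index tuple rank does not match dimensions")
        out = {n: vals[i] for (n, vals), i in zip(self.dimensions, indices)}
        out.update(dict(self.fixed))
        return out

    def to_dict(self) -> dict:
        return {
            "dimensions": {n: list(v) for n, v in self.dimensions},
            "fixed": dict(self.fixed),
        }

    @classmethod
    def from_dict(cls, cfg: dict) -> "SearchSpace":
        return cls.from_mappings(cfg["dimensions"], cfg.get("fixed"))


def default_search_space(delta: float = 0.0213) -> SearchSpace:
    """The study's default grid: 10 epsilon values x 15 ng values with
    beta, beta_red and delta pinned."""
    fixed = dict(FIXED_DEFAULTS)
    fixed["delta"] = delta
    return SearchSpace.from_mappings(
        {"epsilon": EPSILON_GRID, "ng": NG_GRID}, fixed
    )


@dataclass(eq=False)
class PheromoneState:
    """Per-dimension pheromone vectors, normalised so max tau = 1."""

    tau: dict[str, np.ndarray]
    generation: int = 0
    evaporation: float = 1.0

    @classmethod
    def initial(cls, space: SearchSpace, evaporation: float = 1.0) -> "PheromoneState":
        if not 0 <= evaporation <= 1:
            raise ValueError("evaporation must be in [0, 1]")
        return cls(
            tau={n: np.ones(len(v)) for n, v in space.dimensions},
            generation=0,
            evaporation=evaporation,
        )

    def copy(self) -> "PheromoneState":
        return PheromoneState(
            {k: v.copy() for k, v in self.tau.items()}, self.generation, self.evaporation
        )


def choice_probabilities(tau_vector: np.ndarray) -> np.ndarray:
    """Selection probabilities ``P_i = tau_i / sum(tau)``."""
    tau = np.asarray(tau_vector, dtype=np.float64)
    if (tau < 0).any():
        raise ValueError("pheromones must be non-negative")
    total = tau.sum()
    if total <= 0:
        raise ValueError("degenerate pheromone state: all values are zero")
    return tau / total


def sample_config(pheromones: PheromoneState, rng: np.random.Generator) -> tuple[int, ...]:
    """One configuration: an independent categorical draw per dimension."""
    indices = []
    for name, tau in pheromones.tau.items():
        p = choice_probabilities(tau)
        indices.append(int(rng.choice(len(p), p=p)))
    return tuple(indices)


def update_pheromones(
    pheromones: PheromoneState,
    scores: list[tuple[tuple[int, ...], float]],
) -> PheromoneState:
    """Evaporate, deposit per-value mean scores, renormalise.

    For each dimension and candidate value chosen by at least one ant,
    ``tau_i <- (1 - sigma) * tau_i + mean(scores of ants choosing i)``;
    unchosen values only evaporate.  Each dimension is then divided by its
    maximum so pheromones stay in (0, 1].
    """
    if not scores:
        raise ValueError("scores must be non-empty")
    sigma = pheromones.evaporation
    new = pheromones.copy()
    for dim, (name, tau) in enumerate(new.tau.items()):
        sums = np.zeros_like(tau)
        counts = np.zeros(len(tau), dtype=np.int64)
        for indices, score in scores:
            i = indices[dim]
            sums[i] += score
            counts[i] += 1
        tau_new = (1.0 - sigma) * tau
        chosen = counts > 0
        tau_new[chosen] += sums[chosen] / counts[chosen]
        tau_new = np.maximum(tau_new, 0.0)
        peak = tau_new.max()
        if peak > 0:
            tau_new = tau_new / peak
        else:
            # every sampled value failed (negative scores) and evaporation
            # wiped the rest: restart this dimension from a uniform state
            tau_new[:] = 1.0
        new.tau[name] = tau_new
    new.generation = pheromones.generation + 1
    return new


@dataclass(frozen=True)
class ColonyConfig:
    """Colony-level settings for a tuning run."""

    n_ants: int = 50
    max_generations: int = 10
    max_iterations: int = 50
    evaporation: float = 1.0
    seed: int = 0
    reset_generations: bool = True  # generation budget counted per iteration

    def __post_init__(self) -> None:
        if min(self.n_ants, self.max_generations, self.max_iterations) < 1:
            raise ValueError("counts must all be >= 1")
        if not 0 <= self.evaporation <= 1:
            raise ValueError("evaporation must be in [0, 1]")


@dataclass(frozen=True)
class AntRecord:
    indices: tuple[int, ...]
    score: float


@dataclass(eq=False)
class GenerationRecord:
    iteration: int
    generation: int
    ants: list[AntRecord]
    best_indices: tuple[int, ...]
    best_score: float
    tau: dict[str, np.ndarray]


@dataclass(eq=False)
class TuneResult:
    best_config: dict[str, float]
    best_indices: tuple[int, ...]
    accumulated_scores: np.ndarray
    best_image: ImageVolume | None
    best_score: float
    history: list[GenerationRecord]
    stop_reason: str  # max_iterations | generations_exhausted | recon_converged
    space: SearchSpace


@dataclass(eq=False)
class _AntOutcome:
    image_flat: np.ndarray | None
    score: float
    state: AwpcsdState | None
    recon_stop: str | None


def score_ant(
    config: dict[str, float] | tuple[int, ...],
    prev_iter_best: ImageVolume,
    b: ProjectionSet,
    geom: ScanGeometry,
    reference: ImageVolume,
    space: SearchSpace | None = None,
    state: AwpcsdState | None = None,
    max_iter: int = 50,
) -> tuple[ImageVolume, float]:
    """One ant's move: a single outer solver iteration from the shared base
    image with the ant's hyperparameters, scored by correlation against the
    reference.  A failing reconstruction scores -1 and is logged."""
    if isinstance(config, tuple):
        if space is None:
            raise ValueError("space is required when config is an index tuple")
        config = space.config(config)
    if reference.shape != geom.volume_shape:
        raise ValueError("reference shape does not match geometry")
    params = AwpcsdParams(
        epsilon=config["epsilon"],
        ng=int(config["ng"]),
        beta=config.get("beta", 1.0),
        beta_red=config.get("beta_red", 0.99),
        delta=config.get("delta", 0.0213),
        k=config.get("k", 1.0),
        max_iter=max_iter,
    )
    if state is None:
        state = AwpcsdState(
            x=prev_iter_best.values.ravel().astype(np.float64).copy(), beta=params.beta
        )
    else:
        state = state.copy()
        state.x = prev_iter_best.values.ravel().astype(np.float64).copy()
    try:
        res = awpcsd(None, b, geom, params, n_outer=1, state=state)
        score = correlation_coefficient(res.image, reference)
        return res.image, score
    except Exception as exc:
        logger.warning("ant reconstruction failed (%s); scoring -1", exc)
        return prev_iter_best, -1.0


def _default_evaluate(b, geom, reference, space, colony):
    ref_flat = reference.values.ravel()

    def evaluate(indices: tuple[int, ...], base_state: AwpcsdState,
                 rng: np.random.Generator) -> _AntOutcome:
        cfg = space.config(indices)
        params = AwpcsdParams(
            epsilon=cfg["epsilon"],
            ng=int(cfg["ng"]),
            beta=cfg.get("beta", 1.0),
            beta_red=cfg.get("beta_red", 0.99),
            delta=cfg.get("delta", 0.0213),
            k=cfg.get("k", 1.0),
            max_iter=colony.max_iterations,
        )
        try:
            res = awpcsd(None, b, geom, params, n_outer=1, state=base_state)
            score = correlation_coefficient(res.image, reference)
            return _AntOutcome(res.state.x, score, res.state, res.stop_reason)
        except Exception as exc:
            logger.warning("ant reconstruction failed (%s); scoring -1", exc)
            return _AntOutcome(None, -1.0, None, None)

    return evaluate


def aco_tune(
    b: ProjectionSet | None,
    geom: ScanGeometry | None,
    reference: ImageVolume | None,
    space: SearchSpace,
    colony: ColonyConfig,
    evaluate=None,
) -> TuneResult:
    """Run the full colony search and return the tuning result.

    The previous-iteration best starts as a zero image; every ant advances
    it by one solver iteration under its own (epsilon, ng).  ``evaluate``
    may replace the reconstruction-and-score step (used for rigged
    objectives in tests); it receives ``(indices, base_state, rng)`` and
    must return an :class:`_AntOutcome`-compatible object.

    Reproducible: per-ant RNG streams are derived from
    ``(seed, iteration, generation, ant)``.
    """
    if evaluate is None:
        if b is None or geom is None or reference is None:
            raise ValueError("b, geom and reference are required without a custom evaluate")
        if reference.shape != geom.volume_shape:
            raise ValueError("reference shape does not match geometry")
        evaluate = _default_evaluate(b, geom, reference, space, colony)
        n_vox = geom.n_voxels
        voxel_size = geom.voxel_size
        vol_shape = geom.volume_shape
    else:
        n_vox = geom.n_voxels if geom is not None else 1
        voxel_size = geom.voxel_size if geom is not None else (1.0,)
        vol_shape = geom.volume_shape if geom is not None else (1,)

    beta0 = dict(space.fixed).get("beta", 1.0)
    base_state = AwpcsdState(x=np.zeros(n_vox), beta=beta0)

    pher = PheromoneState.initial(space, colony.evaporation)
    accumulated = np.zeros(space.shape)
    history: list[GenerationRecord] = []
    best_score = -np.inf
    best_image_flat: np.ndarray | None = None
    prev_gen_best = -np.inf
    stop_reason = "max_iterations"
    w, g = 1, 1

    while True:
        ants: list[AntRecord] = []
        outcomes: list[_AntOutcome] = []
        converged = False
        for a in range(colony.n_ants):
            rng = np.random.default_rng([colony.seed, w, g, a])
            indices = sample_config(pher, rng)
            out = evaluate(indices, base_state.copy(), rng)
            ants.append(AntRecord(indices, out.score))
            outcomes.append(out)
            accumulated[indices] += out.score
            if out.recon_stop in ("beta_floor", "converged_c_dd"):
                converged = True

        # current-generation best (ties: lowest candidate indices)
        order = sorted(range(len(ants)), key=lambda i: (-ants[i].score, ants[i].indices))
        cur = order[0]
        cur_score = ants[cur].score
        cur_out = outcomes[cur]

        scores = [(r.indices, r.score) for r in ants]
        pher = update_pheromones(pher, scores)
        history.append(
            GenerationRecord(
                iteration=w,
                generation=g,
                ants=ants,
                best_indices=ants[cur].indices,
                best_score=cur_score,
                tau={k: v.copy() for k, v in pher.tau.items()},
            )
        )
        if cur_score > best_score:
            best_score = cur_score
            best_image_flat = None if cur_out.image_flat is None else cur_out.image_flat.copy()

        if converged:
            stop_reason = "recon_converged"
            break

        if cur_score > prev_gen_best and cur_out.state is not None:
            if w >= colony.max_iterations:
                stop_reason = "max_iterations"
                break
            # advance an iteration: the winning image becomes the base
            prev_gen_best = cur_score
            base_state = cur_out.state.copy()
            w += 1
            if colony.reset_generations:
                g = 1
        else:
            prev_gen_best = cur_score
            g += 1
            if g > colony.max_generations:
                stop_reason = "generations_exhausted"
                break

    flat_best = int(np.argmax(accumulated))  # first occurrence = lowest indices
    best_indices = tuple(int(i) for i in np.unravel_index(flat_best, space.shape))
    best_image = None
    if best_image_flat is not None:
        best_image = ImageVolume(best_image_flat.reshape(vol_shape), voxel_size)
    return TuneResult(
        best_config=space.config(best_indices),
        best_indices=best_indices,
        accumulated_scores=accumulated,
        best_image=best_image,
        best_score=best_score,
        history=history,
        stop_reason=stop_reason,
        space=space,
    )
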