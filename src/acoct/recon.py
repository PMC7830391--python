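"""Iterative reconstruction solvers.

Implements the relaxed algebraic sweep (SART), its ordered-subsets variant,
CGLS, the adaptive-weighted total-variation (AwTV) norm/gradient, and the
alternating data-fidelity / edge-preserving TV descent solver (AwPCSD)
whose five hyperparameters (epsilon, ng, beta, beta_red, delta) are the
subject of the tuners in :mod:`acoct.aco` and :mod:`acoct.cv`.

The outer AwPCSD iteration is:

1. ``dd = ||A x - b||``;
2. if ``dd**2 > epsilon``: one relaxed SART sweep over all angles;
3. non-negativity projection ``x = max(0, x)``;
4. ``beta *= beta_red`` (geometric relaxation decay);
5. TV step size ``eta = k * dd / dd_first`` (1 on the first iteration, and
   frozen at its previous value while ``dd_first**2 <= epsilon``);
6. ``ng`` normalised steepest-descent sub-iterations on the AwTV norm.

Stopping: ``beta < beta_floor``, or ``c < c_threshold`` together with
``dd <= epsilon`` where ``c`` is the cosine between the data-update and
TV-update step vectors, or the outer-iteration cap.  Runs are resumable via
:class:`AwpcsdState` (used by the ant-colony tuner to advance one outer
iteration per ant).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Optional

import numpy as np

from .geometry import ImageVolume, ProjectionSet, ScanGeometry, system_matrix

__all__ = [
    "AwpcsdParams",
    "AwpcsdState",
    "IterRecord",
    "ReconResult",
    "sart_sweep",
    "os_sart",
    "estimate_delta",
    "awtv_norm",
    "awtv_gradient",
    "tv_descent",
    "nonneg_project",
    "awpcsd",
    "cgls",
]


@dataclass(frozen=True)
class AwpcsdParams:
    """The five tunable hyperparameters plus iteration limits.

    ``epsilon`` bounds the squared projection residual in the SART gating
    check and the (un-squared) residual in the convergence stopping rule —
    both comparisons follow the solver's literal definitions.
    """

    epsilon: float
    ng: int
    beta: float = 1.0
    beta_red: float = 0.99
    delta: float = 0.0213
    k: float = 1.0
    max_iter: int = 50
    beta_floor: float = 0.005
    c_threshold: float = -0.99

    def __post_init__(self) -> None:
        if not 0 < self.beta <= 1:
            raise ValueError("beta must be in (0, 1]")
        if not 0 < self.beta_red < 1:
            raise ValueError("beta_red must be in (0, 1)")
        if self.ng < 1:
            raise ValueError("ng must be >= 1")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if not self.delta > 0:
            raise ValueError("delta must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass(eq=False)
class AwpcsdState:
    """Resumable solver state: image, current relaxation, first-iteration
    residual (eta reference) and the count of completed outer iterations."""

    x: np.ndarray
    beta: float
    dd_first: Optional[float] = None
    iteration: int = 0
    eta: float = 1.0

    def copy(self) -> "AwpcsdState":
        return AwpcsdState(self.x.copy(), self.beta, self.dd_first, self.iteration, self.eta)


@dataclass(frozen=True)
class IterRecord:
    iteration: int
    dd: float
    awtv: float
    beta: float
    eta: float
    c: float


@dataclass(eq=False)
class ReconResult:
    image: ImageVolume
    trace: list[IterRecord]
    stop_reason: str  # max_iter | beta_floor | converged_c_dd
    state: AwpcsdState


# ---------------------------------------------------------------------------
# algebraic updates


def _angle_subsets(n_angles: int, n_subsets: int) -> list[np.ndarray]:
    """Interleaved angle subsets: subset s takes angles s, s+n_subsets, ..."""
    return [np.arange(s, n_angles, n_subsets) for s in range(n_subsets)]


@lru_cache(maxsize=4096)
def _subset_cache(geom: ScanGeometry, angle_indices: tuple[int, ...]):
    """Row-sum reciprocal (W) and column-sum reciprocal (V) diagonals for
    the rays of one angle subset; zero sums map to zero (no blow-up)."""
    mats = [system_matrix(geom, a) for a in angle_indices]
    row_inv = []
    col_sums = np.zeros(geom.n_voxels)
    for mat in mats:
        rs = np.asarray(mat.sum(axis=1)).ravel()
        with np.errstate(divide="ignore"):
            row_inv.append(np.where(rs > 0, 1.0 / rs, 0.0))
        col_sums += np.asarray(mat.sum(axis=0)).ravel()
    with np.errstate(divide="ignore"):
        v_inv = np.where(col_sums > 0, 1.0 / col_sums, 0.0)
    return mats, row_inv, v_inv


def _subset_update(
    x: np.ndarray,
    b: np.ndarray,
    geom: ScanGeometry,
    angle_indices: tuple[int, ...],
    beta: float,
) -> np.ndarray:
    """One relaxed SART-type update using the rays of ``angle_indices``.

    ``x <- x + beta * V^-1 sum_a A_a^T W_a (b_a - A_a x)`` with W the
    inverse row-sum diagonal and V the inverse column-sum diagonal, both
    restricted to the subset's rays (the classic SART/OS-SART
    normalisation).  Zero sums yield zero updates.
    """
    mats, row_inv, v_inv = _subset_cache(geom, tuple(int(a) for a in angle_indices))
    upd = np.zeros_like(x)
    for a, mat, ri in zip(angle_indices, mats, row_inv):
        resid = b[a].ravel() - mat @ x
        upd += mat.T @ (resid * ri)
    return x + beta * v_inv * upd


def sart_sweep(
    x: ImageVolume, b: ProjectionSet, geom: ScanGeometry, beta: float
) -> ImageVolume:
    """One full SART sweep: sequential per-angle relaxed updates
    ``x <- x + beta * V^-1 A_a^T W_a (b_a - A_a x)``."""
    if not 0 < beta <= 1:
        raise ValueError("beta must be in (0, 1]")
    _check_pair(x, b, geom)
    xv = x.values.ravel().copy()
    for a in range(geom.n_angles):
        xv = _subset_update(xv, b.values, geom, (a,), beta)
    return ImageVolume(xv.reshape(geom.volume_shape), geom.voxel_size)


def os_sart(
    x0: ImageVolume,
    b: ProjectionSet,
    geom: ScanGeometry,
    n_subsets: int,
    n_iter: int,
    beta: float = 1.0,
) -> ImageVolume:
    """Ordered-subsets SART over interleaved angle subsets.

    With ``n_subsets == n_angles`` one pass is identical to
    :func:`sart_sweep`; with ``n_subsets == 1`` each pass is a SIRT-like
    full-data update.  Deterministic.
    """
    if n_subsets < 1 or n_subsets > geom.n_angles:
        raise ValueError("n_subsets must be in [1, n_angles]")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    _check_pair(x0, b, geom)
    subsets = _angle_subsets(geom.n_angles, n_subsets)
    xv = x0.values.ravel().copy()
    for _ in range(n_iter):
        for sub in subsets:
            xv = _subset_update(xv, b.values, geom, tuple(int(a) for a in sub), beta)
    return ImageVolume(xv.reshape(geom.volume_shape), geom.voxel_size)


def estimate_delta(
    b: ProjectionSet,
    geom: ScanGeometry,
    n_iter: int = 20,
    beta: float = 1.0,
    percentile: float = 90.0,
    floor: float = 1e-8,
) -> float:
    """AwTV scale factor: the 90th percentile of a short ordered-subsets
    reconstruction (``n_iter`` passes, ``beta``, ``n_angles // 2`` subsets),
    with a strictly positive fallback floor."""
    if b.values.size == 0:
        raise ValueError("projections must be non-empty")
    n_subsets = max(1, geom.n_angles // 2)
    x0 = ImageVolume(np.zeros(geom.volume_shape), geom.voxel_size)
    recon = os_sart(x0, b, geom, n_subsets=n_subsets, n_iter=n_iter, beta=beta)
    val = float(np.percentile(recon.values, percentile))
    return val if val > 0 else floor


# ---------------------------------------------------------------------------
# adaptive-weighted TV


def _backward_diffs(x: np.ndarray) -> list[np.ndarray]:
    """Backward finite differences per axis, zero on the leading boundary."""
    diffs = []
    for ax in range(x.ndim):
        d = np.zeros_like(x)
        sl_hi = [slice(None)] * x.ndim
        sl_lo = [slice(None)] * x.ndim
        sl_hi[ax] = slice(1, None)
        sl_lo[ax] = slice(None, -1)
        d[tuple(sl_hi)] = x[tuple(sl_hi)] - x[tuple(sl_lo)]
        diffs.append(d)
    return diffs


def awtv_norm(x: ImageVolume | np.ndarray, delta: float) -> float:
    """Adaptive-weighted TV norm.

    ``sum_v sqrt(sum_axis w * D^2)`` with backward differences ``D`` and
    edge-preserving weights ``w = exp(-(D / delta)**2)``; for large
    ``delta`` the weights tend to 1 and the value approaches the isotropic
    TV norm.
    """
    if not delta > 0:
        raise ValueError("delta must be positive")
    arr = x.values if isinstance(x, ImageVolume) else np.asarray(x, dtype=np.float64)
    acc = np.zeros_like(arr)
    for d in _backward_diffs(arr):
        w = np.exp(-((d / delta) ** 2))
        acc += w * d * d
    return float(np.sqrt(acc).sum())


def _default_mu(arr: np.ndarray) -> float:
    return 1e-8 * max(float(np.abs(arr).max(initial=0.0)), 1.0)


def awtv_gradient(
    x: ImageVolume | np.ndarray, delta: float, mu: float | None = None
) -> np.ndarray:
    """Gradient of the smoothed AwTV norm with frozen weights.

    Each sqrt is smoothed to ``sqrt(. + mu**2)`` and the weights ``w`` are
    treated as constants at the current image, so the per-voxel energy is
    ``phi = sqrt(sum_a w_a D_a^2 + mu^2)`` and the gradient is the discrete
    divergence of ``w_a D_a / phi``.  Finite everywhere.
    """
    if not delta > 0:
        raise ValueError("delta must be positive")
    arr = x.values if isinstance(x, ImageVolume) else np.asarray(x, dtype=np.float64)
    if mu is None:
        mu = _default_mu(arr)
    if not mu > 0:
        raise ValueError("mu must be positive")
    diffs = _backward_diffs(arr)
    weights = [np.exp(-((d / delta) ** 2)) for d in diffs]
    phi = np.sqrt(sum(w * d * d for w, d in zip(weights, diffs)) + mu * mu)
    grad = np.zeros_like(arr)
    for ax, (w, d) in enumerate(zip(weights, diffs)):
        flux = w * d / phi
        grad += flux
        sl_hi = [slice(None)] * arr.ndim
        sl_lo = [slice(None)] * arr.ndim
        sl_hi[ax] = slice(1, None)
        sl_lo[ax] = slice(None, -1)
        grad[tuple(sl_lo)] -= flux[tuple(sl_hi)]
    return grad


def tv_descent(
    x: ImageVolume, delta: float, ng: int, eta: float, mu: float | None = None
) -> ImageVolume:
    """``ng`` normalised steepest-descent steps ``x <- x - eta * s/||s||``
    on the AwTV norm, recomputing the gradient each sub-iteration.  A zero
    gradient leaves the image unchanged."""
    if ng < 1:
        raise ValueError("ng must be >= 1")
    if not eta > 0:
        raise ValueError("eta must be positive")
    arr = x.values.copy()
    for _ in range(ng):
        s = awtv_gradient(arr, delta, mu)
        norm = float(np.linalg.norm(s))
        if norm == 0.0:
            break
        arr -= eta * s / norm
    return ImageVolume(arr, x.voxel_size)


def nonneg_project(x: ImageVolume) -> ImageVolume:
    """Elementwise ``max(0, x)``; idempotent."""
    return ImageVolume(np.maximum(x.values, 0.0), x.voxel_size)


# ---------------------------------------------------------------------------
# AwPCSD


def _check_pair(x: ImageVolume, b: ProjectionSet, geom: ScanGeometry) -> None:
    if x.shape != geom.volume_shape:
        raise ValueError(f"volume shape {x.shape} does not match geometry")
    expected = (geom.n_angles, *geom.detector_pixel_counts)
    if b.values.shape != expected:
        raise ValueError(f"projection shape {b.values.shape} does not match geometry")


_ETA_MAX = 10.0


def awpcsd(
    x0: ImageVolume | None,
    b: ProjectionSet,
    geom: ScanGeometry,
    params: AwpcsdParams,
    n_outer: int | None = None,
    state: AwpcsdState | None = None,
    mu: float | None = None,
) -> ReconResult:
    """Alternating data-fidelity / AwTV-descent reconstruction.

    ``n_outer`` caps the number of outer iterations performed by this call
    (``n_outer=1`` advances exactly one iteration, the unit of work per ant
    in the colony tuner).  Passing ``state`` resumes a previous run; a run
    of ``k`` iterations resumed for ``m`` more is identical to a single
    ``k+m``-iteration run.
    """
    if state is None:
        if x0 is None:
            x0 = ImageVolume(np.zeros(geom.volume_shape), geom.voxel_size)
        _check_pair(x0, b, geom)
        state = AwpcsdState(x=x0.values.ravel().astype(np.float64).copy(), beta=params.beta)
    else:
        state = state.copy()
        if state.x.size != geom.n_voxels:
            raise ValueError("state does not match geometry")

    a_full = system_matrix(geom)
    b_flat = b.values.ravel()
    trace: list[IterRecord] = []
    stop_reason = "max_iter"
    done = 0

    while True:
        if state.iteration >= params.max_iter:
            stop_reason = "max_iter"
            break
        if n_outer is not None and done >= n_outer:
            stop_reason = "max_iter"
            break
        w = state.iteration + 1
        x_start = state.x
        dd = float(np.linalg.norm(a_full @ x_start - b_flat))
        if state.dd_first is None:
            state.dd_first = dd

        x = x_start
        if dd * dd > params.epsilon:
            for a in range(geom.n_angles):
                x = _subset_update(x, b.values, geom, (a,), state.beta)
        x_pocs = np.maximum(x, 0.0)

        beta_used = state.beta
        state.beta *= params.beta_red

        # eta follows the residual ratio, gated on the first residual
        # exceeding the tolerance; otherwise it keeps its previous value.
        # A zero first residual means the data are already consistent: the
        # projection-controlled step vanishes and the TV phase is skipped.
        if state.dd_first == 0.0:
            state.eta = 0.0
        elif state.dd_first**2 > params.epsilon:
            state.eta = min(params.k * dd / state.dd_first, _ETA_MAX)
            state.eta = max(state.eta, np.finfo(float).tiny)
        eta = state.eta

        if eta > 0.0:
            x_img = tv_descent(
                ImageVolume(x_pocs.reshape(geom.volume_shape), geom.voxel_size),
                params.delta,
                params.ng,
                eta,
                mu,
            )
            x_tv = x_img.values.ravel()
        else:
            x_tv = x_pocs

        step_data = x_pocs - x_start
        step_tv = x_tv - x_pocs
        nd, nt = np.linalg.norm(step_data), np.linalg.norm(step_tv)
        c = float(step_data @ step_tv / (nd * nt)) if nd > 0 and nt > 0 else 0.0

        state.x = x_tv
        state.iteration = w
        done += 1
        trace.append(
            IterRecord(
                iteration=w,
                dd=dd,
                awtv=awtv_norm(x_tv.reshape(geom.volume_shape), params.delta),
                beta=beta_used,
                eta=eta,
                c=c,
            )
        )

        if state.beta < params.beta_floor:
            stop_reason = "beta_floor"
            break
        if c < params.c_threshold and dd <= params.epsilon:
            stop_reason = "converged_c_dd"
            break

    return ReconResult(
        image=ImageVolume(state.x.reshape(geom.volume_shape), geom.voxel_size),
        trace=trace,
        stop_reason=stop_reason,
        state=state,
    )


# ---------------------------------------------------------------------------
# CGLS


def cgls(
    b: ProjectionSet,
    geom: ScanGeometry,
    n_iter: int,
    x0: ImageVolume | None = None,
) -> ImageVolume:
    """Conjugate gradient on the least-squares problem ``min ||A x - b||``
    using the matched projector pair."""
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    a_full = system_matrix(geom)
    b_flat = b.values.ravel()
    if x0 is None:
        x = np.zeros(geom.n_voxels)
    else:
        _check_pair(x0, b, geom)
        x = x0.values.ravel().astype(np.float64).copy()
    r = b_flat - a_full @ x
    s = a_full.T @ r
    p = s.copy()
    gamma = float(s @ s)
    for _ in range(n_iter):
        if gamma == 0.0:
            break
        q = a_full @ p
        qq = float(q @ q)
        if qq == 0.0:
            break
        alpha = gamma / qq
        x += alpha * p
        r -= alpha * q
        s = a_full.T @ r
        gamma_new = float(s @ s)
        p = s + (gamma_new / gamma) * p
        gamma = gamma_new
    return ImageVolume(x.reshape(geom.volume_shape), geom.voxel_size)
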