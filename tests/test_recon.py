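"""Solver tests: SART/OS-SART, AwTV norm/gradient, the alternating TV
solver and CGLS, each against independent oracles (dense linear algebra,
finite differences, closed forms)."""

from __future__ import annotations

import numpy as np
import pytest

import acoct as a
from acoct.geometry import system_matrix
from acoct.recon import AwpcsdParams, awpcsd, awtv_gradient, awtv_norm, tv_descent


def _zero_vol(geom):
    return a.ImageVolume(np.zeros(geom.volume_shape), geom.voxel_size)


def _residual(x, b, geom):
    return np.linalg.norm(system_matrix(geom) @ x.values.ravel() - b.values.ravel())


# ---------------------------------------------------------------------------
# SART


def test_sart_zero_residual_is_fixed_point(par16, rng):
    x = a.ImageVolume(rng.random(par16.volume_shape), par16.voxel_size)
    b = a.forward_project(x, par16)
    out = a.sart_sweep(x, b, par16, beta=1.0)
    assert np.allclose(out.values, x.values, atol=1e-12)


def test_sart_one_voxel_exact_in_one_step():
    g = a.ScanGeometry("parallel2d", (0.0,), (1, 1), (2.0, 2.0), (1,), (1.0,))
    length = 2.0
    target = 0.7
    b = a.ProjectionSet(np.array([[target * length]]), g.angles)
    x0 = a.ImageVolume(np.array([[0.1]]), g.voxel_size)
    out = a.sart_sweep(x0, b, g, beta=1.0)
    # x <- x + (b - L x) / L solves the single-ray system exactly
    assert out.values[0, 0] == pytest.approx(target, abs=1e-12)


def test_sart_reduces_residual(phantom32):
    g = a.fan_geometry(n=32, n_views=20)
    truth = a.render_phantom(a.thorax_like_spec((32, 32)))
    b = a.forward_project(truth, g)
    x0 = _zero_vol(g)
    before = _residual(x0, b, g)
    after = _residual(a.sart_sweep(x0, b, g, beta=1.0), b, g)
    assert after < before


def test_sart_rejects_bad_beta(par16):
    b = a.ProjectionSet(np.zeros((par16.n_angles, *par16.detector_pixel_counts)), par16.angles)
    with pytest.raises(ValueError):
        a.sart_sweep(_zero_vol(par16), b, par16, beta=0.0)


# ---------------------------------------------------------------------------
# OS-SART


def test_os_sart_reduces_to_sart(par16, rng):
    b = a.ProjectionSet(rng.random((par16.n_angles, *par16.detector_pixel_counts)), par16.angles)
    x0 = a.ImageVolume(rng.random(par16.volume_shape), par16.voxel_size)
    sweep = a.sart_sweep(x0, b, par16, beta=0.8)
    os1 = a.os_sart(x0, b, par16, n_subsets=par16.n_angles, n_iter=1, beta=0.8)
    assert np.array_equal(sweep.values, os1.values)


def test_os_sart_single_subset_reduces_residual(par16):
    truth = a.render_phantom(a.thorax_like_spec((16, 16)))
    b = a.forward_project(truth, par16)
    out = a.os_sart(_zero_vol(par16), b, par16, n_subsets=1, n_iter=1, beta=0.5)
    assert _residual(out, b, par16) < np.linalg.norm(b.values)


def test_os_sart_deterministic(par16, rng):
    b = a.ProjectionSet(rng.random((par16.n_angles, *par16.detector_pixel_counts)), par16.angles)
    r1 = a.os_sart(_zero_vol(par16), b, par16, n_subsets=5, n_iter=2)
    r2 = a.os_sart(_zero_vol(par16), b, par16, n_subsets=5, n_iter=2)
    assert np.array_equal(r1.values, r2.values)


def test_os_sart_rejects_too_many_subsets(par16):
    b = a.ProjectionSet(np.zeros((par16.n_angles, *par16.detector_pixel_counts)), par16.angles)
    with pytest.raises(ValueError):
        a.os_sart(_zero_vol(par16), b, par16, n_subsets=par16.n_angles + 1, n_iter=1)


# ---------------------------------------------------------------------------
# delta estimation


def test_estimate_delta_uniform_disk():
    g = a.fan_geometry(n=32, n_views=40)
    from acoct.phantoms import Ellipse

    v = 0.01
    disk = a.PhantomSpec((Ellipse((0.0, 0.0), (0.35, 0.35), v),), (32, 32))
    b = a.forward_project(a.render_phantom(disk), g)
    delta = a.estimate_delta(b, g)
    assert abs(delta - v) / v < 0.2


def test_estimate_delta_zero_projections_floor():
    g = a.fan_geometry(n=16, n_views=10)
    b = a.ProjectionSet(np.zeros((g.n_angles, *g.detector_pixel_counts)), g.angles)
    assert a.estimate_delta(b, g) == pytest.approx(1e-8)


# ---------------------------------------------------------------------------
# AwTV norm and gradient


def test_awtv_constant_image_zero():
    assert a.awtv_norm(np.full((8, 8), 3.2), delta=0.1) == 0.0


def _isotropic_tv(arr: np.ndarray) -> float:
    """Independent isotropic TV: backward differences, zero boundary."""
    total = np.zeros_like(arr, dtype=float)
    for ax in range(arr.ndim):
        d = np.zeros_like(arr, dtype=float)
        sl = [slice(None)] * arr.ndim
        sl[ax] = slice(1, None)
        d[tuple(sl)] = np.diff(arr, axis=ax)
        total += d * d
    return float(np.sqrt(total).sum())


def test_awtv_large_delta_matches_isotropic_tv(rng):
    arr = rng.random((12, 12))
    got = a.awtv_norm(arr, delta=1e9)
    expected = _isotropic_tv(arr)
    assert abs(got - expected) <= 1e-9 * expected


def test_awtv_two_pixel_formula():
    t, delta = 0.37, 0.5
    val = a.awtv_norm(np.array([0.0, t]), delta=delta)
    # direct evaluation: single difference t with weight exp(-(t/delta)^2)
    w = np.exp(-((t / delta) ** 2))
    assert val == pytest.approx(np.sqrt(w * t * t), rel=1e-12)


def test_awtv_gradient_constant_zero():
    g = awtv_gradient(np.full((6, 6), 1.7), delta=0.1, mu=1e-8)
    assert np.allclose(g, 0.0, atol=1e-12)


def _frozen_smoothed_awtv(arr, base, delta, mu):
    """AwTV with weights frozen at ``base`` and smoothed sqrt (the function
    whose analytic gradient awtv_gradient claims to compute)."""
    total = np.full(arr.shape, mu * mu, dtype=float)
    for ax in range(arr.ndim):
        d = np.zeros_like(arr, dtype=float)
        db = np.zeros_like(base, dtype=float)
        sl = [slice(None)] * arr.ndim
        sl[ax] = slice(1, None)
        d[tuple(sl)] = np.diff(arr, axis=ax)
        db[tuple(sl)] = np.diff(base, axis=ax)
        w = np.exp(-((db / delta) ** 2))
        total += w * d * d
    return float(np.sqrt(total).sum())


def test_awtv_gradient_matches_finite_differences(rng):
    arr = rng.random((8, 8))
    delta, mu = 0.3, 1e-3
    grad = awtv_gradient(arr, delta=delta, mu=mu)
    h = 1e-6
    num = np.zeros_like(arr)
    for idx in np.ndindex(*arr.shape):
        up = arr.copy(); up[idx] += h
        dn = arr.copy(); dn[idx] -= h
        num[idx] = (
            _frozen_smoothed_awtv(up, arr, delta, mu)
            - _frozen_smoothed_awtv(dn, arr, delta, mu)
        ) / (2 * h)
    scale = np.abs(num).max()
    assert np.max(np.abs(grad - num)) / scale < 1e-4


def test_awtv_gradient_odd_symmetry(rng):
    arr = rng.standard_normal((7, 7))
    g1 = awtv_gradient(arr, delta=0.4, mu=1e-6)
    g2 = awtv_gradient(-arr, delta=0.4, mu=1e-6)
    assert np.allclose(g1, -g2, atol=1e-12)


def test_awtv_gradient_finite_everywhere(rng):
    arr = np.zeros((6, 6))  # zero gradient region exercises the smoothing
    assert np.all(np.isfinite(awtv_gradient(arr, delta=0.1)))


# ---------------------------------------------------------------------------
# TV descent


def test_tv_descent_constant_unchanged():
    x = a.ImageVolume(np.full((8, 8), 2.0), (1.0, 1.0))
    out = tv_descent(x, delta=0.1, ng=5, eta=0.5)
    assert np.array_equal(out.values, x.values)


def test_tv_descent_step_norm_is_eta(rng):
    x = a.ImageVolume(rng.random((10, 10)), (1.0, 1.0))
    eta = 0.01
    out = tv_descent(x, delta=0.5, ng=1, eta=eta)
    assert np.linalg.norm(out.values - x.values) == pytest.approx(eta, rel=1e-9)


def test_tv_descent_decreases_awtv(rng):
    arr = rng.random((16, 16))
    x = a.ImageVolume(arr, (1.0, 1.0))
    delta = 0.5
    eta = 0.1 * np.linalg.norm(arr) / 1000.0
    out = tv_descent(x, delta=delta, ng=10, eta=eta)
    assert a.awtv_norm(out.values, delta) < a.awtv_norm(arr, delta)


# ---------------------------------------------------------------------------
# nonneg projection


def test_nonneg_project():
    x = a.ImageVolume(np.array([[1.0, -2.0], [0.0, -0.5]]), (1.0, 1.0))
    out = a.nonneg_project(x)
    assert np.array_equal(out.values, [[1.0, 0.0], [0.0, 0.0]])
    assert np.array_equal(a.nonneg_project(out).values, out.values)
    pos = a.ImageVolume(np.abs(x.values) + 0.1, (1.0, 1.0))
    assert np.array_equal(a.nonneg_project(pos).values, pos.values)
    neg = a.ImageVolume(-np.abs(x.values) - 0.1, (1.0, 1.0))
    assert not a.nonneg_project(neg).values.any()


# ---------------------------------------------------------------------------
# AwPCSD


def test_awpcsd_huge_epsilon_is_tv_only(noisy32):
    truth, geom, b = noisy32
    params = AwpcsdParams(epsilon=1e12, ng=3, max_iter=4, delta=0.01)
    x0 = a.ImageVolume(np.abs(np.random.default_rng(0).random(geom.volume_shape)) * 0.01,
                       geom.voxel_size)
    res = awpcsd(x0, b, geom, params)
    # replicate the TV-only evolution: no SART, POCS no-op on nonneg input,
    # eta frozen at 1 because dd_first^2 <= epsilon
    x = x0
    for _ in range(4):
        x = tv_descent(a.nonneg_project(x), params.delta, params.ng, 1.0)
    assert np.allclose(res.image.values, x.values, atol=1e-12)


def test_awpcsd_beta_decays_geometrically(noisy32):
    truth, geom, b = noisy32
    params = AwpcsdParams(epsilon=0.0, ng=2, beta=1.0, beta_red=0.95, max_iter=6, delta=0.01)
    res = awpcsd(None, b, geom, params)
    betas = [r.beta for r in res.trace]
    assert betas == pytest.approx([0.95**i for i in range(6)], rel=1e-12)


def test_awpcsd_improves_over_first_iteration(scan32):
    # k scales the TV step to the desk-scale image norm (~0.34 here)
    truth, geom, b = scan32
    params = AwpcsdParams(epsilon=1e-6, ng=10, max_iter=30, delta=0.02, k=0.1)
    res1 = awpcsd(None, b, geom, params, n_outer=1)
    res30 = awpcsd(None, b, geom, params)
    from acoct.metrics import relative_error

    assert relative_error(res30.image, truth) < relative_error(res1.image, truth)


def test_awpcsd_warm_start_equals_single_run(noisy32):
    truth, geom, b = noisy32
    params = AwpcsdParams(epsilon=0.0, ng=3, max_iter=12, delta=0.02)
    full = awpcsd(None, b, geom, params)
    part = awpcsd(None, b, geom, params, n_outer=5)
    resumed = awpcsd(None, b, geom, params, state=part.state)
    assert np.array_equal(resumed.image.values, full.image.values)
    combined = part.trace + resumed.trace
    assert [r.dd for r in combined] == [r.dd for r in full.trace]


def test_awpcsd_stops_on_beta_floor(noisy32):
    truth, geom, b = noisy32
    params = AwpcsdParams(epsilon=0.0, ng=1, beta=1.0, beta_red=0.3,
                          beta_floor=0.05, max_iter=100, delta=0.01)
    res = awpcsd(None, b, geom, params)
    assert res.stop_reason == "beta_floor"
    # stops no later than beta0 * beta_red^n < floor
    import math

    bound = math.ceil(math.log(0.05) / math.log(0.3))
    assert len(res.trace) <= bound


def test_awpcsd_plain_tv_limit(rng):
    # with delta -> inf the TV phase must match an independent plain-TV
    # descent step for step
    arr = rng.random((12, 12))
    x = a.ImageVolume(arr, (1.0, 1.0))
    delta = 1e9
    mu = 1e-8
    ng, eta = 4, 0.01
    ours = tv_descent(x, delta, ng, eta, mu=mu)

    cur = arr.copy()
    for _ in range(ng):
        # plain smoothed isotropic TV gradient (independent implementation)
        total = np.full(cur.shape, mu * mu)
        diffs = []
        for ax in range(cur.ndim):
            d = np.zeros_like(cur)
            sl = [slice(None)] * cur.ndim
            sl[ax] = slice(1, None)
            d[tuple(sl)] = np.diff(cur, axis=ax)
            diffs.append(d)
            total += d * d
        phi = np.sqrt(total)
        s = np.zeros_like(cur)
        for ax, d in enumerate(diffs):
            flux = d / phi
            s += flux
            sl_hi = [slice(None)] * cur.ndim
            sl_lo = [slice(None)] * cur.ndim
            sl_hi[ax] = slice(1, None)
            sl_lo[ax] = slice(None, -1)
            s[tuple(sl_lo)] -= flux[tuple(sl_hi)]
        cur = cur - eta * s / np.linalg.norm(s)
    assert np.max(np.abs(ours.values - cur)) < 1e-9


def test_awpcsd_rejects_invalid_params():
    with pytest.raises(ValueError):
        AwpcsdParams(epsilon=-1.0, ng=5)
    with pytest.raises(ValueError):
        AwpcsdParams(epsilon=0.0, ng=0)
    with pytest.raises(ValueError):
        AwpcsdParams(epsilon=0.0, ng=5, beta=1.5)
    with pytest.raises(ValueError):
        AwpcsdParams(epsilon=0.0, ng=5, beta_red=1.0)
    with pytest.raises(ValueError):
        AwpcsdParams(epsilon=0.0, ng=5, delta=0.0)


# ---------------------------------------------------------------------------
# CGLS


def test_cgls_zero_data_zero_image(par16):
    b = a.ProjectionSet(np.zeros((par16.n_angles, *par16.detector_pixel_counts)), par16.angles)
    out = a.cgls(b, par16, n_iter=10)
    assert not out.values.any()


def test_cgls_matches_normal_equations(rng):
    # sub-voxel detector pitch keeps the dense system well conditioned
    g = a.parallel_geometry(n=8, n_views=12, start=13.31,
                            detector_count=24, detector_pitch=0.6)
    dense = system_matrix(g).toarray()
    assert np.linalg.matrix_rank(dense) == dense.shape[1]  # full column rank
    y = rng.random((g.n_angles, *g.detector_pixel_counts))
    x_ls = np.linalg.solve(dense.T @ dense, dense.T @ y.ravel())
    x_cgls = a.cgls(a.ProjectionSet(y, g.angles), g, n_iter=200).values.ravel()
    assert np.linalg.norm(x_cgls - x_ls) / np.linalg.norm(x_ls) < 1e-6


def test_cgls_residual_nonincreasing(rng):
    g = a.fan_geometry(n=12, n_views=8, start=3.7)
    b = a.ProjectionSet(rng.random((g.n_angles, *g.detector_pixel_counts)), g.angles)
    prev = np.inf
    for k in range(1, 8):
        x = a.cgls(b, g, n_iter=k)
        r = _residual(x, b, g)
        assert r <= prev + 1e-10
        prev = r
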