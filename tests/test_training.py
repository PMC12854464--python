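"""Training objective, Sinkhorn loss, sampling, and the fit loop."""

import numpy as np
import pytest

from snapdyn.drift import ArchConfig, DriftModel, init_params
from snapdyn.evaluation import wasserstein_distance
from snapdyn.training import (Adam, LossBreakdown, TrainConfig, action_cost,
                              clip_grads, compute_loss, fit, sample_batch,
                              sinkhorn_w2, training_step)
from snapdyn._autodiff import Tensor


class TestActionCost:
    def test_zero_drifts(self):
        assert action_cost(np.zeros((4, 10, 2)), 0.1) == 0.0

    def test_constant_drift_magnitude(self):
        # |f| = c throughout total time T gives c^2 T
        c, n_steps, dt = 1.5, 20, 0.05
        drifts = np.zeros((n_steps, 7, 2))
        drifts[:, :, 0] = c
        assert np.isclose(action_cost(drifts, dt), c * c * n_steps * dt)

    def test_matches_loop_reference(self, rng):
        drifts = rng.standard_normal((6, 5, 3))
        dts = rng.uniform(0.05, 0.2, size=6)
        ref = 0.0
        for k in range(6):
            for i in range(5):
                ref += np.sum(drifts[k, i] ** 2) / 5 * dts[k]
        assert np.isclose(action_cost(drifts, dts), ref)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            action_cost(np.zeros((0, 5, 2)), 0.1)


class TestSinkhorn:
    def test_identical_clouds_near_zero(self, rng):
        X = rng.standard_normal((15, 2))
        assert sinkhorn_w2(X, X, blur=0.1) < 1e-4

    def test_point_masses_recover_distance(self):
        a, b = np.array([[0.0, 0.0]]), np.array([[3.0, 4.0]])
        assert np.isclose(sinkhorn_w2(a, b, blur=0.01), 5.0, rtol=1e-3)

    def test_symmetry_and_nonnegativity(self, rng):
        A, B = rng.standard_normal((12, 3)), rng.standard_normal((9, 3)) + 1
        s1, s2 = sinkhorn_w2(A, B), sinkhorn_w2(B, A)
        assert np.isclose(s1, s2, rtol=1e-10)
        assert s1 >= 0

    def test_approaches_exact_w2_at_small_blur(self, rng):
        A = rng.standard_normal((20, 2))
        B = rng.standard_normal((20, 2)) + 0.8
        exact = wasserstein_distance(A, B, p=2)
        approx = sinkhorn_w2(A, B, blur=0.01)
        assert abs(approx - exact) / exact < 0.05

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            sinkhorn_w2(np.zeros((0, 2)), np.zeros((3, 2)))


class TestSampleBatch:
    def test_full_batch_is_permutation(self, rng):
        snap = rng.standard_normal((10, 2))
        batch = sample_batch(snap, 10, rng)
        assert np.allclose(np.sort(batch, axis=0), np.sort(snap, axis=0))

    def test_oversampling_uses_replacement(self, rng):
        snap = rng.standard_normal((4, 2))
        batch = sample_batch(snap, 12, rng)
        assert batch.shape == (12, 2)

    def test_uniformity_chi_square(self):
        # frequencies over many draws consistent with uniform multinomial
        from scipy.stats import chisquare

        rng = np.random.default_rng(0)
        snap = np.arange(8, dtype=float).reshape(-1, 1)
        draws = np.concatenate(
            [sample_batch(snap, 4, rng).ravel() for _ in range(2500)])
        counts = np.bincount(draws.astype(int), minlength=8)
        assert chisquare(counts).pvalue > 1e-4

    def test_tiny_batch_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_batch(np.zeros((5, 2)), 1, rng)


def _toy_problem(rng, n_times=3, n_cells=30, d=2):
    times = np.arange(float(n_times))
    snaps = {float(t): rng.standard_normal((n_cells, d)) - 0.3 * t
             for t in times}
    return snaps, times


class TestComputeLoss:
    def test_objective_decomposition(self, rng):
        arch = ArchConfig(d=2, intra_hidden=8, d_ff=8, dropout=0.0)
        params = init_params(arch, rng, zero_final=False)
        params_t = {k: Tensor(v) for k, v in params.items()}
        snaps, times = _toy_problem(rng)
        cfg = TrainConfig(batch_size=8, substeps=3, sigma=0.1, lambda_w=1.7)
        x0 = snaps[0.0][:8]
        observed = {1.0: snaps[1.0][:8], 2.0: snaps[2.0][:8]}
        noise = [rng.standard_normal((8, 2)) for _ in range(6)]
        loss, bd = compute_loss(params_t, arch, x0, observed, times, noise,
                                cfg)
        assert np.isclose(bd.total, bd.action + 1.7 * sum(
            bd.marginal_penalties.values()), atol=1e-6)
        assert np.isclose(loss.item(), bd.total, atol=1e-9)
        assert bd.action >= 0

    def test_zero_init_with_zero_lambda_gives_zero_loss(self, rng):
        arch = ArchConfig(d=2, intra_hidden=8, d_ff=8, dropout=0.0)
        params = init_params(arch, rng, zero_final=True)
        params_t = {k: Tensor(v) for k, v in params.items()}
        snaps, times = _toy_problem(rng)
        cfg = TrainConfig(batch_size=8, substeps=2, sigma=0.0, lambda_w=0.0)
        loss, bd = compute_loss(params_t, arch, snaps[0.0][:8],
                                {1.0: snaps[1.0][:8], 2.0: snaps[2.0][:8]},
                                times, None, cfg)
        assert loss.item() == 0.0
        loss.backward()
        assert np.all(params_t["intra.W2"].grad == 0.0)
        assert np.all(params_t["ffn.W2"].grad == 0.0)

    def test_gradients_match_finite_differences(self, rng):
        # the full objective (unrolled solver + Sinkhorn) on a tiny problem
        arch = ArchConfig(d=2, intra_hidden=4, d_ff=4, dropout=0.0, n_heads=2)
        params = init_params(arch, rng, zero_final=False)
        snaps, times = _toy_problem(rng, n_cells=5)
        cfg = TrainConfig(batch_size=5, substeps=2, sigma=0.1, lambda_w=1.0)
        x0 = snaps[0.0][:5]
        observed = {1.0: snaps[1.0][:5], 2.0: snaps[2.0][:5]}
        noise = [rng.standard_normal((5, 2)) for _ in range(4)]

        def loss_value(p):
            pt = {k: Tensor(v) for k, v in p.items()}
            return compute_loss(pt, arch, x0, observed, times, noise,
                                cfg)[0].item()

        params_t = {k: Tensor(v) for k, v in params.items()}
        loss, _ = compute_loss(params_t, arch, x0, observed, times, noise,
                               cfg)
        loss.backward()
        checked = bad = 0
        for key in params:
            flat = params[key].ravel()
            stride = max(1, flat.size // 6)  # spot-check a few per array
            for idx in range(0, flat.size, stride):
                h = 1e-6 * max(1.0, abs(flat[idx]))
                pp = {k: v.copy() for k, v in params.items()}
                pp[key].ravel()[idx] += h
                pm = {k: v.copy() for k, v in params.items()}
                pm[key].ravel()[idx] -= h
                fd = (loss_value(pp) - loss_value(pm)) / (2 * h)
                an = params_t[key].grad.ravel()[idx]
                checked += 1
                if abs(an - fd) > 1e-3 * max(1.0, abs(fd)):
                    bad += 1
        assert checked >= 40
        assert bad == 0


class TestFit:
    def test_loss_decreases_on_easy_problem(self, ou_series):
        series, _ = ou_series
        arch = ArchConfig(d=2, intra_hidden=16, d_ff=16)
        cfg = TrainConfig(batch_size=32, n_iterations=40, substeps=3)
        snaps = {float(t): series.snapshots[float(t)] for t in series.times}
        _, hist = fit(snaps, series.times, arch, cfg, seed=0)
        first = np.median([h.total for h in hist[:4]])
        last = np.median([h.total for h in hist[-4:]])
        assert last < first

    def test_same_seed_same_parameters(self, ou_series):
        series, _ = ou_series
        arch = ArchConfig(d=2, intra_hidden=8, d_ff=8)
        cfg = TrainConfig(batch_size=16, n_iterations=5, substeps=2)
        snaps = {float(t): series.snapshots[float(t)] for t in series.times}
        m1, h1 = fit(snaps, series.times, arch, cfg, seed=123)
        m2, h2 = fit(snaps, series.times, arch, cfg, seed=123)
        for k in m1.params:
            np.testing.assert_array_equal(m1.params[k], m2.params[k])
        assert [h.total for h in h1] == [h.total for h in h2]

    def test_gradient_clipping_bound_holds(self, ou_series):
        series, _ = ou_series
        arch = ArchConfig(d=2, intra_hidden=8, d_ff=8)
        cfg = TrainConfig(batch_size=16, n_iterations=8, substeps=2,
                          grad_clip_max_norm=0.1)
        snaps = {float(t): series.snapshots[float(t)] for t in series.times}
        _, hist = fit(snaps, series.times, arch, cfg, seed=1)
        for bd in hist:
            assert bd.grad_norm <= 0.1 + 1e-8

    def test_needs_two_time_points(self, rng):
        arch = ArchConfig(d=2)
        with pytest.raises(ValueError):
            fit({0.0: rng.standard_normal((5, 2))}, [0.0], arch,
                TrainConfig())


def test_clip_grads_scales_to_max_norm(rng):
    grads = {"a": rng.standard_normal((3, 3)) * 10,
             "b": rng.standard_normal(4) * 10}
    norm = clip_grads(grads, 0.1)
    total = np.sqrt(sum(np.sum(g * g) for g in grads.values()))
    assert np.isclose(norm, 0.1)
    assert np.isclose(total, 0.1)


def test_batch_subsample_sinkhorn_noise_floor_shrinks_with_batch():
    # two independent subsamples of one snapshot get closer as B grows
    rng = np.random.default_rng(2)
    snap = rng.standard_normal((4000, 2))
    means = []
    for b in (32, 128, 512):
        vals = [sinkhorn_w2(sample_batch(snap, b, rng),
                            sample_batch(snap, b, rng), blur=0.1)
                for _ in range(3)]
        means.append(np.mean(vals))
    assert means[0] > means[1] > means[2]
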