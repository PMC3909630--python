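"""Likelihood, update rules, fixed points and the iteration driver."""

import numpy as np
import pytest
from scipy.optimize import brentq, root
from scipy.special import gammaln

from spectrecon import (
    AcquisitionGeometry,
    AttenuationMap,
    GridSpec,
    ReconConfig,
    attenuate_system_matrix,
    build_system_matrix,
    conventional_update,
    forward_project,
    log_likelihood,
    log_likelihood_gradient,
    mlem_update,
    proposed_update,
    reconstruct,
)

from conftest import random_poisson_system


class TestLogLikelihood:
    def test_empty_data_zero(self):
        A = np.ones((3, 2))
        assert log_likelihood(np.zeros(2), A, np.zeros(3), 0.0) == 0.0

    def test_single_bin_hand_value(self):
        # g = 5, model mean 5: Poisson log-pmf 5 ln5 - 5 - ln(5!)
        A = np.array([[1.0]])
        expected = 5 * np.log(5) - 5 - gammaln(6.0)
        assert log_likelihood([5.0], A, [5.0], 0.0) == pytest.approx(expected)

    def test_scalar_scale_maximised_at_count_match(self, rng):
        A, _, f_true, g = random_poisson_system(rng)
        sens_counts = (A @ f_true).sum()
        # L(c f) over c > 0 peaks where total model counts = total observed
        c_star = g.sum() / sens_counts

        def dL(c):
            return float(f_true @ log_likelihood_gradient(c * f_true, A, g))

        c_root = brentq(dL, 1e-3, 1e3)
        assert c_root == pytest.approx(c_star, rel=1e-10)

    def test_impossible_data_raises(self):
        A = np.array([[1.0]])
        with pytest.raises(ValueError):
            log_likelihood([0.0], A, [3.0], 0.0)

    def test_gradient_matches_finite_differences(self, rng):
        # the scatter-aware score: SC = beta f varies with f
        A, beta, _, g = random_poisson_system(rng, n=20, m=8, scatter=True)
        f = rng.uniform(0.5, 3.0, 8)
        grad = log_likelihood_gradient(f, A, g, beta)
        eps = 1e-6
        for j in range(8):
            fp, fm = f.copy(), f.copy()
            fp[j] += eps
            fm[j] -= eps
            num = (
                log_likelihood(fp, A, g, beta @ fp)
                - log_likelihood(fm, A, g, beta @ fm)
            ) / (2 * eps)
            assert grad[j] == pytest.approx(num, rel=1e-6, abs=1e-8)


class TestMlemUpdate:
    def test_one_pixel_closed_form(self):
        assert mlem_update([1.0], np.array([[1.0]]), [5.0]) == pytest.approx([5.0])

    def test_fixed_point_of_consistent_solution(self, rng):
        A, _, f_true, _ = random_poisson_system(rng)
        g = A @ f_true  # noise-free consistent data
        assert mlem_update(f_true, A, g) == pytest.approx(f_true, rel=1e-12)

    def test_count_preservation(self, rng):
        A, _, _, g = random_poisson_system(rng, n=30, m=64)
        f = np.ones(64)
        sens = A.sum(axis=0)
        for _ in range(20):
            f = mlem_update(f, A, g)
            assert (sens * f).sum() == pytest.approx(g.sum(), rel=1e-12)

    def test_nonnegative_and_finite(self, rng):
        A, _, _, g = random_poisson_system(rng)
        f = np.ones(A.shape[1])
        for _ in range(100):
            f = mlem_update(f, A, g)
        assert np.all(f >= 0) and np.all(np.isfinite(f))


class TestConventionalUpdate:
    def test_reduces_to_mlem_without_scatter(self, rng):
        A, _, _, g = random_poisson_system(rng)
        f = rng.uniform(0.5, 2.0, A.shape[1])
        assert conventional_update(f, A, g, np.zeros(len(g))) == pytest.approx(
            mlem_update(f, A, g), rel=1e-14
        )

    def test_one_pixel_closed_form(self):
        out = conventional_update([1.0], np.array([[1.0]]), [5.0], [1.0])
        assert out == pytest.approx([2.5])

    def test_monotone_likelihood_fixed_scatter(self, rng):
        for trial in range(5):
            A, beta, f_true, g = random_poisson_system(rng, scatter=True)
            SC = beta @ f_true  # fixed additive term
            f = np.ones(A.shape[1])
            prev = -np.inf
            for _ in range(50):
                f = conventional_update(f, A, g, SC)
                ll = log_likelihood(f, A, g, SC)
                assert ll >= prev - 1e-9 * abs(prev)
                prev = ll


class TestProposedUpdate:
    def test_reduces_to_mlem_when_no_scatter(self, rng):
        for _ in range(20):
            A, _, _, g = random_poisson_system(rng)
            f = rng.uniform(0.5, 2.0, A.shape[1])
            beta = np.zeros_like(A)
            lhs = proposed_update(f, A, g, np.zeros(len(g)), beta)
            rhs = mlem_update(f, A, g)
            assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_one_pixel_closed_form(self):
        # a=1, beta=0.5, f0=1 (SC=0.5), g=6: f1 = 6*1.5/1.5 - 0.5 = 5.5
        out = proposed_update(
            [1.0], np.array([[1.0]]), [6.0], [0.5], np.array([[0.5]])
        )
        assert out == pytest.approx([5.5])

    def test_stationary_point_is_fixed_point(self):
        # 2-pixel / 3-bin system: root of the score is a fixed point
        rng = np.random.default_rng(7)
        A = rng.uniform(0.2, 1.0, size=(3, 2))
        beta = rng.uniform(0.05, 0.3, size=(3, 2))
        f_true = np.array([4.0, 2.5])
        g = (A + beta) @ f_true + rng.uniform(0.1, 0.5, 3)

        sol = root(
            lambda f: log_likelihood_gradient(f, A, g, beta), x0=np.array([1.0, 1.0]),
            tol=1e-14,
        )
        assert sol.success
        f_star = sol.x
        assert np.all(f_star > 0)
        out = proposed_update(f_star, A, g, beta @ f_star, beta, clamp_negative=False)
        assert out == pytest.approx(f_star, rel=1e-8)

    def test_clamps_negative_pixels(self):
        # large beta column sum forces a negative numerator for a cold pixel
        A = np.array([[1.0, 0.0], [0.0, 1.0]])
        beta = np.array([[0.0, 5.0], [0.0, 5.0]])
        g = np.array([1.0, 1.0])
        f = np.array([1.0, 0.5])
        out = proposed_update(f, A, g, beta @ f, beta)
        assert np.all(out >= 0)
        raw = proposed_update(f, A, g, beta @ f, beta, clamp_negative=False)
        assert raw.min() < 0  # the clamp actually did something


class TestReconstructDriver:
    def _system(self):
        grid = GridSpec(16, 16, 1, 1.0, 1.0)
        geom = AcquisitionGeometry(16, 1.0, tuple(np.arange(20) * 18.0))
        A = build_system_matrix(grid, geom)
        return grid, geom, A

    def test_point_source_localised(self):
        grid, geom, A = self._system()
        f = np.zeros((16, 16))
        f[5, 9] = 2.0
        g = forward_project(A, f).flat
        res = reconstruct(g, A, None, ReconConfig(method="uncorrected", iterations=40))
        assert np.unravel_index(np.argmax(res.image), res.image.shape) == (5, 9)

    def test_att_cor_noise_free_recovery(self):
        # smooth activity (MLEM recovers low frequencies quickly)
        grid, geom, A = self._system()
        mu = AttenuationMap(np.full((16, 16), 0.1), grid)
        Am = attenuate_system_matrix(A, mu)
        yy, xx = np.meshgrid(np.arange(16), np.arange(16), indexing="ij")
        f = 1.0 + 4.0 * np.exp(-((xx - 9.0) ** 2 + (yy - 6.0) ** 2) / 18.0)
        g = Am.matrix @ f.ravel()
        res = reconstruct(g, Am, None, ReconConfig(method="att_cor", iterations=300))
        nmse = np.sum((res.image - f) ** 2) / np.sum(f**2)
        assert nmse < 0.01

    def test_likelihood_trace_non_decreasing(self):
        grid, geom, A = self._system()
        rng = np.random.default_rng(5)
        f = rng.uniform(0.5, 2.0, size=(16, 16))
        g = rng.poisson(A.matrix @ f.ravel()).astype(float)
        res = reconstruct(g, A, None, ReconConfig(method="uncorrected", iterations=50))
        ll = np.array(res.log_likelihood)
        assert np.all(np.diff(ll) >= -1e-9 * np.abs(ll[:-1]))

    def test_method_input_mismatch_rejected(self):
        grid, geom, A = self._system()
        g = np.ones(A.shape[0])
        with pytest.raises(ValueError):
            reconstruct(g, A, None, ReconConfig(method="att_cor"))
        with pytest.raises(ValueError):
            reconstruct(g, A, None, ReconConfig(method="conventional"))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            ReconConfig(method="osem")
        with pytest.raises(ValueError):
            ReconConfig(iterations=0)
        with pytest.raises(ValueError):
            ReconConfig(initial=0.0)
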