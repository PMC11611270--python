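"""Velocity formulas, degradation-rate conversion, evaluation metrics."""

import numpy as np
import pytest

from labelvelo.data_model import Neighborhoods, build_knn
from labelvelo.velocity import (
    consistency,
    correctness,
    gamma_t_from_gamma_s,
    phase_durations,
    velocity_spliced,
    velocity_total,
)


class TestVelocityFormulas:
    def test_steady_balance_is_zero(self):
        v = velocity_total("baseline", np.array([[2.0]]), 0.5, {"total": np.array([[4.0]])})
        assert v[0, 0] == 0.0

    def test_baseline_arithmetic(self):
        v = velocity_total("baseline", np.array([[2.0]]), 0.5, {"total": np.array([[2.0]])})
        assert v[0, 0] == 1.0

    def test_spliced_zero_at_balance(self):
        assert velocity_spliced(np.array([1.0]), 0.5, np.array([1.0]), np.array([2.0]))[0] == 0.0

    def test_spliced_arithmetic(self):
        assert velocity_spliced(np.array([1.0]), 0.5, np.array([2.0]), np.array([2.0]))[0] == 1.0

    def test_total_and_spliced_forms_agree_under_proportionality(self):
        """r = k s exactly with gamma_t = gamma_s / k makes the two total-RNA
        velocity forms identical."""
        rng = np.random.default_rng(0)
        s = rng.uniform(1, 5, (20, 4))
        k = 2.5
        r = k * s
        gamma_s = 1.3
        gamma_t = gamma_s / k
        alpha = rng.uniform(0.5, 2.0, (20, 4))
        v_total_form = velocity_total("baseline", alpha, gamma_t, {"total": r})
        v_spliced_form = velocity_total("splicing", alpha, gamma_s, {"spliced": s})
        np.testing.assert_allclose(v_total_form, v_spliced_form, atol=1e-12)

    def test_missing_layer_raises(self):
        with pytest.raises(ValueError, match="layer"):
            velocity_total("baseline", np.ones((2, 2)), 0.5, {})


class TestGammaConversion:
    def test_exact_proportionality(self):
        s = np.linspace(1, 5, 30)[:, None]
        k, gamma_t = gamma_t_from_gamma_s(2 * s, s, 1.0)
        assert k[0] == pytest.approx(2.0)
        assert gamma_t[0] == pytest.approx(0.5)

    def test_slope_matches_bruteforce_least_squares(self):
        rng = np.random.default_rng(1)
        s = rng.uniform(0.5, 4, 100)
        r = 1.7 * s + rng.normal(0, 0.2, 100)
        k, _ = gamma_t_from_gamma_s(r, s, 1.0)
        grid = np.linspace(1.0, 2.5, 2001)
        losses = [((r - kk * s) ** 2).sum() for kk in grid]
        assert k == pytest.approx(grid[int(np.argmin(losses))], abs=grid[1] - grid[0])

    def test_gamma_t_below_gamma_s_when_spliced_below_total(self):
        rng = np.random.default_rng(2)
        s = rng.uniform(0.5, 4, (200, 3))
        r = s + rng.uniform(0.1, 2, (200, 3))  # total strictly above spliced
        k, gamma_t = gamma_t_from_gamma_s(r, s, 1.0)
        assert np.all(k >= 1)
        assert np.all(gamma_t <= 1.0)

    def test_zero_spliced_rejected(self):
        with pytest.raises(ValueError):
            gamma_t_from_gamma_s(np.ones(5), np.zeros(5), 1.0)


class TestCorrectness:
    def test_forward_line(self):
        # interior cells extrapolate onto their forward neighbor; the last
        # cell has no forward neighbor (nearest j != i ranks earlier), so the
        # boundary cell is scored incorrect by construction
        x = np.array([[0.0], [1.0], [2.0]])
        v = np.ones((3, 1))
        per_cell, avg = correctness(x, v, np.array([0, 1, 2]))
        np.testing.assert_array_equal(per_cell, [1.0, 1.0, 0.0])
        assert avg == pytest.approx(2 / 3)

    def test_backward_line(self):
        # mirrored: only the first cell's backward extrapolation finds a
        # later-ranked nearest neighbor (there is nothing behind it)
        x = np.array([[0.0], [1.0], [2.0]])
        v = -np.ones((3, 1))
        per_cell, avg = correctness(x, v, np.array([0, 1, 2]))
        np.testing.assert_array_equal(per_cell, [1.0, 0.0, 0.0])
        assert avg == pytest.approx(1 / 3)

    def test_matches_bruteforce_loop(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(40, 3))
        v = rng.normal(size=(40, 3)) * 0.5
        order = rng.permutation(40).astype(float)
        per_cell, avg = correctness(x, v, order)
        for i in range(40):
            target = x[i] + v[i]
            d = np.linalg.norm(x - target, axis=1)
            d[i] = np.inf
            j = int(np.argmin(d))
            assert per_cell[i] == float(order[j] > order[i])

    def test_needs_two_cells(self):
        with pytest.raises(ValueError):
            correctness(np.zeros((1, 2)), np.zeros((1, 2)), np.zeros(1))


class TestConsistency:
    def test_identical_velocities_score_one(self):
        v = np.tile(np.array([1.0, 2.0, 3.0]), (5, 1))
        nb = Neighborhoods(indices=[np.arange(5)] * 5)
        scores, avg = consistency(v, nb)
        np.testing.assert_allclose(scores, 1.0)
        assert avg == pytest.approx(1.0)

    def test_anticorrelated_neighbors_score_minus_one(self):
        v = np.array([[1.0, -1.0, 2.0], [-1.0, 1.0, -2.0]])
        nb = Neighborhoods(indices=[np.array([1]), np.array([0])])
        scores, _ = consistency(v, nb)
        np.testing.assert_allclose(scores, -1.0)

    def test_matches_bruteforce_correlation(self):
        rng = np.random.default_rng(4)
        v = rng.normal(size=(30, 8))
        nb = build_knn(rng.normal(size=(30, 2)), k=5)
        scores, _ = consistency(v, nb)
        for j in range(30):
            ref = v[nb[j]].mean(axis=0)
            expected = np.corrcoef(v[j], ref)[0, 1]
            assert scores[j] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_cell_excluded(self):
        v = np.vstack([np.ones(4), np.random.default_rng(5).normal(size=(3, 4))])
        nb = Neighborhoods(indices=[np.arange(4)] * 4)
        scores, avg = consistency(v, nb)
        assert np.isnan(scores[0])
        assert np.isfinite(avg)


class TestPhaseDurations:
    @staticmethod
    def circle(n=6000, omega=2 * np.pi / 21, seed=2):
        rng = np.random.default_rng(seed)
        theta = rng.uniform(0, 2 * np.pi, n)
        pos = np.stack([np.cos(theta), np.sin(theta)], axis=1)
        vel = omega * np.stack([-np.sin(theta), np.cos(theta)], axis=1)
        relpos = theta / (2 * np.pi)
        bound = 0.44 * 2 * np.pi  # both phases fully inside the 88% stop rule
        phases = np.where(theta < bound, "A", np.where(theta < 2 * bound, "B", "C"))
        return pos, vel, phases, relpos, omega, bound

    def test_constant_angular_speed_recovers_arc_durations(self):
        pos, vel, phases, relpos, omega, bound = self.circle()
        durations = phase_durations(pos, vel, phases, relpos, k=300, dt=0.01)
        expected = bound / omega
        assert durations["A"] == pytest.approx(expected, rel=0.10)
        assert durations["B"] == pytest.approx(expected, rel=0.10)

    def test_step_size_stability(self):
        pos, vel, phases, relpos, *_ = self.circle()
        d1 = phase_durations(pos, vel, phases, relpos, k=300, dt=0.01)
        d2 = phase_durations(pos, vel, phases, relpos, k=300, dt=0.005)
        for phase in ("A", "B"):
            assert abs(d1[phase] - d2[phase]) / d1[phase] < 0.05

    def test_stalled_field_warns_with_partial_result(self):
        pos, _, phases, relpos, *_ = self.circle(n=500)
        with pytest.warns(UserWarning, match="stalled"):
            out = phase_durations(pos, np.zeros_like(pos), phases, relpos, k=100, dt=0.01)
        assert sum(out.values()) == pytest.approx(0.01)

    def test_rejects_out_of_range_positions(self):
        with pytest.raises(ValueError):
            phase_durations(np.zeros((10, 2)), np.zeros((10, 2)), ["A"] * 10, np.ones(10), k=5)
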