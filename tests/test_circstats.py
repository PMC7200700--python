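import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from thetalock.circstats import (
    circ_corr,
    circ_kappa,
    harrison_kanji,
    mean_vector,
    phase_histogram,
    rayleigh_test,
    surrogate_modulation_test,
    tp_index,
    watson_williams,
)

rng = np.random.default_rng(20240917)


def vm(mu_deg, kappa, n, r=rng):
    return np.rad2deg(r.vonmises(np.deg2rad(mu_deg), kappa, n)) % 360.0


class TestPhaseHistogram:
    def test_default_25_bins_counts_sum(self):
        phi = rng.uniform(0, 360, 137)
        h = phase_histogram(phi)
        assert h.size == 25
        assert h.sum() == 137

    def test_one_spike_per_bin_center(self):
        centers = (np.arange(25) + 0.5) * 360.0 / 25.0
        assert np.array_equal(phase_histogram(centers), np.ones(25, dtype=int))

    def test_all_at_zero_fill_first_bin(self):
        h = phase_histogram(np.zeros(11))
        assert h[0] == 11 and h[1:].sum() == 0

    def test_wraparound_boundary(self):
        assert phase_histogram(np.array([359.9]))[-1] == 1

    def test_empty_gives_zero_histogram(self):
        assert phase_histogram(np.array([])).sum() == 0


class TestMeanVector:
    def test_identical_phases_r_one(self):
        r, mu = mean_vector(np.full(10, 123.0))
        assert r == pytest.approx(1.0)
        assert mu == pytest.approx(123.0)

    def test_antipodal_cancellation(self):
        r, _ = mean_vector(np.array([0.0, 180.0]))
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_two_orthogonal_vectors(self):
        r, mu = mean_vector(np.array([0.0, 90.0]))
        assert r == pytest.approx(np.sqrt(2) / 2, rel=1e-12)
        assert mu == pytest.approx(45.0)

    def test_matches_bruteforce_trig_sums(self):
        for _ in range(100):
            phi = rng.uniform(0, 360, rng.integers(2, 200))
            a = np.deg2rad(phi)
            c, s = np.cos(a).sum(), np.sin(a).sum()
            r_ref = np.hypot(c, s) / phi.size
            mu_ref = np.degrees(np.arctan2(s, c)) % 360.0
            r, mu = mean_vector(phi)
            assert r == pytest.approx(r_ref, abs=1e-12)
            assert mu == pytest.approx(mu_ref, abs=1e-9)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        phi = vm(200.0, 3.0, 300)
        r, _ = mean_vector(phi)
        assert r == pytest.approx(float(pingouin.circ_r(np.deg2rad(phi))), abs=1e-10)


class TestRayleigh:
    def test_perfect_locking_tiny_p(self):
        assert rayleigh_test(np.full(100, 40.0)) < 1e-10

    def test_zero_resultant_p_near_one(self):
        phi = np.arange(8) * 45.0
        assert rayleigh_test(phi) > 0.9

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        phi = vm(90.0, 1.0, 80)
        _, p_ref = pingouin.circ_rayleigh(np.deg2rad(phi))
        assert rayleigh_test(phi) == pytest.approx(p_ref, abs=1e-6)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            rayleigh_test(np.array([0.0, 10.0, 20.0]))


class TestTpIndex:
    def test_pure_trough_firing(self):
        assert tp_index(np.zeros(10)) == pytest.approx(1.0)

    def test_pure_peak_firing(self):
        assert tp_index(np.full(10, 180.0)) == pytest.approx(-1.0)

    def test_uniform_near_zero(self):
        assert abs(tp_index(rng.uniform(0, 360, 10_000))) < 0.05

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.floats(min_value=0, max_value=359.99), min_size=1,
                    max_size=50))
    def test_half_cycle_shift_antisymmetry(self, phis):
        phi = np.array(phis)
        assert tp_index(phi) == pytest.approx(-tp_index(phi + 180.0))

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.floats(min_value=0, max_value=359.99), min_size=2,
                    max_size=50))
    def test_full_turn_invariance(self, phis):
        phi = np.array(phis)
        assert tp_index(phi) == pytest.approx(tp_index(phi + 360.0))
        r1, m1 = mean_vector(phi)
        r2, m2 = mean_vector(phi + 360.0)
        assert r1 == pytest.approx(r2) and m1 == pytest.approx(m2)


class TestWatsonWilliams:
    def test_identical_tight_groups_null(self):
        g = vm(100.0, 20.0, 40)
        f, p, ok = watson_williams(g, g.copy())
        assert f == pytest.approx(0.0, abs=1e-9)
        assert p > 0.99
        assert ok

    def test_power_on_separated_groups(self):
        a = vm(0.0, 8.0, 50)
        b = vm(90.0, 8.0, 50)
        _, p, _ = watson_williams(a, b)
        assert p < 1e-3
        # cross-check with a permutation oracle on the same data
        pooled = np.concatenate([a, b])
        from thetalock.circstats import circ_r
        def stat(x, y):
            return abs(np.angle(np.exp(1j * np.deg2rad(x)).mean()
                                / np.exp(1j * np.deg2rad(y)).mean()))
        obs = stat(a, b)
        perm = np.random.default_rng(0)
        exceed = 0
        for _ in range(2000):
            idx = perm.permutation(100)
            if stat(pooled[idx[:50]], pooled[idx[50:]]) >= obs:
                exceed += 1
        assert exceed / 2000 < 1e-3

    def test_low_concentration_flagged(self):
        a = rng.uniform(0, 360, 40)
        b = rng.uniform(0, 360, 40)
        _, _, ok = watson_williams(a, b)
        assert not ok

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            watson_williams(vm(0, 2, 4), vm(0, 2, 30))


class TestHarrisonKanji:
    def test_planted_main_effect_of_a_only(self):
        n = 60
        reps = 40
        hits_a = hits_b = hits_i = 0
        r = np.random.default_rng(5)
        for _ in range(reps):
            A = r.integers(0, 2, n)
            B = r.integers(0, 2, n)
            mu = np.where(A == 1, 80.0, 0.0)
            phi = (mu + np.rad2deg(r.vonmises(0, 4, n))) % 360
            res = harrison_kanji(phi, A, B)
            hits_a += res["A"][3] < 0.05
            hits_b += res["B"][3] < 0.05
            hits_i += res["AxB"][3] < 0.05
        assert hits_a == reps
        assert hits_b <= 0.2 * reps
        assert hits_i <= 0.2 * reps

    def test_single_level_factor_reduces_to_watson_williams(self):
        phi = np.concatenate([vm(0.0, 4.0, 30), vm(60.0, 4.0, 30)])
        A = np.repeat([0, 1], 30)
        B = np.zeros(60, dtype=int)
        res = harrison_kanji(phi, A, B)
        f_ww, p_ww, _ = watson_williams(phi[:30], phi[30:])
        assert res["A"][0] == pytest.approx(f_ww, rel=1e-9)
        assert res["A"][3] == pytest.approx(p_ww, rel=1e-9)

    def test_empty_cell_named(self):
        phi = vm(0, 3, 30)
        A = np.repeat([0, 1], 15)
        B = np.r_[np.zeros(15, int), np.ones(15, int)]  # diagonal design
        with pytest.raises(ValueError, match="empty cell"):
            harrison_kanji(phi, A, B)


class TestSurrogateTest:
    def _cycles(self, kappa, n_cycles, rate, r):
        counts = r.poisson(rate, n_cycles)
        if kappa > 0:
            return [vm(180.0, kappa, c, r) for c in counts]
        return [r.uniform(0, 360, c) for c in counts]

    def test_locked_cell_significant(self):
        r = np.random.default_rng(11)
        hits = 0
        for i in range(20):
            cyc = self._cycles(4.0, 200, 0.6, r)
            res = surrogate_modulation_test(cyc, n_surrogates=200, seed=i)
            hits += res["significant"]
        assert hits >= 19

    def test_single_spike_rejected(self):
        cyc = [np.array([10.0])] + [np.array([])] * 30
        with pytest.raises(ValueError):
            surrogate_modulation_test(cyc)

    def test_too_few_cycles_rejected(self):
        with pytest.raises(ValueError):
            surrogate_modulation_test([np.array([1.0, 2.0])] * 5)


class TestCircCorr:
    def test_linear_phase_relation_detected(self):
        a = rng.uniform(0, 360, 200)
        b = (a + vm(0, 20.0, 200)) % 360
        rho, p = circ_corr(a, b)
        assert rho > 0.5 and p < 1e-6

    def test_independent_angles_null(self):
        a = rng.uniform(0, 360, 200)
        b = rng.uniform(0, 360, 200)
        rho, p = circ_corr(a, b)
        assert abs(rho) < 0.2


def test_kappa_estimate_roundtrip():
    for kappa in (0.5, 2.0, 8.0):
        phi = vm(0.0, kappa, 20_000)
        r, _ = mean_vector(phi)
        assert circ_kappa(r) == pytest.approx(kappa, rel=0.1)
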