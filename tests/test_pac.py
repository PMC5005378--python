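"""Modulation index, PACz surrogates, comodulograms, cluster comparison."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circasleep import Hypnogram, ParameterError, StructureError
from circasleep.pac import cluster_compare, comodulogram, pac_mi, pacz


class TestMI:
    def test_cosine_modulation_is_half(self):
        """Brute-force oracle: |<(1+cos phi) e^{i phi}>| = 1/2 over whole
        cycles."""
        n = 36000
        phi = np.linspace(0, 2 * np.pi * 30, n, endpoint=False)
        # independent oracle: direct summation
        oracle = abs(np.sum((1 + np.cos(phi)) * np.exp(1j * phi)) / n)
        assert oracle == pytest.approx(0.5, abs=1e-9)
        assert pac_mi(phi, 1 + np.cos(phi)) == pytest.approx(0.5, abs=1e-6)

    def test_constant_phase_returns_mean_amplitude(self):
        a = np.linspace(0, 3, 500)
        assert pac_mi(np.full(500, 0.7), a) == pytest.approx(a.mean(), rel=1e-12)

    def test_uniform_phase_cancels(self):
        phi = np.linspace(0, 2 * np.pi * 10, 5000, endpoint=False)
        assert pac_mi(phi, np.ones(5000)) < 1e-12

    def test_length_mismatch(self):
        with pytest.raises(StructureError):
            pac_mi(np.zeros(5), np.zeros(6))

    @given(
        k=st.integers(min_value=-3, max_value=3),
        c=st.floats(min_value=0.1, max_value=10.0),
    )
    @settings(max_examples=20, deadline=None)
    def test_invariances(self, k, c):
        """MI invariant to adding 2 pi k to phases; linear in amplitude."""
        rng = np.random.default_rng(0)
        phi = rng.uniform(-np.pi, np.pi, 400)
        a = rng.random(400) + 0.5
        base = pac_mi(phi, a)
        assert pac_mi(phi + 2 * np.pi * k, a) == pytest.approx(base, rel=1e-9)
        assert pac_mi(phi, c * a) == pytest.approx(c * base, rel=1e-9)


class TestPACz:
    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(1)
        phi = rng.uniform(-np.pi, np.pi, 2000)
        a = rng.random(2000)
        assert pacz(phi, a, 100, seed=7) == pacz(phi, a, 100, seed=7)

    def test_amplitude_scale_invariant(self):
        rng = np.random.default_rng(2)
        phi = rng.uniform(-np.pi, np.pi, 2000)
        a = rng.random(2000)
        assert pacz(phi, a, 100, seed=3) == pytest.approx(
            pacz(phi, 10.0 * a, 100, seed=3), rel=1e-9
        )

    def test_perfect_coupling_separates(self):
        rng = np.random.default_rng(4)
        phi = rng.uniform(-np.pi, np.pi, 6000)
        a = 1 + np.cos(phi)
        assert pacz(phi, a, 200, seed=0) > 5.0

    def test_constant_amplitude_flagged(self):
        phi = np.random.default_rng(5).uniform(-np.pi, np.pi, 500)
        with pytest.warns(UserWarning, match="surrogate"):
            z = pacz(phi, np.ones(500), 100, seed=0)
        assert np.isnan(z)

    def test_too_few_surrogates(self):
        with pytest.raises(ParameterError):
            pacz(np.zeros(100), np.zeros(100), n_surrogates=10)

    def test_matches_explicit_cut_and_swap(self):
        """The FFT-based surrogate MIs equal brute-force cut-and-swap."""
        rng = np.random.default_rng(6)
        phi = rng.uniform(-np.pi, np.pi, 512)
        a = rng.random(512)
        z = np.exp(1j * phi)
        r = np.fft.ifft(np.conj(np.fft.fft(np.conj(z))) * np.fft.fft(a))
        for c in (1, 17, 200, 511):
            brute = abs(np.dot(np.concatenate((a[c:], a[:c])), z)) / 512
            assert abs(r[c]) / 512 == pytest.approx(brute, abs=1e-12)


class TestComodulogram:
    PC = np.arange(4.0, 13.0, 2.0)
    AC = np.arange(20.0, 51.0, 3.0)

    def _comod(self, rec, hyp, ld12, seed=0):
        return comodulogram(
            rec, hyp, ld12, state="W", phase_centers=self.PC,
            amp_centers=self.AC, seed=seed, last_n_cycles=None,
        )["scotophase"]

    def test_uncoupled_stays_near_null(self, wake_recording_pair, ld12):
        hyp, recs = wake_recording_pair
        c = self._comod(recs[0.0], hyp, ld12)
        assert np.nanmax(np.abs(c.pacz)) < 2.0

    def test_coupled_argmax_at_theta_gamma(self, wake_recording_pair, ld12):
        hyp, recs = wake_recording_pair
        c = self._comod(recs[0.8], hyp, ld12)
        fp, fa = c.argmax_cell()
        assert fp == pytest.approx(8.0, abs=2.0)
        assert 30.0 <= fa <= 46.0
        assert np.nanmax(c.pacz) > 3.0

    def test_absent_state_all_missing(self, wake_recording_pair, ld12):
        hyp, recs = wake_recording_pair
        with pytest.warns(UserWarning, match="no qualifying"):
            out = comodulogram(
                recs[0.0], hyp, ld12, state="R", phase_centers=self.PC,
                amp_centers=self.AC, seed=0, last_n_cycles=None,
            )
        assert np.isnan(out["scotophase"].pacz).all()


class TestClusterCompare:
    def test_identical_no_suprathreshold(self):
        rng = np.random.default_rng(0)
        a = [rng.standard_normal((8, 12)) for _ in range(5)]
        res = cluster_compare(a, a, n_perm=200, seed=1)
        assert res.clusters == []

    def test_known_effect_detected_at_true_cell(self):
        rng = np.random.default_rng(1)
        a = [rng.standard_normal((8, 12)) for _ in range(6)]
        b = []
        for m in a:
            x = m + rng.standard_normal((8, 12)) * 0.5
            x[3:6, 6:9] += 3.0
            b.append(x)
        res = cluster_compare(a, b, n_perm=500, seed=2)
        sig = res.significant(0.05)
        assert sig
        true_flat = 4 * 12 + 7
        assert any(true_flat in c.cells for c in sig)

    def test_unpaired_rejected(self):
        a = [np.zeros((4, 4))] * 4
        with pytest.raises(StructureError):
            cluster_compare(a, a[:3])

    def test_few_permutations_warn(self):
        rng = np.random.default_rng(2)
        a = [rng.standard_normal((4, 4)) for _ in range(4)]
        with pytest.warns(UserWarning, match="n_perm"):
            cluster_compare(a, a, n_perm=50, seed=0)

    def test_nan_cells_ignored(self):
        rng = np.random.default_rng(3)
        a = []
        b = []
        for _ in range(5):
            m = rng.standard_normal((6, 6))
            m[0, 0] = np.nan
            a.append(m)
            b.append(m + 0.1 * rng.standard_normal((6, 6)))
        res = cluster_compare(a, b, n_perm=200, seed=4)
        assert np.isnan(res.t_map[0, 0])
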