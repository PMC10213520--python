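"""Free-energy measures: F = A - C, AIC dimension, Gibbs modal form."""

import itertools

import numpy as np
import pytest
from scipy.stats import spearmanr

from mesocortex import correlation_metrics as cm
from mesocortex import field_dynamics as fd
from mesocortex import fixtures as fx


class TestCrossCorrelogram:
    def test_identity_peaks_at_zero(self):
        x = np.random.default_rng(0).normal(size=1000)
        lags, c, deg = cm.cross_correlogram(x, x, tau_max=10)
        assert not deg
        assert c[lags == 0] == pytest.approx(1.0)

    def test_shift_sign_convention(self):
        # y lagging x by 5 steps peaks at +5
        x = np.random.default_rng(1).normal(size=2000)
        y = np.roll(x, 5)
        y[:5] = 0
        lags, c, _ = cm.cross_correlogram(x, y, tau_max=10)
        assert lags[np.argmax(c)] == 5

    def test_independent_noise_stays_small(self):
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            lags, c, _ = cm.cross_correlogram(
                r.normal(size=10_000), r.normal(size=10_000), tau_max=20
            )
            hits += np.abs(c).max() < 0.1
        assert hits >= 19

    def test_degenerate_input_flagged(self):
        x = np.zeros(100)
        lags, c, deg = cm.cross_correlogram(x, np.arange(100.0), tau_max=5)
        assert deg
        assert np.all(c == 0)

    def test_window_guard(self):
        with pytest.raises(ValueError):
            cm.cross_correlogram(np.ones(10), np.ones(10), tau_max=5)


class TestFreeEnergyAC:
    def test_identical_series_cancel(self):
        x = np.random.default_rng(0).normal(size=1000)
        st = cm.free_energy_AC(fd.FluxSeries(values=np.vstack([x, x]), dt=1.0), tau_max=10)
        assert st.A == 2
        assert st.C == pytest.approx(2.0)
        assert st.F == pytest.approx(0.0, abs=1e-9)

    def test_single_group(self):
        x = np.random.default_rng(0).normal(size=400)
        st = cm.free_energy_AC(fd.FluxSeries(values=x[None], dt=1.0), tau_max=10)
        assert st.C == 0.0
        assert st.F == st.A == 1.0

    def test_independent_noise_bounds(self):
        r = np.random.default_rng(3)
        st = cm.free_energy_AC(
            fd.FluxSeries(values=r.normal(size=(2, 10_000)), dt=1.0), tau_max=10
        )
        assert st.A - 0.2 <= st.F <= st.A

    def test_tau_max_guard(self):
        s = fd.FluxSeries(values=np.random.default_rng(0).normal(size=(2, 100)), dt=1.0)
        with pytest.raises(ValueError):
            cm.free_energy_AC(s, tau_max=30)

    def test_decomposition_exact_and_brute_force(self):
        r = np.random.default_rng(4)
        labels = ["E", "I", "E", "I", "E", "I"]
        st = cm.free_energy_AC(
            fd.FluxSeries(values=r.normal(size=(6, 2000)), dt=1.0),
            labels=labels,
            tau_max=8,
        )
        assert st.C_ee + st.C_ii + st.C_ei_ie == pytest.approx(st.C, abs=1e-9)
        # brute-force ordered-pair enumeration
        cee = cii = cei = 0.0
        for i, j in itertools.permutations(range(6), 2):
            v = st.peak_corrs[i, j]
            if labels[i] == labels[j] == "E":
                cee += v
            elif labels[i] == labels[j] == "I":
                cii += v
            else:
                cei += v
        assert st.C_ee == pytest.approx(cee)
        assert st.C_ii == pytest.approx(cii)
        assert st.C_ei_ie == pytest.approx(cei)

    def test_all_e_population_has_no_mixed_terms(self):
        r = np.random.default_rng(5)
        st = cm.free_energy_AC(
            fd.FluxSeries(values=r.normal(size=(3, 1000)), dt=1.0), tau_max=5
        )
        assert st.C_ii == 0.0
        assert st.C_ei_ie == 0.0

    def test_one_e_one_i_is_all_mixed(self):
        r = np.random.default_rng(6)
        st = cm.free_energy_AC(
            fd.FluxSeries(values=r.normal(size=(2, 1000)), dt=1.0),
            labels=["E", "I"],
            tau_max=5,
        )
        assert st.C == pytest.approx(st.C_ei_ie)


class TestSymmetryLowersFreeEnergy:
    def test_spearman_over_symmetry_sweep(self):
        # two groups, K21 = s * K12: free energy falls as coupling
        # becomes bidirectionally symmetric
        k0 = 0.6
        svals = np.linspace(0, 1, 11)
        Fbar = []
        for s in svals:
            Fs = []
            for seed in range(10):
                p = fd.OscillatorParams(
                    D=[0.15, 0.15],
                    N=[1.0, 1.0],
                    K=[[0.0, k0], [s * k0, 0.0]],
                    positions=np.array([0j, 1 + 0j]),
                )
                ser = fd.simulate_field(
                    p, fd.NoiseDrive(1.0, diffusion_length=1.0), 200.0, 0.05, seed=seed
                )
                ser = fd.FluxSeries(values=ser.values[:, 400:], dt=0.05)
                Fs.append(cm.free_energy_AC(ser, tau_max=3.0).F)
            Fbar.append(np.mean(Fs))
        rho, _ = spearmanr(svals, Fbar)
        assert rho <= -0.9


class TestAntenatalSignature:
    def test_constructed_antiphase_case(self):
        t = np.arange(2000) * 0.1
        period = 8.0
        e = np.sin(2 * np.pi * t / period)
        i = -e
        vals = np.vstack([e, e * 1.01 + 1e-3, i, i * 0.99])
        st = cm.free_energy_AC(
            fd.FluxSeries(values=vals, dt=0.1), labels=["E", "E", "I", "I"], tau_max=6.0
        )
        rep = cm.antenatal_signature_check(st, period=period)
        assert rep["signature"]

    def test_independent_noise_fails(self):
        r = np.random.default_rng(0)
        st = cm.free_energy_AC(
            fd.FluxSeries(values=r.normal(size=(6, 4000)), dt=0.1),
            labels=["E", "E", "E", "I", "I", "I"],
            tau_max=6.0,
        )
        rep = cm.antenatal_signature_check(st, period=8.0)
        assert not rep["signature"]

    def test_quarter_period_offset_fails(self):
        t = np.arange(2000) * 0.1
        period = 8.0
        e1 = np.sin(2 * np.pi * t / period)
        e2 = np.sin(2 * np.pi * (t - period / 4) / period)
        vals = np.vstack([e1, e2, -e1, -e2])
        st = cm.free_energy_AC(
            fd.FluxSeries(values=vals, dt=0.1), labels=["E", "E", "I", "I"], tau_max=6.0
        )
        rep = cm.antenatal_signature_check(st, period=period)
        assert rep["verdicts"]["EE"] == "violated"

    def test_too_few_pairs_not_assessable(self):
        r = np.random.default_rng(1)
        st = cm.free_energy_AC(
            fd.FluxSeries(values=r.normal(size=(2, 1000)), dt=0.1),
            labels=["E", "I"],
            tau_max=5.0,
        )
        rep = cm.antenatal_signature_check(st, period=8.0)
        assert rep["verdicts"]["EE"] == "not assessable"


class TestAkaikeDimension:
    @pytest.mark.parametrize("k_true", [1, 2, 3, 4, 5])
    def test_recovers_planted_dimension(self, k_true):
        X = fx.make_factor_flux(k_true, 40, 4000, snr=10, seed=10 + k_true)
        assert cm.akaike_dimension(X, k_max=8).k_star == k_true

    def test_three_factor_recovery_rate(self):
        hits = sum(
            cm.akaike_dimension(fx.make_factor_flux(3, 50, 5000, 10, seed=s), k_max=6).k_star
            == 3
            for s in range(20)
        )
        assert hits >= 19

    def test_pure_noise_selects_at_most_one(self):
        X = np.random.default_rng(5).normal(size=(50, 5000))
        assert cm.akaike_dimension(X, k_max=6).k_star <= 1

    def test_duplicated_rows_leave_k_unchanged(self):
        X = fx.make_factor_flux(2, 30, 3000, 10, seed=7)
        a = cm.akaike_dimension(X, k_max=8)
        b = cm.akaike_dimension(np.vstack([X, X]), k_max=8)
        assert a.k_star == b.k_star
        assert b.n_collapsed == 30

    def test_alpha_decreasing_in_likelihood(self):
        X = fx.make_factor_flux(3, 30, 2000, 10, seed=1)
        res = cm.akaike_dimension(X, k_max=6)
        # at fixed k the criterion is -2 lnL + 2 d(k): monotone down in lnL
        assert np.all(np.diff(res.log_likelihoods) >= -1e-6)
        np.testing.assert_allclose(
            res.alpha_curve, -2 * res.log_likelihoods + 2 * res.n_params
        )

    def test_guards(self):
        with pytest.raises(ValueError):
            cm.akaike_dimension(np.random.default_rng(0).normal(size=(10, 5)), k_max=3)
        with pytest.raises(ValueError):
            cm.akaike_dimension(np.random.default_rng(0).normal(size=(5, 100)), k_max=7)


class TestGibbsFreeEnergy:
    def test_single_mode(self):
        S, F = cm.gibbs_free_energy([2.5], tau_scale=1.0)
        assert S == 0.0
        assert F == 2.5

    def test_equipartition_closed_form(self):
        S, F = cm.gibbs_free_energy([0.25] * 4, tau_scale=1.0)
        assert S == pytest.approx(np.log(4))
        assert F == pytest.approx(1 - np.log(4))

    @pytest.mark.parametrize("m", [2, 3, 4, 5])
    def test_equipartition_minimizes_over_simplex_grid(self, m):
        # brute-force grid search at resolution 0.01 over the energy simplex
        res = 0.05 if m >= 4 else 0.01
        grid = np.arange(0.0, 1.0 + 1e-9, res)
        best_F, best_u = np.inf, None
        for combo in itertools.product(grid, repeat=m - 1):
            last = 1.0 - sum(combo)
            if last < -1e-12:
                continue
            u = np.array(list(combo) + [max(last, 0.0)])
            _, F = cm.gibbs_free_energy(u, tau_scale=1.0)
            if F < best_F - 1e-12:
                best_F, best_u = F, u
        np.testing.assert_allclose(best_u, 1.0 / m, atol=res)
        S_eq, F_eq = cm.gibbs_free_energy(np.full(m, 1.0 / m))
        assert F_eq <= best_F + 1e-9

    def test_zero_energy_terms_contribute_nothing(self):
        S1, _ = cm.gibbs_free_energy([0.5, 0.5, 0.0])
        S2, _ = cm.gibbs_free_energy([0.5, 0.5])
        assert S1 == pytest.approx(S2)

    def test_guards(self):
        with pytest.raises(ValueError):
            cm.gibbs_free_energy([0.0, 0.0])
        with pytest.raises(ValueError):
            cm.gibbs_free_energy([-1.0, 2.0])
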