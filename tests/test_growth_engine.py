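"""Antenatal growth: initialization, plasticity rules, apoptosis, trends."""

import numpy as np
import pytest
from scipy.optimize import brentq

from mesocortex import growth_engine as ge

pytestmark = pytest.mark.filterwarnings("ignore::UserWarning")

EXTENT = (0.0, 8.0, 0.0, 8.0)


class TestInitialization:
    def test_mean_out_degree_matches_sparsity(self):
        pop, syn = ge.init_antenatal_field(500, 0.2, 0.3, 0.02, EXTENT, seed=0)
        outdeg = (syn.rho > 0).sum(axis=1)
        expected = 0.02 * 499
        # binomial CI over 500 cells
        assert abs(outdeg.mean() - expected) < 3 * np.sqrt(expected / 500) * 5

    def test_determinism(self):
        a = ge.init_antenatal_field(100, 0.2, 0.3, 0.05, EXTENT, seed=3)
        b = ge.init_antenatal_field(100, 0.2, 0.3, 0.05, EXTENT, seed=3)
        assert np.array_equal(a[1].rho, b[1].rho)
        assert np.array_equal(a[0].positions, b[0].positions)

    def test_links_almost_entirely_unidirectional(self):
        pop, syn = ge.init_antenatal_field(500, 0.2, 0.3, 0.02, EXTENT, seed=0)
        links = syn.rho > 0
        pair_recip = (links & links.T).sum() / 2
        n_pairs = 500 * 499 / 2
        # reciprocal-pair probability of order sparsity^2, far below sparsity
        assert pair_recip / n_pairs < 0.2 * 0.02

    def test_inhibitory_cells_never_patch(self):
        pop, _ = ge.init_antenatal_field(300, 0.3, 0.4, 0.03, EXTENT, seed=1)
        assert not np.any((pop.cell_type == "I") & (np.asarray(pop.axon_class) == "patch"))

    def test_guards(self):
        with pytest.raises(ValueError):
            ge.init_antenatal_field(100, 0.2, 0.3, 0.5, EXTENT, seed=0)


class TestAxonDensity:
    def test_crossing_matches_bisection(self):
        X = ge.find_X(1.0, 0.5, 0.3, 2.0)
        f = lambda d: ge.axon_density(1.0, 0.5, d) - ge.axon_density(0.3, 2.0, d)
        assert X == pytest.approx(brentq(f, 1e-6, 10.0), abs=1e-9)

    def test_identical_profiles_rejected(self):
        with pytest.raises(ValueError):
            ge.find_X(1.0, 1.0, 1.0, 1.0)

    def test_amplitude_scaling_invariance(self):
        assert ge.find_X(2.0, 0.5, 0.6, 2.0) == pytest.approx(ge.find_X(1.0, 0.5, 0.3, 2.0))


class TestFastRule:
    def test_relaxation_to_baseline(self):
        p = ge.FastParams()
        eps = np.array([0.95])
        for _ in range(1500):
            eps = ge.update_fast(eps, 0.0, 0.0, 0.1, p)
        assert eps[0] == pytest.approx(p.baseline, abs=1e-3)

    def test_depressed_fixed_point_closed_form(self):
        p = ge.FastParams()
        rate = 5.0
        eps = np.array([p.baseline])
        for _ in range(3000):
            eps = ge.update_fast(eps, rate, 0.0, 0.05, p)
        expected = (p.baseline / p.tau_f) / (1 / p.tau_f + p.a_depress * rate)
        assert eps[0] == pytest.approx(expected, rel=1e-4)

    def test_coincident_burst_transient(self):
        p = ge.FastParams()
        eps = np.array([p.baseline])
        for _ in range(5):
            eps = ge.update_fast(eps, 1.0, 1.0, 0.5, p)
        peak = eps[0]
        assert peak > p.baseline
        for _ in range(400):
            eps = ge.update_fast(eps, 0.0, 0.0, 0.5, p)
        assert eps[0] < peak
        assert eps[0] == pytest.approx(p.baseline, abs=1e-3)

    def test_bounds_hold(self):
        p = ge.FastParams()
        eps = np.array([0.5])
        for _ in range(100):
            eps = ge.update_fast(eps, 100.0, 100.0, 1.0, p)
            assert 0.0 <= eps[0] <= p.eps_max


class TestSlowRule:
    def test_zero_crossing_at_threshold(self):
        g, theta = ge.update_slow(np.array([1.0]), 1.0, 2.0, np.array([2.0]), 0.1)
        assert g[0] == pytest.approx(1.0)

    def test_threshold_tracks_rate_squared(self):
        p = ge.SlowParams()
        theta = np.array([0.0])
        g = np.array([1.0])
        for _ in range(8000):
            g, theta = ge.update_slow(g, 1.0, 2.0, theta, 0.05, p)
        assert theta[0] == pytest.approx(4.0, rel=1e-3)

    def test_pathway_competition(self):
        # two inputs to one cell: the one driving above-threshold activity
        # gains while the other loses
        p = ge.SlowParams(eta=0.05)
        g = np.array([1.0, 1.0])
        theta = np.array([1.0])
        for _ in range(200):
            post = np.array([1.5])  # above theta for input 0 only via pre rate
            g0, theta = ge.update_slow(g[:1], 1.0, 1.5, theta, 0.1, p)
            g1, theta = ge.update_slow(g[1:], 1.0, 0.5, theta, 0.1, p)
            g = np.concatenate([g0, g1])
        assert g[0] > 1.0 > g[1]


class TestStructuralRule:
    def test_disuse_decay_rate(self):
        p = ge.StructuralParams()
        rho = np.array([1.0])
        out = ge.structural_update(rho, np.array([0.0]), np.array([0.0]), np.array([0.0]), 1.0, p)
        assert out[0] == pytest.approx(1.0 - p.lam_disuse)

    def test_growth_fixed_point(self):
        p = ge.StructuralParams()
        drive = 1.8 * 0.9  # g * eps well above baseline
        rho = np.array([0.5])
        for _ in range(5000):
            rho = ge.structural_update(
                rho, np.array([1.8]), np.array([0.9]), np.array([1.0]), 0.5, p
            )
        expected = min(p.c_grow * (drive - p.baseline) / p.lam_active, p.rho_max)
        assert rho[0] == pytest.approx(expected, rel=1e-3)

    def test_per_cell_normalization_conserves_output(self):
        r = np.random.default_rng(0)
        rho = r.uniform(0.1, 1.0, size=(10, 10))
        out = ge.structural_update(
            rho,
            r.uniform(0.5, 1.5, (10, 10)),
            r.uniform(0.4, 1.0, (10, 10)),
            r.uniform(0, 1, (10, 10)),
            1.0,
            ge.StructuralParams(),
            normalize=True,
        )
        np.testing.assert_allclose(out.sum(axis=1), rho.sum(axis=1), rtol=0.01)

    def test_absorbing_zero_after_grace(self):
        p = ge.StructuralParams()
        rho = np.array([[p.rho_floor / 2]])
        dormant = np.array([[p.grace_epochs + 1]])
        out = ge.structural_update(
            rho, np.zeros((1, 1)), np.zeros((1, 1)), np.zeros((1, 1)), 1.0, p,
            dormant_epochs=dormant,
        )
        assert out[0, 0] == 0.0


class TestApoptosis:
    def _pop(self, n=100, seed=3):
        return ge.init_antenatal_field(n, 0.2, 0.3, 0.05, EXTENT, seed=seed)

    def test_equal_traces_remove_nobody(self):
        pop, syn = self._pop()
        pop.activity_trace[:] = 1.0
        assert ge.apoptosis_step(pop, syn, 0.05, 40) == 0

    def test_planted_silent_subset_removed_exactly(self):
        pop, syn = self._pop()
        r = np.random.default_rng(0)
        planted = r.choice(100, 10, replace=False)
        pop.activity_trace[:] = 1.0 + 0.1 * r.random(100)
        pop.activity_trace[planted] = 0.0
        removed = ge.apoptosis_step(pop, syn, 0.05, 40)
        removed += ge.apoptosis_step(pop, syn, 0.05, 40)
        assert set(np.flatnonzero(~pop.alive)) == set(planted)

    def test_dead_stays_dead_and_synapses_zero(self):
        pop, syn = self._pop()
        r = np.random.default_rng(1)
        pop.activity_trace[:] = 1.0 + r.random(100)
        pop.activity_trace[:10] = 0.0
        ge.apoptosis_step(pop, syn, 0.2, 10)
        dead = ~pop.alive
        assert np.all(syn.rho[dead, :] == 0)
        assert np.all(syn.rho[:, dead] == 0)
        before = pop.alive.copy()
        ge.apoptosis_step(pop, syn, 0.2, 10)
        assert np.all(pop.alive <= before)  # removal never resurrects

    def test_energy_floor_self_limits_removal(self):
        # the relative-to-median energy floor makes a >50% cull impossible:
        # a strict majority cannot sit below 0.75x its own median
        pop, syn = self._pop()
        r = np.random.default_rng(2)
        pop.activity_trace[:] = r.uniform(0.9, 1.1, 100)
        pop.activity_trace[:45] = 0.01  # large under-consuming minority
        removed = ge.apoptosis_step(pop, syn, 0.95, 1)
        assert removed <= 45
        assert pop.alive.sum() >= 50


class TestSymmetryIndices:
    def test_symmetric_weights_zero(self):
        w = np.array([[0, 1.0], [1.0, 0]])
        fa, wa = ge.symmetry_indices(w, w)
        assert wa == 0.0

    def test_unidirectional_is_one(self):
        w = np.array([[0, 1.0], [0, 0]])
        fa, wa = ge.symmetry_indices(w, w)
        assert wa == 1.0

    def test_matches_brute_force(self):
        r = np.random.default_rng(2)
        w = r.uniform(size=(6, 6))
        np.fill_diagonal(w, 0)
        _, wa = ge.symmetry_indices(w, w)
        num = den = 0.0
        for i in range(6):
            for j in range(i + 1, 6):
                num += abs(w[i, j] - w[j, i])
                den += w[i, j] + w[j, i]
        assert wa == pytest.approx(num / den)

    def test_all_zero_flagged_nan(self):
        fa, wa = ge.symmetry_indices(np.zeros((3, 3)), np.zeros((3, 3)))
        assert np.isnan(fa) and np.isnan(wa)


class TestAntenatalRun:
    @pytest.fixture(scope="class")
    def runs(self):
        cfg = ge.GrowthConfig(n_cells=120, n_epochs=120, metric_stride=5)
        return [ge.run_antenatal_growth(cfg, seed=s) for s in range(3)]

    def test_weight_asymmetry_halves(self, runs):
        for traj, _, _ in runs:
            wa = traj.series("weight_asymmetry")
            assert wa[-1] < 0.5 * wa[0]

    def test_reciprocal_fraction_increases(self, runs):
        for traj, _, _ in runs:
            rf = traj.series("reciprocal_fraction")
            assert rf[-1] > rf[0]

    def test_free_energy_per_pair_decreases(self, runs):
        for traj, _, _ in runs:
            F = traj.series("F_AC_per_pair")
            n = len(F)
            assert F[-n // 4 :].mean() < F[: n // 4].mean()

    def test_weights_stay_finite_nonnegative(self, runs):
        for _, pop, syn in runs:
            for arr in (syn.rho, syn.g, syn.eps):
                assert np.all(np.isfinite(arr))
                assert np.all(arr >= 0)

    def test_survivor_traces_dominate_eliminated(self, runs):
        for _, pop, _ in runs:
            if (~pop.alive).any():
                assert (
                    pop.activity_trace[pop.alive].mean()
                    >= pop.activity_trace[~pop.alive].mean()
                )

    def test_patch_cluster_spacing_near_X(self, runs):
        cfg = ge.GrowthConfig()
        X = ge.find_X(cfg.a_local, cfg.sigma_local, cfg.a_patch, cfg.sigma_patch)
        hits = 0
        for _, pop, _ in runs:
            modal, _ = ge.patch_cluster_spacing(pop, link_radius=X / 2)
            hits += abs(modal - X) <= 0.25 * X
        assert hits >= 2

    def test_determinism_under_seed(self):
        cfg = ge.GrowthConfig(n_cells=60, n_epochs=10, metric_stride=2)
        t1, _, _ = ge.run_antenatal_growth(cfg, seed=5)
        t2, _, _ = ge.run_antenatal_growth(cfg, seed=5)
        assert t1.records == t2.records

    def test_plasticity_disabled_null_control(self):
        cfg = ge.GrowthConfig(
            n_cells=80, n_epochs=20, plasticity_enabled=False, metric_stride=2,
            apoptosis_every=0,
        )
        traj, _, _ = ge.run_antenatal_growth(cfg, seed=0)
        wa = traj.series("weight_asymmetry")
        assert np.ptp(wa) < 1e-12
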