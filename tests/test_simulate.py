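"""Simulator: impulse model, two-compartment ODE, labeling, noise, plates."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import solve_ivp

import steroidokin as sk
from steroidokin.containers import ConfigError, DataError


class TestImpulse:
    def test_identity_when_folds_are_one(self):
        p = sk.ImpulseParams(baseline_rate=3.0, fold_peak=1.0, fold_late=1.0)
        t = np.linspace(0, 24, 50)
        assert np.allclose(sk.impulse_rate(p, t), 3.0)

    def test_late_limit_is_fold_late(self):
        p = sk.ImpulseParams(baseline_rate=2.0, fold_peak=10.0, fold_late=3.0,
                             t_on=0.5, t_off=2.0, slope=4.0)
        assert sk.impulse_rate(p, 1e4) == pytest.approx(6.0, rel=1e-6)

    def test_peak_matches_dense_grid_maximization(self):
        # brute-force argmax over a dense grid is the oracle for the
        # closed-form evaluation at the same points
        p = sk.ImpulseParams(baseline_rate=1.0, fold_peak=20.0, fold_late=1.0,
                             t_on=0.5, t_off=2.0, slope=4.0)
        dense = np.linspace(0, 10, 20001)
        vals = sk.impulse_rate(p, dense)
        brute = max((sk.impulse_rate(p, float(t)), float(t)) for t in dense)
        i = int(np.argmax(vals))
        assert vals[i] == pytest.approx(brute[0])
        assert dense[i] == pytest.approx(brute[1])

    @pytest.mark.parametrize("bad", [
        dict(baseline_rate=0.0),
        dict(fold_peak=-1.0),
        dict(t_on=2.0, t_off=1.0),
        dict(slope=0.0),
    ])
    def test_invalid_params_raise(self, bad):
        with pytest.raises(ConfigError):
            sk.ImpulseParams(**bad)

    def test_negative_time_rejected(self):
        with pytest.raises(ConfigError):
            sk.impulse_rate(sk.ImpulseParams(), -1.0)


class TestTwoCompartmentODE:
    def test_constant_rates_stay_at_steady_state(self):
        kin = sk.GeneKinetics("g", alpha=10.0, gamma=2.0, beta0=0.5)
        imp = sk.ImpulseParams(baseline_rate=10.0)
        grid = np.linspace(0, 24, 25)
        P, M = sk.solve_two_compartment(kin, imp, grid)
        assert np.allclose(P, 10.0 / 2.0, rtol=1e-6)
        assert np.allclose(M, 10.0 / 0.5, rtol=1e-6)

    def test_step_response_matches_closed_form(self):
        # alpha steps a -> b at ~0; near-instant processing (gamma = 1e3)
        # reduces the system to dM/dt = alpha(t) - beta M with the textbook
        # exponential approach M(t) = b/beta + (a - b)/beta * exp(-beta t)
        a, b, beta = 5.0, 20.0, 0.8
        kin = sk.GeneKinetics("g", alpha=a, gamma=1e3, beta0=beta)
        imp = sk.ImpulseParams(baseline_rate=a, fold_peak=b / a, fold_late=b / a,
                               t_on=0.01, t_off=100.0, slope=2000.0)
        grid = np.array([0.0, 0.5, 1.0, 2.0, 4.0, 8.0])
        _, M = sk.solve_two_compartment(kin, imp, grid)
        # closed form referenced to the actual step time (t_on) plus the
        # 1/gamma processing lag
        shift = 0.01 + 1e-3
        expected = b / beta + (a / beta - b / beta) * np.exp(-beta * (grid - shift))
        assert np.allclose(M[1:], expected[1:], rtol=1e-3)

    def test_pure_decay_after_transcription_shutoff(self):
        # transcription collapses to ~0 immediately; the mature pool then
        # decays as M0 * exp(-beta t)
        beta = 0.7
        kin = sk.GeneKinetics("g", alpha=10.0, gamma=50.0, beta0=beta)
        imp = sk.ImpulseParams(baseline_rate=10.0, fold_peak=1e-9, fold_late=1e-9,
                               t_on=0.001, t_off=1000.0, slope=5000.0)
        grid = np.array([0.0, 1.0, 2.0, 3.0, 5.0])
        _, M = sk.solve_two_compartment(kin, imp, grid)
        ratio = M[2:] / M[1]
        assert np.allclose(ratio, np.exp(-beta * (grid[2:] - 1.0)), rtol=1e-5)

    def test_bad_grid_rejected(self):
        kin = sk.GeneKinetics("g", 1.0, 1.0, 1.0)
        with pytest.raises(ConfigError):
            sk.solve_two_compartment(kin, sk.ImpulseParams(), np.array([1.0, 2.0]))
        with pytest.raises(ConfigError):
            sk.solve_two_compartment(kin, sk.ImpulseParams(), np.array([0.0, 2.0, 1.0]))

    def test_decay_switch_accelerates_resolution(self):
        # same transcription, doubled decay after 1 h: the destabilized gene
        # peaks earlier and lower (noise-free expectations)
        imp = sk.ImpulseParams(baseline_rate=50.0, fold_peak=6.0, fold_late=1.0,
                               t_on=1.0, t_off=4.0, slope=4.0)
        grid = np.linspace(0, 24, 97)
        base = sk.GeneKinetics("b", 50.0, 2.0, 0.5)
        destab = sk.GeneKinetics("d", 50.0, 2.0, 0.5,
                                 beta_stim_fold=2.0, beta_switch_time=1.0)
        _, M0 = sk.solve_two_compartment(base, imp, grid)
        _, M1 = sk.solve_two_compartment(destab, imp, grid)
        f0, f1 = M0 / M0[0], M1 / M1[0]
        assert f1.max() < f0.max()
        assert grid[np.argmax(f1)] <= grid[np.argmax(f0)]


class TestLabeledFractions:
    def test_one_compartment_limit(self):
        kin = sk.GeneKinetics("g", 1.0, 1e4, 0.5)
        _, f_m = sk.labeled_fractions(kin, 0.5)
        assert f_m == pytest.approx(1.0 - np.exp(-0.5 * 0.5), rel=1e-3)

    def test_short_and_long_pulse_limits(self):
        kin = sk.GeneKinetics("g", 1.0, 2.0, 0.5)
        f_p0, f_m0 = sk.labeled_fractions(kin, 1e-9)
        assert f_p0 < 1e-6 and f_m0 < 1e-6
        f_p1, f_m1 = sk.labeled_fractions(kin, 1e4)
        assert f_p1 == pytest.approx(1.0) and f_m1 == pytest.approx(1.0)

    def test_equal_rates_value(self):
        # beta = gamma = 1/h, tau = 1 h: the analytic limit gives 1 - 2/e
        kin = sk.GeneKinetics("g", 1.0, 1.0, 1.0)
        _, f_m = sk.labeled_fractions(kin, 1.0)
        assert f_m == pytest.approx(1.0 - 2.0 * np.exp(-1.0), abs=1e-12)

    def test_monotone_in_tau_and_beta(self):
        taus = np.linspace(0.05, 3.0, 15)
        for gamma in (0.5, 2.0, 8.0):
            for beta in (0.1, 1.0, 3.0):
                f = [sk.labeled_fractions(sk.GeneKinetics("g", 1, gamma, beta), t)
                     for t in taus]
                f_p, f_m = zip(*f)
                assert np.all(np.diff(f_p) > 0) and np.all(np.diff(f_m) > 0)
            betas = np.linspace(0.05, 5.0, 20)
            fm = [sk.labeled_fractions(sk.GeneKinetics("g", 1, gamma, b), 1 / 3)[1]
                  for b in betas]
            assert np.all(np.diff(fm) > 0)

    @pytest.mark.parametrize("gamma,beta", [(2.0, 0.5), (1.0, 1.0), (0.7, 3.0)])
    def test_matches_ode_integration_of_labeled_pools(self, gamma, beta):
        # independent oracle: integrate the labeled pools directly
        # (dPl = alpha - gamma Pl, dMl = gamma Pl - beta Ml, zero initial)
        alpha, tau = 10.0, 1.0 / 3.0
        sol = solve_ivp(
            lambda t, y: [alpha - gamma * y[0], gamma * y[0] - beta * y[1]],
            (0, tau), [0.0, 0.0], rtol=1e-11, atol=1e-13,
        )
        f_p_ode = sol.y[0, -1] / (alpha / gamma)
        f_m_ode = sol.y[1, -1] / (alpha / beta)
        f_p, f_m = sk.labeled_fractions(sk.GeneKinetics("g", alpha, gamma, beta), tau)
        assert f_p == pytest.approx(f_p_ode, rel=1e-6)
        assert f_m == pytest.approx(f_m_ode, rel=1e-6)

    def test_invalid_tau(self):
        with pytest.raises(ConfigError):
            sk.labeled_fractions(sk.GeneKinetics("g", 1, 1, 1), 0.0)


class TestSampleCounts:
    def test_zero_expected_gives_zero(self):
        counts = sk.sample_counts(np.zeros((5, 4)), 1.0, 0.05, 0)
        assert counts.sum() == 0

    def test_nb_mean_within_monte_carlo_error(self):
        mean, disp, n = 1000.0, 0.05, 10_000
        counts = sk.sample_counts(np.full((n, 1), mean), 1.0, disp, 42)
        se = np.sqrt((mean + disp * mean**2) / n)
        assert abs(counts.mean() - mean) < 3 * se
        var = counts.var()
        assert 0.8 * (mean + disp * mean**2) < var < 1.2 * (mean + disp * mean**2)

    def test_poisson_degenerate_case(self):
        counts = sk.sample_counts(np.full((20_000, 1), 100.0), 1.0, 0.0, 7)
        assert counts.var() == pytest.approx(100.0, rel=0.1)

    def test_seed_reproducibility(self):
        exp = np.full((50, 6), 37.0)
        a = sk.sample_counts(exp, 1.0, 0.05, 3)
        b = sk.sample_counts(exp, 1.0, 0.05, 3)
        c = sk.sample_counts(exp, 1.0, 0.05, 4)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_invalid_inputs(self):
        with pytest.raises(ConfigError):
            sk.sample_counts(np.ones((2, 2)), 1.0, -0.1, 0)
        with pytest.raises(DataError):
            sk.sample_counts(np.array([[-1.0]]), 1.0, 0.05, 0)


class TestSimulateCourse:
    def test_constant_decay_mature_tracks_precursor(self):
        # quasi-static regime: decay much faster than the impulse changes,
        # so the noise-free mature trajectory is a near-scaled copy of the
        # precursor trajectory (scaling gamma/beta does not affect r)
        arch = sk.Archetype(
            "fast", 1.0,
            sk.ImpulseParams(fold_peak=4.0, fold_late=1.0, t_on=4.0, t_off=12.0,
                             slope=1.0),
            beta_range=(4.0, 8.0), gamma_range=(5.0, 10.0),
        )
        cfg = sk.CourseConfig(n_genes=20, archetypes=[arch], n_reference=0)
        sim = sk.simulate_course(cfg, seed=2)
        for g in sim.expected["mature"].index:
            m = sim.expected["mature"].loc[g]
            p = sim.expected["precursor"].loc[g]
            assert np.corrcoef(m, p)[0, 1] > 0.99

    def test_empty_gene_set(self):
        cfg = sk.CourseConfig(n_genes=0, n_reference=0)
        sim = sk.simulate_course(cfg, seed=0)
        assert sim.course["mature"].counts.shape[0] == 0
        assert sim.course["mature"].sample_meta.shape[0] == 24

    def test_empty_archetypes_rejected(self):
        with pytest.raises(ConfigError):
            sk.simulate_course(sk.CourseConfig(n_genes=10, archetypes=[]), 0)

    def test_destabilized_genes_peak_earlier_and_lower(self, small_sim):
        # matched by archetype: destabilized shares the activated_mid impulse
        truth = small_sim.truth
        exp = small_sim.expected["mature"]
        grid = exp.columns.to_numpy(dtype=float)

        def peak_stats(genes):
            f = exp.loc[genes].to_numpy() / exp.loc[genes].to_numpy()[:, :1]
            return grid[np.argmax(f, axis=1)], f.max(axis=1)

        destab = truth.archetypes.index[truth.archetypes == "destabilized"]
        const = truth.archetypes.index[truth.archetypes == "activated_mid"]
        t_d, h_d = peak_stats(destab)
        t_c, h_c = peak_stats(const)
        assert np.median(t_d) <= np.median(t_c)
        assert np.median(h_d) < np.median(h_c)

    def test_distinct_seeds_distinct_counts(self):
        cfg = sk.CourseConfig(n_genes=20, n_reference=0)
        a = sk.simulate_course(cfg, 1).course["mature"].counts
        b = sk.simulate_course(cfg, 2).course["mature"].counts
        assert not a.equals(b)


class TestSimulateUtrs:
    def test_unplanted_background_frequency(self):
        genes = pd.Series(np.arange(400, dtype=float),
                          index=[f"G{i}" for i in range(400)])
        records, planted = sk.simulate_utrs(genes, "UAUUUAU", 0.0, length=200, seed=5)
        assert planted == []
        n_with = sum("UAUUUAU" in seq for _, seq in records)
        # expected per-sequence hit probability ~ 194 * 4^-7 ~ 0.0118
        expect = 400 * 194 * 0.25**7
        assert n_with <= expect + 4 * np.sqrt(expect) + 1

    def test_full_planting_covers_top_quartile(self):
        genes = pd.Series(np.arange(100, dtype=float),
                          index=[f"G{i}" for i in range(100)])
        records, planted = sk.simulate_utrs(genes, "AUUUA", 1.0, length=80, seed=0)
        top = set(genes.sort_values(ascending=False).index[:25])
        assert set(planted) == top
        seqs = dict(records)
        assert all("AUUUA" in seqs[g] for g in top)

    def test_seed_reproducibility_and_errors(self):
        genes = pd.Series([1.0, 2.0], index=["a", "b"])
        r1, _ = sk.simulate_utrs(genes, "ACG", 0.5, length=30, seed=9)
        r2, _ = sk.simulate_utrs(genes, "ACG", 0.5, length=30, seed=9)
        assert r1 == r2
        dup = pd.Series([1.0, 2.0], index=["a", "a"])
        with pytest.raises(DataError):
            sk.simulate_utrs(dup, "ACG", 0.5, length=30, seed=0)
        with pytest.raises(ConfigError):
            sk.simulate_utrs(genes, "ACG", 1.5, length=30, seed=0)


class TestSimulateScreen:
    def _effects(self):
        sirnas = [f"si{g}_{i}" for g in "AB" for i in (1, 2)]
        return (pd.Series(1.0, index=sirnas),
                pd.Series([s[2] for s in sirnas], index=sirnas))

    def test_noise_free_null_readings_all_equal(self):
        effects, genes = self._effects()
        plate = sk.simulate_screen(effects, genes, n_plates=2, batch_sd=0.0,
                                   noise_sd=0.0, viability_sd=0.0,
                                   viability_read_sd=0.0, seed=0)
        from steroidokin.screen import normalize_wells
        norm = normalize_wells(plate)
        assert np.allclose(norm["normalized"], 1.0)

    def test_batch_factor_cancels_in_normalization(self):
        effects, genes = self._effects()
        plate = sk.simulate_screen(effects, genes, n_plates=2, batch_sd=1.0, seed=3)
        from steroidokin.screen import normalize_wells
        norm1 = normalize_wells(plate)
        scaled = plate.copy()
        scaled.loc[scaled["plate"] == "P1", "aldosterone"] *= 2.0
        norm2 = normalize_wells(scaled)
        pd.testing.assert_series_equal(norm1["normalized"], norm2["normalized"])

    def test_plate_without_mock_rejected(self):
        effects, genes = self._effects()
        with pytest.raises(ConfigError):
            sk.simulate_screen(effects, genes, mocks_per_plate=0, seed=0)
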