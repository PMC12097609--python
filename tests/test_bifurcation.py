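"""Attractor classification, Lyapunov exponents, scans, Hopf detection."""

import warnings

import numpy as np
import pytest

from ecogame import (SolverConfig, StateVector, classify_attractor,
                     hopf_threshold, largest_lyapunov, scan_1d, scan_2d,
                     simulate)
from ecogame import bifurcation as bif
from ecogame.bifurcation import (ClassifierConfig, HopfBracketError,
                                 ScanPolicy)
from ecogame.simulate import FIXED_RK4

LONG = SolverConfig(method=FIXED_RK4, dt_fixed=0.01, t_end=3000.0,
                    transient=1500.0, n_report=3001)
MID = SolverConfig(method=FIXED_RK4, dt_fixed=0.01, t_end=1000.0,
                   transient=500.0, n_report=2001)

# stability threshold of the coexistence state along the fixed strategy x
# at beta0=0.95, frozen from the eigenvalue bisection and confirmed by
# long-horizon simulation (oscillation dies between x=0.36 and 0.38)
X_HOPF = 0.3623756


class TestHopfThreshold:
    def test_two_independent_routes_agree(self, base_params):
        """Sweeping x at fixed beta0 and sweeping beta0 at x=0 probe the
        same effective-transmission threshold: beta* = beta0 (1 - x*)."""
        p95 = base_params.with_updates(beta0=0.95)
        x_star = hopf_threshold(p95, "x", (0.2, 0.8), tol=1e-10)
        beta_star = hopf_threshold(base_params, "beta0", (0.55, 0.7),
                                   tol=1e-10)
        assert x_star == pytest.approx(X_HOPF, abs=1e-5)
        assert 1.0 - beta_star / 0.95 == pytest.approx(x_star, abs=1e-6)

    def test_threshold_separates_stable_from_oscillatory(self, base_params,
                                                         standard_ic):
        """Long-horizon simulation flips from sustained oscillation to decay
        across the eigenvalue crossing."""
        p95 = base_params.with_updates(beta0=0.95)
        sc = SolverConfig(method=FIXED_RK4, dt_fixed=0.01, t_end=12000.0,
                          transient=10000.0, n_report=4001)
        amps = {}
        for x in (X_HOPF - 0.04, X_HOPF + 0.04):
            s0 = StateVector(standard_ic.S, standard_ic.I, standard_ic.P, x)
            post = simulate(p95, s0, sc).post_transient()
            amps[x] = post.S.max() - post.S.min()
        assert amps[X_HOPF - 0.04] > 1e-2
        assert amps[X_HOPF + 0.04] < 1e-4

    def test_bracket_without_sign_change_raises(self, base_params):
        with pytest.raises(HopfBracketError):
            hopf_threshold(base_params.with_updates(beta0=0.95), "x",
                           (0.05, 0.2))

    def test_bracket_with_no_equilibrium_anywhere_raises(self, base_params):
        with pytest.raises(bif.EquilibriumLostError):
            hopf_threshold(base_params.with_updates(beta0=0.95), "x",
                           (0.6, 0.9))


class TestLyapunov:
    def test_negative_at_a_stable_equilibrium(self, base_params):
        lam = largest_lyapunov(base_params,
                               StateVector(0.9, 0.05, 0.05, 0.0),
                               transient=500.0, window=500.0)
        assert lam is not None and lam < 0

    def test_near_zero_on_a_limit_cycle(self, base_params):
        cfg = ClassifierConfig()
        lam = largest_lyapunov(base_params.with_updates(beta0=0.8),
                               StateVector(0.99, 0.01, 0.01, 0.0),
                               config=cfg, transient=3000.0, window=3000.0)
        assert lam is not None and abs(lam) < cfg.chaos_tol

    def test_flagged_not_applicable_on_collapsed_reference(self, base_params):
        # on the total-extinction state the exponent is meaningless; the
        # estimator must refuse rather than return a number
        lam = largest_lyapunov(base_params, StateVector(0.0, 0.0, 0.0, 0.0),
                               transient=200.0, window=200.0)
        assert lam is None


class TestClassifyAttractor:
    def test_steady_coexistence_point(self, base_params):
        """A small kick off the weakly stable coexistence focus decays back,
        and the classifier reports a steady point with no extinctions."""
        from ecogame import coexistence_equilibrium
        p = base_params.with_updates(beta0=0.6)
        eq = coexistence_equilibrium(p)
        kicked = StateVector(*(eq.state.to_array()[:3] * 1.001), 0.0)
        traj = simulate(p, kicked,
                        SolverConfig(method=FIXED_RK4, dt_fixed=0.01,
                                     t_end=24000.0, transient=12000.0,
                                     n_report=4001))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s = classify_attractor(traj)
        assert s.regime == "stable_point"
        assert s.extinct == ()

    def test_disease_free_collapse_is_stable_point_with_extinctions(
            self, base_params, standard_ic):
        traj = simulate(base_params, standard_ic, LONG)  # beta0=0.5
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s = classify_attractor(traj)
        assert s.dynamics == "stable_point"
        assert s.regime == "extinct_I_and_P"
        assert set(s.extinct) == {"I", "P"}

    def test_limit_cycle_coexistence(self, base_params, standard_ic):
        traj = simulate(base_params.with_updates(beta0=0.8), standard_ic,
                        LONG)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s = classify_attractor(traj)
        assert s.regime in ("limit_cycle", "period_doubled")
        assert s.extinct == ()
        assert s.amplitude("S") > 0.1

    def test_allee_predator_extinction_label(self, base_params, standard_ic):
        traj = simulate(base_params.with_updates(beta0=0.95, theta=0.3),
                        standard_ic, LONG)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s = classify_attractor(traj)
        assert s.regime == "extinct_P"
        assert s.dynamics in ("limit_cycle", "period_doubled")

    def test_chaos_rule_engages_above_threshold(self, base_params,
                                                standard_ic, monkeypatch):
        """The decision rule labels chaotic when the measured exponent
        exceeds the chaos tolerance."""
        traj = simulate(base_params.with_updates(beta0=0.8), standard_ic,
                        MID)
        monkeypatch.setattr(bif, "largest_lyapunov",
                            lambda *a, **k: 0.05)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s = classify_attractor(traj)
        assert s.regime == "chaotic"
        assert s.lyapunov == 0.05

    def test_transient_shorter_than_half_horizon_required(self, base_params,
                                                          standard_ic):
        sc = SolverConfig(t_end=100.0, transient=80.0, n_report=201)
        traj = simulate(base_params, standard_ic, sc)
        with pytest.raises(ValueError):
            classify_attractor(traj)


class TestScans:
    def test_single_point_scan_equals_direct_classification(self, base_params,
                                                            standard_ic):
        p = base_params.with_updates(beta0=0.8)
        res = scan_1d(p, "beta0", [0.8], policy=ScanPolicy(state0=standard_ic),
                      solver=MID)
        traj = simulate(p, standard_ic, MID)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            direct = classify_attractor(traj)
        s = res.summaries[(0.8,)]
        assert s.regime == direct.regime
        np.testing.assert_array_equal(s.peak_values["S"],
                                      direct.peak_values["S"])

    def test_regime_ladder_along_transmission_rate(self, base_params,
                                                   standard_ic):
        res = scan_1d(base_params, "beta0", [0.5, 0.8, 0.95],
                      policy=ScanPolicy(state0=standard_ic), solver=LONG)
        assert res.summaries[(0.5,)].dynamics == "stable_point"
        for b in (0.8, 0.95):
            assert res.summaries[(b,)].regime in ("limit_cycle",
                                                  "period_doubled")

    def test_continuation_and_fixed_policies_agree_without_bistability(
            self, base_params, standard_ic):
        grid = [0.7, 0.8, 0.9]
        fixed = scan_1d(base_params, "beta0", grid,
                        policy=ScanPolicy(state0=standard_ic), solver=MID)
        cont = scan_1d(base_params, "beta0", grid,
                       policy=ScanPolicy(state0=standard_ic,
                                         continuation=True), solver=MID)
        for v in grid:
            assert fixed.summaries[(v,)].regime == cont.summaries[(v,)].regime

    def test_scan_labels_unchanged_when_horizon_doubles(self, base_params,
                                                        standard_ic):
        """Regime labels along x are settled away from the bifurcation
        point (settling time diverges at the threshold itself)."""
        p95 = base_params.with_updates(beta0=0.95)
        grid = [0.15, 0.3, 0.55, 0.85]
        pol = ScanPolicy(state0=standard_ic)
        sc1 = SolverConfig(method=FIXED_RK4, dt_fixed=0.01, t_end=6000.0,
                           transient=3000.0, n_report=4001)
        sc2 = SolverConfig(method=FIXED_RK4, dt_fixed=0.01, t_end=12000.0,
                           transient=6000.0, n_report=8001)
        r1 = scan_1d(p95, "x", grid, policy=pol, solver=sc1)
        r2 = scan_1d(p95, "x", grid, policy=pol, solver=sc2)
        for v in grid:
            assert r1.summaries[(v,)].regime == r2.summaries[(v,)].regime

    def test_two_dimensional_single_cell(self, base_params):
        p = base_params.with_updates(beta0=0.95, x_mode="dynamic",
                                     CS=0.5, CP=0.5)
        res = scan_2d(p, ("CS", "e"), ([0.5], [1.0]), solver=MID)
        assert len(res.summaries) == 1
        assert (0.5, 1.0) in res.summaries

    def test_decreasing_grid_rejected(self, base_params):
        with pytest.raises(ValueError):
            scan_1d(base_params, "beta0", [0.9, 0.5], solver=MID)

    def test_long_format_table_and_summary(self, base_params, standard_ic,
                                           tmp_path):
        res = scan_1d(base_params, "beta0", [0.5, 0.8],
                      policy=ScanPolicy(state0=standard_ic), solver=MID)
        df = res.to_frame()
        assert set(df.columns) == {"beta0", "compartment", "peak", "regime"}
        assert set(df["compartment"].dropna()) == {"S", "I", "P"}
        res.write(tmp_path / "scan.csv")
        assert (tmp_path / "scan.csv").exists()
        assert (tmp_path / "scan.csv.json").exists()
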