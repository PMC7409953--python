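"""Closed-form nuisance optima vs numerical oracles; per-type scoring laws."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize, minimize_scalar

import idpscore as ip
from idpscore import DataType, KarplusPriors, UncertaintyConfig

LOG_SQRT_2PI = 0.5 * math.log(2 * math.pi)


def peak(sigma):
    return -(math.log(sigma) + LOG_SQRT_2PI)


def offset_objective(q, target, avg, sq, sex):
    return (peak(sq) - q ** 2 / (2 * sq ** 2)
            + peak(sex) - (target - q - avg) ** 2 / (2 * sex ** 2))


class TestOffsetModel:
    def test_zero_residual_peak(self):
        sol = ip.optimize_offset(5.0, 5.0, 0.3, 0.03)
        assert sol.offset == 0.0
        assert sol.eps_star == 0.0
        assert sol.logp == pytest.approx(peak(0.3) + peak(0.03), abs=1e-12)

    def test_equal_sigmas_split_discrepancy(self):
        sol = ip.optimize_offset(2.0, 0.0, 1.0, 1.0)
        assert sol.offset == pytest.approx(1.0)
        assert sol.eps_star == pytest.approx(1.0)

    def test_sigma_q_zero_pins_offset(self):
        sol = ip.optimize_offset(3.0, 1.0, 0.0, 0.5)
        assert sol.offset == 0.0
        assert sol.eps_star == pytest.approx(2.0)
        assert sol.logp == pytest.approx(peak(0.5) - 4.0 / (2 * 0.25))

    def test_sigma_ex_must_be_positive(self):
        with pytest.raises(ValueError):
            ip.optimize_offset(1.0, 0.0, 0.1, 0.0)

    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(200):
            target, avg = rng.normal(scale=5, size=2)
            sq, sex = rng.uniform(0.05, 3.0, size=2)
            sol = ip.optimize_offset(target, avg, sq, sex)
            res = minimize_scalar(lambda q: -offset_objective(q, target, avg, sq, sex),
                                  bounds=(-50, 50), method="bounded",
                                  options={"xatol": 1e-12})
            assert sol.logp == pytest.approx(-res.fun, abs=1e-8)
            assert sol.offset == pytest.approx(res.x, abs=1e-6)

    @given(target=st.floats(-20, 20), avg=st.floats(-20, 20),
           sq=st.floats(0.01, 5), sex=st.floats(0.01, 5))
    @settings(max_examples=200, deadline=None)
    def test_stationarity_identity(self, target, avg, sq, sex):
        """q* sigma_ex^2 = eps* sigma_q^2 at every optimum."""
        sol = ip.optimize_offset(target, avg, sq, sex)
        assert abs(sol.offset * sex ** 2 - sol.eps_star * sq ** 2) < 1e-10 * max(
            1.0, abs(target - avg))

    def test_logp_maximal_when_average_hits_target(self):
        logps = [ip.optimize_offset(4.0, avg, 0.5, 0.2).logp
                 for avg in np.linspace(2, 6, 201)]
        assert np.argmax(logps) == 100  # avg exactly equal to target


class TestKarplusModel:
    def test_zero_discrepancy_returns_prior_means(self):
        p = KarplusPriors()
        target = p.mu_a + p.mu_b + p.mu_c  # a1 = a2 = 1
        sol = ip.optimize_karplus(1.0, 1.0, target, p, 0.5)
        assert sol.abc == pytest.approx((p.mu_a, p.mu_b, p.mu_c))
        assert sol.eps_star == pytest.approx(0.0)
        expected = (peak(p.sigma_a) + peak(p.sigma_b) + peak(p.sigma_c) + peak(0.5))
        assert sol.logp == pytest.approx(expected, abs=1e-12)

    def test_tight_priors_reduce_to_fixed_karplus(self):
        """sigma_A,B,C -> 0: only the experimental residual term varies."""
        p0 = KarplusPriors()
        tight = KarplusPriors(sigma_a=1e-9, sigma_b=1e-9, sigma_c=1e-9)
        a1, a2, sex = -0.6, 0.5, 0.5
        for target in (4.0, 6.0, 9.0):
            sol = ip.optimize_karplus(a1, a2, target, tight, sex)
            eps0 = target - (p0.mu_a * a2 + p0.mu_b * a1 + p0.mu_c)
            fixed = peak(sex) - eps0 ** 2 / (2 * sex ** 2)
            prior_peaks = peak(1e-9) * 3
            assert sol.logp - prior_peaks == pytest.approx(fixed, abs=1e-6)
            assert sol.abc == pytest.approx((p0.mu_a, p0.mu_b, p0.mu_c), abs=1e-6)

    def test_matches_numerical_3d_maximization(self):
        p = KarplusPriors()
        rng = np.random.default_rng(8)
        for _ in range(100):
            a1 = rng.uniform(-1, 1)
            a2 = rng.uniform(a1 ** 2, 1)
            target = rng.uniform(0, 12)

            def neg(theta):
                a, b, c = theta
                eps = target - (a * a2 + b * a1 + c)
                return -(peak(p.sigma_a) - (a - p.mu_a) ** 2 / (2 * p.sigma_a ** 2)
                         + peak(p.sigma_b) - (b - p.mu_b) ** 2 / (2 * p.sigma_b ** 2)
                         + peak(p.sigma_c) - (c - p.mu_c) ** 2 / (2 * p.sigma_c ** 2)
                         + peak(0.5) - eps ** 2 / (2 * 0.25))

            sol = ip.optimize_karplus(a1, a2, target, p, 0.5)
            res = minimize(neg, [p.mu_a, p.mu_b, p.mu_c], method="Nelder-Mead",
                           options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
            assert sol.logp == pytest.approx(-res.fun, abs=1e-6)

    def test_jensen_violation_rejected(self):
        with pytest.raises(ValueError, match="Jensen"):
            ip.optimize_karplus(0.9, 0.5, 6.0, KarplusPriors(), 0.5)

    def test_logp_maximal_at_zero_discrepancy(self):
        p = KarplusPriors()
        a1, a2 = -0.5, 0.4
        center = p.mu_a * a2 + p.mu_b * a1 + p.mu_c
        logps = [ip.optimize_karplus(a1, a2, center + d, p, 0.5).logp
                 for d in np.linspace(-2, 2, 201)]
        assert np.argmax(logps) == 100


class TestDistanceAveraging:
    def test_equal_distances_identity(self):
        assert ip.ensemble_average_distance([7.3] * 5) == pytest.approx(7.3)

    def test_two_distance_value(self):
        expected = (0.5 * (4.0 ** -6 + 8.0 ** -6)) ** (-1 / 6)
        assert ip.ensemble_average_distance([4.0, 8.0]) == pytest.approx(expected)
        assert expected == pytest.approx(4.478, abs=5e-4)

    def test_weighted_toward_minimum_and_monotone(self):
        d = [6.0, 9.0, 12.0]
        avg = ip.ensemble_average_distance(d)
        assert min(d) < avg < np.mean(d)
        assert ip.ensemble_average_distance(d + [3.0]) < avg

    def test_empty_and_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            ip.ensemble_average_distance([])
        with pytest.raises(ValueError):
            ip.ensemble_average_distance([2.0, -1.0])


class TestScoreType:
    def test_identical_conformers_average_to_that_conformer(self, pool_small,
                                                            restraints_small):
        dt = DataType.CS
        table = pool_small.tables[dt]
        members = np.full(10, 3)
        avg = ip.ensemble_averages(table, members)
        np.testing.assert_allclose(avg, table.values[3], atol=1e-12)

    def test_cs_score_decomposes_into_offset_calls(self):
        cfg = UncertaintyConfig()
        rset = ip.RestraintSet(DataType.CS, ["1.CA", "2.CB", "3.HA"],
                               [55.0, 39.0, 4.1], [0.3, 0.3, 0.03])
        rng = np.random.default_rng(5)
        table = ip.BackCalcTable(DataType.CS, list(range(5)), rset.ids,
                                 rng.normal([55, 39, 4.1], 1.0, size=(5, 3)))
        members = np.array([0, 1, 1, 4, 2])
        ts = ip.score_type(rset, table, members, cfg)
        expected = sum(
            ip.optimize_offset(rset.target[j], table.values[members, j].mean(),
                               cfg.sigma_q(DataType.CS, rset.ids[j]),
                               rset.sigma_exp[j]).logp
            for j in range(3))
        assert ts.total == pytest.approx(expected, abs=1e-10)

    def test_noe_uses_r6_average(self, pool_small, restraints_small):
        dt = DataType.NOE
        members = np.arange(0, 40)
        ts = ip.score_type(restraints_small[dt], pool_small.tables[dt], members)
        d0 = pool_small.tables[dt].values[members, 0]
        assert ts.calc[0] == pytest.approx(ip.ensemble_average_distance(d0))

    def test_fret_averages_efficiencies_not_distances(self):
        """<E> = mean of per-conformer efficiencies (fast-exchange regime)."""
        params = ip.FretParams()
        r = np.array([30.0, 80.0])
        eff = np.array([ip.fret_efficiency(v, params.r0) for v in r])
        rset = ip.RestraintSet(DataType.FRET, ["E.1"], [0.5], [0.02])
        table = ip.BackCalcTable(DataType.FRET, [0, 1], ["E.1"], eff[:, None])
        ts = ip.score_type(rset, table, [0, 1])
        assert ts.calc[0] == pytest.approx(eff.mean())
        assert ts.calc[0] != pytest.approx(ip.fret_efficiency(r.mean(), params.r0))

    def test_mismatched_type_rejected(self, pool_small, restraints_small):
        with pytest.raises(ValueError, match="does not match"):
            ip.score_type(restraints_small[DataType.CS],
                          pool_small.tables[DataType.RDC], [0, 1])


class TestSaxs:
    def _setup(self, n_q=20, ns_override=None):
        cfg = UncertaintyConfig()
        if ns_override is not None:
            cfg.saxs = ip.SaxsParams(ns_override=ns_override)
        q = np.linspace(0.01, 0.3, n_q)
        ids = [format(v, ".8g") for v in q]
        rng = np.random.default_rng(2)
        rset = ip.RestraintSet(DataType.SAXS, ids, np.exp(-q), cfg.saxs_sigma_exp(q))
        table = ip.BackCalcTable(DataType.SAXS, list(range(8)), ids,
                                 np.exp(-np.outer(rng.uniform(0.9, 1.1, 8), q)))
        return cfg, rset, table

    def test_shannon_channels_arithmetic(self):
        assert ip.shannon_channels(math.pi, 0.0, 3.0) == pytest.approx(3.0)
        assert ip.shannon_channels(0.0, 0.0, 1.0) == 0.0
        assert ip.shannon_channels(60.0, 0.01, 0.30) == pytest.approx(5.539, abs=5e-4)
        with pytest.raises(ValueError):
            ip.shannon_channels(60.0, 0.3, 0.1)

    def test_ns_equal_nq_is_unweighted_sum(self):
        cfg, rset, table = self._setup(n_q=20, ns_override=20)
        ts = ip.score_saxs(rset, table, np.arange(8), cfg)
        assert ts.shannon_weight == 1.0
        assert ts.total == pytest.approx(float(ts.logp.sum()), abs=1e-12)

    def test_half_ns_halves_total(self):
        cfg_full, rset, table = self._setup(n_q=20, ns_override=20)
        cfg_half, _, _ = self._setup(n_q=20, ns_override=10)
        full = ip.score_saxs(rset, table, np.arange(8), cfg_full)
        half = ip.score_saxs(rset, table, np.arange(8), cfg_half)
        assert half.total == pytest.approx(0.5 * full.total, abs=1e-12)

    def test_oversampled_curve_weight(self):
        # a 37-point curve carrying ~3 Shannon channels is down-weighted to 3/37
        cfg, rset, table = self._setup(n_q=37, ns_override=3.0)
        ts = ip.score_saxs(rset, table, np.arange(8), cfg)
        assert ts.shannon_weight == pytest.approx(3 / 37)

    def test_residual_only_switch_keeps_norm_constants(self):
        cfg, rset, table = self._setup(n_q=20, ns_override=10)
        cfg.saxs = ip.SaxsParams(ns_override=10, weight_residual_only=True)
        ts = ip.score_saxs(rset, table, np.arange(8), cfg)
        nc = sum(peak(cfg.saxs_sigma_q) + peak(s) for s in rset.sigma_exp)
        expected = nc + 0.5 * (float(ts.logp.sum()) - nc)
        assert ts.total == pytest.approx(expected, abs=1e-10)


class TestTotalScore:
    def test_empty_active_set_is_zero(self, pool_small, restraints_small):
        scores = [ip.score_type(restraints_small[dt], pool_small.tables[dt],
                                np.arange(20)) for dt in restraints_small]
        assert ip.total_score(scores, active=[]) == 0.0

    def test_single_type_equals_its_total(self, pool_small, restraints_small):
        scores = [ip.score_type(restraints_small[dt], pool_small.tables[dt],
                                np.arange(20)) for dt in restraints_small]
        jc = next(s for s in scores if s.datatype is DataType.JC)
        assert ip.total_score(scores, active=[DataType.JC]) == pytest.approx(jc.total)

    def test_all_types_decompose(self, pool_small, restraints_small):
        scores = [ip.score_type(restraints_small[dt], pool_small.tables[dt],
                                np.arange(20)) for dt in restraints_small]
        assert ip.total_score(scores) == pytest.approx(sum(s.total for s in scores))

    def test_removing_one_restraint_changes_total_by_its_logp(self, pool_small,
                                                              restraints_small):
        dt = DataType.PRE
        rset = restraints_small[dt]
        table = pool_small.tables[dt]
        members = np.arange(30)
        full = ip.score_type(rset, table, members)
        sub = ip.RestraintSet(dt, rset.ids[:-1], rset.target[:-1], rset.sigma_exp[:-1])
        sub_table = ip.BackCalcTable(dt, table.conformer_ids, table.restraint_ids[:-1],
                                     table.values[:, :-1])
        reduced = ip.score_type(sub, sub_table, members)
        assert full.total - reduced.total == pytest.approx(float(full.logp[-1]),
                                                           abs=1e-10)
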