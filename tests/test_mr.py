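"""Two-sample MR estimators, diagnostics, FDR adjustment, and the 2x2 OR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from cismr.instruments import InstrumentSet
from cismr.mr import bh_adjust, cochran_q, egger, ivw_fe, or_2x2, wald_ratio
from cismr.simulate import simulate_mr


def make_inst(bx, by, sy, sx=0.01, gene="G"):
    bx = np.asarray(bx, float)
    table = pd.DataFrame({
        "variant_id": [f"rs{i}" for i in range(len(bx))],
        "pos": 1000 * np.arange(len(bx)),
        "beta_exposure": bx,
        "se_exposure": sx,
        "pvalue_exposure": 1e-10,
        "eaf": 0.3,
        "beta_outcome": np.asarray(by, float),
        "se_outcome": np.asarray(sy, float),
        "pvalue_outcome": 0.5,
    })
    return InstrumentSet(gene=gene, protein=gene, table=table)


class TestWaldRatio:
    @pytest.mark.parametrize("bx,by,sy,theta,se", [
        (1.0, 0.174, 0.036, 0.174, 0.036),
        (0.5, 0.1, 0.05, 0.2, 0.1),
        (-0.5, 0.1, 0.05, -0.2, 0.1),
    ])
    def test_closed_form(self, bx, by, sy, theta, se):
        t, s, p = wald_ratio(bx, 0.01, by, sy)
        assert t == pytest.approx(theta)
        assert s == pytest.approx(se)
        assert p == pytest.approx(2 * stats.norm.sf(abs(theta / se)))

    def test_zero_exposure_effect_rejected(self):
        with pytest.raises(ValueError):
            wald_ratio(0.0, 0.01, 0.1, 0.05)


class TestIvwFe:
    def test_single_instrument_equals_wald_ratio(self):
        inst = make_inst([0.5], [0.1], [0.05])
        res = ivw_fe(inst)
        t, s, p = wald_ratio(0.5, 0.01, 0.1, 0.05)
        assert res.method == "wald_ratio"
        assert (res.theta, res.se, res.pvalue) == (t, s, p)

    def test_equal_weight_pair_is_the_mean_ratio(self):
        res = ivw_fe(make_inst([1, 1], [0.2, 0.3], [0.1, 0.1]))
        assert res.theta == pytest.approx(0.25)
        assert res.se == pytest.approx(0.1 / np.sqrt(2))

    def test_matches_wls_through_origin_oracle(self, rng):
        """IVW equals weighted least squares of by on bx through the origin."""
        bx = rng.normal(0.2, 0.1, size=10)
        by = 0.3 * bx + rng.normal(0, 0.02, size=10)
        sy = rng.uniform(0.01, 0.05, size=10)
        res = ivw_fe(make_inst(bx, by, sy))
        w = 1 / sy**2
        x = (bx * np.sqrt(w))[:, None]
        y = by * np.sqrt(w)
        slope = float(np.linalg.lstsq(x, y, rcond=None)[0][0])
        assert res.theta == pytest.approx(slope, abs=1e-10)

    def test_or_fields_are_exponentiated_theta(self):
        res = ivw_fe(make_inst([1, 1], [0.2, 0.3], [0.1, 0.1]))
        assert res.or_point == pytest.approx(np.exp(res.theta))
        assert res.or_low95 == pytest.approx(np.exp(res.theta - 1.96 * res.se))
        assert res.or_high95 == pytest.approx(np.exp(res.theta + 1.96 * res.se))

    def test_recovers_true_effect_with_nominal_coverage(self):
        """theta = 0.3, 50 strong instruments: bias < 0.02, coverage 93-97%."""
        thetas, covered = [], 0
        for seed in range(500):
            inst, truth = simulate_mr(50, theta=0.3, seed=seed)
            res = ivw_fe(inst)
            thetas.append(res.theta)
            lo, hi = res.theta - 1.96 * res.se, res.theta + 1.96 * res.se
            covered += lo <= 0.3 <= hi
        assert np.mean(thetas) == pytest.approx(0.3, abs=0.02)
        assert 0.93 <= covered / 500 <= 0.97

    def test_type_i_error_at_strict_threshold(self):
        """Under theta = 0 the MR test rejects at 5e-4 at its nominal rate."""
        alpha, n_rep = 5e-4, 20_000
        rej = 0
        for seed in range(n_rep):
            inst, _ = simulate_mr(10, theta=0.0, seed=seed)
            rej += ivw_fe(inst).pvalue < alpha
        lo = stats.binom.ppf(0.0025, n_rep, alpha)
        hi = stats.binom.ppf(0.9975, n_rep, alpha)
        assert lo <= rej <= hi


class TestCochranQ:
    def test_homogeneous_ratios_give_zero_q(self):
        inst = make_inst([0.5, 1.0, 2.0], [0.1, 0.2, 0.4], [0.05, 0.05, 0.05])
        res = ivw_fe(inst)
        q, df, p = cochran_q(inst, res.theta)
        assert q == pytest.approx(0.0, abs=1e-20)
        assert df == 2 and p == pytest.approx(1.0)

    def test_hand_computed_two_snp_case(self):
        # ratios 0.2 and 0.3 with equal weights w = bx^2/sy^2 = 100
        inst = make_inst([1.0, 1.0], [0.2, 0.3], [0.1, 0.1])
        q, df, p = cochran_q(inst, 0.25)
        assert q == pytest.approx(100 * (0.05**2 + 0.05**2))
        assert df == 1
        assert p == pytest.approx(stats.chi2.sf(0.5, 1))

    def test_single_instrument_not_testable(self):
        with pytest.raises(ValueError):
            cochran_q(make_inst([1.0], [0.2], [0.1]), 0.2)

    def test_rejection_rate_under_homogeneity(self):
        """Null calibration: ~5% of homogeneous 5-SNP sets reject at 0.05."""
        n_rep, rej = 2000, 0
        for seed in range(n_rep):
            inst, _ = simulate_mr(5, theta=0.2, seed=10_000 + seed)
            res = ivw_fe(inst)
            rej += res.q_pvalue < 0.05
        assert 0.035 <= rej / n_rep <= 0.065


class TestEgger:
    def test_exact_proportional_fit(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        slope, a, a_se, a_p = egger(make_inst(bx, 0.2 * bx, [0.05] * 4))
        assert a == pytest.approx(0.0, abs=1e-12)
        assert slope == pytest.approx(0.2)

    def test_exact_affine_fit(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        slope, a, _, _ = egger(make_inst(bx, 0.05 + 0.2 * bx, [0.05] * 4))
        assert a == pytest.approx(0.05)
        assert slope == pytest.approx(0.2)

    def test_matches_wls_oracle_on_noisy_data(self, rng):
        bx = np.abs(rng.normal(0.2, 0.1, size=20)) + 0.01
        by = 0.04 + 0.3 * bx + rng.normal(0, 0.02, size=20)
        sy = rng.uniform(0.01, 0.05, size=20)
        slope, a, a_se, _ = egger(make_inst(bx, by, sy))
        # explicit normal-equations oracle for weighted affine regression
        w = 1 / sy**2
        X = np.column_stack([np.ones_like(bx), bx])
        xtwx = X.T @ (w[:, None] * X)
        coef = np.linalg.solve(xtwx, X.T @ (w * by))
        assert a == pytest.approx(coef[0], abs=1e-10)
        assert slope == pytest.approx(coef[1], abs=1e-10)

    def test_fewer_than_three_instruments_rejected(self):
        with pytest.raises(ValueError):
            egger(make_inst([0.1, 0.2], [0.02, 0.04], [0.05, 0.05]))

    def test_sign_orientation_invariance(self):
        bx = np.array([0.1, -0.2, 0.3, -0.4])
        by = 0.05 + 0.2 * bx
        by[bx < 0] = 0.05 - 0.2 * bx[bx < 0]  # pleiotropy rides the oriented scale
        flipped = make_inst(-bx, -by, [0.05] * 4)
        same = make_inst(bx, by, [0.05] * 4)
        assert egger(flipped) == pytest.approx(egger(same))

    def test_recovers_injected_directional_pleiotropy(self):
        """alpha = 0.05 on 20 instruments: mean intercept within +/- 0.01."""
        intercepts = []
        for seed in range(500):
            inst, _ = simulate_mr(20, theta=0.0, pleiotropy_alpha=0.05, seed=seed)
            _, a, _, _ = egger(inst)
            intercepts.append(a)
        assert np.mean(intercepts) == pytest.approx(0.05, abs=0.01)


class TestBhAdjust:
    def test_reference_screen_worked_values(self):
        """BH against a 1557-test family reproduces the screen's printed
        adjusted values at ranks 2, 3 and 9 to 3 significant figures."""
        from cismr.datasets import M_PROTEINS, mr_hits_table

        table = mr_hits_table()
        adj = bh_adjust(table["pvalue"].to_numpy(), m_total=M_PROTEINS)
        by_gene = dict(zip(table["gene"], adj))
        assert by_gene["APOC3"] == pytest.approx(1.35e-3, rel=5e-3)
        assert by_gene["MAPK3"] == pytest.approx(3.48e-3, rel=5e-3)
        assert by_gene["DLL1"] == pytest.approx(2.65e-2, rel=5e-3)

    def test_single_p_identity(self):
        assert bh_adjust([0.04], m_total=1)[0] == pytest.approx(0.04)

    def test_matches_statsmodels_when_family_is_fully_observed(self, rng):
        p = rng.uniform(1e-6, 1, size=40)
        ours = bh_adjust(p)
        theirs = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(ours, theirs, atol=1e-12)

    def test_m_total_smaller_than_list_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 0.2], m_total=1)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(1e-9, 1.0), min_size=1, max_size=20),
        st.integers(0, 19),
        st.floats(1.01, 10.0),
    )
    def test_monotone_in_raw_p(self, raw, idx, factor):
        """Increasing any raw p never decreases any adjusted value."""
        raw = list(raw)
        idx %= len(raw)
        base = bh_adjust(raw, m_total=100 + len(raw))
        bumped = list(raw)
        bumped[idx] = min(1.0, bumped[idx] * factor)
        after = bh_adjust(bumped, m_total=100 + len(raw))
        assert np.all(after >= base - 1e-12)

    def test_adjusted_dominate_raw_and_capped(self, rng):
        p = rng.uniform(0, 1, size=30)
        adj = bh_adjust(p, m_total=500)
        assert np.all(adj >= p - 1e-15) and np.all(adj <= 1.0)


class TestOr2x2:
    def test_prs_decile_contrast(self):
        """Top vs bottom polygenic-score decile counts give OR 1.82 (1.60-2.06)."""
        o, lo, hi = or_2x2(723, 6788, 416, 7096)
        assert round(o, 2) == 1.82
        assert round(lo, 2) == 1.60
        assert round(hi, 2) == 2.06

    def test_symmetric_table_is_null(self):
        o, lo, hi = or_2x2(10, 10, 10, 10)
        assert o == pytest.approx(1.0)
        assert lo < 1.0 < hi

    def test_matches_log_odds_difference_oracle(self, rng):
        a, b, c, d = rng.integers(1, 500, size=4)
        o, lo, hi = or_2x2(int(a), int(b), int(c), int(d))
        log_or = (np.log(a) - np.log(b)) - (np.log(c) - np.log(d))
        assert np.log(o) == pytest.approx(log_or, abs=1e-12)

    def test_zero_cell_rejected(self):
        with pytest.raises(ValueError):
            or_2x2(0, 10, 10, 10)
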