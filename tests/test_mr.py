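"""MR estimators against brute-force weighted-regression / weighted-CDF
oracles, plus harmonization rules and estimator invariances."""

import numpy as np
import pandas as pd
import pytest

from agevar import (
    age_stratified_mr,
    harmonize,
    ivw,
    modified_ivw,
    mr_egger,
    to_odds_ratio,
    weighted_median,
)


def _inputs(bx, by, sy, sx=None):
    df = pd.DataFrame({"beta_x": bx, "beta_y": by, "se_y": sy})
    df["se_x"] = sx if sx is not None else 0.0
    df["variant_id"] = [f"v{i}" for i in range(len(df))]
    return df


def _random_inputs(rng, m=15, beta=0.5):
    bx = rng.uniform(0.05, 0.4, m) * rng.choice([-1, 1], m)
    sy = rng.uniform(0.02, 0.1, m)
    by = beta * bx + rng.standard_normal(m) * sy
    return _inputs(bx, by, sy, sx=rng.uniform(0.005, 0.02, m))


class TestHarmonize:
    def _exposure(self):
        return pd.DataFrame(
            dict(variant_id=["v1", "v2", "v3", "v4"],
                 effect_allele=["A", "A", "A", "A"],
                 other_allele=["G", "G", "G", "T"],
                 eaf=[0.3, 0.3, 0.3, 0.5],
                 beta=[0.1, 0.2, 0.3, 0.4], se=[0.01] * 4)
        )

    def test_identical_alleles_pass_through(self):
        exp = self._exposure().iloc[:1]
        out = exp.copy()
        out["beta"] = [0.5]
        merged, log = harmonize(exp, out)
        assert merged["beta_y"].iloc[0] == 0.5
        assert merged["harmonization"].iloc[0] == "aligned"
        assert log == []

    def test_swapped_alleles_negate_outcome(self):
        exp = self._exposure().iloc[1:2]
        out = exp.copy()
        out[["effect_allele", "other_allele"]] = [["G", "A"]]
        out["beta"] = [0.5]
        merged, _ = harmonize(exp, out)
        assert merged["beta_y"].iloc[0] == -0.5
        assert merged["harmonization"].iloc[0] == "flipped"

    def test_palindromic_ambiguous_dropped_and_logged(self):
        exp = self._exposure()
        out = exp.copy()
        merged, log = harmonize(exp, out)
        assert "v4" not in set(merged["variant_id"])  # A/T at eaf 0.5
        assert any(e["variant_id"] == "v4" and e["reason"] == "palindromic_ambiguous"
                   for e in log)

    def test_allele_mismatch_dropped(self):
        exp = self._exposure().iloc[:1]
        out = exp.copy()
        out[["effect_allele", "other_allele"]] = [["C", "G"]]
        out2 = self._exposure().iloc[1:2]
        merged, log = harmonize(pd.concat([exp, out2]), pd.concat([out, out2]))
        assert set(merged["variant_id"]) == {"v2"}
        assert log[0]["reason"] == "allele_mismatch"

    def test_empty_intersection_raises(self):
        exp = self._exposure()
        out = exp.copy()
        out["variant_id"] = ["x1", "x2", "x3", "x4"]
        with pytest.raises(ValueError):
            harmonize(exp, out)


class TestIVW:
    def test_single_snp_wald_ratio(self):
        res = ivw(_inputs([0.1], [0.2], [0.05]))
        assert res.estimate == pytest.approx(2.0, abs=1e-14)
        assert res.se == pytest.approx(0.05 / 0.1, abs=1e-12)

    def test_recoding_invariance(self, rng):
        inp = _random_inputs(rng)
        flipped = inp.copy()
        flip = rng.choice([-1, 1], len(inp))
        flipped["beta_x"] *= flip
        flipped["beta_y"] *= flip
        a, b = ivw(inp), ivw(flipped)
        assert b.estimate == pytest.approx(a.estimate, abs=1e-12)
        assert b.se == pytest.approx(a.se, abs=1e-12)

    def test_scale_equivariance(self, rng):
        inp = _random_inputs(rng)
        scaled = inp.copy()
        scaled["beta_x"] *= 4.0
        assert ivw(scaled).estimate == pytest.approx(ivw(inp).estimate / 4.0, rel=1e-12)

    def test_matches_weighted_regression_oracle(self, rng):
        inp = _random_inputs(rng, m=10)
        w = 1.0 / inp["se_y"] ** 2
        # weighted regression through the origin, explicit normal equation
        oracle = float((w * inp["beta_x"] * inp["beta_y"]).sum()
                       / (w * inp["beta_x"] ** 2).sum())
        res = ivw(inp)
        assert res.estimate == pytest.approx(oracle, abs=1e-10)
        se_fe = float(np.sqrt(1.0 / (w * inp["beta_x"] ** 2).sum()))
        assert ivw(inp, fixed_se=True).se == pytest.approx(se_fe, abs=1e-12)

    def test_ci_covers_truth_in_replicates(self, rng):
        hits = 0
        n_rep = 500
        for _ in range(n_rep):
            inp = _random_inputs(rng, m=10, beta=0.5)
            res = ivw(inp)
            hits += res.ci_lo <= 0.5 <= res.ci_hi
        assert hits / n_rep >= 0.93

    def test_all_zero_exposure_rejected(self):
        with pytest.raises(ValueError):
            ivw(_inputs([0.0, 0.0], [0.1, 0.2], [0.05, 0.05]))


class TestModifiedIVW:
    def _interactions(self, deltas, ses):
        return pd.DataFrame(
            dict(variant_id=[f"v{i}" for i in range(len(deltas))],
                 delta=deltas, se_delta=ses)
        )

    def _outcome(self, betas, ses):
        return pd.DataFrame(
            dict(variant_id=[f"v{i}" for i in range(len(betas))],
                 effect_allele="A", other_allele="G", eaf=0.3,
                 beta=betas, se=ses)
        )

    def test_substitution_identity_with_ivw(self, rng):
        deltas = rng.uniform(-0.02, 0.02, 12)
        by = 0.8 * deltas + rng.standard_normal(12) * 0.01
        inter = self._interactions(deltas, np.full(12, 0.004))
        outcome = self._outcome(by, np.full(12, 0.01))
        res = modified_ivw(inter, outcome)
        direct = ivw(_inputs(deltas, by, np.full(12, 0.01)))
        assert res.estimate == pytest.approx(direct.estimate, abs=1e-14)
        assert res.se == pytest.approx(direct.se, abs=1e-14)
        assert res.method == "ivw_modified"

    def test_all_zero_slopes_rejected(self):
        inter = self._interactions([0.0, 0.0], [0.01, 0.01])
        outcome = self._outcome([0.1, 0.2], [0.05, 0.05])
        with pytest.raises(ValueError):
            modified_ivw(inter, outcome)


class TestMREgger:
    def test_zero_pleiotropy_exact(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        slope, inter = mr_egger(_inputs(bx, 0.7 * bx, [0.05] * 4))
        assert slope.estimate == pytest.approx(0.7, abs=1e-12)
        assert inter.estimate == pytest.approx(0.0, abs=1e-12)

    def test_constant_shift_moves_intercept_only(self, rng):
        inp = _random_inputs(rng, m=8)
        inp["beta_x"] = np.abs(inp["beta_x"])  # fix orientation for the identity
        shifted = inp.copy()
        shifted["beta_y"] += 0.05
        s0, i0 = mr_egger(inp)
        s1, i1 = mr_egger(shifted)
        assert s1.estimate == pytest.approx(s0.estimate, abs=1e-12)
        assert i1.estimate == pytest.approx(i0.estimate + 0.05, abs=1e-12)

    def test_matches_weighted_normal_equations(self, rng):
        inp = _random_inputs(rng, m=12)
        bx = np.abs(inp["beta_x"].to_numpy())
        by = inp["beta_y"].to_numpy() * np.sign(inp["beta_x"].to_numpy())
        w = np.diag(1.0 / inp["se_y"].to_numpy() ** 2)
        x = np.column_stack([np.ones(12), bx])
        coef = np.linalg.solve(x.T @ w @ x, x.T @ w @ by)
        slope, inter = mr_egger(inp)
        assert inter.estimate == pytest.approx(coef[0], abs=1e-10)
        assert slope.estimate == pytest.approx(coef[1], abs=1e-10)

    def test_too_few_snps_rejected(self):
        with pytest.raises(ValueError):
            mr_egger(_inputs([0.1, 0.2], [0.1, 0.2], [0.05, 0.05]))


def _weighted_cdf_oracle(ratios, weights):
    """Brute-force weighted median via the midpoint empirical CDF."""
    order = np.argsort(ratios)
    r, w = np.asarray(ratios)[order], np.asarray(weights)[order]
    w = w / w.sum()
    cum = np.cumsum(w)
    cdf_mid = cum - w / 2
    for i in range(len(r) - 1):
        if cdf_mid[i] <= 0.5 <= cdf_mid[i + 1]:
            t = (0.5 - cdf_mid[i]) / (cdf_mid[i + 1] - cdf_mid[i])
            return r[i] + t * (r[i + 1] - r[i])
    return r[0] if 0.5 < cdf_mid[0] else r[-1]


class TestWeightedMedian:
    def test_equal_weights_middle_ratio(self):
        inp = _inputs([0.1, 0.1, 0.1], [0.1, 0.2, 0.3], [0.05] * 3)
        res = weighted_median(inp, n_boot=50, seed=0)
        assert res.estimate == pytest.approx(2.0, abs=1e-12)

    def test_identical_ratios_return_ratio(self):
        inp = _inputs([0.1, 0.2, 0.4], [0.05, 0.1, 0.2], [0.03, 0.05, 0.07])
        res = weighted_median(inp, n_boot=50, seed=0)
        assert res.estimate == pytest.approx(0.5, abs=1e-12)

    def test_matches_cdf_oracle_unequal_weights(self, rng):
        inp = _random_inputs(rng, m=15)
        res = weighted_median(inp, n_boot=10, seed=0)
        ratios = inp["beta_y"] / inp["beta_x"]
        weights = (inp["beta_x"] / inp["se_y"]) ** 2
        assert res.estimate == pytest.approx(
            _weighted_cdf_oracle(ratios, weights), abs=1e-12
        )

    def test_bootstrap_se_stable_across_seeds(self, rng):
        inp = _random_inputs(rng, m=15)
        a = weighted_median(inp, n_boot=2000, seed=1).se
        b = weighted_median(inp, n_boot=2000, seed=2).se
        assert abs(a - b) / a < 0.05

    def test_zero_exposure_beta_rejected(self):
        with pytest.raises(ValueError):
            weighted_median(_inputs([0.0, 0.1, 0.2], [0.1, 0.1, 0.1], [0.05] * 3))


class TestAgeStratifiedMR:
    def _stratified(self, betas_by_stratum, se=0.02):
        rows = []
        for stratum, betas in betas_by_stratum.items():
            for i, b in enumerate(betas):
                rows.append(dict(variant_id=f"v{i}", effect_allele="A",
                                 other_allele="G", eaf=0.3, beta=b, se=se,
                                 stratum=stratum))
        return pd.DataFrame(rows)

    def test_single_snp_reduces_to_wald_ratio(self):
        strat = self._stratified({1: [0.1], 15: [0.2]})
        outcome = pd.DataFrame(
            dict(variant_id=["v0"], effect_allele="A", other_allele="G",
                 eaf=0.3, beta=[0.3], se=[0.05])
        )
        res = age_stratified_mr(strat, outcome, ["v0"])
        assert res[1].estimate == pytest.approx(3.0, abs=1e-12)
        assert res[15].estimate == pytest.approx(1.5, abs=1e-12)

    def test_amplifying_effects_order_stratum_estimates(self, rng):
        # exposure betas grow with age; outcome generated from old-age betas
        m = 20
        young = rng.uniform(0.05, 0.15, m)
        old = young * 3
        outcome_beta = 0.5 * old + rng.standard_normal(m) * 0.01
        strat = self._stratified({1: young, 15: old}, se=0.02)
        outcome = pd.DataFrame(
            dict(variant_id=[f"v{i}" for i in range(m)], effect_allele="A",
                 other_allele="G", eaf=0.3, beta=outcome_beta, se=0.01)
        )
        res = age_stratified_mr(strat, outcome, [f"v{i}" for i in range(m)])
        assert res[1].estimate > res[15].estimate  # same Gamma over smaller beta_x


class TestOddsRatioTransform:
    @pytest.mark.parametrize("est,expected", [(0.0, 1.0), (np.log(2), 2.0)])
    def test_point_transform(self, est, expected):
        from agevar.mr import MRResult

        res = MRResult("ivw", est, 0.1, est - 0.196, est + 0.196, 0.5, 10)
        assert to_odds_ratio(res)[0] == pytest.approx(expected)

    def test_log_scale_roundtrip_to_reported_precision(self):
        from agevar.mr import MRResult

        res = MRResult("ivw_modified", 0.9969, 0.135, 0.7324, 1.2613, 1e-13, 355)
        or_, (lo, hi) = to_odds_ratio(res)
        assert round(or_, 2) == 2.71
        assert round(lo, 2) == 2.08
        assert round(hi, 2) == 3.53
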