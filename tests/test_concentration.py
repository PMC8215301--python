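"""Concentration-index estimation: ranks, coding, transforms, contrasts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from schoolineq.concentration import (code_outcome, concentration_index,
                                      fractional_rank, grouped_means,
                                      mirror_checks, system_contrast)
from schoolineq.synthetic import COMPREHENSIVE, SELECTIVE
from conftest import exact_two_arm_table, make_ordered

FIVE = ["c1", "c2", "c3", "c4", "c5"]  # disadvantaged -> advantaged


def five_equal_groups(n_per=20):
    return make_ordered(np.repeat(FIVE, n_per), FIVE)


def weighted_cov_oracle(y, r, w):
    """Brute-force weighted covariance, independent of the estimator."""
    sw = w.sum()
    mu_y = (w * y).sum() / sw
    mu_r = (w * r).sum() / sw
    return (w * (y - mu_y) * (r - mu_r)).sum() / sw, mu_y


class TestFractionalRank:
    def test_five_equal_groups_midpoints(self):
        rc = fractional_rank(five_equal_groups())
        assert np.allclose(rc.groups["midpoint"], [0.1, 0.3, 0.5, 0.7, 0.9],
                           atol=1e-12)
        assert np.allclose(np.unique(rc.ranks), [0.1, 0.3, 0.5, 0.7, 0.9],
                           atol=1e-12)

    def test_single_group_gets_half(self):
        rc = fractional_rank(make_ordered(["only"] * 7, ["only"]))
        assert np.allclose(rc.ranks, 0.5)

    def test_two_groups_weighted_shares(self):
        cats = make_ordered(["lo"] * 3 + ["hi"] * 7, ["lo", "hi"])
        rc = fractional_rank(cats)
        assert np.allclose(rc.groups["midpoint"], [0.15, 0.65], atol=1e-12)

    def test_errors(self):
        with pytest.raises(ValueError, match="order"):
            fractional_rank(pd.Categorical(["a", "b"]))
        with pytest.raises(ValueError, match="empty"):
            fractional_rank(make_ordered([], ["a"]))
        with pytest.raises(ValueError, match="zero"):
            fractional_rank(make_ordered(["a", "a"], ["a"]), weights=[0.0, 0.0])

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.lists(st.integers(0, 3), min_size=2, max_size=40),
           st.integers(0, 10_000))
    def test_weighted_rank_mean_is_half(self, codes, wseed):
        codes = np.asarray(codes)
        labels = np.asarray(["a", "b", "c", "d"])[codes]
        cats = make_ordered(labels, ["a", "b", "c", "d"])
        w = np.random.default_rng(wseed).uniform(0.1, 5.0, size=len(codes))
        rc = fractional_rank(cats, w)
        assert np.average(rc.ranks, weights=w) == pytest.approx(0.5, abs=1e-10)
        assert np.all(np.diff(rc.groups["midpoint"]) > 0)


class TestCodeOutcome:
    def test_smoker_orientation(self):
        y = np.array([1, 0, 0, 1, 0], float)  # smoking = worse health
        coding = code_outcome(y, kind="binary", higher_is_better=False)
        assert np.array_equal(coding.attainment, 1 - y)
        assert np.array_equal(coding.attainment + coding.shortfall, np.ones(5))

    def test_unit_interval_identity(self):
        y = np.array([0.0, 0.25, 0.8, 1.0])
        coding = code_outcome(y, bounds=(0, 1))
        assert np.array_equal(coding.attainment, y)

    def test_ordinal_four_levels_scaled(self):
        y = np.array([1, 2, 3, 4], float)
        coding = code_outcome(y, kind="ordinal", bounds=(1, 4))
        assert np.allclose(coding.attainment, [0, 1 / 3, 2 / 3, 1])

    def test_errors(self):
        with pytest.raises(ValueError, match="constant"):
            code_outcome(np.full(5, 2.0))           # observed-range scaling
        with pytest.raises(ValueError, match="0/1"):
            code_outcome(np.array([0.0, 2.0]), kind="binary")
        with pytest.raises(ValueError, match="bounds"):
            code_outcome(np.array([0.0, 5.0]), bounds=(0, 1))


class TestConcentrationIndex:
    def test_identity_outcome_five_groups(self):
        """y = r: brute-force oracle gives mu=0.5, var(r)=0.08, CI=0.32."""
        cats = five_equal_groups()
        rc = fractional_rank(cats)
        coding = code_outcome(rc.ranks.copy(), bounds=(0, 1))
        rel = concentration_index(coding, rc, variant="relative_attainment",
                                  se_method="robust")
        assert rel.estimate == pytest.approx(0.32, abs=1e-12)
        assert rel.var_rank == pytest.approx(0.08, abs=1e-12)
        ab = concentration_index(coding, rc, variant="absolute",
                                 se_method="robust")
        assert ab.estimate == pytest.approx(0.64, abs=1e-12)   # 8*cov = 8*0.08

    def test_constant_outcome_gives_zero(self):
        cats = five_equal_groups(5)
        rc = fractional_rank(cats)
        coding = code_outcome(np.full(len(cats), 0.5), bounds=(0, 1))
        for variant in ("relative_attainment", "relative_shortfall", "absolute"):
            est = concentration_index(coding, rc, variant=variant,
                                      se_method="robust")
            assert est.estimate == pytest.approx(0.0, abs=1e-12)

    def test_regression_transform_equals_covariance_oracle(self):
        """Dual route: WLS slope of the transformed outcome vs 2cov/mu, 8cov."""
        rng = np.random.default_rng(4)
        for _ in range(100):
            n = rng.integers(8, 40)
            k = rng.integers(2, 5)
            codes = rng.integers(0, k, size=n)
            if len(np.unique(codes)) < 2:
                continue
            cats = make_ordered(np.array([f"g{i}" for i in range(k)])[codes],
                                [f"g{i}" for i in range(k)])
            w = rng.uniform(0.1, 4.0, size=n)
            y = rng.uniform(0.05, 0.95, size=n)
            rc = fractional_rank(cats, w)
            coding = code_outcome(y, bounds=(0, 1), weights=w)
            cov, mu = weighted_cov_oracle(y, rc.ranks, w)
            rel = concentration_index(coding, rc, w, "relative_attainment",
                                      se_method="robust")
            assert rel.estimate == pytest.approx(2 * cov / mu, abs=1e-10)
            ab = concentration_index(coding, rc, w, "absolute",
                                     se_method="robust")
            assert ab.estimate == pytest.approx(8 * cov, abs=1e-10)
            assert ab.estimate == pytest.approx(4 * mu * rel.estimate, abs=1e-10)

    def test_relative_index_scale_invariant(self):
        """Affine rescale of the raw outcome with matching bounds leaves the
        relative index unchanged."""
        rng = np.random.default_rng(9)
        cats = five_equal_groups(30)
        rc = fractional_rank(cats)
        raw = rng.uniform(2.0, 9.0, size=len(cats))
        base = concentration_index(code_outcome(raw, bounds=(2, 9)), rc,
                                   variant="relative_attainment",
                                   se_method="robust").estimate
        for a, b in ((3.0, 0.5), (0.1, -4.0), (12.0, 100.0)):
            scaled = a * raw + b
            est = concentration_index(
                code_outcome(scaled, bounds=(a * 2 + b, a * 9 + b)), rc,
                variant="relative_attainment", se_method="robust").estimate
            assert est == pytest.approx(base, abs=1e-10)

    def test_errors(self):
        cats = make_ordered(["a"] * 4, ["a"])
        rc = fractional_rank(cats)
        coding = code_outcome(np.array([0.1, 0.4, 0.2, 0.6]), bounds=(0, 1))
        with pytest.raises(ValueError, match="distinct rank"):
            concentration_index(coding, rc, se_method="robust")
        cats2 = five_equal_groups(2)
        rc2 = fractional_rank(cats2)
        ones = code_outcome(np.ones(len(cats2)), kind="binary")
        with pytest.raises(ValueError, match="outside"):
            concentration_index(ones, rc2, variant="relative_attainment",
                                se_method="robust")


class TestMirror:
    def _estimates(self, y, cats, mu_expect=None):
        rc = fractional_rank(cats)
        att = code_outcome(y, bounds=(0, 1))
        ests = {}
        for variant in ("relative_attainment", "relative_shortfall", "absolute"):
            ests[variant] = concentration_index(att, rc, variant=variant,
                                                se_method="robust")
        sh_abs = concentration_index(
            code_outcome(y, bounds=(0, 1), higher_is_better=False), rc,
            variant="absolute", se_method="robust")
        return ests, sh_abs

    def test_identity_outcome_mirror(self):
        """mu=0.5 makes C_shortfall the exact negative of C_attain."""
        cats = five_equal_groups()
        rc = fractional_rank(cats)
        ests, sh_abs = self._estimates(rc.ranks.copy(), cats)
        assert ests["relative_shortfall"].estimate == pytest.approx(-0.32, abs=1e-12)
        assert sh_abs.estimate == pytest.approx(-0.64, abs=1e-12)
        report = mirror_checks(ests["relative_attainment"],
                               ests["relative_shortfall"],
                               ests["absolute"], sh_abs)
        assert report["relative_identity_ok"] and report["absolute_mirror_ok"]

    def test_mu_080_gives_minus_four_times(self):
        """mu=0.8, C_attain=0.1 implies C_shortfall = -0.4."""
        cats = five_equal_groups()
        rc = fractional_rank(cats)
        y = 0.55 + 0.5 * rc.ranks          # mu=0.8, cov=0.04 -> C=0.1
        ests, _ = self._estimates(y, cats)
        assert ests["relative_attainment"].estimate == pytest.approx(0.1, abs=1e-12)
        assert ests["relative_shortfall"].estimate == pytest.approx(-0.4, abs=1e-12)

    def test_misaligned_pair_rejected(self):
        cats = five_equal_groups()
        ests, _ = self._estimates(fractional_rank(cats).ranks.copy(), cats)
        other_cats = five_equal_groups(7)
        other, _ = self._estimates(fractional_rank(other_cats).ranks.copy(),
                                   other_cats)
        with pytest.raises(ValueError, match="aligned"):
            mirror_checks(ests["relative_attainment"],
                          other["relative_shortfall"])


class TestSystemContrast:
    def test_planted_contrast_recovered_exactly(self):
        table = exact_two_arm_table(0.10, 0.20, n_per_arm=2500)
        c = system_contrast(table, "y", "origin_class",
                            variant="relative_attainment", se_method="robust")
        assert c.comprehensive.estimate == pytest.approx(0.10, abs=1e-6)
        assert c.selective.estimate == pytest.approx(0.20, abs=1e-6)
        assert c.difference == pytest.approx(0.10, abs=1e-6)

    def test_interaction_equals_stratified_difference(self):
        """Fully interacted WLS with arm-specific transforms reproduces the
        stand-alone arm indices algebraically."""
        rng = np.random.default_rng(3)
        from schoolineq.synthetic import generate_cohort, OutcomeSpec
        table, _ = generate_cohort(
            outs=[OutcomeSpec(name="y", alpha=0.25, beta=0.3,
                              system_shift=0.05, system_beta_shift=0.1,
                              noise_sd=0.05)], n=3000, seed=12)
        w = rng.uniform(0.3, 3.0, size=len(table))
        for variant in ("relative_attainment", "relative_shortfall", "absolute"):
            c = system_contrast(table, "y", "origin_class", weights=w,
                                variant=variant, se_method="robust")
            assert c.difference == pytest.approx(
                c.selective.estimate - c.comprehensive.estimate, abs=1e-10)

    def test_null_contrast_centred_on_zero(self):
        """Identical rank slopes in both arms: mean contrast over replicates
        is within 3 MC SEs of 0."""
        from schoolineq.synthetic import ExposureSpec, generate_cohort, OutcomeSpec
        null_exposure = ExposureSpec(intercept=-0.4, coefficients={})
        diffs = []
        for rep in range(200):
            table, _ = generate_cohort(
                exp=null_exposure,
                outs=[OutcomeSpec(name="y", alpha=0.3, beta=0.3,
                                  noise_sd=0.08)], n=1000, seed=1000 + rep)
            c = system_contrast(table, "y", "origin_class",
                                variant="relative_attainment",
                                se_method="robust")
            diffs.append(c.difference)
        diffs = np.asarray(diffs)
        assert abs(diffs.mean()) < 3 * diffs.std(ddof=1) / np.sqrt(len(diffs))

    def test_single_class_arm_rejected(self):
        table = exact_two_arm_table(0.1, 0.1, n_per_arm=200)
        sel = table["system"] == SELECTIVE
        table.loc[sel, "origin_class"] = "routine"
        with pytest.raises(ValueError, match="single stratifier"):
            system_contrast(table, "y", "origin_class", se_method="robust")


class TestPermutationNull:
    def test_contrast_test_size_near_nominal(self):
        """Permuting class labels under the global null: the 5% contrast test
        rejects at close to its nominal rate."""
        from schoolineq.synthetic import generate_cohort, OutcomeSpec
        table, _ = generate_cohort(
            outs=[OutcomeSpec(name="y", alpha=0.45, beta=0.0, noise_sd=0.12)],
            n=800, seed=77)
        rng = np.random.default_rng(5)
        rejections = 0
        n_perm = 1000
        base = table["origin_class"].to_numpy()
        for _ in range(n_perm):
            table["origin_class"] = pd.Categorical(
                rng.permutation(base),
                categories=table["origin_class"].cat.categories
                if hasattr(table["origin_class"], "cat") else None,
                ordered=True)
            c = system_contrast(table, "y", "origin_class",
                                variant="relative_attainment",
                                se_method="robust")
            if abs(c.difference) > 1.959963984540054 * c.se:
                rejections += 1
        assert 0.03 <= rejections / n_perm <= 0.07


class TestBootstrapCalibration:
    def test_recovery_and_interval_coverage(self):
        """Across 200 replicates at n = 10,000 (unconfounded exposure), the
        mean estimated relative CI sits within 3 MC SEs of the planted truth
        and the bootstrap 95% interval covers it between 92% and 98% of the
        time."""
        from schoolineq.synthetic import (ConfounderSpec, ExposureSpec,
                                          generate_cohort,
                                          planted_continuous_outcome)
        spec = ConfounderSpec()
        out = planted_continuous_outcome("y", 0.10, noise_sd=0.05, spec=spec)
        null_exposure = ExposureSpec(intercept=-0.4, coefficients={})
        truth = 0.10
        covered, points = 0, []
        for rep in range(200):
            table, _ = generate_cohort(spec, exp=null_exposure, outs=[out],
                                       n=10_000, seed=90_000 + rep)
            rc = fractional_rank(table["origin_class"].array)
            coding = code_outcome(table["y"].to_numpy(), bounds=(0, 1))
            est = concentration_index(coding, rc,
                                      variant="relative_attainment",
                                      se_method="bootstrap", n_boot=199,
                                      seed=rep)
            points.append(est.estimate)
            if est.lo95 <= truth <= est.hi95:
                covered += 1
        points = np.asarray(points)
        mc_se = points.std(ddof=1) / np.sqrt(len(points))
        assert abs(points.mean() - truth) < 3 * mc_se
        assert 0.92 <= covered / 200 <= 0.98, covered


class TestGroupedMeans:
    def test_single_group_is_plain_mean(self):
        from schoolineq.synthetic import generate_cohort
        table, _ = generate_cohort(n=300, seed=1)
        res = grouped_means(table, "wellbeing", by_system=False)
        assert res["mean"].iloc[0] == pytest.approx(table["wellbeing"].mean())

    def test_weight_doubling_equals_duplication(self):
        from schoolineq.synthetic import generate_cohort
        table, _ = generate_cohort(n=50, seed=2)
        w = np.ones(50)
        w[7] = 2.0
        res_w = grouped_means(table, "wellbeing", weights=w, by_system=False)
        dup = pd.concat([table, table.iloc[[7]]], ignore_index=True)
        dup.attrs = dict(table.attrs)
        res_d = grouped_means(dup, "wellbeing", by_system=False)
        assert res_w["mean"].iloc[0] == pytest.approx(res_d["mean"].iloc[0],
                                                      abs=1e-12)

    def test_planted_system_shift_recovered(self):
        from schoolineq.synthetic import generate_cohort, OutcomeSpec
        table, _ = generate_cohort(
            outs=[OutcomeSpec(name="y", alpha=0.3, beta=0.2,
                              system_shift=0.05, noise_sd=0.1)],
            n=50_000, seed=21)
        from schoolineq.balance import fit_propensity, make_ipw
        conf = table.attrs["confounder_names"]
        ws = make_ipw(fit_propensity(table, conf, "logistic"), table)
        res = grouped_means(table, "y", weights=ws.weights, by_system=True)
        comp = res.loc[res["system"] == COMPREHENSIVE, "mean"].iloc[0]
        sel = res.loc[res["system"] == SELECTIVE, "mean"].iloc[0]
        se = np.hypot(
            *(res.loc[res["system"] == s].apply(
                lambda r: (r["hi95"] - r["lo95"]) / (2 * 1.96), axis=1).iloc[0]
              for s in (COMPREHENSIVE, SELECTIVE)))
        assert abs((sel - comp) - 0.05) < 3 * se

    def test_ability_bins_merge_sparse_margins(self):
        from schoolineq.synthetic import generate_cohort
        table, _ = generate_cohort(n=4000, seed=3)
        res = grouped_means(table, "wellbeing", by_system=True,
                            ability_bins=True, min_cell=50)
        assert (res["n"] >= 1).all()
        assert res["ability_bin"].nunique() > 3
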