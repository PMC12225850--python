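import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import beta

from ldlratio.core import InputError, ValidationError, ncep_categories
from ldlratio.evaluate import (
    bland_altman,
    classify,
    clopper_pearson,
    concordance_summary,
    fit_metrics,
    mcnemar_exact,
    reclassification,
)
from tests.conftest import random_panels


class TestClassify:
    def test_crossing_the_70_boundary_is_under(self):
        r = classify(pd.Series([65.0]), pd.Series([80.0]))
        assert r["status"].iloc[0] == "under"

    def test_equal_values_concordant(self, rng):
        v = pd.Series(rng.uniform(-20, 250, 100))
        assert (classify(v, v)["status"] == "concordant").all()

    def test_labels_agree_with_sign_oracle(self, rng):
        est = pd.Series(rng.uniform(30, 220, 500))
        meas = pd.Series(rng.uniform(30, 220, 500))
        r = classify(est, meas)
        sign = np.sign(ncep_categories(est) - ncep_categories(meas))
        expected = np.where(sign == 0, "concordant", np.where(sign < 0, "under", "over"))
        assert (r["status"].to_numpy() == expected).all()

    def test_unpaired_inputs_rejected(self):
        with pytest.raises(InputError):
            classify(pd.Series([1.0]), pd.Series([1.0, 2.0]))


class TestConcordanceSummary:
    def test_ci_matches_beta_quantile_oracle(self):
        est = pd.Series([80.0] * 8 + [65.0] * 2)
        meas = pd.Series([80.0] * 8 + [80.0] * 2)
        (s,) = concordance_summary(classify(est, meas))
        assert s.concordant == 8 and s.n == 10
        # independent oracle: exact interval from beta quantiles
        assert s.ci_lo == pytest.approx(beta.ppf(0.025, 8, 3), abs=1e-12)
        assert s.ci_hi == pytest.approx(beta.isf(0.025, 9, 2), abs=1e-12)
        assert s.ci_lo == pytest.approx(0.444, abs=5e-4)
        assert s.ci_hi == pytest.approx(0.975, abs=5e-4)

    def test_boundary_cis(self):
        assert clopper_pearson(0, 20)[0] == 0.0
        assert clopper_pearson(20, 20)[1] == 1.0

    def test_status_counts_partition_every_group(self, rng):
        cohort = random_panels(rng, 400)
        est = pd.Series(rng.uniform(30, 220, 400), index=cohort.index)
        results = classify(est, cohort["ldl_d"])
        for kw in ({}, {"group_by": "est_category"},
                   {"group_by": "tg_strata", "tg": cohort[cohort.tg < 400].tg}):
            rows = (
                concordance_summary(results.loc[cohort.tg < 400], **kw)
                if "tg" in kw
                else concordance_summary(results, **kw)
            )
            for s in rows:
                assert s.concordant + s.under + s.over == s.n


class TestMcNemarExact:
    def test_symmetry_and_range(self, rng):
        for _ in range(50):
            b, c = rng.integers(0, 40, 2)
            p = mcnemar_exact(int(b), int(c))
            assert p == mcnemar_exact(int(c), int(b))
            assert 0 < p <= 1

    def test_equal_discordants_cap_at_one(self):
        assert mcnemar_exact(7, 7) == 1.0

    def test_degenerate_zero_discordants(self):
        assert mcnemar_exact(0, 0) == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            mcnemar_exact(-1, 3)

    def test_matches_pmf_enumeration_small_counts(self):
        for n in range(1, 31):
            for b in range(n + 1):
                c = n - b
                m = min(b, c)
                tail = sum(math.comb(n, k) for k in range(m + 1)) / 2**n
                assert mcnemar_exact(b, c) == pytest.approx(min(1.0, 2 * tail), abs=1e-12)

    def test_matches_statsmodels_exact(self):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

        for b, c in [(14, 21), (1, 9), (5, 5), (0, 8), (30, 12)]:
            table = [[0, b], [c, 0]]
            expected = sm_mcnemar(table, exact=True).pvalue
            assert mcnemar_exact(b, c) == pytest.approx(expected, abs=1e-12)


class TestReclassification:
    def test_constructed_block_counts(self):
        # 6 individuals, all measured in 70-99; reference misclassifies 2
        meas = pd.Series([80.0] * 6)
        ref = pd.Series([80.0, 85.0, 90.0, 95.0, 65.0, 65.0])
        alt = pd.Series([80.0] * 6)
        table = reclassification(ref, alt, meas)
        ov = table.overall
        assert (ov.cc, ov.ci, ov.ic, ov.ii) == (4, 0, 2, 0)
        below70 = [b for b in table.blocks if b.label == "<70"][0]
        assert below70.ic == 2 and below70.upward == 2

    def test_block_percentages_sum_to_100(self, rng):
        cohort = random_panels(rng, 1000)
        meas = cohort["ldl_d"]
        ref = meas + rng.normal(0, 15, 1000)
        alt = meas + rng.normal(0, 8, 1000)
        table = reclassification(pd.Series(ref), pd.Series(alt), meas)
        for b in table.blocks + [table.overall]:
            assert b.cc + b.ci + b.ic + b.ii == b.n
            assert b.pct(b.cc) + b.pct(b.ci) + b.pct(b.ic) + b.pct(b.ii) == pytest.approx(
                100.0, abs=0.3
            )

    def test_counts_match_per_row_tabulation_oracle(self, rng):
        cohort = random_panels(rng, 500)
        meas = cohort["ldl_d"].to_numpy()
        ref = meas + rng.normal(0, 20, 500)
        alt = meas + rng.normal(0, 10, 500)
        table = reclassification(pd.Series(ref), pd.Series(alt), pd.Series(meas))
        from tests.test_ratios import oracle_band

        for block in table.blocks:
            counts = {"cc": 0, "ci": 0, "ic": 0, "ii": 0}
            up = down = 0
            for r, a, m in zip(ref, alt, meas):
                if {0: "<70", 1: "70-99", 2: "100-129", 3: "130-159",
                    4: "160-189", 5: ">=190"}[oracle_band(r)] != block.label:
                    continue
                key = ("c" if oracle_band(r) == oracle_band(m) else "i") + (
                    "c" if oracle_band(a) == oracle_band(m) else "i"
                )
                counts[key] += 1
                up += oracle_band(a) > oracle_band(r)
                down += oracle_band(a) < oracle_band(r)
            assert (block.cc, block.ci, block.ic, block.ii) == (
                counts["cc"], counts["ci"], counts["ic"], counts["ii"]
            )
            assert (block.upward, block.downward) == (up, down)


class TestBlandAltman:
    def test_perfect_agreement(self):
        v = pd.Series([100.0, 120.0, 140.0])
        s = bland_altman(v, v)
        assert (s.mean_bias, s.loa_lo, s.loa_hi) == (0.0, 0.0, 0.0)

    def test_constant_offset(self):
        v = pd.Series([100.0, 120.0, 140.0])
        s = bland_altman(v + 10, v)
        assert s.mean_bias == 10.0 and s.loa_lo == 10.0 and s.loa_hi == 10.0

    def test_monte_carlo_normal_differences(self, rng):
        meas = pd.Series(rng.uniform(80, 160, 10000))
        est = meas + rng.normal(-5, 8, 10000)
        s = bland_altman(est, meas)
        assert abs(s.mean_bias - (-5)) < 0.3
        assert abs(s.loa_lo - (-5 - 1.96 * 8)) < 0.5
        assert abs(s.loa_hi - (-5 + 1.96 * 8)) < 0.5

    def test_tg_subgroup_restriction(self, rng):
        cohort = random_panels(rng, 300)
        est = cohort["ldl_d"] + 5
        s = bland_altman(est, cohort["ldl_d"], tg=cohort["tg"], tg_interval=(300, 400))
        assert s.n == ((cohort["tg"] >= 300) & (cohort["tg"] < 400)).sum()

    def test_insufficient_data(self):
        with pytest.raises(InputError):
            bland_altman(pd.Series([1.0]), pd.Series([1.0]))


class TestFitMetrics:
    def test_perfect_estimates(self):
        v = pd.Series([100.0, 120.0, 140.0])
        m = fit_metrics(v, v)
        assert (m["mae"], m["mse"], m["mre"], m["r2"]) == (0.0, 0.0, 0.0, 1.0)

    def test_constant_offset(self):
        v = pd.Series([100.0, 120.0, 140.0])
        m = fit_metrics(v + 7, v)
        assert m["mae"] == 7.0 and m["mse"] == 49.0

    def test_equal_absolute_errors_make_mse_equal_mae_squared(self):
        v = pd.Series([100.0, 120.0, 140.0, 160.0])
        m = fit_metrics(v + pd.Series([3.0, -3.0, 3.0, -3.0]), v)
        assert m["mse"] == pytest.approx(m["mae"] ** 2)

    def test_matches_brute_force_summation(self, rng):
        meas = rng.uniform(50, 200, 400)
        est = meas + rng.normal(0, 10, 400)
        m = fit_metrics(pd.Series(est), pd.Series(meas))
        diff = [e - x for e, x in zip(est, meas)]
        mae = sum(abs(d) for d in diff) / len(diff)
        mse = sum(d * d for d in diff) / len(diff)
        mre = 100 * sum(d / x for d, x in zip(diff, meas)) / len(diff)
        sst = sum((x - np.mean(meas)) ** 2 for x in meas)
        r2 = 1 - sum(d * d for d in diff) / sst
        assert m["mae"] == pytest.approx(mae, rel=1e-12)
        assert m["mse"] == pytest.approx(mse, rel=1e-12)
        assert m["mre"] == pytest.approx(mre, rel=1e-10)
        assert m["r2"] == pytest.approx(r2, rel=1e-10)

    def test_zero_measured_excluded_from_mre(self):
        meas = pd.Series([0.0, 100.0, 100.0])
        est = pd.Series([10.0, 110.0, 110.0])
        m = fit_metrics(est, meas)
        assert m["mre_excluded"] == 1
        assert m["mre"] == pytest.approx(10.0)
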