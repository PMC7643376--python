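import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rbppairsig.dataio import MutationRecords
from rbppairsig.survstats import (
    compute_tmb,
    cox_regression,
    km_logrank,
    subgroup_split,
    wilcoxon_compare,
)
from rbppairsig.model import RiskScores
from conftest import make_clinical


class TestKmLogrank:
    def test_identical_groups_null(self):
        times = [100, 200, 300, 400, 100, 200, 300, 400]
        events = [1, 1, 0, 1, 1, 1, 0, 1]
        clin = make_clinical(times, events)
        groups = pd.Series(["high"] * 4 + ["low"] * 4, index=clin.patient_ids)
        res = km_logrank(groups, clin)
        assert res.p_value == pytest.approx(1.0)
        assert res.hr == pytest.approx(1.0, abs=1e-6)

    def test_six_patient_hand_tabulation(self, six_patient_fixture):
        """Log-rank chi-square equals the exhaustive observed-vs-expected
        tabulation over the six event times."""
        groups, clin = six_patient_fixture
        res = km_logrank(groups, clin)
        # at event times 1..6 the high group has 3,2,1,0,0,0 at risk of 6,5,4,3,2,1
        at_risk = [(3, 6), (2, 5), (1, 4), (0, 3), (0, 2), (0, 1)]
        O = 3.0
        E = sum(nh / nt for nh, nt in at_risk)
        V = sum(
            nh * (nt - nh) / nt**2 if nt > 1 else 0.0  # one death per time, (nt-d)/(nt-1)=1
            for nh, nt in at_risk
        )
        chi2 = (O - E) ** 2 / V
        assert res.chi2 == pytest.approx(chi2, rel=1e-10)
        assert res.p_value == pytest.approx(stats.chi2.sf(chi2, 1), rel=1e-10)

    def test_km_curves_are_proper_step_functions(self, six_patient_fixture):
        groups, clin = six_patient_fixture
        res = km_logrank(groups, clin)
        for curve in (res.km_high, res.km_low):
            s = curve["survival"].to_numpy()
            assert s[0] == 1.0
            assert np.all(np.diff(s) <= 0)

    def test_empty_group_errors(self):
        clin = make_clinical([100, 200], [1, 1])
        groups = pd.Series(["high", "high"], index=clin.patient_ids)
        with pytest.raises(ValueError):
            km_logrank(groups, clin)

    def test_logrank_p_close_to_permutation_p(self):
        rng = np.random.default_rng(55)
        n = 40
        t = rng.exponential(500, n)
        e = (rng.uniform(0, 1500, n) > t).astype(int)
        labels = np.array(["high"] * 20 + ["low"] * 20)
        clin = make_clinical(list(t), list(e))
        groups = pd.Series(labels, index=clin.patient_ids)
        res = km_logrank(groups, clin)
        stat_obs = res.chi2
        from lifelines.statistics import logrank_test

        count = 0
        n_perm = 2000
        for _ in range(n_perm):
            perm = rng.permutation(labels)
            hi = perm == "high"
            r = logrank_test(t[hi], t[~hi], e[hi], e[~hi])
            if r.test_statistic >= stat_obs - 1e-12:
                count += 1
        assert res.p_value == pytest.approx(count / n_perm, abs=0.02)


class TestCoxRegression:
    def test_known_log_hazard_recovery(self):
        """Binary covariate with true log-HR 0.693 is recovered at n=2000."""
        rng = np.random.default_rng(8)
        n = 2000
        x = rng.integers(0, 2, n)
        t = rng.exponential(1000 / np.exp(0.693 * x))
        c = rng.uniform(0, 3000, n)
        clin = make_clinical(
            list(np.minimum(t, c)), list((t <= c).astype(int)), smoking=x
        )
        (res,) = cox_regression(clin, ["smoking"], mode="univariate")
        assert 1.8 <= res.hr <= 2.2
        assert res.ci_low <= res.hr <= res.ci_high

    def test_reciprocal_invariance_on_relabel(self):
        rng = np.random.default_rng(9)
        n = 300
        x = rng.integers(0, 2, n)
        t = rng.exponential(800 / np.exp(0.5 * x))
        clin_a = make_clinical(list(t), [1] * n, gender=x + 1)
        clin_b = make_clinical(list(t), [1] * n, gender=2 - x)
        (ra,) = cox_regression(clin_a, ["gender"])
        (rb,) = cox_regression(clin_b, ["gender"])
        assert ra.hr == pytest.approx(1.0 / rb.hr, abs=1e-9)

    def test_null_covariate_wald_calibration(self):
        """Wald p of an independent covariate rejects at ~nominal 5%."""
        rng = np.random.default_rng(12)
        rejections = 0
        n_rep = 400
        for _ in range(n_rep):
            n = 80
            t = rng.exponential(500, n)
            e = (rng.uniform(0, 1500, n) > t).astype(int)
            x = rng.normal(size=n)
            clin = make_clinical(list(t), list(e), age=x)
            (res,) = cox_regression(clin, ["age"])
            rejections += res.p_value < 0.05
        assert rejections / n_rep == pytest.approx(0.05, abs=0.02)

    def test_multivariate_planted_directions(self):
        from rbppairsig.synthetic import generate_cohort
        from rbppairsig.pairspace import indicator_matrix

        expr, clin, truth = generate_cohort(
            n_tumor=500, n_normal=10, n_genes=12, n_signal_pairs=3,
            gamma=0.8, lambda0=1e-5, stage_loghr=0.5, seed=19,
        )
        ind = indicator_matrix(expr, [(a, b) for a, b, _ in truth.signal_pairs])
        tum_idx = [expr.sample_ids.index(s) for s in clin.patient_ids]
        score = 0.8 * ind[:, tum_idx].sum(axis=0).astype(float)
        scores = RiskScores(clin.patient_ids, score, np.zeros(len(score), int))
        res = cox_regression(clin, ["stage", "risk_score"], scores=scores, mode="multivariate")
        by = {r.variable: r for r in res}
        assert by["stage"].hr > 1
        assert by["risk_score"].hr > 1

    def test_constant_covariate_errors(self):
        clin = make_clinical([100, 200, 300], [1, 1, 0], stage=[2, 2, 2])
        with pytest.raises(ValueError, match="stage"):
            cox_regression(clin, ["stage"])


class TestSubgroupSplit:
    def test_random_halves_partition(self):
        clin = make_clinical(list(range(100, 200)), [1] * 100)
        out = subgroup_split(clin, "random_halves", seed=4)
        a, b = out["half1"], out["half2"]
        assert len(a) == 50 and len(b) == 50
        assert set(a.patient_ids) | set(b.patient_ids) == set(clin.patient_ids)
        again = subgroup_split(clin, "random_halves", seed=4)
        assert again["half1"].patient_ids == a.patient_ids

    def test_age_median_split(self):
        clin = make_clinical([100] * 4, [1] * 4, age=[40, 50, 60, 70])
        out = subgroup_split(clin, "age_median")
        assert sorted(out["younger"].data["age"]) == [40, 50]
        assert sorted(out["older"].data["age"]) == [60, 70]

    def test_stage_category_partition(self):
        clin = make_clinical([100] * 4, [1] * 4, stage=[1, 1, 2, 4])
        out = subgroup_split(clin, "stage")
        assert set(out) == {"stage=1", "stage=2", "stage=4"}
        assert len(out["stage=1"]) == 2

    def test_all_missing_errors(self):
        clin = make_clinical([100, 200], [1, 1])
        with pytest.raises(ValueError):
            subgroup_split(clin, "stage")


class TestComputeTmb:
    def _records(self, rows):
        return MutationRecords(
            pd.DataFrame(
                rows, columns=["sample_id", "gene_symbol", "variant_classification", "chrom", "pos"]
            )
        )

    def test_counts_per_megabase(self):
        rows = [("S1", f"g{i}", "Missense_Mutation", "1", i + 1) for i in range(76)]
        tmb = compute_tmb(self._records(rows), exome_mb=38.0)
        assert tmb.loc[0, "tmb"] == 2.0
        assert tmb.loc[0, "mutation_count"] == 76

    def test_silent_not_counted_by_default(self):
        rows = [
            ("S1", "g1", "Missense_Mutation", "1", 10),
            ("S1", "g2", "Missense_Mutation", "1", 20),
            ("S1", "g3", "Silent", "1", 30),
        ]
        tmb = compute_tmb(self._records(rows))
        assert tmb.loc[0, "mutation_count"] == 2
        all_classes = compute_tmb(self._records(rows), classes=None)
        assert all_classes.loc[0, "mutation_count"] == 3

    def test_empty_records_with_roster(self):
        tmb = compute_tmb(self._records([]), sample_roster=["a", "b", "c"])
        assert list(tmb["tmb"]) == [0.0, 0.0, 0.0]

    def test_additive_over_disjoint_records(self):
        rows1 = [("S1", "g1", "Missense_Mutation", "1", 10)]
        rows2 = [("S1", "g2", "Nonsense_Mutation", "2", 20)]
        both = compute_tmb(self._records(rows1 + rows2))
        a = compute_tmb(self._records(rows1))
        b = compute_tmb(self._records(rows2))
        assert both.loc[0, "mutation_count"] == a.loc[0, "mutation_count"] + b.loc[0, "mutation_count"]


class TestWilcoxonCompare:
    def _series(self, x, y):
        vals = pd.Series(list(x) + list(y), index=[f"i{k}" for k in range(len(x) + len(y))])
        grp = pd.Series(
            ["high"] * len(x) + ["low"] * len(y), index=vals.index
        )
        return vals, grp

    def test_extreme_labeling_exact_p(self):
        vals, grp = self._series([4, 5, 6], [1, 2, 3])
        _, p = wilcoxon_compare(vals, grp, alternative="greater")
        assert p == pytest.approx(1 / 20)

    def test_identical_groups(self):
        vals, grp = self._series([1, 2, 3], [1, 2, 3])
        _, p = wilcoxon_compare(vals, grp)
        assert p == pytest.approx(1.0)

    def test_null_calibration(self):
        rng = np.random.default_rng(14)
        rejections = 0
        n_rep = 400
        for _ in range(n_rep):
            vals, grp = self._series(rng.normal(size=30), rng.normal(size=30))
            _, p = wilcoxon_compare(vals, grp)
            rejections += p < 0.05
        assert rejections / n_rep == pytest.approx(0.05, abs=0.02)

    def test_empty_group_errors(self):
        vals = pd.Series([1.0, 2.0], index=["a", "b"])
        grp = pd.Series(["high", "high"], index=["a", "b"])
        with pytest.raises(ValueError):
            wilcoxon_compare(vals, grp)
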