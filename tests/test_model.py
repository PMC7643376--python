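import numpy as np
import pandas as pd
import pytest

from rbppairsig.dataio import PairSignature, load_packaged_signature
from rbppairsig.model import (
    RiskScores,
    RocCurve,
    choose_cutoff,
    fit_lasso_cox,
    score_samples,
    stratify,
    timedep_roc,
)
from rbppairsig.pairspace import build_pair_matrix, filter_constant_pairs
from rbppairsig.synthetic import apply_monotone_distortion, generate_cohort
from conftest import make_clinical, make_expression


class TestScoreSamples:
    def test_toy_arithmetic(self):
        sig = PairSignature([("A", "B", 0.5), ("C", "D", -0.3)])
        m = make_expression([[5, 1], [3, 2], [7, 1], [2, 2]], genes=list("ABCD"))
        r = score_samples(sig, m)
        # sample 1: A>B and C>D -> 0.5 - 0.3 = 0.2; sample 2: B>A, C=D tie -> 0
        np.testing.assert_allclose(r.score, [0.2, 0.0])

    def test_no_pair_indicates_zero_score(self):
        sig = PairSignature([("A", "B", 0.7)])
        m = make_expression([[1], [2]], genes=["A", "B"])
        assert score_samples(sig, m).score[0] == 0.0

    def test_packaged_signature_column_sum(self):
        """A sample ordered consistently with every Table pair scores the
        sum of the printed coefficient column (computed independently)."""
        import networkx as nx

        sig = load_packaged_signature()
        order = list(nx.topological_sort(nx.DiGraph((a, b) for a, b, _ in sig.pairs)))
        vals = {g: float(len(order) - i) for i, g in enumerate(order)}
        m = make_expression([[vals[g]] for g in order], genes=order)
        r = score_samples(sig, m)
        assert r.score[0] == pytest.approx(0.479067, abs=1e-6)
        assert r.n_missing_pairs[0] == 0

    def test_missing_genes_counted_and_warned(self):
        sig = PairSignature([("A", "B", 0.5), ("C", "D", -0.3), ("E", "F", 0.2)])
        m = make_expression([[5], [1]], genes=["A", "B"])
        r = score_samples(sig, m)
        assert r.score[0] == 0.5
        assert r.n_missing_pairs[0] == 2
        assert r.warnings  # > 50% of pairs unevaluable

    def test_scoring_invariant_to_monotone_distortion(self):
        expr, _, _ = generate_cohort(n_tumor=20, n_normal=5, n_genes=30, n_signal_pairs=3, seed=13)
        sig = PairSignature(
            [("G0001", "G0002", 0.4), ("G0010", "G0003", -0.6), ("G0020", "G0025", 1.1)]
        )
        base = score_samples(sig, expr)
        for seed in range(5):
            after = score_samples(sig, apply_monotone_distortion(expr, seed=seed))
            np.testing.assert_array_equal(base.score, after.score)

    def test_score_bounds(self):
        rng = np.random.default_rng(0)
        expr, _, _ = generate_cohort(n_tumor=30, n_normal=5, n_genes=20, n_signal_pairs=2, seed=14)
        betas = rng.normal(size=8)
        genes = expr.gene_ids
        sig = PairSignature(
            [(genes[2 * i], genes[2 * i + 1], float(b)) for i, b in enumerate(betas)]
        )
        r = score_samples(sig, expr)
        lo = sum(min(b, 0) for b in betas)
        hi = sum(max(b, 0) for b in betas)
        assert np.all(r.score >= lo - 1e-12) and np.all(r.score <= hi + 1e-12)


class TestFitLassoCox:
    def _fitted(self, seed=0, **kwargs):
        expr, clin, truth = generate_cohort(
            n_tumor=250, n_normal=10, n_genes=20, n_signal_pairs=4,
            gamma=0.9, lambda0=1e-5, seed=seed,
        )
        tum = expr.subset_samples(expr.tumor_samples())
        pm = filter_constant_pairs(build_pair_matrix(tum, expr.gene_ids))
        return pm, clin, truth

    def test_full_shrinkage_gives_empty_signature(self):
        pm, clin, _ = self._fitted()
        sig = fit_lasso_cox(pm, clin, alpha=1e6)
        assert len(sig) == 0

    def test_determinism(self):
        pm, clin, _ = self._fitted()
        a = fit_lasso_cox(pm, clin, cv_folds=5, seed=3)
        b = fit_lasso_cox(pm, clin, cv_folds=5, seed=3)
        assert a.pairs == b.pairs

    def test_single_huge_pair_dominates_at_minimal_penalty(self):
        expr, clin, truth = generate_cohort(
            n_tumor=500, n_normal=10, n_genes=12, n_signal_pairs=1,
            gamma=3.0, lambda0=1e-5, seed=17,
        )
        tum = expr.subset_samples(expr.tumor_samples())
        pm = filter_constant_pairs(build_pair_matrix(tum, expr.gene_ids))
        sig = fit_lasso_cox(pm, clin, alpha=1e-4)
        a, b, _ = truth.signal_pairs[0]
        planted = tuple(sorted((a, b)))
        coefs = {(pa, pb): c for pa, pb, c in sig.pairs}
        assert planted in coefs
        assert coefs[planted] > 0
        assert abs(coefs[planted]) == max(abs(c) for c in coefs.values())

    def test_no_events_errors(self):
        pm, clin, _ = self._fitted()
        dead = clin.data.copy()
        dead["os_event"] = 0
        from rbppairsig.dataio import ClinicalTable

        with pytest.raises(ValueError):
            fit_lasso_cox(pm, ClinicalTable(dead))

    def test_unpenalized_refit_keeps_selection(self):
        pm, clin, _ = self._fitted()
        sig_pen = fit_lasso_cox(pm, clin, cv_folds=5, seed=1)
        sig_refit = fit_lasso_cox(pm, clin, cv_folds=5, seed=1, refit=True)
        assert {(a, b) for a, b, _ in sig_refit.pairs} <= {(a, b) for a, b, _ in sig_pen.pairs}
        # refit coefficients are unshrunk: typically larger in magnitude
        common = {(a, b) for a, b, _ in sig_refit.pairs}
        pen = {(a, b): c for a, b, c in sig_pen.pairs}
        ref = {(a, b): c for a, b, c in sig_refit.pairs}
        assert np.mean([abs(ref[k]) >= abs(pen[k]) for k in common]) > 0.5


class TestTimedepRoc:
    def _scores(self, score, time, event):
        ids = [f"p{i}" for i in range(len(score))]
        r = RiskScores(ids, np.asarray(score, float), np.zeros(len(score), int))
        clin = make_clinical(list(time), list(event), index=ids)
        return r, clin

    def test_perfect_classifier_auc_one(self):
        # high scores die before the horizon, low scores all survive past it
        score = [3, 2.5, 2, -1, -2, -3]
        time = [100, 200, 300, 2000, 2500, 3000]
        event = [1, 1, 1, 1, 1, 1]
        r, clin = self._scores(score, time, event)
        roc = timedep_roc(r, clin, horizon=1095)
        assert roc.auc == pytest.approx(1.0)
        cut = choose_cutoff(roc)
        j = roc.points.sensitivity + roc.points.specificity - 1
        assert j.max() == pytest.approx(1.0)
        assert -1 < cut < 2  # any cutoff separating the two score groups

    def test_permuted_scores_auc_half(self):
        """Scores independent of survival: mean AUC ~ 0.5 over replicates."""
        rng = np.random.default_rng(23)
        aucs = []
        for _ in range(200):
            n = 50
            time = rng.exponential(800, n)
            cens = rng.uniform(0, 3000, n)
            t = np.minimum(time, cens)
            e = (time <= cens).astype(int)
            t = np.append(t, 2000.0)  # guarantee follow-up past the horizon
            e = np.append(e, 0)
            score = rng.normal(size=n + 1)
            r, clin = self._scores(score, t, e)
            aucs.append(timedep_roc(r, clin, horizon=1095).auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.03)

    def test_horizon_beyond_followup_errors(self):
        r, clin = self._scores([1, 2], [100, 200], [1, 1])
        with pytest.raises(ValueError):
            timedep_roc(r, clin, horizon=1095)

    def test_sensitivity_specificity_monotone_uncensored(self):
        rng = np.random.default_rng(31)
        n = 80
        score = rng.normal(size=n)
        time = rng.uniform(10, 3000, n)
        event = np.ones(n)
        r, clin = self._scores(score, time, event)
        roc = timedep_roc(r, clin, horizon=1095)
        sens = roc.points["sensitivity"].to_numpy()
        spec = roc.points["specificity"].to_numpy()
        assert np.all(np.diff(sens) <= 1e-12)
        assert np.all(np.diff(spec) >= -1e-12)
        assert np.all((sens >= 0) & (sens <= 1) & (spec >= 0) & (spec <= 1))


class TestChooseCutoff:
    def test_enumerated_tie_breaks_to_smaller_cutoff(self):
        pts = pd.DataFrame(
            {
                "cutoff": [1.0, 2.0, 3.0, 4.0, 5.0],
                "sensitivity": [0.9, 0.8, 0.7, 0.5, 0.2],
                "specificity": [0.2, 0.6, 0.7, 0.7, 0.8],
            }
        )
        # J = 0.1, 0.4, 0.4, 0.2, 0 -> argmax at cutoffs 2 and 3, pick 2
        roc = RocCurve(1095, pts, auc=0.6)
        assert choose_cutoff(roc) == 2.0


class TestStratify:
    def test_published_cutoff_boundaries(self):
        r = RiskScores(["a", "b", "c"], np.array([-0.07, -0.075, -0.08]), np.zeros(3, int))
        g = stratify(r, -0.075)
        assert list(g) == ["high", "low", "low"]
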