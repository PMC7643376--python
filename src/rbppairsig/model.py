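"""Signature fitting, risk scoring, time-dependent ROC and stratification.

The signature is an L1-penalized Cox proportional-hazards fit over
binary pair indicators: the penalty path is computed by coordinate
descent (scikit-survival's Coxnet) and the penalty is chosen by k-fold
cross-validated partial likelihood using the Verweij-van Houwelingen
criterion, CV-PL = sum over folds of [PL(all data; beta_-k) -
PL(training fold; beta_-k)].  Pairs with nonzero coefficients at the
chosen penalty form the signature.

Risk scores are r = sum_k beta_k * s_k over signature pairs, with s_k
the within-sample ordering indicator.  The cutoff is picked on a
Kaplan-Meier-based time-dependent ROC at a fixed horizon (3 years =
1095 days by default) by maximizing Youden's J.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from rbppairsig.dataio import ClinicalTable, ExpressionMatrix, PairSignature
from rbppairsig.pairspace import PairIndicatorMatrix, indicator_matrix

__all__ = [
    "RiskScores",
    "RocCurve",
    "fit_lasso_cox",
    "score_samples",
    "timedep_roc",
    "choose_cutoff",
    "stratify",
]

THREE_YEARS_DAYS = 1095


@dataclass
class RiskScores:
    """Per-sample risk scores with evaluability bookkeeping."""

    sample_ids: list[str]
    score: np.ndarray
    n_missing_pairs: np.ndarray  # signature pairs unevaluable per sample
    warnings: list[str] = field(default_factory=list)

    def as_series(self) -> pd.Series:
        return pd.Series(self.score, index=self.sample_ids, name="risk_score")


@dataclass
class RocCurve:
    """Time-dependent ROC at a fixed horizon.

    ``points`` has columns cutoff / sensitivity / specificity, ordered by
    cutoff; ``auc`` is the trapezoidal area over (1-specificity,
    sensitivity).
    """

    horizon: float
    points: pd.DataFrame
    auc: float


# ---------------------------------------------------------------------------
# Cox partial likelihood (Breslow ties) for cross-validation


def _cox_partial_loglik(X: np.ndarray, time: np.ndarray, event: np.ndarray, beta: np.ndarray) -> float:
    eta = X @ beta
    order = np.argsort(time, kind="stable")
    t, d, e = time[order], event[order].astype(bool), eta[order]
    shift = e.max() if len(e) else 0.0
    # risk-set sums from the largest time downward; risk set at t[i] is i..n-1
    rev_cumsum = np.cumsum(np.exp(e - shift)[::-1])[::-1]
    ll = 0.0
    i, n = 0, len(t)
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        dead = d[i:j]
        n_dead = int(dead.sum())
        if n_dead:
            ll += float(e[i:j][dead].sum())
            ll -= n_dead * (np.log(rev_cumsum[i]) + shift)
        i = j
    return ll


def _align(p: PairIndicatorMatrix, c: ClinicalTable) -> tuple[PairIndicatorMatrix, pd.DataFrame]:
    common = [s for s in p.sample_ids if s in set(c.patient_ids)]
    if not common:
        raise ValueError("no samples shared between pair matrix and clinical table")
    return p.subset_samples(common), c.data.loc[common]


def fit_lasso_cox(
    p: PairIndicatorMatrix,
    c: ClinicalTable,
    cv_folds: int = 10,
    seed: int = 0,
    alpha: float | None = None,
    n_alphas: int = 50,
    alpha_min_ratio: float = 0.01,
    refit: bool = False,
) -> PairSignature:
    """Select signature pairs by L1-penalized Cox regression.

    The penalty path is fit on the full data; the penalty is chosen by
    ``cv_folds``-fold cross-validated partial likelihood with seeded
    fold assignment (pass ``alpha`` to skip CV and use a fixed penalty).
    Returns the pairs with nonzero coefficients; the cutoff field is
    left unset (see :func:`timedep_roc` / :func:`choose_cutoff`).

    With ``refit=True`` the selected pairs are refit by unpenalized Cox
    regression and the refit coefficients are reported instead of the
    penalized ones.
    """
    p_al, clin = _align(p, c)
    time = clin["os_time"].to_numpy(float)
    event = clin["os_event"].to_numpy(float)
    if event.sum() < 2:
        raise ValueError("need at least 2 events to fit a Cox model")

    X_all = p_al.scores.T.astype(float)
    keep = X_all.std(axis=0) > 0
    if not keep.any():
        raise ValueError("all pair features are constant")
    X = X_all[:, keep]
    kept_pairs = [pr for pr, k in zip(p_al.pairs, keep) if k]
    y = Surv.from_arrays(event.astype(bool), time)

    def fit_path(Xf, yf, alphas=None):
        model = CoxnetSurvivalAnalysis(
            l1_ratio=1.0,
            n_alphas=n_alphas,
            alpha_min_ratio=alpha_min_ratio,
            alphas=alphas,
            fit_baseline_model=False,
            tol=1e-7,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(Xf, yf)
        return model

    path = fit_path(X, y)
    alphas = np.asarray(path.alphas_)

    if alpha is None:
        rng = np.random.default_rng(seed)
        n = len(time)
        folds = np.tile(np.arange(cv_folds), n // cv_folds + 1)[:n]
        rng.shuffle(folds)
        cvpl = np.zeros(len(alphas))
        for k in range(cv_folds):
            tr = folds != k
            if event[tr].sum() < 2:
                continue
            try:
                fold_model = fit_path(X[tr], Surv.from_arrays(event[tr].astype(bool), time[tr]), alphas=list(alphas))
            except Exception:
                continue
            fold_alphas = np.asarray(fold_model.alphas_)
            for j in range(len(alphas)):
                # coxnet may truncate the requested path; use nearest fitted alpha
                jj = int(np.argmin(np.abs(fold_alphas - alphas[j])))
                beta = fold_model.coef_[:, jj]
                cvpl[j] += _cox_partial_loglik(X, time, event, beta) - _cox_partial_loglik(
                    X[tr], time[tr], event[tr], beta
                )
        best = int(np.argmax(cvpl))
        chosen_alpha = float(alphas[best])
        beta = path.coef_[:, best]
    else:
        chosen_alpha = float(alpha)
        if chosen_alpha >= alphas[0]:
            beta = np.zeros(X.shape[1])
        else:
            grid = sorted(set(list(alphas) + [chosen_alpha]), reverse=True)
            path = fit_path(X, y, alphas=grid)
            j = int(np.argmin(np.abs(np.asarray(path.alphas_) - chosen_alpha)))
            beta = path.coef_[:, j]

    nz = np.nonzero(beta)[0]
    pairs = [(kept_pairs[i][0], kept_pairs[i][1], float(beta[i])) for i in nz]

    if refit and pairs:
        from lifelines import CoxPHFitter

        df = pd.DataFrame(X[:, nz], columns=[f"f{i}" for i in range(len(nz))])
        df["T"], df["E"] = time, event
        cph = CoxPHFitter()
        cph.fit(df, duration_col="T", event_col="E")
        pairs = [
            (kept_pairs[i][0], kept_pairs[i][1], float(cph.params_[f"f{j}"]))
            for j, i in enumerate(nz)
        ]
        pairs = [(a, b, v) for a, b, v in pairs if v != 0.0]

    meta = {
        "method": "lasso-cox (coordinate descent), CV partial likelihood",
        "alpha": chosen_alpha,
        "cv_folds": cv_folds if alpha is None else 0,
        "seed": seed,
        "n_features": int(X.shape[1]),
        "n_samples": int(X.shape[0]),
        "refit": bool(refit),
    }
    return PairSignature(pairs, cutoff=None, metadata=meta)


def score_samples(sig: PairSignature, m: ExpressionMatrix) -> RiskScores:
    """Risk score per sample: sum of coefficients over pairs with
    expr(gene_a) > expr(gene_b) strictly.

    Pairs with either gene absent from the matrix contribute 0 and are
    counted in ``n_missing_pairs``; samples with more than half of the
    signature unevaluable are flagged in ``warnings``.  Scores are
    computed directly from the expression values, no renormalization.
    """
    present = set(m.gene_ids)
    pairs_ab = [(a, b) for a, b, _ in sig.pairs]
    evaluable = np.array([a in present and b in present for a, b in pairs_ab], dtype=bool)
    ind = indicator_matrix(m, pairs_ab)
    betas = np.array([beta for _, _, beta in sig.pairs])
    score = (betas[:, None] * ind * evaluable[:, None]).sum(axis=0)
    n_missing = np.full(m.n_samples, int((~evaluable).sum()))
    warns: list[str] = []
    if len(sig) and (~evaluable).sum() > 0.5 * len(sig):
        warns.append(
            f"{int((~evaluable).sum())}/{len(sig)} signature pairs unevaluable in this dataset"
        )
    return RiskScores(list(m.sample_ids), score.astype(float), n_missing, warns)


# ---------------------------------------------------------------------------
# time-dependent ROC (Kaplan-Meier estimator)


def _km_at(time: np.ndarray, event: np.ndarray, t: float) -> float:
    """Product-limit survival probability at time t."""
    if len(time) == 0:
        return 1.0
    order = np.argsort(time, kind="stable")
    ts, es = time[order], event[order]
    s = 1.0
    i = 0
    n = len(ts)
    while i < n and ts[i] <= t:
        j = i
        while j < n and ts[j] == ts[i]:
            j += 1
        d = es[i:j].sum()
        at_risk = n - i
        if d:
            s *= 1.0 - d / at_risk
        i = j
    return float(s)


def timedep_roc(r: RiskScores, c: ClinicalTable, horizon: float = THREE_YEARS_DAYS) -> RocCurve:
    """Kaplan-Meier time-dependent ROC of the risk score at ``horizon``.

    With S the overall KM survival at the horizon and S_hi / S_lo the KM
    survival among samples scoring above / at-or-below a cutoff c:

        sensitivity(c) = (1 - S_hi) * P(score > c) / (1 - S)
        specificity(c) = S_lo * P(score <= c) / S

    Candidate cutoffs are the midpoints between sorted unique scores
    plus +/-infinity; estimates are clipped to [0, 1].  When no sample
    is censored before the horizon this reduces exactly to the
    classical binary ROC of the event-before-horizon indicator.
    """
    common = [s for s in r.sample_ids if s in set(c.patient_ids)]
    if not common:
        raise ValueError("no samples shared between scores and clinical table")
    pos = {s: i for i, s in enumerate(r.sample_ids)}
    score = r.score[[pos[s] for s in common]]
    clin = c.data.loc[common]
    time = clin["os_time"].to_numpy(float)
    event = clin["os_event"].to_numpy(float)
    if horizon > time.max():
        raise ValueError(f"horizon {horizon} beyond last observed time {time.max()}")
    if not ((time <= horizon) & (event == 1)).any():
        raise ValueError("no events observed before the horizon")

    s_overall = _km_at(time, event, horizon)
    uniq = np.unique(score)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    cutoffs = np.concatenate(([-np.inf], mids, [np.inf]))

    rows = []
    n = len(score)
    for cut in cutoffs:
        hi = score > cut
        p_hi = hi.mean()
        s_hi = _km_at(time[hi], event[hi], horizon) if hi.any() else 1.0
        s_lo = _km_at(time[~hi], event[~hi], horizon) if (~hi).any() else 1.0
        sens = (1.0 - s_hi) * p_hi / (1.0 - s_overall) if s_overall < 1 else 0.0
        spec = s_lo * (1.0 - p_hi) / s_overall if s_overall > 0 else 0.0
        rows.append((cut, min(max(sens, 0.0), 1.0), min(max(spec, 0.0), 1.0)))

    points = pd.DataFrame(rows, columns=["cutoff", "sensitivity", "specificity"])
    fpr = 1.0 - points["specificity"].to_numpy()
    tpr = points["sensitivity"].to_numpy()
    order = np.lexsort((tpr, fpr))  # ties in FPR traverse upward in TPR
    auc = float(np.trapezoid(tpr[order], fpr[order]))
    return RocCurve(float(horizon), points, auc)


def choose_cutoff(roc: RocCurve) -> float:
    """Cutoff maximizing Youden's J = sensitivity + specificity - 1.

    Ties break toward the smaller cutoff; finite cutoffs are preferred
    over the +/-infinity endpoints when J ties there.
    """
    if len(roc.points) == 0:
        raise ValueError("empty ROC curve")
    pts = roc.points
    j = pts["sensitivity"].to_numpy() + pts["specificity"].to_numpy() - 1.0
    jmax = j.max()
    best = pts["cutoff"].to_numpy()[np.isclose(j, jmax)]
    finite = best[np.isfinite(best)]
    return float(finite.min()) if finite.size else float(best.min())


def stratify(r: RiskScores, cutoff: float) -> pd.Series:
    """Assign each sample to 'high' (score strictly above cutoff) or 'low'."""
    labels = np.where(r.score > cutoff, "high", "low")
    return pd.Series(labels, index=r.sample_ids, name="risk_group")
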