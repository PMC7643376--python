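"""Survival statistics and risk-group comparisons.

Kaplan-Meier curves and log-rank tests, univariate/multivariate Cox
proportional-hazards regression (Efron tie handling via lifelines),
clinical subgroup splits, unpaired Wilcoxon rank-sum comparisons of
per-sample quantities across risk groups, and tumor mutational burden
from MAF-style somatic mutation records.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test
from scipy import stats

from rbppairsig.dataio import ClinicalTable, MutationRecords, NONSILENT_CLASSES
from rbppairsig.model import RiskScores

__all__ = [
    "CoxResult",
    "KmLogrankResult",
    "km_logrank",
    "cox_regression",
    "subgroup_split",
    "compute_tmb",
    "wilcoxon_compare",
]


@dataclass
class CoxResult:
    """Hazard ratio with Wald 95% CI and p-value for one covariate."""

    variable: str
    hr: float
    ci_low: float
    ci_high: float
    p_value: float
    model: str  # "univariate" or "multivariate"

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.hr <= self.ci_high):
            raise ValueError(f"{self.variable}: CI does not bracket HR")


@dataclass
class KmLogrankResult:
    """Two-group KM comparison: curves, log-rank test and group HR."""

    km_high: pd.DataFrame  # columns: time, survival
    km_low: pd.DataFrame
    chi2: float
    p_value: float
    hr: float
    ci_low: float
    ci_high: float
    n_high: int = 0
    n_low: int = 0
    metadata: dict = field(default_factory=dict)


def _km_curve(time: np.ndarray, event: np.ndarray) -> pd.DataFrame:
    kmf = KaplanMeierFitter()
    kmf.fit(time, event)
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()})


def km_logrank(groups: pd.Series, c: ClinicalTable) -> KmLogrankResult:
    """Compare survival between 'high' and 'low' risk groups.

    Returns the per-group product-limit curves, the two-group log-rank
    chi-square and p, and the hazard ratio (high vs low) with Wald 95%
    CI from a single-covariate Cox fit.
    """
    common = [s for s in groups.index if s in set(c.patient_ids)]
    g = groups.loc[common]
    clin = c.data.loc[common]
    hi, lo = g == "high", g == "low"
    if not hi.any() or not lo.any():
        raise ValueError("both risk groups must be nonempty")
    t = clin["os_time"].to_numpy(float)
    e = clin["os_event"].to_numpy(float)
    if e.sum() < 1:
        raise ValueError("need at least one event")

    res = logrank_test(t[hi.to_numpy()], t[lo.to_numpy()], e[hi.to_numpy()], e[lo.to_numpy()])

    df = pd.DataFrame({"T": t, "E": e, "high": hi.astype(float).to_numpy()})
    try:
        cph = CoxPHFitter()
        cph.fit(df, duration_col="T", event_col="E")
    except ConvergenceError:
        # monotone likelihood (e.g. a group without events): stabilize with
        # a small ridge penalty, which keeps HR(swap) = 1/HR symmetry
        cph = CoxPHFitter(penalizer=0.01)
        cph.fit(df, duration_col="T", event_col="E")
    hr = float(np.exp(cph.params_["high"]))
    ci = cph.confidence_intervals_
    ci_low = float(np.exp(ci.loc["high"].iloc[0]))
    ci_high = float(np.exp(ci.loc["high"].iloc[1]))

    return KmLogrankResult(
        km_high=_km_curve(t[hi.to_numpy()], e[hi.to_numpy()]),
        km_low=_km_curve(t[lo.to_numpy()], e[lo.to_numpy()]),
        chi2=float(res.test_statistic),
        p_value=float(res.p_value),
        hr=hr,
        ci_low=ci_low,
        ci_high=ci_high,
        n_high=int(hi.sum()),
        n_low=int(lo.sum()),
    )


def cox_regression(
    c: ClinicalTable,
    covariates: list[str],
    scores: RiskScores | None = None,
    mode: str = "univariate",
) -> list[CoxResult]:
    """Cox proportional-hazards regression of overall survival.

    ``covariates`` name clinical columns (numeric encodings: stage 1-4,
    gender 1/2, age in years) and may include ``"risk_score"`` when
    ``scores`` is given.  Univariate mode fits each covariate alone;
    multivariate fits all jointly.  Complete-case per model; tied event
    times use the Efron approximation.
    """
    if mode not in ("univariate", "multivariate"):
        raise ValueError(f"unknown mode {mode!r}")
    df = c.data.copy()
    if scores is not None:
        s = scores.as_series()
        df["risk_score"] = s.reindex(df.index)
    for cov in covariates:
        if cov not in df.columns:
            raise ValueError(f"covariate {cov!r} not found")

    def fit(cols: list[str]) -> list[CoxResult]:
        sub = df[["os_time", "os_event", *cols]].dropna()
        for col in cols:
            if sub[col].nunique() <= 1:
                raise ValueError(f"covariate {col!r} is constant in the complete cases")
        cph = CoxPHFitter()
        cph.fit(
            sub.rename(columns={"os_time": "T", "os_event": "E"}),
            duration_col="T",
            event_col="E",
        )
        out = []
        ci = cph.confidence_intervals_
        for col in cols:
            out.append(
                CoxResult(
                    variable=col,
                    hr=float(np.exp(cph.params_[col])),
                    ci_low=float(np.exp(ci.loc[col].iloc[0])),
                    ci_high=float(np.exp(ci.loc[col].iloc[1])),
                    p_value=float(cph.summary.loc[col, "p"]),
                    model=mode,
                )
            )
        return out

    if mode == "univariate":
        results: list[CoxResult] = []
        for cov in covariates:
            results.extend(fit([cov]))
        return results
    return fit(list(covariates))


def subgroup_split(
    c: ClinicalTable, by: str, seed: int = 0
) -> dict[str, ClinicalTable]:
    """Partition a cohort for subgroup validation.

    ``by`` is one of ``random_halves`` (seeded 50/50 split),
    ``age_median`` (younger = age <= cohort median), ``gender``,
    ``stage`` or ``n_stage`` (category partitions; patients missing the
    variable are dropped).  Every retained patient lands in exactly one
    subset.
    """
    d = c.data
    if by == "random_halves":
        rng = np.random.default_rng(seed)
        perm = rng.permutation(len(d))
        half = len(d) // 2
        ids = np.array(d.index)
        return {
            "half1": ClinicalTable(d.loc[ids[perm[:half]]].copy()),
            "half2": ClinicalTable(d.loc[ids[perm[half:]]].copy()),
        }
    if by == "age_median":
        age = d["age"]
        if age.isna().all():
            raise ValueError("age entirely missing")
        med = float(age.median())
        young = age <= med
        return {
            "younger": ClinicalTable(d.loc[young & age.notna()].copy()),
            "older": ClinicalTable(d.loc[~young & age.notna()].copy()),
        }
    if by in ("gender", "stage", "n_stage", "t_stage", "m_stage", "smoking"):
        col = d[by]
        if col.isna().all():
            raise ValueError(f"{by} entirely missing")
        out = {}
        for val in sorted(col.dropna().unique()):
            out[f"{by}={int(val)}"] = ClinicalTable(d.loc[col == val].copy())
        return out
    raise ValueError(f"unknown split variable {by!r}")


def compute_tmb(
    mut: MutationRecords,
    exome_mb: float = 38.0,
    classes: frozenset[str] | set[str] | None = NONSILENT_CLASSES,
    sample_roster: list[str] | None = None,
) -> pd.DataFrame:
    """Tumor mutational burden per sample: counted mutations / exome Mb.

    ``classes`` restricts which variant classifications are counted
    (default: non-silent coding classes; ``None`` counts every record).
    Samples in ``sample_roster`` absent from the records get count 0.
    The default denominator of 38 Mb is a conventional exome footprint.
    """
    if exome_mb <= 0:
        raise ValueError("exome_mb must be positive")
    d = mut.data
    if classes is not None:
        d = d[d["variant_classification"].isin(classes)]
    counts = d.groupby("sample_id").size()
    if sample_roster is not None:
        counts = counts.reindex(sample_roster, fill_value=0)
    out = pd.DataFrame(
        {
            "sample_id": counts.index,
            "mutation_count": counts.to_numpy(int),
            "tmb": counts.to_numpy(float) / exome_mb,
        }
    ).reset_index(drop=True)
    return out


def plot_km(result: KmLogrankResult, path: str) -> None:
    """Step plot of the two KM curves with HR and log-rank p annotated."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for curve, label, color in (
        (result.km_high, f"high (n={result.n_high})", "firebrick"),
        (result.km_low, f"low (n={result.n_low})", "steelblue"),
    ):
        ax.step(curve["time"], curve["survival"], where="post", label=label, color=color)
    ax.set_xlabel("time (days)")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend(frameon=False)
    ax.set_title(f"HR {result.hr:.2f} ({result.ci_low:.2f}-{result.ci_high:.2f}), "
                 f"log-rank p {result.p_value:.2g}", fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def wilcoxon_compare(
    values: pd.Series,
    groups: pd.Series,
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Unpaired Wilcoxon rank-sum comparison of 'high' vs 'low' groups.

    Exact null enumeration when both groups have <= 10 observations (and
    no ties span the groups); otherwise the normal approximation with
    tie correction.  Returns (U statistic for the high group, p-value).
    """
    common = values.index.intersection(groups.index)
    v = values.loc[common]
    g = groups.loc[common]
    x = v[g == "high"].to_numpy(float)
    y = v[g == "low"].to_numpy(float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups need at least one observation")
    method = "exact" if (len(x) <= 10 and len(y) <= 10) else "asymptotic"
    if method == "exact" and len(np.unique(np.concatenate([x, y]))) < len(x) + len(y):
        method = "asymptotic"  # exact null distribution assumes no ties
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)
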