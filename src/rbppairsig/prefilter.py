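"""Cohort exclusion, differential-expression screening and candidate filters.

Differential expression between tumor and normal samples is assessed on
log2(x+1)-transformed values with an empirical-Bayes moderated
t-statistic: per-gene sample variances are shrunk toward a common prior
whose degrees of freedom and scale are moment-estimated from the whole
gene family, and p-values are Benjamini-Hochberg adjusted across the
tested family.  With the prior degrees of freedom forced to zero the
statistic reduces exactly to the ordinary two-sample pooled t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from rbppairsig.dataio import ClinicalTable, ExpressionMatrix

__all__ = [
    "DEResult",
    "exclude_short_followup",
    "differential_expression",
    "candidate_filter",
]


@dataclass
class DEResult:
    """Per-gene differential-expression summary (tumor minus normal)."""

    gene: str
    log2fc: float
    t_stat: float
    p_value: float
    fdr: float

    @property
    def direction(self) -> str:
        return "up" if self.log2fc > 0 else "down"


def exclude_short_followup(c: ClinicalTable, min_days: int = 30) -> ClinicalTable:
    """Drop patients with short or missing follow-up.

    Retains exactly the patients with non-missing ``os_time`` and
    ``os_event`` and ``os_time >= min_days`` (30 days ~ one month).
    """
    d = c.data
    keep = d["os_time"].notna() & d["os_event"].notna() & (d["os_time"] >= min_days)
    return ClinicalTable(d.loc[keep].copy())


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(100):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def _fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-estimate (prior_df, prior_s2) of a scaled-inverse-chi2 prior.

    Works on log variances: if s2 ~ s0^2 * chi2_d / d marginally scaled by
    an inverse-chi2 prior with d0 df, then log(s2) has known digamma
    moments; excess spread beyond trigamma(d/2) determines d0.
    """
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if s2.size < 2:
        return np.inf, float(np.median(s2)) if s2.size else 1.0
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_2 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_2 = float(np.exp(emean))
    return d0, s0_2


def differential_expression(
    m: ExpressionMatrix,
    gene_universe: list[str] | None = None,
    fdr_max: float = 0.05,
    lfc_min: float = 0.5,
    prior_df: float | None = None,
    return_all: bool = False,
) -> list[DEResult]:
    """Moderated-t screen of tumor vs normal expression.

    Parameters
    ----------
    m
        Expression matrix containing both tumor and normal samples.
    gene_universe
        Restrict testing to these symbols (e.g. an RNA-binding-protein
        gene list); genes absent from the matrix are ignored.  ``None``
        tests every gene.
    fdr_max, lfc_min
        Significance filter: BH-adjusted p < ``fdr_max`` and
        |log2 fold change| > ``lfc_min``.
    prior_df
        Override the moment-estimated prior degrees of freedom; 0 gives
        the ordinary two-sample pooled t-test.
    return_all
        Return every tested gene instead of only the significant ones.
    """
    tumor = m.tumor_samples()
    normal = m.normal_samples()
    if len(tumor) < 2 or len(normal) < 2:
        raise ValueError("differential expression needs >= 2 samples per group")

    if gene_universe is not None:
        genes = [g for g in m.gene_ids if g in set(gene_universe)]
    else:
        genes = m.gene_ids
    if not genes:
        raise ValueError("no genes to test")

    logx = np.log2(m.values.loc[genes].to_numpy() + 1.0)
    idx_t = [m.sample_ids.index(s) for s in tumor]
    idx_n = [m.sample_ids.index(s) for s in normal]
    xt, xn = logx[:, idx_t], logx[:, idx_n]
    n1, n2 = xt.shape[1], xn.shape[1]

    lfc = xt.mean(axis=1) - xn.mean(axis=1)
    df_resid = n1 + n2 - 2
    ss = xt.var(axis=1, ddof=1) * (n1 - 1) + xn.var(axis=1, ddof=1) * (n2 - 1)
    s2 = ss / df_resid
    stdev_unscaled = np.sqrt(1.0 / n1 + 1.0 / n2)

    if prior_df is None:
        d0, s0_2 = _fit_variance_prior(s2, df_resid)
    elif prior_df == 0:
        d0, s0_2 = 0.0, 0.0
    else:
        d0 = float(prior_df)
        _, s0_2 = _fit_variance_prior(s2, df_resid)

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_2 + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid

    with np.errstate(divide="ignore", invalid="ignore"):
        t = lfc / (np.sqrt(s2_post) * stdev_unscaled)
    t = np.where(np.isfinite(t), t, 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)

    _, fdr, _, _ = multipletests(p, method="fdr_bh")
    results = [
        DEResult(g, float(lfc[i]), float(t[i]), float(p[i]), float(fdr[i]))
        for i, g in enumerate(genes)
    ]
    if return_all:
        return results
    hits = [r for r in results if r.fdr < fdr_max and abs(r.log2fc) > lfc_min]
    hits.sort(key=lambda r: (r.p_value, r.gene))
    return hits


def candidate_filter(
    m: ExpressionMatrix,
    de_genes: list[str],
    mean_min: float = 0.0,
    mad_min: float = 0.5,
    samples: str = "tumor",
    transform: str = "log2p1",
) -> list[str]:
    """Keep DE genes with usable expression level and variability.

    A gene passes when its mean expression exceeds ``mean_min`` and its
    unscaled median absolute deviation (median of |x - median(x)|, no
    1.4826 consistency factor) exceeds ``mad_min``, both computed on
    ``log2(x+1)``-transformed values (``transform="raw"`` uses the raw
    scale) over tumor samples (``samples="all"`` uses every sample).
    Output preserves the input gene order.
    """
    missing = [g for g in de_genes if g not in set(m.gene_ids)]
    if missing:
        raise ValueError(f"candidate genes absent from matrix: {missing[:5]}")
    cols = m.tumor_samples() if samples == "tumor" else m.sample_ids
    x = m.values.loc[de_genes, cols].to_numpy()
    if transform == "log2p1":
        x = np.log2(x + 1.0)
    elif transform != "raw":
        raise ValueError(f"unknown transform {transform!r}")
    means = x.mean(axis=1)
    med = np.median(x, axis=1, keepdims=True)
    mad = np.median(np.abs(x - med), axis=1)
    return [g for g, mu, md in zip(de_genes, means, mad) if mu > mean_min and md > mad_min]
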