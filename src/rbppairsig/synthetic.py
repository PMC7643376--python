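"""Synthetic tumor/normal cohorts with planted pair-order hazard signal.

The generator emulates the statistical structure the pair-signature
pipeline assumes: log-normal expression with gene-specific means and
spreads, a planted subset of differentially expressed genes shifted on
the log2 scale in tumor samples, and exponential proportional-hazards
survival in which the within-sample ordering of planted gene pairs
multiplies the hazard.  Both members of a planted pair share the same
log-expression mean, so each pair indicator is close to Bernoulli(1/2)
and maximally informative; both members are shifted equally in tumors,
so planted pairs survive the differential-expression screen without
their indicator distribution changing.

Censoring is independent Uniform(0, censor_max).  Survival times are
reported in whole days (rounded up), matching day-resolution clinical
tables and producing occasional tied event times.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from rbppairsig.dataio import ClinicalTable, ExpressionMatrix

__all__ = ["SyntheticTruth", "generate_cohort", "apply_monotone_distortion"]


@dataclass
class SyntheticTruth:
    """Ground truth of a generated cohort, kept for recovery tests."""

    signal_pairs: list[tuple[str, str, float]]  # (gene_a, gene_b, log-hazard per indicator)
    de_genes: list[tuple[str, float]]  # (gene, true log2 fold change)
    baseline_hazard: float  # events per day for z = 0
    censor_max: float  # days
    seed: int
    stage_loghr: float = 0.0

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "signal_pairs": [[a, b, float(g)] for a, b, g in self.signal_pairs],
            "de_genes": [[g, float(fc)] for g, fc in self.de_genes],
            "baseline_hazard": float(self.baseline_hazard),
            "censor_max": float(self.censor_max),
            "seed": int(self.seed),
            "stage_loghr": float(self.stage_loghr),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(
            signal_pairs=[tuple(x) for x in d["signal_pairs"]],
            de_genes=[tuple(x) for x in d["de_genes"]],
            baseline_hazard=d["baseline_hazard"],
            censor_max=d["censor_max"],
            seed=d["seed"],
            stage_loghr=d.get("stage_loghr", 0.0),
        )


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def generate_cohort(
    n_tumor: int = 300,
    n_normal: int = 50,
    n_genes: int = 200,
    n_signal_pairs: int = 10,
    gamma: float = 0.8,
    frac_de: float = 0.2,
    log2fc: float = 1.5,
    lambda0: float = 1.0 / 1500.0,
    censor_max: float = 3650.0,
    seed: int = 0,
    stage_loghr: float = 0.0,
    quantize_decimals: int | None = None,
) -> tuple[ExpressionMatrix, ClinicalTable, SyntheticTruth]:
    """Generate a tumor/normal expression cohort with survival.

    Parameters
    ----------
    n_tumor, n_normal
        Sample counts per group; tumor samples double as patients.
    n_genes
        Total genes; must be at least ``2 * n_signal_pairs``.
    n_signal_pairs
        Planted gene pairs whose within-sample ordering carries hazard.
    gamma
        Log-hazard contribution of each pair indicator (s=1 multiplies
        the hazard by exp(gamma)).
    frac_de
        Fraction of genes differentially expressed in tumors; planted
        signal genes are always among them.
    log2fc
        Absolute log2 fold change of DE genes (tumor minus normal).
    lambda0
        Baseline hazard per day for a patient with all indicators 0.
    censor_max
        Upper bound of the uniform censoring-time distribution, days.
    seed
        Seeds every random draw; identical arguments reproduce the
        cohort bit for bit.
    stage_loghr
        Optional extra log-hazard per pathologic stage above I, making
        stage an independent prognostic factor.
    quantize_decimals
        Round expression to this many decimals to create exact ties
        (exercises the ties-score-zero rule); ``None`` disables.
    """
    if n_genes < 2 * n_signal_pairs:
        raise ValueError("n_genes must be at least 2 * n_signal_pairs")
    if not 0 <= frac_de <= 1:
        raise ValueError("frac_de must be in [0, 1]")
    if min(n_tumor, n_normal, n_genes) <= 0:
        raise ValueError("counts must be positive")
    if lambda0 <= 0 or censor_max <= 0:
        raise ValueError("lambda0 and censor_max must be positive")

    rng = np.random.default_rng(seed)
    genes = _gene_names(n_genes)
    tumor_ids = [f"T{i:04d}" for i in range(1, n_tumor + 1)]
    normal_ids = [f"N{i:04d}" for i in range(1, n_normal + 1)]

    # gene-level log2-expression means and spreads; spreads span the
    # MAD=0.5 variability threshold so the candidate filter is exercised
    mu = rng.uniform(1.0, 7.0, size=n_genes)
    sd = rng.uniform(0.3, 1.0, size=n_genes)

    n_signal_genes = 2 * n_signal_pairs
    # both members of a planted pair share mean and spread -> indicator ~ Bern(1/2);
    # spread >= 0.9 keeps their MAD (~0.67*sd on the log2 scale) above the 0.5 filter
    for k in range(n_signal_pairs):
        mu[2 * k + 1] = mu[2 * k]
        sd[2 * k + 1] = sd[2 * k] = max(sd[2 * k], 0.9)

    n_de = max(int(round(frac_de * n_genes)), n_signal_genes if n_signal_pairs else 0)
    n_de = min(n_de, n_genes)
    de_idx = list(range(n_signal_genes)) + list(
        rng.choice(
            np.arange(n_signal_genes, n_genes),
            size=max(0, n_de - n_signal_genes),
            replace=False,
        )
    )
    shift = np.zeros(n_genes)
    for j, gi in enumerate(de_idx):
        if gi < n_signal_genes:
            shift[gi] = log2fc  # pair members move together, ordering unchanged
        else:
            shift[gi] = log2fc if j % 2 == 0 else -log2fc

    log2_tumor = rng.normal(mu[:, None] + shift[:, None], sd[:, None], size=(n_genes, n_tumor))
    log2_normal = rng.normal(mu[:, None], sd[:, None], size=(n_genes, n_normal))
    values = np.exp2(np.concatenate([log2_tumor, log2_normal], axis=1))
    if quantize_decimals is not None:
        values = np.round(values, quantize_decimals)

    columns = tumor_ids + normal_ids
    expr = pd.DataFrame(values, index=genes, columns=columns)
    group = pd.Series(["tumor"] * n_tumor + ["normal"] * n_normal, index=columns)
    matrix = ExpressionMatrix(expr, group)

    signal_pairs = [(genes[2 * k], genes[2 * k + 1], gamma) for k in range(n_signal_pairs)]

    # clinical covariates
    age = np.clip(np.round(rng.normal(65.0, 10.0, n_tumor)), 30, 90)
    gender = rng.choice([1, 2], size=n_tumor)
    stage = rng.choice([1, 2, 3, 4], size=n_tumor, p=[0.55, 0.25, 0.15, 0.05])
    t_stage = np.minimum(stage + rng.integers(0, 2, n_tumor), 4)
    n_stage = np.maximum(stage - rng.integers(1, 3, n_tumor), 0)
    m_stage = (stage == 4).astype(int)
    smoking = rng.choice([0, 1], size=n_tumor, p=[0.25, 0.75])

    # proportional-hazards survival from the planted pair orderings
    tumor_expr = values[:, :n_tumor]
    z = np.zeros(n_tumor)
    for k in range(n_signal_pairs):
        s = (tumor_expr[2 * k, :] > tumor_expr[2 * k + 1, :]).astype(float)
        z += gamma * s
    z += stage_loghr * (stage - 1)
    rate = lambda0 * np.exp(z)
    death = rng.exponential(1.0 / rate)
    censor = rng.uniform(0.0, censor_max, n_tumor)
    os_time = np.ceil(np.minimum(death, censor)).astype(int)
    os_event = (death <= censor).astype(int)

    clinical = ClinicalTable(
        pd.DataFrame(
            {
                "os_time": os_time,
                "os_event": os_event,
                "age": age,
                "gender": gender,
                "stage": stage,
                "t_stage": t_stage,
                "n_stage": n_stage,
                "m_stage": m_stage,
                "smoking": smoking,
            },
            index=pd.Index(tumor_ids, name="patient_id"),
        )
    )

    truth = SyntheticTruth(
        signal_pairs=signal_pairs,
        de_genes=[(genes[gi], float(shift[gi])) for gi in sorted(de_idx)],
        baseline_hazard=lambda0,
        censor_max=censor_max,
        seed=seed,
        stage_loghr=stage_loghr,
    )
    return matrix, clinical, truth


def apply_monotone_distortion(m: ExpressionMatrix, seed: int = 0) -> ExpressionMatrix:
    """Distort each sample by an independent strictly increasing transform.

    Each sample draws one of three transform families — affine with
    positive slope, power with positive exponent, or scaled log1p — with
    random parameters.  Within-sample orderings of all gene pairs, and
    hence every pair indicator and risk score, are exactly preserved;
    anything that depends on the values themselves (means, fold changes,
    MADs) is not.
    """
    rng = np.random.default_rng(seed)
    out = m.values.copy()
    for col in out.columns:
        kind = rng.integers(0, 3)
        x = out[col].to_numpy()
        if kind == 0:
            a = rng.uniform(0.5, 5.0)
            b = rng.uniform(0.0, 10.0)
            out[col] = a * x + b
        elif kind == 1:
            p = rng.uniform(0.3, 2.5)
            out[col] = np.power(x, p)
        else:
            a = rng.uniform(1.0, 100.0)
            out[col] = a * np.log1p(x)
    return ExpressionMatrix(out, m.group.copy())
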