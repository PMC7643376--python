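"""End-to-end discovery and validation runs from a single config.

Discovery mirrors the published modeling funnel: exclude short
follow-up, collapse duplicate probes/samples, screen differential
expression within the gene universe, filter candidates by expression
level and variability, build the pair-indicator matrix, drop
near-constant pairs, fit the L1 Cox signature, score samples, pick the
time-dependent-ROC cutoff, stratify, and run the survival statistics.
Validation applies a fixed signature and cutoff to a new cohort with no
refitting.  Per-stage row counts are logged so the selection funnel can
be read off a run.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from rbppairsig.dataio import (
    ClinicalTable,
    ExpressionMatrix,
    PairSignature,
    read_clinical_table,
    read_expression_matrix,
    read_signature,
    write_signature,
    collapse_duplicates,
)
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
from rbppairsig.prefilter import candidate_filter, differential_expression, exclude_short_followup
from rbppairsig.survstats import KmLogrankResult, cox_regression, km_logrank

__all__ = ["RunConfig", "DiscoveryBundle", "ValidationBundle", "run_discovery", "run_validation"]


@dataclass
class RunConfig:
    """All tunable constants of a pipeline run, with published defaults."""

    # paths (optional when objects are passed in memory)
    expression_path: str | None = None
    groups_path: str | None = None  # two-column TSV: sample_id, tumor/normal
    clinical_path: str | None = None
    gene_universe_path: str | None = None
    signature_path: str | None = None
    output_dir: str | None = None
    # thresholds
    fdr_max: float = 0.05
    lfc_min: float = 0.5
    mad_min: float = 0.5
    mean_min: float = 0.0
    min_days: int = 30
    max_identity: float = 0.90
    horizon_days: int = 1095
    # model
    cv_folds: int = 10
    seed: int = 0
    refit: bool = False
    # covariate rosters for Cox tables
    discovery_covariates: tuple[str, ...] = (
        "age",
        "gender",
        "stage",
        "t_stage",
        "m_stage",
        "n_stage",
        "risk_score",
    )
    validation_covariates: tuple[str, ...] = ("age", "gender", "smoking", "stage", "risk_score")
    # encodings, recorded in the manifest
    gender_encoding: dict = field(default_factory=lambda: {"male": 1, "female": 2})
    stage_encoding: dict = field(default_factory=lambda: {"I": 1, "II": 2, "III": 3, "IV": 4})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "discovery_covariates" in d:
            d["discovery_covariates"] = tuple(d["discovery_covariates"])
        if "validation_covariates" in d:
            d["validation_covariates"] = tuple(d["validation_covariates"])
        return cls(**d)

    def manifest(self) -> dict:
        from rbppairsig import __version__

        m = asdict(self)
        m["package_version"] = __version__
        return m


@dataclass
class DiscoveryBundle:
    signature: PairSignature
    scores: RiskScores
    groups: pd.Series
    roc: RocCurve
    cutoff: float
    de_genes: list[str]
    candidates: list[str]
    km: KmLogrankResult
    cox_univariate: list
    cox_multivariate: list
    funnel: dict
    manifest: dict


@dataclass
class ValidationBundle:
    scores: RiskScores
    groups: pd.Series
    km: KmLogrankResult
    cox_univariate: list
    cox_multivariate: list
    manifest: dict


class StageError(RuntimeError):
    """Wraps a failure with the pipeline stage it occurred in."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except StageError:
        raise
    except Exception as exc:
        raise StageError(name, exc) from exc


def _load_inputs(
    cfg: RunConfig,
    expression: ExpressionMatrix | None,
    clinical: ClinicalTable | None,
) -> tuple[ExpressionMatrix, ClinicalTable]:
    if expression is None:
        if cfg.expression_path is None:
            raise ValueError("no expression matrix given (object or path)")
        group = None
        if cfg.groups_path is not None:
            group = pd.read_csv(cfg.groups_path, sep="\t", index_col=0).iloc[:, 0]
        expression = read_expression_matrix(cfg.expression_path, group=group)
    if clinical is None:
        if cfg.clinical_path is None:
            raise ValueError("no clinical table given (object or path)")
        clinical = read_clinical_table(cfg.clinical_path)
    return expression, clinical


def _read_universe(cfg: RunConfig) -> list[str] | None:
    if cfg.gene_universe_path is None:
        return None
    return [
        line.strip()
        for line in Path(cfg.gene_universe_path).read_text().splitlines()
        if line.strip()
    ]


def run_discovery(
    cfg: RunConfig,
    expression: ExpressionMatrix | None = None,
    clinical: ClinicalTable | None = None,
    gene_universe: list[str] | None = None,
) -> DiscoveryBundle:
    """Fit the full pair signature on a discovery cohort."""
    expression, clinical = _load_inputs(cfg, expression, clinical)
    if gene_universe is None:
        gene_universe = _read_universe(cfg)

    funnel: dict[str, int] = {"patients_in": len(clinical), "genes_in": expression.n_genes}

    clinical = _stage("exclude_short_followup", exclude_short_followup, clinical, cfg.min_days)
    funnel["patients_retained"] = len(clinical)

    expression = _stage("collapse_duplicates", collapse_duplicates, expression)

    de = _stage(
        "differential_expression",
        differential_expression,
        expression,
        gene_universe,
        cfg.fdr_max,
        cfg.lfc_min,
    )
    de_genes = [r.gene for r in de]
    funnel["de_genes"] = len(de_genes)

    candidates = _stage(
        "candidate_filter", candidate_filter, expression, de_genes, cfg.mean_min, cfg.mad_min
    )
    funnel["candidate_genes"] = len(candidates)
    if len(candidates) < 2:
        raise StageError("candidate_filter", ValueError("fewer than 2 candidate genes"))

    retained = [s for s in expression.tumor_samples() if s in set(clinical.patient_ids)]
    tumor_expr = expression.subset_samples(retained)
    pairs = _stage("build_pair_matrix", build_pair_matrix, tumor_expr, candidates)
    funnel["pairs_built"] = pairs.n_pairs
    pairs = _stage("filter_constant_pairs", filter_constant_pairs, pairs, cfg.max_identity)
    funnel["pairs_informative"] = pairs.n_pairs

    signature = _stage(
        "fit_lasso_cox",
        fit_lasso_cox,
        pairs,
        clinical,
        cfg.cv_folds,
        cfg.seed,
        refit=cfg.refit,
    )
    funnel["signature_pairs"] = len(signature)

    scores = _stage("score_samples", score_samples, signature, tumor_expr)
    if len(signature) == 0:
        roc, cutoff = None, 0.0
    else:
        roc = _stage("timedep_roc", timedep_roc, scores, clinical, cfg.horizon_days)
        cutoff = _stage("choose_cutoff", choose_cutoff, roc)
    signature.cutoff = cutoff
    signature.metadata.update(
        {"cutoff_criterion": "youden-j, 3-year time-dependent ROC", "horizon_days": cfg.horizon_days}
    )
    groups = _stage("stratify", stratify, scores, cutoff)

    km = None
    cox_uni: list = []
    cox_multi: list = []
    if len(signature) and groups.nunique() == 2:
        km = _stage("km_logrank", km_logrank, groups, clinical)
        roster = [v for v in cfg.discovery_covariates]
        try:
            cox_uni = cox_regression(clinical, roster, scores=scores, mode="univariate")
            cox_multi = cox_regression(clinical, roster, scores=scores, mode="multivariate")
        except ValueError:
            pass  # e.g. constant covariate in a small synthetic cohort

    bundle = DiscoveryBundle(
        signature=signature,
        scores=scores,
        groups=groups,
        roc=roc,
        cutoff=cutoff,
        de_genes=de_genes,
        candidates=candidates,
        km=km,
        cox_univariate=cox_uni,
        cox_multivariate=cox_multi,
        funnel=funnel,
        manifest=cfg.manifest(),
    )
    if cfg.output_dir:
        _write_discovery(bundle, Path(cfg.output_dir))
    return bundle


def run_validation(
    cfg: RunConfig,
    sig: PairSignature | None = None,
    expression: ExpressionMatrix | None = None,
    clinical: ClinicalTable | None = None,
) -> ValidationBundle:
    """Apply a fixed signature and cutoff to an independent cohort.

    Nothing is refit: coefficients and cutoff come from the signature;
    pairs whose genes are missing from the cohort contribute 0 and are
    reported per sample.
    """
    if sig is None:
        if cfg.signature_path is None:
            raise ValueError("no signature given (object or path)")
        sig = read_signature(cfg.signature_path)
    if sig.cutoff is None:
        raise ValueError("signature has no cutoff set; fit one on a discovery cohort first")
    expression, clinical = _load_inputs(cfg, expression, clinical)

    clinical = _stage("exclude_short_followup", exclude_short_followup, clinical, cfg.min_days)
    expression = _stage("collapse_duplicates", collapse_duplicates, expression)
    scores = _stage("score_samples", score_samples, sig, expression)
    groups = _stage("stratify", stratify, scores, sig.cutoff)

    km = None
    cox_uni: list = []
    cox_multi: list = []
    g = groups.loc[[s for s in groups.index if s in set(clinical.patient_ids)]]
    if g.nunique() == 2:
        km = _stage("km_logrank", km_logrank, groups, clinical)
        roster = [v for v in cfg.validation_covariates]
        try:
            cox_uni = cox_regression(clinical, roster, scores=scores, mode="univariate")
            cox_multi = cox_regression(clinical, roster, scores=scores, mode="multivariate")
        except ValueError:
            pass

    bundle = ValidationBundle(
        scores=scores,
        groups=groups,
        km=km,
        cox_univariate=cox_uni,
        cox_multivariate=cox_multi,
        manifest=cfg.manifest(),
    )
    if cfg.output_dir:
        _write_validation(bundle, Path(cfg.output_dir))
    return bundle


# ---------------------------------------------------------------------------
# artifact writing


def _cox_frame(results: list) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "variable": r.variable,
                "hr": r.hr,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "p_value": r.p_value,
                "model": r.model,
            }
            for r in results
        ]
    )


def _write_scores(scores: RiskScores, groups: pd.Series, path: Path) -> None:
    df = pd.DataFrame(
        {
            "sample_id": scores.sample_ids,
            "risk_score": scores.score,
            "risk_group": groups.loc[scores.sample_ids].to_numpy(),
            "n_missing_pairs": scores.n_missing_pairs,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _write_discovery(b: DiscoveryBundle, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_signature(b.signature, outdir / "signature.tsv")
    _write_scores(b.scores, b.groups, outdir / "scores.tsv")
    if b.roc is not None:
        b.roc.points.to_csv(outdir / "roc_points.tsv", sep="\t", index=False, float_format="%.6g")
    stats = {
        "cutoff": b.cutoff,
        "roc_auc": b.roc.auc if b.roc is not None else None,
        "logrank_p": b.km.p_value if b.km else None,
        "hr": b.km.hr if b.km else None,
        "hr_ci": [b.km.ci_low, b.km.ci_high] if b.km else None,
        "funnel": b.funnel,
    }
    (outdir / "stats.json").write_text(json.dumps(stats, indent=2))
    cox = pd.concat([_cox_frame(b.cox_univariate), _cox_frame(b.cox_multivariate)])
    cox.to_csv(outdir / "cox_table.tsv", sep="\t", index=False, float_format="%.6g")
    (outdir / "manifest.yaml").write_text(yaml.safe_dump(b.manifest, sort_keys=False))


def _write_validation(b: ValidationBundle, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    _write_scores(b.scores, b.groups, outdir / "validation_scores.tsv")
    stats = {
        "logrank_p": b.km.p_value if b.km else None,
        "hr": b.km.hr if b.km else None,
        "hr_ci": [b.km.ci_low, b.km.ci_high] if b.km else None,
        "warnings": b.scores.warnings,
    }
    (outdir / "validation_stats.json").write_text(json.dumps(stats, indent=2))
    cox = pd.concat([_cox_frame(b.cox_univariate), _cox_frame(b.cox_multivariate)])
    cox.to_csv(outdir / "validation_cox_table.tsv", sep="\t", index=False, float_format="%.6g")
    (outdir / "validation_manifest.yaml").write_text(yaml.safe_dump(b.manifest, sort_keys=False))
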