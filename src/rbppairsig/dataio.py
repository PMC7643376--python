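"""I/O and domain containers: expression matrices, clinical tables, mutation
records and pair signatures.

Expression matrices are genes x samples pandas DataFrames of non-negative
values (FPKM-like units).  Clinical tables carry overall-survival time in
days, an event indicator and the numeric covariate encodings used
throughout (gender male=1 / female=2, pathologic stage I-IV mapped to
1-4).  Signatures are serialized as a diffable TSV of
(gene_a, gene_b, coefficient) plus a YAML metadata sidecar holding the
risk-score cutoff.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ParseError",
    "ExpressionMatrix",
    "ClinicalTable",
    "MutationRecords",
    "PairSignature",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_clinical_table",
    "collapse_duplicates",
    "load_packaged_signature",
    "read_signature",
    "write_signature",
    "read_maf",
    "match_patient_ids",
]

#: default TCGA-style barcode prefix length mapping samples to patients
TCGA_PATIENT_PREFIX = 12

CLINICAL_COLUMNS = (
    "os_time",
    "os_event",
    "age",
    "gender",
    "stage",
    "t_stage",
    "n_stage",
    "m_stage",
    "smoking",
)

MAF_REQUIRED_COLUMNS = (
    "Hugo_Symbol",
    "Variant_Classification",
    "Tumor_Sample_Barcode",
    "Chromosome",
    "Start_Position",
)

#: non-silent coding variant classes counted for mutation burden by default
NONSILENT_CLASSES = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Nonstop_Mutation",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Splice_Site",
        "Translation_Start_Site",
    }
)


class ParseError(ValueError):
    """Raised when an input file violates the format contract."""


@dataclass
class ExpressionMatrix:
    """Gene-by-sample non-negative expression values with group labels.

    Parameters
    ----------
    values
        DataFrame indexed by gene symbol with sample identifiers as
        columns; entries are finite and >= 0 (e.g. FPKM).
    group
        Per-sample label, ``"tumor"`` or ``"normal"``, indexed like the
        columns of ``values``.
    """

    values: pd.DataFrame
    group: pd.Series

    def __post_init__(self) -> None:
        self.group = self.group.reindex(self.values.columns)
        if self.group.isna().any():
            missing = self.group.index[self.group.isna()][0]
            raise ValueError(f"sample {missing!r} has no tumor/normal group label")
        bad = set(self.group.unique()) - {"tumor", "normal"}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            raise ValueError("expression values must be finite")
        if (arr < 0).any():
            raise ValueError("expression values must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, samples: list[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[samples], self.group.loc[samples])

    def tumor_samples(self) -> list[str]:
        return list(self.group.index[self.group == "tumor"])

    def normal_samples(self) -> list[str]:
        return list(self.group.index[self.group == "normal"])


@dataclass
class ClinicalTable:
    """Per-patient survival and covariates.

    ``data`` is indexed by patient id with columns ``os_time`` (days),
    ``os_event`` (1 = death, 0 = censored), ``age`` (years), ``gender``
    (male=1, female=2), ``stage``/``t_stage``/``n_stage``/``m_stage``
    (small integers, NaN when missing) and ``smoking`` (0/1 or NaN).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        for col in CLINICAL_COLUMNS:
            if col not in self.data.columns:
                self.data[col] = np.nan
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate patient id {dup!r}")
        ok = self.data["os_event"].dropna().isin([0, 1])
        if not ok.all():
            raise ValueError("os_event must be 0 or 1")
        stage = self.data["stage"].dropna()
        if not stage.isin([1, 2, 3, 4]).all():
            raise ValueError("stage must be in {1,2,3,4} when present")

    @property
    def patient_ids(self) -> list[str]:
        return list(self.data.index)

    def __len__(self) -> int:
        return len(self.data)

    def subset(self, patients: list[str]) -> "ClinicalTable":
        return ClinicalTable(self.data.loc[patients].copy())


@dataclass
class MutationRecords:
    """Somatic mutation calls, one row per called mutation."""

    data: pd.DataFrame  # columns: sample_id, gene_symbol, variant_classification, chrom, pos

    def __post_init__(self) -> None:
        required = ["sample_id", "gene_symbol", "variant_classification", "chrom", "pos"]
        for col in required:
            if col not in self.data.columns:
                raise ValueError(f"mutation records missing column {col!r}")
        if (self.data["sample_id"].astype(str).str.len() == 0).any():
            raise ValueError("empty sample_id in mutation records")
        if len(self.data) and (self.data["pos"] <= 0).any():
            raise ValueError("mutation position must be a positive integer")

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class PairSignature:
    """An ordered list of (gene_a, gene_b, coefficient) with a risk cutoff.

    The stored orientation is meaningful: a pair contributes its
    coefficient to a sample's risk score iff expr(gene_a) > expr(gene_b)
    strictly in that sample.
    """

    pairs: list[tuple[str, str, float]]
    cutoff: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen = set()
        for a, b, beta in self.pairs:
            if a == b:
                raise ValueError(f"degenerate pair ({a}, {b})")
            if (a, b) in seen:
                raise ValueError(f"duplicate pair ({a}, {b})")
            seen.add((a, b))
            if not np.isfinite(beta) or beta == 0:
                raise ValueError(f"coefficient for ({a}, {b}) must be finite and nonzero")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def genes(self) -> list[str]:
        """Distinct gene symbols across all pairs, in order of first use."""
        out: list[str] = []
        for a, b, _ in self.pairs:
            for g in (a, b):
                if g not in out:
                    out.append(g)
        return out

    def coefficient_sum(self) -> float:
        return float(sum(beta for _, _, beta in self.pairs))


# ---------------------------------------------------------------------------
# expression I/O


def _read_delimited(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    if df.columns.size == 0:
        raise ParseError(f"{path}: no data columns found")
    return df


def read_expression_matrix(
    path: str | Path,
    orientation: str = "genes_in_rows",
    group: pd.Series | dict | None = None,
) -> ExpressionMatrix:
    """Read a delimited expression matrix (TSV by default, CSV by suffix).

    Parameters
    ----------
    path
        Delimited text file with one header row and one identifier column.
    orientation
        ``"genes_in_rows"`` (default) or ``"samples_in_rows"``.
    group
        Optional per-sample tumor/normal labels.  When omitted every
        sample is labelled ``"tumor"``.

    Duplicate gene or sample identifiers are preserved here and resolved
    by :func:`collapse_duplicates`.
    """
    if orientation not in ("genes_in_rows", "samples_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = _read_delimited(path)
    if orientation == "samples_in_rows":
        df = df.T
    for j, col in enumerate(df.columns):
        series = pd.to_numeric(df[col], errors="coerce")
        bad = series.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ParseError(f"{path}: non-numeric value at row {row!r}, column {col!r}")
        if series.isna().any():
            row = df.index[series.isna().to_numpy().nonzero()[0][0]]
            raise ParseError(f"{path}: missing value at row {row!r}, column {col!r}")
        if (series < 0).any():
            row = df.index[(series < 0).to_numpy().nonzero()[0][0]]
            raise ParseError(f"{path}: negative value at row {row!r}, column {col!r}")
        df[col] = series
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if group is None:
        grp = pd.Series("tumor", index=df.columns)
    else:
        grp = pd.Series(group).reindex(df.columns)
    return ExpressionMatrix(df.astype(float), grp)


def write_expression_matrix(m: ExpressionMatrix, path: str | Path) -> None:
    """Write genes-in-rows delimited text; sep follows the file suffix."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    # %.6g keeps round-trips exact for values printed to 6 significant digits
    m.values.to_csv(path, sep=sep, float_format="%.6g", index_label="gene")


def read_clinical_table(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    id_column: str | None = None,
) -> ClinicalTable:
    """Read a delimited clinical table.

    ``column_map`` maps file column names to the canonical names
    (``os_time``, ``os_event``, ``age``, ``gender``, ``stage``,
    ``t_stage``, ``n_stage``, ``m_stage``, ``smoking``); canonical names
    already present pass through.  The first column is the patient id
    unless ``id_column`` names another.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    if df.columns.size < 2:
        raise ParseError(f"{path}: clinical table needs an id column and data columns")
    if column_map:
        df = df.rename(columns=column_map)
    idc = id_column or df.columns[0]
    if idc not in df.columns:
        raise ParseError(f"{path}: id column {idc!r} not found")
    df = df.set_index(idc)
    df.index = df.index.astype(str)
    keep = [c for c in CLINICAL_COLUMNS if c in df.columns]
    df = df[keep].apply(pd.to_numeric, errors="coerce")
    return ClinicalTable(df)


def write_clinical_table(c: ClinicalTable, path: str | Path) -> None:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    c.data.to_csv(path, sep=sep, index_label="patient_id")


# ---------------------------------------------------------------------------
# duplicate collapsing


def collapse_duplicates(
    m: ExpressionMatrix,
    probe_to_gene: dict[str, str] | None = None,
    sample_to_patient: dict[str, str] | None = None,
) -> ExpressionMatrix:
    """Average multiple probes per gene and multiple samples per patient.

    Each gene's expression is the arithmetic mean over its probes, and
    each patient's the arithmetic mean over their samples; output rows
    and columns are sorted lexicographically so the operation is
    deterministic and idempotent.  A patient's group label is taken from
    its samples, which must agree.
    """
    values = m.values
    if probe_to_gene is not None:
        unknown = set(probe_to_gene) - set(values.index)
        if unknown:
            raise ValueError(f"probe mapping references unknown probes: {sorted(unknown)[:5]}")
        gene_index = values.index.to_series().replace(probe_to_gene)
    else:
        gene_index = values.index.to_series()
    collapsed = values.groupby(gene_index.to_numpy()).mean()

    if sample_to_patient is not None:
        unknown = set(sample_to_patient) - set(values.columns)
        if unknown:
            raise ValueError(f"sample mapping references unknown samples: {sorted(unknown)[:5]}")
        patient_of = pd.Series(
            [sample_to_patient.get(s, s) for s in collapsed.columns], index=collapsed.columns
        )
    else:
        patient_of = pd.Series(list(collapsed.columns), index=collapsed.columns)

    grouped = collapsed.T.groupby(patient_of.to_numpy()).mean().T
    group_by_patient = {}
    for sample, patient in patient_of.items():
        label = m.group.loc[sample]
        prev = group_by_patient.setdefault(patient, label)
        if prev != label:
            raise ValueError(f"patient {patient!r} has conflicting tumor/normal labels")
    grouped = grouped.sort_index(axis=0).sort_index(axis=1)
    grp = pd.Series({p: group_by_patient[p] for p in grouped.columns})
    return ExpressionMatrix(grouped, grp)


def match_patient_ids(
    sample_ids: list[str], prefix_len: int | None = TCGA_PATIENT_PREFIX
) -> dict[str, str]:
    """Map sample barcodes to patient ids by prefix truncation.

    TCGA-style barcodes identify the patient in their first 12
    characters; shorter ids map to themselves.  ``prefix_len=None``
    disables truncation (exact match).
    """
    if prefix_len is None:
        return {s: s for s in sample_ids}
    return {s: s[:prefix_len] for s in sample_ids}


# ---------------------------------------------------------------------------
# signatures


def load_packaged_signature() -> PairSignature:
    """Load the shipped 33-pair lung-adenocarcinoma RBP signature.

    The signature holds 33 ordered gene pairs over 49 distinct RNA-binding
    protein genes with their fitted L1-Cox coefficients and the published
    risk-score cutoff of -0.075 (chosen by 3-year time-dependent ROC).
    """
    res = importlib.resources.files("rbppairsig") / "data"
    with importlib.resources.as_file(res / "luad_rbp33_signature.tsv") as p:
        sig = read_signature(p)
    return sig


def read_signature(path: str | Path) -> PairSignature:
    """Read a signature TSV; a ``.yaml`` sidecar supplies cutoff/metadata."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    for col in ("gene_a", "gene_b", "coefficient"):
        if col not in df.columns:
            raise ParseError(f"{path}: signature file missing column {col!r}")
    pairs = [
        (str(r.gene_a), str(r.gene_b), float(r.coefficient)) for r in df.itertuples(index=False)
    ]
    cutoff = None
    metadata: dict = {}
    sidecar = path.with_suffix(".yaml")
    if sidecar.exists():
        with open(sidecar) as fh:
            metadata = yaml.safe_load(fh) or {}
        if "cutoff" in metadata:
            cutoff = float(metadata["cutoff"])
    return PairSignature(pairs, cutoff=cutoff, metadata=metadata)


def write_signature(sig: PairSignature, path: str | Path) -> None:
    """Write the pair TSV and a YAML sidecar with cutoff and metadata."""
    path = Path(path)
    df = pd.DataFrame(sig.pairs, columns=["gene_a", "gene_b", "coefficient"])
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    meta = dict(sig.metadata)
    if sig.cutoff is not None:
        meta["cutoff"] = float(sig.cutoff)
    with open(path.with_suffix(".yaml"), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# mutations


def read_maf(path: str | Path) -> MutationRecords:
    """Read a tab-delimited MAF; ``#``-prefixed comment lines are skipped."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in MAF_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: MAF missing required column(s) {missing}")
    out = pd.DataFrame(
        {
            "sample_id": df["Tumor_Sample_Barcode"],
            "gene_symbol": df["Hugo_Symbol"],
            "variant_classification": df["Variant_Classification"],
            "chrom": df["Chromosome"],
            "pos": pd.to_numeric(df["Start_Position"], errors="raise").astype(int),
        }
    )
    return MutationRecords(out)
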