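"""Core containers and I/O: expression matrices, mutation tables, clinical data.

Everything downstream operates on per-gene z-scores, so the central transform
here is :func:`zscore`: ``(x - mean_gene) / sd_gene`` with the *whole analyzed
cohort* as the reference population and population sd (``ddof=0``). Genes with
zero variance cannot be directionally called and are mapped to an all-zero row,
recorded in ``ZExpressionMatrix.degenerate_genes``.

File formats are deliberately minimal tab-delimited text:

* expression — genes in rows, first column ``Hugo_Symbol`` (an optional second
  ``Entrez_Gene_Id`` column is skipped), header row of sample ids;
* mutations — a MAF column subset (``Tumor_Sample_Barcode``, ``Hugo_Symbol``,
  ``Variant_Classification``);
* clinical — one row per sample with survival endpoints and covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "ZExpressionMatrix",
    "MutationTable",
    "NONSYNONYMOUS_CLASSES",
    "KNOWN_VARIANT_CLASSES",
    "load_expression",
    "write_expression",
    "zscore",
    "load_mutations",
    "write_mutations",
    "load_clinical",
    "write_clinical",
]

#: cBioPortal-style non-synonymous variant classes (the default retention set).
NONSYNONYMOUS_CLASSES: frozenset[str] = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Splice_Site",
        "Translation_Start_Site",
        "Nonstop_Mutation",
    }
)

#: classes we recognise but (by default) discard silently, e.g. synonymous.
_SYNONYMOUS_OR_NONCODING: frozenset[str] = frozenset(
    {
        "Silent",
        "Intron",
        "3'UTR",
        "5'UTR",
        "3'Flank",
        "5'Flank",
        "IGR",
        "RNA",
        "Splice_Region",
        "Targeted_Region",
    }
)

KNOWN_VARIANT_CLASSES: frozenset[str] = NONSYNONYMOUS_CLASSES | _SYNONYMOUS_OR_NONCODING

_NA_STRINGS = {"", "NA", "NaN", "nan", "N/A", "null", "NULL"}


@dataclass
class ExpressionMatrix:
    """Gene-by-sample expression, arbitrary (already normalized) units.

    ``data`` is a DataFrame with unique gene symbols as the index and unique
    sample identifiers as columns; no missing values.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("duplicate gene symbols in expression matrix")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate sample identifiers in expression matrix")
        if self.data.isna().any().any():
            raise ValueError("expression matrix contains missing values")

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class ZExpressionMatrix(ExpressionMatrix):
    """Per-gene z-scored expression; see :func:`zscore`."""

    degenerate_genes: frozenset[str] = field(default_factory=frozenset)


@dataclass
class MutationTable:
    """Non-synonymous mutation records plus the set of profiled samples.

    ``records`` has columns ``sample_id``, ``gene``, ``variant_class``; one
    row per mutation call, so a gene may contribute several records for one
    patient. ``profiled_samples`` may exceed the samples carrying any record
    (samples sequenced but wild-type everywhere).
    """

    records: pd.DataFrame
    profiled_samples: frozenset[str]

    def __post_init__(self) -> None:
        required = {"sample_id", "gene", "variant_class"}
        missing = required - set(self.records.columns)
        if missing:
            raise ValueError(f"mutation records missing columns: {sorted(missing)}")
        unknown = set(self.records["sample_id"]) - set(self.profiled_samples)
        if unknown:
            raise ValueError(
                f"{len(unknown)} record sample ids not in profiled_samples, "
                f"e.g. {sorted(unknown)[:3]}"
            )

    def mutated_samples(self, gene: str) -> frozenset[str]:
        """Samples with at least one retained record for ``gene``."""
        sub = self.records.loc[self.records["gene"] == gene, "sample_id"]
        return frozenset(sub)

    @property
    def n_profiled(self) -> int:
        return len(self.profiled_samples)


# ---------------------------------------------------------------------------
# expression I/O


def load_expression(
    path: str | Path,
    *,
    impute: str | None = None,
    dedup: str = "highest_mean",
) -> ExpressionMatrix:
    """Read a tab-delimited gene × sample matrix (cBioPortal export dialect).

    Parameters
    ----------
    impute
        ``None`` (default): any missing cell is a hard error. ``"row_mean"``:
        missing cells are replaced by the mean of the remaining row entries.
    dedup
        Policy for duplicated gene rows; only ``"highest_mean"`` (keep the row
        with the highest mean, warn) is implemented.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if raw.shape[1] < 2:
        raise ValueError(f"{path}: expected at least a gene column and one sample")
    gene_col = raw.columns[0]
    genes = raw[gene_col]
    body = raw.drop(columns=[gene_col])
    if body.columns[0] == "Entrez_Gene_Id":
        body = body.drop(columns=["Entrez_Gene_Id"])

    values = body.apply(pd.to_numeric, errors="coerce")
    bad = values.isna()
    if bad.any().any():
        for i, j in zip(*np.nonzero(bad.to_numpy())):
            cell = body.iat[i, j]
            if cell.strip() not in _NA_STRINGS:
                raise ValueError(
                    f"{path}: unparseable numeric cell {cell!r} at gene "
                    f"{genes.iat[i]!r}, sample {body.columns[j]!r}"
                )
        if impute == "row_mean":
            row_means = values.mean(axis=1, skipna=True)
            values = values.apply(lambda col: col.fillna(row_means))
        else:
            i, j = next(zip(*np.nonzero(bad.to_numpy())))
            raise ValueError(
                f"{path}: missing value at gene {genes.iat[i]!r}, sample "
                f"{body.columns[j]!r}; pass impute='row_mean' to fill"
            )

    values.index = genes.to_numpy()
    if values.index.has_duplicates:
        if dedup != "highest_mean":
            raise ValueError(f"unknown dedup policy {dedup!r}")
        dup = sorted(set(values.index[values.index.duplicated()]))
        warnings.warn(
            f"{path}: duplicated gene rows {dup}; keeping highest-mean row each",
            stacklevel=2,
        )
        order = values.mean(axis=1).to_numpy()
        values = (
            values.assign(_mean=order)
            .sort_values("_mean", ascending=False)
            .groupby(level=0, sort=False)
            .head(1)
            .drop(columns="_mean")
        )
        # restore first-appearance order of the surviving genes
        seen: list[str] = []
        for g in genes:
            if g in values.index and g not in seen:
                seen.append(g)
        values = values.loc[seen]
    values.index.name = "Hugo_Symbol"
    return ExpressionMatrix(values.astype(float))


def write_expression(m: ExpressionMatrix, path: str | Path) -> None:
    """Write the cBioPortal-dialect matrix; bit-stable for fixed input."""
    out = m.data.copy()
    out.index.name = "Hugo_Symbol"
    out.to_csv(path, sep="\t")


def zscore(m: ExpressionMatrix, *, ddof: int = 0) -> ZExpressionMatrix:
    """Standardize each gene over the full cohort: ``(x - mean) / sd``.

    Population sd (``ddof=0``) by default; zero-variance genes map to an
    all-zero row and are listed in ``degenerate_genes``. A single-sample
    matrix is rejected — a one-point sd is meaningless for classification.
    """
    if m.n_samples < 2:
        raise ValueError("z-scoring requires at least 2 samples")
    values = m.data.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=ddof, keepdims=True)
    degenerate = sd[:, 0] == 0.0
    safe_sd = np.where(degenerate[:, None], 1.0, sd)
    z = (values - mean) / safe_sd
    z[degenerate, :] = 0.0
    zdf = pd.DataFrame(z, index=m.data.index, columns=m.data.columns)
    return ZExpressionMatrix(
        zdf, degenerate_genes=frozenset(np.asarray(m.genes)[degenerate])
    )


# ---------------------------------------------------------------------------
# mutation I/O


def load_mutations(
    path: str | Path,
    nonsyn_classes: frozenset[str] = NONSYNONYMOUS_CLASSES,
    *,
    sample_list: list[str] | None = None,
) -> MutationTable:
    """Read a MAF-subset file, retaining only non-synonymous records.

    ``profiled_samples`` comes from ``sample_list`` when given (a sidecar of
    all sequenced samples), otherwise from the union of ids in the file
    (before class filtering). Records with a variant class outside the known
    vocabulary are dropped with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["Tumor_Sample_Barcode", "Hugo_Symbol", "Variant_Classification"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required MAF columns {missing}")
    records = df[required].rename(
        columns={
            "Tumor_Sample_Barcode": "sample_id",
            "Hugo_Symbol": "gene",
            "Variant_Classification": "variant_class",
        }
    )
    unknown = set(records["variant_class"]) - KNOWN_VARIANT_CLASSES - nonsyn_classes
    if unknown:
        warnings.warn(
            f"{path}: dropping records with unknown variant classes "
            f"{sorted(unknown)}",
            stacklevel=2,
        )
    kept = records[records["variant_class"].isin(nonsyn_classes)].reset_index(
        drop=True
    )
    if sample_list is not None:
        profiled = frozenset(sample_list) | frozenset(records["sample_id"])
    else:
        profiled = frozenset(records["sample_id"])
    return MutationTable(kept, profiled_samples=profiled)


def write_mutations(mut: MutationTable, path: str | Path) -> None:
    out = mut.records.rename(
        columns={
            "sample_id": "Tumor_Sample_Barcode",
            "gene": "Hugo_Symbol",
            "variant_class": "Variant_Classification",
        }
    )[["Tumor_Sample_Barcode", "Hugo_Symbol", "Variant_Classification"]]
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# clinical I/O

_CLINICAL_COLUMNS = [
    "hpv_status",
    "anatomical_site",
    "stage",
    "os_time",
    "os_event",
    "dfs_time",
    "dfs_event",
]


def load_clinical(path: str | Path) -> pd.DataFrame:
    """Read the per-sample clinical table, indexed by ``sample_id``.

    HPV status is normalized to ``positive`` / ``negative`` / ``unknown``; a
    missing HPV column yields all-unknown with a warning. Negative times and
    non-binary events are hard errors.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: missing 'sample_id' column")
    if df["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids")
    df = df.set_index("sample_id")
    if "hpv_status" not in df.columns:
        warnings.warn(f"{path}: no hpv_status column; coding all samples unknown",
                      stacklevel=2)
        df["hpv_status"] = "unknown"
    df["hpv_status"] = (
        df["hpv_status"].fillna("unknown").astype(str).str.lower()
    )
    valid_hpv = {"positive", "negative", "unknown"}
    bad_hpv = set(df["hpv_status"]) - valid_hpv
    if bad_hpv:
        raise ValueError(f"{path}: unrecognized hpv_status values {sorted(bad_hpv)}")
    for col in ("os_time", "dfs_time"):
        if col in df.columns:
            t = pd.to_numeric(df[col], errors="raise")
            if (t.dropna() < 0).any():
                raise ValueError(f"{path}: negative {col}")
            df[col] = t
    for col in ("os_event", "dfs_event"):
        if col in df.columns:
            e = pd.to_numeric(df[col], errors="raise")
            if not e.dropna().isin([0, 1]).all():
                raise ValueError(f"{path}: {col} must be 0/1")
            df[col] = e
    return df


def write_clinical(clinical: pd.DataFrame, path: str | Path) -> None:
    out = clinical.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")
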