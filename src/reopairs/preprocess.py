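"""Loading, validation and normalization of tabular inputs.

Expression matrices are plain pandas DataFrames (genes in rows, samples in
columns) wrapped by light validation; probe-level data are collapsed to gene
level by averaging; Illumina-style methylation intensities are converted to
beta values with the standard +100 offset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MethylationData",
    "collapse_probes",
    "compute_beta",
    "filter_sites",
    "load_expression",
    "load_labels",
    "load_probe_map",
    "save_expression",
    "validate_expression",
]


class DataValidationError(ValueError):
    """Raised when an input table violates a structural contract."""


def validate_expression(expr: pd.DataFrame) -> pd.DataFrame:
    """Check an expression DataFrame (genes x samples) and return it.

    Requires unique gene and sample identifiers and fully finite numeric
    values; missing values are rejected (impute explicitly beforehand).
    """
    if expr.index.has_duplicates:
        dups = expr.index[expr.index.duplicated()].unique().tolist()
        raise DataValidationError(f"duplicate gene IDs: {dups}")
    if expr.columns.has_duplicates:
        dups = expr.columns[expr.columns.duplicated()].unique().tolist()
        raise DataValidationError(f"duplicate sample IDs: {dups}")
    values = expr.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = _first_non_numeric(expr)
        raise DataValidationError(f"non-numeric cell at {bad}")
    if not np.isfinite(values).all():
        r, c = np.argwhere(~np.isfinite(values))[0]
        raise DataValidationError(
            f"non-finite value at gene {expr.index[r]!r}, sample {expr.columns[c]!r}"
        )
    return expr


def _first_non_numeric(expr: pd.DataFrame) -> tuple[str, str]:
    for c in expr.columns:
        col = pd.to_numeric(expr[c], errors="coerce")
        if col.isna().any() and not expr[c].isna().all():
            r = col.index[col.isna()][0]
            return (str(r), str(c))
    return ("?", "?")


def load_expression(
    path, dialect: str = "tsv", impute: str | None = None
) -> pd.DataFrame:
    """Read a genes-x-samples expression table.

    Parameters
    ----------
    path
        TSV/CSV file (gzip transparent): header row of sample IDs, first
        column of gene IDs.
    dialect
        ``"tsv"`` or ``"csv"``.
    impute
        ``None`` (default) rejects missing values; ``"row-median"`` fills
        each gene's missing cells with that gene's median across samples.
    """
    sep = {"tsv": "\t", "csv": ","}.get(dialect)
    if sep is None:
        raise ValueError(f"unknown dialect {dialect!r}")
    raw = pd.read_csv(path, sep=sep, index_col=0)
    raw.index = raw.index.astype(str)
    raw.columns = raw.columns.astype(str)
    if raw.index.has_duplicates:
        dups = raw.index[raw.index.duplicated()].unique().tolist()
        raise DataValidationError(f"duplicate gene IDs: {dups}")
    if raw.columns.has_duplicates:
        dups = raw.columns[raw.columns.duplicated()].unique().tolist()
        raise DataValidationError(f"duplicate sample IDs: {dups}")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise DataValidationError(
            f"non-numeric cell at gene {raw.index[r]!r}, sample {raw.columns[c]!r}: "
            f"{raw.iat[r, c]!r}"
        )
    if numeric.isna().to_numpy().any():
        if impute is None:
            r, c = np.argwhere(numeric.isna().to_numpy())[0]
            raise DataValidationError(
                f"missing value at gene {raw.index[r]!r}, sample {raw.columns[c]!r}; "
                "pass impute='row-median' to fill"
            )
        if impute != "row-median":
            raise ValueError(f"unknown impute mode {impute!r}")
        numeric = numeric.apply(lambda row: row.fillna(row.median()), axis=1)
    return validate_expression(numeric.astype(float))


def save_expression(expr: pd.DataFrame, path, dialect: str = "tsv") -> None:
    """Write an expression table; full-precision round trip with load_expression."""
    sep = {"tsv": "\t", "csv": ","}[dialect]
    expr.to_csv(path, sep=sep, float_format="%.17g")


def load_probe_map(path) -> pd.DataFrame:
    """Read a two-column probe_id/gene_id TSV into a probe map.

    An empty gene_id marks an unmapped probe; a probe_id listed with more
    than one distinct gene is flagged multimapped. Returns a DataFrame
    indexed by probe_id with columns ``gene_id`` and ``multimapped``.
    """
    raw = pd.read_csv(
        path, sep="\t", header=0, dtype=str, keep_default_na=False
    )
    raw.columns = ["probe_id", "gene_id"]
    grouped = raw.groupby("probe_id")["gene_id"].agg(lambda g: sorted(set(g) - {""}))
    out = pd.DataFrame(index=grouped.index)
    out["multimapped"] = grouped.map(len) > 1
    out["gene_id"] = [
        genes[0] if len(genes) == 1 else "" for genes in grouped
    ]
    return out


def collapse_probes(probe_matrix: pd.DataFrame, probe_map: pd.DataFrame) -> pd.DataFrame:
    """Collapse a probe-level matrix to gene level.

    Probes mapping to one gene are averaged (arithmetic mean on the loaded
    scale) per sample; unmapped and multimapped probes are discarded.
    Output rows are sorted by gene ID so the result is invariant to probe
    row order.
    """
    missing = probe_matrix.index.difference(probe_map.index)
    if len(missing) > 0:
        raise DataValidationError(
            f"probes absent from map: {sorted(map(str, missing))[:10]}"
        )
    sub = probe_map.loc[probe_matrix.index]
    keep = (~sub["multimapped"]) & (sub["gene_id"] != "")
    kept = probe_matrix.loc[keep.to_numpy()]
    genes = sub.loc[keep.to_numpy(), "gene_id"]
    collapsed = kept.groupby(genes.to_numpy()).mean()
    collapsed = collapsed.sort_index()
    collapsed.index.name = probe_matrix.index.name
    return collapsed


@dataclass
class MethylationData:
    """Per-CpG-site methylated/unmethylated intensities with derived betas.

    beta = M / (U + M + 100), the standard Illumina estimate; the +100
    offset regularizes low-intensity sites, so beta < 1 always.
    """

    M: pd.DataFrame
    U: pd.DataFrame
    chromosome: pd.Series  # site_id -> chromosome label
    beta: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        if not self.M.index.equals(self.U.index) or not self.M.columns.equals(
            self.U.columns
        ):
            raise DataValidationError("M and U must share row/column sets")
        self.beta = compute_beta(self.M, self.U)

    @property
    def site_ids(self) -> pd.Index:
        return self.M.index


def compute_beta(M, U):
    """Elementwise beta value M/(U+M+100); intensities must be >= 0."""
    M_arr = np.asarray(M, dtype=float)
    U_arr = np.asarray(U, dtype=float)
    if M_arr.shape != U_arr.shape:
        raise DataValidationError("M and U must have the same shape")
    if (M_arr < 0).any() or (U_arr < 0).any():
        raise DataValidationError("negative intensity")
    beta = M_arr / (U_arr + M_arr + 100.0)
    if isinstance(M, pd.DataFrame):
        return pd.DataFrame(beta, index=M.index, columns=M.columns)
    return beta


def filter_sites(
    data: MethylationData,
    shared_sites,
    excluded_chroms=frozenset(),
) -> MethylationData:
    """Restrict to platform-shared CpG sites outside excluded chromosomes.

    Keeps exactly the sites in ``shared_sites`` whose chromosome is not in
    ``excluded_chroms`` (e.g. ``{"chrX", "chrY"}``), preserving input order.
    An empty result warns rather than erroring.
    """
    shared = set(shared_sites)
    excluded = set(excluded_chroms)
    keep = [
        s
        for s in data.site_ids
        if s in shared and data.chromosome.get(s) not in excluded
    ]
    if not keep:
        warnings.warn("site filter produced an empty MethylationData", stacklevel=2)
    return MethylationData(
        M=data.M.loc[keep],
        U=data.U.loc[keep],
        chromosome=data.chromosome.loc[keep] if keep else data.chromosome.iloc[:0],
    )


def save_labels(
    labels: pd.Series, path, positive: str = "CIMP+", negative: str = "CIMP-"
) -> None:
    """Write group codes as a two-column sample_id/label TSV."""
    out = pd.DataFrame(
        {
            "sample_id": labels.index,
            "label": np.where(labels.to_numpy() == 1, positive, negative),
        }
    )
    out.to_csv(path, sep="\t", index=False)


def load_labels(path, positive: str = "CIMP+") -> pd.Series:
    """Read a two-column sample_id/label TSV into group codes.

    Samples labeled ``positive`` get group 1 (positive class); all others
    group 2. Returns an int Series indexed by sample_id.
    """
    raw = pd.read_csv(path, sep="\t", header=0, dtype=str, keep_default_na=False)
    raw.columns = ["sample_id", "label"]
    if raw["sample_id"].duplicated().any():
        dups = raw.loc[raw["sample_id"].duplicated(), "sample_id"].tolist()
        raise DataValidationError(f"duplicate sample IDs in labels: {dups}")
    codes = np.where(raw["label"] == positive, 1, 2)
    return pd.Series(codes, index=raw["sample_id"].to_numpy(), name="group")
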