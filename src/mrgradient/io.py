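"""Reading, writing and harmonization of on-disk artifacts.

Expression matrices are tab-separated text with genes in rows (first column
gene symbols, header row sample identifiers).  Gene sets use the GMT dialect
(name, description, members).  Survival tables are TSV with columns
``sample``, ``time``, ``event``.

Gene identifiers are treated as opaque strings; no symbol-aliasing service is
consulted, which keeps the tool fully offline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._log import get_logger

log = get_logger("io")

__all__ = [
    "ExpressionMatrix",
    "GeneSetCollection",
    "SurvivalTable",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_gene_sets",
    "write_gene_sets",
    "read_survival",
    "write_survival",
    "harmonize_cohorts",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of log2-normalized expression.

    Parameters
    ----------
    values
        DataFrame indexed by gene symbol with one column per sample.
    cohort_labels
        Optional per-sample cohort tag (aligned with ``values.columns``).
    """

    values: pd.DataFrame
    cohort_labels: pd.Series | None = None

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            dup = v.index[v.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dup[:5]}")
        if v.columns.duplicated().any():
            dup = v.columns[v.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dup[:5]}")
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if not np.isfinite(arr).all():
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(
                f"non-finite expression value at gene {v.index[bad[0]]!r}, "
                f"sample {v.columns[bad[1]]!r}"
            )
        if self.cohort_labels is not None:
            self.cohort_labels = pd.Series(
                np.asarray(self.cohort_labels), index=v.columns
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class GeneSetCollection:
    """Named gene sets with free-text descriptions."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            deduped = list(dict.fromkeys(members))
            if not deduped:
                raise ValueError(f"gene set {name!r} is empty")
            self.sets[name] = deduped

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]


@dataclass
class SurvivalTable:
    """Right-censored survival outcomes, one row per sample."""

    data: pd.DataFrame  # columns: sample, time, event

    def __post_init__(self) -> None:
        d = self.data
        missing = {"sample", "time", "event"} - set(d.columns)
        if missing:
            raise ValueError(f"survival table missing columns: {sorted(missing)}")
        if d["sample"].duplicated().any():
            raise ValueError("duplicate sample ids in survival table")
        if (d["time"] < 0).any():
            bad = d.loc[d["time"] < 0, "sample"].iloc[0]
            raise ValueError(f"negative survival time for sample {bad!r}")
        if not d["event"].isin([0, 1]).all():
            bad = d.loc[~d["event"].isin([0, 1]), "sample"].iloc[0]
            raise ValueError(f"event indicator outside {{0,1}} for sample {bad!r}")
        self.data = d.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample"])

    def aligned(self, sample_ids: list[str]) -> pd.DataFrame:
        """Rows reindexed to ``sample_ids`` (error on missing samples)."""
        idx = self.data.set_index("sample")
        missing = [s for s in sample_ids if s not in idx.index]
        if missing:
            raise KeyError(f"samples absent from survival table: {missing[:5]}")
        return idx.loc[sample_ids].reset_index()


# ---------------------------------------------------------------------------
# readers / writers


def read_expression_matrix(path: str, transposed: bool = False) -> ExpressionMatrix:
    """Read a TSV expression matrix (genes in rows unless ``transposed``).

    Duplicate gene rows are collapsed by the per-gene maximum (the common
    microarray convention) and the collapse is logged.  A non-numeric cell or
    duplicate sample id is an error.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    col_ids = header[1:]
    if not transposed and len(col_ids) != len(set(col_ids)):
        # header holds sample ids; duplicates are an error (gene-row duplicates
        # are collapsed below instead)
        dup = sorted({c for c in col_ids if col_ids.count(c) > 1})
        raise ValueError(f"duplicate sample ids in header of {path}: {dup[:5]}")
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                      keep_default_na=False)
    raw.columns = col_ids
    try:
        # numpy string->double conversion is correctly rounded (unlike the
        # pandas parser), which the 17-significant-digit round-trip relies on
        num = raw.astype(float)
    except ValueError:
        coerced = raw.apply(pd.to_numeric, errors="coerce")
        i, j = np.argwhere(coerced.isna().to_numpy())[0]
        raise ValueError(
            f"non-numeric cell in {path} at row {raw.index[i]!r}, "
            f"column {raw.columns[j]!r}: {raw.iat[i, j]!r}"
        ) from None
    if transposed:
        num = num.T
    if num.index.duplicated().any():
        dup = num.index[num.index.duplicated()].unique().tolist()
        log.info("collapsing %d duplicate gene rows by maximum: %s",
                 len(dup), dup[:5])
        num = num.groupby(level=0, sort=False).max()
    num.index = num.index.astype(str)
    num.columns = num.columns.astype(str)
    return ExpressionMatrix(num)


def write_expression_matrix(expr: ExpressionMatrix, path: str) -> None:
    """Write at 17 significant digits so finite doubles round-trip exactly."""
    expr.values.to_csv(path, sep="\t", float_format="%.17g", index_label="gene")


def read_gene_sets(path: str) -> GeneSetCollection:
    """Parse a GMT file: ``name<TAB>description<TAB>member...`` per line."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields (need >= 3)"
                )
            name, desc, *members = fields
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            members = [m for m in members if m]
            sets[name] = members
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gene_sets(collection: GeneSetCollection, path: str) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_survival(path: str) -> SurvivalTable:
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lower() for c in df.columns]
    return SurvivalTable(df[["sample", "time", "event"]].assign(
        sample=lambda d: d["sample"].astype(str)
    ))


def write_survival(surv: SurvivalTable, path: str) -> None:
    surv.data.to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# cohort harmonization


def _quantile_normalize(values: pd.DataFrame, reference: np.ndarray) -> pd.DataFrame:
    """Map every column onto the sorted reference distribution (rank-wise)."""
    out = values.copy()
    for col in out.columns:
        order = np.argsort(out[col].to_numpy(), kind="mergesort")
        mapped = np.empty(len(order))
        mapped[order] = reference
        out[col] = mapped
    return out


def harmonize_cohorts(
    cohorts: list[ExpressionMatrix],
    method: str = "quantile",
    cohort_names: list[str] | None = None,
) -> ExpressionMatrix:
    """Merge cohorts into one matrix on the gene intersection.

    With ``method='quantile'`` every column is quantile-normalized onto the
    pooled reference distribution (the rank-wise mean over all columns of all
    cohorts) and genes are then median-centered across the merged matrix.
    ``'median-center'`` skips the quantile step; ``'none'`` only concatenates.

    A single cohort is passed through with gene median centering only, so the
    harmonized output is a fixed point of re-harmonization.

    Gene order of the output is lexicographic regardless of input order.
    """
    if method not in {"quantile", "median-center", "none"}:
        raise ValueError(f"unknown normalization method {method!r}")
    if not cohorts:
        raise ValueError("no cohorts given")
    if cohort_names is None:
        cohort_names = [f"cohort{i}" for i in range(len(cohorts))]

    common = set(cohorts[0].gene_ids)
    for c in cohorts[1:]:
        common &= set(c.gene_ids)
    if not common:
        raise ValueError("gene-id intersection across cohorts is empty")
    genes = sorted(common)

    blocks = [c.values.loc[genes] for c in cohorts]
    labels = np.concatenate([
        np.repeat(name, b.shape[1]) for name, b in zip(cohort_names, blocks)
    ])
    merged = pd.concat(blocks, axis=1)
    if merged.columns.duplicated().any():
        dup = merged.columns[merged.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids across cohorts: {dup[:5]}")

    if len(cohorts) > 1 and method == "quantile":
        reference = np.mean(
            np.sort(merged.to_numpy(), axis=0), axis=1
        )
        merged = _quantile_normalize(merged, reference)
    if method in {"quantile", "median-center"}:
        merged = merged.sub(merged.median(axis=1), axis=0)
    return ExpressionMatrix(merged, cohort_labels=pd.Series(labels, index=merged.columns))
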