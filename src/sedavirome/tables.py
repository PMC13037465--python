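"""LCA-style count tables: parsing, cumulative aggregation, normalisation.

Read classifiers that place each read at the lowest common ancestor of its
hits emit *assigned-only* counts: the count on a genus row excludes reads
assigned to its species.  Community analyses need *cumulative* counts,
where every node carries its own reads plus everything below it.  This
module moves between the two representations, converts cumulative counts
to relative abundances under an explicit denominator scope, and summarises
contamination in extraction/library blanks.

File dialects
-------------
* counts: TSV with columns ``taxid, name, rank, <sample1>, <sample2>, ...``
  (lines starting with ``#`` are ignored);
* sample metadata: CSV or TSV with columns
  ``sample_id, site, environment, age_cal_ka_bp`` where environment is one
  of ``lake``, ``marine``, ``blank``; blanks carry no age.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .taxonomy import TaxonomyTree

__all__ = [
    "ENVIRONMENTS",
    "DEFAULT_EPOCH_BOUNDARY",
    "TableError",
    "CountMatrix",
    "AbundanceMatrix",
    "BlankSummary",
    "read_lca_counts",
    "write_lca_counts",
    "read_sample_metadata",
    "assign_epoch",
    "aggregate_cumulative",
    "relative_abundance",
    "blank_summary",
    "round_sig",
]

ENVIRONMENTS = ("lake", "marine", "blank")

#: Default Holocene/Pleistocene split in cal ka BP.  Samples at or below the
#: boundary are Holocene.
DEFAULT_EPOCH_BOUNDARY = 11.7


class TableError(ValueError):
    """Malformed count/metadata tables or invalid aggregation inputs."""


@dataclass
class CountMatrix:
    """Taxon x sample read counts.

    ``data`` is indexed by integer taxid with one column per sample.
    ``mode`` distinguishes *assigned*-only counts (LCA output, a parent's
    count excludes its children) from *cumulative* counts (a parent's count
    includes every descendant).
    """

    data: pd.DataFrame
    mode: str = "assigned"

    def __post_init__(self) -> None:
        if self.mode not in ("assigned", "cumulative"):
            raise TableError(f"unknown count mode {self.mode!r}")

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    def copy(self) -> "CountMatrix":
        return CountMatrix(self.data.copy(), self.mode)


@dataclass
class AbundanceMatrix:
    """Relative abundances in [0, 1] under an explicit denominator scope.

    ``scope`` is the taxid whose cumulative count is the denominator.
    Samples with zero reads under the scope are flagged as missing (NaN),
    never coerced to zero, so downstream correlations can drop them
    explicitly.
    """

    data: pd.DataFrame
    scope: int

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)


# ---------------------------------------------------------------------------
# i/o


def read_lca_counts(path) -> tuple[CountMatrix, pd.DataFrame]:
    """Parse an LCA-style counts TSV.

    Returns the assigned-only :class:`CountMatrix` plus a taxon annotation
    frame (``taxid, name, rank``).  Duplicated taxid rows are summed with a
    warning (concatenated exports are common); negative or non-integer
    counts are a parse failure naming the offending data row.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"taxid": "int64"})
    required = ["taxid", "name", "rank"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableError(f"counts table missing columns {missing}")
    sample_cols = [c for c in df.columns if c not in required]
    if not sample_cols:
        raise TableError("counts table has no sample columns")

    values = df[sample_cols]
    for i, row in enumerate(values.itertuples(index=False), start=1):
        for c, v in zip(sample_cols, row):
            fv = float(v)
            if fv < 0 or not float(fv).is_integer():
                raise TableError(
                    f"invalid count {v!r} for sample {c!r} in data row {i}"
                )

    if df["taxid"].duplicated().any():
        dups = sorted(df.loc[df["taxid"].duplicated(), "taxid"].unique())
        warnings.warn(
            f"duplicated taxon rows summed for taxids {dups}", stacklevel=2
        )
    counts = (
        df[["taxid", *sample_cols]]
        .groupby("taxid", sort=True)
        .sum()
        .astype("int64")
    )
    annotations = (
        df[["taxid", "name", "rank"]]
        .drop_duplicates("taxid", keep="first")
        .set_index("taxid")
        .sort_index()
    )
    return CountMatrix(counts, "assigned"), annotations


def write_lca_counts(
    counts: CountMatrix,
    annotations: pd.DataFrame,
    path,
    header_comment: str | None = None,
) -> None:
    """Write a counts matrix back to the LCA TSV dialect."""
    ann = annotations.reindex(counts.data.index)
    out = pd.concat(
        [ann[["name", "rank"]], counts.data], axis=1
    ).reset_index(names="taxid")
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        out.to_csv(fh, sep="\t", index=False)


def assign_epoch(age, boundary: float = DEFAULT_EPOCH_BOUNDARY):
    """Holocene iff ``age <= boundary`` (cal ka BP); NaN ages map to None."""
    if age is None or (isinstance(age, float) and math.isnan(age)):
        return None
    return "Holocene" if age <= boundary else "Pleistocene"


def read_sample_metadata(
    path, epoch_boundary: float = DEFAULT_EPOCH_BOUNDARY
) -> pd.DataFrame:
    """Parse sample metadata and derive the geological epoch label.

    Blanks must have no age; non-blank samples must have a non-negative
    age in cal ka BP.
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, comment="#")
    required = ["sample_id", "site", "environment", "age_cal_ka_bp"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableError(f"metadata missing columns {missing}")
    bad_env = set(df["environment"]) - set(ENVIRONMENTS)
    if bad_env:
        raise TableError(f"unknown environment labels {sorted(bad_env)}")
    blanks = df["environment"] == "blank"
    if df.loc[blanks, "age_cal_ka_bp"].notna().any():
        raise TableError("blank samples must not carry an age")
    ages = df.loc[~blanks, "age_cal_ka_bp"]
    if ages.isna().any():
        raise TableError("non-blank samples must carry an age")
    if (ages < 0).any():
        raise TableError("ages must be non-negative cal ka BP")
    df = df.copy()
    df["epoch"] = [
        assign_epoch(a, epoch_boundary) for a in df["age_cal_ka_bp"]
    ]
    return df


# ---------------------------------------------------------------------------
# aggregation and normalisation


def aggregate_cumulative(
    counts: CountMatrix, tree: TaxonomyTree
) -> CountMatrix:
    """Cumulatively aggregate assigned-only counts up the taxonomy.

    Every ancestor of an observed taxon gains a row; for each sample,
    ``cum(t) = assigned(t) + sum(cum(child))``.  The input matrix is left
    untouched.
    """
    if counts.mode != "assigned":
        raise TableError("aggregate_cumulative expects assigned-only counts")
    data = counts.data
    for t in data.index:
        if t not in tree:
            nz = data.loc[t]
            sample = nz[nz > 0].index[0] if (nz > 0).any() else "<none>"
            raise TableError(
                f"taxon {t} (first non-zero sample {sample!r}) absent from taxonomy"
            )
    nodeset: set[int] = set()
    for t in data.index:
        nodeset.update(tree.lineage(int(t)))
    order = tree.postorder(nodeset)

    ncol = data.shape[1]
    zeros = np.zeros(ncol, dtype=np.int64)
    assigned = {int(t): data.loc[t].to_numpy() for t in data.index}
    cum: dict[int, np.ndarray] = {}
    for node in order:
        acc = assigned.get(node, zeros).copy()
        for c in tree.children(node):
            if c in cum:
                acc += cum[c]
        cum[node] = acc
    rows = sorted(cum)
    out = pd.DataFrame(
        np.vstack([cum[t] for t in rows]),
        index=pd.Index(rows, name=data.index.name),
        columns=data.columns,
    )
    return CountMatrix(out, "cumulative")


def relative_abundance(
    counts: CountMatrix, tree: TaxonomyTree, scope="root"
) -> AbundanceMatrix:
    """Total-sum-scale cumulative counts against a denominator scope.

    ``scope`` is a taxid, or ``"root"`` for all mapped reads.  Rows are
    restricted to the scope's subtree.  Samples with zero scope reads are
    flagged NaN rather than zero.  Reads assigned above any observed child
    (e.g. unclassified within the scope's realm) stay countable at the
    scope root, so the root's own abundance is exactly 1 whenever it has
    reads.
    """
    if counts.mode != "cumulative":
        raise TableError("relative_abundance expects cumulative counts")
    scope_t = tree.root if scope in ("root", "all", None) else int(scope)
    if scope_t not in tree:
        raise TableError(f"scope taxon {scope_t} absent from taxonomy")
    if scope_t not in counts.data.index:
        raise TableError(f"scope taxon {scope_t} has no row in the counts")
    sub = set(tree.descendants(scope_t))
    rows = [t for t in counts.data.index if int(t) in sub]
    denom = counts.data.loc[scope_t].to_numpy().astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ab = counts.data.loc[rows].to_numpy(dtype=float) / denom
    ab[:, denom == 0] = np.nan
    out = pd.DataFrame(ab, index=counts.data.loc[rows].index, columns=counts.data.columns)
    return AbundanceMatrix(out, scope_t)


# ---------------------------------------------------------------------------
# blanks


@dataclass
class BlankSummary:
    """Contamination accounting for one taxonomic group (e.g. viruses)."""

    n_blanks: int
    clean_blanks: int
    blank_reads: int
    total_reads: int
    group_root: int
    #: 100 * blank reads / (reads over samples and blanks)
    fraction_pct: float = field(init=False)

    def __post_init__(self) -> None:
        self.fraction_pct = (
            100.0 * self.blank_reads / self.total_reads
            if self.total_reads
            else 0.0
        )

    def fraction_pct_rounded(self, sig: int = 2) -> float:
        return round_sig(self.fraction_pct, sig)


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (0 stays 0)."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def blank_summary(
    counts: CountMatrix, meta: pd.DataFrame, group_root: int
) -> BlankSummary:
    """Summarise group reads carried by blanks.

    Uses the cumulative count of ``group_root`` per sample.  The fraction
    denominator is the group total over samples *and* blanks.
    """
    if counts.mode != "cumulative":
        raise TableError("blank_summary expects cumulative counts")
    blanks = meta.loc[meta["environment"] == "blank", "sample_id"].tolist()
    if not blanks:
        raise TableError("no blank samples in metadata")
    if group_root not in counts.data.index:
        raise TableError(f"group root {group_root} has no row in the counts")
    row = counts.data.loc[group_root]
    known = [s for s in meta["sample_id"] if s in row.index]
    blank_reads = int(row[[s for s in blanks if s in row.index]].sum())
    total = int(row[known].sum())
    clean = int(sum(row.get(s, 0) == 0 for s in blanks))
    return BlankSummary(
        n_blanks=len(blanks),
        clean_blanks=clean,
        blank_reads=blank_reads,
        total_reads=total,
        group_root=int(group_root),
    )
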