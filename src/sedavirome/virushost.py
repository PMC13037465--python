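"""Virus-host pairing, co-occurrence correlation, and significance testing.

Viruses are linked to hosts through a curated pairing table, a VMR-style
(ICTV Virus Metadata Resource) name->host-genus table, or, as a last
resort, the trivial-name convention in which a phage's name carries its
host genus immediately before the token "phage".  Host abundances are
aggregated at a domain-dependent rank -- genus for bacteria, phylum for
eukaryotes, superkingdom for archaea -- reflecting the broader host
ranges of eukaryotic viruses.  Per host group and site, the summed
relative abundance of the group's viruses is correlated with the host
group's cumulative relative abundance (Spearman), and the collection of
coefficients is tested for a positive (or negative) median shift with a
one-sided Wilcoxon signed-rank test, exact for up to 25 coefficients.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .tables import AbundanceMatrix
from .taxonomy import TaxonomyTree

__all__ = [
    "VirusHostError",
    "HOST_AGGREGATION_RANK",
    "SpearmanResult",
    "ShiftTest",
    "build_host_groups",
    "group_abundance_series",
    "spearman",
    "positive_shift_test",
    "exclusion_sensitivity",
    "infer_host_from_name",
    "phage_class_groups",
    "read_pair_table",
]

logger = logging.getLogger(__name__)


class VirusHostError(ValueError):
    """Degenerate correlation inputs or malformed pairing tables."""


#: Host aggregation rank by host domain.
HOST_AGGREGATION_RANK = {
    "bacteria": "genus",
    "eukaryota": "phylum",
    "archaea": "superkingdom",
}

PAIR_COLUMNS = [
    "virus_taxid",
    "virus_name",
    "host_taxid",
    "host_name",
    "host_domain",
    "evidence",
]


def read_pair_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in PAIR_COLUMNS if c not in df.columns]
    if missing:
        raise VirusHostError(f"pair table missing columns {missing}")
    bad = set(df["host_domain"]) - set(HOST_AGGREGATION_RANK)
    if bad:
        raise VirusHostError(f"unknown host domains {sorted(bad)}")
    return df


# ---------------------------------------------------------------------------
# grouping


def build_host_groups(
    pairs: pd.DataFrame, tree: TaxonomyTree
) -> dict[int, set[int]]:
    """Map host group (ancestor at the domain's aggregation rank) to virus set.

    A virus paired to several hosts contributes to each of their groups
    (inclusion semantics).  Pairs whose host lacks an ancestor at the
    required rank are dropped with a warning.
    """
    groups: dict[int, set[int]] = {}
    for row in pairs.itertuples(index=False):
        rank = HOST_AGGREGATION_RANK[row.host_domain]
        anc = tree.ancestor_at_rank(int(row.host_taxid), rank)
        if anc is None:
            warnings.warn(
                f"host {row.host_taxid} has no {rank}-rank ancestor; pair to "
                f"virus {row.virus_taxid} dropped",
                stacklevel=2,
            )
            continue
        groups.setdefault(anc, set()).add(int(row.virus_taxid))
    return groups


@dataclass
class GroupSeries:
    """Aligned virus-sum and host-group abundance series over one site."""

    site: str
    group: int
    frame: pd.DataFrame  # index sample_id; columns age, epoch, virus, host
    empty: bool = False

    def subset(self, epoch: str) -> pd.DataFrame:
        if epoch in (None, "all"):
            return self.frame
        return self.frame[self.frame["epoch"] == epoch]


def group_abundance_series(
    abund: AbundanceMatrix,
    meta: pd.DataFrame,
    site: str,
    group: int,
    virus_taxa,
    exclude_taxa=frozenset(),
) -> GroupSeries:
    """Paired (virus-sum, host-group) series over a site's samples by age.

    Abundances must be on the all-mapped-reads scope.  The host series is
    the group's cumulative relative abundance minus the cumulative
    abundances of any excluded member taxa (e.g. a named strain).  Samples
    with a flagged-missing denominator stay NaN and are dropped later by
    the correlation.
    """
    rows = meta[(meta["site"] == site) & (meta["environment"] != "blank")]
    if len(rows) < 3:
        raise VirusHostError(f"site {site!r} has fewer than 3 samples")
    rows = rows.sort_values("age_cal_ka_bp")
    samples = rows["sample_id"].tolist()

    present = [t for t in virus_taxa if t in abund.data.index]
    if not present:
        frame = pd.DataFrame(
            {
                "age": rows["age_cal_ka_bp"].to_numpy(),
                "epoch": rows["epoch"].to_numpy(),
                "virus": np.nan,
                "host": np.nan,
            },
            index=samples,
        )
        return GroupSeries(site=site, group=group, frame=frame, empty=True)
    virus = abund.data.loc[present, samples].sum(axis=0, skipna=False)

    if group not in abund.data.index:
        host = pd.Series(np.nan, index=samples)
        empty = True
    else:
        host = abund.data.loc[group, samples].astype(float).copy()
        for t in exclude_taxa:
            if t in abund.data.index:
                host = host - abund.data.loc[t, samples]
        host = host.clip(lower=0.0)
        empty = False
    frame = pd.DataFrame(
        {
            "age": rows["age_cal_ka_bp"].to_numpy(),
            "epoch": rows["epoch"].to_numpy(),
            "virus": virus.to_numpy(dtype=float),
            "host": host.to_numpy(dtype=float),
        },
        index=samples,
    )
    return GroupSeries(site=site, group=group, frame=frame, empty=empty)


# ---------------------------------------------------------------------------
# rank statistics


@dataclass
class SpearmanResult:
    rho: float
    pvalue: float
    n: int
    undefined: bool = False
    method: str = "t"


def _exact_spearman_pvalue(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for Spearman's rho (small n).

    Enumerates every permutation of one rank vector; ties are handled by
    average ranks and Pearson correlation on ranks.
    """
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = rx.size
    perms = np.array(list(itertools.permutations(ry)), dtype=float)
    rx_c = rx - rx.mean()
    perms_c = perms - ry.mean()
    denom = np.linalg.norm(rx_c) * np.linalg.norm(ry - ry.mean())
    rhos = perms_c @ rx_c / denom
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def spearman(x, y, exact_max_n: int = 9) -> SpearmanResult:
    """Spearman rank correlation with average ranks for ties.

    Two-sided p-value by exact permutation for n <= ``exact_max_n``, by
    the t approximation otherwise.  Flagged-missing (NaN) pairs are
    dropped; constant series yield an undefined flag rather than a value.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise VirusHostError("series must have equal length")
    mask = np.isfinite(xa) & np.isfinite(ya)
    xa, ya = xa[mask], ya[mask]
    n = xa.size
    if n < 3:
        raise VirusHostError(f"need >= 3 paired observations, got {n}")
    if np.all(xa == xa[0]) or np.all(ya == ya[0]):
        return SpearmanResult(float("nan"), float("nan"), n, undefined=True)
    res = stats.spearmanr(xa, ya)
    rho = float(res.statistic)
    if n <= exact_max_n:
        p = _exact_spearman_pvalue(xa, ya, rho)
        return SpearmanResult(rho, p, n, method="exact-permutation")
    return SpearmanResult(rho, float(res.pvalue), n, method="t")


@dataclass
class ShiftTest:
    """One-sided signed-rank test of correlation coefficients against zero."""

    coefficients: np.ndarray
    statistic: float  # W+ (sum of ranks of positive coefficients)
    pvalue: float
    n: int  # non-zero coefficients used
    direction: str
    method: str


def _wplus_null_sf(ranks2: np.ndarray, w2: int) -> tuple[float, float]:
    """Exact null P(W+ >= w2/2) and P(W+ <= w2/2) for doubled ranks.

    Dynamic programming over the 2^n equiprobable sign assignments; the
    distribution is built by convolving one rank at a time, which is
    exactly the full enumeration without materialising it.
    """
    total = int(ranks2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in ranks2:
        nd = 0.5 * dist
        nd[r:] += 0.5 * dist[: total + 1 - r]
        dist = nd
    p_ge = float(dist[w2:].sum())
    p_le = float(dist[: w2 + 1].sum())
    return p_ge, p_le


def positive_shift_test(rhos, direction: str = "greater") -> ShiftTest:
    """One-sided Wilcoxon signed-rank test of coefficients against zero.

    Zero coefficients are dropped (classical convention), undefined (NaN)
    coefficients are excluded, ties get average ranks.  Exact null
    enumeration for n <= 25; normal approximation with continuity and tie
    correction above.
    """
    if direction not in ("greater", "less"):
        raise VirusHostError(f"unknown direction {direction!r}")
    arr = np.asarray(rhos, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise VirusHostError("no usable coefficients")
    if np.all(arr == 0):
        raise VirusHostError("degenerate: all coefficients are zero")
    nz = arr[arr != 0]
    n = nz.size
    ranks = stats.rankdata(np.abs(nz))
    wplus = float(ranks[nz > 0].sum())
    if n <= 25:
        ranks2 = np.round(2 * ranks).astype(int)
        w2 = int(round(2 * wplus))
        p_ge, p_le = _wplus_null_sf(ranks2, w2)
        p = p_ge if direction == "greater" else p_le
        method = "exact"
    else:
        mu = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var -= float(np.sum(tie_counts**3 - tie_counts)) / 48.0
        sd = np.sqrt(var)
        if direction == "greater":
            p = float(stats.norm.sf((wplus - mu - 0.5) / sd))
        else:
            p = float(stats.norm.cdf((wplus - mu + 0.5) / sd))
        method = "normal"
    return ShiftTest(
        coefficients=arr,
        statistic=wplus,
        pvalue=min(max(p, np.nextafter(0, 1)), 1.0),
        n=n,
        direction=direction,
        method=method,
    )


# ---------------------------------------------------------------------------
# sensitivity and host inference


def exclusion_sensitivity(
    abund: AbundanceMatrix,
    meta: pd.DataFrame,
    site: str,
    group: int,
    virus_taxa,
    candidate_taxa,
    epoch_subsets=("all", "Holocene", "Pleistocene"),
) -> pd.DataFrame:
    """Correlations after excluding candidate host taxa, per epoch subset.

    Rows cover the baseline (no exclusion), each singleton candidate, and
    the full candidate set.
    """
    candidates = sorted(set(candidate_taxa))
    subsets: list[tuple[str, frozenset]] = [("baseline", frozenset())]
    subsets += [(str(c), frozenset({c})) for c in candidates]
    if len(candidates) > 1:
        subsets.append(("all-candidates", frozenset(candidates)))
    rows = []
    for label, excl in subsets:
        series = group_abundance_series(
            abund, meta, site, group, virus_taxa, exclude_taxa=excl
        )
        for epoch in epoch_subsets:
            sub = series.subset(epoch)
            entry = {
                "site": site,
                "group": group,
                "excluded": label,
                "epoch": epoch,
                "n": len(sub),
                "rho": float("nan"),
                "pvalue": float("nan"),
                "undefined": True,
            }
            if not series.empty and len(sub) >= 3:
                try:
                    r = spearman(sub["virus"], sub["host"])
                    entry.update(
                        rho=r.rho, pvalue=r.pvalue, n=r.n, undefined=r.undefined
                    )
                except VirusHostError:
                    pass
            rows.append(entry)
    return pd.DataFrame(rows)


def infer_host_from_name(virus_name: str, known_genera) -> str | None:
    """Host genus from a trivial phage name ("<Genus> phage ...").

    The token immediately preceding a case-insensitive "phage" token is
    returned iff it exactly matches a known genus name; no fuzzy matching
    (false pairings are worse than misses).
    """
    known = set(known_genera)
    tokens = str(virus_name).split()
    for i, tok in enumerate(tokens):
        if tok.lower() == "phage" and i > 0 and tokens[i - 1] in known:
            return tokens[i - 1]
    return None


def phage_class_groups(
    virus_annotations: pd.DataFrame,
    pairs: pd.DataFrame,
    vmr: pd.DataFrame | None,
    tree: TaxonomyTree,
) -> tuple[dict[int, set[int]], list[int]]:
    """Group viruses by the bacterial class of their known or inferred host.

    Resolution order per virus: curated pair -> VMR row -> trivial-name
    inference; conflicts between curated and VMR hosts are logged and the
    curated pair wins.  Returns (class taxid -> virus set, unresolved
    virus taxids).

    ``virus_annotations`` is indexed by virus taxid with a ``name`` column.
    """
    genus_index = tree.names_at_rank("genus")
    curated: dict[int, int] = {}
    for row in pairs.itertuples(index=False):
        if row.host_domain != "bacteria":
            continue
        g = tree.ancestor_at_rank(int(row.host_taxid), "genus")
        if g is not None:
            curated.setdefault(int(row.virus_taxid), g)
    vmr_map: dict[str, str] = {}
    if vmr is not None:
        vmr_map = dict(zip(vmr["virus_name"].astype(str), vmr["host_genus"].astype(str)))

    groups: dict[int, set[int]] = {}
    unresolved: list[int] = []
    for taxid, row in virus_annotations.iterrows():
        taxid = int(taxid)
        name = str(row["name"])
        genus: int | None = None
        if taxid in curated:
            genus = curated[taxid]
            if name in vmr_map:
                vmr_genus = genus_index.get(vmr_map[name])
                if vmr_genus is not None and vmr_genus != genus:
                    logger.info(
                        "virus %s: curated host %s overrides VMR host %s",
                        name, tree.name(genus), vmr_map[name],
                    )
        elif name in vmr_map and vmr_map[name] in genus_index:
            genus = genus_index[vmr_map[name]]
        else:
            inferred = infer_host_from_name(name, genus_index)
            if inferred is not None:
                genus = genus_index[inferred]
        if genus is None:
            unresolved.append(taxid)
            continue
        cls = tree.ancestor_at_rank(genus, "class")
        if cls is None:
            unresolved.append(taxid)
            continue
        groups.setdefault(cls, set()).add(taxid)
    return groups, unresolved
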