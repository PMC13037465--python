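"""Time-binned pairwise core dissimilarity.

Sediment cores are sampled at irregular, core-specific ages, so two cores
cannot be compared sample-by-sample.  Each pair is instead binned over
their overlapping age interval with a bin width equal to the larger of the
two cores' median sampling intervals; species relative abundances are
averaged per core within each bin, Hellinger-transformed, and compared by
Euclidean distance.  The pairwise statistic is the unweighted mean of
those distances over all *shared* bins (bins holding at least one sample
from each core).

Bins are anchored at the start of the overlap; they are half-open
``[lo, hi)`` except the last, which is closed so the oldest overlapping
sample is never dropped.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .community import hellinger_transform
from .tables import AbundanceMatrix

__all__ = [
    "CoreSimError",
    "CoreSeries",
    "median_sampling_interval",
    "pair_bins",
    "core_dissimilarity",
    "dissimilarity_matrix",
    "pairwise_table",
]


class CoreSimError(ValueError):
    """Cores that cannot be binned or compared."""


@dataclass
class CoreSeries:
    """One core's dated samples with species abundance vectors.

    ``abund`` holds one row per sample (aligned with ``ages``, strictly
    increasing) and one column per species; abundances are relative to the
    core's viral reads.
    """

    site: str
    ages: np.ndarray
    abund: pd.DataFrame

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        order = np.argsort(self.ages, kind="stable")
        self.ages = self.ages[order]
        self.abund = self.abund.iloc[order]
        if len(self.ages) != len(self.abund):
            raise CoreSimError("ages and abundance rows differ in length")
        if len(self.ages) >= 2 and (np.diff(self.ages) <= 0).any():
            raise CoreSimError(f"duplicate sample ages in core {self.site!r}")

    @classmethod
    def from_abundance(
        cls, abund: AbundanceMatrix, meta: pd.DataFrame, site: str
    ) -> "CoreSeries":
        rows = meta[(meta["site"] == site) & (meta["environment"] != "blank")]
        if rows.empty:
            raise CoreSimError(f"no samples for site {site!r}")
        samples = rows["sample_id"].tolist()
        mat = abund.data[samples].T
        mat = mat.fillna(0.0)
        return cls(
            site=site,
            ages=rows["age_cal_ka_bp"].to_numpy(dtype=float),
            abund=mat,
        )


def median_sampling_interval(ages) -> float:
    """Median of successive age differences after sorting."""
    a = np.sort(np.asarray(ages, dtype=float))
    if a.size < 2:
        raise CoreSimError("need at least two ages")
    return float(np.median(np.diff(a)))


def pair_bins(core_a: CoreSeries, core_b: CoreSeries) -> np.ndarray:
    """Shared bin edges for a core pair.

    Width is the maximum of the two cores' median sampling intervals; the
    tiling starts at the beginning of the age overlap and extends until
    the overlap is covered.
    """
    lo = max(core_a.ages.min(), core_b.ages.min())
    hi = min(core_a.ages.max(), core_b.ages.max())
    if lo > hi:
        raise CoreSimError(
            f"no shared interval between {core_a.site!r} and {core_b.site!r}"
        )
    width = max(
        median_sampling_interval(core_a.ages),
        median_sampling_interval(core_b.ages),
    )
    n = max(1, math.ceil((hi - lo) / width)) if hi > lo else 1
    return lo + width * np.arange(n + 1)


def _bin_means(
    core: CoreSeries, edges: np.ndarray, columns
) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin mean abundance vectors and sample counts for one core."""
    lo, hi = edges[0], edges[-1]
    width = edges[1] - edges[0]
    n = len(edges) - 1
    mat = core.abund.reindex(columns=columns, fill_value=0.0).to_numpy()
    sums = np.zeros((n, len(columns)))
    cnt = np.zeros(n, dtype=int)
    for age, row in zip(core.ages, mat):
        if age < lo or age > hi:
            continue
        idx = min(int((age - lo) // width), n - 1)
        sums[idx] += row
        cnt[idx] += 1
    means = np.divide(
        sums, cnt[:, None], out=np.zeros_like(sums), where=cnt[:, None] > 0
    )
    return means, cnt


def core_dissimilarity(
    core_a: CoreSeries,
    core_b: CoreSeries,
    exclude_taxa=frozenset(),
) -> float:
    """Mean Hellinger distance across shared time bins.

    ``exclude_taxa`` are dropped from both cores *before* the Hellinger
    transform (renormalisation is implicit in the transform's row-sum
    division).  Bins whose post-exclusion vectors are all-zero on either
    side are dropped with a warning; with no usable shared bins the
    result is NaN (with a warning).
    """
    edges = pair_bins(core_a, core_b)
    cols = core_a.abund.columns.union(core_b.abund.columns)
    keep = [c for c in cols if c not in set(exclude_taxa)]
    means_a, cnt_a = _bin_means(core_a, edges, keep)
    means_b, cnt_b = _bin_means(core_b, edges, keep)
    shared = (cnt_a > 0) & (cnt_b > 0)
    if not shared.any():
        warnings.warn(
            f"no shared bins between {core_a.site!r} and {core_b.site!r}",
            stacklevel=2,
        )
        return float("nan")
    dists = []
    for i in np.flatnonzero(shared):
        va, vb = means_a[i], means_b[i]
        if va.sum() == 0 or vb.sum() == 0:
            warnings.warn(
                f"bin {i} all-zero after exclusion; dropped", stacklevel=2
            )
            continue
        dists.append(
            float(
                np.linalg.norm(
                    hellinger_transform(va) - hellinger_transform(vb)
                )
            )
        )
    if not dists:
        warnings.warn("all shared bins degenerate after exclusion", stacklevel=2)
        return float("nan")
    return float(np.mean(dists))


def dissimilarity_matrix(
    cores, exclude_taxa=frozenset()
) -> pd.DataFrame:
    """Symmetric site x site matrix of core dissimilarities.

    Pairs without age overlap carry NaN; the diagonal is zero.
    """
    cores = list(cores)
    if len(cores) < 2:
        raise CoreSimError("need at least two cores")
    sites = [c.site for c in cores]
    out = pd.DataFrame(0.0, index=sites, columns=sites)
    for i, a in enumerate(cores):
        for j in range(i + 1, len(cores)):
            b = cores[j]
            try:
                d = core_dissimilarity(a, b, exclude_taxa)
            except CoreSimError:
                d = float("nan")
            out.iloc[i, j] = d
            out.iloc[j, i] = d
    return out


def pairwise_table(cores, exclude_taxa=frozenset()) -> pd.DataFrame:
    """Long-form pair table: site_a, site_b, n_shared_bins, distance."""
    cores = list(cores)
    rows = []
    for i, a in enumerate(cores):
        for j in range(i + 1, len(cores)):
            b = cores[j]
            try:
                edges = pair_bins(a, b)
                cols = a.abund.columns.union(b.abund.columns)
                keep = [c for c in cols if c not in set(exclude_taxa)]
                _, ca = _bin_means(a, edges, keep)
                _, cb = _bin_means(b, edges, keep)
                n_shared = int(((ca > 0) & (cb > 0)).sum())
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    d = core_dissimilarity(a, b, exclude_taxa)
            except CoreSimError:
                n_shared, d = 0, float("nan")
            rows.append([a.site, b.site, n_shared, d])
    return pd.DataFrame(
        rows, columns=["site_a", "site_b", "n_shared_bins", "distance"]
    )
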