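"""Species overlap between environments, rarefaction, and beta-diversity transforms.

The Hellinger transform (square root of relative abundance) and
Bray-Curtis dissimilarity feed ordination and the time-binned core
similarity statistic; the transformed/distance matrices are emitted in
standard tabular form and any ordination fitting (NMDS/RDA) is left to
dedicated tools.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis as _sp_braycurtis

from .tables import CountMatrix
from .taxonomy import TaxonomyTree

__all__ = [
    "CommunityError",
    "OverlapResult",
    "RarefactionCurve",
    "hellinger_transform",
    "hellinger_distance",
    "bray_curtis",
    "species_taxa",
    "environment_overlap",
    "rarefy",
    "rarefaction_overlap_curve",
    "round_half_away",
]


class CommunityError(ValueError):
    """Degenerate inputs to community-structure operations."""


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


# ---------------------------------------------------------------------------
# transforms


def hellinger_transform(row) -> np.ndarray:
    """sqrt(x_i / sum x): unit vector in the squared sense."""
    x = np.asarray(row, dtype=float)
    if (x < 0).any():
        raise CommunityError("abundances must be non-negative")
    total = x.sum()
    if total <= 0:
        raise CommunityError("all-zero row cannot be Hellinger-transformed")
    return np.sqrt(x / total)


def hellinger_distance(u, v) -> float:
    """Euclidean distance between Hellinger-transformed rows, in [0, sqrt 2]."""
    return float(
        np.linalg.norm(hellinger_transform(u) - hellinger_transform(v))
    )


def bray_curtis(u, v) -> float:
    """Bray-Curtis dissimilarity sum|u-v| / sum(u+v) in [0, 1]."""
    a = np.asarray(u, dtype=float)
    b = np.asarray(v, dtype=float)
    if a.shape != b.shape:
        raise CommunityError("vectors must have equal length")
    if (a < 0).any() or (b < 0).any():
        raise CommunityError("abundances must be non-negative")
    if a.sum() == 0 and b.sum() == 0:
        raise CommunityError("both vectors are all-zero")
    return float(_sp_braycurtis(a, b))


# ---------------------------------------------------------------------------
# environment overlap


@dataclass
class OverlapResult:
    """Partition of species between two groups with read accounting.

    Percentages are of distinct species, rounded half away from zero so
    that printed triples like 43/39/18 reproduce exactly from the raw
    counts.
    """

    unique_a: int
    unique_b: int
    shared: int
    label_a: str = "A"
    label_b: str = "B"
    unique_reads: int = 0
    shared_reads: int = 0
    taxa_unique_a: frozenset = field(default_factory=frozenset, repr=False)
    taxa_unique_b: frozenset = field(default_factory=frozenset, repr=False)
    taxa_shared: frozenset = field(default_factory=frozenset, repr=False)

    @classmethod
    def from_counts(cls, unique_a: int, unique_b: int, shared: int, **kw):
        return cls(unique_a=unique_a, unique_b=unique_b, shared=shared, **kw)

    @classmethod
    def from_sets(cls, species_a: set, species_b: set, **kw):
        a, b = set(species_a), set(species_b)
        return cls(
            unique_a=len(a - b),
            unique_b=len(b - a),
            shared=len(a & b),
            taxa_unique_a=frozenset(a - b),
            taxa_unique_b=frozenset(b - a),
            taxa_shared=frozenset(a & b),
            **kw,
        )

    @property
    def total(self) -> int:
        return self.unique_a + self.unique_b + self.shared

    def _pct(self, n: int) -> int:
        if self.total == 0:
            return 0
        return round_half_away(100.0 * n / self.total)

    @property
    def pct_unique_a(self) -> int:
        return self._pct(self.unique_a)

    @property
    def pct_unique_b(self) -> int:
        return self._pct(self.unique_b)

    @property
    def pct_shared(self) -> int:
        return self._pct(self.shared)

    # exact (unrounded) proportions, for rarefaction curves
    @property
    def frac_shared(self) -> float:
        return self.shared / self.total if self.total else float("nan")

    @property
    def total_reads(self) -> int:
        return self.unique_reads + self.shared_reads

    @property
    def shared_read_fraction(self) -> float:
        t = self.total_reads
        return self.shared_reads / t if t else float("nan")


def species_taxa(
    counts: CountMatrix, tree: TaxonomyTree, within: int | None = None
) -> list[int]:
    """Taxa at species rank (optionally inside the subtree of ``within``).

    Strains are not listed separately: in cumulative mode their reads are
    already rolled into the parent species row.
    """
    sub = None if within is None else set(tree.descendants(within))
    return [
        int(t)
        for t in counts.data.index
        if tree.rank(int(t)) == "species" and (sub is None or int(t) in sub)
    ]


def _env_samples(meta: pd.DataFrame, env: str) -> list[str]:
    return meta.loc[meta["environment"] == env, "sample_id"].tolist()


def environment_overlap(
    counts: CountMatrix,
    meta: pd.DataFrame,
    tree: TaxonomyTree,
    env_a: str = "lake",
    env_b: str = "marine",
    within: int | None = None,
) -> OverlapResult:
    """Partition species into environment-unique and shared sets.

    A species is present in an environment when it has at least one
    (cumulative) read in any of that environment's samples.  Read
    accounting covers all species-level reads across both environments.
    """
    if counts.mode != "cumulative":
        raise CommunityError("environment_overlap expects cumulative counts")
    sa, sb = _env_samples(meta, env_a), _env_samples(meta, env_b)
    if not sa or not sb:
        missing = env_a if not sa else env_b
        raise CommunityError(f"environment {missing!r} has no samples")
    species = species_taxa(counts, tree, within)
    sub = counts.data.loc[species]
    pres_a = sub[sa].sum(axis=1) > 0
    pres_b = sub[sb].sum(axis=1) > 0
    set_a = set(sub.index[pres_a])
    set_b = set(sub.index[pres_b])
    res = OverlapResult.from_sets(set_a, set_b, label_a=env_a, label_b=env_b)
    reads = sub[sa + sb].sum(axis=1)
    res.shared_reads = int(reads[list(res.taxa_shared)].sum())
    res.unique_reads = int(
        reads[list(res.taxa_unique_a | res.taxa_unique_b)].sum()
    )
    return res


# ---------------------------------------------------------------------------
# rarefaction


def rarefy(sample_counts, depth: int, seed=None, rng=None) -> np.ndarray:
    """Subsample a count vector without replacement to ``depth`` reads.

    Multivariate hypergeometric draw; when ``depth`` meets or exceeds the
    vector total the input is returned unchanged (saturation).
    """
    counts = np.asarray(sample_counts, dtype=np.int64)
    if depth < 0:
        raise CommunityError("depth must be non-negative")
    if (counts < 0).any():
        raise CommunityError("counts must be non-negative")
    total = int(counts.sum())
    if depth >= total:
        return counts.copy()
    if rng is None:
        rng = np.random.default_rng(seed)
    return rng.multivariate_hypergeometric(counts, int(depth))


DEFAULT_DEPTHS = tuple(int(10**k) for k in range(2, 9))


@dataclass
class RarefactionCurve:
    """Overlap proportions as a function of subsampling depth."""

    table: pd.DataFrame  # depth, pct_unique_a, pct_unique_b, pct_shared, distinct_species
    depths: tuple
    reps: int
    seed: int
    mode: str


def rarefaction_overlap_curve(
    counts: CountMatrix,
    meta: pd.DataFrame,
    tree: TaxonomyTree,
    depths=DEFAULT_DEPTHS,
    reps: int = 3,
    seed: int = 0,
    mode: str = "per-sample",
    env_a: str = "lake",
    env_b: str = "marine",
    within: int | None = None,
) -> RarefactionCurve:
    """Environment overlap after rarefying to each target depth.

    ``mode='per-sample'`` rarefies every sample row then pools presence by
    environment (the semantics of per-row subsampling in community
    ecology toolkits); ``mode='pooled'`` subsamples the environment-pooled
    species vector instead.  Percentages in the output are exact
    (unrounded) proportions averaged over replicates.
    """
    if mode not in ("per-sample", "pooled"):
        raise CommunityError(f"unknown rarefaction mode {mode!r}")
    sa, sb = _env_samples(meta, env_a), _env_samples(meta, env_b)
    if not sa or not sb:
        raise CommunityError("both environments need samples")
    species = species_taxa(counts, tree, within)
    mat = counts.data.loc[species]
    ss = np.random.SeedSequence(seed)
    streams = ss.spawn(len(depths) * max(reps, 1))
    rows = []
    for di, depth in enumerate(depths):
        accum = np.zeros(4)
        for r in range(reps):
            rng = np.random.default_rng(streams[di * reps + r])
            if mode == "per-sample":
                pres_a = np.zeros(len(species), dtype=bool)
                pres_b = np.zeros(len(species), dtype=bool)
                for s in sa:
                    pres_a |= rarefy(mat[s].to_numpy(), depth, rng=rng) > 0
                for s in sb:
                    pres_b |= rarefy(mat[s].to_numpy(), depth, rng=rng) > 0
            else:
                pres_a = rarefy(mat[sa].sum(axis=1).to_numpy(), depth, rng=rng) > 0
                pres_b = rarefy(mat[sb].sum(axis=1).to_numpy(), depth, rng=rng) > 0
            ua = int((pres_a & ~pres_b).sum())
            ub = int((pres_b & ~pres_a).sum())
            sh = int((pres_a & pres_b).sum())
            tot = ua + ub + sh
            if tot:
                accum += np.array(
                    [100.0 * ua / tot, 100.0 * ub / tot, 100.0 * sh / tot, tot]
                )
        rows.append([depth, *(accum / max(reps, 1))])
    table = pd.DataFrame(
        rows,
        columns=[
            "depth",
            "pct_unique_a",
            "pct_unique_b",
            "pct_shared",
            "distinct_species",
        ],
    )
    return RarefactionCurve(
        table=table, depths=tuple(depths), reps=reps, seed=seed, mode=mode
    )
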