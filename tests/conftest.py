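"""Shared fixtures and independent oracles.

Oracles here are deliberately written without touching the library code
paths they check: descendant-set summation for cumulative aggregation,
rank-then-Pearson for Spearman, full 2^n sign enumeration for the
signed-rank test, and a lattice grid search for the damage model.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from sedavirome.simulate import SimConfig, simulate_core_set
from sedavirome.tables import aggregate_cumulative, relative_abundance
from sedavirome.taxonomy import TaxonomyTree, parse_taxonomy

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture(scope="session")
def four_node_tree() -> TaxonomyTree:
    """root -> Viruses -> genus G -> species S1, S2 plus family F."""
    nodes = [
        (1, 1, "no-rank"),
        (2, 1, "superkingdom"),
        (3, 2, "family"),
        (4, 3, "genus"),
        (5, 4, "species"),
        (6, 4, "species"),
    ]
    names = [
        (1, "root"),
        (2, "Viruses"),
        (3, "F"),
        (4, "G"),
        (5, "S1"),
        (6, "S2"),
    ]
    return parse_taxonomy(nodes, names)


@pytest.fixture(scope="session")
def default_sim():
    """One default 4-site synthetic core set with derived matrices."""
    res = simulate_core_set(SimConfig.default(1))
    cum = aggregate_cumulative(res.counts, res.tree)
    viral_root = res.tree.find_by_name("Viruses")
    return {
        "res": res,
        "cum": cum,
        "viral_root": viral_root,
        "ab_all": relative_abundance(cum, res.tree, "root"),
        "ab_viral": relative_abundance(cum, res.tree, viral_root),
    }


# ---------------------------------------------------------------------------
# oracles


def descendant_sum_oracle(counts: pd.DataFrame, tree: TaxonomyTree) -> dict:
    """Cumulative counts as brute-force sums over each node's descendant set."""
    nodeset = set()
    for t in counts.index:
        nodeset.update(tree.lineage(int(t)))
    out = {}
    for node in nodeset:
        desc = set(tree.descendants(node))
        rows = [t for t in counts.index if int(t) in desc]
        out[node] = counts.loc[rows].sum(axis=0).to_numpy()
    return out


def average_ranks(values) -> np.ndarray:
    """Tie-averaged ranks, written from first principles."""
    v = np.asarray(values, dtype=float)
    order = np.argsort(v, kind="stable")
    ranks = np.empty(len(v))
    i = 0
    while i < len(v):
        j = i
        while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def rank_then_pearson(x, y) -> float:
    """Spearman oracle: Pearson correlation of tie-averaged ranks."""
    rx = average_ranks(x)
    ry = average_ranks(y)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    return float(rxc @ ryc / np.sqrt((rxc @ rxc) * (ryc @ ryc)))


def signed_rank_enumeration(values, direction: str = "greater") -> tuple[float, float]:
    """Exact one-sided signed-rank p by enumerating all 2^n sign patterns."""
    v = np.asarray(values, dtype=float)
    v = v[v != 0]
    n = v.size
    ranks = average_ranks(np.abs(v))
    w_obs = ranks[v > 0].sum()
    count = 0
    for signs in itertools.product((False, True), repeat=n):
        w = ranks[np.array(signs)].sum()
        hit = w >= w_obs - 1e-12 if direction == "greater" else w <= w_obs + 1e-12
        count += hit
    return w_obs, count / 2.0**n


def damage_grid_oracle(k, n, nb=50, na=50, nl=50):
    """Best (b, A, lam) on a lattice by direct binomial log-likelihood."""
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    x = np.arange(k.size)
    bs = np.linspace(0.0, 0.1, nb)
    As = np.linspace(0.0, 0.5, na)
    ls = np.linspace(0.02, 0.98, nl)
    grid = np.array(list(itertools.product(bs, As, ls)))
    f = grid[:, [0]] + grid[:, [1]] * (1 - grid[:, [2]]) ** x[None, :]
    f = np.clip(f, 1e-12, 1 - 1e-12)
    ll = (k[None, :] * np.log(f) + (n - k)[None, :] * np.log(1 - f)).sum(axis=1)
    best = grid[np.argmax(ll)]
    return {"b": best[0], "A": best[1], "lam": best[2], "ll": float(ll.max())}


def random_taxonomy(rng: np.random.Generator, n_nodes: int) -> TaxonomyTree:
    """Random rooted tree with arbitrary rank labels."""
    ranks = ["no-rank", "superkingdom", "phylum", "class", "order",
             "family", "genus", "species", "strain", "clade"]
    nodes = [(1, 1, "no-rank")]
    for t in range(2, n_nodes + 1):
        parent = int(rng.integers(1, t))
        nodes.append((t, parent, str(rng.choice(ranks))))
    names = [(t, f"taxon-{t}") for t, _, _ in nodes]
    return parse_taxonomy(nodes, names)
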