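"""NCBI-taxdump-style taxonomy tree for lineage and rank queries.

The tree is parsed from two plain tab-separated tables that mirror the
minimal columns of NCBI's ``nodes.dmp`` and ``names.dmp`` (ordinary tabs,
*no* ``|`` field delimiters):

* nodes: ``taxid <TAB> parent_taxid <TAB> rank``
* names: ``taxid <TAB> scientific_name``

The root is the single row whose taxid equals its own parent taxid, as in
the real taxdump (node 1).  Rank labels outside the canonical ordered set
(superkingdom > phylum > class > order > family > genus > species > strain)
are allowed and treated as unranked intermediates: they pass through
aggregation unchanged and are simply never matched by rank walks.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

__all__ = [
    "CANONICAL_RANKS",
    "TaxonomyError",
    "TaxonomyTree",
    "parse_taxonomy",
]

#: Canonical rank labels, most inclusive first.
CANONICAL_RANKS = (
    "superkingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
    "strain",
)


class TaxonomyError(ValueError):
    """Malformed taxonomy: orphan nodes, cycles, or a missing/ambiguous root."""


class TaxonomyTree:
    """Rooted taxonomy with parent pointers, rank labels and names.

    Parameters
    ----------
    parents
        Mapping taxid -> parent taxid.  The root maps to itself.
    ranks
        Mapping taxid -> rank label.
    names
        Mapping taxid -> scientific name.  Missing ids default to the id
        rendered as text.
    root
        Taxid of the root node.
    """

    def __init__(
        self,
        parents: Mapping[int, int],
        ranks: Mapping[int, str],
        names: Mapping[int, str],
        root: int,
    ) -> None:
        self._parents = dict(parents)
        self._ranks = dict(ranks)
        self._names = dict(names)
        self.root = int(root)
        if self.root not in self._parents:
            raise TaxonomyError(f"root {root} is not among the nodes")
        children: dict[int, list[int]] = {t: [] for t in self._parents}
        for t, p in self._parents.items():
            if t != self.root:
                children[p].append(t)
        # deterministic traversal order
        self._children = {t: tuple(sorted(c)) for t, c in children.items()}
        self._name_index: dict[str, int] | None = None

    # -- basic queries ---------------------------------------------------
    def __contains__(self, taxid: int) -> bool:
        return taxid in self._parents

    def __len__(self) -> int:
        return len(self._parents)

    def __iter__(self) -> Iterator[int]:
        return iter(self._parents)

    def parent(self, taxid: int) -> int:
        try:
            return self._parents[taxid]
        except KeyError:
            raise TaxonomyError(f"unknown taxid {taxid}") from None

    def rank(self, taxid: int) -> str:
        self.parent(taxid)  # existence check
        return self._ranks.get(taxid, "no-rank")

    def name(self, taxid: int) -> str:
        self.parent(taxid)
        return self._names.get(taxid, str(taxid))

    def children(self, taxid: int) -> tuple[int, ...]:
        try:
            return self._children[taxid]
        except KeyError:
            raise TaxonomyError(f"unknown taxid {taxid}") from None

    # -- walks -----------------------------------------------------------
    def lineage(self, taxid: int) -> list[int]:
        """Ordered ancestor ids from the root down to ``taxid`` (inclusive)."""
        path = [taxid]
        t = taxid
        while t != self.root:
            t = self.parent(t)
            path.append(t)
            if len(path) > len(self._parents):
                raise TaxonomyError(f"cycle reached from taxid {taxid}")
        path.reverse()
        return path

    def ancestor_at_rank(self, taxid: int, rank: str) -> int | None:
        """Nearest ancestor (or self) carrying ``rank``; None if absent."""
        for t in reversed(self.lineage(taxid)):
            if self._ranks.get(t) == rank:
                return t
        return None

    def descendants(self, taxid: int, include_self: bool = True) -> list[int]:
        """Preorder list of the subtree below ``taxid``."""
        out: list[int] = []
        stack = [taxid]
        while stack:
            t = stack.pop()
            out.append(t)
            stack.extend(reversed(self.children(t)))
        return out if include_self else out[1:]

    def postorder(self, taxids: Iterable[int] | None = None) -> list[int]:
        """Children-before-parents ordering.

        When ``taxids`` is given, the traversal is restricted to that node
        set (which must be closed under taking ancestors up to the root of
        the restriction).
        """
        allowed = None if taxids is None else set(taxids)
        start = self.root
        if allowed is not None and start not in allowed:
            raise TaxonomyError("restricted node set must contain the root")
        out: list[int] = []
        stack: list[tuple[int, bool]] = [(start, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                out.append(node)
                continue
            stack.append((node, True))
            for c in self.children(node):
                if allowed is None or c in allowed:
                    stack.append((c, False))
        return out

    def find_by_name(self, name: str) -> int:
        """Taxid of the node named ``name`` (first match on duplicates)."""
        if self._name_index is None:
            idx: dict[str, int] = {}
            for t in sorted(self._parents):
                idx.setdefault(self._names.get(t, str(t)), t)
            self._name_index = idx
        try:
            return self._name_index[name]
        except KeyError:
            raise TaxonomyError(f"no taxon named {name!r}") from None

    def names_at_rank(self, rank: str) -> dict[str, int]:
        """Mapping name -> taxid over all nodes carrying ``rank``."""
        return {
            self.name(t): t
            for t in sorted(self._parents)
            if self._ranks.get(t) == rank
        }


def _as_frame(obj, columns: list[str], what: str) -> pd.DataFrame:
    if isinstance(obj, pd.DataFrame):
        df = obj.copy()
        df.columns = columns[: df.shape[1]]
        return df
    if isinstance(obj, (str, Path)):
        return pd.read_csv(obj, sep="\t", header=None, names=columns, comment="#")
    # iterable of row tuples
    return pd.DataFrame(list(obj), columns=columns)


def parse_taxonomy(nodes, names=None) -> TaxonomyTree:
    """Build a :class:`TaxonomyTree` from nodes/names tables.

    ``nodes`` and ``names`` may each be a path to a TSV, a DataFrame, or an
    iterable of row tuples.  Exactly one node must be its own parent (the
    root).  Orphans (parent id absent from the node table) and cycles are
    parse failures naming the offending node.
    """
    ndf = _as_frame(nodes, ["taxid", "parent", "rank"], "nodes")
    parents = dict(zip(ndf["taxid"].astype(int), ndf["parent"].astype(int)))
    if len(parents) != len(ndf):
        dup = ndf["taxid"][ndf["taxid"].duplicated()].iloc[0]
        raise TaxonomyError(f"duplicate node row for taxid {dup}")
    ranks = dict(zip(ndf["taxid"].astype(int), ndf["rank"].astype(str)))

    roots = [t for t, p in parents.items() if t == p]
    if len(roots) != 1:
        raise TaxonomyError(
            f"expected exactly one self-parented root, found {len(roots)}"
        )
    root = roots[0]

    for t, p in parents.items():
        if p not in parents:
            raise TaxonomyError(f"orphan node {t}: parent {p} absent")

    # cycle check: iterative colouring
    state: dict[int, int] = {}  # 1 = on path, 2 = done
    for start in parents:
        if state.get(start) == 2:
            continue
        path = []
        t = start
        while True:
            s = state.get(t)
            if s == 2:
                break
            if s == 1:
                raise TaxonomyError(f"cycle detected at taxid {t}")
            state[t] = 1
            path.append(t)
            if t == root:
                break
            t = parents[t]
        for q in path:
            state[q] = 2

    name_map: dict[int, str] = {}
    if names is not None:
        mdf = _as_frame(names, ["taxid", "name"], "names")
        name_map = dict(zip(mdf["taxid"].astype(int), mdf["name"].astype(str)))
    return TaxonomyTree(parents, ranks, name_map, root)
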