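"""Ranked taxonomy model with lineage and lowest-common-ancestor queries.

Every assignment method in this package reduces to questions about a rooted,
rank-labelled taxonomy: what is the lineage of a taxon, what is the deepest
taxon containing a whole set of taxa (LCA), and is one taxon inside another.
This module provides those primitives on top of a plain id -> Taxon map, the
shape of a GenBank/NCBI-style lineage dump.

Canonical ranks, most to least specific, follow the seven levels used in
diet-assessment reporting (species .. phylum).  Taxa with a non-canonical
rank label ("clade", "suborder", "no rank", ...) are kept in the hierarchy
— assignments to clades such as Laniatores or the RTA clade are legitimate —
and are treated as "unranked": their effective reporting rank is derived
from the nearest canonical ancestor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

#: Canonical rank labels ordered most specific -> least specific.
CANONICAL_RANKS: tuple[str, ...] = (
    "species",
    "genus",
    "family",
    "superfamily",
    "order",
    "class",
    "phylum",
)

#: Depth index per canonical rank (species = 0 is the most specific).
RANK_DEPTH: dict[str, int] = {r: i for i, r in enumerate(CANONICAL_RANKS)}

#: Pseudo-depth for anything more rootward than phylum.
ABOVE_PHYLUM_DEPTH: int = len(CANONICAL_RANKS)


class UnknownTaxonError(KeyError):
    """Raised when a taxon id is not present in the index."""


@dataclass(frozen=True)
class Taxon:
    """One node of the taxonomy.

    ``parent_id`` is ``None`` for the single root.  ``rank`` is free text;
    only the canonical labels in :data:`CANONICAL_RANKS` participate in
    rank-based reporting, everything else is handled as unranked.
    """

    id: str
    name: str
    rank: str
    parent_id: str | None = None

    @property
    def is_canonical_rank(self) -> bool:
        return self.rank in RANK_DEPTH


class TaxonomyIndex:
    """Immutable id -> :class:`Taxon` map with ancestor-query primitives.

    Parameters
    ----------
    taxa:
        Taxon records.  Exactly one must have ``parent_id`` of ``None``
        (or equal to its own id, the NCBI dump convention); every other
        parent reference must resolve and the parent graph must be acyclic.
    """

    def __init__(self, taxa: Iterable[Taxon]):
        self._taxa: dict[str, Taxon] = {}
        root: str | None = None
        for t in taxa:
            if t.id in self._taxa:
                raise ValueError(f"duplicate taxon id {t.id!r}")
            if t.parent_id is None or t.parent_id == t.id:
                if t.parent_id == t.id:
                    t = Taxon(t.id, t.name, t.rank, None)
                if root is not None:
                    raise ValueError(f"multiple roots: {root!r} and {t.id!r}")
                root = t.id
            self._taxa[t.id] = t
        if root is None:
            raise ValueError("taxonomy has no root (no taxon with empty parent)")
        self._root = root
        # validate parents resolve and graph is acyclic
        self._lineage_cache: dict[str, tuple[str, ...]] = {}
        for tid in self._taxa:
            self._lineage_ids(tid)

    # -- basic access ------------------------------------------------------

    @property
    def root_id(self) -> str:
        return self._root

    def __contains__(self, taxon_id: str) -> bool:
        return taxon_id in self._taxa

    def __len__(self) -> int:
        return len(self._taxa)

    def __iter__(self):
        return iter(self._taxa.values())

    def get(self, taxon_id: str) -> Taxon:
        try:
            return self._taxa[taxon_id]
        except KeyError:
            raise UnknownTaxonError(taxon_id) from None

    # -- lineage / LCA -----------------------------------------------------

    def _lineage_ids(self, taxon_id: str) -> tuple[str, ...]:
        cached = self._lineage_cache.get(taxon_id)
        if cached is not None:
            return cached
        chain: list[str] = []
        seen: set[str] = set()
        cur: str | None = taxon_id
        while cur is not None:
            if cur in seen:
                raise ValueError(f"cycle in taxonomy at {cur!r}")
            seen.add(cur)
            t = self._taxa.get(cur)
            if t is None:
                raise UnknownTaxonError(cur)
            chain.append(cur)
            cur = t.parent_id
        result = tuple(reversed(chain))  # root ... taxon
        self._lineage_cache[taxon_id] = result
        return result

    def lineage(self, taxon_id: str) -> list[Taxon]:
        """Root-to-taxon chain of :class:`Taxon` records."""
        return [self._taxa[t] for t in self._lineage_ids(taxon_id)]

    def lowest_common_ancestor(self, taxon_ids: Iterable[str]) -> Taxon:
        """Deepest taxon that is an ancestor-or-self of every input.

        Raises ``ValueError`` on an empty input set.
        """
        ids = list(taxon_ids)
        if not ids:
            raise ValueError("lowest_common_ancestor of an empty set")
        common = self._lineage_ids(ids[0])
        for tid in ids[1:]:
            other = self._lineage_ids(tid)
            n = 0
            for a, b in zip(common, other):
                if a != b:
                    break
                n += 1
            common = common[:n]
        # lineages always share at least the root
        return self._taxa[common[-1]]

    def is_within(self, taxon_id: str, candidate_ancestor_id: str) -> bool:
        """True iff ``candidate_ancestor_id`` is ancestor-or-self of ``taxon_id``."""
        if candidate_ancestor_id not in self._taxa:
            raise UnknownTaxonError(candidate_ancestor_id)
        return candidate_ancestor_id in self._lineage_ids(taxon_id)

    def depth(self, taxon_id: str) -> int:
        """Number of edges from the root."""
        return len(self._lineage_ids(taxon_id)) - 1

    # -- rank handling -----------------------------------------------------

    def effective_rank_depth(self, taxon_id: str) -> int:
        """Reporting depth of a taxon on the canonical rank scale.

        A canonical-rank taxon maps to its own rank.  An unranked taxon maps
        one step more specific than its nearest canonical ancestor (a clade
        inside an order reports just below order); an unranked taxon with no
        canonical ancestor below the root sits above phylum.
        """
        t = self.get(taxon_id)
        if t.is_canonical_rank:
            return RANK_DEPTH[t.rank]
        for anc in reversed(self._lineage_ids(taxon_id)[:-1]):
            a = self._taxa[anc]
            if a.is_canonical_rank:
                return RANK_DEPTH[a.rank] - 1
        return ABOVE_PHYLUM_DEPTH

    def nearest_canonical_rank(self, taxon_id: str) -> str | None:
        """Canonical rank of the taxon itself or of its nearest canonical
        ancestor; ``None`` when no canonical rank exists on the lineage."""
        for tid in reversed(self._lineage_ids(taxon_id)):
            t = self._taxa[tid]
            if t.is_canonical_rank:
                return t.rank
        return None

    def ancestor_at_rank(self, taxon_id: str, rank: str) -> Taxon | None:
        """The ancestor-or-self of ``taxon_id`` carrying canonical ``rank``,
        or ``None`` if the lineage skips that rank."""
        for tid in self._lineage_ids(taxon_id):
            t = self._taxa[tid]
            if t.rank == rank:
                return t
        return None
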