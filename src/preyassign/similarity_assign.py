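"""Similarity-based taxonomic assignment: Best BLAST Hit and (weighted) LCA.

Best BLAST Hit (BBH) assigns a query the taxon of its highest-scoring hit.
BLAST scores favour long local alignments, so the top hit is not always the
closest relative: a long match at 98% identity outscores a shorter match at
the same identity even when the shorter one is the true taxon.  Tied top
scores are resolved to the lowest common ancestor of the tied taxa (default)
or to no assignment (``tie_mode='strict'``).

The LCA method is the conservative counterpart: it takes every hit at or
above an identity floor (default 95%) and assigns the lowest common ancestor
of their taxa.  The weighted mode, in the spirit of MEGAN's weighted LCA,
assigns the deepest taxon whose subtree accumulates at least a threshold
fraction (default 0.8) of the total hit weight, where each qualifying hit
contributes its bitscore (or 1 in count mode) to every taxon on its lineage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .formats import HitRecord
from .taxonomy import TaxonomyIndex

METHODS = ("BBH", "LCA", "SAP", "MAP")


@dataclass(frozen=True)
class Assignment:
    """One method's verdict for one sequence.

    ``taxon_id`` is ``None`` for a no-assignment result; ``confidence`` is a
    probability in [0, 1] where the method provides one (SAP/MAP posterior
    support), else ``None``.
    """

    sequence_id: str
    method: str
    taxon_id: str | None
    rank: str | None = None
    confidence: float | None = None
    dataset: str = ""
    notes: str = ""

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.confidence is not None and not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")

    @property
    def assigned(self) -> bool:
        return self.taxon_id is not None


def _with_rank(a: Assignment, taxonomy: TaxonomyIndex) -> Assignment:
    if a.taxon_id is None:
        return a
    return Assignment(
        sequence_id=a.sequence_id,
        method=a.method,
        taxon_id=a.taxon_id,
        rank=taxonomy.get(a.taxon_id).rank,
        confidence=a.confidence,
        dataset=a.dataset,
        notes=a.notes,
    )


def bbh_assign(
    hits: Sequence[HitRecord],
    taxonomy: TaxonomyIndex,
    *,
    tie_mode: str = "lca",
    dataset: str = "",
) -> Assignment:
    """Best-BLAST-hit assignment for one query's hits.

    Ties at the top bitscore are detected on the printed score string
    (BLAST rounds scores, so exact string equality is the faithful test).
    ``tie_mode='lca'`` resolves a multi-taxon tie to the tied taxa's lowest
    common ancestor; ``tie_mode='strict'`` returns no assignment instead.
    """
    if tie_mode not in ("lca", "strict"):
        raise ValueError(f"tie_mode must be 'lca' or 'strict', got {tie_mode!r}")
    recs = [h for h in hits if h.staxid is not None]
    if not recs:
        qid = hits[0].qseqid if hits else ""
        return Assignment(qid, "BBH", None, dataset=dataset, notes="no hits")
    qid = recs[0].qseqid
    top_score = max(h.bitscore for h in recs)
    top = [h for h in recs if h.bitscore == top_score]
    # refine the tie set by printed score string when available
    raw = {h.bitscore_raw for h in top if h.bitscore_raw}
    if len(raw) > 1:
        # distinct printed strings at equal float value: not a printed tie
        top = [top[0]]
    tied_taxa = {h.staxid for h in top}
    if len(tied_taxa) == 1:
        (tid,) = tied_taxa
        return _with_rank(
            Assignment(qid, "BBH", tid, dataset=dataset), taxonomy
        )
    if tie_mode == "strict":
        return Assignment(
            qid, "BBH", None, dataset=dataset,
            notes=f"{len(tied_taxa)} distinct taxa tied at top score",
        )
    lca = taxonomy.lowest_common_ancestor(tied_taxa)
    return _with_rank(
        Assignment(qid, "BBH", lca.id, dataset=dataset, notes="tie resolved to LCA"),
        taxonomy,
    )


def lca_assign(
    hits: Sequence[HitRecord],
    taxonomy: TaxonomyIndex,
    *,
    min_identity: float = 95.0,
    weighted: bool = True,
    weight_threshold: float = 0.8,
    weight_mode: str = "bitscore",
    dataset: str = "",
) -> Assignment:
    """(Weighted) lowest-common-ancestor assignment for one query's hits.

    Qualifying hits are those with ``pident >= min_identity``.  Naive mode
    returns the LCA of their taxa.  Weighted mode accumulates each
    qualifying hit's weight (its bitscore, or 1 with
    ``weight_mode='count'``) along the hit taxon's whole lineage and returns
    the deepest taxon holding at least ``weight_threshold`` of the total
    weight — a taxon keeps the assignment only if enough of the evidence
    lies inside its subtree, which makes the weighted result a
    descendant-or-self of the naive LCA.
    """
    if not (0.0 < weight_threshold <= 1.0):
        raise ValueError(f"weight_threshold must be in (0, 1], got {weight_threshold}")
    if weight_mode not in ("bitscore", "count"):
        raise ValueError(f"weight_mode must be 'bitscore' or 'count'")
    qid = hits[0].qseqid if hits else ""
    qualifying = [
        h for h in hits if h.staxid is not None and h.pident >= min_identity
    ]
    if not qualifying:
        return Assignment(
            qid, "LCA", None, dataset=dataset,
            notes=f"no hits at >= {min_identity}% identity",
        )
    if not weighted:
        lca = taxonomy.lowest_common_ancestor(h.staxid for h in qualifying)
        return _with_rank(Assignment(qid, "LCA", lca.id, dataset=dataset), taxonomy)

    # accumulate weight along each hit taxon's lineage
    acc: dict[str, float] = {}
    total = 0.0
    for h in qualifying:
        w = h.bitscore if weight_mode == "bitscore" else 1.0
        total += w
        for t in taxonomy.lineage(h.staxid):
            acc[t.id] = acc.get(t.id, 0.0) + w
    needed = weight_threshold * total
    eps = 1e-9 * total
    candidates = [tid for tid, w in acc.items() if w >= needed - eps]
    # deepest qualifying taxon; for thresholds > 0.5 the candidates form a
    # single root-to-taxon chain, so depth alone decides; deterministic
    # weight/id tie-break covers low thresholds
    best = max(
        candidates,
        key=lambda tid: (taxonomy.depth(tid), acc[tid], tid),
    )
    return _with_rank(Assignment(qid, "LCA", best, dataset=dataset), taxonomy)
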