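"""Consensus assignments and their summary tables.

A sequence receives a consensus assignment when at least two of the three
voting methods — LCA, SAP and MAP — name the identical taxon.  BBH never
votes: its top-score heuristic is too permissive to arbitrate.  Consensus
calls above the phylum ceiling (Metazoa, Bilateria, unranked superphylum
clades) identify no plausible prey and are dropped.  Within a dataset,
repeated consensus calls to one taxon collapse into a single nonredundant
record carrying its multiplicity.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from ._util import round_half_up
from .similarity_assign import Assignment
from .taxonomy import (
    ABOVE_PHYLUM_DEPTH,
    CANONICAL_RANKS,
    RANK_DEPTH,
    TaxonomyIndex,
)

VOTING_METHODS = ("LCA", "SAP", "MAP")


@dataclass(frozen=True)
class ConsensusAssignment:
    """A 2-of-3 agreement among the voting methods for one sequence."""

    sequence_id: str
    dataset: str
    taxon_id: str | None
    rank: str | None = None
    supporting_methods: tuple[str, ...] = ()

    def __post_init__(self):
        if self.taxon_id is not None and len(self.supporting_methods) < 2:
            raise ValueError("a consensus needs at least two supporting methods")
        if "BBH" in self.supporting_methods:
            raise ValueError("BBH cannot support a consensus")

    @property
    def assigned(self) -> bool:
        return self.taxon_id is not None


def consensus_assign(
    assignments: Sequence[Assignment],
    taxonomy: TaxonomyIndex,
    *,
    compatible: bool = False,
) -> ConsensusAssignment:
    """Combine one sequence's per-method assignments into a consensus.

    Agreement means exact taxon identity by default.  With
    ``compatible=True``, an ancestor/descendant pair also counts as
    agreement and the consensus is the more rootward of the two.  Absent
    assignments never support; BBH is ignored entirely.  A 2-2 split is
    impossible with three voters, so majority is unambiguous.
    """
    votes: dict[str, str] = {}
    dataset = ""
    seq_id = ""
    for a in assignments:
        if a.sequence_id:
            seq_id = a.sequence_id
        if a.dataset:
            dataset = a.dataset
        if a.method in VOTING_METHODS and a.assigned:
            votes[a.method] = a.taxon_id
    if len(votes) >= 2:
        counts = Counter(votes.values())
        taxon, n = counts.most_common(1)[0]
        if n >= 2:
            supporters = tuple(m for m in VOTING_METHODS if votes.get(m) == taxon)
            return ConsensusAssignment(
                seq_id, dataset, taxon, taxonomy.get(taxon).rank, supporters
            )
        if compatible:
            methods = list(votes)
            for i in range(len(methods)):
                for j in range(i + 1, len(methods)):
                    a_t, b_t = votes[methods[i]], votes[methods[j]]
                    if taxonomy.is_within(a_t, b_t):
                        return ConsensusAssignment(
                            seq_id, dataset, b_t, taxonomy.get(b_t).rank,
                            (methods[i], methods[j]),
                        )
                    if taxonomy.is_within(b_t, a_t):
                        return ConsensusAssignment(
                            seq_id, dataset, a_t, taxonomy.get(a_t).rank,
                            (methods[i], methods[j]),
                        )
    return ConsensusAssignment(seq_id, dataset, None)


def drop_uninformative(
    consensus: Iterable[ConsensusAssignment],
    taxonomy: TaxonomyIndex,
    max_rank: str = "phylum",
) -> list[ConsensusAssignment]:
    """Remove consensus calls more rootward than ``max_rank``.

    Unranked clades are placed by their nearest canonical ancestor, so a
    superphylum-level clade (e.g. Lophotrochozoa) falls above the default
    phylum ceiling and is dropped, while an unranked clade inside an order
    is kept.  Unassigned records pass through untouched.
    """
    if max_rank not in RANK_DEPTH:
        raise ValueError(f"max_rank must be one of {CANONICAL_RANKS}")
    ceiling = RANK_DEPTH[max_rank]
    out: list[ConsensusAssignment] = []
    for c in consensus:
        if not c.assigned:
            out.append(c)
            continue
        if taxonomy.effective_rank_depth(c.taxon_id) <= ceiling:
            out.append(c)
    return out


@dataclass(frozen=True)
class NonredundantRecord:
    dataset: str
    taxon_id: str
    rank: str | None
    count: int


def nonredundant(
    consensus: Iterable[ConsensusAssignment],
) -> list[NonredundantRecord]:
    """Collapse repeated consensus taxa within each dataset, keeping
    multiplicity as a count; order follows first appearance."""
    counts: dict[tuple[str, str], list] = {}
    for c in consensus:
        if not c.assigned:
            continue
        key = (c.dataset, c.taxon_id)
        if key in counts:
            counts[key][1] += 1
        else:
            counts[key] = [c.rank, 1]
    return [
        NonredundantRecord(dataset=d, taxon_id=t, rank=v[0], count=v[1])
        for (d, t), v in counts.items()
    ]


@dataclass
class RankCountTable:
    """Counts of consensus assignments per canonical rank per dataset, with
    global per-rank percentages (2 decimals, half-up)."""

    counts: dict[str, dict[str, int]]  # rank -> dataset -> count
    datasets: tuple[str, ...]

    def rank_totals(self) -> dict[str, int]:
        return {r: sum(per_ds.values()) for r, per_ds in self.counts.items()}

    def dataset_totals(self) -> dict[str, int]:
        out = {d: 0 for d in self.datasets}
        for per_ds in self.counts.values():
            for d, n in per_ds.items():
                out[d] = out.get(d, 0) + n
        return out

    @property
    def total(self) -> int:
        return sum(self.rank_totals().values())

    def percentages(self) -> dict[str, float]:
        tot = self.total
        if tot == 0:
            return {r: 0.0 for r in self.counts}
        return {
            r: round_half_up(100.0 * n / tot) for r, n in self.rank_totals().items()
        }

    def pct_at_or_below(self, rank: str) -> float:
        """Share of assignments at ``rank`` or a more specific rank."""
        ceiling = RANK_DEPTH[rank]
        tot = self.total
        if tot == 0:
            return 0.0
        n = sum(
            cnt
            for r, per_ds in self.counts.items()
            for cnt in per_ds.values()
            if r in RANK_DEPTH and RANK_DEPTH[r] <= ceiling
        )
        return round_half_up(100.0 * n / tot)


def rank_count_table(
    consensus: Iterable[ConsensusAssignment],
    taxonomy: TaxonomyIndex,
    datasets: Sequence[str] | None = None,
) -> RankCountTable:
    """Tabulate assigned consensus records by canonical rank and dataset.

    Unranked taxa are counted under the canonical rank nearest their
    effective depth (one step less specific, i.e. their nearest canonical
    ancestor's rank is used for reporting)."""
    assigned = [c for c in consensus if c.assigned]
    ds = tuple(datasets) if datasets is not None else tuple(
        dict.fromkeys(c.dataset for c in assigned)
    )
    counts: dict[str, dict[str, int]] = {r: {} for r in CANONICAL_RANKS}
    for c in assigned:
        rank = c.rank if c.rank in RANK_DEPTH else taxonomy.nearest_canonical_rank(
            c.taxon_id
        )
        if rank is None:
            continue
        counts.setdefault(rank, {})
        counts[rank][c.dataset] = counts[rank].get(c.dataset, 0) + 1
    return RankCountTable(counts=counts, datasets=ds)


def order_level_summary(
    consensus: Iterable[ConsensusAssignment],
    taxonomy: TaxonomyIndex,
    *,
    group_by: Mapping[str, str] | None = None,
) -> dict[str, dict[str, float]]:
    """Per-group order-rank profile of consensus assignments.

    Each assigned consensus taxon is lifted to its order-rank ancestor;
    taxa above order are excluded (they cannot be lifted).  ``group_by``
    maps dataset -> group label (e.g. predator species); defaults to the
    dataset itself.  Counts are scaled to the most abundant order within
    the group, so the top order reads 1.0.
    """
    raw: dict[str, Counter] = {}
    for c in consensus:
        if not c.assigned:
            continue
        order = taxonomy.ancestor_at_rank(c.taxon_id, "order")
        if order is None:
            continue
        group = group_by.get(c.dataset, c.dataset) if group_by else c.dataset
        raw.setdefault(group, Counter())[order.id] += 1
    out: dict[str, dict[str, float]] = {}
    for group, counter in raw.items():
        peak = max(counter.values())
        out[group] = {o: n / peak for o, n in counter.items()}
    return out
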