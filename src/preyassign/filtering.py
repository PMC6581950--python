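"""Three-step filter reducing assembled scaffolds to informative sequences.

The pipeline keeps only scaffolds that can plausibly be identified:

1. the scaffold has at least one BLAST hit at all;
2. it has at least one hit longer than ``min_length`` aligned columns at
   ``min_identity`` percent identity or better (the "95 x 200" rule);
3. it is not on a manual blacklist of known-conflicting sequences
   (cloning/suicide vectors, mis-annotated database entries).

The report mirrors the per-dataset / per-step count table such studies
print: per-step removal percentages over the pooled datasets and the
percentage of sequences remaining from the start.
"""

from __future__ import annotations

import fnmatch
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from ._util import round_half_up
from .formats import HitTable, QuerySequence

STEP_NAMES = ("has_hit", "informative", "blacklist")


def step1_has_hit(
    queries: Sequence[QuerySequence], hits: HitTable
) -> list[QuerySequence]:
    """Keep queries that have at least one hit record."""
    return [q for q in queries if q.id in hits]


def step2_informative(
    queries: Sequence[QuerySequence],
    hits: HitTable,
    min_identity: float = 95.0,
    min_length: int = 200,
    *,
    strict_length: bool = True,
) -> list[QuerySequence]:
    """Keep queries with >= 1 hit at ``min_identity`` or better whose
    alignment is longer than ``min_length`` columns.

    "Longer than" is strict by default (a 200-column hit fails a 200
    threshold); ``strict_length=False`` switches to >= for sensitivity
    analysis.
    """
    if not (0.0 < min_identity <= 100.0):
        raise ValueError(f"min_identity must be in (0, 100], got {min_identity}")

    def qualifies(h) -> bool:
        if h.pident < min_identity:
            return False
        return h.length > min_length if strict_length else h.length >= min_length

    return [q for q in queries if any(qualifies(h) for h in hits.hits_for(q.id))]


@dataclass(frozen=True)
class Blacklist:
    """Manual purge list: query ids, subject-id glob patterns, taxon ids.

    File format is one entry per line with an ``id:``, ``pattern:`` or
    ``taxid:`` prefix; blank lines and ``#`` comments are ignored.
    """

    query_ids: frozenset[str] = frozenset()
    sseqid_patterns: tuple[str, ...] = ()
    taxon_ids: frozenset[str] = frozenset()

    @classmethod
    def from_file(cls, path) -> "Blacklist":
        qids: set[str] = set()
        pats: list[str] = []
        taxids: set[str] = set()
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                if line.startswith("id:"):
                    qids.add(line[3:].strip())
                elif line.startswith("pattern:"):
                    pats.append(line[len("pattern:"):].strip())
                elif line.startswith("taxid:"):
                    taxids.add(line[len("taxid:"):].strip())
                else:
                    raise ValueError(
                        f"{path}:line {lineno}: blacklist entry needs an "
                        f"'id:', 'pattern:' or 'taxid:' prefix: {line!r}"
                    )
        return cls(frozenset(qids), tuple(pats), frozenset(taxids))

    def __bool__(self) -> bool:
        return bool(self.query_ids or self.sseqid_patterns or self.taxon_ids)


def _best_hit(hits: HitTable, qseqid: str):
    recs = hits.hits_for(qseqid)
    if not recs:
        return None
    return max(recs, key=lambda h: h.bitscore)


def step3_blacklist(
    queries: Sequence[QuerySequence],
    blacklist: Blacklist,
    hits: HitTable | None = None,
) -> list[QuerySequence]:
    """Drop queries matching any blacklist entry: the query id listed, its
    best hit's subject id matching a glob pattern, or its best hit's taxon
    listed."""
    if not blacklist:
        return list(queries)
    out: list[QuerySequence] = []
    for q in queries:
        if q.id in blacklist.query_ids:
            continue
        best = _best_hit(hits, q.id) if hits is not None else None
        if best is not None:
            if any(
                fnmatch.fnmatch(best.sseqid, pat) for pat in blacklist.sseqid_patterns
            ):
                continue
            if best.staxid is not None and best.staxid in blacklist.taxon_ids:
                continue
        out.append(q)
    return out


def run_filter(
    queries: Sequence[QuerySequence],
    hits: HitTable,
    *,
    min_identity: float = 95.0,
    min_length: int = 200,
    strict_length: bool = True,
    blacklist: Blacklist | None = None,
) -> tuple[list[QuerySequence], list[int]]:
    """Apply the full three-step filter in its fixed order.

    Returns the survivors and the count vector
    ``[input, after step 1, after step 2, after step 3]``.
    """
    counts = [len(queries)]
    s1 = step1_has_hit(queries, hits)
    counts.append(len(s1))
    s2 = step2_informative(
        s1, hits, min_identity=min_identity, min_length=min_length,
        strict_length=strict_length,
    )
    counts.append(len(s2))
    s3 = step3_blacklist(s2, blacklist or Blacklist(), hits)
    counts.append(len(s3))
    return s3, counts


@dataclass
class FilterReport:
    """Per-dataset and pooled counts after each filter step, plus the
    derived percentages (2 decimals, half-up)."""

    datasets: dict[str, list[int]]
    step_labels: tuple[str, ...] = ("input",) + STEP_NAMES

    @property
    def totals(self) -> list[int]:
        n_steps = len(next(iter(self.datasets.values())))
        return [
            sum(counts[k] for counts in self.datasets.values())
            for k in range(n_steps)
        ]

    @property
    def pct_removed_by_step(self) -> list[float | None]:
        """Percent of each step's entry pool that the step removed, pooled
        over datasets; ``None`` where a step had an empty entry pool."""
        tot = self.totals
        out: list[float | None] = []
        for k in range(len(tot) - 1):
            if tot[k] == 0:
                out.append(None)
            else:
                out.append(round_half_up(100.0 * (tot[k] - tot[k + 1]) / tot[k]))
        return out

    @property
    def pct_remaining_from_start(self) -> list[float | None]:
        """Percent of the initial pool remaining after each step."""
        tot = self.totals
        if tot[0] == 0:
            return [None] * (len(tot) - 1)
        return [round_half_up(100.0 * t / tot[0]) for t in tot[1:]]

    @property
    def pct_eliminated_total(self) -> float | None:
        tot = self.totals
        if tot[0] == 0:
            return None
        return round_half_up(100.0 * (tot[0] - tot[-1]) / tot[0])

    def to_rows(self) -> list[list]:
        """TSV-ready rows: one per dataset, a TOTAL row, then percentage
        rows (``n/a`` for undefined percentages)."""

        def fmt(p):
            return "n/a" if p is None else f"{p:.2f}"

        rows: list[list] = [["dataset", *self.step_labels]]
        for name, counts in self.datasets.items():
            rows.append([name, *counts])
        rows.append(["TOTAL", *self.totals])
        rows.append(["% removed by step", "-", *[fmt(p) for p in self.pct_removed_by_step]])
        rows.append(
            ["% remaining from start", "-", *[fmt(p) for p in self.pct_remaining_from_start]]
        )
        return rows


def summarize_filtering(counts_per_dataset: Mapping[str, Sequence[int]]) -> FilterReport:
    """Build a :class:`FilterReport` from per-dataset count vectors
    (input count followed by survivors of each step).

    Counts must be non-negative and non-increasing within each dataset,
    and every dataset must report the same number of steps.
    """
    datasets = {k: list(v) for k, v in counts_per_dataset.items()}
    if not datasets:
        raise ValueError("no datasets")
    lengths = {len(v) for v in datasets.values()}
    if len(lengths) != 1:
        raise ValueError("datasets report different numbers of steps")
    (n,) = lengths
    if n < 2:
        raise ValueError("need at least an input count and one step")
    for name, counts in datasets.items():
        if any(c < 0 for c in counts):
            raise ValueError(f"negative count in dataset {name!r}")
        if any(a < b for a, b in zip(counts, counts[1:])):
            raise ValueError(f"counts increase across steps in dataset {name!r}")
    labels = ("input",) + tuple(
        STEP_NAMES[: n - 1]
        if n - 1 <= len(STEP_NAMES)
        else STEP_NAMES + tuple(f"step{k}" for k in range(len(STEP_NAMES) + 1, n))
    )
    return FilterReport(datasets=datasets, step_labels=labels)
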