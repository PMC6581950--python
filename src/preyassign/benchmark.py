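"""Method-performance statistics.

Four quantities summarise how the assignment methods behave on one study:

* agreement with the consensus — how often a method named exactly the taxon
  the 2-of-3 consensus settled on (denominator: sequences with a consensus);
* pairwise agreement — how often two methods named the same taxon over the
  whole sequence universe (an absent assignment counts as disagreement);
* the Identification Resolution (IR) index — a weighted mean of assignment
  ranks, species weighted highest, measuring how specific a method's calls
  are; methods are compared with a Mann-Whitney U test on per-item scores;
* individual-based rarefaction of prey orders — the expected number of
  distinct orders in a random subsample of n assignments, computed with the
  exact hypergeometric formula and extrapolated beyond the observed sample
  by seeded multinomial resampling.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import gammaln
from scipy.stats import mannwhitneyu

from ._util import round_half_up
from .consensus import ConsensusAssignment
from .similarity_assign import Assignment
from .taxonomy import RANK_DEPTH, TaxonomyIndex

#: Rank weights for the IR index.  Species carries the maximum (5) and the
#: weights decrease with coarser resolution.  The intermediate values
#: (superfamily 2.5, class 1, phylum 0.5) interpolate that published scheme
#: and are configurable.
DEFAULT_RANK_WEIGHTS: dict[str, float] = {
    "species": 5.0,
    "genus": 4.0,
    "family": 3.0,
    "superfamily": 2.5,
    "order": 2.0,
    "class": 1.0,
    "phylum": 0.5,
}


# ---------------------------------------------------------------------------
# Agreement


def agreement_with_consensus(
    method_assignments: Mapping[str, str | None],
    consensus: Sequence[ConsensusAssignment],
) -> tuple[int, float | None]:
    """Count method calls identical to the consensus taxon.

    ``method_assignments`` maps sequence id -> taxon id (or ``None``).
    Only sequences that actually received a consensus assignment enter the
    denominator.  Returns ``(matches, percent)``; percent is ``None`` when
    no consensus exists.
    """
    with_consensus = [c for c in consensus if c.assigned]
    if not with_consensus:
        return 0, None
    matches = sum(
        1
        for c in with_consensus
        if method_assignments.get(c.sequence_id) == c.taxon_id
    )
    return matches, round_half_up(100.0 * matches / len(with_consensus))


def agreement_from_counts(matches: int, consensus_count: int) -> float | None:
    """Percent agreement from already-tabulated counts (2 decimals)."""
    if consensus_count == 0:
        return None
    return round_half_up(100.0 * matches / consensus_count)


def pairwise_agreement(
    assignments_by_method: Mapping[str, Mapping[str, str | None]],
    universe: Sequence[str],
    *,
    ndigits: int = 0,
) -> dict[tuple[str, str], float]:
    """Symmetric percent-agreement matrix over the full sequence universe.

    Two methods agree on a sequence iff both assigned it and named the same
    taxon; a missing assignment on either side is a disagreement.  Percents
    are rounded to ``ndigits`` (0, integer percent, matches the precision
    such studies print).
    """
    methods = list(assignments_by_method)
    n = len(universe)
    out: dict[tuple[str, str], float] = {}
    for i, m1 in enumerate(methods):
        for m2 in methods[i:]:
            if n == 0:
                pct = 0.0
            else:
                a1 = assignments_by_method[m1]
                a2 = assignments_by_method[m2]
                k = sum(
                    1
                    for s in universe
                    if a1.get(s) is not None and a1.get(s) == a2.get(s)
                )
                pct = round_half_up(100.0 * k / n, ndigits)
            out[(m1, m2)] = pct
            out[(m2, m1)] = pct
    return out


# ---------------------------------------------------------------------------
# Identification Resolution index


@dataclass
class IRResult:
    mean: float
    sd: float
    se: float
    scores: list[float]

    @property
    def n(self) -> int:
        return len(self.scores)


def ir_scores(
    assignments: Iterable[Assignment | ConsensusAssignment],
    taxonomy: TaxonomyIndex,
    weights: Mapping[str, float] | None = None,
) -> list[float]:
    """Per-item IR scores: each assigned item scores its rank's weight.

    Unranked taxa take the weight of the nearest canonical ancestor rank;
    unassigned items are excluded.  A taxon with neither a weighted rank
    nor a canonical ancestor raises."""
    w = dict(DEFAULT_RANK_WEIGHTS if weights is None else weights)
    _validate_weights(w)
    scores: list[float] = []
    for a in assignments:
        tid = a.taxon_id
        if tid is None:
            continue
        rank = taxonomy.get(tid).rank
        if rank not in w:
            rank = taxonomy.nearest_canonical_rank(tid)
            if rank is None or rank not in w:
                raise ValueError(
                    f"taxon {tid!r} has no weighted rank on its lineage"
                )
        scores.append(w[rank])
    return scores


def _validate_weights(w: Mapping[str, float]) -> None:
    ordered = [w[r] for r in RANK_DEPTH if r in w]
    if any(nxt >= prev for prev, nxt in zip(ordered, ordered[1:])):
        raise ValueError(
            "rank weights must strictly decrease from species toward phylum"
        )


def ir_index(
    assignments: Iterable[Assignment | ConsensusAssignment],
    taxonomy: TaxonomyIndex,
    weights: Mapping[str, float] | None = None,
) -> IRResult:
    """Mean IR score with its SD and standard error (SD uses the n-1
    denominator; SE = SD / sqrt(n))."""
    scores = ir_scores(assignments, taxonomy, weights)
    return ir_from_scores(scores)


def ir_from_scores(scores: Sequence[float]) -> IRResult:
    if not scores:
        raise ValueError("no scored assignments")
    arr = np.asarray(scores, dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    se = sd / math.sqrt(len(arr))
    return IRResult(mean=mean, sd=sd, se=se, scores=list(map(float, arr)))


def compare_ir(
    scores_a: Sequence[float], scores_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test on two IR score vectors."""
    if not len(scores_a) or not len(scores_b):
        raise ValueError("empty score vector")
    res = mannwhitneyu(scores_a, scores_b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Rarefaction


def _log_comb(n: float, k: float) -> float:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def rarefaction_expected(category_counts: Sequence[int], n: int) -> float:
    """Exact expected richness in a random subsample of ``n`` of the N
    individuals: E[S_n] = sum_i (1 - C(N - N_i, n) / C(N, n))."""
    counts = [c for c in category_counts if c > 0]
    N = sum(counts)
    if n < 0 or n > N:
        raise ValueError(f"subsample size {n} outside [0, {N}]")
    if n == 0:
        return 0.0
    total = 0.0
    for Ni in counts:
        if N - Ni < n:
            total += 1.0
        else:
            total += 1.0 - math.exp(_log_comb(N - Ni, n) - _log_comb(N, n))
    return total


def rarefaction_curve(
    labels: Sequence[str],
    sizes: Sequence[int],
    *,
    n_boot: int = 1000,
    seed: int | None = None,
) -> list[tuple[int, float]]:
    """Expected-richness curve over a grid of subsample sizes.

    Sizes within the observed sample use the exact hypergeometric
    expectation; sizes beyond it are extrapolated by drawing ``n_boot``
    seeded multinomial samples from the observed category proportions and
    averaging the distinct-category count.
    """
    counter = Counter(labels)
    counts = list(counter.values())
    N = sum(counts)
    rng = np.random.default_rng(seed)
    probs = np.asarray(counts, dtype=float) / N if N else None
    curve: list[tuple[int, float]] = []
    for n in sizes:
        if n <= N:
            curve.append((n, rarefaction_expected(counts, n)))
        else:
            if probs is None:
                raise ValueError("cannot extrapolate from an empty sample")
            draws = rng.multinomial(n, probs, size=n_boot)
            richness = (draws > 0).sum(axis=1)
            curve.append((n, float(richness.mean())))
    return curve


# ---------------------------------------------------------------------------
# Report container


@dataclass
class BenchmarkReport:
    """Per-method benchmark summary for one study."""

    consensus_count: int
    universe_size: int
    agreement: dict[str, tuple[int, float | None]]
    pairwise: dict[tuple[str, str], float]
    ir: dict[str, IRResult]

    def to_rows(self) -> list[list]:
        rows: list[list] = [
            ["metric", "method", "value"],
            ["sequences", "-", self.universe_size],
            ["consensus_assignments", "-", self.consensus_count],
        ]
        for m, (k, pct) in self.agreement.items():
            rows.append(["agreement_matches", m, k])
            rows.append(["agreement_pct", m, "n/a" if pct is None else f"{pct:.2f}"])
        for (m1, m2), pct in sorted(self.pairwise.items()):
            if m1 < m2:
                rows.append(["pairwise_pct", f"{m1}-{m2}", f"{pct:g}"])
        for m, ir in self.ir.items():
            rows.append(["ir_mean", m, f"{ir.mean:.2f}"])
            rows.append(["ir_sd", m, f"{ir.sd:.2f}"])
            rows.append(["ir_se", m, f"{ir.se:.2f}"])
        return rows


def benchmark(
    assignments_by_method: Mapping[str, Mapping[str, str | None]],
    consensus: Sequence[ConsensusAssignment],
    universe: Sequence[str],
    taxonomy: TaxonomyIndex,
    weights: Mapping[str, float] | None = None,
) -> BenchmarkReport:
    """Full benchmark: per-method consensus agreement, pairwise agreement
    matrix, and IR statistics (consensus itself included as method 'CA')."""
    agreement = {
        m: agreement_with_consensus(calls, consensus)
        for m, calls in assignments_by_method.items()
    }
    pairwise = pairwise_agreement(assignments_by_method, universe)
    ir: dict[str, IRResult] = {}
    for m, calls in assignments_by_method.items():
        scored = [
            Assignment(s, m if m in ("BBH", "LCA", "SAP", "MAP") else "LCA", t)
            for s, t in calls.items()
            if t is not None
        ]
        if scored:
            ir[m] = ir_index(scored, taxonomy, weights)
    assigned_consensus = [c for c in consensus if c.assigned]
    if assigned_consensus:
        ir["CA"] = ir_index(assigned_consensus, taxonomy, weights)
    return BenchmarkReport(
        consensus_count=len(assigned_consensus),
        universe_size=len(universe),
        agreement=agreement,
        pairwise=pairwise,
        ir=ir,
    )
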