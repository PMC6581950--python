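# Methods

## Scope and data model

`preyassign` operates strictly downstream of the heavy external tools. BLAST
searches, multiple alignment, alignment trimming and Bayesian tree inference
are not re-implemented; the package consumes their standard outputs (12-column
tabular hits, Newick tree samples and supported consensus trees) together
with a ranked taxonomy supplied as a TSV lineage table (`taxid parent_taxid
rank name`, one root row). The canonical rank ladder used for reporting is
species < genus < family < superfamily < order < class < phylum. Taxa with
any other rank label ("no rank", "clade", "suborder", …) are kept in the
hierarchy — assignments to clades such as Laniatores are legitimate and
common — and are *unranked* for reporting: their effective position is one
step more specific than their nearest canonical ancestor, and they take that
ancestor's rank for rank counts and IR weights. An unranked taxon with no
canonical ancestor below the root (Metazoa, Bilateria, Lophotrochozoa) sits
above phylum and is treated as uninformative for diet purposes.

## Filtering

Three steps in fixed order, each a pure function of the hit table:

1. *has-hit*: the scaffold has ≥ 1 BLAST hit.
2. *informative*: ≥ 1 hit with `pident ≥ 95` **and** alignment length
   strictly `> 200` columns. "Longer than" is read strictly; a flag switches
   to ≥ for sensitivity analysis. The test uses BLAST's aligned-column
   length, not query or subject length, because the criterion is a per-hit
   property.
3. *blacklist*: reproducible automation of a manual curation step. The
   blacklist file holds one entry per line with an `id:` (query id),
   `pattern:` (glob on the best hit's subject id) or `taxid:` (best hit's
   taxon) prefix.

Report percentages (per-step removal over the pooled datasets, survival from
the start) are rounded half-up to 2 decimals, matching the precision such
count tables are printed at.

## Assignment methods

**BBH.** The taxon of the hit with the highest bitscore. Because BLAST
prints rounded scores, ties are detected by exact printed-string equality,
not by an epsilon on floats. A multi-taxon tie resolves, by default, to the
lowest common ancestor of the tied taxa; a `strict` tie mode returns no
assignment instead. Both behaviors are defensible readings of common
practice and the default is the more informative one; the mode is exposed on
the CLI. BBH is known to prefer a longer alignment at equal identity, which
is precisely the failure mode the benchmark quantifies.

**Weighted LCA.** Qualifying hits are those with `pident ≥ 95`. In naive
mode the assignment is the LCA of their taxa. In weighted mode (default)
each qualifying hit contributes its bitscore (or 1, in count mode) to every
taxon on its lineage, and the assignment is the deepest taxon holding at
least `w = 0.8` of the total weight. For any `w > 0.5` the candidates form a
single root-to-leaf chain, so the deepest is unique; for smaller thresholds
the tie-break is deterministic (depth, then accumulated weight, then taxon
id). This subtree-weight-fraction rule is our own concrete formulation of
"weighted LCA" binning — the implementations in established binning tools
are not fully specified in their papers — chosen because it is exactly
testable against an exhaustive-search oracle and shares the conservative
character of those tools. The weighted result is always a descendant-or-self
of the naive LCA, and raising `w` can only move it rootward; both facts are
enforced by property tests.

**Homologue selection.** Tree-based assignment uses up to 50 database
subjects chosen to maximise taxonomic dispersion: subjects are interleaved
hierarchically down the taxonomy (every sister group at each level
contributes one subject before any contributes two; within a terminal taxon
higher bitscores go first). Fewer than 5 distinct subjects aborts tree-based
assignment for that query — too few homologues to support tree inference.

**Midpoint rooting.** Both tree methods midpoint-root before reading clades
off the tree: it is deterministic and needs no outgroup. The implementation
is the classic two-sweep diameter search; the root is placed half way along
the diameter path, splitting an edge or landing on an existing node. Ties
from zero-length branches resolve toward the first edge encountered on the
path (deterministic traversal). A zero-diameter tree has no metric midpoint;
it is left on its existing (topological) root with a warning. Clade supports
are keyed by the bipartition they describe (the leaf-set side not containing
a fixed reference leaf) and re-attached after rerooting, so a support never
migrates to a different split. One intrinsic ambiguity remains: in a rooted
binary tree the two children of the root describe the same bipartition, so
supports printed on both must agree (they do in MrBayes-style output).

**SAP-style assignment.** Each sampled tree is midpoint-rooted; the clade
sister to the query (all other children of its parent, so a query hanging
off the root uses the root's other side) is annotated with the LCA of its
leaf taxa. PP(t) is the fraction of trees whose sister annotation lies
*within* t (membership, the default) or *is exactly* t (`exact` mode, which
is stricter and never credits a parent taxon). The assignment is the deepest
taxon with PP ≥ 0.95; the threshold is inclusive, with a 1e-12 tolerance so
that a tally of exactly 95% of the trees passes despite float division. PP
is non-decreasing along any lineage toward the root and reaches 1 at the
root; these are tested invariants. Multi-tree Newick readers expose a
`burnin_frac` to drop the leading fraction of an MCMC sample.

**MAP-style assignment.** On one midpoint-rooted tree carrying supports,
walk from the query leaf rootward and stop at the first node with support
≥ 0.95 — the smallest well-supported clade containing the query ("most
terminal" read as smallest). The assignment is the LCA of that clade's
non-query leaves, with the node's support as confidence. Reaching the root
without a supported node, or a tree with no supports at all, yields no
assignment (with distinct diagnostics).

## Consensus and summaries

A consensus exists when at least two of LCA, SAP and MAP name the *identical*
taxon; BBH never votes. Exact identity is the default because the two natural
worked examples of the rule both use it; a `compatible` mode (ancestor/
descendant counts as agreement, the more rootward taxon wins) is available
but off by default. With three voters a 2-2 split is impossible, so no
further tie-breaking is needed. Consensus calls above the phylum ceiling are
dropped; within a dataset, repeated calls to one taxon collapse to one
nonredundant record with a multiplicity count. Rank-count tables report
global per-rank percentages at 2 decimals (half-up). Order-level summaries
lift each consensus taxon to its order-rank ancestor (taxa above order are
excluded as unliftable) and scale counts to the most abundant order per
group.

## Benchmarks

*Agreement with consensus* counts method calls identical to the consensus
taxon; only sequences with a consensus enter the denominator. *Pairwise
agreement* uses the full filtered-sequence universe, counting an absent
assignment on either side as disagreement, and is printed at integer
precision. *IR index*: each assigned item scores its rank's weight — species
5, genus 4, family 3, superfamily 2.5, order 2, class 1, phylum 0.5 — and a
method's IR is the mean score with SD and SE (SD uses the n−1 denominator).
The sub-family weights (2.5 / 1 / 0.5) are an interpolation of the published
"5, 4, 3, …" scheme, chosen once because they reproduce the reference
consensus IR of 3.30 from the published rank totals; all weights are
configurable and reports state the scheme used. Both SD and SE are reported
because published "±" values are ambiguous between the two. Method IRs are
compared with a two-sided Mann-Whitney U test (scipy).

*Rarefaction* uses the exact hypergeometric expectation
E[S_n] = Σ_i (1 − C(N−N_i, n)/C(N, n)) inside the observed sample
(computed in log-space via gammaln) and extrapolates beyond N by drawing
R = 1000 seeded multinomial samples from the observed order proportions and
averaging the distinct-order count. The closed-form extrapolators used by
dedicated richness software would also work; the bootstrap is simpler,
seeded, and accurate at these sample sizes (tens to low hundreds of
assignments).

## Synthetic studies

The generator produces exactly what the pipeline consumes — hit tables,
posterior tree samples, supported consensus trees, plus FASTA, lineage and
truth tables — for queries with known source species. It emulates evidence
*post-BLAST*: no reads, no chimeras, no sequence evolution.

* **Taxonomy**: balanced, with configurable fan-outs per level (default
  2×2×2×2×2×2×3 = 192 species).
* **Database completeness** per query: `true-species-present`,
  `congener-only`, `confamilial-only` or `absent`. Subjects are drawn
  per relatedness tier with identities same-species 97–100%, congener
  90–97%, confamilial 80–92%, distant 60–80% (uniform; our construct,
  configurable), and bitscores proportional to identity × length as BLAST's
  are. Under `absent`, every identity falls below the 95% floor, so the
  informative-sequence filter removes the query — the designed behavior.
  The congener-only and confamilial-only scenarios require at least two
  species in the target group: a single relative cannot represent "the
  genus minus the query", and tree annotation would degenerate to that one
  species. Subject picks cover distinct species first, mirroring the
  dispersion-maximising homologue selection.
* **Trees**: subjects are arranged on a taxonomy-faithful topology, with
  non-distant subjects and distant subjects on opposite long stems so the
  midpoint root always falls between them. A fraction *f* (tree fidelity)
  of the T sampled trees attach the query sister to the deepest clade of
  its true lineage the database allows; the rest attach it on a uniformly
  random edge. The consensus tree is the faithful topology with supports
  equal to observed clade frequencies across the sample. The default
  T = 100 trees per query is a desk-scale stand-in for the thousands an
  MCMC run yields; it resolves a 0.95 threshold with granularity 0.01.
* **Determinism**: all randomness flows from the single config seed; equal
  configs regenerate byte-identical directories, and the scenario config is
  embedded in the output for provenance.

What passing synthetic tests shows: the pipeline's logic is correct —
faithful trees plus a complete database yield 100% species-rank consensus
recovery, congener-only databases can never push a consensus to a wrong
species inside the true genus, and zero-fidelity trees never reach a
species-rank posterior. What it does not show: robustness to alignment
error, model misspecification in tree inference, chimeric assemblies,
database mislabeling or uneven taxon sampling, all of which real studies
face and which enter upstream of this package's inputs.

## Problem sizes

The test suite runs entirely at desk scale (seconds): tree samples of 10–60
trees, studies of 4–20 queries, 20-seed recovery batteries with 2 queries
each. The acceptance script additionally runs one full-layout synthetic
study — six datasets totalling 241 queries, 50 trees per query — through the
complete pipeline (about a minute on one core).

## Known limitations

* The weighted-LCA rule and the sub-family IR weights are explicit
  reconstructions (documented above), not re-implementations of any
  specific external tool's internals.
* SAP membership ("within" vs "exact") subtly changes PP tables; the default
  is "within", the more permissive reading, with the alternative one flag
  away.
* Supports on the two root-adjacent edges of a rooted binary input tree are
  conflated (same bipartition).
* The final expert-curation step of a real study — screening consensus
  assignments for biogeographic plausibility — is intentionally not
  automated; the pipeline emits the candidate tables for human review.
* Extrapolated rarefaction values are bootstrap means, so they carry
  Monte-Carlo noise of order 1/√R; the interpolated branch is exact.
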