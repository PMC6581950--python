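"""Tree-based taxonomic assignment from Bayesian tree samples.

Two methods share one phylogenetic core.  Both start from a set of database
homologues of the query (chosen to maximise taxonomic dispersion, up to 50;
fewer than 5 distinct homologues aborts tree-based assignment) and a tree or
tree sample inferred over homologues + query.

*Posterior-sample assignment* ("SAP"-style): over a sample of trees from the
posterior, each tree is midpoint-rooted and the clade sister to the query is
annotated with the lowest common ancestor of its leaf taxa.  The posterior
probability of the query belonging to a taxon t is the fraction of trees
whose sister-clade annotation lies within t.  The assignment is the deepest
taxon reaching PP >= 0.95 (inclusive).

*Single-tree assignment* ("MAP"-style): on one midpoint-rooted tree carrying
clade supports, walk from the query leaf toward the root; the first node
with support >= 0.95 defines the smallest well-supported clade containing
the query, and the assignment is the LCA of that clade's other leaves.

Midpoint rooting is deterministic and outgroup-free, which is why both
methods use it.  Supports are tied to bipartitions (not node identities) so
they survive rerooting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy

from .formats import HitRecord, PhyloTree, TreeSample, node_support
from .similarity_assign import Assignment, _with_rank
from .taxonomy import TaxonomyIndex

DEFAULT_PP_THRESHOLD = 0.95
MIN_HOMOLOGUES = 5
MAX_HOMOLOGUES = 50
_EPS = 1e-12


# ---------------------------------------------------------------------------
# Homologue selection


def select_homologues(
    hits: Sequence[HitRecord],
    taxonomy: TaxonomyIndex,
    *,
    max_n: int = MAX_HOMOLOGUES,
    min_n: int = MIN_HOMOLOGUES,
) -> list[str] | None:
    """Pick up to ``max_n`` subjects maximising taxonomic dispersion.

    Subjects are interleaved hierarchically: at every taxonomy level the
    selection round-robins across sister groups before taking a second
    subject from any one of them, so every represented family contributes a
    subject before any family contributes two.  Within a terminal taxon,
    higher-bitscore subjects go first.

    Returns ``None`` when fewer than ``min_n`` distinct subjects are
    available (tree-based assignment is then skipped).
    """
    best_per_subject: dict[str, HitRecord] = {}
    for h in hits:
        if h.staxid is None:
            continue
        prev = best_per_subject.get(h.sseqid)
        if prev is None or h.bitscore > prev.bitscore:
            best_per_subject[h.sseqid] = h
    if len(best_per_subject) < min_n:
        return None

    def order(recs: list[HitRecord], depth: int) -> list[HitRecord]:
        # group by the lineage element at `depth` (root is depth 0)
        groups: dict[str, list[HitRecord]] = {}
        terminal: list[HitRecord] = []
        for r in recs:
            lin = taxonomy.lineage(r.staxid)
            if len(lin) <= depth + 1:
                terminal.append(r)
            else:
                groups.setdefault(lin[depth + 1].id, []).append(r)
        ordered_terminal = sorted(terminal, key=lambda r: (-r.bitscore, r.sseqid))
        child_seqs = [
            order(g, depth + 1)
            for _, g in sorted(
                groups.items(),
                key=lambda kv: (-max(r.bitscore for r in kv[1]), kv[0]),
            )
        ]
        if ordered_terminal:
            child_seqs.append(ordered_terminal)
        # round-robin interleave of the child sequences
        out: list[HitRecord] = []
        i = 0
        while any(i < len(s) for s in child_seqs):
            for s in child_seqs:
                if i < len(s):
                    out.append(s[i])
            i += 1
        return out

    ranked = order(list(best_per_subject.values()), 0)
    return [r.sseqid for r in ranked[:max_n]]


# ---------------------------------------------------------------------------
# Midpoint rooting with bipartition-stable supports


def _leafset(node: dendropy.Node) -> frozenset[str]:
    return frozenset(
        lf.taxon.label for lf in node.leaf_iter() if lf.taxon is not None
    )


def _bipartition_key(
    clade: frozenset[str], all_leaves: frozenset[str], ref: str
) -> frozenset[str]:
    """Rooting-invariant key for the bipartition an internal edge induces:
    the side not containing a fixed reference leaf."""
    return all_leaves - clade if ref in clade else clade


def _collect_supports(tree: dendropy.Tree) -> dict[frozenset[str], float]:
    all_leaves = _leafset(tree.seed_node)
    ref = min(all_leaves)
    supports: dict[frozenset[str], float] = {}
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node is tree.seed_node:
            continue
        s = node_support(node)
        if s is None:
            continue
        supports[_bipartition_key(_leafset(node), all_leaves, ref)] = s
    return supports


def _restore_supports(
    tree: dendropy.Tree, supports: Mapping[frozenset[str], float]
) -> None:
    all_leaves = _leafset(tree.seed_node)
    ref = min(all_leaves)
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        if node is tree.seed_node:
            node.label = None
            continue
        key = _bipartition_key(_leafset(node), all_leaves, ref)
        s = supports.get(key)
        node.label = None if s is None else repr(s)


def _farthest_from(
    start: dendropy.Node, adjacency: Mapping[int, list]
) -> tuple[dict[int, float], dict[int, dendropy.Node], dendropy.Node]:
    """Single-source distances over the unrooted tree graph; returns the
    farthest *leaf* (first encountered on ties, deterministic traversal)."""
    dist: dict[int, float] = {id(start): 0.0}
    pred: dict[int, dendropy.Node] = {}
    best, best_d = start, 0.0
    stack = [start]
    while stack:
        node = stack.pop()
        d = dist[id(node)]
        if node.is_leaf() and d > best_d:
            best, best_d = node, d
        for nbr, w in adjacency[id(node)]:
            if id(nbr) not in dist:
                dist[id(nbr)] = d + w
                pred[id(nbr)] = node
                stack.append(nbr)
    return dist, pred, best


def midpoint_root(ptree: PhyloTree) -> PhyloTree:
    """Root a tree at the midpoint of its longest leaf-to-leaf path.

    The diameter path is found with the classic two-sweep search (farthest
    leaf from an arbitrary leaf, then farthest leaf from that); the root is
    placed on it half way, splitting an edge or sitting on an existing node
    when the midpoint falls exactly there.  Ties (zero-length branches on
    the path) resolve toward the first edge met walking the path, which the
    deterministic traversal order fixes.

    The input is not modified.  Clade supports are carried across the
    rerooting by bipartition, so a support stays with the split it
    describes.  A tree whose diameter is zero (all branch lengths zero)
    cannot define a metric midpoint; it is left rooted where it stands,
    with a warning.
    """
    tree = ptree.tree.clone(depth=1)
    for edge in tree.preorder_edge_iter():
        if edge.length is None:
            edge.length = 0.0
    supports = _collect_supports(tree)
    out = PhyloTree(
        tree=tree, leaf_taxa=dict(ptree.leaf_taxa), query_leaf=ptree.query_leaf
    )

    adjacency: dict[int, list] = {id(n): [] for n in tree.preorder_node_iter()}
    for node in tree.preorder_node_iter():
        for child in node.child_nodes():
            w = child.edge.length or 0.0
            adjacency[id(node)].append((child, w))
            adjacency[id(child)].append((node, w))
    leaves = [lf for lf in tree.leaf_node_iter()]
    if len(leaves) < 2:
        return out

    _, _, u = _farthest_from(leaves[0], adjacency)
    dist, pred, v = _farthest_from(u, adjacency)
    diameter = dist[id(v)]
    if diameter <= 0.0:
        warnings.warn(
            "tree diameter is zero; keeping the existing (topological) root",
            stacklevel=2,
        )
        _restore_supports(tree, supports)
        return out

    # path u -> v, then walk to the half-way point
    path = [v]
    while path[-1] is not u:
        path.append(pred[id(path[-1])])
    path.reverse()
    half = diameter / 2.0
    cum = 0.0
    for a, b in zip(path, path[1:]):
        w = next(wt for nbr, wt in adjacency[id(a)] if nbr is b)
        if cum + w >= half - 1e-12 * diameter:
            offset = half - cum  # distance from a into the (a, b) edge
            if offset <= 1e-12 * diameter and not a.is_leaf():
                tree.reroot_at_node(a, update_bipartitions=False)
            elif w - offset <= 1e-12 * diameter and not b.is_leaf():
                tree.reroot_at_node(b, update_bipartitions=False)
            else:
                # identify the parent->child orientation of the (a, b) edge
                if b.parent_node is a:
                    edge, tail_part, head_part = b.edge, offset, w - offset
                else:
                    edge, tail_part, head_part = a.edge, w - offset, offset
                tree.reroot_at_edge(
                    edge,
                    length1=tail_part,
                    length2=head_part,
                    update_bipartitions=False,
                )
            break
        cum += w
    _restore_supports(tree, supports)
    return out


# ---------------------------------------------------------------------------
# Clade annotation and the query's sister


def _find_query_node(ptree: PhyloTree) -> dendropy.Node:
    for lf in ptree.tree.leaf_node_iter():
        if lf.taxon is not None and lf.taxon.label == ptree.query_leaf:
            return lf
    raise ValueError(f"query leaf {ptree.query_leaf!r} not found in tree")


def annotate_clade(
    leaves: Iterable[str], ptree: PhyloTree, taxonomy: TaxonomyIndex
):
    """Taxonomic annotation of a set of leaves: the LCA of their taxa
    (query leaf excluded)."""
    taxa = [
        ptree.leaf_taxa[lab] for lab in leaves if lab != ptree.query_leaf
    ]
    if not taxa:
        return None
    return taxonomy.lowest_common_ancestor(taxa)


def sister_clade_leaves(ptree: PhyloTree) -> frozenset[str]:
    """Leaf labels of the clade sister to the query in a rooted tree.

    With the query a direct child of the root, the sister is the root's
    other child (or children, under a polytomy)."""
    q = _find_query_node(ptree)
    parent = q.parent_node
    if parent is None:
        raise ValueError("query leaf is the entire tree")
    labels: set[str] = set()
    for child in parent.child_nodes():
        if child is q:
            continue
        labels.update(_leafset(child))
    return frozenset(labels)


# ---------------------------------------------------------------------------
# SAP-style assignment from a posterior tree sample


@dataclass
class SapResult:
    """Posterior-sample assignment plus the per-taxon PP table behind it."""

    assignment: Assignment
    pp_table: dict[str, float]
    sister_annotations: list[str] = field(default_factory=list)


def sap_assign(
    sample: TreeSample,
    taxonomy: TaxonomyIndex,
    *,
    pp_threshold: float = DEFAULT_PP_THRESHOLD,
    membership: str = "within",
    dataset: str = "",
) -> SapResult:
    """Assign from a sample of posterior trees.

    Each tree is midpoint-rooted; the sister clade of the query is
    annotated with the LCA of its leaf taxa.  For every taxon on an
    observed annotation's lineage, PP(t) is the fraction of trees whose
    annotation lies within t (``membership='exact'`` instead demands the
    annotation be t itself).  The assignment is the deepest taxon with
    PP >= ``pp_threshold``; the threshold is inclusive.
    """
    if membership not in ("within", "exact"):
        raise ValueError("membership must be 'within' or 'exact'")
    n = len(sample)
    annotations: list[str] = []
    for pt in sample.trees:
        rooted = midpoint_root(pt)
        ann = annotate_clade(sister_clade_leaves(rooted), rooted, taxonomy)
        if ann is None:
            continue
        annotations.append(ann.id)
    qid = sample.trees[0].query_leaf
    if not annotations:
        return SapResult(
            Assignment(qid, "SAP", None, dataset=dataset, notes="no annotatable sister"),
            {},
        )
    candidates: set[str] = set()
    for a in set(annotations):
        candidates.update(t.id for t in taxonomy.lineage(a))
    pp: dict[str, float] = {}
    for t in candidates:
        if membership == "within":
            k = sum(1 for a in annotations if taxonomy.is_within(a, t))
        else:
            k = sum(1 for a in annotations if a == t)
        pp[t] = k / n
    passing = [t for t, p in pp.items() if p >= pp_threshold - _EPS]
    if not passing:
        return SapResult(
            Assignment(
                qid, "SAP", None, dataset=dataset,
                notes=f"no taxon at PP >= {pp_threshold}",
            ),
            pp,
            annotations,
        )
    best = max(passing, key=lambda t: (taxonomy.depth(t), pp[t], t))
    a = _with_rank(
        Assignment(qid, "SAP", best, confidence=pp[best], dataset=dataset),
        taxonomy,
    )
    return SapResult(a, pp, annotations)


# ---------------------------------------------------------------------------
# MAP-style assignment from a single supported tree


def map_assign(
    ptree: PhyloTree,
    taxonomy: TaxonomyIndex,
    *,
    pp_threshold: float = DEFAULT_PP_THRESHOLD,
    dataset: str = "",
) -> Assignment:
    """Assign from one tree carrying clade supports.

    After midpoint rooting, walk from the query leaf rootward and stop at
    the first node with support >= ``pp_threshold`` — the smallest
    well-supported clade containing the query.  The assignment is the LCA
    of that clade's non-query leaves, with the node's support as
    confidence.  Reaching the root without a supported node yields no
    assignment.
    """
    rooted = midpoint_root(ptree)
    qid = rooted.query_leaf
    node = _find_query_node(rooted).parent_node
    any_support = False
    while node is not None:
        s = node_support(node)
        if s is not None:
            any_support = True
            if s >= pp_threshold - _EPS:
                ann = annotate_clade(_leafset(node), rooted, taxonomy)
                if ann is None:
                    return Assignment(
                        qid, "MAP", None, dataset=dataset,
                        notes="supported clade contains only the query",
                    )
                return _with_rank(
                    Assignment(qid, "MAP", ann.id, confidence=s, dataset=dataset),
                    taxonomy,
                )
        node = node.parent_node
    note = (
        f"no clade on the query's root path at PP >= {pp_threshold}"
        if any_support
        else "no internal node carries a support value"
    )
    return Assignment(qid, "MAP", None, dataset=dataset, notes=note)
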