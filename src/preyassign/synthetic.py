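"""Ground-truth fixture generation for every pipeline stage.

The generator emulates the evidence a gut-content metagenomics study feeds
this toolkit — BLAST hit tables, posterior tree samples and supported
consensus trees — for queries whose true source taxon is known, so that
filtering, all four assignment methods, the consensus rule and the
benchmarks can be tested end to end without any external database.

Evidence is generated post-BLAST: the alignment, tree inference and search
stages are external tools whose *outputs* this package consumes, so the
fixtures target exactly those outputs.  Two dials control difficulty:

* database completeness per query — whether the true species, only
  congeners, only confamilials, or no relative at all is represented among
  the subjects;
* tree fidelity ``f`` — the fraction of sampled trees that place the query
  sister to the deepest clade of its true lineage that the database allows;
  the remaining trees attach the query uniformly at random.

Hit identities are drawn per relatedness tier (same species 97-100%,
congener 90-97%, confamilial 80-92%, distant 60-80%); bitscores grow with
identity x alignment length, as BLAST's do.  All randomness flows from the
single config seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .formats import (
    HitRecord,
    HitTable,
    PhyloTree,
    TreeSample,
    write_hits,
    write_lineage_table,
    write_newick,
)
from .taxonomy import CANONICAL_RANKS, Taxon, TaxonomyIndex

COMPLETENESS_LEVELS = (
    "true-species-present",
    "congener-only",
    "confamilial-only",
    "absent",
)

#: Dataset layout of the motivating study: six predator-locality datasets
#: with these many post-filter query sequences.
DEFAULT_DATASETS: dict[str, int] = {
    "ImSantoA": 13,
    "ImCubatao": 23,
    "CbSantoA": 37,
    "CbCubatao": 83,
    "CbCantareira": 38,
    "CbItatiaia": 47,
}


class ScenarioError(ValueError):
    """The requested scenario is impossible on the given taxonomy."""


@dataclass
class ScenarioConfig:
    """Knobs of one synthetic study.

    ``taxonomy_shape`` gives fan-outs per level from phylum down to species.
    ``tree_sample_size`` is the number of posterior trees per query; the
    default (100) is a desk-scale stand-in for the thousands an MCMC run
    yields and is enough to resolve a 0.95 posterior-probability threshold.
    """

    seed: int = 0
    taxonomy_shape: tuple[int, ...] = (2, 2, 2, 2, 2, 2, 3)
    datasets: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_DATASETS))
    completeness: str = "true-species-present"
    tree_sample_size: int = 100
    tree_fidelity: float = 1.0
    identity_tiers: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "same_species": (97.0, 100.0),
            "congener": (90.0, 97.0),
            "confamilial": (80.0, 92.0),
            "distant": (60.0, 80.0),
        }
    )
    subjects_per_tier: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {
            "same_species": (3, 6),
            "congener": (4, 8),
            "confamilial": (3, 6),
            "distant": (2, 4),
        }
    )

    def __post_init__(self):
        if not (0.0 <= self.tree_fidelity <= 1.0):
            raise ValueError("tree_fidelity must be in [0, 1]")
        if self.completeness not in COMPLETENESS_LEVELS:
            raise ValueError(f"completeness must be one of {COMPLETENESS_LEVELS}")
        if any(k < 1 for k in self.taxonomy_shape):
            raise ValueError("taxonomy fan-outs must be >= 1")
        tiers = self.identity_tiers
        order = ["same_species", "congener", "confamilial"]
        for hi, lo in zip(order, order[1:]):
            if tiers[hi][0] < tiers[lo][0]:
                raise ValueError("identity tiers must be ordered by relatedness")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["taxonomy_shape"] = list(d["taxonomy_shape"])
        return json.dumps(d, sort_keys=True, indent=1, default=list)


# ---------------------------------------------------------------------------
# Taxonomy generation

_LEVEL_PREFIX = ("p", "c", "o", "sf", "f", "g", "s")
_LEVEL_RANKS = tuple(reversed(CANONICAL_RANKS))  # phylum ... species


def generate_taxonomy(shape: Sequence[int]) -> TaxonomyIndex:
    """Balanced ranked taxonomy with the requested per-level fan-outs.

    ``shape`` lists children per node from phylum level down to species
    level (7 entries).  Ids encode the path (``p1.c2.o1...``) and are fully
    deterministic, so equal shapes give identical taxonomies.
    """
    if len(shape) != len(_LEVEL_RANKS):
        raise ValueError(f"shape needs {len(_LEVEL_RANKS)} fan-outs, got {len(shape)}")
    taxa: list[Taxon] = [Taxon("root", "root", "no rank", None)]

    def expand(parent_id: str, level: int) -> None:
        if level == len(shape):
            return
        for i in range(1, shape[level] + 1):
            tid = (
                f"{_LEVEL_PREFIX[level]}{i}"
                if parent_id == "root"
                else f"{parent_id}.{_LEVEL_PREFIX[level]}{i}"
            )
            taxa.append(Taxon(tid, tid.upper(), _LEVEL_RANKS[level], parent_id))
            expand(tid, level + 1)

    expand("root", 0)
    return TaxonomyIndex(taxa)


def species_ids(taxonomy: TaxonomyIndex) -> list[str]:
    return sorted(t.id for t in taxonomy if t.rank == "species")


# ---------------------------------------------------------------------------
# Per-query evidence


@dataclass
class QueryEvidence:
    query_id: str
    truth: str
    hits: list[HitRecord]
    subject_taxa: dict[str, str]
    sample: TreeSample
    consensus_tree: PhyloTree


def _relatives(taxonomy: TaxonomyIndex, truth: str) -> dict[str, list[str]]:
    """Species pools per relatedness tier for one truth species."""
    lin = {t.rank: t.id for t in taxonomy.lineage(truth) if t.rank in CANONICAL_RANKS}
    genus, family = lin["genus"], lin["family"]
    pools: dict[str, list[str]] = {
        "same_species": [truth],
        "congener": [],
        "confamilial": [],
        "distant": [],
    }
    for sp in species_ids(taxonomy):
        if sp == truth:
            continue
        if taxonomy.is_within(sp, genus):
            pools["congener"].append(sp)
        elif taxonomy.is_within(sp, family):
            pools["confamilial"].append(sp)
        else:
            pools["distant"].append(sp)
    return pools


_ALLOWED_TIERS = {
    "true-species-present": ("same_species", "congener", "confamilial", "distant"),
    "congener-only": ("congener", "confamilial", "distant"),
    "confamilial-only": ("confamilial", "distant"),
    "absent": ("distant",),
}


def _target_tier(completeness: str) -> str | None:
    return {
        "true-species-present": "same_species",
        "congener-only": "congener",
        "confamilial-only": "confamilial",
        "absent": None,
    }[completeness]


def _subtree_newick(
    labels_by_taxon: Mapping[str, list[str]],
    taxonomy: TaxonomyIndex,
    leaf_len: float,
    inner_len: float,
) -> str:
    """Taxonomy-shaped newick for a set of subjects (labels grouped by their
    species taxon), so every taxon forms a clean clade."""

    def rec(taxa: list[str], depth: int) -> str:
        groups: dict[str, list[str]] = {}
        for sp in taxa:
            lin = taxonomy.lineage(sp)
            key = lin[depth + 1].id if len(lin) > depth + 1 else sp
            groups.setdefault(key, []).append(sp)
        parts: list[str] = []
        for key in sorted(groups):
            members = groups[key]
            if len(members) == 1 and members[0] == key:
                labs = labels_by_taxon[key]
                if len(labs) == 1:
                    parts.append(f"{labs[0]}:{leaf_len}")
                else:
                    inner = ",".join(f"{l}:{leaf_len}" for l in labs)
                    parts.append(f"({inner}):{inner_len}")
            else:
                parts.append(rec(members, depth + 1))
        if len(parts) == 1:
            return parts[0]
        return f"({','.join(parts)}):{inner_len}"

    return rec(sorted(labels_by_taxon), 0)


def _insert_query(
    base: dendropy.Tree, query_label: str, target_leaves: frozenset[str] | None,
    rng: np.random.Generator,
) -> dendropy.Tree:
    """Clone the base tree and attach the query leaf either as sister to the
    clade spanning exactly ``target_leaves`` or on a uniformly random edge."""
    tree = base.clone(depth=1)
    if target_leaves is not None:
        node = None
        for n in tree.preorder_node_iter():
            leaves = frozenset(
                lf.taxon.label for lf in n.leaf_iter() if lf.taxon is not None
            )
            if leaves == target_leaves:
                node = n
                break
        if node is None:
            raise ScenarioError("target clade not present in base tree")
    else:
        candidates = [
            n for n in tree.preorder_node_iter() if n.parent_node is not None
        ]
        node = candidates[int(rng.integers(len(candidates)))]
    parent = node.parent_node
    length = node.edge.length or 0.1
    if parent is None:  # target is the whole tree: attach at root
        new_root = dendropy.Node()
        q = dendropy.Node()
        q.taxon = tree.taxon_namespace.require_taxon(label=query_label)
        q.edge.length = 0.1
        new_root.add_child(node)
        node.edge.length = 0.1
        new_root.add_child(q)
        tree.seed_node = new_root
    else:
        parent.remove_child(node)
        joint = dendropy.Node()
        joint.edge.length = length / 2
        node.edge.length = length / 2
        q = dendropy.Node()
        q.taxon = tree.taxon_namespace.require_taxon(label=query_label)
        q.edge.length = 0.1
        joint.add_child(node)
        joint.add_child(q)
        parent.add_child(joint)
    return tree


def _clade_sets(tree: dendropy.Tree) -> set[frozenset[str]]:
    out: set[frozenset[str]] = set()
    for n in tree.preorder_node_iter():
        if n.is_leaf() or n.parent_node is None:
            continue
        out.add(
            frozenset(lf.taxon.label for lf in n.leaf_iter() if lf.taxon is not None)
        )
    return out


def generate_query_evidence(
    query_id: str,
    truth: str,
    taxonomy: TaxonomyIndex,
    config: ScenarioConfig,
    rng: np.random.Generator,
    *,
    completeness: str | None = None,
) -> QueryEvidence:
    """Hit rows, a posterior tree sample and a supported consensus tree for
    one query with a known source taxon."""
    completeness = completeness or config.completeness
    if completeness not in COMPLETENESS_LEVELS:
        raise ScenarioError(f"unknown completeness {completeness!r}")
    pools = _relatives(taxonomy, truth)
    allowed = _ALLOWED_TIERS[completeness]
    target_tier = _target_tier(completeness)
    for tier in allowed[:-1]:
        if not pools[tier]:
            raise ScenarioError(
                f"{completeness!r} impossible: no {tier} species for {truth!r} "
                "(e.g. a monotypic genus)"
            )
    if target_tier in ("congener", "confamilial") and len(pools[target_tier]) < 2:
        raise ScenarioError(
            f"{completeness!r} needs >= 2 {target_tier} species for {truth!r}; "
            "a single relative cannot stand in for the whole group"
        )

    # choose subjects per tier; distinct species go first within a tier
    # (mirrors the dispersion-maximising homologue selection of real runs)
    subject_taxa: dict[str, str] = {}
    tier_of: dict[str, str] = {}
    counter = 0
    for tier in allowed:
        lo, hi = config.subjects_per_tier[tier]
        n = int(rng.integers(lo, hi + 1))
        pool = pools[tier]
        if not pool:
            continue
        picks = list(rng.permutation(pool)[: min(n, len(pool))])
        while len(picks) < n:
            picks.append(pool[int(rng.integers(len(pool)))])
        for sp in picks:
            label = f"{query_id}_s{counter}"
            counter += 1
            subject_taxa[label] = str(sp)
            tier_of[label] = tier

    # hit rows: identity from the tier, bitscore grows with identity x length
    hits: list[HitRecord] = []
    for label in subject_taxa:
        lo, hi = config.identity_tiers[tier_of[label]]
        pident = round(float(rng.uniform(lo, hi)), 2)
        length = int(rng.integers(250, 801))
        bits = round(2.0 * length * pident / 100.0, 1)
        hits.append(
            HitRecord(
                qseqid=query_id,
                sseqid=label,
                pident=pident,
                length=length,
                mismatch=int(round(length * (100.0 - pident) / 100.0)),
                gapopen=0,
                qstart=1,
                qend=length,
                sstart=1,
                send=length,
                evalue=1e-30,
                bitscore=bits,
                staxid=subject_taxa[label],
                bitscore_raw=f"{bits:.1f}",
            )
        )

    # base tree: ingroup (non-distant) and distant group on long stems, so
    # the midpoint root always falls between them
    labels_by_taxon: dict[str, list[str]] = {}
    for label, sp in subject_taxa.items():
        labels_by_taxon.setdefault(sp, []).append(label)
    ingroup_taxa = {
        sp: labs
        for sp, labs in labels_by_taxon.items()
        if any(tier_of[l] != "distant" for l in labs)
    }
    distant_taxa = {
        sp: labs for sp, labs in labels_by_taxon.items() if sp not in ingroup_taxa
    }

    def stem(group: Mapping[str, list[str]]) -> str:
        inner = _subtree_newick(group, taxonomy, 0.1, 0.1)
        if inner.endswith(":0.1"):
            return inner[: -len(":0.1")] + ":2.0"
        return f"({inner}):2.0"

    if ingroup_taxa and distant_taxa:
        nwk = f"({stem(ingroup_taxa)},{stem(distant_taxa)});"
    else:
        only = ingroup_taxa or distant_taxa
        nwk = f"({_subtree_newick(only, taxonomy, 0.1, 0.1)});"
    base = dendropy.Tree.get(
        data=nwk, schema="newick", preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )

    target_tier = _target_tier(completeness)
    target: frozenset[str] | None = None
    if target_tier is not None:
        target = frozenset(
            lab for lab, t in tier_of.items() if t == target_tier
        )
        if not target:
            target = None

    # sampled trees: ceil(f*T) faithful placements, the rest random
    T = config.tree_sample_size
    n_faithful = int(np.ceil(config.tree_fidelity * T)) if target is not None else 0
    trees: list[PhyloTree] = []
    for i in range(T):
        t = _insert_query(
            base, query_id, target if i < n_faithful else None, rng
        )
        trees.append(PhyloTree(tree=t, leaf_taxa=dict(subject_taxa), query_leaf=query_id))
    sample = TreeSample(trees)

    # consensus tree: the faithful topology (or the first sampled one when
    # nothing faithful exists) with supports = observed clade frequencies
    clade_counts: dict[frozenset[str], int] = {}
    for pt in trees:
        for cl in _clade_sets(pt.tree):
            clade_counts[cl] = clade_counts.get(cl, 0) + 1
    cons = (
        _insert_query(base, query_id, target, rng)
        if target is not None
        else trees[0].tree.clone(depth=1)
    )
    for n in cons.preorder_node_iter():
        if n.is_leaf():
            continue
        if n.parent_node is None:
            n.label = None
            continue
        cl = frozenset(
            lf.taxon.label for lf in n.leaf_iter() if lf.taxon is not None
        )
        n.label = repr(clade_counts.get(cl, 0) / T)
    consensus_tree = PhyloTree(
        tree=cons, leaf_taxa=dict(subject_taxa), query_leaf=query_id
    )
    return QueryEvidence(
        query_id=query_id,
        truth=truth,
        hits=hits,
        subject_taxa=subject_taxa,
        sample=sample,
        consensus_tree=consensus_tree,
    )


# ---------------------------------------------------------------------------
# Whole-study generation


@dataclass
class StudyFixture:
    config: ScenarioConfig
    taxonomy: TaxonomyIndex
    truth: dict[str, str]  # query id -> true species
    dataset_of: dict[str, str]  # query id -> dataset
    evidence: dict[str, QueryEvidence]
    subject_taxa: dict[str, str]

    def hit_table(self, dataset: str | None = None) -> HitTable:
        recs: list[HitRecord] = []
        for qid, ev in self.evidence.items():
            if dataset is None or self.dataset_of[qid] == dataset:
                recs.extend(ev.hits)
        return HitTable(recs)


def generate_study(
    config: ScenarioConfig, out_dir: str | Path | None = None
) -> StudyFixture:
    """Generate a full multi-dataset fixture; optionally write it to disk.

    The on-disk layout mirrors what the pipeline consumes: a lineage TSV,
    per-dataset FASTA + hit TSV, per-query multi-tree Newick samples and a
    supported consensus tree, a subject->taxon map and a truth table.
    Everything derives from ``config.seed``, so equal configs regenerate
    byte-identical output.
    """
    rng = np.random.default_rng(config.seed)
    taxonomy = generate_taxonomy(config.taxonomy_shape)
    pool = species_ids(taxonomy)
    truth: dict[str, str] = {}
    dataset_of: dict[str, str] = {}
    evidence: dict[str, QueryEvidence] = {}
    subject_taxa: dict[str, str] = {}
    for ds, n_queries in config.datasets.items():
        for k in range(n_queries):
            qid = f"q_{ds}_{k:03d}"
            sp = pool[int(rng.integers(len(pool)))]
            ev = generate_query_evidence(qid, sp, taxonomy, config, rng)
            truth[qid] = sp
            dataset_of[qid] = ds
            evidence[qid] = ev
            subject_taxa.update(ev.subject_taxa)
    fixture = StudyFixture(
        config=config,
        taxonomy=taxonomy,
        truth=truth,
        dataset_of=dataset_of,
        evidence=evidence,
        subject_taxa=subject_taxa,
    )
    if out_dir is not None:
        _write_study(fixture, Path(out_dir), rng)
    return fixture


_BASES = np.array(list("ACGT"))


def _write_study(fx: StudyFixture, out: Path, rng: np.random.Generator) -> None:
    out.mkdir(parents=True, exist_ok=True)
    (out / "scenario.json").write_text(fx.config.to_json() + "\n")
    write_lineage_table(out / "lineage.tsv", fx.taxonomy)
    with open(out / "truth.tsv", "w") as fh:
        fh.write("query\tdataset\ttrue_taxon\n")
        for qid in fx.truth:
            fh.write(f"{qid}\t{fx.dataset_of[qid]}\t{fx.truth[qid]}\n")
    with open(out / "subject_taxa.tsv", "w") as fh:
        fh.write("sseqid\ttaxid\n")
        for s, t in sorted(fx.subject_taxa.items()):
            fh.write(f"{s}\t{t}\n")
    for ds in fx.config.datasets:
        ds_dir = out / ds
        (ds_dir / "trees").mkdir(parents=True, exist_ok=True)
        qids = [q for q, d in fx.dataset_of.items() if d == ds]
        with open(ds_dir / "queries.fasta", "w") as fh:
            for qid in qids:
                seq = "".join(_BASES[rng.integers(0, 4, int(rng.integers(250, 901)))])
                fh.write(f">{qid}\n{seq}\n")
        write_hits(
            ds_dir / "hits.tsv",
            [h for qid in qids for h in fx.evidence[qid].hits],
        )
        for qid in qids:
            write_newick(ds_dir / "trees" / f"{qid}.sample.nwk", fx.evidence[qid].sample)
            write_newick(ds_dir / "trees" / f"{qid}.map.nwk", fx.evidence[qid].consensus_tree)
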