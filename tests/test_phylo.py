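"""Homologue selection, midpoint rooting, and tree-based assignment."""

import itertools

import dendropy
import numpy as np
import pytest

from preyassign.formats import PhyloTree, TreeSample, node_support, read_newick
from preyassign.phylo_assign import (
    map_assign,
    midpoint_root,
    sap_assign,
    select_homologues,
    sister_clade_leaves,
)

from test_formats import make_hit


def load(tmp_path, nwk, leaf_taxa, query, name="t.nwk"):
    p = tmp_path / name
    p.write_text(nwk + "\n")
    return read_newick(p, leaf_taxa, query)


def leaf_root_distances(pt: PhyloTree) -> dict[str, float]:
    pt.tree.calc_node_root_distances()
    return {
        lf.taxon.label: lf.root_distance
        for lf in pt.tree.leaf_node_iter()
        if lf.taxon is not None
    }


# ---------------------------------------------------------------------------
# Homologue selection


class TestSelectHomologues:
    def test_fewer_than_five_distinct_subjects_is_insufficient(self, mini_taxonomy):
        hits = [
            make_hit(sseqid=f"s{i}", staxid="p_ornatus", bitscore=900.0 - i)
            for i in range(4)
        ]
        assert select_homologues(hits, mini_taxonomy) is None

    def test_fifty_subjects_one_species_all_returned(self, mini_taxonomy):
        hits = [
            make_hit(sseqid=f"s{i}", staxid="c_bergi", bitscore=1000.0 - i)
            for i in range(50)
        ]
        got = select_homologues(hits, mini_taxonomy)
        assert got is not None and len(got) == 50
        assert set(got) == {f"s{i}" for i in range(50)}

    def test_cap_at_max_n(self, mini_taxonomy):
        hits = [
            make_hit(sseqid=f"s{i}", staxid="c_bergi", bitscore=1000.0 - i)
            for i in range(80)
        ]
        assert len(select_homologues(hits, mini_taxonomy)) == 50

    def test_round_robin_across_families(self, mini_taxonomy, rng):
        """Three families in three phyla, 30 subjects each: the selection
        interleaves them, so every family appears in the first three picks
        and the first 3k picks hold exactly k per family."""
        fam_species = {
            "gonyleptidae": ["p_ornatus", "p_bellus", "p_thorellii"],
            "geoplanidae": ["i_marcusi", "c_bergi", "obama_sp"],
            "rhinodrilidae": ["p_corethrurus", "p_spiralis"],
        }
        hits = []
        i = 0
        for fam, species in fam_species.items():
            for k in range(30):
                hits.append(
                    make_hit(
                        sseqid=f"{fam}_{k}",
                        staxid=species[k % len(species)],
                        bitscore=float(rng.uniform(500, 1500)),
                    )
                )
                i += 1
        got = select_homologues(hits, mini_taxonomy)
        assert len(got) == 50
        fam_of = lambda s: s.rsplit("_", 1)[0]
        picks = [fam_of(s) for s in got]
        # every family contributes before any family contributes twice
        first = {f: picks.index(f) for f in fam_species}
        second = {
            f: picks.index(f, picks.index(f) + 1) for f in fam_species
        }
        assert max(first.values()) < min(second.values())
        # and the final selection is far from single-family dominated
        assert all(picks.count(f) >= 12 for f in fam_species)

    def test_within_taxon_higher_bitscore_first(self, mini_taxonomy):
        hits = [
            make_hit(sseqid="low", staxid="c_bergi", bitscore=100.0),
            make_hit(sseqid="high", staxid="c_bergi", bitscore=900.0),
            make_hit(sseqid="mid", staxid="c_bergi", bitscore=500.0),
        ] + [
            make_hit(sseqid=f"pad{i}", staxid="i_marcusi", bitscore=50.0)
            for i in range(3)
        ]
        got = select_homologues(hits, mini_taxonomy)
        order = [s for s in got if s in ("low", "mid", "high")]
        assert order == ["high", "mid", "low"]


# ---------------------------------------------------------------------------
# Midpoint rooting

LT4 = {"A": "p_ornatus", "B": "p_bellus", "C": "c_albus", "D": "b_mori"}


class TestMidpointRoot:
    def test_two_leaf_arithmetic(self, tmp_path):
        pt = load(tmp_path, "(A:1.0,B:3.0);", {"A": "p_ornatus"}, query="B")
        rooted = midpoint_root(pt)
        d = leaf_root_distances(rooted)
        assert d["A"] == pytest.approx(2.0)
        assert d["B"] == pytest.approx(2.0)

    def test_idempotent_on_already_rooted_tree(self, tmp_path):
        pt = load(tmp_path, "((A:1,B:2):1,(C:1,D:2):1);", LT4, query="D")
        once = midpoint_root(pt)
        twice = midpoint_root(once)
        assert leaf_root_distances(once) == pytest.approx(leaf_root_distances(twice))

    @pytest.mark.parametrize("seed", range(6))
    def test_max_root_depth_is_half_diameter(self, tmp_path, seed):
        """All-pairs oracle: on random trees the deepest leaf sits at half
        the tree diameter from the midpoint root."""
        import networkx as nx

        rng = np.random.default_rng(500 + seed)
        n_leaves = int(rng.integers(4, 10))
        labels = [f"L{i}" for i in range(n_leaves)]
        nwk = random_newick(labels, rng)
        pt = load(tmp_path, nwk, {l: "p_ornatus" for l in labels[:-1]}, query=labels[-1])
        rooted = midpoint_root(pt)
        # independent all-pairs path lengths on the unrooted graph
        g = nx.Graph()
        for node in pt.tree.preorder_node_iter():
            if node.parent_node is not None:
                g.add_edge(id(node.parent_node), id(node), weight=node.edge.length)
        name_of = {
            id(lf): lf.taxon.label
            for lf in pt.tree.leaf_node_iter()
        }
        dists = dict(nx.all_pairs_dijkstra_path_length(g, weight="weight"))
        leaf_ids = list(name_of)
        diameter = max(
            dists[a][b] for a, b in itertools.combinations(leaf_ids, 2)
        )
        depths = leaf_root_distances(rooted)
        assert max(depths.values()) == pytest.approx(diameter / 2.0)

    def test_zero_diameter_warns_and_keeps_root(self, tmp_path):
        pt = load(tmp_path, "((A:0,B:0):0,(C:0,D:0):0);", LT4, query="D")
        with pytest.warns(UserWarning, match="diameter"):
            rooted = midpoint_root(pt)
        assert sorted(rooted.leaf_labels()) == ["A", "B", "C", "D"]

    def test_supports_follow_their_bipartitions(self, tmp_path):
        """Rerooting moves nodes around; each support must stay with the
        split it measures, found by leafset after rooting."""
        lt = {**LT4, "E": "i_marcusi", "F": "c_bergi"}
        nwk = "(((A:1,B:1)0.9:1,C:1)0.7:1,(D:6,E:1)0.8:1,F:1);"
        pt = load(tmp_path, nwk, lt, query="F")
        rooted = midpoint_root(pt)
        got = {}
        for node in rooted.tree.preorder_node_iter():
            if node.is_leaf():
                continue
            leaves = frozenset(
                lf.taxon.label for lf in node.leaf_iter() if lf.taxon is not None
            )
            s = node_support(node)
            if s is not None:
                got[leaves] = s
        assert got[frozenset("AB")] == pytest.approx(0.9)
        assert got[frozenset("ABC")] == pytest.approx(0.7)
        # the {D,E} split re-expresses as the complement clade {A,B,C,F}
        assert got[frozenset("ABCF")] == pytest.approx(0.8)

    def test_input_tree_not_modified(self, tmp_path):
        pt = load(tmp_path, "(A:1.0,B:3.0);", {"A": "p_ornatus"}, query="B")
        before = pt.tree.as_string(schema="newick")
        midpoint_root(pt)
        assert pt.tree.as_string(schema="newick") == before


def random_newick(labels, rng) -> str:
    """Random binary topology with random branch lengths."""

    def build(ls):
        if len(ls) == 1:
            return f"{ls[0]}:{rng.uniform(0.1, 5):.3f}"
        k = int(rng.integers(1, len(ls)))
        return (
            f"({build(ls[:k])},{build(ls[k:])}):{rng.uniform(0.1, 5):.3f}"
        )

    ls = list(labels)
    k = max(1, len(ls) // 2)
    return f"({build(ls[:k])},{build(ls[k:])});"


# ---------------------------------------------------------------------------
# SAP-style assignment

SAP_TAXA = {"A": "p_ornatus", "B": "p_bellus", "C": "c_albus", "D": "b_mori"}


def sap_tree(sister: str) -> str:
    """Tree whose query Q is sister to the named leaf; D is a distant
    outgroup on a long stem so the midpoint root separates it."""
    others = [l for l in "ABC" if l != sister]
    return (
        f"((((Q:0.1,{sister}:0.1):0.1,{others[0]}:0.1):0.1,{others[1]}:0.1):2.0,D:2.0);"
    )


def make_sample(tmp_path, composition: dict[str, int]) -> TreeSample:
    text = "".join(sap_tree(s) + "\n" for s, n in composition.items() for _ in range(n))
    p = tmp_path / "sample.nwk"
    p.write_text(text)
    got = read_newick(p, SAP_TAXA, query_leaf="Q")
    return got if isinstance(got, TreeSample) else TreeSample([got])


class TestSAP:
    def test_unanimous_sample_assigns_species_at_pp_one(self, tmp_path, mini_taxonomy):
        sample = make_sample(tmp_path, {"A": 10})
        res = sap_assign(sample, mini_taxonomy)
        assert res.assignment.taxon_id == "p_ornatus"
        assert res.assignment.confidence == pytest.approx(1.0)

    def test_split_within_genus_assigns_genus(self, tmp_path, mini_taxonomy):
        """96 of 100 sisters inside Promitobates, split so no species
        reaches 0.95 alone; 4 elsewhere: genus at PP 0.96."""
        sample = make_sample(tmp_path, {"A": 48, "B": 48, "C": 4})
        res = sap_assign(sample, mini_taxonomy)
        assert res.assignment.taxon_id == "promitobates"
        assert res.assignment.confidence == pytest.approx(0.96)
        # direct tally oracle
        assert res.pp_table["p_ornatus"] == pytest.approx(0.48)
        assert res.pp_table["promitobates"] == pytest.approx(0.96)

    def test_threshold_is_inclusive_at_exactly_095(self, tmp_path, mini_taxonomy):
        sample = make_sample(tmp_path, {"A": 50, "B": 45, "C": 5})
        res = sap_assign(sample, mini_taxonomy)
        assert res.pp_table["promitobates"] == pytest.approx(0.95)
        assert res.assignment.taxon_id == "promitobates"

    def test_below_threshold_no_assignment(self, tmp_path, mini_taxonomy):
        sample = make_sample(tmp_path, {"A": 50, "C": 50})
        res = sap_assign(sample, mini_taxonomy)
        # nothing below Arachnida reaches 0.95; arachnida itself does (1.0)
        assert res.assignment.taxon_id == "arachnida"

    def test_pp_monotone_toward_root_and_one_at_root(self, tmp_path, mini_taxonomy):
        sample = make_sample(tmp_path, {"A": 60, "B": 30, "C": 10})
        res = sap_assign(sample, mini_taxonomy)
        lineage = [t.id for t in mini_taxonomy.lineage("p_ornatus")]
        pps = [res.pp_table[t] for t in lineage if t in res.pp_table]
        assert all(a <= b + 1e-12 for b, a in zip(pps, pps[1:]))
        assert res.pp_table["root"] == pytest.approx(1.0)

    def test_exact_membership_mode_is_stricter(self, tmp_path, mini_taxonomy):
        sample = make_sample(tmp_path, {"A": 48, "B": 48, "C": 4})
        res = sap_assign(sample, mini_taxonomy, membership="exact")
        # sisters annotate to species, never to the genus itself
        assert res.pp_table.get("promitobates", 0.0) == pytest.approx(0.0)

    def test_sister_of_root_child_query(self, tmp_path, mini_taxonomy):
        pt = load(tmp_path, "(Q:5.0,(A:0.1,B:0.1):5.0);", SAP_TAXA, query="Q")
        rooted = midpoint_root(pt)
        assert sister_clade_leaves(rooted) == frozenset("AB")


# ---------------------------------------------------------------------------
# MAP-style assignment


class TestMAP:
    def test_supported_genus_clade(self, tmp_path, mini_taxonomy):
        """Query placed in a PP=1.0 clade whose other leaves are all one
        genus: assignment is that genus."""
        nwk = "(((Q:0.1,A:0.1,B:0.1)1.0:0.1,C:0.1)1.0:2.0,D:2.0);"
        pt = load(tmp_path, nwk, SAP_TAXA, query="Q")
        a = map_assign(pt, mini_taxonomy)
        assert a.taxon_id == "promitobates"
        assert a.confidence == pytest.approx(1.0)

    def test_walks_past_unsupported_parent(self, tmp_path, mini_taxonomy):
        """Parent clade at 0.80 is skipped; the 0.99 grandparent spanning
        one family gives the family at 0.99."""
        lt = {"A": "p_ornatus", "B": "p_thorellii", "C": "c_albus", "D": "b_mori"}
        nwk = "((((Q:0.1,A:0.1)0.80:0.1,B:0.1)0.99:0.1,C:0.1)1.0:2.0,D:2.0);"
        pt = load(tmp_path, nwk, lt, query="Q")
        a = map_assign(pt, mini_taxonomy)
        assert a.taxon_id == "gonyleptidae"
        assert a.confidence == pytest.approx(0.99)

    def test_star_tree_without_supports_gives_no_assignment(self, tmp_path, mini_taxonomy):
        pt = load(tmp_path, "(Q:1,A:1,B:1,C:1);", SAP_TAXA, query="Q")
        a = map_assign(pt, mini_taxonomy)
        assert not a.assigned
        assert "support" in a.notes

    def test_result_contains_sister_annotation(self, tmp_path, mini_taxonomy):
        """The assignment is always ancestor-or-self of the sister clade's
        own annotation in the same tree."""
        nwk = "((((Q:0.1,A:0.1)0.6:0.1,B:0.1)0.97:0.1,C:0.1)1.0:2.0,D:2.0);"
        pt = load(tmp_path, nwk, SAP_TAXA, query="Q")
        a = map_assign(pt, mini_taxonomy)
        rooted = midpoint_root(pt)
        from preyassign.phylo_assign import annotate_clade

        sister_ann = annotate_clade(sister_clade_leaves(rooted), rooted, mini_taxonomy)
        assert mini_taxonomy.is_within(sister_ann.id, a.taxon_id)

    def test_identical_sample_sap_equals_map(self, tmp_path, mini_taxonomy):
        nwk = "(((Q:0.1,A:0.1)1.0:0.1,B:0.1)1.0:2.0,D:2.0);"
        lt = {"A": "p_ornatus", "B": "p_bellus", "D": "b_mori"}
        pt = load(tmp_path, nwk, lt, query="Q")
        sample = TreeSample([pt] * 10)
        sap = sap_assign(sample, mini_taxonomy).assignment
        mp = map_assign(pt, mini_taxonomy)
        assert sap.taxon_id == mp.taxon_id == "p_ornatus"
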