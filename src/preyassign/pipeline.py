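"""End-to-end orchestration: filter -> assign x4 -> consensus -> benchmark.

Consumes a study directory in the layout :func:`preyassign.synthetic.generate_study`
writes (and which mirrors what a real study assembles by hand): a lineage
TSV, a subject->taxon map, and per-dataset FASTA + BLAST hits + per-query
tree files.  Produces plain-TSV artifacts plus a JSON run manifest recording
every threshold actually applied and the checksums of every input read.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from . import __version__
from .benchmark import DEFAULT_RANK_WEIGHTS, BenchmarkReport, benchmark, rarefaction_curve
from .consensus import (
    ConsensusAssignment,
    consensus_assign,
    drop_uninformative,
    nonredundant,
    order_level_summary,
    rank_count_table,
)
from .filtering import Blacklist, run_filter, summarize_filtering
from .formats import (
    PhyloTree,
    TreeSample,
    read_fasta,
    read_hits,
    read_lineage_table,
    read_newick,
    write_assignments,
)
from .phylo_assign import map_assign, sap_assign, select_homologues
from .similarity_assign import Assignment, bbh_assign, lca_assign


@dataclass
class RunConfig:
    """All knobs of one pipeline run."""

    input_dir: Path
    out_dir: Path
    min_identity: float = 95.0
    min_length: int = 200
    strict_length: bool = True
    pp_threshold: float = 0.95
    lca_weight_threshold: float = 0.8
    lca_weighted: bool = True
    bbh_tie_mode: str = "lca"
    rank_ceiling: str = "phylum"
    rank_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RANK_WEIGHTS)
    )
    blacklist_path: Path | None = None
    rarefaction_reps: int = 1000
    seed: int = 0

    def __post_init__(self):
        self.input_dir = Path(self.input_dir)
        self.out_dir = Path(self.out_dir)
        if not (0.0 < self.pp_threshold <= 1.0):
            raise ValueError("pp_threshold must be in (0, 1]")


@dataclass
class RunResult:
    filter_counts: dict[str, list[int]]
    assignments: list[Assignment]
    consensus: list[ConsensusAssignment]
    report: BenchmarkReport
    manifest: dict


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(path: Path, rows) -> None:
    with open(path, "w", newline="") as fh:
        csv.writer(fh, delimiter="\t", lineterminator="\n").writerows(rows)


def run_pipeline(config: RunConfig) -> RunResult:
    """Run the whole pipeline over a study directory.

    Missing tree files degrade gracefully: the affected sequences get no
    SAP/MAP assignment and the consensus falls back on the remaining
    voters.  Every applied threshold is logged in the manifest.
    """
    inp, out = config.input_dir, config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    checksums: dict[str, str] = {}

    taxonomy = read_lineage_table(inp / "lineage.tsv")
    checksums["lineage.tsv"] = _sha256(inp / "lineage.tsv")
    subject_map: dict[str, str] = {}
    with open(inp / "subject_taxa.tsv") as fh:
        next(fh)
        for line in fh:
            s, t = line.rstrip("\n").split("\t")
            subject_map[s] = t
    checksums["subject_taxa.tsv"] = _sha256(inp / "subject_taxa.tsv")
    blacklist = (
        Blacklist.from_file(config.blacklist_path)
        if config.blacklist_path
        else Blacklist()
    )

    datasets = sorted(p.name for p in inp.iterdir() if p.is_dir())
    filter_counts: dict[str, list[int]] = {}
    assignments: list[Assignment] = []
    consensus_list: list[ConsensusAssignment] = []
    per_method: dict[str, dict[str, str | None]] = {
        m: {} for m in ("BBH", "LCA", "SAP", "MAP")
    }
    universe: list[str] = []

    for ds in datasets:
        ds_dir = inp / ds
        queries = read_fasta(ds_dir / "queries.fasta", dataset=ds)
        checksums[f"{ds}/queries.fasta"] = _sha256(ds_dir / "queries.fasta")
        hits = read_hits(ds_dir / "hits.tsv", subject_map)
        checksums[f"{ds}/hits.tsv"] = _sha256(ds_dir / "hits.tsv")
        survivors, counts = run_filter(
            queries,
            hits,
            min_identity=config.min_identity,
            min_length=config.min_length,
            strict_length=config.strict_length,
            blacklist=blacklist,
        )
        filter_counts[ds] = counts

        for q in survivors:
            universe.append(q.id)
            qhits = hits.hits_for(q.id)
            per_seq: list[Assignment] = [
                bbh_assign(qhits, taxonomy, tie_mode=config.bbh_tie_mode, dataset=ds),
                lca_assign(
                    qhits,
                    taxonomy,
                    min_identity=config.min_identity,
                    weighted=config.lca_weighted,
                    weight_threshold=config.lca_weight_threshold,
                    dataset=ds,
                ),
            ]
            homologues = select_homologues(qhits, taxonomy)
            sample_path = ds_dir / "trees" / f"{q.id}.sample.nwk"
            map_path = ds_dir / "trees" / f"{q.id}.map.nwk"
            if homologues is None:
                note = "fewer than 5 homologues"
                per_seq.append(Assignment(q.id, "SAP", None, dataset=ds, notes=note))
                per_seq.append(Assignment(q.id, "MAP", None, dataset=ds, notes=note))
            else:
                if sample_path.exists():
                    sample = read_newick(sample_path, subject_map, q.id)
                    if isinstance(sample, PhyloTree):
                        sample = TreeSample([sample])
                    per_seq.append(
                        sap_assign(
                            sample, taxonomy,
                            pp_threshold=config.pp_threshold, dataset=ds,
                        ).assignment
                    )
                else:
                    per_seq.append(
                        Assignment(q.id, "SAP", None, dataset=ds, notes="no tree sample")
                    )
                if map_path.exists():
                    tree = read_newick(map_path, subject_map, q.id)
                    if isinstance(tree, TreeSample):
                        tree = tree.trees[0]
                    per_seq.append(
                        map_assign(
                            tree, taxonomy,
                            pp_threshold=config.pp_threshold, dataset=ds,
                        )
                    )
                else:
                    per_seq.append(
                        Assignment(q.id, "MAP", None, dataset=ds, notes="no tree")
                    )
            assignments.extend(per_seq)
            for a in per_seq:
                per_method[a.method][q.id] = a.taxon_id
            consensus_list.append(consensus_assign(per_seq, taxonomy))

    kept = drop_uninformative(consensus_list, taxonomy, max_rank=config.rank_ceiling)
    nr = nonredundant(kept)
    ranks = rank_count_table(kept, taxonomy, datasets=datasets)
    report = benchmark(per_method, kept, universe, taxonomy, config.rank_weights)

    # rarefaction of prey orders per dataset, from the LCA assignments
    rarefaction_rows: list[list] = [["dataset", "n", "expected_orders"]]
    for ds in datasets:
        orders: list[str] = []
        for a in assignments:
            if a.method == "LCA" and a.dataset == ds and a.assigned:
                o = taxonomy.ancestor_at_rank(a.taxon_id, "order")
                if o is not None:
                    orders.append(o.id)
        if not orders:
            continue
        n_max = max(len(orders) * 2, 10)
        grid = sorted({*range(1, len(orders) + 1), *range(len(orders), n_max + 1, 5)})
        curve = rarefaction_curve(
            orders, grid, n_boot=config.rarefaction_reps, seed=config.seed
        )
        rarefaction_rows.extend([ds, n, f"{e:.4f}"] for n, e in curve)

    # ---- write artifacts
    filter_report = summarize_filtering(filter_counts)
    _write_tsv(out / "filter_report.tsv", filter_report.to_rows())
    write_assignments(out / "assignments.tsv", assignments, taxonomy)
    cons_rows = [["sequence", "dataset", "taxon_id", "taxon_name", "rank", "methods"]]
    for c in kept:
        name = taxonomy.get(c.taxon_id).name if c.assigned else ""
        cons_rows.append(
            [
                c.sequence_id,
                c.dataset,
                c.taxon_id or "",
                name,
                c.rank or "",
                "+".join(c.supporting_methods),
            ]
        )
    _write_tsv(out / "consensus.tsv", cons_rows)
    nr_rows = [["dataset", "taxon_id", "taxon_name", "rank", "count"]]
    nr_rows.extend(
        [r.dataset, r.taxon_id, taxonomy.get(r.taxon_id).name, r.rank or "", r.count]
        for r in nr
    )
    _write_tsv(out / "nonredundant.tsv", nr_rows)
    rank_rows = [["rank", *datasets, "total", "pct"]]
    pct = ranks.percentages()
    for rank, per_ds in ranks.counts.items():
        total = sum(per_ds.values())
        rank_rows.append(
            [rank, *[per_ds.get(d, 0) for d in datasets], total, f"{pct.get(rank, 0.0):.2f}"]
        )
    _write_tsv(out / "rank_counts.tsv", rank_rows)
    _write_tsv(out / "benchmark.tsv", report.to_rows())
    _write_tsv(out / "rarefaction.tsv", rarefaction_rows)
    order_rows = [["group", "order", "proportion_of_top"]]
    for group, profile in order_level_summary(kept, taxonomy).items():
        for o, p in sorted(profile.items()):
            order_rows.append([group, o, f"{p:.4f}"])
    _write_tsv(out / "order_summary.tsv", order_rows)

    manifest = {
        "tool": "preyassign",
        "version": __version__,
        "methods": ["BBH", "LCA", "SAP", "MAP"],
        "parameters": {
            "min_identity": config.min_identity,
            "min_length": config.min_length,
            "strict_length": config.strict_length,
            "pp_threshold": config.pp_threshold,
            "lca_weighted": config.lca_weighted,
            "lca_weight_threshold": config.lca_weight_threshold,
            "bbh_tie_mode": config.bbh_tie_mode,
            "rank_ceiling": config.rank_ceiling,
            "rank_weights": config.rank_weights,
            "rarefaction_reps": config.rarefaction_reps,
            "seed": config.seed,
        },
        "datasets": datasets,
        "inputs_sha256": checksums,
        "outputs": [
            "filter_report.tsv",
            "assignments.tsv",
            "consensus.tsv",
            "nonredundant.tsv",
            "rank_counts.tsv",
            "benchmark.tsv",
            "rarefaction.tsv",
            "order_summary.tsv",
        ],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return RunResult(
        filter_counts=filter_counts,
        assignments=assignments,
        consensus=kept,
        report=report,
        manifest=manifest,
    )
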