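"""Readers and writers for the file formats the pipeline touches.

The pipeline consumes the standard outputs of external tools — BLAST
tabular hit files (outfmt 6, 12 columns), FASTA query files, and Newick
trees from Bayesian tree inference — plus two simple TSV dialects of our
own: a taxonomy lineage table and an assignment table.

All readers are total on their declared dialects: a malformed row raises a
typed error naming the offending line, never a silent truncation.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence
import warnings

import dendropy
from Bio import SeqIO

from .taxonomy import Taxon, TaxonomyIndex

BLAST6_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


class ParseError(ValueError):
    """Malformed input; message carries file and line context."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = f"{path}:" if path else ""
        if line is not None:
            loc += f"line {line}: "
        super().__init__(f"{loc}{message}")
        self.path = path
        self.line = line


# ---------------------------------------------------------------------------
# BLAST tabular hits


@dataclass(frozen=True)
class HitRecord:
    """One row of BLAST outfmt-6 output joined to its subject taxon.

    Coordinates are 1-based inclusive (BLAST convention); ``length`` is the
    aligned-column count as BLAST reports it.  ``bitscore_raw`` preserves
    the printed score string so that ties can be detected exactly as
    printed, without float-rounding artifacts.
    """

    qseqid: str
    sseqid: str
    pident: float
    length: int
    mismatch: int
    gapopen: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float
    staxid: str | None = None
    bitscore_raw: str = ""

    def __post_init__(self):
        if not (0.0 <= self.pident <= 100.0):
            raise ValueError(f"pident {self.pident} outside [0, 100]")
        if self.length < 1:
            raise ValueError(f"alignment length {self.length} < 1")
        if self.evalue < 0:
            raise ValueError(f"evalue {self.evalue} < 0")


class HitTable:
    """Hit records grouped by query id, preserving file order per query."""

    def __init__(self, records: Iterable[HitRecord] = ()):
        self._by_query: dict[str, list[HitRecord]] = {}
        for rec in records:
            self._by_query.setdefault(rec.qseqid, []).append(rec)

    def hits_for(self, qseqid: str) -> list[HitRecord]:
        return self._by_query.get(qseqid, [])

    def query_ids(self) -> list[str]:
        return list(self._by_query)

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_query.values())

    def __contains__(self, qseqid: str) -> bool:
        return qseqid in self._by_query

    def __iter__(self):
        for recs in self._by_query.values():
            yield from recs


def read_hits(
    path,
    taxon_map: Mapping[str, str] | None = None,
    *,
    on_unmapped: str = "drop",
) -> HitTable:
    """Parse a 12-column BLAST outfmt-6 TSV into a :class:`HitTable`.

    ``taxon_map`` resolves ``sseqid`` -> taxon id.  Subjects missing from
    the map are dropped with a warning (``on_unmapped='drop'``) or raise
    (``on_unmapped='error'``); with ``taxon_map=None`` no join is attempted.
    """
    if on_unmapped not in ("drop", "error"):
        raise ValueError(f"on_unmapped must be 'drop' or 'error', got {on_unmapped!r}")
    records: list[HitRecord] = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 12:
                raise ParseError(
                    f"expected 12 tab-separated columns, found {len(row)}",
                    path=path,
                    line=lineno,
                )
            try:
                rec = HitRecord(
                    qseqid=row[0],
                    sseqid=row[1],
                    pident=float(row[2]),
                    length=int(row[3]),
                    mismatch=int(row[4]),
                    gapopen=int(row[5]),
                    qstart=int(row[6]),
                    qend=int(row[7]),
                    sstart=int(row[8]),
                    send=int(row[9]),
                    evalue=float(row[10]),
                    bitscore=float(row[11]),
                    bitscore_raw=row[11].strip(),
                )
            except ValueError as exc:
                raise ParseError(str(exc), path=path, line=lineno) from None
            if taxon_map is not None:
                staxid = taxon_map.get(rec.sseqid)
                if staxid is None:
                    if on_unmapped == "error":
                        raise ParseError(
                            f"subject {rec.sseqid!r} has no taxon mapping",
                            path=path,
                            line=lineno,
                        )
                    warnings.warn(
                        f"dropping hit to unmapped subject {rec.sseqid!r}",
                        stacklevel=2,
                    )
                    continue
                rec = HitRecord(
                    **{**rec.__dict__, "staxid": staxid}
                )
            records.append(rec)
    return HitTable(records)


def write_hits(path, hits: Iterable[HitRecord]) -> None:
    """Write hit records back to 12-column BLAST outfmt-6 TSV."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for h in hits:
            w.writerow(
                [
                    h.qseqid,
                    h.sseqid,
                    f"{h.pident:g}",
                    h.length,
                    h.mismatch,
                    h.gapopen,
                    h.qstart,
                    h.qend,
                    h.sstart,
                    h.send,
                    f"{h.evalue:g}",
                    h.bitscore_raw or f"{h.bitscore:g}",
                ]
            )


# ---------------------------------------------------------------------------
# FASTA queries


@dataclass(frozen=True)
class QuerySequence:
    id: str
    length: int
    dataset: str = ""

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError(f"sequence {self.id!r} has non-positive length")


def read_fasta(path, dataset: str = "") -> list[QuerySequence]:
    """Read query ids and lengths from a FASTA file; duplicate ids raise."""
    out: list[QuerySequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ParseError(f"duplicate sequence id {rec.id!r}", path=path)
        seen.add(rec.id)
        out.append(QuerySequence(id=rec.id, length=len(rec.seq), dataset=dataset))
    return out


# ---------------------------------------------------------------------------
# Newick trees


@dataclass
class PhyloTree:
    """A tree whose leaves map to taxa and which contains one query leaf.

    ``tree`` is a dendropy tree; ``leaf_taxa`` maps every non-query leaf
    label to a taxon id; ``query_leaf`` names the query tip.  Internal node
    supports live on ``node.label`` as probabilities in [0, 1].
    """

    tree: dendropy.Tree
    leaf_taxa: dict[str, str]
    query_leaf: str

    def leaf_labels(self) -> list[str]:
        return [
            lf.taxon.label for lf in self.tree.leaf_node_iter() if lf.taxon is not None
        ]

    def validate(self, taxonomy: TaxonomyIndex | None = None) -> None:
        labels = self.leaf_labels()
        n_query = labels.count(self.query_leaf)
        if n_query != 1:
            raise ParseError(
                f"query leaf {self.query_leaf!r} occurs {n_query} times (expected 1)"
            )
        for lab in labels:
            if lab == self.query_leaf:
                continue
            if lab not in self.leaf_taxa:
                raise ParseError(f"leaf {lab!r} has no taxon mapping")
            if taxonomy is not None and self.leaf_taxa[lab] not in taxonomy:
                raise ParseError(
                    f"leaf {lab!r} maps to unknown taxon {self.leaf_taxa[lab]!r}"
                )


@dataclass
class TreeSample:
    """A sample of trees over the same leaf set, one query leaf each."""

    trees: list[PhyloTree]

    def __post_init__(self):
        if not self.trees:
            raise ValueError("empty tree sample")
        ref = frozenset(self.trees[0].leaf_labels())
        for i, t in enumerate(self.trees[1:], start=2):
            if frozenset(t.leaf_labels()) != ref:
                raise ParseError(f"tree {i} has a different leaf set than tree 1")

    def __len__(self) -> int:
        return len(self.trees)


def _coerce_supports(tree: dendropy.Tree, support_scale: str, path) -> None:
    """Turn internal node labels into float supports in [0, 1]."""
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        lab = node.label
        if lab is None or lab == "":
            continue
        try:
            val = float(lab)
        except ValueError:
            raise ParseError(
                f"internal node label {lab!r} is not a support value", path=path
            ) from None
        if support_scale == "percent":
            val = val / 100.0
        if not (0.0 <= val <= 1.0):
            raise ParseError(
                f"support {val} outside [0, 1]; pass support_scale='percent' "
                "for percentage supports",
                path=path,
            )
        node.label = repr(val)


def node_support(node: dendropy.Node) -> float | None:
    """Support of an internal node, or None when absent."""
    if node.label in (None, ""):
        return None
    return float(node.label)


def read_newick(
    path,
    leaf_taxa: Mapping[str, str],
    query_leaf: str,
    *,
    support_scale: str = "unit",
    burnin_frac: float = 0.0,
    taxonomy: TaxonomyIndex | None = None,
) -> PhyloTree | TreeSample:
    """Read a single- or multi-tree Newick file.

    Returns a :class:`PhyloTree` for a one-tree file and a
    :class:`TreeSample` otherwise.  ``burnin_frac`` discards the leading
    fraction of a multi-tree file (MrBayes-style burn-in).
    """
    if support_scale not in ("unit", "percent"):
        raise ValueError("support_scale must be 'unit' or 'percent'")
    if not (0.0 <= burnin_frac < 1.0):
        raise ValueError("burnin_frac must be in [0, 1)")
    tree_list = dendropy.TreeList.get(
        path=str(path),
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    if len(tree_list) == 0:
        raise ParseError("no trees in file", path=path)
    trees = list(tree_list)
    if len(trees) > 1 and burnin_frac > 0:
        trees = trees[int(round(burnin_frac * len(trees))):]
    wrapped: list[PhyloTree] = []
    for t in trees:
        _coerce_supports(t, support_scale, path)
        pt = PhyloTree(tree=t, leaf_taxa=dict(leaf_taxa), query_leaf=query_leaf)
        pt.validate(taxonomy)
        wrapped.append(pt)
    if len(wrapped) == 1:
        return wrapped[0]
    return TreeSample(wrapped)


def write_newick(path, trees: PhyloTree | TreeSample | Sequence[PhyloTree]) -> None:
    if isinstance(trees, PhyloTree):
        trees = [trees]
    elif isinstance(trees, TreeSample):
        trees = trees.trees
    with open(path, "w") as fh:
        for pt in trees:
            fh.write(
                pt.tree.as_string(
                    schema="newick",
                    suppress_rooting=True,
                    unquoted_underscores=True,
                ).strip()
                + "\n"
            )


# ---------------------------------------------------------------------------
# Lineage TSV (taxonomy)

LINEAGE_COLUMNS = ("taxid", "parent_taxid", "rank", "name")


def read_lineage_table(path) -> TaxonomyIndex:
    """Read a lineage TSV (``taxid  parent_taxid  rank  name``, header
    required, one root row with empty or self parent)."""
    taxa: list[Taxon] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError("empty lineage table (header required)", path=path)
        if [h.strip().lower() for h in header] != list(LINEAGE_COLUMNS):
            raise ParseError(
                f"expected header {LINEAGE_COLUMNS}, found {tuple(header)}",
                path=path,
                line=1,
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 4:
                raise ParseError("expected 4 columns", path=path, line=lineno)
            taxid, parent, rank, name = (c.strip() for c in row[:4])
            taxa.append(
                Taxon(
                    id=taxid,
                    name=name,
                    rank=rank,
                    parent_id=parent if parent and parent != taxid else None,
                )
            )
    return TaxonomyIndex(taxa)


def write_lineage_table(path, taxonomy: TaxonomyIndex) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(LINEAGE_COLUMNS)
        for t in taxonomy:
            w.writerow([t.id, t.parent_id or "", t.rank, t.name])


# ---------------------------------------------------------------------------
# Assignment TSV

ASSIGNMENT_COLUMNS = (
    "sequence",
    "dataset",
    "method",
    "taxon_id",
    "taxon_name",
    "rank",
    "confidence",
)


def write_assignments(path, assignments, taxonomy: TaxonomyIndex) -> None:
    """Write assignment records (sequence, dataset, method, taxon, rank,
    confidence) as TSV; an unassigned record writes empty taxon fields."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(ASSIGNMENT_COLUMNS)
        for a in assignments:
            if a.taxon_id is not None:
                t = taxonomy.get(a.taxon_id)
                name, rank = t.name, t.rank
            else:
                name, rank = "", ""
            conf = "" if a.confidence is None else f"{a.confidence:.4f}"
            w.writerow(
                [
                    a.sequence_id,
                    getattr(a, "dataset", "") or "",
                    a.method,
                    a.taxon_id or "",
                    name,
                    rank,
                    conf,
                ]
            )


def read_assignments(path) -> list[dict]:
    """Read an assignment TSV back into plain dict rows (empty taxon fields
    become ``None``)."""
    rows: list[dict] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or tuple(reader.fieldnames) != ASSIGNMENT_COLUMNS:
            raise ParseError(
                f"expected header {ASSIGNMENT_COLUMNS}, found {reader.fieldnames}",
                path=path,
            )
        for row in reader:
            rows.append(
                {
                    "sequence": row["sequence"],
                    "dataset": row["dataset"],
                    "method": row["method"],
                    "taxon_id": row["taxon_id"] or None,
                    "taxon_name": row["taxon_name"] or None,
                    "rank": row["rank"] or None,
                    "confidence": float(row["confidence"]) if row["confidence"] else None,
                }
            )
    return rows
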