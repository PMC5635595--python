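"""Readers and writers for the standard formats the pipeline touches.

Trees come in as Newick (parsed with dendropy), alignments as FASTA or
NEXUS character matrices (parsed with Biopython), gene annotations as a
GFF3 subset or a five-column TSV, and similarity searches as BLAST
outfmt-6 tables.  External files use 1-based inclusive coordinates; all
in-memory indices are 0-based half-open.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import dendropy
import pandas as pd
from Bio import AlignIO

from .trees import (
    DatedSpeciesTree,
    GeneTree,
    PolytomyError,
    TreeNode,
    default_species_of,
)

GAP_CHARS = frozenset("-.")


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def _dendropy_to_node(tree: dendropy.Tree) -> TreeNode:
    def convert(dnode) -> TreeNode:
        kids = dnode.child_nodes()
        if kids:
            node = TreeNode(None, dnode.edge.length or 0.0)
        else:
            name = dnode.taxon.label if dnode.taxon else (dnode.label or "")
            node = TreeNode(name, dnode.edge.length or 0.0)
        for k in kids:
            node.add_child(convert(k))
        return node

    return convert(tree.seed_node)


def read_tree(
    path_or_str: str,
    kind: str = "species",
    species_map: Optional[dict[str, str]] = None,
    species_tree: Optional[DatedSpeciesTree] = None,
) -> Union[DatedSpeciesTree, GeneTree]:
    """Read a rooted Newick tree.

    Parameters
    ----------
    path_or_str : str
        File path, or a Newick string (recognised by a ';' in the text).
    kind : {"species", "gene"}
        Species trees must be ultrametric (ages derived from branch
        lengths); gene trees map leaves to species either via
        ``species_map`` or the ``<species>_<n>`` leaf-name convention.
    species_tree : DatedSpeciesTree, optional
        Companion tree used to validate gene leaf species.
    """
    text = path_or_str
    if ";" not in text:
        with open(path_or_str) as fh:
            text = fh.read()
    dtree = dendropy.Tree.get(
        data=text,
        schema="newick",
        rooting="force-rooted",
        preserve_underscores=True,
    )
    root = _dendropy_to_node(dtree)
    if kind == "species":
        return DatedSpeciesTree(root)
    if kind == "gene":
        return GeneTree(root, species_map=species_map, species_tree=species_tree)
    raise ValueError(f"unknown tree kind {kind!r}")


def _fmt(x: float) -> str:
    return format(x, ".17g")


def write_tree(tree: Union[DatedSpeciesTree, GeneTree], path: Optional[str] = None) -> str:
    """Serialize a tree as Newick; byte-stable for fixed input.

    Species trees are written with branch lengths derived from node ages
    (so the chronogram round-trips); gene trees keep their stored branch
    lengths.
    """
    dated = isinstance(tree, DatedSpeciesTree)

    def render(node: TreeNode) -> str:
        if dated and node.parent is not None:
            length = node.parent.age - node.age
        else:
            length = node.length
        suffix = f":{_fmt(length)}" if node.parent is not None else ""
        if node.is_leaf:
            return f"{node.name}{suffix}"
        inner = ",".join(render(c) for c in node.children)
        return f"({inner}){suffix}"

    text = render(tree.root) + ";"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text


def extract_lca_clade(tree: GeneTree, reference_leaves: Iterable[str]) -> GeneTree:
    """Subtree rooted at the LCA of the reference leaves, relabeled by postorder.

    This is the prescreen step that narrows a large homolog tree down to
    the monophyletic clade delineated by a set of trusted (e.g.
    experimentally characterized) members.
    """
    refs = list(reference_leaves)
    if not refs:
        raise ValueError("reference leaf set is empty")
    missing = [r for r in refs if r not in tree.by_name]
    if missing:
        raise ValueError(f"reference leaves absent from tree: {missing}")
    lca = tree.lca([tree.by_name[r] for r in refs])

    def copy(node: TreeNode) -> TreeNode:
        dup = TreeNode(node.name, node.length)
        for c in node.children:
            dup.add_child(copy(c))
        return dup

    new_root = copy(lca)
    new_root.length = 0.0
    keep = {l.name for l in lca.leaves()}
    smap = {k: v for k, v in tree.species_map.items() if k in keep}
    return GeneTree(new_root, species_map=smap)


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

@dataclass
class Alignment:
    """Ordered aligned sequences; rows all of equal length."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if self.rows:
            ncol = len(self.rows[0])
            for rid, row in zip(self.ids, self.rows):
                if len(row) != ncol:
                    raise ValueError(
                        f"ragged alignment: row {rid!r} has length "
                        f"{len(row)}, expected {ncol}"
                    )

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def column(self, j: int) -> str:
        return "".join(row[j] for row in self.rows)

    def occupancy(self, j: int) -> float:
        """Fraction of non-gap characters in column j."""
        col = self.column(j)
        return sum(1 for ch in col if ch not in GAP_CHARS) / len(col)

    def occupancies(self) -> list[float]:
        return [self.occupancy(j) for j in range(self.n_cols)]

    def row(self, rid: str) -> str:
        return self.rows[self.ids.index(rid)]


def read_alignment(path_or_handle, format: str = "fasta") -> Alignment:
    if format not in ("fasta", "nexus"):
        raise ValueError(f"unknown alignment format {format!r}")
    handle = path_or_handle
    if isinstance(handle, str):
        handle = open(handle)
    try:
        if format == "fasta":
            # AlignIO rejects ragged FASTA without naming the row; read
            # records ourselves so the error is informative.
            from Bio import SeqIO

            ids, rows = [], []
            for rec in SeqIO.parse(handle, "fasta"):
                ids.append(rec.id)
                rows.append(str(rec.seq))
            if not ids:
                raise ValueError("empty alignment")
            return Alignment(ids, rows)
        msa = AlignIO.read(handle, "nexus")
        return Alignment([r.id for r in msa], [str(r.seq) for r in msa])
    finally:
        if isinstance(path_or_handle, str):
            handle.close()


def write_alignment(a: Alignment, path: Optional[str] = None, format: str = "fasta") -> str:
    if format == "fasta":
        text = "".join(f">{rid}\n{row}\n" for rid, row in zip(a.ids, a.rows))
    elif format == "nexus":
        lines = [
            "#NEXUS",
            "begin data;",
            f"dimensions ntax={a.n_rows} nchar={a.n_cols};",
            "format datatype=protein missing=? gap=-;",
            "matrix",
        ]
        width = max(len(i) for i in a.ids) + 2
        for rid, row in zip(a.ids, a.rows):
            # NEXUS reserves '.' as the match character; emit gaps as '-'
            lines.append(f"{rid.ljust(width)}{row.replace('.', '-')}")
        lines += [";", "end;"]
        text = "\n".join(lines) + "\n"
    else:
        raise ValueError(f"unknown alignment format {format!r}")
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def occupancy_trim(a: Alignment, threshold: float = 0.7) -> Alignment:
    """Keep columns whose non-gap fraction is >= threshold (trimal -gt).

    Idempotent; column order preserved.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    if a.n_rows == 0 or a.n_cols == 0:
        raise ValueError("cannot trim an empty alignment")
    keep = [j for j in range(a.n_cols) if a.occupancy(j) >= threshold]
    rows = ["".join(row[j] for j in keep) for row in a.rows]
    return Alignment(list(a.ids), rows)


# ---------------------------------------------------------------------------
# Gene annotation (gene order on scaffolds)
# ---------------------------------------------------------------------------

@dataclass
class AnnotationTable:
    """Gene coordinates plus per-scaffold ordinal gene order.

    The ordinal index (0-based, consecutive per scaffold, assigned by
    start coordinate with gene-id tie-break) is what the neighborhood
    window operates on.
    """

    df: pd.DataFrame = field(repr=False)

    COLUMNS = ("gene_id", "scaffold", "start", "end", "strand", "ordinal")

    def __post_init__(self) -> None:
        df = self.df
        dup = df["gene_id"][df["gene_id"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate gene ids: {sorted(set(dup))}")
        if (df["start"] > df["end"]).any():
            bad = df.loc[df["start"] > df["end"], "gene_id"].tolist()
            raise ValueError(f"start > end for genes: {bad}")
        self.df = df.reset_index(drop=True)

    @classmethod
    def from_records(cls, records: Sequence[tuple]) -> "AnnotationTable":
        """records: (gene_id, scaffold, start, end, strand) tuples."""
        df = pd.DataFrame(
            records, columns=["gene_id", "scaffold", "start", "end", "strand"]
        )
        df = df.sort_values(
            ["scaffold", "start", "gene_id"], kind="mergesort"
        ).reset_index(drop=True)
        df["ordinal"] = df.groupby("scaffold").cumcount()
        # restore a deterministic global order: scaffold then ordinal
        return cls(df)

    def scaffold_of(self, gene_id: str) -> str:
        return self._row(gene_id)["scaffold"]

    def _row(self, gene_id: str):
        rows = self.df[self.df["gene_id"] == gene_id]
        if rows.empty:
            raise KeyError(f"gene {gene_id!r} absent from annotation")
        return rows.iloc[0]

    def __len__(self) -> int:
        return len(self.df)


def read_annotation(path_or_handle) -> AnnotationTable:
    """Read gene coordinates from a GFF3 subset (``gene`` features with an
    ``ID=`` attribute) or a 5-column TSV (gene, scaffold, start, end, strand)."""
    handle = path_or_handle
    if isinstance(handle, str):
        handle = open(handle)
    try:
        lines = handle.read().splitlines()
    finally:
        if isinstance(path_or_handle, str):
            handle.close()
    records = []
    is_gff = any(l.startswith("##gff") for l in lines[:5])
    if not is_gff:
        body = [l for l in lines if l and not l.startswith("#")]
        is_gff = bool(body) and len(body[0].split("\t")) == 9
    for lineno, line in enumerate(lines, start=1):
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        try:
            if is_gff:
                if len(parts) != 9:
                    raise ValueError("expected 9 GFF3 columns")
                seqid, _src, ftype, start, end, _score, strand, _phase, attrs = parts
                if ftype != "gene":
                    continue
                gene_id = None
                for kv in attrs.rstrip(";").split(";"):
                    k, _, v = kv.partition("=")
                    if k.strip() == "ID":
                        gene_id = v.strip()
                if gene_id is None:
                    raise ValueError("gene feature without ID attribute")
            else:
                if len(parts) != 5:
                    raise ValueError("expected 5 TSV columns")
                gene_id, seqid, start, end, strand = parts
            records.append((gene_id, seqid, int(start), int(end), strand))
        except ValueError as exc:
            raise ValueError(f"malformed annotation row at line {lineno}: {exc}")
    return AnnotationTable.from_records(records)


def write_annotation(ann: AnnotationTable, path: Optional[str] = None) -> str:
    buf = io.StringIO()
    ann.df[["gene_id", "scaffold", "start", "end", "strand"]].to_csv(
        buf, sep="\t", header=False, index=False
    )
    text = buf.getvalue()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


# ---------------------------------------------------------------------------
# BLAST-like hit tables
# ---------------------------------------------------------------------------

OUTFMT6_COLUMNS = [
    "query", "subject", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


@dataclass
class HitTable:
    """All-vs-all similarity hits with per-hit coverage of the longer sequence."""

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if (self.df["evalue"] < 0).any():
            raise ValueError("negative E-values in hit table")
        cov = self.df["coverage"]
        if ((cov < 0) | (cov > 1)).any():
            raise ValueError("coverage fractions outside [0, 1]")

    def __len__(self) -> int:
        return len(self.df)


def read_hits(
    path_or_handle,
    lengths: Optional[dict[str, int]] = None,
) -> HitTable:
    """Read a BLAST outfmt-6 TSV.

    Either the table carries two extra trailing columns (query length,
    subject length) or a ``lengths`` mapping must be supplied; coverage is
    computed as aligned length / longer-sequence length when absent.
    """
    handle = path_or_handle
    if isinstance(handle, str):
        handle = open(handle)
    try:
        df = pd.read_csv(handle, sep="\t", header=None, comment="#")
    finally:
        if isinstance(path_or_handle, str):
            handle.close()
    ncol = df.shape[1]
    if ncol == 14:
        df.columns = OUTFMT6_COLUMNS + ["qlen", "slen"]
    elif ncol == 12:
        df.columns = OUTFMT6_COLUMNS
        if lengths is None:
            raise ValueError(
                "12-column outfmt-6 table without a lengths sidecar; "
                "supply lengths={id: sequence length}"
            )
        df["qlen"] = df["query"].map(lengths)
        df["slen"] = df["subject"].map(lengths)
        missing = sorted(
            set(df.loc[df["qlen"].isna(), "query"])
            | set(df.loc[df["slen"].isna(), "subject"])
        )
        if missing:
            raise ValueError(f"ids lacking length information: {missing}")
    else:
        raise ValueError(f"expected 12 or 14 tab-separated columns, got {ncol}")
    df["coverage"] = df["length"] / df[["qlen", "slen"]].max(axis=1)
    df["coverage"] = df["coverage"].clip(upper=1.0)
    return HitTable(df)


def hits_from_records(
    records: Sequence[tuple],
) -> HitTable:
    """Build a HitTable from (query, subject, evalue, coverage) tuples."""
    df = pd.DataFrame(records, columns=["query", "subject", "evalue", "coverage"])
    df["pident"] = float("nan")
    df["length"] = 0
    return HitTable(df)


def write_hits(hits: HitTable, path: Optional[str] = None) -> str:
    cols = [c for c in OUTFMT6_COLUMNS + ["qlen", "slen"] if c in hits.df.columns]
    buf = io.StringIO()
    hits.df[cols].to_csv(buf, sep="\t", header=False, index=False)
    text = buf.getvalue()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
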