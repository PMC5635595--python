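"""Mapping exon/intron junctions onto protein-alignment consensus columns.

Intron positions interrupt the coding sequence at a nucleotide offset
``n`` from the CDS start; the junction lands on residue ``n // 3`` with
phase ``n % 3`` (phase-0 junctions belong to the first residue of the
downstream exon).  Junctions are then lifted through a gapped alignment
row to alignment columns, and finally to *consensus* columns — columns
whose occupancy reaches the same 70% threshold used for alignment
trimming — so that junction positions are comparable across genes.
Clade-specific junction presence feeds the same Fisher-exact clade scan
used for syntenic accessory families.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .io_formats import GAP_CHARS, Alignment
from .trees import GeneTree


@dataclass
class GeneModel:
    """A gene's CDS as ordered exon intervals.

    Coordinates are 0-based half-open on the genomic strand; minus-strand
    models are stored in genomic order and processed in transcription
    orientation.
    """

    gene_id: str
    strand: str                      # "+" or "-"
    exons: list[tuple[int, int]]     # genomic order, non-overlapping

    def __post_init__(self) -> None:
        exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 < e1:
                raise ValueError(
                    f"overlapping exons in gene model {self.gene_id!r}"
                )
        self.exons = exons

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def complete(self) -> bool:
        return self.cds_length % 3 == 0

    @property
    def protein_length(self) -> int:
        return self.cds_length // 3

    def transcription_order_exons(self) -> list[tuple[int, int]]:
        return self.exons if self.strand == "+" else list(reversed(self.exons))


@dataclass
class JunctionMap:
    """Junctions of one gene lifted to alignment and consensus coordinates."""

    gene_id: str
    #: per junction: (cds offset, residue index, phase, alignment column,
    #: consensus column index or None)
    junctions: list[tuple[int, int, int, int, Optional[int]]] = field(
        default_factory=list
    )

    def consensus_positions(self) -> list[int]:
        return [c for *_rest, c in self.junctions if c is not None]


def cds_junctions(model: GeneModel) -> list[tuple[int, int]]:
    """Internal exon boundaries as (residue index, phase) pairs.

    Single-exon genes yield an empty list.  The invariant
    ``offset == 3 * residue + phase`` holds for every junction.
    """
    out = []
    offset = 0
    exons = model.transcription_order_exons()
    for s, e in exons[:-1]:
        offset += e - s
        out.append((offset // 3, offset % 3))
    return out


def consensus_columns(a: Alignment, occupancy: float = 0.7) -> list[int]:
    """Alignment columns whose non-gap fraction is >= the threshold."""
    return [j for j in range(a.n_cols) if a.occupancy(j) >= occupancy]


def junctions_to_columns(
    junctions: Sequence[tuple[int, int]],
    gene_id: str,
    a: Alignment,
    occupancy: float = 0.7,
) -> JunctionMap:
    """Lift (residue, phase) junctions through a gapped alignment row.

    The residue index addresses the ungapped sequence of the row; its
    alignment column is found by skipping gap columns.  The consensus
    index is the rank of the junction's column among consensus columns,
    or None when the column itself is below the occupancy threshold.
    """
    row = a.row(gene_id)
    residue_to_col = [
        j for j, ch in enumerate(row) if ch not in GAP_CHARS
    ]
    cons = consensus_columns(a, occupancy)
    cons_rank = {c: i for i, c in enumerate(cons)}
    jmap = JunctionMap(gene_id)
    for residue, phase in junctions:
        if residue >= len(residue_to_col):
            raise ValueError(
                f"junction residue {residue} beyond the {len(residue_to_col)}"
                f"-residue sequence of {gene_id!r} (truncated gene model?)"
            )
        col = residue_to_col[residue]
        jmap.junctions.append(
            (3 * residue + phase, residue, phase, col, cons_rank.get(col))
        )
    return jmap


def junction_column_counts(
    maps: Sequence[JunctionMap], a: Alignment, occupancy: float = 0.7
) -> pd.Series:
    """Junction counts per consensus column (index: consensus rank)."""
    n_cons = len(consensus_columns(a, occupancy))
    counts = pd.Series(0, index=range(n_cons), name="junctions")
    for m in maps:
        for c in m.consensus_positions():
            counts[c] += 1
    return counts


def junction_clade_features(
    maps: Sequence[JunctionMap],
    tree: GeneTree,
    tolerance: int = 0,
) -> dict[str, dict[int, bool]]:
    """Binary per-gene features: has a junction within +-tolerance of each
    observed consensus position.

    The result maps gene id -> {consensus position: present}; it plugs
    into the clade association scan unchanged (each consensus position
    plays the role of one candidate feature).
    """
    by_gene = {m.gene_id: set(m.consensus_positions()) for m in maps}
    positions = sorted({p for s in by_gene.values() for p in s})
    features: dict[str, dict[int, bool]] = {}
    for leaf in tree.leaves:
        present = by_gene.get(leaf.name, set())
        features[leaf.name] = {
            p: any(abs(p - q) <= tolerance for q in present) for p in positions
        }
    return features
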