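"""Genomic-context analysis around focal genes.

Three pieces: (1) extraction of the ±w gene neighborhood of each focal
gene from an annotation table; (2) the clade × CHG association scan —
for every subtree with at least ``min_clade`` leaves and every candidate
homolog group, a two-sided Fisher exact test on the 2×2 table (focal
gene in clade vs not) × (CHG member present in its neighborhood vs
not), Bonferroni-corrected over all subtree×CHG tests, with local
P-minima marked and the most significant nonoverlapping subtrees
reported per CHG; and (3) the neighborhood-retention statistic — for
each internal node of the gene tree, the mean over cross pairs of
descendant leaves of the shared fraction of neighborhood CHGs —
contrasted between event types and against node depth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import AnnotationTable
from .trees import GeneTree, TreeNode


# ---------------------------------------------------------------------------
# Neighborhoods
# ---------------------------------------------------------------------------

@dataclass
class Neighborhood:
    """Ordered ±w genomic context of one focal gene."""

    focal: str
    neighbors: list                    # gene ids, scaffold order, focal excluded
    chg_presence: set = field(default_factory=set)

    def with_membership(self, membership: dict) -> "Neighborhood":
        """Derive the set of CHGs with >= 1 member in the window."""
        self.chg_presence = {
            membership[g] for g in self.neighbors if g in membership
        }
        return self


def extract_neighborhoods(
    ann: AnnotationTable, focal_ids: Sequence[str], w: int = 20
) -> list[Neighborhood]:
    """The <= w genes on each side of each focal gene on its scaffold
    (strand ignored, truncated at scaffold ends)."""
    df = ann.df
    by_scaffold = {
        scf: sub.sort_values("ordinal") for scf, sub in df.groupby("scaffold")
    }
    position = {
        row.gene_id: (row.scaffold, row.ordinal) for row in df.itertuples()
    }
    out = []
    for focal in focal_ids:
        if focal not in position:
            raise ValueError(f"focal gene {focal!r} absent from annotation")
        scf, ordi = position[focal]
        sub = by_scaffold[scf]
        window = sub[
            (sub["ordinal"] >= ordi - w)
            & (sub["ordinal"] <= ordi + w)
            & (sub["gene_id"] != focal)
        ]
        out.append(Neighborhood(focal=focal, neighbors=window["gene_id"].tolist()))
    return out


# ---------------------------------------------------------------------------
# Fisher exact test
# ---------------------------------------------------------------------------

def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher exact test by hypergeometric enumeration.

    P is the sum of probabilities of all tables (with the observed
    margins) at most as probable as the observed one.  The odds ratio
    gets the Haldane 0.5 correction when any cell is zero.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0 or any(
        x != int(x) for x in (a, b, c, d)
    ):
        raise ValueError("cell counts must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n = a + b + c + d
    if n == 0:
        raise ValueError("all-zero contingency table")
    row1, col1 = a + b, a + c
    lo = max(0, col1 - (n - row1))
    hi = min(col1, row1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, row1, col1)
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    p = min(p, 1.0)
    if min(a, b, c, d) == 0:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    return p, odds


# ---------------------------------------------------------------------------
# Clade x CHG association scan
# ---------------------------------------------------------------------------

@dataclass
class AssociationResult:
    """One clade x CHG contingency test."""

    clade: str                          # gene-tree node label
    chg: str
    in_with: int
    in_without: int
    out_with: int
    out_without: int
    raw_p: float
    corrected_p: float
    odds_ratio: float
    n_leaves: int
    local_min: bool = False
    reported: bool = False


def _eligible_subtrees(tree: GeneTree, min_clade: int) -> list[TreeNode]:
    """Internal nodes with >= min_clade leaves; the root (whose complement
    is empty, so no contrast exists) is excluded."""
    return [
        n
        for n in tree.nodes
        if not n.is_leaf
        and n.parent is not None
        and len(n.leaves()) >= min_clade
    ]


def clade_chg_scan(
    tree: GeneTree,
    neighborhoods: Sequence[Neighborhood],
    chgs: Sequence[str],
    min_clade: int = 5,
    alpha: float = 1e-4,
) -> list[AssociationResult]:
    """Fisher-exact scan of every eligible subtree against every CHG.

    Bonferroni correction uses the total test count over all
    subtree x CHG pairs; results come back with local-minimum and
    reported flags already set (see :func:`select_reported`).
    """
    presence = {}
    for nb in neighborhoods:
        presence[nb.focal] = nb.chg_presence
    missing = [l.name for l in tree.leaves if l.name not in presence]
    if missing:
        raise ValueError(f"tree leaves without neighborhoods: {missing}")
    subtrees = _eligible_subtrees(tree, min_clade)
    all_leaves = [l.name for l in tree.leaves]
    total_tests = len(subtrees) * len(chgs)
    results = []
    for node in subtrees:
        inside = {l.name for l in node.leaves()}
        for chg in chgs:
            a = sum(1 for g in inside if chg in presence[g])
            b = len(inside) - a
            c = sum(
                1 for g in all_leaves if g not in inside and chg in presence[g]
            )
            d = len(all_leaves) - len(inside) - c
            raw, odds = fisher_exact_2x2([[a, b], [c, d]])
            results.append(
                AssociationResult(
                    clade=node.label,
                    chg=chg,
                    in_with=a,
                    in_without=b,
                    out_with=c,
                    out_without=d,
                    raw_p=raw,
                    corrected_p=min(1.0, raw * total_tests),
                    odds_ratio=odds,
                    n_leaves=len(inside),
                )
            )
    return select_reported(results, tree, min_clade=min_clade, alpha=alpha)


def select_reported(
    results: list[AssociationResult],
    tree: GeneTree,
    min_clade: int = 5,
    alpha: float = 1e-4,
) -> list[AssociationResult]:
    """Set local-minimum and reported flags per CHG.

    A result is a local minimum when its corrected P is lower than the
    same CHG's corrected P at the parent subtree (ties broken toward the
    smaller subtree) and strictly lower than at every eligible child
    subtree.  The reported set is built greedily by ascending corrected
    P among significant local minima, skipping subtrees that share a
    leaf with an already-reported subtree for that CHG.
    """
    eligible = {n.label for n in _eligible_subtrees(tree, min_clade)}
    parent_of = {}
    children_of: dict[str, list[str]] = {}
    for n in tree.nodes:
        if n.label not in eligible:
            continue
        p = n.parent
        if p is not None and p.label in eligible:
            parent_of[n.label] = p.label
            children_of.setdefault(p.label, []).append(n.label)
    leaf_sets = {
        n.label: frozenset(l.name for l in n.leaves())
        for n in tree.nodes
        if n.label in eligible
    }
    by_chg: dict[str, dict[str, AssociationResult]] = {}
    for r in results:
        by_chg.setdefault(r.chg, {})[r.clade] = r
    for chg, per_clade in by_chg.items():
        for label, r in per_clade.items():
            ok = True
            parent = parent_of.get(label)
            if parent is not None and parent in per_clade:
                ok = r.corrected_p <= per_clade[parent].corrected_p
            if ok:
                for child in children_of.get(label, []):
                    if child in per_clade and not (
                        r.corrected_p < per_clade[child].corrected_p
                    ):
                        ok = False
                        break
            r.local_min = ok
        candidates = sorted(
            (r for r in per_clade.values() if r.local_min and r.corrected_p <= alpha),
            key=lambda r: (r.corrected_p, r.n_leaves, r.clade),
        )
        taken: list[frozenset] = []
        for r in candidates:
            ls = leaf_sets[r.clade]
            if any(ls & t for t in taken):
                continue
            r.reported = True
            taken.append(ls)
    return results


def association_table(results: list[AssociationResult]) -> pd.DataFrame:
    rows = [
        {
            "clade": r.clade,
            "chg": r.chg,
            "in_with": r.in_with,
            "in_without": r.in_without,
            "out_with": r.out_with,
            "out_without": r.out_without,
            "raw_p": r.raw_p,
            "corrected_p": r.corrected_p,
            "odds_ratio": r.odds_ratio,
            "local_min": r.local_min,
            "reported": r.reported,
        }
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "clade", "chg", "in_with", "in_without", "out_with", "out_without",
            "raw_p", "corrected_p", "odds_ratio", "local_min", "reported",
        ],
    )


# ---------------------------------------------------------------------------
# Neighborhood retention by event type
# ---------------------------------------------------------------------------

@dataclass
class RetentionRecord:
    """Shared-context fraction across one internal node of a gene tree."""

    node: str
    retention: float
    depth: int
    event: Optional[str] = None


def _pair_fraction(a: set, b: set, mode: str) -> Optional[float]:
    inter = len(a & b)
    if mode == "min":
        denom = min(len(a), len(b))
    elif mode == "mean":
        denom = (len(a) + len(b)) / 2
    elif mode == "jaccard":
        denom = len(a | b)
    else:
        raise ValueError(f"unknown retention mode {mode!r}")
    if denom == 0:
        return None
    return inter / denom


def neighborhood_retention(
    tree: GeneTree,
    chg_sets: dict,
    mode: str = "min",
) -> list[RetentionRecord]:
    """Mean pairwise shared-CHG fraction across each internal node.

    For node v, the statistic averages |CHG(a) ∩ CHG(b)| / denom over
    all cross pairs (a in the left subtree, b in the right); the
    denominator is the smaller CHG-set size by default (modes: min,
    mean, jaccard).  Depth is the edge count from the root.  Nodes where
    every pair is degenerate (both contexts empty) are skipped.
    """
    records = []
    for node in tree.nodes:
        if node.is_leaf:
            continue
        left = [l.name for l in node.children[0].leaves()]
        right = [l.name for l in node.children[1].leaves()]
        fracs = []
        for a in left:
            for b in right:
                f = _pair_fraction(
                    chg_sets.get(a, set()), chg_sets.get(b, set()), mode
                )
                if f is not None:
                    fracs.append(f)
        if not fracs:
            continue
        records.append(
            RetentionRecord(
                node=node.label,
                retention=float(np.mean(fracs)),
                depth=tree.depth(node),
            )
        )
    return records


@dataclass
class RetentionSummary:
    """Per-event retention means plus the contrasts between event types."""

    means: dict                         # event -> mean retention
    counts: dict                        # event -> n records
    ranksum_p: dict                     # (event1, event2) -> two-sided P
    depth_rho: float
    depth_rho_p: float
    notices: list = field(default_factory=list)


def retention_by_event(
    records: Sequence[RetentionRecord],
    events: Optional[dict] = None,
) -> RetentionSummary:
    """Contrast retention between event classes and against depth.

    ``events`` maps node labels to "S" / "D" / "T" (ignored when the
    records already carry labels).  Wilcoxon rank-sum compares
    speciation vs duplication and transfer vs duplication; Pearson
    correlation relates retention to node depth.  Comparisons with
    fewer than 2 records per class are omitted with a notice.
    """
    labeled = []
    for r in records:
        ev = r.event if r.event is not None else (events or {}).get(r.node)
        if ev is None:
            continue
        labeled.append((ev, r))
    summary = RetentionSummary(
        means={}, counts={}, ranksum_p={}, depth_rho=math.nan, depth_rho_p=math.nan
    )
    by_event: dict[str, list[float]] = {}
    for ev, r in labeled:
        by_event.setdefault(ev, []).append(r.retention)
    for ev, vals in sorted(by_event.items()):
        summary.means[ev] = float(np.mean(vals))
        summary.counts[ev] = len(vals)
    for e1, e2 in (("S", "D"), ("T", "D")):
        v1, v2 = by_event.get(e1, []), by_event.get(e2, [])
        if len(v1) < 2 or len(v2) < 2:
            summary.notices.append(
                f"comparison {e1} vs {e2} omitted: fewer than 2 records per class"
            )
            continue
        if np.ptp(v1 + v2) == 0:
            summary.ranksum_p[(e1, e2)] = 1.0
            summary.notices.append(
                f"comparison {e1} vs {e2}: all retentions equal; P set to 1"
            )
            continue
        summary.ranksum_p[(e1, e2)] = float(stats.ranksums(v1, v2).pvalue)
    depths = [r.depth for _, r in labeled]
    rets = [r.retention for _, r in labeled]
    if len(labeled) >= 3 and np.ptp(depths) > 0 and np.ptp(rets) > 0:
        rho, p = stats.pearsonr(rets, depths)
        summary.depth_rho, summary.depth_rho_p = float(rho), float(p)
    else:
        summary.notices.append(
            "depth correlation undefined (constant retention or depth)"
        )
    return summary


def retention_table(records: Sequence[RetentionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "node": r.node,
                "event": r.event or "",
                "retention": r.retention,
                "depth": r.depth,
            }
            for r in records
        ],
        columns=["node", "event", "retention", "depth"],
    )
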