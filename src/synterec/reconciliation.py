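"""Dated duplication-transfer-loss (DTL) maximum-parsimony reconciliation.

The species tree is a chronogram cut into time slices (the intervals
between consecutive distinct internal-node ages).  A reconciliation embeds
the gene tree into the species tree: each gene node receives an event --
speciation (cost 0, at a species node), duplication (cost ``dup``, on a
species edge within a slice), or transfer (cost ``transfer``, the donor
edge keeps one child and the other child regrafts onto a different edge
alive in the *same* slice) -- and losses (cost ``loss`` each) accrue
whenever a lineage passes a speciation boundary and survives on only one
side.  Transfers between non-contemporaneous lineages are impossible by
construction, which is what makes the dated model stricter (and transfer
calls more conservative) than undated DTL parsimony.

A zero-cost *stem* cell above the species root hosts events ancestral to
the first speciation (duplications predating the root are otherwise
unrepresentable); placing the gene root there, or on any edge/slice,
carries no penalty.

The dynamic program computes the minimum cost together with the *exact*
number of optimal reconciliations (arbitrary-precision integers), which
in turn drives provably uniform sampling of optima by weighted
backtracking.
"""

from __future__ import annotations

import math
import random
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .trees import DatedSpeciesTree, GeneTree, TreeNode

INF = math.inf
_EPS = 1e-9

#: sentinel cell for the stem lineage above the species root
STEM = (-1, -1)


# ---------------------------------------------------------------------------
# Time slices
# ---------------------------------------------------------------------------

class SlicedTree:
    """A dated species tree with its derived time slices.

    Slices are numbered 1 (most recent, ending at the present) through
    ``n_slices`` (ending at the root age); slice ``s`` spans
    ``(boundary[s-1], boundary[s]]`` where the boundaries are the distinct
    internal-node ages (plus 0).  Edges are identified by their child
    node's postorder index; an edge belongs to every slice its time span
    covers, so within one slice the set of contemporaneous edges is
    constant.
    """

    def __init__(self, tree: DatedSpeciesTree, rel_tol: float = 1e-9):
        self.tree = tree
        internal_ages = sorted(n.age for n in tree.nodes if not n.is_leaf)
        boundaries: list[float] = []
        for a in internal_ages:
            if not boundaries or not math.isclose(
                a, boundaries[-1], rel_tol=rel_tol, abs_tol=1e-12
            ):
                boundaries.append(a)
        self.boundaries = boundaries          # ascending; hi of slice s is boundaries[s-1]
        self.n_slices = len(boundaries)
        self._bindex = {}                     # node index -> boundary index of its age
        for n in tree.nodes:
            if not n.is_leaf:
                for bi, b in enumerate(boundaries):
                    if math.isclose(n.age, b, rel_tol=rel_tol, abs_tol=1e-12):
                        self._bindex[n.index] = bi
                        break

        # per-edge alive range of slices (edge = non-root node)
        self.bottom_slice: dict[int, int] = {}
        self.top_slice: dict[int, int] = {}
        for n in tree.nodes:
            if n.parent is None:
                continue
            self.bottom_slice[n.index] = (
                1 if n.is_leaf else self._bindex[n.index] + 2
            )
            self.top_slice[n.index] = self._bindex[n.parent.index] + 1
        self.slice_edges: dict[int, list[int]] = {
            s: [] for s in range(1, self.n_slices + 1)
        }
        for ei, lo in self.bottom_slice.items():
            for s in range(lo, self.top_slice[ei] + 1):
                self.slice_edges[s].append(ei)
        for s in self.slice_edges:
            self.slice_edges[s].sort()
        self.leaf_edge = {
            n.name: n.index for n in tree.nodes if n.is_leaf
        }

    def slice_span(self, s: int) -> tuple[float, float]:
        lo = 0.0 if s == 1 else self.boundaries[s - 2]
        return lo, self.boundaries[s - 1]

    def edge_label(self, eidx: int) -> str:
        return self.tree.nodes[eidx].label


def build_time_slices(tree: DatedSpeciesTree) -> SlicedTree:
    """Derive the time-slice decomposition of a dated species tree."""
    return SlicedTree(tree)


# ---------------------------------------------------------------------------
# Cost schemes and reconciliation records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CostScheme:
    """Event costs; speciation is free.

    Defaults follow the grid commonly used for dated DTL scans of fungal
    gene families: duplication 4, transfer swept over 5..40, loss over
    {1, 2, 3}.
    """

    dup: float = 4.0
    transfer: float = 10.0
    loss: float = 1.0
    transfer_grid: tuple = tuple(range(5, 41))
    loss_grid: tuple = (1, 2, 3)

    def __post_init__(self):
        if self.dup < 0 or self.transfer < 0 or self.loss < 0:
            raise ValueError("event costs must be non-negative")


@dataclass
class NodeEvent:
    event: str                      # "S", "D", "T" or "leaf"
    species: str                    # species edge/node label ("s<k>" or "stem")
    slice: int                      # time slice (0 for stem / speciation-at-node)
    donor: Optional[str] = None     # transfer donor edge label
    recipient: Optional[str] = None  # transfer recipient edge label


@dataclass
class Reconciliation:
    """One complete embedding of a gene tree into the sliced species tree."""

    events: dict[str, NodeEvent]            # gene node label -> event
    losses: list[tuple[str, int]]           # (species edge label, slice)
    entries: dict[str, int]                 # species edge label -> lineages entering at top
    cost: float
    n_dup: int = 0
    n_transfer: int = 0

    @property
    def n_loss(self) -> int:
        return len(self.losses)

    def recomputed_cost(self, costs: CostScheme) -> float:
        return (
            costs.dup * self.n_dup
            + costs.transfer * self.n_transfer
            + costs.loss * self.n_loss
        )


# ---------------------------------------------------------------------------
# The dynamic program
# ---------------------------------------------------------------------------

def _combine(options: list[tuple[float, int]]) -> tuple[float, int]:
    best, cnt = INF, 0
    for c, n in options:
        if n == 0:
            continue
        if c < best - _EPS:
            best, cnt = c, n
        elif c <= best + _EPS:
            cnt += n
    return best, cnt


class _Agg:
    """Per-(gene child, slice) minima over contemporaneous edges,
    supporting 'best excluding one donor edge' queries for transfers."""

    __slots__ = ("min1", "cnt1", "nmin1", "min2", "cnt2")

    def __init__(self, vals: list[tuple[float, int]]):
        min1, cnt1, nmin1 = INF, 0, 0
        min2, cnt2 = INF, 0
        for c, n in vals:
            if n == 0:
                continue
            if c < min1 - _EPS:
                if nmin1:
                    min2, cnt2 = min1, cnt1
                min1, cnt1, nmin1 = c, n, 1
            elif c <= min1 + _EPS:
                cnt1 += n
                nmin1 += 1
            elif c < min2 - _EPS:
                min2, cnt2 = c, n
            elif c <= min2 + _EPS:
                cnt2 += n
        self.min1, self.cnt1, self.nmin1 = min1, cnt1, nmin1
        self.min2, self.cnt2 = min2, cnt2

    def best_excluding(self, cost: float, count: int) -> tuple[float, int]:
        """Best value over the other edges, given this donor edge's own
        (cost, count) contribution to the aggregates."""
        if count and cost <= self.min1 + _EPS and cost >= self.min1 - _EPS:
            if self.nmin1 > 1:
                return self.min1, self.cnt1 - count
            return self.min2, self.cnt2
        return self.min1, self.cnt1


class DTLReconciler:
    """Dated DTL parsimony for one gene tree / sliced species tree pair."""

    def __init__(self, gene: GeneTree, sliced: SlicedTree, costs: CostScheme):
        gene.validate_against(sliced.tree)
        self.gene = gene
        self.sliced = sliced
        self.costs = costs
        self._run_dp()

    # -- DP tables ---------------------------------------------------------

    def _run_dp(self) -> None:
        g, st, c = self.gene, self.sliced, self.costs
        k = st.n_slices
        snodes = st.tree.nodes
        root_children = [ch.index for ch in st.tree.root.children]
        self.D: list[dict] = [None] * len(g.nodes)
        self.E: list[dict] = [None] * len(g.nodes)

        for u in g.nodes:  # postorder: children first
            Du: dict = {}
            Eu: dict = {}
            if u.is_leaf:
                target = st.leaf_edge[g.species_of(u)]
                D1 = D2 = None
            else:
                u1, u2 = u.children
                D1, D2 = self.D[u1.index], self.D[u2.index]

            for s in range(1, k + 1):
                edges = st.slice_edges[s]
                if not u.is_leaf:
                    agg1 = _Agg([D1.get((e, s), (INF, 0)) for e in edges])
                    agg2 = _Agg([D2.get((e, s), (INF, 0)) for e in edges])
                for e in edges:
                    opts: list[tuple[float, int]] = []
                    if u.is_leaf:
                        if s == 1 and e == target:
                            opts.append((0.0, 1))
                    else:
                        c1, n1 = D1.get((e, s), (INF, 0))
                        c2, n2 = D2.get((e, s), (INF, 0))
                        # duplication: both children stay on this edge/slice
                        if n1 and n2:
                            opts.append((c.dup + c1 + c2, n1 * n2))
                        # transfer: one child stays, the other regrafts onto
                        # a different contemporaneous edge
                        if n1:
                            oc, on = agg2.best_excluding(c2, n2)
                            if on:
                                opts.append((c.transfer + c1 + oc, n1 * on))
                        if n2:
                            oc, on = agg1.best_excluding(c1, n1)
                            if on:
                                opts.append((c.transfer + c2 + oc, n2 * on))
                        # speciation at the node closing this edge
                        enode = snodes[e]
                        if not enode.is_leaf and st.bottom_slice[e] == s:
                            f1, f2 = (ch.index for ch in enode.children)
                            a1, m1 = D1.get((f1, s - 1), (INF, 0))
                            a2, m2 = D2.get((f2, s - 1), (INF, 0))
                            if m1 and m2:
                                opts.append((a1 + a2, m1 * m2))
                            b1, l1 = D1.get((f2, s - 1), (INF, 0))
                            b2, l2 = D2.get((f1, s - 1), (INF, 0))
                            if l1 and l2:
                                opts.append((b1 + b2, l1 * l2))
                    Eu[(e, s)] = _combine(opts)

                    # descend: event lower down this edge's subtree
                    dopts = [Eu[(e, s)]]
                    if st.bottom_slice[e] == s:
                        enode = snodes[e]
                        if not enode.is_leaf:
                            for f in enode.children:
                                fc, fn = Du.get((f.index, s - 1), (INF, 0))
                                if fn:
                                    dopts.append((c.loss + fc, fn))
                    else:
                        dopts.append(Du.get((e, s - 1), (INF, 0)))
                    Du[(e, s)] = _combine(dopts)

            # stem cell above the species root
            opts = []
            if not u.is_leaf:
                c1, n1 = D1.get(STEM, (INF, 0))
                c2, n2 = D2.get(STEM, (INF, 0))
                if n1 and n2:
                    opts.append((c.dup + c1 + c2, n1 * n2))
                f1, f2 = root_children
                a1, m1 = D1.get((f1, k), (INF, 0))
                a2, m2 = D2.get((f2, k), (INF, 0))
                if m1 and m2:
                    opts.append((a1 + a2, m1 * m2))
                b1, l1 = D1.get((f2, k), (INF, 0))
                b2, l2 = D2.get((f1, k), (INF, 0))
                if l1 and l2:
                    opts.append((b1 + b2, l1 * l2))
            Eu[STEM] = _combine(opts)
            dopts = [Eu[STEM]]
            for f in root_children:
                fc, fn = Du.get((f, k), (INF, 0))
                if fn:
                    dopts.append((c.loss + fc, fn))
            Du[STEM] = _combine(dopts)

            self.D[u.index] = Du
            self.E[u.index] = Eu

        # root: its event may sit at any cell (or the stem), no penalty above
        root_opts = list(self.E[g.root.index].values())
        self.min_cost, self.n_optima = _combine(root_opts)
        if self.n_optima == 0:
            raise ValueError("no feasible reconciliation (unmapped leaves?)")

    # -- sampling ----------------------------------------------------------

    def sample(self, n: int, seed: int) -> list[Reconciliation]:
        """Draw ``n`` reconciliations uniformly from the set of optima.

        Sampling backtracks through the DP weighted by the exact optimum
        counts, so every optimal reconciliation has probability
        ``1 / n_optima``; a fixed seed reproduces the sample exactly.
        """
        if n <= 0:
            raise ValueError("sample size must be positive")
        rng = random.Random(seed)
        Eroot = self.E[self.gene.root.index]
        cells = [
            (cell, cnt)
            for cell, (cost, cnt) in sorted(Eroot.items())
            if cnt and cost <= self.min_cost + _EPS
        ]
        out = []
        for _ in range(n):
            rec = Reconciliation(events={}, losses=[], entries={}, cost=self.min_cost)
            cell = self._weighted_choice(rng, cells)
            self._expand_event(rng, self.gene.root, cell, rec)
            assert (
                abs(rec.recomputed_cost(self.costs) - self.min_cost) < 1e-6
            ), "sampled reconciliation cost mismatch"
            out.append(rec)
        return out

    @staticmethod
    def _weighted_choice(rng, options):
        total = sum(w for _, w in options)
        r = rng.randrange(total)
        for item, w in options:
            if r < w:
                return item
            r -= w
        raise AssertionError("weighted choice fell through")

    def _expand_event(self, rng, u: TreeNode, cell, rec: Reconciliation) -> None:
        """Realize gene node u's event at the given cell and recurse."""
        g, st, c = self.gene, self.sliced, self.costs
        target_cost, _ = self.E[u.index][cell]
        snodes = st.tree.nodes

        if u.is_leaf:
            e, s = cell
            rec.events[u.label] = NodeEvent("leaf", st.edge_label(e), s)
            return

        u1, u2 = u.children
        D1, D2 = self.D[u1.index], self.D[u2.index]
        options = []  # (descriptor, count)

        if cell == STEM:
            c1, n1 = D1.get(STEM, (INF, 0))
            c2, n2 = D2.get(STEM, (INF, 0))
            if n1 and n2 and abs(c.dup + c1 + c2 - target_cost) < _EPS:
                options.append((("D", STEM, STEM), n1 * n2))
            f1, f2 = (ch.index for ch in st.tree.root.children)
            k = st.n_slices
            for a, b in ((f1, f2), (f2, f1)):
                x1, m1 = D1.get((a, k), (INF, 0))
                x2, m2 = D2.get((b, k), (INF, 0))
                if m1 and m2 and abs(x1 + x2 - target_cost) < _EPS:
                    options.append((("S", (a, k), (b, k)), m1 * m2))
            kind, cell1, cell2 = self._weighted_choice(rng, options)
            label = "stem" if kind == "D" else st.tree.root.label
            rec.events[u.label] = NodeEvent(kind, label, 0)
            if kind == "D":
                rec.n_dup += 1
            else:
                rec.entries[st.edge_label(cell1[0])] = (
                    rec.entries.get(st.edge_label(cell1[0]), 0) + 1
                )
                rec.entries[st.edge_label(cell2[0])] = (
                    rec.entries.get(st.edge_label(cell2[0]), 0) + 1
                )
            self._descend(rng, u1, cell1, rec)
            self._descend(rng, u2, cell2, rec)
            return

        e, s = cell
        edges = st.slice_edges[s]
        c1, n1 = D1.get((e, s), (INF, 0))
        c2, n2 = D2.get((e, s), (INF, 0))
        if n1 and n2 and abs(c.dup + c1 + c2 - target_cost) < _EPS:
            options.append((("D", (e, s), (e, s), None), n1 * n2))
        for e2 in edges:
            if e2 == e:
                continue
            o2, m2 = D2.get((e2, s), (INF, 0))
            if n1 and m2 and abs(c.transfer + c1 + o2 - target_cost) < _EPS:
                options.append((("T", (e, s), (e2, s), e2), n1 * m2))
            o1, m1 = D1.get((e2, s), (INF, 0))
            if n2 and m1 and abs(c.transfer + o1 + c2 - target_cost) < _EPS:
                options.append((("Trev", (e2, s), (e, s), e2), m1 * n2))
        enode = snodes[e]
        if not enode.is_leaf and st.bottom_slice[e] == s:
            f1, f2 = (ch.index for ch in enode.children)
            for a, b in ((f1, f2), (f2, f1)):
                x1, m1 = D1.get((a, s - 1), (INF, 0))
                x2, m2 = D2.get((b, s - 1), (INF, 0))
                if m1 and m2 and abs(x1 + x2 - target_cost) < _EPS:
                    options.append((("S", (a, s - 1), (b, s - 1), None), m1 * m2))

        kind, cell1, cell2, extra = self._weighted_choice(rng, options)
        if kind == "D":
            rec.events[u.label] = NodeEvent("D", st.edge_label(e), s)
            rec.n_dup += 1
        elif kind in ("T", "Trev"):
            rec.events[u.label] = NodeEvent(
                "T", st.edge_label(e), s,
                donor=st.edge_label(e), recipient=st.edge_label(extra),
            )
            rec.n_transfer += 1
        else:
            rec.events[u.label] = NodeEvent("S", enode.label, s)
            for cl in (cell1, cell2):
                lbl = st.edge_label(cl[0])
                rec.entries[lbl] = rec.entries.get(lbl, 0) + 1
        self._descend(rng, u1, cell1, rec)
        self._descend(rng, u2, cell2, rec)

    def _descend(self, rng, u: TreeNode, cell, rec: Reconciliation) -> None:
        """Walk gene lineage u down from its placement cell to its event,
        recording losses at one-sided speciation passages."""
        st, c = self.sliced, self.costs
        while True:
            target_cost, _ = self.D[u.index][cell]
            options = []
            ec, en = self.E[u.index].get(cell, (INF, 0))
            if en and abs(ec - target_cost) < _EPS:
                options.append((("event", None), en))
            if cell == STEM:
                k = st.n_slices
                for f in st.tree.root.children:
                    fc, fn = self.D[u.index].get((f.index, k), (INF, 0))
                    if fn and abs(c.loss + fc - target_cost) < _EPS:
                        options.append((("pass", (f.index, k)), fn))
            else:
                e, s = cell
                enode = st.tree.nodes[e]
                if st.bottom_slice[e] == s:
                    if not enode.is_leaf:
                        for f in enode.children:
                            fc, fn = self.D[u.index].get((f.index, s - 1), (INF, 0))
                            if fn and abs(c.loss + fc - target_cost) < _EPS:
                                options.append((("pass", (f.index, s - 1)), fn))
                else:
                    fc, fn = self.D[u.index].get((e, s - 1), (INF, 0))
                    if fn and abs(fc - target_cost) < _EPS:
                        options.append((("cont", (e, s - 1)), fn))
            kind, nxt = self._weighted_choice(rng, options)
            if kind == "event":
                self._expand_event(rng, u, cell, rec)
                return
            if kind == "pass":
                # surviving side nxt; the sibling edge is lost
                if cell == STEM:
                    siblings = [ch.index for ch in st.tree.root.children]
                else:
                    siblings = [
                        ch.index for ch in st.tree.nodes[cell[0]].children
                    ]
                lost = [f for f in siblings if f != nxt[0]][0]
                rec.losses.append((st.edge_label(lost), nxt[1]))
                lbl = st.edge_label(nxt[0])
                rec.entries[lbl] = rec.entries.get(lbl, 0) + 1
            cell = nxt


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def mpr_cost(
    gene: GeneTree, sliced: SlicedTree, costs: CostScheme
) -> tuple[float, int]:
    """Minimum reconciliation cost and the exact number of optima."""
    r = DTLReconciler(gene, sliced, costs)
    return r.min_cost, r.n_optima


def sample_optima(
    gene: GeneTree,
    sliced: SlicedTree,
    costs: CostScheme,
    n: int = 1000,
    seed: int = 0,
) -> list[Reconciliation]:
    """Uniform sample of ``n`` maximum-parsimony reconciliations."""
    return DTLReconciler(gene, sliced, costs).sample(n, seed)


def lca_dl_reconcile(
    gene: GeneTree, tree: DatedSpeciesTree, dup: float = 4.0, loss: float = 1.0
) -> Reconciliation:
    """Classical LCA duplication-loss reconciliation (the transfer-free,
    undated limit of the DTL model; closed form, no search)."""
    mapping: dict[int, TreeNode] = {}
    depth = {n.index: tree.depth(n) for n in tree.nodes}
    events: dict[str, NodeEvent] = {}
    n_dup = 0
    n_loss = 0
    for u in gene.nodes:
        if u.is_leaf:
            sp = gene.species_of(u)
            if sp not in tree.by_name:
                raise ValueError(f"leaf species {sp!r} absent from species tree")
            mapping[u.index] = tree.by_name[sp]
            events[u.label] = NodeEvent("leaf", tree.by_name[sp].label, 1)
        else:
            m1 = mapping[u.children[0].index]
            m2 = mapping[u.children[1].index]
            m = tree._lca2(m1, m2)
            mapping[u.index] = m
            is_dup = m is m1 or m is m2
            if is_dup:
                n_dup += 1
                events[u.label] = NodeEvent("D", m.label, 0)
            else:
                events[u.label] = NodeEvent("S", m.label, 0)
            for child in u.children:
                mc = mapping[child.index]
                gap = depth[mc.index] - depth[m.index]
                n_loss += gap if is_dup else max(gap - 1, 0)
    rec = Reconciliation(
        events=events,
        losses=[("", 0)] * n_loss,
        entries={},
        cost=dup * n_dup + loss * n_loss,
        n_dup=n_dup,
    )
    return rec


# ---------------------------------------------------------------------------
# Event-support profiling over the cost grid
# ---------------------------------------------------------------------------

@dataclass
class EventSupportGrid:
    """Per-(transfer cost, loss cost) event frequencies over sampled optima."""

    tree_id: str
    dup: float
    thetas: tuple
    losses: tuple
    n_samples: int
    #: (theta, L) -> gene node label -> {"S": f, "D": f, "T": f, "leaf": f}
    support: dict = field(default_factory=dict)
    #: (theta, L) -> gene node label -> modal (species, ...) mapping
    mapping: dict = field(default_factory=dict)
    #: (theta, L) -> gene node label -> modal (donor, recipient) among T samples
    transfer_pairs: dict = field(default_factory=dict)
    #: gene node label -> frozenset of leaf names (bipartition identity)
    bipartitions: dict = field(default_factory=dict)


def _substream_seed(seed: int, tree_id: str, dup: float, theta: float, L: float) -> int:
    key = f"{tree_id}|{dup}|{theta}|{L}".encode()
    return (int(seed) * 2654435761 + zlib.crc32(key)) % (2**31 - 1)


def event_support(
    gene: GeneTree,
    sliced: SlicedTree,
    dup: float = 4.0,
    thetas: Sequence[float] = tuple(range(5, 41)),
    losses: Sequence[float] = (1, 2, 3),
    n: int = 1000,
    seed: int = 0,
    tree_id: str = "tree",
) -> EventSupportGrid:
    """Sample optima at every (theta, L) combination and tabulate per-node
    event frequencies.

    Sub-streams are keyed by (tree id, dup, theta, L), so enlarging the
    grid never perturbs frequencies already computed for other cells.
    """
    if not thetas or not losses:
        raise ValueError("cost grid must be non-empty")
    grid = EventSupportGrid(
        tree_id=tree_id, dup=dup, thetas=tuple(thetas),
        losses=tuple(losses), n_samples=n,
    )
    for u in gene.nodes:
        grid.bipartitions[u.label] = gene.leaf_set(u)
    for L in losses:
        for theta in thetas:
            costs = CostScheme(dup=dup, transfer=theta, loss=L)
            recs = sample_optima(
                gene, sliced, costs, n=n,
                seed=_substream_seed(seed, tree_id, dup, theta, L),
            )
            cell_sup: dict[str, dict[str, float]] = {}
            cell_map: dict[str, str] = {}
            cell_pairs: dict[str, tuple[str, str]] = {}
            for u in gene.nodes:
                tally: dict[str, int] = {}
                where: dict[str, int] = {}
                pairs: dict[tuple[str, str], int] = {}
                for rec in recs:
                    ev = rec.events[u.label]
                    tally[ev.event] = tally.get(ev.event, 0) + 1
                    where[ev.species] = where.get(ev.species, 0) + 1
                    if ev.event == "T":
                        key = (ev.donor, ev.recipient)
                        pairs[key] = pairs.get(key, 0) + 1
                cell_sup[u.label] = {k: v / n for k, v in tally.items()}
                cell_map[u.label] = min(
                    where.items(), key=lambda kv: (-kv[1], kv[0])
                )[0]
                if pairs:
                    cell_pairs[u.label] = min(
                        pairs.items(), key=lambda kv: (-kv[1], kv[0])
                    )[0]
            grid.support[(theta, L)] = cell_sup
            grid.mapping[(theta, L)] = cell_map
            grid.transfer_pairs[(theta, L)] = cell_pairs
    return grid


@dataclass
class TransferCall:
    """A putative horizontal transfer with its robustness bookkeeping."""

    node: str
    donor: Optional[str]
    recipient: Optional[str]
    top_cost: float                         # max theta with majority support at the reporting L
    consistent: bool
    majorities: dict                        # (theta, L) -> bool
    tree_id: str = "tree"


def _consistent_in_grid(
    grid: EventSupportGrid, node: str, majority: float, n_consecutive: int
) -> bool:
    """Majority transfer support at >= n_consecutive consecutive theta
    values for every loss cost in the grid."""
    for L in grid.losses:
        run = best = 0
        for theta in grid.thetas:
            frac = grid.support[(theta, L)].get(node, {}).get("T", 0.0)
            run = run + 1 if frac > majority else 0
            best = max(best, run)
        if best < min(n_consecutive, len(grid.thetas)):
            return False
    return True


def call_transfers(
    grids: Union[EventSupportGrid, Sequence[EventSupportGrid]],
    majority: float = 0.5,
    report_loss: float = 1,
    n_consecutive: int = 2,
) -> list[TransferCall]:
    """Turn event-support grids into transfer calls.

    A gene node is called iff its transfer fraction exceeds ``majority``
    in some grid cell.  The *top transfer cost* is the largest theta with
    majority support at the reporting loss cost; a call is *consistent*
    when majority support holds over >= ``n_consecutive`` consecutive
    theta values for every loss cost, on every supplied topology that
    contains the node's bipartition.
    """
    if isinstance(grids, EventSupportGrid):
        grids = [grids]
    calls: list[TransferCall] = []
    for grid in grids:
        for node in sorted(grid.bipartitions):
            majorities = {}
            any_majority = False
            for (theta, L), sup in grid.support.items():
                frac = sup.get(node, {}).get("T", 0.0)
                majorities[(theta, L)] = frac > majority
                any_majority = any_majority or frac > majority
            if not any_majority:
                continue
            rl = report_loss if report_loss in grid.losses else grid.losses[0]
            tops = [t for t in grid.thetas if majorities.get((t, rl))]
            top = max(tops) if tops else min(grid.thetas)
            consistent = _consistent_in_grid(grid, node, majority, n_consecutive)
            # cross-check on every other topology containing the bipartition
            bip = grid.bipartitions[node]
            for other in grids:
                if other is grid:
                    continue
                match = [
                    nd for nd, b in other.bipartitions.items() if b == bip
                ]
                if match:
                    consistent = consistent and _consistent_in_grid(
                        other, match[0], majority, n_consecutive
                    )
            donor = recipient = None
            pair = grid.transfer_pairs.get((top, rl), {}).get(node)
            if pair is None:
                for cell in sorted(grid.transfer_pairs):
                    if node in grid.transfer_pairs[cell]:
                        pair = grid.transfer_pairs[cell][node]
                        break
            if pair is not None:
                donor, recipient = pair
            calls.append(
                TransferCall(
                    node=node, donor=donor, recipient=recipient,
                    top_cost=top, consistent=consistent,
                    majorities=majorities, tree_id=grid.tree_id,
                )
            )
    return calls


def transfer_report(calls: list[TransferCall]) -> pd.DataFrame:
    """Tabular transfer report: one row per call."""
    rows = []
    for c in calls:
        rows.append(
            {
                "tree": c.tree_id,
                "node": c.node,
                "donor": c.donor,
                "recipient": c.recipient,
                "top_transfer_cost": c.top_cost,
                "consistent": c.consistent,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["tree", "node", "donor", "recipient", "top_transfer_cost", "consistent"],
    )


# ---------------------------------------------------------------------------
# Per-species-branch event summaries
# ---------------------------------------------------------------------------

def summarize_events_on_species(
    recs_by_family: Union[list[Reconciliation], list[list[Reconciliation]]],
    sliced: SlicedTree,
) -> pd.DataFrame:
    """Per-species-branch duplication / loss / resident-gene summary.

    For each gene family the sampled optima are summarized per species
    edge by the modal per-sample tally (ties toward the smaller count);
    families are then summed.  Gene counts are lineages crossing the
    branch's top boundary.
    """
    if recs_by_family and isinstance(recs_by_family[0], Reconciliation):
        recs_by_family = [recs_by_family]  # type: ignore[list-item]
    edges = [n.label for n in sliced.tree.nodes if n.parent is not None]
    totals = {e: {"duplications": 0, "losses": 0, "genes": 0} for e in edges}
    for recs in recs_by_family:
        per_edge: dict[str, dict[str, list[int]]] = {
            e: {"duplications": [], "losses": [], "genes": []} for e in edges
        }
        for rec in recs:
            dup_tally = {e: 0 for e in edges}
            loss_tally = {e: 0 for e in edges}
            for ev in rec.events.values():
                if ev.event == "D" and ev.species in dup_tally:
                    dup_tally[ev.species] += 1
            for edge_lbl, _slice in rec.losses:
                loss_tally[edge_lbl] += 1
            for e in edges:
                per_edge[e]["duplications"].append(dup_tally[e])
                per_edge[e]["losses"].append(loss_tally[e])
                per_edge[e]["genes"].append(rec.entries.get(e, 0))
        for e in edges:
            for key in ("duplications", "losses", "genes"):
                vals = per_edge[e][key]
                counts: dict[int, int] = {}
                for v in vals:
                    counts[v] = counts.get(v, 0) + 1
                modal = min(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0]
                totals[e][key] += modal
    rows = [
        {"branch": e, **totals[e]} for e in edges
    ]
    return pd.DataFrame(rows, columns=["branch", "duplications", "losses", "genes"])


def events_table(recs: list[Reconciliation], sample_ids: Optional[list] = None) -> pd.DataFrame:
    """Flat events table (one row per gene node per sampled reconciliation)."""
    rows = []
    for i, rec in enumerate(recs):
        sid = sample_ids[i] if sample_ids else i
        for label in sorted(rec.events, key=lambda l: (len(l), l)):
            ev = rec.events[label]
            rows.append(
                {
                    "sample": sid,
                    "gene_node": label,
                    "event": ev.event,
                    "species": ev.species,
                    "slice": ev.slice,
                    "donor": ev.donor or "",
                    "recipient": ev.recipient or "",
                }
            )
    return pd.DataFrame(
        rows,
        columns=["sample", "gene_node", "event", "species", "slice", "donor", "recipient"],
    )
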