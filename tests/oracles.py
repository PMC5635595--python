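"""Independent oracles used by the test suite.

The DTL oracle here enumerates *complete* reconciliation scenarios
(event tuples plus loss placements) by explicit recursion over descent
paths and event choices, computing each scenario's cost from its event
multiset.  It shares nothing with the production dynamic program beyond
the time-slice decomposition, and is feasible only for tiny instances —
which is exactly its job.
"""

from __future__ import annotations

import itertools
from collections import Counter

from synterec.reconciliation import STEM, CostScheme, SlicedTree
from synterec.trees import GeneTree


def _descents(sliced: SlicedTree, cell):
    """All cells reachable from ``cell`` by pure descent, with the loss
    records ((lost edge label, slice)) accumulated along the way."""
    yield cell, ()
    if cell == STEM:
        root = sliced.tree.root
        k = sliced.n_slices
        for f in root.children:
            lost = [c for c in root.children if c is not f][0]
            for sub, losses in _descents(sliced, (f.index, k)):
                yield sub, ((lost.label, k),) + losses
        return
    e, s = cell
    enode = sliced.tree.nodes[e]
    if sliced.bottom_slice[e] == s:
        if enode.is_leaf:
            return
        for f in enode.children:
            lost = [c for c in enode.children if c is not f][0]
            for sub, losses in _descents(sliced, (f.index, s - 1)):
                yield sub, ((lost.label, s - 1),) + losses
    else:
        for sub, losses in _descents(sliced, (e, s - 1)):
            yield sub, losses


def _event_options(gene: GeneTree, sliced: SlicedTree, u, cell):
    """All events gene node u can undergo at ``cell``.

    Yields (event record, event kind, [(child, placement cell), ...]).
    Event records are (label, kind, location label, slice, recipient).
    """
    snodes = sliced.tree.nodes
    if cell == STEM:
        if u.is_leaf:
            return
        u1, u2 = u.children
        yield (u.label, "D", "stem", 0, None), "D", [(u1, STEM), (u2, STEM)]
        root = sliced.tree.root
        f1, f2 = root.children
        k = sliced.n_slices
        for a, b in ((f1, f2), (f2, f1)):
            yield (
                (u.label, "S", root.label, 0, None),
                "S",
                [(u1, (a.index, k)), (u2, (b.index, k))],
            )
        return
    e, s = cell
    if u.is_leaf:
        if s == 1 and e == sliced.leaf_edge[gene.species_of(u)]:
            yield (u.label, "leaf", sliced.edge_label(e), 1, None), "leaf", []
        return
    u1, u2 = u.children
    yield (
        (u.label, "D", sliced.edge_label(e), s, None),
        "D",
        [(u1, (e, s)), (u2, (e, s))],
    )
    for e2 in sliced.slice_edges[s]:
        if e2 == e:
            continue
        yield (
            (u.label, "T", sliced.edge_label(e), s, sliced.edge_label(e2)),
            "T",
            [(u1, (e, s)), (u2, (e2, s))],
        )
        yield (
            (u.label, "T", sliced.edge_label(e), s, sliced.edge_label(e2)),
            "T",
            [(u1, (e2, s)), (u2, (e, s))],
        )
    enode = snodes[e]
    if not enode.is_leaf and sliced.bottom_slice[e] == s:
        f1, f2 = enode.children
        for a, b in ((f1, f2), (f2, f1)):
            yield (
                (u.label, "S", enode.label, s, None),
                "S",
                [(u1, (a.index, s - 1)), (u2, (b.index, s - 1))],
            )


def _scenarios(gene: GeneTree, sliced: SlicedTree, u, placement, cache):
    """All completions of gene subtree u placed (entering) at ``placement``.

    Returns a list of (events tuple, losses tuple, (n_dup, n_transfer)).
    Results are cached per (node, placement): the same exhaustive list,
    computed once.
    """
    key = (id(u), placement)
    if key in cache:
        return cache[key]
    out = []
    for cell, path_losses in _descents(sliced, placement):
        out.extend(_scenarios_at(gene, sliced, u, cell, path_losses, cache))
    cache[key] = out
    return out


def _scenarios_at(gene, sliced, u, cell, path_losses, cache):
    for record, kind, child_placements in _event_options(gene, sliced, u, cell):
        d = 1 if kind == "D" else 0
        t = 1 if kind == "T" else 0
        if not child_placements:
            yield (record,), path_losses, (d, t)
            continue
        child_lists = [
            _scenarios(gene, sliced, ch, pl, cache) for ch, pl in child_placements
        ]
        for combo in itertools.product(*child_lists):
            events = (record,)
            losses = path_losses
            dd, tt = d, t
            for ev, lo, (cd, ct) in combo:
                events += ev
                losses += lo
                dd += cd
                tt += ct
            yield events, losses, (dd, tt)


def enumerate_reconciliations(gene: GeneTree, sliced: SlicedTree, costs: CostScheme):
    """Exhaustively enumerate every time-consistent reconciliation.

    Returns (list of (cost, canonical scenario), Counter cost -> count).
    The gene root's event may sit at any cell or the stem, with no losses
    charged above it.
    """
    cells = [STEM] + [
        (e, s) for s in range(1, sliced.n_slices + 1) for e in sliced.slice_edges[s]
    ]
    cache: dict = {}
    out = []
    for cell in cells:
        for events, losses, (d, t) in _scenarios_at(gene, sliced, gene.root, cell, (), cache):
            cost = costs.dup * d + costs.transfer * t + costs.loss * len(losses)
            canon = (tuple(sorted(events)), tuple(sorted(losses)))
            out.append((cost, canon))
    seen = set()
    for _, canon in out:
        assert canon not in seen, f"oracle produced duplicate scenario {canon}"
        seen.add(canon)
    dist = Counter(cost for cost, _ in out)
    return out, dist


def brute_min_and_count(gene: GeneTree, sliced: SlicedTree, costs: CostScheme):
    """Minimum cost and exact optimum count by full enumeration."""
    scenarios, dist = enumerate_reconciliations(gene, sliced, costs)
    best = min(dist)
    return best, dist[best]


def optimal_scenarios(gene: GeneTree, sliced: SlicedTree, costs: CostScheme):
    """Canonical tuples of all minimum-cost scenarios."""
    scenarios, dist = enumerate_reconciliations(gene, sliced, costs)
    best = min(dist)
    return {canon for cost, canon in scenarios if cost == best}


def reconciliation_to_canon(rec):
    """Canonical tuple of a production Reconciliation, comparable with the
    oracle's scenario representation."""
    events = tuple(
        sorted(
            (label, ev.event, ev.species, ev.slice, ev.recipient)
            for label, ev in rec.events.items()
        )
    )
    losses = tuple(sorted(rec.losses))
    return events, losses
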