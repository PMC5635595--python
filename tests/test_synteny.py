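"""Neighborhood windows, Fisher exact scan, reporting rules, retention."""

from __future__ import annotations

import itertools
import math
import random

import pytest
from scipy import stats as sstats

from conftest import gene
from synterec.io_formats import AnnotationTable
from synterec.synteny import (
    Neighborhood,
    clade_chg_scan,
    extract_neighborhoods,
    fisher_exact_2x2,
    neighborhood_retention,
    retention_by_event,
    select_reported,
)
from synterec.synthetic_data import (
    PlantedAssociation,
    SimConfig,
    simulate_retention_decay,
    simulate_retention_pairs,
)
from synterec.trees import GeneTree, TreeNode


def linear_annotation(n: int, scaffold: str = "scf1") -> AnnotationTable:
    return AnnotationTable.from_records(
        [(f"g{i}", scaffold, 100 * i + 1, 100 * i + 50, "+") for i in range(n)]
    )


class TestNeighborhoods:
    def test_truncated_at_scaffold_start(self):
        ann = linear_annotation(30)
        (nb,) = extract_neighborhoods(ann, ["g0"], w=20)
        assert len(nb.neighbors) == 20
        assert "g0" not in nb.neighbors

    def test_mid_scaffold_full_window(self):
        ann = linear_annotation(100)
        (nb,) = extract_neighborhoods(ann, ["g50"], w=20)
        assert len(nb.neighbors) == 40

    def test_nearby_focal_genes_see_each_other(self):
        ann = linear_annotation(30)
        nbs = extract_neighborhoods(ann, ["g10", "g15"], w=20)
        assert "g15" in nbs[0].neighbors and "g10" in nbs[1].neighbors

    def test_absent_focal_errors(self):
        with pytest.raises(ValueError, match="zz"):
            extract_neighborhoods(linear_annotation(5), ["zz"])


class TestFisher:
    def test_diagonal_4_table(self):
        p, _ = fisher_exact_2x2([[4, 0], [0, 4]])
        assert p == pytest.approx(2 / 70)

    def test_flat_table_p_one(self):
        p, odds = fisher_exact_2x2([[2, 2], [2, 2]])
        assert p == pytest.approx(1.0)
        assert odds == pytest.approx(1.0)

    def test_diagonal_10_table(self):
        p, _ = fisher_exact_2x2([[10, 0], [0, 10]])
        assert p == pytest.approx(2 / math.comb(20, 10))

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[0, 0], [0, 0]])

    def test_haldane_odds_on_zero_cell(self):
        _, odds = fisher_exact_2x2([[3, 0], [1, 4]])
        assert odds == pytest.approx((3.5 * 4.5) / (0.5 * 1.5))

    def test_matches_scipy_exhaustively_small_totals(self):
        """Exact agreement with the independent implementation for every
        2x2 table with total <= 30."""
        for n in range(1, 31):
            for a in range(n + 1):
                for b in range(n - a + 1):
                    for c in range(n - a - b + 1):
                        d = n - a - b - c
                        p, _ = fisher_exact_2x2([[a, b], [c, d]])
                        ref = sstats.fisher_exact([[a, b], [c, d]])[1]
                        assert p == pytest.approx(ref, rel=1e-9), (a, b, c, d)


def balanced_tree(names):
    nodes = [TreeNode(n) for n in names]
    while len(nodes) > 1:
        nxt = []
        for i in range(0, len(nodes), 2):
            p = TreeNode()
            p.add_child(nodes[i])
            p.add_child(nodes[i + 1])
            nxt.append(p)
        nodes = nxt
    return GeneTree(nodes[0], species_map={n: n for n in names})


class TestCladeScan:
    def test_ubiquitous_chg_never_reported(self):
        names = [f"x{i}" for i in range(8)]
        t = balanced_tree(names)
        nbs = [Neighborhood(n, [], chg_presence={"ch1"}) for n in names]
        res = clade_chg_scan(t, nbs, ["ch1"], min_clade=4)
        assert all(r.raw_p == 1.0 for r in res)
        assert not any(r.reported for r in res)

    def test_exclusive_clade_association_closed_form(self):
        """CHG present exactly in one 4-leaf clade of an 8-leaf balanced
        tree: raw P is the hypergeometric 2/70 and Bonferroni multiplies
        by the number of subtree x CHG tests."""
        names = [f"x{i}" for i in range(8)]
        t = balanced_tree(names)
        inside = set(names[:4])
        nbs = [
            Neighborhood(n, [], chg_presence={"ch1"} if n in inside else set())
            for n in names
        ]
        res = clade_chg_scan(t, nbs, ["ch1"], min_clade=4, alpha=0.1)
        # eligible subtrees: the two 4-leaf halves (root excluded)
        assert len(res) == 2
        hit = [r for r in res if r.in_with == 4][0]
        assert hit.raw_p == pytest.approx(2 / 70)
        assert hit.corrected_p == pytest.approx(2 / 70 * 2)
        assert hit.reported

    def test_planted_association_recovered_in_large_tree(self):
        cfg = SimConfig(seed=3)
        names = [f"y{i}" for i in range(64)]
        t = balanced_tree(names)
        clade = {l.name for l in t.nodes[22].leaves()} if not t.nodes[
            22
        ].is_leaf else set(names[:8])
        rng = random.Random(9)
        nbs = []
        for n in names:
            present = rng.random() < (0.95 if n in clade else 0.05)
            nbs.append(
                Neighborhood(n, [], chg_presence={"chP"} if present else set())
            )
        res = clade_chg_scan(t, nbs, ["chP"], min_clade=5, alpha=1e-4)
        reported = [r for r in res if r.reported]
        assert len(reported) == 1
        rep_leaves = {
            l.name for l in t.by_label[reported[0].clade].leaves()
        }
        # reported clade closely matches the planted one
        assert len(rep_leaves ^ clade) <= 2

    def test_missing_neighborhood_errors(self):
        names = [f"x{i}" for i in range(8)]
        t = balanced_tree(names)
        nbs = [Neighborhood(n, [], set()) for n in names[:-1]]
        with pytest.raises(ValueError, match="x7"):
            clade_chg_scan(t, nbs, ["ch1"])


class TestSelectReported:
    def _scan(self, presence_by_leaf, chg="ch1", min_clade=2, alpha=0.05):
        names = sorted(presence_by_leaf)
        t = balanced_tree(names)
        nbs = [
            Neighborhood(
                n, [], chg_presence={chg} if presence_by_leaf[n] else set()
            )
            for n in names
        ]
        return t, clade_chg_scan(t, nbs, [chg], min_clade=min_clade, alpha=alpha)

    def test_two_disjoint_significant_clades_both_reported(self):
        # 32 leaves; CHG exclusively in leaves 0-7 and 16-23 (two disjoint
        # 8-leaf clades); both enrichments must be reported, and every
        # reported subtree (including depleted complements, found by the
        # two-sided test) must be pairwise nonoverlapping
        presence = {f"x{i:02d}": (i < 8 or 16 <= i < 24) for i in range(32)}
        t, res = self._scan(presence, min_clade=8, alpha=0.05)
        reported = [r for r in res if r.reported]
        enriched = {r.clade for r in reported if r.odds_ratio > 1}
        planted = {
            n.label
            for n in t.nodes
            if not n.is_leaf
            and {l.name for l in n.leaves()}
            in ({f"x{i:02d}" for i in range(8)}, {f"x{i:02d}" for i in range(16, 24)})
        }
        assert planted <= enriched
        leafsets = [
            {l.name for l in t.by_label[r.clade].leaves()} for r in reported
        ]
        for a, b in itertools.combinations(leafsets, 2):
            assert not (a & b)

    def test_nested_significant_clades_only_best_reported(self):
        presence = {f"x{i:02d}": i < 4 for i in range(16)}
        t, res = self._scan(presence, min_clade=4, alpha=0.05)
        reported = [r for r in res if r.reported]
        assert len(reported) == 1
        assert {l.name for l in t.by_label[reported[0].clade].leaves()} == {
            f"x{i:02d}" for i in range(4)
        }

    def test_local_minimum_is_the_peak_clade(self):
        presence = {f"x{i:02d}": i < 4 for i in range(16)}
        t, res = self._scan(presence, min_clade=4, alpha=0.5)
        best = min(res, key=lambda r: r.corrected_p)
        assert best.local_min

    def test_bonferroni_subset_of_uncorrected(self):
        rng = random.Random(4)
        presence = {f"x{i:02d}": rng.random() < 0.4 for i in range(16)}
        t, res = self._scan(presence, min_clade=4, alpha=0.05)
        reported = {r.clade for r in res if r.reported}
        uncorrected = {r.clade for r in res if r.raw_p <= 0.05 and r.local_min}
        assert reported <= uncorrected or not reported


class TestRetention:
    def test_identical_sets_full_retention(self):
        t = balanced_tree(["a", "b"])
        sets = {"a": {"c1", "c2"}, "b": {"c1", "c2"}}
        (rec,) = neighborhood_retention(t, sets)
        assert rec.retention == 1.0

    def test_disjoint_sets_zero(self):
        t = balanced_tree(["a", "b"])
        sets = {"a": {"c1"}, "b": {"c2"}}
        (rec,) = neighborhood_retention(t, sets)
        assert rec.retention == 0.0

    def test_hand_computed_mean_over_cross_pairs(self):
        t = balanced_tree(["a", "b", "c", "d"])
        sets = {
            "a": {"1", "2", "3", "4"},
            "b": {"1", "2", "5", "6"},
            "c": {"1", "2", "7", "8"},
            "d": {"9", "10", "11", "12"},
        }
        recs = {r.node: r for r in neighborhood_retention(t, sets)}
        root = t.root.label
        # cross pairs at root: (a,c) 0.5, (a,d) 0, (b,c) 0.5, (b,d) 0
        assert recs[root].retention == pytest.approx(0.25)

    def test_invariant_to_child_swap(self):
        sets = {"a": {"1", "2"}, "b": {"1", "3"}, "c": {"4"}, "d": {"1"}}
        t1 = balanced_tree(["a", "b", "c", "d"])
        t2 = balanced_tree(["c", "d", "a", "b"])
        r1 = sorted(r.retention for r in neighborhood_retention(t1, sets))
        r2 = sorted(r.retention for r in neighborhood_retention(t2, sets))
        assert r1 == pytest.approx(r2)

    def test_planted_event_retentions_recovered(self):
        """Single-event gene pairs with planted retention probabilities
        0.40 / 0.11 / 0.21 are recovered within +-0.05 and the
        speciation-vs-duplication contrast is detected."""
        cfg = SimConfig(seed=11)
        study = simulate_retention_pairs(cfg, n_per_class=40)
        records = []
        events = {}
        for tree, event in study.families:
            recs = neighborhood_retention(tree, study.chg_sets)
            for r in recs:
                r.event = event
                records.append(r)
        summary = retention_by_event(records)
        assert summary.means["S"] == pytest.approx(0.40, abs=0.05)
        assert summary.means["D"] == pytest.approx(0.11, abs=0.05)
        assert summary.means["T"] == pytest.approx(0.21, abs=0.05)
        assert summary.ranksum_p[("S", "D")] < 0.01

    def test_depth_decay_gives_negative_correlation(self):
        cfg = SimConfig(seed=5)
        tree, sets = simulate_retention_decay(cfg, depth=12)
        records = neighborhood_retention(tree, sets)
        for r in records:
            r.event = "S"
        summary = retention_by_event(records)
        assert summary.depth_rho < 0

    def test_all_equal_retentions_reported_degenerate(self):
        t = balanced_tree(["a", "b", "c", "d"])
        sets = {k: {"1", "2"} for k in "abcd"}
        records = neighborhood_retention(t, sets)
        events = {r.node: ev for r, ev in zip(records, ["S", "D", "D"])}
        summary = retention_by_event(records, events)
        assert summary.ranksum_p.get(("S", "D"), 1.0) == 1.0
        assert math.isnan(summary.depth_rho)
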