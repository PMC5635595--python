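"""Dated DTL reconciliation: hand-worked instances, oracle equivalence,
sampling determinism/uniformity, DL limit, grid profiling and transfer calls."""

from __future__ import annotations

import random

import pytest
from scipy import stats

from conftest import gene, random_chronogram, random_gene_tree, species
from oracles import (
    brute_min_and_count,
    optimal_scenarios,
    reconciliation_to_canon,
)
from synterec.reconciliation import (
    CostScheme,
    SlicedTree,
    build_time_slices,
    call_transfers,
    event_support,
    lca_dl_reconcile,
    mpr_cost,
    sample_optima,
    summarize_events_on_species,
)


# ---------------------------------------------------------------------------
# Time slices
# ---------------------------------------------------------------------------

class TestTimeSlices:
    def test_three_taxon_slices(self, three_taxon):
        t, st = three_taxon
        assert st.n_slices == 2
        names = {
            s: sorted(
                t.nodes[e].name or t.nodes[e].label for e in st.slice_edges[s]
            )
            for s in (1, 2)
        }
        assert names[1] == ["A", "B", "C"]
        # slice 2 holds the (A,B) ancestor edge and C's edge
        ab = t.lca([t.by_name["A"], t.by_name["B"]])
        assert sorted(st.slice_edges[2]) == sorted([ab.index, t.by_name["C"].index])

    def test_two_taxon_single_slice(self):
        t = species("(A:1,B:1);")
        st = SlicedTree(t)
        assert st.n_slices == 1
        assert len(st.slice_edges[1]) == 2

    def test_caterpillar_slice_sizes(self):
        t = species("(((A:1,B:1):1,C:2):1,D:3);")
        st = build_time_slices(t)
        assert st.n_slices == 3
        assert [len(st.slice_edges[s]) for s in (1, 2, 3)] == [4, 3, 2]

    def test_slices_partition_root_span(self):
        rng = random.Random(5)
        for _ in range(10):
            t = random_chronogram(rng, 8)
            st = SlicedTree(t)
            lo, _ = st.slice_span(1)
            assert lo == 0.0
            for s in range(2, st.n_slices + 1):
                assert st.slice_span(s)[0] == st.slice_span(s - 1)[1]
            assert st.slice_span(st.n_slices)[1] == pytest.approx(t.root.age)
            # each edge appears exactly in the slices its span covers
            for n in t.nodes:
                if n.parent is None:
                    continue
                for s in range(1, st.n_slices + 1):
                    lo, hi = st.slice_span(s)
                    covered = n.age <= lo + 1e-12 and n.parent.age >= hi - 1e-12
                    assert (n.index in st.slice_edges[s]) == covered


# ---------------------------------------------------------------------------
# Hand-worked MPR instances
# ---------------------------------------------------------------------------

class TestMprWorkedExamples:
    def test_congruent_family_costs_zero(self, three_taxon):
        t, st = three_taxon
        g = gene("((A_1:1,B_1:1):1,C_1:2);")
        cost, count = mpr_cost(g, st, CostScheme(dup=4, transfer=10, loss=1))
        assert cost == 0
        assert count == 1
        rec = sample_optima(g, st, CostScheme(), n=1, seed=0)[0]
        events = {e.event for l, e in rec.events.items() if not l.startswith("A")}
        assert all(
            ev.event in ("S", "leaf") for ev in rec.events.values()
        )

    def test_forced_duplication(self):
        t = species("(A:1,B:1);")
        st = SlicedTree(t)
        g = gene("(A_1:1,A_2:1);")
        cost, _ = mpr_cost(g, st, CostScheme(dup=4, transfer=100, loss=1))
        assert cost == 4

    def test_transfer_beats_duplication_loss(self, three_taxon):
        """((a,c),b) on ((A,B),C): DL-only optimum costs 7; a single
        contemporaneous A<->C transfer costs 5 and wins at theta=5."""
        t, st = three_taxon
        g = gene("((A_1:1,C_1:1):1,B_1:2);")
        cost_dl, _ = mpr_cost(g, st, CostScheme(dup=4, transfer=1000, loss=1))
        assert cost_dl == 7
        cost, _ = mpr_cost(g, st, CostScheme(dup=4, transfer=5, loss=1))
        assert cost == 5
        rec = sample_optima(g, st, CostScheme(dup=4, transfer=5, loss=1), 5, 1)[0]
        assert rec.n_transfer == 1 and rec.n_dup == 0

    def test_unmapped_leaf_errors(self, three_taxon):
        t, st = three_taxon
        g = gene("(A_1:1,D_1:1);")
        with pytest.raises(ValueError, match="absent"):
            mpr_cost(g, st, CostScheme())


# ---------------------------------------------------------------------------
# Oracle equivalence and cost monotonicity
# ---------------------------------------------------------------------------

def _random_instance(rng):
    n_sp = rng.randint(3, 5)
    n_leaves = rng.randint(3, 5)
    t = random_chronogram(rng, n_sp)
    g = random_gene_tree(rng, t.taxa, n_leaves)
    costs = CostScheme(
        dup=rng.randint(1, 6),
        transfer=rng.randint(1, 8),
        loss=rng.randint(0, 3),
    )
    return t, g, costs


class TestOracleEquivalence:
    def test_dp_equals_enumeration_on_random_instances(self):
        """DP minimum cost and exact optimum count match full scenario
        enumeration on random small instances with random costs."""
        rng = random.Random(20240917)
        for i in range(60):
            t, g, costs = _random_instance(rng)
            st = SlicedTree(t)
            bcost, bcount = brute_min_and_count(g, st, costs)
            cost, count = mpr_cost(g, st, costs)
            assert cost == pytest.approx(bcost), f"instance {i}"
            assert count == bcount, f"instance {i}"

    def test_sampled_optima_are_valid_scenarios(self):
        rng = random.Random(7)
        t, g, costs = _random_instance(rng)
        st = SlicedTree(t)
        opt = optimal_scenarios(g, st, costs)
        for rec in sample_optima(g, st, costs, n=30, seed=3):
            assert reconciliation_to_canon(rec) in opt

    def test_cost_monotone_in_each_event_cost(self):
        rng = random.Random(99)
        for _ in range(10):
            t = random_chronogram(rng, 5)
            g = random_gene_tree(rng, t.taxa, 5)
            st = SlicedTree(t)
            base = CostScheme(dup=3, transfer=6, loss=1)
            c0, _ = mpr_cost(g, st, base)
            for kwargs in ({"dup": 4}, {"transfer": 7}, {"loss": 2}):
                params = {"dup": 3, "transfer": 6, "loss": 1, **kwargs}
                c1, _ = mpr_cost(g, st, CostScheme(**params))
                assert c1 >= c0 - 1e-9


class TestSampling:
    def test_seed_determinism(self, three_taxon):
        t, st = three_taxon
        g = gene("((A_1:1,C_1:1):1,B_1:2);")
        costs = CostScheme(dup=4, transfer=5, loss=1)
        s1 = sample_optima(g, st, costs, n=20, seed=7)
        s2 = sample_optima(g, st, costs, n=20, seed=7)
        assert [reconciliation_to_canon(r) for r in s1] == [
            reconciliation_to_canon(r) for r in s2
        ]

    def test_unique_optimum_all_samples_identical(self, three_taxon):
        t, st = three_taxon
        g = gene("((A_1:1,B_1:1):1,C_1:2);")
        recs = sample_optima(g, st, CostScheme(), n=10, seed=0)
        canons = {reconciliation_to_canon(r) for r in recs}
        assert len(canons) == 1

    def test_uniform_over_enumerated_optima(self):
        """Empirical frequencies over brute-force-enumerated optima are
        consistent with the uniform distribution (chi-square, alpha 0.01)."""
        t = species("(((A:1,B:1):1,C:2):1,D:3);")
        st = SlicedTree(t)
        # two stacked duplications on the deep D edge: the slice of each
        # duplication is free subject to ordering, giving 6 optima
        g = gene("(D_1,(D_2,D_3));")
        costs = CostScheme(dup=3, transfer=4, loss=1)
        opt = sorted(optimal_scenarios(g, st, costs))
        k = len(opt)
        assert 2 <= k <= 12
        _, count = mpr_cost(g, st, costs)
        assert count == k
        n = 10_000
        recs = sample_optima(g, st, costs, n=n, seed=11)
        index = {canon: i for i, canon in enumerate(opt)}
        observed = [0] * k
        for rec in recs:
            observed[index[reconciliation_to_canon(rec)]] += 1
        chi = stats.chisquare(observed)
        assert chi.pvalue > 0.01


# ---------------------------------------------------------------------------
# DL limit
# ---------------------------------------------------------------------------

class TestDlLimit:
    def test_worked_dl_example(self, three_taxon):
        t, st = three_taxon
        g = gene("((A_1:1,C_1:1):1,B_1:2);")
        rec = lca_dl_reconcile(g, t, dup=4, loss=1)
        assert rec.n_dup == 1 and rec.n_loss == 3 and rec.cost == 7

    def test_congruent_dl(self, three_taxon):
        t, _ = three_taxon
        g = gene("((A_1:1,B_1:1):1,C_1:2);")
        rec = lca_dl_reconcile(g, t)
        assert rec.n_dup == 0 and rec.n_loss == 0

    def test_prohibitive_transfer_cost_recovers_lca_dl(self):
        """With transfers priced out, the dated MPR equals the closed-form
        LCA duplication-loss reconciliation, including duplication sets."""
        rng = random.Random(123)
        for _ in range(40):
            t = random_chronogram(rng, rng.randint(3, 6))
            g = random_gene_tree(rng, t.taxa, rng.randint(3, 6))
            st = SlicedTree(t)
            dl = lca_dl_reconcile(g, t, dup=4, loss=1)
            theta = 4 * len(g.nodes) + len(t.nodes) + 10
            costs = CostScheme(dup=4, transfer=theta, loss=1)
            cost, _ = mpr_cost(g, st, costs)
            assert cost == pytest.approx(dl.cost)
            rec = sample_optima(g, st, costs, n=5, seed=1)[0]
            dp_dups = {l for l, e in rec.events.items() if e.event == "D"}
            dl_dups = {l for l, e in dl.events.items() if e.event == "D"}
            assert dp_dups == dl_dups


# ---------------------------------------------------------------------------
# Event support and transfer calls
# ---------------------------------------------------------------------------

class TestEventSupport:
    def test_congruent_family_full_speciation_support(self, three_taxon):
        t, st = three_taxon
        g = gene("((A_1:1,B_1:1):1,C_1:2);")
        grid = event_support(
            g, st, dup=4, thetas=(5, 10), losses=(1,), n=50, seed=0
        )
        for cell, sup in grid.support.items():
            for u in g.nodes:
                if u.is_leaf:
                    continue
                assert sup[u.label].get("S", 0.0) == 1.0

    def test_grid_has_108_cells_at_default_grid(self, three_taxon):
        """The default profile is theta in 5..40 crossed with L in {1,2,3}."""
        t, st = three_taxon
        g = gene("(A_1:1,B_1:1);")
        grid = event_support(g, st, n=5, seed=0)
        assert len(grid.support) == 36 * 3 == 108

    def test_substreams_stable_under_grid_extension(self, three_taxon):
        t, st = three_taxon
        g = gene("((A_1:1,C_1:1):1,B_1:2);")
        small = event_support(g, st, thetas=(5,), losses=(1,), n=40, seed=9)
        big = event_support(g, st, thetas=(5, 8), losses=(1, 2), n=40, seed=9)
        assert small.support[(5, 1)] == big.support[(5, 1)]

    def test_transfer_majority_flips_with_theta(self, three_taxon):
        """On the A<->C transfer instance the transfer wins while theta is
        below the duplication-loss alternative (cost 7) and vanishes above."""
        t, st = three_taxon
        g = gene("((A_1:1,C_1:1):1,B_1:2);")
        grid = event_support(
            g, st, dup=4, thetas=(5, 6, 8, 10), losses=(1,), n=100, seed=4
        )
        x = g.root.children[0] if not g.root.children[0].is_leaf else g.root.children[1]
        fracs = {
            th: grid.support[(th, 1)][x.label].get("T", 0.0)
            for th in (5, 6, 8, 10)
        }
        assert fracs[5] > 0.5 and fracs[6] > 0.5
        assert fracs[8] == 0.0 and fracs[10] == 0.0

    def test_call_transfers_monotone_in_majority(self, three_taxon):
        t, st = three_taxon
        g = gene("((A_1:1,C_1:1):1,B_1:2);")
        grid = event_support(
            g, st, dup=4, thetas=(5, 6, 8), losses=(1, 2), n=100, seed=4
        )
        calls_50 = {c.node for c in call_transfers(grid, majority=0.5)}
        calls_90 = {c.node for c in call_transfers(grid, majority=0.9)}
        assert calls_90 <= calls_50

    def test_congruent_family_no_calls(self, three_taxon):
        t, st = three_taxon
        g = gene("((A_1:1,B_1:1):1,C_1:2);")
        grid = event_support(g, st, thetas=(5, 10), losses=(1,), n=50, seed=0)
        assert call_transfers(grid) == []


class TestBranchSummary:
    def test_congruent_family_one_gene_everywhere(self, three_taxon):
        t, st = three_taxon
        g = gene("((A_1:1,B_1:1):1,C_1:2);")
        recs = sample_optima(g, st, CostScheme(), n=5, seed=0)
        table = summarize_events_on_species(recs, st)
        assert (table["duplications"] == 0).all()
        assert (table["losses"] == 0).all()
        assert (table["genes"] == 1).all()

    def test_family_set_totals_within_resimulation_range(self):
        """Summed per-branch duplication counts over 20 simulated families
        fall inside the central 95% range of true visible duplication
        totals under re-simulation of the same process."""
        from synterec.synthetic_data import (
            simulate_chronogram,
            simulate_dtl_family,
            substream,
        )

        t = simulate_chronogram(15, seed=21)
        st = SlicedTree(t)
        costs = CostScheme(dup=4, transfer=10, loss=1)
        recs_by_family = []
        for i in range(20):
            g, _ = simulate_dtl_family(
                t, 0.20, 0.055, 0.30, seed=substream(50, "branch", i)
            )
            recs_by_family.append(sample_optima(g, st, costs, n=30, seed=i))
        table = summarize_events_on_species(recs_by_family, st)
        inferred_total = int(table["duplications"].sum())
        totals = []
        for rep in range(50):
            tot = 0
            for i in range(20):
                _, truth = simulate_dtl_family(
                    t, 0.20, 0.055, 0.30, seed=substream(rep + 1000, "re", i)
                )
                tot += truth.visible_count("D")
            totals.append(tot)
        totals.sort()
        lo, hi = totals[1], totals[-2]  # ~central 95% of 50 replicates
        assert lo <= inferred_total <= hi

    def test_single_duplication_on_one_branch(self):
        t = species("(A:1,B:1);")
        st = SlicedTree(t)
        g = gene("((A_1:1,A_2:1):1,B_1:2);")
        recs = sample_optima(g, st, CostScheme(dup=4, transfer=100, loss=1), 20, 0)
        table = summarize_events_on_species(recs, st)
        assert table["duplications"].sum() == 1
        dup_row = table[table["duplications"] == 1].iloc[0]
        assert dup_row["branch"] == t.by_name["A"].label
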