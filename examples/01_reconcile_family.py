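"""Reconcile one simulated gene family against its dated species tree.

Simulates a 12-taxon chronogram and a gene family evolved with explicit
duplication/transfer/loss rates, then computes the minimum dated-DTL
reconciliation cost, the exact number of co-optimal reconciliations, and
one uniformly sampled optimum with its event list.
"""

from synterec import (
    CostScheme,
    SlicedTree,
    mpr_cost,
    sample_optima,
    simulate_chronogram,
    simulate_dtl_family,
)

species = simulate_chronogram(n_taxa=12, seed=8)
gene, truth = simulate_dtl_family(
    species, dup_rate=0.3, transfer_rate=0.1, loss_rate=0.3, seed=5
)
sliced = SlicedTree(species)
costs = CostScheme(dup=4, transfer=10, loss=1)

cost, n_optima = mpr_cost(gene, sliced, costs)
rec = sample_optima(gene, sliced, costs, n=1, seed=0)[0]

print(f"gene family: {len(gene.leaves)} genes in {len(set(gene.species_map.values()))} species")
print(f"true events: {sorted(truth.node_events.values())}")
print(f"minimum cost {cost:g} with {n_optima} co-optimal reconciliations")
print(f"sampled optimum: {rec.n_dup} duplications, {rec.n_transfer} transfers, {rec.n_loss} losses")
for label in sorted(rec.events, key=lambda l: int(l[1:])):
    ev = rec.events[label]
    if ev.event in ("D", "T"):
        extra = f" -> {ev.recipient}" if ev.event == "T" else ""
        print(f"  {label}: {ev.event} on species edge {ev.species} (slice {ev.slice}){extra}")
# The cost is Δ·dups + θ·transfers + L·losses; the optimum count shows how
# ambiguous the embedding is, which is why support is averaged over samples.
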