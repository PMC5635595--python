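"""Profile transfer support across the cost grid and call transfers.

A transfer is trusted when it keeps majority support among sampled
optimal reconciliations as the transfer cost rises (it is "most evident
at highly penalized cost") and stays consistent across loss costs.
This example uses the canonical 3-taxon instance where a single
contemporaneous A<->C transfer (cost theta) competes with a
duplication-plus-losses explanation (cost 7).
"""

from synterec import (
    SlicedTree,
    call_transfers,
    event_support,
    read_tree,
)

species = read_tree("((A:1,B:1):1,C:2);", kind="species")
gene = read_tree("((A_1:1,C_1:1):1,B_1:2);", kind="gene", species_tree=species)
sliced = SlicedTree(species)

grid = event_support(
    gene, sliced, dup=4, thetas=(5, 6, 7, 8, 10), losses=(1, 2, 3),
    n=200, seed=1, tree_id="demo",
)
node = "g3"  # the (A_1, C_1) cherry
print("transfer fraction among sampled optima for node g3:")
for L in (1, 2, 3):
    fracs = [grid.support[(th, L)][node].get("T", 0.0) for th in (5, 6, 7, 8, 10)]
    print(f"  L={L}: " + "  ".join(f"theta={th}: {f:.2f}" for th, f in zip((5, 6, 7, 8, 10), fracs)))

for call in call_transfers(grid, report_loss=1):
    print(
        f"call: node {call.node}, donor {call.donor} -> recipient {call.recipient}, "
        f"top transfer cost {call.top_cost}, consistent={call.consistent}"
    )
# Support collapses once theta exceeds the duplication-loss alternative;
# the top cost records where the majority was last held.
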