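"""Contrast neighborhood retention across event types.

Generates single-event gene pairs with planted retention probabilities
(0.40 speciation / 0.11 duplication / 0.21 transfer), measures the mean
pairwise shared-CHG fraction across each pair, and contrasts the event
classes with the Wilcoxon rank-sum test; a separate depth-decay
simulation shows the negative retention-depth correlation.
"""

from synterec import (
    SimConfig,
    neighborhood_retention,
    retention_by_event,
    simulate_retention_decay,
    simulate_retention_pairs,
)

cfg = SimConfig(seed=11)
study = simulate_retention_pairs(cfg, n_per_class=40)
records = []
for tree, event in study.families:
    for r in neighborhood_retention(tree, study.chg_sets):
        r.event = event
        records.append(r)
summary = retention_by_event(records)

print("recovered mean retention by event (planted 0.40 / 0.11 / 0.21):")
for ev, name in (("S", "speciation"), ("D", "duplication"), ("T", "transfer")):
    print(f"  {name:12s} {summary.means[ev]:.3f}  (n={summary.counts[ev]})")
print(f"speciation vs duplication rank-sum P = {summary.ranksum_p[('S', 'D')]:.2e}")

tree, sets = simulate_retention_decay(SimConfig(seed=5), depth=12)
decay = neighborhood_retention(tree, sets)
for r in decay:
    r.event = "S"
rho = retention_by_event(decay).depth_rho
print(f"depth-decay simulation: Pearson rho(retention, depth) = {rho:.2f}")
# Duplications scramble the genomic context most; the retention statistic
# makes that contrast quantitative and testable.
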