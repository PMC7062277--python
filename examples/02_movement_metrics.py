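"""Detect hunting events, classify the immediate response and summarize the
movement metrics of the two groups.

Fleeing deer cross the shooting line during the drive: fast, straight,
long immediate paths.  Staying deer hide inside: slow, reversing, short
paths.  By the first dawn both groups have covered similar distances.
"""
from drivehunt import compare_group_distances, simulate_events
from drivehunt.events import compute_events, events_table

sim = simulate_events(120, rng=2)
events = compute_events(sim.trajectories, sim.hunts, sim.areas)
tab = events_table(events)

summary = tab.groupby("classification")[
    ["speed_max_kmh", "sinuosity", "dist_immediate_m", "dist_delayed_m"]
].median()
print("median movement metrics per immediate-response group:")
print(summary.round(2).to_string())

cmp_i = compare_group_distances(tab, "immediate")
cmp_d = compare_group_distances(tab, "delayed")
print(f"\nimmediate distances, staying vs fleeing: "
      f"t = {cmp_i.statistic:.2f}, df = {cmp_i.df}, p = {cmp_i.pvalue:.2g}")
print(f"delayed distances,   staying vs fleeing: "
      f"t = {cmp_d.statistic:.2f}, df = {cmp_d.df}, p = {cmp_d.pvalue:.2g}")
# A strongly negative immediate t (staying cover less ground during the
# drive) and a much weaker delayed contrast mirror the two-phase response.
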