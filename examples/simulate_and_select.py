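"""Simulate a sorting campaign and run the full selection analysis on it.

A default-condition campaign (wild type at 92%, 5000 NNK variants, five
rounds of increasing stringency, duplicate sequencing at 1e6 reads) is
generated with known per-clone fitness, then analysed exactly as real data
would be: replicate-common clone sets, PSERMs for the last two round
transitions, top-40 overlap, cysteine filter. The known fitness landscape
lets us check what the selection actually found.
"""

from psermkit import SimConfig, merge_replicates, pserms_for_rounds, \
    select_clones, simulate_campaign
from psermkit.simulate import evaluate_recovery

cfg = SimConfig()
sim = simulate_campaign(cfg, seed=7)
labels = cfg.round_labels

print(f"library: wild type at {cfg.wt_fraction_initial:.0%} plus "
      f"{cfg.n_variants} variants")
wt = {r: sim.pool_freqs.loc[cfg.wt_string, r] for r in labels}
print("wild-type pool frequency by round:",
      {r: f"{f:.3f}" for r, f in wt.items()})
print(f"clones common to both replicates in any round: "
      f"{len(sim.table.clones)}")

strict = merge_replicates(
    sim.tallies, labels, mode="common-required-rounds",
    required_rounds=labels[:-1], allow_absent_rounds=[labels[-1]],
    wt_string=cfg.wt_string,
)
print(f"clones common to both replicates in rounds {','.join(labels[:-1])}: "
      f"{len(strict.clones)} (scored candidates)")

pserms = pserms_for_rounds(
    sim.table, [(labels[-1], labels[-2]), (labels[-2], labels[-3])])
report = select_clones(
    sim.table, pserms, k=40, exclude_wt=True,
    comparator_rounds=(labels[-1], labels[0], labels[-2]),
    clones=strict.clones,
)
print(f"\ntop-40 overlap of the two PSERMs: {len(report.overlap)} clones; "
      f"{len(report.removed_for_cysteine)} removed for unpaired cysteine; "
      f"{len(report.final)} selected")

recovery = evaluate_recovery(report, sim.fitness)
print(f"mean true fitness of the selection: "
      f"{recovery['final_mean_fitness']:.2f} "
      f"(library 90th percentile: {recovery['library_fitness_p90']:.2f})")
print("capture of true top-1% clones in each metric's top 40:")
for metric, frac in recovery["capture_top_k"].items():
    print(f"  {metric:>14}: {frac:.0%}")
print("\nthe PSERM rankings recover more of the genuinely fittest clones "
      "than terminal frequency or enrichment-ratio rankings, because they "
      "pool evidence across all clones at each mutated position")
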