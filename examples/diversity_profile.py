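"""Alpha diversity, rarefaction-averaged beta diversity, and ordination.

Computes Hill numbers per sample, a Bray-Curtis similarity matrix averaged
over repeated rarefaction draws, and a PCoA ordination of the day-7
communities of a simulated experiment.
"""

import numpy as np

from phagecosm import SimulationConfig, simulate_experiment
from phagecosm.diversity import averaged_similarity, hill_profile, pcoa

bundle = simulate_experiment(SimulationConfig(seed=3003))
day7 = bundle.samples.frame.query("day == 7")
counts7 = bundle.counts.select_samples(day7["sample_id"])

prof = hill_profile(counts7).frame.merge(
    day7, left_on="sample_id", right_on="sample_id"
)
print("Mean Hill diversity at day 7 by treatment "
      "(D0 = richness, D1 = exp Shannon, D2 = inverse Simpson):")
print(prof.groupby("treatment")[["D0", "D1", "D2", "evenness"]].mean().round(2))
print("Antibiotic-treated communities lose effective taxa at every order;\n"
      "phage-treated ones stay close to the untreated controls.\n")

depth = int(counts7.sample_sums.min())
sim = averaged_similarity(counts7, "bray_curtis", depth=depth, repetitions=25, seed=3003)
print(f"Bray-Curtis similarity averaged over {sim.averaged_over} rarefactions "
      f"to {sim.depth} reads; mean off-diagonal = "
      f"{sim.values[np.triu_indices(len(sim.sample_ids), 1)].mean():.3f}")

ordn = pcoa(sim, k=2)
print(f"PCoA axes 1-2 explain {100 * ordn.proportion_explained[:2].sum():.1f}% "
      f"of the (positive-eigenvalue) distance variance;")
print(f"{len(ordn.negative_eigenvalues)} negative eigenvalues were excluded "
      "(Bray-Curtis is semi-metric).")
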