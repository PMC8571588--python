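"""ABC scenario choice: which colonization route produced the data?

Simulates pseudo-observed data under the Floreana-first topology
(San Cristobal -> Floreana -> Isabela), builds a small rejection
reference table over all nine stage-2 topologies, and reports each
scenario's posterior probability from the discriminant logistic
regression at the observed point.  The run is deliberately small
(2,000 simulations) so it finishes in about a minute; raise ``N_SIM``
for sharper posteriors.
"""

import numpy as np

from ssrtrace.abc import (
    SummaryStatDesign,
    abc_rejection,
    model_posterior,
    summary_statistics,
)
from ssrtrace.coalescent import simulate_allele_sizes
from ssrtrace.scenarios import stage2_scenarios

N_SIM = 2000

ss = stage2_scenarios()
samples = {"Mainland": 15, "SCY": 15, "ISA": 15, "FLO": 10}
design = SummaryStatDesign.full(list(samples))

truth = ss.templates[3]  # S2-4: SCY -> FLO -> ISA
# a parameter point where the route is identifiable: Floreana colonized
# long before Isabela, through a real founder bottleneck
params = dict(
    n_mainland=20000, n_scy=1500, n_isa=2000, n_flo=300,
    n_found_scy=10, n_found_isa=60, n_found_flo=25,
    t_scy=1500, t_flo=800, t_isa=100, bottleneck_duration=20,
)
observed = summary_statistics(
    simulate_allele_sizes(truth.build(params), samples, 11, 12345), design
)

table = abc_rejection(
    observed, ss, design, samples, n_sim=N_SIM, retain_fraction=0.05, seed=99
)
pps = model_posterior(table)
for name, info in sorted(pps.items(), key=lambda kv: -kv[1]["pp"]):
    lo, hi = info["ci"]
    print(f"{name}: PP={info['pp']:.3f} [{lo:.3f}, {hi:.3f}]")
print(
    "\nThe generating topology and its mirror ordering of the island"
    "\nchain (SCY -> ISA -> FLO) collect essentially all the posterior"
    "\nmass; separating those two is exactly what the full 20,000-"
    "\nsimulation budget and the regression posterior are for."
)
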