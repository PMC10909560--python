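"""Simulate a three-group indicator panel and recover the groups.

Draws 1000 areas from the reference three-group design (mixing 0.2/0.3/0.5,
linear trajectories, 2pp noise, four indicators unobserved at the first
time point), fits the multi-trajectory mixture at the true G, and reports
how well the latent structure is recovered.
"""

import numpy as np
from sklearn.metrics import adjusted_rand_score

import migtraj as m

sim = m.generate_panel(m.three_group_spec(n_areas=1000, seed=42))
model = m.fit(sim.panel, m.ModelSpec(n_groups=3, orders=3, seed=0, n_starts=2))

print(f"log likelihood: {model.logL:.1f}  (converged in {model.n_iter} EM iterations)")
print(f"mixing proportions: {np.round(model.pi, 3)}  (truth ~ 0.5/0.3/0.2 descending)")
print(f"adjusted Rand vs true labels: {adjusted_rand_score(sim.true_labels, model.labels):.3f}")
print(f"noise SDs per indicator: {np.round(model.sigma, 2)}  (truth: 2.0 pp)")
print()
print("fitted mean trajectory, group 1, internal in-mover share:")
print(" ", np.round(m.trajectory_means(model, 0, 0), 2), "(percent, per census)")
# ARI near 1 and sigma near 2pp mean the latent groups were fully recovered.
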