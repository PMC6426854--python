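"""Alpha diversity of one sample: Chao1, Shannon, and a rarefaction curve.

Chao1 extrapolates richness from singletons/doubletons (F1, F2); Shannon
is entropy in nats; rarefaction subsamples reads without replacement at
10 evenly spaced depths.
"""

import numpy as np

import chaintrace as ct

rng = np.random.default_rng(0)
# a community of 120 taxa with log-normal-ish abundances, shallowly sampled
# so rare taxa show up as singletons/doubletons
abund = rng.lognormal(0, 1.5, size=120)
counts = rng.multinomial(1500, abund / abund.sum())
counts = counts[counts > 0]

est, s_obs, f1, f2 = ct.chao1(counts)
h = ct.shannon(counts)
print(f"observed taxa S_obs = {s_obs}, singletons F1 = {f1}, doubletons F2 = {f2}")
print(f"Chao1 = {est:.1f}  (>= S_obs; extrapolates unseen rare taxa)")
print(f"Shannon H = {h:.3f} nats (max possible ln S = {np.log(s_obs):.3f})")

print("rarefaction (depth -> mean observed taxa):")
for depth, obs in ct.rarefaction_curve(counts, n_points=10, seed=1):
    print(f"  {depth:>6d} -> {obs:.1f}")
# the curve plateaus near S_obs, showing sequencing depth covers the
# community's biodiversity; at full depth it equals S_obs exactly
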