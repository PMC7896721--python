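"""Heterozygosity, LD decay and LD-based effective population size.

Ne comes from the Sved relation Ne_t = (1/4c)(1/r^2 - 1): mean r^2 at
genetic distance c Morgans reflects the population size about
t = 1/(2c) generations ago.
"""

from introsel import DemographyParams, simulate_panel
from introsel.diversity import estimate_ne, het_stats, ld_decay, ld_extent

_, gm, _ = simulate_panel(DemographyParams(seed=42))

for pop in ("P1", "P2", "P3"):
    ho, he = het_stats(gm, pop)
    print(f"{pop}: Ho = {ho:.4f}, He = {he:.4f}")
# expect Ho ~ He within noise (the simulated populations mate randomly);
# P2 is the most diverse because it carries both lineages

pairs = ld_decay(gm, "P2", max_dist_bp=25_000_000)
extent = ld_extent(pairs, r2_target=0.3)
print(f"LD extent (r^2 = 0.3): {extent / 1e3:.0f} kb")

est = estimate_ne(pairs, t_max=5)
print(f"LD-based Ne over the last ~5 generations: {est.recent_mean:.0f}")
# the simulator's census size is 100 diploids; the estimate carries the
# 1/n sampling floor of r^2, so treat it as order-of-magnitude
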