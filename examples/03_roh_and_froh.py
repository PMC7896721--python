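"""Call runs of homozygosity and summarize inbreeding as F_ROH.

The caller emulates the PLINK sliding-window scheme; the minimum SNP
count per run comes from the Lencz false-positive formula.  F_ROH is
total ROH length over the genome length, split into length classes
that index the age of the underlying inbreeding.
"""

from introsel import DemographyParams, simulate_panel
from introsel.roh import ROHParams, call_roh, min_roh_snps, roh_inbreeding

_, gm, _ = simulate_panel(DemographyParams(seed=42))

l_min = min_roh_snps(alpha=0.05, n_s=gm.n_snp, n_i=gm.n_ind, het=0.25)
print(f"Lencz minimum run length at het 0.25: {l_min} SNPs")

params = ROHParams(genome_length_bp=150e6)  # the simulated autosome span
rs = call_roh(gm, params)
print(f"called {len(rs.segments)} segments (min {rs.min_snps_used} SNPs each)")

froh = roh_inbreeding(rs, gm, genome_length_bp=150e6)
print(froh.describe().loc[["mean", "max"], ["froh", "froh_lt5", "froh_gt10"]])
# froh_lt5 reflects older background inbreeding; froh_gt10 flags recent
# close mating.  Small drifting populations accumulate substantial ROH.
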