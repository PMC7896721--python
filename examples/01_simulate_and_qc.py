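"""Simulate the four-population admixture scenario and run QC.

The scenario is (((P1, P2), P3), O): P2 is the recipient breed, P3 the
donor, P1 the unadmixed sister lineage, O the outgroup.  A pulse moved
25% of P2's ancestry to P3 twenty generations ago.
"""

from introsel import DemographyParams, QCParams, apply_qc, simulate_panel

panel, gm, truth = simulate_panel(DemographyParams(seed=42))
print(f"simulated {gm.n_ind} individuals x {gm.n_snp} SNPs")
print(f"true donor-ancestry fraction in P2: {truth.donor_fraction('P2'):.3f}")
# the truth tracts make every downstream detector testable: this number
# is what the D statistic, f_dM windows and ancestry estimates chase

filtered, report = apply_qc(gm, QCParams())
print(
    f"QC: {report.n_snp_in} -> {report.n_snp_out} SNPs "
    f"({report.removed_maf_snps} failed MAF >= 0.01), "
    f"{report.n_ind_in} -> {report.n_ind_out} individuals"
)
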