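# Methods

## The synthetic study design

All tests and the acceptance script run on data from the forward
Wright–Fisher simulator in `introsel.simulate`.  The scenario is the
four-population tree `(((P1, P2), P3), O)`: an ancestral population of
standing variation (allele-1 frequencies drawn Uniform(0.05, 0.95), no
new mutation afterwards) splits off the outgroup O, then the donor
lineage P3, then the sister pair P1/P2; a single pulse at
`admix_gen` generations before present draws each P2 parent from P3
with probability `admix_frac`.

Default conditions (chosen once as a realistic conserved-breed
setting, and used everywhere): 100 diploids per population, splits at
200 / 120 / 60 generations, pulse fraction 0.25 at generation 20,
three 50-Mb chromosomes with ~1,200 SNPs each at a uniform 1 cM/Mb
map, samples of 20/30/50/30 for O/P1/P2/P3.  One full simulation runs
in a few seconds; calibration tests that need many replicates use a
scaled replicate (1,200 SNPs, splits 120/80/40, pulse at 10) so the
whole suite stays fast.  These sizes are the package's own choice of
problem scale; tests that specifically need full power (the D-statistic
recovery checks) use the default conditions.

What the simulator does and does not emulate:

- **Does**: genetic drift, realistic within-chromosome LD from
  recombination (crossovers Poisson on the cM map), admixture tracts
  of realistic length, exact local-ancestry truth (`TruthTracts`,
  propagated through every meiosis by bookkeeping), phased haplotypes,
  an outgroup usable for polarization (the ancestral-allele annotation
  is the root population's major allele).
- **Does not**: new mutation (all polymorphism is standing ancestral
  variation, so site-frequency-spectrum shape is not realistic),
  selection during the simulation, genotyping error, sex chromosomes,
  non-uniform recombination maps (configurable but uniform by
  default).  Passing tests therefore demonstrate correctness of the
  estimators under drift + admixture + recombination, not robustness
  to array ascertainment or genotyping artefacts.

At the pulse generation the simulator records the allele frequencies
of the recipient's native parental pool and of the donor pool
(`TruthTracts.source_freqs`).  These are the reference panels handed
to the supervised ancestry estimator in tests and in the pipeline's
simulated mode: the supervised model assumes references drawn from the
true mixing sources, and with a deeply diverged proxy (e.g. the sister
lineage P1 instead of P2's own native source) the proportion estimate
is biased toward 1/2, as for any fixed-reference mixture model.  On
real data the practitioner must supply reference frequencies from
panels believed close to the true sources.

Phenotypes are `y = Σ x_k β_k + g + e` with `g ~ MVN(0, Vg·K)` drawn
exactly from the panel's GRM `K`, `e ~ N(0, 1)`, and `Vg` set so the
genetic share of variance equals the requested `h2` (scaled by the
mean GRM diagonal).  This makes Haseman–Elston regression an unbiased
oracle for the realized heritability, which the test suite exploits.

## Estimator choices and numerical details

- **QC order** is fixed: IBS-duplicate removal (keep the
  lexicographically smallest id, for reproducibility), then MAF ≥
  0.01, then call rate ≥ 0.90 for SNPs and then individuals, then
  autosomes only.  Missing dosages are a sentinel (−1); every
  statistic skips missing pairwise-complete.  Positions are 1-based
  inclusive; segment lengths are `end − start + 1`.
- **LD** is composite genotypic r² (squared Pearson correlation of
  dosages) throughout — pruning, decay curves, and the Sved equation —
  matching standard SNP-array practice with unphased input.
- **Expected heterozygosity** carries the small-sample factor
  `2n/(2n−1)`; allele frequencies for the inbreeding coefficient `F`
  are computed within each individual's own population.
- **Ne curve**: pairs binned into 20 equal-width bins of c in
  [0.005, 0.25] M; "recent" Ne averages bins with t = 1/(2c) ≤ 5.
  The sampling floor E[r²] ≈ 1/n biases Ne downward for small samples;
  `estimate_ne(..., sample_size_correction=n)` subtracts it and is
  used in the simulator-truth recovery test (documented option,
  default off).
- **ROH caller**: window of 50 SNPs sliding one SNP at a time,
  ≤1 heterozygous and ≤5 missing calls per passing window, SNP hit
  fraction ≥ 0.05, runs split at gaps > 1 Mb, accepted at ≥ l SNPs
  (Lencz rule with α = 0.05 and het = mean observed heterozygosity of
  the analysed panel, unless overridden), length ≥ 1 Mb and density ≥
  1 SNP/100 kb.  Candidate runs are trimmed to the outermost
  homozygous non-missing SNP.  Like the tool this emulates, run
  boundaries next to heterozygous flanking sequence carry one-SNP
  uncertainty from the hit-fraction rule; the exactness tests
  therefore flank planted runs with missing-call guard blocks, which
  pin the trim to the planted span.
- **F_ROH** divides by the real pig autosome length 2.45 Gb by
  default; the pipeline substitutes the simulated genome span when
  running on synthetic panels.
- **Weir–Cockerham FST** uses the 1984 variance components a, b, c;
  per-SNP θ may be negative and is kept; genome-wide θ is the ratio of
  sums.  Population-tree distances truncate negative pairwise θ at 0.
- **NJ trees** use the Saitou–Nei algorithm (via scikit-bio) on 1−IBS
  (individuals) or FST (populations) matrices.
- **Supervised ancestry**: dosages modelled Binomial(2, Σ_l q_l p_lk)
  with fixed reference frequencies clamped to [1e-3, 1−1e-3];
  maximized by the standard allele-responsibility EM on the simplex
  (≤5000 iterations, tolerance 1e-9).  An unsupervised ADMIXTURE-style
  model is intentionally out of scope: the conservation tiers only
  need a per-individual native-lineage proportion.
- **Conservation tiers**: cutpoints at the mean, mean−1SD and
  mean−2SD of the native proportion (≥mean nucleus; the two 1-SD bands
  candidate tiers; <mean−2SD discard); individuals with F or F_ROH
  above their own mean+2SD are flagged as inbreeding outliers.
- **Families**: the tiers' companion rule — cut tree edges
  longest-first, accepting a cut only if every resulting leaf group
  keeps ≥ `min_boars` males, until no further cut is possible or a
  requested family count is reached.  This maximizes the number of
  boar-containing monophyletic families; the count is exposed as an
  override because tree shape alone does not determine a unique
  partition.
- **iHS**: EHH computed outward until < 0.05, integrated by trapezoid
  against cM (1 cM/Mb fallback); uiHS = ln(iHH_ancestral/iHH_derived);
  standardized within 50 derived-allele-frequency bins, bins with <20
  SNPs merged with neighbours; SNPs without ancestral-allele
  orientation keep their map orientation and contribute to the |iHS|
  ranking only.  Significance is the empirical top 1% of |iHS| with
  ±50 kb flanks.
- **EigenGWAS**: per-SNP regression of the PC1 score on dosage,
  χ² = (β̂/se)², genomic control λ = median χ²/0.4549 (switchable
  off), Bonferroni 0.05/m.  Note that regressing a PC on the SNPs it
  was computed from carries an intrinsic (1+√(n/m))² inflation even in
  a panmictic population; the null-calibration test runs in the array
  regime m ≫ n where this vanishes, and genomic control absorbs it
  elsewhere.
- **Site patterns** polarize each SNP so the outgroup-major allele is
  ancestral (ties left as is).  D = Σ(ABBA−BABA)/Σ(ABBA+BABA) on
  sample frequencies; SE by leave-one-block-out jackknife over 5-Mb
  blocks (size exposed); Z = D/SE with a two-sided normal p.  The
  point estimate is exactly the ratio of sums — the jackknife only
  supplies the SE.
- **f3(A; B, C)** per site is `(a−b)(a−c) − a(1−a)/(n_A−1)` with
  n_A the number of sampled alleles: since
  `E[a(1−a)]·n/(n−1) = p(1−p)`, this correction makes the site term
  unbiased for the population value, verified by the drifted-copy
  null test.  Significance: jackknife Z < −2.
- **Windows**: exactly 10 SNPs stepping by 2, never spanning
  chromosomes.  f_dM uses the dynamic-donor denominator (p2 ≥ p1 uses
  max(p2,p3); otherwise the mirrored term with a sign flip) and lies
  in [−1, 1].  Because the input is an array, dxy and π are
  per-variant (not per-bp) means — the absolute values are *not*
  comparable to sequence-based diversity, only to each other.  Window
  significance Z-transforms f_dM over all defined windows and takes
  the upper one-sided tail at p < 0.01, so the f_dM threshold is
  dataset-specific by construction (≈ mean + 2.326·SD).  A window
  vector with zero variance yields no significant windows.  The π
  comparison (recipient vs unadmixed sister) is reported over windows
  with f_dM > 0 by default, with the significant-only variant
  available.
- **LMM**: REML, EMMAX-style — eigendecompose K once, profile
  δ = Ve/Vg on the covariate-only model over a 61-point log grid in
  [1e-4, 1e4] refined by bounded scalar minimization, then GLS per SNP
  in the rotated basis with Wald χ²₁ p-values.  Missing dosages are
  mean-imputed for this stage only.  Raw p-values are reported (no
  multiple-testing correction by default, matching the small
  candidate-panel use case).

## Degenerate inputs and tie rules

Empty QC results raise explicitly rather than returning empty
matrices.  Empirical top-q thresholds include ties (a constant score
vector returns everything).  Monomorphic SNPs are excluded from the
GRM and contribute He = Ho = 0.  The NJ step requires ≥3 taxa;
jackknives require ≥2 blocks and the implementation warns rather than
extrapolates when a chromosome is shorter than an ROH window.

## Known limitations

- Per-variant π/dxy, no per-bp normalization (array data).
- The iHS scan is exact but unoptimized (per-SNP EHH walks); panels
  beyond ~10⁵ SNPs × 10³ haplotypes would want the usual pruned-tree
  optimizations.
- The supervised ancestry estimator is only as good as its reference
  frequencies; reference misspecification biases proportions toward
  1/2 (see above).
- The LD-based Ne is a point diagnostic, not a NeEstimator
  replacement: no correction for admixture or overlapping
  generations.
- VCF input, cross-chip allele harmonization, phasing and imputation
  are out of scope; phased input is accepted as given and the
  simulator emits phase directly.
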