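# Methods

## The generative model

`ssdskit.synthetic_data` is a forward model of what an SSDS ChIP assay
of RPA, DMC1 or RAD51 sees in an F1-hybrid (B6 × CAST) mouse testis.
One signal fragment is produced per DSB-processing event:

1. **Hotspot choice** — multinomial, proportional to hotspot heat
   (log-normal across hotspots, σ = 0.5 by default). In
   strand-exchange-proficient ("WT") simulations the heats of symmetric
   autosomal hotspots are multiplied by a *lifespan multiplier*
   (default 2.0): inter-homolog strand-exchange intermediates outlive
   inter-sister ones, and longer-lived ssDNA intermediates accumulate
   proportionally more bound protein. Asymmetric and X non-PAR hotspots,
   whose breaks are ultimately sister-repaired, do not receive it.
2. **Broken homolog** — B6 with probability `f_true`. By default
   asymmetric hotspots are fully one-sided (`f_true` ∈ {0, 1},
   `asym_band = 0`): a motif-disrupting SNP that abolishes PRDM9
   binding abolishes breaks on that homolog entirely. The band is a
   parameter; setting e.g. 0.05 draws asymmetric `f_true` in
   [0.95, 1] ∪ [0, 0.05] and reintroduces minor-homolog breaks, which
   then contaminate the repair-template panels by exactly that share.
   X non-PAR hotspots sit on the single (maternal, B6) X.
3. **Break position** — hotspot center + Gaussian offset, sd
   `dsb_sd` = 150 bp by default. This is the DSB-location kernel that
   the deconvolution stage later inverts; it is the generator's truth,
   never estimated. 150 bp reflects the tight clustering of SPO11
   breaks around the PRDM9 motif. (A 300-bp spread was tried first and
   rejected: it blurs the resection decay and the 750-bp renewed-binding
   peak into a single hump whose inversion is no longer identifiable at
   realistic depth — the dip between the true components is shallower
   than the blur width, and no nonnegative solution separates them.)
4. **Resection length** — gamma(shape 4, mean 1000 bp). Resection
   extent varies between breaks; the gamma is a flexible positive
   family and both parameters are exposed.
5. **Footprint component and offset** — each (genotype, protein) preset
   is a mixture of components giving the near-edge distance *d* from
   the break:
   - `resection_uniform` (d ~ U(0, L)): protein coats the whole tract —
     KO RPA, KO RAD51 (RAD51 spreads over the entire filament when DMC1
     is absent);
   - `proximal` / `distal` (lower/upper half of the tract): WT DMC1
     sits break-proximal, WT RAD51 junction-proximal;
   - `fixed_peak` (fragment midpoint ~ N(750, 100) bp): renewed RPA
     binding of the DSB homolog after recombinase dissociation,
     producing the secondary profile peak in the 700–800 bp band
     (weight 0.25 of the WT RPA footprint). The 100-bp width encodes
     that the observed peak is confined to that band.
6. **Polarity** — ssDNA left of the break is recovered on the forward
   strand, right of the break on the reverse strand; the resected end
   reported (left/right) is a fair coin.
7. **Repair-template emission** (WT only, probability 0.2 per event,
   RPA only) — the displaced D-loop strand on the *other* homolog,
   offset N(300, 150) bp from the break, length N(600, 150) bp,
   polarity mirrored. The template:initiating ratio is not a measured
   quantity; 0.2 makes the template panels clearly visible without
   dominating, and is a config knob.
8. **Wrong-polarity emission** (WT only, probability 0.1) — signal on
   the DSB homolog on the side that was resected away (newly
   synthesized DNA after strand exchange), using the D-loop geometry.
   Both 7 and 8 are disabled in the knockout *and* at X non-PAR
   hotspots (sister repair produces no inter-homolog intermediate).
9. **Background** — Poisson(rate × genome length) uniform fragments,
   random strand and random haplotype; default 1e-4 fragments/bp.

Fragment lengths are N(150, 30) truncated at 50 bp (short-read scale;
not a measured quantity). Fragments crossing a chromosome end are
truncated, never dropped, so heat proportionality stays exact; the
truncation count is logged.

The `simulate_h3k4me3` generator emits a protein-agnostic PRDM9
surrogate: fragments around hotspot centers on the homolog PRDM9
actually bound. The per-hotspot B6 fraction *f* is estimated from this
set by default. Estimating *f* from the ssDNA fragments themselves is
supported (`f_source: fragments`) but biased in WT RPA: template
fragments sit on the opposite homolog and pull f̂ toward 0.5, exactly
why a PRDM9-proxy assay is the right source.

### What the simulator does not emulate

Sequence-level reads (no bases, no mapping, no alignment bias), PCR
duplicates, chromatin accessibility bias, crossover/noncrossover
resolution, SPO11-oligo fine structure, inter-hotspot variation in the
break-position kernel, and realistic inter-chromosome heterogeneity.
Passing tests therefore validate the *statistical machinery* (role
assignment, deconvolution, class comparison) under a faithful geometry,
not the read-processing layers that real SSDS data additionally need.

## Analysis stages

**Haplotype assignment** tallies parental alleles at overlapped SNPs
(regular 200-bp grid by default, so P(informative) =
E[min(1, len/spacing)] in closed form). The rule is strict: any allele
mixture → `conflicting`, excluded downstream. In simulation the
genotyper is perfect with an optional per-SNP miscall rate ε. Real
read realignment to two haplotypes is out of scope.

**Symmetry** uses f̂ = n_B6/(n_B6+n_CAST) with an exact Clopper–Pearson
95% CI (statsmodels `proportion_confint(method="beta")`), inclusive
thresholds f̂ ≥ 0.9 / f̂ ≤ 0.1, and a minimum of 10 informative
fragments for a defined label (the minimum is ours; no published value
exists).

**Peak calling** pools both strands (a break flanks signal on both
sides), histograms fragment midpoints, tests windows (default 1000 bp,
step 500) against Poisson(ρ·window), BH-corrects over all tested
windows (q ≤ 0.01, ≥ 5 fragments), merges significant windows within
500 bp and re-scores the merged intervals. ρ is estimated as fragments
fully outside a mask divided by unmasked bp; the pipeline bootstraps ρ
from the whole-genome rate, calls provisional peaks, and re-estimates ρ
outside them. Corrected intensity n − ρ·ℓ counts fragment *midpoints*
(each fragment in at most one interval) and may be negative — clamping
would bias class comparisons built on sums and medians. Subtraction
(not division) is used for the background correction.

**Profiles** bin fragment midpoints at signed distance from the hotspot
center (40-bp bins, ±2500 bp window — chosen to resolve the 700–800 bp
feature), flip sign and strand for minus-orientation hotspots, use only
asymmetric hotspots, assign roles from haplotype calls, and average per
hotspot (uniform weights; heat weighting is an option). Midpoint
binning (not full-extent coverage) keeps mass conservation exact:
total profile mass × n_hotspots = contributing fragments.

**Deconvolution** solves min ‖y − Hs‖² + λ‖s‖², s ≥ 0 per
(strand × role) panel with Lawson–Hanson NNLS (ridge folded in by
design-matrix augmentation; KKT conditions verified to 1e-8 scaled).
H is the truncated Toeplitz matrix of the supplied kernel; interior
columns sum to 1, edge columns to less. Numerical notes:

- Gaussian kernels are severely ill-conditioned (the Toeplitz symbol
  decays like exp(−σ²ω²/2)); noiseless exact inversion is only
  meaningful for σ ≲ 2 bins. With sampling noise, a small ridge is
  required: the pipeline default λ = 1e-2 (profile units are fragments
  per hotspot per bin, O(1)–O(10)) stabilizes the inversion while
  leaving footprint peak positions within one bin of truth across
  seeds. λ = 0 on noisy profiles yields the classic spiky NNLS
  artifacts.
- `scipy.optimize.nnls` iteration cap is raised to 50n; hitting it
  raises with advice rather than returning a bad solution.
- Residual(λ>0) ≥ residual(λ=0) ≥ unconstrained LS residual, asserted
  in tests.

**Comparison** scales each sample by its total corrected intensity over
shared autosomal hotspots (× geometric mean of totals), then reports
per class (symmetric / asymmetric pooled / X non-PAR) the median
log2(WT/KO) with a 2000-replicate seeded bootstrap CI of the median.
Hotspots nonpositive in either sample are excluded and counted; classes
under 5 usable hotspots are reported undetermined. A median + bootstrap
was chosen over a parametric test because the class contrast is a
descriptive, not inferential, claim.

## Determinism

Every stage takes an explicit seed; the pipeline derives stage seeds as
`global_seed + 100·stage_index` and emits a SHA-256 manifest. Reruns
are byte-identical (asserted in tests; floats are serialized via
`repr` so round-trips are exact).

## Problem sizes

The bundled demo and the acceptance script use 2 autosomes × 2 Mb + one
X, 100 hotspots, 1–2 × 10⁵ signal fragments per genotype, 20 seeded
repetitions for recovery statistics and 500 hotspots for classification
fidelity — sizes at which every targeted effect is comfortably resolved
while a full run completes in tens of seconds.

## Known limitations

- Haplotype assignment exists only in simulation mode (truth-label
  lookup with optional miscalls); there is no sequence.
- A single shared DSB-location kernel across hotspots; real hotspots
  differ in width and the per-hotspot extension is not on the tested
  surface.
- The lifespan multiplier is a reduced-form stand-in for intermediate
  kinetics; it reproduces the class-wise intensity ordering, not any
  absolute lifespan.
- The peak caller is a generic Poisson/BH scanner, not a
  re-implementation of any published hotspot caller.
- X non-PAR biology is reduced to "no homolog, no inter-homolog
  intermediates"; PAR-specific behavior is not modeled.
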