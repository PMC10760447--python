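# ssdskit

Strand- and homolog-resolved analysis of SSDS (single-stranded DNA
sequencing) maps of meiotic DSB hotspots, with a mechanistic fragment
simulator.

## The problem

Meiotic recombination starts with programmed double-strand breaks (DSBs)
at PRDM9-positioned hotspots. The broken ends are resected into 3′ ssDNA
overhangs bound successively by RPA, DMC1 and RAD51, and the resulting
filament invades the homologous chromosome, forming a D-loop whose
displaced strand is again RPA-coated. SSDS ChIP assays of these proteins
in an F1-hybrid mouse (B6 × CAST) are doubly informative:

- **strand** tells you which side of the break a fragment came from
  (ssDNA left of the break is recovered on the forward strand, right of
  the break on the reverse strand);
- **haplotype** (via the dense SNPs of the hybrid) tells you whether a
  fragment came from the *DSB-initiating* chromosome or from the
  *repair-template* chromosome — provided the hotspot is *asymmetric*,
  i.e. PRDM9 binds (and breaks) essentially only one homolog.

Comparing wild-type maps with maps from a strand-exchange-defective
mutant (a *Dmc1* knockout) then isolates which binding configurations
require strand invasion. `ssdskit` is for computational biologists who
want a tested, fully simulated re-implementation of this analysis: every
stage runs on synthetic data with complete truth labels, so each
statistical step can be validated against ground truth.

## What it computes

Per-hotspot B6 fraction and symmetry: with `n_B6`, `n_CAST` the
informative fragment (or H3K4me3 surrogate) counts in a hotspot,

    f̂ = n_B6 / (n_B6 + n_CAST),   asymmetric ⇔ f̂ ≥ 0.9 or f̂ ≤ 0.1

(thresholds inclusive, exact Clopper–Pearson 95% CI attached).

Background-corrected hotspot intensity: `I = n − ρ·ℓ` for an interval of
length ℓ containing n fragment midpoints at genome-wide background rate
ρ (fragments/bp). Peaks are called by a sliding-window Poisson test with
Benjamini–Hochberg FDR control.

Footprint deconvolution: within a hotspot the breaks scatter about the
center with a known kernel *k*, so the aggregate profile is y = H s,
where H is the Toeplitz convolution matrix of *k* and *s* the per-break
binding footprint. The footprint is recovered as

    ŝ = argmin_{s ≥ 0} ‖y − H s‖² + λ‖s‖²

an exact nonnegative least-squares fit (`FootprintDeconvolution(...).fit()`
returns a results object, statsmodels-style).

Genotype contrast: per hotspot class (symmetric / asymmetric / X
non-PAR), the median log2(WT/KO) of library-scaled intensities with a
seeded bootstrap CI of the median.

## Worked example

```python
from ssdskit import synthetic_data as sd, haplotype as hap, profiles as pr, deconv as dc

genome, hotspots = sd.simulate_genome(seed=1)          # 2 autosomes + X, 100 hotspots
cfg = sd.preset_config("WT", "RPA", seed=2, n_signal_fragments=100_000,
                       background_rate=1e-4)
fragments, log = sd.simulate_fragments(genome, hotspots, cfg)

h3k = sd.simulate_h3k4me3(genome, hotspots, seed=3)    # PRDM9 surrogate for f
sym, frame = hap.symmetry_table(hotspots, h3k, hap.assign_haplotypes(h3k, genome))

calls = hap.assign_haplotypes(fragments, genome)
profile = pr.aggregate_profile(fragments, calls, hotspots, sym)
kernel = dc.DsbLocationKernel.gaussian(cfg.dsb_sd, profile.binsize)
print(dc.FootprintDeconvolution(profile, kernel, ridge=1e-2).fit().summary())
```

prints

```
Footprint deconvolution (nonnegative least squares)
  bins: 125 x 40 bp, window +/-2500 bp, ridge 0.01
  panel                           mass    residual   argmax bp
  F/dsb_initiating                 218       3.274        -720
  F/repair_template              57.05      0.7057         600
  R/dsb_initiating                 216       3.184         760
  R/repair_template              54.76        1.11        -600
```

Reading this: the DSB-initiating footprint peaks ~720–760 bp from the
break (the renewed RPA binding that follows successful strand invasion;
negative on the forward strand because ssDNA left of the break is
recovered there), and the repair-template panels carry D-loop signal
~600 bp out with *mirrored* polarity. Re-running with the
`("DMC1KO", "RPA")` preset leaves the repair-template panels at
background: no strand exchange, no D-loop.

The same pipeline runs from the shell:

```
ssdskit run --outdir demo --seed 11          # simulate → peaks → haplotype →
                                             # profile → deconvolve → compare
```

which writes BED/TSV artifacts for every stage plus `manifest.json` with
SHA-256 digests (reruns are byte-identical) and a summary including the
per-class WT/KO comparison.

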