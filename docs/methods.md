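# Methods

This note documents the models and procedures implemented in `svld`,
the assumptions behind them, the tunable parameters that matter, and
what the synthetic data can and cannot show about real data.

## LD estimators

All LD is computed within one population on phased 0/1 haplotypes.
For loci A and B with alternative-allele frequencies p_A, p_B and
haplotype frequency p_AB,

    r² = (p_AB − p_A p_B)² / (p_A p_B (1 − p_A)(1 − p_B)).

r² is undefined for monomorphic loci; such variants are excluded from
pairing. Because r² is a convex quadratic in p_AB, its maximum over the
feasible region (the Fréchet interval
`max(0, p_A + p_B − 1) ≤ p_AB ≤ min(p_A, p_B)`) is attained at one of
the two bounds; `r2max` evaluates both and takes the larger value,
which is exact (no grid search needed — the test suite nevertheless
checks agreement with a 10⁵-point grid to 1e−9). The standardized
coefficient `r²_S = r²/r²max` removes the component of LD attributable
to allele-frequency differences (ΔMAF) between the two loci; it is
clipped only against floating-point overshoot.

Conventions, chosen once and used everywhere:

- internal coordinates are 0-based half-open; VCF I/O converts at the
  boundary, so a VCF DEL at POS 1001 with END 1500 spans [1000, 1500);
- SV–SNP distance is the minimum distance from the SNP to either
  breakpoint (a SNP 100 bp left of a 10 kb DEL is at distance 100);
  SNP–SNP distance is the coordinate difference;
- SNPs positioned on an SV's span are excluded from pairs with that SV
  only (their calls may be influenced by the SV), not globally;
- distance bins are upper-closed 500 bp intervals, so bin 1 is
  (0, 500] and a pair at exactly 500 bp falls in it; the default range
  is 100 kb (200 bins);
- relative LD divides SV-class bin means by SNP–SNP bin means, in
  percent, and averages bins 1–10; the quoted SD is across those ten
  ratios (ddof = 1);
- bootstrap CIs are percentile intervals from resampling within-bin
  values (default 100,000 resamples) at Bonferroni-corrected levels
  α = 0.05/n_bins; bins with more than 10⁶ values skip the CI (it
  would be negligibly narrow at great cost), as do bins with fewer
  than two.

## Consensus filter

Five rules applied in fixed order after a SURVIVOR-style merge
(greedy left-to-right chaining of same-type, same-chromosome records
whose start *and* end each differ by ≤ 1000 bp from the previous chain
member; canonical breakpoints are lower medians across callers):

1. caller overlap: ≥ 2 of 3 callers;
2. genotype concordance: per sample, the consensus genotype is any
   value with ≥ 2 caller votes (non-supporting callers do not vote);
   samples without one become missing, and SVs with > 2 such samples
   are removed;
3. high-coverage regions: a window is flagged when its cross-sample
   mean exceeds 2μ + 2σ, where μ and σ are the mean and SD of the
   cross-sample window means over all autosomal windows (the threshold
   is read as separate terms, not 2(μ+σ), and the comparison is
   strict); flagged windows < 1000 bp apart merge, and an SV whose
   half-open breakpoint confidence interval intersects a region is
   removed (a zero-width CI degenerates to the breakpoint base);
4. DHFFC: median 100 bp-window coverage fully inside the span divided
   by the median over the two 1 kb flanks (pooled); undefined when no
   window fits inside or the flank median is zero, and undefined
   values are untestable. Het DEL valid in the closed interval
   [0.1, 0.9]; hom DEL valid strictly below 0.25; het DUP strictly
   above 1.1; hom DUP strictly above 1.5; reference and missing
   genotypes are never tested. More than one wrong genotype, or a
   wrong fraction above 10 % of tested genotypes, removes the SV;
   otherwise wrong genotypes become missing. INV and BND carry no
   usable coverage signal and bypass rules 4–5;
5. SNP support on DELs: per carrier sample, the violation rate is
   violating SNP calls (het call on a het-DEL sample; any non-missing
   call on a hom-DEL sample) divided by the number of SNPs on the DEL.
   The DEL is removed when the summed rate exceeds 2 or half the
   number of carrier samples. A `snp_support_halved` switch divides by
   twice the SNP count instead — the per-allele reading of the rate;
   the simple ratio is the default.

Genotypes set to missing by rules 2/4/5 are refilled only by the
explicit fill stage, never silently. A review manifest (variant,
caller support, missingness, DHFFC summary) replaces an image-based
visual screen, which is out of scope.

### Fill / phasing stand-in

Statistical imputation and phasing (beagle in the original workflows)
are replaced by a documented stand-in: missing genotypes are drawn from
the variant's non-missing allele frequency, and heterozygote phase is
copied from an optional *phase template* wherever the template's dosage
agrees (random assignment otherwise). In synthetic runs the template is
the truth panel, which emulates a phasing step that recovers the true
haplotypes; genotypes corrupted by caller errors get random phase and
therefore genuinely decorrelate. Without a template, random phasing
destroys inter-variant haplotype correlation entirely, which is the
correct behavior for a genotype-only panel but makes haplotype-LD
downstream meaningless — hence the template is the default in the
pipeline. Purely random phasing is *not* a model of beagle's accuracy;
this is the main idealization of the fill stage.

## Synthetic data generator

The generator's purpose is to produce panels whose *statistical
structure* matches what the analyses assume, with a recorded ground
truth — not demographic realism.

**Haplotypes.** Each population has K founders; every haplotype copies
founder segments whose lengths are exponential with mean L, so
co-inheritance of two sites decays as exp(−d/L). The expected sample
r² of co-inherited sites is ≈ 1/(K−1), so K sets the short-range LD
level and L the decay scale. The three default populations use
K = 3/4/6 and L = 40/20/10 kb (WL/BL/BR), reproducing the ordering
strong → weak of white layer, brown layer and broiler panels.

**Variants.** Every variant — SNP or SV — is constructed by one
mechanism: a target frequency drawn from a per-type Beta spectrum
(scaled to (0, 0.5]), a founder background of ceil(target·K) founders
at its locus, and a carrier set thinned to round(2N·target) haplotypes
keeping those with the longest shared founder segment around the locus
("nested-first", an age-like sub-lineage). This makes realized
frequencies essentially unbiased for the configured spectra (rounding
and background caps contribute < 0.01 absolute bias) while keeping
carrier sets coherent with the local haplotype structure, so
standardized LD between SVs and SNPs matches SNP–SNP levels by
construction symmetry. Per-type spectra: SNP Beta(0.8, 1.6); DEL
slightly rare-shifted Beta(0.72, 1.68); DUP strongly rare-shifted
Beta(0.35, 2.5); INV/BND common-shifted Beta(1.8, 1.1). DUPs
additionally have one carrier replaced by a random non-carrier
haplotype — a recurrent second mutational origin, the mechanism by
which real duplications (NAHR products) escape single-lineage tagging;
this is what separates DUP tagged shares from DEL/SNP shares without
affecting the ΔMAF-only experiments (`error_free` configurations
disable it). SV spans are log-normal with medians 443 bp (DEL), 3 kb
(DUP) and 5 kb (INV) — DEL matching the published scale and DUP/INV
scaled down to fit 5 Mb chromosomes — floored at 300 bp so every DEL
covers at least two depth windows; BNDs carry a single breakpoint and
no length. SVs are placed without overlap, clear of chromosome ends,
and preferentially in SNP-poor neighborhoods (local 5 kb SNP count at
or below the median), mirroring the observed lower SNP density around
SVs.

**Depth.** Per-sample window coverage is Normal(mean·factor, SD)
truncated at zero in 100 bp windows; the factor is 1/0.5/0 inside DEL
spans and 1/1.5/2 inside DUP spans by dosage, proportional for partial
windows. Sample means are uniform in [5, 17]×; the Normal (rather than
Poisson) noise matches the window-mean scale. Artifact regions multiply
coverage by a configurable fold (default 4) in all samples and are
placed away from SVs so that error-free runs stay clean.

**Callsets.** Each of three mock callers detects each SV with per-type
sensitivity (default 0.95), jitters breakpoints Normal(0, SD) with
per-caller SDs of 20–100 bp, corrupts genotypes at per-type rates
(1 % DEL, 4 % others), and finally applies a dedicated hom→het miscall
channel to DUP/INV/BND dosage-2 genotypes (default rate 0.5 per
caller). The channel acts last, so a rate of 1 guarantees no emitted
homozygous-variant genotype. Every injected error is recorded in the
truth set, which is what lets tests attribute each filter decision.
The rates are free parameters of the generator, not estimates for any
real caller.

**What passing tests do not show.** The generator has no recurrent
mutation beyond the single-swap DUP channel, no gene conversion, no
selection, no real recombination map, no mapping-error structure
beyond flat artifact folds, and its SNP density (~1.5/kb) is an order
of magnitude below real WGS panels — absolute tagged shares are
therefore far below published values even though their ordering across
variant classes is reproduced. Conclusions from synthetic runs are
about the *behavior of the methods*, not about chickens.

## Mechanism-attribution experiment

`reproduce_qualitative_pattern` checks the qualitative pattern on the
desk preset (documented reference seed 2): relative r²(DEL) within
[90, 110] %; relative r²(DUP) below relative r²(DEL); Δ = relative
r²_S − relative r² positive for DUP/INV/BND; tagged shares ordered
SNP ≥ DEL > DUP > INV/BND. Two error-free ablations isolate the ΔMAF
mechanism: with the rare DUP spectrum active, relative r²(DUP) drops
well below 100 % while relative r²_S stays within [90, 110] % (the gap
is carried by allele-frequency differences alone); replacing the DUP
spectrum with the SNP spectrum brings Δ(DUP) to ≈ 0. Adding the error
channels back drops relative r²_S(DUP) further — the second mechanism,
reduced genotyping accuracy. Relative values are averaged over the
three populations to reduce class-size noise. These checks are
stochastic; individual seeds can miss single checks by small margins,
which is why the reference seed is part of the documented preset.

## Sizes and numerical choices

The desk preset (2 chromosomes × 5 Mb, 25 samples × 3 populations,
~15k SNPs, 300 SVs split 120/60/60/60) keeps a full pipeline run at
about a minute and the whole test suite at a few minutes; the split
gives every SV class enough members for stable bin means. Bootstrap
CIs in pipeline runs default off (the estimator is exposed and tested
separately) because 100,000 resamples across 200 bins × 5 classes
dominate runtime without changing any decision. Merge tie-breaks use
lower medians; HWE p values use the probability-ordering two-sided
convention without mid-p; the chromosome-bias regression is OLS with
intercept and a t-test of the slope against 1, with zero-residual fits
reported as p = 1 on the identity line. The HWE scan's Bonferroni
factor is the number of testable variants of the same class in the
same population. Mean tag curves average variants with a defined
r²_tag at each grid point; shares count variants with no pool SNP as
untagged. The compact letter display uses insert-and-absorb: start
with one group of all classes, split at each significant pair, absorb
subset groups.

## Known limitations

- The fill stage is not an imputation model; imputation accuracy
  cannot be studied with it.
- BND records carry no mate coordinates; breakend graph semantics are
  out of scope.
- The exact HWE test conditions on the minor-allele count; extremely
  large cohorts would want a faster normal approximation, which is not
  implemented.
- Multi-allelic records are rejected at VCF input (the analyses assume
  bivariate variants throughout).
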