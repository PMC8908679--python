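# svld — consensus SV filtering and SV–SNP linkage disequilibrium

Structural variants (SVs — deletions, duplications, inversions and
translocation breakpoints) are hard to call accurately from short-read
sequencing, yet their phenotypic effects matter for breeding and
association studies. Whether those effects can be captured by nearby SNP
markers depends on the linkage disequilibrium (LD) between each SV and
its surrounding SNPs. `svld` implements, as a tested reusable library,
the two halves of that question for multi-population livestock panels
(its synthetic presets emulate three commercial chicken populations):

1. **A precision-first consensus filter** for SV callsets from three
   callers: a SURVIVOR-style merge with 1 kb breakpoint tolerance
   followed by five rules — caller overlap (≥ 2 of 3), per-sample
   genotype concordance (2-of-3 votes, SVs with > 2 discordant samples
   dropped), removal of SVs whose breakpoint confidence intervals fall
   into unusually high-coverage regions (window mean > 2μ + 2σ, flagged
   windows merged when < 1 kb apart), coverage consistency of DEL/DUP
   genotypes via the duphold flanking fold change (DHFFC; het DEL in
   [0.1, 0.9], hom DEL < 0.25, het DUP > 1.1, hom DUP > 1.5; more than
   one wrong or > 10 % wrong genotypes drops the SV), and SNP support
   on DELs (SNP calls must be homozygous on het-DEL and missing on
   hom-DEL samples).

2. **LD and taggability analyses** on phased haplotype panels:

   - pairwise squared haplotype correlation
     `r² = (p_AB − p_A p_B)² / (p_A p_B (1 − p_A)(1 − p_B))`,
   - its frequency-difference bound `r²max` (the larger value of r² at
     the Fréchet bounds of p_AB) and the standardized `r²_S = r²/r²max`,
   - decay curves as means in 500 bp distance bins up to 100 kb with
     Bonferroni-corrected percentile-bootstrap confidence intervals,
   - SV–SNP LD relative to SNP–SNP LD averaged over the first ten bins,
   - tag-SNP curves `r²_tag(d)` (best r² within distance d), tagged
     shares at `r²_tag > 0.75`, SNP-density statistics with pairwise
     Wilcoxon rank-sum comparisons, and array-manifest pools,
   - Hardy–Weinberg exact-test scans (Haldane's conditional test) with
     Bonferroni correction within SV class, genome-fraction statistics
     and a chromosome-length bias regression.

A first-class **synthetic-data generator** emulates the statistical
structure such analyses assume — three populations with different LD
strength (founder-mosaic haplotypes), MAF spectra shifted by variant
type, per-caller genotype errors, breakpoint jitter, a dedicated
hom→het miscall channel that reproduces the deficit of homozygous
non-DEL SV genotypes, coverage profiles in 100 bp windows and
high-coverage artifact regions — so every stage runs and is testable
with no external data and a known ground truth.

## Worked example

```python
from svld import SimConfig, run_filter_pipeline, simulate_all

config = SimConfig(seed=2)           # desk preset: 2 x 5 Mb, 75 samples
data = simulate_all(config)          # panel + truth + depth + 3 callsets
result = run_filter_pipeline(
    data.callsets, data.depth, data.truth.snp_calls,
    genome=config.genome, samples=data.truth.sample_ids,
)
print(result.report.to_frame().to_string(index=False))
```

```
                 rule  input  removed  retained  genotypes_set_missing
       caller_overlap    300        1       299                      0
 genotype_concordance    299       35       264                     70
high_coverage_regions    264        0       264                      0
                dhffc    264       11       253                      3
      del_snp_support    253        4       249                      0
```

Of 300 simulated SVs, one lacked two-caller support, 35 had too many
genotype-discordant samples, 11 failed the DHFFC coverage check and 4
failed SNP support on their span; 73 individual genotypes were demoted
to missing for re-imputation instead of dropping the variant. Each row
conserves counts (input = removed + retained).

The `examples/` directory holds one short narrative script per
capability (simulation, filtering, LD decay and relative LD, tag SNPs
and array pools, HWE scan, full pipeline). `svld run-all --out run
--seed 2` executes the whole chain through on-disk VCF/BED/TSV stages.

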