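"""LD decay between SVs and SNPs, and the relative-LD summary.

Computes pairwise r², its frequency bound r²max and the standardized
r²_S on the truth panel of one simulation, bins the pairs in 500 bp
distance bins and expresses SV-SNP LD relative to SNP-SNP LD over the
first ten bins (i.e. within 5 kb).
"""

from svld import SimConfig, bin_decay, ld_pairs, relative_ld, simulate_all

data = simulate_all(SimConfig(seed=2))

for pop in ("WL", "BL", "BR"):
    sub = data.panel.subset_population(pop)
    decay = bin_decay(ld_pairs(sub, max_dist=100_000))
    snp = decay[decay.pair_class == "SNP-SNP"]
    first_bin = snp.loc[snp.bin == 1, "mean_r2"].iloc[0]
    line = [f"{pop}: SNP-SNP r2(<=500bp)={first_bin:.2f}"]
    for cls in ("DEL-SNP", "DUP-SNP", "INV-SNP", "BND-SNP"):
        rl = relative_ld(decay[decay.pair_class == cls], snp)
        line.append(f"{cls.split('-')[0]} {rl.rel_r2_mean:.0f}%/{rl.rel_r2s_mean:.0f}%")
    print("  ".join(line))

# Per population: the first-bin SNP-SNP r² reflects the population's LD
# strength (WL > BL > BR), and each SV class shows its mean LD relative
# to SNP-SNP as raw%/standardized%.  DELs sit near 100/100; DUPs show a
# strongly reduced raw value that standardization largely recovers —
# their gap is carried by local allele-frequency differences.
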