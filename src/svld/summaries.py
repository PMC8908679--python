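"""Callset descriptive statistics: lengths, genome fractions, MAF spectra,
Hardy–Weinberg exact tests and chromosome-length bias regression."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import gammaln

from .datamodel import (
    MISSING,
    GenomeTable,
    HaplotypePanel,
    VariantRecord,
    VType,
)


@dataclass
class GenotypeCounts:
    """Non-missing genotype counts of one variant in one population."""

    n_homref: int
    n_het: int
    n_homvar: int

    def __post_init__(self) -> None:
        if min(self.n_homref, self.n_het, self.n_homvar) < 0:
            raise ValueError("genotype counts must be non-negative")

    @property
    def n(self) -> int:
        return self.n_homref + self.n_het + self.n_homvar

    @property
    def alt_count(self) -> int:
        return self.n_het + 2 * self.n_homvar

    @classmethod
    def from_dosages(cls, dosages: np.ndarray) -> "GenotypeCounts":
        d = np.asarray(dosages)
        d = d[d != MISSING]
        return cls(int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum()))


@dataclass
class HWEResult:
    """Exact Hardy–Weinberg test result for one variant."""

    p: float
    deviation: float  # observed n_homvar - expected n*q^2
    p_bonf: float = np.nan
    significant: bool = False


def hwe_exact(counts: GenotypeCounts) -> HWEResult:
    """Two-sided exact Hardy–Weinberg test (Haldane's conditional test).

    Conditions on the sample size and the minor-allele count; the
    heterozygote count then has probabilities proportional to
    ``n! / (n_homref! n_het! n_homvar!) · 2^n_het``.  The two-sided p value
    sums the probabilities of all configurations no more likely than the
    observed one.  The deviation is reported for the variant allele:
    observed homozygous-variant count minus ``n·q²``.
    """
    n = counts.n
    n_alt = counts.alt_count
    if n_alt == 0 or n_alt == 2 * n:
        raise ValueError("exact test undefined for a monomorphic variant")
    minor = min(n_alt, 2 * n - n_alt)
    hets = np.arange(minor % 2, minor + 1, 2)
    # feasibility: hom_minor = (minor - het) / 2 and hom_major >= 0
    hom_minor = (minor - hets) // 2
    hom_major = n - hets - hom_minor
    ok = hom_major >= 0
    hets, hom_minor, hom_major = hets[ok], hom_minor[ok], hom_major[ok]
    logw = (
        -gammaln(hom_major + 1)
        - gammaln(hets + 1)
        - gammaln(hom_minor + 1)
        + hets * np.log(2.0)
    )
    logw -= logw.max()
    w = np.exp(logw)
    probs = w / w.sum()
    obs = probs[hets == counts.n_het][0]
    p = float(probs[probs <= obs * (1 + 1e-12)].sum())
    q = n_alt / (2 * n)
    deviation = counts.n_homvar - n * q * q
    return HWEResult(p=min(p, 1.0), deviation=float(deviation))


def hwe_scan(
    records: list[VariantRecord],
    populations: list[str],
    population: str,
) -> pd.DataFrame:
    """HWE exact tests for all testable variants of one population.

    Bonferroni correction is applied within variant class (the correction
    factor is the number of testable variants of the same class).
    """
    mask = np.array([p == population for p in populations])
    if not mask.any():
        raise KeyError(f"no samples in population {population!r}")
    rows = []
    for r in records:
        counts = GenotypeCounts.from_dosages(r.genotypes[mask])
        if counts.n == 0 or counts.alt_count in (0, 2 * counts.n):
            continue
        res = hwe_exact(counts)
        rows.append(
            {
                "id": r.id,
                "pair_class": r.vtype.value,
                "n_homref": counts.n_homref,
                "n_het": counts.n_het,
                "n_homvar": counts.n_homvar,
                "p": res.p,
                "deviation": res.deviation,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["id", "pair_class", "n_homref", "n_het", "n_homvar", "p", "deviation"],
    )
    if df.empty:
        df["p_bonf"] = df["significant"] = pd.Series(dtype=float)
        return df
    class_size = df.groupby("pair_class")["id"].transform("count")
    df["p_bonf"] = np.minimum(1.0, df["p"] * class_size)
    df["significant"] = df["p_bonf"] < 0.05
    return df


def hwe_deficit_share(scan: pd.DataFrame, vclass: str) -> float:
    """Share of negative deviations among significant results of a class."""
    sig = scan[(scan["pair_class"] == vclass) & scan["significant"]]
    if sig.empty:
        return np.nan
    return float((sig["deviation"] < 0).mean())


def _union_length(intervals: list[tuple[int, int]]) -> int:
    total, cur_a, cur_b = 0, None, None
    for a, b in sorted(intervals):
        if cur_b is None or a > cur_b:
            if cur_b is not None:
                total += cur_b - cur_a
            cur_a, cur_b = a, b
        else:
            cur_b = max(cur_b, b)
    if cur_b is not None:
        total += cur_b - cur_a
    return total


def affected_fraction(panel: HaplotypePanel, genome: GenomeTable) -> pd.DataFrame:
    """Per-individual fraction of the autosomal genome affected per type.

    For each haplotype, the union length of spans carrying the alternative
    allele (SNPs contribute 1 bp; BNDs 1 bp for the breakpoint) divided by
    the autosomal length; the individual's value is the mean of its two
    haplotypes.  The homozygous-DEL fraction uses the union of positions
    deleted on *both* haplotypes.
    """
    auto_len = genome.autosomal_length()
    autosomes = set(genome.autosomes())
    types = [t.value for t in VType]
    rows = []
    for i, sample in enumerate(panel.sample_ids):
        spans_h = {t: ([], []) for t in types}
        homdel: list[tuple[str, int, int]] = []
        del_by_hap: tuple[list, list] = ([], [])
        for j, v in enumerate(panel.variants):
            if v.chrom not in autosomes:
                continue
            a0 = panel.alleles[2 * i, j]
            a1 = panel.alleles[2 * i + 1, j]
            if not (a0 or a1):
                continue
            span = (v.start, v.end if v.vtype.has_span else v.start + 1)
            if a0:
                spans_h[v.vtype.value][0].append((v.chrom, *span))
            if a1:
                spans_h[v.vtype.value][1].append((v.chrom, *span))
            if v.vtype is VType.DEL:
                if a0:
                    del_by_hap[0].append((v.chrom, *span))
                if a1:
                    del_by_hap[1].append((v.chrom, *span))
        row = {"sample": sample, "population": panel.populations[i]}
        for t in types:
            fracs = []
            for h in (0, 1):
                by_chrom: dict[str, list[tuple[int, int]]] = {}
                for chrom, a, b in spans_h[t][h]:
                    by_chrom.setdefault(chrom, []).append((a, b))
                ln = sum(_union_length(iv) for iv in by_chrom.values())
                fracs.append(ln / auto_len)
            row[f"frac_{t}"] = float(np.mean(fracs))
        row["frac_homdel"] = _homozygous_del_fraction(del_by_hap, auto_len)
        rows.append(row)
    return pd.DataFrame(rows)


def _homozygous_del_fraction(del_by_hap, auto_len: int) -> float:
    """Union of positions deleted on both haplotypes over autosome length."""
    total = 0
    chroms = {c for c, _, _ in del_by_hap[0]} & {c for c, _, _ in del_by_hap[1]}
    for chrom in chroms:
        iv0 = sorted((a, b) for c, a, b in del_by_hap[0] if c == chrom)
        iv1 = sorted((a, b) for c, a, b in del_by_hap[1] if c == chrom)
        # intersection of the two union sets
        merged0 = _merge(iv0)
        merged1 = _merge(iv1)
        k = 0
        for a, b in merged0:
            while k < len(merged1) and merged1[k][1] <= a:
                k += 1
            kk = k
            while kk < len(merged1) and merged1[kk][0] < b:
                total += min(b, merged1[kk][1]) - max(a, merged1[kk][0])
                kk += 1
    return total / auto_len


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[list[int]] = []
    for a, b in sorted(intervals):
        if out and a <= out[-1][1]:
            out[-1][1] = max(out[-1][1], b)
        else:
            out.append([a, b])
    return [(a, b) for a, b in out]


def callset_summaries(
    records: list[VariantRecord], genome: GenomeTable
) -> dict[str, pd.DataFrame]:
    """Length statistics, genome coverage and MAF spectrum of a callset.

    BNDs carry no length and are excluded from length/coverage statistics;
    coverage is the union of spans per type over the autosomal length.
    """
    autosomes = set(genome.autosomes())
    auto_len = genome.autosomal_length()
    lrows, crows, mrows = [], [], []
    for t in VType:
        recs = [r for r in records if r.vtype is t and r.chrom in autosomes]
        if t is not VType.BND and recs:
            lengths = np.array([r.length for r in recs])
            lrows.append(
                {
                    "pair_class": t.value,
                    "n": len(recs),
                    "median_length": float(np.median(lengths)),
                    "max_length": int(lengths.max()),
                }
            )
            by_chrom: dict[str, list[tuple[int, int]]] = {}
            for r in recs:
                span = (r.start, r.end if r.vtype.has_span else r.start + 1)
                by_chrom.setdefault(r.chrom, []).append(span)
            cov = sum(_union_length(iv) for iv in by_chrom.values())
            crows.append(
                {
                    "pair_class": t.value,
                    "covered_bp": cov,
                    "fraction_pct": 100.0 * cov / auto_len,
                }
            )
        for r in recs:
            f = r.alt_frequency()
            if np.isfinite(f):
                mrows.append(
                    {"id": r.id, "pair_class": t.value, "maf": float(min(f, 1 - f))}
                )
    return {
        "lengths": pd.DataFrame(lrows),
        "coverage": pd.DataFrame(crows),
        "maf": pd.DataFrame(mrows, columns=["id", "pair_class", "maf"]),
    }


def chromosome_bias(
    records: list[VariantRecord], genome: GenomeTable, vtype: VType
) -> tuple[float, float, float]:
    """Regression of relative per-chromosome variant counts on relative
    chromosome length.

    Returns (slope, p value of H0: slope = 1, R²).  A perfect line of
    identity (zero residuals) reports p = 1.
    """
    chroms = genome.autosomes()
    if len(chroms) < 3:
        raise ValueError("need at least three chromosomes for the regression")
    counts = np.array(
        [sum(1 for r in records if r.vtype is vtype and r.chrom == c) for c in chroms],
        dtype=float,
    )
    if counts.sum() == 0:
        raise ValueError(f"no {vtype.value} records to regress")
    lengths = np.array([genome.lengths[c] for c in chroms], dtype=float)
    y = counts / counts.sum()
    x = lengths / lengths.sum()
    model = sm.OLS(y, sm.add_constant(x)).fit()
    slope = float(model.params[1])
    bse = float(model.bse[1])
    if bse == 0 or not np.isfinite(bse) or model.ssr < 1e-24:
        # degenerate zero-residual fit: identity line reports p = 1
        p = 1.0 if abs(slope - 1.0) < 1e-9 else 0.0
    else:
        t = (slope - 1.0) / bse
        p = float(2 * stats.t.sf(abs(t), df=model.df_resid))
    return slope, p, float(model.rsquared)
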