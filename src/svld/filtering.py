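"""Consensus merge of per-caller SV callsets and the five-rule filter.

The pipeline mirrors a precision-first consensus calling strategy for
short-read SV detection:

1. caller overlap — keep SVs supported by at least two of three callers
   (merged beforehand with a 1000 bp breakpoint tolerance);
2. genotype concordance — per sample, the consensus genotype is the one
   two callers agree on; samples without such support become missing, and
   an SV with more than two such samples is dropped;
3. high-coverage regions — windows whose cross-sample mean coverage
   exceeds 2·μ + 2·σ (μ, σ over all autosomal window means) mark likely
   mapping artifacts; nearby flagged windows are merged and SVs whose
   breakpoint confidence intervals fall inside are dropped;
4. flanking fold change — DEL/DUP genotypes must show the expected
   depth ratio (DHFFC) relative to their flanks; SVs with more than one
   inconsistent genotype or more than 10% inconsistent are dropped,
   otherwise the offending genotypes become missing;
5. SNP support on DELs — SNP calls must be homozygous on het-DEL samples
   and missing on hom-DEL samples; summed per-sample violation rates
   above 2, or above half the carrier count, drop the DEL.

INV and BND carry no usable coverage signal and bypass rules 4–5.
Genotypes set to missing here are refilled only by
:func:`fill_missing_genotypes`, never silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    MISSING,
    DepthProfile,
    GenomeTable,
    HaplotypePanel,
    VariantRecord,
    VType,
)

RULE_NAMES = (
    "caller_overlap",
    "genotype_concordance",
    "high_coverage_regions",
    "dhffc",
    "del_snp_support",
)


@dataclass
class FilterConfig:
    """Thresholds of the consensus filter (defaults as used in the field)."""

    merge_tolerance: int = 1000
    max_discordant_samples: int = 2
    coverage_merge_gap: int = 1000
    dhffc_flank: int = 1000
    het_del_bounds: tuple[float, float] = (0.1, 0.9)
    hom_del_max: float = 0.25
    het_dup_min: float = 1.1
    hom_dup_min: float = 1.5
    max_wrong_genotypes: int = 1
    max_wrong_fraction: float = 0.10
    snp_support_sum_max: float = 2.0
    snp_support_carrier_frac: float = 0.5
    # per-allele reading of the SNP-violation rate (divides by
    # twice the SNP count); default is the simple violations/SNPs ratio
    snp_support_halved: bool = False


def _lower_median(values: Sequence[int]) -> int:
    """Median with even ties resolved to the smaller central value."""
    v = sorted(values)
    return v[(len(v) - 1) // 2]


@dataclass
class MergedSV:
    """One consensus SV with its per-caller evidence."""

    record: VariantRecord
    per_caller: dict[str, VariantRecord]
    consensus: np.ndarray | None = None
    dhffc: np.ndarray | None = None
    missing_by_discordance: int = 0

    @property
    def caller_support(self) -> frozenset[str]:
        return frozenset(self.per_caller)


@dataclass
class HighCoverageRegions:
    """Merged intervals of unusually high cross-sample coverage."""

    regions: list[tuple[str, int, int]]
    threshold: float

    def __post_init__(self) -> None:
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for c, a, b in self.regions:
            by_chrom.setdefault(c, []).append((a, b))
        for iv in by_chrom.values():
            iv.sort()
        self._by_chrom = by_chrom

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """True if half-open [start, end) intersects any region."""
        for a, b in self._by_chrom.get(chrom, ()):
            if a >= end:
                break
            if start < b and a < end:
                return True
        return False


@dataclass
class FilterReport:
    """Per-rule bookkeeping: input = removed + retained at every rule."""

    rows: list[dict] = field(default_factory=list)

    def add(self, rule: str, n_in: int, n_removed: int, gt_missing: int = 0) -> None:
        self.rows.append(
            {
                "rule": rule,
                "input": n_in,
                "removed": n_removed,
                "retained": n_in - n_removed,
                "genotypes_set_missing": gt_missing,
            }
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows,
            columns=["rule", "input", "removed", "retained", "genotypes_set_missing"],
        )


def merge_callsets(
    callsets: Mapping[str, Sequence[VariantRecord]], tolerance: int = 1000
) -> list[MergedSV]:
    """SURVIVOR-style merge of per-caller callsets.

    SVs of the same type on the same chromosome whose start AND end each
    differ by at most ``tolerance`` from the previous chain member are
    merged greedily left-to-right; BNDs compare the single breakpoint.
    Canonical breakpoints are the (lower) median over supporting callers.
    """
    tagged = [
        (caller, rec)
        for caller, recs in callsets.items()
        for rec in recs
    ]
    groups: dict[tuple[str, VType], list[tuple[str, VariantRecord]]] = {}
    for caller, rec in tagged:
        groups.setdefault((rec.chrom, rec.vtype), []).append((caller, rec))
    merged: list[MergedSV] = []
    for (chrom, vtype), members in groups.items():
        members.sort(key=lambda t: (t[1].start, t[1].end, t[0]))
        cluster: list[tuple[str, VariantRecord]] = []
        for caller, rec in members:
            if cluster:
                prev = cluster[-1][1]
                near = abs(rec.start - prev.start) <= tolerance and (
                    vtype is VType.BND or abs(rec.end - prev.end) <= tolerance
                )
            else:
                near = False
            if near:
                cluster.append((caller, rec))
            else:
                if cluster:
                    merged.append(_finalize_cluster(cluster))
                cluster = [(caller, rec)]
        if cluster:
            merged.append(_finalize_cluster(cluster))
    merged.sort(key=lambda m: (m.record.chrom, m.record.start, m.record.end))
    return merged


def _finalize_cluster(cluster: list[tuple[str, VariantRecord]]) -> MergedSV:
    per_caller: dict[str, VariantRecord] = {}
    for caller, rec in cluster:
        per_caller.setdefault(caller, rec)  # first record per caller wins
    recs = list(per_caller.values())
    vtype = recs[0].vtype
    start = _lower_median([r.start for r in recs])
    if vtype is VType.BND:
        end = start + 1
    else:
        end = max(start + 1, _lower_median([r.end for r in recs]))
    ci_start = (min(r.ci_start[0] for r in recs), max(r.ci_start[1] for r in recs))
    ci_end = (min(r.ci_end[0] for r in recs), max(r.ci_end[1] for r in recs))
    base = recs[0].id.rsplit(".", 1)[0]
    canonical = VariantRecord(
        id=base,
        chrom=recs[0].chrom,
        start=start,
        end=end,
        vtype=vtype,
        ci_start=ci_start,
        ci_end=ci_end,
        caller_support=frozenset(per_caller),
    )
    return MergedSV(record=canonical, per_caller=per_caller)


def filter_caller_overlap(
    merged: Sequence[MergedSV], min_callers: int = 2
) -> tuple[list[MergedSV], list[MergedSV]]:
    """Rule 1: at least two of the three callers must support the SV."""
    retained = [m for m in merged if len(m.per_caller) >= min_callers]
    removed = [m for m in merged if len(m.per_caller) < min_callers]
    return retained, removed


def consensus_genotypes(
    merged: Sequence[MergedSV], max_discordant_samples: int = 2
) -> tuple[list[MergedSV], list[MergedSV]]:
    """Rule 2: per-sample consensus genotype supported by two callers.

    Callers not supporting the SV contribute no vote.  A sample with no
    genotype reaching two votes becomes missing and counts as discordant;
    the SV is removed when more than ``max_discordant_samples`` samples are
    discordant.
    """
    retained, removed = [], []
    for m in merged:
        votes = np.stack([r.genotypes for r in m.per_caller.values()])
        n_samples = votes.shape[1]
        consensus = np.full(n_samples, MISSING, dtype=np.int8)
        discordant = 0
        for s in range(n_samples):
            col = votes[:, s]
            winner = MISSING
            for g in (0, 1, 2):
                if int((col == g).sum()) >= 2:
                    winner = g
                    break
            if winner == MISSING:
                discordant += 1
            consensus[s] = winner
        m.consensus = consensus
        m.missing_by_discordance = discordant
        m.record = m.record.with_genotypes(consensus)
        (removed if discordant > max_discordant_samples else retained).append(m)
    return retained, removed


def flag_high_coverage_regions(
    depth: DepthProfile,
    merge_gap: int = 1000,
    genome: GenomeTable | None = None,
) -> HighCoverageRegions:
    """Rule 3 input: windows whose cross-sample mean exceeds 2·μ + 2·σ.

    μ and σ are the mean and SD of the cross-sample window means over all
    autosomal windows (all windows when no genome table is given).
    Flagged windows closer than ``merge_gap`` are merged into regions.
    """
    chroms = depth.chromosomes()
    if genome is not None:
        chroms = [c for c in chroms if genome.autosome.get(c, True)]
    means = {c: depth.cross_sample_mean(c) for c in chroms}
    pooled = np.concatenate(list(means.values()))
    mu, sigma = float(pooled.mean()), float(pooled.std())
    threshold = 2.0 * mu + 2.0 * sigma
    w = depth.window_size
    regions: list[tuple[str, int, int]] = []
    for chrom in chroms:
        flagged = np.flatnonzero(means[chrom] > threshold)
        if len(flagged) == 0:
            continue
        start = int(flagged[0]) * w
        end = (int(flagged[0]) + 1) * w
        for wi in flagged[1:]:
            ws, we = int(wi) * w, (int(wi) + 1) * w
            if ws - end < merge_gap:
                end = we
            else:
                regions.append((chrom, start, end))
                start, end = ws, we
        regions.append((chrom, start, end))
    return HighCoverageRegions(regions=regions, threshold=threshold)


def filter_high_coverage(
    merged: Sequence[MergedSV], regions: HighCoverageRegions
) -> tuple[list[MergedSV], list[MergedSV]]:
    """Rule 3: drop SVs whose breakpoint CIs intersect a flagged region."""
    retained, removed = [], []
    for m in merged:
        hit = any(
            regions.overlaps(m.record.chrom, a, b)
            for a, b in m.record.ci_intervals()
        )
        (removed if hit else retained).append(m)
    return retained, removed


def compute_dhffc(
    record: VariantRecord,
    depth: DepthProfile,
    flank: int = 1000,
    samples: Sequence[str] | None = None,
) -> np.ndarray:
    """Duphold-style flanking fold change per sample for a DEL/DUP.

    Median coverage of the 100 bp windows fully inside the span divided by
    the median over the two flanks (pooled, windows fully inside each
    flank).  NaN when no inside window exists or the flank median is zero.
    """
    if record.vtype not in (VType.DEL, VType.DUP):
        raise ValueError("DHFFC is defined for DEL/DUP records only")
    w = depth.window_size
    samples = list(samples or depth.samples)
    n_win = len(depth.data[samples[0]][record.chrom])

    def _contained(a: int, b: int) -> np.ndarray:
        lo = int(np.ceil(max(a, 0) / w))
        hi = int(np.floor(min(b, n_win * w) / w))
        return np.arange(lo, max(lo, hi))

    inside = _contained(record.start, record.end)
    flanks = np.concatenate(
        [
            _contained(record.start - flank, record.start),
            _contained(record.end, record.end + flank),
        ]
    )
    out = np.full(len(samples), np.nan)
    if len(inside) == 0 or len(flanks) == 0:
        return out
    for i, s in enumerate(samples):
        vec = depth.data[s][record.chrom]
        denom = float(np.median(vec[flanks]))
        if denom > 0:
            out[i] = float(np.median(vec[inside])) / denom
    return out


def filter_dhffc(
    merged: Sequence[MergedSV],
    depth: DepthProfile,
    config: FilterConfig = FilterConfig(),
    samples: Sequence[str] | None = None,
) -> tuple[list[MergedSV], list[MergedSV], int]:
    """Rule 4: coverage-consistency of DEL/DUP genotypes via DHFFC.

    Heterozygous DELs must fall within the het-DEL bounds (closed
    interval), homozygous DELs below ``hom_del_max`` (strict), het DUPs
    above ``het_dup_min`` and hom DUPs above ``hom_dup_min`` (strict).
    Reference and missing genotypes are never tested; genotypes without a
    defined DHFFC are untestable.  An SV is removed when the number of
    wrong genotypes exceeds ``max_wrong_genotypes`` or the wrong fraction
    exceeds ``max_wrong_fraction``; otherwise wrong genotypes are set to
    missing.  INV/BND pass through untouched.  Returns (retained, removed,
    genotypes set missing).
    """
    retained, removed = [], []
    n_missing = 0
    lo, hi = config.het_del_bounds
    for m in merged:
        if m.record.vtype not in (VType.DEL, VType.DUP):
            m.dhffc = None
            retained.append(m)
            continue
        d = compute_dhffc(m.record, depth, flank=config.dhffc_flank, samples=samples)
        m.dhffc = d
        g = m.consensus
        testable = np.isin(g, (1, 2)) & np.isfinite(d)
        if m.record.vtype is VType.DEL:
            ok = np.where(g == 1, (d >= lo) & (d <= hi), d < config.hom_del_max)
        else:
            ok = np.where(g == 1, d > config.het_dup_min, d > config.hom_dup_min)
        wrong = testable & ~ok
        n_wrong, n_tested = int(wrong.sum()), int(testable.sum())
        if n_wrong > config.max_wrong_genotypes or (
            n_tested > 0 and n_wrong / n_tested > config.max_wrong_fraction
        ):
            removed.append(m)
        else:
            if n_wrong:
                g = g.copy()
                g[wrong] = MISSING
                m.consensus = g
                m.record = m.record.with_genotypes(g)
                n_missing += n_wrong
            retained.append(m)
    return retained, removed, n_missing


def filter_del_snp_support(
    merged: Sequence[MergedSV],
    snp_records: Sequence[VariantRecord],
    config: FilterConfig = FilterConfig(),
) -> tuple[list[MergedSV], list[MergedSV], int]:
    """Rule 5: SNP calls on DEL spans must be consistent with the DEL.

    A violation is a heterozygous SNP call on a het-DEL sample or any
    non-missing SNP call on a hom-DEL sample.  Per sample the violation
    rate is violations / SNPs-on-the-DEL (halved when
    ``snp_support_halved``).  The DEL is removed when the summed rate
    exceeds ``snp_support_sum_max`` or half the number of carrier samples;
    otherwise violating DEL genotypes are set to missing.  Non-DELs pass
    through untouched.
    """
    by_chrom: dict[str, tuple[np.ndarray, list[VariantRecord]]] = {}
    for chrom in {r.chrom for r in snp_records}:
        recs = sorted(
            (r for r in snp_records if r.chrom == chrom), key=lambda r: r.start
        )
        by_chrom[chrom] = (np.array([r.start for r in recs]), recs)
    retained, removed = [], []
    n_missing = 0
    for m in merged:
        if m.record.vtype is not VType.DEL:
            retained.append(m)
            continue
        pos, recs = by_chrom.get(m.record.chrom, (np.array([], int), []))
        lo, hi = np.searchsorted(pos, [m.record.start, m.record.end])
        on_del = recs[lo:hi]
        g = m.consensus
        carriers = int(np.isin(g, (1, 2)).sum())
        if not on_del or carriers == 0:
            retained.append(m)
            continue
        denom = len(on_del) * (2 if config.snp_support_halved else 1)
        viol_count = np.zeros(len(g), dtype=int)
        for snp in on_del:
            sg = snp.genotypes
            viol_count += ((g == 1) & (sg == 1)).astype(int)
            viol_count += ((g == 2) & (sg != MISSING)).astype(int)
        rates = viol_count / denom
        total = float(rates.sum())
        if total > config.snp_support_sum_max or total > (
            config.snp_support_carrier_frac * carriers
        ):
            removed.append(m)
        else:
            bad = viol_count > 0
            if bad.any():
                g = g.copy()
                g[bad] = MISSING
                m.consensus = g
                m.record = m.record.with_genotypes(g)
                n_missing += int(bad.sum())
            retained.append(m)
    return retained, removed, n_missing


def fill_missing_genotypes(
    records: Sequence[VariantRecord],
    sample_ids: Sequence[str],
    populations: Sequence[str],
    seed: int = 0,
    phase_template: HaplotypePanel | None = None,
) -> HaplotypePanel:
    """Build a phased panel, filling missing genotypes by frequency sampling.

    A documented stand-in for statistical imputation: each missing
    genotype draws two alleles from the variant's non-missing alternative
    allele frequency.  Heterozygote phase comes from ``phase_template``
    (matched by variant id) wherever the template's dosage agrees — the
    stand-in for a phasing step that recovers the true haplotypes — and is
    assigned at random otherwise.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    ordered = sorted(records, key=lambda r: (r.chrom, r.start, r.end, r.id))
    n = len(sample_ids)
    tmpl_col: dict[str, int] = {}
    if phase_template is not None:
        if list(phase_template.sample_ids) != list(sample_ids):
            raise ValueError("phase template sample order must match sample_ids")
        tmpl_col = {v.id: j for j, v in enumerate(phase_template.variants)}
    alleles = np.zeros((2 * n, len(ordered)), dtype=np.uint8)
    for j, r in enumerate(ordered):
        g = r.genotypes
        if g is None or len(g) != n:
            raise ValueError(f"{r.id}: genotypes missing or of wrong length")
        ok = g != MISSING
        p = float(g[ok].sum()) / (2.0 * int(ok.sum())) if ok.any() else 0.0
        h0 = np.where(g == 2, 1, 0).astype(np.uint8)
        h1 = h0.copy()
        het = g == 1
        hap_choice = rng.integers(2, size=n)
        h0[het & (hap_choice == 0)] = 1
        h1[het & (hap_choice == 1)] = 1
        miss = ~ok
        if miss.any():
            draws = rng.random((int(miss.sum()), 2)) < p
            h0[miss] = draws[:, 0]
            h1[miss] = draws[:, 1]
        if r.id in tmpl_col:
            tj = tmpl_col[r.id]
            t0 = phase_template.alleles[0::2, tj]
            t1 = phase_template.alleles[1::2, tj]
            same = (t0.astype(np.int8) + t1) == g
            h0[same] = t0[same]
            h1[same] = t1[same]
        alleles[0::2, j] = h0
        alleles[1::2, j] = h1
    return HaplotypePanel(
        alleles=alleles,
        sample_ids=list(sample_ids),
        variants=ordered,
        populations=list(populations),
    )


@dataclass
class PipelineResult:
    """Output of :func:`run_filter_pipeline`."""

    retained: list[MergedSV]
    removed: dict[str, list[MergedSV]]
    report: FilterReport
    regions: HighCoverageRegions
    review_manifest: pd.DataFrame

    @property
    def records(self) -> list[VariantRecord]:
        return [m.record for m in self.retained]


def run_filter_pipeline(
    callsets: Mapping[str, Sequence[VariantRecord]],
    depth: DepthProfile,
    snp_records: Sequence[VariantRecord],
    config: FilterConfig = FilterConfig(),
    genome: GenomeTable | None = None,
    samples: Sequence[str] | None = None,
) -> PipelineResult:
    """Merge the callsets and apply the five rules in order.

    The review manifest lists every retained SV with its caller support
    and DHFFC summary (plumbing in place of an image-based visual screen).
    """
    report = FilterReport()
    removed: dict[str, list[MergedSV]] = {}

    merged = merge_callsets(callsets, tolerance=config.merge_tolerance)

    current, rm = filter_caller_overlap(merged)
    removed["caller_overlap"] = rm
    report.add("caller_overlap", len(merged), len(rm))

    n_in = len(current)
    current, rm = consensus_genotypes(current, config.max_discordant_samples)
    removed["genotype_concordance"] = rm
    gt_missing = sum(m.missing_by_discordance for m in current)
    report.add("genotype_concordance", n_in, len(rm), gt_missing)

    regions = flag_high_coverage_regions(
        depth, merge_gap=config.coverage_merge_gap, genome=genome
    )
    n_in = len(current)
    current, rm = filter_high_coverage(current, regions)
    removed["high_coverage_regions"] = rm
    report.add("high_coverage_regions", n_in, len(rm))

    n_in = len(current)
    current, rm, n_miss = filter_dhffc(current, depth, config, samples=samples)
    removed["dhffc"] = rm
    report.add("dhffc", n_in, len(rm), n_miss)

    n_in = len(current)
    current, rm, n_miss = filter_del_snp_support(current, snp_records, config)
    removed["del_snp_support"] = rm
    report.add("del_snp_support", n_in, len(rm), n_miss)

    manifest = pd.DataFrame(
        {
            "id": [m.record.id for m in current],
            "chrom": [m.record.chrom for m in current],
            "start": [m.record.start for m in current],
            "end": [m.record.end for m in current],
            "vtype": [m.record.vtype.value for m in current],
            "callers": [",".join(sorted(m.per_caller)) for m in current],
            "n_missing": [int((m.consensus == MISSING).sum()) for m in current],
            "dhffc_median": [
                float(np.nanmedian(m.dhffc)) if m.dhffc is not None and np.isfinite(m.dhffc).any() else np.nan
                for m in current
            ],
        }
    )
    return PipelineResult(
        retained=current,
        removed=removed,
        report=report,
        regions=regions,
        review_manifest=manifest,
    )
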