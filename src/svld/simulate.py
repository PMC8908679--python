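"""Synthetic phased SNP+SV panels with controllable LD structure.

The generator emulates the statistical structure of phased whole-genome
panels from a few commercial chicken populations so that every downstream
stage (consensus filtering, LD decay, taggability, HWE scans) can run on
data whose ground truth is known.

Haplotypes are built by a K-founder mosaic model: each haplotype copies
founder segments whose lengths are exponential with mean ``L``, so expected
SNP–SNP r² decays with distance on the scale of ``L``.  The *level* of LD
at short range is controlled by the founder count ``K`` (for co-inherited
sites the expected sample r² is roughly ``1/(K-1)``), so populations with
few founders and long segments show strong LD.  Structural variants are
planted on founder-segment backgrounds (complete LD with the local
backbone) and their carriers are then resampled towards a type-specific
target MAF, which creates controlled local ΔMAF — the mechanism that
separates DUP–SNP LD from SNP–SNP LD.

Mock caller callsets add per-caller breakpoint jitter, genotype errors and
a dedicated hom→het miscall channel for DUP/INV/BND that reproduces the
deficit of homozygous non-DEL SV genotypes.  Every injected error is
recorded in the :class:`TruthSet` so tests can attribute filter decisions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .datamodel import (
    MISSING,
    DepthProfile,
    GenomeTable,
    HaplotypePanel,
    VariantRecord,
    VType,
)

_SV_TYPES = (VType.DEL, VType.DUP, VType.INV, VType.BND)
# rng stream ids per stage, so stages are reproducible independently
_STAGE_PANEL, _STAGE_SV, _STAGE_DEPTH, _STAGE_CALLS = 1, 2, 3, 4


@dataclass
class PopulationConfig:
    """One population's sample size and LD-shape parameters."""

    n_samples: int
    n_founders: int
    segment_length: float  # mean founder-segment length L in bp


@dataclass
class SimConfig:
    """All knobs of the synthetic panel generator.

    Defaults form the desk-scale preset: 2 chromosomes x 5 Mb, three
    populations of 25 samples whose founder counts / segment lengths give
    the LD ordering WL > BL > BR, ~15k SNPs, 300 SVs, per-sample sequencing
    depth means between 5 and 17x.
    """

    seed: int = 0
    populations: dict[str, PopulationConfig] = field(
        default_factory=lambda: {
            "WL": PopulationConfig(25, 3, 40_000.0),
            "BL": PopulationConfig(25, 4, 20_000.0),
            "BR": PopulationConfig(25, 6, 10_000.0),
        }
    )
    chromosome_lengths: dict[str, int] = field(
        default_factory=lambda: {"1": 5_000_000, "2": 5_000_000}
    )
    snp_density: float = 0.0015  # SNPs per bp
    sv_counts: dict[VType, int] = field(
        default_factory=lambda: {
            VType.DEL: 120,
            VType.DUP: 60,
            VType.INV: 60,
            VType.BND: 60,
        }
    )
    # MAF spectrum per variant type: Beta(a, b) scaled to (0, 0.5].
    # DUP strongly shifted to rare, DEL slightly; INV/BND shifted common.
    maf_beta: dict[VType, tuple[float, float]] = field(
        default_factory=lambda: {
            VType.SNP: (0.8, 1.6),
            VType.DEL: (0.72, 1.68),
            VType.DUP: (0.35, 2.5),
            VType.INV: (1.8, 1.1),
            VType.BND: (1.8, 1.1),
        }
    )
    # log-normal span medians (bp); DEL shortest, INV longest.  DEL spans
    # are floored at 300 bp so each DEL covers at least two full depth
    # windows and carries a coverage signal.
    sv_length_median: dict[VType, float] = field(
        default_factory=lambda: {VType.DEL: 443.0, VType.DUP: 3000.0, VType.INV: 5000.0}
    )
    sv_length_sigma: float = 0.7
    min_sv_length: int = 300
    sv_margin: int = 2500  # clearance between SVs / chromosome ends (> DHFFC flank)
    # place SVs in SNP-poor neighborhoods: candidate positions are accepted
    # only where the SNP count within 5 kb is at or below this quantile of
    # local densities (None disables the bias)
    sv_density_quantile: float | None = 0.5
    callers: tuple[str, ...] = ("delly", "manta", "lumpy")
    caller_sensitivity: dict[str, dict[VType, float]] = field(default_factory=dict)
    genotype_error_rate: dict[str, dict[VType, float]] = field(default_factory=dict)
    hom_to_het_rate: dict[VType, float] = field(
        default_factory=lambda: {VType.DUP: 0.5, VType.INV: 0.5, VType.BND: 0.5}
    )
    # SV classes with recurrent mutational origins (one carrier replaced by
    # a haplotype from an independent lineage)
    recurrent_types: tuple[VType, ...] = (VType.DUP,)
    breakpoint_jitter_sd: dict[str, float] = field(
        default_factory=lambda: {"delly": 30.0, "manta": 20.0, "lumpy": 100.0}
    )
    depth_mean_range: tuple[float, float] = (5.0, 17.0)
    depth_sd: float = 1.0
    depth_window: int = 100
    n_artifact_regions: int = 4
    artifact_fold: float = 4.0
    artifact_length: int = 2000

    def __post_init__(self) -> None:
        for c in self.callers:
            self.caller_sensitivity.setdefault(
                c, {t: 0.95 for t in _SV_TYPES}
            )
            self.genotype_error_rate.setdefault(
                c,
                {
                    VType.DEL: 0.01,
                    VType.DUP: 0.04,
                    VType.INV: 0.04,
                    VType.BND: 0.04,
                },
            )

    def validate(self) -> None:
        for name, pop in self.populations.items():
            if pop.n_samples <= 0 or pop.n_founders < 2 or pop.segment_length <= 0:
                raise ValueError(f"population {name}: invalid parameters")
        for c in self.callers:
            for t, s in self.caller_sensitivity[c].items():
                if not 0 <= s <= 1:
                    raise ValueError(f"sensitivity out of [0,1] for {c}/{t}")
            for t, e in self.genotype_error_rate[c].items():
                if not 0 <= e <= 1:
                    raise ValueError(f"error rate out of [0,1] for {c}/{t}")
        for t, r in self.hom_to_het_rate.items():
            if not 0 <= r <= 1:
                raise ValueError(f"hom->het rate out of [0,1] for {t}")

    @property
    def genome(self) -> GenomeTable:
        return GenomeTable(lengths=dict(self.chromosome_lengths))

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stage])


def error_free(config: SimConfig) -> SimConfig:
    """Copy of ``config`` with perfect callers, no coverage artifacts, no
    depth noise and no recurrent-origin carriers: the only mechanism that
    separates SV classes from SNPs is their MAF spectrum (ΔMAF)."""
    cfg = replace(
        config,
        caller_sensitivity={
            c: {t: 1.0 for t in _SV_TYPES} for c in config.callers
        },
        genotype_error_rate={
            c: {t: 0.0 for t in _SV_TYPES} for c in config.callers
        },
        hom_to_het_rate={t: 0.0 for t in config.hom_to_het_rate},
        breakpoint_jitter_sd={c: 0.0 for c in config.callers},
        n_artifact_regions=0,
        depth_sd=0.0,
        recurrent_types=(),
    )
    return cfg


@dataclass
class TruthSet:
    """Ground truth of one simulation run (immutable once generated)."""

    config: SimConfig
    sample_ids: list[str]
    populations: list[str]
    snp_records: list[VariantRecord]
    sv_records: list[VariantRecord] = field(default_factory=list)
    # per population / chromosome: list over haplotypes of (segment_ends, founder_ids)
    mosaics: dict[str, dict[str, list[tuple[np.ndarray, np.ndarray]]]] = field(
        default_factory=dict
    )
    sv_carriers: dict[str, np.ndarray] = field(default_factory=dict)  # id -> hap rows
    # per population / chromosome: a fixed per-haplotype jitter that, added
    # to the shared-segment radius, defines the linear lineage order every
    # variant's carrier slice is drawn from
    lineage_tie: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    artifact_regions: list[tuple[str, int, int]] = field(default_factory=list)
    snp_calls: list[VariantRecord] = field(default_factory=list)
    depth_means: dict[str, float] = field(default_factory=dict)
    # (caller, variant id, sample index, true dosage, emitted dosage)
    caller_errors: list[tuple[str, str, int, int, int]] = field(default_factory=list)
    dropped_sv: dict[str, list[str]] = field(default_factory=dict)  # caller -> ids

    def founder_at(self, population: str, chrom: str, pos: int) -> np.ndarray:
        """Founder id copied at ``pos`` for each haplotype of a population."""
        out = []
        for ends, fids in self.mosaics[population][chrom]:
            out.append(fids[np.searchsorted(ends, pos, side="right")])
        return np.asarray(out)

    def pop_hap_rows(self, population: str) -> np.ndarray:
        """Global haplotype row indices belonging to one population."""
        idx = [i for i, p in enumerate(self.populations) if p == population]
        return np.sort(np.concatenate([[2 * i, 2 * i + 1] for i in idx]))


def _draw_maf(rng: np.random.Generator, beta: tuple[float, float], n: int) -> np.ndarray:
    a, b = beta
    return np.clip(0.5 * rng.beta(a, b, size=n), 0.005, 0.5)


def _run_bounds(ends: np.ndarray, fids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per segment, the physical bounds of its maximal same-founder run."""
    n = len(fids)
    run_lo = np.empty(n)
    run_hi = np.empty(n)
    start = 0
    for k in range(1, n + 1):
        if k == n or fids[k] != fids[start]:
            lo = ends[start - 1] if start > 0 else 0.0
            hi = ends[k - 1]
            run_lo[start:k] = lo
            run_hi[start:k] = hi
            start = k
    return run_lo, run_hi


def simulate_panel(config: SimConfig) -> tuple[HaplotypePanel, TruthSet]:
    """Build the phased SNP backbone panel for all populations.

    SNP positions are uniform per chromosome at the configured density and
    shared across populations.  Each SNP is assigned, per population, the
    union background of one or more founders (roughly matching its target
    frequency) and its carrier count is then drawn Binomial(2N, p); excess
    carriers are dropped nested-first (longest shared founder segment
    kept), so rare SNPs sit on coherent sub-haplotypes the way young
    alleles do.  Realized allele frequencies are thereby unbiased for the
    configured spectrum while LD still decays on the founder-segment
    scale.
    """
    config.validate()
    rng = config.rng(_STAGE_PANEL)
    sample_ids: list[str] = []
    pops: list[str] = []
    for name, pop in config.populations.items():
        sample_ids += [f"{name}_{i:03d}" for i in range(pop.n_samples)]
        pops += [name] * pop.n_samples

    # SNP positions and target frequencies
    positions: dict[str, np.ndarray] = {}
    for chrom, ln in config.chromosome_lengths.items():
        n_snp = int(round(config.snp_density * ln))
        pos = np.sort(rng.choice(ln, size=n_snp, replace=False)) if n_snp else np.array([], int)
        positions[chrom] = pos
    target_maf = {
        chrom: _draw_maf(rng, config.maf_beta[VType.SNP], len(pos))
        for chrom, pos in positions.items()
    }

    # founder mosaics per population
    mosaics: dict[str, dict[str, list[tuple[np.ndarray, np.ndarray]]]] = {}
    for name, pop in config.populations.items():
        mosaics[name] = {}
        n_hap = 2 * pop.n_samples
        for chrom, ln in config.chromosome_lengths.items():
            per_hap = []
            for _ in range(n_hap):
                n_seg = max(2, int(3 * ln / pop.segment_length) + 8)
                ends = np.cumsum(rng.exponential(pop.segment_length, size=n_seg))
                while ends[-1] <= ln:  # pragma: no cover - generous preallocation
                    ends = np.append(
                        ends, ends[-1] + rng.exponential(pop.segment_length, size=n_seg).cumsum()
                    )
                ends = ends[: np.searchsorted(ends, ln) + 1]
                fids = rng.integers(pop.n_founders, size=len(ends))
                per_hap.append((ends, fids))
            mosaics[name][chrom] = per_hap

    # alleles: founder-background union, then a carrier slice per SNP
    lineage_tie: dict[str, dict[str, np.ndarray]] = {}
    n_hap_total = 2 * len(sample_ids)
    cols: list[np.ndarray] = []
    records: list[VariantRecord] = []
    for chrom in config.chromosome_lengths:
        pos = positions[chrom]
        if len(pos) == 0:
            continue
        chrom_cols = np.zeros((n_hap_total, len(pos)), dtype=np.uint8)
        row0 = 0
        for name, pop in config.populations.items():
            n_hap = 2 * pop.n_samples
            k = pop.n_founders
            founder_at = np.empty((n_hap, len(pos)), dtype=np.int64)
            radius = np.empty((n_hap, len(pos)))
            for h, (ends, fids) in enumerate(mosaics[name][chrom]):
                seg = np.searchsorted(ends, pos, side="right")
                founder_at[h] = fids[seg]
                run_lo, run_hi = _run_bounds(ends, fids)
                radius[h] = np.minimum(pos - run_lo[seg], run_hi[seg] - pos)
            p = target_maf[chrom]
            # enough founders that the background covers the target
            # frequency; the carrier count itself is deterministic so
            # neighboring SNPs in the same background stay in high LD
            n_founders_per_snp = np.minimum(k, np.ceil(p * k).astype(int))
            m_per_snp = np.maximum(1, np.round(n_hap * p).astype(int))
            tie = rng.random(n_hap)
            lineage_tie.setdefault(name, {})[chrom] = tie
            for j in range(len(pos)):
                chosen = rng.choice(k, size=n_founders_per_snp[j], replace=False)
                background = np.flatnonzero(np.isin(founder_at[:, j], chosen))
                m = m_per_snp[j]
                if m >= len(background):
                    carriers = background
                else:
                    # nested-first thinning: keep the haplotypes with the
                    # longest shared founder segment, so a rare SNP is a
                    # coherent sub-lineage of its background
                    score = radius[background, j] + tie[background]
                    carriers = background[np.argsort(-score)[:m]]
                chrom_cols[row0 + carriers, j] = 1
            row0 += n_hap
        cols.append(chrom_cols)
        for j, p in enumerate(pos):
            records.append(
                VariantRecord(
                    id=f"snp_{chrom}_{p + 1}",
                    chrom=chrom,
                    start=int(p),
                    end=int(p) + 1,
                    vtype=VType.SNP,
                    ref="A",
                    alt="C",
                )
            )
    alleles = (
        np.concatenate(cols, axis=1)
        if cols
        else np.empty((n_hap_total, 0), dtype=np.uint8)
    )
    dos = alleles[0::2].astype(np.int8) + alleles[1::2]
    for j, r in enumerate(records):
        r.genotypes = dos[:, j]
    panel = HaplotypePanel(
        alleles=alleles, sample_ids=sample_ids, variants=records, populations=pops
    )
    truth = TruthSet(
        config=config,
        sample_ids=sample_ids,
        populations=pops,
        snp_records=records,
        mosaics=mosaics,
        lineage_tie=lineage_tie,
    )
    return panel, truth


def _draw_sv_layout(
    config: SimConfig,
    rng: np.random.Generator,
    snp_positions: Mapping[str, np.ndarray],
) -> list[tuple[str, int, int, VType]]:
    """Non-overlapping SV spans with clearance from each other and edges.

    When ``sv_density_quantile`` is set, candidate spans are kept only in
    SNP-poor neighborhoods (local SNP count within 5 kb at or below that
    quantile of densities probed along the chromosome).
    """
    chroms = list(config.chromosome_lengths)
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    thresh: dict[str, float] = {}
    if config.sv_density_quantile is not None:
        for chrom, ln in config.chromosome_lengths.items():
            probes = rng.integers(config.sv_margin, max(config.sv_margin + 1, ln - config.sv_margin), size=200)
            pos = snp_positions.get(chrom, np.array([], int))
            counts = np.searchsorted(pos, probes + 5000) - np.searchsorted(pos, probes - 5000)
            thresh[chrom] = float(np.quantile(counts, config.sv_density_quantile))
    layout = []
    for vtype in _SV_TYPES:
        for _ in range(config.sv_counts.get(vtype, 0)):
            if vtype is VType.BND:
                length = 1
            else:
                length = int(
                    rng.lognormal(
                        np.log(config.sv_length_median[vtype]), config.sv_length_sigma
                    )
                )
                length = max(length, config.min_sv_length)
            for _attempt in range(500):
                chrom = chroms[rng.integers(len(chroms))]
                ln = config.chromosome_lengths[chrom]
                lo, hi = config.sv_margin, ln - config.sv_margin - length
                if hi <= lo:
                    continue
                start = int(rng.integers(lo, hi))
                end = start + length
                m = config.sv_margin
                if not all(end + m <= a or b + m <= start for a, b in placed[chrom]):
                    continue
                if chrom in thresh and _attempt < 400:
                    pos = snp_positions.get(chrom, np.array([], int))
                    mid = (start + end) // 2
                    local = np.searchsorted(pos, mid + 5000) - np.searchsorted(pos, mid - 5000)
                    if local > thresh[chrom]:
                        continue
                placed[chrom].append((start, end))
                layout.append((chrom, start, end, vtype))
                break
            else:  # pragma: no cover - layout space exhausted
                raise RuntimeError("could not place SV without overlap")
    return layout


def plant_svs(
    panel: HaplotypePanel,
    truth: TruthSet,
    config: SimConfig,
    mode: str = "resample",
) -> tuple[HaplotypePanel, TruthSet]:
    """Plant SVs on founder-segment backgrounds in the backbone panel.

    Each SV is built exactly like a backbone SNP: a founder-segment
    background at its locus (complete LD with the local backbone) whose
    carriers are thinned, nested-first, to the type's target MAF.  The
    type-specific MAF spectra thereby create controlled local ΔMAF — the
    DUP spectrum is strongly rare-shifted, so DUP–SNP LD drops while its
    standardized counterpart does not.  ``mode="inherit"`` skips the
    thinning and keeps the full background of one founder (complete
    coupling to the local backbone); default ``"resample"`` thins.  SNP
    *calls* (not the truth panel) are made consistent with DELs:
    homozygous calls on het-DEL samples, missing on hom-DEL samples.
    """
    if mode in ("auto",):
        mode = "resample"
    if mode not in ("resample", "inherit"):
        raise ValueError("mode must be 'resample' or 'inherit'")
    rng = config.rng(_STAGE_SV)
    snp_positions = {
        chrom: np.array(
            sorted(r.start for r in truth.snp_records if r.chrom == chrom)
        )
        for chrom in config.chromosome_lengths
    }
    layout = _draw_sv_layout(config, rng, snp_positions)
    n_hap_total = 2 * len(truth.sample_ids)

    counters = {t: 0 for t in _SV_TYPES}
    sv_records: list[VariantRecord] = []
    sv_cols: list[np.ndarray] = []
    for chrom, start, end, vtype in layout:
        counters[vtype] += 1
        vid = f"{vtype.value.lower()}_{counters[vtype]}"
        target = float(_draw_maf(rng, config.maf_beta[vtype], 1)[0])
        col = np.zeros(n_hap_total, dtype=np.uint8)
        row0 = 0
        for name, pop in config.populations.items():
            n_hap = 2 * pop.n_samples
            k = pop.n_founders
            founders_here = truth.founder_at(name, chrom, start)
            if mode == "inherit":
                founder = int(rng.integers(k))
                carriers = np.flatnonzero(founders_here == founder)
            else:
                n_f = min(k, max(1, int(np.ceil(target * k))))
                chosen = rng.choice(k, size=n_f, replace=False)
                background = np.flatnonzero(np.isin(founders_here, chosen))
                m = max(1, int(round(n_hap * target)))
                if m >= len(background):
                    carriers = background
                else:
                    # nested-first thinning by the same lineage order the
                    # backbone SNPs use (shared per-haplotype tie)
                    radii = np.array(
                        [
                            _shared_radius(
                                truth.mosaics[name][chrom][h],
                                int(founders_here[h]),
                                start,
                            )
                            for h in background
                        ],
                        dtype=float,
                    )
                    tie = truth.lineage_tie[name][chrom][background]
                    carriers = background[np.argsort(-(radii + tie))[:m]]
                if vtype in config.recurrent_types and len(carriers) >= 2:
                    # recurrent second origin: one carrier stems from an
                    # independent lineage, so the SV never co-segregates
                    # exactly with a single-lineage SNP
                    non_carriers = np.setdiff1d(np.arange(n_hap), carriers)
                    if len(non_carriers):
                        carriers = carriers.copy()
                        carriers[int(rng.integers(len(carriers)))] = int(
                            rng.choice(non_carriers)
                        )
            col[row0 + carriers] = 1
            row0 += n_hap
        dosage = col[0::2].astype(np.int8) + col[1::2]
        rec = VariantRecord(
            id=vid,
            chrom=chrom,
            start=start,
            end=end if vtype is not VType.BND else start + 1,
            vtype=vtype,
            genotypes=dosage,
        )
        sv_records.append(rec)
        sv_cols.append(col)
        truth.sv_carriers[vid] = np.flatnonzero(col)

    # merge SV columns into the panel in coordinate order
    merged = list(zip(panel.variants, [panel.alleles[:, j] for j in range(panel.n_variants)]))
    merged += list(zip(sv_records, sv_cols))
    merged.sort(key=lambda t: (t[0].chrom, t[0].start, t[0].vtype is not VType.SNP, t[0].id))
    new_alleles = (
        np.column_stack([c for _, c in merged])
        if merged
        else np.empty((n_hap_total, 0), dtype=np.uint8)
    )
    new_panel = HaplotypePanel(
        alleles=new_alleles,
        sample_ids=panel.sample_ids,
        variants=[v for v, _ in merged],
        populations=panel.populations,
    )
    truth.sv_records = sv_records

    # SNP call table with DEL-consistency adjustments
    truth.snp_calls = _del_consistent_snp_calls(truth, panel)

    # artifact regions, clear of every SV neighborhood
    regions: list[tuple[str, int, int]] = []
    chroms = list(config.chromosome_lengths)
    spans: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    for r in sv_records:
        spans[r.chrom].append((r.start - config.sv_margin, r.end + config.sv_margin))
    for _ in range(config.n_artifact_regions):
        for _attempt in range(200):
            chrom = chroms[rng.integers(len(chroms))]
            ln = config.chromosome_lengths[chrom]
            start = int(rng.integers(0, ln - config.artifact_length))
            end = start + config.artifact_length
            if all(end <= a or b <= start for a, b in spans[chrom]):
                regions.append((chrom, start, end))
                spans[chrom].append((start, end))
                break
    truth.artifact_regions = regions
    return new_panel, truth


def _shared_radius(
    mosaic: tuple[np.ndarray, np.ndarray], founder: int, pos: int
) -> float:
    """Radius around ``pos`` over which a haplotype keeps copying ``founder``.

    Consecutive segments from the same founder are walked through; the
    radius is the min of the left and right extents.
    """
    ends, fids = mosaic
    k = int(np.searchsorted(ends, pos, side="right"))
    left = k
    while left > 0 and fids[left - 1] == founder:
        left -= 1
    right = k
    while right + 1 < len(fids) and fids[right + 1] == founder:
        right += 1
    left_edge = ends[left - 1] if left > 0 else 0.0
    right_edge = ends[right]
    return float(min(pos - left_edge, right_edge - pos))


def _del_consistent_snp_calls(
    truth: TruthSet, snp_panel: HaplotypePanel
) -> list[VariantRecord]:
    """SNP genotype calls adjusted for overlap with planted DELs.

    On a het-DEL sample the call reflects only the surviving haplotype
    (homozygous); on a hom-DEL sample the call is missing.
    """
    calls = [r.with_genotypes(r.genotypes.copy()) for r in truth.snp_records]
    pos_by_chrom: dict[str, np.ndarray] = {}
    idx_by_chrom: dict[str, np.ndarray] = {}
    for chrom in {r.chrom for r in calls}:
        pairs = [(r.start, j) for j, r in enumerate(calls) if r.chrom == chrom]
        pos_by_chrom[chrom] = np.array([p for p, _ in pairs])
        idx_by_chrom[chrom] = np.array([j for _, j in pairs])
    col_of = {id(v): j for j, v in enumerate(snp_panel.variants)}
    for sv in truth.sv_records:
        if sv.vtype is not VType.DEL:
            continue
        pos = pos_by_chrom.get(sv.chrom)
        if pos is None or len(pos) == 0:
            continue
        lo, hi = np.searchsorted(pos, [sv.start, sv.end])
        inside = idx_by_chrom[sv.chrom][lo:hi]
        if len(inside) == 0:
            continue
        carriers = truth.sv_carriers[sv.id]
        carrier_count = np.zeros(len(truth.sample_ids), dtype=int)
        np.add.at(carrier_count, carriers // 2, 1)
        for s in np.flatnonzero(carrier_count == 2):
            for j in inside:
                calls[j].genotypes[s] = MISSING
        for s in np.flatnonzero(carrier_count == 1):
            deleted_hap = carriers[carriers // 2 == s][0]
            surviving = 2 * s + (1 - deleted_hap % 2)
            for j in inside:
                allele = snp_panel.alleles[surviving, col_of[id(truth.snp_records[j])]]
                calls[j].genotypes[s] = 2 * int(allele)
    return calls


def simulate_depth(truth: TruthSet, config: SimConfig) -> DepthProfile:
    """Per-sample window coverage consistent with the planted CNV dosages.

    Coverage per window is Normal(mean_s * factor, sd) truncated at zero,
    where factor is 1 / 0.5 / 0 inside DEL spans (het / hom) and
    1 / 1.5 / 2 inside DUP spans; partially covered windows scale with the
    overlap fraction.  Artifact regions multiply coverage in all samples.
    """
    rng = config.rng(_STAGE_DEPTH)
    w = config.depth_window
    lo, hi = config.depth_mean_range
    means = lo + (hi - lo) * rng.random(len(truth.sample_ids))
    truth.depth_means = dict(zip(truth.sample_ids, means.tolist()))

    n_windows = {
        chrom: int(np.ceil(ln / w)) for chrom, ln in config.chromosome_lengths.items()
    }
    # per-chromosome multiplicative factor per sample
    factors: dict[str, np.ndarray] = {
        chrom: np.ones((len(truth.sample_ids), n), dtype=np.float64)
        for chrom, n in n_windows.items()
    }
    for sv in truth.sv_records:
        if sv.vtype not in (VType.DEL, VType.DUP):
            continue
        mult = {VType.DEL: (1.0, 0.5, 0.0), VType.DUP: (1.0, 1.5, 2.0)}[sv.vtype]
        f = factors[sv.chrom]
        w_lo, w_hi = sv.start // w, (sv.end - 1) // w
        for wi in range(w_lo, min(w_hi + 1, f.shape[1])):
            ov = (min(sv.end, (wi + 1) * w) - max(sv.start, wi * w)) / w
            for s, d in enumerate(sv.genotypes):
                if d in (1, 2):
                    f[s, wi] *= 1.0 + (mult[d] - 1.0) * ov
    for chrom, start, end, in truth.artifact_regions:
        f = factors[chrom]
        w_lo, w_hi = start // w, (end - 1) // w
        for wi in range(w_lo, min(w_hi + 1, f.shape[1])):
            ov = (min(end, (wi + 1) * w) - max(start, wi * w)) / w
            f[:, wi] *= 1.0 + (config.artifact_fold - 1.0) * ov

    data: dict[str, dict[str, np.ndarray]] = {s: {} for s in truth.sample_ids}
    for chrom, n in n_windows.items():
        noise = rng.normal(0.0, config.depth_sd, size=(len(truth.sample_ids), n))
        cov = np.maximum(0.0, factors[chrom] * means[:, None] + noise)
        for i, s in enumerate(truth.sample_ids):
            data[s][chrom] = cov[i]
    return DepthProfile(window_size=w, data=data)


def simulate_callsets(
    truth: TruthSet, config: SimConfig
) -> dict[str, list[VariantRecord]]:
    """Three error-prone per-caller callsets derived from the truth.

    Each caller detects each SV with its per-type sensitivity, jitters the
    breakpoints (Normal, rounded to integers) and corrupts genotypes at the
    configured rates, including the hom→het miscall channel for
    DUP/INV/BND.  All injected errors are appended to
    ``truth.caller_errors``; dropped SVs to ``truth.dropped_sv``.
    """
    rng = config.rng(_STAGE_CALLS)
    callsets: dict[str, list[VariantRecord]] = {}
    for caller in config.callers:
        out: list[VariantRecord] = []
        dropped: list[str] = []
        jit = config.breakpoint_jitter_sd[caller]
        for sv in truth.sv_records:
            if rng.random() >= config.caller_sensitivity[caller][sv.vtype]:
                dropped.append(sv.id)
                continue
            if jit > 0:
                ds = int(round(rng.normal(0.0, jit)))
                de = int(round(rng.normal(0.0, jit)))
            else:
                ds = de = 0
            start = max(0, sv.start + ds)
            if sv.vtype is VType.BND:
                end = start + 1
            else:
                end = max(start + 1, sv.end + de)
            geno = sv.genotypes.copy()
            hh = config.hom_to_het_rate.get(sv.vtype, 0.0)
            err = config.genotype_error_rate[caller][sv.vtype]
            for s in range(len(geno)):
                true_gt = int(sv.genotypes[s])
                g = true_gt
                if err > 0 and rng.random() < err:
                    g = int(rng.choice([x for x in (0, 1, 2) if x != g]))
                # the dedicated miscall channel acts last, so a rate of 1
                # guarantees no emitted homozygous-variant genotype
                if g == 2 and hh > 0 and rng.random() < hh:
                    g = 1
                if g != true_gt:
                    truth.caller_errors.append((caller, sv.id, s, true_gt, g))
                geno[s] = g
            ci = int(np.ceil(2 * jit)) if jit > 0 else 0
            out.append(
                VariantRecord(
                    id=f"{sv.id}.{caller}",
                    chrom=sv.chrom,
                    start=start,
                    end=end,
                    vtype=sv.vtype,
                    genotypes=geno,
                    ci_start=(-ci, ci),
                    ci_end=(-ci, ci),
                    caller_support=frozenset({caller}),
                )
            )
        callsets[caller] = sorted(out, key=lambda r: (r.chrom, r.start, r.end))
        truth.dropped_sv[caller] = dropped
    return callsets


@dataclass
class SimData:
    """Convenience bundle of one full simulation run."""

    panel: HaplotypePanel
    truth: TruthSet
    depth: DepthProfile
    callsets: dict[str, list[VariantRecord]]


def simulate_all(config: SimConfig, mode: str = "auto") -> SimData:
    """Run all four generator stages with one config."""
    panel, truth = simulate_panel(config)
    panel, truth = plant_svs(panel, truth, config, mode=mode)
    depth = simulate_depth(truth, config)
    callsets = simulate_callsets(truth, config)
    return SimData(panel=panel, truth=truth, depth=depth, callsets=callsets)
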