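"""Core domain types for SV/SNP variant panels.

Coordinate convention: all internal intervals are 0-based, half-open
``[start, end)``.  VCF I/O converts to/from the 1-based inclusive POS
convention at the boundary (:mod:`svld.io`).

Genotypes are stored as per-sample alternative-allele dosages in
``{0, 1, 2}`` with ``-1`` as the missing sentinel (:data:`MISSING`).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

MISSING: int = -1
"""Sentinel dosage for a missing genotype call."""


class VType(str, enum.Enum):
    """Variant class: bivariate SNP or one of four SV classes.

    BND records carry a single breakpoint and no length; DEL/DUP/INV span
    ``[start, end)``.
    """

    SNP = "SNP"
    DEL = "DEL"
    DUP = "DUP"
    INV = "INV"
    BND = "BND"

    @property
    def is_sv(self) -> bool:
        return self is not VType.SNP

    @property
    def has_span(self) -> bool:
        """True for classes with a defined length (everything but SNP/BND)."""
        return self in (VType.DEL, VType.DUP, VType.INV)


@dataclass
class VariantRecord:
    """One variant (SNP or SV) with per-sample dosage genotypes.

    Parameters
    ----------
    id:
        Unique variant identifier.
    chrom:
        Chromosome name.
    start, end:
        0-based half-open span.  SNPs and BNDs have ``end == start + 1``.
    vtype:
        Variant class.
    genotypes:
        Per-sample alt-allele dosage in ``{0, 1, 2}`` or :data:`MISSING`.
    ci_start, ci_end:
        Breakpoint confidence offsets ``(lo, hi)`` around ``start`` and
        ``end`` (lo <= 0 <= hi), as in VCF CIPOS/CIEND.
    caller_support:
        Identifiers of the callers supporting this record.
    ref, alt:
        Explicit alleles for SNPs; SVs use symbolic ALTs on output.
    """

    id: str
    chrom: str
    start: int
    end: int
    vtype: VType
    genotypes: np.ndarray | None = None
    ci_start: tuple[int, int] = (0, 0)
    ci_end: tuple[int, int] = (0, 0)
    caller_support: frozenset[str] = frozenset()
    ref: str = "N"
    alt: str | None = None

    def __post_init__(self) -> None:
        self.vtype = VType(self.vtype)
        if self.vtype in (VType.SNP, VType.BND):
            if self.end != self.start + 1:
                raise ValueError(
                    f"{self.vtype.value} {self.id}: end must equal start+1"
                )
        elif self.end <= self.start:
            raise ValueError(f"{self.id}: end must exceed start for {self.vtype.value}")
        if self.genotypes is not None:
            self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
            bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
            if bad.any():
                raise ValueError(f"{self.id}: dosages outside {{0,1,2,missing}}")
        self.caller_support = frozenset(self.caller_support)

    @property
    def length(self) -> int | None:
        """Span length in bp; None for BND (no length information)."""
        if self.vtype is VType.BND:
            return None
        return self.end - self.start

    @property
    def breakpoints(self) -> tuple[int, ...]:
        if self.vtype is VType.BND:
            return (self.start,)
        return (self.start, self.end)

    def ci_intervals(self) -> list[tuple[int, int]]:
        """Half-open confidence intervals around each breakpoint.

        A zero-width CI degenerates to the single breakpoint base
        ``[bp, bp + 1)``.
        """
        out = []
        for bp, (lo, hi) in zip(
            self.breakpoints, (self.ci_start, self.ci_end)
        ):
            a, b = bp + lo, bp + hi
            if b <= a:
                b = a + 1
            out.append((a, b))
        return out

    def with_genotypes(self, genotypes: np.ndarray) -> "VariantRecord":
        return replace(self, genotypes=np.asarray(genotypes, dtype=np.int8))

    def alt_frequency(self) -> float:
        """Alt-allele frequency among non-missing genotypes (NaN if none)."""
        if self.genotypes is None:
            return float("nan")
        ok = self.genotypes != MISSING
        if not ok.any():
            return float("nan")
        return float(self.genotypes[ok].sum()) / (2.0 * int(ok.sum()))


@dataclass
class HaplotypePanel:
    """Phased 0/1 allele matrix (2N haplotypes x M variants).

    Haplotype rows ``2i`` and ``2i + 1`` belong to sample ``i``.  Panels are
    constructed only after the missing-genotype fill stage, so no missing
    alleles are allowed.
    """

    alleles: np.ndarray
    sample_ids: list[str]
    variants: list[VariantRecord]
    populations: list[str]

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.uint8)
        n_hap, m = self.alleles.shape
        if n_hap != 2 * len(self.sample_ids):
            raise ValueError("panel must have two haplotype rows per sample")
        if m != len(self.variants):
            raise ValueError("allele columns must match variant_index")
        if len(self.populations) != len(self.sample_ids):
            raise ValueError("one population label per sample required")
        if not np.isin(self.alleles, (0, 1)).all():
            raise ValueError("panel alleles must be 0/1 (no missing)")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def allele_frequencies(self) -> np.ndarray:
        return self.alleles.mean(axis=0)

    def dosages(self) -> np.ndarray:
        """(N x M) matrix of 0/1/2 dosages."""
        return (self.alleles[0::2].astype(np.int8) + self.alleles[1::2])

    def subset_population(self, population: str) -> "HaplotypePanel":
        keep = [i for i, p in enumerate(self.populations) if p == population]
        if not keep:
            raise KeyError(f"no samples in population {population!r}")
        rows = np.sort(np.concatenate([[2 * i, 2 * i + 1] for i in keep]))
        return HaplotypePanel(
            alleles=self.alleles[rows],
            sample_ids=[self.sample_ids[i] for i in keep],
            variants=self.variants,
            populations=[population] * len(keep),
        )

    def subset_variants(self, idx: Sequence[int]) -> "HaplotypePanel":
        idx = list(idx)
        return HaplotypePanel(
            alleles=self.alleles[:, idx],
            sample_ids=list(self.sample_ids),
            variants=[self.variants[i] for i in idx],
            populations=list(self.populations),
        )

    def population_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p, None)
        return list(seen)


@dataclass
class DepthProfile:
    """Per-sample mean coverage in fixed-size windows tiling each chromosome.

    ``data[sample][chrom]`` is a dense vector; window ``w`` covers
    ``[w * window_size, (w + 1) * window_size)``.
    """

    window_size: int
    data: dict[str, dict[str, np.ndarray]]

    def __post_init__(self) -> None:
        if self.window_size <= 0:
            raise ValueError("window size must be positive")
        for sample, per_chrom in self.data.items():
            for chrom, vec in per_chrom.items():
                vec = np.asarray(vec, dtype=np.float64)
                if (vec < 0).any():
                    raise ValueError(f"negative coverage: {sample}/{chrom}")
                per_chrom[chrom] = vec

    @property
    def samples(self) -> list[str]:
        return list(self.data)

    def chromosomes(self) -> list[str]:
        first = next(iter(self.data.values()))
        return list(first)

    def window_index(self, pos: int) -> int:
        return pos // self.window_size

    def sample_vector(self, sample: str, chrom: str) -> np.ndarray:
        return self.data[sample][chrom]

    def cross_sample_mean(self, chrom: str) -> np.ndarray:
        """Mean over samples of the per-window coverages."""
        return np.mean([self.data[s][chrom] for s in self.data], axis=0)


@dataclass
class GenomeTable:
    """Chromosome name -> length (bp), with an autosome flag per chromosome."""

    lengths: dict[str, int]
    autosome: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, ln in self.lengths.items():
            if ln <= 0:
                raise ValueError(f"chromosome {name}: length must be > 0")
        for name in self.lengths:
            self.autosome.setdefault(name, True)

    @property
    def chromosomes(self) -> list[str]:
        return list(self.lengths)

    def autosomes(self) -> list[str]:
        return [c for c in self.lengths if self.autosome[c]]

    def autosomal_length(self) -> int:
        return sum(self.lengths[c] for c in self.autosomes())


def sort_records(records: Iterable[VariantRecord]) -> list[VariantRecord]:
    """Sort records by (chrom, start, end, id)."""
    return sorted(records, key=lambda r: (r.chrom, r.start, r.end, r.id))
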