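"""Pairwise linkage disequilibrium between SVs/SNPs on phased haplotypes.

LD is the squared haplotype correlation

    r² = (p_AB − p_A p_B)² / (p_A p_B (1 − p_A)(1 − p_B))

with p_A, p_B the alternative-allele frequencies and p_AB the haplotype
frequency.  Because the attainable r² is bounded by the allele-frequency
difference of the two loci, r² is also reported relative to that bound:
r²max is the larger of the two values of r² at the Fréchet bounds of p_AB
(max(0, p_A + p_B − 1) and min(p_A, p_B); exact since r² is a convex
quadratic in p_AB), and r²_S = r² / r²max is the standardized coefficient
that removes the ΔMAF-dependent component.

Decay curves are arithmetic means of r² (and r²_S) in 500 bp distance bins
with Bonferroni-corrected percentile-bootstrap confidence intervals;
relative-LD summaries express SV–SNP bin means as percentages of the
SNP–SNP bin means, averaged over the first ten bins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import HaplotypePanel, VType

PAIR_COLUMNS = [
    "id_a",
    "id_b",
    "pair_class",
    "distance",
    "p_a",
    "p_b",
    "p_ab",
    "dmaf",
    "r2",
    "r2max",
    "r2s",
]


def haplotype_r2(alleles_a: np.ndarray, alleles_b: np.ndarray) -> tuple[float, float, float, float]:
    """r² between two phased 0/1 allele vectors.

    Returns ``(r2, p_a, p_b, p_ab)``.  Raises for monomorphic input (the
    correlation is undefined there).
    """
    a = np.asarray(alleles_a, dtype=float)
    b = np.asarray(alleles_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("allele vectors must be equal-length 1-D arrays")
    p_a, p_b = a.mean(), b.mean()
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        raise ValueError("r2 undefined for a monomorphic locus")
    p_ab = float((a * b).mean())
    num = (p_ab - p_a * p_b) ** 2
    den = p_a * p_b * (1 - p_a) * (1 - p_b)
    return num / den, float(p_a), float(p_b), p_ab


def r2max(p_a, p_b):
    """Maximum attainable r² given the two allele frequencies.

    Evaluates r² at both Fréchet bounds of the haplotype frequency and
    returns the larger value.  Accepts scalars or arrays.
    """
    p_a = np.asarray(p_a, dtype=float)
    p_b = np.asarray(p_b, dtype=float)
    if np.any((p_a <= 0) | (p_a >= 1) | (p_b <= 0) | (p_b >= 1)):
        raise ValueError("allele frequencies must lie in (0, 1)")
    den = p_a * p_b * (1 - p_a) * (1 - p_b)
    d_lo = np.maximum(0.0, p_a + p_b - 1.0) - p_a * p_b
    d_hi = np.minimum(p_a, p_b) - p_a * p_b
    out = np.maximum(d_lo**2, d_hi**2) / den
    return float(out) if out.ndim == 0 else out


def r2s(r2, r2_max):
    """Standardized r²: r² / r²max, clipped against float overshoot only."""
    r2 = np.asarray(r2, dtype=float)
    r2_max = np.asarray(r2_max, dtype=float)
    if np.any(r2_max <= 0):
        raise ValueError("r2max must be positive")
    val = r2 / r2_max
    if np.any(val > 1.0 + 1e-9):
        raise ValueError("r2 exceeds r2max beyond float tolerance")
    val = np.clip(val, 0.0, 1.0)
    return float(val) if val.ndim == 0 else val


def _maf(p: np.ndarray) -> np.ndarray:
    return np.minimum(p, 1.0 - p)


def _pair_frame(
    ids_a, ids_b, pair_class, dist, p_a, p_b, p_ab
) -> pd.DataFrame:
    num = (p_ab - p_a * p_b) ** 2
    den = p_a * p_b * (1 - p_a) * (1 - p_b)
    r2 = num / den
    rmax = r2max(p_a, p_b)
    return pd.DataFrame(
        {
            "id_a": ids_a,
            "id_b": ids_b,
            "pair_class": pair_class,
            "distance": dist,
            "p_a": p_a,
            "p_b": p_b,
            "p_ab": p_ab,
            "dmaf": np.abs(_maf(p_a) - _maf(p_b)),
            "r2": r2,
            "r2max": rmax,
            "r2s": np.clip(r2 / rmax, 0.0, 1.0),
        }
    )


class _PairBuffer:
    """Accumulates pair arrays and flushes them as DataFrame chunks."""

    def __init__(self, chunk_rows: int = 200_000) -> None:
        self.chunk_rows = chunk_rows
        self.rows = 0
        self.parts: list[tuple] = []

    def add(self, ids_a, ids_b, pair_class, dist, p_a, p_b, p_ab) -> None:
        self.parts.append((ids_a, ids_b, pair_class, dist, p_a, p_b, p_ab))
        self.rows += len(dist)

    def flush(self) -> pd.DataFrame | None:
        if not self.parts:
            return None
        cat = [np.concatenate([p[i] for p in self.parts]) for i in range(7)]
        self.parts, self.rows = [], 0
        return _pair_frame(*cat)


def iter_ld_pairs(
    panel: HaplotypePanel,
    max_dist: int = 100_000,
    include_snp_snp: bool = True,
    include_sv_snp: bool = True,
    chunk_rows: int = 200_000,
) -> Iterator[pd.DataFrame]:
    """Stream LD pairs of one population's panel as DataFrame chunks.

    SV–SNP distance is the minimum distance from the SNP position to either
    SV breakpoint; SNPs located on an SV's span are excluded for that SV
    only.  SNP–SNP distance is the coordinate difference.  Pairs at
    distance 0 or beyond ``max_dist`` and monomorphic loci are skipped.
    All haplotypes of the panel enter each pair, so callers should pass a
    single-population panel (see :meth:`HaplotypePanel.subset_population`).
    Memory stays bounded by ``chunk_rows`` per emitted chunk.
    """
    X = panel.alleles
    n_hap = X.shape[0]
    freq = X.mean(axis=0)
    poly = (freq > 0) & (freq < 1)
    is_snp = np.array([v.vtype is VType.SNP for v in panel.variants])
    buf = _PairBuffer(chunk_rows)

    for chrom in dict.fromkeys(v.chrom for v in panel.variants):
        on_chrom = np.array([v.chrom == chrom for v in panel.variants])
        snp_cols = np.flatnonzero(on_chrom & is_snp & poly)
        if len(snp_cols) == 0:
            continue
        snp_pos = np.array([panel.variants[j].start for j in snp_cols])
        order = np.argsort(snp_pos, kind="stable")
        snp_cols, snp_pos = snp_cols[order], snp_pos[order]
        snp_ids = np.array([panel.variants[j].id for j in snp_cols])
        Xs = X[:, snp_cols].astype(np.float64)
        ps = freq[snp_cols]
        snp_cls = np.array(["SNP-SNP"])

        if include_snp_snp:
            for k in range(len(snp_cols)):
                hi = np.searchsorted(snp_pos, snp_pos[k] + max_dist, side="right")
                lo = k + 1
                if hi <= lo:
                    continue
                dist = snp_pos[lo:hi] - snp_pos[k]
                keep = dist > 0
                if not keep.any():
                    continue
                p_ab = (Xs[:, k] @ Xs[:, lo:hi][:, keep]) / n_hap
                n = int(keep.sum())
                buf.add(
                    np.repeat(snp_ids[k], n),
                    snp_ids[lo:hi][keep],
                    np.repeat(snp_cls, n),
                    dist[keep].astype(np.int64),
                    np.repeat(ps[k], n),
                    ps[lo:hi][keep],
                    p_ab,
                )
                if buf.rows >= buf.chunk_rows:
                    yield buf.flush()

        if include_sv_snp:
            sv_cols = np.flatnonzero(on_chrom & ~is_snp & poly)
            for j in sv_cols:
                sv = panel.variants[j]
                lo = np.searchsorted(snp_pos, sv.start - max_dist)
                hi = np.searchsorted(snp_pos, sv.end + max_dist, side="right")
                if hi <= lo:
                    continue
                pos = snp_pos[lo:hi]
                dist = np.min(
                    np.abs(pos[:, None] - np.array(sv.breakpoints)[None, :]), axis=1
                )
                keep = (dist > 0) & (dist <= max_dist)
                if sv.vtype.has_span:
                    keep &= ~((pos >= sv.start) & (pos < sv.end))
                if not keep.any():
                    continue
                p_ab = (X[:, j].astype(np.float64) @ Xs[:, lo:hi][:, keep]) / n_hap
                n = int(keep.sum())
                buf.add(
                    np.repeat(sv.id, n),
                    snp_ids[lo:hi][keep],
                    np.repeat(np.array([f"{sv.vtype.value}-SNP"]), n),
                    dist[keep].astype(np.int64),
                    np.repeat(freq[j], n),
                    ps[lo:hi][keep],
                    p_ab,
                )
                if buf.rows >= buf.chunk_rows:
                    yield buf.flush()
    final = buf.flush()
    if final is not None:
        yield final


def ld_pairs(panel: HaplotypePanel, max_dist: int = 100_000, **kwargs) -> pd.DataFrame:
    """Collect :func:`iter_ld_pairs` into one DataFrame (desk-scale sizes)."""
    chunks = list(iter_ld_pairs(panel, max_dist=max_dist, **kwargs))
    if not chunks:
        return pd.DataFrame(columns=PAIR_COLUMNS)
    return pd.concat(chunks, ignore_index=True)


def bin_decay(
    pairs: pd.DataFrame | Iterable[pd.DataFrame],
    bin_width: int = 500,
    max_dist: int = 100_000,
) -> pd.DataFrame:
    """Mean r² / r²_S per distance bin and pair class.

    Bin ``b`` covers ``(bin_width*(b-1), bin_width*b]`` (upper-closed, so a
    pair at exactly 500 bp falls in bin 1).  Empty bins are reported with
    ``n = 0``.
    """
    if isinstance(pairs, pd.DataFrame):
        pairs = [pairs]
    acc: dict[tuple[str, int], np.ndarray] = {}
    classes: set[str] = set()
    for chunk in pairs:
        if chunk.empty:
            continue
        b = np.ceil(chunk["distance"].to_numpy() / bin_width).astype(int)
        for cls, grp in chunk.assign(_bin=b).groupby("pair_class", sort=False):
            classes.add(cls)
            for bi, g in grp.groupby("_bin", sort=False):
                key = (cls, int(bi))
                s = acc.setdefault(key, np.zeros(3))
                s += (len(g), g["r2"].sum(), g["r2s"].sum())
    n_bins = int(np.ceil(max_dist / bin_width))
    rows = []
    for cls in sorted(classes):
        for b in range(1, n_bins + 1):
            n, s2, s2s = acc.get((cls, b), (0.0, np.nan, np.nan))
            rows.append(
                {
                    "pair_class": cls,
                    "bin": b,
                    "bin_start": (b - 1) * bin_width,
                    "bin_end": b * bin_width,
                    "n": int(n),
                    "mean_r2": s2 / n if n else np.nan,
                    "mean_r2s": s2s / n if n else np.nan,
                }
            )
    return pd.DataFrame(rows)


def bootstrap_bin_ci(
    values: np.ndarray,
    n_boot: int = 100_000,
    n_bins_for_bonferroni: int = 200,
    rng: np.random.Generator | int | None = None,
    max_values: int = 1_000_000,
) -> tuple[float, float] | None:
    """Bonferroni-corrected percentile-bootstrap CI of a bin mean.

    Resamples the values within the bin ``n_boot`` times with replacement
    and takes percentiles at ``α/2`` and ``1 − α/2`` with
    ``α = 0.05 / n_bins_for_bonferroni``.  Returns None for bins with more
    than ``max_values`` values (the estimate would be needlessly expensive
    and its CI negligibly narrow) and for bins with fewer than two values.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 2 or n > max_values:
        return None
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    alpha = 0.05 / n_bins_for_bonferroni
    means = np.empty(n_boot)
    chunk = max(1, int(5_000_000 // n))
    for i in range(0, n_boot, chunk):
        k = min(chunk, n_boot - i)
        idx = rng.integers(0, n, size=(k, n))
        means[i : i + k] = values[idx].mean(axis=1)
    lo, hi = np.quantile(means, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def decay_with_ci(
    pairs: pd.DataFrame,
    bin_width: int = 500,
    max_dist: int = 100_000,
    n_boot: int = 100_000,
    seed: int | None = None,
    metrics: tuple[str, ...] = ("r2", "r2s"),
) -> pd.DataFrame:
    """Binned decay curve plus bootstrap CIs for both LD metrics."""
    decay = bin_decay(pairs, bin_width=bin_width, max_dist=max_dist)
    n_bins = int(np.ceil(max_dist / bin_width))
    rng = np.random.default_rng(seed)
    b = np.ceil(pairs["distance"].to_numpy() / bin_width).astype(int) if not pairs.empty else np.array([], int)
    for metric in metrics:
        los, his = [], []
        for _, row in decay.iterrows():
            vals = (
                pairs.loc[
                    (pairs["pair_class"] == row["pair_class"]) & (b == row["bin"]),
                    metric,
                ].to_numpy()
                if not pairs.empty
                else np.array([])
            )
            ci = bootstrap_bin_ci(
                vals, n_boot=n_boot, n_bins_for_bonferroni=n_bins, rng=rng
            )
            los.append(np.nan if ci is None else ci[0])
            his.append(np.nan if ci is None else ci[1])
        decay[f"ci_lo_{metric}"] = los
        decay[f"ci_hi_{metric}"] = his
    return decay


@dataclass
class RelativeLDSummary:
    """SV–SNP LD relative to SNP–SNP LD over the first bins, in percent."""

    pair_class: str
    rel_r2_mean: float
    rel_r2_sd: float
    rel_r2s_mean: float
    rel_r2s_sd: float

    @property
    def delta(self) -> float:
        """Relative r²_S minus relative r² (positive when standardization
        closes part of the LD gap)."""
        return self.rel_r2s_mean - self.rel_r2_mean


def relative_ld(
    decay_sv: pd.DataFrame, decay_snp: pd.DataFrame, first_n: int = 10
) -> RelativeLDSummary:
    """Mean ± SD of per-bin SV/SNP LD ratios (percent) over bins 1..first_n."""
    sv = decay_sv.set_index("bin").loc[range(1, first_n + 1)]
    snp = decay_snp.set_index("bin").loc[range(1, first_n + 1)]
    if (sv["n"] == 0).any() or (snp["n"] == 0).any():
        raise ValueError(f"all of the first {first_n} bins must be non-empty")
    ratio_r2 = 100.0 * sv["mean_r2"].to_numpy() / snp["mean_r2"].to_numpy()
    ratio_r2s = 100.0 * sv["mean_r2s"].to_numpy() / snp["mean_r2s"].to_numpy()
    cls = str(decay_sv["pair_class"].iloc[0])
    return RelativeLDSummary(
        pair_class=cls,
        rel_r2_mean=float(ratio_r2.mean()),
        rel_r2_sd=float(ratio_r2.std(ddof=1)),
        rel_r2s_mean=float(ratio_r2s.mean()),
        rel_r2s_sd=float(ratio_r2s.std(ddof=1)),
    )


def delta_maf_summary(pairs: pd.DataFrame, max_dist: int = 5000) -> pd.DataFrame:
    """Median and quartiles of ΔMAF per pair class within ``max_dist``."""
    close = pairs[pairs["distance"] <= max_dist]
    rows = []
    for cls, grp in close.groupby("pair_class"):
        q1, med, q3 = np.quantile(grp["dmaf"], [0.25, 0.5, 0.75])
        rows.append(
            {"pair_class": cls, "n": len(grp), "q1": q1, "median": med, "q3": q3}
        )
    return pd.DataFrame(rows)


def dosage_dhffc_r2(snp_dosages: np.ndarray, dhffc_values: np.ndarray) -> float:
    """Squared Pearson correlation of 0/1/2 SNP dosages with DHFFC values."""
    x = np.asarray(snp_dosages, dtype=float)
    y = np.asarray(dhffc_values, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    r = stats.pearsonr(x, y).statistic
    return float(r * r)
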