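"""Tag-SNP analysis: maximal r² within distance and SNP-density statistics.

A variant's taggability r²_tag(d) is the maximum r² between the variant
and any SNP of a pool of potential tag SNPs within distance d.  Curves are
running maxima over the distance grid (hence non-decreasing); a variant
counts as *tagged* at a distance when r²_tag exceeds a threshold (0.75 by
convention, strict).  Array pools are the intersection of the variable WGS
SNPs with an array manifest, which makes pool restriction a subset
operation — taggability under a subset pool can never exceed the full
pool's.
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import HaplotypePanel, VType

DEFAULT_GRID = np.arange(1000, 100_001, 1000)


def wgs_pool(panel: HaplotypePanel) -> np.ndarray:
    """Column indices of the variable (polymorphic) SNPs in a panel."""
    freq = panel.alleles.mean(axis=0)
    return np.flatnonzero(
        [
            v.vtype is VType.SNP and 0 < f < 1
            for v, f in zip(panel.variants, freq)
        ]
    )


def array_pool(
    panel: HaplotypePanel, pool: np.ndarray, manifest: set[tuple[str, int]]
) -> np.ndarray:
    """Restrict a tag-SNP pool to positions present on an array manifest."""
    keep = [
        j
        for j in pool
        if (panel.variants[j].chrom, panel.variants[j].start) in manifest
    ]
    return np.asarray(keep, dtype=int)


@dataclass
class TagResult:
    """Taggability curve of one variant over a distance grid."""

    variant_id: str
    pair_class: str
    grid: np.ndarray
    r2_tag: np.ndarray  # NaN where no pool SNP within the distance
    best_tag: list[str | None]
    n_pool: np.ndarray  # variable pool SNPs within each grid distance


def pool_index(panel: HaplotypePanel, pool: np.ndarray) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-chromosome ``(columns, positions)`` arrays of a pool, sorted by
    position — precomputed once for many :func:`tag_curve` calls."""
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for j in np.asarray(pool, dtype=int):
        v = panel.variants[j]
        by_chrom.setdefault(v.chrom, []).append((v.start, j))
    for chrom, pairs in by_chrom.items():
        pairs.sort()
        out[chrom] = (
            np.array([j for _, j in pairs], dtype=int),
            np.array([p for p, _ in pairs], dtype=int),
        )
    return out


def tag_curve(
    panel: HaplotypePanel,
    variant_col: int,
    pool: np.ndarray,
    grid: np.ndarray = DEFAULT_GRID,
    index: dict[str, tuple[np.ndarray, np.ndarray]] | None = None,
) -> TagResult:
    """r²_tag curve of one panel column against a pool of SNP columns.

    Pool SNPs on the variant's own span are excluded (their calls may be
    influenced by the variant), as are pairs at distance zero.  Ties on r²
    resolve to the smaller distance, then the smaller coordinate.
    """
    grid = np.asarray(grid)
    v = panel.variants[variant_col]
    X = panel.alleles
    freq = X.mean(axis=0)
    if freq[variant_col] in (0.0, 1.0):
        raise ValueError(f"{v.id}: monomorphic variant has no defined r2")
    if index is None:
        index = pool_index(panel, pool)
    chrom_pool, pos = index.get(v.chrom, (np.array([], int), np.array([], int)))
    # window of candidates within the largest grid distance
    lo = np.searchsorted(pos, v.start - int(grid[-1]))
    hi = np.searchsorted(pos, v.end + int(grid[-1]), side="right")
    chrom_pool, pos = chrom_pool[lo:hi], pos[lo:hi]
    bps = np.array(v.breakpoints)
    dist = (
        np.min(np.abs(pos[:, None] - bps[None, :]), axis=1)
        if len(pos)
        else np.array([], dtype=int)
    )
    keep = (dist > 0) & (chrom_pool != variant_col)
    if v.vtype.has_span:
        keep &= ~((pos >= v.start) & (pos < v.end))
    cols, dist, pos = chrom_pool[keep], dist[keep], pos[keep]

    n_pool = np.searchsorted(np.sort(dist), grid, side="right")
    if len(cols) == 0:
        return TagResult(
            v.id, f"{v.vtype.value}", grid, np.full(len(grid), np.nan),
            [None] * len(grid), n_pool,
        )

    n_hap = X.shape[0]
    a = X[:, variant_col].astype(np.float64)
    p_a = freq[variant_col]
    p_b = freq[cols]
    p_ab = (a @ X[:, cols].astype(np.float64)) / n_hap
    num = (p_ab - p_a * p_b) ** 2
    den = p_a * p_b * (1 - p_a) * (1 - p_b)
    r2 = num / den

    order = np.lexsort((pos, dist))
    r2o, disto, colso = r2[order], dist[order], cols[order]
    run_max = np.maximum.accumulate(r2o)
    # index of the first achiever of the running max (ties -> smaller
    # distance then coordinate, already the sort order)
    achiever = np.zeros(len(r2o), dtype=int)
    best = 0
    for k in range(len(r2o)):
        if r2o[k] > r2o[best]:
            best = k
        achiever[k] = best
    upto = np.searchsorted(disto, grid, side="right") - 1
    r2_tag = np.where(upto >= 0, run_max[np.maximum(upto, 0)], np.nan)
    best_tag = [
        panel.variants[colso[achiever[u]]].id if u >= 0 else None for u in upto
    ]
    return TagResult(v.id, f"{v.vtype.value}", grid, r2_tag, best_tag, n_pool)


def tag_curves(
    panel: HaplotypePanel,
    variant_cols: Iterable[int],
    pool: np.ndarray,
    grid: np.ndarray = DEFAULT_GRID,
) -> list[TagResult]:
    """Tag curves for many variants, skipping monomorphic ones."""
    freq = panel.alleles.mean(axis=0)
    index = pool_index(panel, pool)
    return [
        tag_curve(panel, j, pool, grid, index=index)
        for j in variant_cols
        if 0 < freq[j] < 1
    ]


def mean_tag_curves(
    results: Sequence[TagResult],
    n_boot: int = 10_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-class mean r²_tag curves with Bonferroni bootstrap CIs.

    The mean at each grid point is over variants with a defined r²_tag
    there; CIs come from resampling variants, Bonferroni-corrected across
    grid points.
    """
    rng = np.random.default_rng(seed)
    rows = []
    by_class: dict[str, list[TagResult]] = {}
    for r in results:
        by_class.setdefault(r.pair_class, []).append(r)
    for cls, rs in sorted(by_class.items()):
        grid = rs[0].grid
        mat = np.stack([r.r2_tag for r in rs])  # variants x grid
        alpha = 0.05 / len(grid)
        for gi, g in enumerate(grid):
            vals = mat[:, gi]
            ok = ~np.isnan(vals)
            n = int(ok.sum())
            mean = float(vals[ok].mean()) if n else np.nan
            if n >= 2:
                idx = rng.integers(0, n, size=(n_boot, n))
                means = vals[ok][idx].mean(axis=1)
                lo, hi = np.quantile(means, [alpha / 2, 1 - alpha / 2])
            else:
                lo = hi = mean
            rows.append(
                {
                    "pair_class": cls,
                    "distance": int(g),
                    "n": n,
                    "mean_r2_tag": mean,
                    "ci_lo": float(lo),
                    "ci_hi": float(hi),
                }
            )
    return pd.DataFrame(rows)


def share_tagged(
    results: Sequence[TagResult], distance: int, threshold: float = 0.75
) -> float:
    """Fraction of variants with r²_tag strictly above the threshold.

    Variants with no pool SNP within the distance count as untagged.
    """
    if not results:
        raise ValueError("no tag results given")
    tagged = 0
    for r in results:
        gi = int(np.searchsorted(r.grid, distance))
        if gi >= len(r.grid):
            gi = len(r.grid) - 1
        val = r.r2_tag[gi]
        if np.isfinite(val) and val > threshold:
            tagged += 1
    return tagged / len(results)


def snp_density(
    panel: HaplotypePanel,
    variant_cols: Iterable[int],
    pool: np.ndarray,
    distance: int = 5000,
    r2_floor: float | None = None,
) -> pd.DataFrame:
    """Count of variable pool SNPs within ``distance`` of each variant.

    With ``r2_floor`` set, only pool SNPs in LD of at least that r² count
    (the tag-SNP reading of density).  SNPs on the variant's span are
    excluded as in the LD analysis.
    """
    X = panel.alleles
    freq = X.mean(axis=0)
    n_hap = X.shape[0]
    pool = np.asarray(pool, dtype=int)
    index = pool_index(panel, pool)
    rows = []
    for j in variant_cols:
        v = panel.variants[j]
        if not (0 < freq[j] < 1):
            continue
        cols, pos = index.get(v.chrom, (np.array([], int), np.array([], int)))
        lo = np.searchsorted(pos, v.start - distance)
        hi = np.searchsorted(pos, v.end + distance, side="right")
        cols, pos = cols[lo:hi], pos[lo:hi]
        sel = cols != j
        cols, pos = cols[sel], pos[sel]
        bps = np.array(v.breakpoints)
        dist = (
            np.min(np.abs(pos[:, None] - bps[None, :]), axis=1)
            if len(pos)
            else np.array([], dtype=int)
        )
        keep = (dist > 0) & (dist <= distance)
        if v.vtype.has_span:
            keep &= ~((pos >= v.start) & (pos < v.end))
        cols = cols[keep]
        if r2_floor is not None and len(cols):
            a = X[:, j].astype(np.float64)
            p_a, p_b = freq[j], freq[cols]
            p_ab = (a @ X[:, cols].astype(np.float64)) / n_hap
            r2 = (p_ab - p_a * p_b) ** 2 / (p_a * p_b * (1 - p_a) * (1 - p_b))
            cols = cols[r2 >= r2_floor]
        rows.append(
            {"id": v.id, "pair_class": v.vtype.value, "count": int(len(cols))}
        )
    return pd.DataFrame(rows, columns=["id", "pair_class", "count"])


def compare_density(counts: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Bonferroni-corrected pairwise Wilcoxon rank-sum tests on densities.

    ``counts`` needs columns ``pair_class`` and ``count``.  Returns the
    pairwise table with corrected p values; compact letter groups are in
    :func:`letter_groups`.
    """
    classes = sorted(counts["pair_class"].unique())
    pairs = [
        (a, b) for i, a in enumerate(classes) for b in classes[i + 1 :]
    ]
    rows = []
    for a, b in pairs:
        xa = counts.loc[counts["pair_class"] == a, "count"]
        xb = counts.loc[counts["pair_class"] == b, "count"]
        if len(xa) < 2 or len(xb) < 2:
            continue
        p = stats.mannwhitneyu(xa, xb, alternative="two-sided").pvalue
        rows.append(
            {
                "class_a": a,
                "class_b": b,
                "p": float(p),
                "p_bonf": min(1.0, float(p) * len(pairs)),
            }
        )
    df = pd.DataFrame(rows, columns=["class_a", "class_b", "p", "p_bonf"])
    df["significant"] = df["p_bonf"] < alpha if len(df) else pd.Series(dtype=bool)
    return df


def letter_groups(comparisons: pd.DataFrame, classes: Sequence[str]) -> dict[str, str]:
    """Greedy insert-and-absorb compact letter display.

    Starts from one group containing all classes and splits it at every
    significant pair; redundant (subset) groups are absorbed.
    """
    groups: list[set[str]] = [set(classes)]
    sig_pairs = [
        (r["class_a"], r["class_b"])
        for _, r in comparisons.iterrows()
        if r["significant"]
    ]
    for a, b in sig_pairs:
        for g in [g for g in groups if a in g and b in g]:
            groups.remove(g)
            groups.extend([g - {a}, g - {b}])
        # absorb subsets
        groups = [
            g
            for g in groups
            if g and not any(g < h for h in groups if h is not g)
        ]
    # deduplicate while preserving order
    seen: list[set[str]] = []
    for g in groups:
        if g not in seen:
            seen.append(g)
    letters: dict[str, str] = {c: "" for c in classes}
    for letter, g in zip(string.ascii_lowercase, seen):
        for c in sorted(g):
            letters[c] += letter
    return letters
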