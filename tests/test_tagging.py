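"""Tag-SNP curves, tagged shares, density statistics and array pools."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from svld.datamodel import HaplotypePanel, VariantRecord, VType
from svld.tagging import (
    TagResult,
    array_pool,
    compare_density,
    letter_groups,
    mean_tag_curves,
    share_tagged,
    snp_density,
    tag_curve,
    tag_curves,
    wgs_pool,
)


def _snp(id, pos):
    return VariantRecord(id=id, chrom="1", start=pos, end=pos + 1, vtype=VType.SNP)


def _panel(columns: dict[str, tuple[int, list[int]]], vtype=None):
    """Build a panel from {id: (position, allele column)}."""
    variants, cols = [], []
    for vid, (pos, col) in sorted(columns.items(), key=lambda t: t[1][0]):
        vt = (vtype or {}).get(vid, VType.SNP)
        end = pos + 1 if vt in (VType.SNP, VType.BND) else pos + 1000
        variants.append(VariantRecord(id=vid, chrom="1", start=pos, end=end, vtype=vt))
        cols.append(col)
    alleles = np.array(cols, dtype=np.uint8).T
    n = alleles.shape[0] // 2
    return HaplotypePanel(alleles, [f"s{i}" for i in range(n)], variants, ["p"] * n)


class TestTagCurve:
    def test_single_pool_snp(self):
        """One pool SNP at 3 kb with r² = 0.6ish: absent before, flat after."""
        a = [1, 1, 1, 1, 0, 0, 0, 0]
        b = [1, 1, 1, 0, 1, 0, 0, 0]  # r2 = 0.25 with a
        panel = _panel({"v": (1000, a), "t": (4000, b)})
        vcol = [j for j, v in enumerate(panel.variants) if v.id == "v"][0]
        pool = np.array([j for j, v in enumerate(panel.variants) if v.id == "t"])
        res = tag_curve(panel, vcol, pool, grid=np.array([1000, 2000, 3000, 4000]))
        assert np.isnan(res.r2_tag[0]) and np.isnan(res.r2_tag[1])
        assert res.r2_tag[2] == pytest.approx(0.25)
        assert res.r2_tag[3] == pytest.approx(0.25)
        assert res.best_tag[2] == "t"
        assert res.n_pool.tolist() == [0, 0, 1, 1]

    def test_identical_column_gives_one(self):
        a = [1, 1, 0, 0, 1, 0, 0, 0]
        panel = _panel({"v": (1000, a), "t": (1500, a)})
        vcol = 0 if panel.variants[0].id == "v" else 1
        pool = np.array([1 - vcol])
        res = tag_curve(panel, vcol, pool, grid=np.array([1000]))
        assert res.r2_tag[0] == pytest.approx(1.0)

    def test_exhaustive_oracle_on_fixture(self, rng):
        """Running max equals brute force over all pool pairs per grid point."""
        n_hap, n_snp = 20, 50
        positions = np.sort(rng.choice(100_000, size=n_snp, replace=False))
        cols = {}
        for i, p in enumerate(positions):
            col = rng.integers(0, 2, n_hap)
            while col.min() == col.max():
                col = rng.integers(0, 2, n_hap)
            cols[f"s{i:02d}"] = (int(p), col.tolist())
        panel = _panel(cols)
        pool = np.arange(panel.n_variants)
        grid = np.arange(5000, 100_001, 5000)
        for vcol in [0, 10, 49]:
            res = tag_curve(panel, vcol, pool, grid=grid)
            v = panel.variants[vcol]
            for gi, g in enumerate(grid):
                best = np.nan
                for j in pool:
                    if j == vcol:
                        continue
                    d = abs(panel.variants[j].start - v.start)
                    if 0 < d <= g:
                        from svld.ld import haplotype_r2
                        r2, *_ = haplotype_r2(
                            panel.alleles[:, vcol], panel.alleles[:, j]
                        )
                        best = r2 if np.isnan(best) else max(best, r2)
                if np.isnan(best):
                    assert np.isnan(res.r2_tag[gi])
                else:
                    assert res.r2_tag[gi] == pytest.approx(best)

    def test_monotone_non_decreasing(self, noisy_sim):
        sub = noisy_sim.panel.subset_population("WL")
        pool = wgs_pool(sub)
        freq = sub.alleles.mean(axis=0)
        sv_cols = [
            j for j, v in enumerate(sub.variants)
            if v.vtype is not VType.SNP and 0 < freq[j] < 1
        ]
        for res in tag_curves(sub, sv_cols, pool, grid=np.arange(5000, 100_001, 5000)):
            vals = res.r2_tag[np.isfinite(res.r2_tag)]
            assert (np.diff(vals) >= -1e-12).all()

    def test_snp_on_span_excluded(self):
        a = [1, 1, 0, 0, 1, 0, 0, 0]
        panel = _panel(
            {"v": (1000, a), "inside": (1500, a), "outside": (3000, a)},
            vtype={"v": VType.DUP},
        )
        vcol = [j for j, v in enumerate(panel.variants) if v.id == "v"][0]
        pool = np.array([j for j, v in enumerate(panel.variants) if v.id != "v"])
        res = tag_curve(panel, vcol, pool, grid=np.array([800, 2500]))
        # "inside" (on the 1 kb span) is skipped; "outside" tags at 2 kb
        assert np.isnan(res.r2_tag[0])
        assert res.best_tag[1] == "outside"


class TestPoolMonotonicity:
    def test_subset_pool_never_better(self, noisy_sim, rng):
        sub = noisy_sim.panel.subset_population("BL")
        pool = wgs_pool(sub)
        sparse = np.sort(rng.choice(pool, size=len(pool) // 10, replace=False))
        grid = np.arange(10_000, 100_001, 10_000)
        freq = sub.alleles.mean(axis=0)
        sv_cols = [
            j for j, v in enumerate(sub.variants)
            if v.vtype is not VType.SNP and 0 < freq[j] < 1
        ][:40]
        dense_res = tag_curves(sub, sv_cols, pool, grid=grid)
        sparse_res = tag_curves(sub, sv_cols, sparse, grid=grid)
        for d, s in zip(dense_res, sparse_res):
            both = np.isfinite(d.r2_tag) & np.isfinite(s.r2_tag)
            assert (s.r2_tag[both] <= d.r2_tag[both] + 1e-12).all()
            assert not (np.isnan(d.r2_tag) & np.isfinite(s.r2_tag)).any()


class TestShareTagged:
    def _res(self, value):
        return TagResult("v", "SNP", np.array([1000]), np.array([value]), [None], np.array([1]))

    def test_all_tagged(self):
        assert share_tagged([self._res(1.0)] * 4, 1000) == 1.0

    def test_threshold_is_strict(self):
        assert share_tagged([self._res(0.75)], 1000) == 0.0
        assert share_tagged([self._res(0.7500001)], 1000) == 1.0

    def test_fraction(self):
        rs = [self._res(0.9)] * 3 + [self._res(0.1)] * 6 + [self._res(np.nan)]
        assert share_tagged(rs, 1000) == pytest.approx(0.3)

    def test_monotone_in_distance_and_threshold(self, noisy_sim):
        sub = noisy_sim.panel.subset_population("WL")
        pool = wgs_pool(sub)
        grid = np.arange(10_000, 100_001, 10_000)
        res = tag_curves(sub, pool[:80], pool, grid=grid)
        shares_d = [share_tagged(res, d) for d in (10_000, 50_000, 100_000)]
        assert shares_d == sorted(shares_d)
        shares_t = [share_tagged(res, 50_000, t) for t in (0.9, 0.75, 0.5)]
        assert shares_t == sorted(shares_t)


class TestDensity:
    def test_planted_counts(self):
        cols = {"v": (10_000, [1, 1, 0, 0, 1, 0, 0, 0])}
        for i in range(7):
            cols[f"near{i}"] = (10_600 + 500 * i, [1, 0, 1, 0, 0, 1, 0, 0])
        cols["far"] = (40_000, [1, 0, 1, 0, 0, 1, 0, 0])
        panel = _panel(cols)
        vcol = [j for j, v in enumerate(panel.variants) if v.id == "v"][0]
        pool = np.array([j for j, v in enumerate(panel.variants) if v.id != "v"])
        out = snp_density(panel, [vcol], pool, distance=5000)
        assert out["count"].iloc[0] == 7

    def test_no_neighbors(self):
        panel = _panel({"v": (10_000, [1, 0, 1, 0]), "far": (90_000, [1, 1, 0, 0])})
        vcol = [j for j, v in enumerate(panel.variants) if v.id == "v"][0]
        out = snp_density(panel, [vcol], np.array([1 - vcol]), distance=5000)
        assert out["count"].iloc[0] == 0

    def test_r2_floor_subset(self, noisy_sim):
        sub = noisy_sim.panel.subset_population("BR")
        pool = wgs_pool(sub)
        cols = pool[:60]
        full = snp_density(sub, cols, pool)
        floored = snp_density(sub, cols, pool, r2_floor=0.75)
        merged = full.merge(floored, on="id", suffixes=("_full", "_floor"))
        assert (merged["count_floor"] <= merged["count_full"]).all()

    def test_svs_in_snp_poor_regions(self, noisy_sim):
        """The generator plants SVs away from SNP-dense neighborhoods."""
        sub = noisy_sim.panel.subset_population("BL")
        pool = wgs_pool(sub)
        freq = sub.alleles.mean(axis=0)
        sv_cols = [
            j for j, v in enumerate(sub.variants)
            if v.vtype is not VType.SNP and 0 < freq[j] < 1
        ]
        dens = snp_density(sub, list(pool[:150]) + sv_cols, pool)
        med = dens.assign(
            is_snp=dens.pair_class == "SNP"
        ).groupby("is_snp")["count"].median()
        assert med[True] > med[False]


class TestCompareDensity:
    def test_identical_distributions(self):
        counts = pd.DataFrame(
            {"pair_class": ["A"] * 30 + ["B"] * 30, "count": list(range(30)) * 2}
        )
        out = compare_density(counts)
        assert out["p_bonf"].iloc[0] == 1.0
        letters = letter_groups(out, ["A", "B"])
        assert letters["A"] == letters["B"]

    def test_disjoint_distributions(self):
        counts = pd.DataFrame(
            {
                "pair_class": ["A"] * 50 + ["B"] * 50,
                "count": list(range(1, 51)) + list(range(101, 151)),
            }
        )
        out = compare_density(counts)
        assert out["p_bonf"].iloc[0] < 0.05
        letters = letter_groups(out, ["A", "B"])
        assert set(letters["A"]) & set(letters["B"]) == set()

    def test_single_class_empty(self):
        counts = pd.DataFrame({"pair_class": ["A"] * 5, "count": range(5)})
        assert compare_density(counts).empty

    def test_three_class_letters(self):
        counts = pd.DataFrame(
            {
                "pair_class": ["A"] * 40 + ["B"] * 40 + ["C"] * 40,
                "count": list(range(40)) + list(range(2, 42)) + list(range(200, 240)),
            }
        )
        out = compare_density(counts)
        letters = letter_groups(out, ["A", "B", "C"])
        assert set(letters["C"]) & (set(letters["A"]) | set(letters["B"])) == set()
        assert set(letters["A"]) & set(letters["B"])


class TestArrayPool:
    def test_disjoint_manifest_empty_pool(self, noisy_sim):
        sub = noisy_sim.panel.subset_population("WL")
        pool = wgs_pool(sub)
        restricted = array_pool(sub, pool, {("9", 1)})
        assert len(restricted) == 0
        res = tag_curve(sub, int(pool[0]), restricted, grid=np.array([50_000]))
        assert np.isnan(res.r2_tag[0])

    def test_superset_manifest_identity(self, noisy_sim):
        sub = noisy_sim.panel.subset_population("WL")
        pool = wgs_pool(sub)
        manifest = {(sub.variants[j].chrom, sub.variants[j].start) for j in pool}
        assert np.array_equal(array_pool(sub, pool, manifest), pool)

    def test_dense_vs_sparse_arrays(self, noisy_sim, rng):
        """A 600k-like dense manifest tags at least as well as a 10k-like
        sparse manifest at every grid point."""
        sub = noisy_sim.panel.subset_population("BL")
        pool = wgs_pool(sub)
        sites = [(sub.variants[j].chrom, sub.variants[j].start) for j in pool]
        dense = set(sites[::2])
        sparse = set(sites[::40])  # nested, much sparser
        sparse &= dense
        p_dense = array_pool(sub, pool, dense)
        p_sparse = array_pool(sub, pool, sparse)
        grid = np.arange(20_000, 100_001, 20_000)
        freq = sub.alleles.mean(axis=0)
        sv_cols = [
            j for j, v in enumerate(sub.variants)
            if v.vtype is not VType.SNP and 0 < freq[j] < 1
        ][:30]
        d_curves = mean_tag_curves(tag_curves(sub, sv_cols, p_dense, grid=grid), n_boot=10, seed=0)
        s_curves = mean_tag_curves(tag_curves(sub, sv_cols, p_sparse, grid=grid), n_boot=10, seed=0)
        merged = d_curves.merge(s_curves, on=["pair_class", "distance"], suffixes=("_d", "_s"))
        ok = merged.dropna(subset=["mean_r2_tag_d", "mean_r2_tag_s"])
        # means are over tagged variants only; compare where both defined
        assert (ok["mean_r2_tag_d"] >= ok["mean_r2_tag_s"] - 0.05).all()


def test_mean_tag_curves_basics():
    grid = np.array([1000, 2000])
    r1 = TagResult("a", "SNP", grid, np.array([0.2, 0.2]), [None, None], np.array([1, 1]))
    r2_ = TagResult("b", "SNP", grid, np.array([0.8, 0.8]), [None, None], np.array([1, 1]))
    out = mean_tag_curves([r1, r2_], n_boot=200, seed=0)
    assert out["mean_r2_tag"].tolist() == [pytest.approx(0.5)] * 2
    assert ((out["ci_lo"] <= out["mean_r2_tag"]) & (out["mean_r2_tag"] <= out["ci_hi"])).all()
    single = mean_tag_curves([r1], n_boot=10, seed=0)
    assert single["mean_r2_tag"].tolist() == [pytest.approx(0.2)] * 2
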