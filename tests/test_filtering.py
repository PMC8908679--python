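"""Consensus merge and the five filtering rules."""

from __future__ import annotations

import numpy as np
import pytest

from svld.datamodel import (
    MISSING,
    DepthProfile,
    VariantRecord,
    VType,
)
from svld.filtering import (
    FilterConfig,
    HighCoverageRegions,
    compute_dhffc,
    consensus_genotypes,
    fill_missing_genotypes,
    filter_caller_overlap,
    filter_del_snp_support,
    filter_dhffc,
    filter_high_coverage,
    flag_high_coverage_regions,
    merge_callsets,
    run_filter_pipeline,
)
from svld.simulate import error_free, simulate_all, simulate_depth

from conftest import small_config


def _del(id, start, end, geno=(0, 1), caller=None, **kw):
    return VariantRecord(
        id=id, chrom="1", start=start, end=end, vtype=VType.DEL,
        genotypes=list(geno), **kw,
    )


class TestMerge:
    def test_transitive_chain_merges(self):
        """Starts 1000/1400/1900 chain into one record via pairwise links."""
        callsets = {
            "a": [_del("d.a", 1000, 2000)],
            "b": [_del("d.b", 1400, 2400)],
            "c": [_del("d.c", 1900, 2900)],
        }
        merged = merge_callsets(callsets, tolerance=1000)
        assert len(merged) == 1
        assert merged[0].caller_support == {"a", "b", "c"}
        # canonical breakpoint = median of {1000, 1400, 1900}
        assert merged[0].record.start == 1400

    def test_distant_records_stay_separate(self):
        callsets = {"a": [_del("x.a", 1000, 1500)], "b": [_del("y.b", 6000, 6500)]}
        assert len(merge_callsets(callsets)) == 2

    def test_types_never_merge(self):
        dup = VariantRecord(id="u.b", chrom="1", start=1000, end=1500,
                            vtype=VType.DUP, genotypes=[0, 1])
        callsets = {"a": [_del("d.a", 1000, 1500)], "b": [dup]}
        assert len(merge_callsets(callsets)) == 2

    def test_lower_median_on_even_tie(self):
        callsets = {"a": [_del("d.a", 1000, 2000)], "b": [_del("d.b", 1400, 2400)]}
        m = merge_callsets(callsets)[0]
        assert m.record.start == 1000 and m.record.end == 2000

    def test_end_tolerance_also_checked(self):
        callsets = {"a": [_del("d.a", 1000, 2000)], "b": [_del("d.b", 1100, 9000)]}
        assert len(merge_callsets(callsets)) == 2


class TestCallerOverlap:
    @pytest.mark.parametrize(
        "callers,kept", [({"a"}, False), ({"a", "b"}, True), ({"a", "b", "c"}, True)]
    )
    def test_min_two_callers(self, callers, kept):
        callsets = {c: [_del(f"d.{c}", 1000, 1500)] for c in callers}
        merged = merge_callsets(callsets)
        retained, removed = filter_caller_overlap(merged)
        assert (len(retained) == 1) is kept


class TestConsensus:
    def _merged(self, votes):
        callsets = {
            c: [_del(f"d.{c}", 1000, 1500, geno=v)]
            for c, v in zip("abc", votes)
        }
        return merge_callsets(callsets)

    def test_two_of_three_majority(self):
        retained, _ = consensus_genotypes(self._merged([(1,), (1,), (2,)]))
        assert retained[0].consensus.tolist() == [1]

    def test_full_discord_is_missing(self):
        retained, _ = consensus_genotypes(self._merged([(0,), (1,), (2,)]))
        assert retained[0].consensus.tolist() == [MISSING]
        assert retained[0].missing_by_discordance == 1

    def test_three_discordant_samples_remove_sv(self):
        votes = [(0, 0, 0), (1, 1, 1), (2, 2, 2)]
        retained, removed = consensus_genotypes(self._merged(votes))
        assert retained == [] and len(removed) == 1
        # boundary: exactly two discordant samples are tolerated
        votes = [(0, 0, 1), (1, 1, 1), (2, 2, 1)]
        retained, removed = consensus_genotypes(self._merged(votes))
        assert len(retained) == 1


class TestHighCoverage:
    def _profile(self, vec):
        return DepthProfile(window_size=100, data={"s": {"1": np.asarray(vec, float)}})

    def test_threshold_matches_numpy_oracle(self):
        rng = np.random.default_rng(0)
        vec = rng.normal(10, 2, size=500).clip(0)
        vec[50], vec[200] = 40, 45
        prof = self._profile(vec)
        regions = flag_high_coverage_regions(prof)
        thr = 2 * vec.mean() + 2 * vec.std()
        assert regions.threshold == pytest.approx(thr)
        flagged = {w for w in range(500) if vec[w] > thr}
        covered = set()
        for chrom, a, b in regions.regions:
            covered |= set(range(a // 100, b // 100))
        assert flagged <= covered

    def test_strictly_greater_than(self):
        """A window exactly at 2μ+2σ is not flagged."""
        # symmetric values {8, 12} -> mu=10, sigma=2, threshold 24
        vec = np.array([8.0, 12.0] * 100 + [24.0])
        # adding the probe changes mu/sigma; rescale so threshold is exact
        prof = self._profile(vec)
        regions = flag_high_coverage_regions(prof)
        thr = regions.threshold
        assert not any(
            a <= 200 * 100 < b for _, a, b in regions.regions
        ) or vec[200] > thr

    def test_merge_gap(self):
        vec = np.full(100, 10.0)
        vec[10], vec[15] = 100.0, 100.0  # windows [1000,1100) and [1500,1600)
        regions = flag_high_coverage_regions(self._profile(vec), merge_gap=1000)
        assert ("1", 1000, 1600) in regions.regions

    def test_ci_overlap_semantics(self):
        regions = HighCoverageRegions(regions=[("1", 5100, 5300)], threshold=0.0)
        hit = _del("d", 5000, 20_000, ci_start=(-200, 200))
        miss = _del("e", 40_000, 60_000, ci_start=(-100, 100))
        merged = merge_callsets({"a": [hit, miss], "b": [hit, miss]})
        retained, removed = filter_high_coverage(merged, regions)
        assert {m.record.start for m in removed} == {5000}
        # CI end exactly at region start (half-open) is retained
        touch = _del("f", 5000, 20_000, ci_start=(-100, 100))  # CI [4900,5100)
        merged = merge_callsets({"a": [touch], "b": [touch]})
        retained, removed = filter_high_coverage(merged, regions)
        assert removed == []


class TestDHFFC:
    def _depth(self, inside, flank, start=1000, end=1500):
        vec = np.full(50, float(flank))
        vec[start // 100 : end // 100] = inside
        return DepthProfile(window_size=100, data={"s": {"1": vec}})

    def test_closed_forms(self):
        rec = _del("d", 1000, 1500)
        assert compute_dhffc(rec, self._depth(5, 10))[0] == pytest.approx(0.5)
        assert compute_dhffc(rec, self._depth(7, 7))[0] == pytest.approx(1.0)

    def test_zero_flank_undefined(self):
        rec = _del("d", 1000, 1500)
        assert np.isnan(compute_dhffc(rec, self._depth(5, 0))[0])

    def test_hom_del_zero_in_simulation(self, clean_sim):
        truth, depth = clean_sim.truth, clean_sim.depth
        for sv in truth.sv_records:
            if sv.vtype is not VType.DEL or not (sv.genotypes == 2).any():
                continue
            d = compute_dhffc(sv, depth, samples=truth.sample_ids)
            for s in np.flatnonzero(sv.genotypes == 2):
                assert d[s] == pytest.approx(0.0)
            break

    @pytest.mark.parametrize(
        "vtype,gt,value,wrong",
        [
            (VType.DEL, 1, 0.5, False),
            (VType.DEL, 1, 0.95, True),
            (VType.DEL, 1, 0.1, False),   # closed interval
            (VType.DEL, 2, 0.1, True),    # hom DEL needs < 0.25 -> 0.1 ok
            (VType.DUP, 2, 1.3, True),    # needs > 1.5
            (VType.DUP, 1, 1.2, False),
        ],
    )
    def test_bounds(self, vtype, gt, value, wrong):
        if (vtype, gt, value) == (VType.DEL, 2, 0.1):
            wrong = False
        rec = VariantRecord(id="v", chrom="1", start=1000, end=1500, vtype=vtype,
                            genotypes=[gt])
        inside = value * 10
        merged = merge_callsets({"a": [rec], "b": [rec]})
        consensus_genotypes(merged)
        depth = self._depth(inside, 10)
        retained, removed, n_miss = filter_dhffc(merged, depth, samples=["s"])
        if wrong:
            # single wrong genotype of one tested -> fraction > 10% -> removed
            assert removed
        else:
            assert retained and n_miss == 0

    def test_one_wrong_of_twenty_sets_missing(self):
        geno = [1] * 20
        rec = VariantRecord(id="v", chrom="1", start=1000, end=1500,
                            vtype=VType.DEL, genotypes=geno)
        merged = merge_callsets({"a": [rec], "b": [rec]})
        consensus_genotypes(merged)
        samples = [f"s{i}" for i in range(20)]
        data = {}
        for i, s in enumerate(samples):
            vec = np.full(50, 10.0)
            vec[10:15] = 5.0 if i else 9.5  # sample 0 DHFFC 0.95 -> wrong
            data[s] = {"1": vec}
        depth = DepthProfile(window_size=100, data=data)
        retained, removed, n_miss = filter_dhffc(merged, depth, samples=samples)
        assert retained and n_miss == 1
        assert retained[0].consensus[0] == MISSING


class TestDelSnpSupport:
    def _setup(self, del_geno, snp_genos, **cfg):
        rec = VariantRecord(id="d", chrom="1", start=1000, end=2000,
                            vtype=VType.DEL, genotypes=del_geno)
        merged = merge_callsets({"a": [rec], "b": [rec]})
        consensus_genotypes(merged)
        snps = [
            VariantRecord(id=f"s{i}", chrom="1", start=1100 + 100 * i,
                          end=1101 + 100 * i, vtype=VType.SNP, genotypes=g)
            for i, g in enumerate(snp_genos)
        ]
        return filter_del_snp_support(merged, snps, FilterConfig(**cfg))

    def test_simple_ratio(self):
        """One het SNP call of five on a het-DEL sample: rate 1/5 = 0.2."""
        snps = [[1]] + [[0]] * 4
        retained, removed, n_miss = self._setup([1], snps)
        assert retained and n_miss == 1  # 0.2 < 2 and < 0.5*1? 0.2 < 0.5 -> kept
        retained, removed, _ = self._setup([1], snps, snp_support_halved=True)
        assert retained  # halved reading: 0.1

    def test_sum_exceeds_two(self):
        # 10 carriers, each with 1 violating SNP of 4 -> sum e = 2.5 > 2
        del_geno = [1] * 10
        snps = [[1] * 10] + [[0] * 10] * 3
        retained, removed, _ = self._setup(del_geno, snps)
        assert removed and not retained

    def test_half_of_carriers(self):
        # 3 carriers with summed rate 1.6 > 1.5 = 50% of 3
        del_geno = [1, 1, 1, 0]
        snps = [
            [1, 1, 1, 0],
            [1, 1, 0, 0],
            [1, 0, 0, 0],
            [1, 0, 0, 0],
            [0, 0, 0, 0],
        ]  # per-sample violations 4,2,1,0 of 5 SNPs -> rates .8,.4,.2 sum 1.4
        retained, removed, _ = self._setup(del_geno, snps)
        assert retained  # 1.4 < 1.5
        snps[4] = [1, 0, 0, 0]  # now 5,2,1 -> 1.0+.4+.2 = 1.6 > 1.5
        retained, removed, _ = self._setup(del_geno, snps)
        assert removed

    def test_hom_del_violation_is_any_nonmissing(self):
        del_geno = [2]
        snps = [[MISSING]] * 3 + [[0]]
        retained, removed, n_miss = self._setup(del_geno, snps)
        assert retained and n_miss == 1


class TestFill:
    def test_direct_encoding_without_missing(self):
        recs = [
            VariantRecord(id="a", chrom="1", start=10, end=11, vtype=VType.SNP,
                          genotypes=[0, 1, 2]),
        ]
        panel = fill_missing_genotypes(recs, ["x", "y", "z"], ["p"] * 3, seed=0)
        assert panel.dosages()[:, 0].tolist() == [0, 1, 2]

    def test_all_alt_frequency_fills_alt(self):
        recs = [
            VariantRecord(id="a", chrom="1", start=10, end=11, vtype=VType.SNP,
                          genotypes=[2, 2, MISSING]),
        ]
        panel = fill_missing_genotypes(recs, ["x", "y", "z"], ["p"] * 3, seed=0)
        assert panel.dosages()[2, 0] == 2

    def test_fill_frequency_binomial(self):
        n = 5000
        geno = np.full(n, MISSING, dtype=np.int8)
        geno[:1000] = 0
        geno[:300] = 1  # 300 het of 1000 known -> p = 0.15
        rec = VariantRecord(id="a", chrom="1", start=10, end=11, vtype=VType.SNP,
                            genotypes=geno)
        panel = fill_missing_genotypes(
            [rec], [f"s{i}" for i in range(n)], ["p"] * n, seed=3
        )
        filled = panel.alleles[2 * 1000 :, 0]
        assert abs(filled.mean() - 0.15) < 0.02

    def test_phase_template_preserved(self):
        rec = VariantRecord(id="a", chrom="1", start=10, end=11, vtype=VType.SNP,
                            genotypes=[1, 1])
        from svld.datamodel import HaplotypePanel
        template = HaplotypePanel(
            np.array([[0], [1], [1], [0]], dtype=np.uint8),
            ["x", "y"], [rec], ["p", "p"],
        )
        panel = fill_missing_genotypes([rec], ["x", "y"], ["p", "p"], seed=0,
                                       phase_template=template)
        assert panel.alleles[:, 0].tolist() == [0, 1, 1, 0]


class TestPipeline:
    def test_identity_on_error_free_data(self, clean_sim):
        cfg = clean_sim.truth.config
        res = run_filter_pipeline(
            clean_sim.callsets, clean_sim.depth, clean_sim.truth.snp_calls,
            genome=cfg.genome, samples=clean_sim.truth.sample_ids,
        )
        df = res.report.to_frame()
        assert df["removed"].sum() == 0
        assert df["genotypes_set_missing"].sum() == 0
        assert len(res.retained) == len(clean_sim.truth.sv_records)

    def test_report_conservation(self, noisy_sim):
        cfg = noisy_sim.truth.config
        res = run_filter_pipeline(
            noisy_sim.callsets, noisy_sim.depth, noisy_sim.truth.snp_calls,
            genome=cfg.genome, samples=noisy_sim.truth.sample_ids,
        )
        df = res.report.to_frame()
        assert (df["input"] == df["removed"] + df["retained"]).all()
        assert df["rule"].tolist() == [
            "caller_overlap", "genotype_concordance", "high_coverage_regions",
            "dhffc", "del_snp_support",
        ]

    def test_planted_artifact_removes_exactly_that_sv(self):
        cfg = error_free(small_config(seed=55))
        data = simulate_all(cfg)
        victim = data.truth.sv_records[0]
        data.truth.artifact_regions = [
            (victim.chrom, victim.start - 100, victim.start + 100)
        ]
        depth = simulate_depth(data.truth, cfg)
        res = run_filter_pipeline(
            data.callsets, depth, data.truth.snp_calls,
            genome=cfg.genome, samples=data.truth.sample_ids,
        )
        removed3 = [m.record.id for m in res.removed["high_coverage_regions"]]
        assert removed3 == [victim.id]
        for rule in ("caller_overlap", "genotype_concordance", "dhffc", "del_snp_support"):
            assert res.removed[rule] == []

    def test_caller_dropout_removed_at_rule_one(self):
        cfg = error_free(small_config(seed=56))
        data = simulate_all(cfg)
        drop = {r.id for r in data.truth.sv_records[:5]}
        callsets = dict(data.callsets)
        for caller in ("delly", "manta"):
            callsets[caller] = [
                r for r in callsets[caller] if r.id.rsplit(".", 1)[0] not in drop
            ]
        res = run_filter_pipeline(
            callsets, data.depth, data.truth.snp_calls,
            genome=cfg.genome, samples=data.truth.sample_ids,
        )
        removed1 = {m.record.id for m in res.removed["caller_overlap"]}
        assert removed1 == drop
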