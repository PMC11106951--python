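import numpy as np
import pandas as pd
import pytest

import chromstate as cs
from chromstate.hmm_segmentation import _merge_segments


def seg_from_path(path, bin_size=200):
    path = np.asarray(path)
    grid = cs.BinGrid(bin_size, {"chr1": bin_size * len(path)})
    return cs.Segmentation(
        grid=grid,
        segments=_merge_segments(grid, {"chr1": path}),
        state_path={"chr1": path},
    )


class TestExtractTssRegions:
    def test_twenty_bins_is_broad(self):
        path = [8] * 5 + [1, 1, 2, 2] * 5 + [8] * 5
        regions, hist, summary = cs.extract_tss_regions(seg_from_path(path))
        (r,) = regions
        assert r.length == 4000 and r.is_broad
        assert summary["n_broad"] == 1

    def test_nineteen_bins_is_not_broad(self):
        path = [8] * 5 + [1] * 19 + [8] * 5
        (r,), _, summary = cs.extract_tss_regions(seg_from_path(path))
        assert r.length == 3800 and not r.is_broad
        assert summary["pct_broad"] == 0.0

    def test_interrupted_run_splits(self):
        path = [8, 1, 1, 3, 1, 1, 8]
        regions, _, _ = cs.extract_tss_regions(seg_from_path(path))
        assert [r.length for r in regions] == [400, 400]
        assert all(r.states_spanned <= {1, 2} for r in regions)

    def test_mixed_12_runs_are_single_regions(self):
        path = [8, 1, 2, 1, 2, 8]
        regions, _, _ = cs.extract_tss_regions(seg_from_path(path))
        assert len(regions) == 1 and regions[0].states_spanned == {1, 2}

    def test_regions_reconstruct_tss_coverage(self, small_study,
                                              small_config):
        ct = small_config.cell_types[0]
        seg = cs.Segmentation(
            grid=small_study.grid,
            segments=_merge_segments(small_study.grid,
                                     small_study.truth.state_path[ct]),
            state_path=small_study.truth.state_path[ct],
        )
        regions, hist, summary = cs.extract_tss_regions(seg)
        region_bp = sum(r.length for r in regions)
        truth_bp = sum(
            int(np.isin(p, [1, 2]).sum()) * 200
            for p in small_study.truth.state_path[ct].values()
        )
        assert region_bp == truth_bp
        assert hist.sum() == summary["n_regions"] == len(regions)

    def test_empty_tss_states_rejected(self):
        with pytest.raises(ValueError):
            cs.extract_tss_regions(seg_from_path([1, 2]), tss_states=set())


class TestGenesForRegions:
    def test_tss_window_attachment(self):
        seg = seg_from_path([8] * 10 + [1] * 10 + [8] * 30)
        (region,), _, _ = cs.extract_tss_regions(seg)
        # region spans [2000, 4000)
        inside = cs.GeneModel("in", cs.GenomicInterval("chr1", 3000, 3400, "+"))
        near = cs.GeneModel("near", cs.GenomicInterval("chr1", 4900, 5900, "+"))
        far = cs.GeneModel("far", cs.GenomicInterval("chr1", 5200, 6200, "+"))
        cs.genes_for_regions([region], [inside, near, far], window=1000)
        assert region.genes == ["in", "near"]  # far TSS is 1201 bp past end

    def test_matches_bruteforce_pairs(self, small_study, small_config):
        ct = small_config.cell_types[0]
        seg = cs.Segmentation(
            grid=small_study.grid,
            segments=_merge_segments(small_study.grid,
                                     small_study.truth.state_path[ct]),
            state_path=small_study.truth.state_path[ct],
        )
        regions, _, _ = cs.extract_tss_regions(seg)
        mapping = cs.genes_for_regions(regions, small_study.genes)
        for i, r in enumerate(regions):
            expect = sorted(
                g.gene_id
                for g in small_study.genes
                if g.interval.chrom == r.interval.chrom
                and max(0, g.tss - 1000) < r.interval.end
                and g.tss + 1001 > r.interval.start
            )
            assert sorted(mapping[i]) == expect


class TestTmm:
    def test_identical_columns(self):
        counts = pd.DataFrame({"a": [10, 20, 30, 5], "b": [10, 20, 30, 5]})
        f = cs.tmm_factors(counts)
        assert np.allclose(f, 1.0)

    def test_doubled_column_closed_form(self):
        rng = np.random.default_rng(0)
        a = rng.poisson(100, 500) + 1
        counts = pd.DataFrame({"a": a, "b": 2 * a})
        f = cs.tmm_factors(counts)
        assert f["b"] / f["a"] == pytest.approx(2.0, abs=1e-6)
        assert f["a"] == pytest.approx(1 / np.sqrt(2), abs=1e-6)
        assert np.exp(np.log(f).mean()) == pytest.approx(1.0)

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.poisson(50, size=(300, 3)) + 1,
                              columns=list("abc"))
        f1 = cs.tmm_factors(counts)
        f2 = cs.tmm_factors(counts.sample(frac=1, random_state=7))
        assert np.allclose(f1, f2)

    def test_scaling_one_sample_scales_its_factor(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(rng.poisson(80, size=(400, 3)) + 1,
                              columns=list("abc"))
        f1 = cs.tmm_factors(counts)
        counts2 = counts.copy()
        counts2["b"] = counts2["b"] * 3
        f2 = cs.tmm_factors(counts2)
        # precision weights shift slightly with the counts, so the scaling
        # law holds to ~1e-3 rather than exactly
        assert f2["b"] / f2["a"] == pytest.approx(3 * f1["b"] / f1["a"],
                                                  rel=2e-3)

    def test_all_zero_sample_rejected(self):
        counts = pd.DataFrame({"a": [1, 2], "b": [0, 0]})
        with pytest.raises(ValueError, match="zero"):
            cs.tmm_factors(counts)


class TestCpm:
    def test_reference_case(self):
        counts = pd.DataFrame({"s": [100] + [0] * 9})
        counts.loc[1] = 1e6 - 100  # library size 1e6
        mat = cs.cpm(counts, pd.Series({"s": 1.0}))
        assert mat.loc[0, "s"] == pytest.approx(100.0)

    def test_doubling_counts_with_doubled_factor_is_invariant(self):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(rng.poisson(60, size=(300, 2)) + 1,
                              columns=["a", "b"])
        f1 = cs.tmm_factors(counts)
        c1 = cs.cpm(counts, f1)
        counts2 = counts.copy()
        counts2["b"] = counts2["b"] * 2
        f2 = cs.tmm_factors(counts2)
        c2 = cs.cpm(counts2, f2)
        assert np.allclose(c1["b"], c2["b"], rtol=2e-3)

    def test_call_expressed(self):
        cpm_mat = pd.DataFrame(
            {"a1": [5.0, 0.2, 2.0], "a2": [4.0, 0.1, 0.5]},
            index=["g1", "g2", "g3"],
        )
        samples = pd.DataFrame(
            {"sample_id": ["a1", "a2"], "cell_type": ["A", "A"],
             "category": ["x", "x"]}
        )
        flags = cs.call_expressed(cpm_mat, samples)
        assert flags["A"].tolist() == [True, False, False]


class TestSpecificity:
    def test_welch_example(self):
        assert cs.welch_t([10, 12], [2, 4, 3]) == pytest.approx(6.928, abs=1e-3)

    def test_zero_when_identical(self):
        assert cs.welch_t([5, 5], [5, 5]) == 0.0

    def test_antisymmetry(self):
        a, b = [10.0, 12.0, 9.0], [2.0, 4.0, 3.0]
        assert cs.welch_t(a, b) == pytest.approx(-cs.welch_t(b, a))

    @pytest.fixture
    def expr_setup(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(100)]
        samples = pd.DataFrame(
            {
                "sample_id": ["A1", "A2", "A3", "B1", "B2", "B3"],
                "cell_type": ["A"] * 3 + ["B"] * 3,
                "category": ["catA"] * 3 + ["catB"] * 3,
            }
        )
        base = rng.lognormal(np.log(200), 0.5, size=100)
        mean = np.tile(base[:, None], (1, 6))
        mean[:10, :3] *= 8  # first 10 genes A-specific
        counts = pd.DataFrame(rng.poisson(mean), index=genes,
                              columns=samples["sample_id"])
        return counts, samples

    def test_planted_genes_rank_top(self, expr_setup):
        counts, samples = expr_setup
        res = cs.specificity_t(counts, samples, "A")
        top = {r.gene_id for r in res if r.is_specific}
        assert len(top) == 10  # ceil(0.10 * 100)
        assert len(top & {f"g{i}" for i in range(10)}) >= 9

    def test_ranks_are_permutation(self, expr_setup):
        counts, samples = expr_setup
        res = cs.specificity_t(counts, samples, "B")
        assert sorted(r.rank for r in res) == list(range(1, 101))
        ts = [r.t_stat for r in res if np.isfinite(r.t_stat)]
        assert ts == sorted(ts, reverse=True)

    def test_leave_category_out_excludes_same_category(self):
        # a third cell type in A's category must not enter the comparison
        rng = np.random.default_rng(6)
        samples = pd.DataFrame(
            {
                "sample_id": ["A1", "A2", "C1", "C2", "B1", "B2"],
                "cell_type": ["A", "A", "C", "C", "B", "B"],
                "category": ["fib", "fib", "fib", "fib", "tro", "tro"],
            }
        )
        counts = pd.DataFrame(
            rng.poisson(100, size=(50, 6)) + 1, columns=samples["sample_id"],
            index=[f"g{i}" for i in range(50)],
        )
        # gene g0 high in A and C (category-wide), not in B
        counts.loc["g0", ["A1", "A2", "C1", "C2"]] = 2000
        res_lco = cs.specificity_t(counts, samples, "A")
        res_all = cs.specificity_t(counts, samples, "A", mode="all-others")
        t_lco = next(r.t_stat for r in res_lco if r.gene_id == "g0")
        t_all = next(r.t_stat for r in res_all if r.gene_id == "g0")
        # with C excluded the contrast against B stays strong
        assert t_lco > t_all

    def test_too_few_samples_rejected(self):
        samples = pd.DataFrame(
            {"sample_id": ["A1", "B1", "B2"], "cell_type": ["A", "B", "B"],
             "category": ["a", "b", "b"]}
        )
        counts = pd.DataFrame(np.ones((5, 3)), columns=samples["sample_id"])
        with pytest.raises(ValueError):
            cs.specificity_t(counts, samples, "A")


class TestOverlap:
    def test_paper_style_proportion(self):
        broad = {f"g{i}" for i in range(52)}
        specific = {f"g{i}" for i in range(27)} | {"x1", "x2"}
        k, total, pct = cs.broad_specific_overlap(broad, specific)
        assert (k, total) == (27, 52)
        assert pct == pytest.approx(51.9, abs=0.05)

    def test_disjoint_and_subset(self):
        assert cs.broad_specific_overlap({"a"}, {"b"})[2] == 0.0
        assert cs.broad_specific_overlap({"a", "b"}, {"a", "b", "c"})[2] == 100.0

    def test_empty_broad_rejected(self):
        with pytest.raises(ValueError):
            cs.broad_specific_overlap(set(), {"a"})
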