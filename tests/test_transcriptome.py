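"""MA transform, loess normalization, moderated t, filtering, Venn."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from fermscope import transcriptome as tr
from fermscope.errors import DesignError, InsufficientDataError


class TestMATransform:
    def test_equal_channels(self):
        m, a = tr.ma_transform([1000.0], [1000.0])
        assert m[0] == pytest.approx(0.0, abs=1e-12)
        assert a[0] == pytest.approx(np.log2(1000.0), abs=1e-12)

    def test_fourfold_sample(self):
        m, _ = tr.ma_transform([4000.0], [1000.0])
        assert m[0] == pytest.approx(2.0, abs=1e-12)

    @given(
        st.lists(
            st.tuples(st.floats(1e-3, 1e6), st.floats(1e-3, 1e6)),
            min_size=1,
            max_size=30,
        )
    )
    def test_agrees_with_direct_log_arithmetic(self, pairs):
        s = np.array([p[0] for p in pairs])
        r = np.array([p[1] for p in pairs])
        m, a = tr.ma_transform(s, r)
        assert np.allclose(m, np.log2(s) - np.log2(r), atol=1e-12)
        assert np.allclose(a, (np.log2(s) + np.log2(r)) / 2, atol=1e-12)

    def test_nonpositive_intensity_flagged(self):
        m, a = tr.ma_transform([100.0, -5.0, 0.0], [100.0, 100.0, 100.0])
        assert np.isnan(m[1]) and np.isnan(m[2]) and np.isfinite(m[0])


def ma_frame(m, a, block=1):
    return pd.DataFrame({"probe_id": [f"p{i}" for i in range(len(m))],
                         "block": block, "M": m, "A": a})


class TestLoessNormalization:
    def test_constant_offset_removed(self):
        a = np.linspace(7, 13, 60)
        frame = ma_frame(np.full(60, 0.8), a)
        out = tr.printtip_loess_normalize(frame)
        assert np.allclose(out["M"], 0.0, atol=1e-9)

    def test_planted_linear_bias_removed(self):
        a = np.linspace(7, 13, 80)
        frame = ma_frame(0.5 + 0.1 * a, a)
        out = tr.printtip_loess_normalize(frame)
        interior = (a > 7.5) & (a < 12.5)
        assert np.abs(out["M"][interior]).max() < 1e-6

    def test_tips_corrected_independently(self):
        a = np.linspace(7, 13, 40)
        frame = pd.concat(
            [ma_frame(np.full(40, +1.0), a, block=1),
             ma_frame(np.full(40, -1.0), a, block=2)],
            ignore_index=True,
        )
        out = tr.printtip_loess_normalize(frame)
        assert np.allclose(out["M"], 0.0, atol=1e-9)

    def test_idempotent_on_linear_bias(self):
        a = np.linspace(7, 13, 80)
        frame = ma_frame(0.3 - 0.05 * a, a)
        once = tr.printtip_loess_normalize(frame)
        twice = tr.printtip_loess_normalize(once)
        assert np.abs(once["M"] - twice["M"]).max() < 1e-6

    def test_small_tip_group_median_centers(self):
        frame = ma_frame([1.0, 1.2, 0.8, 1.1, 0.9], np.linspace(8, 10, 5))
        with pytest.warns(UserWarning, match="median-centering"):
            out = tr.printtip_loess_normalize(frame)
        assert np.median(out["M"]) == pytest.approx(0.0, abs=1e-12)


class TestConsolidateDyeSwap:
    def make(self, m_values, swapped):
        return pd.DataFrame(
            {
                "probe_id": [f"p{i}" for i in range(len(m_values))],
                "block": 1,
                "M": m_values,
                "A": 10.0,
                "sample": "s1",
                "swapped": swapped,
            }
        )

    def test_pair_mean(self):
        # both members already in sample orientation: +1.5 and +0.5 average to 1.0
        pair = [self.make([1.5], False), self.make([0.5], True)]
        out = tr.consolidate_dye_swap(pair)
        assert out["M"].iloc[0] == pytest.approx(1.0)
        assert out["n_arrays"].iloc[0] == 2

    def test_replicate_spots_averaged_first(self):
        arr = self.make([1.0, 3.0], False)
        arr["probe_id"] = ["p0", "p0"]
        out = tr.consolidate_dye_swap([arr])
        assert out["M"].iloc[0] == pytest.approx(2.0)

    def test_partial_gene_flagged(self):
        a = self.make([1.0, 2.0], False)
        b = self.make([2.0], True)
        out = tr.consolidate_dye_swap([a, b])
        assert bool(out.loc["p1", "partial"]) is True
        assert out.loc["p1", "M"] == pytest.approx(2.0)

    def test_probe_map_collapses_to_gene(self):
        arr = self.make([1.0, 3.0], False)
        probe_map = pd.Series({"p0": "geneX", "p1": "geneX"})
        out = tr.consolidate_dye_swap([arr], probe_map=probe_map)
        assert list(out.index) == ["geneX"]
        assert out["M"].iloc[0] == pytest.approx(2.0)


class TestModeratedT:
    def test_zero_prior_df_is_ordinary_t(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 0.4, size=(200, 6))
        res = tr.moderated_t(pd.DataFrame(x), prior_df=0)
        t_ref, p_ref = stats.ttest_1samp(x, 0.0, axis=1)
        assert np.allclose(res.table["t"], t_ref, atol=1e-10)
        assert np.allclose(res.table["p"], p_ref, atol=1e-10)

    def test_infinite_prior_pools_variance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 0.4, size=(200, 6))
        res = tr.moderated_t(pd.DataFrame(x), prior_df=np.inf)
        expected = x.mean(axis=1) / np.sqrt(res.s0_sq / 6)
        assert np.allclose(res.table["t"], expected, atol=1e-10)

    def test_zero_variance_gene_gets_finite_t(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 0.3, size=(100, 4))
        x[0] = 0.5  # identical replicates, sample variance zero
        res = tr.moderated_t(pd.DataFrame(x))
        assert np.isfinite(res.table["t"].iloc[0])
        assert 0 < res.table["p"].iloc[0] <= 1

    def test_single_array_raises(self):
        with pytest.raises(InsufficientDataError):
            tr.moderated_t(pd.DataFrame(np.zeros((10, 1))))

    def test_matches_independent_reference_implementation(self, tmp_path):
        """t and p agree with the R/Bioconductor eBayes fit to ~1e-12."""
        import subprocess

        rng = np.random.default_rng(99)
        s = 0.25 * np.sqrt(5.0 / rng.chisquare(5.0, size=400))
        x = rng.normal(0.1, s[:, None], size=(400, 6))
        frame = pd.DataFrame(x)
        frame.to_csv(tmp_path / "m.tsv", sep="\t", index=False)
        script = tmp_path / "check.R"
        script.write_text(
            'suppressMessages(library(limma))\n'
            f'x <- as.matrix(read.delim("{tmp_path / "m.tsv"}"))\n'
            'fit <- eBayes(lmFit(x, design = matrix(1, ncol(x), 1)))\n'
            'write.table(data.frame(t = fit$t[, 1], p = fit$p.value[, 1]),\n'
            f'            "{tmp_path / "ref.tsv"}", sep = "\\t", row.names = FALSE)\n'
        )
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        ref = pd.read_csv(tmp_path / "ref.tsv", sep="\t")
        res = tr.moderated_t(frame)
        assert np.allclose(res.table["t"], ref["t"], atol=1e-10)
        assert np.allclose(res.table["p"], ref["p"], atol=1e-12)

    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(2024)
        s = 0.3 * np.sqrt(4.0 / rng.chisquare(4.0, size=5000))
        x = rng.normal(0.0, s[:, None], size=(5000, 6))
        res = tr.moderated_t(pd.DataFrame(x))
        frac = float((res.table["p"] < 0.05).mean())
        assert frac == pytest.approx(0.05, abs=0.01)


class TestFilterAndVenn:
    def long(self, rows):
        return pd.DataFrame(rows, columns=["gene", "strain", "M", "A", "p"])

    def test_boundary_a_excluded(self):
        res = self.long([("g1", "S", 2.0, 7.5, 0.001)])
        flags = tr.filter_de(res)
        assert not flags["in_union"].any()

    def test_single_strain_union_membership(self):
        res = self.long(
            [("g1", "S1", 1.2, 8.0, 0.01), ("g1", "S2", 0.2, 8.0, 0.6)]
        )
        flags = tr.filter_de(res)
        assert bool(flags.loc["g1", "S1"]) and not bool(flags.loc["g1", "S2"])
        assert bool(flags.loc["g1", "in_union"])

    def test_constructed_union_size(self):
        rng = np.random.default_rng(3)
        rows = []
        for i in range(30):  # planted passers
            rows.append((f"de{i:02d}", "S1", 2.0, 9.0, 1e-4))
        for i in range(100):  # nulls well under the M threshold
            rows.append((f"null{i:03d}", "S1", float(rng.uniform(-0.5, 0.5)), 9.0, 0.5))
        flags = tr.filter_de(self.long(rows))
        assert int(flags["in_union"].sum()) == 30

    def test_venn_all_false(self):
        flags = pd.DataFrame(False, index=["g1", "g2"], columns=["S1", "S2"])
        venn = tr.venn_partition(flags, universe=["g1", "g2", "g3"])
        assert venn.complement == 3 and venn.union == 0

    @given(st.integers(0, 2**31 - 1))
    def test_venn_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        universe = [f"g{i}" for i in range(200)]
        flags = pd.DataFrame(
            rng.random((200, 3)) < 0.2, index=universe, columns=["S1", "S2", "S3"]
        )
        venn = tr.venn_partition(flags, universe)
        # exhaustive enumeration oracle
        for combo, count in venn.region_counts.items():
            expected = 0
            for g in universe:
                members = {s for s in ("S1", "S2", "S3") if flags.loc[g, s]}
                if members == set(combo):
                    expected += 1
            assert count == expected
        assert sum(venn.region_counts.values()) + venn.complement == 200

    def test_flags_outside_universe_raise(self):
        flags = pd.DataFrame(True, index=["gX"], columns=["S1"])
        with pytest.raises(DesignError):
            tr.venn_partition(flags, universe=["g1"])


class TestIntersectPlatforms:
    def test_identical_lists(self):
        assert tr.intersect_platforms(["a", "b"], ["b", "a"]) == ["a", "b"]

    def test_disjoint_lists(self):
        assert tr.intersect_platforms(["a"], ["b"]) == []

    def test_case_normalized_and_deduplicated(self):
        assert tr.intersect_platforms(["GeneA", "genea", "b"], ["GENEA"]) == ["genea"]

    def test_empty_input_raises(self):
        with pytest.raises(DesignError):
            tr.intersect_platforms([], ["a"])

    @given(st.integers(0, 2**31 - 1))
    def test_matches_membership_scan(self, seed):
        rng = np.random.default_rng(seed)
        pool = [f"g{i}" for i in range(50)]
        a = list(rng.choice(pool, size=30, replace=True))
        b = list(rng.choice(pool, size=30, replace=True))
        expected = sorted({x for x in map(str.lower, a) if x in set(map(str.lower, b))})
        assert tr.intersect_platforms(a, b) == expected


class TestPipelineEquivariance:
    def test_global_dye_swap_leaves_consolidated_m_unchanged(self):
        from fermscope.synthetic_data import Hybridization, simulate_microarray
        from fermscope.synthetic_data.arrays import ArrayTruth

        genes = [f"g{i:02d}" for i in range(30)]
        truth = ArrayTruth(
            platform_genes={"K12": genes},
            lfc=pd.DataFrame({"S": np.linspace(-2, 2, 30)}, index=genes),
            base_log2=pd.Series(np.linspace(8, 12, 30), index=genes),
            dye_bias=np.array([[0.2, 0.03]] * 2),
            n_printtips=2,
            spot_noise_sd=0.0,
            seed=0,
        )

        def consolidated(swap_first):
            design = [
                Hybridization("s1", "S", swapped=swap_first, platform="K12"),
                Hybridization("s1", "S", swapped=not swap_first, platform="K12"),
            ]
            scans = simulate_microarray(truth, design)
            mas = [tr.spot_table_to_ma(f) for f in scans.values()]
            return tr.consolidate_dye_swap(mas)["M"]

        a = consolidated(False)
        b = consolidated(True)
        assert np.allclose(a.to_numpy(), b.to_numpy(), atol=1e-12)
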