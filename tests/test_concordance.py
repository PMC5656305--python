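"""Replicate-concordance cascade: merging, counting, normalization, filtering, QC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import chromconverge as cc
from chromconverge.concordance import map_regions_to_sources


def intervals_df(triples):
    return pd.DataFrame(triples, columns=["chrom", "start", "end"])


class TestMergeRegions:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ([("chr1", 10, 20)], [("chr1", 15, 30)], [(10, 30)]),
            ([("chr1", 10, 20)], [("chr1", 20, 30)], [(10, 30)]),  # book-ended
            ([("chr1", 10, 20)], [], [(10, 20)]),
            ([("chr1", 10, 20), ("chr1", 40, 50)], [("chr1", 15, 45)], [(10, 50)]),
        ],
    )
    def test_merge_examples(self, a, b, expected):
        merged = cc.merge_regions(intervals_df(a), intervals_df(b))
        assert list(zip(merged["start"], merged["end"])) == expected

    def test_malformed_interval_named_in_error(self):
        with pytest.raises(ValueError, match="chr1:20-20"):
            cc.merge_regions(intervals_df([("chr1", 20, 20)]), intervals_df([]))

    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["chr1", "chr2"]),
                st.integers(0, 500),
                st.integers(1, 200),
            ),
            max_size=30,
        ),
        st.lists(
            st.tuples(
                st.sampled_from(["chr1", "chr2"]),
                st.integers(0, 500),
                st.integers(1, 200),
            ),
            max_size=30,
        ),
    )
    def test_merge_preserves_union_and_is_disjoint(self, a, b):
        df_a = intervals_df([(c, s, s + w) for c, s, w in a])
        df_b = intervals_df([(c, s, s + w) for c, s, w in b])
        merged = cc.merge_regions(df_a, df_b)
        # disjoint and sorted, with a strict gap between consecutive blocks
        for _, sub in merged.groupby("chrom"):
            starts, ends = sub["start"].to_numpy(), sub["end"].to_numpy()
            assert (starts[1:] > ends[:-1]).all()
        # base-level union conservation
        def cover(df):
            covered = set()
            for _, r in df.iterrows():
                covered.update((r["chrom"], p) for p in range(r["start"], r["end"]))
            return covered
        assert cover(merged) == cover(df_a) | cover(df_b)

    def test_order_invariance(self, peak_simulation):
        rep1, rep2, _, _ = peak_simulation
        shuffled = rep1.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = cc.merge_regions(rep1, rep2).drop(columns="name")
        b = cc.merge_regions(shuffled, rep2).drop(columns="name")
        pd.testing.assert_frame_equal(a, b)


class TestCountReads:
    @pytest.mark.parametrize(
        "positions, expected",
        [
            ([5, 15, 25], 1),
            ([10, 19, 20], 2),  # half-open: 20 excluded, 10 included
            ([], 0),
        ],
    )
    def test_boundary_convention(self, positions, expected):
        regions = pd.DataFrame(
            {"chrom": ["chr1"], "start": [10], "end": [20], "name": ["r0"]}
        )
        reads = {"s": pd.DataFrame({"chrom": ["chr1"] * len(positions), "pos": positions})}
        counts = cc.count_reads_in_regions(regions, reads)
        assert counts.loc["r0", "s"] == expected

    def test_each_read_counted_at_most_once(self, peak_simulation):
        rep1, rep2, reads, _ = peak_simulation
        merged = cc.merge_regions(rep1, rep2)
        counts = cc.count_reads_in_regions(merged, reads)
        for sample, table in reads.items():
            assert counts[sample].sum() <= len(table)


class TestNormalization:
    def test_equal_libraries_are_identity(self):
        raw = pd.DataFrame({"rep1": [100], "rep2": [100]})
        norm = cc.normalize_to_library_size(raw, {"rep1": 1e6, "rep2": 1e6})
        pd.testing.assert_frame_equal(norm, raw.astype(float))

    def test_rescaling_to_mean_library(self):
        # hand arithmetic: mean library 1.5e6 -> 100*1.5 and 200*0.75
        raw = pd.DataFrame({"rep1": [100], "rep2": [200]})
        norm = cc.normalize_to_library_size(raw, {"rep1": 1e6, "rep2": 2e6})
        assert norm.loc[0, "rep1"] == pytest.approx(150.0)
        assert norm.loc[0, "rep2"] == pytest.approx(150.0)

    def test_zero_count_stays_zero(self):
        raw = pd.DataFrame({"rep1": [0], "rep2": [50]})
        norm = cc.normalize_to_library_size(raw, {"rep1": 2e6, "rep2": 1e6})
        assert norm.loc[0, "rep1"] == 0

    def test_zero_library_size_rejected(self):
        raw = pd.DataFrame({"rep1": [1], "rep2": [1]})
        with pytest.raises(ValueError):
            cc.normalize_to_library_size(raw, {"rep1": 0, "rep2": 1e6})


class TestConcordanceFilter:
    def make(self, pairs):
        return pd.DataFrame(
            {
                "chrom": "chr1",
                "start": range(0, 100 * len(pairs), 100),
                "end": range(50, 100 * len(pairs) + 50, 100),
                "norm_rep1": [p[0] for p in pairs],
                "norm_rep2": [p[1] for p in pairs],
            }
        )

    def test_rule_application_and_flags(self):
        # (150, 90): mean 120 > 100, ratio 1.67 < 2 -> kept
        # (300, 100): ratio 3 -> high_ratio
        # (120, 80): mean exactly 100 -> rejected (strict threshold)
        kept, rejected = cc.concordance_filter(
            self.make([(150, 90), (300, 100), (120, 80)])
        )
        assert list(kept["norm_rep1"]) == [150]
        flags = dict(zip(rejected["norm_rep1"], rejected["qc_flags"]))
        assert flags[300] == "high_ratio"
        assert flags[120] == "low_mean"

    def test_boundary_mean_exactly_at_threshold_rejected(self):
        kept, rejected = cc.concordance_filter(self.make([(100, 100)]))
        assert len(kept) == 0 and rejected["qc_flags"].iloc[0] == "low_mean"

    def test_one_zero_count_is_infinite_ratio(self):
        kept, rejected = cc.concordance_filter(self.make([(0, 500)]))
        assert len(kept) == 0
        assert np.isinf(rejected["ratio"].iloc[0])
        assert "high_ratio" in rejected["qc_flags"].iloc[0]

    def test_both_zero_flagged_low_mean(self):
        _, rejected = cc.concordance_filter(self.make([(0, 0)]))
        assert "low_mean" in rejected["qc_flags"].iloc[0]

    @given(
        st.lists(
            st.tuples(st.floats(0, 1000), st.floats(0, 1000)), min_size=1, max_size=50
        )
    )
    def test_conservation_kept_plus_rejected(self, pairs):
        peaks = self.make(pairs)
        kept, rejected = cc.concordance_filter(peaks)
        assert len(kept) + len(rejected) == len(peaks)
        assert (kept["qc_flags"] == "").all()
        assert (rejected["qc_flags"] != "").all()


class TestClusterQC:
    def _synthetic(self, n_strong=50, n_noise=50, seed=0):
        rng = np.random.default_rng(seed)
        rows, read_rows = [], []
        for i in range(n_strong + n_noise):
            centre = 5000 * (i + 1)
            rows.append(("chr1", centre - 250, centre + 250, f"p{i:03d}"))
            if i < n_strong:
                pos = rng.normal(centre, 40, size=400).astype(int)
            else:
                pos = rng.integers(centre - 500, centre + 500, size=40)
            read_rows.extend(("chr1", int(p)) for p in pos)
        peaks = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
        reads = {"rep1": pd.DataFrame(read_rows, columns=["chrom", "pos"])}
        return peaks, reads

    def test_identical_profiles_flag_nothing(self):
        peaks, reads = self._synthetic(n_strong=20, n_noise=0, seed=1)
        labels, flagged = cc.cluster_qc(peaks, reads, k=2, seed=0)
        assert flagged == []

    def test_noise_cluster_is_flagged(self):
        peaks, reads = self._synthetic(seed=2)
        labels, flagged = cc.cluster_qc(peaks, reads, k=2, seed=0)
        assert len(flagged) == 1
        flagged_peaks = set(labels.index[labels.isin(flagged)])
        noise = set(range(50, 100))
        agreement = len(flagged_peaks & noise) / 50
        assert agreement >= 0.95

    def test_k_larger_than_peak_count_rejected(self):
        peaks, reads = self._synthetic(n_strong=3, n_noise=0)
        with pytest.raises(ValueError, match="exceeds"):
            cc.cluster_qc(peaks, reads, k=5)


class TestFullCascade:
    def test_recovery_on_default_conditions(self, peak_simulation):
        rep1, rep2, reads, truth = peak_simulation
        kept, rejected = cc.run_concordance(rep1, rep2, reads)
        mapping = map_regions_to_sources(
            pd.concat([kept, rejected]), rep1, rep2
        )
        kept_sources = set().union(*(mapping[n] for n in kept["name"]))
        true_set, spurious = set(truth.true_peaks), set(truth.spurious_peaks)
        assert len(true_set & kept_sources) / len(true_set) >= 0.95
        assert len(spurious - kept_sources) / len(spurious) >= 0.90

    def test_stage_conservation(self, peak_simulation):
        rep1, rep2, reads, _ = peak_simulation
        merged = cc.merge_regions(rep1, rep2)
        kept, rejected = cc.run_concordance(rep1, rep2, reads)
        assert len(kept) + len(rejected) == len(merged)

    def test_chromosome_exclusion(self, peak_simulation):
        rep1, rep2, reads, _ = peak_simulation
        kept, rejected = cc.run_concordance(
            rep1, rep2, reads, exclude_chroms=("chr1",)
        )
        table = pd.concat([kept, rejected])
        assert not (table["chrom"] == "chr1").any()
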