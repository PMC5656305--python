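"""Synthetic-data generators: determinism, capacity, truth consistency, NB calibration."""

import numpy as np
import pandas as pd
import pytest

import chromconverge as cc
from chromconverge.simulate import CapacityError


class TestMakeGenome:
    def test_zero_genes_gives_valid_layout_and_empty_annotation(self):
        layout, annotation = cc.make_genome(1, 1_000_000, 0, seed=1)
        assert layout.total_length == 1_000_000
        assert annotation.empty

    def test_same_seed_gives_identical_tables(self):
        _, a = cc.make_genome(1, 1_000_000, 100, seed=7)
        _, b = cc.make_genome(1, 1_000_000, 100, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_different_seed_differs(self):
        _, a = cc.make_genome(1, 1_000_000, 100, seed=7)
        _, b = cc.make_genome(1, 1_000_000, 100, seed=8)
        assert not a.equals(b)

    def test_overfull_genome_raises_capacity_error(self):
        with pytest.raises(CapacityError):
            cc.make_genome(1, 10_000, 100, seed=1)

    def test_gene_geometry_invariants(self, small_genome):
        layout, annotation = small_genome
        assert annotation["strand"].isin(["+", "-"]).all()
        for _, g in annotation.iterrows():
            length = layout.chrom_lengths[g["chrom"]]
            assert 0 <= g["tss"] < length and 0 <= g["tes"] < length
        minus = annotation[annotation["strand"] == "-"]
        assert (minus["tss"] > minus["tes"]).all()
        plus = annotation[annotation["strand"] == "+"]
        assert (plus["tss"] < plus["tes"]).all()

    def test_gene_bodies_do_not_overlap(self, small_genome):
        _, annotation = small_genome
        for _, sub in annotation.groupby("chrom"):
            lo = np.minimum(sub["tss"], sub["tes"]).sort_values().to_numpy()
            hi = np.maximum(sub["tss"], sub["tes"]).to_numpy()[
                np.argsort(np.minimum(sub["tss"], sub["tes"]).to_numpy())
            ]
            assert (lo[1:] > hi[:-1]).all()


class TestSimulatePeakReplicates:
    def test_promoter_peaks_sit_at_tss_with_signal(self, small_genome):
        layout, annotation = small_genome
        rep1, rep2, reads, truth = cc.simulate_peak_replicates(
            annotation, layout, 50, 0, 0, 0, mean_depth=500, seed=3
        )
        assert len(rep1) == 50 and len(truth.true_peaks) == 50
        tss_by_chrom = {c: s["tss"].to_numpy() for c, s in annotation.groupby("chrom")}
        for _, p in rep1.iterrows():
            mid = (p["start"] + p["end"]) // 2
            assert np.abs(tss_by_chrom[p["chrom"]] - mid).min() <= 1000
        counts = cc.count_reads_in_regions(
            rep1.assign(name=rep1["name"]), reads
        )
        assert (counts > 0).all().all()

    def test_discordant_regions_have_large_replicate_ratio(self, small_genome):
        # Monte-Carlo oracle (200k NB draw pairs at means 500/1500, d=0.05):
        # P(max/min >= 2) = 0.897. With 20 regions the observed fraction must
        # sit above the binomial lower bound for that probability (~0.75), and
        # the mean ratio must exceed the concordance cutoff of 2.
        layout, annotation = small_genome
        rep1, rep2, reads, truth = cc.simulate_peak_replicates(
            annotation, layout, 0, 0, 0, 20, mean_depth=500, dispersion=0.05, seed=5
        )
        merged = cc.merge_regions(rep1, rep2)
        raw = cc.count_reads_in_regions(merged, reads)
        libs = {s: max(len(t), 1) for s, t in reads.items()}
        norm = cc.normalize_to_library_size(raw, libs)
        ratio = norm.max(axis=1) / norm.min(axis=1)
        assert (ratio >= 2).mean() >= 0.75
        assert ratio.mean() > 2.0

    def test_all_zero_request_gives_empty_outputs(self, small_genome):
        layout, annotation = small_genome
        rep1, rep2, reads, truth = cc.simulate_peak_replicates(
            annotation, layout, 0, 0, 0, 0, seed=1
        )
        assert rep1.empty and rep2.empty
        assert not truth.true_peaks and not truth.spurious_peaks

    def test_truth_ids_match_tables_exactly(self, peak_simulation):
        rep1, rep2, _, truth = peak_simulation
        table_ids = set(rep1["name"])
        assert table_ids == set(rep2["name"])
        truth_ids = set(truth.true_peaks) | set(truth.spurious_peaks)
        assert truth_ids == table_ids

    def test_determinism(self, small_genome):
        layout, annotation = small_genome
        a = cc.simulate_peak_replicates(annotation, layout, 10, 5, 5, 5, seed=9)
        b = cc.simulate_peak_replicates(annotation, layout, 10, 5, 5, 5, seed=9)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[2]["rep1"], b[2]["rep1"])


class TestSimulateCounts:
    def test_zero_de_fraction_gives_no_de_truth(self):
        _, truth = cc.simulate_counts(200, 2, de_fraction=0.0,
                                      shared_de_fraction=0.0, seed=1)
        for table in truth.de_truth.values():
            assert (table["status"] == "null").all()
            assert (table["true_log2fc"] == 0).all()

    def test_de_and_shared_gene_counts_are_exact(self):
        matrices, truth = cc.simulate_counts(
            1000, 3, de_fraction=0.1, shared_de_fraction=0.05, seed=2
        )
        de_sets = {
            c: set(t.loc[t["status"] != "null", "gene_id"])
            for c, t in truth.de_truth.items()
        }
        a, b = de_sets.values()
        assert len(a) == 100 and len(b) == 100
        assert len(a & b) == 50

    def test_zero_lfc_with_de_genes_is_rejected(self):
        with pytest.raises(ValueError, match="contradictory"):
            cc.simulate_counts(100, 2, de_fraction=0.1, lfc=0.0, seed=1)

    def test_shared_fraction_cannot_exceed_de_fraction(self):
        with pytest.raises(ValueError):
            cc.simulate_counts(100, 2, de_fraction=0.05, shared_de_fraction=0.1, seed=1)

    def test_lowly_expressed_genes_fall_below_background_threshold(self):
        matrices, _ = cc.simulate_counts(
            1000, 3, de_fraction=0.0, shared_de_fraction=0.0,
            lowly_expressed_fraction=0.2, seed=3,
        )
        cm = matrices["trr"]
        totals = cm.counts.sum(axis=1)
        assert (totals < 10).mean() >= 0.15  # ~200 genes planted low

    def test_nb_marginal_variance_matches_dispersion(self):
        # var ~ mu + d*mu^2: the mean method-of-moments dispersion across
        # thousands of null genes recovers d within Monte-Carlo error
        d = 0.05
        matrices, _ = cc.simulate_counts(
            5000, 4, de_fraction=0.0, shared_de_fraction=0.0,
            lowly_expressed_fraction=0.0, dispersion=d, seed=4,
        )
        counts = matrices["trr"].counts.to_numpy(dtype=float)
        mu = counts.mean(axis=1)
        var = counts.var(axis=1, ddof=1)
        keep = mu > 50
        est = np.mean((var[keep] - mu[keep]) / mu[keep] ** 2)
        assert est == pytest.approx(d, abs=0.01)

    def test_determinism(self):
        a, _ = cc.simulate_counts(300, 2, seed=6)
        b, _ = cc.simulate_counts(300, 2, seed=6)
        pd.testing.assert_frame_equal(a["trr"].counts, b["trr"].counts)


class TestSimulateCourtship:
    def test_group_sizes_exact_and_reproducible(self):
        sizes = {"control": (56, 59), "knockdown": (60, 62)}
        a, _ = cc.simulate_courtship(sizes, seed=8)
        b, _ = cc.simulate_courtship(sizes, seed=8)
        pd.testing.assert_frame_equal(a, b)
        counts = a.groupby(["genotype", "condition"]).size()
        assert counts[("control", "naive")] == 56
        assert counts[("control", "trained")] == 59
        assert counts[("knockdown", "naive")] == 60
        assert counts[("knockdown", "trained")] == 62

    def test_true_li_recorded_from_means(self):
        _, truth = cc.simulate_courtship(
            {"A": (10, 10), "B": (10, 10)},
            naive_mean=0.8,
            trained_mean_by_genotype={"A": 0.2, "B": 0.8},
            seed=1,
        )
        li = truth.courtship_truth.set_index("genotype")["true_li"]
        assert li["A"] == pytest.approx(0.75)
        assert li["B"] == pytest.approx(0.0)

    def test_cis_bounded_and_centred(self):
        table, _ = cc.simulate_courtship(
            {"A": (200, 200)}, naive_mean=0.7,
            trained_mean_by_genotype={"A": 0.3}, concentration=20.0, seed=2,
        )
        assert table["ci"].between(0, 1).all()
        means = table.groupby("condition")["ci"].mean()
        assert means["naive"] == pytest.approx(0.7, abs=0.05)
        assert means["trained"] == pytest.approx(0.3, abs=0.05)

    def test_invalid_mean_rejected(self):
        with pytest.raises(ValueError):
            cc.simulate_courtship({"A": (5, 5)}, naive_mean=1.2, seed=1)
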