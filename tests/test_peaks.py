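"""Peak intersection, peak-gene assignment, binning, features, DE and SEs."""

import numpy as np
import pandas as pd
import pytest

from rbomics.peaks import (
    BIN_DISTAL, BIN_FAR, BIN_MID, BIN_PROMOTER, annotate_peak_features,
    assign_peaks_to_genes, distance_bin, high_confidence_peaks,
    integrate_with_de, super_enhancer_overlap,
)
from rbomics.simulate import simulate_integration_fixture

from oracles import naive_bin, naive_feature, naive_high_confidence, naive_nearest_gene


def bed(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def random_bed(rng, n, span=100_000, width=500):
    starts = rng.integers(0, span, n)
    chroms = rng.choice(["chr1", "chr2"], n)
    return bed(sorted(zip(chroms, starts, starts + rng.integers(50, width, n))))


class TestHighConfidence:
    def test_identical_sets_self_intersection(self):
        a = bed([("chr1", 10, 50), ("chr1", 100, 150)])
        out = high_confidence_peaks(a, a.copy())
        pd.testing.assert_frame_equal(out, a)

    def test_disjoint_sets_empty(self):
        a = bed([("chr1", 10, 50)])
        b = bed([("chr1", 60, 80), ("chr2", 10, 50)])
        assert high_confidence_peaks(a, b).empty

    def test_union_span_of_overlapping_pair(self):
        a = bed([("chr1", 10, 50)])
        b = bed([("chr1", 40, 90)])
        out = high_confidence_peaks(a, b)
        assert out.iloc[0].tolist() == ["chr1", 10, 90]

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(0)
        a, b = random_bed(rng, 30), random_bed(rng, 30)
        ab = high_confidence_peaks(a, b)
        ba = high_confidence_peaks(b, a)
        pd.testing.assert_frame_equal(ab, ba)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_quadratic_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a, b = random_bed(rng, 40), random_bed(rng, 40)
        got = sorted(map(tuple, high_confidence_peaks(a, b).itertuples(index=False)))
        expected = naive_high_confidence(
            list(map(tuple, a.itertuples(index=False))),
            list(map(tuple, b.itertuples(index=False))))
        assert got == expected

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            high_confidence_peaks(bed([("chr1", 50, 50)]), bed([("chr1", 0, 10)]))


class TestDistanceBin:
    @pytest.mark.parametrize("d, b", [
        (0, BIN_PROMOTER), (3000, BIN_PROMOTER), (-3000, BIN_PROMOTER),
        (3001, BIN_MID), (10_000, BIN_MID), (10_001, BIN_DISTAL),
        (50_000, BIN_DISTAL), (100_000, BIN_DISTAL), (100_001, BIN_FAR)])
    def test_edges(self, d, b):
        assert distance_bin(d) == b


class TestAssignPeaksToGenes:
    GENES = pd.DataFrame({
        "gene_id": ["GA", "GB"], "chrom": ["chr1", "chr1"],
        "tss": [100_001, 400_001], "strand": ["+", "-"],
    })

    def _one_peak(self, center):
        return bed([("chr1", center - 100, center + 100)])

    def test_promoter_window_plus_strand(self):
        links = assign_peaks_to_genes(self._one_peak(102_000), self.GENES)
        row = links.iloc[0]
        assert row.gene_id == "GA" and row.signed_distance == 2000
        assert row.bin == BIN_PROMOTER

    def test_distal_bin(self):
        links = assign_peaks_to_genes(self._one_peak(150_000), self.GENES)
        assert links.iloc[0].bin == BIN_DISTAL
        assert links.iloc[0].signed_distance == 50_000

    def test_minus_strand_downstream_is_positive(self):
        # peak 2 kb 3' of a minus-strand TSS lies at lower coordinates
        links = assign_peaks_to_genes(self._one_peak(398_000), self.GENES)
        row = links.iloc[0]
        assert row.gene_id == "GB" and row.signed_distance == 2000
        assert row.bin == BIN_PROMOTER

    def test_chromosome_without_genes(self):
        links = assign_peaks_to_genes(bed([("chrX", 0, 200)]), self.GENES)
        row = links.iloc[0]
        assert row.gene_id is None and row.bin == BIN_FAR

    def test_tie_breaks_lexicographically(self):
        genes = pd.DataFrame({
            "gene_id": ["ZZ", "AA"], "chrom": "chr1",
            "tss": [1001, 3001], "strand": ["+", "+"]})
        links = assign_peaks_to_genes(self._one_peak(2000), genes)
        assert links.iloc[0].gene_id == "AA"

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        n_genes, n_peaks = 25, 60
        genes = pd.DataFrame({
            "gene_id": [f"G{i:03d}" for i in range(n_genes)],
            "chrom": rng.choice(["chr1", "chr2"], n_genes),
            "tss": rng.integers(1, 500_000, n_genes),
            "strand": rng.choice(["+", "-"], n_genes),
        })
        peaks = random_bed(rng, n_peaks, span=500_000)
        links = assign_peaks_to_genes(peaks, genes)
        by_chrom = {
            c: [(g.gene_id, int(g.tss) - 1, g.strand) for g in grp.itertuples()]
            for c, grp in genes.groupby("chrom")}
        for peak, link in zip(peaks.itertuples(), links.itertuples()):
            center = (peak.start + peak.end) // 2
            gid, signed = naive_nearest_gene(center, by_chrom[peak.chrom])
            assert link.gene_id == gid
            assert link.signed_distance == signed
            assert link.bin == naive_bin(signed)


class TestAnnotateFeatures:
    def test_promoter_beats_exon(self):
        genes = pd.DataFrame({"gene_id": ["G1"], "chrom": ["chr1"],
                              "tss": [5001], "strand": ["+"]})
        structures = pd.DataFrame(
            [("chr1", 4000, 6000, "exon")],
            columns=["chrom", "start", "end", "feature"])
        peaks = bed([("chr1", 4900, 5100)])
        assert annotate_peak_features(peaks, genes, structures).iloc[0] == "promoter"

    def test_intergenic_fallback(self):
        genes = pd.DataFrame({"gene_id": ["G1"], "chrom": ["chr1"],
                              "tss": [5001], "strand": ["+"]})
        peaks = bed([("chr1", 500_000, 500_200)])
        assert annotate_peak_features(peaks, genes).iloc[0] == "intergenic"

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_priority_oracle(self, seed):
        rng = np.random.default_rng(200 + seed)
        genes = pd.DataFrame({
            "gene_id": [f"G{i}" for i in range(10)], "chrom": "chr1",
            "tss": rng.integers(1, 200_000, 10), "strand": "+"})
        feats = rng.choice(["utr5", "utr3", "exon", "intron"], 40)
        starts = rng.integers(0, 200_000, 40)
        structures = pd.DataFrame({
            "chrom": "chr1", "start": starts,
            "end": starts + rng.integers(100, 5000, 40), "feature": feats})
        peaks = random_bed(rng, 50, span=200_000)
        got = annotate_peak_features(peaks, genes, structures)
        tss0 = genes["tss"].to_numpy() - 1
        intervals = [(s, e, f) for s, e, f in
                     zip(structures.start, structures.end, structures.feature)]
        intervals += [(max(t - 3000, 0), t + 3001, "promoter") for t in tss0]
        for peak, label in zip(peaks.itertuples(), got):
            center = (peak.start + peak.end) // 2
            expected = naive_feature(center, intervals) \
                if peak.chrom == "chr1" else "intergenic"
            assert label == expected


class TestIntegrateWithDE:
    def _fixture(self):
        fx = simulate_integration_fixture(80, 160, seed=7, replicate_overlap=1.0)
        links = assign_peaks_to_genes(fx.peaks_a, fx.genes)
        return fx, links

    def test_no_significant_genes_means_no_linked_peaks(self):
        fx, links = self._fixture()
        de = fx.de.assign(fdr=0.9)
        _, summary = integrate_with_de(links, de)
        assert summary.n_de_linked_peaks == 0

    def test_direction_counts_partition_linked_peaks(self):
        fx, links = self._fixture()
        _, summary = integrate_with_de(links, fx.de)
        assert summary.n_up_peaks + summary.n_down_peaks == summary.n_de_linked_peaks
        assert summary.n_up_genes + summary.n_down_genes == summary.n_de_genes_with_peak
        assert sum(summary.bin_counts.values()) == summary.n_de_linked_peaks

    def test_planted_fixture_exact_recovery(self):
        fx, links = self._fixture()
        labeled, summary = integrate_with_de(links, fx.de)
        sig = fx.de[fx.de.fdr < 0.05].set_index("gene_id")
        expected_dir = [
            "none" if g not in sig.index
            else ("up" if sig.loc[g, "log_fold_change"] > 0 else "down")
            for g in fx.truth["gene_id"]]
        assert labeled["de_direction"].tolist() == expected_dir

    def test_duplicate_gene_id_is_error(self):
        fx, links = self._fixture()
        dup = pd.concat([fx.de, fx.de.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValueError):
            integrate_with_de(links, dup)


class TestSuperEnhancers:
    def test_two_of_four(self):
        peaks = bed([("chr1", 100, 200), ("chr1", 5000, 5100)])
        ses = bed([("chr1", 0, 300), ("chr1", 4900, 5200),
                   ("chr1", 9000, 9500), ("chr2", 0, 1000)])
        assert super_enhancer_overlap(peaks, ses) == (2, 4, 50.0)

    def test_no_peaks(self):
        ses = bed([("chr1", 0, 300), ("chr1", 400, 500)])
        assert super_enhancer_overlap(bed([]), ses) == (0, 2, 0.0)

    def test_reported_fraction_arithmetic(self):
        # 446 of 1834 single-base SEs hit by one wide peak -> 24.3%
        ses = bed([("chr1", i * 10, i * 10 + 5) for i in range(1834)])
        peaks = bed([("chr1", 0, 446 * 10 - 5)])
        n_hit, n_total, pct = super_enhancer_overlap(peaks, ses)
        assert (n_hit, n_total, pct) == (446, 1834, 24.3)
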