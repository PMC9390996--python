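"""Generator contracts: determinism, planted truth, stated distributions."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chisquare

from rbomics.cnv import arm_call_table, arm_score
from rbomics.peaks import assign_peaks_to_genes, high_confidence_peaks
from rbomics.simulate import (
    CohortSimConfig, simulate_arm_segments, simulate_count_matrix,
    simulate_integration_fixture, simulate_variant_cohort,
)


class TestDeterminism:
    def test_variant_cohort(self):
        cfg = CohortSimConfig(n_tumors=8, seed=3)
        t1, p1 = simulate_variant_cohort(cfg)
        t2, p2 = simulate_variant_cohort(CohortSimConfig(n_tumors=8, seed=3))
        pd.testing.assert_frame_equal(t1, t2)
        assert dict(p1.items()) == dict(p2.items())

    def test_arm_segments(self):
        s1, t1 = simulate_arm_segments(4, {("S001", "6p"): 0.4}, 0.1, seed=5)
        s2, t2 = simulate_arm_segments(4, {("S001", "6p"): 0.4}, 0.1, seed=5)
        pd.testing.assert_frame_equal(s1, s2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_integration_fixture(self):
        f1 = simulate_integration_fixture(30, 60, seed=6)
        f2 = simulate_integration_fixture(30, 60, seed=6)
        for attr in ("peaks_a", "peaks_b", "genes", "de",
                     "super_enhancers", "truth"):
            pd.testing.assert_frame_equal(getattr(f1, attr), getattr(f2, attr))

    def test_count_matrix(self):
        m1, b1, g1, l1 = simulate_count_matrix(60, 200, seed=7)
        m2, b2, g2, l2 = simulate_count_matrix(60, 200, seed=7)
        assert (m1 != m2).nnz == 0
        assert b1 == b2 and g1 == g2
        pd.testing.assert_frame_equal(l1, l2)


class TestVariantCohort:
    def test_zero_rates_empty(self):
        cfg = CohortSimConfig(n_tumors=10, somatic_rate=0, germline_rate=0,
                              artifact_rate=0, seed=1)
        table, pon = simulate_variant_cohort(cfg)
        assert table.empty and len(pon) == 0

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            CohortSimConfig(somatic_rate=-1)
        with pytest.raises(ValueError):
            CohortSimConfig(frac_matched=1.5)

    def test_somatic_rate_within_three_se(self):
        cfg = CohortSimConfig(n_tumors=20, somatic_rate=10, germline_rate=0,
                              artifact_rate=0, seed=21)
        table, _ = simulate_variant_cohort(cfg)
        n = len(table[table.truth_class == "somatic"])
        # Poisson(10) per sample, 20 samples: SE of the mean = sqrt(10/20)
        mean = n / 20
        assert abs(mean - 10) <= 3 * np.sqrt(10 / 20)

    def test_keys_unique_per_sample(self, small_cohort):
        table, _ = small_cohort
        keys = table[["sample_id", "chrom", "pos", "ref", "alt"]]
        assert not keys.duplicated().any()

    def test_somatic_never_in_panel(self, small_cohort):
        table, pon = small_cohort
        somatic = table[table.truth_class == "somatic"]
        for r in somatic.itertuples():
            assert (r.chrom, r.pos, r.ref, r.alt) not in pon

    def test_germline_in_matched_blood(self, small_cohort):
        table, _ = small_cohort
        matched_germ = table[(table.truth_class == "germline")
                             & table.matched_normal_available]
        assert (matched_germ["blood_alt_reads"] > 1).mean() > 0.95

    def test_class_counts_follow_rates(self):
        """Chi-square goodness of fit of truth-class totals over many seeds."""
        rates = {"somatic": 5.0, "germline": 10.0, "artifact": 3.0}
        totals = {c: 0 for c in rates}
        for seed in range(100):
            cfg = CohortSimConfig(n_tumors=3, frac_matched=1.0,
                                  somatic_rate=rates["somatic"],
                                  germline_rate=rates["germline"],
                                  artifact_rate=rates["artifact"], seed=seed)
            table, _ = simulate_variant_cohort(cfg)
            counts = table["truth_class"].value_counts()
            for c in rates:
                totals[c] += int(counts.get(c, 0))
        observed = np.array([totals[c] for c in rates])
        expected = np.array([rates[c] for c in rates])
        expected = expected / expected.sum() * observed.sum()
        assert chisquare(observed, expected).pvalue > 0.001


class TestArmSegments:
    def test_noiseless_planted_gain_exact(self):
        segs, _ = simulate_arm_segments(2, {("S001", "1q"): 0.3}, 0.0, seed=2)
        s1 = segs[segs.sample_id == "S001"]
        on_1q = s1[(s1.chrom == "chr1") & (s1.start >= 124_535_434)]
        assert (on_1q["log2_ratio"] == 0.3).all()
        assert arm_score(s1, "1q") == pytest.approx(0.3)

    def test_no_events_noiseless_all_zero(self):
        segs, _ = simulate_arm_segments(2, None, 0.0, seed=2)
        assert (segs["log2_ratio"] == 0.0).all()

    def test_unknown_arm_rejected(self):
        with pytest.raises(KeyError):
            simulate_arm_segments(2, {("S001", "chr1_q"): 0.3}, 0.0, seed=2)

    def test_segments_tile_arms_exactly(self):
        segs, _ = simulate_arm_segments(1, None, 0.0, seed=4)
        from rbomics._arms import ARM_TABLE
        for arm in ARM_TABLE.itertuples():
            sub = segs[(segs.chrom == arm.chrom) & (segs.start >= arm.start)
                       & (segs.end <= arm.end)]
            assert sub["start"].min() == arm.start
            assert sub["end"].max() == arm.end
            assert ((sub["end"] - sub["start"]) > 0).all()
            assert (sub.sort_values("start")["start"].to_numpy()[1:]
                    == sub.sort_values("start")["end"].to_numpy()[:-1]).all()

    def test_score_recovery_under_noise(self):
        """Monte-Carlo: planted +0.3 with sd 0.05 recovers within 0.05 in
        >= 95% of samples (weighted-mean variance is far below sd^2)."""
        events = {(f"S{i + 1:03d}", "1q"): 0.3 for i in range(50)}
        segs, _ = simulate_arm_segments(50, events, noise_sd=0.05, seed=6)
        errors = [abs(arm_score(segs[segs.sample_id == s], "1q") - 0.3)
                  for s in segs["sample_id"].unique()]
        assert np.mean(np.array(errors) < 0.05) >= 0.95


class TestIntegrationFixture:
    def test_all_promoter_when_forced(self):
        fx = simulate_integration_fixture(20, 50, frac_promoter=1.0,
                                          frac_mid=0, frac_distal=0, seed=3)
        assert (fx.truth["bin"] == "promoter_3kb").all()

    def test_zero_overlap_empty_intersection(self):
        fx = simulate_integration_fixture(20, 50, replicate_overlap=0.0, seed=3)
        assert high_confidence_peaks(fx.peaks_a, fx.peaks_b).empty

    def test_truth_bins_recovered_exactly(self):
        fx = simulate_integration_fixture(60, 150, seed=4)
        links = assign_peaks_to_genes(fx.peaks_a, fx.genes)
        assert links["bin"].tolist() == fx.truth["bin"].tolist()
        assert links["gene_id"].tolist() == fx.truth["gene_id"].tolist()
        assert links["signed_distance"].tolist() == \
            fx.truth["signed_distance"].tolist()

    def test_no_genes_with_peaks_rejected(self):
        with pytest.raises(ValueError):
            simulate_integration_fixture(0, 10, seed=1)


class TestCountMatrix:
    def test_no_lowq_all_pass(self):
        from rbomics.scqc import qc_filter
        m, bc, genes, labels = simulate_count_matrix(100, 200, frac_lowq=0.0,
                                                     seed=5)
        report, _, kept = qc_filter(m, bc, genes)
        assert (labels["qc_label"] == "pass").all()
        assert len(kept) == 100

    def test_planted_low_umi_cell(self):
        m, bc, genes, labels = simulate_count_matrix(30, 200, frac_lowq=0.1,
                                                     seed=6)
        umi_cells = labels[labels.qc_label == "fail_umi"]["barcode"]
        totals = np.asarray(m.sum(axis=0)).ravel()
        for b in umi_cells:
            assert totals[bc.index(b)] == 350

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            simulate_count_matrix(10, 200, frac_lowq=1.5)
        with pytest.raises(ValueError):
            simulate_count_matrix(10, 50)
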