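import numpy as np
import pandas as pd
import pytest

from carboxmeta import binning
from carboxmeta import synthetic as syn
from carboxmeta.annotations import build_profile
from carboxmeta.binqc import BinGeneContent, completeness, duplicated_cscg
from carboxmeta.enrichment import log_odds_ratio


class TestCategoryTables:
    def test_no_planted_effect_gives_empty_truth(self):
        spec = syn.default_community_spec(0, n_categories=20, n_genes=500, enriched={})
        tabs = syn.generate_category_tables(spec)
        assert tabs.truth == {}

    def test_determinism_same_seed_identical_tables(self):
        spec = syn.default_community_spec(3, n_categories=30, n_genes=1000)
        t1 = syn.generate_category_tables(spec)
        t2 = syn.generate_category_tables(spec)
        pd.testing.assert_frame_equal(t1.table_a, t2.table_a)
        pd.testing.assert_frame_equal(t1.table_b, t2.table_b)

    def test_planted_factor_recovered_as_log_odds(self):
        # Monte-Carlo over 20 seeds: mean empirical LOR of the factor-4
        # category approaches ln 4 (community B enriched -> negative in A-vs-B)
        lors = []
        for seed in range(20):
            spec = syn.default_community_spec(seed, enriched={10: 4.0})
            tabs = syn.generate_category_tables(spec)
            pa = build_profile(tabs.table_a, "A", "PFAM")
            pb = build_profile(tabs.table_b, "B", "PFAM")
            lor, _, _ = log_odds_ratio(
                pa["CAT0010"], pa.total, pb["CAT0010"], pb.total
            )
            lors.append(-lor)
        assert np.mean(lors) == pytest.approx(np.log(4.0), abs=0.3)

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            syn.CommunitySpec(2, np.array([0.6, 0.6]), np.ones(2), 10, 10, 0)
        with pytest.raises(ValueError):
            syn.CommunitySpec(2, np.array([0.5, 0.5]), np.array([1.0, 0.0]), 10, 10, 0)


class TestGenerateContigs:
    def test_empirical_kmer_vector_converges(self):
        spec = syn.TaxonSignatureSpec.from_nucleotide_freqs(
            "T", 45.0, gc_sd=0.0, n_contigs=1, contig_length_range=(100_000, 100_000)
        )
        out = syn.generate_contigs([spec], 5)
        sig = binning.kmer_signature(next(iter(out.sequences.values())))
        assert np.abs(sig - spec.expected_signature).sum() < 0.05

    def test_degenerate_noise_gives_identical_gc_and_depth(self):
        spec = syn.TaxonSignatureSpec.from_nucleotide_freqs(
            "T", 40.0, gc_sd=0.0, depth_sd=0.0, n_contigs=5,
            contig_length_range=(1000, 1500),
        )
        out = syn.generate_contigs([spec], 1)
        assert out.metadata["gc_pct"].nunique() == 1
        assert out.metadata["depth"].nunique() == 1

    def test_planted_gc_tracks_sequence_composition(self):
        spec = syn.TaxonSignatureSpec.from_nucleotide_freqs(
            "T", 60.0, gc_sd=3.0, n_contigs=5, contig_length_range=(5000, 6000)
        )
        out = syn.generate_contigs([spec], 2)
        for row in out.metadata.itertuples():
            realized = binning.gc_percent(out.sequences[row.contig_id])
            assert realized == pytest.approx(row.gc_pct, abs=3.0)

    def test_determinism(self):
        specs = [syn.TaxonSignatureSpec.from_nucleotide_freqs(
            "T", 50.0, n_contigs=2, contig_length_range=(1000, 1200))]
        a = syn.generate_contigs(specs, 9)
        b = syn.generate_contigs(specs, 9)
        assert a.sequences == b.sequences
        pd.testing.assert_frame_equal(a.metadata, b.metadata)

    def test_empty_spec_list_rejected(self):
        with pytest.raises(ValueError):
            syn.generate_contigs([], 0)

    def test_transition_matrix_constructor_consistent(self):
        t = np.array([[0.7, 0.1, 0.1, 0.1]] * 4)
        spec = syn.TaxonSignatureSpec.from_transition_matrix("T", t, n_contigs=1)
        assert spec.kmer_weights.sum() == pytest.approx(1.0)
        # chain heavily favors A -> AAA mass dominates
        assert spec.kmer_weights[0] == max(spec.kmer_weights)


class TestGenerateHitTable:
    def test_zero_fraction_empty_table(self):
        spec = syn.CoveragePlantSpec("G", 1000, 0.0)
        assert syn.generate_hit_table(spec, 5000, 0).empty

    def test_forced_arithmetic_row_count(self):
        spec = syn.CoveragePlantSpec("G", 2770, 0.89)
        hits = syn.generate_hit_table(spec, 50_000, 0)
        assert len(hits) == 2465  # round(0.89 * 2770)
        assert hits["gene_id"].is_unique

    def test_pure_high_identity_mixture(self):
        spec = syn.CoveragePlantSpec("G", 500, 0.5, identity_distribution=(0, 0, 1))
        hits = syn.generate_hit_table(spec, 5000, 1)
        assert ((hits["identity_pct"] > 90) & (hits["identity_pct"] <= 100)).all()

    def test_infeasible_fraction_rejected(self):
        spec = syn.CoveragePlantSpec("G", 1000, 1.5)
        with pytest.raises(ValueError):
            syn.generate_hit_table(spec, 1000, 0)


class TestGenerateQcInventory:
    def test_full_presence_gives_complete_bin(self):
        inv = syn.generate_qc_inventory(syn.QcPlantSpec(50, 1.0, 20, 0.0), 0)
        content = BinGeneContent.from_iterable(
            "b", np.repeat(inv.bin_content["category"], inv.bin_content["copies"])
        )
        assert completeness(content, inv.reference) == 100.00
        assert duplicated_cscg(content, inv.reference) == 0.00

    def test_forced_rounding_of_present_core(self):
        inv = syn.generate_qc_inventory(syn.QcPlantSpec(123, 0.8134, 59, 0.0), 1)
        core_present = set(inv.bin_content["category"]) & inv.reference.core_genes
        assert len(core_present) == 100  # round(0.8134 * 123)
        assert inv.expected_completeness == 81.30

    def test_planted_duplication_exact(self):
        inv = syn.generate_qc_inventory(syn.QcPlantSpec(50, 0.9, 59, 0.1186), 2)
        dup = inv.bin_content.loc[inv.bin_content["copies"] >= 2, "category"]
        assert len(set(dup) & inv.reference.cscg) == 7  # round(0.1186 * 59)
        assert inv.expected_duplication == 11.86


class TestFermentationReplicates:
    def test_zero_sd_replicates_equal_planted_means(self):
        means = {"acetic": 60.0, "propionic": 10.0, "butyric": 30.0}
        spec = syn.FermentationPlantSpec(
            acid_means=means, acid_sds={a: 0.0 for a in means}, seed=4
        )
        out = syn.generate_fermentation_replicates(spec)
        for acid, mean in means.items():
            vals = out.measurements.loc[out.measurements["acid"] == acid, "pct"]
            assert np.allclose(vals, mean)

    def test_sample_means_within_two_se_of_plants(self):
        # Monte-Carlo: many replicates -> empirical means near planted means
        spec = syn.thermophilic_spectrum_spec(seed=7)
        spec.n_replicates = 400
        out = syn.generate_fermentation_replicates(spec)
        wide = out.measurements.pivot(index="replicate", columns="acid", values="pct")
        for acid, mean in spec.acid_means.items():
            se = spec.acid_sds[acid] / np.sqrt(len(wide)) + 1e-9
            # flooring at 0 biases small-mean acids upward; allow that slack
            assert abs(wide[acid].mean() - mean) < max(2 * se, 1.0)

    def test_determinism(self):
        spec = syn.thermophilic_spectrum_spec(seed=5)
        a = syn.generate_fermentation_replicates(spec)
        b = syn.generate_fermentation_replicates(spec)
        pd.testing.assert_frame_equal(a.measurements, b.measurements)

    def test_replicate_spectra_are_compositions(self):
        out = syn.generate_fermentation_replicates(syn.mesophilic_spectrum_spec(3))
        sums = out.measurements.groupby("replicate")["pct"].sum()
        assert np.allclose(sums, 100.0)

    def test_batch_mass_columns_match_plants(self):
        spec = syn.mesophilic_spectrum_spec(2)
        out = syn.generate_fermentation_replicates(spec)
        for batch in out.batches:
            assert batch.vs_loaded_g == spec.vs_loaded_g
            assert batch.vs_loaded_g - batch.vs_remaining_g == pytest.approx(spec.vs_digested_g)
            assert batch.total_acid_g == pytest.approx(spec.acid_total_g)

    def test_invalid_means_sum_rejected(self):
        with pytest.raises(ValueError):
            syn.FermentationPlantSpec(
                acid_means={"acetic": 70.0, "butyric": 40.0},
                acid_sds={"acetic": 1.0, "butyric": 1.0},
            )
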