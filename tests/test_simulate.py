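import numpy as np
import pandas as pd
import pytest

from stinkgland.catalog import validate_catalog
from stinkgland.design import CONTROL_TISSUE, GLAND_TISSUES, SampleDesign
from stinkgland.phenotype import WILD_TYPE, STATUS_COLUMNS
from stinkgland.simulate import (
    DEFAULT_MORPHOLOGY_PROBS,
    VolatileEffectModel,
    default_reference_profile,
    gene_lists_from_venn,
    generate_catalog,
    generate_geneset_mapping,
    make_truth,
    phenotype_table_from_composition,
    simulate_counts,
    simulate_screen_tables,
)


class TestGenerateCatalog:
    def test_empty(self):
        assert len(generate_catalog(0)) == 0

    def test_same_seed_identical(self):
        a = generate_catalog(50, isoforms_per_gene=(1, 3), seed=42)
        b = generate_catalog(50, isoforms_per_gene=(1, 3), seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_fixed_isoform_count(self):
        catalog = generate_catalog(100, isoforms_per_gene=2, seed=1)
        assert len(catalog) == 200
        assert catalog["gene_id"].nunique() == 100
        validate_catalog(catalog)

    def test_invalid_length_range_rejected(self):
        with pytest.raises(ValueError, match="length_range"):
            generate_catalog(10, length_range=(0, 100))

    def test_lengths_within_range(self):
        catalog = generate_catalog(200, length_range=(300, 400), seed=3)
        assert catalog["length_bp"].between(300, 400).all()


class TestSimulateCounts:
    def test_same_seed_identical(self, design):
        catalog = generate_catalog(30, seed=5)
        truth = make_truth(list(catalog["gene_id"]))
        a = simulate_counts(catalog, design, truth, seed=9)
        b = simulate_counts(catalog, design, truth, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_missing_gene_in_truth_named(self, design):
        catalog = generate_catalog(3, seed=0)
        truth = make_truth(list(catalog["gene_id"])[:-1])
        with pytest.raises(KeyError, match="Tc_000003"):
            simulate_counts(catalog, design, truth, seed=0)

    def test_poisson_limit_mean_matches_configuration(self, design):
        """dispersion=0: over 10,000 draws the mean sits within 3 SE."""
        mu = 200.0
        catalog = generate_catalog(10_000, length_range=(1000, 1000), seed=1)
        truth = make_truth(list(catalog["gene_id"]), baseline_mean=mu, dispersion=0.0)
        counts = simulate_counts(catalog, design, truth, seed=2)
        control = counts[design.control_sample].to_numpy()
        se = np.sqrt(mu / len(control))
        assert abs(control.mean() - mu) < 3 * se

    def test_planted_log2fc_recovered_empirically(self, design):
        """Mean log2 count ratio of planted genes lies within 0.5 of 6."""
        catalog = generate_catalog(1000, length_range=(1000, 1000), seed=4)
        genes = list(catalog["gene_id"])
        truth = make_truth(
            genes, planted_genes=genes, effect_log2fc=6.0,
            baseline_mean=200.0, dispersion=0.05,
        )
        counts = simulate_counts(catalog, design, truth, seed=5)
        gland = counts[design.gland_samples[0]].to_numpy().astype(float)
        control = counts[design.control_sample].to_numpy().astype(float)
        ratios = np.log2(np.maximum(gland, 1) / np.maximum(control, 1))
        assert abs(ratios.mean() - 6.0) < 0.5

    def test_zero_counts_occur_for_low_means(self, design):
        catalog = generate_catalog(500, seed=6)
        truth = make_truth(list(catalog["gene_id"]), baseline_mean=0.05, dispersion=0.0)
        counts = simulate_counts(catalog, design, truth, seed=7)
        assert (counts.to_numpy() == 0).any()

    def test_adding_a_sample_does_not_perturb_others(self):
        catalog = generate_catalog(20, seed=8)
        truth = make_truth(list(catalog["gene_id"]))
        base_design = SampleDesign.canonical()
        extended = SampleDesign(
            samples=dict(base_design.samples) | {"extra-gland": GLAND_TISSUES[0]},
            library_sizes=dict(base_design.library_sizes),
        )
        a = simulate_counts(catalog, base_design, truth, seed=1)
        b = simulate_counts(catalog, extended, truth, seed=1)
        pd.testing.assert_frame_equal(a, b[a.columns])

    def test_library_size_scales_expected_counts(self):
        catalog = generate_catalog(2000, length_range=(1000, 1000), seed=2)
        truth = make_truth(list(catalog["gene_id"]), baseline_mean=50.0, dispersion=0.0)
        small = SampleDesign.canonical(library_size=1_000_000)
        big = SampleDesign.canonical(library_size=2_000_000)
        c_small = simulate_counts(catalog, small, truth, seed=3)
        c_big = simulate_counts(catalog, big, truth, seed=3)
        ratio = c_big.to_numpy().mean() / c_small.to_numpy().mean()
        assert ratio == pytest.approx(2.0, rel=0.05)


class TestGenesetMapping:
    def test_zero_fusions_is_bijection(self):
        catalog = generate_catalog(25, seed=0)
        mapping = generate_geneset_mapping(catalog, n_fusions=0, seed=0)
        assert mapping["source_id"].is_unique
        assert mapping["target_id"].is_unique
        assert len(mapping) == 25

    def test_fusions_are_pairwise(self):
        catalog = generate_catalog(208, seed=1)
        mapping = generate_geneset_mapping(catalog, n_fusions=4, seed=1)
        assert len(mapping) == 212
        sizes = mapping.groupby("target_id").size()
        assert (sizes.value_counts() == pd.Series({1: 204, 2: 4})).all()

    def test_same_seed_identical(self):
        catalog = generate_catalog(40, seed=2)
        a = generate_geneset_mapping(catalog, n_fusions=5, seed=3)
        b = generate_geneset_mapping(catalog, n_fusions=5, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_too_many_fusions_rejected(self):
        catalog = generate_catalog(5, seed=0)
        with pytest.raises(ValueError, match="n_fusions"):
            generate_geneset_mapping(catalog, n_fusions=5)


class TestScreenTables:
    def test_all_wild_type_degenerate(self):
        probs = {label: 0.0 for label in DEFAULT_MORPHOLOGY_PROBS} | {WILD_TYPE: 1.0}
        records, profiles = simulate_screen_tables(
            [f"g{i}" for i in range(20)], morphology_probs=probs, seed=0
        )
        assert (records["morphology"] == WILD_TYPE).all()
        assert (records[list(STATUS_COLUMNS)] == "normal").all().all()
        ref = default_reference_profile()
        for region in ("abdominal", "thoracic"):
            sub = profiles[profiles["region"] == region]
            for compound in ref.columns:
                assert (sub[compound] == ref.loc[region, compound]).all()

    def test_label_frequencies_match_probabilities(self):
        """Law of large numbers: uniform over 8 labels at n=80,000."""
        labels = list(DEFAULT_MORPHOLOGY_PROBS)
        probs = {label: 1 / 8 for label in labels}
        records, _ = simulate_screen_tables(
            [f"g{i}" for i in range(80_000)], morphology_probs=probs, seed=1
        )
        freqs = records["morphology"].value_counts(normalize=True)
        assert (abs(freqs.reindex(labels).fillna(0.0) - 0.125) <= 0.01).all()

    def test_probabilities_must_sum_to_one(self):
        probs = {label: 0.2 for label in DEFAULT_MORPHOLOGY_PROBS}
        with pytest.raises(ValueError, match="sum"):
            simulate_screen_tables(["g1"], morphology_probs=probs)

    def test_same_seed_identical(self):
        genes = [f"g{i}" for i in range(50)]
        a_rec, a_prof = simulate_screen_tables(genes, seed=4)
        b_rec, b_prof = simulate_screen_tables(genes, seed=4)
        pd.testing.assert_frame_equal(a_rec, b_rec)
        pd.testing.assert_frame_equal(a_prof, b_prof)

    def test_statuses_consistent_with_profiles(self):
        """Classifying the emitted profiles reproduces the emitted statuses."""
        from stinkgland.phenotype import classify_volatiles

        genes = [f"g{i}" for i in range(40)]
        records, profiles = simulate_screen_tables(
            genes, volatile_effect_model=VolatileEffectModel(), seed=6
        )
        ref = default_reference_profile()
        for _, row in records.iterrows():
            prof = (
                profiles[profiles["gene_id"] == row["gene_id"]]
                .set_index("region")[list(ref.columns)]
            )
            status = classify_volatiles(prof, ref, reduction_fraction=0.10)
            for col in STATUS_COLUMNS:
                assert status[col] == row[col]


class TestCompositionBuilders:
    def test_phenotype_table_has_exact_composition(self):
        table = phenotype_table_from_composition(
            {"IV": 3, "I": 2}, {"bq_both_only": 2, "restricted": 1, "none": 2}
        )
        assert len(table) == 5
        assert (table["morphology"].value_counts()[["IV", "I"]] == [3, 2]).all()

    def test_volatile_composition_must_cover_all_genes(self):
        with pytest.raises(ValueError, match="cover"):
            phenotype_table_from_composition({"IV": 3}, {"none": 1})

    def test_gene_lists_realize_requested_regions(self):
        lists = gene_lists_from_venn(
            {"A": 2, "B": 1, "A+B": 3}, names=("A", "B", "C")
        )
        assert len(lists["A"]) == 5
        assert len(lists["B"]) == 4
        assert len(set(lists["A"]) & set(lists["B"])) == 3
        assert lists["C"] == []
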