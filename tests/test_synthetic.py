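"""Synthetic study generator: library structure, spectra, feature tables."""

import itertools
import json

import numpy as np
import pytest

from foliarchem import (ConfigurationError, EffectConfig, StudyDesign,
                        bray_curtis_pair, cosine_score,
                        default_effect_config, default_study_design,
                        generate_compound_library, generate_study_fixture,
                        pairwise_matrix, simulate_feature_table, simulate_spectra)

from .conftest import small_effect_config, tiny_design


class TestEffectConfigValidation:
    @pytest.mark.parametrize("field,value", [
        ("singleton_fraction", 1.5), ("age_turnover", -0.1),
        ("inducible_fraction", 2.0), ("species_compound_overlap", -1.0),
    ])
    def test_proportions_out_of_range_named(self, field, value):
        with pytest.raises(ConfigurationError, match=field):
            EffectConfig(**{field: value})

    @pytest.mark.parametrize("field,value", [
        ("n_classes", 0), ("compounds_per_class", 0), ("peaks_per_compound", 0),
        ("induction_fold", 0.5), ("noise_sigma", -0.1),
    ])
    def test_counts_and_effects_validated(self, field, value):
        with pytest.raises(ConfigurationError, match=field):
            EffectConfig(**{field: value})


class TestCompoundLibrary:
    def test_counts_forced_by_config(self):
        lib = generate_compound_library(
            EffectConfig(n_classes=2, compounds_per_class=3, singleton_fraction=0.0))
        assert len(lib) == 6
        assert sorted({c.class_id for c in lib.compounds}) == [0, 1]

    def test_singleton_fraction_of_total(self):
        # 5 class compounds + singleton_fraction 0.5 of the total -> 5 singletons
        lib = generate_compound_library(
            EffectConfig(n_classes=1, compounds_per_class=5, singleton_fraction=0.5))
        assert len(lib) == 10
        assert sum(1 for c in lib.compounds if c.class_id is None) == 5

    def test_same_seed_identical_library(self):
        cfg = EffectConfig(n_classes=3, compounds_per_class=2, seed=12)
        l1, l2 = generate_compound_library(cfg), generate_compound_library(cfg)
        for a, b in zip(l1.compounds, l2.compounds):
            assert a.id == b.id and a.class_id == b.class_id
            np.testing.assert_array_equal(a.mz, b.mz)
            np.testing.assert_array_equal(a.intensity, b.intensity)

    def test_class_members_share_template_peaks_singletons_do_not(self):
        cfg = EffectConfig(n_classes=2, compounds_per_class=4,
                           singleton_fraction=0.2, seed=5)
        lib = generate_compound_library(cfg)
        classes = {}
        for c in lib.compounds:
            classes.setdefault(c.class_id, []).append(c)
        for cid, members in classes.items():
            if cid is None:
                continue
            for a, b in itertools.combinations(members, 2):
                shared = np.intersect1d(a.mz, b.mz).size
                assert shared >= 0.5 * cfg.peaks_per_compound
        singles = classes.get(None, [])
        class_mz = np.concatenate([c.mz for c in lib.compounds if c.class_id is not None])
        for s in singles:
            assert np.intersect1d(s.mz, class_mz).size == 0

    def test_default_library_emulates_study_scale(self):
        lib = generate_compound_library(default_effect_config())
        assert len(lib) == 1302
        assert sum(1 for c in lib.compounds if c.class_id is None) == 498


class TestSimulateSpectra:
    def test_noiseless_replicates_are_identical(self):
        cfg = EffectConfig(n_classes=1, compounds_per_class=2, singleton_fraction=0.0)
        lib = generate_compound_library(cfg)
        spectra = simulate_spectra(lib, 3, mz_jitter=0.0, intensity_cv=0.0, seed=1)
        assert len(spectra) == 6
        for k in (0, 3):
            assert cosine_score(spectra[k], spectra[k + 1]) == pytest.approx(1.0, abs=1e-12)

    def test_replicate_cosine_exceeds_cluster_threshold(self):
        lib = generate_compound_library(EffectConfig(n_classes=2, compounds_per_class=2,
                                                     singleton_fraction=0.0, seed=2))
        spectra = simulate_spectra(lib, 3, mz_jitter=0.005, intensity_cv=0.2, seed=3)
        for k in range(0, len(spectra), 3):
            for r in range(1, 3):
                assert cosine_score(spectra[k], spectra[k + r],
                                    fragment_tol=0.02) > 0.95

    def test_within_class_cosine_exceeds_between_class(self):
        lib = generate_compound_library(EffectConfig(n_classes=3, compounds_per_class=4,
                                                     singleton_fraction=0.0, seed=6))
        specs = {c.id: c.spectrum() for c in lib.compounds}
        cls = {c.id: c.class_id for c in lib.compounds}
        within, between = [], []
        for a, b in itertools.combinations(specs, 2):
            s = cosine_score(specs[a], specs[b], allow_precursor_shift=True)
            (within if cls[a] == cls[b] else between).append(s)
        assert np.mean(within) > np.mean(between)
        assert np.mean(within) > 0.6  # class structure survives the network threshold

    def test_invalid_noise_config_rejected(self):
        lib = generate_compound_library(EffectConfig(n_classes=1, compounds_per_class=1))
        with pytest.raises(ConfigurationError, match="mz_jitter"):
            simulate_spectra(lib, 1, mz_jitter=-0.1)
        with pytest.raises(ConfigurationError, match="intensity_cv"):
            simulate_spectra(lib, 1, intensity_cv=-0.5)
        with pytest.raises(ConfigurationError):
            simulate_spectra(lib, 0)


class TestSimulateFeatureTable:
    def test_no_noise_no_effects_gives_identical_conspecific_rows(self):
        cfg = small_effect_config(age_turnover=0.0, induction_fold=1.0,
                                  noise_sigma=0.0, inducible_fraction=0.0)
        table, meta, _ = simulate_feature_table(tiny_design(), cfg)
        focal_rows = meta.loc[(meta.species == "Inga_focalis"), "sample_id"]
        t = table.loc[focal_rows]
        assert (t.nunique(axis=0) <= 1).all()  # every column constant

    def test_zero_overlap_congeners_share_no_compounds(self):
        cfg = small_effect_config(species_compound_overlap=0.0)
        table, meta, _ = simulate_feature_table(tiny_design(n_congeners=2), cfg)
        leafs = meta[meta.sample_type == "leaf"].set_index("sample_id")
        congeners = leafs.index[leafs.species.str.contains("_sp")]
        a, b = table.loc[congeners[0]], table.loc[congeners[1]]
        assert bray_curtis_pair(a.to_numpy(), b.to_numpy()) == 0.0

    def test_within_species_similarity_exceeds_between(self):
        table, meta, _ = simulate_feature_table(default_study_design(),
                                                small_effect_config())
        leafs = meta[meta.sample_type == "leaf"].set_index("sample_id")
        sim = pairwise_matrix(table.loc[leafs.index], "BC")
        sp = leafs.species.to_numpy()
        gen = leafs.genus.to_numpy()
        iu = np.triu_indices(len(leafs), 1)
        v = sim.to_numpy()[iu]
        same_sp = sp[iu[0]] == sp[iu[1]]
        same_gen = gen[iu[0]] == gen[iu[1]]
        assert v[same_sp].mean() > v[same_gen & ~same_sp].mean()

    def test_intensities_nonnegative_and_ids_unique(self):
        table, meta, _ = simulate_feature_table(tiny_design(), small_effect_config())
        assert (table.to_numpy() >= 0).all()
        assert meta.sample_id.is_unique
        assert set(meta.sample_id) == set(table.index)

    def test_induction_raises_inducible_intensities(self):
        cfg = small_effect_config(induction_fold=10.0, inducible_fraction=0.3,
                                  noise_sigma=0.0, age_turnover=0.0)
        table, meta, truth = simulate_feature_table(tiny_design(), cfg)
        leafs = meta[meta.sample_type == "leaf"].set_index("sample_id")
        sp = "Inga_focalis"
        ja = leafs.index[(leafs.species == sp) & (leafs.treatment == "JA")]
        ctl = leafs.index[(leafs.species == sp) & (leafs.treatment == "control")]
        ind = truth["inducible"][sp]
        ratio = table.loc[ja, ind].mean() / table.loc[ctl, ind].mean()
        np.testing.assert_allclose(ratio, 10.0, rtol=1e-9)

    def test_capacity_error_names_genus(self):
        cfg = small_effect_config(compounds_per_species=500)
        with pytest.raises(ConfigurationError, match="Inga"):
            simulate_feature_table(tiny_design(), cfg)


class TestStudyFixture:
    def test_default_design_is_the_102_sample_study(self):
        d = default_study_design()
        assert d.n_leaf_samples == 102
        assert sum(d.genera.values()) == 45
        n = 102
        assert n * (n - 1) // 2 == 5151

    def test_three_samples_make_three_pairs(self):
        design = StudyDesign(genera={"Inga": 1}, focal_species={"Inga": "If"},
                             replicates_per_cell=1, include_blanks=0,
                             cell_counts={"If": (1, 1, 0, 0)})
        # cell_counts with zeros: 2 focal + 1 congener = 3 leaf samples
        assert design.n_leaf_samples == 3
        assert 3 * 2 // 2 == 3

    def test_fixture_bundle_written_and_rerun_identical(self, tmp_path):
        design = tiny_design()
        cfg = small_effect_config()
        p1 = generate_study_fixture(design, cfg, tmp_path / "a", n_replicates=2)
        p2 = generate_study_fixture(design, cfg, tmp_path / "b", n_replicates=2)
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes(), key
        truth = json.loads(p1["truth"].read_text())
        assert set(truth["contaminants"]).isdisjoint(
            set().union(*truth["species_pools"].values()))
        assert truth["n_leaf_samples"] == design.n_leaf_samples

    def test_blanks_contain_only_contaminants(self, tmp_path):
        table, meta, truth = simulate_feature_table(tiny_design(blanks=2),
                                                    small_effect_config())
        blanks = meta.loc[meta.sample_type == "blank", "sample_id"]
        blk = table.loc[blanks]
        nonzero = blk.columns[(blk > 0).any(axis=0)]
        assert set(nonzero) == set(truth["contaminants"])

    def test_design_validation(self):
        with pytest.raises(ConfigurationError):
            StudyDesign(genera={"Inga": 2}, focal_species={"Piper": "x"})
        with pytest.raises(ConfigurationError, match="unknown focal"):
            StudyDesign(genera={"Inga": 2}, focal_species={"Inga": "x"},
                        cell_counts={"y": (1, 1, 1, 1)})
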