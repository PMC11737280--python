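import numpy as np
import pandas as pd
import pytest

from maldicci.cci import CCIConfig, cci
from maldicci.preprocess import PreprocessConfig, preprocess_dataset
from maldicci.refdb import (
    DIFFERENT_SPECIES,
    REPLICATE,
    SAME_SPECIES,
    DatabaseError,
    ReferenceDatabase,
    all_pairs_cci,
    bank_to_bank_best_match,
    build_database,
    cross_panel_cci,
    enumerate_cross_pairs,
    enumerate_pairs,
    load_database,
    median_with_neginf,
    merge_databases,
    percentile_with_neginf,
    qc_filter,
    save_database,
    specimen_median_matrix,
    summarize_similarity,
)
from maldicci.spectra_io import SpectrumMeta
from maldicci.synthetic import GeneratorConfig, generate_panels

from conftest import make_processed


def meta(sid, specimen, spot, species, panel="reference"):
    return SpectrumMeta(sid, specimen, spot, species, panel)


class TestBuildDatabase:
    def test_two_specimens_two_spots(self, processed_panels):
        pref, ref_meta, _, _ = processed_panels
        db = build_database(pref, ref_meta)
        info = db.summary()
        assert info["n_spectra"] == len(pref)
        assert info["n_species"] == 3

    def test_conflicting_species_labels_rejected(self, processed_panels):
        pref, ref_meta, _, _ = processed_panels
        bad_meta = list(ref_meta)
        m = bad_meta[0]
        bad_meta[0] = SpectrumMeta(m.spectrum_id, m.specimen_id, m.spot_index,
                                   "another_species", m.panel)
        with pytest.raises(DatabaseError, match="conflicting"):
            build_database(pref, bad_meta)

    def test_species_set_size(self):
        config = GeneratorConfig(n_species=25, specimens_per_species=1,
                                 spots_per_specimen=1, test_specimens_per_species=0,
                                 spot_noise=0.0, baseline_amplitude=0.0, seed=8)
        ref, ref_meta, _, _ = generate_panels(config)
        processed = preprocess_dataset(ref, PreprocessConfig(align=False))
        db = build_database(processed, ref_meta)
        assert len(db.species_set) == 25

    def test_spectrum_without_metadata_excluded(self, processed_panels, caplog):
        pref, ref_meta, _, _ = processed_panels
        with caplog.at_level("WARNING"):
            db = build_database(pref, ref_meta[1:])
        assert len(db) == len(pref) - 1
        assert "no metadata" in caplog.text


class TestPairEnumeration:
    def test_pair_count_formula(self):
        metas = [meta(f"s{i}", f"spec{i // 3}", i % 3 + 1, f"sp{i // 6}")
                 for i in range(10)]
        pairs = list(enumerate_pairs(metas))
        assert len(pairs) == 10 * 9 // 2
        categories = [c for _, _, c in pairs]
        assert set(categories) <= {REPLICATE, SAME_SPECIES, DIFFERENT_SPECIES}

    def test_cross_pair_count(self):
        queries = [meta(f"q{i}", f"q{i}", 1, "a", "test") for i in range(7)]
        refs = [meta(f"r{i}", f"r{i}", 1, "b") for i in range(13)]
        assert sum(1 for _ in enumerate_cross_pairs(queries, refs)) == 91

    def test_two_spectra_one_pair(self):
        metas = [meta("a", "x", 1, "sp"), meta("b", "x", 2, "sp")]
        pairs = list(enumerate_pairs(metas))
        assert len(pairs) == 1
        assert pairs[0][2] == REPLICATE


class TestAllPairsCCI:
    def test_row_count_and_partition(self, small_db):
        table = all_pairs_cci(small_db)
        n = len(small_db)
        assert len(table) == n * (n - 1) // 2
        counts = table["category"].value_counts()
        assert counts.sum() == len(table)

    def test_values_match_pairwise_cci(self, small_db):
        table = all_pairs_cci(small_db).set_index(["id_a", "id_b"])
        by_id = {s.spectrum_id: s for s in small_db.spectra}
        sample = table.sample(n=10, random_state=0)
        for (id_a, id_b), row in sample.iterrows():
            expected = cci(by_id[id_a], by_id[id_b]).log10cci
            if np.isfinite(expected):
                assert row["log10cci"] == pytest.approx(expected, abs=1e-10)
            else:
                assert row["log10cci"] == -np.inf

    def test_block_size_invariance(self, small_db):
        a = all_pairs_cci(small_db, block_size=4)
        b = all_pairs_cci(small_db, block_size=100)
        pd.testing.assert_frame_equal(a, b)


class TestCrossPanelCCI:
    def test_row_count(self, processed_panels, small_db):
        _, _, ptest, test_meta = processed_panels
        table = cross_panel_cci(ptest, test_meta, small_db)
        assert len(table) == len(ptest) * len(small_db)

    def test_one_by_one(self, processed_panels, small_db):
        _, _, ptest, test_meta = processed_panels
        table = cross_panel_cci(ptest[:1], test_meta, small_db)
        assert len(table) == len(small_db)


class TestPercentilesWithNegInf:
    def test_all_neg_inf(self):
        out = percentile_with_neginf(np.array([-np.inf] * 5), [25.0, 50.0, 75.0])
        assert all(v == -np.inf for v in out)

    def test_neg_inf_sorts_lowest(self):
        assert median_with_neginf(np.array([-np.inf, -10.0, -2.0])) == -10.0

    def test_matches_numpy_for_finite(self):
        rng = np.random.default_rng(4)
        values = rng.normal(size=101)
        got = percentile_with_neginf(values, [2.5, 50.0, 97.5])
        expected = np.percentile(values, [2.5, 50.0, 97.5])
        np.testing.assert_allclose(got, expected, atol=1e-12)


class TestSummaries:
    def test_constant_values(self):
        table = pd.DataFrame(
            {"category": [REPLICATE] * 4, "log10cci": [-5.0] * 4}
        )
        (summary,) = [s for s in summarize_similarity(table) if s.n_pairs]
        assert summary.median_log10cci == -5.0
        assert summary.iqr_low == -5.0 and summary.iqr_high == -5.0

    def test_hierarchy_on_synthetic_panel(self, small_db):
        table = all_pairs_cci(small_db)
        by_cat = {s.category: s for s in summarize_similarity(table)}
        assert (
            by_cat[REPLICATE].median_log10cci
            > by_cat[SAME_SPECIES].median_log10cci
            > by_cat[DIFFERENT_SPECIES].median_log10cci
        )


class TestSpecimenMedianMatrix:
    def test_single_specimen(self, processed_panels):
        pref, ref_meta, _, _ = processed_panels
        one = [m for m in ref_meta if m.specimen_id == ref_meta[0].specimen_id]
        spectra = [s for s in pref if s.spectrum_id in {m.spectrum_id for m in one}]
        db = build_database(spectra, one)
        matrix = specimen_median_matrix(db)
        assert matrix.shape == (1, 1)
        table = all_pairs_cci(db)
        assert matrix.iloc[0, 0] == median_with_neginf(table["log10cci"].to_numpy())

    def test_symmetric(self, small_db):
        matrix = specimen_median_matrix(small_db)
        pd.testing.assert_frame_equal(matrix, matrix.T)

    def test_within_species_blocks_higher(self, small_db):
        matrix = specimen_median_matrix(small_db)
        species_of = {spec: small_db.meta[sid].species_label
                      for sid in small_db.spectrum_ids
                      for spec in [small_db.meta[sid].specimen_id]}
        within, between = [], []
        for a in matrix.index:
            for b in matrix.columns:
                if a == b:
                    continue
                (within if species_of[a] == species_of[b] else between).append(
                    matrix.loc[a, b]
                )
        assert median_with_neginf(np.array(within)) > median_with_neginf(np.array(between))


class TestBankToBank:
    def test_two_specimens_same_species_full_concordance(self, processed_panels):
        pref, ref_meta, _, _ = processed_panels
        species = ref_meta[0].species_label
        keep = [m for m in ref_meta if m.species_label == species]
        spectra = [s for s in pref if s.spectrum_id in {m.spectrum_id for m in keep}]
        db = build_database(spectra, keep)
        matches = bank_to_bank_best_match(db, disable_self=True)
        assert matches["eligible"].all()
        assert matches["concordant"].all()

    def test_disable_same_species_single_species_db(self, processed_panels):
        pref, ref_meta, _, _ = processed_panels
        species = ref_meta[0].species_label
        keep = [m for m in ref_meta if m.species_label == species]
        spectra = [s for s in pref if s.spectrum_id in {m.spectrum_id for m in keep}]
        db = build_database(spectra, keep)
        matches = bank_to_bank_best_match(db, disable_same_species=True)
        assert not matches["eligible"].any()

    def test_well_separated_panel_concordance(self, small_db):
        matches = bank_to_bank_best_match(small_db, disable_self=True)
        assert matches["concordant"].mean() >= 0.95

    def test_self_match_disabled(self, small_db):
        matches = bank_to_bank_best_match(small_db, disable_self=True)
        assert (matches["best_match_id"] != matches["spectrum_id"]).all()


class TestQCFilter:
    def test_neg_inf_cutoff_removes_nothing(self, small_db):
        filtered, report = qc_filter(small_db, -np.inf)
        assert len(filtered) == len(small_db)
        assert not report["removed"].any()

    def test_zero_cutoff_removes_everything(self, small_db, caplog):
        with caplog.at_level("WARNING"):
            filtered, report = qc_filter(small_db, 0.0)
        assert len(filtered) == 0
        assert report["removed"].all()

    def test_corrupted_spectrum_detected(self):
        # 5 spots per specimen: one corrupted spectrum pulls only its own
        # replicate median to the bottom, its siblings keep a finite median
        config = GeneratorConfig(n_species=2, specimens_per_species=1,
                                 spots_per_specimen=5, test_specimens_per_species=0,
                                 seed=11)
        ref, ref_meta, _, _ = generate_panels(config)
        pref = preprocess_dataset(ref, PreprocessConfig())
        rng = np.random.default_rng(0)
        target = sorted(s.spectrum_id for s in pref)[0]
        corrupted = []
        for s in pref:
            if s.spectrum_id == target:
                noise = rng.random(s.intensity.size)
                corrupted.append(make_processed(noise / noise.sum(), s.spectrum_id))
            else:
                corrupted.append(s)
        db = build_database(corrupted, ref_meta)
        pair_table = all_pairs_cci(db)
        replicate = pair_table[pair_table["category"] == REPLICATE]
        other_medians = []
        for sid in db.spectrum_ids:
            if sid == target:
                continue
            mask = (replicate["id_a"] == sid) | (replicate["id_b"] == sid)
            other_medians.append(
                median_with_neginf(replicate.loc[mask, "log10cci"].to_numpy())
            )
        assert all(np.isfinite(m) for m in other_medians)
        cutoff = min(other_medians) - 1.0
        filtered, report = qc_filter(db, cutoff, pair_table=pair_table)
        removed = set(report.loc[report["removed"], "spectrum_id"])
        assert removed == {target}


class TestMerge:
    def _split(self, db):
        ids = db.spectrum_ids
        half = len(ids) // 2
        first = ReferenceDatabase(
            spectra=[s for s in db.spectra if s.spectrum_id in set(ids[:half])],
            meta={i: db.meta[i] for i in ids[:half]},
        )
        second = ReferenceDatabase(
            spectra=[s for s in db.spectra if s.spectrum_id in set(ids[half:])],
            meta={i: db.meta[i] for i in ids[half:]},
        )
        return first, second

    def test_merge_with_empty_is_identity(self, small_db):
        empty = ReferenceDatabase(spectra=[], meta={})
        merged = merge_databases(small_db, empty)
        assert merged.spectrum_ids == small_db.spectrum_ids

    def test_merge_counts_add_up(self, small_db):
        a, b = self._split(small_db)
        merged = merge_databases(a, b)
        assert len(merged) == len(small_db)
        assert merged.species_set == small_db.species_set
        assert len(merged.specimen_ids) == len(small_db.specimen_ids)

    def test_merge_commutative_in_content(self, small_db):
        a, b = self._split(small_db)
        ab = merge_databases(a, b)
        ba = merge_databases(b, a)
        assert ab.spectrum_ids == ba.spectrum_ids

    def test_id_collision_rejected(self, small_db):
        with pytest.raises(DatabaseError, match="collision"):
            merge_databases(small_db, small_db)


class TestPersistence:
    def test_save_load_round_trip(self, small_db, tmp_path):
        save_database(small_db, tmp_path / "db")
        loaded = load_database(tmp_path / "db")
        assert loaded.spectrum_ids == small_db.spectrum_ids
        assert loaded.species_set == small_db.species_set
        for a, b in zip(loaded.spectra, small_db.spectra):
            np.testing.assert_array_equal(a.intensity, b.intensity)
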