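import numpy as np
import pytest

from iluq.chem import (
    Conditions,
    EmptyDatasetError,
    ParseError,
    PropertyDataset,
    PropertyRecord,
    SchemaError,
    ValidationError,
    parse_ion_pair,
    read_dataset,
    split_dataset,
    write_dataset,
)


class TestConditions:
    def test_defaults_are_standard_ambient(self):
        c = Conditions()
        assert c.temperature_K == pytest.approx(298.15)
        assert c.pressure_kPa == pytest.approx(101.325)

    @pytest.mark.parametrize("kwargs", [
        {"temperature_K": 0.0},
        {"temperature_K": -5.0},
        {"pressure_kPa": 0.0},
        {"pressure_kPa": float("nan")},
    ])
    def test_nonpositive_values_rejected(self, kwargs):
        with pytest.raises(ValueError):
            Conditions(**kwargs)


class TestParseIonPair:
    def test_simplest_valid_pair(self):
        pair = parse_ion_pair("[NH4+].[Cl-]", "p1")
        assert pair.cation_smiles == "[NH4+]"
        assert pair.anion_smiles == "[Cl-]"

    def test_canonicalizes_components(self):
        a = parse_ion_pair("C(C)[N+](C)(C)C.[Br-]", "p1")
        b = parse_ion_pair("CC[N+](C)(C)C.[Br-]", "p2")
        assert a.cation_smiles == b.cation_smiles

    def test_unparsable_smiles_is_parse_error(self):
        with pytest.raises(ParseError):
            parse_ion_pair("not_a_smiles.[Cl-]", "p1")

    def test_neutral_cation_violates_charge_rule(self):
        with pytest.raises(ValidationError, match="cation"):
            parse_ion_pair("C.[Cl-]", "p1")

    def test_multivalent_rejected_in_strict_mode_only(self):
        # Ca(2+) / two chlorides cannot be expressed as one anion component,
        # but a 2+/2- pair exercises the multivalence rule directly.
        text = "[Ca+2].[O-]S(=O)(=O)[O-]"
        with pytest.raises(ValidationError):
            parse_ion_pair(text, "p1", charge_mode="strict")
        pair = parse_ion_pair(text, "p1", charge_mode="permissive")
        assert pair.charge_mode == "permissive"

    def test_relaxed_mode_accepts_neutral_molecules(self):
        pair = parse_ion_pair("c1ccccc1.CCO", "p1", charge_mode="relaxed")
        assert pair.smiles.count(".") == 1

    def test_wrong_number_of_dots(self):
        with pytest.raises(ParseError):
            parse_ion_pair("[NH4+]", "p1")
        with pytest.raises(ParseError):
            parse_ion_pair("[NH4+].[Cl-].[Cl-]", "p1")


class TestPropertyRecord:
    def test_co2_capacity_must_be_mole_fraction(self, ammonium_chloride):
        with pytest.raises(ValueError):
            PropertyRecord(ammonium_chloride, Conditions(), "co2_capacity", 1.2)

    def test_refractive_index_exceeds_one(self, ammonium_chloride):
        with pytest.raises(ValueError):
            PropertyRecord(ammonium_chloride, Conditions(), "refractive_index", 0.9)

    def test_unknown_property_rejected(self, ammonium_chloride):
        with pytest.raises(ValueError):
            PropertyRecord(ammonium_chloride, Conditions(), "density", 1.0)


def _write_csv(path, rows, header="cation_smiles,anion_smiles,temperature_K,pressure_kPa,value"):
    path.write_text(header + "\n" + "\n".join(rows) + "\n")


class TestDatasetIO:
    def test_read_valid_rows(self, tmp_path):
        f = tmp_path / "d.csv"
        _write_csv(f, [
            "[NH4+],[Cl-],298.15,101.325,1.5",
            "C[N+](C)(C)C,[Br-],300,101.325,1.8",
            "CC[N+](C)(C)C,CC(=O)[O-],310,101.325,2.0",
        ])
        ds = read_dataset(f, "viscosity")
        assert len(ds) == 3

    def test_invalid_smiles_row_skipped_not_fatal(self, tmp_path):
        f = tmp_path / "d.csv"
        _write_csv(f, [
            "[NH4+],[Cl-],298.15,101.325,1.5",
            "bogus,[Br-],300,101.325,1.8",
            "CC[N+](C)(C)C,CC(=O)[O-],310,101.325,2.0",
        ])
        ds = read_dataset(f, "viscosity")
        assert len(ds) == 2

    def test_missing_value_column_is_schema_error(self, tmp_path):
        f = tmp_path / "d.csv"
        _write_csv(f, ["[NH4+],[Cl-],298.15,101.325"],
                   header="cation_smiles,anion_smiles,temperature_K,pressure_kPa")
        with pytest.raises(SchemaError):
            read_dataset(f, "viscosity")

    def test_all_rows_invalid_is_empty_dataset_error(self, tmp_path):
        f = tmp_path / "d.csv"
        _write_csv(f, ["bogus,[Br-],300,101.325,1.8"])
        with pytest.raises(EmptyDatasetError):
            read_dataset(f, "viscosity")

    def test_round_trip_preserves_records_and_splits(self, tmp_path, small_dataset):
        ds, _ = small_dataset
        train, test = split_dataset(ds, 0.3, seed=4)
        merged = PropertyDataset(
            property_name=ds.property_name,
            records=train.records + test.records,
            split_labels=train.split_labels + test.split_labels,
        )
        f = tmp_path / "round.csv"
        write_dataset(merged, f)
        back = read_dataset(f, ds.property_name)
        assert len(back) == len(merged)
        assert back.split_labels == merged.split_labels
        for a, b in zip(back.records, merged.records):
            assert a.ion_pair.smiles == b.ion_pair.smiles
            assert a.conditions.temperature_K == pytest.approx(
                b.conditions.temperature_K, rel=0, abs=0)
            assert a.value == pytest.approx(b.value, rel=0, abs=0)

    def test_write_empty_dataset_errors(self, tmp_path):
        with pytest.raises(EmptyDatasetError):
            write_dataset(PropertyDataset("viscosity"), tmp_path / "e.csv")


class TestSplitDataset:
    def test_cardinality_and_disjointness(self, small_dataset):
        ds, _ = small_dataset
        sub = ds.subset(range(10))
        train, test = split_dataset(sub, 0.2, seed=1)
        assert len(train) == 8 and len(test) == 2
        train_ids = {(r.ion_pair.pair_id, r.conditions) for r in train}
        test_ids = {(r.ion_pair.pair_id, r.conditions) for r in test}
        assert not train_ids & test_ids
        assert len(train_ids | test_ids) == 10

    def test_same_seed_reproduces_split(self, small_dataset):
        ds, _ = small_dataset
        a = split_dataset(ds, 0.25, seed=9)
        b = split_dataset(ds, 0.25, seed=9)
        assert [r.ion_pair.pair_id for r in a[1]] == [r.ion_pair.pair_id for r in b[1]]

    def test_different_seeds_generally_differ(self, small_dataset):
        ds, _ = small_dataset
        test_sets = []
        for seed in (1, 2):
            _, test = split_dataset(ds.subset(range(10)), 0.2, seed=seed)
            test_sets.append({r.ion_pair.pair_id for r in test})
        assert test_sets[0] != test_sets[1]

    @pytest.mark.parametrize("frac", [0.0, 1.0, -0.1, 1.5])
    def test_fraction_out_of_range(self, small_dataset, frac):
        ds, _ = small_dataset
        with pytest.raises(ValueError):
            split_dataset(ds, frac, seed=0)

    def test_partition_property_across_seeds_and_fractions(self, small_dataset):
        ds, _ = small_dataset
        n = len(ds)
        for seed in range(5):
            for frac in (0.1, 0.2, 0.5):
                train, test = split_dataset(ds, frac, seed=seed)
                assert len(train) + len(test) == n
                assert len(test) == int(round(frac * n))

    def test_duplicate_records_flagged(self, small_dataset):
        ds, _ = small_dataset
        doubled = PropertyDataset(
            property_name=ds.property_name,
            records=ds.records[:3] + ds.records[:1],
        )
        mask = doubled.duplicate_mask()
        assert mask.tolist() == [False, False, False, True]
        assert len(doubled.deduplicate()) == 3
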