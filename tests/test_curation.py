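"""Curation: standardisation, activity labels, duplicate handling."""

import math

import pytest

from acqsar.curation import (
    CompoundSet,
    InvalidActivityError,
    InvalidStructureError,
    RawEntry,
    UnitConflictError,
    compute_activity_label,
    curate,
    standardise,
    standardise_smiles,
    unify_duplicates,
)
from rdkit import Chem


class TestStandardise:
    def test_canonical_smiles_unchanged(self):
        assert standardise_smiles("c1ccccc1") == "c1ccccc1"

    def test_desalting_keeps_largest_organic_fragment(self):
        out = standardise_smiles("Cl.NCCc1ccccc1")
        assert len(Chem.GetMolFrags(Chem.MolFromSmiles(out))) == 1
        assert out == Chem.CanonSmiles("NCCc1ccccc1")

    def test_isotopes_stripped(self):
        assert standardise_smiles("[13CH3]c1ccccc1") == standardise_smiles("Cc1ccccc1")

    @pytest.mark.parametrize("bad", ["C(", "", "   ", "not-a-smiles"])
    def test_unparseable_raises(self, bad):
        with pytest.raises(InvalidStructureError):
            standardise_smiles(bad)

    def test_idempotent(self):
        once = standardise_smiles("CC(=O)Oc1ccccc1C(=O)O.[Na+]")
        assert standardise_smiles(once) == once

    def test_entry_wrapper_preserves_activity(self):
        entry = standardise(RawEntry("Cl.NCCc1ccccc1", 12.5, "nM"))
        assert entry.activity_value == 12.5
        assert "." not in entry.smiles_raw


class TestActivityLabel:
    @pytest.mark.parametrize(
        "value,expected",
        [(1.0, 0.0), (1000.0, -3.0), (0.1, 1.0), (10.0, -1.0)],
    )
    def test_negative_log10_in_original_unit(self, value, expected):
        assert compute_activity_label(value, "nM") == pytest.approx(expected, abs=1e-12)

    def test_no_unit_conversion(self):
        # same numeric value gives the same label whatever the unit
        assert compute_activity_label(50.0, "nM") == compute_activity_label(50.0, "uM")

    def test_three_orders_of_magnitude_give_delta_three(self):
        d = compute_activity_label(1.3, "nM") - compute_activity_label(1290.0, "nM")
        assert d == pytest.approx(3.0, abs=0.01)

    @pytest.mark.parametrize("bad", [0.0, -5.0, float("nan")])
    def test_non_positive_raises(self, bad):
        with pytest.raises(InvalidActivityError):
            compute_activity_label(bad, "nM")


class TestUnifyDuplicates:
    def test_geometric_mean_within_order_of_magnitude(self):
        smi = standardise_smiles("Cc1ccccc1")
        merged = unify_duplicates([RawEntry(smi, 100.0, "nM"), RawEntry(smi, 900.0, "nM")])
        assert merged.activity_value == pytest.approx(300.0)

    def test_boundary_factor_ten_is_unified(self):
        smi = "c1ccccc1"
        merged = unify_duplicates([RawEntry(smi, 10.0, "nM"), RawEntry(smi, 100.0, "nM")])
        assert merged is not None

    def test_unreliable_set_removed(self):
        smi = "c1ccccc1"
        assert unify_duplicates([RawEntry(smi, 10.0, "nM"), RawEntry(smi, 1000.0, "nM")]) is None

    def test_singleton_identity(self):
        merged = unify_duplicates([RawEntry("c1ccccc1", 500.0, "nM")])
        assert merged.activity_value == pytest.approx(500.0)

    def test_mixed_units_raise(self):
        smi = "c1ccccc1"
        with pytest.raises(UnitConflictError):
            unify_duplicates([RawEntry(smi, 1.0, "nM"), RawEntry(smi, 1.0, "uM")])

    def test_geometric_mean_equals_arithmetic_label_mean(self):
        smi = "c1ccccc1"
        values = [3.0, 7.0, 21.0]
        merged = unify_duplicates([RawEntry(smi, v, "nM") for v in values])
        label_of_mean = -math.log10(merged.activity_value)
        mean_of_labels = sum(-math.log10(v) for v in values) / len(values)
        assert label_of_mean == pytest.approx(mean_of_labels, abs=1e-12)


class TestCurate:
    ENTRIES = [
        RawEntry("Cc1ccccc1", 10.0, "nM"),
        RawEntry("Cl.Cc1ccccc1", 90.0, "nM"),       # duplicate after desalting
        RawEntry("CCc1ccccc1", 5.0, "nM"),
        RawEntry("c1ccccc1O", 1.0, "nM"),
        RawEntry("c1ccccc1O", 5000.0, "nM"),        # unreliable duplicate set
        RawEntry("C(C(", 1.0, "nM"),                # parse failure
    ]

    def test_counts_and_bookkeeping(self):
        compounds, log = curate(self.ENTRIES)
        assert log.n_parse_failures == 1
        assert log.n_duplicate_sets_unified == 1
        assert log.n_duplicate_sets_removed == 1
        # distinct standardised structures (3) minus removed sets (1)
        assert len(compounds) == 2 == log.n_output

    def test_order_invariance(self):
        a, _ = curate(self.ENTRIES)
        b, _ = curate(list(reversed(self.ENTRIES)))
        key = lambda cs: {(r.smiles_canonical, round(r.activity_label, 12)) for r in cs}
        assert key(a) == key(b)

    def test_idempotence(self):
        compounds, _ = curate(self.ENTRIES)
        again, log2 = curate(
            [RawEntry(r.smiles_canonical, r.activity_value, r.unit) for r in compounds]
        )
        assert {r.smiles_canonical for r in again} == {r.smiles_canonical for r in compounds}
        assert log2.n_duplicate_sets_unified == 0 == log2.n_duplicate_sets_removed

    def test_unique_ids_and_smiles_enforced(self):
        compounds, _ = curate(self.ENTRIES)
        with pytest.raises(ValueError):
            CompoundSet(records=list(compounds.records) + [compounds.records[0]])
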