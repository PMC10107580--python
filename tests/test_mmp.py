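"""MMP engine: cut enumeration, detection vs brute force, AC/PD labels."""

import numpy as np
import pytest
from rdkit import Chem

from acqsar.curation import CompoundRecord, CompoundSet, standardise_smiles
from acqsar.mmp import (
    AC,
    HALF_AC,
    NON_AC,
    MMPSet,
    UndefinedDirectionError,
    assign_ac_class,
    assign_pd_label,
    check_constraints,
    detect_mmps,
    detect_mmps_brute_force,
    enumerate_h_decompositions,
    enumerate_single_cuts,
    finalise_mmp_set,
    label_mmps,
    read_mmp_csv,
    write_mmp_set,
)


def make_set(smiles_to_label: dict[str, float]) -> CompoundSet:
    records = [
        CompoundRecord(f"C{i}", standardise_smiles(smi), 10.0 ** (-lab), lab)
        for i, (smi, lab) in enumerate(sorted(smiles_to_label.items()))
    ]
    return CompoundSet(records=records)


class TestEnumeration:
    def test_toluene_single_bond_two_orientations(self):
        decomps = enumerate_single_cuts("Cc1ccccc1")
        assert len(decomps) == 2
        cores = {(d.core_smiles, d.n_core, d.n_var) for d in decomps}
        assert ("*c1ccccc1", 6, 1) in cores
        assert ("*C", 1, 6) in cores

    def test_ring_bonds_never_cut(self):
        assert enumerate_single_cuts("C1CCCCC1") == []

    def test_single_heavy_atom_has_no_cuts(self):
        assert enumerate_single_cuts("C") == []

    def test_double_bonds_not_cut(self):
        # ethene's only heavy bond is a double bond
        assert enumerate_single_cuts("C=C") == []

    def test_h_decompositions_have_zero_atom_variable_part(self):
        decomps = enumerate_h_decompositions("c1ccccc1")
        # all six aromatic CH positions are symmetric -> same core SMILES
        assert {d.core_smiles for d in decomps} == {"*c1ccccc1"}
        assert all(d.n_var == 0 for d in decomps)

    def test_reassembly_reproduces_parent(self):
        # stitching core and variable part back together gives the molecule
        smi = standardise_smiles("CCOc1ccc2ncccc2c1")
        for d in enumerate_single_cuts(smi):
            core = Chem.MolFromSmiles(d.core_smiles.replace("*", "[*:1]"))
            var = Chem.MolFromSmiles(d.variable_smiles.replace("*", "[*:1]"))
            rejoined = Chem.molzip(Chem.CombineMols(core, var))
            assert Chem.MolToSmiles(rejoined) == smi


class TestDetection:
    def test_toluene_ethylbenzene_form_one_mmp(self):
        cs = make_set({"Cc1ccccc1": 0.0, "CCc1ccccc1": 1.0})
        mmps = detect_mmps(cs)
        assert len(mmps) == 1
        rec = mmps.records[0]
        # canonical core maximises heavy atoms: the benzyl core (H <-> CH3
        # exchange) beats the phenyl core (CH3 <-> C2H5 exchange)
        assert rec.core_smiles == "*Cc1ccccc1"
        assert rec.n_core == 7
        assert detect_mmps_brute_force(cs).pairs() == mmps.pairs()

    def test_oversized_variable_part_rejected(self):
        cs = make_set({"Cc1ccccc1": 0.0, "CCCCCCCCCCCCCCc1ccccc1": 1.0})
        assert len(detect_mmps(cs)) == 0
        assert len(detect_mmps_brute_force(cs)) == 0

    def test_hydrogen_replacement_pair(self):
        cs = make_set({"c1ccccc1": 0.0, "Oc1ccccc1": 2.5})
        mmps = detect_mmps(cs)
        assert len(mmps) == 1
        rec = mmps.records[0]
        assert {rec.var_smiles_1, rec.var_smiles_2} == {"[H][*]", "*O"}
        assert {rec.n_var_1, rec.n_var_2} == {0, 1}

    def test_self_pairing_impossible(self):
        cs = make_set({"Cc1ccccc1": 0.0})
        assert len(detect_mmps(cs)) == 0

    def test_symmetry_under_compound_permutation(self):
        smis = {"Cc1ccccc1": 0.0, "CCc1ccccc1": 1.0, "Oc1ccccc1": 2.0, "Clc1ccccc1": 0.5}
        records = [
            CompoundRecord(f"C{i}", standardise_smiles(s), 10.0 ** (-l), l)
            for i, (s, l) in enumerate(smis.items())
        ]
        a = detect_mmps(CompoundSet(records=list(records)))
        b = detect_mmps(CompoundSet(records=list(reversed(records))))
        key = lambda m: {(r.pair, r.core_smiles) for r in m}
        assert key(a) == key(b)

    def test_every_record_satisfies_size_constraints(self, default_run):
        check_constraints(default_run.mmps_labelled)  # raises on violation

    def test_brute_force_equivalence_on_random_subsets(self, small_noise_free_run):
        comp = list(small_noise_free_run.compounds)
        rng = np.random.default_rng(11)
        for _ in range(5):
            idx = rng.choice(len(comp), size=20, replace=False)
            subset = CompoundSet(records=[comp[i] for i in idx])
            fast, slow = detect_mmps(subset), detect_mmps_brute_force(subset)
            assert fast.pairs() == slow.pairs()
            assert {(r.pair, r.core_smiles) for r in fast} == {
                (r.pair, r.core_smiles) for r in slow
            }


class TestLabels:
    @pytest.mark.parametrize(
        "delta,expected",
        [(0.0, NON_AC), (1.0, NON_AC), (1.0000001, HALF_AC), (1.5, HALF_AC), (1.9999999, HALF_AC), (2.0, AC), (3.7, AC)],
    )
    def test_class_boundaries(self, delta, expected):
        assert assign_ac_class(0.0, delta) == expected
        assert assign_ac_class(delta, 0.0) == expected

    def test_classes_partition_for_random_deltas(self):
        rng = np.random.default_rng(0)
        for d in rng.uniform(0, 5, size=200):
            assert assign_ac_class(0.0, d) in (AC, HALF_AC, NON_AC)

    def test_pd_label_is_larger_label(self):
        assert assign_pd_label("a", "b", -1.0, -3.0) == "a"
        assert assign_pd_label("a", "b", -3.0, -1.0) == "b"

    def test_pd_tie_raises(self):
        with pytest.raises(UndefinedDirectionError):
            assign_pd_label("a", "b", 0.0, 0.0)

    def test_finalise_counts_and_removal(self):
        cs = make_set({"Cc1ccccc1": 0.0, "CCc1ccccc1": 2.5, "Oc1ccccc1": 1.5})
        labelled = label_mmps(detect_mmps(cs), cs)
        final, summary = finalise_mmp_set(labelled)
        assert summary.n_mmps == len(labelled)
        assert summary.n_ac + summary.n_half_ac + summary.n_non_ac == summary.n_mmps
        assert len(final) == summary.n_ac + summary.n_non_ac
        assert all(r.ac_class in (AC, NON_AC) for r in final)

    def test_delta_consistent_with_class_on_fixture(self, small_noise_free_run):
        for r in small_noise_free_run.mmps_labelled:
            assert assign_ac_class(0.0, r.delta_label) == r.ac_class


class TestRoundTrip:
    def test_csv_round_trip(self, tmp_path, small_noise_free_run):
        path = tmp_path / "mmps.csv"
        write_mmp_set(small_noise_free_run.mmps, path)
        loaded = read_mmp_csv(path)
        assert loaded.pairs() == small_noise_free_run.mmps.pairs()
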