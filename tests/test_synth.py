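"""Synthetic landscape generator: determinism, combinatorics, planted cliffs."""

import numpy as np
import pytest

from acqsar.curation import RawEntry, curate
from acqsar.mmp import AC, NON_AC, detect_mmps, label_mmps
from acqsar.synth import (
    DEFAULT_CLIFF_FRAGMENT,
    OVERSIZED_SUBSTITUENT,
    assemble,
    default_landscape,
    generate,
    heavy_atom_count,
    verify_recovery,
)


class TestSpecAndAssembly:
    def test_default_spec_shape(self):
        spec = default_landscape(seed=0)
        assert spec.n_compounds == 1000
        assert DEFAULT_CLIFF_FRAGMENT in spec.substituent_library
        assert spec.cliff_fragments == {DEFAULT_CLIFF_FRAGMENT}
        assert all(abs(v) <= 0.5 for v in spec.substituent_effects.values())

    def test_cliff_effect_floor_enforced(self):
        spec = default_landscape(seed=0)
        with pytest.raises(ValueError):
            type(spec)(**{**spec.__dict__, "cliff_effect": 1.0})

    def test_assembly_parses_and_is_canonical(self):
        smi = assemble("[*:1]c1ccc2ccccc2c1", "[*:1]OC")
        from rdkit import Chem

        assert Chem.MolFromSmiles(smi) is not None
        assert smi == Chem.CanonSmiles(smi)

    def test_heavy_atom_count_ignores_attachment(self):
        assert heavy_atom_count("[*:1]C(F)(F)F") == 4
        assert heavy_atom_count("[H]") == 0


class TestGenerate:
    def test_seeded_determinism(self):
        spec = default_landscape(seed=42, n_scaffolds=4, n_substituents=8)
        t1, g1 = generate(spec)
        t2, g2 = generate(spec)
        assert t1.equals(t2)
        assert g1.true_labels == g2.true_labels

    def test_combinatorial_counts(self):
        spec = default_landscape(seed=1, n_scaffolds=3, n_substituents=20, duplicate_rate=0.0, salt_rate=0.0)
        table, truth = generate(spec)
        assert len(truth.true_labels) == 60
        assert len(truth.pairs) == 3 * 20 * 19 // 2  # 570 candidate pairs

    def test_noise_free_deltas_follow_effect_model(self):
        spec = default_landscape(seed=2, n_scaffolds=2, n_substituents=6, noise_sd=0.0)
        _, truth = generate(spec)
        for p in truth.pairs:
            assert p.delta_noise_free == pytest.approx(
                abs(truth.true_labels[p.smiles_1] - truth.true_labels[p.smiles_2])
            )

    def test_cliff_pairs_planted_on_active_scaffolds(self):
        spec = default_landscape(seed=5, n_scaffolds=6, n_substituents=12, noise_sd=0.0)
        _, truth = generate(spec)
        cliff_smiles = {s for s, sub in truth.substituent_of.items() if sub == DEFAULT_CLIFF_FRAGMENT}
        for p in truth.pairs:
            involves_cliff = bool({p.smiles_1, p.smiles_2} & cliff_smiles)
            on_active = p.scaffold_index in truth.cliff_active_scaffolds
            if involves_cliff and on_active:
                assert p.ac_class == AC
        assert truth.class_counts()[AC] > 0

    def test_salts_and_duplicates_present(self):
        spec = default_landscape(seed=0, n_scaffolds=5, n_substituents=10, duplicate_rate=0.3, salt_rate=0.3)
        table, truth = generate(spec)
        assert len(table) > len(truth.true_labels)
        assert any("." in s for s in table.smiles)

    def test_class_imbalance_in_study_regime(self, default_run):
        counts = default_run.truth.class_counts()
        ratio = counts[NON_AC] / counts[AC]
        assert 10 <= ratio <= 70


class TestRecovery:
    def test_recovery_complete_and_exact_at_sigma_zero(self, small_noise_free_run):
        run = small_noise_free_run
        rep = verify_recovery(run.mmps_labelled, run.truth, run.compounds)
        assert rep.recovery == 1.0
        assert rep.label_agreement == 1.0
        assert rep.n_unexpected_missing == 0

    def test_oversized_substituent_flagged_expected_missing(self):
        spec = default_landscape(seed=9, n_scaffolds=3, n_substituents=8, noise_sd=0.0,
                                 duplicate_rate=0.0, salt_rate=0.0, duplicate_jitter=0.0)
        spec.substituent_library.append(OVERSIZED_SUBSTITUENT)
        spec.substituent_effects[OVERSIZED_SUBSTITUENT] = 0.2
        table, truth = generate(spec)
        oversized = [p for p in truth.pairs if not p.expected_mmp]
        assert len(oversized) == 3 * 8  # every pair with the macrocycle, per scaffold
        compounds, _ = curate([RawEntry(r.smiles, r.activity, r.unit) for r in table.itertuples()])
        labelled = label_mmps(detect_mmps(compounds), compounds)
        rep = verify_recovery(labelled, truth, compounds)
        assert rep.recovery == 1.0
        assert rep.n_expected_missing == len(oversized)

    def test_empty_substituent_library_yields_empty_landscape(self):
        spec = default_landscape(seed=0, n_scaffolds=2, n_substituents=4)
        spec.substituent_library = []
        spec.cliff_fragments = set()
        table, truth = generate(spec)
        assert len(truth.true_labels) == 0 and len(truth.pairs) == 0
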