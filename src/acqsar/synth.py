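"""Synthetic structure-activity landscapes with planted activity cliffs.

The generator assembles congeneric series — ring-system scaffolds decorated
with one exchangeable substituent — so matched molecular pairs exist in
quantity by construction. The noise-free activity label of a compound is

    a = base(scaffold) + effect(substituent, scaffold) + context(scaffold, substituent)

with a designated cliff substituent carrying a large effect (>= 2.5 log10
units) on a seeded subset of scaffolds and none on the rest: activity cliffs
in real series are context-dependent, and a globally additive cliff fragment
would be trivially learnable from fingerprints. Ordinary substituent effects
stay within about a third of a log unit, so same-scaffold pairs not involving an active
cliff substituent are overwhelmingly non-ACs, giving the strong class
imbalance (about 1:20 to 1:40 AC:non-AC) typical of assay extracts.

Measured labels add Gaussian noise (sd ``noise_sd``, log10 units); reported
activities are ``10**(-label)`` in nM. Configurable fractions of rows are
duplicated (with a small multiplicative value jitter) and salt-decorated, to
exercise the curation pipeline. Every random draw derives from ``seed``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem

from .curation import CompoundSet
from .mmp import (
    AC,
    DEFAULT_CORE_RATIO,
    DEFAULT_MAX_VAR_ATOMS,
    DEFAULT_MAX_VAR_DIFF,
    HALF_AC,
    NON_AC,
    MMPSet,
    assign_ac_class,
)

H_SUBSTITUENT = "[H]"

#: Scaffold templates: distinct ring systems, one substitution point each,
#: >= 10 heavy atoms so the shared core always dominates the exchanged part.
SCAFFOLD_TEMPLATES: tuple[str, ...] = (
    "[*:1]c1ccc2ccccc2c1",            # naphthalene
    "[*:1]c1ccc2ncccc2c1",            # quinoline
    "[*:1]c1ccc2[nH]ccc2c1",          # indole
    "[*:1]c1ccc2occc2c1",             # benzofuran
    "[*:1]c1ccc2sccc2c1",             # benzothiophene
    "[*:1]c1ccc2nccnc2c1",            # quinoxaline
    "[*:1]c1ccc2ncncc2c1",            # quinazoline-like
    "[*:1]c1ccc2c(c1)OCO2",           # benzodioxole
    "[*:1]c1ccc2c(c1)CCC2",           # indane
    "[*:1]c1ccc2c(c1)CCCC2",          # tetralin
    "[*:1]c1ccc2c(c1)oc(C)n2",        # methylbenzoxazole
    "[*:1]c1ccc2c(c1)sc(C)n2",        # methylbenzothiazole
    "[*:1]c1ccc2c(c1)nc(C)[nH]2",     # methylbenzimidazole
    "[*:1]c1ccc2c(c1)C(=O)CC2",       # indanone
    "[*:1]c1ccc2c(c1)C(=O)CCC2",      # tetralone
    "[*:1]c1ccc2scnc2c1",             # benzothiazole
    "[*:1]c1ccc2cc(C)c(C)cc2c1",      # dimethylnaphthalene
    "[*:1]c1ccc2cnccc2c1",            # isoquinoline
    "[*:1]c1ccc2c(c1)N(C)C(=O)C2",    # oxindole-like
    "[*:1]c1ccc2c(c1)CC(=O)O2",       # benzofuranone
    "[*:1]c1ccc2c(c1)CCO2",           # dihydrobenzofuran
    "[*:1]c1ccc2c(c1)CCN2C",          # N-methylindoline
    "[*:1]c1ccc2c(c1)C(C)(C)CC2",     # gem-dimethylindane
    "[*:1]c1ccc2nc(C)ccc2c1",         # methylquinoline
    "[*:1]c1ccc2[nH]c(C)cc2c1",       # methylindole
    "[*:1]c1ccc2c(c1)CCS2",           # dihydrobenzothiophene
    "[*:1]c1ccc2c(c1)CCCN2C",         # N-methyltetrahydroquinoline
    "[*:1]c1ccc2c(c1)c(C)co2",        # dimethylbenzofuran-like
    "[*:1]c1ccc2c(C)cccc2c1",         # methylnaphthalene isomer
    "[*:1]c1ccc2c(c1)OCCO2",          # benzodioxine
)

#: Substituent library (<= 5 heavy atoms each, attachment marked [*:1]).
SUBSTITUENT_LIBRARY: tuple[str, ...] = (
    H_SUBSTITUENT,
    "[*:1]C", "[*:1]CC", "[*:1]CCC", "[*:1]C(C)C", "[*:1]CCCC",
    "[*:1]C(C)(C)C", "[*:1]C1CC1", "[*:1]C1CCC1",
    "[*:1]O", "[*:1]OC", "[*:1]OCC", "[*:1]OC(C)C", "[*:1]OCCO",
    "[*:1]N", "[*:1]NC", "[*:1]N(C)C", "[*:1]NCC", "[*:1]NC(C)=O",
    "[*:1]F", "[*:1]Cl", "[*:1]Br", "[*:1]I",
    "[*:1]C#N", "[*:1]C(F)(F)F", "[*:1]OC(F)(F)F",
    "[*:1]C=O", "[*:1]C(C)=O", "[*:1]C(=O)O", "[*:1]C(=O)OC",
    "[*:1]C(N)=O", "[*:1]C(=O)NC",
    "[*:1]S", "[*:1]SC", "[*:1]S(C)=O", "[*:1]S(C)(=O)=O",
    "[*:1]C=C", "[*:1]C#C", "[*:1]CO", "[*:1]CCO", "[*:1]CN",
    "[*:1]N1CCCC1", "[*:1]OCC#N",
)

#: Default cliff-inducing substituent (sulfonamide-like, strongly felt only on
#: scaffolds where its binding context exists).
DEFAULT_CLIFF_FRAGMENT = "[*:1]S(N)(=O)=O"

#: A macrocyclic substituent of 14 ring atoms: every internal bond is a ring
#: bond, so its only decomposition is the full 14-atom variable part, which
#: violates the 13-atom constraint — pairs involving it are expected missing.
OVERSIZED_SUBSTITUENT = "[*:1]C1CCCCCCCCCCCCC1"

SALT_FRAGMENTS: tuple[str, ...] = ("Cl", "O", "[Na+]")


def heavy_atom_count(fragment_smiles: str) -> int:
    """Heavy atoms in a fragment SMILES, ignoring the attachment dummy."""
    if fragment_smiles == H_SUBSTITUENT:
        return 0
    mol = Chem.MolFromSmiles(fragment_smiles)
    if mol is None:
        raise ValueError(f"unparseable fragment: {fragment_smiles!r}")
    return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() > 1)


def assemble(scaffold_template: str, substituent: str) -> str:
    """Canonical SMILES of scaffold + substituent joined at the attachment."""
    scaffold = Chem.MolFromSmiles(scaffold_template)
    if scaffold is None:
        raise ValueError(f"unparseable scaffold template: {scaffold_template!r}")
    if substituent == H_SUBSTITUENT:
        rw = Chem.RWMol(scaffold)
        dummies = [a.GetIdx() for a in rw.GetAtoms() if a.GetAtomicNum() == 0]
        if len(dummies) != 1:
            raise ValueError(f"template needs exactly one attachment: {scaffold_template!r}")
        rw.RemoveAtom(dummies[0])
        mol = rw.GetMol()
    else:
        sub = Chem.MolFromSmiles(substituent)
        if sub is None:
            raise ValueError(f"unparseable substituent: {substituent!r}")
        mol = Chem.molzip(Chem.CombineMols(scaffold, sub))
    Chem.SanitizeMol(mol)
    return Chem.MolToSmiles(mol)


@dataclass
class LandscapeSpec:
    """Parameters of one synthetic SAR landscape.

    ``substituent_effects`` maps fragment SMILES to ordinary effects (log10
    units); ``cliff_fragments`` carry ``cliff_effect`` instead, on a seeded
    fraction ``cliff_scaffold_fraction`` of scaffolds. ``context_sd`` is the
    sd of the per-(scaffold, substituent) context term.
    """

    scaffold_templates: list[str]
    substituent_library: list[str]
    base_potency: list[float]
    substituent_effects: dict[str, float]
    cliff_fragments: set[str] = field(default_factory=set)
    cliff_effect: float = 3.0
    cliff_scaffold_fraction: float = 0.5
    context_sd: float = 0.10
    noise_sd: float = 0.3
    seed: int = 0
    duplicate_rate: float = 0.05
    duplicate_jitter: float = 0.02
    salt_rate: float = 0.05

    def __post_init__(self) -> None:
        if len(self.base_potency) != len(self.scaffold_templates):
            raise ValueError("need one base potency per scaffold")
        if not set(self.cliff_fragments) <= set(self.substituent_library):
            raise ValueError("cliff_fragments must be a subset of the substituent library")
        if abs(self.cliff_effect) < 2.5:
            raise ValueError("cliff effect must be at least 2.5 log10 units")
        for frag in self.substituent_library:
            if heavy_atom_count(frag) > DEFAULT_MAX_VAR_ATOMS and frag != OVERSIZED_SUBSTITUENT:
                raise ValueError(f"substituent exceeds {DEFAULT_MAX_VAR_ATOMS} heavy atoms: {frag!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def n_compounds(self) -> int:
        return len(self.scaffold_templates) * len(self.substituent_library)


def default_landscape(
    seed: int = 0,
    n_scaffolds: int = 25,
    n_substituents: int = 40,
    noise_sd: float = 0.3,
    duplicate_rate: float = 0.05,
    duplicate_jitter: float = 0.02,
    salt_rate: float = 0.05,
) -> LandscapeSpec:
    """The default study landscape: ~1000 compounds (25 scaffolds x 40
    substituents including one cliff fragment), base potencies in the
    0.3 nM - 1 uM range, ordinary effects within +-0.35 log units."""
    if n_scaffolds > len(SCAFFOLD_TEMPLATES):
        raise ValueError(f"at most {len(SCAFFOLD_TEMPLATES)} scaffold templates available")
    if n_substituents > len(SUBSTITUENT_LIBRARY) + 1:
        raise ValueError(f"at most {len(SUBSTITUENT_LIBRARY) + 1} substituents available")
    rng = np.random.default_rng(seed)
    scaffolds = list(SCAFFOLD_TEMPLATES[:n_scaffolds])
    ordinary = list(SUBSTITUENT_LIBRARY[: n_substituents - 1])
    library = ordinary + [DEFAULT_CLIFF_FRAGMENT]
    effects = {frag: float(rng.uniform(-0.35, 0.35)) for frag in ordinary}
    effects[DEFAULT_CLIFF_FRAGMENT] = 0.0  # replaced by cliff_effect where active
    base = [float(rng.uniform(-3.0, -0.5)) for _ in scaffolds]
    return LandscapeSpec(
        scaffold_templates=scaffolds,
        substituent_library=library,
        base_potency=base,
        substituent_effects=effects,
        cliff_fragments={DEFAULT_CLIFF_FRAGMENT},
        noise_sd=noise_sd,
        seed=seed,
        duplicate_rate=duplicate_rate,
        duplicate_jitter=duplicate_jitter,
        salt_rate=salt_rate,
    )


@dataclass(frozen=True)
class TruthPair:
    """One same-scaffold compound pair with its noise-free delta and class."""

    smiles_1: str
    smiles_2: str
    scaffold_index: int
    delta_noise_free: float
    ac_class: str
    expected_mmp: bool  # size-constraint arithmetic with the scaffold as core


@dataclass
class GroundTruth:
    """Noise-free bookkeeping for a generated landscape."""

    true_labels: dict[str, float]            # canonical SMILES -> noise-free label
    scaffold_of: dict[str, int]
    substituent_of: dict[str, str]
    pairs: list[TruthPair]
    cliff_active_scaffolds: set[int]

    def pair_index(self) -> dict[frozenset[str], TruthPair]:
        return {frozenset((p.smiles_1, p.smiles_2)): p for p in self.pairs}

    def class_counts(self) -> dict[str, int]:
        out = {AC: 0, HALF_AC: 0, NON_AC: 0}
        for p in self.pairs:
            out[p.ac_class] += 1
        return out

    def to_json(self, path) -> None:
        payload = {
            "true_labels": self.true_labels,
            "scaffold_of": self.scaffold_of,
            "substituent_of": self.substituent_of,
            "cliff_active_scaffolds": sorted(self.cliff_active_scaffolds),
            "pairs": [p.__dict__ for p in self.pairs],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def _expected_mmp(n_scaffold: int, n_var_1: int, n_var_2: int) -> bool:
    return (
        n_var_1 <= DEFAULT_MAX_VAR_ATOMS
        and n_var_2 <= DEFAULT_MAX_VAR_ATOMS
        and n_scaffold >= DEFAULT_CORE_RATIO * max(n_var_1, n_var_2)
        and abs(n_var_1 - n_var_2) <= DEFAULT_MAX_VAR_DIFF
    )


def generate(spec: LandscapeSpec) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate the raw compound table and its ground truth.

    The table has columns smiles, activity (nM), unit and includes the
    configured duplicate and salt contamination; the ground truth records
    noise-free labels and every same-scaffold pair with its implied class.
    """
    rng = np.random.default_rng(spec.seed)
    n_sc = len(spec.scaffold_templates)
    n_sub = len(spec.substituent_library)

    n_cliff_active = int(round(spec.cliff_scaffold_fraction * n_sc))
    cliff_active = set(map(int, rng.choice(n_sc, size=n_cliff_active, replace=False)))
    context = rng.normal(0.0, spec.context_sd, size=(n_sc, n_sub)) if spec.context_sd > 0 else np.zeros((n_sc, n_sub))

    sub_heavy = [heavy_atom_count(s) for s in spec.substituent_library]
    scaffold_heavy = [
        heavy_atom_count(t.replace("[*:1]", "[*]")) for t in spec.scaffold_templates
    ]

    true_labels: dict[str, float] = {}
    scaffold_of: dict[str, int] = {}
    substituent_of: dict[str, str] = {}
    smiles_grid: list[list[str]] = []
    for i, template in enumerate(spec.scaffold_templates):
        row = []
        for j, sub in enumerate(spec.substituent_library):
            smi = assemble(template, sub)
            if smi in true_labels:
                raise ValueError(f"assembled duplicate structure {smi!r} from template {template!r}")
            if sub in spec.cliff_fragments:
                effect = spec.cliff_effect if i in cliff_active else 0.0
            else:
                effect = spec.substituent_effects[sub]
            true_labels[smi] = spec.base_potency[i] + effect + float(context[i, j])
            scaffold_of[smi] = i
            substituent_of[smi] = sub
            row.append(smi)
        smiles_grid.append(row)

    pairs: list[TruthPair] = []
    for i in range(n_sc):
        for j1 in range(n_sub):
            for j2 in range(j1 + 1, n_sub):
                s1, s2 = smiles_grid[i][j1], smiles_grid[i][j2]
                delta = abs(true_labels[s1] - true_labels[s2])
                pairs.append(
                    TruthPair(
                        smiles_1=s1,
                        smiles_2=s2,
                        scaffold_index=i,
                        delta_noise_free=delta,
                        ac_class=assign_ac_class(true_labels[s1], true_labels[s2]),
                        expected_mmp=_expected_mmp(scaffold_heavy[i], sub_heavy[j1], sub_heavy[j2]),
                    )
                )

    rows = []
    for smi, label0 in true_labels.items():
        label = label0 + (rng.normal(0.0, spec.noise_sd) if spec.noise_sd > 0 else 0.0)
        value = 10.0 ** (-label)
        reported = smi
        if rng.random() < spec.salt_rate:
            reported = smi + "." + str(rng.choice(SALT_FRAGMENTS))
        rows.append({"smiles": reported, "activity": value, "unit": "nM"})
        if rng.random() < spec.duplicate_rate:
            jitter = 1.0 + rng.uniform(-spec.duplicate_jitter, spec.duplicate_jitter)
            rows.append({"smiles": smi, "activity": value * jitter, "unit": "nM"})

    return pd.DataFrame(rows), GroundTruth(
        true_labels=true_labels,
        scaffold_of=scaffold_of,
        substituent_of=substituent_of,
        pairs=pairs,
        cliff_active_scaffolds=cliff_active,
    )


@dataclass
class RecoveryReport:
    """Agreement between detected MMPs and the generator's ground truth."""

    n_expected: int
    n_recovered: int
    n_expected_missing: int          # pairs the size constraints exclude, absent as expected
    n_unexpected_missing: int
    n_class_compared: int
    n_class_matches: int

    @property
    def recovery(self) -> float:
        return self.n_recovered / self.n_expected if self.n_expected else float("nan")

    @property
    def label_agreement(self) -> float:
        return self.n_class_matches / self.n_class_compared if self.n_class_compared else float("nan")


def verify_recovery(detected: MMPSet, truth: GroundTruth, compounds: CompoundSet) -> RecoveryReport:
    """Check that detection found every constraint-satisfying ground-truth pair
    and that detected AC classes match the noise-free classes."""
    smiles_of = {r.compound_id: r.smiles_canonical for r in compounds}
    detected_by_smiles: dict[frozenset[str], str | None] = {}
    for r in detected:
        key = frozenset((smiles_of[r.id_1], smiles_of[r.id_2]))
        detected_by_smiles[key] = r.ac_class

    n_expected = n_recovered = n_exp_missing = n_unexp_missing = 0
    n_cmp = n_match = 0
    for p in truth.pairs:
        key = frozenset((p.smiles_1, p.smiles_2))
        present = key in detected_by_smiles
        if p.expected_mmp:
            n_expected += 1
            if present:
                n_recovered += 1
                n_cmp += 1
                if detected_by_smiles[key] == p.ac_class:
                    n_match += 1
            else:
                n_unexp_missing += 1
        elif not present:
            n_exp_missing += 1
    return RecoveryReport(
        n_expected=n_expected,
        n_recovered=n_recovered,
        n_expected_missing=n_exp_missing,
        n_unexpected_missing=n_unexp_missing,
        n_class_compared=n_cmp,
        n_class_matches=n_match,
    )
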