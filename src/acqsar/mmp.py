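"""Matched molecular pair (MMP) enumeration, canonical cores and AC labels.

An MMP is an unordered pair of compounds that share a structural core and
differ by a single substituent exchange at one site. Pairs are found by
single cuts of acyclic single bonds (plus hydrogen replacements, so that
H <-> OH style transformations are representable), subject to the size
constraints conventional in the MMP literature:

* the core must contain at least twice as many heavy atoms as either
  variable part,
* each variable part may contain at most 13 heavy atoms,
* the two variable parts may differ by at most 8 heavy atoms.

Each pair is labelled by its absolute activity-label difference
``delta = |a(s) - a(s~)|`` (log10 units):

* ``AC``      if delta >= 2   (activities differ by a factor >= 100),
* ``non-AC``  if delta <= 1   (factor <= 10),
* ``half-AC`` otherwise; half-ACs are removed before any classification.

The potency direction (PD) of a pair is the identity of its more active
compound (larger activity label).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import pandas as pd
from rdkit import Chem

from .curation import CompoundRecord, CompoundSet

AC = "AC"
HALF_AC = "half-AC"
NON_AC = "non-AC"

#: Default size constraints: (core >= ratio * var, var <= max_var, |v1-v2| <= max_diff)
DEFAULT_CORE_RATIO = 2.0
DEFAULT_MAX_VAR_ATOMS = 13
DEFAULT_MAX_VAR_DIFF = 8

_H_VAR_SMILES = "[H][*]"  # canonical SMILES of a hydrogen variable part


class UndefinedDirectionError(ValueError):
    """Raised when the potency direction of an exactly tied pair is requested."""


@dataclass(frozen=True)
class Decomposition:
    """One (core, variable part) fragmentation of a molecule at a single site."""

    core_smiles: str
    variable_smiles: str
    n_core: int
    n_var: int


@dataclass(frozen=True)
class MMPRecord:
    """An unordered matched pair with its canonical core and labels."""

    id_1: str
    id_2: str
    core_smiles: str
    var_smiles_1: str
    var_smiles_2: str
    n_core: int
    n_var_1: int
    n_var_2: int
    delta_label: float | None = None
    ac_class: str | None = None
    pd_label: str | None = None

    @property
    def pair(self) -> frozenset[str]:
        return frozenset((self.id_1, self.id_2))


@dataclass
class MMPSet:
    """A collection of MMP records over a compound set (the set M)."""

    records: list[MMPRecord]

    def __post_init__(self) -> None:
        pairs = [r.pair for r in self.records]
        if len(pairs) != len(set(pairs)):
            raise ValueError("at most one MMP record per unordered compound pair")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def pairs(self) -> set[frozenset[str]]:
        return {r.pair for r in self.records}

    def cores(self) -> set[str]:
        return {r.core_smiles for r in self.records}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "compound_id_1": [r.id_1 for r in self.records],
                "compound_id_2": [r.id_2 for r in self.records],
                "core_smiles": [r.core_smiles for r in self.records],
                "var_smiles_1": [r.var_smiles_1 for r in self.records],
                "var_smiles_2": [r.var_smiles_2 for r in self.records],
                "delta_label": [r.delta_label for r in self.records],
                "ac_class": [r.ac_class for r in self.records],
                "pd_label": [r.pd_label for r in self.records],
            }
        )


def _fragment_smiles(mol: Chem.Mol, atom_ids: set[int], attach_atom: int) -> str:
    """Canonical SMILES of the sub-molecule over ``atom_ids`` with a wildcard
    attachment attached to ``attach_atom``."""
    emol = Chem.RWMol()
    mapping: dict[int, int] = {}
    for aid in sorted(atom_ids):
        atom = mol.GetAtomWithIdx(aid)
        new = Chem.Atom(atom.GetAtomicNum())
        new.SetFormalCharge(atom.GetFormalCharge())
        new.SetIsAromatic(atom.GetIsAromatic())
        new.SetChiralTag(atom.GetChiralTag())
        new.SetNumExplicitHs(atom.GetTotalNumHs())
        new.SetNoImplicit(True)
        mapping[aid] = emol.AddAtom(new)
    for bond in mol.GetBonds():
        a, b = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if a in atom_ids and b in atom_ids:
            emol.AddBond(mapping[a], mapping[b], bond.GetBondType())
    star = emol.AddAtom(Chem.Atom(0))
    emol.AddBond(mapping[attach_atom], star, Chem.BondType.SINGLE)
    # the attachment replaces one hydrogen / the cut-bond neighbour
    at = emol.GetAtomWithIdx(mapping[attach_atom])
    if at.GetNumExplicitHs() > 0 and _needs_h_removal(mol, attach_atom, atom_ids):
        at.SetNumExplicitHs(at.GetNumExplicitHs() - 1)
    frag = emol.GetMol()
    try:
        Chem.SanitizeMol(frag)
    except Exception:
        return ""
    return Chem.MolToSmiles(frag)


def _needs_h_removal(mol: Chem.Mol, attach_atom: int, atom_ids: set[int]) -> bool:
    """True when the attachment replaces a hydrogen (H-cut) rather than the
    neighbour lost by a heavy-bond cut."""
    kept_neighbours = sum(1 for n in mol.GetAtomWithIdx(attach_atom).GetNeighbors() if n.GetIdx() in atom_ids)
    return kept_neighbours == mol.GetAtomWithIdx(attach_atom).GetDegree()


def _connected_component(mol: Chem.Mol, start: int, broken: tuple[int, int]) -> set[int]:
    """Atom ids reachable from ``start`` without traversing the broken bond."""
    seen = {start}
    stack = [start]
    a, b = broken
    while stack:
        cur = stack.pop()
        for nb in mol.GetAtomWithIdx(cur).GetNeighbors():
            nid = nb.GetIdx()
            if {cur, nid} == {a, b}:
                continue
            if nid not in seen:
                seen.add(nid)
                stack.append(nid)
    return seen


def enumerate_single_cuts(compound: CompoundRecord | str) -> list[Decomposition]:
    """All decompositions from single cuts of acyclic heavy-atom single bonds.

    Each cuttable bond contributes both (core, variable) orientations. Ring
    bonds are never cut; a molecule without a cuttable bond yields ``[]``.
    """
    smiles = compound.smiles_canonical if isinstance(compound, CompoundRecord) else compound
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    decomps: list[Decomposition] = []
    for bond in mol.GetBonds():
        if bond.IsInRing() or bond.GetBondType() != Chem.BondType.SINGLE:
            continue
        a, b = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        side_a = _connected_component(mol, a, (a, b))
        side_b = _connected_component(mol, b, (a, b))
        smi_a = _fragment_smiles(mol, side_a, a)
        smi_b = _fragment_smiles(mol, side_b, b)
        if not smi_a or not smi_b:
            continue
        na, nb_ = len(side_a), len(side_b)
        decomps.append(Decomposition(core_smiles=smi_a, variable_smiles=smi_b, n_core=na, n_var=nb_))
        decomps.append(Decomposition(core_smiles=smi_b, variable_smiles=smi_a, n_core=nb_, n_var=na))
    return decomps


def enumerate_h_decompositions(compound: CompoundRecord | str) -> list[Decomposition]:
    """Decompositions whose variable part is a hydrogen atom (zero heavy atoms).

    One per heavy atom bearing at least one hydrogen: the core is the whole
    molecule with an attachment at that position. These make hydrogen
    replacements (e.g. H <-> OH) representable as MMPs.
    """
    smiles = compound.smiles_canonical if isinstance(compound, CompoundRecord) else compound
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    all_atoms = set(range(mol.GetNumAtoms()))
    n = mol.GetNumAtoms()
    decomps = []
    for atom in mol.GetAtoms():
        if atom.GetTotalNumHs() < 1:
            continue
        core = _fragment_smiles(mol, all_atoms, atom.GetIdx())
        if core:
            decomps.append(
                Decomposition(core_smiles=core, variable_smiles=_H_VAR_SMILES, n_core=n, n_var=0)
            )
    return decomps


def all_decompositions(
    compound: CompoundRecord | str,
    max_var_atoms: int = DEFAULT_MAX_VAR_ATOMS,
    core_ratio: float = DEFAULT_CORE_RATIO,
) -> list[Decomposition]:
    """Heavy-bond and hydrogen decompositions, pre-filtered by the one-sided
    constraints (own variable part <= ``max_var_atoms`` and core >=
    ``core_ratio`` x own variable part), which every valid pairing must satisfy."""
    decomps = enumerate_single_cuts(compound) + enumerate_h_decompositions(compound)
    return [
        d
        for d in decomps
        if d.n_var <= max_var_atoms and d.n_core >= core_ratio * d.n_var
    ]


def _valid_pairing(
    d1: Decomposition,
    d2: Decomposition,
    core_ratio: float,
    max_var_atoms: int,
    max_var_diff: int,
) -> bool:
    if d1.core_smiles != d2.core_smiles or d1.variable_smiles == d2.variable_smiles:
        return False
    return (
        d1.n_var <= max_var_atoms
        and d2.n_var <= max_var_atoms
        and d1.n_core >= core_ratio * max(d1.n_var, d2.n_var)
        and abs(d1.n_var - d2.n_var) <= max_var_diff
    )


def _canonical_record(
    id_1: str, id_2: str, pairings: list[tuple[Decomposition, Decomposition]]
) -> MMPRecord:
    """Pick the canonical shared core: largest heavy-atom count, ties broken by
    the lexicographically smallest canonical core SMILES."""
    best = min(pairings, key=lambda p: (-p[0].n_core, p[0].core_smiles))
    d1, d2 = best
    return MMPRecord(
        id_1=id_1,
        id_2=id_2,
        core_smiles=d1.core_smiles,
        var_smiles_1=d1.variable_smiles,
        var_smiles_2=d2.variable_smiles,
        n_core=d1.n_core,
        n_var_1=d1.n_var,
        n_var_2=d2.n_var,
    )


def detect_mmps(
    compounds: CompoundSet,
    core_ratio: float = DEFAULT_CORE_RATIO,
    max_var_atoms: int = DEFAULT_MAX_VAR_ATOMS,
    max_var_diff: int = DEFAULT_MAX_VAR_DIFF,
) -> MMPSet:
    """Fragment-and-index MMP detection.

    Decompositions of every compound are grouped by canonical core SMILES;
    within a group, every compound pair with differing variable parts that
    satisfies the size constraints forms a candidate. Each unordered pair
    yields exactly one record, carrying its canonical core.
    """
    by_core: dict[str, dict[str, list[Decomposition]]] = {}
    for rec in compounds:
        for d in all_decompositions(rec, max_var_atoms=max_var_atoms, core_ratio=core_ratio):
            by_core.setdefault(d.core_smiles, {}).setdefault(rec.compound_id, []).append(d)

    candidates: dict[tuple[str, str], list[tuple[Decomposition, Decomposition]]] = {}
    for per_compound in by_core.values():
        if len(per_compound) < 2:
            continue
        ids = sorted(per_compound)
        for ia, ib in itertools.combinations(ids, 2):
            for d1, d2 in itertools.product(per_compound[ia], per_compound[ib]):
                if _valid_pairing(d1, d2, core_ratio, max_var_atoms, max_var_diff):
                    candidates.setdefault((ia, ib), []).append((d1, d2))

    records = [
        _canonical_record(ia, ib, pairings)
        for (ia, ib), pairings in sorted(candidates.items())
    ]
    return MMPSet(records=records)


def detect_mmps_brute_force(
    compounds: CompoundSet,
    core_ratio: float = DEFAULT_CORE_RATIO,
    max_var_atoms: int = DEFAULT_MAX_VAR_ATOMS,
    max_var_diff: int = DEFAULT_MAX_VAR_DIFF,
) -> MMPSet:
    """All-pairs reference detector: compares the full decomposition lists of
    every compound pair directly, without the core index. Used as the
    correctness oracle for :func:`detect_mmps`."""
    decomp_lists = {
        rec.compound_id: enumerate_single_cuts(rec) + enumerate_h_decompositions(rec)
        for rec in compounds
    }
    ids = sorted(decomp_lists)
    records = []
    for ia, ib in itertools.combinations(ids, 2):
        pairings = [
            (d1, d2)
            for d1 in decomp_lists[ia]
            for d2 in decomp_lists[ib]
            if _valid_pairing(d1, d2, core_ratio, max_var_atoms, max_var_diff)
        ]
        if pairings:
            records.append(_canonical_record(ia, ib, pairings))
    return MMPSet(records=records)


def assign_ac_class(
    a1: float, a2: float, ac_threshold: float = 2.0, non_ac_threshold: float = 1.0
) -> str:
    """AC iff |a1-a2| >= 2, non-AC iff <= 1, half-AC strictly in between.

    Comparisons use exact IEEE float semantics (no epsilon); the log10
    thresholds are overridable but default to the factor-100 / factor-10
    convention."""
    if not non_ac_threshold < ac_threshold:
        raise ValueError("need non_ac_threshold < ac_threshold")
    delta = abs(a1 - a2)
    if delta >= ac_threshold:
        return AC
    if delta <= non_ac_threshold:
        return NON_AC
    return HALF_AC


def assign_pd_label(id_1: str, id_2: str, a1: float, a2: float) -> str:
    """The compound id with the larger activity label (the more potent one)."""
    if a1 == a2:
        raise UndefinedDirectionError(f"tied activity labels for {id_1}/{id_2}")
    return id_1 if a1 > a2 else id_2


def label_mmps(
    mmps: MMPSet,
    compounds: CompoundSet,
    ac_threshold: float = 2.0,
    non_ac_threshold: float = 1.0,
) -> MMPSet:
    """Attach delta_label, ac_class and pd_label to every record."""
    labels = compounds.labels()
    out = []
    for r in mmps:
        missing = {r.id_1, r.id_2} - labels.keys()
        if missing:
            raise KeyError(f"MMP references unknown compound ids: {sorted(missing)}")
        a1, a2 = labels[r.id_1], labels[r.id_2]
        pd_label = None if a1 == a2 else assign_pd_label(r.id_1, r.id_2, a1, a2)
        out.append(
            replace(r, delta_label=abs(a1 - a2), ac_class=assign_ac_class(a1, a2, ac_threshold, non_ac_threshold), pd_label=pd_label)
        )
    return MMPSet(records=out)


@dataclass
class MMPSummary:
    """Table-style count summary of a labelled MMP collection."""

    n_mmps: int
    n_ac: int
    n_half_ac: int
    n_non_ac: int

    @property
    def ac_to_non_ac(self) -> float | None:
        return self.n_non_ac / self.n_ac if self.n_ac else None


def finalise_mmp_set(mmps: MMPSet) -> tuple[MMPSet, MMPSummary]:
    """Drop half-ACs and report counts over the labelled input."""
    classes = [r.ac_class for r in mmps]
    if any(c is None for c in classes):
        raise ValueError("finalise_mmp_set requires labelled records (run label_mmps first)")
    summary = MMPSummary(
        n_mmps=len(mmps),
        n_ac=classes.count(AC),
        n_half_ac=classes.count(HALF_AC),
        n_non_ac=classes.count(NON_AC),
    )
    kept = [r for r in mmps if r.ac_class in (AC, NON_AC)]
    return MMPSet(records=kept), summary


def check_constraints(
    mmps: MMPSet,
    core_ratio: float = DEFAULT_CORE_RATIO,
    max_var_atoms: int = DEFAULT_MAX_VAR_ATOMS,
    max_var_diff: int = DEFAULT_MAX_VAR_DIFF,
) -> None:
    """Assert the three size constraints on every record (raises on violation)."""
    for r in mmps:
        if r.n_core < core_ratio * max(r.n_var_1, r.n_var_2):
            raise AssertionError(f"core-size constraint violated on {r.pair}")
        if r.n_var_1 > max_var_atoms or r.n_var_2 > max_var_atoms:
            raise AssertionError(f"variable-part size constraint violated on {r.pair}")
        if abs(r.n_var_1 - r.n_var_2) > max_var_diff:
            raise AssertionError(f"variable-part difference constraint violated on {r.pair}")


def write_mmp_set(mmps: MMPSet, path) -> None:
    mmps.to_frame().to_csv(path, index=False)


def read_mmp_csv(path) -> MMPSet:
    """Import an externally generated MMP table (mmpdb-style CSV dialect with
    columns compound_id_1, compound_id_2, core_smiles, var_smiles_1,
    var_smiles_2) into an MMPSet. The native detector remains the default path."""
    df = pd.read_csv(path)

    def _n_heavy(smi: str) -> int:
        if smi == _H_VAR_SMILES:
            return 0
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"unparseable fragment SMILES {smi!r}")
        return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() > 1)

    records = [
        MMPRecord(
            id_1=str(r.compound_id_1),
            id_2=str(r.compound_id_2),
            core_smiles=str(r.core_smiles),
            var_smiles_1=str(r.var_smiles_1),
            var_smiles_2=str(r.var_smiles_2),
            n_core=_n_heavy(str(r.core_smiles)),
            n_var_1=_n_heavy(str(r.var_smiles_1)),
            n_var_2=_n_heavy(str(r.var_smiles_2)),
        )
        for r in df.itertuples()
    ]
    return MMPSet(records=records)
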