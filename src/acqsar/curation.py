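"""Standardise raw SMILES + activity tables into a deduplicated compound set.

The curation pipeline mirrors common medicinal-chemistry practice for
assay-extract tables: structures are desalted (largest organic fragment),
stripped of isotope annotations and canonicalised; unparseable rows are
dropped; duplicate structures are unified by geometric averaging of their
activities when the measurements agree to within one order of magnitude and
discarded as unreliable otherwise.

Activity labels are the negative decadic logarithm of the measured activity
*in its original unit* (nM for K_i, uM for IC_50), i.e. pK_i / pIC_50 values
additively shifted towards zero.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

VALID_UNITS = frozenset({"nM", "uM", "µM"})


class InvalidStructureError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""


class InvalidActivityError(ValueError):
    """Raised for non-positive activity values (the log label is undefined)."""


class UnitConflictError(ValueError):
    """Raised when duplicate entries of one structure carry different units."""


@dataclass(frozen=True)
class RawEntry:
    """One raw table row: a SMILES string with a measured activity."""

    smiles_raw: str
    activity_value: float
    unit: str = "nM"

    def __post_init__(self) -> None:
        if self.activity_value <= 0 or not math.isfinite(self.activity_value):
            raise InvalidActivityError(
                f"activity must be a positive finite number, got {self.activity_value!r}"
            )
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {sorted(VALID_UNITS)}")


@dataclass(frozen=True)
class CompoundRecord:
    """A standardised compound with its activity and derived label a(s)."""

    compound_id: str
    smiles_canonical: str
    activity_value: float
    activity_label: float
    unit: str = "nM"


@dataclass
class CompoundSet:
    """A curated collection of compounds (the data set D)."""

    records: list[CompoundRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.compound_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("compound_ids must be unique within a CompoundSet")
        smis = [r.smiles_canonical for r in self.records]
        if len(smis) != len(set(smis)):
            raise ValueError("canonical SMILES must be unique within a CompoundSet")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def by_id(self) -> dict[str, CompoundRecord]:
        return {r.compound_id: r for r in self.records}

    def labels(self) -> dict[str, float]:
        return {r.compound_id: r.activity_label for r in self.records}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "compound_id": [r.compound_id for r in self.records],
                "smiles": [r.smiles_canonical for r in self.records],
                "activity": [r.activity_value for r in self.records],
                "activity_label": [r.activity_label for r in self.records],
                "unit": [r.unit for r in self.records],
            }
        )


@dataclass
class CurationLog:
    """Bookkeeping counts emitted alongside a curated table."""

    n_input: int = 0
    n_parse_failures: int = 0
    n_duplicate_sets_unified: int = 0
    n_duplicate_sets_removed: int = 0
    n_output: int = 0
    parse_failure_rows: list[int] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)


def _strip_isotopes(mol: Chem.Mol) -> None:
    for atom in mol.GetAtoms():
        atom.SetIsotope(0)


def _largest_fragment(mol: Chem.Mol) -> Chem.Mol:
    """Keep the fragment with most heavy atoms; ties broken by the
    lexicographically smallest canonical SMILES."""
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) == 1:
        return frags[0]
    keyed = []
    for f in frags:
        smi = Chem.MolToSmiles(f)
        keyed.append((-f.GetNumHeavyAtoms(), smi, f))
    keyed.sort(key=lambda t: (t[0], t[1]))
    return keyed[0][2]


def standardise_smiles(smiles_raw: str) -> str:
    """Return a canonical, desalted, isotope-free SMILES of the largest fragment.

    Idempotent: standardising an already-standardised SMILES is a no-op.

    Raises
    ------
    InvalidStructureError
        If the input does not parse into a sanitisable molecule.
    """
    if not smiles_raw or not smiles_raw.strip():
        raise InvalidStructureError("empty SMILES")
    mol = Chem.MolFromSmiles(smiles_raw)
    if mol is None:
        raise InvalidStructureError(f"unparseable SMILES: {smiles_raw!r}")
    _strip_isotopes(mol)
    mol = _largest_fragment(mol)
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:  # pragma: no cover - rarely reachable after parse
        raise InvalidStructureError(f"unsanitisable structure: {smiles_raw!r}") from exc
    return Chem.MolToSmiles(mol)


def standardise(entry: RawEntry) -> RawEntry:
    """Standardise one raw entry (see :func:`standardise_smiles`)."""
    return RawEntry(
        smiles_raw=standardise_smiles(entry.smiles_raw),
        activity_value=entry.activity_value,
        unit=entry.unit,
    )


def compute_activity_label(activity_value: float, unit: str = "nM") -> float:
    """a(s) = -log10(activity in its original unit); no conversion to molar."""
    if unit not in VALID_UNITS:
        raise ValueError(f"unknown unit {unit!r}")
    if activity_value <= 0 or not math.isfinite(activity_value):
        raise InvalidActivityError(f"activity must be positive, got {activity_value!r}")
    return -math.log10(activity_value)


def unify_duplicates(entries: list[RawEntry]) -> RawEntry | None:
    """Unify duplicate measurements of one structure, or drop them.

    If max/min <= 10 (same order of magnitude, boundary inclusive) the set is
    unified at the geometric mean of the values; otherwise the measurements
    are considered unreliable and ``None`` (a removal verdict) is returned.
    """
    if not entries:
        raise ValueError("empty duplicate set")
    smis = {e.smiles_raw for e in entries}
    if len(smis) != 1:
        raise ValueError("duplicate set must share one standardised SMILES")
    units = {e.unit for e in entries}
    if len(units) != 1:
        raise UnitConflictError(f"mixed units in duplicate set: {sorted(units)}")
    if len(entries) == 1:
        return entries[0]  # geometric mean of a singleton is exact identity
    values = [e.activity_value for e in entries]
    if max(values) / min(values) > 10.0:
        return None
    geo_mean = math.exp(sum(math.log(v) for v in values) / len(values))
    return RawEntry(smiles_raw=entries[0].smiles_raw, activity_value=geo_mean, unit=entries[0].unit)


def curate(entries: list[RawEntry], provenance: str = "", id_prefix: str = "CPD") -> tuple[CompoundSet, CurationLog]:
    """Run the full curation pipeline on raw entries.

    Order invariant: the resulting CompoundSet (as a set of records) does not
    depend on the input row order; compound ids are assigned in canonical
    SMILES sort order.
    """
    log = CurationLog(n_input=len(entries))
    by_smiles: dict[str, list[RawEntry]] = {}
    for i, entry in enumerate(entries):
        try:
            std = standardise(entry)
        except InvalidStructureError:
            log.n_parse_failures += 1
            log.parse_failure_rows.append(i)
            continue
        by_smiles.setdefault(std.smiles_raw, []).append(std)

    unified: list[RawEntry] = []
    for smi in sorted(by_smiles):
        group = by_smiles[smi]
        if len(group) > 1:
            merged = unify_duplicates(group)
            if merged is None:
                log.n_duplicate_sets_removed += 1
                continue
            log.n_duplicate_sets_unified += 1
            unified.append(merged)
        else:
            unified.append(group[0])

    width = max(4, len(str(len(unified))))
    records = [
        CompoundRecord(
            compound_id=f"{id_prefix}{i:0{width}d}",
            smiles_canonical=e.smiles_raw,
            activity_value=e.activity_value,
            activity_label=compute_activity_label(e.activity_value, e.unit),
            unit=e.unit,
        )
        for i, e in enumerate(unified)
    ]
    log.n_output = len(records)
    return CompoundSet(records=records, provenance=provenance), log


def read_raw_table(path) -> list[RawEntry]:
    """Read a raw compound table (CSV with columns smiles, activity, unit)."""
    df = pd.read_csv(path)
    missing = {"smiles", "activity"} - set(df.columns)
    if missing:
        raise ValueError(f"input table missing columns: {sorted(missing)}")
    if "unit" not in df.columns:
        df["unit"] = "nM"
    return [
        RawEntry(smiles_raw=str(r.smiles), activity_value=float(r.activity), unit=str(r.unit))
        for r in df.itertuples()
    ]


def curate_table(path, provenance: str = "") -> tuple[CompoundSet, CurationLog]:
    """Read and curate a raw CSV table in one step."""
    return curate(read_raw_table(path), provenance=provenance or str(path))


def write_compound_set(compounds: CompoundSet, path) -> None:
    compounds.to_frame().to_csv(path, index=False)


def read_compound_set(path, provenance: str = "") -> CompoundSet:
    df = pd.read_csv(path)
    records = [
        CompoundRecord(
            compound_id=str(r.compound_id),
            smiles_canonical=str(r.smiles),
            activity_value=float(r.activity),
            activity_label=float(r.activity_label),
            unit=str(getattr(r, "unit", "nM")),
        )
        for r in df.itertuples()
    ]
    return CompoundSet(records=records, provenance=provenance or str(path))
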