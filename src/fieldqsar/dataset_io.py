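"""Compound tables, activity conversion and SDF structure I/O.

Activities are inhibition constants Ki in nanomolar; modelling uses the
negative decadic logarithm of the molar Ki,

    pKi = -log10(Ki [M]) = 9 - log10(Ki [nM]),

so a 1 nM ligand has pKi 9 and a 1 M ligand pKi 0.  The packaged reference
table carries 33 imidazo[1,2-a]-pyridine positive allosteric modulators of
the α1-GABA_A receptor (zolpidem among them) with their measured Ki, the
realized 25/8 train/test split, and the predicted pKi of three published
field-based QSAR models, which downstream modules use as worked-example
oracles.

Structures travel as SDF V2000.  Fractional partial charges and per-atom
typing flags do not fit the integer charge block of V2000, so they ride in
data tags: ``PARTIAL_CHARGES`` (one value per atom, whitespace-separated),
``ATOM_TYPES`` (one token per atom built from the letters D/A/H/R for
donor/acceptor/hydrophobe/aromatic, ``-`` when untyped) and
``SCAFFOLD_ATOMS`` (indices of the common-scaffold atoms).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import SDWriter
from rdkit.Geometry import Point3D

from .errors import DomainError, FormatError, ValidationError
from .molecule import FLAG_CODES, FLAG_KEYS, Molecule3D

SET_LABELS = ("train", "test", "external")

_CHARGE_TAG = "PARTIAL_CHARGES"
_TYPES_TAG = "ATOM_TYPES"
_SCAFFOLD_TAG = "SCAFFOLD_ATOMS"

# ---------------------------------------------------------------------------
# activity conversion


def ki_to_pki(ki_nm: float) -> float:
    """Convert a Ki in nM to pKi = 9 - log10(Ki).

    Monotone decreasing in Ki; raises :class:`DomainError` for non-positive
    or non-finite input.
    """
    ki = float(ki_nm)
    if not math.isfinite(ki) or ki <= 0:
        raise DomainError(f"Ki must be a positive finite value in nM, got {ki_nm!r}")
    return 9.0 - math.log10(ki)


def pki_to_ki(pki: float) -> float:
    """Inverse of :func:`ki_to_pki`: Ki in nM = 10**(9 - pKi)."""
    p = float(pki)
    if not math.isfinite(p):
        raise DomainError(f"pKi must be finite, got {pki!r}")
    return 10.0 ** (9.0 - p)


# ---------------------------------------------------------------------------
# compound records


@dataclass
class CompoundRecord:
    """One molecule of the series: activity, set membership, structure link."""

    id: str
    ki: float | None          # nM
    pki: float
    set_label: str
    structure_ref: Molecule3D | None = None
    meta: dict | None = None

    def __post_init__(self) -> None:
        if self.set_label not in SET_LABELS:
            raise ValidationError(
                f"{self.id}: set label {self.set_label!r} not in {SET_LABELS}"
            )
        if self.ki is not None:
            if self.ki <= 0 or not math.isfinite(self.ki):
                raise ValidationError(f"{self.id}: Ki must be positive, got {self.ki}")
            if abs(self.pki - ki_to_pki(self.ki)) > 5e-4:
                raise ValidationError(
                    f"{self.id}: pKi {self.pki} inconsistent with Ki {self.ki} nM "
                    f"(expected {ki_to_pki(self.ki):.4f})"
                )


def _normalize_minus(series: pd.Series) -> pd.Series:
    """Replace typographic minus signs (U+2212) with ASCII hyphens."""
    if series.dtype == object:
        return series.str.replace("−", "-", regex=False)
    return series


def load_compound_table(path: str | Path) -> list[CompoundRecord]:
    """Read a CSV of columns ``id, ki_nm, set`` (optional ``pki``) into records.

    A printed pKi column, when present, is kept verbatim and validated
    against the Ki to 5e-4; otherwise pKi is computed.  Extra ``pred_*``
    columns are preserved in each record's ``meta``.
    """
    df = pd.read_csv(path, dtype={"id": str})
    for col in ("id", "ki_nm", "set"):
        if col not in df.columns:
            raise FormatError(f"compound table {path} lacks required column {col!r}")
    if df["id"].duplicated().any():
        dupes = df.loc[df["id"].duplicated(), "id"].tolist()
        raise ValidationError(f"duplicate compound ids in {path}: {dupes}")
    records = []
    pred_cols = [c for c in df.columns if c.startswith("pred_")]
    for _, row in df.iterrows():
        ki = float(pd.to_numeric(_normalize_minus(pd.Series([row["ki_nm"]]))[0]))
        if ki <= 0:
            raise ValidationError(f"{row['id']}: non-positive Ki {ki}")
        pki = float(row["pki"]) if "pki" in df.columns else ki_to_pki(ki)
        meta = {c: float(row[c]) for c in pred_cols if pd.notna(row[c])}
        if "pharm_model" in df.columns:
            meta["pharm_model"] = bool(int(row["pharm_model"]))
        records.append(
            CompoundRecord(id=str(row["id"]), ki=ki, pki=pki,
                           set_label=str(row["set"]), meta=meta or None)
        )
    return records


def prediction_table(path: str | Path) -> pd.DataFrame:
    """Load a compound CSV with ``pred_<model>`` columns into tidy long form.

    Returns a DataFrame with columns ``id, actual_pki, model, predicted_pki,
    residual`` where ``residual = predicted - actual`` (the sign convention
    of the reference table: over-prediction gives a positive residual).
    """
    df = pd.read_csv(path, dtype={"id": str})
    pred_cols = [c for c in df.columns if c.startswith("pred_")]
    if not pred_cols:
        raise FormatError(f"{path} carries no pred_* columns")
    if "pki" in df.columns:
        actual = df["pki"].astype(float)
    else:
        actual = df["ki_nm"].map(ki_to_pki)
    rows = []
    for col in pred_cols:
        model = col[len("pred_"):]
        for cid, act, pred in zip(df["id"], actual, df[col].astype(float)):
            rows.append((cid, act, model, pred, pred - act))
    return pd.DataFrame(rows, columns=["id", "actual_pki", "model",
                                       "predicted_pki", "residual"])


# packaged reference data -----------------------------------------------------

def _data_path(name: str):
    return resources.files("fieldqsar.data").joinpath(name)


def load_reference_compounds() -> list[CompoundRecord]:
    """The packaged 33-compound imidazopyridine activity table (25 train / 8 test)."""
    with resources.as_file(_data_path("imidazopyridine_activities.csv")) as p:
        return load_compound_table(p)


def load_reference_predictions() -> pd.DataFrame:
    """Tidy predicted-pKi table of the three reference QSAR models."""
    with resources.as_file(_data_path("imidazopyridine_activities.csv")) as p:
        return prediction_table(p)


def load_reference_adme() -> pd.DataFrame:
    """Predicted ADME/T property table for the screened hits and references."""
    with resources.as_file(_data_path("adme_properties.csv")) as p:
        return pd.read_csv(p, dtype={"id": str})


def load_reference_docking_scores() -> pd.DataFrame:
    with resources.as_file(_data_path("docking_scores.csv")) as p:
        return pd.read_csv(p, dtype={"id": str})


def load_reference_energies() -> pd.DataFrame:
    """MM-PBSA energy decomposition table (kJ/mol) for four receptor complexes."""
    with resources.as_file(_data_path("binding_energy_components.csv")) as p:
        return pd.read_csv(p, dtype={"id": str})


# ---------------------------------------------------------------------------
# SDF structure I/O


def _flags_token(mol: Molecule3D, i: int) -> str:
    token = "".join(FLAG_CODES[k] for k in FLAG_KEYS if mol.flags[k][i])
    return token or "-"


def _to_rdkit(mol: Molecule3D) -> Chem.Mol:
    rw = Chem.RWMol()
    for elem in mol.elements:
        try:
            rw.AddAtom(Chem.Atom(elem))
        except RuntimeError as exc:
            raise FormatError(f"{mol.id}: unknown element symbol {elem!r}") from exc
    for i, j, order in mol.bonds:
        rw.AddBond(int(i), int(j), Chem.BondType.values.get(order, Chem.BondType.SINGLE))
    conf = Chem.Conformer(mol.n_atoms)
    for i, (x, y, z) in enumerate(mol.coords):
        conf.SetAtomPosition(i, Point3D(float(x), float(y), float(z)))
    out = rw.GetMol()
    out.AddConformer(conf)
    out.UpdatePropertyCache(strict=False)
    out.SetProp("_Name", mol.id)
    out.SetProp(_CHARGE_TAG, " ".join(f"{q:.6f}" for q in mol.charges))
    out.SetProp(_TYPES_TAG, " ".join(_flags_token(mol, i) for i in range(mol.n_atoms)))
    if mol.scaffold_map:
        out.SetProp(_SCAFFOLD_TAG, " ".join(str(k) for k in mol.scaffold_map))
    return out


def write_structures(molecules: Iterable[Molecule3D], path: str | Path) -> None:
    """Write molecules as SDF V2000 with charge/typing sidecar tags."""
    writer = SDWriter(str(path))
    writer.SetKekulize(False)
    try:
        for mol in molecules:
            writer.write(_to_rdkit(mol))
    finally:
        writer.close()


_CODE_TO_FLAG = {v: k for k, v in FLAG_CODES.items()}


def read_structures(path: str | Path) -> list[Molecule3D]:
    """Read an SDF written by :func:`write_structures` back into molecules.

    Raises :class:`FormatError` when the per-atom charge or typing tags do
    not match the atom count, or when an element symbol is unknown.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"SDF file not found: {path}")
    supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
    molecules = []
    for idx, rd in enumerate(supplier):
        if rd is None:
            raise FormatError(f"{path}: unparseable SDF record #{idx}")
        n = rd.GetNumAtoms()
        elements = [a.GetSymbol() for a in rd.GetAtoms()]
        if any(Chem.Atom(e).GetAtomicNum() == 0 for e in elements):
            raise FormatError(f"{path}: record #{idx} has unknown element symbol")
        coords = rd.GetConformer().GetPositions()
        if not rd.HasProp(_CHARGE_TAG):
            raise FormatError(f"{path}: record #{idx} lacks {_CHARGE_TAG} tag")
        charges = np.array([float(v) for v in rd.GetProp(_CHARGE_TAG).split()])
        if charges.size != n:
            raise FormatError(
                f"{path}: record #{idx} has {n} atoms but {charges.size} charges"
            )
        tokens = rd.GetProp(_TYPES_TAG).split() if rd.HasProp(_TYPES_TAG) else ["-"] * n
        if len(tokens) != n:
            raise FormatError(
                f"{path}: record #{idx} has {n} atoms but {len(tokens)} type tokens"
            )
        flags = {k: np.zeros(n, bool) for k in FLAG_KEYS}
        for i, tok in enumerate(tokens):
            for ch in tok:
                if ch in _CODE_TO_FLAG:
                    flags[_CODE_TO_FLAG[ch]][i] = True
        scaffold = ([int(v) for v in rd.GetProp(_SCAFFOLD_TAG).split()]
                    if rd.HasProp(_SCAFFOLD_TAG) else [])
        bonds = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), int(b.GetBondTypeAsDouble()))
                 for b in rd.GetBonds()]
        molecules.append(Molecule3D(
            id=rd.GetProp("_Name") if rd.HasProp("_Name") else f"mol{idx}",
            elements=elements, coords=coords, charges=charges, flags=flags,
            bonds=bonds, scaffold_map=scaffold,
            formal_charge=float(charges.sum()),
        ))
    return molecules


def validate_dataset(records: Sequence[CompoundRecord],
                     molecules: Sequence[Molecule3D] | None = None) -> dict:
    """Cross-check a compound table against an optional structure file.

    Returns a summary dict with record counts per set label and a list of
    invariant violations (empty when everything is consistent).
    """
    problems: list[str] = []
    counts = {label: 0 for label in SET_LABELS}
    for rec in records:
        counts[rec.set_label] += 1
    if molecules is not None:
        mol_ids = {m.id for m in molecules}
        rec_ids = {r.id for r in records}
        for missing in sorted(rec_ids - mol_ids):
            problems.append(f"no structure for compound {missing}")
        sizes = {len(m.scaffold_map) for m in molecules}
        if len(sizes) > 1:
            problems.append(f"inconsistent scaffold sizes across library: {sorted(sizes)}")
        for m in molecules:
            try:
                m.validate()
            except ValidationError as exc:
                problems.append(str(exc))
    return {"n_records": len(records), "counts": counts, "problems": problems}
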