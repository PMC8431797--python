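"""In-memory container for pre-aligned 3D small molecules.

Molecules in this package are "field-realistic" rather than chemically
exhaustive: each atom carries an element symbol, Cartesian coordinates,
a fractional partial charge and four pharmacophore typing flags
(hydrogen-bond donor, acceptor, hydrophobe, aromatic).  Congeneric series
share a rigid common scaffold; ``scaffold_map`` lists the atom indices of
that scaffold, in a fixed order that defines the atom correspondence used
for rigid superposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ValidationError

#: Pharmacophore typing flags carried per atom.
FLAG_KEYS = ("donor", "acceptor", "hydrophobe", "aromatic")

#: Compact single-letter codes used when serializing flags to SDF data tags.
FLAG_CODES = {"donor": "D", "acceptor": "A", "hydrophobe": "H", "aromatic": "R"}

#: van der Waals radii (Å) used for steric weights and probe combination rules.
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "S": 1.80, "Cl": 1.75, "Br": 1.85, "I": 1.98, "P": 1.80,
}


@dataclass
class Molecule3D:
    """One molecule of a congeneric series, already placed in a common frame."""

    id: str
    elements: list[str]
    coords: np.ndarray          # (n, 3) Å
    charges: np.ndarray         # (n,) elementary charges
    flags: dict[str, np.ndarray]  # FLAG_KEYS -> (n,) bool
    bonds: list[tuple[int, int, int]] = field(default_factory=list)  # (i, j, order)
    scaffold_map: list[int] = field(default_factory=list)
    formal_charge: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        self.charges = np.asarray(self.charges, dtype=float).ravel()
        for key in FLAG_KEYS:
            self.flags[key] = np.asarray(self.flags.get(key, np.zeros(self.n_atoms, bool)), dtype=bool)

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def validate(self) -> None:
        """Check structural invariants; raise :class:`ValidationError` on failure."""
        n = self.n_atoms
        if self.coords.shape != (n, 3) or self.charges.shape != (n,):
            raise ValidationError(f"{self.id}: atom-array shape mismatch")
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError(f"{self.id}: non-finite coordinates")
        if np.any(np.abs(self.charges) > 2.0):
            raise ValidationError(f"{self.id}: per-atom charge exceeds 2 e")
        if abs(self.charges.sum() - self.formal_charge) > 1e-6:
            raise ValidationError(
                f"{self.id}: net charge {self.charges.sum():.6f} deviates from "
                f"declared formal charge {self.formal_charge:.6f}"
            )
        for key in FLAG_KEYS:
            if self.flags[key].shape != (n,):
                raise ValidationError(f"{self.id}: flag array {key!r} has wrong length")
        for i, j, _ in self.bonds:
            if not (0 <= i < n and 0 <= j < n and i != j):
                raise ValidationError(f"{self.id}: bond ({i},{j}) out of range")
        if any(not 0 <= k < n for k in self.scaffold_map):
            raise ValidationError(f"{self.id}: scaffold_map index out of range")

    def copy(self) -> "Molecule3D":
        return replace(
            self,
            elements=list(self.elements),
            coords=self.coords.copy(),
            charges=self.charges.copy(),
            flags={k: v.copy() for k, v in self.flags.items()},
            bonds=list(self.bonds),
            scaffold_map=list(self.scaffold_map),
            meta=dict(self.meta),
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Molecule3D":
        """Return a copy with coordinates mapped through ``x -> R x + t``."""
        out = self.copy()
        out.coords = self.coords @ np.asarray(rotation).T + np.asarray(translation)
        return out

    def scaffold_coords(self) -> np.ndarray:
        return self.coords[list(self.scaffold_map)]

    def vdw_radii(self) -> np.ndarray:
        return np.array([VDW_RADII.get(e, 1.70) for e in self.elements])
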