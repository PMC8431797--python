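"""Rigid superposition of congeneric molecules onto a template.

The correspondence is the scaffold-map order: congeneric series share an
indexed common scaffold, so no graph matching is needed.  Superposition is
the least-squares proper rotation + translation (Kabsch); reflections are
excluded.  The same coordinate RMSD is used to express re-docking checks
against the conventional 2.0 Å acceptance threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import DegenerateInputError, DomainError
from .molecule import Molecule3D

RMSD_DOCKING_THRESHOLD = 2.0  # Å; conventional re-docking acceptance bound


@dataclass
class Superposition:
    rotation: np.ndarray      # 3x3 proper orthonormal
    translation: np.ndarray   # Å
    rmsd: float               # Å over the correspondence atoms

    def __post_init__(self):
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-8:
            raise DegenerateInputError("rotation must be proper (det +1)")
        if self.rmsd < 0:
            raise DomainError("rmsd must be non-negative")


def _check_correspondence(mobile: Molecule3D, template: Molecule3D) -> tuple[np.ndarray, np.ndarray]:
    a = mobile.scaffold_coords()
    b = template.scaffold_coords()
    if len(a) != len(b) or len(a) < 3:
        raise DegenerateInputError(
            f"need >=3 matched scaffold atoms, got {len(a)} vs {len(b)}")
    centered = a - a.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise DegenerateInputError("scaffold correspondence points are collinear")
    return a, b


def kabsch_align(mobile: Molecule3D, template: Molecule3D) -> tuple[Superposition, Molecule3D]:
    """Least-squares rigid superposition of mobile scaffold onto template scaffold.

    All mobile atoms are transformed; the template is untouched.  The
    returned rotation is always proper (no reflections).
    """
    a, b = _check_correspondence(mobile, template)
    a_mean, b_mean = a.mean(axis=0), b.mean(axis=0)
    rot, _ = Rotation.align_vectors(b - b_mean, a - a_mean)
    r = rot.as_matrix()
    t = b_mean - r @ a_mean
    # recompute the residual directly: scipy's rssd loses precision near zero
    diff = a @ r.T + t - b
    rmsd = float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))
    sup = Superposition(rotation=r, translation=t, rmsd=rmsd)
    return sup, mobile.transformed(r, t)


def coord_rmsd(a: Molecule3D, b: Molecule3D,
               mapping: list[tuple[int, int]] | None = None) -> float:
    """Root-mean-square coordinate distance over mapped atom pairs.

    No superposition is applied — this measures the deviation in the
    frame the molecules already occupy (the re-docking convention).
    ``mapping`` defaults to the identity over all atoms when both
    molecules have the same atom count.
    """
    if mapping is None:
        if a.n_atoms != b.n_atoms:
            raise DomainError("implicit identity mapping needs equal atom counts")
        mapping = [(i, i) for i in range(a.n_atoms)]
    if not mapping:
        raise DomainError("empty atom mapping")
    ia = [i for i, _ in mapping]
    ib = [j for _, j in mapping]
    if max(ia) >= a.n_atoms or max(ib) >= b.n_atoms or min(ia + ib) < 0:
        raise DomainError("mapping index out of range")
    diff = a.coords[ia] - b.coords[ib]
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))


def rmsd_passes(rmsd: float, threshold: float = RMSD_DOCKING_THRESHOLD) -> bool:
    """True when a pose-reproduction RMSD is below the acceptance threshold."""
    return rmsd < threshold
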