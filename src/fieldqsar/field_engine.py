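"""Molecular interaction fields on a rectangular grid around aligned molecules.

Two field families are produced for a library sharing one frame:

* CoMFA-style probe energies (kcal/mol): a Lennard-Jones 6-12 steric term
  for an sp3-carbon-like probe and a Coulomb electrostatic term for a +1 e
  probe charge with a distance-dependent dielectric ε(r) = r,

      E_ele(q) = 332.0636 · q_probe · Σ_i q_i / r_iq²,

  both clamped to ±30 kcal/mol by default.  Electrostatic values inside a
  sterically clamped region are retained (not mean-substituted) and the
  clamped points are flagged.

* CoMSIA-style similarity indices (dimensionless): Gaussian-attenuated
  sums, A_k(q) = −Σ_i w_ik exp(−α r_iq²) with probe weight +1 and per-atom
  weights of partial charge (E), cubed van der Waals radius (S) or typing
  flags (H, D, A); no clamping is needed because the Gaussian has no
  singularity.

Columns of near-zero variance over the training set are masked before
regression, and each field channel is scaled to equal total variance
(CoMFA-STD style) so no channel dominates the PLS solely through its units.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace

import numpy as np
from scipy.spatial.distance import cdist

from .errors import DegenerateInputError, DomainError, ValidationError
from .molecule import Molecule3D

COULOMB_CONSTANT = 332.0636  # kcal·Å·mol⁻¹·e⁻²

#: Lennard-Jones well depth (kcal/mol) and r_min/2 (Å) per element.
LJ_PARAMS = {
    "H": (0.0157, 1.20), "C": (0.107, 1.70), "N": (0.095, 1.55),
    "O": (0.116, 1.52), "F": (0.061, 1.47), "S": (0.250, 1.80),
    "Cl": (0.265, 1.75), "Br": (0.320, 1.85), "P": (0.200, 1.80),
}
_LJ_DEFAULT = (0.107, 1.70)


@dataclass(frozen=True)
class ProbeParams:
    """sp3-carbon-like probe with unit positive charge (classical defaults)."""
    charge: float = 1.0
    epsilon: float = 0.107   # kcal/mol
    rmin_half: float = 1.70  # Å


@dataclass(frozen=True)
class GridSpec:
    origin: tuple[float, float, float]
    spacing: float
    dimensions: tuple[int, int, int]

    def __post_init__(self):
        if self.spacing <= 0:
            raise DomainError("grid spacing must be > 0")
        if any(d < 1 for d in self.dimensions):
            raise DomainError("grid dimensions must be >= 1")

    @property
    def n_points(self) -> int:
        nx, ny, nz = self.dimensions
        return nx * ny * nz

    def points(self) -> np.ndarray:
        """All grid nodes as an (n_points, 3) array, x-fastest last axis order."""
        axes = [np.asarray(self.origin)[k] + self.spacing * np.arange(self.dimensions[k])
                for k in range(3)]
        mesh = np.meshgrid(*axes, indexing="ij")
        return np.stack(mesh, axis=-1).reshape(-1, 3)

    def contains(self, coords: np.ndarray) -> bool:
        lo = np.asarray(self.origin)
        hi = lo + self.spacing * (np.asarray(self.dimensions) - 1)
        return bool(np.all(coords >= lo - 1e-9) and np.all(coords <= hi + 1e-9))


@dataclass
class FieldBlock:
    """Compounds × (grid points × channels) descriptor matrix.

    ``matrix`` holds raw (clamped but unscaled) values; ``column_mask`` and
    ``block_scale`` are set by :func:`filter_and_scale` and applied lazily
    by :meth:`design_matrix`, so cross-validation can re-derive scaling on
    training folds without recomputing fields.
    """

    matrix: np.ndarray                     # (n_molecules, n_points * n_channels)
    channels: list[str]
    grid: GridSpec
    ids: list[str]
    unit: str
    column_mask: np.ndarray = None         # bool (p,); None = all retained
    block_scale: dict[str, float] = dc_field(default_factory=dict)
    steric_clamped: np.ndarray | None = None   # bool (n, n_points) for CoMFA blocks

    def __post_init__(self):
        if self.column_mask is None:
            self.column_mask = np.ones(self.matrix.shape[1], bool)

    @property
    def n_points(self) -> int:
        return self.grid.n_points

    def column_channels(self) -> np.ndarray:
        """Channel label of every column (channels are stored block-wise)."""
        return np.repeat(np.asarray(self.channels, object), self.n_points)

    def col_scale(self) -> np.ndarray:
        scale = np.ones(self.matrix.shape[1])
        for c, f in self.block_scale.items():
            scale[self.column_channels() == c] = f
        return scale

    def design_matrix(self, rows=None) -> np.ndarray:
        """Masked, block-scaled matrix ready for regression."""
        m = self.matrix if rows is None else self.matrix[rows]
        return m[:, self.column_mask] * self.col_scale()[self.column_mask]

    def rows(self, idx) -> "FieldBlock":
        return replace(self, matrix=self.matrix[idx],
                       ids=[self.ids[i] for i in idx],
                       steric_clamped=None if self.steric_clamped is None
                       else self.steric_clamped[idx])


def build_grid(molecules: list[Molecule3D], spacing: float = 2.0,
               margin: float = 4.0) -> GridSpec:
    """Axis-aligned grid covering all atoms plus a margin, snapped to whole steps."""
    if not molecules:
        raise ValidationError("cannot build a grid from an empty molecule set")
    if spacing <= 0 or margin < 0:
        raise DomainError("need spacing > 0 and margin >= 0")
    coords = np.vstack([m.coords for m in molecules])
    lo = coords.min(axis=0) - margin
    hi = coords.max(axis=0) + margin
    origin = np.floor(lo / spacing) * spacing
    dims = np.ceil((hi - origin) / spacing - 1e-9).astype(int) + 1
    return GridSpec(origin=tuple(float(v) for v in origin), spacing=float(spacing),
                    dimensions=tuple(int(v) for v in dims))


# ---------------------------------------------------------------------------
# CoMFA probe energies


def comfa_values_at_points(mol: Molecule3D, points: np.ndarray,
                           probe: ProbeParams = ProbeParams(),
                           clamp: float = 30.0,
                           dielectric: str = "distance") -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(steric, electrostatic, steric-clamped flag) at arbitrary points."""
    if mol.charges is None or mol.charges.size != mol.n_atoms:
        raise ValidationError(f"{mol.id}: partial charges missing")
    r = cdist(points, mol.coords)
    r = np.maximum(r, 1e-6)
    eps = np.empty(mol.n_atoms)
    rmin = np.empty(mol.n_atoms)
    for i, e in enumerate(mol.elements):
        e_i, rh_i = LJ_PARAMS.get(e, _LJ_DEFAULT)
        eps[i] = np.sqrt(probe.epsilon * e_i)
        rmin[i] = probe.rmin_half + rh_i
    frac6 = (rmin / r) ** 6
    steric = np.sum(eps * (frac6 * frac6 - 2.0 * frac6), axis=1)
    clamped = np.abs(steric) > clamp
    steric = np.clip(steric, -clamp, clamp)
    if dielectric == "distance":
        ele = COULOMB_CONSTANT * probe.charge * np.sum(mol.charges / r**2, axis=1)
    elif dielectric == "constant":
        ele = COULOMB_CONSTANT * probe.charge * np.sum(mol.charges / r, axis=1)
    else:
        raise DomainError(f"unknown dielectric model {dielectric!r}")
    ele = np.clip(ele, -clamp, clamp)
    return steric, ele, clamped


def comfa_fields(molecules: list[Molecule3D], grid: GridSpec,
                 probe: ProbeParams = ProbeParams(),
                 clamp: float = 30.0, dielectric: str = "distance") -> FieldBlock:
    """Steric + electrostatic probe-energy block over a molecule library."""
    if not molecules:
        raise ValidationError("empty molecule set")
    points = grid.points()
    for m in molecules:
        if not grid.contains(m.coords):
            raise ValidationError(f"{m.id}: atoms outside the field grid")
    s_rows, e_rows, flags = [], [], []
    for m in molecules:
        s, e, c = comfa_values_at_points(m, points, probe, clamp, dielectric)
        s_rows.append(s)
        e_rows.append(e)
        flags.append(c)
    matrix = np.hstack([np.vstack(s_rows), np.vstack(e_rows)])
    return FieldBlock(matrix=matrix, channels=["S", "E"], grid=grid,
                      ids=[m.id for m in molecules], unit="kcal/mol",
                      steric_clamped=np.vstack(flags))


# ---------------------------------------------------------------------------
# CoMSIA similarity indices

_COMSIA_FLAG = {"H": "hydrophobe", "D": "donor", "A": "acceptor"}


def comsia_values_at_points(mol: Molecule3D, points: np.ndarray,
                            channels: tuple[str, ...] = ("S", "E", "H", "D", "A"),
                            alpha: float = 0.3) -> dict[str, np.ndarray]:
    """Gaussian similarity indices per requested channel at arbitrary points."""
    if alpha <= 0:
        raise DomainError("attenuation must be > 0")
    weights = {}
    for c in channels:
        if c == "E":
            weights[c] = mol.charges
        elif c == "S":
            weights[c] = mol.vdw_radii() ** 3
        else:
            key = _COMSIA_FLAG.get(c)
            if key is None:
                raise DomainError(f"unknown CoMSIA channel {c!r}")
            if key not in mol.flags:
                raise ValidationError(f"{mol.id}: missing typing flags for channel {c}")
            weights[c] = mol.flags[key].astype(float)
    r2 = cdist(points, mol.coords, metric="sqeuclidean")
    g = np.exp(-alpha * r2)
    return {c: -(g @ w) for c, w in weights.items()}


def comsia_fields(molecules: list[Molecule3D], grid: GridSpec,
                  channels: tuple[str, ...] = ("S", "E", "H", "D", "A"),
                  alpha: float = 0.3) -> FieldBlock:
    if not molecules:
        raise ValidationError("empty molecule set")
    points = grid.points()
    rows = {c: [] for c in channels}
    for m in molecules:
        vals = comsia_values_at_points(m, points, channels, alpha)
        for c in channels:
            rows[c].append(vals[c])
    matrix = np.hstack([np.vstack(rows[c]) for c in channels])
    return FieldBlock(matrix=matrix, channels=list(channels), grid=grid,
                      ids=[m.id for m in molecules], unit="similarity")


# ---------------------------------------------------------------------------
# pretreatment


def filter_and_scale(block: FieldBlock, min_sd: float = 0.05,
                     clamp: float | None = None,
                     train_rows=None) -> FieldBlock:
    """Mask low-information columns and equalize channel variance.

    Columns whose standard deviation over the training rows falls below
    ``min_sd`` are masked.  Each channel is then assigned the factor that
    brings its total retained-column variance to 1, so two channels with
    raw variances v and 4v get factors in ratio 2:1.  ``clamp`` optionally
    re-clamps raw values (CoMFA-style blocks are already clamped at build
    time).  The matrix itself is left raw; see
    :meth:`FieldBlock.design_matrix`.
    """
    if block.matrix.size == 0:
        raise DegenerateInputError("empty field block")
    matrix = block.matrix
    if clamp is not None:
        matrix = np.clip(matrix, -clamp, clamp)
    train = matrix if train_rows is None else matrix[train_rows]
    sd = train.std(axis=0, ddof=0)
    mask = sd >= min_sd
    if not mask.any():
        raise DegenerateInputError("all field columns masked: no variance above min_sd")
    labels = block.column_channels()
    scales = {}
    for c in block.channels:
        cols = (labels == c) & mask
        total_var = float(np.sum(sd[cols] ** 2))
        scales[c] = 1.0 / np.sqrt(total_var) if total_var > 0 else 1.0
    return replace(block, matrix=matrix, column_mask=mask, block_scale=scales)
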