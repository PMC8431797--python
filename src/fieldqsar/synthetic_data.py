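"""Synthetic congeneric libraries with a known latent field→activity model.

The reference study deposits activities but no coordinates, so every
structure-dependent stage here is exercised on generated libraries that
mimic its design: a rigid fused-bicycle scaffold (an imidazopyridine-like
core of 12 atoms with an exocyclic amide) carrying two variable R-groups,
Ra on the amide nitrogen and Rb on the six-ring, drawn from finite pools
of fragments.  All molecules share the scaffold placed identically in a
common frame, i.e. the library is born pre-aligned, as a template-aligned
congeneric series would be after superposition.

Activity is linear in *generator-side* descriptors of the R-group atoms —
per-channel sums matching the five field channels (steric volume, partial
charge, hydrophobe/donor/acceptor counts) — plus Gaussian noise:

    pKi = intercept + Σ_c w_c · d_c(R atoms) + N(0, noise_sd²),

clipped to [4, 10].  The latent relation lives on the generator side, not
on the grid fields computed downstream, so recovering it by PLS on grid
fields is a genuine test rather than a tautology.

Decoy sets for enrichment studies are perturbed variants of active
molecules: strong positional jitter plus random typing-flag dropout push
them off any geometric pharmacophore hypothesis while keeping their size
and composition active-like, and their latent activity is forced below
the active range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .errors import DomainError, ValidationError
from .molecule import FLAG_KEYS, VDW_RADII, Molecule3D
from .pharmacophore import PharmacophoreFeature, PharmacophoreModel

CHANNELS = ("S", "E", "H", "D", "A")

# Effect sizes chosen so a default library spans ~1.6 pKi across its
# structural variation, the span of the reference congeneric series.
DEFAULT_COEFFICIENTS = {"S": 0.075, "E": -0.90, "H": 0.09, "D": -0.12, "A": 0.15}

PKI_RANGE = (4.0, 10.0)

_RA_ANCHOR = 11   # amide nitrogen
_RB_ANCHOR = 2    # six-ring carbon para to the fusion bond
_N_SCAFFOLD = 12


def _rot2(v: np.ndarray, deg: float) -> np.ndarray:
    a = math.radians(deg)
    c, s = math.cos(a), math.sin(a)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1], 0.0])


def _scaffold_template() -> Molecule3D:
    """The rigid 12-atom fused-bicycle scaffold with amide arm, planar in z=0."""
    bond = 1.40
    hexagon = np.array([
        [bond * math.cos(math.radians(90 + 60 * k)),
         bond * math.sin(math.radians(90 + 60 * k)), 0.0] for k in range(6)
    ])
    # fuse a regular pentagon on the outside of edge (atom 0, atom 1)
    a, b = hexagon[0], hexagon[1]
    d = (b - a) / np.linalg.norm(b - a)
    penta = [b.copy()]
    heading = -d
    for _ in range(3):
        heading = _rot2(heading, -72.0)
        penta.append(penta[-1] + bond * heading)
    ring5_new = np.array(penta[1:])            # atoms 6, 7, 8
    centroid = hexagon.mean(axis=0)
    u7 = ring5_new[1] - centroid
    u7 = u7 / np.linalg.norm(u7)
    c9 = ring5_new[1] + 1.50 * u7              # carbonyl carbon
    o10 = c9 + 1.23 * _rot2(u7, 50.0)          # carbonyl oxygen
    n11 = c9 + 1.34 * _rot2(u7, -55.0)         # amide nitrogen (Ra anchor)
    coords = np.vstack([hexagon, ring5_new, c9, o10, n11]).round(4)
    elements = ["C", "C", "C", "C", "N", "C", "N", "C", "C", "C", "O", "N"]
    charges = np.array([0.10, 0.10, 0.10, 0.10, -0.28, 0.10,
                        -0.24, 0.10, 0.10, 0.47, -0.40, -0.25])
    flags = {k: np.zeros(12, bool) for k in FLAG_KEYS}
    flags["aromatic"][:9] = True
    flags["hydrophobe"][:9] = True
    flags["acceptor"][[4, 6, 10]] = True
    flags["donor"][11] = True
    bonds = [(0, 1, 2), (1, 2, 1), (2, 3, 2), (3, 4, 1), (4, 5, 2), (5, 0, 1),
             (1, 6, 1), (6, 7, 2), (7, 8, 1), (8, 0, 2),
             (7, 9, 1), (9, 10, 2), (9, 11, 1)]
    return Molecule3D(id="scaffold", elements=elements, coords=coords,
                      charges=charges, flags=flags, bonds=bonds,
                      scaffold_map=list(range(12)), formal_charge=charges.sum())


def scaffold_template() -> Molecule3D:
    """A fresh copy of the common scaffold in the library frame."""
    return _scaffold_template().copy()


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic congeneric library.

    The seed fully determines the library: the same spec twice yields
    byte-identical SDF output (coordinates are rounded to 4 decimals and
    charges to 6 at generation time).
    """

    n_molecules: int = 33
    n_scaffold_atoms: int = _N_SCAFFOLD
    ra_pool_size: int = 6
    rb_pool_size: int = 6
    latent_coefficients: dict[str, float] = dc_field(
        default_factory=lambda: dict(DEFAULT_COEFFICIENTS))
    intercept: float = 5.8
    noise_sd: float = 0.1
    seed: int = 0
    fragment_atoms: tuple[int, int] = (3, 6)   # heavy atoms per R-group, inclusive

    def validate(self) -> None:
        if self.n_molecules < 1:
            raise ValidationError("n_molecules must be >= 1")
        if self.ra_pool_size < 1 or self.rb_pool_size < 1:
            raise ValidationError("empty R-group pool: pool sizes must be >= 1")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.n_scaffold_atoms != _N_SCAFFOLD:
            raise ValidationError(f"scaffold template has {_N_SCAFFOLD} atoms")
        unknown = set(self.latent_coefficients) - set(CHANNELS)
        if unknown:
            raise ValidationError(f"unknown latent channels {sorted(unknown)}")


@dataclass
class _GenFragment:
    """R-group geometry in the local attachment frame (+x points outward)."""
    elements: list[str]
    local: np.ndarray
    charges: np.ndarray
    flags: dict[str, np.ndarray]


def _make_fragment(rng: np.random.Generator, n_atoms: int) -> _GenFragment:
    elements = list(rng.choice(["C", "N", "O", "F"], size=n_atoms,
                               p=[0.5, 0.2, 0.2, 0.1]))
    local = np.zeros((n_atoms, 3))
    for k in range(n_atoms):
        local[k] = [1.5 * (k + 1),
                    rng.uniform(-0.9, 0.9),
                    rng.uniform(-0.3, 0.3)]
    charges = rng.uniform(-0.35, 0.35, size=n_atoms).round(6)
    flags = {k: np.zeros(n_atoms, bool) for k in FLAG_KEYS}
    for i, e in enumerate(elements):
        flags["hydrophobe"][i] = e == "C"
        if e in ("N", "O"):
            flags["donor"][i] = rng.random() < 0.4
        if e in ("N", "O", "F"):
            flags["acceptor"][i] = rng.random() < 0.7
    return _GenFragment(elements, local.round(4), charges, flags)


def _attachment_frame(scaffold: Molecule3D, anchor: int) -> tuple[np.ndarray, np.ndarray]:
    """Origin and rotation mapping fragment-local +x to the outward direction."""
    centroid = scaffold.coords[:9].mean(axis=0)
    u = scaffold.coords[anchor] - centroid
    u[2] = 0.0
    u = u / np.linalg.norm(u)
    v = np.array([-u[1], u[0], 0.0])
    w = np.array([0.0, 0.0, 1.0])
    return scaffold.coords[anchor], np.column_stack([u, v, w])


def _assemble(mol_id: str, ra: _GenFragment, rb: _GenFragment) -> Molecule3D:
    scaffold = _scaffold_template()
    parts = [(_RA_ANCHOR, ra), (_RB_ANCHOR, rb)]
    elements = list(scaffold.elements)
    coords = [scaffold.coords]
    charges = [scaffold.charges]
    flags = {k: [scaffold.flags[k]] for k in FLAG_KEYS}
    bonds = list(scaffold.bonds)
    cut_bonds = {}
    offset = scaffold.n_atoms
    for side, (anchor, frag) in zip(("Ra", "Rb"), parts):
        origin, rot = _attachment_frame(scaffold, anchor)
        n = len(frag.elements)
        elements.extend(frag.elements)
        coords.append((frag.local @ rot.T + origin).round(4))
        charges.append(frag.charges)
        for k in FLAG_KEYS:
            flags[k].append(frag.flags[k])
        bonds.append((anchor, offset, 1))
        bonds.extend((offset + k, offset + k + 1, 1) for k in range(n - 1))
        cut_bonds[side] = (anchor, offset)
        offset += n
    q = np.concatenate(charges)
    return Molecule3D(
        id=mol_id, elements=elements, coords=np.vstack(coords), charges=q,
        flags={k: np.concatenate(v) for k, v in flags.items()}, bonds=bonds,
        scaffold_map=list(range(_N_SCAFFOLD)), formal_charge=q.sum(),
        meta={"cut_bonds": cut_bonds},
    )


def true_descriptors(mol: Molecule3D, r_group_atoms: np.ndarray | None = None) -> dict[str, float]:
    """Generator-side field descriptors: per-channel sums over R-group atoms."""
    if r_group_atoms is None:
        mask = np.ones(mol.n_atoms, bool)
        mask[list(mol.scaffold_map)] = False
        r_group_atoms = np.flatnonzero(mask)
    idx = np.asarray(r_group_atoms, int)
    radii = np.array([VDW_RADII.get(mol.elements[i], 1.70) for i in idx])
    return {
        "S": float(np.sum((radii / 1.70) ** 3)),
        "E": float(mol.charges[idx].sum()),
        "H": float(mol.flags["hydrophobe"][idx].sum()),
        "D": float(mol.flags["donor"][idx].sum()),
        "A": float(mol.flags["acceptor"][idx].sum()),
    }


@dataclass
class SyntheticLibrary:
    """A generated library plus the ground truth that produced it."""
    spec: SyntheticSpec
    molecules: list[Molecule3D]
    records: list            # CompoundRecord; typed loosely to avoid an import cycle
    descriptors: pd.DataFrame          # one row per molecule, columns CHANNELS
    coefficients: dict[str, float]
    intercept: float
    clip_count: int

    def __iter__(self):
        return iter((self.molecules, self.records))


def generate_library(spec: SyntheticSpec) -> SyntheticLibrary:
    """Generate a congeneric library with known latent activity structure.

    Pool fragments have fixed geometry; each molecule samples one Ra and
    one Rb pool member, so field variation across the library has rank at
    most ``(ra_pool-1) + (rb_pool-1)`` and activity, being additive in the
    pool choice, is exactly linear in the centered field matrix when
    ``noise_sd`` is zero.
    """
    from .dataset_io import CompoundRecord  # local import: dataset_io is format-side

    spec.validate()
    rng = np.random.default_rng(spec.seed)
    sizes = spec.fragment_atoms
    ra_pool = [_make_fragment(rng, int(rng.integers(sizes[0], sizes[1] + 1)))
               for _ in range(spec.ra_pool_size)]
    rb_pool = [_make_fragment(rng, int(rng.integers(sizes[0], sizes[1] + 1)))
               for _ in range(spec.rb_pool_size)]
    w = {c: spec.latent_coefficients.get(c, 0.0) for c in CHANNELS}

    molecules, records, rows, ids = [], [], [], []
    clip_count = 0
    for i in range(spec.n_molecules):
        ra_i = int(rng.integers(spec.ra_pool_size))
        rb_i = int(rng.integers(spec.rb_pool_size))
        mol = _assemble(f"SYN{i + 1:03d}", ra_pool[ra_i], rb_pool[rb_i])
        d = true_descriptors(mol)
        latent = spec.intercept + sum(w[c] * d[c] for c in CHANNELS)
        noise = float(rng.normal(0.0, spec.noise_sd)) if spec.noise_sd > 0 else 0.0
        pki = latent + noise
        if not PKI_RANGE[0] <= pki <= PKI_RANGE[1]:
            clip_count += 1
            pki = min(max(pki, PKI_RANGE[0]), PKI_RANGE[1])
        mol.meta.update(ra_index=ra_i, rb_index=rb_i, latent_pki=latent,
                        is_active=True)
        molecules.append(mol)
        set_label = "test" if i % 4 == 3 else "train"
        ki = 10.0 ** (9.0 - pki)
        records.append(CompoundRecord(id=mol.id, ki=ki, pki=pki,
                                      set_label=set_label, structure_ref=mol))
        rows.append([d[c] for c in CHANNELS])
        ids.append(mol.id)
    descriptors = pd.DataFrame(rows, columns=list(CHANNELS), index=ids)
    return SyntheticLibrary(spec=spec, molecules=molecules, records=records,
                            descriptors=descriptors, coefficients=w,
                            intercept=spec.intercept, clip_count=clip_count)


# ---------------------------------------------------------------------------
# decoys


def generate_decoys(source, n_decoys: int, seed: int, *,
                    jitter_range: tuple[float, float] = (0.8, 2.2),
                    flag_dropout: float = 0.3,
                    activity_margin: float = 0.2) -> list[Molecule3D]:
    """Perturbed inactive variants of a set of actives.

    Each decoy copies a random active, jitters every atom with a per-decoy
    amplitude drawn from ``jitter_range`` (Å) and drops each typing flag
    with probability ``flag_dropout``.  When ``source`` is a
    :class:`SyntheticLibrary`, the decoy's latent activity is forced below
    the least-active training compound by ``activity_margin`` pKi units via
    its charge channel.
    """
    library = source if isinstance(source, SyntheticLibrary) else None
    actives = library.molecules if library is not None else list(source)
    if not actives:
        raise ValidationError("cannot build decoys from an empty active set")
    if n_decoys < 1:
        raise DomainError(f"n_decoys must be >= 1, got {n_decoys}")
    rng = np.random.default_rng(seed)
    threshold = None
    if library is not None:
        threshold = min(r.pki for r in library.records) - activity_margin
    decoys = []
    for i in range(n_decoys):
        src = actives[int(rng.integers(len(actives)))]
        mol = src.copy()
        mol.id = f"DEC{i + 1:04d}"
        sd = rng.uniform(*jitter_range)
        mol.coords = (mol.coords + rng.normal(0.0, sd, mol.coords.shape)).round(4)
        for key in FLAG_KEYS:
            drop = rng.random(mol.n_atoms) < flag_dropout
            mol.flags[key] = mol.flags[key] & ~drop
        if threshold is not None and library is not None:
            w_e = library.coefficients.get("E", 0.0)
            if abs(w_e) > 1e-12:
                d = true_descriptors(mol)
                latent = library.intercept + sum(
                    library.coefficients[c] * d[c] for c in CHANNELS)
                if latent > threshold:
                    shift = (threshold - latent) / w_e
                    r_idx = np.flatnonzero(~np.isin(np.arange(mol.n_atoms),
                                                    mol.scaffold_map))
                    if r_idx.size:
                        mol.charges = mol.charges.copy()
                        mol.charges[r_idx] += shift / r_idx.size
                        mol.charges = np.clip(mol.charges, -2.0, 2.0).round(6)
                        mol.formal_charge = float(mol.charges.sum())
        mol.meta = dict(mol.meta, is_active=False, source=src.id)
        decoys.append(mol)
    return decoys


# ---------------------------------------------------------------------------
# pharmacophore-matched actives and the 6-feature reference hypothesis


def reference_pharmacophore(tolerance: float = 1.0) -> PharmacophoreModel:
    """The packaged 6-feature hypothesis: 3 hydrophobic centres, 2 acceptors,
    1 donor, laid out on the scaffold frame (ring centroids, scaffold
    nitrogen, carbonyl oxygen, amide N-H) plus a pendant-aryl hydrophobic
    centre beyond the Rb attachment."""
    scf = _scaffold_template()
    hex_centroid = scf.coords[:6].mean(axis=0)
    ring5 = scf.coords[[0, 1, 6, 7, 8]].mean(axis=0)
    centroid9 = scf.coords[:9].mean(axis=0)
    u = scf.coords[_RB_ANCHOR] - centroid9
    u = u / np.linalg.norm(u)
    aryl = scf.coords[_RB_ANCHOR] + 2.8 * u
    feats = [
        PharmacophoreFeature("HY", hex_centroid, tolerance),
        PharmacophoreFeature("HY", ring5, tolerance),
        PharmacophoreFeature("HY", aryl, tolerance),
        PharmacophoreFeature("AA", scf.coords[6], tolerance),
        PharmacophoreFeature("AA", scf.coords[10], tolerance),
        PharmacophoreFeature("DA", scf.coords[11], tolerance),
    ]
    return PharmacophoreModel(feats)


def generate_actives_on_model(model: PharmacophoreModel, n: int, seed: int,
                              jitter_sd: float = 0.15) -> list[Molecule3D]:
    """Molecules whose perceived features sit on the model centroids.

    Hydrophobic features become flagged five-membered carbon rings centred
    near the feature (positional jitter ``jitter_sd`` Å); acceptor/donor
    features become flagged nitrogen atoms.  Components are joined into a
    single connected graph with tree-like linker bonds so ring perception
    sees exactly one ring per hydrophobic feature.
    """
    if n < 1:
        raise DomainError("n must be >= 1")
    rng = np.random.default_rng(seed)
    actives = []
    for m in range(n):
        elements: list[str] = []
        coords: list[np.ndarray] = []
        charges: list[float] = []
        flags = {k: [] for k in FLAG_KEYS}
        bonds: list[tuple[int, int, int]] = []
        component_heads = []
        for feat in model.features:
            center = feat.centroid + rng.normal(0.0, jitter_sd, 3)
            start = len(elements)
            if feat.kind == "HY":
                for k in range(5):
                    ang = 2 * math.pi * k / 5
                    pos = center + np.array([0.8 * math.cos(ang),
                                             0.8 * math.sin(ang), 0.0])
                    elements.append("C")
                    coords.append(pos)
                    charges.append(0.02)
                    for key in FLAG_KEYS:
                        flags[key].append(key in ("hydrophobe", "aromatic"))
                bonds.extend((start + k, start + (k + 1) % 5, 1) for k in range(5))
            else:
                elements.append("N")
                coords.append(center)
                charges.append(-0.25 if feat.kind == "AA" else -0.15)
                for key in FLAG_KEYS:
                    flags[key].append(
                        (key == "acceptor" and feat.kind == "AA")
                        or (key == "donor" and feat.kind == "DA"))
            component_heads.append(start)
        for prev, head in zip(component_heads, component_heads[1:]):
            bonds.append((prev, head, 1))
        q = np.array(charges)
        actives.append(Molecule3D(
            id=f"ACT{m + 1:03d}", elements=elements,
            coords=np.array(coords).round(4), charges=q,
            flags={k: np.array(v, bool) for k, v in flags.items()},
            bonds=bonds, scaffold_map=[], formal_charge=q.sum(),
            meta={"is_active": True},
        ))
    return actives
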