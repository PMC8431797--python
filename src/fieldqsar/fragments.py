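"""R-group fragmentation, topological fragment search and combinatorial
enumeration — the fragment-based QSAR (topomer-style) analog.

Molecules of a congeneric series are cut at declared acyclic bonds into an
Ra and an Rb side.  Each fragment gets a cheap topological descriptor —
counts of heavy-atom shortest-path lengths 1..10 stratified by element
class pair (C-like, N-like, O-like, halogen, other) — whose L1 distance
(``topdist``) is a proper metric used for similarity thresholding during
fragment searches.  An additive field model fitted per side assigns every
fragment an activity contribution, so candidate molecules assembled from
an Ra × Rb pool carry the prediction

    pKi = intercept + contribution(Ra) + contribution(Rb).

The commercial topomer machinery builds canonical fragment conformers;
here fragments keep their generator geometry (the library is already in
one frame), a documented deviation that preserves the bookkeeping while
staying fully reproducible.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import networkx as nx
import numpy as np

from .errors import DomainError, ValidationError
from .field_engine import build_grid, comsia_fields, filter_and_scale
from .molecule import FLAG_KEYS, Molecule3D
from .pls_qsar import fit_pls

ELEMENT_CLASSES = {
    "C": 0, "Si": 0,
    "N": 1, "P": 1,
    "O": 2, "S": 2,
    "F": 3, "Cl": 3, "Br": 3, "I": 3,
}
_N_CLASSES = 5
_MAX_PATH = 10
_CLASS_PAIRS = [(i, j) for i in range(_N_CLASSES) for j in range(i, _N_CLASSES)]
_PAIR_INDEX = {p: k for k, p in enumerate(_CLASS_PAIRS)}

DESCRIPTOR_LENGTH = len(_CLASS_PAIRS) * _MAX_PATH

DEFAULT_TOPDIST_MAX = 185.0
DEFAULT_MIN_HEAVY = 3


@dataclass
class FragmentRecord:
    """One side of a cut molecule, with geometry and topological descriptor."""

    id: str
    side: str                      # "Ra" or "Rb"
    parent_id: str
    atoms: list[int]               # indices into the parent molecule
    attachment_atom: int           # parent index of the atom that carried the cut bond
    scaffold_anchor: int | None    # parent index on the other side of the cut
    molecule: Molecule3D           # fragment-only submolecule (parent geometry)
    descriptor: np.ndarray
    heavy_atom_count: int
    contribution: float | None = None


def _bond_graph(mol: Molecule3D) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(mol.n_atoms))
    g.add_edges_from((i, j) for i, j, _ in mol.bonds)
    return g


def _submolecule(mol: Molecule3D, atoms: list[int], frag_id: str) -> Molecule3D:
    index = {a: k for k, a in enumerate(atoms)}
    bonds = [(index[i], index[j], o) for i, j, o in mol.bonds
             if i in index and j in index]
    charges = mol.charges[atoms]
    return Molecule3D(
        id=frag_id, elements=[mol.elements[a] for a in atoms],
        coords=mol.coords[atoms], charges=charges,
        flags={k: mol.flags[k][atoms] for k in FLAG_KEYS}, bonds=bonds,
        scaffold_map=[], formal_charge=float(charges.sum()),
    )


def fragment_descriptor(mol: Molecule3D) -> np.ndarray:
    """Shortest-path-length counts per element-class pair, lengths 1..10.

    Hydrogens are excluded; each unordered heavy-atom pair contributes one
    count.  The L1 distance between two such vectors is a metric.
    """
    heavy = [i for i, e in enumerate(mol.elements) if e != "H"]
    g = _bond_graph(mol).subgraph(heavy)
    vec = np.zeros(DESCRIPTOR_LENGTH)
    lengths = dict(nx.all_pairs_shortest_path_length(g, cutoff=_MAX_PATH))
    for i, j in itertools.combinations(heavy, 2):
        lij = lengths.get(i, {}).get(j)
        if lij is None or lij < 1:
            continue
        ci = ELEMENT_CLASSES.get(mol.elements[i], 4)
        cj = ELEMENT_CLASSES.get(mol.elements[j], 4)
        pair = _PAIR_INDEX[(min(ci, cj), max(ci, cj))]
        vec[pair * _MAX_PATH + (lij - 1)] += 1
    return vec


def fragment_cut(mol: Molecule3D, cut_bond: tuple[int, int]) -> tuple[FragmentRecord, FragmentRecord]:
    """Cut one acyclic bond into two fragments.

    The side containing scaffold atom 0 (atom 0 when no scaffold is
    declared) is labelled Ra; the other Rb.  Ring bonds and cuts that do
    not yield exactly two components are rejected.
    """
    i, j = cut_bond
    bond_set = {(a, b) for a, b, _ in mol.bonds} | {(b, a) for a, b, _ in mol.bonds}
    if (i, j) not in bond_set:
        raise DomainError(f"{mol.id}: no bond between atoms {i} and {j}")
    g = _bond_graph(mol)
    g.remove_edge(i, j)
    comps = list(nx.connected_components(g))
    if len(comps) != 2:
        raise DomainError(
            f"{mol.id}: cutting bond ({i},{j}) yields {len(comps)} components "
            "(ring bonds cannot be cut)")
    ref_atom = mol.scaffold_map[0] if mol.scaffold_map else 0
    comps.sort(key=lambda c: ref_atom not in c)
    records = []
    for side, comp in zip(("Ra", "Rb"), comps):
        atoms = sorted(comp)
        inside, outside = (i, j) if i in comp else (j, i)
        sub = _submolecule(mol, atoms, f"{mol.id}:{side}")
        records.append(FragmentRecord(
            id=f"{mol.id}:{side}", side=side, parent_id=mol.id, atoms=atoms,
            attachment_atom=inside, scaffold_anchor=outside, molecule=sub,
            descriptor=fragment_descriptor(sub),
            heavy_atom_count=sum(1 for e in sub.elements if e != "H"),
        ))
    return records[0], records[1]


def cut_r_groups(mol: Molecule3D) -> dict[str, FragmentRecord]:
    """Cut both declared R-group attachment bonds of a library molecule.

    Requires ``mol.meta['cut_bonds']`` as written by the synthetic
    generator: a mapping side → (scaffold anchor, first fragment atom).
    The returned fragments are the non-scaffold sides, relabelled by the
    attachment they came from.
    """
    cut_bonds = mol.meta.get("cut_bonds")
    if not cut_bonds:
        raise ValidationError(f"{mol.id}: no declared R-group cut bonds")
    out = {}
    for side, bond in cut_bonds.items():
        scaffold_side, r_side = fragment_cut(mol, tuple(bond))
        frag = replace(r_side, side=side, id=f"{mol.id}:{side}")
        frag.molecule = replace(frag.molecule, id=frag.id)
        out[side] = frag
    return out


def topdist(a: FragmentRecord, b: FragmentRecord, unit: float = 1.0) -> float:
    """L1 distance between fragment descriptors, scaled by the config unit."""
    if a.descriptor.shape != b.descriptor.shape:
        raise DomainError("fragment descriptors have different lengths")
    return float(np.abs(a.descriptor - b.descriptor).sum() * unit)


def search_fragments(pool: list[FragmentRecord], query: FragmentRecord,
                     topdist_max: float = DEFAULT_TOPDIST_MAX,
                     min_heavy: int = DEFAULT_MIN_HEAVY,
                     unit: float = 1.0) -> list[FragmentRecord]:
    """Fragments within a topological distance of the query, above the
    minimum heavy-atom size (the fragment-search screening step)."""
    return [f for f in pool
            if f.heavy_atom_count >= min_heavy
            and topdist(f, query, unit) <= topdist_max]


# ---------------------------------------------------------------------------
# additive per-side field model


class AdditiveFragmentModel:
    """Field model additive over the two R-group sides.

    Per side, similarity-index fields (S and E channels) of the fragment
    alone — the other side zeroed by construction — are computed on a
    side-specific grid; a single PLS fit on the concatenated side blocks
    yields per-side coefficient slices.  Contributions are reported
    relative to the training mean of each side, so

        predict(Ra, Rb) = intercept + contribution(Ra) + contribution(Rb)

    holds exactly, with intercept = mean training activity.
    """

    def __init__(self, grid_spacing: float = 2.0, margin: float = 3.0,
                 channels: tuple[str, ...] = ("S", "E"), alpha: float = 0.3,
                 min_sd: float = 1e-6, max_components: int = 25):
        self.grid_spacing = grid_spacing
        self.margin = margin
        self.channels = channels
        self.alpha = alpha
        self.min_sd = min_sd
        self.max_components = max_components
        self._sides: dict[str, dict] = {}
        self.intercept: float | None = None

    def _side_matrix(self, side: str, frags: list[FragmentRecord]) -> np.ndarray:
        info = self._sides[side]
        block = comsia_fields([f.molecule for f in frags], info["grid"],
                              channels=self.channels, alpha=self.alpha)
        block.column_mask = info["mask"]
        block.block_scale = info["scale"]
        return block.design_matrix()

    def fit(self, fragment_pairs: list[dict[str, FragmentRecord]], y) -> "AdditiveFragmentModel":
        y = np.asarray(y, float).ravel()
        if len(fragment_pairs) != y.size:
            raise DomainError("one fragment pair per activity required")
        sides = ("Ra", "Rb")
        mats = []
        for side in sides:
            frags = [p[side] for p in fragment_pairs]
            grid = build_grid([f.molecule for f in frags],
                              self.grid_spacing, self.margin)
            block = comsia_fields([f.molecule for f in frags], grid,
                                  channels=self.channels, alpha=self.alpha)
            block = filter_and_scale(block, min_sd=self.min_sd)
            self._sides[side] = {"grid": grid, "mask": block.column_mask,
                                 "scale": block.block_scale}
            mats.append(block.design_matrix())
        x = np.hstack(mats)
        k = min(self.max_components, x.shape[0] - 1, x.shape[1])
        summary = fit_pls(x, y, n_components=k)
        self.intercept = summary.y_mean
        split = mats[0].shape[1]
        offsets = {"Ra": (0, split), "Rb": (split, x.shape[1])}
        for side in sides:
            lo, hi = offsets[side]
            self._sides[side]["coef"] = summary.coefficients[lo:hi]
            self._sides[side]["x_mean"] = summary.x_mean[lo:hi]
        self.summary = summary
        return self

    def contribution(self, frag: FragmentRecord) -> float:
        """Predicted pKi increment of one fragment relative to the side mean."""
        if self.intercept is None:
            raise ValidationError("model not fitted")
        if frag.side not in self._sides:
            raise DomainError(f"fragment side {frag.side!r} unknown to this model")
        info = self._sides[frag.side]
        x = self._side_matrix(frag.side, [frag])[0]
        return float((x - info["x_mean"]) @ info["coef"])

    def predict_pair(self, ra: FragmentRecord, rb: FragmentRecord) -> float:
        if ra.side != "Ra" or rb.side != "Rb":
            raise DomainError("predict_pair expects an (Ra, Rb) fragment pair")
        return self.intercept + self.contribution(ra) + self.contribution(rb)


# ---------------------------------------------------------------------------
# combinatorial enumeration


@dataclass
class CandidateMolecule:
    id: str
    ra_id: str
    rb_id: str
    molecule: Molecule3D
    predicted_pki: float | None


def assemble_candidate(scaffold: Molecule3D, ra: FragmentRecord,
                       rb: FragmentRecord, mol_id: str) -> Molecule3D:
    """Scaffold plus two fragments at their stored attachment frames.

    Fragments keep the geometry they had in their parent molecules; since
    the whole library shares one frame, the union of coordinates is the
    assembled candidate.
    """
    elements = list(scaffold.elements)
    coords = [scaffold.coords]
    charges = [scaffold.charges]
    flags = {k: [scaffold.flags[k]] for k in FLAG_KEYS}
    bonds = list(scaffold.bonds)
    cut_bonds = {}
    offset = scaffold.n_atoms
    for frag in (ra, rb):
        sub = frag.molecule
        local_attach = frag.atoms.index(frag.attachment_atom)
        elements.extend(sub.elements)
        coords.append(sub.coords)
        charges.append(sub.charges)
        for k in FLAG_KEYS:
            flags[k].append(sub.flags[k])
        bonds.append((frag.scaffold_anchor, offset + local_attach, 1))
        bonds.extend((i + offset, j + offset, o) for i, j, o in sub.bonds)
        cut_bonds[frag.side] = (frag.scaffold_anchor, offset + local_attach)
        offset += sub.n_atoms
    q = np.concatenate(charges)
    return Molecule3D(
        id=mol_id, elements=elements, coords=np.vstack(coords), charges=q,
        flags={k: np.concatenate(v) for k, v in flags.items()}, bonds=bonds,
        scaffold_map=list(scaffold.scaffold_map), formal_charge=q.sum(),
        meta={"cut_bonds": cut_bonds, "ra_id": ra.id, "rb_id": rb.id},
    )


def _graph_hash(mol: Molecule3D) -> str:
    g = nx.Graph()
    for i, e in enumerate(mol.elements):
        g.add_node(i, element=e)
    g.add_edges_from((i, j) for i, j, _ in mol.bonds)
    return nx.weisfeiler_lehman_graph_hash(g, node_attr="element")


def enumerate_combinations(ra_pool: list[FragmentRecord],
                           rb_pool: list[FragmentRecord],
                           scaffold: Molecule3D,
                           model: AdditiveFragmentModel | None = None,
                           dedupe: bool = False) -> list[CandidateMolecule]:
    """All |Ra|×|Rb| assembled candidates (graph-duplicates dropped when
    ``dedupe``), each carrying the additive activity prediction when a
    fitted side model is supplied."""
    if not ra_pool or not rb_pool:
        raise ValidationError("both fragment pools must be non-empty")
    candidates = []
    seen = set()
    for n, (ra, rb) in enumerate(itertools.product(ra_pool, rb_pool), start=1):
        mol = assemble_candidate(scaffold, ra, rb, f"CAND{n:04d}")
        if dedupe:
            h = _graph_hash(mol)
            if h in seen:
                continue
            seen.add(h)
        pred = model.predict_pair(ra, rb) if model is not None else None
        candidates.append(CandidateMolecule(id=mol.id, ra_id=ra.id, rb_id=rb.id,
                                            molecule=mol, predicted_pki=pred))
    return candidates
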