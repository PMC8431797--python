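"""Fixed-feature pharmacophore models, feature perception and fit scoring.

A model is a set of feature spheres — hydrophobic centres (HY), hydrogen
bond acceptor atoms (AA) and donor atoms (DA) — each with a centroid and a
tolerance radius.  Molecules are assumed pre-aligned to the model frame
(the congeneric-series convention); there is no pose search.

The fit score is a 0–100 geometric match,

    qfit = 100 · exp(-mean_i d_i²/τ_i²),

maximised over injective assignments of features to same-kind candidates.
In strict mode (default) the score is zero as soon as any feature has no
candidate within its search radius, mirroring the all-features semantics
of a 3D search query; partial mode scores the matched subset and applies
a matched/total count penalty.  Scores are comparable in spirit to the
commercial QFIT (same scale, same >50 screening threshold), not numerically.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field as dc_field

import networkx as nx
import numpy as np
import yaml

from .errors import DomainError, ValidationError
from .molecule import Molecule3D

FEATURE_KINDS = ("HY", "AA", "DA")

#: candidates farther than this multiple of the tolerance radius are not considered
SEARCH_RADIUS_FACTOR = 2.5


@dataclass(frozen=True)
class PharmacophoreFeature:
    kind: str
    centroid: np.ndarray
    tolerance: float

    def __post_init__(self):
        if self.kind not in FEATURE_KINDS:
            raise ValidationError(f"unknown feature kind {self.kind!r}")
        if self.tolerance <= 0:
            raise ValidationError("feature tolerance must be > 0")
        object.__setattr__(self, "centroid", np.asarray(self.centroid, float))


@dataclass
class PharmacophoreModel:
    features: list[PharmacophoreFeature]

    def __post_init__(self):
        if not self.features:
            raise ValidationError("a pharmacophore model needs at least one feature")

    def counts(self) -> dict[str, int]:
        out = {k: 0 for k in FEATURE_KINDS}
        for f in self.features:
            out[f.kind] += 1
        return out

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "PharmacophoreModel":
        return PharmacophoreModel([
            PharmacophoreFeature(f.kind, np.asarray(rotation) @ f.centroid + translation,
                                 f.tolerance)
            for f in self.features
        ])

    @classmethod
    def from_yaml(cls, path) -> "PharmacophoreModel":
        with open(path) as fh:
            entries = yaml.safe_load(fh)
        return cls([PharmacophoreFeature(e["kind"], [e["x"], e["y"], e["z"]],
                                         float(e.get("tolerance", 1.0)))
                    for e in entries])

    def to_yaml(self, path) -> None:
        entries = [{"kind": f.kind, "x": float(f.centroid[0]), "y": float(f.centroid[1]),
                    "z": float(f.centroid[2]), "tolerance": float(f.tolerance)}
                   for f in self.features]
        with open(path, "w") as fh:
            yaml.safe_dump(entries, fh, sort_keys=False)


@dataclass
class MatchResult:
    qfit: float
    assignment: list[tuple[int, np.ndarray]]   # (feature index, matched point)
    matched_count: int


def perceive_features(mol: Molecule3D) -> dict[str, list[np.ndarray]]:
    """Candidate points per feature kind.

    HY candidates are centroids of rings (independent cycles) in the bond
    graph restricted to hydrophobe- or aromatic-flagged atoms; AA and DA
    candidates are the acceptor- and donor-flagged atom positions.
    """
    for key in ("hydrophobe", "aromatic", "donor", "acceptor"):
        if key not in mol.flags:
            raise ValidationError(f"{mol.id}: missing typing flags {key!r}")
    hydro = mol.flags["hydrophobe"] | mol.flags["aromatic"]
    g = nx.Graph()
    g.add_nodes_from(np.flatnonzero(hydro).tolist())
    for i, j, _ in mol.bonds:
        if hydro[i] and hydro[j]:
            g.add_edge(i, j)
    rings = nx.cycle_basis(g)
    return {
        "HY": [mol.coords[list(ring)].mean(axis=0) for ring in rings],
        "AA": [mol.coords[i] for i in np.flatnonzero(mol.flags["acceptor"])],
        "DA": [mol.coords[i] for i in np.flatnonzero(mol.flags["donor"])],
    }


def _best_kind_assignment(feats, cands):
    """Minimal total d²/τ² over injective feature→candidate maps for one kind.

    Returns (cost, pairs) or None when some feature has no admissible
    candidate.  Feature counts are tiny (≤3 per kind in practice), so the
    exhaustive scan over candidate permutations is exact and cheap.
    """
    admissible = []
    for fi, feat in feats:
        opts = []
        search = SEARCH_RADIUS_FACTOR * feat.tolerance
        for ci, point in enumerate(cands):
            d2 = float(np.sum((point - feat.centroid) ** 2))
            if d2 <= search * search:
                opts.append((ci, d2 / feat.tolerance ** 2))
        if not opts:
            return None
        admissible.append((fi, opts))
    best = None
    def rec(k, used, cost, pairs):
        nonlocal best
        if best is not None and cost >= best[0]:
            return
        if k == len(admissible):
            if best is None or cost < best[0]:
                best = (cost, list(pairs))
            return
        fi, opts = admissible[k]
        for ci, c in opts:
            if ci in used:
                continue
            used.add(ci)
            pairs.append((fi, ci))
            rec(k + 1, used, cost + c, pairs)
            pairs.pop()
            used.remove(ci)
    rec(0, set(), 0.0, [])
    return best


def qfit_score(mol: Molecule3D, model: PharmacophoreModel, *,
               strict: bool = True) -> MatchResult:
    """Best-assignment geometric fit of a molecule to a feature model."""
    cands = perceive_features(mol)
    total_cost = 0.0
    pairs: list[tuple[int, np.ndarray]] = []
    matched = 0
    for kind in FEATURE_KINDS:
        feats = [(i, f) for i, f in enumerate(model.features) if f.kind == kind]
        if not feats:
            continue
        result = _best_kind_assignment(feats, cands[kind])
        if result is None:
            if strict:
                return MatchResult(0.0, [], 0)
            continue
        cost, kind_pairs = result
        total_cost += cost
        matched += len(kind_pairs)
        pairs.extend((fi, cands[kind][ci]) for fi, ci in kind_pairs)
    if matched == 0:
        return MatchResult(0.0, [], 0)
    score = 100.0 * float(np.exp(-total_cost / matched))
    if not strict:
        score *= matched / len(model.features)
    return MatchResult(score, pairs, matched)


def screen_by_pharmacophore(library, model: PharmacophoreModel,
                            threshold: float = 50.0, *,
                            strict: bool = True):
    """Retain molecules with qfit strictly above ``threshold``.

    Returns ``(retained_ids, scores, enrichment_counts)`` where
    ``enrichment_counts`` is the ``(ha, ht, a, d)`` tuple for
    :mod:`fieldqsar.validation_metrics` when activity labels
    (``meta['is_active']``) are present on every molecule, else ``None``.
    """
    molecules = list(library)
    if not molecules:
        raise ValidationError("empty library")
    if not 0.0 <= threshold <= 100.0:
        raise DomainError("threshold must lie in [0, 100]")
    scores = {m.id: qfit_score(m, model, strict=strict).qfit for m in molecules}
    retained = [mid for mid, s in scores.items() if s > threshold]
    counts = None
    if all("is_active" in m.meta for m in molecules):
        active_ids = {m.id for m in molecules if m.meta["is_active"]}
        ha = sum(1 for mid in retained if mid in active_ids)
        counts = (ha, len(retained), len(active_ids), len(molecules))
    return retained, scores, counts
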