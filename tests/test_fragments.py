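"""Fragment cutting, topological distance, additive model and enumeration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fieldqsar as fq
from fieldqsar.errors import DomainError, ValidationError
from fieldqsar.fragments import (
    AdditiveFragmentModel,
    _graph_hash,
    assemble_candidate,
    cut_r_groups,
    enumerate_combinations,
    fragment_cut,
    search_fragments,
    topdist,
)
from fieldqsar.molecule import FLAG_KEYS, Molecule3D
from fieldqsar.synthetic_data import CHANNELS, scaffold_template, true_descriptors


def _two_atom():
    return Molecule3D(id="x", elements=["C", "N"],
                      coords=np.array([[0, 0, 0], [1.5, 0, 0.0]]),
                      charges=np.zeros(2),
                      flags={k: np.zeros(2, bool) for k in FLAG_KEYS},
                      bonds=[(0, 1, 1)])


@pytest.fixture(scope="module")
def cut_library():
    lib = fq.generate_library(fq.SyntheticSpec(
        seed=13, n_molecules=32, noise_sd=0.0, ra_pool_size=4, rb_pool_size=4))
    pairs = [cut_r_groups(m) for m in lib.molecules]
    return lib, pairs


@pytest.fixture(scope="module")
def fitted_model(cut_library):
    lib, pairs = cut_library
    y = np.array([r.pki for r in lib.records])
    return AdditiveFragmentModel().fit(pairs, y), lib, pairs, y


class TestFragmentCut:
    def test_two_atom_molecule(self):
        ra, rb = fragment_cut(_two_atom(), (0, 1))
        assert ra.side == "Ra" and 0 in ra.atoms and len(ra.atoms) == 1
        assert rb.side == "Rb" and rb.atoms == [1]

    def test_ring_bond_rejected(self, small_library):
        with pytest.raises(DomainError, match="ring"):
            fragment_cut(small_library.molecules[0], (0, 1))   # scaffold ring bond

    def test_nonexistent_bond_rejected(self, small_library):
        with pytest.raises(DomainError, match="no bond"):
            fragment_cut(small_library.molecules[0], (0, 7))

    def test_r_groups_graph_identical_within_pool_slot(self, cut_library):
        """Molecules sharing a pool member yield graph-identical fragments."""
        lib, pairs = cut_library
        by_slot = {}
        for m, p in zip(lib.molecules, pairs):
            by_slot.setdefault(("Ra", m.meta["ra_index"]), set()).add(
                _graph_hash(p["Ra"].molecule))
            by_slot.setdefault(("Rb", m.meta["rb_index"]), set()).add(
                _graph_hash(p["Rb"].molecule))
        assert all(len(hashes) == 1 for hashes in by_slot.values())

    def test_reassembly_reproduces_parent(self, cut_library):
        lib, pairs = cut_library
        for m, p in zip(lib.molecules[:5], pairs[:5]):
            re = assemble_candidate(scaffold_template(), p["Ra"], p["Rb"], "re")
            assert re.n_atoms == m.n_atoms
            np.testing.assert_allclose(np.sort(re.coords, axis=0),
                                       np.sort(m.coords, axis=0), atol=1e-9)
            assert _graph_hash(re) == _graph_hash(m)


class TestTopdist:
    def test_identity_and_symmetry(self, cut_library):
        _, pairs = cut_library
        a, b = pairs[0]["Ra"], pairs[1]["Ra"]
        assert topdist(a, a) == 0.0
        assert topdist(a, b) == topdist(b, a)

    def test_single_extra_path_unit(self):
        """Appending one atom adds exactly its new shortest paths to the L1."""
        m = _two_atom()
        m3 = Molecule3D(id="y", elements=["C", "N", "C"],
                        coords=np.array([[0, 0, 0], [1.5, 0, 0], [3.0, 0, 0.0]]),
                        charges=np.zeros(3),
                        flags={k: np.zeros(3, bool) for k in FLAG_KEYS},
                        bonds=[(0, 1, 1), (1, 2, 1)])
        fa = fragment_cut(m, (0, 1))[0]
        fb = fragment_cut(m3, (1, 2))[0]   # CN fragment vs C fragment
        # descriptors differ by the C-N length-1 path only
        assert topdist(fa, fb) == 1.0

    def test_metric_axioms_over_seeded_triples(self):
        lib = fq.generate_library(fq.SyntheticSpec(seed=23, n_molecules=40,
                                                   ra_pool_size=8, rb_pool_size=8))
        frags = []
        for m in lib.molecules:
            p = cut_r_groups(m)
            frags.extend([p["Ra"], p["Rb"]])
        rng = np.random.default_rng(99)
        for _ in range(500):
            a, b, c = (frags[i] for i in rng.integers(len(frags), size=3))
            dab, dbc, dac = topdist(a, b), topdist(b, c), topdist(a, c)
            assert dab >= 0 and dab == topdist(b, a)
            assert dac <= dab + dbc + 1e-12
        assert all(topdist(f, f) == 0 for f in frags[:10])

    def test_search_thresholds(self, cut_library):
        _, pairs = cut_library
        pool = [p["Ra"] for p in pairs]
        query = pool[0]
        hits = search_fragments(pool, query, topdist_max=0.0, min_heavy=1)
        assert all(topdist(f, query) == 0 for f in hits) and query in hits
        assert search_fragments(pool, query, topdist_max=1e9, min_heavy=99) == []


class TestAdditiveModel:
    def test_additive_prediction_identity(self, fitted_model):
        """intercept + contribution(Ra) + contribution(Rb) equals the model
        prediction on every training molecule exactly."""
        model, lib, pairs, y = fitted_model
        for p in pairs:
            pred = model.predict_pair(p["Ra"], p["Rb"])
            assert pred == pytest.approx(
                model.intercept + model.contribution(p["Ra"])
                + model.contribution(p["Rb"]), abs=1e-9)

    def test_noiseless_recovery_of_training_activities(self, fitted_model):
        model, lib, pairs, y = fitted_model
        pred = np.array([model.predict_pair(p["Ra"], p["Rb"]) for p in pairs])
        np.testing.assert_allclose(pred, y, atol=1e-6)

    def test_contributions_recover_generator_increments(self, fitted_model):
        """Per-side contributions equal the generator's latent fragment
        increments up to one additive constant per side."""
        model, lib, pairs, y = fitted_model
        w = lib.coefficients
        for side in ("Ra", "Rb"):
            slots = {}
            for m, p in zip(lib.molecules, pairs):
                slots.setdefault(m.meta[f"{side.lower()}_index"], p[side])
            truth, fitted = [], []
            for frag in slots.values():
                d = true_descriptors(frag.molecule,
                                     np.arange(frag.molecule.n_atoms))
                truth.append(sum(w[c] * d[c] for c in CHANNELS))
                fitted.append(model.contribution(frag))
            truth, fitted = np.asarray(truth), np.asarray(fitted)
            np.testing.assert_allclose(truth - truth.mean(),
                                       fitted - fitted.mean(), atol=1e-6)

    def test_side_mismatch_rejected(self, fitted_model):
        model, lib, pairs, _ = fitted_model
        with pytest.raises(DomainError):
            model.predict_pair(pairs[0]["Rb"], pairs[0]["Ra"])


class TestEnumeration:
    def test_cartesian_product_count(self, fitted_model):
        model, lib, pairs, _ = fitted_model
        ras = list({p["Ra"].id: p["Ra"] for p in pairs}.values())
        rbs = list({p["Rb"].id: p["Rb"] for p in pairs}.values())
        cands = enumerate_combinations(ras[:3], rbs[:3], scaffold_template(),
                                       model=model)
        assert len(cands) == 9
        for c in cands:
            assert c.predicted_pki == pytest.approx(
                model.intercept + model.contribution(
                    next(r for r in ras if r.id == c.ra_id))
                + model.contribution(next(r for r in rbs if r.id == c.rb_id)),
                abs=1e-9)

    def test_dedupe_on_duplicate_pool_entries(self, cut_library):
        """Repeating a pool entry must not multiply the candidate count when
        graph-level deduplication is on."""
        lib, pairs = cut_library
        # pick pool slots that are pairwise non-isomorphic at the graph level
        slots = {}
        for m, p in zip(lib.molecules, pairs):
            slots.setdefault(_graph_hash(p["Ra"].molecule), p["Ra"])
        ras = list(slots.values())[:2]
        rb_slots = {}
        for m, p in zip(lib.molecules, pairs):
            rb_slots.setdefault(_graph_hash(p["Rb"].molecule), p["Rb"])
        rbs = list(rb_slots.values())[:2]
        if len(ras) < 2 or len(rbs) < 2:
            pytest.skip("library lacks two non-isomorphic pool fragments")
        base = enumerate_combinations(ras, rbs, scaffold_template(), dedupe=True)
        dup = enumerate_combinations(ras + [ras[0]], rbs + [rbs[1]],
                                     scaffold_template(), dedupe=True)
        assert len(base) == 4
        assert len(dup) == len(base)

    def test_empty_pool_rejected(self, cut_library):
        _, pairs = cut_library
        with pytest.raises(ValidationError):
            enumerate_combinations([], [pairs[0]["Rb"]], scaffold_template())
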