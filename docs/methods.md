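# Methods

`fieldqsar` implements the computational core of ligand-based virtual
screening for a congeneric small-molecule series: field-based 3D-QSAR
(CoMFA/CoMSIA style) with PLS regression and internal/external validation,
pharmacophore fit scoring with decoy-set enrichment statistics, fragment
(R-group) modelling and enumeration, a rule-based ADME/T screening cascade,
and MM-PBSA energy bookkeeping.  This note records the models, conventions
and numerical choices, and what the synthetic test bed does and does not
establish about real data.

## Activity scale

Affinities enter as inhibition constants Ki in nM and are modelled as
pKi = −log10(Ki [M]) = 9 − log10(Ki [nM]).  The packaged reference table
(33 imidazo[1,2-a]-pyridine positive allosteric modulators of the
α1-GABA_A receptor, zolpidem included) spans pKi 6.081–7.680 with a
realized 25/8 train/test split.  The split ships as data and is never
re-randomized: the realized assignment is part of the published record,
and every downstream worked example depends on it.  Residuals are
predicted − actual throughout.

## Interaction fields

Molecules are assumed pre-aligned in one frame (the congeneric-series
convention; the synthetic generator emits libraries already aligned, and
`alignment.kabsch_align` superposes external structures via the indexed
scaffold correspondence).  A rectangular grid covers all atoms plus a
margin, snapped outward to whole steps.

* **Probe energies (CoMFA style, kcal/mol).**  Steric: Lennard-Jones 6-12
  for an sp3-carbon-like probe (ε = 0.107 kcal/mol, r_min/2 = 1.70 Å),
  combined with per-element parameters by ε_ij = √(ε_i ε_j),
  R_min,ij = r_min,i/2 + r_min,j/2.  Electrostatic: Coulomb term
  332.0636·q_probe·Σ q_i/(ε(r)·r) with distance-dependent dielectric
  ε(r) = r (switchable to constant).  Both clamped to ±30 kcal/mol.
  Electrostatics inside the steric core are retained and flagged, not
  mean-substituted — a simpler, documented convention.
* **Similarity indices (CoMSIA style, dimensionless).**
  A_k(q) = −Σ_i w_ik·exp(−α r²) with α = 0.3 Å⁻², probe weight +1 and
  atom weights: partial charge (E), r_vdW³ (S), and 0/1 typing flags
  (H, D, A).
* **Pretreatment.**  Columns with training-set SD < 0.05 are masked; each
  channel is scaled so its total retained-column variance is equal
  (CoMFA-STD style).  Scaling is stored, not baked into the matrix, so
  cross-validation can re-derive it per fold.

Grid spacing 2.0 Å and margin 4.0 Å are classical defaults; the reference
study reports no grid parameters, so exact reproduction of commercial
field values is not attempted (tests therefore anchor on the study's
*printed* statistics, not on its fields).

## PLS and internal validation

Single-response NIPALS with deflation on X, deterministic, capped at 15
components by default (the largest component count the reference models
report).  Definitions: r² = 1 − SSE/SST; SEE = √(SSE/(n − onc − 1));
F = (r²/onc)/((1 − r²)/(n − onc − 1)); q² = 1 − PRESS/SST by leave-one-out
with centering and channel scaling recomputed on each fold's n−1 rows
(the column mask stays fixed so dimensions are stable).  The optimal
component count is the argmax of the q² profile, exact ties broken toward
fewer components; when deflation exhausts the rank of X early, the
effective count is reported.  Per-channel field contributions are shares
of Σ_j |b_j|·s_j (s_j = column SD): the field never defines its
contribution formula, so this package's convention is stated explicitly
and tested.  The conventional trust gate q² > 0.5, r² > 0.6, SEE ≪ 1 is
exposed as `quality_gate`.

## External validation

The Golbraikh–Tropsha/Roy suite: RMSE, r², through-origin slopes and
determination coefficients, r_m² pair, Δr_m², mean r_m², and predictive
r_pred² = 1 − Σ(ŷ−y)²/Σ(y−ȳ_train)² (training-mean denominator, the
standard predictive-r² definition).  The slope conventions are ambiguous
in the literature; this package fixes

    k  = Σyŷ/Σŷ²,  r₀²  = 1 − Σ(y − kŷ)²/Σ(y − ȳ)²,
    k′ = Σyŷ/Σy²,  r₀′² = 1 − Σ(ŷ − k′y)²/Σ(ŷ − ȳ̂)²,

the unique assignment under which recomputing the reference worked example
from its printed test-set predictions reproduces the published k/k′ pair
(0.9973/1.0019, recomputed 0.998/1.002).  r_m² = r²(1 − √(r² − r₀²)) with
a negative radicand floored at zero (possible when r₀² > r²).  Published
cells derived from unrounded predictions can differ from recomputation at
3-decimal precision by up to ~0.015 on the r_m² family; tests use
tolerances consistent with that rounding floor.  The pass gate applies
r_pred² > 0.6, 0.85 < k (or k′) < 1.15, Δr_m² < 0.2, mean r_m² > 0.5 and
(r² − r₀²)/r² < 0.1.

## Pharmacophore model and fit score

A model is a fixed list of feature spheres — hydrophobic centres (HY),
acceptor atoms (AA), donor atoms (DA) — with tolerance radii (default
1.0 Å).  Perception: HY candidates are centroids of rings (independent
cycles) among hydrophobe/aromatic-flagged atoms; AA/DA candidates are the
flagged atoms.  The fit score is

    qfit = 100·exp(−mean_i d_i²/τ_i²)

over the best injective same-kind assignment (exhaustive; candidate pools
are pruned at 2.5τ).  Strict mode scores 0 when any feature is
unassignable; partial mode scores the matched subset times matched/total.
Molecules are taken pre-aligned to the model frame — no pose search, a
stated limitation.  The commercial QFIT functional form is proprietary:
scores here share its scale (0–100) and screening threshold (strictly
above 50), not its numerical values.  The packaged 6-feature reference
hypothesis (3 HY, 2 AA, 1 DA) is laid out on the synthetic scaffold frame:
two ring centroids plus a pendant-aryl position, the scaffold ring
nitrogen and carbonyl oxygen, and the amide N–H.

Enrichment against a decoy database uses EF = (Ha/Ht)/(A/D) and
GH = [Ha(3A+Ht)/(4HtA)]·[1 − (Ht−Ha)/(D−A)], with the usual acceptance
bands EF > 1 and 0.6 < GH < 1.  `find_enrichment_counts` inverts printed
(EF, GH) pairs to integer (Ha, Ht) by exhaustive search.

## Fragments and enumeration

Molecules are cut at declared acyclic bonds into Ra/Rb sides (the side
holding scaffold atom 0 is Ra; ring bonds are rejected).  The topological
descriptor is the count vector of heavy-atom shortest-path lengths 1–10
per element-class pair (C-like, N-like, O-like, halogen, other; 150
entries); `topdist` is its L1 distance — a proper metric — with the
published thresholds (topdist ≤ 185 config units, ≥ 3 heavy atoms) as
defaults.  The commercial TOPDIST is proprietary and its units
undocumented; the threshold is honored as a configurable number, not a
reproduced quantity.  Fragments keep their generator geometry rather than
canonical conformers — a documented deviation that keeps the bookkeeping
exact and reproducible.

The additive model computes per-side similarity fields (S, E) of each
fragment alone on a side-specific grid and fits one PLS across the
concatenated side blocks.  Contributions are reported relative to each
side's training mean, so predict(Ra, Rb) = ȳ + c(Ra) + c(Rb) holds to
machine precision, and on noiseless synthetic libraries the fitted
contributions reproduce the generator's latent fragment increments up to
one additive constant per side.

## Screening cascade and energies

Stages (any order, fail-fast validated): pharmacophore (qfit > 50),
fragment similarity, docking-score filter (docking score > 9 AND
Cscore > 4), ADME/T rules.  All inequalities are strict, exactly as the
criteria are typeset (MW = 500 is rejected by 150 < MW < 500).  Docking
scores and ADME properties are always external inputs; the default rule
set mirrors the published criterion list (MW, TPSA, GI absorption, BBB and
CNS permeability, Caco2, intestinal absorption, CYP inhibition flags,
hERG, skin sensitization, Lipinski violations, synthetic accessibility
< 4).  "Low total clearance" is not a sharp numeric criterion and is left
out of the default rules.  Rejection logs keep the first failing rule per
record.  Energies are kJ/mol; ingest validation enforces
ΔG_binding = ΔE_vdW + ΔE_ele + ΔG_PB + ΔG_SA within 0.01 kJ/mol
(0.005 kJ/mol in tests, the rounding floor of the packaged table).

## Synthetic data: what it emulates and what it does not

The generator builds congeneric libraries around a rigid 12-atom
fused-bicycle scaffold (an imidazopyridine-like core with an exocyclic
amide arm) carrying two R-groups drawn from finite fixed-geometry pools.
Activity is linear in generator-side descriptors of the R-group atoms —
per-channel sums (Σr_vdW³, Σq, hydrophobe/donor/acceptor counts) — plus
Gaussian noise, clipped to pKi ∈ [4, 10].  Key consequences:

* Because pool fragments have fixed geometry, the centered field matrix
  has rank ≤ (|Ra|−1) + (|Rb|−1) and activity is *exactly* linear in it
  when noise is zero — so full-rank PLS must reach r² = 1, a sharp
  correctness oracle rather than a tautology (the latent relation lives on
  generator-side descriptors, not on the grid fields being fitted).
* A 4×1 pool yields latent rank exactly 3, giving a clean
  component-number recovery scenario (selection hits 3 in ≥80% of seeds
  at noise 0.1, n = 40).
* Defaults (n = 33, 6×6 pools, intercept 5.8, noise 0.1 pKi) are chosen so
  a default library spans ≈1.6 pKi — the span of the reference series —
  with residual noise comparable to the reference models' SEE (~0.09).
* Decoys are actives perturbed by per-decoy positional jitter drawn from
  U(0.8, 2.2) Å with 30% typing-flag dropout, and their latent activity is
  forced below the least-active training compound: geometrically off-model
  but size- and composition-matched, in the spirit of curated decoy sets.
* One seeded NumPy generator per spec; coordinates are rounded to 4
  decimals and charges to 6 at generation, so the same spec yields
  byte-identical SDF output across runs and platforms.

The molecules are field-realistic, not chemically valid: no valence model,
no force-field geometry, R-groups are jittered chains.  Passing tests
therefore establish the *correctness of the computational machinery*
(fields, PLS, validation statistics, matching, bookkeeping) under known
ground truth — they do not establish that any particular commercial-field
reproduction or prospective prediction on real chemistry would succeed.
Quantities that depend on unreleased inputs (the original 3D structures,
the commercial field implementation, the live compound database) are out
of reach by construction; the package instead reproduces every statistic
that is recomputable from the published tables.

## Numerical choices and degenerate inputs

Superposition uses proper rotations only (reflections excluded); the
residual is recomputed directly from transformed coordinates because the
SVD-side residual loses precision near zero.  Fewer than 3 or collinear
correspondence points raise a degenerate-alignment error.  Grid distances
are floored at 1e−6 Å before the Coulomb/LJ singularities.  Zero-variance
activities, empty field blocks after masking, empty libraries/pools, ring
cuts, and non-finite thresholds all raise typed errors rather than
propagating NaNs.  Problem sizes in the test suite (12–40-molecule
libraries, 3-Å-spaced oracle grids, a 3915-compound enrichment run) are
chosen to exercise every code path at interactive speed.
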