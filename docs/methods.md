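# Methods

## Problem and model

`clasp-sites` predicts candidate catalytic sites in single-chain protein
structures by combining two signals:

1. **Spatial congruence.** An active-site *motif* is an ordered set of
   3–5 catalytic residues taken from a reference enzyme, each reduced to
   one designated *reactive atom* (Ser OG, Lys NZ, His NE2, Asp OD1, …).
   The motif stores the n(n−1)/2 pairwise reactive-atom distances
   `d_ref` (Å).  A candidate match in a query structure is an ordered
   residue tuple whose types fall in the per-site stereochemical groups
   and whose pairwise distances all lie within a tolerance τ_d of
   `d_ref` (and below a global cutoff).

2. **Electrostatic conformity.** For each motif pair the reference
   structure also fixes a potential difference `P_ref` (kT/e) between
   the two reactive atoms, evaluated on a finite-difference solution of
   the linearized Poisson–Boltzmann (PB) equation.  Within an enzyme
   family these pairwise PDs occupy a narrow band, so candidates whose
   PDs deviate strongly are unlikely to be functional analogues even
   when the geometry matches.

The combined score of a match is

    S = w_d · Σᵢ |d_q,i − d_ref,i| / d_ref,i
      + w_p · Σᵢ |P_q,i − P_ref,i| / max(|P_ref,i|, P_floor)

with the PD sum skipping pairs where both |P_q| and |P_ref| fall below
an ignore band ε_zero (charge-neutral pairs carry no signal).  Distance
deviations are normalized by the reference distance — a 1 Å deviation
matters more across 4 Å than across 8 Å — and PD deviations by the
reference magnitude, so large-PD pairs are more loosely constrained.
Lower is better; a motif scored against its own reference structure
scores exactly zero.  Because only the qualitative ingredients of the
scoring are established, absolute score values are implementation
defined here; orderings and the zero self-score are the meaningful
outputs.

Defaults: `w_d = w_p = 1`, `ε_zero = 25 kT/e`, `P_floor = 50 kT/e`,
cutoff 15 Å, τ_d = 1.5 Å.  All are exposed on the API and CLI.

## Stereochemical groups

Groups trade sensitivity against specificity: a permissive nucleophile
group admits Tyr in a Ser site (the class C β-lactamase substitution),
while singleton `<Xaa>only` groups pin a site to one residue type.
Defaults: Ser-like {Ser, Thr, Tyr, Cys}, Lys-like {Lys, Arg, His},
Asp-like {Asp, Glu}, His-like {His}; singleton groups exist for all 20
amino acids and Catalytic Site Atlas-derived motifs default to them.

## Poisson–Boltzmann solver

* **Discretization.** Node-centred cubic lattice; charges spread to the
  eight surrounding nodes with trilinear weights; dielectric set to the
  solute value (default 2) inside the probe-inflated (1.4 Å) union of
  atom spheres and the solvent value (default 78) outside, harmonically
  averaged on cell faces.  Temperature 298 K; potentials in kT/e with
  the Coulomb prefactor computed from physical constants at run time.
* **Boundary.** Single-level Dirichlet from a solvent-dielectric Coulomb
  superposition (Debye-screened if the ionic strength is nonzero; the
  default is zero, where the equation reduces to the Poisson equation).
* **Iteration.** Red–black successive over-relaxation, ω = 1.9,
  relative-update tolerance 1e−6, cap 20 000 sweeps; non-convergence
  raises with the final residual.
* **Grid sizing.** 10 Å padding; spacing defaults to the largest value
  in [0.4, 1.0] Å (preferring 0.6 Å) whose node count fits a
  configurable cap.  Node potentials are grid-sensitive; pairwise
  *differences* on the same grid are the robust observable, and the test
  suite checks <5 % drift of pair PDs under grid halving on the Coulomb
  fixture.
* **Validation.** On a uniform-dielectric monopole the solved potential
  tracks the analytic Coulomb potential within 5 % (measured ≈1.2 % at
  0.6 Å spacing); a symmetric dipole's mid-plane potential is exactly
  zero; pair PDs are exactly antisymmetric and linear in the charges.

An out-of-process backend contract (`external_backend`) renders the same
parameters into a pdb2pqr + apbs pipeline and reads the OpenDX grid
back; when the executables are absent it fails with an explicit
unavailable error and the internal solver remains the working path.

## Charges and radii

The internal pipeline runs on heavy atoms with a PARSE-like table:
per-residue partial charges sum to the formal charge at pH 7 (Asp/Glu
−1, Lys/Arg +1, His neutral), the Ser OG charge is −0.49 e, and radii
are element-based (C 1.70, N 1.50, O 1.40, S 1.85 Å).  Metal ions (Zn,
Mg) are kept with formal +2 charge and tabulated radii, with a
configurable exclusion flag.  Protonation-state prediction is out of
scope; assignment is a pure function of (residue type, atom name), so
translating a structure never changes a parameter.  The table and the
reactive-atom map are plain-text configs, hot-swappable per run.

## Search algorithm

Sites are ordered by ascending candidate count and extended depth-first;
a partial tuple survives only while every new pairwise distance
satisfies both the cutoff and the per-pair tolerance, which makes the
pruned search exact — a brute-force Cartesian enumeration with the
identical acceptance predicate serves as its oracle (asserted on 100+
seeded random fixtures).  Assignment is injective (one residue cannot
fill two sites), candidates come from one chain at a time, and output is
sorted by residue ids for determinism.  Matching uses distances only, so
it is rigid-motion invariant and — a documented limitation — blind to
mirror images.

## Synthetic study conditions

Real crystal structures are deliberately not required; the generators
plant the study conditions:

* **Geometries.** Toy single-chain PDB files carry full functional side
  chains grafted on alanine-like scaffolds, with reactive atoms at exact
  target coordinates.  The serine-protease triad uses the published
  trypsin distances (S–H 3.3, S–D 7.8, H–D 5.5 Å) and the
  alkaline-phosphatase site the published shrimp-AP values (4.6, 7.7,
  3.2 Å) as inputs; the class A β-lactamase tetrad geometry is synthetic
  (plausible coordinates, no crystallographic source).  Arbitrary
  deviation patterns are realized exactly by classical-MDS embedding of
  the target distance matrix.
* **Family PD band.** Positive (family-member) PDs are drawn per pair
  from a normal profile whose means/SDs are the published class A
  β-lactamase reference values (means of order ±100–250 kT/e, SDs
  7.8–24 kT/e); decoys draw uniformly from ±350 kT/e.
* **Labeled score sets.** 5 planted true sites vs 45 spatially congruent
  decoys per seed, geometry jitter σ = 0.25 Å for both classes, 20
  seeds.  Decoys match the motif geometry *by construction*, so spatial
  scoring alone is near chance on this design and any discrimination
  gain is attributable to the PD term.  The false-positive worked
  example plants a candidate whose |Δd| pattern is exactly
  {0.2, 0.7, 0.5, 0.3, 0.7, 1.0} Å and whose |ΔPD| pattern is
  {9, 229, 122, 219, 113, 106} kT/e.

What passing these tests does **not** show: performance on real crystal
structures (side-chain packing, waters, partial occupancy, conformational
spread), multi-chain composite sites, or chirality discrimination.  The
generators emulate the geometry/PD logic, not protein physics.

## Numerical choices and edge cases

* Altloc resolution keeps the highest occupancy, ties broken by altloc
  letter; first MODEL only; waters dropped; insertion codes preserved
  verbatim and residues matched by (chain, number, icode).
* Pair order is canonical lexicographic (i, j), i < j over site index;
  the PD of pair (i, j) is φ(site i) − φ(site j), so PD(a,b) = −PD(b,a)
  exactly.
* Ties in best-match selection break by (score, distance term, residue
  ids); "no match" is an explicit error, never a sentinel score, and
  library rankings list no-match motifs separately.
* ROC sweeps use an inclusive threshold (score ≤ t ⇒ predicted
  positive), anchored at the origin.
* All-zero charge systems short-circuit to φ ≡ 0; points outside a grid
  raise bounds errors rather than extrapolating.
* pKa estimation adds charging-energy/ln 10 to the intrinsic pKa, signed
  so that destabilizing an acid's deprotonated form raises its pKa and a
  base's protonated form lowers it.

## Problem sizes

The shipped test suite and the reproduction script run entirely on the
synthetic fixtures: grids up to ~80³ nodes at 0.5–0.8 Å spacing, toy
structures of 3–10 residues, 100-seed search-oracle sweeps and
20-seed × 50-structure discrimination experiments.  These sizes are the
package's own scaled-down study design; the same code paths accept
full-size PDB inputs, for which the external PB backend is the intended
fidelity reference.

## Known limitations

* Single polypeptide chains only; composite subunit-shared sites are out
  of scope.
* Mirror-image (chirality) configurations are indistinguishable to a
  distance-only matcher; asserted as a property, not fixed.
* The internal PB solver has no focusing and no nonlinear term; the
  ionic-strength parameter only screens boundary values and adds the
  linear volume term.
* Heavy-atom charges are a simplification; absolute node potentials are
  not comparable to hydrogen-resolved force-field pipelines, though
  pairwise differences behave consistently.
* Published absolute scores of the original method are not reproducible
  (weights unpublished); this implementation fixes its own closed form
  and treats orderings as the comparable surface.
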