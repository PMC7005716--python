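# Methods

## Model overview

The package computes persistent homology of Vietoris–Rips filtrations
driven by weighted distance matrices, per local structural domain. A
domain is a labelled subset of atoms; for DNA duplexes the domains are
base pairs or base steps (two stacked pairs), enumerated positionally —
chain-1 residue i pairs chain-2 residue L−i+1, base-step windows cover
pair indices (i, i+1) and overlap by one pair, and "non-terminal"
drops the first and last window (an n-mer gives n−1 steps, n−3
non-terminal).

Homology is computed over GF(2) in dimensions 0 and 1 only: local
domains contain a few dozen atoms, for which β₂ and higher carry no
signal; triangles are constructed solely as killers of 1-cycles. A
matrix entry of +∞ means "never an edge" — computationally any value
larger than the filtration window; simplices carrying it are never
created.

## Filtration constructions

All constructors return a symmetric, zero-diagonal matrix and record
their provenance. The localized weighting keeps d(x_i, x_j) only for
atoms in different residues (residue identity = PDB chain + residue
number + insertion code); multi-level pushes bonded pairs (explicit
bond list, or heavy-atom pairs within 1.7 Å — safely above the
1.0–1.5 Å covalent β₀ band — when no list is given) or all pairs with
d ≤ n to ∞; interactive keeps only cross-molecule pairs; the
radius-scaled matrix d/(v_i+v_j) realizes the weighted Rips complex
whose edges at scale t satisfy d ≤ t v_i + t v_j. The superlevel edge
transform w → w_max − w maps the decreasing clique-weight filtration of
a weighted graph onto the same increasing machinery; w_max is recorded
so barcodes can be reported on the original weight scale. The
k-distance breaks ties by (distance, index) with a stable sort.

## Persistence computation

Standard boundary-matrix column reduction with columns stored as
integer bitmasks. The filtration order is (value, dimension,
lexicographic vertex tuple), which makes output deterministic across
platforms; any valid tie-break permutation yields the same interval
multiset. Dimension 0 is recomputed independently by union-find on the
sorted edges and the two answers must agree — this cross-check runs on
every call. Conventions:

* all dimension-0 intervals are kept, so their count equals the vertex
  count (one infinite bar per connected component of the final
  complex);
* zero-persistence pairs in dimension ≥ 1 (a cycle filled the instant
  it appears, e.g. the second diagonal of a square) are dropped by
  default (`keep_zero_length=True` restores them);
* infinite deaths are serialized as the literal `inf`, never clamped;
* `betti_at` and the PBN use the closed interval [birth, death], so a
  bar counts at both endpoints.

Default filtration windows: 10 Å for barcode inspection, 8 Å when
feeding the feature grid (the grid ends at 7.9 Å).

## Weighted homology (exact)

The weight ring is fixed to ℤ. Divisibility (w(face) | w(coface)) is
validated before any boundary is formed; the weighted boundary entries
w(σ)/w(d_iσ) are exact integers, and ∂∂ = 0 holds identically. Ranks
and null spaces are computed over ℚ with Fraction-based Gaussian
elimination — floating point is never used in this module. The
p-persistent rank uses dim(B ∩ Z) = rank B + rank Z − rank [B | Z]
after embedding level-i cycles into the level-(i+p) chain space.
Torsion (off by default) comes from an integer Smith normal form.
Constant weights reduce everything to ordinary simplicial homology,
which is the cross-check the tests exercise against an independent
exact-rank oracle.

## Idealized DNA generator

Base geometry: published standard-reference-frame idealized heavy-atom
coordinates for A, T, G, C (base atoms + C1′), bundled as package data.
The Watson–Crick partner is the y/z-flip of the standard frame; with
all parameters zero the A-T pair has minimum inter-base heavy-atom
distance 2.96 Å (the N1···N3 hydrogen bond) and G-C has three contacts
under 3.1 Å.

CEHS transforms: with Γ = √(tilt² + roll²) and φ = atan2(tilt, roll),

    R₂   = Rz(ω/2 − φ) · Ry(Γ)   · Rz(ω/2 + φ)
    Rmid = Rz(ω/2 − φ) · Ry(Γ/2) · Rz(φ)

and the translation (shift, slide, rise) is expressed in mid-frame
coordinates. Step parameters place pair i+1 relative to pair i;
base-pair parameters use the same algebra with (buckle, propeller,
opening) as the rotation and describe base 1 relative to the flipped
base-2 frame, so positive stretch pulls the bases apart along the pair
y axis. The analyzer does not invert these formulas symbolically: it
fits each base frame by Kabsch superposition onto the standard
coordinates, bends the two frames onto their mid-plane about the hinge
axis z₁ × z₂, reads the twist between in-plane x axes, and decomposes
the bending angle along the mid-frame axes. Builder and analyzer agree
to ~1e-13 over random parameter draws, which is the package's internal
consistency guarantee (tested at 1e-6).

Parameter sweeps take n equally spaced values on [μ − 2σ, μ + 2σ] with
every other parameter at its mean. The bundled mean/SD table
(`data/helical_defaults.yaml`) holds representative B-DNA crystal
survey values and is fully overridable; no test or acceptance result
depends on the defaults' exact numbers.

Atom selections: `all-heavy`; `base+C1'` (the analysis default,
matching the helical-coordinate convention); `cehs-subset` ({C8, C4,
N1, C1′} purine / {N3, C6, C1′} pyrimidine). Hydrogens are dropped on
reading by default; first-listed altLoc wins; all MODELs of a
multi-model file must share one atom roster.

## Features and analysis

The PBN grid is 60 samples per homology dimension from 2.0 Å at 0.1 Å
spacing. Sampling "2.0 to 8.0 inclusive" would give 61 points and a
122-length vector, which contradicts the fixed feature length of 120;
the grid is therefore left-closed, [2.0, 7.9], β₀ block before β₁
block, step blocks in 5′→3′ order, all recorded in a self-describing
layout. PBN images are ln(PBN + 1), one row per structure.

PCA is the eigendecomposition of the column-mean-centered covariance
(via SVD); each component's sign is fixed so its largest-magnitude
loading is positive. Trajectory ensembles are pooled for fitting and
each trajectory is projected with the shared components and counted on
the shared occupancy grid, so areas are comparable. The occupancy area
counts cells with population strictly greater than 5% (configurable)
of the fullest cell, on a grid covering the pooled bounding box padded
5% per side; the grid spec is always reported alongside the area.

## Synthetic study conditions

The generators state their regimes, noise and seeds in a manifest:

* **Forms**: A-like (slide −1.5 Å, roll 9°, twist 31°, rise 2.83 Å),
  B-like (slide 0.23 Å, roll 0.6°, twist 36°, rise 3.32 Å), and a
  left-handed Z-like regime (twist −30°, rise 3.7 Å), with per-step
  Gaussian noise (SD: shift 0.3 Å, slide 0.4 Å, rise 0.15 Å, tilt 2°,
  roll 3°, twist 3°). Every form pair differs by ≥ 2 noise SDs in at
  least two step parameters. Default: 10 structures per form on an
  8-mer.
* **Two-state trajectories**: frames alternate between the B regime and
  the same regime offset by +9° roll and −9° twist (three noise SDs
  each) on a 16-mer.
* **Confined vs free**: the same single-state generator with the noise
  SD halved for the confined copy.

Problem sizes used by the test suite: 80 frames per trajectory for the
mixture-model checks (BIC needs this many samples to be consistent on
the discrete PBN features), 100 frames per ensemble on a 20×20 shared
grid for the confinement comparison (at these sample sizes a 50×50
grid would leave nearly every cell with at most one frame), and 30
structures for the three-form classification.

What the generator does *not* emulate: sugar/backbone atoms (domains
contain base + C1′ only), sequence-dependent parameter correlations,
correlated dynamics between steps or along time (frames are i.i.d.
draws), solvent and ions, and anharmonic transitions. Passing tests
therefore demonstrate that the topological featurization separates
geometric regimes of the stated effect size — not that it reproduces
any particular experimental ensemble.

## Known limitations

* Homology is capped at dimension 1; no landscapes/images/diagram
  vectorizations beyond the PBN.
* Intra-base ring geometry is fixed by the bundled standard
  coordinates: the purine five-ring β₁ bar always dies at ≈2.19 Å (its
  second-shortest chord), the six-rings near 2.38–2.45 Å, regardless of
  helical parameters.
* The weighted-homology module accepts only ℤ weights; arbitrary
  commutative rings, weighted cohomology, and integration of weighted
  boundaries into the Rips pipeline (beyond the constant-weight
  equivalence) are out of scope.
* Weighted alpha/Čech/Morse constructions are represented only through
  their Rips surrogates; the rigidity and k-distance functions are
  provided as evaluable weight functions, not as filtration builders.
* No helical-parameter extraction from arbitrary crystal structures:
  the CEHS analyzer assumes the bundled idealized base geometry.
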