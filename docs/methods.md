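# Methods

## Rigid transforms and screws

A binding geometry is stored as a proper rotation `R` (orthonormality and
`det = +1` enforced at 1e-8) plus a translation `t`, acting as
`x ↦ Rx + t`. Decomposition into screw parameters follows Chasles: the
angle and axis come from the axis–angle form of `R`; the signed axial
advance is `d = t·û`; the axis point solves `(I − R)p = t − d·û` by
least squares with the constraint `p·û = 0` (the along-axis component of
an axis point has no effect and is removed, which makes the canonical
form stable under repeated canonicalization). Reconstruction uses the
exact Rodrigues formula, so decompose∘reconstruct round-trips to
≈1e-14 on matrix entries.

Degenerate branches: rotations below 1e-6° are treated as pure
translations (axis along `t`, angle 0; identity maps to a zero screw
about ẑ by convention); half-turns are handled by the axis–angle
backend, which is well-conditioned at 180°. The canonical screw form has
`d ≥ 0` (axis flipped otherwise) with ties at `|d| ≤ 1e-9` Å broken by
`θ ≥ 0`; handedness is then right iff θ > 0. All public APIs are
degree-denominated; radians are internal.

Superposition is least-squares rigid fitting (Kabsch, via the SVD-based
rotation alignment in SciPy) on atoms matched by `(residue_seq,
atom_name)`. The default atom set is Cα. Fewer than 3 pairs, or a
matched set of rank < 2 after centering, raises a degenerate-fit error.
When comparing filament conformers, the conserved core excludes the
N-terminal domain (residues 1–37) and the flexible loops L1/L2, which
are disordered in the compressed crystal form.

## Filament construction

A filament stores monomer copies with their placements. The interface
label's transform is applied **in the upstream monomer's frame**:
`placement(k+1) = placement(k) ∘ t_label`. The alternative (applying the
switched screw in the global frame) would not leave the switched
interface with the compressed binding geometry; the chosen convention
guarantees `interface_screw(k, frame="local") = t_label` exactly, which
is the defining property of "monomer k switched its interface". The
reference mixed pattern is five extended interfaces, one compressed, five
extended — a dodecamer reported with display indices (i−5)…(i+6) via
`index_offset=-5`, the switched interface between (i) and (i+1).

The kink between the two segments flanking a split is measured on
global-frame interface screws: within a regular segment all interfaces
share one axis direction (conjugation by a rotation about the helix axis
leaves the axis invariant), so the per-segment direction is the
sign-aligned mean of its interface axes and the kink is the angle between
the two means. This is exact for noise-free builds and averages out
coordinate noise for crystal-derived ones.

Region grafting (e.g. transplanting the compressed-form N-terminal
domain onto one monomer, or assigning the extended-form loop
conformations) superposes the source onto the target over an anchor
residue range, then swaps the target's region atoms for the transformed
source region. Steric consequences are reported by the contact analysis,
never repaired — energy-based refinement is out of scope.

## DNA threading and metrics

Strands are threaded as one trinucleotide template per monomer,
transformed by that monomer's placement and renumbered 1..3n. Backbone
continuity is judged on O3′(n)–P(n+1) distances with a 2.0 Å threshold:
the covalent bond is ≈1.6 Å, and rigid-template threading across a
regular interface reproduces it, so 2.0 Å separates bonded from broken
unambiguously.

Stretch and unwinding are measured on phosphates **about the filament
axis**, not a local DNA axis: per-step rise is the projection of each
P→P step on the axis; per-step twist is the angle between successive
radial components about the axis (steps of near-zero radius are skipped
with a warning). References are B-form rise 3.38 Å and twist 34.3°
(36.0° selectable; both conventions are in circulation, and the ±5-point
acceptance bands cover the difference). Reported values are
`100·(rise/ref − 1)` and `100·(1 − twist/ref)`.

An optional junction "closure" (`blend_junction`) re-places the first
downstream triplet with slerp/lerp-interpolated placements. It is a
cosmetic geometric blend for producing visually continuous models and is
not a substitute for physical refinement; no metric uses it.

## Analysis metrics

* **Groove-entrance width** at monomer k: minimum heavy-atom distance
  between its C-terminal domain and the N-terminal domains of monomers
  k+5, k+6, k+7. Heavy atoms (not Cα only) are used; the choice is one
  of two defensible readings and is isolated behind the annotation
  object for sensitivity analysis. Near the filament end the partner set
  is truncated and flagged rather than erroring, so interior values of a
  12-mer match those of longer builds. The C-terminal domain has no
  canonical numeric range; the default 270–328 contains the cross-groove
  contact residues 287–297 and is configurable.
* **Pairing detection** is purely geometric: a criterion is a set of
  clauses, each an OR over atom-pair distance conditions, read from
  `data/pairing_criteria.yaml` (never hard-coded). Hydrogen–acceptor
  conditions use 2.5 Å and apply when the model carries hydrogens
  (MD frames); donor–acceptor heavy fallbacks use 3.5 Å (crystal-derived
  models). Atom names are validated against the standard nucleotide
  vocabulary at load time. The Watson–Crick A:T rule uses N1(A)–N3(T)
  and N6(A)–O4(T); the Hoogsteen rule uses N7(A)–N3(T)/H3 and
  N6(A)/H61/H62–O2(T); the R-type triplet couples one base from each of
  three strands through the adenine amino/N1 face.
* **Melting bubbles** are maximal unpaired runs of a per-position duplex
  mask; run lengths plus paired count always equal the mask length.
* **Stacking partition**: consecutive bases stack when ring centroids
  are within 4.5 Å and ring planes within 30° (normals from the smallest
  singular vector of the centered ring atoms; ≥3 ring atoms required).
  Run lengths always sum to the base count.
* **Stability** of a pairing time series is a trailing-window call:
  stable if satisfied in ≥80% of the last window (default: last fifth of
  the frames). The threshold is a configurable convention.

Trajectories are multi-model PDB files (or in-memory frame lists) with
fixed atom tables; per-frame metric values are by construction identical
to the single-structure operations applied to that frame, and the CSV
output is byte-deterministic.

## Synthetic ground truth

The generator module emulates each input class with programmed
parameters:

* **Filaments**: pseudo-monomers (single-atom domain markers inside the
  default annotation ranges plus a seeded random body cloud at 25 Å
  radius) placed on a programmed screw. The extended preset is
  58.4°/15.4 Å per monomer (pitch 94.9 Å) and the compressed preset
  58.3°/13.4 Å (pitch 82.7 Å) — the centers of the two documented pitch
  regimes. A programmed kink pre-rotates downstream placements about an
  in-plane axis at the junction, so the measured kink equals the
  programmed one exactly.
* **DNA**: phosphates on a helix of programmed rise/twist/radius
  (defaults: B-form 3.38 Å/34.3°/8.9 Å); bases as idealized planar
  hexagons (1.38 Å bonds) perpendicular to the helix axis, with
  substituents placed so generated duplexes satisfy the Watson–Crick
  criterion exactly (N1–N3 and N6–O4 at 2.85 Å, H-bonds at 1.85 Å). The
  filament-bound site-I regime corresponds to rise 5.07 Å, twist 20.6°.
  The site template generator places three nucleotides on the one-third
  screw of a filament interface, so threading it along the matching
  regular filament is continuous by construction.
* **Trajectories**: programmed inter-atom distance series realized by
  rigid translation of the target residue along the initial separation
  direction; programmed and reference residues are excluded from the
  optional Gaussian jitter so realized distances equal the program to
  1e-6.

What the synthetic data does **not** model: side-chain chemistry, real
base-pair step geometry (the duplex is a parallel idealized ladder),
sequence-dependent mechanics, thermal motion beyond isotropic jitter,
and realistic monomer dimensions (pseudo-domain markers give groove
widths near 74 Å, not the ≈28 Å of real extended filaments). Passing the
synthetic suite therefore demonstrates the correctness of the geometry
and detection algorithms, not agreement with crystal-structure values;
the crystal-derived checks in the acceptance tests perform that
comparison when the accession files are supplied under `data/pdb/`.

## Problem sizes and defaults

The test suite and acceptance script use 12-monomer filaments, 36-nt
strands (3 per monomer), 1000 random transforms for round-trip checks,
and 80–100-frame trajectories — sizes at which every quantity is exact
or converged while the whole suite runs in seconds. Key defaults:
continuity threshold 2.0 Å; pairing 2.5 Å (H) / 3.5 Å (heavy); stacking
4.5 Å / 30°; contact cutoff 4.0 Å; B-DNA references 3.38 Å / 34.3°;
annotation ranges N 1–37, L1 157–164, L2 194–210, LexA 225–245,
C 270–328 (L1/L2 figure-legend variants 156–165/194–212 accepted).

## Known limitations

No molecular dynamics, energetics, or electrostatics; insertion codes
are rejected (RecA structures need none); PDB serial capacity is 99 999
atoms (no hybrid numbering); mmCIF is read-only territory for the
underlying parser and not exposed; binary trajectory formats are not
implemented — multi-model PDB is the supported, fully tested path.
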