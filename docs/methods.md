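# Methods

## The decomposition

Each SSU domain (body, head) is treated as a rigid body whose orientation is
measured relative to a classical reference structure. The net domain
transform `x ↦ R x + t` is obtained in two superposition steps: the model is
first placed into the reference coordinate frame by least-squares (Kabsch)
superposition of the *frame-of-reference* core — the LSU rRNA core for body
angles, the SSU body core for head angles — and the transform mapping the
reference domain core onto the model domain core is then computed in that
common frame. All superpositions use backbone phosphate (P) atoms, one per
residue, with equal weights.

The rotation part is factored as

```
R = Rot(T̂(ψ), θ) · Rot(R̂_ref, ϕ),      T̂(ψ) = Rot(R̂_ref, ψ) · ẑ₀
```

with R̂_ref the fixed reference axis and ẑ₀ the zero-tilt direction. θ is the
angle between R·R̂_ref and R̂_ref; T̂ is the line of nodes (unit vector along
R̂_ref × R·R̂_ref, oriented so the tilt is by +θ); ψ is the signed azimuth of
T̂ from ẑ₀, right-handed about R̂_ref, in (−180°, 180°]. The residual rotation
`Rot(T̂, θ)⁻¹·R` fixes R̂_ref exactly, so ϕ is read off as its signed angle
about R̂_ref and the factorisation is exact to machine precision — the
round-trip property the test suite enforces at 1e-6°.

**Order convention.** The factor order "tilt after primary rotation" makes ψ
the azimuth of the tilt axis in the *reference* frame. The opposite order
would measure ψ in the rotated frame; the two differ by ϕ. This choice is
fixed everywhere (decomposition, reconstruction, fixture generation).

**Rotation center and residual translation.** x_c is the point on the
reference axis line `{p + s·R̂_ref}` minimising `|(R − I)x + t|`; the 1D
least-squares solution is closed-form. Δx = (R − I)x_c + t is the minimal
residual. Two consequences worth knowing:

- *Gauge*: a translation component along `u = (R − I)·R̂_ref` is exactly
  absorbable by sliding x_c along the axis, so Δx is only defined modulo
  that direction. The fixture generator projects requested ground-truth
  translations into this canonical gauge and records the effective norm.
- *Degenerate tilt*: for θ below the tolerance (default 0.25°,
  configurable), ψ is undefined (reported NA) and ϕ falls back to the
  signed axis-angle about R̂_ref. In this branch the x_c minimisation uses
  the projected pure rotation `Rot(R̂_ref, ϕ)`: against a spurious
  sub-tolerance tilt the unconstrained minimiser would slide x_c
  arbitrarily far along the axis and absorb a random fraction of a genuine
  perpendicular translation (|Δx| would be discontinuous at θ = 0). The
  price is a bounded |Δx| bias of at most 2·sin(tol/2)·|x_c| for true tilts
  just under the tolerance; the exact decomposition remains available by
  setting the tolerance to zero.

**Pairwise metrics.** The Euler–Rodrigues angle
`arccos((tr(R_a R_bᵀ) − 1)/2)` collapses rotation and tilt into one number;
δθ, the angle between the two structures' current primary axes, isolates
tilt differences and is invariant to composing either structure with any
rotation about its own current axis. When two structures tilt in the same
direction δθ is the difference of their tilt magnitudes; in antiparallel
directions, the sum.

## Reference frames

The body axis is the screw axis of the reference rotation between the
classical and body-rotated reference structures after LSU-core alignment;
the head axis likewise from the head-rotated structure after body-core
alignment. Screw decomposition realises the "minimal residual translation"
definition of the axis position; the axis point is reported closest to the
classical domain-core centroid. The positive sense is classical → rotated
(ratchet, swivel), so reference rotations are positive by construction and
a reference pair differing by under 1° is rejected as degenerate.

Zero-tilt directions are operational, versioned definitions (the azimuth
origin is arbitrary; only ψ differences between structures are
convention-free): for the body, the in-plane component of the vector from
the axis to the centroid of 16S helix h44 (the helix is not perpendicular
to the axis, so projection is mandatory); for the head, the in-plane
component of the E-site → A-site codon-region vector, approximating the
mRNA binding track. The anchor residue sets and the head/body partition
(head = 16S residues 921–1396) ship as versioned text files in
`radkit/data/`.

Because crystallographic reference coordinates are not bundled, the package
generates a deterministic *synthetic* reference triple (fixed seed 20220)
and derives frames from it; frames rebuilt from the same inputs are
bit-identical, and rebuilding after any global rigid motion of the
reference structures moves the frames equivariantly (property-tested).
Against real reference structures the same code path applies unchanged;
absolute ψ values would then be offset by a constant relative to any other
choice of zero direction.

## Core identification

Correspondence to reference numbering uses Needleman–Wunsch global
alignment (match +2, mismatch −1, gap open −5, gap extend −1, all
configurable) via Biopython's PairwiseAligner. An alignment is rejected
when its score falls below 20% of the maximum attainable score — an
identity-based floor cannot reject unrelated sequences, which still match
~45% of positions by chance under gapped alignment of a 4-letter alphabet.
Modified nucleotides map to parent bases through a built-in table; unmapped
residues pass through with a warning.

Pruning to the conserved core: after an initial superposition, matched
pairs deviating > 8 Å are dropped (spatial-consistency filter); then each
iteration superposes the core, stops if RMSD ≤ 1.0 Å, and otherwise removes
residues deviating more than 2× the current RMSD (or the worst 5% if none
qualify). The RMSD is non-increasing across iterations because removed
residues always deviate above the quadratic mean. Minimum core guards (100
residues; 50 for the head) stop pruning with a `converged=False` flag
rather than an error. Under 0.5 Å coordinate noise the cores converge at
0.85–0.95 Å with >95% of residues retained, matching the ~1 Å population
scale the method targets on real structures.

## Synthetic fixtures

The generator emulates only what the pipeline consumes: per-residue P-atom
point clouds with RNA-like backbone spacing (5.9 Å steps of a persistent
random walk), confined to globular volumes with a radial bias toward a
shell at 0.75 of the domain radius so the radii of gyration (~44 Å LSU,
~38 Å body, ~23 Å head) resemble real subunits rather than centrally
condensed clouds. Default sizes are 1980 (LSU), 789 (body) and 360 (head)
residues — the mean core sizes of real structures. Residue numbering is
*E. coli*-style so the packaged head set and anchor residues apply; 23S-style
LSU numbering starts at 900 so the H101 probe residues exist.

Ground-truth orientations are applied with independently constructed
Rodrigues matrices (head truth in the body frame first, then body truth in
the LSU frame), followed by seeded Gaussian coordinate noise and random
residue dropout. What the fixtures do **not** emulate: base-pairing
geometry, actual rRNA folds, proteins bound at interfaces, heterogeneous
per-residue uncertainty, and systematic (non-isotropic) modelling error.
Passing tests therefore demonstrate the correctness and noise robustness of
the geometry pipeline, not the behaviour of the alignment stage on deeply
divergent rRNA (a mutation operator with substitutions and short indels
covers moderate divergence).

**Recovery limits under the study conditions** (σ = 0.3 Å per coordinate,
5% dropout): the domain axis direction is estimated to ~0.04°, which is
also the accuracy floor for ϕ and θ (observed grid maxima ~0.1°, within
the 0.2° band). ψ inherits a 1/sin θ amplification — about 0.5° at θ = 4°
— so its recovery is validated at 1° for θ ≥ 2° and is intrinsically
without margin at the small-tilt end; |Δx| is recovered to <0.1 Å.

## smFRET distances

Probe sites are resolved by molecule: rRNA selectors map to the identified
16S/23S chains; protein selectors are matched by global sequence identity
(≥60%) against a caller-supplied registry of reference sequences, since
chain naming is inconsistent across entries. Built-in probe definitions:
S6 residue 41 Cα ↔ L9 residue 11 Cα; S11 residue 75 Cα ↔ L9 residue 11 Cα;
and the geometric centers of the h44 turn (16S U1450–G1453) ↔ H101 turn
(23S C2853–U2865). Structures missing a site are skipped and reported, and
a resolution filter (default 5 Å or better) gates ensemble fits.

Response curves are fitted by least squares: a four-parameter sigmoid
`y = a + b·tanh((x − x₀)/w)` (reporting the responsive window [x₀−w, x₀+w])
and a three-parameter power law `y = a + b·(x − x_min + 1)^c`. Both forms
are minimal operational choices; flat or non-convergent data are flagged
rather than raised. Correlations report Pearson and Spearman coefficients.

## Numerical choices

- Angles are degrees at every interface; radians internally.
- Orthonormality tolerance for rotations: 1e-9; degenerate-angle cutoff
  0.25° (configurable); reflection guard in Kabsch flips the smallest
  singular direction.
- Kabsch rejects N < 3 or collinear geometry (second singular value
  ≤ 1e-12 of the first).
- Alternate conformers: highest occupancy wins, ties broken alphabetically
  by altloc. Author numbering is used for reporting, label numbering kept
  internally.
- TSV exports are deterministically ordered (by accession) with fixed float
  formatting, so re-runs are byte-identical.

## Known limitations

- Frames and absolute ψ values depend on the packaged operational anchor
  definitions; comparisons *between* structures (ϕ, θ, δθ, E–R, ψ
  differences) do not.
- Ribosomes that violate the two-major-rRNA-strands assumption (fragmented
  rRNA, heavily protein-substituted mitoribosomes) are out of scope; chain
  selection requires strands > 500 nt.
- |Δx| near the tilt-degeneracy threshold trades a small bias for noise
  robustness (see above).
- The smFRET module computes label-site distances only — no dye, linker or
  photophysics modelling.
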