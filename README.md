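# radkit

Quantitative comparison of ribosome structures via an Euler-style angle
decomposition of small-subunit (SSU) domain orientations.

## The problem

During translation the ribosomal SSU body rotates ("ratchets") relative to
the large subunit (LSU) and the SSU head rotates ("swivels") relative to the
body; both domains also tilt about axes orthogonal to these primary
rotations and can undergo small residual translations. With thousands of
deposited ribosome structures, single-number rotation measures are
ambiguous as soon as motion occurs about more than one axis. radkit gives
structural biologists, simulators and single-molecule experimentalists a
complete six-degree-of-freedom description of each domain:

- **ϕ** — primary rotation about a fixed reference axis R̂_ref (degrees),
- **θ** — tilt: the angle between the current domain axis R̂ = R·R̂_ref and
  R̂_ref,
- **ψ** — tilt direction: azimuth of the tilt axis (line of nodes) in the
  plane perpendicular to R̂_ref, measured from a fixed zero direction,
- **x_c** — the rotation center: the point on the reference axis minimising
  the residual translation,
- **Δx** — that minimal residual translation (Å).

The rotation factors exactly as `R = Rot(T̂(ψ), θ) · Rot(R̂_ref, ϕ)`. Pairwise
metrics complete the toolkit: the Euler–Rodrigues angle
`ϕ^E–R = arccos((tr(R_a R_bᵀ) − 1)/2)` (net 1D orientation difference) and
`δθ = arccos((R_a R̂_ref)·(R_b R̂_ref))` (tilt difference independent of the
primary rotation).

The coordinate system is pinned by reference structures: a classical
(unrotated) ribosome defines the origin, a body-rotated and a head-rotated
structure define the two rotation axes via screw-axis decomposition of the
reference rotations. Before any fitting, each model rRNA is mapped onto
*E. coli* reference numbering by global sequence alignment, the 16S is
partitioned into head and body by a packaged residue set, and each domain is
pruned to a structurally conserved "core" (~1 Å RMSD) on which rigid-body
(Kabsch) superposition is performed using backbone P atoms.

A synthetic-fixture generator builds pseudo-ribosomes (RNA-like random-walk
point clouds with realistic sizes and *E. coli*-style numbering) with
exactly known domain orientations, so the entire pipeline is testable
without downloading structures. An smFRET module computes published
label-site distances (S6–L9, S11–L9, h44–H101) and fits their response to
rotation with tanh and power-law curves.

## Worked example

```python
from radkit import analyze_structure, synthetic_reference_set
from radkit.synthetic_fixtures import DomainTruth, FixtureSpec, generate_model

reference = synthetic_reference_set()          # classical structure + frames
spec = FixtureSpec(
    seed=42,
    body_truth=DomainTruth(phi_deg=8.0, theta_deg=3.0, psi_deg=40.0),
    head_truth=DomainTruth(18.0, 5.0, -30.0, delta_x=(2.0, 0.0, 0.0)),
    noise_sigma=0.3, dropout_fraction=0.05,    # emulate coordinate error
)
model, truth = generate_model(spec, reference.frames, reference.classical)
result = analyze_structure(model, reference)
for domain, a in result.angles.items():
    print(f"{domain}: phi={a.phi_deg:.2f} theta={a.theta_deg:.2f} "
          f"psi={a.psi_deg:.2f} |dx|={a.delta_x_norm:.2f}")
```

prints

```
body: phi=8.01 theta=3.06 psi=39.63 |dx|=0.08
head: phi=17.94 theta=5.01 psi=-29.67 |dx|=2.00
```

i.e. the applied body ratchet (8°), tilt (3°) and tilt direction (40°) and
the head swivel/tilt/translation are recovered to ~0.1° / ~0.1 Å despite
0.3 Å coordinate noise and 5% missing residues (ψ, whose conditioning
degrades as 1/sin θ, is recovered to within ~0.5° at these tilts).

The same pipeline runs from the shell on mmCIF/PDB files:

```bash
radkit fixtures --seed 20220 --out refdir        # synthetic reference triple
radkit analyze --model model.cif --reference refdir --out orientations.tsv
radkit compare --model-a a.cif --model-b b.cif --reference refdir --domain body
radkit summarize --results orientations.tsv
```

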