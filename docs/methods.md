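# Methods

This note documents the models, algorithms, parameter choices, and known
limitations behind `rescaffold`.  Nothing here makes empirical claims
beyond what the test suite and `scripts/acceptance.py` compute.

## Problem setting

Motif re-scaffolding starts from a characterized serine hydrolase
template and keeps only a small set of backbone segments carrying the
catalytic triad (nucleophile Ser, base His, acid Asp) plus the residues
that shape the oxyanion hole.  Generative structure models rebuild the
rest of the protein around the fixed motif; sequence-design models then
assign side chains to the new backbone.  Because these generators produce
many candidates of variable quality, the practical bottleneck is the
screen: deciding, from predicted structures, docked ligand poses,
trajectory snapshots, and designed sequences, which few candidates merit
expression.  `rescaffold` implements that screen and the bookkeeping
around it.

## Motif specification (`motif_scaffold`)

A `MotifSpec` is a list of `(chain, start, end)` residue segments plus
exactly one residue each for the roles *nucleophile*, *base*, and *acid*.
Segments are inclusive on both ends, may not overlap on the same chain,
and every catalytic residue must lie inside a segment.  `spec_summary`
reports the retained residue count and its percentage of the template
length (rounded to the nearest integer), e.g. a 44-residue motif is 17 %
of a 258-residue template.

**Contig strings.**  For inpainting-style generators, `contig_string`
emits `A160-170/g1-g2/A205-220/...` where gap entries give the allowed
number of rebuilt residues between kept segments.  Given a target total
length range (e.g. 140–185 aa), the gap budget (target minus retained
residues) is apportioned across the gaps proportionally to the lengths of
the template's intervening regions, using largest-remainder rounding so
the parsed minimum and maximum totals equal the requested targets
exactly.  `parse_contig` inverts the grammar and is the round-trip oracle
in the tests.

**Superposition.**  `kabsch_superpose` computes the optimal rigid-body
alignment of two point sets: center both sets, form the covariance
`H = B₀ᵀA₀`, take the SVD `H = USVᵀ`, and set
`R = V·diag(1, 1, sign(det(VUᵀ)))·Uᵀ` so the rotation is always proper
(no reflection).  `motif_rmsd` applies this to the motif backbone atoms
(`N, CA, C, O` by default) after building a residue correspondence
between template and design.  The tests check agreement with
`scipy.spatial.transform.Rotation.align_vectors` and with a
derivative-free multistart minimizer over rotations.

## Screening thresholds (`screening_pipeline`)

Defaults in `ScreenConfig`, all overridable:

| Parameter | Default | Meaning |
| --- | --- | --- |
| `plddt_min` | 70 | mean Cα pLDDT must be **strictly greater** |
| `ptm_min` | 0.7 | pTM must be strictly greater |
| `motif_rmsd_max` | 2.5 Å | motif backbone RMSD, inclusive |
| `energy_window` | [−4, 0] kcal/mol | docking energy, inclusive both ends |
| `attack_dist_max` | 4.0 Å | Ser Oγ → ester carbonyl C, strict `<` |
| `min_oxyanion_donors` | 2 | backbone N within 3.5 Å of carbonyl O |
| `traj_rmsd_max` | 5.0 Å | Cα RMSD to frame 0 after superposition |
| `traj_horizon` | 20 ns | window in which the RMSD bound must hold |
| `min_run` | 5 | minimum SAAR/CHAA run length |
| `exposure_min` | 0.25 | relative SASA for "exposed" residues |
| `link_dist` | 8.0 Å | Cβ single-linkage distance for patches |
| `flank` | 2 | residues widened around each pathology run |

Strict-versus-inclusive choices are deliberate: confidence thresholds are
quality floors that a borderline model should not clear, while the RMSD
and energy bounds are acceptance windows that include their endpoints.

`run_screen` evaluates four stages — static quality (pLDDT, pTM, motif
RMSD), docking (energy window, attack distance, oxyanion donors),
stability (trajectory RMSD within the horizon), and sequence pathology.
Each candidate ends in exactly one terminal stage (`generated`,
`static_pass`, `docked_pass`, `stable_pass`, `pathology_flagged`,
`accepted`); the summary counts how many candidates *reached* each stage,
so the tallies are monotone non-increasing along the funnel.  By default
stages short-circuit; `exhaustive=True` evaluates all gates anyway for
diagnostics.  Pathology-flagged candidates are kept separate from
rejects because they are redesign inputs, not failures of the backbone.
Per-candidate failures raise nothing: errors are recorded on the record
and surfaced in the report (and as a nonzero CLI exit code).

## Active-site audit (`active_site_audit`)

A `LigandPose` carries labeled atoms and annotated ester groups
(a carbonyl C=O at < 1.30 Å plus an ester C–O in 1.30–1.6 Å bonded to a
second carbon).  `attack_distance` is the minimum over ester groups of
the Ser Oγ to carbonyl-carbon distance, matching the near-attack
geometry requirement.  `find_oxyanion_donors` lists backbone amide
nitrogens within 3.5 Å of the carbonyl oxygen — two or more donors
indicate a formed oxyanion hole.  `triad_geometry` reports
Ser Oγ–His Nε2 and min(His Nδ1–Asp Oδ1/Oδ2) distances with a 3.5 Å
hydrogen-bond criterion.  Docking energies are taken as given from the
external docking tool; the audit only windows them.

## Stability and surface (`stability_surface`)

`ca_rmsd_timecourse` computes the Cα RMSD of each trajectory frame to the
first frame, by default after optimal superposition (so global tumbling
is removed and the series reflects internal deformation).  The gate fails
only if the RMSD is strictly above the bound at some time point at or
before the horizon; excursions after 20 ns are out of scope by
construction.

**SASA** is computed with the Shrake–Rupley method: `n_points = 960`
quasi-uniform sphere points per atom from a golden-spiral construction,
probe radius 1.4 Å, van der Waals radii C 1.70, N 1.55, O 1.52, S 1.80 Å,
neighbor search via a k-d tree.  Accuracy is validated against closed
forms (isolated sphere exact; two overlapping spheres via the spherical
cap area `2πR(R − d/2)`) and for convergence against a 4000-point run.
Relative exposure divides residue SASA by the theoretical maximum per
residue type (Tien et al. 2013); residues above 0.25 count as exposed.
Hydrophobic patches are single-linkage clusters (union-find) of exposed
hydrophobic residues' Cβ atoms within 8 Å; Gly uses Cα as anchor.

## Sequence pathology (`sequence_pathology`)

SAAR runs are maximal homopolymer substrings of length ≥ `min_run`; CHAA
runs are maximal substrings over the hydrophobic alphabet
{A, V, L, I, M, F, W} of length ≥ `min_run` that contain at least two
distinct letters — identical spans are reported once, as SAAR, so the
two annotations never duplicate an interval.  Intervals are half-open
`[start, end)`.  `redesign_mask` turns runs (and exposed-patch positions)
into a keep/redesign mask, widening by `flank` residues, forcing
protected (catalytic) positions to stay kept with a warning, and
emitting a contig string whose gap entries are fixed-length (`n-n`)
because fixed-backbone sequence redesign must not change the length.

## Kinetics (`kinetics`)

Rates follow v = Vmax·S/(Km + S) with substrate in g/L — mass
concentration is the natural unit for polymeric substrates such as PET
film, where molarity is ill-defined.  Fitting uses untransformed
nonlinear least squares (`scipy.optimize.curve_fit`); linearizations
(Lineweaver–Burk) are avoided because they distort the error structure.
Initial values are Vmax₀ = max observed rate and Km₀ = the substrate
concentration nearest half of it.  Standard errors come from the
Jacobian covariance; a fit is flagged non-identifiable when Km falls
outside the sampled substrate range.  Catalytic efficiency is reported
as Vmax/Km (L g⁻¹ min⁻¹), defined only for converged fits.

## Synthetic fixtures (`fixtures`)

The generator exists so every gate can be exercised with known ground
truth, offline:

- `make_toy_scaffold` builds an idealized helical backbone (100° turn,
  1.5 Å rise, 2.3 Å Cα radius) with a planted Ser/His/Asp triad whose
  Oγ–Nε2 and Nδ1–Oδ distances hit requested targets exactly, outward Cβ
  atoms, and optionally a planted hydrophobic surface patch.
- `perturb_to_rmsd` displaces atoms along a random direction field
  projected orthogonal to the six rigid-body modes, then bisects the
  amplitude until the *post-superposition* RMSD matches the target to
  1e-4 Å — so a "2.00 Å design" really measures 2.00 Å.
- `make_drift_trajectory` produces frames at prescribed Cα-RMSD values;
  `make_pose_at_distance` places a six-atom ester fragment at an exact
  attack distance with clash checking; `make_mm_dataset` generates
  Michaelis–Menten data with multiplicative noise and attached truth;
  `make_candidate_batch` plants known counts of each failure mode so
  screen tallies have exact expected values.

What the fixtures do **not** emulate: real protein energetics or sterics
(the helix is geometric, not physical), force-field dynamics (trajectory
frames are independent controlled perturbations, not integrated MD),
docking scores (energies are assigned, not computed), and measurement
error structure beyond i.i.d. multiplicative noise on rates.  Conclusions
about real designs require the external tools the fixtures stand in for.

## Numerical choices

- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; derived seeds stay below 2³¹.
- RMSD comparisons in tests use absolute tolerances at the scale of the
  bisection tolerance (1e-4 Å) or looser.
- SASA occlusion uses squared distances; the neighbor cutoff is the
  maximum possible contact distance, so no occluding atom is missed.
- `size_metrics` rounds percentages half away from zero to match
  conventional reporting.

## Open decisions and limitations

- pLDDT is taken as the mean over Cα B-factors of a *predicted* model;
  files without predicted provenance are rejected rather than silently
  averaged, at the cost of one extra argument at read time.
- The oxyanion-hole criterion counts backbone N donors only; side-chain
  donors (e.g. Thr Oγ1) are not counted, which is conservative.
- Hydrophobic patch severity is reported by residue count and summed
  SASA; no attempt is made to translate that into an aggregation
  propensity score.
- The screen treats gates as independent; no joint score or ranking
  model is fit across criteria beyond the lexicographic `rank_candidates`
  ordering.
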