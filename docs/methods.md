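# Methods

`membmode` analyses trajectories of a peripheral membrane protein —
prototypically a receptor tyrosine-kinase cytosolic domain — interacting
with a PIP-containing bilayer, and ships a Brownian-dynamics generator
that produces such trajectories with known ground truth. This note
records the models, the parameters that matter, the numerical choices,
and what the synthetic data can and cannot show.

## Coordinate conventions

All coordinates are nanometres; times are nanoseconds. Boxes are
orthorhombic and the membrane normal is the z axis (inputs are assumed
pre-oriented, as bilayer simulations are). PDB files are Å on disk and
converted at the boundary; GRO and XTC are nm. Minimum-image distances
are used in every cutoff analysis. Residue ids are kept 1-based as in
the input file so that residues can be reported by their biological
numbering (e.g. H609); particle indices are 0-based internally.
Centre-of-mass calculations are mass-weighted by default with a uniform
72 amu coarse-bead mass when the format carries none, so they coincide
with bead-count centroids unless the user supplies masses.

## Orientation and binding modes

The orientation of the protein in frame *t* is summarised by the zz
element `Rzz` of the least-squares (Kabsch) rotation superposing the
frame's protein coordinates onto a reference pose. The reference
defaults to the first-frame coordinates; since only *relative*
orientation is interpretable, the density map below is meaningful for
any fixed reference. The Kabsch solver uses the SVD with a determinant
sign correction so reflections are never returned; rotations are
orthogonal with det +1 to 1e-8 by construction and this is asserted.

Two distances accompany `Rzz`: `dz`, the |z| separation of the protein
and membrane centres of mass (minimum image along z), and `d`, the full
3-D minimum-image COM separation. The binned, normalised 2-D histogram
rho(Rzz, dz) is reported together with the ratio map
`deltaD = rho / rho0`, `rho0 = max(rho)`, so the global maximum is 1 by
definition. Default bins: 0.05 in Rzz, 0.1 nm in distance — fine enough
to separate two orientational modes without empty-bin noise at the
frame counts a desk-scale run produces. Whether the published
distance-axis of such maps is `dz` or `d` is ambiguous in places; both
are computed and the map can be built on either (default `dz`).

A frame is *bound* when `dz <= 5.0` nm — the upper edge of the 4–5 nm
band that indicates a stable kinase–membrane interaction — and bound
*intervals* are maximal runs of at least `min_dwell = 10` frames, which
suppresses grazing encounters. Binding *modes* are classified by lobe
engagement rather than by Rzz windows (no published Rzz boundaries
exist, and the modes are defined by which lobes touch the membrane):
with N and C the counts of membrane headgroup beads within 0.8 nm of
the N- and C-lobe respectively, a bound frame is

- MODE1 (N-lobe only; activation loop exposed) when `N >= 1` and
  `C <= 0.25 * N`,
- MODE2 (C-lobe engaged, alone or with the N-lobe; activation loop
  masked) when `C >= 1` otherwise,
- UNBOUND when neither lobe touches (and for all frames outside bound
  intervals).

The `0.25` C-lobe tolerance admits incidental single-bead C-lobe
grazing during mode-1 binding. The dominant mode of a trajectory is the
majority label over mode-labelled frames; with no such frames it is
reported as UNBOUND.

## Contacts

For each protein residue and lipid species, the contact count is the
number of target particles within the 0.8 nm cutoff (minimum image) of
any particle of the residue, counted per target particle. Targets are
headgroup beads by default; a flag widens to whole lipids. The
*normalised* profile divides each species' time-averaged counts by that
species' maximum over residues, so values lie in [0, 1] with the top
residue at 1 (the published bar plots' normalisation constant is not
stated; per-species max-over-residues is this package's documented
choice, and it is scale-invariant and idempotent). Neighbour search
uses a periodic k-d tree (`scipy.spatial.cKDTree` with `boxsize`); the
test suite checks it against an all-pairs 27-image brute force.

## PIP counting, residence times, diffusion

A lipid molecule is *interacting* in a frame when any of its headgroup
beads is within 0.8 nm of any protein particle; a molecule counts once
per frame however many beads are inside. Count distributions are
summarised by a moment-matched Gaussian (mean = sample mean, sd =
population sd) — stable for small samples, and the published fits'
method is not stated. Counts are restricted to bound frames by default
(the distributions describe the membrane-bound state); a flag pools all
frames.

Residence times are maximal per-lipid interaction runs after merging
gaps of at most `gap_tolerance` frames (default 1, absorbing single-
frame cutoff flicker). A lipid is *persistent* when its longest dwell
covers at least half the analysed frames, else *transient*; both
thresholds are exposed.

Lateral diffusion uses the 2-D Einstein relation. Per species, in-plane
headgroup positions are unwrapped by accumulating minimum-image step
displacements (exact while per-frame steps are below half the box, as
they are for all generated data), the time-origin-averaged MSD is
computed with the standard FFT algorithm, and `D = slope / 4` from a
least-squares line (with intercept) over lags between 10% and 50% of
the maximum — the usual compromise that avoids the poorly-averaged
long-lag tail; no published fit window exists to match.

## Rigid-body assembly

Composite receptor models are built by superposing a domain pose's
anchor (the TM helix) onto target anchor frames and measuring COM
separations between placed copies; assembled models carry no box and
clashes (pairs closer than 0.3 nm) are reported, never resolved. The
`synthetic_dimer_anchors` helper builds two stand-in anchor
arrangements — it does not reproduce any external ectodomain model —
chosen so a compact, inward-facing pair yields ~6 nm kinase–kinase
separation and a spread, outward-facing pair ~10 nm, preserving the
ordering that compact arrangements bring kinase domains closer.

## The synthetic generator

The generator is an overdamped Brownian-dynamics toy, not a physical
membrane model. Design:

- **Protein.** A rigid body of ~70 beads: two fused spherical shells
  (radius 1.4 nm, centres 2.6 nm apart) for the N- and C-lobes, patch
  beads P1 (residues 609/615/617) and P2 (629/633/638/639) on the
  N-lobe face tilted ~30° toward the membrane, a 4-bead patch on the
  C-lobe underside (CFACE), two activation-loop marker beads in the
  cleft, and a JM-anchor bead. Because P1/P2 point down-and-outward,
  P1/P2-driven binding tilts the C-lobe ~1.3 nm off the surface (mode 1
  geometry); CFACE-driven binding lays the C-lobe on the surface
  (mode 2 geometry).
- **Membrane.** `n_lipids = 360` two-bead columns in a 15×15 nm plane:
  headgroup at z = 0, distal bead at z = −3.8 nm, so the membrane COM
  sits at the bilayer midplane (−1.9 nm) and a surface-bound protein
  shows the characteristic 4–5 nm COM separation. Lipids diffuse in xy
  (periodic) at per-species coefficients, default 0.05 nm²/ns for all
  species — a typical coarse-grained lipid value — so any measured
  PIP2 slowdown is entirely protein-induced. Composition defaults to
  PC:PS:PIP2 90:5:5 (the PIP3 variant 83:15:2 is a parameter choice
  away); species counts use largest-remainder rounding so realised
  counts are exact and deterministic.
- **Forces.** Patch beads attract headgroups of charged species through
  a smooth truncated well: full depth `epsilon * w(patch, species)`
  (kT) inside 0.42 nm, cosine-ramped to zero at the 1.2 nm interaction
  range. The flat core matters: bead excluded volume keeps patch–head
  distances near 0.5–0.8 nm, where a pure cosine well would retain
  almost none of its nominal depth. Default `epsilon = 3 kT` with
  wild-type weights P1: 2.5 (PIP2/PIP3) / 0.8 (PS); P2: 1.5 / 0.5;
  CFACE: 1.0 / 0.3; PC is always 0. The CFACE well is deliberately
  shallow enough to escape within a ~1 µs run, making mode 2 a real
  but secondary, convertible state for the wild type, while the
  charge-reversal emulation (P1/P2 weights sign-flipped) leaves CFACE
  as the only attractive surface and shifts binding to mode 2.
- **Protein dynamics.** Translation at `D = 0.03 nm²/ns` and rigid-body
  rotation at `D_rot = 0.01 rad²/ns` (small random rotation vectors
  composed each step, re-orthonormalised every 200 steps), both with
  force/torque drift terms (kT = 1). The rotational coefficient is at
  the slow end for a free domain but appropriate for a membrane-
  proximal one; much faster rotation would wag the patch beads (lever
  arm ~2 nm) hard enough to actively stir trapped lipids — an artifact,
  not a physical prediction.
- **Walls.** The membrane surface is impenetrable: any step that would
  push a bead below z = 0.3 nm is projected back. A reflecting ceiling
  10 nm below the top of the 30 nm box keeps the protein out of
  interaction range of the membrane's periodic image, so "bound" is
  unambiguous.
- **Tether.** A harmonic spring (k = 5 kT/nm², rest length 3 nm)
  between the JM-anchor bead and a fixed point on the membrane plane
  emulates the TM+JM-tethered construct.
- **Timestep.** `dt = 0.05 ns`, 20 000 steps (1 µs) saved every 20
  steps by default — the scale on which binding is established in the
  emulated systems, and a few seconds of compute per run. Drift per
  step stays well below both the noise amplitude and the force-ramp
  width.
- **Seeding.** One `numpy` Generator per run with a fixed draw order
  per step; identical parameters and seed give bit-identical
  trajectories and ground truth.
- **Ground truth.** Every saved frame records `dz`, the engaged patch
  (a patch with a strictly attractive weight whose bead is within the
  interaction range of a matching headgroup; labels NONE/P1/P2/P1P2/
  CFACE), and the recruited lipid ids (within range of any patch).
  Bound intervals are threshold crossings of `dz` at 5 nm.
  `start_engaged="P1"` (used by the `p1_only` scenario) initialises the
  protein with that patch facing the membrane at contact height with a
  random azimuth — *planting* engagement so single-patch recovery can
  be tested without waiting for a diffusive search; the dynamics are
  then free to keep or break the contact.

### Study scenarios

Scenario constructors freeze the conditions used by the tests and the
acceptance script: `wildtype` (all patches attractive), `p1_only`
(strong P1-only attraction, w_PIP2 = 4, planted P1 engagement),
`mutant_p1p2` (P1/P2 sign-flipped). Encounter runs start with the
protein COM 8 nm above the headgroup plane (≈10 nm from the membrane
COM); bound-state studies pre-position it at 3.2 nm (just above
contact), the standard trick for sampling an already-bound state at
desk scale. Ensembles use five replicas per condition with matched
seeds across paired conditions.

### What the generator does and does not emulate

It plants the *qualitative structure* the analyses must recover:
orientation-dependent binding through localised patches, two
geometrically distinct modes, patch-residue contact enrichment,
attraction-driven local PIP2 accumulation and slowdown, and
tether-enhanced binding. It has no MARTINI energetics, no lipid–lipid
interactions or excluded volume, no membrane undulations or curvature,
no solvent, a rigid protein, and kinetics that are not calibrated to
any real system. Passing tests therefore demonstrate that the analysis
stack measures what it claims on data with known truth — not that the
toy reproduces the physics of a real receptor at a real membrane.
Quantities tied to real-system magnitudes (absolute interacting-lipid
counts, absolute mode fractions, µs-scale kinetics) are only
directionally comparable.

## Problem sizes

Default analyses run on 1001-frame, ~790-particle trajectories; the
test suite and the acceptance script use five-replica ensembles per
condition, three seeds × 500 lipids × 1000 steps for planted-diffusion
recovery, and 10⁵ draws for histogram-law checks. These sizes give
each directional contrast a comfortable margin over its replica-to-
replica spread while keeping a full run of everything in a few minutes
on one core.

## Known limitations

- Orthorhombic boxes only; triclinic inputs are rejected explicitly.
- The membrane plane is assumed flat and z-normal; no plane fitting for
  curved or undulating bilayers.
- Mode classification depends on the domain map; mislabelled lobes
  produce systematically wrong (not noisy) mode labels.
- The normalisation of contact profiles is per-species max-over-
  residues; bar heights are not comparable across species with very
  different absolute contact levels.
- `lateral_diffusion` assumes a constant frame interval and measures a
  single pooled coefficient per species; it does not separate bound
  from free sub-populations.
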