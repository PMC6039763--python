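# membmode

Analysis of how a peripheral membrane protein — prototypically the
cytosolic kinase domain of a receptor tyrosine kinase — binds the inner
leaflet of a PIP-containing membrane, for people working with
coarse-grained or atomistic bilayer trajectories. The package computes:

- **Orientation–distance density maps.** Per frame, the zz element of
  the Kabsch rotation fitting the protein onto a reference pose
  (*R*<sub>zz</sub>) and the protein–membrane centre-of-mass separation
  (*d*<sub>z</sub> along the membrane normal, and the 3-D *d*). Their
  normalised 2-D histogram ρ(*R*<sub>zz</sub>, *d*<sub>z</sub>) is
  reported as the ratio map ΔD = ρ/ρ₀ with ρ₀ the global maximum.
- **Bound-state detection and binding-mode classification.** Bound
  intervals are dwell-filtered runs with *d*<sub>z</sub> ≤ 5 nm (the
  upper edge of the 4–5 nm stable-interaction band); bound frames are
  labelled *mode 1* (N-lobe engages the membrane, activation loop
  exposed) or *mode 2* (C-lobe engaged, activation loop masked) from
  headgroup contacts within 0.8 nm.
- **Per-residue lipid contact profiles** per species (PC/PS/PIP2/PIP3),
  normalised to the top residue, plus JM↔kinase intramolecular contact
  frequencies.
- **PIP nanoclustering statistics.** Per-frame interacting-lipid
  counts (a molecule counts once when any headgroup bead is within
  0.8 nm of the protein), Gaussian summaries of their distribution,
  per-lipid interaction time courses, residence times with
  persistent/transient labelling, and species-resolved lateral
  diffusion coefficients from MSD = 4*D*t.
- **Rigid-body integrative placement.** Superposing domain poses onto
  shared TM-anchor frames and measuring inter-domain COM separations in
  the assembled composite.
- **A synthetic Brownian-dynamics generator** (`membmode.synth`): a
  rigid two-lobe protein with charged patches P1 (residues
  H609/R615/K617) and P2 (K629/K633/K638/K639), an optional JM tether,
  and a diffusing PC/PS/PIP membrane — producing trajectories in the
  package's standard formats with full ground truth (bound intervals,
  engaged patch, recruited lipids, planted diffusion coefficients), so
  every analysis stage is testable without running MD.

Standard formats (GRO/PDB structures, XTC/DCD/multi-model-PDB
trajectories) are read and written through MDAnalysis; species and
domain assignment always comes from a small YAML map file, never from
chemical inference. See `docs/methods.md` for models, parameters and
limitations.

## Worked example

Simulate a wild-type encounter pre-positioned at the membrane surface
and run the analysis stack:

```python
from membmode import synth
from membmode.clusters import (count_distribution_fit,
                               interacting_lipid_count, lateral_diffusion)
from membmode.orient import (ReferencePose, classify_bound, classify_mode,
                             orientation_series)
from membmode.synth import SyntheticParams
from membmode.traj import Domain, Species, select

params = SyntheticParams.wildtype(seed=3, start_height=3.2)
traj, truth = synth.simulate_encounter(params)

top = traj.topology
protein = select(top, species=Species.PROTEIN)
membrane = select(top, domain=Domain.LIPID)
heads = select(top, domain=Domain.LIPID, headgroup=True)

ref = ReferencePose(traj.frames[0].coordinates[protein.indices], protein)
series = orientation_series(traj, protein, membrane, ref)
bound = classify_bound(series)          # dz <= 5 nm for >= 10 frames
modes = classify_mode(traj, select(top, domain=Domain.NLOBE),
                      select(top, domain=Domain.CLOBE), heads, bound)

counts = interacting_lipid_count(traj, protein, "PIP2")
fit = count_distribution_fit(counts, bound)
d = lateral_diffusion(traj, ["PC", "PIP2"])
```

Summarising those results prints:

```text
bound fraction       : 0.53
median bound dz      : 4.48 nm
dominant mode        : MODE1
interacting PIP2     : 5.0 +/- 3.2 (bound frames)
D(PC), D(PIP2)       : 0.051, 0.041 nm^2/ns
```

Reading: the kinase is membrane-bound for half of the 1 µs run, sitting
at the 4–5 nm COM separation characteristic of a stable interaction,
with the productive N-lobe-down orientation (mode 1). While bound it
gathers on average five PIP2 molecules into its interaction shell, and
that recruitment shows up as slower lateral diffusion of PIP2 relative
to the bulk PC background — the nanoclustering signature.

## Command line

Every stage is also a subcommand of the `membmode` console script:

```sh
membmode simulate --seed 3 --out run/            # GRO + XTC + maps + truth
membmode orient   --traj run/trajectory.xtc --top run/system.gro \
                  --maps run/maps.yaml --out orient/
membmode contacts --traj ... --cutoff 0.8 --out contacts.csv
membmode clusters --traj ... --species PIP2 --out clusters/
membmode diffusion --traj ... --species PC,PS,PIP2 --out D.json
membmode run      --config pipeline.yaml --out results/   # whole pipeline
```

`membmode run` drives simulate → orient → contacts → clusters →
diffusion from one YAML config and writes a `report.json`; identical
config and seed reproduce every output byte-identically.

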