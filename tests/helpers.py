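"""Shared test utilities: brute-force oracles and small fixture builders."""

from __future__ import annotations

import itertools

import numpy as np

from membmode.orient import ReferencePose, classify_bound, classify_mode, \
    orientation_series
from membmode.traj import Domain, Frame, Selection, Species, Topology, \
    Trajectory, select


def brute_force_min_image(a, b, box):
    """Minimum distance over all 27 periodic images (oracle).

    Points are first wrapped into the primary cell, after which the
    nearest image is always among the 27 neighbours.
    """
    box = np.asarray(box, dtype=float)
    a = np.mod(np.asarray(a, dtype=float), box)
    b = np.mod(np.asarray(b, dtype=float), box)
    best = np.inf
    for sx, sy, sz in itertools.product((-1, 0, 1), repeat=3):
        d = np.linalg.norm(a - (b + np.array([sx, sy, sz]) * box))
        best = min(best, d)
    return best


def brute_force_contact_count(residue_coords, target_coords, box, cutoff):
    """Number of target particles within cutoff of any residue particle,
    via the 27-image oracle."""
    n = 0
    for t in target_coords:
        if any(brute_force_min_image(r, t, box) <= cutoff
               for r in residue_coords):
            n += 1
    return n


def toy_topology(n_protein=0, lipid_species=(), protein_domains=None,
                 protein_resids=None):
    """Minimal topology: n_protein protein beads followed by one
    single-bead (headgroup) lipid per entry of lipid_species."""
    names, resids, resnames, mols, domains, species, heads = \
        [], [], [], [], [], [], []
    for i in range(n_protein):
        names.append("BB")
        resids.append(protein_resids[i] if protein_resids else 600 + i)
        resnames.append("KIN")
        mols.append(0)
        domains.append(protein_domains[i] if protein_domains
                       else Domain.NLOBE.value)
        species.append(Species.PROTEIN.value)
        heads.append(False)
    for j, sp in enumerate(lipid_species):
        names.append("PO4")
        resids.append(1000 + j)
        resnames.append("LIP")
        mols.append(1 + j)
        domains.append(Domain.LIPID.value)
        species.append(sp)
        heads.append(True)
    return Topology(
        particle_names=np.array(names, dtype=object),
        residue_ids=np.array(resids),
        residue_names=np.array(resnames, dtype=object),
        molecule_ids=np.array(mols),
        domain_labels=np.array(domains, dtype=object),
        species=np.array(species, dtype=object),
        is_headgroup=np.array(heads),
    )


def make_trajectory(topology, coords_per_frame, box=(10.0, 10.0, 10.0),
                    dt=1.0):
    frames = [Frame(coordinates=np.asarray(c, dtype=float),
                    box=np.asarray(box, dtype=float), time=i * dt)
              for i, c in enumerate(coords_per_frame)]
    return Trajectory(topology=topology, frames=frames)


def classify_run(traj, min_dwell=10):
    """Standard bound/mode classification used across ensemble tests."""
    top = traj.topology
    protein = select(top, species=Species.PROTEIN)
    membrane = select(top, domain=Domain.LIPID)
    heads = select(top, domain=Domain.LIPID, headgroup=True)
    ref = ReferencePose(traj.frames[0].coordinates[protein.indices],
                        protein)
    series = orientation_series(traj, protein, membrane, ref)
    bound = classify_bound(series, min_dwell=min_dwell)
    modes = classify_mode(traj, select(top, domain=Domain.NLOBE),
                          select(top, domain=Domain.CLOBE), heads, bound)
    return series, bound, modes
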