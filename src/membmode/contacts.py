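"""Cutoff-based contact statistics.

Contacts follow the convention of counting, for each protein residue
and lipid species, the number of lipid target particles (headgroup
beads by default) within a cutoff distance (default 0.8 nm, minimum
image) of any particle of that residue. Per-species profiles are
normalised to the maximum time-averaged count over residues, giving
"normalized contact frequency" bars in [0, 1] with the top residue at 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .traj import Selection, Topology, Trajectory, select

__all__ = [
    "ContactProfile",
    "contact_counts",
    "normalized_contact_profile",
    "intramolecular_contacts",
]


@dataclass
class ContactProfile:
    residues: np.ndarray  # ordered residue ids
    species: list  # lipid species names
    raw_counts: np.ndarray  # (n_res, n_species) mean counts per frame
    normalized: np.ndarray  # (n_res, n_species) in [0, 1]
    cutoff: float
    n_frames: int

    def to_frame(self, topology: Topology | None = None) -> pd.DataFrame:
        rows = []
        names = {}
        if topology is not None:
            for rid, rname in zip(topology.residue_ids,
                                  topology.residue_names):
                names.setdefault(int(rid), str(rname))
        for i, rid in enumerate(self.residues):
            for j, sp in enumerate(self.species):
                rows.append((int(rid), names.get(int(rid), ""), sp,
                             self.raw_counts[i, j], self.normalized[i, j]))
        return pd.DataFrame(rows, columns=["residue_id", "residue_name",
                                           "species", "raw_mean",
                                           "normalized"])


def _group_by_residue(topology: Topology, sel: Selection):
    """Ordered residue ids and their particle-index lists within sel."""
    rids = topology.residue_ids[sel.indices]
    order = []
    groups = {}
    for idx, rid in zip(sel.indices, rids):
        rid = int(rid)
        if rid not in groups:
            groups[rid] = []
            order.append(rid)
        groups[rid].append(idx)
    return np.array(order), [np.array(groups[r]) for r in order]


def contact_counts(traj: Trajectory, protein_sel: Selection,
                   cutoff: float = 0.8, species=None,
                   headgroup_only: bool = True,
                   frames=None) -> tuple[np.ndarray, np.ndarray, list]:
    """Per-frame, per-residue, per-species interacting-particle counts.

    For each frame, residue and lipid species: the number of target
    particles (headgroup beads unless ``headgroup_only=False``) within
    ``cutoff`` (minimum image) of any particle of the residue, counted
    per target particle. Returns (counts[(res, species, frame)],
    residue_ids, species_list).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if len(protein_sel) == 0:
        raise ValueError("protein selection is empty")
    top = traj.topology
    if species is None:
        species = [s for s in ("PC", "PS", "PIP2", "PIP3")
                   if np.any(top.species == s)]
    species = list(species)
    res_ids, res_groups = _group_by_residue(top, protein_sel)
    frame_idx = range(traj.n_frames) if frames is None else list(frames)

    target_idx = {}
    for sp in species:
        mask = top.species == sp
        if headgroup_only:
            mask &= top.is_headgroup
        target_idx[sp] = np.nonzero(mask)[0]

    counts = np.zeros((len(res_ids), len(species), len(list(frame_idx))))
    for fi, f in enumerate(frame_idx):
        fr = traj.frames[f]
        pos = np.mod(fr.coordinates, fr.box)
        for sj, sp in enumerate(species):
            tidx = target_idx[sp]
            if len(tidx) == 0:
                continue
            tree = cKDTree(pos[tidx], boxsize=fr.box)
            for ri, grp in enumerate(res_groups):
                hits = tree.query_ball_point(pos[grp], r=cutoff)
                touched = set()
                for h in hits:
                    touched.update(h)
                counts[ri, sj, fi] = len(touched)
    return counts, res_ids, species


def normalized_contact_profile(counts: np.ndarray, residue_ids: np.ndarray,
                               species: list,
                               cutoff: float = 0.8) -> ContactProfile:
    """Time-average raw counts and normalise per species by the maximum
    over residues (an all-zero species stays zero)."""
    raw = counts.mean(axis=2)
    norm = np.zeros_like(raw)
    for j in range(raw.shape[1]):
        m = raw[:, j].max()
        if m > 0:
            norm[:, j] = raw[:, j] / m
    return ContactProfile(residues=np.asarray(residue_ids), species=species,
                          raw_counts=raw, normalized=norm, cutoff=cutoff,
                          n_frames=counts.shape[2])


def intramolecular_contacts(traj: Trajectory, selA: Selection,
                            selB: Selection,
                            cutoff: float = 0.8) -> pd.DataFrame:
    """Fraction of frames in which each residue of selA (and of selB)
    has any cross-selection particle pair within cutoff.

    Typical use: selA = JM segment, selB = kinase domain, giving the
    per-residue JM-kinase contact frequency.
    """
    if np.intersect1d(selA.indices, selB.indices).size:
        raise ValueError("selections must be disjoint")
    top = traj.topology
    ridsA, grpsA = _group_by_residue(top, selA)
    ridsB, grpsB = _group_by_residue(top, selB)
    hitsA = np.zeros(len(ridsA))
    hitsB = np.zeros(len(ridsB))
    for fr in traj.frames:
        pos = np.mod(fr.coordinates, fr.box)
        treeB = cKDTree(pos[selB.indices], boxsize=fr.box)
        treeA = cKDTree(pos[selA.indices], boxsize=fr.box)
        for i, grp in enumerate(grpsA):
            if any(len(h) for h in treeB.query_ball_point(pos[grp],
                                                          r=cutoff)):
                hitsA[i] += 1
        for i, grp in enumerate(grpsB):
            if any(len(h) for h in treeA.query_ball_point(pos[grp],
                                                          r=cutoff)):
                hitsB[i] += 1
    n = traj.n_frames
    rows = ([(int(r), "A", h / n) for r, h in zip(ridsA, hitsA)] +
            [(int(r), "B", h / n) for r, h in zip(ridsB, hitsB)])
    return pd.DataFrame(rows, columns=["residue_id", "group", "frequency"])
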