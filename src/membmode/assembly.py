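"""Rigid-body integrative placement.

Domain poses (e.g. a membrane-bound kinase conformation taken from a
trajectory) are superimposed onto shared anchor frames — the TM helix
acting as the common reference — and inter-domain centre-of-mass
distances are measured on the assembled, non-periodic composite model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .orient import RigidTransform, superpose
from .traj import Selection

__all__ = [
    "DomainPose",
    "anchor_transform",
    "place_domain",
    "pair_separation",
    "clash_pairs",
    "assemble",
    "synthetic_dimer_anchors",
]


@dataclass
class DomainPose:
    coordinates: np.ndarray  # (n, 3) nm
    anchor_sel: Selection  # indices into coordinates (the TM anchor)
    label: str = ""

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=np.float64)
        anchor = self.coordinates[self.anchor_sel.indices]
        if anchor.shape[0] < 3:
            raise ValueError("anchor needs at least 3 particles")
        c = anchor - anchor.mean(axis=0)
        if np.linalg.matrix_rank(c, tol=1e-10) < 2:
            raise ValueError("anchor particles are collinear")

    @property
    def anchor_coordinates(self) -> np.ndarray:
        return self.coordinates[self.anchor_sel.indices]


def anchor_transform(pose: DomainPose,
                     target_anchor: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform carrying the pose's anchor onto the
    target anchor coordinates."""
    target_anchor = np.asarray(target_anchor, dtype=np.float64)
    if target_anchor.shape != pose.anchor_coordinates.shape:
        raise ValueError("anchor particle counts differ")
    T, _ = superpose(pose.anchor_coordinates, target_anchor)
    return T


def place_domain(pose: DomainPose,
                 transform: RigidTransform) -> np.ndarray:
    """Apply x -> R x + t to all pose coordinates (rigid, chirality
    preserving)."""
    return transform.apply(pose.coordinates)


def pair_separation(placed_a: np.ndarray, placed_b: np.ndarray) -> float:
    """Euclidean distance between the centroids of two placed domains
    (no periodicity: assembled models are not periodic)."""
    a = np.asarray(placed_a, dtype=float)
    b = np.asarray(placed_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("placed coordinates must be nonempty")
    return float(np.linalg.norm(a.mean(axis=0) - b.mean(axis=0)))


def clash_pairs(placed_a: np.ndarray, placed_b: np.ndarray,
                threshold: float = 0.3) -> list[tuple[int, int]]:
    """Cross-domain particle pairs closer than threshold (reported,
    never resolved)."""
    a = np.asarray(placed_a)[:, None, :]
    b = np.asarray(placed_b)[None, :, :]
    d = np.linalg.norm(a - b, axis=2)
    return [(int(i), int(j)) for i, j in zip(*np.nonzero(d < threshold))]


def assemble(pose: DomainPose, anchors) -> dict:
    """Place one copy of the pose on each labelled anchor frame.

    ``anchors`` is a mapping label -> (n_anchor, 3) coordinates. Returns
    a dict with placed coordinates per label, all pairwise COM
    separations, and clash counts.
    """
    placed = {}
    for label, target in anchors.items():
        T = anchor_transform(pose, np.asarray(target))
        placed[label] = place_domain(pose, T)
    labels = sorted(placed)
    separations = {}
    clashes = {}
    for i, la in enumerate(labels):
        for lb in labels[i + 1:]:
            separations[f"{la}-{lb}"] = pair_separation(placed[la],
                                                        placed[lb])
            clashes[f"{la}-{lb}"] = len(clash_pairs(placed[la], placed[lb]))
    return {"placed": placed, "separations": separations, "clashes": clashes}


def synthetic_dimer_anchors(pose: DomainPose, arrangement: str) -> dict:
    """Synthetic two-copy anchor geometries for a receptor dimer.

    These are constructed stand-ins for external ectodomain-derived TM
    arrangements (which are not part of this package): two copies of the
    pose's own anchor are laid out either as a "parallel-close"
    arrangement (anchor frames far apart but facing each other, bringing
    the attached domains close) or an "upright-far" arrangement (anchor
    frames nearer but facing away, pushing the domains apart). Returns
    {label: anchor coordinates} for use with :func:`assemble`.
    """
    anchor = pose.anchor_coordinates
    c = pose.coordinates.mean(axis=0)
    flip = np.diag([-1.0, -1.0, 1.0])  # 180 degrees about z
    if arrangement == "parallel-close":
        # copy B faces copy A: COM separation ~6 nm
        gap = 6.0 + 2.0 * c[0]
        a = anchor
        b = anchor @ flip.T + np.array([gap, 0.0, 0.0])
    elif arrangement == "upright-far":
        # copies face away from each other: COM separation ~10 nm
        gap = 10.0 - 2.0 * c[0]
        a = anchor @ flip.T
        b = anchor + np.array([gap, 0.0, 0.0])
    else:
        raise ValueError("arrangement must be 'parallel-close' or "
                         "'upright-far'")
    return {"copyA": a, "copyB": b}
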