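"""Orientation and binding-mode analysis.

The orientation of the protein in each frame is summarised by the zz
element of the rotation matrix (Rzz) obtained from a least-squares
(Kabsch) superposition onto a reference pose, and by its centre-of-mass
separation from the membrane: dz, the perpendicular (z) component, and
d, the full 3-D separation. A 2-D histogram of (Rzz, dz) normalised by
its global maximum gives the density-ratio map

    dD(Rzz, dz) = rho(Rzz, dz) / rho0,   rho0 = max rho.

Bound states are maximal runs of frames with dz below a threshold (the
stable-interaction band sits at 4-5 nm for a kinase-sized domain on a
bilayer), and binding modes are classified by which kinase lobes touch
the membrane headgroups: mode 1 engages the N-lobe only (activation
loop exposed), mode 2 engages both lobes (activation loop masked).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .traj import (Frame, Selection, Topology, Trajectory, center_of_mass,
                   min_image_displacement)

__all__ = [
    "RigidTransform",
    "ReferencePose",
    "OrientationSeries",
    "OrientationDensity",
    "ModeLabel",
    "superpose",
    "orientation_series",
    "density_map",
    "classify_bound",
    "classify_mode",
]


@dataclass
class RigidTransform:
    """Proper rigid-body transform x -> R @ x + t."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=np.float64)
        self.translation = np.asarray(self.translation, dtype=np.float64)
        R = self.rotation
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthogonal")
        if abs(np.linalg.det(R) - 1.0) > 1e-8:
            raise ValueError("rotation must have determinant +1")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


@dataclass
class ReferencePose:
    coordinates: np.ndarray  # (n, 3) nm
    selection: Selection

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=np.float64)
        _check_fittable(self.coordinates)


def _check_fittable(x: np.ndarray) -> None:
    if x.shape[0] < 3:
        raise ValueError("superposition needs at least 3 particles")
    c = x - x.mean(axis=0)
    if np.linalg.matrix_rank(c, tol=1e-10) < 2:
        raise ValueError("superposition needs non-collinear particles")


def superpose(mobile: np.ndarray, reference: np.ndarray,
              weights=None) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition of mobile onto reference (Kabsch).

    Returns the proper rotation + translation minimising the weighted
    RMSD, with reflections excluded by sign correction, and the
    minimised RMSD itself (nm).
    """
    mobile = np.asarray(mobile, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if mobile.shape != reference.shape:
        raise ValueError("mobile and reference shapes differ")
    _check_fittable(mobile)
    _check_fittable(reference)
    if weights is None:
        w = np.ones(len(mobile))
    else:
        w = np.asarray(weights, dtype=np.float64)
    wsum = w.sum()
    cm = (w[:, None] * mobile).sum(axis=0) / wsum
    cr = (w[:, None] * reference).sum(axis=0) / wsum
    P = mobile - cm
    Q = reference - cr
    H = P.T @ (w[:, None] * Q)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cr - R @ cm
    resid = P @ R.T - Q
    rmsd = float(np.sqrt((w * (resid ** 2).sum(axis=1)).sum() / wsum))
    return RigidTransform(rotation=R, translation=t), rmsd


@dataclass
class OrientationSeries:
    """Per-frame (time, Rzz, dz, d) records, backed by a DataFrame."""

    frame: pd.DataFrame  # columns: time, rzz, dz, d

    def __post_init__(self):
        req = {"time", "rzz", "dz", "d"}
        if not req.issubset(self.frame.columns):
            raise ValueError(f"series needs columns {sorted(req)}")
        rzz = self.frame["rzz"].to_numpy()
        if np.any(np.abs(rzz) > 1 + 1e-9):
            raise ValueError("Rzz outside [-1, 1]")

    @property
    def n_frames(self) -> int:
        return len(self.frame)


def orientation_series(traj: Trajectory, protein_sel: Selection,
                       membrane_sel: Selection, ref: ReferencePose,
                       mass_weighted: bool = True) -> OrientationSeries:
    """Compute per-frame Rzz and protein-membrane COM separations.

    Rzz is the zz element of the Kabsch rotation fitting the frame's
    protein (at the reference-pose selection) onto the reference
    coordinates; dz is |delta z| of the protein and membrane centres of
    mass under the minimum image along z; d is the minimum-image 3-D
    COM separation.
    """
    if len(protein_sel) == 0 or len(membrane_sel) == 0:
        raise ValueError("selections must be nonempty")
    top = traj.topology
    fit_idx = ref.selection.indices
    rows = []
    for fr in traj.frames:
        T, _ = superpose(fr.coordinates[fit_idx], ref.coordinates)
        # the rotation carrying the frame pose onto the reference
        rzz = float(T.rotation[2, 2])
        com_p = center_of_mass(fr, protein_sel, top, mass_weighted)
        com_m = center_of_mass(fr, membrane_sel, top, mass_weighted)
        disp = min_image_displacement(com_p, com_m, fr.box)
        rows.append((fr.time, rzz, abs(disp[2]),
                     float(np.linalg.norm(disp))))
    df = pd.DataFrame(rows, columns=["time", "rzz", "dz", "d"])
    return OrientationSeries(frame=df)


@dataclass
class OrientationDensity:
    rzz_edges: np.ndarray
    d_edges: np.ndarray
    rho: np.ndarray  # (n_rzz, n_d), sums to 1
    deltaD: np.ndarray
    rho0: float

    def to_frame(self) -> pd.DataFrame:
        """Long-format grid (bin centres, rho, deltaD) for CSV export."""
        rc = 0.5 * (self.rzz_edges[:-1] + self.rzz_edges[1:])
        dc = 0.5 * (self.d_edges[:-1] + self.d_edges[1:])
        ii, jj = np.meshgrid(np.arange(len(rc)), np.arange(len(dc)),
                             indexing="ij")
        return pd.DataFrame({
            "rzz": rc[ii.ravel()], "d": dc[jj.ravel()],
            "rho": self.rho.ravel(), "deltaD": self.deltaD.ravel()})


def density_map(series: OrientationSeries, rzz_edges=None, d_edges=None,
                distance: str = "dz") -> OrientationDensity:
    """Normalised 2-D (Rzz, distance) histogram and its ratio map.

    ``distance`` selects the z-component separation ("dz", default) or
    the 3-D COM separation ("d").
    """
    if distance not in ("dz", "d"):
        raise ValueError("distance must be 'dz' or 'd'")
    rzz = series.frame["rzz"].to_numpy()
    dist = series.frame[distance].to_numpy()
    if rzz_edges is None:
        rzz_edges = np.arange(-1.0, 1.0 + 1e-12, 0.05)
    if d_edges is None:
        hi = np.ceil(dist.max() * 10) / 10 + 0.1
        d_edges = np.arange(0.0, hi + 1e-12, 0.1)
    counts, rzz_edges, d_edges = np.histogram2d(
        rzz, dist, bins=[np.asarray(rzz_edges), np.asarray(d_edges)])
    total = counts.sum()
    if total == 0:
        raise ValueError("no observations fall inside the binned domain")
    rho = counts / total
    rho0 = float(rho.max())
    return OrientationDensity(rzz_edges=rzz_edges, d_edges=d_edges,
                              rho=rho, deltaD=rho / rho0, rho0=rho0)


def classify_bound(series: OrientationSeries, d_threshold: float = 5.0,
                   min_dwell: int = 10,
                   distance: str = "dz") -> list[tuple[int, int]]:
    """Maximal runs of frames with separation <= threshold, lasting at
    least ``min_dwell`` frames. Intervals are half-open (start, stop)
    frame-index pairs, disjoint and ordered."""
    if min_dwell < 1:
        raise ValueError("min_dwell must be >= 1")
    below = series.frame[distance].to_numpy() <= d_threshold
    return _runs(below, min_dwell)


def _runs(mask: np.ndarray, min_len: int = 1) -> list[tuple[int, int]]:
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        return []
    padded = np.concatenate([[False], mask, [False]]).astype(np.int8)
    d = np.diff(padded)
    starts = np.nonzero(d == 1)[0]
    stops = np.nonzero(d == -1)[0]
    return [(int(a), int(b)) for a, b in zip(starts, stops)
            if b - a >= min_len]


class ModeLabel(str, Enum):
    MODE1 = "MODE1"
    MODE2 = "MODE2"
    UNBOUND = "UNBOUND"


@dataclass
class ModeClassification:
    labels: list  # per-frame ModeLabel
    dominant: ModeLabel
    n_contacts: np.ndarray = field(default=None)  # (n_frames, 2) N/C counts


def _lobe_contact_counts(frame: Frame, lobe_idx: np.ndarray,
                         target_idx: np.ndarray, cutoff: float) -> int:
    """Number of target particles within cutoff of any lobe particle
    (minimum image, per-target counting)."""
    box = frame.box
    pos = np.mod(frame.coordinates, box)
    tree = cKDTree(pos[target_idx], boxsize=box)
    hits = tree.query_ball_point(pos[lobe_idx], r=cutoff)
    touched = set()
    for h in hits:
        touched.update(h)
    return len(touched)


def classify_mode(traj: Trajectory, nlobe_sel: Selection,
                  clobe_sel: Selection,
                  membrane_headgroup_sel: Selection,
                  bound_intervals,
                  cutoff: float = 0.8,
                  clobe_contact_threshold: float = 0.25,
                  contact_floor: int = 1) -> ModeClassification:
    """Label bound frames mode 1 / mode 2 by lobe-membrane engagement.

    With N = N-lobe and C = C-lobe headgroup-contact counts for a bound
    frame: mode 1 requires N above the contact floor with C at most
    ``clobe_contact_threshold * N`` (tolerating incidental grazing);
    any other engagement of either lobe above the floor is mode 2.
    Bound frames without any lobe contact, and all frames outside the
    bound intervals, are labelled unbound. The dominant mode is the
    majority label over mode-labelled frames.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    bound_mask = np.zeros(traj.n_frames, dtype=bool)
    for a, b in bound_intervals:
        bound_mask[a:b] = True
    labels = []
    counts = np.zeros((traj.n_frames, 2), dtype=int)
    for i, fr in enumerate(traj.frames):
        if not bound_mask[i]:
            labels.append(ModeLabel.UNBOUND)
            continue
        n = _lobe_contact_counts(fr, nlobe_sel.indices,
                                 membrane_headgroup_sel.indices, cutoff)
        c = _lobe_contact_counts(fr, clobe_sel.indices,
                                 membrane_headgroup_sel.indices, cutoff)
        counts[i] = (n, c)
        if n >= contact_floor and c <= clobe_contact_threshold * n:
            labels.append(ModeLabel.MODE1)
        elif c >= contact_floor:
            labels.append(ModeLabel.MODE2)
        else:
            labels.append(ModeLabel.UNBOUND)
    n1 = sum(1 for l in labels if l is ModeLabel.MODE1)
    n2 = sum(1 for l in labels if l is ModeLabel.MODE2)
    if n1 == 0 and n2 == 0:
        dominant = ModeLabel.UNBOUND
    else:
        dominant = ModeLabel.MODE1 if n1 >= n2 else ModeLabel.MODE2
    return ModeClassification(labels=labels, dominant=dominant,
                              n_contacts=counts)
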