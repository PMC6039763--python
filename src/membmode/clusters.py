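"""PIP nanoclustering, residence-time and lateral-diffusion statistics.

A lipid molecule counts as interacting when any of its headgroup beads
lies within a cutoff (default 0.8 nm) of any protein particle; a
molecule counts once per frame regardless of how many of its beads are
inside the cutoff. Count distributions are summarised by a
moment-matched Gaussian; per-lipid boolean time courses yield dwell
(residence) times with optional gap tolerance; lateral diffusion
coefficients come from the 2-D Einstein relation MSD = 4 D t fitted
over an intermediate lag window, with periodic-boundary unwrapping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .orient import _runs
from .traj import Selection, Trajectory

__all__ = [
    "LipidTimecourse",
    "GaussianFit",
    "DiffusionResult",
    "interacting_lipid_count",
    "count_distribution_fit",
    "lipid_timecourse",
    "residence_times",
    "lateral_diffusion",
]


@dataclass
class LipidTimecourse:
    species: str
    lipid_ids: np.ndarray  # ordered molecule ids
    matrix: np.ndarray  # bool, (n_lipids, n_frames)
    cutoff: float

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=bool)
        if self.matrix.shape[0] != len(self.lipid_ids):
            raise ValueError("matrix rows must match lipid_ids")

    def counts(self) -> np.ndarray:
        return self.matrix.sum(axis=0)


@dataclass
class GaussianFit:
    mean: float
    sd: float
    n: int

    def __post_init__(self):
        if self.n < 1 or self.sd < 0:
            raise ValueError("invalid Gaussian fit")


@dataclass
class DiffusionResult:
    D: dict  # species -> nm^2/ns
    msd_curves: dict  # species -> DataFrame(lag_ns, msd_nm2)
    fit_window: tuple  # (lag_min, lag_max) ns


def _species_head_molecules(traj: Trajectory, species: str):
    top = traj.topology
    mask = (top.species == species) & top.is_headgroup
    if not np.any(top.species == species):
        raise ValueError(f"species {species} absent from topology")
    idx = np.nonzero(mask)[0]
    mols = top.molecule_ids[idx]
    return idx, mols


def lipid_timecourse(traj: Trajectory, protein_sel: Selection,
                     species: str, cutoff: float = 0.8) -> LipidTimecourse:
    """Boolean (lipid x frame) interaction matrix for one species."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    head_idx, head_mols = _species_head_molecules(traj, species)
    lipid_ids = np.unique(head_mols)
    mol_row = {int(m): i for i, m in enumerate(lipid_ids)}
    mat = np.zeros((len(lipid_ids), traj.n_frames), dtype=bool)
    for fi, fr in enumerate(traj.frames):
        pos = np.mod(fr.coordinates, fr.box)
        tree = cKDTree(pos[protein_sel.indices], boxsize=fr.box)
        hits = tree.query_ball_point(pos[head_idx], r=cutoff)
        for bead, h in enumerate(hits):
            if h:
                mat[mol_row[int(head_mols[bead])], fi] = True
    return LipidTimecourse(species=species, lipid_ids=lipid_ids,
                           matrix=mat, cutoff=cutoff)


def interacting_lipid_count(traj: Trajectory, protein_sel: Selection,
                            species: str,
                            cutoff: float = 0.8) -> np.ndarray:
    """Per-frame number of distinct lipid molecules of the species with
    any headgroup bead within cutoff of any protein particle."""
    return lipid_timecourse(traj, protein_sel, species, cutoff).counts()


def count_distribution_fit(series, bound_intervals=None) -> GaussianFit:
    """Moment-matched Gaussian over the count series, optionally
    restricted to frames inside bound intervals."""
    series = np.asarray(series, dtype=float)
    if bound_intervals is not None:
        mask = np.zeros(len(series), dtype=bool)
        for a, b in bound_intervals:
            mask[a:b] = True
        series = series[mask]
    if len(series) < 2:
        raise ValueError("need at least 2 observations for a fit")
    return GaussianFit(mean=float(series.mean()),
                       sd=float(series.std(ddof=0)), n=len(series))


def residence_times(tc: LipidTimecourse,
                    gap_tolerance: int = 1,
                    persistent_fraction: float = 0.5) -> pd.DataFrame:
    """Per-lipid dwell lengths after merging gaps <= gap_tolerance.

    A lipid is labelled persistent when its longest dwell covers at
    least ``persistent_fraction`` of the analysed frames, transient
    otherwise.
    """
    if gap_tolerance < 0:
        raise ValueError("gap_tolerance must be >= 0")
    n_frames = tc.matrix.shape[1]
    rows = []
    for lid, row in zip(tc.lipid_ids, tc.matrix):
        merged = _merge_gaps(row, gap_tolerance)
        dwells = [b - a for a, b in merged]
        longest = max(dwells, default=0)
        label = ("persistent" if longest >= persistent_fraction * n_frames
                 else "transient")
        rows.append((int(lid), dwells, longest, label))
    return pd.DataFrame(rows, columns=["lipid_id", "dwells",
                                       "longest_dwell", "label"])


def _merge_gaps(row: np.ndarray, gap_tolerance: int):
    runs = _runs(np.asarray(row, dtype=bool))
    if not runs or gap_tolerance == 0:
        return runs
    merged = [runs[0]]
    for a, b in runs[1:]:
        pa, pb = merged[-1]
        if a - pb <= gap_tolerance:
            merged[-1] = (pa, b)
        else:
            merged.append((a, b))
    return merged


def _unwrap_xy(pos: np.ndarray, box_xy: np.ndarray) -> np.ndarray:
    """Remove periodic jumps from (n_frames, n, 2) positions by
    accumulating minimum-image step displacements (exact for steps
    shorter than half the box)."""
    steps = np.diff(pos, axis=0)
    steps -= box_xy * np.round(steps / box_xy)
    return np.concatenate([pos[:1], pos[:1] + np.cumsum(steps, axis=0)])


def _msd_fft(x: np.ndarray) -> np.ndarray:
    """Time-origin-averaged MSD of (T, n, dim) positions via FFT."""
    T = x.shape[0]
    nfft = 1 << (2 * T - 1).bit_length()
    S2 = np.zeros((T, x.shape[1]))
    for d in range(x.shape[2]):
        f = np.fft.rfft(x[:, :, d], n=nfft, axis=0)
        acf = np.fft.irfft(f * f.conj(), n=nfft, axis=0)[:T].real
        S2 += acf
    norm = np.arange(T, 0, -1)[:, None]
    S2 /= norm
    sq = (x ** 2).sum(axis=2)
    ssum = np.cumsum(sq, axis=0)
    rsum = np.cumsum(sq[::-1], axis=0)
    S1 = np.empty_like(S2)
    S1[0] = 2 * ssum[-1] / T
    for m in range(1, T):
        S1[m] = (ssum[-1] - ssum[m - 1] + rsum[-1] - rsum[m - 1]) / (T - m)
    return (S1 - 2 * S2).mean(axis=1)


def lateral_diffusion(traj: Trajectory, species,
                      fit_window=(0.1, 0.5)) -> DiffusionResult:
    """Species-resolved lateral diffusion from the 2-D Einstein relation.

    The ensemble- and time-origin-averaged in-plane MSD of each species'
    headgroup beads (one bead per molecule is sufficient; all headgroup
    beads of a molecule move together in the generator, and for real
    data the first headgroup bead per molecule is used) is fitted as
    MSD = 4 D t by least squares over ``fit_window`` expressed as
    fractions of the maximum lag.
    """
    if traj.n_frames < 3:
        raise ValueError("need at least 3 frames")
    times = traj.times
    dts = np.diff(times)
    if not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-9):
        raise ValueError("lateral_diffusion requires a constant time step")
    dt = float(dts[0])
    if isinstance(species, str):
        species = [species]
    box_xy = traj.frames[0].box[:2]
    D = {}
    curves = {}
    T = traj.n_frames
    lags = np.arange(T) * dt
    lo = max(1, int(np.floor(fit_window[0] * (T - 1))))
    hi = max(lo + 2, int(np.ceil(fit_window[1] * (T - 1))) + 1)
    for sp in species:
        head_idx, head_mols = _species_head_molecules(traj, sp)
        # one representative headgroup bead per molecule
        _, first = np.unique(head_mols, return_index=True)
        idx = head_idx[np.sort(first)]
        pos = traj.coordinates(idx)[:, :, :2]
        unwrapped = _unwrap_xy(pos, box_xy)
        msd = _msd_fft(unwrapped)
        msd[0] = 0.0
        slope = np.polyfit(lags[lo:hi], msd[lo:hi], 1)[0]
        D[sp] = float(max(slope / 4.0, 0.0))
        curves[sp] = pd.DataFrame({"lag_ns": lags, "msd_nm2": msd})
    return DiffusionResult(D=D, msd_curves=curves,
                           fit_window=(lags[lo], lags[hi - 1]))
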