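"""Core data model for membrane-protein trajectories.

Coordinates are stored in nanometres throughout; periodic boxes are
orthorhombic, with the membrane normal along z. Particles carry a lipid
species (PC / PS / PIP2 / PIP3, or PROTEIN), a headgroup flag, and a
coarse domain label (TM, JM, kinase N-lobe / C-lobe, activation loop).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "Species",
    "Domain",
    "Topology",
    "Frame",
    "Trajectory",
    "Selection",
    "min_image_displacement",
    "min_image_distance",
    "center_of_mass",
    "select",
]

DEFAULT_BEAD_MASS = 72.0  # amu; typical 4-to-1 coarse-grained bead

LIPID_SPECIES = ("PC", "PS", "PIP2", "PIP3")


class Species(str, Enum):
    PROTEIN = "PROTEIN"
    PC = "PC"
    PS = "PS"
    PIP2 = "PIP2"
    PIP3 = "PIP3"


class Domain(str, Enum):
    TM = "TM"
    JM = "JM"
    NLOBE = "NLOBE"
    CLOBE = "CLOBE"
    ACTLOOP = "ACTLOOP"
    LIPID = "LIPID"
    OTHER = "OTHER"


@dataclass
class Topology:
    """Per-particle metadata, stored column-wise as numpy arrays."""

    particle_names: np.ndarray  # str
    residue_ids: np.ndarray  # int, 1-based as in the input file
    residue_names: np.ndarray  # str
    molecule_ids: np.ndarray  # int; one id per lipid molecule / protein chain
    domain_labels: np.ndarray  # str, values of Domain
    species: np.ndarray  # str, values of Species
    is_headgroup: np.ndarray  # bool
    masses: np.ndarray = None  # amu

    def __post_init__(self):
        n = len(self.particle_names)
        if self.masses is None:
            self.masses = np.full(n, DEFAULT_BEAD_MASS)
        self.particle_names = np.asarray(self.particle_names, dtype=object)
        self.residue_names = np.asarray(self.residue_names, dtype=object)
        self.residue_ids = np.asarray(self.residue_ids, dtype=np.int64)
        self.molecule_ids = np.asarray(self.molecule_ids, dtype=np.int64)
        self.domain_labels = np.asarray(self.domain_labels, dtype=object)
        self.species = np.asarray(self.species, dtype=object)
        self.is_headgroup = np.asarray(self.is_headgroup, dtype=bool)
        self.masses = np.asarray(self.masses, dtype=np.float64)
        self.validate()

    @property
    def n_particles(self) -> int:
        return len(self.particle_names)

    @property
    def particle_ids(self) -> np.ndarray:
        return np.arange(self.n_particles)

    def validate(self) -> None:
        n = self.n_particles
        for name in ("residue_ids", "residue_names", "molecule_ids",
                     "domain_labels", "species", "is_headgroup", "masses"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"topology field {name!r} has wrong length")
        if np.any(self.masses <= 0):
            raise ValueError("masses must be strictly positive")
        is_lipid = np.isin(self.species, LIPID_SPECIES)
        if np.any(self.is_headgroup & ~is_lipid):
            raise ValueError("is_headgroup set on a non-lipid particle")
        if np.any(is_lipid & (self.domain_labels != Domain.LIPID.value)):
            raise ValueError("lipid particles must carry domain label LIPID")

    def __eq__(self, other) -> bool:
        if not isinstance(other, Topology):
            return NotImplemented
        return all(
            np.array_equal(getattr(self, f), getattr(other, f))
            for f in ("particle_names", "residue_ids", "residue_names",
                      "molecule_ids", "domain_labels", "species",
                      "is_headgroup", "masses")
        )


@dataclass
class Frame:
    """One snapshot: coordinates (nm), orthorhombic box lengths (nm), time (ns)."""

    coordinates: np.ndarray  # (n, 3)
    box: np.ndarray  # (3,)
    time: float = 0.0

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=np.float64)
        self.box = np.asarray(self.box, dtype=np.float64)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must have shape (n, 3)")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("box must be three strictly positive lengths")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates must be finite")


@dataclass
class Trajectory:
    topology: Topology
    frames: list = field(default_factory=list)

    def __post_init__(self):
        n = self.topology.n_particles
        for f in self.frames:
            if f.coordinates.shape[0] != n:
                raise ValueError(
                    f"frame has {f.coordinates.shape[0]} particles, "
                    f"topology has {n}")
        times = self.times
        if len(times) > 1 and np.any(np.diff(times) <= 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    def coordinates(self, indices=None) -> np.ndarray:
        """Stack coordinates as (n_frames, n_sel, 3)."""
        if indices is None:
            return np.stack([f.coordinates for f in self.frames])
        indices = np.asarray(indices)
        return np.stack([f.coordinates[indices] for f in self.frames])


@dataclass
class Selection:
    indices: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=np.int64)
        if len(np.unique(self.indices)) != len(self.indices):
            raise ValueError("selection contains duplicate indices")

    def __len__(self) -> int:
        return len(self.indices)


def min_image_displacement(a, b, box) -> np.ndarray:
    """Minimum-image displacement a - b for an orthorhombic box (broadcasts)."""
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    box = np.asarray(box, dtype=float)
    return d - box * np.round(d / box)


def min_image_distance(a, b, box) -> float:
    """Euclidean distance under the minimum-image convention."""
    box = np.asarray(box, dtype=float)
    if np.any(box <= 0):
        raise ValueError("box lengths must be positive")
    d = min_image_displacement(a, b, box)
    return float(np.linalg.norm(d, axis=-1)) if d.ndim == 1 else \
        np.linalg.norm(d, axis=-1)


def center_of_mass(frame: Frame, sel: Selection, topology: Topology,
                   mass_weighted: bool = True) -> np.ndarray:
    """Mass-weighted mean position of the selection (nm).

    With ``mass_weighted=False`` the plain centroid (bead-count weighting)
    is returned; with the uniform default bead mass the two coincide.
    """
    if len(sel) == 0:
        raise ValueError("center_of_mass of an empty selection")
    x = frame.coordinates[sel.indices]
    if not mass_weighted:
        return x.mean(axis=0)
    m = topology.masses[sel.indices]
    return (m[:, None] * x).sum(axis=0) / m.sum()


def select(topology: Topology, species=None, domain=None,
           residue_range=None, residue_ids=None, headgroup=None,
           label: str = "") -> Selection:
    """Select particles by conjunction of simple predicates.

    Parameters are combined with logical AND; ``None`` means "no
    constraint". ``residue_range`` is an inclusive (lo, hi) pair on the
    1-based residue ids preserved from the input file.
    """
    mask = np.ones(topology.n_particles, dtype=bool)
    if species is not None:
        vals = [species] if isinstance(species, (str, Species)) else species
        vals = [Species(v).value for v in vals]
        mask &= np.isin(topology.species, vals)
    if domain is not None:
        vals = [domain] if isinstance(domain, (str, Domain)) else domain
        vals = [Domain(v).value for v in vals]
        mask &= np.isin(topology.domain_labels, vals)
    if residue_range is not None:
        lo, hi = residue_range
        mask &= (topology.residue_ids >= lo) & (topology.residue_ids <= hi)
    if residue_ids is not None:
        mask &= np.isin(topology.residue_ids, np.asarray(list(residue_ids)))
    if headgroup is not None:
        mask &= topology.is_headgroup == bool(headgroup)
    idx = np.nonzero(mask)[0]
    if len(idx) == 0:
        warnings.warn(f"selection {label or '(unlabelled)'} is empty",
                      stacklevel=2)
    return Selection(indices=idx, label=label)
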