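"""Reading and writing structures, trajectories and annotation maps.

Standard formats (PDB, GRO, XTC, DCD) go through MDAnalysis; internally
everything is nanometres (PDB is Å on disk, converted at the boundary).
Species and domain assignment never comes from chemistry: a YAML map file
tells the reader which residue names are lipids (and which of their
particle names are headgroup beads), and which residue-id ranges belong
to which protein domain.

Map schema::

    species:
      POPC: {species: PC, headgroup: [PO4, NC3]}
      POP2: {species: PIP2, headgroup: [PO4, P1, P2]}
    domains:
      - {first: 590, last: 599, label: JM}
      - {first: 600, last: 699, label: NLOBE}

A residue whose name is in ``species`` is a lipid; otherwise its residue
id must fall in a ``domains`` range (protein). Anything else is an error
naming the residue.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import yaml

from .traj import (DEFAULT_BEAD_MASS, Domain, Frame, Species, Topology,
                   Trajectory)

__all__ = [
    "load_maps",
    "write_maps",
    "read_structure",
    "read_trajectory",
    "write_structure",
    "write_trajectory",
    "read_text_trajectory",
    "write_text_trajectory",
]

_ANGSTROM = 10.0  # nm -> Angstrom


class ParseError(ValueError):
    pass


def load_maps(path):
    """Load a species/domain map file; returns (species_map, domain_map)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return data.get("species", {}), data.get("domains", [])


def write_maps(path, species_map, domain_map) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"species": species_map, "domains": domain_map}, fh,
                       sort_keys=True)


def _domain_for_resid(resid: int, domain_map) -> str | None:
    for entry in domain_map:
        if entry["first"] <= resid <= entry["last"]:
            return Domain(entry["label"]).value
    return None


def _import_mda():
    import MDAnalysis as mda
    return mda


def _check_orthorhombic(dimensions, where: str) -> np.ndarray:
    if dimensions is None or np.all(dimensions[:3] == 0):
        raise ParseError(f"{where}: no periodic box information found")
    angles = dimensions[3:6]
    if np.any(np.abs(np.asarray(angles) - 90.0) > 1e-3):
        raise ParseError(
            f"{where}: triclinic boxes are unsupported (angles {angles})")
    return np.asarray(dimensions[:3], dtype=float) / _ANGSTROM


def read_structure(path, species_map, domain_map):
    """Read a PDB/GRO structure and annotate it via the maps.

    Returns (Topology, Frame) with coordinates in nm.
    """
    mda = _import_mda()
    path = Path(path)
    if isinstance(species_map, (str, Path)):
        species_map, domain_map = load_maps(species_map)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path))
    except Exception as exc:  # noqa: BLE001 - re-raise with context
        raise ParseError(f"cannot parse {path}: {exc}") from exc

    names, resids, resnames = [], [], []
    mol_ids, domains, species, heads = [], [], [], []
    lipid_mol = 0
    for res in u.residues:
        rname = str(res.resname).strip()
        rid = int(res.resid)
        if rname in species_map:
            entry = species_map[rname]
            sp = Species(entry["species"]).value
            headnames = set(entry.get("headgroup", []))
            lipid_mol += 1
            mol = -lipid_mol  # placeholder sign; fixed below
            for atom in res.atoms:
                names.append(str(atom.name).strip())
                resids.append(rid)
                resnames.append(rname)
                mol_ids.append(mol)
                domains.append(Domain.LIPID.value)
                species.append(sp)
                heads.append(str(atom.name).strip() in headnames)
        else:
            label = _domain_for_resid(rid, domain_map)
            if label is None:
                raise ParseError(
                    f"residue {rname} {rid} in {path.name} is not in the "
                    "species map and not covered by the domain map")
            for atom in res.atoms:
                names.append(str(atom.name).strip())
                resids.append(rid)
                resnames.append(rname)
                mol_ids.append(0)  # single protein chain
                domains.append(label)
                species.append(Species.PROTEIN.value)
                heads.append(False)
    # lipid molecule ids follow the protein chain id
    mol_ids = [(-m if m < 0 else m) for m in mol_ids]

    top = Topology(
        particle_names=np.array(names, dtype=object),
        residue_ids=np.array(resids),
        residue_names=np.array(resnames, dtype=object),
        molecule_ids=np.array(mol_ids),
        domain_labels=np.array(domains, dtype=object),
        species=np.array(species, dtype=object),
        is_headgroup=np.array(heads),
    )
    box = _check_orthorhombic(u.dimensions, str(path))
    frame = Frame(coordinates=u.atoms.positions / _ANGSTROM, box=box,
                  time=0.0)
    return top, frame


_READERS = {".xtc": "XTC", ".dcd": "DCD", ".pdb": "PDB"}


def read_trajectory(path, topology: Topology) -> Trajectory:
    """Read a multi-frame trajectory (XTC/DCD/multi-model PDB or the
    plain-text dialect) against an existing topology."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".txt", ".traj"):
        return read_text_trajectory(path, topology)
    if suffix not in _READERS:
        raise ParseError(f"unsupported trajectory format: {path.name}")
    mda = _import_mda()
    from MDAnalysis.coordinates.DCD import DCDReader
    from MDAnalysis.coordinates.PDB import PDBReader
    from MDAnalysis.coordinates.XTC import XTCReader
    reader_cls = {"XTC": XTCReader, "DCD": DCDReader, "PDB": PDBReader}[
        _READERS[suffix]]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reader = reader_cls(str(path))
        if reader.n_atoms != topology.n_particles:
            raise ParseError(
                f"{path.name}: expected {topology.n_particles} particles, "
                f"found {reader.n_atoms}")
        frames = []
        for ts in reader:
            box = _check_orthorhombic(ts.dimensions, f"{path.name} frame "
                                      f"{ts.frame}")
            frames.append(Frame(coordinates=ts.positions / _ANGSTROM,
                                box=box, time=float(ts.time) / 1000.0))
        reader.close()
    return Trajectory(topology=topology, frames=frames)


def _residue_blocks(topology: Topology):
    """Contiguous (start, stop) runs sharing residue id and name."""
    rid, rname = topology.residue_ids, topology.residue_names
    breaks = [0]
    for i in range(1, topology.n_particles):
        if rid[i] != rid[i - 1] or rname[i] != rname[i - 1]:
            breaks.append(i)
    breaks.append(topology.n_particles)
    return list(zip(breaks[:-1], breaks[1:]))


def _make_universe(topology: Topology, frame: Frame):
    mda = _import_mda()
    blocks = _residue_blocks(topology)
    resindex = np.zeros(topology.n_particles, dtype=int)
    for k, (a, b) in enumerate(blocks):
        resindex[a:b] = k
    u = mda.Universe.empty(
        n_atoms=topology.n_particles, n_residues=len(blocks),
        atom_resindex=resindex, n_segments=1, trajectory=True)
    u.add_TopologyAttr("names", [str(s) for s in topology.particle_names])
    u.add_TopologyAttr("resids",
                       [int(topology.residue_ids[a]) for a, _ in blocks])
    u.add_TopologyAttr("resnames",
                       [str(topology.residue_names[a]) for a, _ in blocks])
    u.add_TopologyAttr("masses", topology.masses)
    u.atoms.positions = frame.coordinates * _ANGSTROM
    u.dimensions = np.concatenate([frame.box * _ANGSTROM, [90.0, 90.0, 90.0]])
    return u


def write_structure(path, topology: Topology, frame: Frame) -> None:
    """Write a single-frame GRO (nm) or PDB (Å) structure."""
    path = Path(path)
    u = _make_universe(topology, frame)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def write_trajectory(path, traj: Trajectory) -> None:
    """Write frames to XTC/DCD (via MDAnalysis) or the text dialect."""
    path = Path(path)
    if path.suffix.lower() in (".txt", ".traj"):
        write_text_trajectory(path, traj)
        return
    mda = _import_mda()
    u = _make_universe(traj.topology, traj.frames[0])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=traj.topology.n_particles) as w:
            for i, fr in enumerate(traj.frames):
                u.atoms.positions = fr.coordinates * _ANGSTROM
                u.dimensions = np.concatenate(
                    [fr.box * _ANGSTROM, [90.0, 90.0, 90.0]])
                u.trajectory.ts.time = fr.time * 1000.0  # ps
                u.trajectory.ts.frame = i
                w.write(u.atoms)


# ---------------------------------------------------------------------------
# plain-text one-frame-per-block dialect (fixtures; byte-stable round trip)

_TEXT_HEADER = "# membmode trajectory v1"


def write_text_trajectory(path, traj: Trajectory) -> None:
    with open(path, "w") as fh:
        fh.write(f"{_TEXT_HEADER}\n")
        fh.write(f"nparticles {traj.topology.n_particles}\n")
        for fr in traj.frames:
            fh.write("frame time_ns %.6f box_nm %.6f %.6f %.6f\n"
                     % (fr.time, *fr.box))
            for x, y, z in fr.coordinates:
                fh.write("%.6f %.6f %.6f\n" % (x, y, z))


def read_text_trajectory(path, topology: Topology) -> Trajectory:
    frames = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0] != _TEXT_HEADER:
        raise ParseError(f"{path}: line 1: not a membmode text trajectory")
    if not lines[1].startswith("nparticles "):
        raise ParseError(f"{path}: line 2: missing particle count")
    n = int(lines[1].split()[1])
    if n != topology.n_particles:
        raise ParseError(f"{path}: expected {topology.n_particles} "
                         f"particles, found {n}")
    i = 2
    while i < len(lines):
        parts = lines[i].split()
        if parts[0] != "frame":
            raise ParseError(f"{path}: line {i + 1}: expected frame header")
        time = float(parts[2])
        box = np.array([float(v) for v in parts[4:7]])
        coords = np.empty((n, 3))
        for j in range(n):
            try:
                coords[j] = [float(v) for v in lines[i + 1 + j].split()]
            except (ValueError, IndexError) as exc:
                raise ParseError(
                    f"{path}: line {i + 2 + j}: bad coordinate line") from exc
        frames.append(Frame(coordinates=coords, box=box, time=time))
        i += 1 + n
    return Trajectory(topology=topology, frames=frames)
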