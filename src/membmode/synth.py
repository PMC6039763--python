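"""Synthetic Brownian-dynamics generator with planted ground truth.

The generator emulates, at toy scale, the encounter of a peripheral
kinase domain with a PIP-containing bilayer: a rigid two-lobe protein
(fused spherical bead shells for the N- and C-lobes) carrying charged
surface patches diffuses over a flat membrane of laterally diffusing
lipids. Patch P1 (residues 609/615/617) and P2 (629/633/638/639) sit on
the N-lobe outer face tilted toward the membrane; a third patch (CFACE)
sits on the underside of the C-lobe, so that P1/P2-driven binding tilts
the C-lobe away from the bilayer (mode 1 geometry) while CFACE-driven
binding presents the C-lobe (mode 2 geometry). Sign-flipping the P1/P2
weights emulates the charge-reversal (aspartate) mutants. An optional
harmonic tether between a JM-anchor bead and a fixed membrane anchor
emulates the TM+JM-tethered construct.

Dynamics are overdamped Langevin: per step, displacement =
sqrt(2 D dt) xi + D F dt (kT = 1, forces in kT/nm), with lipids
confined to the membrane plane (periodic in xy) and the protein moving
and rotating as a rigid body above an impenetrable membrane surface.
Attraction between patch beads and lipid headgroups is a smooth
truncated well: full depth epsilon * patch_weight(species) inside half
the interaction range, cosine-ramped to zero at the interaction range
(a flat-bottomed core keeps the nominal depth effective at the bead
contact distances the excluded-volume floor allows). Each lipid is a
two-bead column (headgroup at z = 0, distal bead at z = -3.8 nm), so
the membrane COM sits at the bilayer midplane and the protein-membrane
COM separation of a bound protein falls in the 4-5 nm band
characteristic of a stably bound kinase-sized domain. Identical parameters and seed
give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .orient import _runs
from .traj import (Domain, Frame, Selection, Species, Topology, Trajectory)

__all__ = [
    "TetherParams",
    "SyntheticParams",
    "GroundTruth",
    "ProteinModel",
    "build_protein",
    "simulate_encounter",
    "simulate_membrane_only",
    "ground_truth_report",
    "species_map_for_generator",
    "domain_map_for_generator",
]

# membrane geometry (nm): every lipid is a two-bead column with its
# headgroup in the interaction plane at z = 0 and a distal bead at the
# far side of the bilayer, putting the membrane COM at z = -1.9
_Z_HEAD = 0.0
_Z_TAIL = -3.8
_Z_FLOOR = 0.3  # hard floor for protein beads above the headgroup plane

_LOBE_RADIUS = 1.4
_LOBE_SEP = 2.6  # distance between lobe centres

_SPECIES_ORDER = ("PC", "PS", "PIP2", "PIP3")
_RESNAMES = {"PC": "POPC", "PS": "POPS", "PIP2": "POP2", "PIP3": "POP3"}

P1_RESIDUES = (609, 615, 617)
P2_RESIDUES = (629, 633, 638, 639)
CFACE_RESIDUES = (712, 716, 720, 724)


@dataclass
class TetherParams:
    enabled: bool = False
    k: float = 5.0  # kT/nm^2
    rest_length: float = 3.0  # nm
    anchor: tuple | None = None  # (x, y) on the membrane plane


@dataclass
class SyntheticParams:
    box: tuple = (15.0, 15.0, 30.0)
    n_lipids: int = 360
    composition: dict = field(default_factory=lambda: {
        "PC": 0.90, "PS": 0.05, "PIP2": 0.05, "PIP3": 0.0})
    D_species: dict = field(default_factory=lambda: {
        "PC": 0.05, "PS": 0.05, "PIP2": 0.05, "PIP3": 0.05})
    D_protein_trans: float = 0.03  # nm^2/ns
    D_protein_rot: float = 0.01  # rad^2/ns
    patch_weights: dict = field(default_factory=lambda: {
        "P1": {"PS": 0.8, "PIP2": 2.5, "PIP3": 2.5},
        "P2": {"PS": 0.5, "PIP2": 1.5, "PIP3": 1.5},
        "CFACE": {"PS": 0.3, "PIP2": 1.0, "PIP3": 1.0},
    })
    patch_defs: dict = field(default_factory=lambda: {
        "P1": list(P1_RESIDUES), "P2": list(P2_RESIDUES),
        "CFACE": list(CFACE_RESIDUES)})
    interaction_range: float = 1.2  # nm
    epsilon: float = 3.0  # kT
    tether: TetherParams = field(default_factory=TetherParams)
    dt: float = 0.05  # ns
    n_steps: int = 20000
    save_every: int = 20
    seed: int = 0
    start_height: float = 8.0  # initial protein COM above the headgroup plane
    start_engaged: str | None = None  # plant this patch at the membrane
    bound_threshold: float = 5.0  # dz threshold for ground-truth bound frames

    def validate(self) -> None:
        comp = sum(self.composition.get(s, 0.0) for s in _SPECIES_ORDER)
        if abs(comp - 1.0) > 1e-9:
            raise ValueError(f"composition sums to {comp}, not 1")
        if any(v < 0 for v in self.D_species.values()) or \
                self.D_protein_trans < 0 or self.D_protein_rot < 0:
            raise ValueError("diffusion coefficients must be >= 0")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_lipids < 1 or self.n_steps < 1 or self.save_every < 1:
            raise ValueError("n_lipids, n_steps, save_every must be >= 1")
        model = build_protein()
        for patch, resids in self.patch_defs.items():
            missing = set(resids) - set(model.residue_ids.tolist())
            if missing:
                raise ValueError(
                    f"patch {patch} residues {sorted(missing)} do not "
                    "exist in the generated protein model")

    # -- convenience scenario constructors -------------------------------
    @classmethod
    def wildtype(cls, seed: int = 0, **overrides) -> "SyntheticParams":
        """Wild-type patch weights; kwargs override any field."""
        return replace(cls(seed=seed), **overrides)

    @classmethod
    def p1_only(cls, seed: int = 0, **overrides) -> "SyntheticParams":
        """Strong attraction on P1 only (P2 and the C-lobe face off)."""
        p = cls(seed=seed)
        p.patch_weights = {"P1": {"PS": 0.8, "PIP2": 4.0, "PIP3": 4.0},
                           "P2": {}, "CFACE": {}}
        p.start_engaged = "P1"
        return replace(p, **overrides)

    @classmethod
    def mutant_p1p2(cls, seed: int = 0, **overrides) -> "SyntheticParams":
        """Charge-reversal emulation: P1 and P2 weights sign-flipped."""
        p = cls(seed=seed)
        pw = {k: dict(v) for k, v in p.patch_weights.items()}
        for patch in ("P1", "P2"):
            pw[patch] = {sp: -w for sp, w in pw[patch].items()}
        p.patch_weights = pw
        return replace(p, **overrides)


@dataclass
class GroundTruth:
    """Planted truth recorded every saved frame."""

    bound_intervals: list  # (start, stop) half-open frame intervals
    engaged_patch: list  # per-frame: NONE/P1/P2/P1P2/CFACE
    recruited_ids: list  # per-frame sorted tuple of lipid molecule ids
    D_planted: dict  # species -> nm^2/ns
    dz: np.ndarray = None  # per-frame protein-membrane COM |dz|
    unwrapped_xy: np.ndarray = None  # (n_frames, n_lipids, 2), no PBC wrap


@dataclass
class ProteinModel:
    body_coords: np.ndarray  # (n, 3) COM-centred body frame
    names: np.ndarray
    residue_ids: np.ndarray
    domain_labels: np.ndarray
    patch_indices: dict  # patch -> particle indices
    jm_index: int


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(1.0 - z ** 2)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


def build_protein() -> ProteinModel:
    """Deterministic toy rigid body: two fused spherical bead shells
    (N-lobe, C-lobe), P1/P2 patch beads on the N-lobe face tilted toward
    the membrane, a C-lobe underside patch, an activation-loop marker in
    the inter-lobe cleft and a JM-anchor bead."""
    cN = np.array([-_LOBE_SEP / 2, 0.0, 0.0])
    cC = np.array([+_LOBE_SEP / 2, 0.0, 0.0])
    coords, names, resids, domains = [], [], [], []

    def add(xyz, name, rid, dom):
        coords.append(np.asarray(xyz, dtype=float))
        names.append(name)
        resids.append(rid)
        domains.append(dom)

    def shell(centre, other, rid0, skip, dom):
        rid = rid0
        for u in _fibonacci_sphere(26):
            p = centre + _LOBE_RADIUS * u
            if np.linalg.norm(p - other) < _LOBE_RADIUS:  # inside partner
                continue
            while rid in skip:
                rid += 1
            add(p, "BB", rid, dom)
            rid += 1

    shell(cN, cC, 600, set(P1_RESIDUES) | set(P2_RESIDUES),
          Domain.NLOBE.value)
    shell(cC, cN, 700, set(CFACE_RESIDUES), Domain.CLOBE.value)

    p1_dirs = [(-0.55, -0.25, -0.80), (-0.55, 0.0, -0.80),
               (-0.55, 0.25, -0.80)]
    for rid, u in zip(P1_RESIDUES, p1_dirs):
        add(cN + _LOBE_RADIUS * _unit(u), "P1", rid, Domain.NLOBE.value)
    p2_dirs = [(-0.25, -0.30, -0.92), (-0.25, -0.10, -0.92),
               (-0.25, 0.10, -0.92), (-0.25, 0.30, -0.92)]
    for rid, u in zip(P2_RESIDUES, p2_dirs):
        add(cN + _LOBE_RADIUS * _unit(u), "P2", rid, Domain.NLOBE.value)
    cf_dirs = [(0.15, -0.30, -0.95), (0.15, -0.10, -0.95),
               (0.15, 0.10, -0.95), (0.15, 0.30, -0.95)]
    for rid, u in zip(CFACE_RESIDUES, cf_dirs):
        add(cC + _LOBE_RADIUS * _unit(u), "CF", rid, Domain.CLOBE.value)
    # activation-loop marker beads in the inter-lobe cleft
    add((0.0, -0.4, 1.2), "AL", 770, Domain.ACTLOOP.value)
    add((0.0, 0.4, 1.2), "AL", 771, Domain.ACTLOOP.value)
    # JM anchor bead on the N-lobe outer face
    add(cN + _LOBE_RADIUS * _unit((-0.85, 0.0, -0.35)), "JMB", 590,
        Domain.JM.value)

    coords = np.array(coords)
    coords -= coords.mean(axis=0)
    resids = np.array(resids)
    patch_indices = {
        "P1": np.nonzero(np.isin(resids, P1_RESIDUES))[0],
        "P2": np.nonzero(np.isin(resids, P2_RESIDUES))[0],
        "CFACE": np.nonzero(np.isin(resids, CFACE_RESIDUES))[0],
    }
    return ProteinModel(
        body_coords=coords, names=np.array(names, dtype=object),
        residue_ids=resids, domain_labels=np.array(domains, dtype=object),
        patch_indices=patch_indices,
        jm_index=int(np.nonzero(resids == 590)[0][0]))


def largest_remainder_counts(composition: dict, n: int) -> dict:
    """Deterministic integer species counts with exact total n."""
    fracs = [composition.get(s, 0.0) for s in _SPECIES_ORDER]
    raw = [f * n for f in fracs]
    counts = [int(math.floor(r)) for r in raw]
    short = n - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: (raw[i] - counts[i], i),
                   reverse=True)
    for i in order[:short]:
        counts[i] += 1
    return dict(zip(_SPECIES_ORDER, counts))


def _lipid_species_array(params: SyntheticParams) -> np.ndarray:
    counts = largest_remainder_counts(params.composition, params.n_lipids)
    out = []
    for sp in _SPECIES_ORDER:
        out.extend([sp] * counts[sp])
    return np.array(out, dtype=object)


def _make_topology(params: SyntheticParams, model: ProteinModel,
                   lip_species: np.ndarray) -> Topology:
    n_prot = len(model.body_coords)
    n_lip = params.n_lipids
    names = list(model.names)
    resids = list(model.residue_ids)
    resnames = ["KIN"] * n_prot
    mols = [0] * n_prot
    domains = list(model.domain_labels)
    species = [Species.PROTEIN.value] * n_prot
    heads = [False] * n_prot
    for i in range(n_lip):
        sp = str(lip_species[i])
        for name, is_head in (("PO4", True), ("C1A", False)):
            names.append(name)
            resids.append(1000 + i)
            resnames.append(_RESNAMES[sp])
            mols.append(1 + i)
            domains.append(Domain.LIPID.value)
            species.append(sp)
            heads.append(is_head)
    return Topology(
        particle_names=np.array(names, dtype=object),
        residue_ids=np.array(resids),
        residue_names=np.array(resnames, dtype=object),
        molecule_ids=np.array(mols),
        domain_labels=np.array(domains, dtype=object),
        species=np.array(species, dtype=object),
        is_headgroup=np.array(heads),
    )


def _lipid_bead_coords(lip_xy: np.ndarray) -> np.ndarray:
    """(n_lipids * 2, 3) bead coordinates, head then tail per molecule."""
    n = len(lip_xy)
    out = np.empty((2 * n, 3))
    out[0::2, :2] = lip_xy
    out[0::2, 2] = _Z_HEAD
    out[1::2, :2] = lip_xy
    out[1::2, 2] = _Z_TAIL
    return out


def _engagement_label(engaged: set) -> str:
    if "P1" in engaged and "P2" in engaged:
        return "P1P2"
    if "P1" in engaged:
        return "P1"
    if "P2" in engaged:
        return "P2"
    if "CFACE" in engaged:
        return "CFACE"
    return "NONE"


def simulate_encounter(params: SyntheticParams) -> tuple[Trajectory,
                                                         GroundTruth]:
    """Run the rigid-protein / diffusing-membrane Brownian dynamics."""
    params.validate()
    model = build_protein()
    rng = np.random.default_rng(params.seed)
    box = np.asarray(params.box, dtype=float)
    box_xy = box[:2]
    dt = params.dt
    rc = params.interaction_range
    ceiling = box[2] - 10.0  # keeps the protein out of binding range of
    # the membrane's periodic image through the top face
    if ceiling <= params.start_height:
        ceiling = box[2] - 4.0

    lip_species = _lipid_species_array(params)
    n_lip = params.n_lipids
    lip_xy = rng.uniform(0.0, 1.0, size=(n_lip, 2)) * box_xy
    D_lip = np.array([params.D_species.get(str(s), 0.0)
                      for s in lip_species])

    # per-patch, per-lipid attraction weights
    patch_w = {}
    for patch, wmap in params.patch_weights.items():
        patch_w[patch] = np.array([wmap.get(str(s), 0.0)
                                   for s in lip_species])

    B = model.body_coords
    q = rng.normal(size=4)
    R = Rotation.from_quat(q / np.linalg.norm(q)).as_matrix()
    com = np.array([box[0] / 2, box[1] / 2, params.start_height])
    if params.start_engaged is not None:
        # plant engagement: orient the named patch toward the membrane
        # (random azimuth) and start at contact height
        idx = model.patch_indices[params.start_engaged]
        u = _unit(B[idx].mean(axis=0))
        axis = np.cross(u, [0.0, 0.0, -1.0])
        norm = np.linalg.norm(axis)
        angle = math.acos(np.clip(-u[2], -1.0, 1.0))
        R0 = (Rotation.from_rotvec(axis / norm * angle).as_matrix()
              if norm > 1e-12 else np.eye(3))
        phi = rng.uniform(0.0, 2.0 * math.pi)
        R = Rotation.from_euler("z", phi).as_matrix() @ R0
        com[2] = _Z_FLOOR + 0.1 - (B @ R.T)[:, 2].min()
    anchor_xy = (np.array(params.tether.anchor, dtype=float)
                 if params.tether.anchor is not None
                 else box_xy / 2.0)

    # raise the start point if a random orientation pokes through the floor
    minz = (B @ R.T)[:, 2].min() + com[2]
    if minz < _Z_FLOOR:
        com[2] += _Z_FLOOR - minz

    Dp, Dr = params.D_protein_trans, params.D_protein_rot
    sig_t = math.sqrt(2.0 * Dp * dt)
    sig_r = math.sqrt(2.0 * Dr * dt)
    sig_l = np.sqrt(2.0 * D_lip * dt)[:, None]

    mem_com_z = 0.5 * (_Z_HEAD + _Z_TAIL)

    frames, dz_list, engaged_list, recruited_list = [], [], [], []
    heads_z = np.full(n_lip, _Z_HEAD)

    def record(step):
        world = B @ R.T + com
        coords = np.concatenate([world, _lipid_bead_coords(lip_xy)])
        frames.append(Frame(coordinates=coords, box=box.copy(),
                            time=step * dt))
        dzv = com[2] - mem_com_z
        dzv = abs(dzv - box[2] * round(dzv / box[2]))
        dz_list.append(dzv)
        engaged = set()
        recruited = set()
        for patch, idx in model.patch_indices.items():
            ppos = world[idx]
            dxy = lip_xy[None, :, :] - ppos[:, None, :2]
            dxy -= box_xy * np.round(dxy / box_xy)
            dzc = heads_z[None, :] - ppos[:, None, 2]
            r = np.sqrt((dxy ** 2).sum(axis=2) + dzc ** 2)
            within = r < rc
            if within.any():
                w = patch_w.get(patch, np.zeros(n_lip))
                if (within & (w > 0)[None, :]).any():
                    engaged.add(patch)
                recruited.update(
                    (1 + np.nonzero(within.any(axis=0))[0]).tolist())
        engaged_list.append(_engagement_label(engaged))
        recruited_list.append(tuple(sorted(recruited)))

    record(0)
    for step in range(1, params.n_steps + 1):
        world_patch = {p: B[idx] @ R.T + com
                       for p, idx in model.patch_indices.items()}
        F = np.zeros(3)
        tau = np.zeros(3)
        F_lip = np.zeros((n_lip, 2))
        r0 = 0.35 * rc  # flat-bottomed core; cosine ramp from r0 to rc
        ramp = rc - r0
        pref = params.epsilon * math.pi / (2.0 * ramp)
        for patch, ppos in world_patch.items():
            w = patch_w.get(patch)
            if w is None or not np.any(w):
                continue
            active = np.nonzero(w)[0]
            dxy = lip_xy[active][None, :, :] - ppos[:, None, :2]
            dxy -= box_xy * np.round(dxy / box_xy)
            dzc = heads_z[active][None, :] - ppos[:, None, 2]
            r2 = (dxy ** 2).sum(axis=2) + dzc ** 2
            mask = (r2 < rc * rc) & (r2 > r0 * r0)
            if not mask.any():
                continue
            r = np.sqrt(np.maximum(r2, 1e-12))
            fmag = np.where(mask,
                            pref * w[active][None, :] *
                            np.sin(math.pi * (r - r0) / ramp) / r, 0.0)
            fx = fmag * dxy[:, :, 0]
            fy = fmag * dxy[:, :, 1]
            fz = fmag * dzc
            fb = np.stack([fx.sum(axis=1), fy.sum(axis=1),
                           fz.sum(axis=1)], axis=1)
            F += fb.sum(axis=0)
            tau += np.cross(ppos - com, fb).sum(axis=0)
            np.add.at(F_lip[:, 0], active, -fx.sum(axis=0))
            np.add.at(F_lip[:, 1], active, -fy.sum(axis=0))
        if params.tether.enabled:
            jm = B[model.jm_index] @ R.T + com
            dxy = anchor_xy - jm[:2]
            dxy -= box_xy * np.round(dxy / box_xy)
            delta = np.array([dxy[0], dxy[1], 0.0 - jm[2]])
            dist = np.linalg.norm(delta)
            if dist > 1e-12:
                ft = params.tether.k * (dist - params.tether.rest_length) \
                    * delta / dist
                F += ft
                tau += np.cross(jm - com, ft)

        com = com + Dp * F * dt + sig_t * rng.normal(size=3)
        omega = Dr * tau * dt + sig_r * rng.normal(size=3)
        R = Rotation.from_rotvec(omega).as_matrix() @ R
        lip_xy = lip_xy + D_lip[:, None] * F_lip * dt \
            + sig_l * rng.normal(size=(n_lip, 2))
        lip_xy = np.mod(lip_xy, box_xy)
        com[:2] = np.mod(com[:2], box_xy)
        if com[2] > ceiling:
            com[2] = 2.0 * ceiling - com[2]
        minz = (B @ R.T)[:, 2].min() + com[2]
        if minz < _Z_FLOOR:
            com[2] += _Z_FLOOR - minz
        if step % 200 == 0:  # fight orthogonality drift
            U, _, Vt = np.linalg.svd(R)
            R = U @ Vt
        if step % params.save_every == 0:
            record(step)

    dz = np.array(dz_list)
    gt = GroundTruth(
        bound_intervals=_runs(dz <= params.bound_threshold),
        engaged_patch=engaged_list,
        recruited_ids=recruited_list,
        D_planted=dict(params.D_species),
        dz=dz,
    )
    top = _make_topology(params, model, lip_species)
    return Trajectory(topology=top, frames=frames), gt


def simulate_membrane_only(params: SyntheticParams) -> tuple[Trajectory,
                                                             GroundTruth]:
    """Protein-free membrane: free 2-D diffusion at the planted
    per-species coefficients; saved-frame displacements are drawn
    directly (statistically identical to stepwise sampling)."""
    params.validate()
    model = build_protein()  # only for topology symmetry; not included
    del model
    rng = np.random.default_rng(params.seed)
    box = np.asarray(params.box, dtype=float)
    box_xy = box[:2]
    lip_species = _lipid_species_array(params)
    n_lip = params.n_lipids
    lip_xy = rng.uniform(0.0, 1.0, size=(n_lip, 2)) * box_xy
    D_lip = np.array([params.D_species.get(str(s), 0.0)
                      for s in lip_species])
    n_saved = params.n_steps // params.save_every
    dt_frame = params.dt * params.save_every
    sig = np.sqrt(2.0 * D_lip * dt_frame)[:, None]

    top = _lipids_only_topology(params, lip_species)
    frames = []
    unwrapped = np.empty((n_saved + 1, n_lip, 2))
    pos = lip_xy.copy()
    unwrapped[0] = pos
    frames.append(Frame(coordinates=_lipid_bead_coords(
        np.mod(pos, box_xy)), box=box.copy(), time=0.0))
    for k in range(1, n_saved + 1):
        pos = pos + sig * rng.normal(size=(n_lip, 2))
        unwrapped[k] = pos
        frames.append(Frame(coordinates=_lipid_bead_coords(
            np.mod(pos, box_xy)), box=box.copy(), time=k * dt_frame))
    gt = GroundTruth(bound_intervals=[], engaged_patch=["NONE"] *
                     (n_saved + 1), recruited_ids=[()] * (n_saved + 1),
                     D_planted=dict(params.D_species),
                     dz=np.full(n_saved + 1, np.inf),
                     unwrapped_xy=unwrapped)
    return Trajectory(topology=top, frames=frames), gt


def _lipids_only_topology(params: SyntheticParams,
                          lip_species: np.ndarray) -> Topology:
    names, resids, resnames, mols, domains, species, heads = \
        [], [], [], [], [], [], []
    for i in range(params.n_lipids):
        sp = str(lip_species[i])
        for name, is_head in (("PO4", True), ("C1A", False)):
            names.append(name)
            resids.append(1000 + i)
            resnames.append(_RESNAMES[sp])
            mols.append(1 + i)
            domains.append(Domain.LIPID.value)
            species.append(sp)
            heads.append(is_head)
    return Topology(
        particle_names=np.array(names, dtype=object),
        residue_ids=np.array(resids),
        residue_names=np.array(resnames, dtype=object),
        molecule_ids=np.array(mols),
        domain_labels=np.array(domains, dtype=object),
        species=np.array(species, dtype=object),
        is_headgroup=np.array(heads),
    )


def ground_truth_report(gt: GroundTruth) -> dict:
    """Deterministic aggregation of a GroundTruth record."""
    n = len(gt.engaged_patch)
    bound = sum(b - a for a, b in gt.bound_intervals)
    labels = [l for l in gt.engaged_patch if l != "NONE"]
    if labels:
        uniq = sorted(set(labels))
        dominant = max(uniq, key=lambda u: (labels.count(u), u))
    else:
        dominant = "NONE"
    mean_recruited = (sum(len(r) for r in gt.recruited_ids) / n
                      if n else 0.0)
    return {
        "bound_fraction": bound / n if n else 0.0,
        "dominant_engaged_patch": dominant,
        "mean_recruited_count": mean_recruited,
        "D_planted": dict(gt.D_planted),
    }


def species_map_for_generator() -> dict:
    return {resname: {"species": sp, "headgroup": ["PO4"]}
            for sp, resname in _RESNAMES.items()}


def domain_map_for_generator() -> list:
    return [
        {"first": 585, "last": 599, "label": "JM"},
        {"first": 600, "last": 699, "label": "NLOBE"},
        {"first": 700, "last": 769, "label": "CLOBE"},
        {"first": 770, "last": 779, "label": "ACTLOOP"},
    ]
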