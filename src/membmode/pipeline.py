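"""One-config pipeline: simulate -> orient -> contacts -> clusters ->
diffusion -> report.

The configuration is a YAML mapping with three blocks::

    seed: 7
    simulate: true            # or false with explicit input paths
    synthetic: {...}          # SyntheticParams overrides (optional)
    inputs:                   # used when simulate is false
      structure: sys.gro
      trajectory: traj.xtc
      maps: maps.yaml
    analysis:
      cutoff: 0.8             # nm, contact cutoff
      bound_threshold: 5.0    # nm, dz threshold for the bound state
      min_dwell: 10           # frames
      clobe_contact_threshold: 0.25
      rzz_bin: 0.05
      d_bin: 0.1
      cluster_species: [PIP2]
      gap_tolerance: 1
      fit_window: [0.1, 0.5]
      all_frames: false       # count distributions over all frames

Rerunning the same config into a fresh directory reproduces every
output byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import clusters as cl
from . import contacts as ct
from . import io as mio
from . import orient as orm
from . import synth
from .traj import Domain, Species, select

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("membmode")

_ANALYSIS_DEFAULTS = {
    "cutoff": 0.8,
    "bound_threshold": 5.0,
    "min_dwell": 10,
    "clobe_contact_threshold": 0.25,
    "rzz_bin": 0.05,
    "d_bin": 0.1,
    "cluster_species": ["PIP2"],
    "gap_tolerance": 1,
    "fit_window": [0.1, 0.5],
    "all_frames": False,
}


@dataclasses.dataclass
class RunConfig:
    seed: int = 0
    simulate: bool = True
    synthetic: dict = dataclasses.field(default_factory=dict)
    inputs: dict = dataclasses.field(default_factory=dict)
    analysis: dict = dataclasses.field(default_factory=dict)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise PipelineError("config", f"unknown config keys: "
                                f"{sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        if not self.simulate:
            for key in ("structure", "trajectory", "maps"):
                p = self.inputs.get(key)
                if p is None or not Path(p).exists():
                    raise PipelineError(
                        "config", f"input path for {key!r} missing or does "
                        f"not exist: {p}")
        unknown = set(self.analysis) - set(_ANALYSIS_DEFAULTS)
        if unknown:
            raise PipelineError("config", "unknown analysis keys: "
                                f"{sorted(unknown)}")

    def analysis_params(self) -> dict:
        out = dict(_ANALYSIS_DEFAULTS)
        out.update(self.analysis)
        return out


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {message}")


def _stage(name):
    def deco(fn):
        def wrapper(*a, **k):
            log.info("stage %s", name)
            try:
                return fn(*a, **k)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001
                raise PipelineError(name, str(exc)) from exc
        return wrapper
    return deco


@_stage("simulate")
def _simulate(cfg: RunConfig, outdir: Path):
    syn = dict(cfg.synthetic)
    tether = syn.pop("tether", None)
    params = synth.SyntheticParams(seed=cfg.seed, **syn)
    if tether:
        params.tether = synth.TetherParams(**tether)
    traj, gt = synth.simulate_encounter(params)
    mio.write_structure(outdir / "system.gro", traj.topology,
                        traj.frames[0])
    mio.write_trajectory(outdir / "trajectory.xtc", traj)
    mio.write_maps(outdir / "maps.yaml", synth.species_map_for_generator(),
                   synth.domain_map_for_generator())
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(synth.ground_truth_report(gt), fh, sort_keys=True,
                  indent=2)
    return gt


@_stage("read")
def _read(structure, trajectory, maps):
    species_map, domain_map = mio.load_maps(maps)
    top, _ = mio.read_structure(structure, species_map, domain_map)
    return mio.read_trajectory(trajectory, top)


@_stage("orient")
def _orient(traj, ap, outdir: Path):
    top = traj.topology
    protein = select(top, species=Species.PROTEIN, label="protein")
    membrane = select(top, domain=Domain.LIPID, label="membrane")
    heads = select(top, domain=Domain.LIPID, headgroup=True, label="heads")
    nlobe = select(top, domain=Domain.NLOBE, label="nlobe")
    clobe = select(top, domain=Domain.CLOBE, label="clobe")
    ref = orm.ReferencePose(
        coordinates=traj.frames[0].coordinates[protein.indices],
        selection=protein)
    series = orm.orientation_series(traj, protein, membrane, ref)
    rzz_edges = np.arange(-1.0, 1.0 + 1e-12, ap["rzz_bin"])
    dmax = series.frame["dz"].max()
    d_edges = np.arange(0.0, dmax + 2 * ap["d_bin"], ap["d_bin"])
    density = orm.density_map(series, rzz_edges, d_edges)
    bound = orm.classify_bound(series, ap["bound_threshold"],
                               ap["min_dwell"])
    modes = orm.classify_mode(
        traj, nlobe, clobe, heads, bound, cutoff=ap["cutoff"],
        clobe_contact_threshold=ap["clobe_contact_threshold"])
    out = series.frame.copy()
    out["mode"] = [m.value for m in modes.labels]
    out.to_csv(outdir / "orientation_series.csv", index=False,
               float_format="%.6f")
    density.to_frame().to_csv(outdir / "orientation_density.csv",
                              index=False, float_format="%.6g")
    n_bound = int(sum(b - a for a, b in bound))
    labels = [m.value for m in modes.labels]
    return {
        "bound_intervals": [[int(a), int(b)] for a, b in bound],
        "bound_fraction": n_bound / traj.n_frames,
        "dominant_mode": modes.dominant.value,
        "mode1_frames": labels.count("MODE1"),
        "mode2_frames": labels.count("MODE2"),
        "mean_dz_bound": (float(np.mean([
            series.frame["dz"].iloc[a:b].mean() for a, b in bound]))
            if bound else None),
    }, bound


@_stage("contacts")
def _contacts(traj, ap, outdir: Path):
    top = traj.topology
    protein = select(top, species=Species.PROTEIN, label="protein")
    counts, rids, species = ct.contact_counts(traj, protein,
                                              cutoff=ap["cutoff"])
    profile = ct.normalized_contact_profile(counts, rids, species,
                                            cutoff=ap["cutoff"])
    df = profile.to_frame(top)
    df.to_csv(outdir / "contact_profile.csv", index=False,
              float_format="%.6f")
    top5 = {}
    for j, sp in enumerate(species):
        order = np.argsort(profile.normalized[:, j])[::-1][:5]
        top5[sp] = [int(profile.residues[i]) for i in order
                    if profile.normalized[i, j] > 0]
    return {"top5_residues": top5}


@_stage("clusters")
def _clusters(traj, ap, bound, outdir: Path):
    top = traj.topology
    protein = select(top, species=Species.PROTEIN, label="protein")
    out = {}
    for sp in ap["cluster_species"]:
        if not np.any(top.species == sp):
            continue
        tc = cl.lipid_timecourse(traj, protein, sp, cutoff=ap["cutoff"])
        counts = tc.counts()
        np.savetxt(outdir / f"counts_{sp}.csv", counts, fmt="%d",
                   header="interacting_count", comments="")
        np.savetxt(outdir / f"timecourse_{sp}.csv",
                   tc.matrix.astype(int), fmt="%d", delimiter=",")
        intervals = None if ap["all_frames"] else bound
        try:
            fit = cl.count_distribution_fit(counts, intervals)
            out[sp] = {"mean": fit.mean, "sd": fit.sd, "n": fit.n}
        except ValueError:
            out[sp] = {"mean": None, "sd": None, "n": 0}
        res = cl.residence_times(tc, gap_tolerance=ap["gap_tolerance"])
        res_out = res.copy()
        res_out["dwells"] = res_out["dwells"].map(
            lambda d: ";".join(map(str, d)))
        res_out.to_csv(outdir / f"residence_{sp}.csv", index=False)
        out[sp]["n_persistent"] = int((res["label"] == "persistent").sum())
    return {"interacting_counts": out}


@_stage("diffusion")
def _diffusion(traj, ap, outdir: Path):
    top = traj.topology
    present = [sp for sp in ("PC", "PS", "PIP2", "PIP3")
               if np.any(top.species == sp)]
    result = cl.lateral_diffusion(traj, present,
                                  fit_window=tuple(ap["fit_window"]))
    for sp, curve in result.msd_curves.items():
        curve.to_csv(outdir / f"msd_{sp}.csv", index=False,
                     float_format="%.6f")
    return {"D_nm2_per_ns": {sp: round(v, 6)
                             for sp, v in result.D.items()},
            "fit_window_ns": [float(result.fit_window[0]),
                              float(result.fit_window[1])]}


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run all stages in dependency order; returns the report dict and
    writes report.json plus per-stage files into ``outdir``."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level, 20))
    ap = config.analysis_params()

    gt = None
    if config.simulate:
        gt = _simulate(config, outdir)
        structure = outdir / "system.gro"
        trajectory = outdir / "trajectory.xtc"
        maps = outdir / "maps.yaml"
    else:
        structure = config.inputs["structure"]
        trajectory = config.inputs["trajectory"]
        maps = config.inputs["maps"]

    traj = _read(structure, trajectory, maps)
    report = {"seed": config.seed,
              "n_frames": traj.n_frames,
              "analysis": ap}
    orient_out, bound = _orient(traj, ap, outdir)
    report["orient"] = orient_out
    report["contacts"] = _contacts(traj, ap, outdir)
    report["clusters"] = _clusters(traj, ap, bound, outdir)
    report["diffusion"] = _diffusion(traj, ap, outdir)
    if gt is not None:
        gtr = synth.ground_truth_report(gt)
        report["ground_truth"] = {
            "bound_fraction": gtr["bound_fraction"],
            "dominant_engaged_patch": gtr["dominant_engaged_patch"],
            "mean_recruited_count": gtr["mean_recruited_count"],
            "bound_fraction_recovery_gap": abs(
                gtr["bound_fraction"] - orient_out["bound_fraction"]),
        }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, sort_keys=True, indent=2)
        fh.write("\n")
    return report
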