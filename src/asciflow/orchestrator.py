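"""Configuration, pipeline orchestration and result serialization.

A :class:`RunConfig` (YAML on disk) fully determines a run; outputs embed
the configuration digest and package version so results are traceable.
Three modes: ``cavity`` (breathing-driven ascites flow + cycle summary),
``bioreactor`` (operating points for target FSS levels + arclength
profiles), and ``verify`` (the analytic verification suite).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import bioreactor as br
from . import io as mio
from . import kinematics as kin
from . import verify as vf
from .flow import FluidProperties, SolverSettings, run_cycles
from .geometry import CavitySpec, build_cavity_mesh
from .wss import CycleSummary, config_digest, summarize

log = logging.getLogger(__name__)


@dataclass
class OutputSettings:
    directory: str = "out"
    write_vtu: bool = True
    vtu_stride: int = 1


@dataclass
class BioreactorConfig:
    targets_dyn_cm2: tuple = (1.0, 5.0, 11.0)
    cell: br.CellModel = field(default_factory=br.CellModel)
    chamber: br.ChamberSpec = field(default_factory=br.ChamberSpec)
    hydrogel: br.HydrogelSpec = field(default_factory=br.HydrogelSpec)


@dataclass
class RunConfig:
    mode: str = "cavity"
    geometry: CavitySpec = field(default_factory=CavitySpec)
    preset: str | None = "regular"
    breathing: kin.BreathingPreset | None = None
    fluid: FluidProperties = field(default_factory=FluidProperties)
    solver: SolverSettings = field(default_factory=SolverSettings)
    mesh_motion: kin.MeshMotionSettings = field(
        default_factory=kin.MeshMotionSettings)
    bioreactor: BioreactorConfig = field(default_factory=BioreactorConfig)
    output: OutputSettings = field(default_factory=OutputSettings)

    def __post_init__(self) -> None:
        if self.mode not in ("cavity", "bioreactor", "verify"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "cavity" and self.preset is None \
                and self.breathing is None:
            raise ValueError("cavity mode needs a preset or explicit "
                             "breathing parameters")

    def breathing_preset(self) -> kin.BreathingPreset:
        return self.breathing if self.breathing is not None \
            else kin.preset(self.preset)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def digest(self) -> str:
        # output locations do not alter the scientific content of a run
        d = self.to_dict()
        d.pop("output", None)
        return config_digest(d)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        conv = {
            "geometry": lambda d: CavitySpec(**_tupled(d, "ovary_centers")),
            "breathing": lambda d: kin.BreathingPreset(**d),
            "fluid": lambda d: FluidProperties(**d),
            "solver": lambda d: SolverSettings(**d),
            "mesh_motion": lambda d: kin.MeshMotionSettings(**d),
            "output": lambda d: OutputSettings(**d),
        }
        for key, fn in conv.items():
            if key in data and isinstance(data[key], dict):
                data[key] = fn(data[key])
        if isinstance(data.get("bioreactor"), dict):
            bd = dict(data["bioreactor"])
            for key, typ in (("cell", br.CellModel),
                             ("chamber", br.ChamberSpec),
                             ("hydrogel", br.HydrogelSpec)):
                if isinstance(bd.get(key), dict):
                    bd[key] = typ(**bd[key])
            if "targets_dyn_cm2" in bd:
                bd["targets_dyn_cm2"] = tuple(bd["targets_dyn_cm2"])
            data["bioreactor"] = BioreactorConfig(**bd)
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f) or {})

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(_plain(self.to_dict()), f, sort_keys=True)


def _tupled(d: dict, key: str) -> dict:
    d = dict(d)
    if key in d:
        d[key] = tuple(tuple(c) for c in d[key])
    return d


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


# ---------------------------------------------------------------------------
# pipeline entry point
# ---------------------------------------------------------------------------


def run(config: RunConfig) -> dict:
    """Execute the configured pipeline; returns a manifest of written files."""
    out = config.output.directory
    os.makedirs(out, exist_ok=True)
    digest = config.digest()
    manifest = {"mode": config.mode, "config_digest": digest,
                "version": __version__, "files": []}
    try:
        if config.mode == "cavity":
            _run_cavity(config, out, digest, manifest)
        elif config.mode == "bioreactor":
            _run_bioreactor(config, out, digest, manifest)
        else:
            _run_verify(config, out, digest, manifest)
    except Exception as exc:
        failure = {"config_digest": digest, "version": __version__,
                   "error": str(exc)}
        path = os.path.join(out, "failure.json")
        with open(path, "w") as f:
            json.dump(failure, f, indent=2, sort_keys=True)
        raise
    path = os.path.join(out, "manifest.json")
    with open(path, "w") as f:
        json.dump(manifest, f, indent=2, sort_keys=True)
    return manifest


def _run_cavity(config: RunConfig, out: str, digest: str,
                manifest: dict) -> None:
    mesh = build_cavity_mesh(config.geometry)
    preset = config.breathing_preset()
    history = run_cycles(mesh, preset, config.geometry, config.fluid,
                         config.solver, config.mesh_motion)
    cfg_dict = config.to_dict()
    cfg_dict.pop("output", None)
    summary = summarize(history, mesh, config=cfg_dict)
    data = summary.to_dict()
    data["version"] = __version__
    data["preset"] = _plain(dataclasses.asdict(preset))
    data["periodicity_residuals"] = history.periodicity_residuals
    spath = os.path.join(out, "cycle_summary.json")
    with open(spath, "w") as f:
        json.dump(_plain(data), f, indent=2, sort_keys=True)
    manifest["files"].append(spath)

    rows = []
    for patch, pm in summary.patches.items():
        for t, smax, smean in zip(pm.times, pm.spatial_max_series,
                                  pm.spatial_mean_series):
            rows.append({"time_s": t, "patch": patch,
                         "spatial_mean_dyncm2": smean,
                         "spatial_max_dyncm2": smax})
    cpath = os.path.join(out, "patch_timeseries.csv")
    pd.DataFrame(rows).to_csv(cpath, index=False)
    manifest["files"].append(cpath)

    if config.output.write_vtu:
        pvd = mio.export_history(out, mesh, history,
                                 stride=config.output.vtu_stride)
        manifest["files"].append(pvd)
    manifest["summary"] = _plain(summary.to_dict())


def _run_bioreactor(config: RunConfig, out: str, digest: str,
                    manifest: dict) -> None:
    bc = config.bioreactor
    points = []
    for target in bc.targets_dyn_cm2:
        op = br.inverse_design(target, bc.cell, bc.chamber, bc.hydrogel,
                               config.fluid)
        points.append(op)
        cell = dataclasses.replace(bc.cell, inlet_speed=op.inlet_speed)
        prof = br.cell_fss_profile(cell, config.fluid)
        cpath = os.path.join(out, f"cell_fss_profile_{target:g}.csv")
        pd.DataFrame({"arclength_m": prof["arclength_m"],
                      "fss_dyncm2": prof["fss_dyn_cm2"]}).to_csv(
            cpath, index=False)
        manifest["files"].append(cpath)
        if config.output.write_vtu:
            vpath = os.path.join(out, f"cell_channel_{target:g}.vtu")
            mio.write_vtu(vpath, prof["mesh"])
            manifest["files"].append(vpath)
    opath = os.path.join(out, "operating_points.json")
    payload = {"config_digest": digest, "version": __version__,
               "operating_points": [op.to_dict() for op in points]}
    with open(opath, "w") as f:
        json.dump(_plain(payload), f, indent=2, sort_keys=True)
    manifest["files"].append(opath)
    manifest["operating_points"] = payload["operating_points"]


def _run_verify(config: RunConfig, out: str, digest: str,
                manifest: dict) -> None:
    reports = vf.verify_all()
    payload = {"config_digest": digest, "version": __version__, "cases": {}}
    for name, rep in reports.items():
        payload["cases"][name] = {
            "passed": bool(rep.passed),
            "tolerance": rep.tolerance,
            "records": _plain(rep.records),
            "observed_order": rep.observed_order(),
            "details": _plain(rep.details),
        }
    vpath = os.path.join(out, "verification.json")
    with open(vpath, "w") as f:
        json.dump(_plain(payload), f, indent=2, sort_keys=True)
    manifest["files"].append(vpath)
    manifest["all_passed"] = all(r.passed for r in reports.values())


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------


def report(summary: CycleSummary | dict, out_dir: str = "out",
           compare: CycleSummary | dict | None = None) -> list[str]:
    """Human-readable table + FSS time-series plot for a cycle summary.

    ``compare`` overlays a second summary (e.g. active vs regular
    breathing).  Returns the written file paths.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    os.makedirs(out_dir, exist_ok=True)
    d = summary.to_dict() if isinstance(summary, CycleSummary) else summary
    lines = [
        f"cycle summary (config {d['config_digest']})",
        f"  mean speed: {d['mean_speed_cm_s']:.3f} cm/s",
        f"  peak speed: {d['peak_speed_cm_s']:.3f} cm/s",
    ]
    for patch, pm in d["patches"].items():
        lines.append(f"  {patch}: mean FSS {pm['mean_fss_dyn_cm2']:.3f}, "
                     f"peak FSS {pm['peak_fss_dyn_cm2']:.3f} dynes/cm^2")
    tpath = os.path.join(out_dir, "summary_table.txt")
    with open(tpath, "w") as f:
        f.write("\n".join(lines) + "\n")

    fig, ax = plt.subplots(figsize=(7, 4))
    for patch, pm in d["patches"].items():
        t = np.asarray(pm["times_s"])
        ax.plot(t - t[0], pm["spatial_max_dyn_cm2"], label=patch)
    if compare is not None:
        c = compare.to_dict() if isinstance(compare, CycleSummary) else compare
        for patch, pm in c["patches"].items():
            t = np.asarray(pm["times_s"])
            ax.plot(t - t[0], pm["spatial_max_dyn_cm2"], "--",
                    label=f"{patch} (compare)")
    ax.set_xlabel("time in cycle (s)")
    ax.set_ylabel("max FSS on patch (dynes/cm$^2$)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    ppath = os.path.join(out_dir, "fss_timeseries.png")
    fig.savefig(ppath, dpi=120)
    plt.close(fig)
    return [tpath, ppath]
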