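"""End-to-end orchestration: synthetic or user data in, consolidated report out.

A pipeline run mirrors the structure of a membrane-comparison study: a set
of named membrane systems (each a trajectory, generated or loaded) scored
for membrane contact and insertion onsets, optional dimer/stacking event
detection, plus the monolayer branches (CMC estimation, adsorption
kinetics, group statistics, aggregate imaging).  Every number in the report
is traceable: the provenance block records the config hash, the global seed
and the package version, and each stage logs the parameters it used.

Runs are deterministic for a fixed config + seed (per-system seeds are
derived from the global seed); stages fail independently and failures are
reported per stage while successful stages are retained.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .errors import ConfigError, SeroraftError, ValidationError
from .interaction_geometry import detect_dissociation_event, detect_stacking_pairs
from .membrane_metrics import (average_protrusion_series, compute_contact_score,
                               detect_insertion_onset, ligand_com_series)
from .synthetic_data import (gen_aggregate_image_series, gen_kinetics_curve,
                             gen_membrane_trajectory, gen_tensiometry_curve,
                             spec_from_dict)
from .tensiometry import (KineticsCurve, TensiometryCurve, anova_tukey,
                          estimate_cmc, fit_binding_kinetics)
from .imaging import GrayImage, aggregate_area_series
from .trajectory_io import read_topology, read_xyz_trajectory

_TOP_LEVEL_KEYS = {"scenario", "seed", "metrics", "stacking", "dissociation",
                   "systems", "tensiometry", "kinetics", "imaging", "groups",
                   "out_dir"}

_DEFAULT_METRICS = {
    "cutoff": 4.0,
    "persistence_frames": 10,
    "occupancy_min": 0.9,
    "protrusion_species": "POPC",
    "membrane_roles": ["phospholipid", "sterol", "ganglioside"],
}
_DEFAULT_STACKING = {"d_max": 5.0, "angle_max": 30.0}
_DEFAULT_DISSOCIATION = {"dwell_frames": 5, "release_d": 8.0}


@dataclass
class PipelineConfig:
    scenario: str
    seed: int = 0
    metrics: dict = field(default_factory=dict)
    stacking: dict = field(default_factory=dict)
    dissociation: dict = field(default_factory=dict)
    systems: list[dict] = field(default_factory=list)
    tensiometry: dict | None = None
    kinetics: dict | None = None
    imaging: dict | None = None
    groups: dict | None = None
    out_dir: str | None = None

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        if not isinstance(doc, dict):
            raise ConfigError("config must be a mapping")
        unknown = set(doc) - _TOP_LEVEL_KEYS
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "scenario" not in doc:
            raise ConfigError("config requires a 'scenario' name")
        cfg = cls(**{k: doc[k] for k in doc})
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        p = Path(path)
        if not p.exists():
            raise ConfigError(f"config file not found: {p}")
        doc = yaml.safe_load(p.read_text())
        return cls.from_dict(doc)

    def validate(self) -> None:
        if not isinstance(self.seed, int):
            raise ConfigError("seed must be an integer")
        for i, system in enumerate(self.systems):
            if "name" not in system:
                raise ConfigError(f"systems[{i}]: requires a 'name'")
            has_spec = "trajectory" in system
            has_paths = "trajectory_path" in system and "topology_path" in system
            if not (has_spec or has_paths):
                raise ConfigError(
                    f"systems[{i}] ({system['name']}): needs either a "
                    f"'trajectory' spec or 'trajectory_path' + 'topology_path'"
                )
        for key in ("tensiometry", "kinetics"):
            section = getattr(self, key)
            if section is not None and "spec" not in section \
                    and "csv" not in section:
                raise ConfigError(f"{key}: needs either 'spec' or 'csv'")
        if self.imaging is not None and "spec" not in self.imaging:
            raise ConfigError("imaging: needs a 'spec' (synthetic series)")

    def canonical_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]


@dataclass
class ReportBundle:
    provenance: dict
    systems: list[dict] = field(default_factory=list)
    cmc: dict | None = None
    kinetics: dict | None = None
    areas: dict | None = None
    stats: dict | None = None
    stage_errors: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ReportBundle":
        doc = json.loads(text)
        return cls(**doc)


def _system_seed(base: int, index: int) -> int:
    return (base * 1000 + 97 * index) % (2 ** 31)


def _run_membrane_stage(cfg: PipelineConfig) -> list[dict]:
    metrics = {**_DEFAULT_METRICS, **cfg.metrics}
    stack_p = {**_DEFAULT_STACKING, **cfg.stacking}
    diss_p = {**_DEFAULT_DISSOCIATION, **cfg.dissociation}
    out = []
    for i, system in enumerate(cfg.systems):
        name = system["name"]
        if "trajectory" in system:
            spec_dict = dict(system["trajectory"])
            spec_dict.setdefault("seed", _system_seed(cfg.seed, i))
            spec = spec_from_dict("trajectory", spec_dict)
            bundle = gen_membrane_trajectory(spec)
            topology, traj = bundle.topology, bundle.trajectory
            truth = bundle.truth
        else:
            tpath = Path(system["trajectory_path"])
            ppath = Path(system["topology_path"])
            for p in (tpath, ppath):
                if not p.exists():
                    raise ValidationError(f"system {name!r}: missing input file {p}")
            topology = read_topology(ppath)
            traj = read_xyz_trajectory(tpath, dt=float(system.get("dt", 0.1)))
            truth = None

        score = compute_contact_score(
            traj, topology, cutoff=metrics["cutoff"],
            membrane_roles=tuple(metrics["membrane_roles"]))
        prot = average_protrusion_series(traj, topology,
                                         metrics["protrusion_species"])
        onsets = {}
        for lig in topology.molecules_with_role("ligand"):
            com = ligand_com_series(traj, topology, lig.id)
            rep = detect_insertion_onset(
                com, prot, persistence_frames=metrics["persistence_frames"],
                occupancy_min=metrics["occupancy_min"])
            onsets[str(lig.id)] = rep.onset_time

        events = []
        if len(topology.molecules_with_role("ligand")) >= 2:
            series = detect_stacking_pairs(traj, topology,
                                           d_max=stack_p["d_max"],
                                           angle_max=stack_p["angle_max"])
            for pair, s in series.items():
                ev = detect_dissociation_event(
                    s, dwell_frames=diss_p["dwell_frames"],
                    release_d=diss_p["release_d"])
                if ev.formed_at is not None:
                    events.append({"pair": list(pair),
                                   "formed_at_ns": ev.formed_at,
                                   "dissociated_at_ns": ev.dissociated_at})
        out.append({
            "name": name,
            "score_total": score.total,
            "n_frames": traj.n_frames,
            "onset_ns": onsets,
            "dimer_events": events,
            "parameters": {**metrics, **{f"stacking_{k}": v
                                         for k, v in stack_p.items()}},
            "planted_truth": truth,
        })
    return out


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute the configured stages in dependency order.

    Idempotent for a fixed config + seed.  Stage failures are caught and
    recorded in ``stage_errors``; successful stages are retained.
    """
    config.validate()
    bundle = ReportBundle(provenance={
        "scenario": config.scenario,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "seroraft_version": __version__,
    })

    if config.systems:
        try:
            bundle.systems = _run_membrane_stage(config)
        except SeroraftError as exc:
            bundle.stage_errors["membrane"] = str(exc)

    if config.tensiometry is not None:
        try:
            section = config.tensiometry
            if "spec" in section:
                spec_dict = dict(section["spec"])
                spec_dict.setdefault("seed", _system_seed(config.seed, 811))
                curve = gen_tensiometry_curve(
                    spec_from_dict("tensiometry", spec_dict)).curve
            else:
                path = Path(section["csv"])
                if not path.exists():
                    raise ValidationError(f"tensiometry: missing input file {path}")
                curve = TensiometryCurve.from_csv(path)
            est = estimate_cmc(curve, n_boot=int(section.get("n_boot", 0)),
                               seed=config.seed)
            bundle.cmc = {
                "cmc_mM": est.cmc, "slope_below": est.slope_below,
                "slope_above": est.slope_above, "degenerate": est.degenerate,
                "ci": list(est.ci) if est.ci else None,
            }
        except SeroraftError as exc:
            bundle.stage_errors["tensiometry"] = str(exc)

    if config.kinetics is not None:
        try:
            section = config.kinetics
            if "spec" in section:
                spec_dict = dict(section["spec"])
                spec_dict.setdefault("seed", _system_seed(config.seed, 823))
                curve = gen_kinetics_curve(
                    spec_from_dict("kinetics", spec_dict)).curve
            else:
                path = Path(section["csv"])
                if not path.exists():
                    raise ValidationError(f"kinetics: missing input file {path}")
                curve = KineticsCurve.from_csv(path)
            fit = fit_binding_kinetics(curve)
            at = float(section.get("report_at", 60.0))
            bundle.kinetics = {
                "pi0": fit.pi0, "delta_pi_inf": fit.delta_pi_inf,
                "rate_k_per_min": fit.rate_k,
                "report_at_min": at, "delta_pi_at": fit.delta_pi_at(at),
            }
        except SeroraftError as exc:
            bundle.stage_errors["kinetics"] = str(exc)

    if config.imaging is not None:
        try:
            spec_dict = dict(config.imaging["spec"])
            spec_dict.setdefault("seed", _system_seed(config.seed, 829))
            images = gen_aggregate_image_series(
                spec_from_dict("images", spec_dict))
            series = aggregate_area_series(
                images.images, images.times,
                min_component_px=int(config.imaging.get("min_component_px", 25)))
            bundle.areas = {
                "times": series.times,
                "area_px2": series.area_px2,
                "area_mm2": series.area_mm2,
                "n_components": series.n_components,
            }
        except SeroraftError as exc:
            bundle.stage_errors["imaging"] = str(exc)

    if config.groups is not None:
        try:
            cmp_ = anova_tukey(config.groups)
            bundle.stats = {
                "f_stat": cmp_.f_stat, "p_value": cmp_.p_value,
                "tukey": cmp_.table.to_dict(orient="records"),
            }
        except SeroraftError as exc:
            bundle.stage_errors["stats"] = str(exc)

    return bundle


def generate_report(bundle: ReportBundle, format: str = "json") -> str:
    """Serialize a report bundle; provenance first in the readable form."""
    if format == "json":
        return bundle.to_json()
    if format != "markdown":
        raise ConfigError(f"unknown report format {format!r}")
    lines = ["# Pipeline report", "", "## Provenance", ""]
    for k, v in sorted(bundle.provenance.items()):
        lines.append(f"- {k}: {v}")
    if bundle.systems:
        lines += ["", "## Membrane systems", "",
                  "| system | score total | onsets (ns) | dimer events |",
                  "|---|---|---|---|"]
        for s in bundle.systems:
            onsets = ", ".join(
                f"{k}: {('%.4f' % v) if v is not None else 'none'}"
                for k, v in s["onset_ns"].items())
            lines.append(f"| {s['name']} | {s['score_total']} | {onsets} | "
                         f"{len(s['dimer_events'])} |")
    if bundle.cmc is not None:
        lines += ["", "## CMC", "", f"- cmc_mM: {bundle.cmc['cmc_mM']:.4f}",
                  f"- degenerate: {bundle.cmc['degenerate']}"]
    if bundle.kinetics is not None:
        k = bundle.kinetics
        lines += ["", "## Adsorption kinetics", "",
                  f"- delta_pi_inf: {k['delta_pi_inf']:.4f} mN/m",
                  f"- rate_k: {k['rate_k_per_min']:.4f} 1/min",
                  f"- delta_pi at {k['report_at_min']:g} min: "
                  f"{k['delta_pi_at']:.4f} mN/m"]
    if bundle.areas is not None:
        lines += ["", "## Aggregate areas", "",
                  "| time | area_px2 | area_mm2 | components |", "|---|---|---|---|"]
        for t, apx, amm, nc in zip(bundle.areas["times"],
                                   bundle.areas["area_px2"],
                                   bundle.areas["area_mm2"],
                                   bundle.areas["n_components"]):
            lines.append(f"| {t:g} | {apx:.1f} | {amm:.4f} | {nc} |")
    if bundle.stats is not None:
        lines += ["", "## Group statistics", "",
                  f"- F: {bundle.stats['f_stat']:.4f}",
                  f"- p: {bundle.stats['p_value']:.3g}"]
    if bundle.stage_errors:
        lines += ["", "## Stage errors", ""]
        for k, v in sorted(bundle.stage_errors.items()):
            lines.append(f"- {k}: {v}")
    return "\n".join(lines) + "\n"
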