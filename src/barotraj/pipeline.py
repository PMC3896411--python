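"""Configuration-driven orchestration of the analysis stages.

A :class:`RunConfig` names the inputs per pressure label and the cutoffs
used throughout; :func:`run_pipeline` executes the requested stages and
emits publication-table-shaped TSV reports (surface/volume/
compressibility, free-energy breakdown, ATP contacts, salt-bridge
categories, per-residue RMSF, propeller angle, attack-geometry FES).
Delta columns are always X_high - X_low of the same table. Every output
carries a header comment with the config hash and seed; a rerun with the
same config and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import active_site, geometry, interactions, surface_volume, thermo
from .model_io import (
    DEFAULT_SUBDOMAIN_RANGES,
    AnnotationConfig,
    Trajectory,
    annotate_topology,
    load_trajectory,
)

__all__ = ["RunConfig", "StageError", "run_pipeline"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """All knobs of one pipeline run (defaults mirror the study setup:
    277 K, 0.1 vs 60 MPa, 3.2 Å salt-bridge cutoff, 1.4 Å probe)."""

    inputs: Mapping[str, Mapping[str, str]] = field(default_factory=dict)
    outdir: str = "barotraj_out"
    temperature: float = 277.0
    pressure_labels: tuple[str, str] = ("0.1MPa", "60MPa")
    salt_bridge_cutoff: float = 3.2
    hbond_distance: float = 3.0
    hbond_angle: float = 160.0
    mg_cutoff: float = 2.6
    theta_min: float = 109.3
    probe_radius: float = 1.4
    sasa_points: int = 960
    volume_grid: float = 0.25
    poisson_grid: float = 0.4
    subdomain_ranges: Mapping[int, tuple] = field(
        default_factory=lambda: DEFAULT_SUBDOMAIN_RANGES
    )
    ss_labels: Mapping[int, str] | None = None  # external H/E/C per residue
    propeller_order: tuple[int, int, int, int] = (2, 1, 3, 4)
    n_blocks: int = 5
    surface_stride: int = 1
    kappa_source: str = "vex"  # "vex" (per-frame excluded volume) or "box"
    seed: int = 0
    stages: tuple[str, ...] = ("volume", "interactions", "geometry",
                               "activesite", "thermo")

    def __post_init__(self) -> None:
        for name, val in (
            ("salt_bridge_cutoff", self.salt_bridge_cutoff),
            ("hbond_distance", self.hbond_distance),
            ("mg_cutoff", self.mg_cutoff),
            ("probe_radius", self.probe_radius),
        ):
            if val <= 0:
                raise ValueError(f"{name} must be positive")
        if len(set(self.pressure_labels)) != len(self.pressure_labels):
            raise ValueError("pressure labels must be distinct")

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _header(config: RunConfig, units: str) -> str:
    return (
        f"# config={config.hash()} seed={config.seed} units={units}\n"
    )


def _write(df: pd.DataFrame, path: Path, config: RunConfig, units: str) -> None:
    with open(path, "w") as fh:
        fh.write(_header(config, units))
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def _load_inputs(config: RunConfig) -> dict[str, Trajectory]:
    out = {}
    for label, paths in config.inputs.items():
        out[label] = load_trajectory(
            paths["structure"], paths["frames"], paths.get("scalars")
        )
    return out


def _annotation_config(config: RunConfig, ss_labels=None) -> AnnotationConfig:
    return AnnotationConfig(
        subdomain_ranges=config.subdomain_ranges, ss_labels=ss_labels
    )


def stage_volume(trajs: Mapping[str, Trajectory], config: RunConfig) -> pd.DataFrame:
    rows = []
    for label, traj in trajs.items():
        idx = range(0, traj.n_frames, config.surface_stride)
        vex, areas = [], []
        for i in idx:
            s = traj.frame_structure(i)
            vex.append(
                surface_volume.excluded_volume(
                    s, probe=config.probe_radius, grid_spacing=config.volume_grid
                )
            )
            areas.append(
                surface_volume.sasa(
                    s, probe=config.probe_radius, n_points=config.sasa_points
                )
            )
        v_mean, v_sd = surface_volume.series_stats(np.array(vex))
        a_mean, a_sd = surface_volume.series_stats(np.array(areas))
        if config.kappa_source == "box" and traj.volumes is not None:
            series = surface_volume.VolumeSeries(
                values=traj.volumes, temperature=config.temperature
            )
        else:
            series = surface_volume.VolumeSeries(
                values=np.array(vex), temperature=config.temperature
            )
        kappa = surface_volume.isothermal_compressibility(series)
        rows.append(
            dict(label=label, vex_mean=v_mean, vex_sd=v_sd,
                 sasa_mean=a_mean, sasa_sd=a_sd, kappa_gpa=kappa)
        )
    df = pd.DataFrame(rows)
    lo, hi = config.pressure_labels
    if {lo, hi}.issubset(set(df["label"])):
        dlo = df[df.label == lo].iloc[0]
        dhi = df[df.label == hi].iloc[0]
        delta = dict(label=f"delta({hi}-{lo})",
                     vex_mean=dhi.vex_mean - dlo.vex_mean, vex_sd=np.nan,
                     sasa_mean=dhi.sasa_mean - dlo.sasa_mean, sasa_sd=np.nan,
                     kappa_gpa=dhi.kappa_gpa - dlo.kappa_gpa)
        df = pd.concat([df, pd.DataFrame([delta])], ignore_index=True)
    return df


def stage_interactions(
    trajs: Mapping[str, Trajectory], config: RunConfig, ss_labels=None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    cat_rows, tag_rows, rate_rows = [], [], []
    for label, traj in trajs.items():
        annotation = annotate_topology(
            traj.topology, _annotation_config(config, ss_labels)
        )
        profile = interactions.assign_secondary_structure(
            traj.topology, external=ss_labels
        )
        per_frame = []
        for k in range(traj.n_frames):
            recs = interactions.detect_salt_bridges(
                traj.frames[k], annotation, config.salt_bridge_cutoff
            )
            interactions.classify_salt_bridges(
                recs, profile, annotation.subdomains
            )
            per_frame.append(recs)
        summary = interactions.aggregate_interactions(per_frame)
        row = {"label": label}
        for cat, (m, sd) in summary.category_stats.items():
            row[f"{cat}_mean"] = m
            row[f"{cat}_sd"] = sd
        cat_rows.append(row)
        for tag, (m, sd) in sorted(summary.atp_tag_stats.items()):
            tag_rows.append(dict(label=label, contact=tag, mean=m, sd=sd))
        for (ra, rb), rate in sorted(summary.formation_rates.items()):
            rate_rows.append(
                dict(label=label, residue_a=ra, residue_b=rb, rate=rate)
            )
    return (
        pd.DataFrame(cat_rows),
        pd.DataFrame(tag_rows),
        pd.DataFrame(rate_rows),
    )


def stage_geometry(
    trajs: Mapping[str, Trajectory], config: RunConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    rmsf_rows, prop_rows = [], []
    for label, traj in trajs.items():
        backbone = traj.topology.backbone_indices()
        annotation = annotate_topology(traj.topology, _annotation_config(config))
        if traj.n_frames >= 2 and backbone.size >= 3:
            per_res = geometry.rmsf(traj, selection=backbone)
            for rid, val in sorted(per_res.items()):
                rmsf_rows.append(dict(label=label, residue=rid, rmsf=val))
        for k in range(traj.n_frames):
            try:
                ang = geometry.propeller_angle(
                    traj.frame_structure(k),
                    annotation.subdomains,
                    order=config.propeller_order,
                )
            except ValueError:
                break
            prop_rows.append(dict(label=label, frame=k, propeller_deg=ang))
    return pd.DataFrame(rmsf_rows), pd.DataFrame(prop_rows)


def stage_active_site(
    trajs: Mapping[str, Trajectory], config: RunConfig
) -> tuple[pd.DataFrame, dict[str, active_site.FESGrid]]:
    rows, grids = [], {}
    for label, traj in trajs.items():
        annotation = annotate_topology(traj.topology, _annotation_config(config))
        records = []
        for k in range(traj.n_frames):
            rec = active_site.assign_nucleophilic_water(
                traj.frames[k], annotation, theta_min=config.theta_min, frame=k
            )
            if rec is not None:
                records.append(rec)
                rows.append(
                    dict(label=label, frame=k, water=rec.water_residue,
                         theta=rec.theta, d_nu=rec.d_nu)
                )
        if records:
            grids[label] = active_site.theta_d_free_energy_surface(records)
    return pd.DataFrame(rows), grids


def stage_thermo(
    trajs: Mapping[str, Trajectory], config: RunConfig
) -> pd.DataFrame:
    lo, hi = config.pressure_labels
    if not {lo, hi}.issubset(trajs):
        raise ValueError(f"thermo stage needs both labels {lo!r} and {hi!r}")
    stats = {}
    for label in (lo, hi):
        traj = trajs[label]
        if traj.energies is None:
            raise ValueError(f"{label}: no per-frame energies supplied")
        (e_mean, e_sd), _ = thermo.mean_conformational_energy(traj.energies)
        areas = [
            surface_volume.sasa(
                traj.frame_structure(i), probe=config.probe_radius,
                n_points=config.sasa_points,
            )
            for i in range(0, traj.n_frames, config.surface_stride)
        ]
        a_mean, a_sd = surface_volume.series_stats(np.array(areas))
        gamma = thermo.surface_tension(config.temperature)
        s_mean, s_sd, _ = thermo.block_entropy(
            traj, config.temperature, n_blocks=config.n_blocks
        )
        stats[label] = dict(
            e=(e_mean, e_sd),
            mu=(gamma * a_mean, gamma * a_sd),
            ts=(config.temperature * s_mean, config.temperature * s_sd),
        )
    de = thermo.delta_with_sd(stats[hi]["e"], stats[lo]["e"])
    dmu = thermo.delta_with_sd(stats[hi]["mu"], stats[lo]["mu"])
    dts = thermo.delta_with_sd(stats[hi]["ts"], stats[lo]["ts"])
    breakdown = thermo.free_energy_shift(de, dmu, dts, label=f"{hi}-{lo}")
    return pd.DataFrame(
        [
            dict(
                label=breakdown.label,
                delta_e_conf=de[0], delta_e_conf_sd=de[1],
                delta_delta_mu=dmu[0], delta_delta_mu_sd=dmu[1],
                t_delta_s=dts[0], t_delta_s_sd=dts[1],
                delta_g=breakdown.delta_g[0], delta_g_sd=breakdown.delta_g[1],
            )
        ]
    )


def run_pipeline(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Execute the configured stages and write the TSV report bundle.

    Returns the tables keyed by report name; any stage failure raises
    :class:`StageError` naming the stage.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        trajs = _load_inputs(config)
    except Exception as exc:
        raise StageError("load", exc) from exc
    bundle: dict[str, pd.DataFrame] = {}

    def run(stage, fn, *a):
        try:
            return fn(*a)
        except Exception as exc:
            raise StageError(stage, exc) from exc

    if "volume" in config.stages:
        df = run("volume", stage_volume, trajs, config)
        bundle["table2"] = df
        _write(df, outdir / "table2.tsv", config, "Vex:Å^3 SASA:Å^2 kappa:GPa^-1")
    if "interactions" in config.stages:
        cats, tags, rates = run("interactions", stage_interactions, trajs,
                                config, config.ss_labels)
        bundle["table5"], bundle["table4"], bundle["rates"] = cats, tags, rates
        _write(cats, outdir / "table5.tsv", config, "counts/frame")
        _write(tags, outdir / "table4.tsv", config, "counts/frame")
        _write(rates, outdir / "formation_rates.tsv", config, "fraction")
    if "geometry" in config.stages:
        rmsf_df, prop_df = run("geometry", stage_geometry, trajs, config)
        bundle["rmsf"], bundle["propeller"] = rmsf_df, prop_df
        _write(rmsf_df, outdir / "rmsf.tsv", config, "Å")
        _write(prop_df, outdir / "propeller.tsv", config,
               f"deg order={config.propeller_order}")
    if "activesite" in config.stages:
        rec_df, grids = run("activesite", stage_active_site, trajs, config)
        bundle["nucleophilic_water"] = rec_df
        _write(rec_df, outdir / "nucleophilic_water.tsv", config, "deg/Å")
        for label, grid in grids.items():
            fes = pd.DataFrame(
                grid.free_energy,
                index=[f"{t:.1f}" for t in grid.theta_edges[:-1]],
                columns=[f"{d:.2f}" for d in grid.d_edges[:-1]],
            )
            path = outdir / f"fes_{label}.tsv"
            with open(path, "w") as fh:
                fh.write(_header(config, "kBT; rows theta, cols d_Nu"))
                fes.to_csv(fh, sep="\t", float_format="%.6g")
            bundle[f"fes_{label}"] = fes
    if "thermo" in config.stages:
        try:
            df = stage_thermo(trajs, config)
        except StageError:
            raise
        except ValueError as exc:
            # thermo is optional when inputs carry no energy tables
            df = None
            if "no per-frame energies" not in str(exc):
                raise StageError("thermo", exc) from exc
        except Exception as exc:
            raise StageError("thermo", exc) from exc
        if df is not None:
            bundle["table3"] = df
            _write(df, outdir / "table3.tsv", config, "kcal/mol")

    log = dict(config_hash=config.hash(), seed=config.seed,
               stages=list(config.stages), labels=list(trajs))
    (outdir / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))
    return bundle
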