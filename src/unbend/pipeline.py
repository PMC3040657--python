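"""Experiment orchestration: configs, presets, suites, reports.

This module glues the simulator and the analysis stack into the four
experiment shapes of a forced-unbending study:

* ``cv_pull`` — constant-velocity pulls; force-extension curve, force
  peaks, buried-SASA / H-bond / hinge-angle / distance-metric series.
* ``cf_pull_series`` — a ladder of constant-force runs over several
  seeds; waiting times, their medians per force, and the Bell fit.
* ``free_from_snapshot`` — free relaxation from partially- or
  fully-extended snapshots of a previous pull (rebending vs stability).
* ``recover`` — statistical parameter recovery: two-state escape
  simulation plus Bell fitting over replicates against known truth.

Every stochastic stage takes an explicit seed; a run directory always
contains the config echo, a manifest with the config hash, and the
tables needed to re-derive every figure-style quantity.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cg_simulator import (CgConfig, PullingProtocol, SimParams,
                           build_bent_model, run_dynamics, snapshot_restart)
from .constants import NM_PER_NS_TO_A_PER_NS, spring_kcal_to_pn_per_a
from .hinges import HingePair, cooperativity_fit, hinge_angle_series
from .interactions import (DistanceMetricSpec, com_distance_series,
                           detect_contact_event, hbond_count_series)
from .kinetics import (WaitingTimeRule, detect_force_peaks,
                       detect_waiting_time, fit_bell, simulate_escape)
from .model_io import (Selection, Trajectory, extension_series,
                       read_trajectory_csv, resolve_selection, rmsd_series,
                       write_annotations, write_pdb, write_trajectory_csv)
from .sasa import SasaParams, buried_sasa

__all__ = ["PRESETS", "load_config", "cmd_simulate", "cmd_analyze",
           "cmd_kinetics", "cmd_recover", "run_cv_experiment",
           "run_cf_suite", "run_snapshot_suite", "sasa_drop_window",
           "default_hinge_pairs", "combined_interface_sasa",
           "DEFAULT_CF_FORCES", "DEFAULT_CF_DURATIONS"]

log = logging.getLogger("unbend")

#: constant-force ladder (pN-analog) used by the shipped presets.
DEFAULT_CF_FORCES = (97.0, 122.0, 146.0, 170.0, 195.0)
#: per-force run caps (ns): low forces wait longer before escaping.
DEFAULT_CF_DURATIONS = {97.0: 500.0, 122.0: 300.0, 146.0: 200.0,
                        170.0: 150.0, 195.0: 120.0}

PRESETS = {
    "equilibrate": {
        "protocol": {"mode": "free"},
        "sim": {"duration_ns": 20.0, "save_stride": 100},
    },
    "cv_pull": {
        "protocol": {"mode": "constant-velocity",
                     "pull": "pull_betaA", "constraint": "constrain_betaTD",
                     "spring_k_kcal_mol_A2": 0.5, "speed_A_ns": 2.0},
        "sim": {"duration_ns": 100.0, "save_stride": 100},
    },
    "cf_pull_series": {
        "protocol": {"mode": "constant-force",
                     "pull": "pull_betaA", "constraint": "constrain_betaTD"},
        "forces_pN": list(DEFAULT_CF_FORCES),
        "durations_ns": {str(int(f)): d for f, d in DEFAULT_CF_DURATIONS.items()},
        "seeds": [1, 2, 3, 4, 5],
        "sim": {"save_stride": 50},
    },
    "free_from_snapshot": {
        "protocol": {"mode": "free", "constraint": "constrain_betaTD"},
        "sim": {"duration_ns": 40.0, "save_stride": 100},
    },
    "recover": {
        "truth": {"t0_ns": 728.0, "dx_A": 1.2, "temperature_K": 300.0},
        "forces_pN": list(DEFAULT_CF_FORCES),
        "samples_per_force": 100,
        "replicates": 200,
    },
}


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


def _deep_merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], val)
        else:
            out[key] = val
    return out


def load_config(source) -> dict:
    """Load a run config from a YAML path or dict; apply preset + units.

    The returned dict has resolved keys: ``model`` (a CgConfig), ``sim``
    (SimParams kwargs minus seed) and ``protocol`` (PullingProtocol
    kwargs with pull/constraint as composite names), plus suite-specific
    entries (forces_pN, durations_ns, seeds, truth, snapshot, ...).
    Spring constants may be given in kcal mol⁻¹ Å⁻² and speeds in
    nm ns⁻¹; they are converted to pN/Å and Å/ns here.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            doc = yaml.safe_load(fh) or {}
    else:
        doc = dict(source or {})
    preset = doc.pop("preset", None)
    if preset is not None:
        if preset not in PRESETS:
            raise KeyError(f"unknown preset {preset!r}; known: {sorted(PRESETS)}")
        doc = _deep_merge(PRESETS[preset], doc)

    model_cfg = CgConfig(**doc.pop("model", {}))

    sim_raw = dict(doc.pop("sim", {}))
    sim = {
        "temperature": float(sim_raw.pop("temperature_K", 300.0)),
        "gamma": float(sim_raw.pop("gamma", 1.0)),
        "dt": float(sim_raw.pop("dt_ns", 0.002)),
        "duration": float(sim_raw.pop("duration_ns", 10.0)),
        "save_stride": int(sim_raw.pop("save_stride", 50)),
    }
    sim_raw.pop("seed", None)
    if sim_raw:
        raise KeyError(f"unknown sim keys: {sorted(sim_raw)}")

    proto_raw = dict(doc.pop("protocol", {}))
    proto = {"mode": proto_raw.pop("mode", "free"),
             "pull": proto_raw.pop("pull", None),
             "constraint": proto_raw.pop("constraint", None),
             "direction": proto_raw.pop("direction", "fixed")}
    if "spring_k_kcal_mol_A2" in proto_raw:
        proto["spring_k"] = spring_kcal_to_pn_per_a(
            float(proto_raw.pop("spring_k_kcal_mol_A2")))
    elif "spring_k_pN_A" in proto_raw:
        proto["spring_k"] = float(proto_raw.pop("spring_k_pN_A"))
    if "constraint_k_kcal_mol_A2" in proto_raw:
        proto["constraint_k"] = spring_kcal_to_pn_per_a(
            float(proto_raw.pop("constraint_k_kcal_mol_A2")))
    if "speed_nm_ns" in proto_raw:
        proto["speed"] = float(proto_raw.pop("speed_nm_ns")) * NM_PER_NS_TO_A_PER_NS
    elif "speed_A_ns" in proto_raw:
        proto["speed"] = float(proto_raw.pop("speed_A_ns"))
    if "force_pN" in proto_raw:
        proto["force"] = float(proto_raw.pop("force_pN"))
    if proto_raw:
        raise KeyError(f"unknown protocol keys: {sorted(proto_raw)}")

    resolved = {"model": model_cfg, "sim": sim, "protocol": proto}
    for key in ("forces_pN", "durations_ns", "seeds", "truth",
                "samples_per_force", "replicates", "noiseless", "snapshot",
                "analysis", "output_dir"):
        if key in doc:
            resolved[key] = doc.pop(key)
    if doc:
        raise KeyError(f"unknown config keys: {sorted(doc)}")
    return resolved


def _config_hash(config: dict) -> str:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        if isinstance(o, Path):
            return str(o)
        raise TypeError(type(o))
    blob = json.dumps(config, sort_keys=True, default=default).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _protocol_from_config(proto: dict, model, dmap, force=None) -> PullingProtocol:
    kwargs = {k: v for k, v in proto.items()
              if k not in ("pull", "constraint") and v is not None}
    if proto.get("pull"):
        kwargs["pull_serials"] = tuple(int(s) for s in resolve_selection(
            model, dmap, Selection(composites=(proto["pull"],))))
    if proto.get("constraint"):
        kwargs["constraint_serials"] = tuple(int(s) for s in resolve_selection(
            model, dmap, Selection(composites=(proto["constraint"],))))
    if force is not None:
        kwargs["force"] = float(force)
    return PullingProtocol(**kwargs)


# ---------------------------------------------------------------------------
# simulate
# ---------------------------------------------------------------------------


def cmd_simulate(config: dict, output_dir, seed: int = 0) -> dict:
    """Build the model, run the configured protocol, write run outputs.

    Returns the manifest (also written to ``manifest.json``).  When the
    config carries a ``forces_pN`` list (the constant-force suite), one
    subdirectory per force level and seed is produced.
    """
    from . import __version__ as pkg_version
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    log.info("unbend %s | seed %d | config hash %s",
             pkg_version, seed, _config_hash(config))
    model, topo, dmap = build_bent_model(config["model"])
    write_pdb(model, out / "model.pdb")
    write_annotations(model, out / "annotations.csv")
    dmap.to_yaml(out / "domain_map.yaml")
    _write_topology_csv(topo, out / "topology.csv")
    files = ["model.pdb", "annotations.csv", "domain_map.yaml", "topology.csv"]

    if "forces_pN" in config:      # constant-force suite
        durations = {float(k): float(v)
                     for k, v in (config.get("durations_ns") or {}).items()}
        seeds = [int(seed) + int(s) for s in config.get("seeds", [0])]
        for force in config["forces_pN"]:
            for s in seeds:
                sub = out / f"F{int(force)}_seed{s}"
                sub.mkdir(exist_ok=True)
                dur = durations.get(float(force), config["sim"]["duration"])
                params = SimParams(**{**config["sim"], "duration": dur}, seed=s)
                proto = _protocol_from_config(config["protocol"], model, dmap,
                                              force=force)
                traj, rec = run_dynamics(model, topo, proto, params,
                                         cfg=config["model"])
                write_trajectory_csv(traj, sub / "trajectory.csv")
                rec.to_csv(sub / "forces.csv", index=False)
                files += [f"{sub.name}/trajectory.csv", f"{sub.name}/forces.csv"]
                log.info("cf run force=%s seed=%s frames=%d",
                         force, s, traj.n_frames)
    else:
        params = SimParams(**config["sim"], seed=int(seed))
        proto = _protocol_from_config(config["protocol"], model, dmap)
        initial = None
        if "snapshot" in config:
            snap = config["snapshot"]
            src = read_trajectory_csv(Path(snap["run_dir"]) / "trajectory.csv")
            initial = snapshot_restart(src, int(snap["frame"]))
        traj, rec = run_dynamics(model, topo, proto, params,
                                 cfg=config["model"], initial_coords=initial)
        write_trajectory_csv(traj, out / "trajectory.csv")
        rec.to_csv(out / "forces.csv", index=False)
        files += ["trajectory.csv", "forces.csv"]
        log.info("run mode=%s frames=%d", proto.mode, traj.n_frames)

    manifest = {
        "config_hash": _config_hash(config),
        "seed": int(seed),
        "unbend_version": pkg_version,
        "files": files,
        "wall_time_s": round(time.time() - t_start, 3),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    log.removeHandler(handler)
    handler.close()
    return manifest


def _write_topology_csv(topo, path) -> None:
    rows = []
    for (i, j), rest, k in zip(topo.springs, topo.spring_rest, topo.spring_k):
        rows.append(("spring", int(i), int(j), float(rest), float(k),
                     np.nan, ""))
    for (i, j), rest, brk, k, eps, cls in zip(
            topo.contacts, topo.contact_rest, topo.contact_break,
            topo.contact_k, topo.contact_eps, topo.contact_class):
        rows.append(("contact", int(i), int(j), float(rest), float(k),
                     float(brk), cls))
    pd.DataFrame(rows, columns=["kind", "i", "j", "rest_A", "k_pN_A",
                                "break_A", "class"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# analysis helpers shared by cmd_analyze, tests and the acceptance script
# ---------------------------------------------------------------------------


def _default_metric_specs(model) -> list:
    """Shipped distance metrics on the synthetic model's named beads."""
    name = model.name.astype(str)
    chain = model.chain.astype(str)
    nd = tuple(int(s) for s in model.serial[name == "ND"])
    oa = tuple(int(s) for s in model.serial[name == "OA"])
    cb_hyb = tuple(int(s) for s in model.serial[(name == "CB")
                                                & (model.resid <= 36)
                                                & (chain == "B")])
    cb_egf = tuple(int(s) for s in model.serial[(name == "CB")
                                                & (model.resid >= 37)])
    cgb = tuple(int(s) for s in model.serial[name == "CG"])
    ion = tuple(int(s) for s in model.serial[name == "ION"])
    specs = [
        DistanceMetricSpec("salt_bridge_D393_R633", nd, oa,
                           threshold=4.0, direction="below"),
        DistanceMetricSpec("hydrophobic_cluster", cb_hyb, cb_egf,
                           threshold=4.0, direction="below"),
    ]
    if cgb and ion:
        specs.append(DistanceMetricSpec("genu_ion_D457", cgb, ion,
                                        threshold=4.0, direction="below"))
    return specs


def default_hinge_pairs(topo) -> list:
    """The two knees plus the adjacent EGF2/EGF3 pair, as measured hinges.

    Each side of a hinge is the whole leg segment (two domains) rather
    than a single domain: the coarse beads leave individual domains some
    orientational slack, and the elongated segments pin the fitted
    rigid-body orientation to the well-restrained backbone geometry.
    """
    d = topo.domains
    seg = lambda *names: np.concatenate([d[n] for n in names])
    return [
        HingePair("thigh/calf-1", seg("beta-propeller", "thigh"),
                  seg("calf-1", "calf-2")),
        HingePair("EGF1/EGF2", seg("PSI", "EGF1"), seg("EGF2", "EGF3")),
        HingePair("EGF2/EGF3", seg("EGF1", "EGF2"), seg("EGF3", "EGF4")),
    ]



def _smoothed_wide(hinge_table: pd.DataFrame, window: int = 25) -> pd.DataFrame:
    """Pivot hinge series to wide form and apply a centered rolling mean.

    The knee angles of the coarse model carry fast orientational
    fluctuations on top of the slow opening; a ~2 ns rolling mean keeps
    the opening trajectory and suppresses the wobble before the
    cooperativity regression.
    """
    wide = hinge_table.pivot(index="time_ns", columns="pair",
                             values="angle_deg")
    return wide.rolling(window, center=True, min_periods=1).mean()


def combined_interface_sasa(traj: Trajectory, model, dmap, topo,
                            params: SasaParams = SasaParams(),
                            stride: int = 5) -> pd.DataFrame:
    """Headpiece/tailpiece buried SASA per frame, by interface domain.

    Head-side domains (hybrid, βA) are restricted within the headpiece;
    tail-side domains (EGF4, βTD) within the tailpiece; ``total`` is the
    unrestricted headpiece value.  Long format: time_ns, domain,
    buried_area_A2.
    """
    hp = resolve_selection(model, dmap, Selection(composites=("headpiece",)))
    tp = resolve_selection(model, dmap, Selection(composites=("tailpiece",)))
    domains = {dom: model.serial[topo.domains[dom]]
               for dom in ("hybrid", "betaA", "EGF4", "betaTD")}
    rows = []
    for k in range(0, traj.n_frames, stride):
        frame = traj.coords[k]
        t = float(traj.times[k])
        rows.append((t, "total",
                     buried_sasa(model, hp, tp, params=params, coords=frame)))
        for dom in ("hybrid", "betaA"):
            rows.append((t, dom, buried_sasa(model, hp, tp,
                                             restrict=domains[dom],
                                             params=params, coords=frame)))
        for dom in ("EGF4", "betaTD"):
            rows.append((t, dom, buried_sasa(model, tp, hp,
                                             restrict=domains[dom],
                                             params=params, coords=frame)))
    return pd.DataFrame(rows, columns=["time_ns", "domain", "buried_area_A2"])


def sasa_drop_window(series: pd.DataFrame, domain: str = "hybrid",
                     smooth: int = 5, lo: float = 0.85,
                     hi: float = 0.15) -> tuple:
    """Time window over which a buried-SASA series makes its major drop.

    The series for ``domain`` is smoothed by a centered rolling mean and
    the window is where it crosses from ``lo`` to ``hi`` of the
    initial-to-final drop.  Returns (t_start, t_end).
    """
    sel = series[series.domain == domain]
    t = sel.time_ns.to_numpy()
    v = (sel.buried_area_A2.rolling(smooth, center=True, min_periods=1)
         .mean().to_numpy())
    n10 = max(1, len(v) // 10)
    v0, v1 = v[:n10].mean(), v[-n10:].mean()
    if v0 <= v1:
        raise ValueError("series shows no net drop")
    lo_level = v1 + lo * (v0 - v1)
    hi_level = v1 + hi * (v0 - v1)
    below_lo = np.flatnonzero(v < lo_level)
    below_hi = np.flatnonzero(v < hi_level)
    t_start = float(t[below_lo[0]]) if len(below_lo) else float(t[-1])
    t_end = float(t[below_hi[0]]) if len(below_hi) else float(t[-1])
    return t_start, t_end


def run_cv_experiment(config: dict | None = None, seed: int = 11,
                      sasa_stride: int = 5) -> dict:
    """One constant-velocity unbending run with the full analysis.

    Returns the model objects, trajectory, force record, extension
    series, force-extension curve + peaks, buried-SASA table, H-bond
    series, hinge-angle table and hinge cooperativity fits.
    """
    config = config or load_config({"preset": "cv_pull"})
    model, topo, dmap = build_bent_model(config["model"])
    proto = _protocol_from_config(config["protocol"], model, dmap)
    params = SimParams(**config["sim"], seed=seed)
    traj, rec = run_dynamics(model, topo, proto, params, cfg=config["model"])
    pull_idx = model.index_of(np.asarray(proto.pull_serials))
    con_idx = model.index_of(np.asarray(proto.constraint_serials))
    ext = extension_series(traj, pull_idx, con_idx)
    order = np.argsort(ext[:, 1])
    curve = np.column_stack([ext[order, 1],
                             rec.spring_force_pN.to_numpy()[order]])
    peaks = detect_force_peaks(curve, smoothing_window=4.0, min_prominence=30.0)
    sasa_table = combined_interface_sasa(traj, model, dmap, topo,
                                         stride=sasa_stride)
    hyb = model.serial[topo.domains["hybrid"]]
    td = model.serial[topo.domains["betaTD"]]
    hbonds = hbond_count_series(traj, model, hyb, td, stride=sasa_stride)
    pairs = default_hinge_pairs(topo)
    hinge_table = hinge_angle_series(traj, pairs)
    wide = _smoothed_wide(hinge_table)
    fits = {}
    from .hinges import default_window_rule
    x = wide["thigh/calf-1"].to_numpy()
    for y_name in ("EGF1/EGF2", "EGF2/EGF3"):
        y = wide[y_name].to_numpy()
        # pre-straightening: stop when either hinge reaches its plateau
        hi = min(default_window_rule(x)[1], default_window_rule(y)[1])
        fits[y_name] = cooperativity_fit(x, y, x_name="thigh/calf-1",
                                         y_name=y_name, window=(0, hi))
    return {"model": model, "topo": topo, "dmap": dmap, "traj": traj,
            "record": rec, "extension": ext, "curve": curve, "peaks": peaks,
            "sasa": sasa_table, "hbonds": hbonds, "hinges": hinge_table,
            "cooperativity": fits}


def run_cf_suite(config: dict | None = None, base_seed: int = 0,
                 rule: WaitingTimeRule = WaitingTimeRule()) -> dict:
    """Constant-force ladder: waiting times, per-force medians, Bell fit.

    Waiting times come from the head-tail (pull-COM to constraint-COM)
    distance traces; a run that never escapes within its cap enters the
    median as +inf, so a median is finite once most seeds escape.
    """
    config = config or load_config({"preset": "cf_pull_series"})
    model, topo, dmap = build_bent_model(config["model"])
    durations = {float(k): float(v)
                 for k, v in (config.get("durations_ns") or {}).items()}
    seeds = [int(base_seed) + int(s) for s in config.get("seeds", [1, 2, 3, 4, 5])]
    rows = []
    for force in config["forces_pN"]:
        proto = _protocol_from_config(config["protocol"], model, dmap,
                                      force=force)
        dur = durations.get(float(force), config["sim"]["duration"])
        for s in seeds:
            params = SimParams(**{**config["sim"], "duration": dur}, seed=s)
            traj, rec = run_dynamics(model, topo, proto, params,
                                     cfg=config["model"])
            dist = np.linalg.norm(
                rec[["pull_com_x", "pull_com_y", "pull_com_z"]].to_numpy()
                - rec[["constraint_com_x", "constraint_com_y",
                       "constraint_com_z"]].to_numpy(), axis=1)
            wt = detect_waiting_time(
                np.column_stack([rec.time_ns.to_numpy(), dist]), rule)
            rows.append((float(force), s, wt))
    table = pd.DataFrame(rows, columns=["force_pN", "seed", "waiting_time_ns"])
    medians = (table.assign(wt=table.waiting_time_ns.astype(float)
                            .fillna(np.inf))
               .groupby("force_pN").wt.median())
    finite = medians[np.isfinite(medians)]
    fit = fit_bell(list(finite.items())) if len(finite) >= 2 else None
    return {"table": table, "medians": medians, "fit": fit}


def run_snapshot_suite(kind: str = "partial", n_seeds: int = 6,
                       config: dict | None = None, cv_seed: int = 11,
                       duration: float = 60.0) -> dict:
    """Free relaxations from partially- or fully-extended snapshots.

    ``partial`` snapshots are taken right after the major force peak of
    a constant-velocity run (interface contacts broken, knees still
    bent); ``full`` snapshots once extension first reaches 90% of the
    run's final value.  Returns per-seed start/final head-tail
    distances, the hydrophobic-cluster recontact time if any, and the
    fractions of runs that rebent / stayed extended.
    """
    if kind not in ("partial", "full"):
        raise ValueError("kind must be 'partial' or 'full'")
    config = config or load_config({"preset": "cv_pull"})
    model, topo, dmap = build_bent_model(config["model"])
    proto = _protocol_from_config(config["protocol"], model, dmap)
    params = SimParams(**config["sim"], seed=cv_seed)
    traj, rec = run_dynamics(model, topo, proto, params, cfg=config["model"])
    pull_idx = model.index_of(np.asarray(proto.pull_serials))
    con_idx = model.index_of(np.asarray(proto.constraint_serials))
    ext = extension_series(traj, pull_idx, con_idx)
    if kind == "partial":
        order = np.argsort(ext[:, 1])
        curve = np.column_stack([ext[order, 1],
                                 rec.spring_force_pN.to_numpy()[order]])
        peaks = detect_force_peaks(curve, smoothing_window=4.0,
                                   min_prominence=30.0)
        target_ext = (peaks[0].extension if peaks else 0.1 * ext[-1, 1]) + 5.0
        frame = int(np.argmax(ext[:, 1] >= target_ext))
    else:
        frame = int(np.argmax(ext[:, 1] >= 0.9 * ext[-1, 1]))
    start = snapshot_restart(traj, frame)
    free = PullingProtocol(mode="free",
                           constraint_serials=proto.constraint_serials)
    hyd_spec = next(s for s in _default_metric_specs(model)
                    if s.name == "hydrophobic_cluster")
    rows = []
    for s in range(n_seeds):
        fp = SimParams(**{**config["sim"], "duration": duration},
                       seed=1000 + cv_seed + s)
        ftraj, _ = run_dynamics(model, topo, free, fp, cfg=config["model"],
                                initial_coords=start)
        d = np.linalg.norm(ftraj.coords[:, pull_idx].mean(axis=1)
                           - ftraj.coords[:, con_idx].mean(axis=1), axis=1)
        tail = float(d[-max(1, len(d) // 10):].mean())
        event = detect_contact_event(
            com_distance_series(ftraj, model, hyd_spec), hyd_spec)
        rows.append({"seed": fp.seed, "start_A": float(d[0]),
                     "final_A": tail, "hydrophobic_recontact_ns": event})
    frac_rebent = float(np.mean([r["final_A"] < r["start_A"] for r in rows]))
    frac_stable = float(np.mean([abs(r["final_A"] - r["start_A"])
                                 <= 0.2 * r["start_A"] for r in rows]))
    return {"kind": kind, "snapshot_frame": frame,
            "snapshot_extension_A": float(ext[frame, 1]),
            "runs": rows, "fraction_rebent": frac_rebent,
            "fraction_stable": frac_stable}


# ---------------------------------------------------------------------------
# CLI-facing commands
# ---------------------------------------------------------------------------


def cmd_analyze(config: dict, run_dir, output_dir=None) -> dict:
    """Analyze a simulated run directory into CSV tables.

    Emits extension, RMSD, force-extension curve + detected peaks,
    buried-SASA, H-bond-count, hinge-angle + cooperativity and
    distance-metric tables next to the trajectory (or in ``output_dir``).
    """
    run_dir = Path(run_dir)
    out = Path(output_dir) if output_dir else run_dir
    out.mkdir(parents=True, exist_ok=True)
    traj_path = run_dir / "trajectory.csv"
    if not traj_path.exists():
        raise FileNotFoundError(f"expected trajectory at {traj_path}")
    model, topo, dmap = build_bent_model(config["model"])
    traj = read_trajectory_csv(traj_path, topology=model)
    rec = pd.read_csv(run_dir / "forces.csv")
    stride = int((config.get("analysis") or {}).get("sasa_stride", 5))

    pull = resolve_selection(model, dmap, Selection(
        composites=(config["protocol"].get("pull") or "pull_betaA",)))
    con = resolve_selection(model, dmap, Selection(
        composites=(config["protocol"].get("constraint")
                    or "constrain_betaTD",)))
    pull_idx, con_idx = model.index_of(pull), model.index_of(con)

    ext = extension_series(traj, pull_idx, con_idx)
    pd.DataFrame(ext, columns=["time_ns", "extension_A"]).to_csv(
        out / "extension.csv", index=False)
    rms = rmsd_series(traj, traj.coords[0], np.arange(model.n_atoms))
    pd.DataFrame(rms, columns=["time_ns", "rmsd_A"]).to_csv(
        out / "rmsd.csv", index=False)

    order = np.argsort(ext[:, 1])
    curve = np.column_stack([ext[order, 1],
                             rec.spring_force_pN.to_numpy()[order]])
    pd.DataFrame(curve, columns=["extension_A", "force_pN"]).to_csv(
        out / "force_extension.csv", index=False)
    span = curve[-1, 0] - curve[0, 0]
    peaks = (detect_force_peaks(curve, smoothing_window=4.0,
                                min_prominence=30.0) if span > 4.0 else [])
    pd.DataFrame([(p.extension, p.force, p.prominence) for p in peaks],
                 columns=["extension_A", "force_pN", "prominence_pN"]).to_csv(
        out / "force_peaks.csv", index=False)

    combined_interface_sasa(traj, model, dmap, topo, stride=stride).to_csv(
        out / "buried_sasa.csv", index=False)
    hyb = model.serial[topo.domains["hybrid"]]
    td = model.serial[topo.domains["betaTD"]]
    hbond_count_series(traj, model, hyb, td, stride=stride).to_csv(
        out / "hbond_counts.csv", index=False)

    hinge_table = hinge_angle_series(traj, default_hinge_pairs(topo))
    hinge_table.to_csv(out / "hinge_angles.csv", index=False)
    fits = []
    wide = _smoothed_wide(hinge_table)
    from .hinges import default_window_rule
    x = wide["thigh/calf-1"].to_numpy()
    for y_name in ("EGF1/EGF2", "EGF2/EGF3"):
        if np.ptp(x) > 1.0:
            y = wide[y_name].to_numpy()
            hi = min(default_window_rule(x)[1], default_window_rule(y)[1])
            fit = cooperativity_fit(x, y, x_name="thigh/calf-1",
                                    y_name=y_name, window=(0, hi))
            fits.append((fit.x_name, fit.y_name, fit.slope, fit.intercept,
                         fit.r2, fit.window[0], fit.window[1]))
    pd.DataFrame(fits, columns=["pair_x", "pair_y", "slope", "intercept",
                                "r2", "window_lo", "window_hi"]).to_csv(
        out / "cooperativity.csv", index=False)

    for spec in _default_metric_specs(model):
        ser = com_distance_series(traj, model, spec)
        pd.DataFrame(ser, columns=["time_ns", "distance_A"]).to_csv(
            out / f"metric_{spec.name}.csv", index=False)
    return {"n_frames": traj.n_frames, "n_peaks": len(peaks),
            "tables": sorted(p.name for p in out.glob("*.csv"))}


def cmd_kinetics(config: dict, run_dirs, temperature_k: float = 300.0,
                 rule: WaitingTimeRule = WaitingTimeRule()) -> dict:
    """Waiting times + Bell fit over a set of constant-force run dirs."""
    rows = []
    for rd in sorted(str(r) for r in run_dirs):
        rd = Path(rd)
        rec = pd.read_csv(rd / "forces.csv")
        force = float(np.median(np.abs(rec.spring_force_pN)))
        dist = np.linalg.norm(
            rec[["pull_com_x", "pull_com_y", "pull_com_z"]].to_numpy()
            - rec[["constraint_com_x", "constraint_com_y",
                   "constraint_com_z"]].to_numpy(), axis=1)
        wt = detect_waiting_time(
            np.column_stack([rec.time_ns.to_numpy(), dist]), rule)
        rows.append((force, str(rd), wt))
    table = pd.DataFrame(rows, columns=["force_pN", "run", "waiting_time_ns"])
    detected = table.dropna(subset=["waiting_time_ns"])
    if len(detected) < 2 or detected.force_pN.nunique() < 2:
        raise ValueError("need detected transitions at >=2 distinct forces; "
                         "try longer runs or higher forces")
    medians = detected.groupby("force_pN").waiting_time_ns.median()
    fit = fit_bell(list(medians.items()), temperature_k=temperature_k)
    return {
        "waiting_times": table.to_dict(orient="records"),
        "medians": {float(k): float(v) for k, v in medians.items()},
        "bell_fit": {"t0_ns": fit.t0, "t0_se": fit.t0_se, "dx_A": fit.dx,
                     "dx_se": fit.dx_se, "r2": fit.r2,
                     "n_points": fit.n_points, "kBT_pN_A": fit.kbt},
    }


def cmd_recover(config: dict | None = None, seed: int = 0) -> dict:
    """Parameter-recovery experiment for the Bell fitting procedure.

    Draws exponential escape times at the configured truth (t0, Δx) over
    the force ladder, fits ln(mean waiting time) vs force per replicate,
    and reports the median and spread of the recovered parameters.
    """
    config = config or load_config({"preset": "recover"})
    truth = config["truth"]
    t0_true = float(truth["t0_ns"])
    dx_true = float(truth["dx_A"])
    temp = float(truth.get("temperature_K", 300.0))
    forces = [float(f) for f in config["forces_pN"]]
    m = int(config.get("samples_per_force", 100))
    reps = int(config.get("replicates", 200))
    noiseless = bool(config.get("noiseless", False))
    from .constants import kbt
    rng = np.random.default_rng(seed)
    t0s, dxs = [], []
    for _ in range(reps):
        if noiseless:    # waiting times set to their exact means τ(F)
            means = [(f, t0_true * np.exp(-f * dx_true / kbt(temp)))
                     for f in forces]
        else:
            rep_seed = int(rng.integers(0, 2 ** 31 - 1))
            draws = simulate_escape(t0_true, dx_true, forces,
                                    temperature_k=temp,
                                    samples_per_force=m, seed=rep_seed)
            means = [(f, draws[draws[:, 0] == f, 1].mean()) for f in forces]
        fit = fit_bell(means, temperature_k=temp)
        t0s.append(fit.t0)
        dxs.append(fit.dx)
    t0s, dxs = np.array(t0s), np.array(dxs)
    return {
        "truth": {"t0_ns": t0_true, "dx_A": dx_true, "temperature_K": temp},
        "design": {"forces_pN": forces, "samples_per_force": m,
                   "replicates": reps, "seed": int(seed)},
        "t0_ns": {"median": float(np.median(t0s)),
                  "iqr": [float(np.percentile(t0s, 25)),
                          float(np.percentile(t0s, 75))]},
        "dx_A": {"median": float(np.median(dxs)),
                 "iqr": [float(np.percentile(dxs, 25)),
                         float(np.percentile(dxs, 75))]},
    }
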