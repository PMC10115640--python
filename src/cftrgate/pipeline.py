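"""End-to-end reproducible runs: model -> simulate -> render -> QC ->
idealize -> analyze -> report.

A run is fully described by a :class:`RunConfig`; the SHA-256 hash of the
canonical config is embedded in every output file so any artifact can be
traced to the exact configuration (and seeds) that produced it.
Re-running the same config reproduces all numeric outputs bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .calibration import SATURATING_ATP, observable_vector
from .gating_model import Protocol, RateSet, build_topology, simulate_ssa, \
    stationary_distribution, occupancy_relaxation
from .kinetics import extract_dwells, fit_hill, fit_relaxation, \
    transition_frequency
from .synthetic_traces import EmissionModel, generate_ensemble
from .trace_qc import QcCriteria, SkmModel, ensemble_histogram, \
    compute_fret, idealize_trace, qc_select

__all__ = ["RunConfig", "run_pipeline", "make_figures"]


@dataclass(frozen=True)
class RunConfig:
    variant: str = "WT"
    atp_molar: float = SATURATING_ATP
    phosphorylated: bool = True
    n_traces: int = 100
    trace_duration_s: float = 60.0
    frame_ms: float = 100.0
    ssa_duration_s: float = 2000.0
    n_groups: int = 5
    seed: int = 0
    rate_overrides: dict = field(default_factory=dict)
    emission_overrides: dict = field(default_factory=dict)
    qc_overrides: dict = field(default_factory=dict)
    flicker_bridge_s: float = 0.010
    compute_dose_response: bool = True

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        canon = json.dumps(self.as_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> dict:
    """Execute every stage and return (and optionally write) the report
    bundle.  A stage failure aborts with the stage name; completed stages
    are preserved in the returned bundle."""
    bundle: dict = {
        "config": config.as_dict(),
        "config_hash": config.config_hash(),
        "version": __version__,
        "stages": {},
    }
    bundle["_timing"] = {}
    log = bundle["stages"]
    stage = "setup"
    try:
        graph = build_topology(config.variant, overrides=config.rate_overrides or None)
        emission = EmissionModel.for_condition(
            config.atp_molar, config.variant,
            frame_ms=config.frame_ms, **config.emission_overrides)
        criteria = QcCriteria(**config.qc_overrides) if config.qc_overrides \
            else QcCriteria()
        protocol = Protocol(duration_s=config.trace_duration_s,
                            atp_schedule=((0.0, config.atp_molar),),
                            phosphorylated=config.phosphorylated)

        stage = "model_observables"
        t0 = time.time()
        obs = {}
        if config.phosphorylated and config.atp_molar > 0:
            try:
                stat = stationary_distribution(graph, config.atp_molar)
                obs.update(po=stat.po, pdim=stat.pdim,
                           coupling_ratio=stat.po / stat.pdim,
                           turnover_per_s=stat.turnover_per_s)
            except np.linalg.LinAlgError:
                obs["note"] = "stationary solve unavailable for this condition"
            if config.compute_dose_response and config.variant == "WT":
                full = observable_vector(graph)
                obs.update(full.as_dict())
                conc = np.geomspace(1e-6, 3e-3, 25)
                po_c, pdim_c = [], []
                for c in conc:
                    s = stationary_distribution(graph, c)
                    po_c.append(s.po)
                    pdim_c.append(s.pdim)
                bundle["dose_response"] = {
                    "atp_molar": conc, "po": po_c, "pdim": pdim_c}
                p0 = np.zeros(graph.n_states)
                p0[graph.index("SEP_apo")] = 1.0
                up = occupancy_relaxation(graph, p0, config.atp_molar, 8.0, 0.01)
                down = occupancy_relaxation(
                    graph, stationary_distribution(graph, config.atp_molar).pi,
                    0.0, 120.0, 0.05)
                bundle["relaxations"] = {
                    "activation": {"t": up.times, "po": up.po, "pdim": up.pdim},
                    "withdrawal": {"t": down.times, "po": down.po,
                                   "pdim": down.pdim},
                }
        bundle["observables"] = obs
        log[stage] = {}
        bundle["_timing"][stage] = round(time.time() - t0, 3)

        stage = "ssa_dwells"
        t0 = time.time()
        ssa_protocol = Protocol(duration_s=config.ssa_duration_s,
                                atp_schedule=((0.0, config.atp_molar),),
                                phosphorylated=config.phosphorylated)
        path = simulate_ssa(graph, ssa_protocol, seed=config.seed)
        dimer_names = {graph.states[i].name: "dimerized" for i in graph.dimer_set}
        open_names = {graph.states[i].name: "conducting" for i in graph.open_set}
        bundle["ssa"] = {
            "n_segments": int(len(path.states)),
            "n_hydrolysis_events": int(len(path.hydrolysis_events)),
            "turnover_per_s": len(path.hydrolysis_events) / path.duration_s,
            "seed": config.seed,
        }
        dwell_summary = {}
        dwell_tables = {}
        for label, amap, bridge in (
                ("dimerized", dimer_names, 0.0),
                ("conducting", open_names, config.flicker_bridge_s)):
            try:
                table = extract_dwells(path, amap, bridge_s=bridge)
                dwell_tables[label] = table
                dwell_summary[label] = {
                    "n": int((~table.data.censored).sum()),
                    "mean_s": table.mean_dwell(label),
                }
            except ValueError:
                dwell_summary[label] = {"n": 0, "mean_s": None}
        if all(v.get("mean_s") for v in dwell_summary.values()):
            dwell_summary["ratio"] = (dwell_summary["dimerized"]["mean_s"]
                                      / dwell_summary["conducting"]["mean_s"])
        bundle["dwells"] = dwell_summary
        bundle["_dwell_tables"] = dwell_tables
        log[stage] = {"seed": config.seed}
        bundle["_timing"][stage] = round(time.time() - t0, 3)

        stage = "traces"
        t0 = time.time()
        ens = generate_ensemble(graph, protocol, config.n_traces, emission,
                                seed=config.seed + 1)
        accepted, reports = qc_select(ens.traces, criteria)
        idealized = [idealize_trace(t, criteria=criteria) for t in accepted]
        rej = {}
        for r in reports:
            if not r.accepted:
                rej[r.reason] = rej.get(r.reason, 0) + 1
        fret_arrays = []
        for tr, it in zip(accepted, idealized):
            e = compute_fret(tr)
            fret_arrays.append(np.where(it.labels == "dark", np.nan, e))
        groups = (np.arange(len(accepted)) * config.n_groups
                  // max(len(accepted), 1))
        hist = ensemble_histogram(fret_arrays, bins=44, groups=groups,
                                  idealized=idealized)
        freq = transition_frequency(idealized)
        bundle["trace_analysis"] = {
            "n_generated": config.n_traces,
            "n_accepted": len(accepted),
            "rejections": rej,
            "qc_criteria": criteria.as_dict(),
            "state_means": list(map(float, hist.get("state_means", ()))),
            "high_occupancy": hist.get("high_occupancy"),
            "transition_frequency_per_s": freq["pooled_per_s"],
        }
        bundle["histogram"] = {k: hist[k] for k in
                               ("bin_centers", "mean_density", "sem_density")}
        log[stage] = {"seed": config.seed + 1}
        bundle["_timing"][stage] = round(time.time() - t0, 3)
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    if outdir is not None:
        _write_bundle(bundle, Path(outdir))
    return bundle


def _write_bundle(bundle: dict, outdir: Path) -> None:
    import pandas as pd

    outdir.mkdir(parents=True, exist_ok=True)
    tag = {"config_hash": bundle["config_hash"], "version": bundle["version"]}
    report = {k: v for k, v in bundle.items() if not k.startswith("_")}
    with open(outdir / "report.json", "w") as fh:
        json.dump(_jsonable(report), fh, indent=1)
    with open(outdir / "log.json", "w") as fh:
        json.dump(_jsonable({"config_hash": bundle["config_hash"],
                             "stage_seconds": bundle.get("_timing", {})}),
                  fh, indent=1)
    for label, table in bundle.get("_dwell_tables", {}).items():
        df = table.data.copy()
        df["config_hash"] = tag["config_hash"]
        df.to_csv(outdir / f"dwells_{label}.csv", index=False)
    if "dose_response" in bundle:
        pd.DataFrame(_jsonable(bundle["dose_response"])).assign(**tag).to_csv(
            outdir / "dose_response.csv", index=False)
    if "histogram" in bundle:
        pd.DataFrame(_jsonable(bundle["histogram"])).assign(**tag).to_csv(
            outdir / "fret_histogram.csv", index=False)
    if "relaxations" in bundle:
        for name, series in bundle["relaxations"].items():
            pd.DataFrame(_jsonable(series)).assign(**tag).to_csv(
                outdir / f"relaxation_{name}.csv", index=False)


def make_figures(bundle: dict, outdir: str | Path) -> list[Path]:
    """Static figures (and matching CSVs through ``run_pipeline``):
    population FRET histogram, dwell survival curves, dose response, and
    pre-steady-state relaxations.  Sections absent from the bundle are
    skipped with a warning."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    tag = bundle.get("config_hash", "")

    if "histogram" in bundle:
        h = bundle["histogram"]
        fig, ax = plt.subplots(figsize=(4, 3))
        centers = np.asarray(h["bin_centers"], dtype=float)
        mean = np.asarray(h["mean_density"], dtype=float)
        sem = np.asarray(h["sem_density"], dtype=float)
        ax.fill_between(centers, mean - sem, mean + sem, alpha=0.3)
        ax.plot(centers, mean)
        ax.set(xlabel="FRET efficiency", ylabel="probability density",
               title=f"population histogram [{tag}]")
        fig.tight_layout()
        p = outdir / "fret_histogram.png"
        fig.savefig(p, dpi=150)
        plt.close(fig)
        written.append(p)
    else:
        warnings.warn("histogram section missing; figure skipped")

    if "_dwell_tables" in bundle and bundle["_dwell_tables"]:
        fig, ax = plt.subplots(figsize=(4, 3))
        for label, table in bundle["_dwell_tables"].items():
            d = np.sort(table.dwells(label))
            if len(d) == 0:
                continue
            surv = 1.0 - np.arange(len(d)) / len(d)
            ax.semilogy(d, surv, drawstyle="steps-post", label=label)
        ax.set(xlabel="dwell time (s)", ylabel="survival",
               title=f"dwell survival [{tag}]")
        ax.legend()
        fig.tight_layout()
        p = outdir / "dwell_survival.png"
        fig.savefig(p, dpi=150)
        plt.close(fig)
        written.append(p)
    else:
        warnings.warn("dwell section missing; figure skipped")

    if "dose_response" in bundle:
        d = bundle["dose_response"]
        fig, ax = plt.subplots(figsize=(4, 3))
        c = np.asarray(d["atp_molar"], dtype=float) * 1e6
        ax.semilogx(c, d["po"], "o-", label="Po")
        ax.semilogx(c, d["pdim"], "s-", label="Pdim")
        ax.set(xlabel="ATP (uM)", ylabel="probability",
               title=f"ATP dose response [{tag}]")
        ax.legend()
        fig.tight_layout()
        p = outdir / "dose_response.png"
        fig.savefig(p, dpi=150)
        plt.close(fig)
        written.append(p)
    else:
        warnings.warn("dose-response section missing; figure skipped")

    if "relaxations" in bundle:
        fig, axes = plt.subplots(1, 2, figsize=(7, 3))
        for ax, (name, series) in zip(axes, bundle["relaxations"].items()):
            t = np.asarray(series["t"], dtype=float)
            ax.plot(t, series["po"], label="Po")
            ax.plot(t, series["pdim"], label="Pdim")
            ax.set(xlabel="time (s)", ylabel="occupancy", title=name)
            ax.legend()
        fig.suptitle(f"relaxations [{tag}]")
        fig.tight_layout()
        p = outdir / "relaxations.png"
        fig.savefig(p, dpi=150)
        plt.close(fig)
        written.append(p)
    else:
        warnings.warn("relaxation section missing; figure skipped")
    return written
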