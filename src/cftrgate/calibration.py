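"""Rate-constant estimation against experimental observables.

The gating-cycle topology is fixed; the rate constants are free parameters
estimated by constrained multi-start least squares so that deterministic
model observables reproduce measured channel behaviour: steady-state open
and dimerization probabilities, the dimerized/open dwell-time ratio, the
activation time constant after an ATP jump, the bi-exponential NBD
separation after ATP withdrawal, the ATP EC50s of opening and
dimerization, and the ATP turnover rate (a window target — the model is
known to overestimate it somewhat).

Only deterministic quantities (linear stationary solves, master-equation
relaxations, first-passage dwell means) enter the objective, keeping it
noise-free; stochastic simulation is reserved for validation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy.optimize import least_squares

from .gating_model import (
    RateSet,
    StateGraph,
    _RATE_FIELDS,
    build_topology,
    mean_class_dwell,
    occupancy_relaxation,
    stationary_distribution,
)
from .kinetics import fit_hill, fit_relaxation

__all__ = [
    "ObservableSet", "CalibrationTarget", "CalibrationReport",
    "observable_vector", "calibrate_rates", "default_targets",
    "DEFAULT_BOUNDS",
]

SATURATING_ATP = 3e-3   # molar; the reference "saturating" condition
FLICKER_BRIDGE_S = 0.010  # openings interrupted by <10 ms flickers form one burst


@dataclass(frozen=True)
class ObservableSet:
    """Deterministic model observables on the experimental scale."""

    po: float                 # stationary open probability at 3 mM ATP
    pdim: float               # stationary dimerized (high-FRET) occupancy at 3 mM
    coupling_ratio: float     # po / pdim
    dwell_ratio: float        # mean dimerized dwell / mean open-burst dwell
    tau_opening_s: float      # mono-exponential activation constant after ATP jump
    tau_sep_fast_s: float     # fast bi-exponential separation constant at ATP = 0
    tau_sep_slow_s: float     # slow bi-exponential separation constant at ATP = 0
    ec50_open_M: float        # Hill midpoint (n = 1) of Po(c)
    ec50_dim_M: float         # Hill midpoint (n = 1) of Pdim(c)
    turnover_per_s: float     # stationary hydrolysis flux at 3 mM
    fit_flags: tuple = ()     # per-observable fit warnings, never silent defaults

    def as_dict(self) -> dict[str, float]:
        return {
            k: float(getattr(self, k))
            for k in ("po", "pdim", "coupling_ratio", "dwell_ratio",
                      "tau_opening_s", "tau_sep_fast_s", "tau_sep_slow_s",
                      "ec50_open_M", "ec50_dim_M", "turnover_per_s")
        }


def observable_vector(graph: StateGraph, rates: RateSet | None = None) -> ObservableSet:
    """Compute the full observable set for a graph (all deterministic).

    The activation constant comes from a mono-exponential fit of the open
    occupancy after an instantaneous jump from the apo separated state to
    3 mM ATP; the separation constants from a bi-exponential fit of the
    dimerized occupancy after setting ATP to 0 from the 3 mM stationary
    state; EC50s from Hill fits (coefficient fixed to 1) over a log grid
    from 1 uM to 3 mM.
    """
    if rates is not None:
        graph = graph.with_rates(rates)
    flags: list[str] = []

    stat = stationary_distribution(graph, SATURATING_ATP)

    # activation after ATP jump, starting from the apo separated state
    p0 = np.zeros(graph.n_states)
    p0[graph.index("SEP_apo")] = 1.0
    relax_up = occupancy_relaxation(graph, p0, SATURATING_ATP,
                                    horizon_s=8.0, grid_s=0.005)
    fit_up = fit_relaxation(relax_up.times, relax_up.po, n_components=1)
    if not fit_up.converged:
        flags.append("tau_opening: fit did not converge")

    # NBD separation after complete ATP withdrawal
    relax_down = occupancy_relaxation(graph, stat.pi, 0.0,
                                      horizon_s=120.0, grid_s=0.05)
    fit_down = fit_relaxation(relax_down.times, relax_down.pdim, n_components=2)
    if not fit_down.converged:
        flags.append("tau_sep: fit did not converge")

    # ATP dose responses of stationary occupancies
    conc = np.geomspace(1e-6, 3e-3, 25)
    po_c = np.empty_like(conc)
    pdim_c = np.empty_like(conc)
    for i, c in enumerate(conc):
        s = stationary_distribution(graph, c)
        po_c[i], pdim_c[i] = s.po, s.pdim
    hill_open = fit_hill(conc, po_c, fix_n=True)
    hill_dim = fit_hill(conc, pdim_c, fix_n=True)
    for nm, h in (("ec50_open", hill_open), ("ec50_dim", hill_dim)):
        if h.flagged:
            flags.append(f"{nm}: {h.flagged}")

    # deterministic aggregated dwell means at saturating ATP
    dimer_dwell = mean_class_dwell(graph, SATURATING_ATP, graph.dimer_set)
    burst_dwell = mean_class_dwell(graph, SATURATING_ATP, graph.open_set,
                                   bridge_s=FLICKER_BRIDGE_S)

    return ObservableSet(
        po=stat.po,
        pdim=stat.pdim,
        coupling_ratio=stat.po / stat.pdim,
        dwell_ratio=dimer_dwell / burst_dwell,
        tau_opening_s=float(fit_up.taus[0]),
        tau_sep_fast_s=float(fit_down.taus[0]),
        tau_sep_slow_s=float(fit_down.taus[1]),
        ec50_open_M=hill_open.ec50_molar,
        ec50_dim_M=hill_dim.ec50_molar,
        turnover_per_s=stat.turnover_per_s,
        fit_flags=tuple(flags),
    )


# ---------------------------------------------------------------------------
# targets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CalibrationTarget:
    name: str
    value: float | None = None
    tolerance: float = 0.1      # relative; scales the residual
    weight: float = 1.0
    kind: str = "point"         # "point" or "window"
    lo: float | None = None
    hi: float | None = None

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError("weight must be > 0")
        if self.kind == "point" and self.value is None:
            raise ValueError(f"point target {self.name} needs a value")
        if self.kind == "window" and (self.lo is None or self.hi is None):
            raise ValueError(f"window target {self.name} needs (lo, hi)")

    def residual(self, observed: float) -> float:
        if self.kind == "point":
            scale = self.tolerance * abs(self.value)
            return np.sqrt(self.weight) * (observed - self.value) / scale
        mid = 0.5 * (self.lo + self.hi)
        if self.lo <= observed <= self.hi:
            return 0.0
        edge = self.lo if observed < self.lo else self.hi
        return np.sqrt(self.weight) * (observed - edge) / (self.tolerance * mid)


def default_targets() -> list[CalibrationTarget]:
    """The experimental target set shipped with the package (with source
    annotations in the data file)."""
    text = resources.files("cftrgate.data").joinpath(
        "calibration_targets.yaml").read_text()
    raw = yaml.safe_load(text)
    return [CalibrationTarget(**t) for t in raw["targets"]]


def targets_from_observables(obs: ObservableSet,
                             names: Sequence[str] | None = None,
                             tolerance: float = 0.05) -> list[CalibrationTarget]:
    """Build point targets from an existing observable set (round-trip /
    self-consistency studies)."""
    names = names or ("po", "pdim", "dwell_ratio", "tau_opening_s",
                      "tau_sep_fast_s", "tau_sep_slow_s",
                      "ec50_open_M", "ec50_dim_M", "turnover_per_s")
    return [CalibrationTarget(name=n, value=getattr(obs, n), tolerance=tolerance)
            for n in names]


# rate bounds spanning physiological single-channel kinetics
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    name: ((1e3, 1e8) if name in ("k_bind", "k6") else (1e-3, 1e3))
    for name in _RATE_FIELDS
}


@dataclass
class CalibrationReport:
    rates: RateSet
    observables: ObservableSet
    objective: float
    residuals: dict[str, float]
    missed: list[str]
    best_restart: int
    seed: int
    n_restarts: int
    converged: bool

    def as_dict(self) -> dict:
        return {
            "rates": self.rates.as_dict(),
            "observables": self.observables.as_dict(),
            "objective": self.objective,
            "residuals": self.residuals,
            "missed_targets": self.missed,
            "best_restart": self.best_restart,
            "seed": self.seed,
            "n_restarts": self.n_restarts,
            "converged": self.converged,
        }

    def summary(self) -> str:
        lines = [f"calibration: objective {self.objective:.4g} "
                 f"(restart {self.best_restart}/{self.n_restarts}, seed {self.seed})"]
        for name, r in self.residuals.items():
            mark = " *MISSED*" if name in self.missed else ""
            lines.append(f"  {name:16s} residual {r:+.3f}{mark}")
        for k, v in self.rates.as_dict().items():
            lines.append(f"  {k:12s} = {v:.6g}")
        return "\n".join(lines)


def _objective_residuals(log_rates, targets, variant, penalty=50.0):
    rates = RateSet.from_dict(
        {n: 10.0 ** lr for n, lr in zip(_RATE_FIELDS, log_rates)})
    try:
        graph = build_topology(variant, rates=rates)
        obs = observable_vector(graph)
        return np.array([t.residual(getattr(obs, t.name)) for t in targets]), obs
    except Exception:
        return np.full(len(targets), penalty), None


def calibrate_rates(
    targets: Sequence[CalibrationTarget] | None = None,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    init: RateSet | None = None,
    restarts: int = 1,
    seed: int = 0,
    variant: str = "WT",
    perturb_sd: float = 0.35,
    max_nfev: int = 400,
) -> CalibrationReport:
    """Estimate rate constants by bounded multi-start least squares.

    Rates are optimized in log10 space within ``bounds``.  Restart 0 uses
    ``init`` unperturbed; later restarts perturb every log-rate by a
    Gaussian of sd ``perturb_sd`` decades (seeded, so the whole procedure
    is deterministic).  Ties between equal-objective restarts go to the
    lowest restart index.  The objective is invariant to target order.
    """
    if targets is None:
        targets = default_targets()
    if restarts < 1:
        raise ValueError("need at least one restart")
    bounds = dict(DEFAULT_BOUNDS, **(bounds or {}))
    lo = np.array([np.log10(bounds[n][0]) for n in _RATE_FIELDS])
    hi = np.array([np.log10(bounds[n][1]) for n in _RATE_FIELDS])
    if (lo >= hi).any():
        raise ValueError("infeasible bounds")
    if init is None:
        init = RateSet.wt_calibrated()
    x_init = np.clip(
        np.log10(np.maximum([getattr(init, n) for n in _RATE_FIELDS], 1e-300)),
        lo, hi)

    rng = np.random.default_rng(seed)
    best = None
    any_converged = False
    for r in range(restarts):
        x0 = x_init if r == 0 else np.clip(
            x_init + rng.normal(0.0, perturb_sd, size=len(x_init)), lo, hi)
        res = least_squares(
            lambda x: _objective_residuals(x, targets, variant)[0],
            x0, bounds=(lo, hi), method="trf", max_nfev=max_nfev,
            xtol=1e-10, ftol=1e-10, gtol=1e-10)
        cost = float(res.cost)
        # status 0 means the evaluation budget was reached: a usable
        # (budget-limited) iterate, not an optimizer failure
        any_converged = any_converged or res.status >= 0
        if best is None or cost < best[0] - 1e-15:
            best = (cost, res.x.copy(), r)
    if not any_converged:
        raise RuntimeError("all calibration restarts failed to converge")

    _, x_best, r_best = best
    residuals, obs = _objective_residuals(x_best, targets, variant)
    rates = RateSet.from_dict(
        {n: 10.0 ** x for n, x in zip(_RATE_FIELDS, x_best)})
    resid_map = {t.name: float(v) for t, v in zip(targets, residuals)}
    missed = [t.name for t, v in zip(targets, residuals)
              if abs(v) > np.sqrt(t.weight)]  # |obs - target| > tolerance
    return CalibrationReport(
        rates=rates, observables=obs, objective=float(np.sum(residuals ** 2)),
        residuals=resid_map, missed=missed, best_restart=r_best, seed=seed,
        n_restarts=restarts, converged=True)


def save_rates(rates: RateSet, path, provenance: Mapping | None = None) -> None:
    payload = {"rates": rates.as_dict()}
    if provenance:
        payload["provenance"] = dict(provenance)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
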