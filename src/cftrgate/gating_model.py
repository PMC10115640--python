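"""Continuous-time Markov model of the CFTR gating cycle.

The model encodes the ATP-driven gating cycle of the phosphorylated CFTR
channel as a nine-state continuous-time Markov chain.  The two
nucleotide-binding domains (NBDs) of CFTR dimerize upon ATP binding;
conformational changes within the NBD-dimerized channel open the pore;
ATP hydrolysis at the catalytically competent ("consensus") site drives
the cycle forward through a post-hydrolytic open state, ADP release and
a dynamically isomerizing intermediate from which the channel either
rebinds ATP (remaining near-dimerized) or separates completely.

States
------
======  ===========  ==========  =========================================
name    NBD class    conducting  description
======  ===========  ==========  =========================================
SEP_apo  separated    no         NBDs apart, no nucleotide bound
SEP_atp  separated    no         NBDs apart, ATP bound at both sites
DIM_closed dimerized  no         tight NBD dimer, pore still closed
OPEN_pre dimerized    yes        pre-hydrolytic open burst
FLICKER  dimerized    no         brief flicker closure within the burst
OPEN_post dimerized   yes        post-hydrolytic (ADP·Pi) open state
DIM_ADP  dimerized    no         non-conductive dimer, ADP bound
INT_dimer dimerized   no         consensus site empty, dimer-like
INT_sep  separated    no         consensus site empty, NBDs apart
======  ===========  ==========  =========================================

Openings occur only from NBD-dimerized states, so the open probability can
never exceed the dimerization probability (coupling ratio <= 1 by
construction).  Two transitions are ATP-concentration dependent
(pseudo-first order): initial ATP association (``k_bind``) and ATP
rebinding to the isomerizing intermediate (``k6``).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.linalg import expm, solve

__all__ = [
    "GatingState",
    "RateSet",
    "StateGraph",
    "StatePath",
    "Protocol",
    "StationaryResult",
    "Relaxation",
    "build_topology",
    "stationary_distribution",
    "occupancy_relaxation",
    "simulate_ssa",
    "mean_class_dwell",
    "class_switch_frequency",
    "VARIANTS",
]

NBD_CLASSES = ("separated", "intermediate", "dimerized")
FRET_CLASSES = ("low", "mid", "high")

#: fret class implied by each NBD class (distance between the fluorophore
#: attachment points on NBD1/NBD2 tracks NBD approach)
_FRET_OF_NBD = {"separated": "low", "intermediate": "mid", "dimerized": "high"}


@dataclass(frozen=True)
class GatingState:
    """A single conformational/ligation state of the gating cycle."""

    name: str
    nbd_class: str
    pore_conducting: bool
    consensus_occupancy: str = "empty"
    degenerate_occupancy: str = "empty"

    def __post_init__(self) -> None:
        if self.nbd_class not in NBD_CLASSES:
            raise ValueError(f"unknown nbd_class {self.nbd_class!r}")
        if self.pore_conducting and self.nbd_class != "dimerized":
            raise ValueError(
                f"state {self.name}: a conducting pore requires dimerized NBDs"
            )

    @property
    def fret_class(self) -> str:
        return _FRET_OF_NBD[self.nbd_class]


_RATE_FIELDS = (
    "k_bind", "k_unbind", "k1", "k2", "k3", "k_flick_on", "k_flick_off",
    "k4", "k5", "k6", "k7_fwd", "k7_rev", "k8",
)

#: transitions whose rate is multiplied by the ATP concentration (molar)
ATP_PROPORTIONAL = frozenset({"k_bind", "k6"})


@dataclass(frozen=True)
class RateSet:
    """Rate constants of the gating cycle.

    Unimolecular rates are in s^-1; ``k_bind`` and ``k6`` are bimolecular
    ATP-association constants in M^-1 s^-1 and enter the generator as
    ``rate * [ATP]``.
    """

    k_bind: float      # ATP association to the separated channel (M^-1 s^-1)
    k_unbind: float    # ATP dissociation from the separated channel (s^-1)
    k1: float          # NBD dimerization with ATP at both sites (s^-1)
    k2: float          # rate-limiting conformational change opening the pore (s^-1)
    k3: float          # ATP hydrolysis at the consensus site (s^-1)
    k_flick_on: float  # entry into the flicker-closed substate (s^-1)
    k_flick_off: float # return from the flicker closure (s^-1)
    k4: float          # post-hydrolytic closure to the non-conductive dimer (s^-1)
    k5: float          # ADP release (s^-1)
    k6: float          # ATP rebinding to the isomerizing intermediate (M^-1 s^-1)
    k7_fwd: float      # intermediate isomerization, dimer-like -> separated-like (s^-1)
    k7_rev: float      # intermediate isomerization, separated-like -> dimer-like (s^-1)
    k8: float          # complete NBD separation from the intermediate (s^-1)

    def __post_init__(self) -> None:
        for name in _RATE_FIELDS:
            value = getattr(self, name)
            if not np.isfinite(value) or value < 0:
                raise ValueError(f"rate {name} must be finite and >= 0, got {value}")

    def replace(self, **overrides: float) -> "RateSet":
        unknown = set(overrides) - set(_RATE_FIELDS)
        if unknown:
            raise ValueError(f"unknown rate name(s): {sorted(unknown)}")
        return dataclasses.replace(self, **overrides)

    def scale(self, **factors: float) -> "RateSet":
        """Return a copy with the named rates multiplied by the given factors."""
        return self.replace(**{k: getattr(self, k) * f for k, f in factors.items()})

    def as_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in _RATE_FIELDS}

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "RateSet":
        return cls(**{name: float(d[name]) for name in _RATE_FIELDS})

    @classmethod
    def wt_calibrated(cls) -> "RateSet":
        """The wild-type rate set shipped with the package.

        These values are the output of :func:`cftrgate.calibration.calibrate_rates`
        run against the default experimental target set (see
        ``cftrgate/data/calibration_targets.yaml``); they can be regenerated
        with ``cftrgate calibrate``.
        """
        text = resources.files("cftrgate.data").joinpath("wt_rates.json").read_text()
        return cls.from_dict(json.loads(text)["rates"])


#: canonical state order
STATE_NAMES = (
    "SEP_apo", "SEP_atp", "DIM_closed", "OPEN_pre", "FLICKER",
    "OPEN_post", "DIM_ADP", "INT_dimer", "INT_sep",
)

# (from, to, rate name, ATP-proportional)
_EDGES = (
    ("SEP_apo", "SEP_atp", "k_bind", True),
    ("SEP_atp", "SEP_apo", "k_unbind", False),
    ("SEP_atp", "DIM_closed", "k1", False),
    ("DIM_closed", "OPEN_pre", "k2", False),
    ("OPEN_pre", "FLICKER", "k_flick_on", False),
    ("FLICKER", "OPEN_pre", "k_flick_off", False),
    ("OPEN_pre", "OPEN_post", "k3", False),
    ("OPEN_post", "DIM_ADP", "k4", False),
    ("DIM_ADP", "INT_dimer", "k5", False),
    ("INT_dimer", "DIM_closed", "k6", True),
    ("INT_dimer", "INT_sep", "k7_fwd", False),
    ("INT_sep", "INT_dimer", "k7_rev", False),
    ("INT_sep", "SEP_atp", "k8", False),
)

HYDROLYSIS_EDGE = ("OPEN_pre", "OPEN_post")


def _default_states(intermediate: Iterable[str] = ()) -> tuple[GatingState, ...]:
    """Build the canonical states, optionally re-classing some as intermediate."""
    intermediate = set(intermediate)
    state_spec = {
        "SEP_apo": ("separated", False, "empty", "empty"),
        "SEP_atp": ("separated", False, "ATP", "ATP"),
        "DIM_closed": ("dimerized", False, "ATP", "ATP"),
        "OPEN_pre": ("dimerized", True, "ATP", "ATP"),
        "FLICKER": ("dimerized", False, "ATP", "ATP"),
        "OPEN_post": ("dimerized", True, "ADP_Pi", "ATP"),
        "DIM_ADP": ("dimerized", False, "ADP", "ATP"),
        "INT_dimer": ("dimerized", False, "empty", "ATP"),
        "INT_sep": ("separated", False, "empty", "ATP"),
    }
    states = []
    for name, (nbd, cond, cons, deg) in state_spec.items():
        if name in intermediate:
            nbd, cond = "intermediate", False
        states.append(GatingState(name, nbd, cond, cons, deg))
    return tuple(states)


# Variant presets are qualitative: multiplicative adjustments of the
# calibrated wild-type rates that reproduce each variant's documented
# phenotype (see docs/methods.md).  ``intermediate`` lists states whose
# NBD approach is incomplete in that variant and which therefore emit at
# the variant's intermediate FRET value.
VARIANTS: dict[str, dict] = {
    "WT": {"scale": {}, "intermediate": ()},
    # catalytic-base substitution: no hydrolysis, NBD separation all but
    # abolished (non-hydrolytic closure is a rare event outside this model)
    "E1371Q": {"set": {"k3": 1e-6}, "intermediate": ()},
    # degenerate-site ATP stacking removed: no long-lived ATP retention,
    # rapid full separation and slowed re-dimerization (both sites must
    # reload), giving fast low/high cycling at roughly half the wild-type
    # dimerized occupancy
    "W401A": {"scale": {"k1": 0.02, "k7_fwd": 4.0, "k7_rev": 0.2, "k8": 30.0,
                        "k6": 0.3},
              "intermediate": ()},
    # consensus-site ATP stacking removed: opening nearly abolished and
    # dimerization/separation transitions slow and infrequent
    "Y1219A": {"scale": {"k1": 0.001, "k2": 0.04}, "intermediate": ()},
    # consensus-site G551D: ATP-bound channel arrests in an intermediate
    # NBD approach; opening is rare and hydrolysis nearly abolished
    "G551D": {"scale": {"k1": 0.1, "k2": 0.01, "k3": 0.4},
              "intermediate": ("DIM_closed", "INT_dimer")},
    # TM-hinge L927P: intermediate NBD approach with frequent but very
    # short-lived excursions to the tight dimer / open state
    "L927P": {"scale": {"k2": 0.2, "k3": 15.0, "k4": 15.0},
              "intermediate": ("DIM_closed", "INT_dimer")},
}


@dataclass(frozen=True)
class StateGraph:
    """The gating cycle as a labelled rate graph.

    ``generator(atp)`` returns the CTMC generator matrix Q at a given ATP
    concentration (molar): ``Q[i, j]`` is the rate i -> j for i != j and
    each row sums to zero.
    """

    states: tuple[GatingState, ...]
    rates: RateSet
    variant: str = "WT"
    phosphorylated: bool = True

    def __post_init__(self) -> None:
        if len({s.name for s in self.states}) != len(self.states):
            raise ValueError("duplicate state names")

    # --- index helpers -------------------------------------------------
    def index(self, name: str) -> int:
        for i, s in enumerate(self.states):
            if s.name == name:
                return i
        raise KeyError(name)

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def open_set(self) -> tuple[int, ...]:
        return tuple(i for i, s in enumerate(self.states) if s.pore_conducting)

    @property
    def dimer_set(self) -> tuple[int, ...]:
        """States counted as NBD-dimerized (dimerized or intermediate-dimer-like)."""
        return tuple(
            i for i, s in enumerate(self.states)
            if s.nbd_class in ("dimerized", "intermediate")
        )

    @property
    def fret_classes(self) -> tuple[str, ...]:
        return tuple(s.fret_class for s in self.states)

    def with_rates(self, rates: RateSet) -> "StateGraph":
        return dataclasses.replace(self, rates=rates)

    # --- generator -----------------------------------------------------
    def effective_rate(self, name: str) -> float:
        value = getattr(self.rates, name)
        if name == "k1" and not self.phosphorylated:
            return 0.0  # unphosphorylated R domain blocks NBD dimerization
        return value

    def edges(self, atp: float) -> list[tuple[int, int, str, float]]:
        out = []
        for src, dst, name, atp_dep in _EDGES:
            rate = self.effective_rate(name)
            if atp_dep:
                rate *= atp
            out.append((self.index(src), self.index(dst), name, rate))
        return out

    def generator(self, atp: float) -> np.ndarray:
        if atp < 0:
            raise ValueError("ATP concentration must be >= 0")
        n = self.n_states
        q = np.zeros((n, n))
        for i, j, _name, rate in self.edges(atp):
            q[i, j] += rate
        np.fill_diagonal(q, q.diagonal() - q.sum(axis=1))
        return q

    @property
    def hydrolysis_edge(self) -> tuple[int, int]:
        return self.index(HYDROLYSIS_EDGE[0]), self.index(HYDROLYSIS_EDGE[1])


def build_topology(
    variant: str = "WT",
    overrides: Mapping[str, float] | None = None,
    rates: RateSet | None = None,
    phosphorylated: bool = True,
) -> StateGraph:
    """Build the canonical nine-state gating-cycle graph for a variant.

    Parameters
    ----------
    variant:
        One of ``WT, E1371Q, W401A, Y1219A, G551D, L927P``.  Non-WT
        variants apply the documented preset adjustments on top of the
        base rates.
    overrides:
        Optional explicit rate overrides (applied after the preset).
    rates:
        Base rate set; defaults to the calibrated wild-type rates.
    phosphorylated:
        When False the R domain blocks dimerization (k1 forced to 0 in
        the generator).
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; known: {sorted(VARIANTS)}")
    preset = VARIANTS[variant]
    base = rates if rates is not None else RateSet.wt_calibrated()
    if preset.get("scale"):
        base = base.scale(**preset["scale"])
    if preset.get("set"):
        base = base.replace(**preset["set"])
    if overrides:
        base = base.replace(**overrides)  # raises on unknown/negative rates
    states = _default_states(preset.get("intermediate", ()))
    return StateGraph(states=states, rates=base, variant=variant,
                      phosphorylated=phosphorylated)


# ---------------------------------------------------------------------------
# deterministic computations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StationaryResult:
    pi: np.ndarray
    po: float
    pdim: float
    turnover_per_s: float


def _stationary_pi(q: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    n = q.shape[0]
    a = q.T.copy()
    a[-1, :] = 1.0  # replace one balance equation with the normalization
    b = np.zeros(n)
    b[-1] = 1.0
    pi = solve(a, b)
    resid = float(np.abs(q.T @ pi).max())
    if resid > tol or not np.isfinite(pi).all():
        raise np.linalg.LinAlgError(
            f"stationary solve failed (residual {resid:.2e}); generator may be "
            "reducible at this ATP concentration"
        )
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def stationary_distribution(graph: StateGraph, atp: float) -> StationaryResult:
    """Exact stationary occupancy and its summary observables.

    Solves ``Q^T pi = 0`` with ``sum(pi) = 1``.  ``po`` sums occupancy over
    conducting states, ``pdim`` over NBD-dimerized (and intermediate)
    states, and the turnover rate is the stationary hydrolysis flux
    ``k3 * pi(OPEN_pre)`` in ATP per channel per second.
    """
    if atp <= 0:
        raise ValueError("stationary distribution requires ATP > 0")
    q = graph.generator(atp)
    pi = _stationary_pi(q)
    i_pre, _ = graph.hydrolysis_edge
    return StationaryResult(
        pi=pi,
        po=float(pi[list(graph.open_set)].sum()),
        pdim=float(pi[list(graph.dimer_set)].sum()),
        turnover_per_s=float(graph.effective_rate("k3") * pi[i_pre]),
    )


@dataclass(frozen=True)
class Relaxation:
    """Deterministic occupancy relaxation p(t) on a uniform time grid."""

    times: np.ndarray
    occupancy: np.ndarray  # shape (n_times, n_states)
    open_set: tuple[int, ...]
    dimer_set: tuple[int, ...]

    @property
    def po(self) -> np.ndarray:
        return self.occupancy[:, list(self.open_set)].sum(axis=1)

    @property
    def pdim(self) -> np.ndarray:
        return self.occupancy[:, list(self.dimer_set)].sum(axis=1)


def occupancy_relaxation(
    graph: StateGraph,
    initial: Sequence[float],
    atp: float,
    horizon_s: float,
    grid_s: float,
) -> Relaxation:
    """Solve the master equation dp/dt = Q^T p on a uniform grid.

    Uses one matrix exponential of the generator over a single grid step,
    then propagates; exact for a time-homogeneous generator.
    """
    p0 = np.asarray(initial, dtype=float)
    if p0.shape != (graph.n_states,):
        raise ValueError("initial occupancy has wrong length")
    if abs(p0.sum() - 1.0) > 1e-8 or (p0 < -1e-12).any():
        raise ValueError("initial occupancy must be a probability vector")
    if horizon_s <= 0 or grid_s <= 0:
        raise ValueError("horizon and grid must be positive")
    n_steps = int(round(horizon_s / grid_s))
    step = expm(graph.generator(atp).T * grid_s)
    occ = np.empty((n_steps + 1, graph.n_states))
    occ[0] = p0
    for k in range(n_steps):
        occ[k + 1] = step @ occ[k]
    times = np.arange(n_steps + 1) * grid_s
    return Relaxation(times=times, occupancy=occ,
                      open_set=graph.open_set, dimer_set=graph.dimer_set)


# ---------------------------------------------------------------------------
# protocols and stochastic simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Protocol:
    """Piecewise-constant ATP protocol.

    ``atp_schedule`` is a list of ``(start_s, atp_molar)`` pairs with
    strictly increasing start times beginning at 0.  ADP is not modelled.
    """

    duration_s: float
    atp_schedule: tuple[tuple[float, float], ...] = ((0.0, 3e-3),)
    phosphorylated: bool = True
    adp_molar: float = 0.0
    temperature_c: float | None = 25.0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")
        if not self.atp_schedule:
            raise ValueError("empty ATP schedule")
        starts = [s for s, _ in self.atp_schedule]
        if starts[0] != 0.0 or any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("schedule start times must strictly increase from 0")
        if any(c < 0 for _, c in self.atp_schedule):
            raise ValueError("ATP concentrations must be >= 0")

    def atp_at(self, t: float) -> float:
        atp = self.atp_schedule[0][1]
        for start, conc in self.atp_schedule:
            if t >= start:
                atp = conc
            else:
                break
        return atp

    def breakpoints(self) -> list[float]:
        return [s for s, _ in self.atp_schedule[1:] if s < self.duration_s]


@dataclass
class StatePath:
    """A simulated trajectory: (state, entry time, dwell) segments tiling
    [0, duration]."""

    states: np.ndarray        # int indices into graph.states
    entry_s: np.ndarray
    dwell_s: np.ndarray
    protocol: Protocol
    hydrolysis_events: np.ndarray
    seed: int
    state_names: tuple[str, ...] = STATE_NAMES

    @property
    def duration_s(self) -> float:
        return float(self.entry_s[-1] + self.dwell_s[-1])

    def state_time_fractions(self, n_states: int | None = None) -> np.ndarray:
        n = n_states or len(self.state_names)
        out = np.zeros(n)
        np.add.at(out, self.states, self.dwell_s)
        return out / out.sum()

    def segments(self) -> Iterable[tuple[int, float, float]]:
        return zip(self.states.tolist(), self.entry_s.tolist(), self.dwell_s.tolist())

    def to_csv(self, path, sidecar: bool = True) -> None:
        import hashlib

        import pandas as pd

        df = pd.DataFrame({
            "state": [self.state_names[i] for i in self.states],
            "entry_s": self.entry_s,
            "dwell_s": self.dwell_s,
        })
        df.to_csv(path, index=False)
        if sidecar:
            meta = {
                "seed": int(self.seed),
                "duration_s": self.duration_s,
                "n_hydrolysis_events": int(len(self.hydrolysis_events)),
                "protocol": {
                    "phosphorylated": self.protocol.phosphorylated,
                    "atp_schedule": [list(x) for x in self.protocol.atp_schedule],
                    "duration_s": self.protocol.duration_s,
                },
            }
            meta["protocol_hash"] = hashlib.sha256(
                json.dumps(meta["protocol"], sort_keys=True).encode()
            ).hexdigest()[:16]
            with open(str(path) + ".json", "w") as fh:
                json.dump(meta, fh, indent=1)


def simulate_ssa(
    graph: StateGraph,
    protocol: Protocol,
    seed: int,
    initial_state: int | str | None = None,
) -> StatePath:
    """Exact Gillespie simulation of the gating cycle under a protocol.

    At each ATP-schedule breakpoint the pending dwell is re-drawn under the
    new generator; this is exact because exponential holding times are
    memoryless.  Hydrolysis events record each firing of the consensus-site
    hydrolysis transition.  Identical (graph, protocol, seed) inputs give
    identical paths.
    """
    rng = np.random.default_rng(seed)
    graph = dataclasses.replace(graph, phosphorylated=protocol.phosphorylated)
    if initial_state is None:
        state = graph.index("SEP_apo")
    elif isinstance(initial_state, str):
        state = graph.index(initial_state)
    else:
        state = int(initial_state)

    i_pre, i_post = graph.hydrolysis_edge
    breakpoints = protocol.breakpoints() + [protocol.duration_s]
    epoch_start = 0.0
    t = 0.0
    states, entries, dwells, hydrolysis = [], [], [], []

    def emit(s: int, t0: float, t1: float) -> None:
        if t1 <= t0:
            return
        if states and states[-1] == s and np.isclose(entries[-1] + dwells[-1], t0):
            dwells[-1] += t1 - t0  # merge across breakpoint redraws
        else:
            states.append(s)
            entries.append(t0)
            dwells.append(t1 - t0)

    for bp in breakpoints:
        atp = protocol.atp_at(epoch_start)
        q = graph.generator(atp)
        while t < bp:
            out_rates = q[state].copy()
            out_rates[state] = 0.0
            total = out_rates.sum()
            if total <= 0.0:
                emit(state, t, bp)  # absorbing under this generator
                t = bp
                break
            dwell = rng.exponential(1.0 / total)
            if t + dwell >= bp:
                emit(state, t, bp)  # memoryless redraw at the breakpoint
                t = bp
                break
            nxt = int(rng.choice(len(out_rates), p=out_rates / total))
            emit(state, t, t + dwell)
            t += dwell
            if state == i_pre and nxt == i_post:
                hydrolysis.append(t)
            state = nxt
        epoch_start = bp
    return StatePath(
        states=np.array(states, dtype=int),
        entry_s=np.array(entries),
        dwell_s=np.array(dwells),
        protocol=protocol,
        hydrolysis_events=np.array(hydrolysis),
        seed=int(seed),
        state_names=tuple(s.name for s in graph.states),
    )


# ---------------------------------------------------------------------------
# first-passage utilities (deterministic dwell means)
# ---------------------------------------------------------------------------


def mean_class_dwell(
    graph: StateGraph,
    atp: float,
    members: Sequence[int],
    bridge_s: float = 0.0,
) -> float:
    """Stationary mean aggregated sojourn time in a set of states.

    With ``bridge_s > 0`` an excursion out of the set shorter than
    ``bridge_s`` (for example a flicker closure within an open burst) is
    bridged: its duration is included in the sojourn and the sojourn
    continues on return.  Computed exactly from the generator by
    first-passage linear algebra; entries into the set are weighted by
    stationary flux.
    """
    q = graph.generator(atp)
    pi = _stationary_pi(q)
    n = graph.n_states
    members = sorted(set(int(m) for m in members))
    others = [i for i in range(n) if i not in members]
    if not members or not others:
        raise ValueError("member set must be a proper non-empty subset")
    q_cc = q[np.ix_(members, members)]
    q_cn = q[np.ix_(members, others)]
    ones_c = np.ones(len(members))

    # mean sojourn and exit distribution of the un-bridged aggregate
    a = solve(q_cc, -ones_c)           # E[time to leave the set | start state]
    m_exit = solve(q_cc, -q_cn)        # P(exit into state n | start state)

    if bridge_s > 0.0:
        q_nn = q[np.ix_(others, others)]
        q_nc = q[np.ix_(others, members)]
        e_tau = expm(q_nn * bridge_s)
        ones_n = np.ones(len(others))
        # W[n, j] = P(return to the set at j within bridge_s | left into n)
        w = solve(q_nn, (e_tau - np.eye(len(others))) @ q_nc)
        # E[min(T_return, bridge) contribution for bridged gaps]
        int_surv = solve(q_nn, (e_tau - np.eye(len(others))) @ ones_n)
        gap = int_surv - bridge_s * (e_tau @ ones_n)
        u = solve(np.eye(len(members)) - m_exit @ w, a + m_exit @ gap)
    else:
        u = a

    # stationary entry flux into the set
    flux = np.array([pi[others] @ q[np.ix_(others, [j])].ravel() for j in members])
    if flux.sum() <= 0:
        raise ValueError("no stationary flux into the aggregate")
    entry = flux / flux.sum()
    return float(entry @ u)


def class_switch_frequency(graph: StateGraph, atp: float) -> float:
    """Stationary frequency (s^-1) of switches between the low-FRET class
    and the mid/high-FRET classes — the model-level analogue of the
    transition frequency measured from idealized traces."""
    q = graph.generator(atp)
    pi = _stationary_pi(q)
    low = np.array([s.fret_class == "low" for s in graph.states])
    freq = 0.0
    for i in range(graph.n_states):
        for j in range(graph.n_states):
            if i != j and low[i] != low[j]:
                freq += pi[i] * q[i, j]
    return float(freq)
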