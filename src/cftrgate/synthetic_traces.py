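"""Synthetic smFRET and single-channel observables.

Renders simulated state paths into the two kinds of raw data the analysis
chain consumes:

* camera-integrated two-colour fluorescence traces (donor/acceptor
  intensities per frame) with Gaussian intensity noise, single-step donor
  photobleaching and transient donor blinking;
* low-pass-filtered single-channel current traces with a single open
  conductance level.

Frame integration is explicit: the noise-free FRET value of a frame is the
dwell-time-weighted average of the state emission means within that frame,
so fast transitions are genuinely blurred at long integration times.
During donor dark periods (blinking, and permanently after bleaching) the
donor is not excited and neither channel emits; such frames carry only
noise and are flagged dark in the truth annotations.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal

from .gating_model import Protocol, StateGraph, StatePath, simulate_ssa

__all__ = [
    "EmissionModel", "FretTrace", "CurrentTrace", "FretEnsemble",
    "render_fret_trace", "render_current_trace", "generate_ensemble",
]

#: FRET emission means of the NBD-separated state: the apo channel sits at
#: 0.25; nucleotide binding shifts the separated-state emission to 0.28
#: without a global conformational change.
LOW_FRET_APO = 0.25
LOW_FRET_ATP = 0.28
HIGH_FRET = 0.49
MID_FRET_BY_VARIANT = {"G551D": 0.37, "L927P": 0.31}


@dataclass(frozen=True)
class EmissionModel:
    """Emission parameters for rendering FRET traces.

    ``intensity_noise_sd`` is the per-channel, per-frame Gaussian noise in
    the same arbitrary units as ``total_intensity``.  The defaults give a
    realized FRET standard deviation of ~0.05 and a total-intensity
    signal-to-noise ratio of ~10 at 100 ms integration.
    """

    fret_means: dict = field(
        default_factory=lambda: {"low": LOW_FRET_ATP, "mid": 0.37, "high": HIGH_FRET})
    total_intensity: float = 1000.0
    intensity_noise_sd: float = 70.0
    frame_ms: float = 100.0
    donor_bleach_mean_s: float = 30.0
    blink_rate_per_s: float = 0.02
    blink_mean_dur_s: float = 0.3
    background: float = 0.0

    def __post_init__(self) -> None:
        for k, v in self.fret_means.items():
            if not 0.0 < v < 1.0:
                raise ValueError(f"FRET mean {k}={v} outside (0, 1)")
        if self.intensity_noise_sd <= 0 or self.frame_ms <= 0:
            raise ValueError("noise sd and frame duration must be positive")

    @property
    def frame_s(self) -> float:
        return self.frame_ms / 1000.0

    @classmethod
    def for_condition(cls, atp_molar: float, variant: str = "WT",
                      **overrides) -> "EmissionModel":
        means = {
            "low": LOW_FRET_APO if atp_molar <= 0 else LOW_FRET_ATP,
            "mid": MID_FRET_BY_VARIANT.get(variant, 0.37),
            "high": HIGH_FRET,
        }
        return cls(fret_means=means, **overrides)

    def snr(self) -> float:
        """Nominal total-intensity signal-to-noise ratio: mean total
        intensity divided by the within-state sd of total intensity."""
        return self.total_intensity / (np.sqrt(2.0) * self.intensity_noise_sd)


@dataclass
class FretTrace:
    """A frame-sampled two-colour fluorescence trace.

    ``truth`` fields are generator-side annotations (per-frame true FRET
    class, the noise-free FRET value, bleach time and blink intervals);
    they exist only for synthetic traces and are never used by the
    analysis code paths under test.
    """

    trace_id: str
    times_s: np.ndarray
    donor: np.ndarray
    acceptor: np.ndarray
    frame_s: float
    true_class: np.ndarray | None = None      # low/mid/high/dark per frame
    true_fret: np.ndarray | None = None       # nan on dark frames
    bleach_time_s: float | None = None
    blink_intervals: tuple = ()
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.donor) != len(self.acceptor) or len(self.donor) != len(self.times_s):
            raise ValueError("channel arrays must have equal length")

    @property
    def n_frames(self) -> int:
        return len(self.times_s)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "trace_id": self.trace_id,
            "frame": np.arange(self.n_frames),
            "time_s": self.times_s,
            "donor": self.donor,
            "acceptor": self.acceptor,
        })


@dataclass
class CurrentTrace:
    """A filtered single-channel current trace (pA)."""

    times_s: np.ndarray
    current_pA: np.ndarray
    open_amplitude_pA: float
    filter_hz: float
    noise_sd_pA: float
    true_conducting: np.ndarray | None = None
    seed: int | None = None


def _emitting_intervals(duration: float, bleach_t: float, blinks) -> list:
    """[0, bleach) minus blink intervals, as sorted disjoint intervals."""
    edge = min(bleach_t, duration)
    intervals = [(0.0, edge)]
    for b0, b1 in blinks:
        out = []
        for a0, a1 in intervals:
            if b1 <= a0 or b0 >= a1:
                out.append((a0, a1))
                continue
            if b0 > a0:
                out.append((a0, b0))
            if b1 < a1:
                out.append((b1, a1))
        intervals = out
    return [(a, b) for a, b in intervals if b > a]


def render_fret_trace(
    path: StatePath,
    emission: EmissionModel,
    seed: int,
    graph: StateGraph | None = None,
    fret_classes: Sequence[str] | None = None,
    trace_id: str = "trace0",
) -> FretTrace:
    """Render a state path into a camera-integrated FRET trace.

    ``fret_classes`` gives the FRET class of each state index; it defaults
    to the classes of ``graph`` (one of which must be provided).
    """
    if fret_classes is None:
        if graph is None:
            raise ValueError("need graph or fret_classes")
        fret_classes = graph.fret_classes
    dt = emission.frame_s
    duration = path.duration_s
    n_frames = int(np.floor(duration / dt + 1e-9))
    if n_frames < 1:
        raise ValueError("path shorter than one camera frame")

    rng = np.random.default_rng(seed)
    bleach_t = rng.exponential(emission.donor_bleach_mean_s)
    # donor blinking: Poisson-distributed dark intervals before bleaching
    blinks = []
    t = rng.exponential(1.0 / emission.blink_rate_per_s) if emission.blink_rate_per_s > 0 else np.inf
    while t < min(bleach_t, duration):
        d = rng.exponential(emission.blink_mean_dur_s)
        blinks.append((t, min(t + d, min(bleach_t, duration))))
        t = t + d + rng.exponential(1.0 / emission.blink_rate_per_s)

    emit_iv = _emitting_intervals(duration, bleach_t, blinks)
    state_mean = np.array([emission.fret_means[c] for c in fret_classes])

    # accumulate emitting time and emitting-time-weighted FRET per frame
    w = np.zeros(n_frames)          # emitting seconds within each frame
    wf = np.zeros(n_frames)         # sum of emitting seconds * state FRET mean
    class_time = {}                 # per-frame dwell time per fret class
    cls_w = np.zeros((n_frames, 3))
    cls_index = {"low": 0, "mid": 1, "high": 2}
    for s, t0, d in path.segments():
        t1 = t0 + d
        # truth class occupancy uses the full frame time (bleach-independent)
        f0, f1 = int(t0 / dt), min(int(np.ceil(t1 / dt)), n_frames)
        for f in range(f0, f1):
            ov = min(t1, (f + 1) * dt) - max(t0, f * dt)
            if ov > 0:
                cls_w[f, cls_index[fret_classes[s]]] += ov
        for a0, a1 in emit_iv:
            lo, hi = max(t0, a0), min(t1, a1)
            if hi <= lo:
                continue
            g0, g1 = int(lo / dt), min(int(np.ceil(hi / dt)), n_frames)
            for f in range(g0, g1):
                ov = min(hi, (f + 1) * dt) - max(lo, f * dt)
                if ov > 0:
                    w[f] += ov
                    wf[f] += ov * state_mean[s]

    frac = w / dt
    with np.errstate(invalid="ignore", divide="ignore"):
        fret_frame = np.where(w > 0, wf / np.maximum(w, 1e-300), np.nan)
    acceptor = emission.total_intensity * np.nan_to_num(fret_frame) * frac
    donor = emission.total_intensity * (1.0 - np.nan_to_num(fret_frame)) * frac
    acceptor = acceptor + emission.background + rng.normal(
        0.0, emission.intensity_noise_sd, n_frames)
    donor = donor + emission.background + rng.normal(
        0.0, emission.intensity_noise_sd, n_frames)

    dark = frac < 0.5
    dominant = np.array(["low", "mid", "high"])[cls_w.argmax(axis=1)]
    true_class = np.where(dark, "dark", dominant)
    true_fret = np.where(dark, np.nan, fret_frame)
    return FretTrace(
        trace_id=trace_id,
        times_s=np.arange(n_frames) * dt,
        donor=donor,
        acceptor=acceptor,
        frame_s=dt,
        true_class=true_class,
        true_fret=true_fret,
        bleach_time_s=float(bleach_t) if bleach_t < duration else None,
        blink_intervals=tuple(blinks),
        seed=int(seed),
    )


def render_current_trace(
    path: StatePath,
    amplitude_pA: float = 1.0,
    filter_hz: float = 100.0,
    noise_sd_pA: float = 0.15,
    sample_hz: float = 2000.0,
    seed: int = 0,
    graph: StateGraph | None = None,
    conducting: Sequence[bool] | None = None,
) -> CurrentTrace:
    """Render a state path into a low-pass-filtered current trace.

    The raw signal is a boxcar at ``amplitude_pA`` whenever the pore
    conducts plus white Gaussian noise, filtered with a 4-pole low-pass
    Bessel filter (the electrophysiology convention; applied causally, so
    fast flickers are attenuated exactly as in filtered recordings).
    """
    if amplitude_pA <= 0:
        raise ValueError("open amplitude must be positive")
    if sample_hz < 10 * filter_hz:
        raise ValueError("sampling rate must be at least 10x the filter corner")
    if conducting is None:
        if graph is None:
            raise ValueError("need graph or conducting flags")
        conducting = [s.pore_conducting for s in graph.states]
    conducting = np.asarray(conducting, dtype=bool)

    n = int(np.floor(path.duration_s * sample_hz))
    times = np.arange(n) / sample_hz
    open_flag = np.zeros(n, dtype=bool)
    for s, t0, d in path.segments():
        if conducting[s]:
            i0 = int(np.ceil(t0 * sample_hz - 1e-9))
            i1 = min(int(np.floor((t0 + d) * sample_hz + 1e-9)) + 1, n)
            open_flag[i0:i1] = True
    rng = np.random.default_rng(seed)
    raw = amplitude_pA * open_flag + rng.normal(0.0, noise_sd_pA, n)
    sos = signal.bessel(4, filter_hz, btype="low", fs=sample_hz, output="sos")
    filtered = signal.sosfilt(sos, raw)
    return CurrentTrace(
        times_s=times,
        current_pA=filtered,
        open_amplitude_pA=amplitude_pA,
        filter_hz=filter_hz,
        noise_sd_pA=noise_sd_pA,
        true_conducting=open_flag,
        seed=int(seed),
    )


@dataclass
class FretEnsemble:
    traces: list
    paths: list
    graph: StateGraph
    protocol: Protocol
    emission: EmissionModel
    seed: int

    def __len__(self) -> int:
        return len(self.traces)

    def to_frame(self):
        import pandas as pd

        return pd.concat([t.to_frame() for t in self.traces], ignore_index=True)


def _draw_initial_states(graph, protocol, n, rng):
    """Stationary initial states where defined; otherwise the separated
    pool with ATP bound at its binding equilibrium (or plain apo)."""
    from .gating_model import stationary_distribution

    atp0 = protocol.atp_at(0.0)
    eff_graph = dataclasses.replace(graph, phosphorylated=protocol.phosphorylated)
    if atp0 > 0 and protocol.phosphorylated:
        try:
            pi = stationary_distribution(eff_graph, atp0).pi
            return rng.choice(graph.n_states, size=n, p=pi)
        except np.linalg.LinAlgError:
            pass
    if atp0 > 0:
        kb, ku = graph.rates.k_bind * atp0, graph.rates.k_unbind
        p_bound = kb / (kb + ku) if kb + ku > 0 else 0.0
        bound = rng.random(n) < p_bound
        return np.where(bound, graph.index("SEP_atp"), graph.index("SEP_apo"))
    return np.full(n, graph.index("SEP_apo"))


def generate_ensemble(
    graph: StateGraph,
    protocol: Protocol,
    n_traces: int,
    emission: EmissionModel,
    seed: int,
) -> FretEnsemble:
    """Simulate and render an ensemble of independent FRET traces.

    Per-trace seeds are derived deterministically from the master seed.
    Initial states are drawn from the stationary distribution of the
    starting condition, so steady-state ensembles are stationary from the
    first frame.
    """
    if n_traces < 1:
        raise ValueError("n_traces must be >= 1")
    master = np.random.default_rng(seed)
    sub_seeds = master.integers(0, 2**31 - 1, size=(n_traces, 2))
    init_states = _draw_initial_states(graph, protocol, n_traces, master)
    traces, paths = [], []
    for k in range(n_traces):
        path = simulate_ssa(graph, protocol, seed=int(sub_seeds[k, 0]),
                            initial_state=int(init_states[k]))
        trace = render_fret_trace(path, emission, seed=int(sub_seeds[k, 1]),
                                  graph=graph, trace_id=f"trace{k:04d}")
        traces.append(trace)
        paths.append(path)
    return FretEnsemble(traces=traces, paths=paths, graph=graph,
                        protocol=protocol, emission=emission, seed=int(seed))
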