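"""Dwell-time, dose-response and relaxation analysis.

This module computes the summary statistics of gating kinetics used
throughout the package: aggregated dwell-time tables with flicker
bridging, censoring-aware exponential survival fits, Hill dose-response
fits (coefficient fixed to 1 by default), mono/bi-exponential relaxation
fits, the coupling ratio between open and dimerization probabilities,
and the low/high FRET class transition frequency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, minimize

__all__ = [
    "DwellTable", "DoseResponseFit", "RelaxationFit", "SurvivalFit",
    "extract_dwells", "fit_survival", "fit_hill", "fit_relaxation",
    "coupling_ratio", "transition_frequency", "segments_from_labels",
]


@dataclass
class DwellTable:
    """Aggregated sojourn times; ``data`` has columns
    trace_id, state_label, start_s, dwell_s, censored."""

    data: pd.DataFrame

    def dwells(self, label: str, include_censored: bool = False) -> np.ndarray:
        d = self.data[self.data.state_label == label]
        if not include_censored:
            d = d[~d.censored]
        return d.dwell_s.to_numpy()

    def mean_dwell(self, label: str, include_censored: bool = False) -> float:
        values = self.dwells(label, include_censored)
        if len(values) == 0:
            raise ValueError(f"no dwells for label {label!r}")
        return float(values.mean())

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def segments_from_labels(labels: Sequence, frame_s: float):
    """Collapse per-frame labels into (label, start_s, duration_s) runs."""
    segs = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            segs.append((labels[start], start * frame_s, (i - start) * frame_s))
            start = i
    return segs


def extract_dwells(
    traces,
    aggregate_map: Mapping,
    bridge_s: float = 0.0,
    frame_s: float | None = None,
) -> DwellTable:
    """Extract maximal aggregated sojourns from idealized traces or state
    paths.

    Parameters
    ----------
    traces:
        Either a single object or a list.  Each item may be a
        :class:`~cftrgate.gating_model.StatePath` (continuous segments), a
        sequence of per-frame labels (requires ``frame_s``), or an
        ``IdealizedTrace``.
    aggregate_map:
        Mapping from raw state names/labels to aggregate class names.
        Raw states absent from the mapping are treated as "other":
        they interrupt sojourns (subject to bridging) but produce no rows.
    bridge_s:
        Interruptions shorter than this are bridged into the surrounding
        sojourn of the same class (their time included).

    The first and last sojourn of each trace are marked censored (their
    true duration is cut by the observation window).
    """
    if bridge_s < 0:
        raise ValueError("bridge_s must be >= 0")
    items = traces if isinstance(traces, (list, tuple)) else [traces]
    if not items:
        raise ValueError("no traces given")
    all_rows = []
    for k, item in enumerate(items):
        segments, trace_id = _as_segments(item, frame_s, default_id=k)
        rows = _merge_sojourns(segments, aggregate_map, bridge_s, trace_id)
        if rows:
            first, last = 0, len(rows) - 1
            for idx, (tid, label, s0, d) in enumerate(rows):
                all_rows.append((tid, label, s0, d, idx in (first, last)))
    df = pd.DataFrame(
        all_rows, columns=["trace_id", "state_label", "start_s", "dwell_s", "censored"]
    )
    if len(df) == 0:
        raise ValueError("no aggregated sojourns found")
    return DwellTable(df)


def _as_segments(item, frame_s, default_id):
    from .gating_model import StatePath

    if isinstance(item, StatePath):
        names = item.state_names
        return (
            [(names[s], t0, d) for s, t0, d in item.segments()],
            getattr(item, "seed", default_id),
        )
    if hasattr(item, "labels") and hasattr(item, "frame_s"):  # IdealizedTrace
        return (
            segments_from_labels(list(item.labels), item.frame_s),
            getattr(item, "trace_id", default_id),
        )
    if frame_s is None:
        raise ValueError("frame_s is required for per-frame label sequences")
    return segments_from_labels(list(item), frame_s), default_id


def _merge_sojourns(segments, aggregate_map, bridge_s, trace_id):
    """Maximal sojourns per aggregate class with short-gap bridging."""
    rows = []
    current = None  # [label, start, end]
    pending_gap = 0.0
    for raw, start, dur in segments:
        label = aggregate_map.get(raw)
        if current is None:
            if label is not None:
                current = [label, start, start + dur]
            continue
        if label == current[0]:
            current[2] = start + dur  # contiguous or bridged continuation
            pending_gap = 0.0
        elif label is None:
            pending_gap += dur
            if pending_gap >= bridge_s:
                rows.append((trace_id, current[0], current[1], current[2] - current[1]))
                current, pending_gap = None, 0.0
        else:
            rows.append((trace_id, current[0], current[1], current[2] - current[1]))
            current = [label, start, start + dur]
            pending_gap = 0.0
    if current is not None:
        rows.append((trace_id, current[0], current[1], current[2] - current[1]))
    return rows


# ---------------------------------------------------------------------------
# survival / exponential mixture fits
# ---------------------------------------------------------------------------


@dataclass
class SurvivalFit:
    rates: np.ndarray       # per-second, ascending
    weights: np.ndarray
    n_components: int
    log_likelihood: float
    bic: float
    n_uncensored: int
    converged: bool = True

    @property
    def taus(self) -> np.ndarray:
        return 1.0 / self.rates[::-1]  # ascending time constants


def _exp_mixture_nll(params, t, censored, k):
    # params: log rates (k), logit weights (k-1)
    rates = np.exp(params[:k])
    if k > 1:
        w = np.concatenate([params[k:], [0.0]])
        w = np.exp(w - w.max())
        w = w / w.sum()
    else:
        w = np.ones(1)
    dens = np.zeros_like(t)
    surv = np.zeros_like(t)
    for r, wi in zip(rates, w):
        dens += wi * r * np.exp(-r * t)
        surv += wi * np.exp(-r * t)
    ll = np.where(censored, np.log(np.maximum(surv, 1e-300)),
                  np.log(np.maximum(dens, 1e-300)))
    return -ll.sum()


def fit_survival(
    dwells: DwellTable | np.ndarray,
    n_components: int = 1,
    label: str | None = None,
    censored: np.ndarray | None = None,
    min_uncensored_per_component: int = 50,
) -> SurvivalFit:
    """Maximum-likelihood exponential(-mixture) fit with right censoring.

    Censored sojourns (trace boundaries) contribute survival terms rather
    than density terms, which avoids the upward rate bias of discarding
    them.  The BIC of the 1-component fit is always reported alongside so
    mixture support can be assessed.
    """
    if isinstance(dwells, DwellTable):
        if label is None:
            labels = dwells.data.state_label.unique()
            if len(labels) != 1:
                raise ValueError("label is required for multi-class tables")
            label = labels[0]
        sub = dwells.data[dwells.data.state_label == label]
        t = sub.dwell_s.to_numpy(dtype=float)
        cens = sub.censored.to_numpy(dtype=bool)
    else:
        t = np.asarray(dwells, dtype=float)
        cens = (np.zeros(len(t), dtype=bool) if censored is None
                else np.asarray(censored, dtype=bool))
    if len(t) == 0 or (t <= 0).any():
        raise ValueError("dwells must be positive and non-empty")
    n_unc = int((~cens).sum())
    if n_unc == 0 or np.ptp(t[~cens]) == 0 and n_unc > 1:
        raise ValueError("degenerate dwell sample")
    if n_unc < min_uncensored_per_component * n_components:
        warnings.warn(
            f"only {n_unc} uncensored dwells for {n_components} component(s); "
            "estimates may be unstable", stacklevel=2)

    k = n_components
    mean_t = t[~cens].mean()
    if k == 1:
        # closed-form MLE with right censoring: rate = n_unc / total time
        rate = n_unc / t.sum()
        nll = _exp_mixture_nll(np.log([rate]), t, cens, 1)
        bic = 2 * nll + 1 * np.log(len(t))
        return SurvivalFit(np.array([rate]), np.array([1.0]), 1, -nll, bic, n_unc)
    x0 = np.concatenate([np.log(1.0 / (mean_t * np.geomspace(0.3, 3.0, k))),
                         np.zeros(k - 1)])
    res = minimize(_exp_mixture_nll, x0, args=(t, cens, k), method="Nelder-Mead",
                   options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10})
    rates = np.exp(res.x[:k])
    w = np.concatenate([res.x[k:], [0.0]])
    w = np.exp(w - w.max())
    w = w / w.sum()
    order = np.argsort(rates)
    nll = res.fun
    bic = 2 * nll + (2 * k - 1) * np.log(len(t))
    return SurvivalFit(rates[order], w[order], k, -nll, bic, n_unc,
                       converged=bool(res.success))


# ---------------------------------------------------------------------------
# Hill dose-response fit
# ---------------------------------------------------------------------------


@dataclass
class DoseResponseFit:
    ec50_molar: float
    amplitude: float
    hill_n: float
    residuals: np.ndarray
    fixed_n: bool
    flagged: str | None = None

    @property
    def ec50_uM(self) -> float:
        return self.ec50_molar * 1e6


def fit_hill(
    dose: Sequence[float],
    response: Sequence[float],
    fix_n: bool = True,
    weights: Sequence[float] | None = None,
) -> DoseResponseFit:
    """Least-squares Hill fit ``A * c^n / (c^n + EC50^n)``; n is fixed to 1
    by default.  EC50 is scale-equivariant in the dose units."""
    c = np.asarray(dose, dtype=float)
    y = np.asarray(response, dtype=float)
    if len(c) < 4:
        raise ValueError("need at least 4 doses")
    if (c <= 0).any() or (y < 0).any():
        raise ValueError("doses must be positive and responses >= 0")
    sigma = None if weights is None else 1.0 / np.asarray(weights, dtype=float)
    ec50_0 = float(np.exp(np.interp(0.5 * y.max(), y / max(y.max(), 1e-12),
                                    np.log(c)))) if y.max() > 0 else np.median(c)
    flagged = None
    if ec50_0 <= c.min() * 1.01 or ec50_0 >= c.max() * 0.99:
        flagged = "midpoint at or outside the dose range"
    if fix_n:
        def model(cc, a, ec50):
            return a * cc / (cc + ec50)
        p0 = [max(y.max(), 1e-9), ec50_0]
        popt, _ = curve_fit(model, c, y, p0=p0, sigma=sigma, maxfev=20000,
                            bounds=([0, c.min() * 1e-4], [np.inf, c.max() * 1e4]))
        a, ec50, n = popt[0], popt[1], 1.0
    else:
        def model(cc, a, ec50, n):
            return a * cc ** n / (cc ** n + ec50 ** n)
        p0 = [max(y.max(), 1e-9), ec50_0, 1.0]
        popt, _ = curve_fit(model, c, y, p0=p0, sigma=sigma, maxfev=20000,
                            bounds=([0, c.min() * 1e-4, 0.2],
                                    [np.inf, c.max() * 1e4, 5.0]))
        a, ec50, n = popt
    resid = y - model(c, *popt)
    return DoseResponseFit(float(ec50), float(a), float(n), resid, fix_n, flagged)


# ---------------------------------------------------------------------------
# exponential relaxation fits
# ---------------------------------------------------------------------------


@dataclass
class RelaxationFit:
    n_components: int
    taus: np.ndarray        # seconds, ascending
    amplitudes: np.ndarray  # signed, matching taus
    offset: float
    rss: float
    converged: bool
    bic: float = np.nan

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.full_like(t, self.offset)
        for a, tau in zip(self.amplitudes, self.taus):
            out += a * np.exp(-t / tau)
        return out


def _fit_exp_sum(t, y, n, tau_grid):
    """Separable least squares: amplitudes/offset are linear given taus."""
    best = None
    for taus in tau_grid:
        basis = np.column_stack([np.exp(-t / tau) for tau in taus] + [np.ones_like(t)])
        coef, *_ = np.linalg.lstsq(basis, y, rcond=None)
        rss = float(((basis @ coef - y) ** 2).sum())
        if best is None or rss < best[0]:
            best = (rss, np.asarray(taus, dtype=float), coef)
    return best


def fit_relaxation(
    times: Sequence[float],
    values: Sequence[float],
    n_components: int = 1,
) -> RelaxationFit:
    """Fit ``y(t) = offset + sum_i a_i exp(-t / tau_i)``.

    A coarse log-spaced grid search over time constants (with amplitudes
    solved linearly) seeds a non-linear refinement, which makes the
    bi-exponential fit robust to widely separated time constants.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.shape != y.shape or len(t) < 2 * n_components + 2:
        raise ValueError("insufficient data for the requested fit")
    span = t[-1] - t[0]
    grid = np.geomspace(max(span * 1e-3, np.diff(t).min() * 0.5), span * 3.0, 25)
    if n_components == 1:
        tau_grid = [(g,) for g in grid]
    elif n_components == 2:
        tau_grid = [(g1, g2) for i, g1 in enumerate(grid) for g2 in grid[i + 2:]]
    else:
        raise ValueError("n_components must be 1 or 2")
    rss0, taus0, coef0 = _fit_exp_sum(t, y, n_components, tau_grid)

    def model(tt, *params):
        taus = np.exp(params[:n_components])
        out = np.full_like(tt, params[-1])
        for a, tau in zip(params[n_components:-1], taus):
            out += a * np.exp(-tt / tau)
        return out

    p0 = np.concatenate([np.log(taus0), coef0])
    converged = True
    try:
        popt, _ = curve_fit(model, t, y, p0=p0, maxfev=20000)
    except RuntimeError:
        popt, converged = p0, False
    taus = np.exp(popt[:n_components])
    amps = np.asarray(popt[n_components:-1])
    order = np.argsort(taus)
    resid = y - model(t, *popt)
    rss = float((resid ** 2).sum())
    n_par = 2 * n_components + 1
    n_obs = len(t)
    bic = n_obs * np.log(max(rss / n_obs, 1e-300)) + n_par * np.log(n_obs)
    return RelaxationFit(n_components, taus[order], amps[order], float(popt[-1]),
                         rss, converged, bic)


# ---------------------------------------------------------------------------
# scalar summaries
# ---------------------------------------------------------------------------


def coupling_ratio(po: float, pdim: float) -> float:
    """Open probability divided by dimerization probability."""
    if pdim <= 0:
        raise ValueError("coupling ratio undefined for pdim = 0")
    return po / pdim


def transition_frequency(
    traces,
    frame_s: float | None = None,
    low_labels: Sequence = ("low",),
    high_labels: Sequence = ("mid", "high"),
) -> dict:
    """Frequency of switches between low- and mid/high-FRET classes.

    Accepts idealized traces (per-frame labels) or label sequences; frames
    outside both classes (dark/blink) are excluded from the analyzable
    time and do not create switches.  Returns per-trace frequencies and
    the pooled estimate (total switches / total analyzable time).
    """
    items = traces if isinstance(traces, (list, tuple)) else [traces]
    low_labels, high_labels = set(low_labels), set(high_labels)
    per_trace, total_sw, total_t = [], 0, 0.0
    for item in items:
        if hasattr(item, "labels") and hasattr(item, "frame_s"):
            labels, dt = list(item.labels), item.frame_s
        else:
            if frame_s is None:
                raise ValueError("frame_s required for raw label sequences")
            labels, dt = list(item), frame_s
        classes = [
            "L" if lab in low_labels else "H" if lab in high_labels else None
            for lab in labels
        ]
        usable = [c for c in classes if c is not None]
        n_switch = sum(1 for a, b in zip(usable, usable[1:]) if a != b)
        t_usable = len(usable) * dt
        if t_usable > 0:
            per_trace.append(n_switch / t_usable)
        total_sw += n_switch
        total_t += t_usable
    if total_t <= 0:
        raise ValueError("no analyzable time")
    return {
        "pooled_per_s": total_sw / total_t,
        "per_trace_per_s": np.asarray(per_trace),
        "n_switches": total_sw,
        "analyzable_s": total_t,
    }


def warn_if_time_averaged(mean_dwell_s: float, frame_s: float, n_frames: int = 3):
    """Warn when fitted dwells are shorter than ~3 camera frames: in that
    regime transitions are obscured by frame averaging and rate estimates
    are biased."""
    if mean_dwell_s < n_frames * frame_s:
        warnings.warn(
            f"mean fitted dwell {mean_dwell_s:.3g}s is below {n_frames} frames "
            f"({n_frames * frame_s:.3g}s); transition rates are likely "
            "underestimated due to time averaging", stacklevel=2)
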