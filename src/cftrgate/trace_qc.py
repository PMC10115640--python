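"""Trace quality control and segmental k-means idealization.

Mirrors the standard single-molecule FRET analysis chain: per-frame FRET
efficiency from donor/acceptor intensities, deterministic trace-selection
criteria (single-step donor photobleaching, signal-to-noise ratio,
donor-blink count, frames above baseline, high-FRET artefact exclusion),
and idealization of the selected trajectories with the segmental k-means
algorithm using a two-state model (low/high FRET) whose means are
re-estimated from the data.

Manual curation of photophysical artefacts, as practised interactively in
trace-analysis GUIs, is replaced here by the deterministic filters so runs
are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .synthetic_traces import FretTrace

__all__ = [
    "QcCriteria", "QcReport", "SkmModel", "IdealizedTrace",
    "compute_fret", "qc_select", "skm_idealize", "idealize_trace",
    "ensemble_histogram", "detect_bleach_and_blinks",
]


@dataclass(frozen=True)
class QcCriteria:
    """Trace-selection thresholds.

    Defaults follow the conventional criteria for camera-based smFRET:
    single-step donor photobleaching, signal-to-noise ratio above 8, fewer
    than 4 donor-blinking events, FRET above baseline for at least 50
    frames, and exclusion of traces whose FRET exceeds 0.8 (a nucleotide-
    insensitive subpopulation attributed to denatured molecules).  The
    baseline value of 0.1 is a package default.
    """

    min_snr: float = 8.0
    max_blinks: int = 3
    min_frames_above_baseline: int = 50
    require_single_step_bleach: bool = True
    max_fret: float = 0.8
    baseline: float = 0.1
    # detection internals: a bleach step must deplete >=80% of the
    # pre-bleach level; dark frames fall below 30% of that level
    dark_fraction: float = 0.30
    bleach_depletion: float = 0.80
    min_intermediate_run: int = 5

    def __post_init__(self) -> None:
        if min(self.min_snr, self.min_frames_above_baseline, self.max_fret,
               self.baseline) <= 0:
            raise ValueError("QC thresholds must be positive")

    def as_dict(self) -> dict:
        return asdict(self)


def compute_fret(trace: FretTrace | tuple) -> np.ndarray:
    """Per-frame FRET efficiency E = I_A / (I_A + I_D).

    Frames with non-positive total intensity are dark and returned as NaN
    rather than a number.
    """
    if isinstance(trace, FretTrace):
        donor, acceptor = trace.donor, trace.acceptor
    else:
        donor, acceptor = trace
    donor = np.asarray(donor, dtype=float)
    acceptor = np.asarray(acceptor, dtype=float)
    if donor.shape != acceptor.shape:
        raise ValueError("donor and acceptor must have the same length")
    total = donor + acceptor
    with np.errstate(invalid="ignore", divide="ignore"):
        e = acceptor / total
    return np.where(total > 0, e, np.nan)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, end) index pairs of True runs."""
    out = []
    i = 0
    n = len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            out.append((i, j))
            i = j
        else:
            i += 1
    return out


def detect_bleach_and_blinks(total: np.ndarray, criteria: QcCriteria):
    """Locate the donor bleach step and blink intervals on a total-intensity
    trace.

    The fluorophore level is estimated robustly from the bright frames; a
    terminal dark run whose level is depleted by >=80% is the bleach step,
    and earlier dark runs (which recover) are blinks.  Returns a dict with
    the level, the bleach frame (or None), blink runs, and the per-frame
    dark mask.
    """
    total = np.asarray(total, dtype=float)
    # a short running mean suppresses per-frame noise so dark runs are
    # contiguous; the window is small relative to blink/bleach durations
    win = min(5, max(1, len(total) // 4))
    kernel = np.ones(win) / win
    sm = np.convolve(total, kernel, mode="same")
    bright = sm[sm > 0.5 * np.percentile(sm, 98)]
    level = float(np.median(bright)) if len(bright) else float(np.median(sm))
    dark = sm < criteria.dark_fraction * level
    runs = _runs(dark)
    bleach_idx = None
    blink_runs = runs
    if runs and runs[-1][1] == len(total):
        tail = runs[-1]
        post = total[tail[0]:]
        if np.mean(post) < (1.0 - criteria.bleach_depletion) * level:
            bleach_idx = tail[0]
            blink_runs = runs[:-1]
    return {
        "level": level,
        "bleach_idx": bleach_idx,
        "blink_runs": blink_runs,
        "dark": dark,
        "smoothed": sm,
    }


@dataclass
class QcReport:
    trace_id: str
    accepted: bool
    reason: str | None
    metrics: dict
    criteria: QcCriteria

    def as_dict(self) -> dict:
        return {"trace_id": self.trace_id, "accepted": self.accepted,
                "reason": self.reason, "metrics": self.metrics,
                "criteria": self.criteria.as_dict()}


def _qc_one(trace: FretTrace, criteria: QcCriteria) -> QcReport:
    total = trace.donor + trace.acceptor
    metrics: dict = {}
    try:
        det = detect_bleach_and_blinks(total, criteria)
    except Exception:
        return QcReport(trace.trace_id, False, "unevaluable", metrics, criteria)
    level, bleach_idx = det["level"], det["bleach_idx"]
    metrics["level"] = level
    metrics["bleach_frame"] = bleach_idx

    # 1. single-step donor photobleaching
    if criteria.require_single_step_bleach:
        if bleach_idx is None or bleach_idx < 2:
            return QcReport(trace.trace_id, False, "single_step_bleach",
                            metrics, criteria)
    end = bleach_idx if bleach_idx is not None else len(total)
    pre = slice(0, end)
    dark_pre = det["dark"][pre]
    # persistent intermediate levels before the bleach indicate multi-step
    # photobleaching (for example two active donors)
    sm_pre = det["smoothed"][pre]
    inter = (~dark_pre) & (sm_pre < 0.7 * level)
    inter_runs = [r for r in _runs(inter) if r[1] - r[0] >= criteria.min_intermediate_run]
    if criteria.require_single_step_bleach and inter_runs:
        metrics["intermediate_runs"] = len(inter_runs)
        return QcReport(trace.trace_id, False, "single_step_bleach",
                        metrics, criteria)

    # 2. donor blink count
    n_blinks = len([r for r in det["blink_runs"] if r[0] < end])
    metrics["n_blinks"] = n_blinks
    if n_blinks > criteria.max_blinks:
        return QcReport(trace.trace_id, False, "blinks", metrics, criteria)

    # 3. signal-to-noise ratio of the total intensity
    bright_pre = total[pre][(~dark_pre) & ~inter]
    if len(bright_pre) < 2:
        return QcReport(trace.trace_id, False, "unevaluable", metrics, criteria)
    snr = float(np.mean(bright_pre) / max(np.std(bright_pre, ddof=1), 1e-12))
    metrics["snr"] = snr
    if snr <= criteria.min_snr:
        return QcReport(trace.trace_id, False, "snr", metrics, criteria)

    # 4. FRET above baseline for enough frames
    fret = compute_fret(trace)[pre]
    usable = (~dark_pre) & ~inter & np.isfinite(fret)
    n_above = int(np.sum(usable & (fret > criteria.baseline)))
    metrics["frames_above_baseline"] = n_above
    if n_above < criteria.min_frames_above_baseline:
        return QcReport(trace.trace_id, False, "frames_above_baseline",
                        metrics, criteria)

    # 5. high-FRET artefact exclusion
    med = float(np.median(fret[usable]))
    metrics["median_fret"] = med
    if med > criteria.max_fret:
        return QcReport(trace.trace_id, False, "max_fret", metrics, criteria)

    return QcReport(trace.trace_id, True, None, metrics, criteria)


def qc_select(
    traces: Sequence[FretTrace],
    criteria: QcCriteria | None = None,
) -> tuple[list[FretTrace], list[QcReport]]:
    """Apply the selection criteria, in order, to every trace.

    Returns the accepted subset (input order preserved) and a per-trace
    report naming the first failed criterion of each rejected trace.
    """
    criteria = criteria or QcCriteria()
    reports = [_qc_one(t, criteria) for t in traces]
    accepted = [t for t, r in zip(traces, reports) if r.accepted]
    return accepted, reports


# ---------------------------------------------------------------------------
# segmental k-means idealization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SkmModel:
    """Two-state Gaussian observation model for segmental k-means.

    The default state means/widths (0.25 +/- 0.1 and 0.48 +/- 0.1) are the
    conventional starting model for this sensor; with ``re_estimate`` the
    means are refined from the assigned frames.  ``switch_penalty`` is the
    uniform log-penalty (nats) per state switch in the most-likely-path
    segmentation.
    """

    means: tuple[float, float] = (0.25, 0.48)
    sds: tuple[float, float] = (0.1, 0.1)
    re_estimate: bool = True
    switch_penalty: float = 3.0
    labels: tuple[str, str] = ("low", "high")

    def __post_init__(self) -> None:
        if not self.means[0] < self.means[1]:
            raise ValueError("state means must be strictly ordered")
        if min(self.sds) <= 0:
            raise ValueError("state sds must be positive")


@dataclass
class IdealizedTrace:
    trace_id: str
    labels: np.ndarray            # per-frame: model labels or "dark"
    means: tuple[float, float]    # re-estimated state means
    log_likelihood: float
    frame_s: float
    n_iter: int
    converged: bool


def _viterbi_two_state(e: np.ndarray, means, sds, penalty: float) -> np.ndarray:
    """Most likely state sequence under Gaussian emissions with a uniform
    switch penalty; e contains no NaNs."""
    n = len(e)
    ll = np.empty((n, 2))
    for s in range(2):
        ll[:, s] = -0.5 * ((e - means[s]) / sds[s]) ** 2 - np.log(sds[s])
    score = ll[0].copy()
    back = np.zeros((n, 2), dtype=np.int8)
    for t in range(1, n):
        for s in range(2):
            stay = score[s]
            switch = score[1 - s] - penalty
            if stay >= switch:
                back[t, s] = s
                best = stay
            else:
                back[t, s] = 1 - s
                best = switch
            ll[t, s] += best
        score = ll[t]
    path = np.empty(n, dtype=np.int8)
    path[-1] = int(np.argmax(score))
    for t in range(n - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path, float(score.max())


def skm_idealize(
    fret: np.ndarray,
    model: SkmModel | None = None,
    max_iter: int = 50,
    frame_s: float = 0.1,
    trace_id: str = "trace0",
) -> IdealizedTrace:
    """Segmental k-means idealization of a FRET series.

    Alternates (a) most-likely path segmentation (Viterbi with Gaussian
    emissions and a uniform switch penalty) and (b) re-estimation of the
    state means from the assigned frames, until the assignment no longer
    changes.  NaN frames (dark/blinking) are excluded; Viterbi restarts
    independently on each contiguous usable stretch.  The segmentation
    objective is non-decreasing across iterations.
    """
    model = model or SkmModel()
    e = np.asarray(fret, dtype=float)
    usable = np.isfinite(e)
    if usable.sum() < 2:
        raise ValueError("fewer than 2 usable frames")
    means = list(model.means)
    prev = None
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        assign = np.full(len(e), -1, dtype=np.int8)
        total_ll = 0.0
        for i0, i1 in _runs(usable):
            path, ll = _viterbi_two_state(e[i0:i1], means, model.sds,
                                          model.switch_penalty)
            assign[i0:i1] = path
            total_ll += ll
        if model.re_estimate:
            new_means = list(means)
            for s in range(2):
                sel = e[assign == s]
                if len(sel):
                    new_means[s] = float(sel.mean())
            means = new_means
        if prev is not None and np.array_equal(assign, prev):
            converged = True
            break
        prev = assign
        if not model.re_estimate:
            converged = True
            break
    labels = np.where(assign >= 0,
                      np.asarray(model.labels, dtype=object)[assign], "dark")
    if means[0] > means[1]:  # keep label order tied to mean order
        means = means[::-1]
    return IdealizedTrace(
        trace_id=trace_id,
        labels=labels.astype(str),
        means=(means[0], means[1]),
        log_likelihood=total_ll,
        frame_s=frame_s,
        n_iter=n_iter,
        converged=converged,
    )


def idealize_trace(
    trace: FretTrace,
    model: SkmModel | None = None,
    criteria: QcCriteria | None = None,
    max_iter: int = 50,
) -> IdealizedTrace:
    """Convenience wrapper: mask dark/bleached/blink frames on a raw trace,
    then run segmental k-means on the remainder."""
    criteria = criteria or QcCriteria()
    det = detect_bleach_and_blinks(trace.donor + trace.acceptor, criteria)
    fret = compute_fret(trace)
    mask = det["dark"].copy()
    if det["bleach_idx"] is not None:
        mask[det["bleach_idx"]:] = True
    fret = np.where(mask, np.nan, fret)
    return skm_idealize(fret, model, max_iter=max_iter,
                        frame_s=trace.frame_s, trace_id=trace.trace_id)


# ---------------------------------------------------------------------------
# population histograms
# ---------------------------------------------------------------------------


def ensemble_histogram(
    fret_arrays: Sequence[np.ndarray],
    bins: int | np.ndarray = 40,
    groups: Sequence | None = None,
    range_: tuple[float, float] = (-0.1, 1.0),
    idealized: Sequence[IdealizedTrace] | None = None,
) -> dict:
    """Population FRET histogram with per-experiment averaging.

    Traces are partitioned into groups (independent experiments); each
    group is histogrammed with density normalization and the mean and
    standard error across groups are returned.  If idealized traces are
    supplied, the high-FRET occupancy (fraction of assigned frames in the
    upper state) is included.
    """
    if len(fret_arrays) == 0:
        raise ValueError("empty ensemble")
    if groups is None:
        groups = np.zeros(len(fret_arrays), dtype=int)
    groups = np.asarray(groups)
    edges = (np.linspace(*range_, bins + 1) if np.isscalar(bins)
             else np.asarray(bins, dtype=float))
    group_ids = np.unique(groups)
    dens = []
    for gid in group_ids:
        vals = np.concatenate(
            [np.asarray(a)[np.isfinite(a)] for a, g in zip(fret_arrays, groups)
             if g == gid] or [np.array([])])
        if len(vals) == 0:
            raise ValueError(f"empty group {gid!r}")
        h, _ = np.histogram(vals, bins=edges, density=True)
        dens.append(h)
    dens = np.asarray(dens)
    out = {
        "bin_centers": 0.5 * (edges[:-1] + edges[1:]),
        "bin_edges": edges,
        "mean_density": dens.mean(axis=0),
        "sem_density": (dens.std(axis=0, ddof=1) / np.sqrt(len(dens))
                        if len(dens) > 1 else np.zeros(dens.shape[1])),
        "n_groups": len(group_ids),
    }
    if idealized is not None:
        all_labels = np.concatenate([t.labels for t in idealized])
        assigned = np.isin(all_labels, ("low", "high"))
        if assigned.sum():
            out["high_occupancy"] = float(
                np.sum(all_labels == "high") / assigned.sum())
        means = np.array([t.means for t in idealized])
        out["state_means"] = means.mean(axis=0)
    return out
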