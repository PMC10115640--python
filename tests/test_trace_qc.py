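import numpy as np
import pytest

from cftrgate.gating_model import Protocol, build_topology
from cftrgate.synthetic_traces import EmissionModel, FretTrace, generate_ensemble
from cftrgate.trace_qc import (
    QcCriteria,
    SkmModel,
    compute_fret,
    detect_bleach_and_blinks,
    ensemble_histogram,
    idealize_trace,
    qc_select,
    skm_idealize,
)


class TestComputeFret:
    @pytest.mark.parametrize("donor,acceptor,expected", [
        (100.0, 100.0, 0.5),
        (100.0, 0.0, 0.0),
        (300.0, 100.0, 0.25),
    ])
    def test_efficiency_formula(self, donor, acceptor, expected):
        e = compute_fret((np.array([donor]), np.array([acceptor])))
        assert e[0] == pytest.approx(expected)

    def test_dark_frames_are_nan_not_numeric(self):
        e = compute_fret((np.array([0.0, -5.0, 100.0]),
                          np.array([0.0, 5.0, 100.0])))
        assert np.isnan(e[0]) and np.isnan(e[1])
        assert e[2] == 0.5

    def test_bounded_for_nonnegative_intensities(self):
        rng = np.random.default_rng(0)
        d = rng.uniform(0, 1000, 500)
        a = rng.uniform(0, 1000, 500)
        e = compute_fret((d, a))
        ok = np.isfinite(e)
        assert ((e[ok] >= 0) & (e[ok] <= 1)).all()

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            compute_fret((np.zeros(3), np.zeros(4)))


def synth_trace(rng, n=300, level=1000.0, fret=0.3, noise=30.0,
                bleach_at=200, blink_runs=(), steps=(), trace_id="t"):
    """Hand-built trace: constant FRET, optional bleach step, blink runs
    [(start, stop)], and intermediate-intensity steps [(start, stop, frac)]."""
    frac = np.ones(n)
    frac[bleach_at:] = 0.0
    for b0, b1 in blink_runs:
        frac[b0:b1] = 0.0
    for s0, s1, f in steps:
        frac[s0:s1] = f
    donor = level * (1 - fret) * frac + rng.normal(0, noise, n)
    acceptor = level * fret * frac + rng.normal(0, noise, n)
    return FretTrace(trace_id=trace_id, times_s=np.arange(n) * 0.1,
                     donor=donor, acceptor=acceptor, frame_s=0.1)


class TestQcSelect:
    def test_clean_trace_accepted(self):
        rng = np.random.default_rng(0)
        accepted, reports = qc_select([synth_trace(rng)])
        assert len(accepted) == 1
        assert reports[0].accepted

    def test_two_step_bleach_rejected(self):
        rng = np.random.default_rng(1)
        # second fluorophore: half-intensity plateau before the final step
        tr = synth_trace(rng, steps=((120, 200, 0.5),))
        _, reports = qc_select([tr])
        assert not reports[0].accepted
        assert reports[0].reason == "single_step_bleach"

    def test_no_bleach_rejected(self):
        rng = np.random.default_rng(2)
        _, reports = qc_select([synth_trace(rng, bleach_at=300)])
        assert reports[0].reason == "single_step_bleach"

    def test_excess_blinks_rejected(self):
        rng = np.random.default_rng(3)
        blinks = tuple((20 * k, 20 * k + 5) for k in range(1, 6))  # 5 blinks
        tr = synth_trace(rng, blink_runs=blinks)
        _, reports = qc_select([tr])
        assert reports[0].reason == "blinks"
        # three blinks ("fewer than 4") still pass
        tr3 = synth_trace(np.random.default_rng(3), blink_runs=blinks[:3])
        _, reports3 = qc_select([tr3])
        assert reports3[0].accepted

    def test_low_snr_rejected(self):
        rng = np.random.default_rng(4)
        tr = synth_trace(rng, noise=180.0)  # SNR ~ 4, half the threshold
        _, reports = qc_select([tr])
        assert reports[0].reason == "snr"

    def test_too_few_frames_above_baseline_rejected(self):
        rng = np.random.default_rng(5)
        tr = synth_trace(rng, bleach_at=25)  # only 25 usable frames
        _, reports = qc_select([tr])
        assert reports[0].reason == "frames_above_baseline"

    def test_high_fret_artefact_rejected(self):
        rng = np.random.default_rng(6)
        tr = synth_trace(rng, fret=0.9)
        _, reports = qc_select([tr])
        assert reports[0].reason == "max_fret"

    def test_defect_injection_recovers_clean_set(self):
        rng = np.random.default_rng(7)
        clean = [synth_trace(rng, trace_id=f"clean{k}") for k in range(20)]
        defects = []
        for k in range(4):
            defects.append(synth_trace(rng, steps=((100, 200, 0.5),),
                                       trace_id=f"two_step{k}"))
            defects.append(synth_trace(
                rng, blink_runs=tuple((15 * j, 15 * j + 5)
                                      for j in range(1, 9)),
                trace_id=f"blinky{k}"))
            defects.append(synth_trace(rng, noise=180.0, trace_id=f"dim{k}"))
            defects.append(synth_trace(rng, fret=0.9, trace_id=f"high{k}"))
        accepted, _ = qc_select(clean + defects)
        assert {t.trace_id for t in accepted} == {t.trace_id for t in clean}

    def test_order_stability(self):
        rng = np.random.default_rng(8)
        traces = [synth_trace(rng, trace_id=f"t{k}") for k in range(10)]
        traces[3] = synth_trace(rng, fret=0.9, trace_id="t3")
        fwd, _ = qc_select(traces)
        rev, _ = qc_select(traces[::-1])
        assert {t.trace_id for t in fwd} == {t.trace_id for t in rev}

    def test_unevaluable_trace_rejected_with_reason(self):
        tr = FretTrace(trace_id="short", times_s=np.arange(4) * 0.1,
                       donor=np.zeros(4), acceptor=np.zeros(4), frame_s=0.1)
        _, reports = qc_select([tr])
        assert not reports[0].accepted

    def test_criteria_serialized_in_report(self):
        rng = np.random.default_rng(9)
        _, reports = qc_select([synth_trace(rng)])
        d = reports[0].as_dict()
        assert d["criteria"]["min_snr"] == 8.0


class TestSkm:
    def test_noiseless_two_level_exact(self):
        e = np.array([0.25] * 40 + [0.49] * 40 + [0.25] * 20)
        ideal = skm_idealize(e, SkmModel())
        assert (ideal.labels[:40] == "low").all()
        assert (ideal.labels[40:80] == "high").all()
        assert ideal.means[0] == pytest.approx(0.25, abs=1e-12)
        assert ideal.means[1] == pytest.approx(0.49, abs=1e-12)
        assert ideal.converged

    def test_noisy_truth_accuracy_above_95_percent(self):
        rng = np.random.default_rng(1)
        truth = np.repeat(rng.integers(0, 2, 40), 20)  # ~2 s dwells
        e = np.where(truth == 1, 0.49, 0.25) + rng.normal(0, 0.05, len(truth))
        ideal = skm_idealize(e, SkmModel())
        got = (ideal.labels == "high").astype(int)
        assert np.mean(got == truth) >= 0.95

    def test_objective_non_decreasing_over_iterations(self):
        rng = np.random.default_rng(2)
        truth = np.repeat(rng.integers(0, 2, 30), 15)
        e = np.where(truth == 1, 0.49, 0.25) + rng.normal(0, 0.08, len(truth))
        lls = [skm_idealize(e, SkmModel(), max_iter=k).log_likelihood
               for k in range(1, 6)]
        assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))

    def test_dark_frames_labelled_dark(self):
        e = np.array([0.25, np.nan, np.nan, 0.49, 0.49])
        ideal = skm_idealize(e, SkmModel())
        assert list(ideal.labels[1:3]) == ["dark", "dark"]

    def test_all_dark_rejected(self):
        with pytest.raises(ValueError):
            skm_idealize(np.array([np.nan, np.nan]), SkmModel())

    def test_model_validation(self):
        with pytest.raises(ValueError):
            SkmModel(means=(0.5, 0.3))
        with pytest.raises(ValueError):
            SkmModel(sds=(0.1, 0.0))

    def test_g551d_reestimates_intermediate_mean(self, wt_rates):
        g = build_topology("G551D", rates=wt_rates)
        em = EmissionModel.for_condition(3e-3, "G551D")
        ens = generate_ensemble(g, Protocol(duration_s=60.0), 30, em, seed=12)
        accepted, _ = qc_select(ens.traces)
        ideals = [idealize_trace(t) for t in accepted]
        n_hi = np.array([np.sum(i.labels == "high") for i in ideals])
        hi = np.array([i.means[1] for i in ideals])
        pooled = float((hi * n_hi).sum() / n_hi.sum())
        assert pooled == pytest.approx(0.37, abs=0.02)

    def test_occupancy_roundtrip_at_low_noise(self, wt_graph):
        # FRET sd ~ 0.01: idealized occupancy within 1% of generator truth
        em = EmissionModel.for_condition(3e-3, intensity_noise_sd=14.0,
                                         donor_bleach_mean_s=1e9,
                                         blink_rate_per_s=0.0)
        ens = generate_ensemble(wt_graph, Protocol(duration_s=60.0), 25, em,
                                seed=13)
        truth_hi, got_hi, n_tot = 0, 0, 0
        for tr in ens.traces:
            ideal = idealize_trace(tr)
            live = (tr.true_class != "dark") & (ideal.labels != "dark")
            truth_hi += np.sum(tr.true_class[live] == "high")
            got_hi += np.sum(ideal.labels[live] == "high")
            n_tot += live.sum()
        assert abs(got_hi - truth_hi) / n_tot < 0.01


class TestEnsembleHistogram:
    def test_delta_ensemble_occupies_single_bin(self):
        arrays = [np.full(200, 0.305) for _ in range(4)]
        h = ensemble_histogram(arrays, bins=22, range_=(0.0, 1.1))
        assert np.count_nonzero(h["mean_density"]) == 1

    def test_group_averaging_shapes(self):
        rng = np.random.default_rng(0)
        arrays = [rng.normal(0.3, 0.05, 300) for _ in range(6)]
        h = ensemble_histogram(arrays, bins=30, groups=[0, 0, 1, 1, 2, 2])
        assert h["n_groups"] == 3
        assert h["mean_density"].shape == h["sem_density"].shape
        assert (h["sem_density"] >= 0).all()

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            ensemble_histogram([])

    def test_dephosphorylated_atp_centred_at_028(self, wt_rates):
        g = build_topology("WT", rates=wt_rates, phosphorylated=False)
        prot = Protocol(duration_s=60.0, phosphorylated=False)
        em = EmissionModel.for_condition(3e-3)
        ens = generate_ensemble(g, prot, 30, em, seed=14)
        accepted, _ = qc_select(ens.traces)
        arrays = []
        for tr in accepted:
            e = compute_fret(tr)
            det = detect_bleach_and_blinks(tr.donor + tr.acceptor,
                                           QcCriteria())
            mask = det["dark"].copy()
            if det["bleach_idx"] is not None:
                mask[det["bleach_idx"]:] = True
            arrays.append(np.where(mask, np.nan, e))
        h = ensemble_histogram(arrays, bins=60, range_=(0.0, 1.0))
        centre = h["bin_centers"][np.argmax(h["mean_density"])]
        assert centre == pytest.approx(0.28, abs=0.02)
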