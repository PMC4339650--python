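"""MEA analysis: filtering, noise, spikes, bursts, summaries, viability."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_force_bursts
from synaptoscope.mea import (
    Burst,
    BurstParams,
    ElectrodeTrace,
    SpikeTrain,
    bandpass_filter,
    classify_active,
    detect_bursts,
    detect_spikes,
    estimate_noise_rms,
    exclude_settling,
    summarize_well,
    viability_percent,
)

FS = 12_500.0


# ---------------------------------------------------------------------------
# filter


def test_filter_removes_dc():
    trace = ElectrodeTrace(np.full(25_000, 50.0), FS)
    out = bandpass_filter(trace).samples
    assert len(out) == 25_000
    assert abs(np.mean(out)) < 1e-6 * 50.0


def test_filter_passband_and_stopband():
    t = np.arange(int(FS * 2)) / FS
    mid = slice(6_000, -6_000)
    pass_amp = np.abs(
        bandpass_filter(ElectrodeTrace(np.sin(2 * np.pi * 1000 * t), FS)).samples[mid]
    ).max()
    assert abs(pass_amp - 1.0) < 0.05
    stop_amp = np.abs(
        bandpass_filter(ElectrodeTrace(np.sin(2 * np.pi * 50 * t), FS)).samples[mid]
    ).max()
    assert stop_amp < 0.05


def test_filter_rejects_low_sampling_rate():
    with pytest.raises(ValueError, match="Nyquist"):
        ElectrodeTrace(np.zeros(100), 8000.0)


# ---------------------------------------------------------------------------
# noise RMS


def test_plain_rms_of_unit_sine():
    t = np.arange(int(FS)) / FS
    x = np.sin(2 * np.pi * 1000 * t)
    assert estimate_noise_rms(x, method="plain") == pytest.approx(
        1 / math.sqrt(2), rel=1e-3
    )


def test_robust_rms_matches_gaussian_sd():
    rng = np.random.default_rng(0)
    x = rng.normal(0, 2.0, int(FS * 60))
    assert estimate_noise_rms(x) == pytest.approx(2.0, rel=0.05)


def test_robust_rms_insensitive_to_sparse_spikes():
    rng = np.random.default_rng(1)
    x = rng.normal(0, 2.0, int(FS * 60))
    idx = rng.integers(0, len(x), 300)
    x[idx] += 20.0
    assert estimate_noise_rms(x) == pytest.approx(2.0, rel=0.10)


def test_zero_trace_rms_is_zero():
    assert estimate_noise_rms(np.zeros(100)) == 0.0


# ---------------------------------------------------------------------------
# spike detection


def test_noise_only_false_positives_below_one_per_minute():
    rng = np.random.default_rng(2)
    trace = ElectrodeTrace(rng.normal(0, 2.0, int(FS * 60)), FS)
    filt = bandpass_filter(trace)
    train = detect_spikes(filt, estimate_noise_rms(filt.samples))
    assert len(train.spike_times_s) < 1


def test_injected_spikes_recovered_within_1ms():
    from synaptoscope.synthetic import RecordingSpec, generate_recording

    spec = RecordingSpec(duration_s=30.0, n_wells=1, electrodes_per_well=1,
                         background_rate_hz=4.0, burst_rate_per_min=0.0,
                         amplitude_uv=16.0, noise_rms_uv=2.0)
    traces, truth = generate_recording(spec, seed=3)
    filt = bandpass_filter(ElectrodeTrace(traces[("well00", "e00")], spec.fs))
    train = detect_spikes(filt, estimate_noise_rms(filt.samples))
    true_times = truth.electrodes[0].spike_times_s
    assert len(true_times) >= 100
    hits = sum(np.abs(train.spike_times_s - t).min() <= 1e-3 for t in true_times)
    assert hits >= 0.95 * len(true_times)


def test_subthreshold_trace_gives_empty_train():
    x = np.zeros(12_500)
    x[100] = 1.0
    train = detect_spikes(ElectrodeTrace(x, FS), noise_rms=1.0)  # thr = 6
    assert len(train.spike_times_s) == 0


def test_zero_noise_rms_rejected_with_floor_hint():
    with pytest.raises(ValueError, match="floor"):
        detect_spikes(ElectrodeTrace(np.zeros(100), FS), noise_rms=0.0)


def test_detection_amplitude_scale_invariant():
    """Scaling a trace by c > 0 leaves detected spike times unchanged."""
    rng = np.random.default_rng(4)
    x = rng.normal(0, 2.0, int(FS * 10))
    for i in range(0, len(x), 12_500):
        x[i : i + 5] += 30.0
    for c in (0.1, 7.3):
        t1 = detect_spikes(ElectrodeTrace(x, FS), estimate_noise_rms(x))
        t2 = detect_spikes(ElectrodeTrace(c * x, FS), estimate_noise_rms(c * x))
        assert np.array_equal(t1.spike_times_s, t2.spike_times_s)


# ---------------------------------------------------------------------------
# settling exclusion and activity


def test_settling_window_arithmetic():
    times, analyzed = exclude_settling(np.array([60.0, 200.0, 500.0]), 1980.0)
    assert np.allclose(times, [20.0, 320.0])
    assert analyzed == 1800.0


def test_settling_empty_input():
    times, analyzed = exclude_settling(np.array([]), 1980.0)
    assert len(times) == 0 and analyzed == 1800.0


def test_all_spikes_in_settling_window_dropped():
    times, _ = exclude_settling(np.array([10.0, 100.0, 179.9]), 1980.0)
    assert len(times) == 0


def test_short_recording_policy():
    with pytest.raises(ValueError, match="exclusion"):
        exclude_settling(np.array([1.0]), 60.0)
    times, analyzed = exclude_settling(np.array([1.0]), 60.0, on_short="zero")
    assert np.allclose(times, [1.0]) and analyzed == 60.0


def test_active_boundary_is_inclusive():
    mk = lambda n: SpikeTrain(np.linspace(1, 1799, n), 1800.0)  # noqa: E731
    assert classify_active(mk(150)) is True  # exactly 5/min
    assert classify_active(mk(149)) is False
    assert classify_active(SpikeTrain(np.array([]), 1800.0)) is False


# ---------------------------------------------------------------------------
# bursts


def test_four_spikes_in_30ms_is_one_burst():
    bursts = detect_bursts(np.array([0.0, 0.01, 0.02, 0.03]))
    assert len(bursts) == 1
    b = bursts[0]
    assert (b.n_spikes, b.start_s, b.end_s) == (4, 0.0, 0.03)
    assert b.duration_s == pytest.approx(0.03)


def test_short_run_fails_min_duration():
    assert detect_bursts(np.array([0.0, 0.005, 0.010, 0.015])) == []


def test_three_spikes_fail_min_count():
    assert detect_bursts(np.array([0.0, 0.02, 0.04])) == []


def test_nonpositive_burst_params_rejected():
    with pytest.raises(ValueError):
        detect_bursts(np.array([0.0]), BurstParams(min_spikes=0))


def test_reported_bursts_satisfy_printed_criteria():
    rng = np.random.default_rng(5)
    for _ in range(50):
        times = np.sort(rng.uniform(0, 3.0, size=rng.integers(0, 60)))
        for b in detect_bursts(times):
            assert b.n_spikes >= 4
            assert b.duration_s >= 0.02
        bs = detect_bursts(times)
        for b1, b2 in zip(bs[:-1], bs[1:]):
            assert b2.start_s - b1.end_s >= 0.1


@pytest.mark.parametrize("scale", [0.05, 0.3, 1.0])
def test_burst_detector_matches_bruteforce_oracle(scale):
    """Detector output equals an independent enumeration of maximal
    qualifying runs on hundreds of random trains at several ISI scales."""
    rng = np.random.default_rng(int(scale * 1000))
    for _ in range(400):
        n = int(rng.integers(0, 51))
        times = np.sort(rng.uniform(0, scale * n + 0.1, size=n))
        got = detect_bursts(times)
        exp = brute_force_bursts(times)
        assert len(got) == len(exp)
        for b, (i, j) in zip(got, exp):
            assert b.n_spikes == j - i + 1
            assert b.start_s == pytest.approx(times[i])
            assert b.end_s == pytest.approx(times[j])


# ---------------------------------------------------------------------------
# well summaries and viability


def _train(n, minutes=30.0, well="w", elec="e"):
    dur = minutes * 60.0
    times = np.linspace(0.5, dur - 0.5, n) if n else np.array([])
    return SpikeTrain(times, dur, well, elec)


def test_mfr_averages_active_electrodes_only():
    trains = [_train(300, elec="a"), _train(600, elec="b")]
    summary = summarize_well(trains, [[], []])
    assert summary.mean_firing_rate_per_min == pytest.approx(15.0)
    assert summary.n_active_electrodes == 2


def test_mbr_with_inactive_electrodes_excluded():
    active = _train(600, elec="a")
    inactive = [_train(3, elec=str(i)) for i in range(3)]
    bursts = [[Burst(0, 0.05, 5)] * 6, [], [], []]
    summary = summarize_well([active] + inactive, bursts)
    assert summary.n_active_electrodes == 1
    assert summary.mean_burst_rate_per_min == pytest.approx(0.2)


def test_zero_active_electrodes_flags_rates_missing():
    summary = summarize_well([_train(3), _train(0)], [[], []])
    assert summary.n_active_electrodes == 0
    assert math.isnan(summary.mean_firing_rate_per_min)
    assert math.isnan(summary.mean_burst_rate_per_min)


def test_summary_matches_direct_recomputation():
    rng = np.random.default_rng(6)
    trains, bursts = [], []
    for i in range(8):
        n = int(rng.integers(0, 400))
        trains.append(_train(n, elec=str(i)))
        nb = int(rng.integers(0, 10))
        bursts.append([Burst(j, j + 0.05, 5) for j in range(nb)])
    s = summarize_well(trains, bursts)
    active = [(t, b) for t, b in zip(trains, bursts) if t.rate_per_min >= 5]
    assert s.n_active_electrodes == len(active)
    assert s.mean_firing_rate_per_min == pytest.approx(
        np.mean([len(t.spike_times_s) / 30 for t, _ in active])
    )
    assert s.mean_burst_rate_per_min == pytest.approx(
        np.mean([len(b) / 30 for _, b in active])
    )


def test_viability_formula():
    assert viability_percent(100, 25) == pytest.approx(75.0)
    assert viability_percent(50, 0) == pytest.approx(100.0)
    assert math.isnan(viability_percent(0, 0))
    with pytest.raises(ValueError):
        viability_percent(10, 11)
    with pytest.raises(ValueError):
        viability_percent(-1, 0)


@settings(deadline=None, max_examples=50)
@given(
    times=st.lists(
        st.floats(0, 10, allow_nan=False, width=32), min_size=0, max_size=50
    )
)
def test_burst_oracle_equivalence_property(times):
    t = np.sort(np.unique(np.asarray(times, dtype=float)))
    got = detect_bursts(t)
    exp = brute_force_bursts(t)
    assert [(b.n_spikes, b.start_s, b.end_s) for b in got] == [
        (j - i + 1, pytest.approx(t[i]), pytest.approx(t[j])) for i, j in exp
    ]
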