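"""Spike, burst and well-level network-activity analysis for multi-well MEAs.

The analysis chain mirrors standard extracellular practice: a zero-phase
Butterworth band-pass (300-5000 Hz), a spike threshold at 6x each channel's
RMS noise, exclusion of the first 3 min of a 33-min recording (amplifier and
culture settling), an activity criterion of >= 5 spikes/min for an electrode
to count at all, max-interval burst detection (>= 4 spikes, >= 0.02 s
duration, >= 0.1 s between bursts), and per-well mean firing / bursting
rates averaged over active electrodes only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt

MISSING = float("nan")

BAND_HZ = (300.0, 5000.0)
FILTER_ORDER = 2  # applied forward-backward: effective order 4
ACTIVE_SPIKES_PER_MIN = 5.0
SETTLING_EXCLUSION_S = 180.0


@dataclass
class ElectrodeTrace:
    samples: np.ndarray  # voltage, uV
    fs: float  # samples/s
    well_id: str = "well00"
    electrode_id: str = "e00"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace samples must be finite")
        if self.fs <= 2 * BAND_HZ[1]:
            raise ValueError(
                f"fs={self.fs} violates Nyquist for the {BAND_HZ[1]} Hz "
                "low-pass corner; need fs > 10000"
            )


@dataclass
class SpikeTrain:
    spike_times_s: np.ndarray  # sorted, within [0, analyzed_duration_s]
    analyzed_duration_s: float
    well_id: str = "well00"
    electrode_id: str = "e00"
    active: bool | None = None

    @property
    def rate_per_min(self) -> float:
        return len(self.spike_times_s) / (self.analyzed_duration_s / 60.0)


@dataclass(frozen=True)
class Burst:
    start_s: float
    end_s: float
    n_spikes: int

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class BurstParams:
    """Printed burst criteria plus the max-interval grouping parameter.

    ``max_isi_s`` (the largest in-burst inter-spike interval) is not part of
    the printed definition; it defaults to the inter-burst interval, a common
    max-interval convention.
    """

    min_spikes: int = 4
    min_duration_s: float = 0.02
    min_interburst_s: float = 0.1
    max_isi_s: float = 0.1

    def validate(self) -> None:
        if (
            self.min_spikes < 1
            or self.min_duration_s <= 0
            or self.min_interburst_s <= 0
            or self.max_isi_s <= 0
        ):
            raise ValueError("burst parameters must be positive")


@dataclass
class WellActivitySummary:
    well_id: str
    n_active_electrodes: int
    mean_firing_rate_per_min: float  # averaged over active electrodes
    mean_burst_rate_per_min: float


# ---------------------------------------------------------------------------
# trace-level operations


def bandpass_filter(trace: ElectrodeTrace) -> ElectrodeTrace:
    """Zero-phase Butterworth band-pass, 300/5000 Hz corners."""
    sos = butter(FILTER_ORDER, BAND_HZ, btype="bandpass", fs=trace.fs, output="sos")
    filtered = sosfiltfilt(sos, trace.samples)
    return ElectrodeTrace(
        samples=filtered,
        fs=trace.fs,
        well_id=trace.well_id,
        electrode_id=trace.electrode_id,
    )


def estimate_noise_rms(
    samples: np.ndarray, method: str = "robust"
) -> float:
    """RMS noise of a (filtered) trace.

    ``robust`` (default) uses median(|x|)/0.6745, which is insensitive to
    sparse large spikes; ``plain`` is the literal root mean square.
    """
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        return 0.0
    if method == "plain":
        return float(np.sqrt(np.mean(x**2)))
    if method == "robust":
        return float(np.median(np.abs(x)) / 0.6745)
    raise ValueError(f"unknown noise RMS method {method!r}")


def detect_spikes(
    trace: ElectrodeTrace,
    noise_rms: float,
    threshold_factor: float = 6.0,
    refractory_s: float = 0.001,
    polarity: str = "both",
) -> SpikeTrain:
    """Threshold-crossing spike detection at ``threshold_factor`` x RMS noise.

    Crossings closer than the refractory dead time are grouped into one
    event; the spike time is the extremum sample of the event.  Bipolar
    detection (both polarities) is the default.
    """
    if noise_rms <= 0:
        raise ValueError(
            "noise_rms must be > 0; for silent channels supply a noise floor "
            "parameter instead of the estimate"
        )
    x = trace.samples
    thr = threshold_factor * noise_rms
    if polarity == "both":
        over = np.abs(x) > thr
    elif polarity == "negative":
        over = x < -thr
    elif polarity == "positive":
        over = x > thr
    else:
        raise ValueError(f"unknown polarity {polarity!r}")
    idx = np.nonzero(over)[0]
    if idx.size == 0:
        return SpikeTrain(
            spike_times_s=np.empty(0),
            analyzed_duration_s=len(x) / trace.fs,
            well_id=trace.well_id,
            electrode_id=trace.electrode_id,
        )
    dead = max(int(round(refractory_s * trace.fs)), 1)
    breaks = np.nonzero(np.diff(idx) > dead)[0]
    groups = np.split(idx, breaks + 1)
    times = np.empty(len(groups))
    for i, g in enumerate(groups):
        ext = g[np.argmax(np.abs(x[g]))]
        times[i] = ext / trace.fs
    return SpikeTrain(
        spike_times_s=times,
        analyzed_duration_s=len(x) / trace.fs,
        well_id=trace.well_id,
        electrode_id=trace.electrode_id,
    )


# ---------------------------------------------------------------------------
# spike-train operations


def exclude_settling(
    spike_times_s: np.ndarray,
    record_duration_s: float,
    exclusion_s: float = SETTLING_EXCLUSION_S,
    on_short: str = "error",
) -> tuple[np.ndarray, float]:
    """Drop spikes in the initial settling window and re-reference times.

    Returns ``(times, analyzed_duration)`` with times measured from the end
    of the settling window.  A recording shorter than the window raises by
    default; ``on_short='zero'`` instead disables the exclusion (for
    scaled-down recordings).
    """
    t = np.asarray(spike_times_s, dtype=float)
    if record_duration_s < exclusion_s:
        if on_short == "zero":
            exclusion_s = 0.0
        else:
            raise ValueError(
                f"recording ({record_duration_s} s) shorter than the "
                f"{exclusion_s} s exclusion window"
            )
    kept = t[t >= exclusion_s] - exclusion_s
    return np.sort(kept), record_duration_s - exclusion_s


def classify_active(train: SpikeTrain) -> bool:
    """Active iff the firing rate is at least 5 spikes/min (inclusive)."""
    if train.analyzed_duration_s <= 0:
        raise ValueError("analyzed_duration_s must be > 0")
    active = train.rate_per_min >= ACTIVE_SPIKES_PER_MIN
    train.active = bool(active)
    return train.active


def detect_bursts(
    spike_times_s: np.ndarray, params: BurstParams = BurstParams()
) -> list[Burst]:
    """Max-interval burst detection with the printed criteria.

    Maximal runs of spikes whose consecutive intervals are all <= max_isi
    are formed first; runs with fewer than ``min_spikes`` spikes or shorter
    than ``min_duration_s`` are discarded; surviving runs separated by less
    than ``min_interburst_s`` are merged and the criteria re-checked.
    """
    params.validate()
    t = np.asarray(spike_times_s, dtype=float)
    if np.any(np.diff(t) < 0):
        raise ValueError("spike times must be sorted")
    if t.size == 0:
        return []
    # maximal runs with ISI <= max_isi
    breaks = np.nonzero(np.diff(t) > params.max_isi_s)[0]
    runs = np.split(np.arange(t.size), breaks + 1)

    def qualifies(i0: int, i1: int) -> bool:
        n = i1 - i0 + 1
        return n >= params.min_spikes and t[i1] - t[i0] >= params.min_duration_s

    kept = [(r[0], r[-1]) for r in runs if qualifies(r[0], r[-1])]
    # merge qualifying runs closer than the inter-burst interval, re-check
    merged: list[list[int]] = []
    for i0, i1 in kept:
        if merged and t[i0] - t[merged[-1][1]] < params.min_interburst_s:
            merged[-1][1] = i1
        else:
            merged.append([i0, i1])
    return [
        Burst(start_s=float(t[i0]), end_s=float(t[i1]), n_spikes=int(i1 - i0 + 1))
        for i0, i1 in merged
        if qualifies(i0, i1)
    ]


# ---------------------------------------------------------------------------
# well-level summaries


def summarize_well(
    trains: list[SpikeTrain], bursts_per_electrode: list[list[Burst]]
) -> WellActivitySummary:
    """Mean firing and bursting rate over the well's ACTIVE electrodes.

    Inactive electrodes contribute to neither numerator nor denominator.
    With zero active electrodes the rates are missing (NaN), not zero.
    """
    if len(trains) != len(bursts_per_electrode):
        raise ValueError("need one burst list per spike train")
    if not trains:
        raise ValueError("summarize_well needs at least one electrode")
    well_ids = {tr.well_id for tr in trains}
    if len(well_ids) != 1:
        raise ValueError("all trains must come from one well")
    durations = {round(tr.analyzed_duration_s, 9) for tr in trains}
    if len(durations) != 1:
        raise ValueError("all trains must share one analyzed duration")
    active = [
        (tr, bursts)
        for tr, bursts in zip(trains, bursts_per_electrode)
        if (tr.active if tr.active is not None else classify_active(tr))
    ]
    if not active:
        return WellActivitySummary(
            well_id=trains[0].well_id,
            n_active_electrodes=0,
            mean_firing_rate_per_min=MISSING,
            mean_burst_rate_per_min=MISSING,
        )
    minutes = trains[0].analyzed_duration_s / 60.0
    mfr = float(np.mean([len(tr.spike_times_s) / minutes for tr, _ in active]))
    mbr = float(np.mean([len(b) / minutes for _, b in active]))
    return WellActivitySummary(
        well_id=trains[0].well_id,
        n_active_electrodes=len(active),
        mean_firing_rate_per_min=mfr,
        mean_burst_rate_per_min=mbr,
    )


def viability_percent(hoechst_count: int, pi_count: int) -> float:
    """Percent viable cells: (Hoechst - PI) / Hoechst x 100.

    Hoechst stains all nuclei, propidium iodide only dead cells.  Zero
    Hoechst-stained cells gives a missing value (NaN).
    """
    if hoechst_count < 0 or pi_count < 0:
        raise ValueError("cell counts must be >= 0")
    if pi_count > hoechst_count:
        raise ValueError("PI-stained count cannot exceed Hoechst-stained count")
    if hoechst_count == 0:
        return MISSING
    return (hoechst_count - pi_count) / hoechst_count * 100.0


# ---------------------------------------------------------------------------
# convenience: full per-electrode chain


def analyze_trace(
    trace: ElectrodeTrace,
    record_duration_s: float | None = None,
    threshold_factor: float = 6.0,
    noise_method: str = "robust",
    exclusion_s: float = SETTLING_EXCLUSION_S,
    on_short: str = "error",
    burst_params: BurstParams = BurstParams(),
) -> tuple[SpikeTrain, list[Burst]]:
    """Filter, detect spikes, exclude settling, classify, detect bursts."""
    filtered = bandpass_filter(trace)
    rms = estimate_noise_rms(filtered.samples, method=noise_method)
    if rms <= 0:
        train = SpikeTrain(
            spike_times_s=np.empty(0),
            analyzed_duration_s=len(trace.samples) / trace.fs,
            well_id=trace.well_id,
            electrode_id=trace.electrode_id,
        )
    else:
        train = detect_spikes(filtered, rms, threshold_factor)
    duration = record_duration_s or train.analyzed_duration_s
    times, analyzed = exclude_settling(
        train.spike_times_s, duration, exclusion_s, on_short
    )
    train = SpikeTrain(
        spike_times_s=times,
        analyzed_duration_s=analyzed,
        well_id=trace.well_id,
        electrode_id=trace.electrode_id,
    )
    classify_active(train)
    bursts = detect_bursts(train.spike_times_s, burst_params) if train.active else []
    return train, bursts
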