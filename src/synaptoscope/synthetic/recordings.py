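"""Synthetic multi-well MEA recordings with ground-truth spike trains.

Each electrode carries a spike train made of Poisson background spikes plus
embedded bursts (>= 4 spikes with short intra-burst intervals).  Raw voltage
traces are rendered as Gaussian noise of a requested RMS plus a biphasic
extracellular spike waveform placed at every true spike time, so that spike
and burst detectors can be scored against exact truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

DEFAULT_FS = 12_500.0  # samples/s; comfortably above the 5 kHz low-pass corner


@dataclass(frozen=True)
class RecordingSpec:
    """Parameters of one synthetic recording session (all electrodes alike).

    Rates may be overridden per electrode via ``generate_recording``'s
    ``rates_hz`` argument.  ``amplitude_uv`` is the negative peak of the
    spike waveform; ``noise_rms_uv`` the broadband noise RMS.
    """

    fs: float = DEFAULT_FS
    duration_s: float = 1980.0  # 33 min
    n_wells: int = 1
    electrodes_per_well: int = 64
    background_rate_hz: float = 0.5
    burst_rate_per_min: float = 2.0
    burst_n_spikes_mean: float = 6.0
    intra_burst_isi_s: float = 0.015
    amplitude_uv: float = 16.0
    noise_rms_uv: float = 2.0
    refractory_s: float = 0.002

    def validate(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")
        if self.fs < 2 * 5000:
            raise ValueError("fs must exceed twice the 5 kHz waveform band")
        if self.amplitude_uv <= 0:
            raise ValueError("spike amplitude_uv must be > 0")
        if self.noise_rms_uv < 0:
            raise ValueError("noise_rms_uv must be >= 0")
        if self.background_rate_hz < 0 or self.burst_rate_per_min < 0:
            raise ValueError("rates must be >= 0")
        if self.intra_burst_isi_s <= 0:
            raise ValueError("intra_burst_isi_s must be > 0")


@dataclass
class ElectrodeTruth:
    well_id: str
    electrode_id: str
    spike_times_s: np.ndarray  # sorted, within [0, duration]
    burst_slices: list[tuple[int, int]]  # index ranges [i, j) into spike_times
    amplitude_uv: float
    noise_rms_uv: float


@dataclass
class RecordingGroundTruth:
    spec: RecordingSpec
    electrodes: list[ElectrodeTruth]
    seed: int

    def electrode(self, well_id: str, electrode_id: str) -> ElectrodeTruth:
        for e in self.electrodes:
            if e.well_id == well_id and e.electrode_id == electrode_id:
                return e
        raise KeyError((well_id, electrode_id))


def spike_waveform(fs: float, amplitude_uv: float) -> np.ndarray:
    """Biphasic extracellular spike: one windowed sine cycle, ~1.2 ms,
    normalised so the negative peak equals -amplitude_uv."""
    n = max(int(round(1.2e-3 * fs)), 8)
    t = np.arange(n) / n
    w = -np.sin(2 * math.pi * t) * np.hanning(n)
    return amplitude_uv * w / np.abs(w).max()


def generate_spike_train(
    rng: np.random.Generator,
    duration_s: float,
    background_rate_hz: float,
    burst_rate_per_min: float,
    burst_n_spikes_mean: float,
    intra_burst_isi_s: float,
    refractory_s: float = 0.002,
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Poisson background + embedded bursts; returns sorted times and the
    index ranges of the embedded bursts after merging."""
    n_bg = rng.poisson(background_rate_hz * duration_s)
    background = rng.uniform(0.0, duration_s, size=n_bg)

    burst_spikes: list[np.ndarray] = []
    n_bursts = rng.poisson(burst_rate_per_min * duration_s / 60.0)
    starts = np.sort(rng.uniform(0.0, max(duration_s - 1.0, 0.0), size=n_bursts))
    kept_starts: list[float] = []
    for s in starts:
        if not kept_starts or s - kept_starts[-1] > 1.0:  # >= 1 s apart
            kept_starts.append(float(s))
    for s in kept_starts:
        n_spk = 4 + rng.poisson(max(burst_n_spikes_mean - 4.0, 0.0))
        # intra-burst ISIs strictly below the stated parameter
        isis = rng.uniform(0.45 * intra_burst_isi_s, 0.95 * intra_burst_isi_s,
                           size=n_spk - 1)
        times = s + np.concatenate([[0.0], np.cumsum(isis)])
        burst_spikes.append(times[times < duration_s])

    # drop background spikes colliding with burst spikes or each other
    all_burst = np.concatenate(burst_spikes) if burst_spikes else np.empty(0)
    if len(all_burst):
        keep = np.array(
            [np.abs(all_burst - b).min() > refractory_s for b in background]
        ) if len(background) else np.empty(0, dtype=bool)
        background = background[keep] if len(background) else background
    background = np.sort(background)
    if len(background) > 1:
        keep_idx = [0]
        for i in range(1, len(background)):
            if background[i] - background[keep_idx[-1]] > refractory_s:
                keep_idx.append(i)
        background = background[keep_idx]

    times = np.sort(np.concatenate([background, all_burst]))
    # locate each burst's index range in the merged train
    slices: list[tuple[int, int]] = []
    for bs in burst_spikes:
        if len(bs) >= 4:
            i = int(np.searchsorted(times, bs[0] - 1e-12))
            slices.append((i, i + len(bs)))
    return times, slices


def generate_recording(
    spec: RecordingSpec,
    seed: int = 0,
    rates_hz: dict[tuple[str, str], float] | None = None,
    burst_rates_per_min: dict[tuple[str, str], float] | None = None,
    render_raw: bool = True,
) -> tuple[dict[tuple[str, str], np.ndarray] | None, RecordingGroundTruth]:
    """Generate a multi-well recording.

    Returns ``(traces, truth)`` where ``traces`` maps (well_id, electrode_id)
    to a float32 voltage array in uV, or ``None`` when ``render_raw`` is
    False (spike-time-only mode).  ``rates_hz`` and ``burst_rates_per_min``
    optionally override the background and burst rates per electrode.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    n_samples = int(round(spec.duration_s * spec.fs))
    wave = spike_waveform(spec.fs, spec.amplitude_uv)
    peak_offset = int(np.argmin(wave))  # negative extremum sample

    traces: dict[tuple[str, str], np.ndarray] | None = {} if render_raw else None
    electrodes: list[ElectrodeTruth] = []
    for w in range(spec.n_wells):
        well_id = f"well{w:02d}"
        for e in range(spec.electrodes_per_well):
            electrode_id = f"e{e:02d}"
            rate = spec.background_rate_hz
            if rates_hz is not None:
                rate = rates_hz.get((well_id, electrode_id), rate)
            burst_rate = spec.burst_rate_per_min if rate > 0 else 0.0
            if burst_rates_per_min is not None:
                burst_rate = burst_rates_per_min.get((well_id, electrode_id), burst_rate)
            if rate < 0 or burst_rate < 0:
                raise ValueError("rates must be >= 0")
            times, slices = generate_spike_train(
                rng,
                spec.duration_s,
                rate,
                burst_rate,
                spec.burst_n_spikes_mean,
                spec.intra_burst_isi_s,
                spec.refractory_s,
            )
            electrodes.append(
                ElectrodeTruth(
                    well_id=well_id,
                    electrode_id=electrode_id,
                    spike_times_s=times,
                    burst_slices=slices,
                    amplitude_uv=spec.amplitude_uv,
                    noise_rms_uv=spec.noise_rms_uv,
                )
            )
            if render_raw:
                trace = rng.normal(0.0, spec.noise_rms_uv, size=n_samples)
                for t in times:
                    i0 = int(round(t * spec.fs)) - peak_offset
                    j0 = i0 + len(wave)
                    wi, wj = 0, len(wave)
                    if i0 < 0:
                        wi, i0 = -i0, 0
                    if j0 > n_samples:
                        wj -= j0 - n_samples
                        j0 = n_samples
                    if wi < wj:
                        trace[i0:j0] += wave[wi:wj]
                traces[(well_id, electrode_id)] = trace.astype(np.float32)

    return traces, RecordingGroundTruth(spec=spec, electrodes=electrodes, seed=seed)
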