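"""End-to-end study orchestration: the desk-scale reproduction harness.

``run_all`` regenerates the full analysis structure of a synaptogenesis
ontogeny study from synthetic data: an imaging arm (fields -> endpoints ->
well means -> two-way ANOVA + Sidak contrasts), an MEA arm (spike trains ->
activity summaries -> the same statistics) and an ELISA arm.  Every stage is
deterministic under the master seed, and every output row carries ids that
resolve back to the generating design.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, hci, io as sio, mea, stats
from .synthetic import (
    ImagingParams,
    RecordingSpec,
    design_table,
    field_seed,
    generate_elisa_plate,
    generate_field,
    generate_field_geometry,
    generate_recording,
    preset_profile,
)

logger = logging.getLogger(__name__)

ENDPOINT_COLUMNS = [
    "neurons_per_field",
    "dendrite_length_per_neuron_um",
    "vglut_per_cell_body",
    "vgat_per_cell_body",
    "vglut_per_um_dendrite",
    "vgat_per_um_dendrite",
    "vglut_total_per_neuron",
    "vgat_total_per_neuron",
    "ei_ratio_cell_body",
    "ei_ratio_dendrite",
    "ei_ratio_total",
]

# Per-condition MEA activity: (fraction of active electrodes, firing rate of
# active electrodes in Hz, burst rate of active electrodes per minute).
# Activity rises to a DIV-14 peak and partially regresses afterwards, with
# cortical cultures firing and bursting harder at the peak.
MEA_ACTIVITY = {
    ("hippocampal", 7): (0.50, 0.40, 1.0),
    ("hippocampal", 14): (0.80, 1.00, 4.0),
    ("hippocampal", 21): (0.60, 0.50, 1.5),
    ("hippocampal", 28): (0.60, 0.50, 1.5),
    ("cortical", 7): (0.35, 0.30, 1.0),
    ("cortical", 14): (0.80, 2.00, 8.0),
    ("cortical", 21): (0.60, 0.80, 2.5),
    ("cortical", 28): (0.60, 0.70, 2.5),
}
INACTIVE_RATE_HZ = 0.02  # 1.2 spikes/min, below the 5/min activity criterion

# Synaptophysin level rises with DIV identically in both cell types (a time
# main effect with no cell-type effect).
ELISA_LEVELS = {7: 0.20, 14: 0.32, 21: 0.48, 28: 0.58}


@dataclass(frozen=True)
class StudyConfig:
    """Design and parameters of one synthetic study run."""

    seed: int = 0
    cell_types: tuple[str, ...] = ("hippocampal", "cortical")
    divs: tuple[int, ...] = (7, 14, 21, 28)
    wells_per_condition: int = 3
    fields_per_well: int = 12
    imaging: ImagingParams = dc_field(
        default_factory=lambda: ImagingParams(shape=(256, 320))
    )
    hci_params: hci.HCIParams = dc_field(default_factory=hci.HCIParams)
    detection: str = "image"  # 'image' (render + detect) | 'truth' (geometry)
    # MEA arm
    mea_electrodes_per_well: int = 16
    mea_duration_s: float = 1980.0
    mea_exclusion_s: float = 180.0
    mea_render_raw: bool = False
    mea_fs: float = 12_500.0
    # ELISA arm
    elisa_plates: int = 3
    elisa_noise_sd: float = 0.04
    # statistics
    alpha: float = 0.05
    posthoc_strategy: str = "all_pairwise"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "StudyConfig":
        kwargs = dict(raw)
        if "imaging" in kwargs and isinstance(kwargs["imaging"], dict):
            img = dict(kwargs["imaging"])
            if "shape" in img:
                img["shape"] = tuple(img["shape"])
            kwargs["imaging"] = ImagingParams(**img)
        if "hci_params" in kwargs and isinstance(kwargs["hci_params"], dict):
            kwargs["hci_params"] = hci.HCIParams(**kwargs["hci_params"])
        for key in ("cell_types", "divs"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


@dataclass
class StudyReport:
    """All tables produced by one run, plus provenance."""

    config: StudyConfig
    tables: dict[str, pd.DataFrame] = dc_field(default_factory=dict)

    @property
    def provenance(self) -> dict:
        return {
            "config_hash": self.config.config_hash(),
            "seed": self.config.seed,
            "version": __version__,
        }

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in sorted(self.tables):
            sio.write_csv(self.tables[name], outdir / f"{name}.csv")
        with open(outdir / "provenance.json", "w") as fh:
            json.dump(self.provenance, fh, sort_keys=True, indent=2)
        with open(outdir / "config.json", "w") as fh:
            json.dump(self.config.to_dict(), fh, sort_keys=True, indent=2,
                      default=str)


# ---------------------------------------------------------------------------
# imaging arm


def _truth_endpoints(truth) -> hci.FieldEndpoints:
    """Endpoints computed directly from ground-truth geometry (no images)."""
    puncta = [
        hci.Punctum(
            centroid=p.center, area_px=0, peak_intensity=0.0, channel=p.channel,
            compartment=p.compartment if p.compartment != "background" else "excluded",
            neuron_id=p.neuron_id if p.neuron_id >= 0 else None,
        )
        for p in truth.puncta
    ]
    neurons = [
        hci.NeuronObject(
            neuron_id=t.neuron_id,
            nucleus_centroid=t.nucleus_center,
            soma_mask=np.zeros((1, 1), dtype=bool),
            dendrite_length_um=t.dendrite_length_um,
        )
        for t in truth.neurons
    ]
    return hci.compute_field_endpoints(neurons, puncta)


def run_imaging_study(config: StudyConfig) -> StudyReport:
    """Generate, quantify and statistically analyse the imaging arm."""
    table = design_table(
        config.cell_types,
        config.divs,
        config.wells_per_condition,
        config.fields_per_well,
        config.seed,
    )
    rows = []
    for _, drow in table.iterrows():
        profile = preset_profile(drow["cell_type"], int(drow["div"]))
        seed = int(drow["seed"])
        try:
            if config.detection == "truth":
                truth = generate_field_geometry(profile, config.imaging, seed)
                endpoints = _truth_endpoints(truth)
            else:
                images, truth = generate_field(profile, config.imaging, seed)
                _, _, endpoints = hci.analyze_field(images, config.hci_params)
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(
                f"imaging stage failed for field {drow['field_id']}"
            ) from exc
        rows.append({**drow.to_dict(), **endpoints.as_dict()})
    fields = pd.DataFrame(rows)

    usable = fields[fields["neurons_per_field"] > 0]
    n_empty = len(fields) - len(usable)
    if n_empty:
        logger.warning("%d field(s) with zero neurons excluded from well means",
                       n_empty)
    wells = (
        usable.groupby(["cell_type", "div", "well_id"], sort=True)[ENDPOINT_COLUMNS]
        .mean()
        .reset_index()
    )

    anova_frames, contrast_frames = [], []
    for endpoint in ENDPOINT_COLUMNS:
        obs = wells.rename(columns={endpoint: "value"})[
            ["cell_type", "div", "well_id", "value"]
        ]
        try:
            res = stats.two_way_anova(obs, endpoint=endpoint)
        except (ValueError, stats.DegenerateDataError) as exc:
            logger.warning("ANOVA skipped for %s: %s", endpoint, exc)
            continue
        res = stats.AnovaResult(endpoint=endpoint, effects=res.effects)
        anova_frames.append(res.frame())
        contrasts = stats.sidak_posthoc(
            obs, res, alpha=config.alpha, strategy=config.posthoc_strategy
        )
        if len(contrasts):
            contrast_frames.append(contrasts)
    report = StudyReport(config=config)
    report.tables["imaging_field_endpoints"] = fields
    report.tables["imaging_well_endpoints"] = wells
    report.tables["imaging_anova"] = (
        pd.concat(anova_frames, ignore_index=True) if anova_frames else pd.DataFrame()
    )
    report.tables["imaging_contrasts"] = (
        pd.concat(contrast_frames, ignore_index=True)
        if contrast_frames
        else pd.DataFrame()
    )
    logger.info(
        "imaging arm: %d fields, %d wells", len(fields), len(wells)
    )
    return report


# ---------------------------------------------------------------------------
# MEA arm


def run_mea_study(config: StudyConfig) -> StudyReport:
    """Generate and analyse the MEA arm (spike-time mode by default)."""
    summaries = []
    spikes_rows = []
    cond_idx = 0
    for ct in config.cell_types:
        for div in config.divs:
            key = (ct, div)
            if key not in MEA_ACTIVITY:
                raise ValueError(f"no MEA activity preset for {key}")
            frac_active, active_rate, burst_rate = MEA_ACTIVITY[key]
            spec = RecordingSpec(
                fs=config.mea_fs,
                duration_s=config.mea_duration_s,
                n_wells=config.wells_per_condition,
                electrodes_per_well=config.mea_electrodes_per_well,
            )
            cond_seed = field_seed(config.seed, 100_000 + cond_idx)
            cond_idx += 1
            pick = np.random.default_rng(cond_seed)
            rates, brates = {}, {}
            for w in range(spec.n_wells):
                for e in range(spec.electrodes_per_well):
                    kye = (f"well{w:02d}", f"e{e:02d}")
                    if pick.uniform() < frac_active:
                        rates[kye] = active_rate
                        brates[kye] = burst_rate
                    else:
                        rates[kye] = INACTIVE_RATE_HZ
                        brates[kye] = 0.0
            traces, truth = generate_recording(
                spec,
                seed=cond_seed,
                rates_hz=rates,
                burst_rates_per_min=brates,
                render_raw=config.mea_render_raw,
            )
            by_well: dict[str, list] = {}
            for elec in truth.electrodes:
                if config.mea_render_raw:
                    trace = mea.ElectrodeTrace(
                        samples=traces[(elec.well_id, elec.electrode_id)],
                        fs=spec.fs,
                        well_id=elec.well_id,
                        electrode_id=elec.electrode_id,
                    )
                    train, bursts = mea.analyze_trace(
                        trace,
                        record_duration_s=spec.duration_s,
                        exclusion_s=config.mea_exclusion_s,
                        on_short="zero",
                    )
                else:
                    times, analyzed = mea.exclude_settling(
                        elec.spike_times_s,
                        spec.duration_s,
                        config.mea_exclusion_s,
                        on_short="zero",
                    )
                    train = mea.SpikeTrain(
                        spike_times_s=times,
                        analyzed_duration_s=analyzed,
                        well_id=elec.well_id,
                        electrode_id=elec.electrode_id,
                    )
                    mea.classify_active(train)
                    bursts = (
                        mea.detect_bursts(train.spike_times_s)
                        if train.active
                        else []
                    )
                by_well.setdefault(elec.well_id, []).append((train, bursts))
                for t in train.spike_times_s:
                    spikes_rows.append(
                        {
                            "cell_type": ct,
                            "div": div,
                            "well_id": f"{ct[:4]}_div{div:02d}_{elec.well_id}",
                            "electrode_id": elec.electrode_id,
                            "time_s": float(t),
                        }
                    )
            for well_id, pairs in sorted(by_well.items()):
                trains = [p[0] for p in pairs]
                bursts = [p[1] for p in pairs]
                summary = mea.summarize_well(trains, bursts)
                summaries.append(
                    {
                        "cell_type": ct,
                        "div": div,
                        "well_id": f"{ct[:4]}_div{div:02d}_{well_id}",
                        "n_active_electrodes": summary.n_active_electrodes,
                        "mean_firing_rate_per_min": summary.mean_firing_rate_per_min,
                        "mean_burst_rate_per_min": summary.mean_burst_rate_per_min,
                    }
                )
    wells = pd.DataFrame(summaries)

    anova_frames, contrast_frames = [], []
    for endpoint in (
        "n_active_electrodes",
        "mean_firing_rate_per_min",
        "mean_burst_rate_per_min",
    ):
        obs = wells.rename(columns={endpoint: "value"})[
            ["cell_type", "div", "well_id", "value"]
        ]
        try:
            res = stats.two_way_anova(obs, endpoint=endpoint)
        except (ValueError, stats.DegenerateDataError) as exc:
            logger.warning("ANOVA skipped for %s: %s", endpoint, exc)
            continue
        anova_frames.append(res.frame())
        contrasts = stats.sidak_posthoc(
            obs, res, alpha=config.alpha, strategy=config.posthoc_strategy
        )
        if len(contrasts):
            contrast_frames.append(contrasts)
    report = StudyReport(config=config)
    report.tables["mea_well_summaries"] = wells
    report.tables["mea_spikes"] = pd.DataFrame(
        spikes_rows, columns=["cell_type", "div", "well_id", "electrode_id", "time_s"]
    )
    report.tables["mea_anova"] = (
        pd.concat(anova_frames, ignore_index=True) if anova_frames else pd.DataFrame()
    )
    report.tables["mea_contrasts"] = (
        pd.concat(contrast_frames, ignore_index=True)
        if contrast_frames
        else pd.DataFrame()
    )
    logger.info("MEA arm: %d wells", len(wells))
    return report


# ---------------------------------------------------------------------------
# ELISA arm


def run_elisa_study(config: StudyConfig) -> StudyReport:
    """Generate plates, normalise, and run the ontogeny ANOVA."""
    rows = []
    for plate_idx in range(config.elisa_plates):
        levels = {}
        for ct in config.cell_types:
            for div in config.divs:
                if div not in ELISA_LEVELS:
                    raise ValueError(f"no ELISA level preset for DIV {div}")
                levels[f"{ct}_div{div:02d}"] = ELISA_LEVELS[div]
        plate = generate_elisa_plate(
            levels,
            noise_sd=config.elisa_noise_sd,
            seed=field_seed(config.seed, 200_000 + plate_idx),
        )
        norm = stats.normalize_elisa(plate)
        for _, r in norm.iterrows():
            ct, div_s = r["sample_id"].rsplit("_div", maxsplit=1)
            rows.append(
                {
                    "cell_type": ct,
                    "div": int(div_s),
                    "well_id": f"plate{plate_idx}",
                    "value": r["normalized"],
                }
            )
    obs = pd.DataFrame(rows)
    report = StudyReport(config=config)
    report.tables["elisa_values"] = obs
    try:
        res = stats.two_way_anova(obs, endpoint="synaptophysin")
        report.tables["elisa_anova"] = res.frame()
        report.tables["elisa_contrasts"] = stats.sidak_posthoc(
            obs, res, alpha=config.alpha, strategy=config.posthoc_strategy
        )
    except (ValueError, stats.DegenerateDataError) as exc:
        logger.warning("ELISA ANOVA skipped: %s", exc)
    return report


# ---------------------------------------------------------------------------
# umbrella


def run_all(config: StudyConfig, outdir: str | Path | None = None) -> StudyReport:
    """Run all three arms; optionally write every table under ``outdir``."""
    report = StudyReport(config=config)
    for part in (run_imaging_study(config), run_mea_study(config),
                 run_elisa_study(config)):
        report.tables.update(part.tables)
    if outdir is not None:
        report.write(outdir)
    return report
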