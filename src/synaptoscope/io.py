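"""On-disk interchange formats.

Image fields are one single-channel TIFF per channel plus a sidecar CSV of
field metadata; ground truth is stored as plain CSV tables keyed by field id.
Raw MEA traces are flat little-endian float32 binaries (channel-major) with a
CSV header table; spike-time-only datasets are a single CSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .hci import FieldImageSet

CHANNELS = ("nuclei", "map2", "vglut1", "vgat")
FLOAT_FMT = "%.10g"  # fixed formatting keeps outputs byte-identical per seed


def write_field_images(outdir: str | Path, field_id: str, images: FieldImageSet) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for ch in CHANNELS:
        tifffile.imwrite(outdir / f"{field_id}_{ch}.tif", images.plane(ch))


def read_field_images(
    indir: str | Path, field_id: str, pixel_size_um: float = 0.5
) -> FieldImageSet:
    indir = Path(indir)
    planes = {ch: tifffile.imread(indir / f"{field_id}_{ch}.tif") for ch in CHANNELS}
    return FieldImageSet(
        nuclei_plane=planes["nuclei"],
        map2_plane=planes["map2"],
        vglut1_plane=planes["vglut1"],
        vgat_plane=planes["vgat"],
        pixel_size_um=pixel_size_um,
    )


def render_overlay(images, neurons, puncta) -> np.ndarray:
    """QC overlay: MAP2 in grey, soma masks blue, skeletons cyan, assigned
    vGLUT1 puncta red, assigned vGAT puncta green, excluded puncta dim."""
    map2 = images.map2_plane.astype(float)
    lo, hi = np.percentile(map2, (1, 99.5))
    base = np.clip((map2 - lo) / max(hi - lo, 1e-9), 0, 1) * 120
    rgb = np.stack([base, base, base], axis=-1)
    for n in neurons:
        rgb[n.soma_mask] = [40, 60, 200]
        if len(n.dendrite_skeleton):
            rr, cc = n.dendrite_skeleton[:, 0], n.dendrite_skeleton[:, 1]
            rgb[rr, cc] = [0, 200, 200]
    for p in puncta:
        r, c = int(round(p.centroid[0])), int(round(p.centroid[1]))
        if not (0 <= r < rgb.shape[0] and 0 <= c < rgb.shape[1]):
            continue
        if p.compartment == "excluded":
            color = [80, 80, 80]
        elif p.channel == "vglut1":
            color = [255, 40, 40]
        else:
            color = [40, 255, 40]
        rgb[max(r - 1, 0): r + 2, max(c - 1, 0): c + 2] = color
    return rgb.astype(np.uint8)


def write_overlay(path: str | Path, images, neurons, puncta) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, render_overlay(images, neurons, puncta))


def write_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Deterministic CSV writer (fixed float format, no index)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def write_traces(
    outdir: str | Path,
    traces: dict[tuple[str, str], np.ndarray],
    fs: float,
    duration_s: float,
) -> None:
    """Flat binary per electrode (little-endian float32) + CSV header table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for (well, electrode), samples in traces.items():
        fname = f"{well}_{electrode}.f32"
        samples.astype("<f4").tofile(outdir / fname)
        rows.append(
            {
                "well_id": well,
                "electrode_id": electrode,
                "file": fname,
                "fs": fs,
                "duration_s": duration_s,
                "n_samples": len(samples),
            }
        )
    write_csv(pd.DataFrame(rows), outdir / "traces.csv")


def read_traces(indir: str | Path) -> tuple[dict[tuple[str, str], np.ndarray], float]:
    indir = Path(indir)
    header = pd.read_csv(indir / "traces.csv")
    traces = {}
    fs = float(header["fs"].iloc[0])
    for _, row in header.iterrows():
        samples = np.fromfile(indir / row["file"], dtype="<f4")
        traces[(row["well_id"], row["electrode_id"])] = samples.astype(float)
    return traces, fs


def write_spike_times(path: str | Path, spikes: pd.DataFrame) -> None:
    """Spike-time CSV with columns (well_id, electrode_id, time_s)."""
    write_csv(spikes, path)


def read_spike_times(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
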