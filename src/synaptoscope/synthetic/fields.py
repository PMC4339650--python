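"""Synthetic four-channel immunofluorescence fields with full ground truth.

Each generated field emulates one 20x field of view of a dissociated neuronal
culture stained for nuclei (Hoechst-like), MAP2 (somata + dendrites; axons are
MAP2-negative and therefore absent from this plane), vGLUT1 (excitatory
presynaptic puncta) and vGAT (inhibitory presynaptic puncta):

* somata are non-overlapping disks, each with a nucleus;
* dendrites are smooth random polylines rooted on the soma boundary;
* puncta are PSF-blurred Gaussian spots placed on dendrites, inside somata, or
  as off-neuron background distractors, with a hard-core minimum spacing that
  models the physical size of presynaptic boutons;
* the vGLUT1 plane additionally carries continuous low-intensity axon-like
  streaks that have no ground-truth puncta and must be rejected downstream.

Every random draw goes through one ``numpy.random.Generator`` seeded by the
caller, so identical (parameters, seed) give bit-identical images, and the
emitted :class:`FieldGroundTruth` records the exact geometry used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.draw import disk as draw_disk
from skimage.draw import line as draw_line

from ..hci import FieldImageSet
from .profiles import CultureProfile, preset_profile

# Hard-core exclusion between puncta centres, modelling bouton size (~1-2 um).
DENDRITE_PUNCTA_MIN_SPACING_UM = 2.0
SOMA_PUNCTA_MIN_SPACING_PX = 5.0
# Dendritic puncta start this far (arc length, px) from the soma boundary so
# that soma-mask dilation in the analysis cannot swallow them.
DENDRITE_PUNCTA_SOMA_CLEARANCE_PX = 10.0


@dataclass(frozen=True)
class ImagingParams:
    """Rendering parameters of the synthetic microscope.

    Intensities are arbitrary 16-bit-range units.  ``contact_tolerance_px`` is
    the dendrite-contact tolerance the ground-truth labels are generated to
    respect (2 px = 1 um at the default 0.5 um/px).
    """

    shape: tuple[int, int] = (520, 696)
    pixel_size_um: float = 0.5
    psf_sigma_px: float = 1.5
    noise_sd: float = 20.0
    background_offset: float = 100.0
    punctum_peak: float = 200.0
    nucleus_intensity: float = 3000.0
    soma_intensity: float = 2500.0
    dendrite_intensity: float = 1600.0
    streak_peak: float = 70.0
    contact_tolerance_px: float = 2.0

    def validate(self) -> None:
        if self.shape[0] < 64 or self.shape[1] < 64:
            raise ValueError("field dimensions must be at least 64x64 px")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class NeuronTruth:
    """True geometry of one neuron: soma disk, nucleus, dendrite polylines."""

    neuron_id: int
    soma_center: tuple[float, float]  # (row, col) px
    soma_radius_px: float
    nucleus_center: tuple[float, float]
    polylines: list[np.ndarray]  # each (N, 2) float (row, col) px
    dendrite_length_um: float


@dataclass
class PunctumTruth:
    """True centre, channel and compartment of one synaptic punctum."""

    center: tuple[float, float]  # (row, col) px
    channel: str  # 'vglut1' | 'vgat'
    compartment: str  # 'cell_body' | 'dendrite' | 'background'
    neuron_id: int  # -1 for background


@dataclass
class FieldGroundTruth:
    neurons: list[NeuronTruth]
    puncta: list[PunctumTruth]
    imaging: ImagingParams
    seed: int
    profile: CultureProfile | None = None

    def puncta_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "row": [p.center[0] for p in self.puncta],
                "col": [p.center[1] for p in self.puncta],
                "channel": [p.channel for p in self.puncta],
                "compartment": [p.compartment for p in self.puncta],
                "neuron_id": [p.neuron_id for p in self.puncta],
            }
        )

    def neurons_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "neuron_id": [n.neuron_id for n in self.neurons],
                "soma_row": [n.soma_center[0] for n in self.neurons],
                "soma_col": [n.soma_center[1] for n in self.neurons],
                "soma_radius_px": [n.soma_radius_px for n in self.neurons],
                "nucleus_row": [n.nucleus_center[0] for n in self.neurons],
                "nucleus_col": [n.nucleus_center[1] for n in self.neurons],
                "dendrite_length_um": [n.dendrite_length_um for n in self.neurons],
            }
        )

    def count(self, channel: str, compartment: str) -> int:
        return sum(
            1
            for p in self.puncta
            if p.channel == channel and p.compartment == compartment
        )

    def total_dendrite_length_um(self) -> float:
        return float(sum(n.dendrite_length_um for n in self.neurons))


# ---------------------------------------------------------------------------
# geometry helpers


def polyline_length_px(points: np.ndarray) -> float:
    if len(points) < 2:
        return 0.0
    return float(np.sum(np.linalg.norm(np.diff(points, axis=0), axis=1)))


def min_dist_to_polyline(point: np.ndarray, poly: np.ndarray) -> float:
    """Minimum Euclidean distance from a point to a polyline (segment-wise)."""
    if len(poly) == 1:
        return float(np.linalg.norm(point - poly[0]))
    a = poly[:-1]
    b = poly[1:]
    ab = b - a
    ap = point[None, :] - a
    denom = np.einsum("ij,ij->i", ab, ab)
    denom[denom == 0] = 1.0
    t = np.clip(np.einsum("ij,ij->i", ap, ab) / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return float(np.min(np.linalg.norm(point[None, :] - proj, axis=1)))


def _point_on_polyline(poly: np.ndarray, arclen: float) -> tuple[np.ndarray, np.ndarray]:
    """Point and unit tangent at a given arc length along a polyline."""
    seg = np.diff(poly, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    arclen = min(max(arclen, 0.0), cum[-1])
    i = int(np.searchsorted(cum, arclen, side="right") - 1)
    i = min(i, len(seg) - 1)
    frac = (arclen - cum[i]) / seg_len[i] if seg_len[i] > 0 else 0.0
    pt = poly[i] + frac * seg[i]
    tangent = seg[i] / seg_len[i] if seg_len[i] > 0 else np.array([1.0, 0.0])
    return pt, tangent


# ---------------------------------------------------------------------------
# geometry generation


def _place_somata(
    rng: np.random.Generator,
    n: int,
    shape: tuple[int, int],
    radius_mean: float,
    radius_sd: float,
) -> list[tuple[np.ndarray, float]]:
    """Place n non-overlapping soma disks; raise if the field is too crowded."""
    placed: list[tuple[np.ndarray, float]] = []
    max_tries = 400 * max(n, 1)
    tries = 0
    while len(placed) < n:
        if tries >= max_tries:
            raise ValueError(
                "could not place non-overlapping somata: neurons_per_field too "
                "large for the field dimensions"
            )
        tries += 1
        r_px = max(rng.normal(radius_mean, radius_sd), 0.5 * radius_mean)
        margin = r_px + 6.0
        center = np.array(
            [
                rng.uniform(margin, shape[0] - margin),
                rng.uniform(margin, shape[1] - margin),
            ]
        )
        ok = all(
            np.linalg.norm(center - c) >= r_px + r + 8.0 for c, r in placed
        )
        if ok:
            placed.append((center, float(r_px)))
    return placed


def _grow_dendrite(
    rng: np.random.Generator,
    start: np.ndarray,
    direction: float,
    target_len_px: float,
    shape: tuple[int, int],
    somata: list[tuple[np.ndarray, float]],
    own_index: int,
    step_px: float = 3.0,
    turn_sd: float = 0.18,
) -> np.ndarray:
    """Random smooth polyline from the soma boundary; stops at field borders
    and at foreign somata."""
    points = [start.copy()]
    pos = start.copy()
    theta = direction
    grown = 0.0
    while grown < target_len_px:
        theta += rng.normal(0.0, turn_sd)
        step = np.array([math.sin(theta), math.cos(theta)]) * step_px
        nxt = pos + step
        if not (2.0 <= nxt[0] <= shape[0] - 3.0 and 2.0 <= nxt[1] <= shape[1] - 3.0):
            break
        blocked = False
        for j, (c, r) in enumerate(somata):
            if j != own_index and np.linalg.norm(nxt - c) < r + 3.0:
                blocked = True
                break
        if blocked:
            break
        points.append(nxt)
        pos = nxt
        grown += step_px
    return np.asarray(points)


def _sample_arclengths_hardcore(
    rng: np.random.Generator,
    n_target: int,
    lo: float,
    hi: float,
    min_spacing: float,
) -> list[float]:
    """Sequential random adsorption of points on [lo, hi] with a hard core."""
    if hi <= lo or n_target <= 0:
        return []
    accepted: list[float] = []
    tries = 0
    while len(accepted) < n_target and tries < 60 * n_target:
        tries += 1
        s = rng.uniform(lo, hi)
        if all(abs(s - a) >= min_spacing for a in accepted):
            accepted.append(s)
    return accepted


def _sample_disk_hardcore(
    rng: np.random.Generator,
    n_target: int,
    center: np.ndarray,
    radius: float,
    min_spacing: float,
) -> list[np.ndarray]:
    accepted: list[np.ndarray] = []
    tries = 0
    while len(accepted) < n_target and tries < 80 * max(n_target, 1):
        tries += 1
        rr = radius * math.sqrt(rng.uniform())
        th = rng.uniform(0, 2 * math.pi)
        pt = center + rr * np.array([math.sin(th), math.cos(th)])
        if all(np.linalg.norm(pt - a) >= min_spacing for a in accepted):
            accepted.append(pt)
    return accepted


# ---------------------------------------------------------------------------
# rendering helpers


def _add_gaussian_spot(
    img: np.ndarray, center: tuple[float, float], sigma: float, peak: float
) -> None:
    r0, c0 = center
    half = int(math.ceil(4 * sigma))
    rlo = max(int(math.floor(r0)) - half, 0)
    rhi = min(int(math.floor(r0)) + half + 1, img.shape[0])
    clo = max(int(math.floor(c0)) - half, 0)
    chi = min(int(math.floor(c0)) + half + 1, img.shape[1])
    if rlo >= rhi or clo >= chi:
        return
    rr, cc = np.meshgrid(
        np.arange(rlo, rhi, dtype=float), np.arange(clo, chi, dtype=float),
        indexing="ij",
    )
    img[rlo:rhi, clo:chi] += peak * np.exp(
        -((rr - r0) ** 2 + (cc - c0) ** 2) / (2.0 * sigma**2)
    )


def _draw_polyline(canvas: np.ndarray, poly: np.ndarray) -> None:
    pts = np.round(poly).astype(int)
    for (r1, c1), (r2, c2) in zip(pts[:-1], pts[1:]):
        rr, cc = draw_line(r1, c1, r2, c2)
        valid = (
            (rr >= 0) & (rr < canvas.shape[0]) & (cc >= 0) & (cc < canvas.shape[1])
        )
        canvas[rr[valid], cc[valid]] = 1.0


# ---------------------------------------------------------------------------
# main generators


def generate_field(
    profile: CultureProfile,
    imaging: ImagingParams | None = None,
    seed: int = 0,
) -> tuple[FieldImageSet, FieldGroundTruth]:
    """Render one four-channel field and its ground truth.

    Deterministic: identical (profile, imaging, seed) give bit-identical
    planes and identical ground-truth records.
    """
    profile.validate()
    imaging = imaging or ImagingParams()
    imaging.validate()
    rng = np.random.default_rng(seed)
    neurons, puncta = _generate_geometry(rng, profile, imaging)
    images = _render(rng, neurons, puncta, profile, imaging)
    truth = FieldGroundTruth(
        neurons=neurons, puncta=puncta, imaging=imaging, seed=seed,
        profile=profile,
    )
    return images, truth


def generate_field_geometry(
    profile: CultureProfile,
    imaging: ImagingParams | None = None,
    seed: int = 0,
) -> FieldGroundTruth:
    """Ground truth only, skipping image rendering (same geometry stream)."""
    profile.validate()
    imaging = imaging or ImagingParams()
    imaging.validate()
    rng = np.random.default_rng(seed)
    neurons, puncta = _generate_geometry(rng, profile, imaging)
    return FieldGroundTruth(
        neurons=neurons, puncta=puncta, imaging=imaging, seed=seed,
        profile=profile,
    )


def _generate_geometry(
    rng: np.random.Generator,
    profile: CultureProfile,
    imaging: ImagingParams,
) -> tuple[list[NeuronTruth], list[PunctumTruth]]:
    shape = imaging.shape
    px = imaging.pixel_size_um

    somata = _place_somata(
        rng,
        int(round(profile.neurons_per_field)),
        shape,
        profile.soma_radius_um[0] / px,
        profile.soma_radius_um[1] / px,
    )

    neurons: list[NeuronTruth] = []
    for i, (center, r_px) in enumerate(somata):
        # nucleus sits near the soma centre
        off = rng.normal(0.0, 0.15 * r_px, size=2)
        nucleus = center + off
        k = int(rng.integers(profile.dendrites_per_neuron[0],
                             profile.dendrites_per_neuron[1] + 1))
        total_target_px = (
            profile.dendrite_length_um / px * rng.lognormal(0.0, 0.15)
        )
        fractions = rng.dirichlet(np.full(max(k, 1), 3.0)) if k else []
        base_angle = rng.uniform(0, 2 * math.pi)
        polylines: list[np.ndarray] = []
        for d in range(k):
            theta = base_angle + 2 * math.pi * d / k + rng.normal(0.0, 0.25)
            start = center + r_px * np.array([math.sin(theta), math.cos(theta)])
            poly = _grow_dendrite(
                rng, start, theta, total_target_px * fractions[d], shape,
                somata, own_index=i,
            )
            if len(poly) >= 2:
                polylines.append(poly)
        true_len_um = sum(polyline_length_px(p) for p in polylines) * px
        neurons.append(
            NeuronTruth(
                neuron_id=i,
                soma_center=(float(center[0]), float(center[1])),
                soma_radius_px=r_px,
                nucleus_center=(float(nucleus[0]), float(nucleus[1])),
                polylines=polylines,
                dendrite_length_um=float(true_len_um),
            )
        )

    puncta: list[PunctumTruth] = []
    min_spacing_px = DENDRITE_PUNCTA_MIN_SPACING_UM / px
    for neuron in neurons:
        for channel, dens, soma_count in (
            ("vglut1", profile.vglut_density_per_um, profile.vglut_soma_count),
            ("vgat", profile.vgat_density_per_um, profile.vgat_soma_count),
        ):
            # dendritic puncta: along each polyline, hard-core spaced
            for poly in neuron.polylines:
                length_px = polyline_length_px(poly)
                lo = DENDRITE_PUNCTA_SOMA_CLEARANCE_PX
                hi = length_px - 2.0
                if hi <= lo:
                    continue
                expected = dens * (hi - lo) * px
                n_target = rng.poisson(expected)
                for s in _sample_arclengths_hardcore(
                    rng, n_target, lo, hi, min_spacing_px
                ):
                    pt, tangent = _point_on_polyline(poly, s)
                    normal = np.array([-tangent[1], tangent[0]])
                    jitter = float(np.clip(rng.normal(0.0, 0.5), -1.5, 1.5))
                    cpt = pt + jitter * normal
                    puncta.append(
                        PunctumTruth(
                            center=(float(cpt[0]), float(cpt[1])),
                            channel=channel,
                            compartment="dendrite",
                            neuron_id=neuron.neuron_id,
                        )
                    )
            # cell-body puncta: inside the soma disk, hard-core spaced
            n_soma = rng.poisson(soma_count)
            for pt in _sample_disk_hardcore(
                rng,
                n_soma,
                np.asarray(neuron.soma_center),
                max(neuron.soma_radius_px - 2.0, 1.0),
                SOMA_PUNCTA_MIN_SPACING_PX,
            ):
                puncta.append(
                    PunctumTruth(
                        center=(float(pt[0]), float(pt[1])),
                        channel=channel,
                        compartment="cell_body",
                        neuron_id=neuron.neuron_id,
                    )
                )

    # background distractors: compact puncta far from every neuron
    n_bg = rng.poisson(profile.axonal_background_rate)
    clearance = imaging.contact_tolerance_px + 4.0
    bg_placed = 0
    tries = 0
    while bg_placed < n_bg and tries < 200 * max(n_bg, 1):
        tries += 1
        pt = np.array(
            [rng.uniform(4, shape[0] - 5), rng.uniform(4, shape[1] - 5)]
        )
        near = False
        for neuron in neurons:
            if (
                np.linalg.norm(pt - np.asarray(neuron.soma_center))
                < neuron.soma_radius_px + clearance
            ):
                near = True
                break
            for poly in neuron.polylines:
                if min_dist_to_polyline(pt, poly) < clearance:
                    near = True
                    break
            if near:
                break
        if not near:
            channel = "vglut1" if rng.uniform() < 0.5 else "vgat"
            puncta.append(
                PunctumTruth(
                    center=(float(pt[0]), float(pt[1])),
                    channel=channel,
                    compartment="background",
                    neuron_id=-1,
                )
            )
            bg_placed += 1

    return neurons, puncta


def _render(
    rng: np.random.Generator,
    neurons: list[NeuronTruth],
    puncta: list[PunctumTruth],
    profile: CultureProfile,
    imaging: ImagingParams,
) -> FieldImageSet:
    shape = imaging.shape
    px = imaging.pixel_size_um

    nuclei_plane = np.zeros(shape, dtype=float)
    nucleus_sigma = profile.nucleus_radius_um / px / 2.0
    for n in neurons:
        _add_gaussian_spot(
            nuclei_plane, n.nucleus_center, nucleus_sigma, imaging.nucleus_intensity
        )

    soma_bin = np.zeros(shape, dtype=float)
    dend_bin = np.zeros(shape, dtype=float)
    for n in neurons:
        rr, cc = draw_disk(n.soma_center, n.soma_radius_px, shape=shape)
        soma_bin[rr, cc] = 1.0
        for poly in n.polylines:
            _draw_polyline(dend_bin, poly)
    map2_plane = imaging.soma_intensity * gaussian_filter(
        soma_bin, 1.0
    ) + imaging.dendrite_intensity * gaussian_filter(dend_bin, 0.8)

    vglut_plane = np.zeros(shape, dtype=float)
    vgat_plane = np.zeros(shape, dtype=float)
    for p in puncta:
        target = vglut_plane if p.channel == "vglut1" else vgat_plane
        _add_gaussian_spot(target, p.center, imaging.psf_sigma_px, imaging.punctum_peak)

    # MAP2-negative axon-like streaks: continuous low-intensity labelling in
    # the vGLUT1 plane only (no ground-truth puncta on them)
    n_streaks = rng.poisson(profile.axon_streaks_per_field)
    if n_streaks:
        streak_bin = np.zeros(shape, dtype=float)
        for _ in range(n_streaks):
            start = np.array(
                [rng.uniform(5, shape[0] - 6), rng.uniform(5, shape[1] - 6)]
            )
            theta = rng.uniform(0, 2 * math.pi)
            length = rng.uniform(100, 250)
            poly = [start.copy()]
            pos = start.copy()
            grown = 0.0
            while grown < length:
                theta += rng.normal(0.0, 0.25)
                nxt = pos + 3.0 * np.array([math.sin(theta), math.cos(theta)])
                if not (
                    2 <= nxt[0] <= shape[0] - 3 and 2 <= nxt[1] <= shape[1] - 3
                ):
                    break
                poly.append(nxt)
                pos = nxt
                grown += 3.0
            if len(poly) >= 2:
                _draw_polyline(streak_bin, np.asarray(poly))
        streak = gaussian_filter(streak_bin, 1.5)
        if streak.max() > 0:
            vglut_plane += imaging.streak_peak * streak / streak.max()

    planes = []
    for plane in (nuclei_plane, map2_plane, vglut_plane, vgat_plane):
        noisy = plane + imaging.background_offset
        if imaging.noise_sd > 0:
            noisy = noisy + rng.normal(0.0, imaging.noise_sd, size=shape)
        planes.append(np.clip(noisy, 0.0, None).astype(np.float32))

    return FieldImageSet(
        nuclei_plane=planes[0],
        map2_plane=planes[1],
        vglut1_plane=planes[2],
        vgat_plane=planes[3],
        pixel_size_um=px,
    )


# ---------------------------------------------------------------------------
# study designs


def field_seed(master_seed: int, index: int) -> int:
    """Deterministic per-field seed derived from a master seed."""
    return int(np.random.SeedSequence([master_seed, index]).generate_state(1)[0]
               & 0x7FFFFFFF)


def design_table(
    cell_types: Sequence[str],
    divs: Sequence[int],
    wells_per_condition: int,
    fields_per_well: int = 12,
    master_seed: int = 0,
) -> pd.DataFrame:
    """Enumerate every (condition, well, field) of an ontogeny design.

    Twelve fields of view per well is the imaging default.  Row count is
    ``len(cell_types) * len(divs) * wells_per_condition * fields_per_well``.
    """
    if not cell_types or not divs:
        raise ValueError("design must name at least one cell type and one DIV")
    if wells_per_condition < 1:
        raise ValueError("wells_per_condition must be >= 1")
    for ct in cell_types:
        preset_profile(ct, divs[0])  # raises on unknown cell type
    rows = []
    idx = 0
    for ct in cell_types:
        for div in divs:
            for w in range(wells_per_condition):
                well_id = f"{ct[:4]}_div{div:02d}_w{w:02d}"
                for f in range(fields_per_well):
                    rows.append(
                        {
                            "cell_type": ct,
                            "div": div,
                            "well_id": well_id,
                            "field_id": f"{well_id}_f{f:02d}",
                            "seed": field_seed(master_seed, idx),
                        }
                    )
                    idx += 1
    return pd.DataFrame(rows)


def generate_ontogeny_dataset(
    cell_types: Sequence[str],
    divs: Sequence[int],
    wells_per_condition: int,
    fields_per_well: int = 12,
    seed: int = 0,
    imaging: ImagingParams | None = None,
    profile_overrides: dict | None = None,
    render: bool = True,
) -> Iterator[tuple[pd.Series, FieldImageSet | None, FieldGroundTruth]]:
    """Lazily generate every field of an ontogeny design.

    Yields ``(design_row, images, ground_truth)`` in design-table order.  With
    ``render=False`` only the geometry/ground truth is produced (images are
    ``None``), which is much faster and sufficient for design-level checks.

    ``profile_overrides`` maps ``(cell_type, div)`` to a replacement
    :class:`CultureProfile`.
    """
    table = design_table(
        cell_types, divs, wells_per_condition, fields_per_well, seed
    )
    overrides = profile_overrides or {}
    for _, row in table.iterrows():
        key = (row["cell_type"], row["div"])
        profile = overrides.get(key) or preset_profile(*key)
        if render:
            images, truth = generate_field(profile, imaging, int(row["seed"]))
        else:
            images, truth = None, generate_field_geometry(
                profile, imaging, int(row["seed"])
            )
        yield row, images, truth
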