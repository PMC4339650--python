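"""High-content image analysis of excitatory vs inhibitory synaptic puncta.

Pipeline for one four-channel field of view:

1. :func:`detect_nuclei` — intensity-thresholded connected components in the
   nuclei plane, filtered by area.
2. :func:`mask_cell_bodies` — MAP2-positive cell bodies around detected
   nuclei (morphological opening removes thin processes; merged bodies are
   split by nearest-nucleus partition; a small dilation restores the mask to
   the stained outline).
3. :func:`trace_dendrites` — skeletonised MAP2-positive processes connected
   to a selected soma; length from 8-connected steps (1 per orthogonal step,
   sqrt(2) per diagonal, times the pixel size).  MAP2-negative axons never
   enter this plane and are therefore never traced.
4. :func:`detect_puncta` — background-subtracted (white top-hat) spot
   detection with intensity, area and compactness criteria; continuous
   low-intensity axon streaks fail the compactness/area criteria.
5. :func:`assign_puncta` — sequential compartment rule: a punctum contained
   in a cell-body mask belongs to that neuron's cell body; otherwise, if its
   centroid lies within the contact tolerance of a traced dendrite skeleton
   it belongs to that neuron's dendrite compartment; otherwise it is excluded
   from every endpoint.
6. :func:`compute_field_endpoints` — the eight per-field endpoints plus the
   three log10 excitatory/inhibitory ratios.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial import cKDTree
from skimage.measure import label as cc_label, regionprops
from skimage.morphology import disk, opening, skeletonize, white_tophat
from skimage.segmentation import expand_labels

logger = logging.getLogger(__name__)

MISSING = float("nan")

SQRT2 = math.sqrt(2.0)


# ---------------------------------------------------------------------------
# containers


@dataclass
class FieldImageSet:
    """Four aligned single-channel intensity planes of one field of view."""

    nuclei_plane: np.ndarray
    map2_plane: np.ndarray
    vglut1_plane: np.ndarray
    vgat_plane: np.ndarray
    pixel_size_um: float = 0.5

    def __post_init__(self) -> None:
        shapes = {
            self.nuclei_plane.shape,
            self.map2_plane.shape,
            self.vglut1_plane.shape,
            self.vgat_plane.shape,
        }
        if len(shapes) != 1:
            raise ValueError("all four planes must share one shape")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.nuclei_plane.shape

    def plane(self, channel: str) -> np.ndarray:
        return {
            "nuclei": self.nuclei_plane,
            "map2": self.map2_plane,
            "vglut1": self.vglut1_plane,
            "vgat": self.vgat_plane,
        }[channel]


@dataclass
class NucleusCandidate:
    centroid: tuple[float, float]  # (row, col)
    area_px: int


@dataclass
class NeuronObject:
    """One selected neuron: soma mask, later a dendrite skeleton + length."""

    neuron_id: int
    nucleus_centroid: tuple[float, float]
    soma_mask: np.ndarray  # boolean, full field shape (dilated outline)
    soma_core: np.ndarray | None = None  # pre-dilation body, used for tracing
    dendrite_skeleton: np.ndarray = dc_field(
        default_factory=lambda: np.empty((0, 2), dtype=int)
    )  # (N, 2) pixel coords
    dendrite_length_um: float = 0.0
    touches_border: bool = False


@dataclass
class Punctum:
    centroid: tuple[float, float]
    area_px: int
    peak_intensity: float
    channel: str  # 'vglut1' | 'vgat'
    compartment: str = "unassigned"  # 'cell_body' | 'dendrite' | 'excluded'
    neuron_id: int | None = None


@dataclass
class FieldEndpoints:
    """The eight per-field endpoints and three log10 E/I ratios.

    ``float('nan')`` marks a missing (undefined) value, e.g. per-um densities
    when no dendrite was traced, or ratios with a zero count.
    """

    neurons_per_field: int
    dendrite_length_per_neuron_um: float
    vglut_per_cell_body: float
    vgat_per_cell_body: float
    vglut_per_um_dendrite: float
    vgat_per_um_dendrite: float
    vglut_total_per_neuron: float
    vgat_total_per_neuron: float
    ei_ratio_cell_body: float
    ei_ratio_dendrite: float
    ei_ratio_total: float

    def as_dict(self) -> dict[str, float]:
        return {
            "neurons_per_field": self.neurons_per_field,
            "dendrite_length_per_neuron_um": self.dendrite_length_per_neuron_um,
            "vglut_per_cell_body": self.vglut_per_cell_body,
            "vgat_per_cell_body": self.vgat_per_cell_body,
            "vglut_per_um_dendrite": self.vglut_per_um_dendrite,
            "vgat_per_um_dendrite": self.vgat_per_um_dendrite,
            "vglut_total_per_neuron": self.vglut_total_per_neuron,
            "vgat_total_per_neuron": self.vgat_total_per_neuron,
            "ei_ratio_cell_body": self.ei_ratio_cell_body,
            "ei_ratio_dendrite": self.ei_ratio_dendrite,
            "ei_ratio_total": self.ei_ratio_total,
        }


@dataclass(frozen=True)
class HCIParams:
    """Tunable thresholds of the image-analysis algorithm.

    Detection thresholds are expressed in robust noise units: a plane's
    background level and spread are estimated by the median and the
    normalised median absolute deviation, and a feature must exceed
    ``background + nsigma * spread``.  Area filters are in pixels at the
    default 0.5 um/px; the contact tolerance of 2 px corresponds to 1 um.
    """

    nucleus_nsigma: float = 6.0
    nucleus_min_area_px: int = 30
    nucleus_max_area_px: int = 300
    map2_nsigma: float = 5.0
    soma_opening_radius_px: int = 4
    soma_min_area_px: int = 60
    soma_dilation_px: int = 5
    puncta_nsigma: float = 5.0
    puncta_smooth_sigma_px: float = 1.0
    puncta_log_sigma_px: float = 1.4  # LoG scale used to split touching spots
    puncta_log_nsigma: float = 7.0  # blob-strength floor for chains of spots
    puncta_min_curvature_ratio: float = 0.3  # Hessian isotropy floor (blob vs ridge)
    puncta_min_area_px: int = 2
    puncta_max_area_px: int = 60
    puncta_max_eccentricity: float = 0.98
    tophat_radius_px: int = 4
    peak_min_distance_px: int = 2
    contact_tolerance_px: float = 2.0


DEFAULT_PARAMS = HCIParams()


# ---------------------------------------------------------------------------
# shared helpers


def robust_threshold(plane: np.ndarray, nsigma: float) -> float:
    """Background + nsigma * robust spread (median / scaled MAD)."""
    bg = float(np.median(plane))
    mad = float(np.median(np.abs(plane - bg))) * 1.4826
    return bg + nsigma * mad


def _check_plane(plane: np.ndarray) -> None:
    if plane.ndim != 2:
        raise ValueError("plane must be 2-D")
    if not np.all(np.isfinite(plane)):
        raise ValueError("plane must be finite")
    if plane.size and plane.min() < 0:
        raise ValueError("plane must be nonnegative")


# ---------------------------------------------------------------------------
# 1. nuclei


def detect_nuclei(
    nuclei_plane: np.ndarray, params: HCIParams = DEFAULT_PARAMS
) -> list[NucleusCandidate]:
    """Detect nucleus candidates as thresholded components with area filters.

    An all-zero (or featureless) plane yields an empty list, not an error.
    """
    _check_plane(nuclei_plane)
    thr = robust_threshold(nuclei_plane, params.nucleus_nsigma)
    mask = nuclei_plane > thr
    labels = cc_label(mask, connectivity=2)
    out = []
    for region in regionprops(labels):
        if params.nucleus_min_area_px <= region.area <= params.nucleus_max_area_px:
            out.append(
                NucleusCandidate(
                    centroid=(float(region.centroid[0]), float(region.centroid[1])),
                    area_px=int(region.area),
                )
            )
    return out


# ---------------------------------------------------------------------------
# 2. cell bodies


def _map2_mask(map2_plane: np.ndarray, params: HCIParams) -> np.ndarray:
    thr = robust_threshold(map2_plane, params.map2_nsigma)
    return map2_plane > thr


def mask_cell_bodies(
    map2_plane: np.ndarray,
    nuclei: list[NucleusCandidate],
    params: HCIParams = DEFAULT_PARAMS,
) -> list[NeuronObject]:
    """Mask the MAP2-positive cell body around each nucleus.

    Thin processes are removed by a morphological opening; the surviving
    body blobs are matched to nuclei.  A nucleus with no surrounding MAP2
    signal (a non-neuronal cell) produces no neuron.  Bodies containing
    several nuclei are split by nearest-nucleus partition (logged).  The
    final mask is dilated by ``soma_dilation_px`` to recover the outline
    eroded by the opening, with overlaps again resolved by proximity.
    """
    _check_plane(map2_plane)
    if not nuclei:
        return []
    mask = _map2_mask(map2_plane, params)
    body = opening(mask, disk(params.soma_opening_radius_px))
    body_labels = cc_label(body, connectivity=2)

    centroids = np.array([n.centroid for n in nuclei])
    rows = np.clip(np.round(centroids[:, 0]).astype(int), 0, map2_plane.shape[0] - 1)
    cols = np.clip(np.round(centroids[:, 1]).astype(int), 0, map2_plane.shape[1] - 1)
    blob_of_nucleus = body_labels[rows, cols]

    # nearest-nucleus partition: seed labels at nuclei that landed in a body
    seeds = np.zeros_like(body_labels)
    selected: list[int] = []
    for i, blob in enumerate(blob_of_nucleus):
        if blob > 0:
            seeds[rows[i], cols[i]] = len(selected) + 1
            selected.append(i)
    if not selected:
        return []
    counts = np.bincount(blob_of_nucleus[blob_of_nucleus > 0])
    if np.any(counts > 1):
        logger.warning(
            "cell-body mask contained multiple nuclei; split by nearest nucleus"
        )
    # grow nucleus seeds without bound, then clip to the body mask
    core_partition = expand_labels(seeds, distance=max(map2_plane.shape))
    core_partition[~body] = 0
    # restore the opened-away outline
    partition = expand_labels(core_partition, distance=params.soma_dilation_px)
    partition[~mask] = 0

    neurons: list[NeuronObject] = []
    h, w = map2_plane.shape
    for k, i in enumerate(selected, start=1):
        soma = partition == k
        core = core_partition == k
        if soma.sum() < params.soma_min_area_px:
            continue
        rr, cc = np.nonzero(soma)
        touches = bool(
            rr.min() == 0 or cc.min() == 0 or rr.max() == h - 1 or cc.max() == w - 1
        )
        neurons.append(
            NeuronObject(
                neuron_id=len(neurons),
                nucleus_centroid=nuclei[i].centroid,
                soma_mask=soma,
                soma_core=core,
                touches_border=touches,
            )
        )
    return neurons


# ---------------------------------------------------------------------------
# 3. dendrites


def skeleton_length_um(coords: np.ndarray, pixel_size_um: float) -> float:
    """Length of an 8-connected skeleton pixel set.

    Builds the pixel-adjacency graph (weight 1 for orthogonal, sqrt(2) for
    diagonal neighbours) and sums its minimum spanning forest, which counts
    each step once and drops redundant corner edges.
    """
    coords = np.asarray(coords)
    n = len(coords)
    if n < 2:
        return 0.0
    index = {(int(r), int(c)): i for i, (r, c) in enumerate(coords)}
    src, dst, wts = [], [], []
    for i, (r, c) in enumerate(coords):
        r, c = int(r), int(c)
        for dr, dc, w in ((0, 1, 1.0), (1, 0, 1.0), (1, 1, SQRT2), (1, -1, SQRT2)):
            j = index.get((r + dr, c + dc))
            if j is not None:
                src.append(i)
                dst.append(j)
                wts.append(w)
    if not src:
        return 0.0
    graph = coo_matrix((wts, (src, dst)), shape=(n, n))
    mst = minimum_spanning_tree(graph)
    return float(mst.sum()) * pixel_size_um


def trace_dendrites(
    map2_plane: np.ndarray,
    neurons: list[NeuronObject],
    params: HCIParams = DEFAULT_PARAMS,
    pixel_size_um: float = 0.5,
) -> list[NeuronObject]:
    """Skeletonise MAP2-positive processes and attach them to somata.

    The MAP2 mask is thinned to a one-pixel skeleton; pixels inside any soma
    mask are discarded, and each remaining skeleton component is kept only
    if it approaches a soma (within 3 px), assigned to the nearest one.
    Components connected to no selected soma are ignored.  Neurons are
    modified in place (skeleton pixel set and length) and returned.
    """
    _check_plane(map2_plane)
    if not neurons:
        return neurons
    mask = _map2_mask(map2_plane, params)
    skel = skeletonize(mask)
    soma_labels = np.zeros(map2_plane.shape, dtype=np.int32)
    for n in neurons:
        core = n.soma_core if n.soma_core is not None else n.soma_mask
        soma_labels[core] = n.neuron_id + 1
    skel = skel & (soma_labels == 0)
    near_soma = expand_labels(soma_labels, distance=3)

    comp = cc_label(skel, connectivity=2)
    skeleton_pixels: dict[int, list[np.ndarray]] = {n.neuron_id: [] for n in neurons}
    for region in regionprops(comp):
        coords = region.coords
        owner_labels = near_soma[coords[:, 0], coords[:, 1]]
        owner_labels = owner_labels[owner_labels > 0]
        if owner_labels.size == 0:
            continue  # not connected to any selected soma (axon-analogue)
        counts = np.bincount(owner_labels)
        owner = int(np.argmax(counts)) - 1
        skeleton_pixels[owner].append(coords)
    for n in neurons:
        if skeleton_pixels[n.neuron_id]:
            coords = np.vstack(skeleton_pixels[n.neuron_id])
        else:
            coords = np.empty((0, 2), dtype=int)
        n.dendrite_skeleton = coords
        n.dendrite_length_um = skeleton_length_um(coords, pixel_size_um)
    return neurons


# ---------------------------------------------------------------------------
# 4. puncta detection


def detect_puncta(
    channel_plane: np.ndarray,
    channel: str,
    params: HCIParams = DEFAULT_PARAMS,
) -> list[Punctum]:
    """Detect compact fluorescent spots in one synaptic-marker plane.

    The plane is background-subtracted with a white top-hat, thresholded in
    robust noise units, and segmented into components.  Components outside
    the [min, max] area window or too elongated (eccentricity above the
    compactness criterion) are rejected — this removes the continuous
    low-intensity labelling along MAP2-negative axons.  Touching spot pairs
    are split at their local intensity maxima.
    """
    from scipy.ndimage import gaussian_filter, gaussian_laplace
    from skimage.feature import hessian_matrix, hessian_matrix_eigvals, peak_local_max

    _check_plane(channel_plane)
    plane = channel_plane.astype(float)
    tophat = white_tophat(plane, disk(params.tophat_radius_px))
    flat = tophat
    if params.puncta_smooth_sigma_px > 0:
        # matched-filter smoothing: boosts spot-to-noise before thresholding
        flat = gaussian_filter(tophat, params.puncta_smooth_sigma_px)
    # blob-scale response: sharper maxima than raw intensity, used to split
    # touching spots into individual puncta and to tell chains of bright
    # blobs apart from continuous ridge-like (axonal) labelling
    log_resp = -gaussian_laplace(tophat, params.puncta_log_sigma_px)
    log_med = float(np.median(log_resp))
    log_mad = float(np.median(np.abs(log_resp - log_med))) * 1.4826
    log_thr = log_med + params.puncta_log_nsigma * log_mad
    # principal curvature ratio at punctum scale: ~1 for isotropic blobs,
    # ~0 for ridge-like (axonal) structures
    hess = hessian_matrix(tophat, sigma=params.puncta_log_sigma_px, order="rc",
                          use_gaussian_derivatives=False)
    ev_hi, ev_lo = hessian_matrix_eigvals(hess)  # ev_lo is most negative

    def _curvature_ratio(r: int, c: int) -> float:
        l1, l2 = ev_lo[r, c], ev_hi[r, c]
        if l1 >= 0 or l2 >= 0:
            return 0.0
        return float(l2 / l1)
    # threshold in units of the residual noise spread of the flattened plane
    mad = float(np.median(np.abs(flat - np.median(flat)))) * 1.4826
    if mad == 0:
        return []
    thr = float(np.median(flat)) + params.puncta_nsigma * mad
    mask = flat > thr
    labels = cc_label(mask, connectivity=2)
    out: list[Punctum] = []
    for region in regionprops(labels, intensity_image=flat):
        if region.area < params.puncta_min_area_px:
            continue
        sub = region.image_intensity * region.image
        r0, c0, r1, c1 = region.bbox
        sub_log = log_resp[r0:r1, c0:c1] * region.image
        peaks = peak_local_max(
            sub_log,
            min_distance=params.peak_min_distance_px,
            threshold_abs=0.25 * float(sub_log.max()),
            exclude_border=False,
        )
        if (
            region.area > 12
            and region.eccentricity > params.puncta_max_eccentricity
        ):
            # elongated: a continuous low-intensity (axonal) streak unless it
            # resolves into a chain of at least two strong, isotropic
            # blob-scale peaks
            strong = [
                p for p in peaks
                if sub_log[p[0], p[1]] >= log_thr
                and _curvature_ratio(r0 + p[0], c0 + p[1])
                >= params.puncta_min_curvature_ratio
            ]
            if len(strong) < 2:
                continue
            peaks = np.asarray(strong)
        if region.area > params.puncta_max_area_px:
            # oversized: either a clump of touching spots (split at peaks)
            # or diffuse non-punctate labelling (rejected)
            if len(peaks) < 2 or region.area / len(peaks) > params.puncta_max_area_px:
                continue
        if len(peaks) <= 1:
            out.append(
                Punctum(
                    centroid=(
                        float(region.centroid_weighted[0]),
                        float(region.centroid_weighted[1]),
                    ),
                    area_px=int(region.area),
                    peak_intensity=float(region.image_intensity.max()),
                    channel=channel,
                )
            )
        else:
            share = int(region.area // len(peaks))
            for pr, pc in peaks:
                out.append(
                    Punctum(
                        centroid=(float(r0 + pr), float(c0 + pc)),
                        area_px=share,
                        peak_intensity=float(sub[pr, pc]),
                        channel=channel,
                    )
                )
    return out


# ---------------------------------------------------------------------------
# 5. compartment assignment


def assign_puncta(
    puncta: list[Punctum],
    neurons: list[NeuronObject],
    contact_tolerance_px: float = DEFAULT_PARAMS.contact_tolerance_px,
) -> list[Punctum]:
    """Assign each punctum to a compartment by the sequential contact rule.

    Cell-body containment is checked first; otherwise the punctum is a
    dendritic synapse of the neuron whose skeleton lies within the contact
    tolerance (nearest skeleton wins; exact ties go to the lowest neuron
    id); otherwise it is excluded.  Puncta are modified in place.
    """
    if contact_tolerance_px < 0:
        raise ValueError("contact tolerance must be >= 0")
    if not neurons:
        for p in puncta:
            p.compartment = "excluded"
            p.neuron_id = None
        return puncta

    shape = neurons[0].soma_mask.shape
    soma_labels = np.zeros(shape, dtype=np.int32)
    for n in neurons:
        soma_labels[n.soma_mask] = n.neuron_id + 1

    skel_coords = [n.dendrite_skeleton for n in neurons]
    all_coords = (
        np.vstack([c for c in skel_coords if len(c)])
        if any(len(c) for c in skel_coords)
        else np.empty((0, 2))
    )
    owner = np.concatenate(
        [np.full(len(c), n.neuron_id) for n, c in zip(neurons, skel_coords) if len(c)]
    ) if len(all_coords) else np.empty(0, dtype=int)
    tree = cKDTree(all_coords) if len(all_coords) else None

    for p in puncta:
        r = int(round(p.centroid[0]))
        c = int(round(p.centroid[1]))
        r = min(max(r, 0), shape[0] - 1)
        c = min(max(c, 0), shape[1] - 1)
        lab = soma_labels[r, c]
        if lab > 0:
            p.compartment = "cell_body"
            p.neuron_id = int(lab - 1)
            continue
        if tree is not None:
            k = min(8, len(all_coords))
            dist, idx = tree.query(np.asarray(p.centroid, dtype=float), k=k)
            dist = np.atleast_1d(dist)
            idx = np.atleast_1d(idx)
            within = dist <= contact_tolerance_px + 1e-9
            if within.any():
                dmin = dist[within].min()
                candidates = idx[within][dist[within] <= dmin + 1e-9]
                p.compartment = "dendrite"
                p.neuron_id = int(owner[candidates].min())
                continue
        p.compartment = "excluded"
        p.neuron_id = None
    return puncta


# ---------------------------------------------------------------------------
# 6. endpoints


def ei_ratio(vglut_count: float, vgat_count: float) -> float:
    """log10(excitatory / inhibitory) puncta; NaN if either count is zero."""
    if vglut_count < 0 or vgat_count < 0:
        raise ValueError("puncta counts must be >= 0")
    if vglut_count == 0 or vgat_count == 0:
        return MISSING
    return float(math.log10(vglut_count / vgat_count))


def compute_field_endpoints(
    neurons: list[NeuronObject], puncta: list[Punctum]
) -> FieldEndpoints:
    """Per-field endpoints from assigned puncta and traced neurons.

    Per-neuron endpoints are field totals divided by the neuron count;
    per-um endpoints divide dendritic counts by the total traced dendrite
    length.  A field with zero neurons, or zero traced length, yields NaN
    for the affected endpoints rather than a division by zero.
    """
    n_neurons = len(neurons)
    counts = {("vglut1", "cell_body"): 0, ("vglut1", "dendrite"): 0,
              ("vgat", "cell_body"): 0, ("vgat", "dendrite"): 0}
    for p in puncta:
        if p.compartment in ("cell_body", "dendrite"):
            counts[(p.channel, p.compartment)] += 1
    total_len = sum(n.dendrite_length_um for n in neurons)
    vglut_cb = counts[("vglut1", "cell_body")]
    vglut_dn = counts[("vglut1", "dendrite")]
    vgat_cb = counts[("vgat", "cell_body")]
    vgat_dn = counts[("vgat", "dendrite")]

    if n_neurons == 0:
        logger.info("field with zero neurons: endpoints flagged missing")
        per = lambda x: MISSING  # noqa: E731
    else:
        per = lambda x: x / n_neurons  # noqa: E731
    if total_len > 0:
        per_um = lambda x: x / total_len  # noqa: E731
    else:
        per_um = lambda x: MISSING  # noqa: E731

    return FieldEndpoints(
        neurons_per_field=n_neurons,
        dendrite_length_per_neuron_um=per(total_len),
        vglut_per_cell_body=per(vglut_cb),
        vgat_per_cell_body=per(vgat_cb),
        vglut_per_um_dendrite=per_um(vglut_dn),
        vgat_per_um_dendrite=per_um(vgat_dn),
        vglut_total_per_neuron=per(vglut_cb + vglut_dn),
        vgat_total_per_neuron=per(vgat_cb + vgat_dn),
        ei_ratio_cell_body=ei_ratio(vglut_cb, vgat_cb),
        ei_ratio_dendrite=ei_ratio(vglut_dn, vgat_dn),
        ei_ratio_total=ei_ratio(vglut_cb + vglut_dn, vgat_cb + vgat_dn),
    )


# ---------------------------------------------------------------------------
# convenience: whole-field analysis


def analyze_field(
    images: FieldImageSet, params: HCIParams = DEFAULT_PARAMS
) -> tuple[list[NeuronObject], list[Punctum], FieldEndpoints]:
    """Run the full per-field pipeline and return neurons, puncta, endpoints."""
    nuclei = detect_nuclei(images.nuclei_plane, params)
    neurons = mask_cell_bodies(images.map2_plane, nuclei, params)
    trace_dendrites(images.map2_plane, neurons, params, images.pixel_size_um)
    puncta = detect_puncta(images.vglut1_plane, "vglut1", params)
    puncta += detect_puncta(images.vgat_plane, "vgat", params)
    assign_puncta(puncta, neurons, params.contact_tolerance_px)
    endpoints = compute_field_endpoints(neurons, puncta)
    return neurons, puncta, endpoints
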