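"""Image analysis: nuclei, cell bodies, tracing, puncta, assignment, endpoints."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import oracle_compartment
from synaptoscope.hci import (
    NeuronObject,
    Punctum,
    analyze_field,
    assign_puncta,
    compute_field_endpoints,
    detect_nuclei,
    detect_puncta,
    ei_ratio,
    mask_cell_bodies,
    skeleton_length_um,
    trace_dendrites,
)
from synaptoscope.synthetic import ImagingParams, generate_field, preset_profile

rng0 = np.random.default_rng(0)


def _noise_plane(shape, rng, sd=20.0, offset=100.0):
    return np.clip(offset + rng.normal(0, sd, shape), 0, None)


def _add_spot(plane, r, c, sigma, peak):
    rr, cc = np.meshgrid(np.arange(plane.shape[0]), np.arange(plane.shape[1]),
                         indexing="ij")
    plane += peak * np.exp(-((rr - r) ** 2 + (cc - c) ** 2) / (2 * sigma**2))


# ---------------------------------------------------------------------------
# nuclei


def test_blank_plane_yields_no_nuclei():
    assert detect_nuclei(np.zeros((64, 64))) == []


def test_seven_separated_blobs_recovered_within_2px():
    rng = np.random.default_rng(1)
    plane = _noise_plane((200, 200), rng)
    centers = [(30, 30), (30, 100), (30, 170), (100, 30), (100, 170),
               (170, 60), (170, 140)]
    for r, c in centers:
        _add_spot(plane, r, c, 3.0, 3000.0)
    found = detect_nuclei(plane)
    assert len(found) == 7
    for r, c in centers:
        d = min(math.hypot(n.centroid[0] - r, n.centroid[1] - c) for n in found)
        assert d <= 2.0


def test_blob_below_min_area_excluded():
    rng = np.random.default_rng(2)
    plane = _noise_plane((100, 100), rng)
    _add_spot(plane, 50, 50, 0.8, 3000.0)  # tiny blob, above-threshold area < 30
    assert detect_nuclei(plane) == []


# ---------------------------------------------------------------------------
# cell bodies


def test_nucleus_without_map2_produces_no_neuron():
    rng = np.random.default_rng(3)
    map2 = _noise_plane((100, 100), rng)
    nuclei_plane = _noise_plane((100, 100), rng)
    _add_spot(nuclei_plane, 50, 50, 3.0, 3000.0)
    nuclei = detect_nuclei(nuclei_plane)
    assert len(nuclei) == 1
    assert mask_cell_bodies(map2, nuclei) == []


def test_empty_nucleus_list_gives_empty_neurons():
    assert mask_cell_bodies(np.zeros((64, 64)), []) == []


def test_soma_count_matches_ground_truth(hippocampal_div21_field):
    images, truth = hippocampal_div21_field
    nuclei = detect_nuclei(images.nuclei_plane)
    neurons = mask_cell_bodies(images.map2_plane, nuclei)
    assert len(neurons) == len(truth.neurons)
    # each detected soma contains exactly one true soma centre
    for n in neurons:
        hits = sum(
            n.soma_mask[int(round(t.soma_center[0])), int(round(t.soma_center[1]))]
            for t in truth.neurons
        )
        assert hits == 1


# ---------------------------------------------------------------------------
# dendrite length conventions


def test_straight_horizontal_process_length():
    coords = np.array([(10, c) for c in range(5, 105)])
    assert skeleton_length_um(coords, 0.5) == pytest.approx(49.5)


def test_diagonal_process_length():
    coords = np.array([(5 + i, 5 + i) for i in range(100)])
    assert skeleton_length_um(coords, 0.5) == pytest.approx(49.5 * math.sqrt(2))


def test_traced_tree_length_close_to_polyline_truth(hippocampal_div21_field):
    images, truth = hippocampal_div21_field
    nuclei = detect_nuclei(images.nuclei_plane)
    neurons = mask_cell_bodies(images.map2_plane, nuclei)
    trace_dendrites(images.map2_plane, neurons, pixel_size_um=images.pixel_size_um)
    traced = sum(n.dendrite_length_um for n in neurons)
    true = truth.total_dendrite_length_um()
    assert abs(traced - true) / true < 0.10


# ---------------------------------------------------------------------------
# puncta detection


def test_blank_plane_yields_no_puncta():
    assert detect_puncta(np.zeros((64, 64)), "vglut1") == []


def test_fifty_separated_spots_recovered_without_false_positives():
    rng = np.random.default_rng(4)
    sd = 20.0
    plane = _noise_plane((300, 300), rng, sd=sd)
    centers = [(20 + 40 * (k // 7), 20 + 40 * (k % 7)) for k in range(50)]
    for r, c in centers:
        _add_spot(plane, r, c, 1.5, 5 * sd)
    found = detect_puncta(plane, "vglut1")
    matched = 0
    for p in found:
        d = min(math.hypot(p.centroid[0] - r, p.centroid[1] - c)
                for r, c in centers)
        assert d <= 3.0, "false positive detection"
    for r, c in centers:
        d = min(math.hypot(p.centroid[0] - r, p.centroid[1] - c) for p in found)
        matched += d <= 3.0
    assert matched >= 48


def test_long_low_streak_rejected_by_compactness():
    """A continuous axon-like streak above threshold still yields no puncta."""
    rng = np.random.default_rng(5)
    plane = _noise_plane((200, 200), rng)
    rr = np.arange(20, 180)
    for dr in (-1, 0, 1):
        plane[rr + dr, rr] += 100.0  # 3-px-wide diagonal streak at 5x noise sd
    assert detect_puncta(plane, "vglut1") == []


def test_detected_count_nondecreasing_in_density():
    """Scaling true puncta density up never lowers expected detected counts."""
    imaging = ImagingParams(shape=(192, 256))
    base = preset_profile("cortical", 14)
    denser = base.with_(
        vglut_density_per_um=base.vglut_density_per_um * 1.5,
        vglut_soma_count=base.vglut_soma_count * 1.5,
    )
    def mean_detected(profile):
        total = 0
        for seed in range(4):
            images, _ = generate_field(profile, imaging, seed=seed)
            total += len(detect_puncta(images.vglut1_plane, "vglut1"))
        return total / 4
    assert mean_detected(denser) >= mean_detected(base)


# ---------------------------------------------------------------------------
# assignment


def _toy_neurons():
    shape = (60, 60)
    soma = np.zeros(shape, bool)
    rr, cc = np.meshgrid(np.arange(60), np.arange(60), indexing="ij")
    soma[(rr - 15) ** 2 + (cc - 15) ** 2 <= 36] = True
    skel = np.array([(40, c) for c in range(10, 50)])
    n0 = NeuronObject(neuron_id=0, nucleus_centroid=(15.0, 15.0), soma_mask=soma,
                      dendrite_skeleton=skel)
    return [n0]


def test_assignment_rule_instantiation():
    neurons = _toy_neurons()
    inside = Punctum((15.0, 16.0), 4, 10.0, "vglut1")
    near = Punctum((41.0, 30.0), 4, 10.0, "vglut1")  # 1 px from skeleton
    far = Punctum((55.0, 55.0), 4, 10.0, "vglut1")  # ~14 px from everything
    assign_puncta([inside, near, far], neurons, contact_tolerance_px=2.0)
    assert (inside.compartment, inside.neuron_id) == ("cell_body", 0)
    assert (near.compartment, near.neuron_id) == ("dendrite", 0)
    assert (far.compartment, far.neuron_id) == ("excluded", None)


def test_soma_containment_beats_dendrite_contact():
    """The sequential rule checks cell-body containment first."""
    neurons = _toy_neurons()
    # a second neuron's skeleton passes right through neuron 0's soma edge
    skel = np.array([(15, c) for c in range(5, 25)])
    neurons.append(
        NeuronObject(neuron_id=1, nucleus_centroid=(50.0, 15.0),
                     soma_mask=np.zeros((60, 60), bool), dendrite_skeleton=skel)
    )
    p = Punctum((15.0, 14.0), 4, 10.0, "vgat")  # on skeleton AND inside soma
    assign_puncta([p], neurons, contact_tolerance_px=2.0)
    assert (p.compartment, p.neuron_id) == ("cell_body", 0)


def test_equidistant_tie_broken_by_lowest_neuron_id():
    shape = (40, 40)
    empty = np.zeros(shape, bool)
    a = NeuronObject(0, (5.0, 5.0), empty,
                     dendrite_skeleton=np.array([(10, 18)]))
    b = NeuronObject(1, (30.0, 30.0), empty,
                     dendrite_skeleton=np.array([(10, 22)]))
    p = Punctum((10.0, 20.0), 4, 10.0, "vglut1")
    assign_puncta([p], [b, a], contact_tolerance_px=2.0)
    assert p.neuron_id == 0


def test_negative_tolerance_rejected():
    with pytest.raises(ValueError, match="tolerance"):
        assign_puncta([], _toy_neurons(), contact_tolerance_px=-1.0)


@pytest.mark.parametrize("seed", [7, 8, 9])
def test_assignment_matches_all_pairs_oracle(seed):
    """Injecting ground-truth puncta, assignment equals the brute-force
    all-pairs distance oracle on every punctum."""
    imaging = ImagingParams(shape=(192, 256))
    images, truth = generate_field(preset_profile("hippocampal", 21),
                                   imaging, seed=seed)
    nuclei = detect_nuclei(images.nuclei_plane)
    neurons = mask_cell_bodies(images.map2_plane, nuclei)
    trace_dendrites(images.map2_plane, neurons,
                    pixel_size_um=imaging.pixel_size_um)
    puncta = [Punctum(p.center, 4, 10.0, p.channel) for p in truth.puncta]
    assign_puncta(puncta, neurons, contact_tolerance_px=2.0)
    for p in puncta:
        comp, nid = oracle_compartment(p.centroid, neurons, tolerance=2.0)
        assert (p.compartment, p.neuron_id) == (comp, nid)


# ---------------------------------------------------------------------------
# endpoints and ratios


def test_endpoint_arithmetic_and_conservation():
    shape = (30, 30)
    n1 = NeuronObject(0, (5.0, 5.0), np.zeros(shape, bool),
                      dendrite_length_um=100.0)
    n2 = NeuronObject(1, (20.0, 20.0), np.zeros(shape, bool),
                      dendrite_length_um=60.0)
    puncta = (
        [Punctum((0, 0), 1, 1.0, "vglut1", "cell_body", 0)] * 6
        + [Punctum((0, 0), 1, 1.0, "vglut1", "dendrite", 0)] * 14
        + [Punctum((0, 0), 1, 1.0, "vgat", "cell_body", 1)] * 4
        + [Punctum((0, 0), 1, 1.0, "vgat", "excluded", None)] * 3
    )
    ep = compute_field_endpoints([n1, n2], puncta)
    assert ep.vglut_total_per_neuron == pytest.approx(10.0)
    assert ep.vglut_per_cell_body == pytest.approx(3.0)
    assert ep.vglut_per_um_dendrite == pytest.approx(14 / 160.0)
    # conservation: totals decompose exactly into soma + dendrite
    assert ep.vglut_total_per_neuron * 2 == 6 + 14
    assert ep.vgat_total_per_neuron * 2 == 4 + 0
    assert ep.dendrite_length_per_neuron_um == pytest.approx(80.0)


def test_zero_neurons_flags_endpoints_missing():
    ep = compute_field_endpoints([], [])
    assert math.isnan(ep.vglut_total_per_neuron)
    assert ep.neurons_per_field == 0


def test_zero_dendrite_length_gives_missing_density_not_zero_division():
    n = NeuronObject(0, (5.0, 5.0), np.zeros((20, 20), bool),
                     dendrite_length_um=0.0)
    ep = compute_field_endpoints([n], [])
    assert math.isnan(ep.vglut_per_um_dendrite)


def test_ei_ratio_printed_values():
    assert ei_ratio(10, 10) == pytest.approx(0.0)
    assert ei_ratio(100, 10) == pytest.approx(1.0)
    assert math.isnan(ei_ratio(5, 0))
    assert math.isnan(ei_ratio(0, 0))
    with pytest.raises(ValueError):
        ei_ratio(-1, 5)


@settings(deadline=None, max_examples=60)
@given(a=st.integers(1, 10_000), b=st.integers(1, 10_000))
def test_ei_ratio_antisymmetry(a, b):
    assert ei_ratio(a, b) == pytest.approx(-ei_ratio(b, a))


def test_full_field_analysis_conserves_counts(hippocampal_div21_field):
    images, _ = hippocampal_div21_field
    neurons, puncta, ep = analyze_field(images)
    for ch, total in (("vglut1", ep.vglut_total_per_neuron),
                      ("vgat", ep.vgat_total_per_neuron)):
        cb = sum(p.compartment == "cell_body" and p.channel == ch for p in puncta)
        dn = sum(p.compartment == "dendrite" and p.channel == ch for p in puncta)
        assert total * len(neurons) == pytest.approx(cb + dn)
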