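"""Shared fixtures and independent oracles for the test suite.

The oracle implementations here are deliberately naive (brute-force loops,
direct sum-of-squares algebra) and independent of the package's code paths
they are used to check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from synaptoscope.synthetic import ImagingParams, generate_field, preset_profile

SMALL_SHAPE = (256, 320)


@pytest.fixture(scope="session")
def small_imaging() -> ImagingParams:
    return ImagingParams(shape=SMALL_SHAPE)


@pytest.fixture(scope="session")
def hippocampal_div21_field(small_imaging):
    """One rendered hippocampal DIV-21 field plus its ground truth."""
    profile = preset_profile("hippocampal", 21)
    return generate_field(profile, small_imaging, seed=7)


# ---------------------------------------------------------------------------
# oracles


def brute_force_bursts(
    times: np.ndarray,
    min_spikes: int = 4,
    min_duration: float = 0.02,
    min_interburst: float = 0.1,
    max_isi: float = 0.1,
) -> list[tuple[int, int]]:
    """Enumerate maximal qualifying runs by explicit scanning.

    Returns [start_index, end_index] pairs (inclusive) of bursts after the
    same discard-then-merge-then-recheck convention as the detector, derived
    here from first principles: maximal ISI-bounded runs found by a linear
    scan, filters applied by direct comparison, merging by pairwise check.
    """
    t = list(map(float, times))
    n = len(t)
    runs = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and t[j + 1] - t[j] <= max_isi:
            j += 1
        runs.append((i, j))
        i = j + 1
    qualifying = [
        (i, j)
        for (i, j) in runs
        if (j - i + 1) >= min_spikes and (t[j] - t[i]) >= min_duration
    ]
    merged: list[list[int]] = []
    for i, j in qualifying:
        if merged and t[i] - t[merged[-1][1]] < min_interburst:
            merged[-1][1] = j
        else:
            merged.append([i, j])
    return [
        (i, j)
        for (i, j) in merged
        if (j - i + 1) >= min_spikes and (t[j] - t[i]) >= min_duration
    ]


def oracle_compartment(
    center: tuple[float, float],
    neurons,
    tolerance: float,
) -> tuple[str, int | None]:
    """All-pairs distance re-derivation of the sequential assignment rule."""
    r = int(round(center[0]))
    c = int(round(center[1]))
    for n in sorted(neurons, key=lambda n: n.neuron_id):
        mask = n.soma_mask
        if 0 <= r < mask.shape[0] and 0 <= c < mask.shape[1] and mask[r, c]:
            return "cell_body", n.neuron_id
    best = (np.inf, None)
    for n in neurons:
        for pr, pc in n.dendrite_skeleton:
            d = float(np.hypot(center[0] - pr, center[1] - pc))
            if d < best[0] - 1e-9 or (
                abs(d - best[0]) <= 1e-9 and (best[1] is None or n.neuron_id < best[1])
            ):
                best = (d, n.neuron_id)
    if best[0] <= tolerance + 1e-9:
        return "dendrite", best[1]
    return "excluded", None


def balanced_two_way_ss(df: pd.DataFrame):
    """Direct sum-of-squares decomposition for a balanced two-way layout.

    Returns dict of (F, df_num, df_den, p) per effect, computed with plain
    group-mean algebra and the F survival function.
    """
    from scipy.stats import f as fdist

    y = df["value"].to_numpy(dtype=float)
    a = df["div"].to_numpy()
    b = df["cell_type"].to_numpy()
    a_levels = sorted(set(a))
    b_levels = sorted(set(b))
    grand = y.mean()
    n = len(y)
    r = n // (len(a_levels) * len(b_levels))

    ss_a = sum(
        (y[a == ai].mean() - grand) ** 2 * (y[a == ai]).size for ai in a_levels
    )
    ss_b = sum(
        (y[b == bi].mean() - grand) ** 2 * (y[b == bi]).size for bi in b_levels
    )
    ss_cells = 0.0
    ss_res = 0.0
    for ai in a_levels:
        for bi in b_levels:
            cell = y[(a == ai) & (b == bi)]
            ss_cells += len(cell) * (cell.mean() - grand) ** 2
            ss_res += float(((cell - cell.mean()) ** 2).sum())
    ss_ab = ss_cells - ss_a - ss_b
    df_a = len(a_levels) - 1
    df_b = len(b_levels) - 1
    df_ab = df_a * df_b
    df_res = n - len(a_levels) * len(b_levels)
    out = {}
    for name, ss, dfn in (
        ("time", ss_a, df_a),
        ("cell_type", ss_b, df_b),
        ("interaction", ss_ab, df_ab),
    ):
        F = (ss / dfn) / (ss_res / df_res)
        out[name] = (F, dfn, df_res, float(fdist.sf(F, dfn, df_res)))
    out["ss"] = {
        "time": ss_a,
        "cell_type": ss_b,
        "interaction": ss_ab,
        "residual": ss_res,
        "total": float(((y - grand) ** 2).sum()),
    }
    del r
    return out


def dist_point_to_segments(point: np.ndarray, poly: np.ndarray) -> float:
    """Naive loop version of point-to-polyline distance."""
    best = np.inf
    for k in range(len(poly) - 1):
        a, b = poly[k], poly[k + 1]
        ab = b - a
        denom = float(ab @ ab)
        tpar = 0.0 if denom == 0 else float(np.clip((point - a) @ ab / denom, 0, 1))
        proj = a + tpar * ab
        best = min(best, float(np.linalg.norm(point - proj)))
    if len(poly) == 1:
        best = float(np.linalg.norm(point - poly[0]))
    return best
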