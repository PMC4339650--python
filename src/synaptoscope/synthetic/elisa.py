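"""Synthetic ELISA absorbance plates (450 nm readout, blank wells included).

Absorbance = blank + gain * true_level + Gaussian noise.  Samples are run in
triplicate by default, as is standard practice for sandwich ELISAs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def generate_elisa_plate(
    levels: dict[str, float],
    blank_level: float = 0.05,
    gain: float = 1.0,
    noise_sd: float = 0.0,
    n_replicates: int = 3,
    n_blanks: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Return a plate table with columns (well, role, sample_id, replicate,
    absorbance).  ``levels`` maps sample id to its true relative analyte
    level (arbitrary units)."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if n_replicates < 1 or n_blanks < 1:
        raise ValueError("need at least one replicate and one blank well")
    for sid, lev in levels.items():
        if lev < 0:
            raise ValueError(f"level for sample {sid!r} must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    well = 0
    for b in range(n_blanks):
        rows.append(
            {
                "well": f"W{well:03d}",
                "role": "blank",
                "sample_id": "",
                "replicate": b,
                "absorbance": blank_level + rng.normal(0.0, noise_sd),
            }
        )
        well += 1
    for sid, lev in levels.items():
        for rep in range(n_replicates):
            rows.append(
                {
                    "well": f"W{well:03d}",
                    "role": "sample",
                    "sample_id": sid,
                    "replicate": rep,
                    "absorbance": blank_level + gain * lev + rng.normal(0.0, noise_sd),
                }
            )
            well += 1
    df = pd.DataFrame(rows)
    df["absorbance"] = df["absorbance"].clip(lower=0.0)
    return df
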