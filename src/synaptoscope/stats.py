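"""Ontogeny statistics: ELISA normalisation, two-way ANOVA, Sidak post hoc.

Endpoints are analysed as well means in a fixed-effects two-way ANOVA with
culture age (DIV) and cell type as factors.  When the interaction is
significant at alpha = 0.05, post-hoc mean contrasts compare cell types
within each time point and time points within each cell type; when only a
main effect is significant, the data are collapsed over the other factor
before the contrasts.  Families of contrasts are Sidak-adjusted:
p_adj = 1 - (1 - p)^m.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

logger = logging.getLogger(__name__)

ALPHA = 0.05


class DegenerateDataError(ValueError):
    """Raised when the response carries no variance (F undefined)."""


@dataclass(frozen=True)
class AnovaResult:
    """F, degrees of freedom and p for time, cell type and their interaction."""

    endpoint: str
    effects: dict[str, tuple[float, int, int, float]]  # name -> (F, df1, df2, p)

    def f(self, effect: str) -> float:
        return self.effects[effect][0]

    def p(self, effect: str) -> float:
        return self.effects[effect][3]

    def frame(self) -> pd.DataFrame:
        rows = [
            {
                "endpoint": self.endpoint,
                "effect": name,
                "F": F,
                "df_num": d1,
                "df_den": d2,
                "p": p,
            }
            for name, (F, d1, d2, p) in self.effects.items()
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ELISA


def normalize_elisa(plate: pd.DataFrame) -> pd.DataFrame:
    """Blank-subtract a plate and average replicates per sample.

    Expects columns (role, sample_id, absorbance) with at least one
    ``role == 'blank'`` well.  Normalised value = absorbance minus the
    plate's mean blank; replicate wells are averaged to one value per
    sample.  Negative normalised values (sub-blank samples) are retained
    and flagged, never clipped.
    """
    blanks = plate.loc[plate["role"] == "blank", "absorbance"]
    if blanks.empty:
        raise ValueError("plate has no blank wells; cannot normalize")
    blank_mean = float(blanks.mean())
    samples = plate[plate["role"] == "sample"].copy()
    samples["normalized"] = samples["absorbance"] - blank_mean
    out = (
        samples.groupby("sample_id", sort=False)["normalized"]
        .mean()
        .reset_index()
    )
    out["below_blank"] = out["normalized"] < 0
    if out["below_blank"].any():
        logger.warning(
            "%d sample(s) normalized below the plate blank", out["below_blank"].sum()
        )
    return out


# ---------------------------------------------------------------------------
# two-way ANOVA


def two_way_anova(
    table: pd.DataFrame,
    endpoint: str | None = None,
    value_col: str = "value",
    time_col: str = "div",
    cell_col: str = "cell_type",
) -> AnovaResult:
    """Fixed-effects two-way ANOVA with interaction (Type II for unbalanced).

    ``table`` holds one row per well with the endpoint value and the two
    factors.  Missing values are dropped (logged).  Requires >= 2 levels per
    factor and replication within cells so the interaction is testable; a
    response with zero total variance raises :class:`DegenerateDataError`.
    """
    df = table.copy()
    if endpoint is not None and "endpoint_name" in df.columns:
        df = df[df["endpoint_name"] == endpoint]
    n0 = len(df)
    df = df.dropna(subset=[value_col])
    if len(df) < n0:
        logger.info("dropped %d missing observations", n0 - len(df))
    for col in (time_col, cell_col):
        if df[col].nunique() < 2:
            raise ValueError(f"factor {col!r} needs >= 2 levels")
    cell_sizes = df.groupby([time_col, cell_col], observed=True)[value_col].size()
    if (cell_sizes < 2).any():
        raise ValueError(
            "interaction untestable: every (time, cell type) cell needs >= 2 "
            "replicates"
        )
    y = df[value_col].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise DegenerateDataError(
            "response has zero total variance; F is undefined"
        )
    work = pd.DataFrame(
        {
            "y": y,
            "t": df[time_col].astype(str).to_numpy(),
            "g": df[cell_col].astype(str).to_numpy(),
        }
    )
    model = smf.ols("y ~ C(t) * C(g)", data=work).fit()
    tab = sm.stats.anova_lm(model, typ=2)
    df_den = int(tab.loc["Residual", "df"])
    effects = {}
    for name, key in (("time", "C(t)"), ("cell_type", "C(g)"),
                      ("interaction", "C(t):C(g)")):
        effects[name] = (
            float(tab.loc[key, "F"]),
            int(tab.loc[key, "df"]),
            df_den,
            float(tab.loc[key, "PR(>F)"]),
        )
    return AnovaResult(endpoint=endpoint or value_col, effects=effects)


# ---------------------------------------------------------------------------
# Sidak post hoc


def sidak_adjust(p_raw: float, m: int) -> float:
    """Sidak family-wise adjustment: 1 - (1 - p)^m, capped at 1."""
    if not 0 <= p_raw <= 1:
        raise ValueError("p_raw must be in [0, 1]")
    if m < 1:
        raise ValueError("family size m must be >= 1")
    return float(min(1.0 - (1.0 - p_raw) ** m, 1.0))


def _pooled_error(df: pd.DataFrame, value_col, time_col, cell_col):
    """Residual mean square and df of the full interaction model."""
    grouped = df.groupby([time_col, cell_col], observed=True)[value_col]
    ss_res = float(((df[value_col] - grouped.transform("mean")) ** 2).sum())
    df_res = len(df) - grouped.ngroups
    return ss_res / df_res, df_res


def _contrast(
    df: pd.DataFrame, sel_a, sel_b, value_col, mse: float, dfe: int
) -> tuple[float, float]:
    ya = df.loc[sel_a, value_col]
    yb = df.loc[sel_b, value_col]
    est = float(ya.mean() - yb.mean())
    se = np.sqrt(mse * (1.0 / len(ya) + 1.0 / len(yb)))
    if se == 0:  # zero pooled error: means differ exactly or not at all
        return est, 0.0 if est != 0 else 1.0
    tval = est / se
    p = float(2 * sps.t.sf(abs(tval), dfe))
    return est, p


def sidak_posthoc(
    table: pd.DataFrame,
    anova: AnovaResult,
    alpha: float = ALPHA,
    strategy: str = "all_pairwise",
    value_col: str = "value",
    time_col: str = "div",
    cell_col: str = "cell_type",
) -> pd.DataFrame:
    """Sidak-adjusted mean contrasts following the two-way ANOVA.

    With a significant interaction: cell types are compared within each
    time point (one family) and time points within each cell type (a second
    family, all-pairwise by default or each level vs the first with
    ``strategy='vs_first'``).  Without an interaction, each significant
    main effect is followed up on data collapsed over the other factor.
    t statistics use the pooled residual error of the interaction model
    (or of the collapsed one-way model after collapsing).

    Returns a table with (family, level_a, level_b, within, estimate,
    p_raw, p_adj, significant).
    """
    df = table.dropna(subset=[value_col]).copy()
    if anova.endpoint not in (value_col,) and "endpoint_name" in df.columns:
        df = df[df["endpoint_name"] == anova.endpoint]
    mse, dfe = _pooled_error(df, value_col, time_col, cell_col)
    times = sorted(df[time_col].unique())
    cells = sorted(df[cell_col].unique())

    def time_pairs():
        if strategy == "vs_first":
            return [(times[0], t) for t in times[1:]]
        if strategy == "all_pairwise":
            return list(itertools.combinations(times, 2))
        raise ValueError(f"unknown strategy {strategy!r}")

    rows = []
    if anova.p("interaction") < alpha:
        # family 1: cell types within each time point
        fam = []
        for t in times:
            for a, b in itertools.combinations(cells, 2):
                fam.append(
                    (
                        "cell_type_within_time",
                        a,
                        b,
                        t,
                        (df[time_col] == t) & (df[cell_col] == a),
                        (df[time_col] == t) & (df[cell_col] == b),
                    )
                )
        rows.append((fam, mse, dfe))
        # family 2: time points within each cell type
        fam = []
        for g in cells:
            for a, b in time_pairs():
                fam.append(
                    (
                        "time_within_cell_type",
                        a,
                        b,
                        g,
                        (df[cell_col] == g) & (df[time_col] == a),
                        (df[cell_col] == g) & (df[time_col] == b),
                    )
                )
        rows.append((fam, mse, dfe))
    else:
        # collapse rule: follow up each significant main effect on data
        # pooled over the other factor
        if anova.p("time") < alpha:
            one_way = df.groupby(time_col, observed=True)[value_col]
            ss = float(((df[value_col] - one_way.transform("mean")) ** 2).sum())
            dfe_c = len(df) - one_way.ngroups
            mse_c = ss / dfe_c
            fam = [
                (
                    "time_collapsed",
                    a,
                    b,
                    "all",
                    df[time_col] == a,
                    df[time_col] == b,
                )
                for a, b in time_pairs()
            ]
            rows.append((fam, mse_c, dfe_c))
        if anova.p("cell_type") < alpha:
            one_way = df.groupby(cell_col, observed=True)[value_col]
            ss = float(((df[value_col] - one_way.transform("mean")) ** 2).sum())
            dfe_c = len(df) - one_way.ngroups
            mse_c = ss / dfe_c
            fam = [
                (
                    "cell_type_collapsed",
                    a,
                    b,
                    "all",
                    df[cell_col] == a,
                    df[cell_col] == b,
                )
                for a, b in itertools.combinations(cells, 2)
            ]
            rows.append((fam, mse_c, dfe_c))

    out = []
    for fam, mse_f, dfe_f in rows:
        m = len(fam)
        for family, a, b, within, sel_a, sel_b in fam:
            est, p_raw = _contrast(df, sel_a, sel_b, value_col, mse_f, dfe_f)
            p_adj = sidak_adjust(p_raw, m)
            out.append(
                {
                    "endpoint": anova.endpoint,
                    "family": family,
                    "level_a": a,
                    "level_b": b,
                    "within": within,
                    "estimate": est,
                    "p_raw": p_raw,
                    "p_adj": p_adj,
                    "significant": p_adj < alpha,
                }
            )
    return pd.DataFrame(
        out,
        columns=[
            "endpoint", "family", "level_a", "level_b", "within",
            "estimate", "p_raw", "p_adj", "significant",
        ],
    )
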