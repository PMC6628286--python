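"""Control-based quartile schemes and the combined E-DII + NEAC exposures.

Case-control analyses express dietary scores as quartiles of the *control*
distribution (sex-specific where both sexes are studied), so that case
inclusion can never move the category bounds.  Two joint exposures are built
on top of the quartiles:

* an **inflammatory–antioxidant profile** in 0..6: the E-DII quartile coded
  0,1,2,3 (ascending: more inflammatory) plus the NEAC quartile coded 3,2,1,0
  (descending: less antioxidant).  0 = anti-inflammatory and high-antioxidant
  diet, 6 = pro-inflammatory and low-antioxidant diet;
* a **four-level median cross-classification** of E-DII and NEAC, with the
  low-inflammatory / high-antioxidant cell as the reference.

Conventions (documented because quartile counts near ties depend on them):
percentiles use linear interpolation between order statistics (the "type 7"
estimator, numpy's default) and intervals are closed above / open below, i.e.
Q1 iff value <= q25, Q4 iff value > q75.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("dietinflam.profiles")

__all__ = [
    "QuartileScheme",
    "quartile_cutpoints",
    "assign_quartile",
    "edii_neac_profile",
    "combined_median_category",
    "COMBINED_LEVELS",
    "attach_exposures",
]

#: Levels of the median cross-classification; first level is the reference.
COMBINED_LEVELS = (
    "low_edii_high_teac",   # reference: anti-inflammatory, high antioxidant
    "low_edii_low_teac",
    "high_edii_high_teac",
    "high_edii_low_teac",
)


@dataclass(frozen=True)
class QuartileScheme:
    """Quartile cutpoints estimated on one control group."""

    group_key: str
    cutpoints: tuple[float, float, float]  # (q25, q50, q75)
    source_n: int


def quartile_cutpoints(values, group_key: str = "all") -> QuartileScheme:
    """Empirical 25/50/75 percentiles of control exposure values."""
    arr = np.asarray(values, float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 4:
        raise ValueError(
            f"group {group_key!r}: need at least 4 control values, got {arr.size}"
        )
    q25, q50, q75 = np.quantile(arr, [0.25, 0.50, 0.75])  # linear interpolation
    if not (q25 < q50 < q75):
        logger.warning(
            "group %r: tied cutpoints (%g, %g, %g); quartiles will saturate",
            group_key, q25, q50, q75,
        )
    return QuartileScheme(group_key, (float(q25), float(q50), float(q75)), int(arr.size))


def assign_quartile(value, scheme: QuartileScheme):
    """Quartile 1..4 under the closed-above convention.

    Q1 iff value <= q25; Q2 iff q25 < value <= q50; Q3 iff q50 < value <= q75;
    Q4 iff value > q75.  Accepts scalars or arrays.
    """
    arr = np.asarray(value, float)
    if not np.isfinite(arr).all():
        raise ValueError("non-finite exposure value in quartile assignment")
    q25, q50, q75 = scheme.cutpoints
    q = 1 + (arr > q25).astype(int) + (arr > q50).astype(int) + (arr > q75).astype(int)
    return int(q) if np.isscalar(value) or arr.ndim == 0 else q


def edii_neac_profile(edii_q, neac_q):
    """Combined profile 0..6 from the two quartile codes.

    ``(edii_q - 1) + (4 - neac_q)``: ascending in E-DII quartile, descending
    in NEAC quartile.
    """
    eq = np.asarray(edii_q, int)
    nq = np.asarray(neac_q, int)
    if ((eq < 1) | (eq > 4) | (nq < 1) | (nq > 4)).any():
        raise ValueError("quartile codes must lie in 1..4")
    prof = (eq - 1) + (4 - nq)
    return int(prof) if np.isscalar(edii_q) else prof


def combined_median_category(edii, neac, edii_median: float, neac_median: float):
    """Median cross-classification of E-DII and NEAC (TEAC).

    "low" E-DII means value <= median (closed above, as for quartiles); "high"
    TEAC means value > median.  Returns one of :data:`COMBINED_LEVELS`.
    """
    for m, label in ((edii_median, "edii"), (neac_median, "neac")):
        if m is None or not np.isfinite(m):
            raise ValueError(f"missing {label} median")
    e = np.asarray(edii, float)
    t = np.asarray(neac, float)
    low_e = e <= edii_median
    high_t = t > neac_median
    idx = np.where(low_e, np.where(high_t, 0, 1), np.where(high_t, 2, 3))
    if np.isscalar(edii):
        return COMBINED_LEVELS[int(idx)]
    return np.array([COMBINED_LEVELS[i] for i in np.ravel(idx)]).reshape(idx.shape)


def attach_exposures(
    study: pd.DataFrame,
    edii_col: str = "edii",
    neac_col: str = "teac_no_coffee",
    sex_col: str | None = "sex",
    case_col: str = "case_status",
) -> tuple[pd.DataFrame, dict[str, dict[str, QuartileScheme]]]:
    """Add quartile, profile and combined-category columns to a study table.

    Cutpoints and medians are computed on controls only (``case_col == 0``),
    within sex groups when ``sex_col`` is given (the convention when both
    sexes are analysed; pass ``None`` for single-sex studies).  Returns the
    augmented copy and the schemes used, keyed by exposure then group.
    """
    df = study.copy()
    groups = df[sex_col].astype(str) if sex_col is not None else pd.Series("all", index=df.index)
    controls = df[case_col].astype(int) == 0
    schemes: dict[str, dict[str, QuartileScheme]] = {"edii": {}, "neac": {}}
    medians: dict[str, dict[str, float]] = {"edii": {}, "neac": {}}
    for key in sorted(groups.unique()):
        in_group = groups == key
        for exp, col in (("edii", edii_col), ("neac", neac_col)):
            vals = df.loc[in_group & controls, col]
            schemes[exp][key] = quartile_cutpoints(vals, group_key=f"{exp}:{key}")
            medians[exp][key] = float(np.median(vals))
    edii_q = np.empty(len(df), int)
    neac_q = np.empty(len(df), int)
    combined = np.empty(len(df), object)
    for key in schemes["edii"]:
        mask = (groups == key).to_numpy()
        edii_q[mask] = assign_quartile(df.loc[mask, edii_col].to_numpy(), schemes["edii"][key])
        neac_q[mask] = assign_quartile(df.loc[mask, neac_col].to_numpy(), schemes["neac"][key])
        combined[mask] = combined_median_category(
            df.loc[mask, edii_col].to_numpy(),
            df.loc[mask, neac_col].to_numpy(),
            medians["edii"][key],
            medians["neac"][key],
        )
    df["edii_quartile"] = edii_q
    df["neac_quartile"] = neac_q
    df["profile"] = edii_neac_profile(edii_q, neac_q)
    df["combined_category"] = combined
    return df, schemes
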