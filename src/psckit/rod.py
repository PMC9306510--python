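"""Relative-optical-density (ROD) quantification for immunofluorescence.

Grey values (8-bit, 0-255) measured in hippocampal subfields are
background-corrected against a non-immunoreactive reference region and
converted to relative optical densities,

    ROD = log10(256 / (255 - grey)),

then averaged up the sampling hierarchy: the cryotome sections of each
vibratome slice are averaged first, those vibratome means are averaged
per mouse, and group statistics (mean +/- SEM, Student's t) are computed
over mouse values — so the animal, not the section, is the unit of
replication.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "SaturationError",
    "rod_from_grey",
    "hierarchical_mean",
    "relative_percent",
    "group_t_test",
    "ROD_REGIONS",
]

ROD_REGIONS = ("DG-ML", "CA1-so", "CA1-sr", "CA1-slm", "CA3-so", "CA3-sr")


class SaturationError(ValueError):
    """Background-corrected grey value at or above the 255 ceiling."""


def rod_from_grey(grey, background=0.0, clamp_negative: bool = False):
    """Convert grey values to ROD after background subtraction.

    The background is deducted from the grey value first, then the
    corrected value enters log10(256/(255 - value)).  Values >= 255 after
    correction saturate the formula and raise; negative corrected values
    (background brighter than signal) raise unless ``clamp_negative``
    clamps them to zero.  Strictly increasing in grey; scalars in, scalar
    out.
    """
    grey_arr = np.asarray(grey, dtype=float)
    bg_arr = np.asarray(background, dtype=float)
    net = grey_arr - bg_arr
    if np.any(net >= 255.0):
        raise SaturationError(
            "background-corrected grey value >= 255 saturates the ROD formula")
    if np.any(net < 0.0):
        if not clamp_negative:
            raise ValueError(
                "background exceeds grey value; pass clamp_negative=True to "
                "clamp the corrected value to 0")
        net = np.maximum(net, 0.0)
    rod = np.log10(256.0 / (255.0 - net))
    return float(rod) if np.isscalar(grey) or np.ndim(grey) == 0 else rod


def hierarchical_mean(measurements: pd.DataFrame, condition: str | None = None,
                      region: str | None = None,
                      clamp_negative: bool = False) -> dict:
    """Cryotome -> vibratome -> mouse -> group averaging of ROD values.

    ``measurements`` needs columns region, condition, mouse_id,
    vibratome_id, cryotome_id, grey, background.  Unbalanced designs
    average over the children that exist (a vibratome slice with a single
    cryotome section contributes that section's value).  Returns the
    per-mouse means and the group mean +/- SEM with n = number of mice.
    """
    df = measurements.copy()
    if condition is not None:
        df = df[df["condition"] == condition]
    if region is not None:
        df = df[df["region"] == region]
    if df.empty:
        raise ValueError("no measurements match the requested subset")
    keys = ["mouse_id", "vibratome_id", "cryotome_id"]
    if df[keys].isna().any().any():
        raise ValueError("orphan measurement: incomplete hierarchy keys")
    df = df.assign(rod=rod_from_grey(df["grey"].to_numpy(),
                                     df["background"].to_numpy(),
                                     clamp_negative=clamp_negative))
    vib = df.groupby(["mouse_id", "vibratome_id"])["rod"].mean()
    mouse = vib.groupby("mouse_id").mean()
    values = mouse.to_numpy()
    sem = float(values.std(ddof=1) / math.sqrt(values.size)) \
        if values.size > 1 else float("nan")
    return {
        "mouse_means": mouse.to_dict(),
        "mean": float(values.mean()),
        "sem": sem,
        "n_mice": int(values.size),
    }


def relative_percent(treated_mean: float, control_mean: float) -> int:
    """Treated mean as an integer percent of control, rounded half-up."""
    if control_mean <= 0:
        raise ValueError("control mean must be positive")
    return int(math.floor(100.0 * treated_mean / control_mean + 0.5))


def group_t_test(a_mouse_means, b_mouse_means) -> float:
    """Two-sided equal-variance Student's t p-value on per-mouse means.

    Degenerate zero-variance input is resolved directly: identical group
    means give p = 1, perfectly separated constant groups give p = 0.
    """
    a = np.asarray(a_mouse_means, dtype=float)
    b = np.asarray(b_mouse_means, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per group")
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(sps.ttest_ind(a, b, equal_var=True).pvalue)


@dataclass(frozen=True)
class RegionComparison:
    region: str
    control_mean: float
    control_sem: float
    treated_mean: float
    treated_sem: float
    percent: int
    p_value: float


def compare_regions(measurements: pd.DataFrame, control: str, treated: str,
                    regions=ROD_REGIONS) -> pd.DataFrame:
    """Per-region group table: mean +/- SEM, percent of control, t-test p."""
    rows = []
    for region in regions:
        ctrl = hierarchical_mean(measurements, condition=control, region=region)
        trt = hierarchical_mean(measurements, condition=treated, region=region)
        rows.append(RegionComparison(
            region=region,
            control_mean=ctrl["mean"], control_sem=ctrl["sem"],
            treated_mean=trt["mean"], treated_sem=trt["sem"],
            percent=relative_percent(trt["mean"], ctrl["mean"]),
            p_value=group_t_test(list(ctrl["mouse_means"].values()),
                                 list(trt["mouse_means"].values())),
        ).__dict__)
    return pd.DataFrame(rows)
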