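"""Growth quantification: OD600 time-series AUC, spot-assay ratios, and
pairwise group comparisons with significance-star labels."""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import ttest_ind

from editscan.stats import star_label


class UndefinedRatioError(ValueError):
    pass


@dataclass
class GrowthCurve:
    """One OD600 time series (hours vs readings) for a strain/condition."""

    times: np.ndarray
    od: np.ndarray
    strain: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.times.shape != self.od.shape or self.times.size < 2:
            raise ValueError("times and od must be equal-length with >= 2 points")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.od < 0):
            raise ValueError("negative OD reading")


def auc(curve: GrowthCurve) -> float:
    """Trapezoidal area under the growth curve, in OD*hours."""
    return float(np.trapezoid(curve.od, curve.times))


@dataclass
class SpotMeasurement:
    strain: str
    pixel_density_inducing: float
    pixel_density_repressing: float

    def __post_init__(self) -> None:
        if self.pixel_density_inducing < 0 or self.pixel_density_repressing < 0:
            raise ValueError("pixel densities must be non-negative")


def relative_growth(spot: SpotMeasurement) -> float:
    """Growth under induction relative to repression (pixel-density ratio)."""
    if spot.pixel_density_repressing == 0:
        raise UndefinedRatioError(f"zero repressing density for {spot.strain!r}")
    return spot.pixel_density_inducing / spot.pixel_density_repressing


def compare_groups(groups: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Pairwise two-sided Welch t-tests with star labels.

    Groups need >= 2 values each. If both groups are zero-variance the
    comparison degenerates to exact equality: p = 1 when the means match,
    p = 0 otherwise.
    """
    arrays: Dict[str, np.ndarray] = {}
    for label, values in groups.items():
        arr = np.asarray(list(values), dtype=float)
        if arr.size < 2:
            raise ValueError(f"group {label!r} needs >= 2 values")
        arrays[label] = arr
    rows = []
    for la, lb in combinations(arrays, 2):
        xa, xb = arrays[la], arrays[lb]
        if xa.std() == 0.0 and xb.std() == 0.0:
            p = 1.0 if xa.mean() == xb.mean() else 0.0
        else:
            p = float(ttest_ind(xa, xb, equal_var=False).pvalue)
        rows.append(
            {
                "group_a": la,
                "group_b": lb,
                "mean_a": float(xa.mean()),
                "mean_b": float(xb.mean()),
                "p": p,
                "stars": star_label(p),
            }
        )
    return pd.DataFrame(rows)


# -------------------------------------------------------------------- TSV IO

def auc_table(curves_tsv: str) -> pd.DataFrame:
    """Per-(strain, replicate) AUC from a (time_h, od600, strain, replicate) TSV."""
    df = pd.read_csv(curves_tsv, sep="\t")
    rows = []
    for (strain, replicate), group in df.groupby(["strain", "replicate"]):
        group = group.sort_values("time_h")
        curve = GrowthCurve(group["time_h"].to_numpy(), group["od600"].to_numpy(), strain)
        rows.append({"strain": strain, "replicate": replicate, "auc": auc(curve)})
    return pd.DataFrame(rows)


def spot_table(spots_tsv: str) -> pd.DataFrame:
    """Relative growth per (strain, replicate) from a spot-density TSV."""
    df = pd.read_csv(spots_tsv, sep="\t")
    rows = []
    for row in df.itertuples(index=False):
        spot = SpotMeasurement(row.strain, row.density_gal, row.density_glu)
        rows.append(
            {
                "strain": row.strain,
                "replicate": row.replicate,
                "relative_growth": relative_growth(spot),
            }
        )
    return pd.DataFrame(rows)
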