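"""Group-median association analysis between morphometry and biomechanics.

Specimens scanned by micro-CT and specimens tested to failure in
three-point bending are different animals, so per-specimen pairing is
impossible; association is therefore assessed across *treatment-group
medians* (unpaired design, n = number of groups).  For each of the seven
morphometric parameters against each biomechanical outcome (breaking load
in N, stiffness in N/mm) this module reports the sample Pearson
correlation with its two-sided t-test p-value (df = n - 2) and the
ordinary-least-squares line with the morphometric parameter as the
reported dependent variable.

With n = 4 groups these correlations are exploratory: |r| must exceed
0.95 to reach p < 0.05.

The reference group-median table (groups C = cefuroxime, D = diclofenac,
P = prednisolone, K = control) ships as a packaged CSV fixture.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "MICROCT_VARIABLES",
    "BIOMECH_VARIABLES",
    "GroupTable",
    "AssociationResult",
    "median_iqr",
    "pearson",
    "ols",
    "associate_all",
    "load_group_table",
    "plot_association_panels",
]

BIOMECH_VARIABLES = ("load", "stiffness")
MICROCT_VARIABLES = ("bv_mm3", "tmd_mgHAcm3", "bmc_mg", "smi", "da", "bs", "tbth_mm")


@dataclass
class AssociationResult:
    """Pearson + OLS summary for one (biomechanics, morphometry) pair.

    The regression is reported as ``y = slope * x + intercept`` with the
    morphometric parameter as dependent variable ``y``.
    """

    x_name: str
    y_name: str
    r: float
    p: float
    slope: float
    intercept: float
    n: int


class GroupTable:
    """Per-group medians (and IQRs) of biomechanical and morphometric medians.

    Thin wrapper over two wide DataFrames indexed by group label with one
    column per variable.
    """

    def __init__(self, medians: pd.DataFrame, iqrs: Optional[pd.DataFrame] = None):
        required = set(BIOMECH_VARIABLES) | set(MICROCT_VARIABLES)
        missing = required - set(medians.columns)
        if missing:
            raise ValueError(f"group table lacks columns: {sorted(missing)}")
        if medians[list(required)].isna().any().any():
            raise ValueError("group table contains missing cells")
        self.medians = medians
        self.iqrs = iqrs

    @property
    def groups(self) -> list:
        return list(self.medians.index)

    def __len__(self) -> int:
        return len(self.medians)

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "GroupTable":
        """Build from a long CSV with columns group, variable, median[, iqr]."""
        med = df.pivot(index="group", columns="variable", values="median")
        iqr = df.pivot(index="group", columns="variable", values="iqr") if "iqr" in df else None
        return cls(med, iqr)


def median_iqr(values: Sequence[float]):
    """Median and interquartile range (linear interpolation of order statistics)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot summarise an empty sample")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return float(med), float(q3 - q1)


def pearson(x: Sequence[float], y: Sequence[float]):
    """Sample Pearson r with two-sided p from the t-distribution (df = n - 2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("pearson needs two equal-length samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation is undefined for a constant sample")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def ols(x: Sequence[float], y: Sequence[float]):
    """Least-squares slope and intercept of y on x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("ols needs two equal-length samples with n >= 2")
    if np.ptp(x) == 0:
        raise ValueError("regression is undefined for a constant regressor")
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def associate_all(table: GroupTable) -> List[AssociationResult]:
    """All 14 morphometry-vs-biomechanics associations across group medians."""
    if len(table) < 3:
        raise ValueError("need at least 3 groups for correlation")
    out = []
    for mech in BIOMECH_VARIABLES:
        x = table.medians[mech].to_numpy()
        for var in MICROCT_VARIABLES:
            y = table.medians[var].to_numpy()
            r, p = pearson(x, y)
            slope, intercept = ols(x, y)
            out.append(
                AssociationResult(
                    x_name=mech, y_name=var, r=r, p=p,
                    slope=slope, intercept=intercept, n=len(x),
                )
            )
    return out


def results_frame(results: List[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])


def load_group_table(path=None) -> GroupTable:
    """Load a group table CSV; defaults to the packaged reference medians."""
    if path is None:
        ref = resources.files("callusct.data").joinpath("group_medians.csv")
        with resources.as_file(ref) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    return GroupTable.from_long(df)


def plot_association_panels(table: GroupTable, mech: str, out_path) -> None:
    """Scatter of group medians with the fitted line, one panel per parameter."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = table.medians[mech].to_numpy()
    fig, axes = plt.subplots(2, 4, figsize=(14, 7))
    for ax, var in zip(axes.ravel(), MICROCT_VARIABLES):
        y = table.medians[var].to_numpy()
        r, _ = pearson(x, y)
        slope, intercept = ols(x, y)
        ax.scatter(x, y, color="k")
        xs = np.linspace(x.min(), x.max(), 10)
        ax.plot(xs, slope * xs + intercept, "r-")
        ax.set_xlabel(mech)
        ax.set_ylabel(var)
        ax.set_title(f"{var} = {slope:.4g}·{mech} + {intercept:.4g} (r = {r:.2f})")
    axes.ravel()[-1].axis("off")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
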