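"""QSPR statistics and correlation-derived criterion weights.

The quantitative structure-property relationship (QSPR) stage links a
physicochemical property (e.g. boiling point, enthalpy of vaporization) to
topological indices through simple linear regression: per index we report
the Pearson correlation r and the standard error of estimate of the
y-on-x least-squares fit.

The correlations then become multi-criteria weights by ratio weighting,
``w_i = r_i / sum_j r_j``, and each criterion is classified as beneficial
(to be maximized) or non-beneficial (to be minimized) by comparing its
weight to a threshold.  The default threshold is 0.11; see
``docs/methods.md`` for why it is not 0.10 and how to override the split
per criterion.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    ConstantVectorError,
    InsufficientDataError,
    LengthMismatchError,
    NonPositiveCorrelationError,
)

__all__ = [
    "QsprFit",
    "CriterionSpec",
    "pearson_r",
    "regression_se",
    "fit_indices",
    "ratio_weights",
    "classify_criteria",
    "make_criteria",
    "BENEFICIAL_THRESHOLD",
]

#: Default weight threshold separating beneficial from non-beneficial criteria.
BENEFICIAL_THRESHOLD: float = 0.11


@dataclass(frozen=True)
class QsprFit:
    """Correlation and regression error of one index against one property."""

    index_name: str
    r: float
    se: float

    def __post_init__(self) -> None:
        if abs(self.r) > 1 + 1e-12:
            raise ValueError(f"|r| must be <= 1, got {self.r}")
        if self.se < 0:
            raise ValueError(f"standard error must be >= 0, got {self.se}")


@dataclass(frozen=True)
class CriterionSpec:
    """Weight and orientation of one ranking criterion."""

    name: str
    weight: float
    beneficial: bool

    @property
    def orientation(self) -> str:
        return "beneficial" if self.beneficial else "non_beneficial"


def _paired(x: Sequence[float], y: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.ndim != 1 or ya.ndim != 1:
        raise ValueError("x and y must be one-dimensional")
    if xa.shape[0] != ya.shape[0]:
        raise LengthMismatchError(f"len(x)={xa.shape[0]} != len(y)={ya.shape[0]}")
    return xa, ya


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson product-moment correlation of two paired vectors.

    Requires n >= 3 and non-constant x and y.
    """
    xa, ya = _paired(x, y)
    if xa.shape[0] < 3:
        raise InsufficientDataError("pearson_r needs at least 3 observations")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ConstantVectorError("correlation is undefined for a constant vector")
    return float(stats.pearsonr(xa, ya).statistic)


def regression_se(x: Sequence[float], y: Sequence[float]) -> float:
    """Standard error of estimate of the simple least-squares fit of y on x.

    Computed as sqrt(SSE / (n - 2)), the residual standard deviation with
    two degrees of freedom spent on slope and intercept.
    """
    xa, ya = _paired(x, y)
    n = xa.shape[0]
    if n < 3:
        raise InsufficientDataError("regression_se needs at least 3 observations")
    if np.ptp(xa) == 0:
        raise ConstantVectorError("regression on a constant predictor is undefined")
    fit = stats.linregress(xa, ya)
    residuals = ya - (fit.intercept + fit.slope * xa)
    return float(np.sqrt(np.sum(residuals**2) / (n - 2)))


def fit_indices(
    property_values: Sequence[float] | pd.Series,
    index_values: pd.DataFrame,
) -> pd.DataFrame:
    """Fit one property against every index column.

    Parameters
    ----------
    property_values
        Property per molecule, aligned with the rows of ``index_values``.
    index_values
        Molecules x indices table (e.g. from :func:`toporank.indices.index_table`).

    Returns
    -------
    DataFrame indexed by index name with columns ``r`` and ``se``.
    """
    y = np.asarray(property_values, dtype=float)
    fits = [
        QsprFit(col, pearson_r(index_values[col], y), regression_se(index_values[col], y))
        for col in index_values.columns
    ]
    return pd.DataFrame(
        {"r": [f.r for f in fits], "se": [f.se for f in fits]},
        index=[f.index_name for f in fits],
    )


def ratio_weights(r_values: Mapping[str, float]) -> dict[str, float]:
    """Criterion weights ``w_i = r_i / sum_j r_j`` from positive correlations.

    Raises :class:`NonPositiveCorrelationError` if any r <= 0: the ratio
    scheme presumes every criterion correlates positively with the property.
    """
    if not r_values:
        raise ValueError("r_values is empty")
    for name, r in r_values.items():
        if r <= 0:
            raise NonPositiveCorrelationError(
                f"r({name}) = {r}; ratio weighting needs r > 0"
            )
    total = sum(r_values.values())
    return {name: r / total for name, r in r_values.items()}


def classify_criteria(
    weights: Mapping[str, float], threshold: float = BENEFICIAL_THRESHOLD
) -> dict[str, str]:
    """Label each criterion beneficial (w > threshold) or non-beneficial.

    Weights must sum to 1 (they come from :func:`ratio_weights`).
    """
    total = sum(weights.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"weights must sum to 1, got {total}")
    return {
        name: "beneficial" if w > threshold else "non_beneficial"
        for name, w in weights.items()
    }


def make_criteria(
    r_values: Mapping[str, float],
    threshold: float = BENEFICIAL_THRESHOLD,
    orientation_overrides: Mapping[str, str] | None = None,
) -> list[CriterionSpec]:
    """Build ranking criteria from a correlation vector in one step.

    Runs :func:`ratio_weights` then :func:`classify_criteria`; individual
    orientations can be forced via ``orientation_overrides`` (mapping
    criterion name to ``"beneficial"`` or ``"non_beneficial"``).
    """
    weights = ratio_weights(r_values)
    orientation = classify_criteria(weights, threshold)
    if orientation_overrides:
        unknown = set(orientation_overrides) - set(orientation)
        if unknown:
            raise KeyError(f"overrides for unknown criteria: {sorted(unknown)}")
        orientation.update(orientation_overrides)
    return [
        CriterionSpec(name, weights[name], orientation[name] == "beneficial")
        for name in r_values
    ]
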