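"""Multi-criteria decision making: VIKOR compromise ranking and SAW.

VIKOR evaluates each alternative j by its weighted normalized distances to
the per-criterion ideal points:

    S_j = sum_i w_i (f_i+ - f_ij) / (f_i+ - f_i-)     (Manhattan, group utility)
    R_j = max_i w_i (f_i+ - f_ij) / (f_i+ - f_i-)     (Chebyshev, individual regret)
    Q_j = v (S_j - S+)/(S- - S+) + (1 - v)(R_j - R+)/(R- - R+)

where f_i+ is the column max for beneficial criteria and the column min for
non-beneficial ones (f_i- the opposite), S+ = min_j S_j, S- = max_j S_j and
likewise for R.  Smaller S, R, Q are better; the compromise parameter v
(default 0.5) trades group utility against individual regret.

SAW (simple additive weighting) normalizes the decision matrix per
criterion, multiplies by the weights and sums; higher totals are better
under the default convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from collections.abc import Sequence
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    ConstantCriterionError,
    DegenerateSpreadError,
    ZeroInCriterionError,
)
from .qspr import CriterionSpec

__all__ = [
    "DecisionMatrix",
    "IdealPoints",
    "VikorResult",
    "SawResult",
    "ideal_points",
    "vikor",
    "saw",
    "rank",
]


@dataclass(frozen=True)
class DecisionMatrix:
    """Alternatives x criteria matrix of real criterion values f_ij."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        f = self.frame
        if f.shape[0] < 2:
            raise ValueError("need at least 2 alternatives")
        if f.shape[1] < 1:
            raise ValueError("need at least 1 criterion")
        if f.isna().any().any():
            raise ValueError("decision matrix has missing cells")
        if f.index.has_duplicates or f.columns.has_duplicates:
            raise ValueError("alternative and criterion labels must be unique")
        object.__setattr__(self, "frame", f.astype(float))

    @classmethod
    def from_csv(cls, path: str | Path) -> "DecisionMatrix":
        """Read a matrix CSV: alternatives as rows, criterion names as header."""
        return cls(pd.read_csv(path, index_col=0))

    @property
    def alternatives(self) -> list[str]:
        return list(self.frame.index)

    @property
    def criteria(self) -> list[str]:
        return list(self.frame.columns)


@dataclass(frozen=True)
class IdealPoints:
    """Per-criterion ideal best (f_plus) and ideal worst (f_minus) values."""

    f_plus: pd.Series
    f_minus: pd.Series
    dropped: tuple[str, ...] = ()


@dataclass(frozen=True)
class VikorResult:
    """S, R, Q values and the three rankings for one VIKOR run."""

    s: pd.Series
    r: pd.Series
    q: pd.Series
    rank_s: pd.Series
    rank_r: pd.Series
    rank_q: pd.Series
    v: float
    dropped_criteria: tuple[str, ...] = ()

    @property
    def table(self) -> pd.DataFrame:
        """S, R, Q and the Q-rank, one row per alternative."""
        return pd.DataFrame(
            {"S": self.s, "R": self.r, "Q": self.q, "rank": self.rank_q}
        )

    def ordering(self) -> list[str]:
        """Alternatives from best (rank 1) to worst by Q."""
        return list(self.q.sort_values(kind="stable").index)

    def compromise_report(self) -> dict[str, object]:
        """Standard VIKOR compromise-set check (informational only).

        Reports whether the Q-best alternative has an *acceptable advantage*
        (Q of the runner-up exceeds it by at least 1/(m-1)) and *acceptable
        stability* (it is also best by S or by R), plus the compromise set
        when the advantage condition fails.  Ranks reported elsewhere are
        by Q alone.
        """
        ordered = self.ordering()
        m = len(ordered)
        dq = 1.0 / (m - 1)
        best, runner = ordered[0], ordered[1]
        advantage = (self.q[runner] - self.q[best]) >= dq
        stability = self.rank_s[best] == 1 or self.rank_r[best] == 1
        compromise = [a for a in ordered if self.q[a] - self.q[best] < dq]
        return {
            "best": best,
            "acceptable_advantage": bool(advantage),
            "acceptable_stability": bool(stability),
            "compromise_set": compromise if not advantage else [best],
        }


@dataclass(frozen=True)
class SawResult:
    """Normalized matrix, weighted scores and totals for one SAW run."""

    normalized: pd.DataFrame
    weighted: pd.DataFrame
    totals: pd.Series
    ranks: pd.Series
    rank_direction: str = "desc"
    dropped_criteria: tuple[str, ...] = ()

    @property
    def table(self) -> pd.DataFrame:
        return pd.DataFrame({"total_score": self.totals, "rank": self.ranks})


def _align_specs(
    matrix: DecisionMatrix, specs: Sequence[CriterionSpec]
) -> dict[str, CriterionSpec]:
    by_name = {s.name: s for s in specs}
    missing = set(matrix.criteria) - set(by_name)
    if missing:
        raise ValueError(f"no CriterionSpec for criteria: {sorted(missing)}")
    return by_name


def ideal_points(
    matrix: DecisionMatrix,
    specs: Sequence[CriterionSpec],
    *,
    on_constant: str = "drop",
) -> IdealPoints:
    """Ideal best/worst per criterion given each criterion's orientation.

    Beneficial criteria take f+ = column max and f- = column min;
    non-beneficial criteria the reverse.  A constant column (f+ = f-) is
    dropped with a warning by default (``on_constant="error"`` raises
    :class:`ConstantCriterionError` instead).
    """
    if on_constant not in ("drop", "error"):
        raise ValueError("on_constant must be 'drop' or 'error'")
    by_name = _align_specs(matrix, specs)
    f = matrix.frame
    constant = [c for c in f.columns if f[c].max() == f[c].min()]
    if constant:
        if on_constant == "error":
            raise ConstantCriterionError(
                f"criteria with no spread across alternatives: {constant}"
            )
        warnings.warn(
            f"dropping constant criteria (no spread): {constant}", stacklevel=2
        )
        f = f.drop(columns=constant)
        if f.shape[1] == 0:
            raise ConstantCriterionError("all criteria are constant")
    plus, minus = {}, {}
    for c in f.columns:
        lo, hi = f[c].min(), f[c].max()
        plus[c], minus[c] = (hi, lo) if by_name[c].beneficial else (lo, hi)
    return IdealPoints(pd.Series(plus), pd.Series(minus), tuple(constant))


def rank(scores: Sequence[float] | pd.Series, direction: str = "asc") -> np.ndarray:
    """Competition ranks (1 = best; ties share a rank, next rank skips).

    ``direction="asc"`` ranks the smallest score first, ``"desc"`` the
    largest.  With ties the result follows the 1, 2, 2, 4 convention.
    """
    arr = np.asarray(scores, dtype=float)
    if arr.size == 0:
        raise ValueError("scores is empty")
    if direction == "asc":
        return stats.rankdata(arr, method="min").astype(int)
    if direction == "desc":
        return stats.rankdata(-arr, method="min").astype(int)
    raise ValueError("direction must be 'asc' or 'desc'")


def _ranked(series: pd.Series, direction: str = "asc") -> pd.Series:
    return pd.Series(rank(series.to_numpy(), direction), index=series.index)


def vikor(
    matrix: DecisionMatrix,
    specs: Sequence[CriterionSpec],
    v: float = 0.5,
    *,
    on_constant: str = "drop",
) -> VikorResult:
    """Run the VIKOR compromise ranking.

    Parameters
    ----------
    matrix
        Alternatives x criteria decision matrix.
    specs
        Weight and orientation per criterion; must cover every column.
    v
        Compromise parameter in [0, 1]: weight of group utility S versus
        individual regret R in Q.

    Raises
    ------
    DegenerateSpreadError
        If all alternatives share the same S or the same R, which leaves
        Q undefined (0/0).
    """
    if not 0.0 <= v <= 1.0:
        raise ValueError(f"v must lie in [0, 1], got {v}")
    by_name = _align_specs(matrix, specs)
    ideals = ideal_points(matrix, specs, on_constant=on_constant)
    f = matrix.frame[ideals.f_plus.index]
    w = pd.Series({c: by_name[c].weight for c in f.columns})
    # weighted normalized distance of every cell to its criterion ideal
    d = (ideals.f_plus - f).div(ideals.f_plus - ideals.f_minus, axis=1).mul(w, axis=1)
    s = d.sum(axis=1)
    r = d.max(axis=1)
    s_plus, s_minus = s.min(), s.max()
    r_plus, r_minus = r.min(), r.max()
    if s_plus == s_minus or r_plus == r_minus:
        raise DegenerateSpreadError(
            "no spread in S or R across alternatives; Q is undefined"
        )
    q = v * (s - s_plus) / (s_minus - s_plus) + (1 - v) * (r - r_plus) / (
        r_minus - r_plus
    )
    return VikorResult(
        s=s,
        r=r,
        q=q,
        rank_s=_ranked(s),
        rank_r=_ranked(r),
        rank_q=_ranked(q),
        v=v,
        dropped_criteria=ideals.dropped,
    )


def _normalize_linear_max(col: pd.Series, beneficial: bool) -> pd.Series:
    if beneficial:
        top = col.max()
        if top == 0:
            raise ZeroInCriterionError(f"criterion {col.name!r} has max 0")
        return col / top
    if (col == 0).any():
        raise ZeroInCriterionError(
            f"criterion {col.name!r} contains 0; min/x normalization undefined"
        )
    return col.min() / col


def saw(
    matrix: DecisionMatrix,
    specs: Sequence[CriterionSpec],
    *,
    normalization: str = "linear_max",
    rank_direction: str = "desc",
    on_constant: str = "drop",
) -> SawResult:
    """Simple additive weighting: normalize, weight, sum, rank.

    ``normalization="linear_max"`` (default) maps beneficial criteria to
    f_ij / f_max and non-beneficial ones to f_min / f_ij; ``"minmax"``
    rescales each column to [0, 1] with the orientation folded in.  With
    the defaults a higher total score is better (rank 1 = highest total);
    both conventions are configurable because practice varies.
    """
    if normalization not in ("linear_max", "minmax"):
        raise ValueError("normalization must be 'linear_max' or 'minmax'")
    by_name = _align_specs(matrix, specs)
    f = matrix.frame
    dropped: tuple[str, ...] = ()
    if normalization == "minmax":
        ideals = ideal_points(matrix, specs, on_constant=on_constant)
        f = f[ideals.f_plus.index]
        dropped = ideals.dropped
        norm = (ideals.f_plus - f).div(ideals.f_plus - ideals.f_minus, axis=1)
        norm = 1.0 - norm  # 1 = ideal best, 0 = ideal worst
    else:
        norm = pd.DataFrame(
            {c: _normalize_linear_max(f[c], by_name[c].beneficial) for c in f.columns}
        )
    w = pd.Series({c: by_name[c].weight for c in norm.columns})
    weighted = norm.mul(w, axis=1)
    totals = weighted.sum(axis=1)
    return SawResult(
        normalized=norm,
        weighted=weighted,
        totals=totals,
        ranks=_ranked(totals, rank_direction),
        rank_direction=rank_direction,
        dropped_criteria=dropped,
    )
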