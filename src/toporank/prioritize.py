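"""End-to-end drug prioritization workflows.

Glues the stages together: correlation vector -> ratio weights ->
beneficial/non-beneficial split -> VIKOR (or SAW) ranking of a decision
matrix.  :func:`lung_disorder_case_study` runs the bundled 16-drug panel
under both properties (boiling point and enthalpy of vaporization) and
reports how often the two rankings agree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from collections.abc import Mapping

import pandas as pd

from . import datasets
from .mcdm import DecisionMatrix, SawResult, VikorResult, saw, vikor
from .qspr import BENEFICIAL_THRESHOLD, make_criteria

__all__ = ["prioritize", "CaseStudyReport", "lung_disorder_case_study"]

logger = logging.getLogger(__name__)


def prioritize(
    matrix: DecisionMatrix,
    r_values: Mapping[str, float],
    *,
    method: str = "vikor",
    v: float = 0.5,
    threshold: float = BENEFICIAL_THRESHOLD,
    orientation_overrides: Mapping[str, str] | None = None,
    normalization: str = "linear_max",
    rank_direction: str = "desc",
) -> VikorResult | SawResult:
    """Rank alternatives from a decision matrix and a correlation vector.

    Weights come from ratio weighting of ``r_values``; orientations from the
    weight threshold (overridable per criterion).  ``method`` selects VIKOR
    (compromise parameter ``v``) or SAW (``normalization`` and
    ``rank_direction`` apply).
    """
    specs = make_criteria(r_values, threshold, orientation_overrides)
    beneficial = sorted(s.name for s in specs if s.beneficial)
    logger.info("weights: %s", {s.name: round(s.weight, 6) for s in specs})
    logger.info("beneficial criteria (w > %.3g): %s", threshold, beneficial)
    if method == "vikor":
        return vikor(matrix, specs, v=v)
    if method == "saw":
        return saw(
            matrix, specs, normalization=normalization, rank_direction=rank_direction
        )
    raise ValueError("method must be 'vikor' or 'saw'")


@dataclass(frozen=True)
class CaseStudyReport:
    """Both VIKOR runs of the bundled lung-drug panel and their agreement."""

    bp: VikorResult
    ev: VikorResult
    weights: pd.DataFrame
    orientation: dict[str, str]
    concordant_drugs: tuple[str, ...]

    @property
    def n_concordant(self) -> int:
        """Number of drugs ranked identically under BP and EV."""
        return len(self.concordant_drugs)

    def summary(self) -> pd.DataFrame:
        """One row per drug: S, R, Q and rank under each property."""
        out = pd.concat(
            {"BP": self.bp.table, "EV": self.ev.table}, axis=1
        )
        out[("", "same_rank")] = [
            d in self.concordant_drugs for d in out.index
        ]
        return out


def lung_disorder_case_study(
    v: float = 0.5,
    threshold: float = BENEFICIAL_THRESHOLD,
    weight_assignment: str = "positional",
) -> CaseStudyReport:
    """VIKOR-rank the 16 bundled lung-disorder drugs under BP and EV.

    For each property the index-vs-property correlations are ratio-weighted,
    criteria are split into beneficial/non-beneficial at ``threshold``, and
    VIKOR runs on the bundled index matrix with compromise parameter ``v``.
    The report carries both result tables and the set of drugs whose BP and
    EV ranks coincide.

    ``weight_assignment`` selects how correlations map onto the matrix
    columns: ``"positional"`` (default) reproduces the published ranking,
    which paired the correlation vector with the columns by position;
    ``"by_name"`` matches each correlation to its own index column (see
    ``docs/methods.md`` for why the two differ).
    """
    matrix = datasets.load_lung_drug_indices()
    if weight_assignment == "positional":
        bp_r = datasets.bp_ranking_correlations()
        ev_r = datasets.ev_ranking_correlations()
    elif weight_assignment == "by_name":
        bp_r = datasets.bp_correlations()
        ev_r = datasets.ev_correlations()
    else:
        raise ValueError("weight_assignment must be 'positional' or 'by_name'")
    bp_res = prioritize(matrix, bp_r, v=v, threshold=threshold)
    ev_res = prioritize(matrix, ev_r, v=v, threshold=threshold)
    bp_specs = make_criteria(bp_r, threshold)
    orientation = {s.name: s.orientation for s in bp_specs}
    weights = pd.DataFrame(
        {
            "bp_weight": {s.name: s.weight for s in bp_specs},
            "ev_weight": {s.name: s.weight for s in make_criteria(ev_r, threshold)},
        }
    )
    concordant = tuple(
        drug
        for drug in matrix.alternatives
        if int(bp_res.rank_q[drug]) == int(ev_res.rank_q[drug])
    )
    return CaseStudyReport(
        bp=bp_res,
        ev=ev_res,
        weights=weights,
        orientation=orientation,
        concordant_drugs=concordant,
    )
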