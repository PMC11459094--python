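"""Bundled case-study data: 16 lung-disorder drugs.

The package ships the published inputs of its motivating case study:

* the decision matrix of nine degree-based topological indices for 16
  drugs used against lung disorders (bronchodilators, corticosteroids,
  leukotriene-pathway drugs);
* the Pearson correlations (and regression standard errors) of each index
  against boiling point (BP) and enthalpy of vaporization (EV) for those
  drugs — the raw BP/EV measurements themselves are not distributed, so
  the correlations are data, not derived here;
* the epinephrine molecular graph, its worked edge partition, and its
  SMILES string, used as the reference molecule throughout docs and tests.
"""

from __future__ import annotations

from functools import lru_cache
from importlib.resources import files

import pandas as pd

from .mcdm import DecisionMatrix
from .molgraph import EdgePartition

__all__ = [
    "load_lung_drug_indices",
    "load_property_correlations",
    "bp_correlations",
    "ev_correlations",
    "EPINEPHRINE_SMILES",
    "EPINEPHRINE_EDGES",
    "epinephrine_partition",
]

#: Hydrogen-suppressed epinephrine (adrenaline): catechol ring bearing a
#: beta-hydroxy-N-methyl side chain; 13 heavy atoms, 13 bonds.
EPINEPHRINE_SMILES = "CNCC(O)c1ccc(O)c(O)c1"

#: The same molecule as an explicit bond list over labelled heavy atoms.
EPINEPHRINE_EDGES: tuple[tuple[str, str], ...] = (
    ("C_methyl", "N"),
    ("N", "C_methylene"),
    ("C_methylene", "C_carbinol"),
    ("C_carbinol", "O_hydroxyl"),
    ("C_carbinol", "C1_ring"),
    ("C1_ring", "C2_ring"),
    ("C2_ring", "C3_ring"),
    ("C3_ring", "C4_ring"),
    ("C4_ring", "C5_ring"),
    ("C5_ring", "C6_ring"),
    ("C6_ring", "C1_ring"),
    ("C4_ring", "O_phenol_para"),
    ("C5_ring", "O_phenol_meta"),
)


def epinephrine_partition() -> EdgePartition:
    """Degree-pair edge partition of epinephrine: 13 edges over 5 pairs."""
    return EdgePartition({(1, 2): 1, (1, 3): 3, (2, 2): 2, (2, 3): 5, (3, 3): 2})


def _data_path(name: str):
    return files("toporank.data").joinpath(name)


@lru_cache(maxsize=None)
def _read_csv(name: str, **kwargs) -> pd.DataFrame:
    with _data_path(name).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh, **kwargs)


def load_lung_drug_indices() -> DecisionMatrix:
    """Decision matrix: 16 lung-disorder drugs x 9 topological indices."""
    return DecisionMatrix(_read_csv("lung_drug_indices.csv", index_col=0).copy())


def load_property_correlations() -> pd.DataFrame:
    """Per-index correlation r and regression SE against BP and EV.

    Indexed by index name with columns ``bp_r``, ``bp_se``, ``ev_r``,
    ``ev_se``.  BP standard errors are in kelvin-scale property units,
    EV ones in kJ/mol; r is dimensionless.
    """
    return _read_csv("property_correlations.csv", index_col=0).copy()


def bp_correlations() -> dict[str, float]:
    """Index -> Pearson r against boiling point, ordered as the matrix columns."""
    table = load_property_correlations()["bp_r"]
    return {name: float(table[name]) for name in load_lung_drug_indices().criteria}


def ev_correlations() -> dict[str, float]:
    """Index -> Pearson r against enthalpy of vaporization."""
    table = load_property_correlations()["ev_r"]
    return {name: float(table[name]) for name in load_lung_drug_indices().criteria}


#: Row order of the original correlation tabulation.  The published ranking
#: paired this row order positionally with the decision-matrix column order,
#: so five of the nine criterion columns carry the correlation of a
#: *different* index (e.g. the H column carries the F correlation).
CORRELATION_ROW_ORDER: tuple[str, ...] = (
    "RA", "ABC", "M1", "M2", "SCI", "F", "GA", "H", "HM",
)


def _ranking_assignment(column: str) -> dict[str, float]:
    corr = load_property_correlations()[column]
    columns = load_lung_drug_indices().criteria
    return {
        col: float(corr[row]) for col, row in zip(columns, CORRELATION_ROW_ORDER)
    }


def bp_ranking_correlations() -> dict[str, float]:
    """BP correlations as assigned to the matrix columns in the published ranking.

    The original case study paired the correlation vector with the matrix
    columns by *position* (:data:`CORRELATION_ROW_ORDER` onto the column
    order), not by index name.  Reproducing the published S/R/Q tables
    requires this assignment; use :func:`bp_correlations` for the
    name-matched vector.  See ``docs/methods.md``.
    """
    return _ranking_assignment("bp_r")


def ev_ranking_correlations() -> dict[str, float]:
    """EV correlations under the same positional column assignment."""
    return _ranking_assignment("ev_r")
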