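"""Nine degree-based topological indices.

Each index is a sum over edges of a symmetric function of the endpoint
degrees ``(d_u, d_v)``, so it can be evaluated from a degree-pair edge
partition alone:

=====  ==============================  ===============================
name   index                           per-edge contribution
=====  ==============================  ===============================
RA     Randic (connectivity)           1 / sqrt(d_u d_v)
ABC    atom-bond connectivity          sqrt((d_u + d_v - 2)/(d_u d_v))
M1     first Zagreb                    d_u + d_v
M2     second Zagreb                   d_u d_v
SCI    sum-connectivity                1 / sqrt(d_u + d_v)
F      forgotten                       d_u^2 + d_v^2
GA     geometric-arithmetic            2 sqrt(d_u d_v)/(d_u + d_v)
H      harmonic                        2/(d_u + d_v)
HM     hyper-Zagreb                    (d_u + d_v)^2
=====  ==============================  ===============================

All values are computed in double precision; rounding is left to
presentation.  The ABC contribution of a (1, 1) edge is 0 (sqrt of zero),
which is defined, not an error.
"""

from __future__ import annotations

import math
from enum import Enum
from collections.abc import Mapping

import pandas as pd

from .errors import InvalidDegreeError
from .molgraph import EdgePartition, MolecularGraph, edge_partition

__all__ = [
    "IndexName",
    "INDEX_ORDER",
    "index_contribution",
    "compute_index",
    "compute_all",
    "index_table",
]


class IndexName(str, Enum):
    """Closed enumeration of the supported degree-based indices."""

    RA = "RA"
    ABC = "ABC"
    M1 = "M1"
    M2 = "M2"
    SCI = "SCI"
    F = "F"
    GA = "GA"
    H = "H"
    HM = "HM"


#: Column order used for tabular presentation.
INDEX_ORDER: tuple[IndexName, ...] = (
    IndexName.ABC,
    IndexName.RA,
    IndexName.M1,
    IndexName.M2,
    IndexName.HM,
    IndexName.H,
    IndexName.SCI,
    IndexName.F,
    IndexName.GA,
)

_CONTRIBUTIONS = {
    IndexName.RA: lambda a, b: 1.0 / math.sqrt(a * b),
    IndexName.ABC: lambda a, b: math.sqrt((a + b - 2) / (a * b)),
    IndexName.M1: lambda a, b: float(a + b),
    IndexName.M2: lambda a, b: float(a * b),
    IndexName.SCI: lambda a, b: 1.0 / math.sqrt(a + b),
    IndexName.F: lambda a, b: float(a * a + b * b),
    IndexName.GA: lambda a, b: 2.0 * math.sqrt(a * b) / (a + b),
    IndexName.H: lambda a, b: 2.0 / (a + b),
    IndexName.HM: lambda a, b: float((a + b) ** 2),
}


def _check_degree(d: object) -> int:
    if isinstance(d, bool) or not isinstance(d, int):
        raise InvalidDegreeError(f"degree {d!r} is not an integer")
    if d < 1:
        raise InvalidDegreeError(f"degree {d} must be >= 1")
    return d


def index_contribution(name: IndexName | str, a: int, b: int) -> float:
    """Per-edge term of index *name* for an edge with endpoint degrees (a, b).

    Symmetric in (a, b); degrees must be positive integers.
    """
    return _CONTRIBUTIONS[IndexName(name)](_check_degree(a), _check_degree(b))


def _as_partition(source: EdgePartition | MolecularGraph) -> EdgePartition:
    if isinstance(source, MolecularGraph):
        return edge_partition(source)
    return source


def compute_index(
    source: EdgePartition | MolecularGraph, name: IndexName | str
) -> float:
    """Evaluate one index as the count-weighted sum over degree pairs.

    Accepts either an :class:`EdgePartition` or a :class:`MolecularGraph`
    (reduced to its partition first).  An empty partition yields 0.
    """
    f = _CONTRIBUTIONS[IndexName(name)]
    return sum(
        count * f(_check_degree(a), _check_degree(b))
        for (a, b), count in _as_partition(source).items()
    )


def compute_all(
    source: EdgePartition | MolecularGraph,
) -> dict[IndexName, float]:
    """All nine indices at once; identical to nine :func:`compute_index` calls."""
    partition = _as_partition(source)
    return {name: compute_index(partition, name) for name in IndexName}


def index_table(
    molecules: Mapping[str, EdgePartition | MolecularGraph],
) -> pd.DataFrame:
    """Index values for a named collection of molecules.

    Returns a DataFrame with one row per molecule and the nine indices as
    columns in :data:`INDEX_ORDER`.
    """
    rows = {
        label: {n.value: v for n, v in compute_all(source).items()}
        for label, source in molecules.items()
    }
    frame = pd.DataFrame.from_dict(rows, orient="index")
    return frame[[n.value for n in INDEX_ORDER]]
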