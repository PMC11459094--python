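"""Exception hierarchy for toporank.

All package-specific errors derive from :class:`TopoRankError` so callers can
catch a single base class at CLI or pipeline boundaries.
"""


class TopoRankError(Exception):
    """Base class for all toporank errors."""


# --- molecular graph construction -------------------------------------------

class GraphError(TopoRankError):
    """Invalid molecular graph input."""


class EmptyInputError(GraphError):
    """No edges (or no atoms) were supplied."""


class SelfLoopError(GraphError):
    """An edge joins a vertex to itself."""


class DuplicateEdgeError(GraphError):
    """The same unordered vertex pair appears more than once."""


class DisconnectedGraphError(GraphError):
    """The graph has more than one connected component."""


class SmilesParseError(GraphError):
    """A SMILES string could not be parsed."""


# --- indices ----------------------------------------------------------------

class InvalidDegreeError(TopoRankError):
    """A degree value is not a positive integer."""


# --- statistics / weighting -------------------------------------------------

class LengthMismatchError(TopoRankError):
    """Paired vectors have different lengths."""


class ConstantVectorError(TopoRankError):
    """A vector is constant where variation is required."""


class InsufficientDataError(TopoRankError):
    """Too few observations for the requested statistic."""


class NonPositiveCorrelationError(TopoRankError):
    """Ratio weighting requires strictly positive correlations."""


# --- multi-criteria ranking -------------------------------------------------

class ConstantCriterionError(TopoRankError):
    """A criterion takes the same value for every alternative."""


class DegenerateSpreadError(TopoRankError):
    """All alternatives share the same S (or R); the compromise index Q is undefined."""


class ZeroInCriterionError(TopoRankError):
    """Ratio normalization hit a zero denominator."""


# --- synthetic data ---------------------------------------------------------

class InfeasibleConfigError(TopoRankError):
    """Requested synthetic graph parameters admit no valid graph."""
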