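import numpy as np
import pandas as pd
import pytest

from toporank.molgraph import EdgePartition

# Printed reference values for the bundled 16-drug case study:
# S, R, Q and rank per drug under each property's correlation weights.
_BP_ROWS = [
    ("Prednisone", 0.527392105, 0.071511068, 0.397714246, 10),
    ("Methylprednisolone", 0.520804376, 0.067757243, 0.362124907, 7),
    ("Prednisolone", 0.54296303, 0.068162602, 0.404753247, 11),
    ("Epinephrine", 0.638243902, 0.135219512, 1.0, 16),
    ("Salbutamol", 0.601727818, 0.119077899, 0.832156082, 13),
    ("Levosalbutamol", 0.618575117, 0.127336402, 0.914710696, 15),
    ("Fluticasone", 0.509280745, 0.072783795, 0.372989036, 8),
    ("Salmeterol", 0.361888448, 0.05594497, 0.000239342, 1),
    ("Flunisolide", 0.464835707, 0.060075513, 0.212461108, 3),
    ("Ciclesonide", 0.361756098, 0.102243902, 0.292016399, 4),
    ("Mometasone", 0.450132572, 0.090690919, 0.378969321, 9),
    ("Vilanterol", 0.394635128, 0.069542256, 0.145219109, 2),
    ("Formoterol", 0.464735555, 0.073336968, 0.295922571, 5),
    ("Beclometasone", 0.423257793, 0.092423867, 0.341299062, 6),
    ("Montelukast", 0.519858807, 0.093927028, 0.52547288, 12),
    ("Zileuton", 0.605031291, 0.119453293, 0.840497758, 14),
]

_EV_ROWS = [
    ("Prednisone", 0.528974263, 0.064658425, 0.426815195, 6),
    ("Methylprednisolone", 0.524923022, 0.061264316, 0.393204055, 5),
    ("Prednisolone", 0.554421627, 0.07495934, 0.556502937, 11),
    ("Epinephrine", 0.599036818, 0.122261923, 1.0, 16),
    ("Salbutamol", 0.571980933, 0.107667101, 0.835191937, 13),
    ("Levosalbutamol", 0.584089984, 0.115134223, 0.915864042, 15),
    ("Fluticasone", 0.524607346, 0.078010011, 0.516302268, 9),
    ("Salmeterol", 0.361462583, 0.054609429, 0.0, 1),
    ("Flunisolide", 0.472049044, 0.063165896, 0.295979225, 3),
    ("Ciclesonide", 0.400963182, 0.107503495, 0.474057902, 7),
    ("Mometasone", 0.479851685, 0.097621467, 0.567051853, 12),
    ("Vilanterol", 0.384906253, 0.067882115, 0.147434254, 2),
    ("Formoterol", 0.454388706, 0.071586238, 0.321043495, 4),
    ("Beclometasone", 0.455272446, 0.097178301, 0.512046946, 8),
    ("Montelukast", 0.498069192, 0.08745275, 0.530238473, 10),
    ("Zileuton", 0.575119521, 0.108659305, 0.849130515, 14),
]


def _frame(rows):
    frame = pd.DataFrame(rows, columns=["drug", "S", "R", "Q", "rank"])
    return frame.set_index("drug")


@pytest.fixture(scope="session")
def bp_reference() -> pd.DataFrame:
    return _frame(_BP_ROWS)


@pytest.fixture(scope="session")
def ev_reference() -> pd.DataFrame:
    return _frame(_EV_ROWS)


@pytest.fixture(scope="session")
def epinephrine_expected() -> dict[str, float]:
    """Reference index values for the epinephrine row of the bundled matrix."""
    return {
        "ABC": 9.439677,
        "RA": 6.147066,
        "M1": 60.0,
        "M2": 67.0,
        "HM": 286.0,
        "H": 5.833333,
        "SCI": 6.129915,
        "F": 152.0,
        "GA": 12.43986,
    }


@pytest.fixture
def epinephrine_partition() -> EdgePartition:
    return EdgePartition({(1, 2): 1, (1, 3): 3, (2, 2): 2, (2, 3): 5, (3, 3): 2})


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240924)
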