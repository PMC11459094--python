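"""VIKOR and SAW rankings: examples, invariants, and a brute-force oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from toporank.errors import (
    ConstantCriterionError,
    DegenerateSpreadError,
    ZeroInCriterionError,
)
from toporank.mcdm import DecisionMatrix, ideal_points, rank, saw, vikor
from toporank.qspr import CriterionSpec


def _matrix(values, alternatives=None, criteria=None):
    values = np.asarray(values, dtype=float)
    alternatives = alternatives or [f"alt{i}" for i in range(values.shape[0])]
    criteria = criteria or [f"c{i}" for i in range(values.shape[1])]
    return DecisionMatrix(pd.DataFrame(values, index=alternatives, columns=criteria))


def _specs(weights, beneficial):
    return [
        CriterionSpec(f"c{i}", w, ben)
        for i, (w, ben) in enumerate(zip(weights, beneficial))
    ]


def brute_force_vikor(values, weights, beneficial, v=0.5):
    """Independent direct-summation oracle with explicit loops."""
    values = np.asarray(values, dtype=float)
    m, n = values.shape
    s = np.zeros(m)
    r = np.zeros(m)
    for j in range(m):
        terms = []
        for i in range(n):
            col = values[:, i]
            f_plus = col.max() if beneficial[i] else col.min()
            f_minus = col.min() if beneficial[i] else col.max()
            terms.append(weights[i] * (f_plus - values[j, i]) / (f_plus - f_minus))
        s[j] = sum(terms)
        r[j] = max(terms)
    q = v * (s - s.min()) / (s.max() - s.min()) + (1 - v) * (r - r.min()) / (
        r.max() - r.min()
    )
    return s, r, q


class TestIdealPoints:
    def test_beneficial_takes_max(self):
        ip = ideal_points(_matrix([[1], [5], [3]]), _specs([1.0], [True]))
        assert ip.f_plus["c0"] == 5 and ip.f_minus["c0"] == 1

    def test_non_beneficial_takes_min(self):
        ip = ideal_points(_matrix([[1], [5], [3]]), _specs([1.0], [False]))
        assert ip.f_plus["c0"] == 1 and ip.f_minus["c0"] == 5

    def test_constant_criterion_dropped_with_warning(self):
        matrix = _matrix([[1, 7], [2, 7]])
        with pytest.warns(UserWarning, match="constant"):
            ip = ideal_points(matrix, _specs([0.5, 0.5], [True, True]))
        assert ip.dropped == ("c1",)
        with pytest.raises(ConstantCriterionError):
            ideal_points(matrix, _specs([0.5, 0.5], [True, True]), on_constant="error")


class TestRank:
    @pytest.mark.parametrize(
        "scores,direction,expected",
        [
            ([0.3, 0.1, 0.2], "asc", [3, 1, 2]),
            ([5, 5, 1], "asc", [2, 2, 1]),
            ([2, 4], "desc", [2, 1]),
            ([1, 1, 1], "asc", [1, 1, 1]),
        ],
    )
    def test_competition_ranking(self, scores, direction, expected):
        assert rank(scores, direction).tolist() == expected


class TestVikor:
    def test_two_alternative_endpoints(self):
        result = vikor(_matrix([[1], [0]]), _specs([1.0], [True]))
        assert result.s.tolist() == [0.0, 1.0]
        assert result.r.tolist() == [0.0, 1.0]
        assert result.q.tolist() == [0.0, 1.0]
        assert result.rank_q.tolist() == [1, 2]

    def test_q_in_unit_interval_and_extremes(self, rng):
        values = rng.uniform(0, 10, size=(8, 4))
        result = vikor(_matrix(values), _specs([0.3, 0.3, 0.2, 0.2], [True, True, False, False]))
        assert ((result.q >= 0) & (result.q <= 1)).all()
        assert result.q.min() == 0.0 or result.q.min() == pytest.approx(0.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_matches_brute_force_oracle(self, seed):
        gen = np.random.default_rng(seed)
        values = gen.uniform(1, 100, size=(4, 3))
        weights = gen.dirichlet(np.ones(3))
        beneficial = gen.random(3) < 0.5
        s_exp, r_exp, q_exp = brute_force_vikor(values, weights, beneficial)
        result = vikor(_matrix(values), _specs(weights, beneficial))
        np.testing.assert_allclose(result.s.to_numpy(), s_exp, atol=1e-12)
        np.testing.assert_allclose(result.r.to_numpy(), r_exp, atol=1e-12)
        np.testing.assert_allclose(result.q.to_numpy(), q_exp, atol=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1), a=st.floats(0.1, 50), b=st.floats(-100, 100))
    def test_per_criterion_affine_invariance(self, seed, a, b):
        """Replacing one criterion column by a*f + b (a > 0) leaves S, R, Q
        unchanged: the normalized distances are scale- and shift-free."""
        gen = np.random.default_rng(seed)
        values = gen.uniform(1, 100, size=(5, 3))
        specs = _specs(gen.dirichlet(np.ones(3)), [True, False, True])
        base = vikor(_matrix(values), specs)
        transformed = values.copy()
        transformed[:, 1] = a * transformed[:, 1] + b
        alt = vikor(_matrix(transformed), specs)
        np.testing.assert_allclose(base.s, alt.s, atol=1e-9)
        np.testing.assert_allclose(base.r, alt.r, atol=1e-9)
        np.testing.assert_allclose(base.q, alt.q, atol=1e-9)

    def test_v_extremes_match_s_and_r_rankings(self, rng):
        values = rng.uniform(0, 1, size=(7, 4))
        specs = _specs(rng.dirichlet(np.ones(4)), [True, True, True, False])
        matrix = _matrix(values)
        only_s = vikor(matrix, specs, v=1.0)
        only_r = vikor(matrix, specs, v=0.0)
        assert only_s.rank_q.tolist() == only_s.rank_s.tolist()
        assert only_r.rank_q.tolist() == only_r.rank_r.tolist()

    def test_r_bounded_by_max_weight_and_s_in_unit_interval(self, rng):
        weights = rng.dirichlet(np.ones(5))
        result = vikor(
            _matrix(rng.uniform(0, 9, size=(6, 5))),
            _specs(weights, [True, False, True, False, True]),
        )
        assert (result.r <= weights.max() + 1e-12).all()
        assert ((result.s >= -1e-12) & (result.s <= 1 + 1e-12)).all()

    def test_degenerate_spread_raises(self):
        # perfectly symmetric alternatives: every S (and R) is identical
        with pytest.raises(DegenerateSpreadError):
            vikor(_matrix([[1, 2], [2, 1]]), _specs([0.5, 0.5], [True, True]))

    def test_all_constant_criteria_raises(self):
        with pytest.warns(UserWarning):
            with pytest.raises(ConstantCriterionError):
                vikor(
                    _matrix([[1, 2], [1, 2], [1, 2]]),
                    _specs([0.5, 0.5], [True, True]),
                )

    def test_compromise_report_structure(self, rng):
        result = vikor(
            _matrix(rng.uniform(0, 1, size=(5, 3))),
            _specs([0.4, 0.3, 0.3], [True, True, False]),
        )
        report = result.compromise_report()
        assert report["best"] == result.ordering()[0]
        assert isinstance(report["acceptable_advantage"], bool)
        assert report["best"] in report["compromise_set"]


class TestSaw:
    def test_single_beneficial_criterion_linear_max(self):
        result = saw(_matrix([[2], [4]]), _specs([1.0], [True]))
        assert result.totals.tolist() == [0.5, 1.0]
        assert result.ranks.tolist() == [2, 1]

    def test_additivity_over_identical_criteria(self):
        values = np.array([[2.0], [4.0], [5.0]])
        single = saw(_matrix(values), _specs([1.0], [True]))
        triple = saw(
            _matrix(np.repeat(values, 3, axis=1)),
            _specs([1.0, 1.0, 1.0], [True, True, True]),
        )
        np.testing.assert_allclose(triple.totals, 3 * single.totals)

    def test_non_beneficial_inversion(self):
        result = saw(_matrix([[2], [4]]), _specs([1.0], [False]))
        assert result.totals.tolist() == [1.0, 0.5]
        assert result.ranks.tolist() == [1, 2]

    def test_zero_in_non_beneficial_column_raises(self):
        with pytest.raises(ZeroInCriterionError):
            saw(_matrix([[0], [4]]), _specs([1.0], [False]))

    def test_minmax_normalization_bounds(self, rng):
        result = saw(
            _matrix(rng.uniform(0, 10, size=(6, 3))),
            _specs([0.5, 0.3, 0.2], [True, False, True]),
            normalization="minmax",
        )
        assert ((result.normalized >= 0) & (result.normalized <= 1)).all().all()

    def test_rank_direction_flips_order(self, rng):
        matrix = _matrix(rng.uniform(1, 10, size=(5, 2)))
        specs = _specs([0.6, 0.4], [True, False])
        desc = saw(matrix, specs, rank_direction="desc")
        asc = saw(matrix, specs, rank_direction="asc")
        assert desc.ranks.idxmin() == asc.ranks.idxmax()


class TestDecisionMatrix:
    def test_validation(self):
        with pytest.raises(ValueError):
            DecisionMatrix(pd.DataFrame({"a": [1.0]}))  # one alternative
        with pytest.raises(ValueError):
            DecisionMatrix(pd.DataFrame({"a": [1.0, np.nan]}))

    def test_from_csv_roundtrip(self, tmp_path):
        frame = pd.DataFrame(
            [[1.0, 2.0], [3.0, 4.0]], index=["x", "y"], columns=["c0", "c1"]
        )
        path = tmp_path / "m.csv"
        frame.to_csv(path)
        loaded = DecisionMatrix.from_csv(path)
        assert loaded.alternatives == ["x", "y"]
        pd.testing.assert_frame_equal(loaded.frame, frame)
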