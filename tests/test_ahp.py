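"""AHP core: matrix validation, eigenvector priorities, consistency,
expert aggregation and hierarchy composition."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sarcostage.ahp import (
    Hierarchy,
    Node,
    RANDOM_INDEX,
    aggregate_experts,
    compose_hierarchy,
    priority_vector,
    row_geometric_mean,
    validate_matrix,
)
from sarcostage.exceptions import InputValidationError
from sarcostage.expert_fixtures import fixture_expert_matrices, fixture_hierarchy


def random_reciprocal(rng, n):
    a = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a[i, j] = np.exp(rng.uniform(-np.log(9), np.log(9)))
            a[j, i] = 1 / a[i, j]
    return a


def test_validate_matrix_accepts_identity():
    assert validate_matrix(np.ones((3, 3))).shape == (3, 3)


@pytest.mark.parametrize(
    "matrix, message",
    [
        ([[1, 2], [0.4, 1]], "reciprocity"),
        ([[1, 2, 3], [0.5, 1, 2]], "square"),
        ([[1]], "order"),
        ([[1, -2], [-0.5, 1]], "positive"),
        ([[2, 2], [0.5, 1]], "diagonal"),
    ],
)
def test_validate_matrix_rejections(matrix, message):
    with pytest.raises(InputValidationError, match=message):
        validate_matrix(matrix)


def test_saaty_scale_enforcement_for_raw_experts():
    m = [[1, 2.37], [1 / 2.37, 1]]
    validate_matrix(m)  # aggregates may be any positive reals
    with pytest.raises(InputValidationError, match="Saaty"):
        validate_matrix(m, require_saaty=True)


def test_priority_all_ones():
    res = priority_vector(np.ones((3, 3)))
    assert res.weights == pytest.approx([1 / 3] * 3, abs=1e-12)
    assert res.lambda_max == pytest.approx(3.0, abs=1e-10)
    assert res.consistency_ratio == pytest.approx(0.0, abs=1e-10)


def test_priority_consistent_matrix_closed_form():
    """Consistent a_ij = w_i/w_j gives weights proportional to any column."""
    m = [[1, 2, 4], [0.5, 1, 2], [0.25, 0.5, 1]]
    res = priority_vector(m)
    assert res.weights == pytest.approx([4 / 7, 2 / 7, 1 / 7], abs=1e-10)
    assert res.lambda_max == pytest.approx(3.0, abs=1e-10)
    assert res.consistency_ratio == pytest.approx(0.0, abs=1e-10)


@pytest.mark.parametrize("n", [3, 4, 5, 6, 7])
def test_priority_matches_eigendecomposition_oracle(n, rng):
    a = random_reciprocal(rng, n)
    res = priority_vector(a)
    vals, vecs = np.linalg.eig(a)
    k = np.argmax(vals.real)
    w = np.abs(vecs[:, k].real)
    w = w / w.sum()
    assert res.weights == pytest.approx(w, abs=1e-8)
    assert res.lambda_max == pytest.approx(float(vals[k].real), abs=1e-8)
    assert res.lambda_max >= n - 1e-9  # lambda_max >= n for reciprocal matrices


@pytest.mark.parametrize("n", [3, 5, 7])
def test_priority_invariant_under_permutation(n, rng):
    a = random_reciprocal(rng, n)
    perm = rng.permutation(n)
    res = priority_vector(a)
    res_p = priority_vector(a[np.ix_(perm, perm)])
    assert res_p.weights == pytest.approx(res.weights[perm], abs=1e-9)
    assert res_p.lambda_max == pytest.approx(res.lambda_max, abs=1e-9)


def test_row_geometric_mean_cross_check(rng):
    """For near-consistent matrices the two priority methods agree closely."""
    a = np.array([[1, 2, 4], [0.5, 1, 2], [0.25, 0.5, 1]])
    assert row_geometric_mean(a) == pytest.approx(priority_vector(a).weights, abs=1e-10)


def test_weights_normalised(rng):
    res = priority_vector(random_reciprocal(rng, 6))
    assert res.weights.sum() == pytest.approx(1.0, abs=1e-12)
    assert np.all(res.weights >= 0)


def test_aggregate_single_and_identical_matrices():
    m = np.array([[1, 3], [1 / 3, 1]])
    assert aggregate_experts([m]) == pytest.approx(m)
    assert aggregate_experts([m] * 10) == pytest.approx(m)


def test_aggregate_matrix_with_its_reciprocal_partner():
    m = np.array([[1, 5], [0.2, 1]])
    agg = aggregate_experts([m, m.T])  # transpose = entry-wise reciprocal
    assert agg == pytest.approx(np.ones((2, 2)), abs=1e-12)


def test_aggregate_mixed_orders_rejected():
    with pytest.raises(InputValidationError):
        aggregate_experts([np.ones((3, 3)), np.ones((4, 4))])


@given(st.integers(0, 2**31 - 1), st.integers(3, 7))
def test_aggregation_preserves_reciprocity(seed, n):
    rng = np.random.default_rng(seed)
    ms = [random_reciprocal(rng, n) for _ in range(3)]
    agg = aggregate_experts(ms)
    assert np.max(np.abs(agg * agg.T - 1)) < 1e-12


def test_random_index_table_pinned():
    assert RANDOM_INDEX == (0.0, 0.0, 0.58, 0.90, 1.12, 1.24, 1.32, 1.41, 1.45, 1.49)


# ---------------------------------------------------------------------------
# hierarchy composition


def test_single_child_chain_gives_leaf_weight_one():
    h = Hierarchy(
        dimensions=[Node("dim", children=[Node("mid", local_weight=1.0,
                                               children=[Node("leaf", local_weight=1.0)])])]
    )
    assert compose_hierarchy(h) == {"dim": {"leaf": 1.0}}


def test_canonical_self_care_leaf_weight():
    """Self-care local x postural local reproduces the within-dimension
    leaf weight back-computed from the published composites."""
    from sarcostage.expert_fixtures import canonical_hierarchy

    weights = compose_hierarchy(canonical_hierarchy())
    # 0.5543 x 0.1495 = 0.0829 (= stage A postural 0.058 / 0.70), to 3 s.f.
    assert weights["physiological"]["postural_transition"] == pytest.approx(0.0829, abs=5e-4)
    for dim_weights in weights.values():
        assert sum(dim_weights.values()) == pytest.approx(1.0, abs=1e-9)


def test_hierarchy_rejects_bad_sibling_weights():
    h = Hierarchy(
        dimensions=[Node("d", children=[Node("a", local_weight=0.7), Node("b", local_weight=0.2)])]
    )
    with pytest.raises(InputValidationError, match="sum"):
        compose_hierarchy(h)


def test_hierarchy_json_round_trip():
    d = {
        "dimensions": [
            {"name": "d", "children": [
                {"name": "x", "local_weight": 0.25},
                {"name": "y", "local_weight": 0.75},
            ]},
            {"name": "e", "children": [
                {"name": "u"}, {"name": "v"}, {"name": "w"},
            ], "matrix": [[1, 1, 1], [1, 1, 1], [1, 1, 1]]},
        ]
    }
    weights = compose_hierarchy(Hierarchy.from_dict(d))
    assert weights["d"] == pytest.approx({"x": 0.25, "y": 0.75})
    assert weights["e"]["u"] == pytest.approx(1 / 3, abs=1e-9)


def test_fixture_experts_aggregate_below_cr_threshold():
    """Synthetic expert panels stay within the 0.1 consistency bound at
    every hierarchy level, and the fixture hierarchy has 14 leaves."""
    for level, ms in fixture_expert_matrices().items():
        for m in ms:
            validate_matrix(m, require_saaty=True)
        res = priority_vector(aggregate_experts(ms))
        assert res.consistency_ratio < 0.1, level
    h = fixture_hierarchy()
    assert len(h.leaves()) == 14
    weights = compose_hierarchy(h)
    for dim_weights in weights.values():
        assert sum(dim_weights.values()) == pytest.approx(1.0, abs=1e-9)
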