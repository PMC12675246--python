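"""Dynamic weighting, composite-weight reproduction, rating and grading."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sarcostage.exceptions import InputValidationError, RatingError
from sarcostage.staging import Stage
from sarcostage.stratification import (
    ALL_LEAVES,
    Grade,
    IndicatorRatings,
    InstrumentPanel,
    LOCAL_WEIGHTS,
    RatingBands,
    compose_stage_weights,
    dimension_weights,
    grade_for_score,
    intervention_score,
    rate_indicators,
)


@pytest.mark.parametrize(
    "stage, triple",
    [
        (Stage.A, (0.70, 0.20, 0.10)),
        (Stage.B, (0.65, 0.25, 0.10)),
        (Stage.C, (0.60, 0.30, 0.10)),
        (Stage.D, (0.55, 0.35, 0.10)),
    ],
)
def test_dimension_weights_table(stage, triple):
    w = dimension_weights(stage)
    assert w == triple
    assert sum(w) == pytest.approx(1.0)
    assert w[2] == 0.10  # external fixed at 10% throughout


def test_dimension_weights_unknown_stage():
    with pytest.raises(InputValidationError):
        dimension_weights("E")


@pytest.mark.parametrize(
    "leaf, stage, printed",
    [
        ("musculoskeletal_deterioration", Stage.B, 0.209),
        ("sports_anxiety", Stage.D, 0.189),
        ("familial_support", Stage.A, 0.075),
        ("familial_support", Stage.D, 0.075),
        ("activity_radius", Stage.C, 0.074),
    ],
)
def test_composite_weight_spot_cells(leaf, stage, printed):
    cw = compose_stage_weights(stage=stage)
    assert cw.rounded()[leaf] == printed


def test_composite_weights_sum_to_one():
    for stage in Stage:
        cw = compose_stage_weights(stage=stage)
        assert sum(cw.weights.values()) == pytest.approx(1.0, abs=1e-12)


def test_compose_rejects_bad_locals():
    bad = dict(LOCAL_WEIGHTS)
    bad["sports_anxiety"] += 0.2
    with pytest.raises(InputValidationError):
        compose_stage_weights(bad, Stage.A)
    with pytest.raises(InputValidationError, match="missing"):
        compose_stage_weights({"sports_anxiety": 1.0}, Stage.A)


def test_global_rank_stage_a():
    """Stage A ordering: self-care block first, then musculoskeletal,
    anxiety, activity radius, familial support."""
    ranks = compose_stage_weights(stage=Stage.A).global_rank()
    assert ranks["postural_transition"] == 1
    assert ranks["musculoskeletal_deterioration"] == 2
    assert ranks["sports_anxiety"] == 3
    assert ranks["activity_radius"] == 4
    assert ranks["familial_support"] == 5


# ---------------------------------------------------------------------------
# ratings


def _best_panel():
    return InstrumentPanel(sarcf=0, adl_independence=100, fesi=16, hads=0, gses=40, ses_total=9)


def _worst_panel():
    return InstrumentPanel(sarcf=10, adl_independence=0, fesi=64, hads=42, gses=10, ses_total=3)


def test_rate_indicators_extremes():
    best = rate_indicators(_best_panel(), Stage.A)
    assert set(best.ratings.values()) == {1}
    worst = rate_indicators(_worst_panel(), Stage.D)
    assert set(worst.ratings.values()) == {4}


def test_fesi_boundaries_map_to_higher_severity():
    """Sweep the full FES-I range: rating steps exactly at each cut-point."""
    bands = RatingBands((20, 28, 39))
    for v in range(16, 65):
        expected = 1 + sum(v >= c for c in (20, 28, 39))
        assert bands.rate(v) == expected
    # and through the full panel path
    p = _best_panel()
    for cut, expected in [(20, 2), (28, 3), (39, 4)]:
        panel = InstrumentPanel(p.sarcf, p.adl_independence, cut, p.hads, p.gses, p.ses_total)
        assert rate_indicators(panel, Stage.A).ratings["sports_anxiety"] == expected


def test_rating_monotone_for_reversed_instruments():
    bands = RatingBands((18, 25, 30), higher_is_worse=False)
    values = [bands.rate(v) for v in range(10, 41)]
    assert values == sorted(values, reverse=True)
    assert bands.rate(40) == 1 and bands.rate(10) == 4


def test_rate_indicators_range_errors():
    p = _best_panel()
    with pytest.raises(RatingError, match="sarcf"):
        rate_indicators(
            InstrumentPanel(11, p.adl_independence, p.fesi, p.hads, p.gses, p.ses_total), Stage.A
        )


def test_indicator_ratings_validation():
    with pytest.raises(RatingError, match="unrated"):
        IndicatorRatings(stage=Stage.A, ratings={"sports_anxiety": 1})
    with pytest.raises(RatingError, match="not in 1..4"):
        IndicatorRatings(stage=Stage.A, ratings={leaf: 5 for leaf in ALL_LEAVES})


# ---------------------------------------------------------------------------
# intervention score


def _ratings(value, stage=Stage.A):
    return IndicatorRatings(stage=stage, ratings={leaf: value for leaf in ALL_LEAVES})


@pytest.mark.parametrize(
    "value, expected_grade", [(1, Grade.I), (2, Grade.II), (3, Grade.II), (4, Grade.III)]
)
def test_uniform_ratings_score_and_grade(value, expected_grade):
    for stage in Stage:
        cw = compose_stage_weights(stage=stage)
        res = intervention_score(_ratings(value, stage), cw)
        # normalised locals make the weights sum exactly to 1
        assert res.total_score == pytest.approx(float(value), abs=1e-12)
        assert res.grade == expected_grade


def test_grade_boundaries():
    assert grade_for_score(1.999) == Grade.I
    assert grade_for_score(2.0) == Grade.II  # "less than 2" -> boundary is II
    assert grade_for_score(3.2) == Grade.II  # "between 2 and 3.2" inclusive
    assert grade_for_score(3.2000001) == Grade.III


def test_intervention_score_dot_product_oracle(rng):
    cw = compose_stage_weights(stage=Stage.A)
    values = {leaf: int(r) for leaf, r in zip(ALL_LEAVES, rng.integers(1, 5, len(ALL_LEAVES)))}
    res = intervention_score(IndicatorRatings(stage=Stage.A, ratings=values), cw)
    hand_sum = 0.0
    for leaf in ALL_LEAVES:
        hand_sum += values[leaf] * cw.weights[leaf]
    assert res.total_score == pytest.approx(hand_sum, abs=1e-12)


def test_stage_mismatch_rejected():
    cw = compose_stage_weights(stage=Stage.B)
    with pytest.raises(InputValidationError, match="stage"):
        intervention_score(_ratings(2, Stage.A), cw)


@given(
    st.lists(st.integers(1, 4), min_size=14, max_size=14),
    st.sampled_from(list(Stage)),
    st.integers(0, 13),
)
def test_raising_one_rating_never_decreases_score(values, stage, idx):
    cw = compose_stage_weights(stage=stage)
    ratings = dict(zip(ALL_LEAVES, values))
    base = intervention_score(IndicatorRatings(stage=stage, ratings=ratings), cw).total_score
    leaf = ALL_LEAVES[idx]
    if ratings[leaf] < 4:
        ratings[leaf] += 1
        raised = intervention_score(IndicatorRatings(stage=stage, ratings=ratings), cw).total_score
        assert raised >= base


@given(st.lists(st.integers(1, 4), min_size=14, max_size=14))
def test_score_bounds_and_grade_monotonicity(values):
    ratings = dict(zip(ALL_LEAVES, values))
    scores = []
    for stage in Stage:
        cw = compose_stage_weights(stage=stage)
        res = intervention_score(IndicatorRatings(stage=stage, ratings=ratings), cw)
        assert 1.0 - 1e-9 <= res.total_score <= 4.0 + 1e-9
        scores.append(res.total_score)
    # psychological ratings above physiological ones => score grows A -> D
    psych = np.mean([ratings[l] for l in ("sports_anxiety", "social_engagement", "self_efficacy")])
    phys = np.max(
        [ratings[l] for l in ALL_LEAVES if l not in (
            "sports_anxiety", "social_engagement", "self_efficacy",
            "familial_support", "financial_capacity")]
    )
    if min(ratings["sports_anxiety"], ratings["social_engagement"], ratings["self_efficacy"]) > phys:
        assert all(a <= b + 1e-12 for a, b in zip(scores, scores[1:]))
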