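"""Dynamic weighting and tiered intervention grading.

The evaluation hierarchy has three dimensions whose weights shift with the
progression stage while external factors stay fixed at 10%:

=======  =============  =============  ========
stage    physiological  psychological  external
=======  =============  =============  ========
A        0.70           0.20           0.10
B        0.65           0.25           0.10
C        0.60           0.30           0.10
D        0.55           0.35           0.10
=======  =============  =============  ========

Within each dimension the 14 leaf indicators carry stage-invariant local
weights; a leaf's composite weight is ``local x dimension weight``.  Each
leaf is rated 1-4 from a mapped clinical instrument (SARC-F, ADL, FES-I,
HADS, GSES, SES) and the total intervention score is the weighted sum
``sum(rating x composite weight)``, mapped to Grade I (< 2), II (2 to 3.2,
both ends inclusive) or III (> 3.2).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping

from .exceptions import InputValidationError, RatingError
from .staging import Stage

# ---------------------------------------------------------------------------
# hierarchy layout

PHYSIOLOGICAL = "physiological"
PSYCHOLOGICAL = "psychological"
EXTERNAL = "external"

SELF_CARE_LEAVES = (
    "postural_transition",
    "ambulation",
    "toileting",
    "dressing",
    "feeding",
    "bathing",
    "grooming",
)

LEAVES_BY_DIMENSION: dict[str, tuple[str, ...]] = {
    PHYSIOLOGICAL: ("musculoskeletal_deterioration", "activity_radius") + SELF_CARE_LEAVES,
    PSYCHOLOGICAL: ("sports_anxiety", "social_engagement", "self_efficacy"),
    EXTERNAL: ("familial_support", "financial_capacity"),
}

ALL_LEAVES: tuple[str, ...] = sum(LEAVES_BY_DIMENSION.values(), ())

DIMENSION_OF = {leaf: dim for dim, leaves in LEAVES_BY_DIMENSION.items() for leaf in leaves}

# ---------------------------------------------------------------------------
# stage-dependent dimension weights (external fixed at 10%)

DIMENSION_WEIGHTS: dict[Stage, dict[str, float]] = {
    Stage.A: {PHYSIOLOGICAL: 0.70, PSYCHOLOGICAL: 0.20, EXTERNAL: 0.10},
    Stage.B: {PHYSIOLOGICAL: 0.65, PSYCHOLOGICAL: 0.25, EXTERNAL: 0.10},
    Stage.C: {PHYSIOLOGICAL: 0.60, PSYCHOLOGICAL: 0.30, EXTERNAL: 0.10},
    Stage.D: {PHYSIOLOGICAL: 0.55, PSYCHOLOGICAL: 0.35, EXTERNAL: 0.10},
}


def dimension_weights(stage: Stage) -> tuple[float, float, float]:
    """The (physiological, psychological, external) weight triple of a stage."""
    if not isinstance(stage, Stage):
        try:
            stage = Stage[str(stage)]
        except KeyError:
            raise InputValidationError(f"unknown stage {stage!r}") from None
    w = DIMENSION_WEIGHTS[stage]
    return (w[PHYSIOLOGICAL], w[PSYCHOLOGICAL], w[EXTERNAL])


# ---------------------------------------------------------------------------
# canonical local weights: back-derived once from the published Stage A
# composites (composite / dimension weight) and frozen

STAGE_A_COMPOSITES: dict[str, float] = {
    "musculoskeletal_deterioration": 0.225,
    "activity_radius": 0.086,
    "postural_transition": 0.058,
    "ambulation": 0.058,
    "toileting": 0.058,
    "dressing": 0.039,
    "feeding": 0.078,
    "bathing": 0.058,
    "grooming": 0.039,
    "sports_anxiety": 0.108,
    "social_engagement": 0.059,
    "self_efficacy": 0.033,
    "familial_support": 0.075,
    "financial_capacity": 0.025,
}


def derive_local_weights(
    stage_a_composites: Mapping[str, float] | None = None,
    *,
    normalize: bool = True,
) -> dict[str, float]:
    """Back-derive stage-invariant local weights from Stage A composites.

    local = composite / dimension weight at Stage A.  The published
    composites are rounded to 3 decimals, so the raw physiological locals
    sum to 0.9986 rather than 1.  With ``normalize`` (the default, used for
    scoring) each dimension's locals are rescaled to sum exactly to 1, which
    keeps the intervention score exactly on the 1-4 rating scale; with
    ``normalize=False`` the raw ratios are returned, which recompose to the
    published table cells as printed.
    """
    comp = dict(stage_a_composites or STAGE_A_COMPOSITES)
    missing = set(ALL_LEAVES) - comp.keys()
    if missing:
        raise InputValidationError(f"missing Stage A composites for {sorted(missing)}")
    wa = DIMENSION_WEIGHTS[Stage.A]
    raw = {leaf: comp[leaf] / wa[DIMENSION_OF[leaf]] for leaf in ALL_LEAVES}
    if not normalize:
        return raw
    sums = {dim: sum(raw[l] for l in leaves) for dim, leaves in LEAVES_BY_DIMENSION.items()}
    return {leaf: raw[leaf] / sums[DIMENSION_OF[leaf]] for leaf in ALL_LEAVES}


#: canonical stage-invariant local weights
LOCAL_WEIGHTS: dict[str, float] = derive_local_weights()


@dataclass(frozen=True)
class CompositeWeights:
    """Per-leaf composite weights (local x dimension weight) for one stage."""

    stage: Stage
    weights: dict[str, float]

    def rounded(self, decimals: int = 3) -> dict[str, float]:
        """Display rounding (round-half-up, as in the published tables)."""
        q = Decimal(10) ** -decimals
        return {
            k: float(Decimal(repr(v)).quantize(q, rounding=ROUND_HALF_UP))
            for k, v in self.weights.items()
        }

    def global_rank(self) -> dict[str, int]:
        """1-based rank of each leaf by descending composite weight; the
        seven self-care leaves rank as one block by their summed weight."""
        blocks: dict[str, float] = {}
        for leaf, w in self.weights.items():
            key = "self_care" if leaf in SELF_CARE_LEAVES else leaf
            blocks[key] = blocks.get(key, 0.0) + w
        order = sorted(blocks, key=blocks.get, reverse=True)
        rank_of_block = {b: i + 1 for i, b in enumerate(order)}
        return {
            leaf: rank_of_block["self_care" if leaf in SELF_CARE_LEAVES else leaf]
            for leaf in self.weights
        }


def compose_stage_weights(
    local_weights: Mapping[str, float] | None = None,
    stage: Stage = Stage.A,
) -> CompositeWeights:
    """Compose leaf composite weights for a stage: local x dimension weight.

    ``local_weights`` defaults to the canonical Stage-A-derived locals; each
    dimension's locals must sum to 1 within 0.005 (printed-rounding slack).
    """
    locals_ = dict(local_weights or LOCAL_WEIGHTS)
    missing = set(ALL_LEAVES) - locals_.keys()
    if missing:
        raise InputValidationError(f"missing local weights for {sorted(missing)}")
    for dim, leaves in LEAVES_BY_DIMENSION.items():
        s = sum(locals_[l] for l in leaves)
        if abs(s - 1.0) > 0.005:
            raise InputValidationError(f"{dim} local weights sum to {s:.4f}, expected 1")
    dw = DIMENSION_WEIGHTS[stage]
    return CompositeWeights(
        stage=stage,
        weights={leaf: locals_[leaf] * dw[DIMENSION_OF[leaf]] for leaf in ALL_LEAVES},
    )


# ---------------------------------------------------------------------------
# indicator severity ratings from clinical instruments


@dataclass(frozen=True)
class InstrumentPanel:
    """The clinical instrument scores one participant brings to rating."""

    sarcf: float  # 0-10, higher worse
    adl_independence: float  # 0-100, higher better
    fesi: float  # 16-64, higher worse
    hads: float  # 0-42, higher worse
    gses: float  # 10-40, higher better
    ses_total: int  # 3-9, higher better


@dataclass(frozen=True)
class RatingBands:
    """Monotone 1-4 rating cut-points for one instrument.

    ``cuts`` are three ascending thresholds; for a higher-is-worse
    instrument the rating is 1 + number of cuts at or below the value
    (boundaries map to the higher-severity side); higher-is-better
    instruments count cuts the value falls below.
    """

    cuts: tuple[float, float, float]
    higher_is_worse: bool = True

    def rate(self, value: float) -> int:
        if list(self.cuts) != sorted(self.cuts):
            raise InputValidationError(f"cut-points {self.cuts} not ascending")
        if self.higher_is_worse:
            return 1 + sum(value >= c for c in self.cuts)
        return 1 + sum(value < c for c in reversed(self.cuts))


#: default instrument -> rating cut-points; overridable per call.  The
#: SARC-F bands follow its screening convention; the others are documented
#: package defaults, not validated clinical thresholds.
DEFAULT_RATING_CONFIG: dict[str, RatingBands] = {
    "sarcf": RatingBands((2, 4, 7)),
    "adl": RatingBands((50, 75, 95), higher_is_worse=False),
    "fesi": RatingBands((20, 28, 39)),
    "hads": RatingBands((8, 15, 22)),
    "gses": RatingBands((18, 25, 30), higher_is_worse=False),
    "ses": RatingBands((4, 6, 8), higher_is_worse=False),
}

#: which instrument rates each leaf
LEAF_INSTRUMENT: dict[str, str] = {
    "musculoskeletal_deterioration": "sarcf",
    "activity_radius": "sarcf",
    **{leaf: "adl" for leaf in SELF_CARE_LEAVES},
    "sports_anxiety": "fesi",
    "social_engagement": "hads",
    "self_efficacy": "gses",
    "familial_support": "ses",
    "financial_capacity": "ses",
}

_INSTRUMENT_RANGES = {
    "sarcf": (0, 10),
    "adl": (0, 100),
    "fesi": (16, 64),
    "hads": (0, 42),
    "gses": (10, 40),
    "ses": (3, 9),
}

_PANEL_FIELD = {
    "sarcf": "sarcf",
    "adl": "adl_independence",
    "fesi": "fesi",
    "hads": "hads",
    "gses": "gses",
    "ses": "ses_total",
}


@dataclass(frozen=True)
class IndicatorRatings:
    """1-4 severity rating for each of the 14 leaf indicators."""

    stage: Stage
    ratings: dict[str, int]

    def __post_init__(self):
        missing = set(ALL_LEAVES) - self.ratings.keys()
        if missing:
            raise RatingError(f"unrated leaves: {sorted(missing)}")
        for leaf, r in self.ratings.items():
            if r not in (1, 2, 3, 4):
                raise RatingError(f"leaf {leaf}: rating {r!r} not in 1..4")


def rate_indicators(
    panel: InstrumentPanel,
    stage: Stage,
    config: Mapping[str, RatingBands] | None = None,
) -> IndicatorRatings:
    """Rate all 14 leaves 1-4 from the participant's instrument panel."""
    cfg = dict(DEFAULT_RATING_CONFIG)
    if config:
        cfg.update(config)
    ratings: dict[str, int] = {}
    for leaf in ALL_LEAVES:
        instr = LEAF_INSTRUMENT[leaf]
        value = getattr(panel, _PANEL_FIELD[instr], None)
        if value is None:
            raise RatingError(f"leaf {leaf}: instrument {instr} missing from panel")
        lo, hi = _INSTRUMENT_RANGES[instr]
        if not lo <= value <= hi:
            raise RatingError(f"leaf {leaf}: {instr} value {value} outside [{lo}, {hi}]")
        ratings[leaf] = cfg[instr].rate(value)
    return IndicatorRatings(stage=stage, ratings=ratings)


# ---------------------------------------------------------------------------
# intervention score and grade


class Grade(enum.Enum):
    I = "I"
    II = "II"
    III = "III"


#: grade boundaries: < 2 -> I; 2..3.2 inclusive -> II; > 3.2 -> III
GRADE_CUTS = (2.0, 3.2)


def grade_for_score(total_score: float, cuts: tuple[float, float] = GRADE_CUTS) -> Grade:
    lo, hi = cuts
    if total_score < lo:
        return Grade.I
    if total_score <= hi:
        return Grade.II
    return Grade.III


@dataclass(frozen=True)
class InterventionResult:
    stage: Stage
    total_score: float
    grade: Grade


def intervention_score(
    ratings: IndicatorRatings, cw: CompositeWeights
) -> InterventionResult:
    """Total intervention score: sum over leaves of rating x composite weight
    (un-rounded weights), graded I / II / III at the 2 and 3.2 cut-offs."""
    if ratings.stage != cw.stage:
        raise InputValidationError(
            f"ratings are for stage {ratings.stage.name}, weights for {cw.stage.name}"
        )
    total = sum(ratings.ratings[leaf] * cw.weights[leaf] for leaf in ALL_LEAVES)
    return InterventionResult(stage=cw.stage, total_score=total, grade=grade_for_score(total))
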