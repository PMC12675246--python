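"""Synthetic expert judgment matrices for the AHP workflow.

The original expert pairwise comparisons are not published, so this module
ships *synthetic* fixture matrices: for each hierarchy level, three mock
experts whose entries are the target weight ratios (from the canonical local
weights) perturbed by a fixed per-expert factor and snapped to the discrete
Saaty scale.  They exercise the full aggregate -> eigenvector -> consistency
pipeline and are consistent enough that every level's aggregated consistency
ratio is below the 0.1 acceptability bound; they are NOT the study's data.
"""

from __future__ import annotations

import numpy as np

from .ahp import Hierarchy, Node, SAATY_SCALE, aggregate_experts
from .stratification import (
    EXTERNAL,
    LOCAL_WEIGHTS,
    PHYSIOLOGICAL,
    PSYCHOLOGICAL,
    SELF_CARE_LEAVES,
)

#: deterministic multiplicative perturbation applied by each mock expert to
#: every above-diagonal ratio before Saaty rounding
_EXPERT_FACTORS = (0.8, 1.0, 1.25)


def _saaty_round(x: float) -> float:
    scale = np.asarray(SAATY_SCALE)
    return float(scale[np.argmin(np.abs(np.log(scale) - np.log(x)))])


def matrix_from_weights(weights, factor: float = 1.0) -> np.ndarray:
    """Reciprocal Saaty-scale matrix approximating the ratios w_i / w_j."""
    w = np.asarray(weights, dtype=float)
    n = len(w)
    a = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a[i, j] = _saaty_round(w[i] / w[j] * factor)
            a[j, i] = 1.0 / a[i, j]
    return a


def _level_targets() -> dict[str, np.ndarray]:
    lw = LOCAL_WEIGHTS
    self_care_total = sum(lw[l] for l in SELF_CARE_LEAVES)
    phys_secondary = np.array(
        [lw["musculoskeletal_deterioration"], lw["activity_radius"], self_care_total]
    )
    return {
        "physiological_secondary": phys_secondary / phys_secondary.sum(),
        "self_care": np.array([lw[l] for l in SELF_CARE_LEAVES]) / self_care_total,
        "psychological": np.array(
            [lw["sports_anxiety"], lw["social_engagement"], lw["self_efficacy"]]
        ),
        "external": np.array([lw["familial_support"], lw["financial_capacity"]]),
    }


def fixture_expert_matrices() -> dict[str, list[np.ndarray]]:
    """Three synthetic expert matrices per hierarchy level."""
    return {
        level: [matrix_from_weights(w, f) for f in _EXPERT_FACTORS]
        for level, w in _level_targets().items()
    }


def fixture_hierarchy() -> Hierarchy:
    """Indicator hierarchy whose local weights come from the aggregated
    synthetic expert matrices (AHP route, for the end-to-end demo)."""
    agg = {k: aggregate_experts(v) for k, v in fixture_expert_matrices().items()}
    return Hierarchy(
        dimensions=[
            Node(
                PHYSIOLOGICAL,
                matrix=agg["physiological_secondary"],
                children=[
                    Node("musculoskeletal_deterioration"),
                    Node("activity_radius"),
                    Node(
                        "self_care",
                        matrix=agg["self_care"],
                        children=[Node(l) for l in SELF_CARE_LEAVES],
                    ),
                ],
            ),
            Node(
                PSYCHOLOGICAL,
                matrix=agg["psychological"],
                children=[
                    Node("sports_anxiety"),
                    Node("social_engagement"),
                    Node("self_efficacy"),
                ],
            ),
            Node(
                EXTERNAL,
                matrix=agg["external"],
                children=[Node("familial_support"), Node("financial_capacity")],
            ),
        ]
    )


def canonical_hierarchy() -> Hierarchy:
    """Hierarchy carrying the canonical (published-table-derived) local
    weights explicitly, normalised within each dimension."""
    lw = LOCAL_WEIGHTS
    self_care_total = sum(lw[l] for l in SELF_CARE_LEAVES)
    phys_total = lw["musculoskeletal_deterioration"] + lw["activity_radius"] + self_care_total
    return Hierarchy(
        dimensions=[
            Node(
                PHYSIOLOGICAL,
                children=[
                    Node(
                        "musculoskeletal_deterioration",
                        local_weight=lw["musculoskeletal_deterioration"] / phys_total,
                    ),
                    Node("activity_radius", local_weight=lw["activity_radius"] / phys_total),
                    Node(
                        "self_care",
                        local_weight=self_care_total / phys_total,
                        children=[
                            Node(l, local_weight=lw[l] / self_care_total)
                            for l in SELF_CARE_LEAVES
                        ],
                    ),
                ],
            ),
            Node(
                PSYCHOLOGICAL,
                children=[
                    Node("sports_anxiety", local_weight=lw["sports_anxiety"]),
                    Node("social_engagement", local_weight=lw["social_engagement"]),
                    Node("self_efficacy", local_weight=lw["self_efficacy"]),
                ],
            ),
            Node(
                EXTERNAL,
                children=[
                    Node("familial_support", local_weight=lw["familial_support"]),
                    Node("financial_capacity", local_weight=lw["financial_capacity"]),
                ],
            ),
        ]
    )
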