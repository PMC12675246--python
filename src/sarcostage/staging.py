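"""Four-stage progression model (A-D), SES grouping, and triangulation.

The behavioural stage model describes progressive functional loss:

* **A** Functional Compensation — unrestricted mobility, full ADL
  independence, single-muscle-group fatigue, no movement avoidance;
* **B** Compensation Attenuation — community-level mobility, adaptive
  strategies in instrumental ADL, multi-muscle-group decline, situational
  movement anxiety;
* **C** Decompensation — mobility near the residence, partial assistance in
  basic ADL, core muscle deterioration, persistent movement fear;
* **D** Dependence — home-bound, dependent basic ADL, systemic strength
  loss, behavioural freezing.

Stage can be assigned from the questionnaire band (plus ADL independence),
from SARC-F, or from a DXA lean-mass index; the three routes are compared by
:func:`triangulate` on a small validation subsample stratified by
socioeconomic status (SES).
"""

from __future__ import annotations

import enum
from collections import defaultdict
from dataclasses import dataclass
from typing import Mapping, Sequence

from .exceptions import InputValidationError, NotStageableError
from .questionnaire import BandedScore, RiskBand


class Stage(enum.IntEnum):
    A = 0
    B = 1
    C = 2
    D = 3

    @property
    def phase_name(self) -> str:
        return {
            Stage.A: "FunctionalCompensation",
            Stage.B: "CompensationAttenuation",
            Stage.C: "Decompensation",
            Stage.D: "Dependence",
        }[self]


class SesGroup(enum.Enum):
    LOW = "Low"
    MEDIUM = "Medium"
    HIGH = "High"


@dataclass(frozen=True)
class SesScore:
    """Socioeconomic status: three 1-3 bands summed to a 3-9 total."""

    income_band: int
    education_band: int
    occupation_band: int
    total: int
    group: SesGroup


def ses_score(income_band: int, education_band: int, occupation_band: int) -> SesScore:
    """Sum the three SES bands and classify Low (3-4) / Medium (5-6) / High (7-9)."""
    for name, b in (
        ("income_band", income_band),
        ("education_band", education_band),
        ("occupation_band", occupation_band),
    ):
        if b not in (1, 2, 3):
            raise InputValidationError(f"{name} must be 1, 2 or 3; got {b!r}")
    total = income_band + education_band + occupation_band
    group = SesGroup.LOW if total <= 4 else SesGroup.MEDIUM if total <= 6 else SesGroup.HIGH
    return SesScore(income_band, education_band, occupation_band, total, group)


#: ADL independence score at or above which a participant counts as fully independent
ADL_FULL_INDEPENDENCE = 95.0


def assign_stage(
    banded: BandedScore,
    adl_independence: float,
    *,
    adl_full_cut: float = ADL_FULL_INDEPENDENCE,
) -> Stage:
    """Assign the progression stage from questionnaire band and ADL status.

    Default mapping: pre-sarcopenia band -> A; high-risk band -> B when ADL
    is fully independent, else C; disabling band -> D.  The Healthy band is
    below the staging threshold and raises :class:`NotStageableError`.
    """
    if not 0 <= adl_independence <= 100:
        raise InputValidationError(f"adl_independence {adl_independence} outside [0, 100]")
    band = banded.band
    if band is RiskBand.HEALTHY:
        raise NotStageableError("Healthy band (total < 9) is not stageable")
    if band is RiskBand.PRE_SARCOPENIA:
        return Stage.A
    if band is RiskBand.HIGH_RISK:
        return Stage.B if adl_independence >= adl_full_cut else Stage.C
    return Stage.D


#: SARC-F upper bounds per stage: 0-1 -> A, 2-3 -> B, 4-6 -> C, 7-10 -> D
SARCF_CUTPOINTS = (2, 4, 7)


def stage_from_sarcf(sarcf: float, cutpoints: Sequence[float] = SARCF_CUTPOINTS) -> Stage:
    """Monotone step mapping of the SARC-F score (0-10) to a stage.

    ``cutpoints`` are the three ascending lower bounds of stages B, C, D;
    a score equal to a cut-point maps to the higher-severity side.
    """
    if not 0 <= sarcf <= 10:
        raise InputValidationError(f"sarcf {sarcf} outside [0, 10]")
    if list(cutpoints) != sorted(cutpoints) or len(cutpoints) != 3:
        raise InputValidationError("cutpoints must be 3 ascending values")
    stage = sum(sarcf >= c for c in cutpoints)
    return Stage(stage)


#: default ALMI (kg/m^2) lower bounds of stages A, B, C per sex; below the
#: last bound is stage D.  Synthetic defaults: monotone and configurable,
#: not validated clinical thresholds.
DXA_CUTPOINTS = {
    "male": (7.0, 6.0, 5.0),
    "female": (5.5, 4.7, 3.9),
}


def stage_from_dxa(
    almi: float, sex: str, cutpoints: Mapping[str, Sequence[float]] | None = None
) -> Stage:
    """Map appendicular lean mass index (DXA) to a stage, decreasing in mass."""
    if almi <= 0:
        raise InputValidationError(f"almi must be positive; got {almi}")
    cuts = (cutpoints or DXA_CUTPOINTS).get(sex)
    if cuts is None:
        raise InputValidationError(f"unknown sex {sex!r}")
    if list(cuts) != sorted(cuts, reverse=True) or len(cuts) != 3:
        raise InputValidationError("cutpoints must be 3 descending values")
    stage = sum(almi < c for c in cuts)
    return Stage(stage)


@dataclass
class TriangulationReport:
    """Exact-agreement proportions of three staging routes, overall and per
    SES group."""

    agreement_overall: float
    agreement_by_group: dict[str, float]
    n_by_group: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "agreement_overall": self.agreement_overall,
            "agreement_by_group": self.agreement_by_group,
            "n_by_group": self.n_by_group,
        }


def triangulate(
    ses_groups: Sequence[SesGroup],
    self_stages: Sequence[Stage],
    sarcf_stages: Sequence[Stage],
    dxa_stages: Sequence[Stage],
    *,
    per_group: int = 5,
    strict: bool = True,
) -> TriangulationReport:
    """Exact-agreement check of self-assessed vs SARC-F vs DXA staging.

    In strict mode the subsample must contain all three SES groups with
    exactly ``per_group`` subjects each (the validation design).
    """
    n = len(ses_groups)
    if not len(self_stages) == len(sarcf_stages) == len(dxa_stages) == n:
        raise InputValidationError("all four sequences must have equal length")
    counts: dict[str, int] = defaultdict(int)
    agree: dict[str, int] = defaultdict(int)
    for g, a, b, c in zip(ses_groups, self_stages, sarcf_stages, dxa_stages):
        counts[g.value] += 1
        if a == b == c:
            agree[g.value] += 1
    if strict:
        expected = {g.value: per_group for g in SesGroup}
        if dict(counts) != expected:
            raise InputValidationError(
                f"unbalanced SES groups: {dict(counts)} (expected {expected})"
            )
    return TriangulationReport(
        agreement_overall=sum(agree.values()) / n,
        agreement_by_group={g: agree[g] / c for g, c in counts.items()},
        n_by_group=dict(counts),
    )
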