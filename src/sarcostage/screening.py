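"""Exclusion screening funnel.

Participants flow through three ordered exclusion gates before analysis:

1. missing data — any missing questionnaire item excludes the record;
2. confounding comorbidity — any flagged condition from a closed set of nine
   categories that can mimic sarcopenic phenotypes (joint disease, metabolic/
   endocrine, neurological, ...) excludes the record, whether clinically
   confirmed or symptomatic-undiagnosed;
3. score threshold — totals below 9 points (the Healthy band) are excluded
   from sarcopenia-specific assessment.

The funnel report carries the counts at every gate plus a per-category,
per-diagnostic-status breakdown of the comorbidity exclusions.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

from .exceptions import InputValidationError
from .questionnaire import BandedScore, score_items


class ExclusionCategory(enum.Enum):
    """The nine confounding-pathology categories, in priority order.

    When a participant carries several flags, the recorded category is the
    first in this order (the ordering follows the categories' mechanistic
    grouping, largest first)."""

    JOINT_DISEASES = "JointDiseases"
    METABOLIC_ENDOCRINE = "MetabolicEndocrine"
    NEUROLOGICAL = "Neurological"
    CARDIOVASCULAR = "Cardiovascular"
    CHRONIC_RESPIRATORY = "ChronicRespiratory"
    POSTOPERATIVE_RECOVERY = "PostoperativeRecovery"
    VISUAL_SYSTEM = "VisualSystem"
    INFLAMMATORY_AUTOIMMUNE = "InflammatoryAutoimmune"
    OTHER = "Other"


#: priority rank of each category (lower = recorded first)
CATEGORY_PRIORITY = {c: i for i, c in enumerate(ExclusionCategory)}


class DiagnosticStatus(enum.Enum):
    CONFIRMED = "confirmed"
    SYMPTOMATIC_UNDIAGNOSED = "symptomatic_undiagnosed"


class ScreenStatus(enum.Enum):
    PASS = "pass"
    EXCLUDED_MISSING = "excluded_missing"
    EXCLUDED_COMORBIDITY = "excluded_comorbidity"
    EXCLUDED_BELOW_THRESHOLD = "excluded_below_threshold"


#: minimum questionnaire total for sarcopenia-specific assessment
SCORE_THRESHOLD = 9


@dataclass(frozen=True)
class ScreenResult:
    status: ScreenStatus
    category: ExclusionCategory | None = None
    diagnostic_status: DiagnosticStatus | None = None


def _coerce_comorbidity(item) -> tuple[ExclusionCategory, DiagnosticStatus]:
    cat, st = item
    if not isinstance(cat, ExclusionCategory):
        try:
            cat = ExclusionCategory(cat)
        except ValueError:
            raise InputValidationError(f"unknown exclusion category {cat!r}") from None
    if not isinstance(st, DiagnosticStatus):
        try:
            st = DiagnosticStatus(st)
        except ValueError:
            raise InputValidationError(f"unknown diagnostic status {st!r}") from None
    return cat, st


def screen_missing(item_responses) -> ScreenStatus:
    """Excluded iff any of the 12 item slots is missing (None or NaN)."""
    if len(item_responses) != 12:
        raise InputValidationError(f"expected 12 item slots, got {len(item_responses)}")
    for v in item_responses:
        if v is None or v != v:  # NaN-safe
            return ScreenStatus.EXCLUDED_MISSING
    return ScreenStatus.PASS


def screen_comorbidity(comorbidities: Iterable) -> ScreenResult:
    """Excluded iff the flag set is non-empty; attribution is the highest-
    priority category among the flags."""
    flags = [_coerce_comorbidity(c) for c in comorbidities]
    if not flags:
        return ScreenResult(ScreenStatus.PASS)
    cat, st = min(flags, key=lambda cs: CATEGORY_PRIORITY[cs[0]])
    return ScreenResult(ScreenStatus.EXCLUDED_COMORBIDITY, category=cat, diagnostic_status=st)


def screen_threshold(banded: BandedScore) -> ScreenStatus:
    """Pass iff the total reaches the 9-point diagnostic threshold."""
    if banded.total >= SCORE_THRESHOLD:
        return ScreenStatus.PASS
    return ScreenStatus.EXCLUDED_BELOW_THRESHOLD


@dataclass
class FunnelReport:
    """Participant counts at each screening stage.

    Invariants: ``n_analytic = n_surveyed - n_missing_excluded`` and
    ``n_final = n_analytic - n_comorbidity_excluded - n_below_threshold_excluded``;
    the category breakdown sums to ``n_comorbidity_excluded``.
    """

    n_surveyed: int
    n_missing_excluded: int
    n_analytic: int
    n_comorbidity_excluded: int
    n_below_threshold_excluded: int
    n_final: int
    comorbidity_breakdown: dict[str, dict[str, int]] = field(default_factory=dict)
    statuses: dict = field(default_factory=dict, repr=False)

    def validate(self) -> None:
        if self.n_analytic != self.n_surveyed - self.n_missing_excluded:
            raise InputValidationError("funnel arithmetic broken: n_analytic")
        if self.n_final != (
            self.n_analytic - self.n_comorbidity_excluded - self.n_below_threshold_excluded
        ):
            raise InputValidationError("funnel arithmetic broken: n_final")
        total = sum(sum(d.values()) for d in self.comorbidity_breakdown.values())
        if total != self.n_comorbidity_excluded:
            raise InputValidationError("comorbidity breakdown does not sum to its total")

    def to_dict(self) -> dict:
        return {
            "n_surveyed": self.n_surveyed,
            "n_missing_excluded": self.n_missing_excluded,
            "n_analytic": self.n_analytic,
            "n_comorbidity_excluded": self.n_comorbidity_excluded,
            "n_below_threshold_excluded": self.n_below_threshold_excluded,
            "n_final": self.n_final,
            "comorbidity_breakdown": self.comorbidity_breakdown,
        }


def screen_participant(item_responses, comorbidities) -> ScreenResult:
    """Apply the three gates in order to one participant's record."""
    if screen_missing(item_responses) is ScreenStatus.EXCLUDED_MISSING:
        return ScreenResult(ScreenStatus.EXCLUDED_MISSING)
    banded = score_items(item_responses)
    comorbid = screen_comorbidity(comorbidities)
    if comorbid.status is ScreenStatus.EXCLUDED_COMORBIDITY:
        return comorbid
    if screen_threshold(banded) is ScreenStatus.EXCLUDED_BELOW_THRESHOLD:
        return ScreenResult(ScreenStatus.EXCLUDED_BELOW_THRESHOLD)
    return ScreenResult(ScreenStatus.PASS)


def run_funnel(cohort: Iterable) -> FunnelReport:
    """Screen a cohort of participants and tabulate the exclusion funnel.

    ``cohort`` is an iterable of objects exposing ``id``, ``item_responses``
    and ``comorbidities`` (e.g. :class:`sarcostage.cohort.Participant`).
    Every participant receives exactly one terminal status.
    """
    statuses: dict = {}
    breakdown: Counter = Counter()
    n = n_miss = n_com = n_thr = 0
    for p in cohort:
        n += 1
        try:
            result = screen_participant(p.item_responses, p.comorbidities)
        except InputValidationError as exc:
            raise InputValidationError(f"participant {p.id}: {exc}") from exc
        statuses[p.id] = result
        if result.status is ScreenStatus.EXCLUDED_MISSING:
            n_miss += 1
        elif result.status is ScreenStatus.EXCLUDED_COMORBIDITY:
            n_com += 1
            breakdown[(result.category.value, result.diagnostic_status.value)] += 1
        elif result.status is ScreenStatus.EXCLUDED_BELOW_THRESHOLD:
            n_thr += 1
    if n == 0:
        raise InputValidationError("cohort is empty")
    nested: dict[str, dict[str, int]] = {}
    for (cat, st), count in sorted(breakdown.items()):
        nested.setdefault(cat, {})[st] = count
    report = FunnelReport(
        n_surveyed=n,
        n_missing_excluded=n_miss,
        n_analytic=n - n_miss,
        n_comorbidity_excluded=n_com,
        n_below_threshold_excluded=n_thr,
        n_final=n - n_miss - n_com - n_thr,
        comorbidity_breakdown=nested,
        statuses=statuses,
    )
    report.validate()
    return report
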