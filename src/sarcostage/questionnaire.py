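"""Scoring of the 12-item sarcopenia self-assessment and its psychometrics.

The instrument has 12 items in four domains (strength, endurance, balance,
functional adaptation), each scored 0-3, giving a 0-36 total that is banded
into four risk categories:

=============================  =======
band                           total
=============================  =======
Healthy                        0-8
Pre-sarcopenia compensation    9-16
High risk                      17-24
Disabling degeneration         >= 25
=============================  =======

Reliability/validity statistics (Cronbach's alpha, KMO sampling adequacy,
Bartlett's sphericity test) are computed from their standard closed forms.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .exceptions import DegenerateInputError, IncompleteResponsesError, InputValidationError

N_ITEMS = 12
MAX_ITEM = 3

#: item index blocks per assessment domain (0-based, inclusive ranges)
DOMAINS = {
    "strength": (0, 1, 2),
    "endurance": (3, 4, 5),
    "balance": (6, 7, 8),
    "functional_adaptation": (9, 10, 11),
}

#: lower band edges; a total below 9 is Healthy, >= 25 Disabling.
BAND_EDGES = (9, 17, 25)


class RiskBand(enum.IntEnum):
    """Questionnaire risk band, ordered by severity."""

    HEALTHY = 0
    PRE_SARCOPENIA = 1
    HIGH_RISK = 2
    DISABLING = 3

    @property
    def label(self) -> str:
        return {
            RiskBand.HEALTHY: "Healthy",
            RiskBand.PRE_SARCOPENIA: "PreSarcopeniaCompensation",
            RiskBand.HIGH_RISK: "HighRisk",
            RiskBand.DISABLING: "DisablingDegeneration",
        }[self]


@dataclass(frozen=True)
class BandedScore:
    """Questionnaire total and the risk band containing it."""

    total: int
    band: RiskBand


def band_for_total(total: int) -> RiskBand:
    """Map a 0-36 questionnaire total to its risk band."""
    if not 0 <= total <= N_ITEMS * MAX_ITEM:
        raise InputValidationError(f"total {total} outside [0, {N_ITEMS * MAX_ITEM}]")
    return RiskBand(int(np.digitize(total, BAND_EDGES)))


def score_items(responses: Sequence) -> BandedScore:
    """Sum the 12 item responses and assign the risk band.

    Parameters
    ----------
    responses
        Exactly 12 values, each an integer in {0, 1, 2, 3}.  ``None`` or NaN
        marks a missing response and raises :class:`IncompleteResponsesError`
        (missing data is an upstream screening concern, never imputed here).
    """
    if len(responses) != N_ITEMS:
        raise InputValidationError(f"expected {N_ITEMS} item responses, got {len(responses)}")
    total = 0
    for i, v in enumerate(responses):
        if v is None or (isinstance(v, float) and math.isnan(v)):
            raise IncompleteResponsesError(f"item {i + 1} is missing")
        iv = int(v)
        if iv != v or not 0 <= iv <= MAX_ITEM:
            raise InputValidationError(f"item {i + 1} value {v!r} not in {{0..{MAX_ITEM}}}")
        total += iv
    return BandedScore(total=total, band=band_for_total(total))


def _as_matrix(score_matrix) -> np.ndarray:
    x = np.asarray(score_matrix, dtype=float)
    if x.ndim != 2:
        raise InputValidationError("score matrix must be 2-D (participants x items)")
    if np.isnan(x).any():
        raise InputValidationError("score matrix contains missing cells")
    return x


def cronbach_alpha(score_matrix) -> float:
    """Cronbach's alpha, the internal-consistency reliability coefficient.

    alpha = k/(k-1) * (1 - sum_i var_i / var_total), with sample (n-1
    denominator) variances over participants.
    """
    x = _as_matrix(score_matrix)
    n, k = x.shape
    if k < 2 or n < 2:
        raise InputValidationError("need at least 2 items and 2 participants")
    item_vars = x.var(axis=0, ddof=1)
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise DegenerateInputError("total score variance is zero; alpha undefined")
    return k / (k - 1) * (1.0 - item_vars.sum() / total_var)


def subscale_alphas(score_matrix) -> dict[str, float]:
    """Cronbach's alpha per 3-item assessment domain."""
    x = _as_matrix(score_matrix)
    return {name: cronbach_alpha(x[:, list(idx)]) for name, idx in DOMAINS.items()}


def _correlation(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = int(np.flatnonzero(sd == 0)[0])
        raise DegenerateInputError(f"item {bad + 1} has zero variance")
    return np.corrcoef(x, rowvar=False)


def kmo_measure(score_matrix) -> tuple[float, np.ndarray]:
    """Kaiser-Meyer-Olkin measure of sampling adequacy.

    KMO = sum r_ij^2 / (sum r_ij^2 + sum q_ij^2) over i != j, where q are the
    anti-image (partial) correlations obtained from the inverse correlation
    matrix.  Returns the overall measure and the per-item measures.
    """
    x = _as_matrix(score_matrix)
    r = _correlation(x)
    k = r.shape[0]
    try:
        rinv = np.linalg.inv(r)
    except np.linalg.LinAlgError as exc:
        raise DegenerateInputError("correlation matrix is singular") from exc
    d = np.sqrt(np.outer(np.diag(rinv), np.diag(rinv)))
    q = -rinv / d  # partial correlations, sign convention: q_ij = -rinv_ij / sqrt(rinv_ii rinv_jj)
    off = ~np.eye(k, dtype=bool)
    r2 = r[off] ** 2
    q2 = q[off] ** 2
    denom = r2.sum() + q2.sum()
    if denom == 0:
        raise DegenerateInputError("all off-diagonal correlations are zero; KMO is 0/0")
    overall = r2.sum() / denom
    r2_item = (r**2 * off).sum(axis=1)
    q2_item = (q**2 * off).sum(axis=1)
    per_item_denom = r2_item + q2_item
    if np.any(per_item_denom == 0):
        raise DegenerateInputError("an item has no correlation with any other; KMO is 0/0")
    return float(overall), r2_item / per_item_denom


def bartlett_sphericity(score_matrix) -> tuple[float, int, float]:
    """Bartlett's test that the correlation matrix is the identity.

    chi2 = -(n - 1 - (2k + 5)/6) * ln det(R); df = k(k-1)/2; the p-value is
    the chi-square upper tail.
    """
    x = _as_matrix(score_matrix)
    n, k = x.shape
    if n <= k:
        raise InputValidationError(f"need more participants ({n}) than items ({k})")
    r = _correlation(x)
    sign, logdet = np.linalg.slogdet(r)
    if sign <= 0:
        raise DegenerateInputError("correlation matrix is not positive definite")
    statistic = -(n - 1 - (2 * k + 5) / 6.0) * logdet
    df = k * (k - 1) // 2
    p = float(stats.chi2.sf(statistic, df))
    return float(statistic), df, p


def psychometrics_report(score_matrix) -> dict:
    """Full reliability/validity report: alpha (overall and per subscale),
    KMO and Bartlett's test, as a JSON-serialisable dict."""
    overall, per_item = kmo_measure(score_matrix)
    chi2, df, p = bartlett_sphericity(score_matrix)
    return {
        "alpha_overall": cronbach_alpha(score_matrix),
        "alpha_subscales": subscale_alphas(score_matrix),
        "kmo_overall": overall,
        "kmo_per_item": list(map(float, per_item)),
        "bartlett": {"statistic": chi2, "df": df, "p_value": p},
    }
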