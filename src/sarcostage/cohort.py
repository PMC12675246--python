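"""Synthetic cohort generator.

Emulates the statistical structure of an urban ageing survey so the whole
pipeline is testable without any real data: age-stratified demographics,
a graded item-response model for the 12 questionnaire items, latent
progression bands per age band, confounding-comorbidity flags, instrument
scores conditional on the latent band, and item-level missingness.

Item model
----------
Each participant carries a latent severity ``theta`` in [0, 1].  Item k's
response is the number of thresholds cleared under a graded (cumulative
logistic) model::

    P(item >= k) = logistic((theta - tau_k) / s),   tau_1 < tau_2 < tau_3

A single uniform draw per item realises the ordered response, so raising
``theta`` while holding the draw fixed can never lower an item score.

Latent bands draw ``theta`` from Beta distributions whose means are solved
numerically so each band's expected 12-item total sits at the midpoint of
its score range (4 / 12.5 / 20.5 / 28.5).  An age band may instead pin a
single calibrated severity distribution via ``mean_total_target`` (used for
the 31-40 band, whose published mean total is 8.2); the ground-truth band
label is then the band whose score range contains the expected total at the
drawn ``theta``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy import optimize, special, stats

from .exceptions import ConfigurationError, InputValidationError
from .questionnaire import N_ITEMS
from .screening import DiagnosticStatus, ExclusionCategory

AGE_BANDS = ("<=30", "31-40", "41-50", "51-60", "61-70", "71-80", ">=81")
AGE_RANGES = {
    "<=30": (18, 30),
    "31-40": (31, 40),
    "41-50": (41, 50),
    "51-60": (51, 60),
    "61-70": (61, 70),
    "71-80": (71, 80),
    ">=81": (81, 95),
}

LATENT_BANDS = ("Healthy", "PreSarc", "HighRisk", "Disabling")

#: continuous band edges for expected totals (discrete bands are 0-8 / 9-16
#: / 17-24 / >=25)
_CONT_EDGES = (8.5, 16.5, 24.5)

#: expected-total calibration targets: the midpoint of each band's range
BAND_TOTAL_TARGETS = (4.0, 12.5, 20.5, 28.5)

INSURANCE_TYPES = ("EmpIns", "ResIns", "NRCMS", "StuIns", "NoIns")

INSTRUMENTS = ("sarcf", "adl_independence", "fesi", "hads", "gses")
INSTRUMENT_RANGES = {
    "sarcf": (0.0, 10.0),
    "adl_independence": (0.0, 100.0),
    "fesi": (16.0, 64.0),
    "hads": (0.0, 42.0),
    "gses": (10.0, 40.0),
}


class ItemModel(BaseModel):
    """Graded-response model: shared thresholds on latent severity."""

    model_config = ConfigDict(frozen=True)

    thresholds: tuple[float, float, float] = (0.25, 0.50, 0.75)
    noise_scale: float = 0.07

    @model_validator(mode="after")
    def _check(self):
        t = self.thresholds
        if not (0 < t[0] < t[1] < t[2] < 1):
            raise ValueError(f"thresholds must be strictly increasing within (0,1); got {t}")
        if self.noise_scale <= 0:
            raise ValueError("noise_scale must be positive")
        return self


class BandConfig(BaseModel):
    """One age band: demographics plus either a latent-band mixture or a
    calibrated mean-total target."""

    model_config = ConfigDict(frozen=True)

    male_share: float = 0.5
    education_mean: float = 10.0
    education_sd: float = 3.0
    insurance_probs: dict[str, float] = Field(default_factory=lambda: {"ResIns": 1.0})
    income_mean: float = 5000.0
    income_sd: float = 2000.0
    latent_mix: Optional[tuple[float, float, float, float]] = None
    mean_total_target: Optional[float] = None

    @model_validator(mode="after")
    def _check(self):
        if (self.latent_mix is None) == (self.mean_total_target is None):
            raise ValueError("exactly one of latent_mix / mean_total_target must be set")
        if self.latent_mix is not None and abs(sum(self.latent_mix) - 1.0) > 1e-9:
            raise ValueError(f"latent_mix sums to {sum(self.latent_mix)}, expected 1")
        if not 0 <= self.male_share <= 1:
            raise ValueError(f"male_share {self.male_share} outside [0,1]")
        unknown = set(self.insurance_probs) - set(INSURANCE_TYPES)
        if unknown:
            raise ValueError(f"unknown insurance types {sorted(unknown)}")
        if abs(sum(self.insurance_probs.values()) - 1.0) > 1e-9:
            raise ValueError("insurance_probs must sum to 1")
        return self


def _default_bands() -> dict[str, BandConfig]:
    """Age-band defaults mirroring the survey's baseline table and the
    published age-band score profiles."""
    return {
        "<=30": BandConfig(
            male_share=145 / 281, education_mean=13.5, education_sd=3.5,
            insurance_probs={"StuIns": 0.65, "EmpIns": 0.25, "ResIns": 0.10},
            income_mean=2500, income_sd=1800,
            latent_mix=(1.0, 0.0, 0.0, 0.0),
        ),
        "31-40": BandConfig(
            male_share=89 / 171, education_mean=14.2, education_sd=2.8,
            insurance_probs={"EmpIns": 0.78, "ResIns": 0.19, "NoIns": 0.03},
            income_mean=12800, income_sd=4500,
            mean_total_target=8.2,
        ),
        "41-50": BandConfig(
            male_share=152 / 274, education_mean=12.1, education_sd=3.1,
            insurance_probs={"EmpIns": 0.75, "ResIns": 0.23, "NoIns": 0.02},
            income_mean=11200, income_sd=4000,
            latent_mix=(0.55, 0.33, 0.12, 0.0),
        ),
        "51-60": BandConfig(
            male_share=188 / 344, education_mean=10.3, education_sd=3.4,
            insurance_probs={"EmpIns": 0.65, "ResIns": 0.25, "NRCMS": 0.08, "NoIns": 0.02},
            income_mean=8500, income_sd=3000,
            latent_mix=(0.429, 0.286, 0.285, 0.0),
        ),
        "61-70": BandConfig(
            male_share=241 / 447, education_mean=8.7, education_sd=3.8,
            insurance_probs={"EmpIns": 0.48, "ResIns": 0.35, "NRCMS": 0.15, "NoIns": 0.02},
            income_mean=5500, income_sd=2000,
            latent_mix=(0.0, 0.45, 0.40, 0.15),
        ),
        "71-80": BandConfig(
            male_share=63 / 103, education_mean=6.5, education_sd=4.1,
            insurance_probs={"EmpIns": 0.30, "ResIns": 0.45, "NRCMS": 0.23, "NoIns": 0.02},
            income_mean=3500, income_sd=1200,
            latent_mix=(0.0, 0.15, 0.50, 0.35),
        ),
        ">=81": BandConfig(
            male_share=24 / 63, education_mean=5.1, education_sd=4.3,
            insurance_probs={"EmpIns": 0.85, "NRCMS": 0.15},
            income_mean=2800, income_sd=800,
            latent_mix=(0.0, 0.15, 0.45, 0.40),
        ),
    }


def _default_age_mix() -> dict[str, float]:
    counts = {"<=30": 281, "31-40": 171, "41-50": 274, "51-60": 344,
              "61-70": 447, "71-80": 103, ">=81": 63}
    n = sum(counts.values())
    return {b: c / n for b, c in counts.items()}


def _default_comorbidity_rates() -> dict[str, tuple[float, float]]:
    # (confirmed, symptomatic-undiagnosed) marginal flag probabilities,
    # category counts over the analytic sample size 1,683
    counts = {
        "JointDiseases": (380, 95),
        "MetabolicEndocrine": (126, 35),
        "Neurological": (76, 15),
        "Cardiovascular": (66, 14),
        "ChronicRespiratory": (39, 7),
        "PostoperativeRecovery": (43, 0),
        "VisualSystem": (11, 10),
        "InflammatoryAutoimmune": (15, 2),
        "Other": (9, 7),
    }
    return {k: (c / 1683, s / 1683) for k, (c, s) in counts.items()}


#: instrument score (mean, sd) per latent band; sampled from a truncated
#: Gaussian within the instrument's range
DEFAULT_INSTRUMENT_PARAMS: dict[str, tuple[tuple[float, float], ...]] = {
    "sarcf": ((0.5, 1.0), (1.5, 1.0), (4.5, 1.0), (8.0, 1.0)),
    "adl_independence": ((99.0, 2.0), (96.0, 4.0), (78.0, 10.0), (45.0, 12.0)),
    "fesi": ((18.0, 2.0), (23.0, 4.0), (33.0, 6.0), (47.0, 7.0)),
    "hads": ((4.0, 3.0), (9.0, 4.0), (17.0, 5.0), (26.0, 6.0)),
    "gses": ((34.0, 3.0), (30.0, 4.0), (22.0, 4.0), (15.0, 4.0)),
}

#: default item-level missing probability: solves
#: 1 - (1 - r)^12 = 45/1728 for the participant-level missing share
DEFAULT_MISSING_RATE = 1.0 - (1.0 - 45 / 1728) ** (1.0 / N_ITEMS)

#: SES banding of generated records: income (CNY/month) and education (years)
SES_INCOME_CUTS = (4000.0, 9000.0)
SES_EDUCATION_CUTS = (6.5, 12.5)

#: Beta concentration of the per-band latent severity distributions
THETA_CONCENTRATION = 200.0


class SimConfig(BaseModel):
    """Full synthetic-cohort specification; defaults reproduce the study
    conditions (n = 1,728 invited, the published age mix, band profiles,
    comorbidity category rates and the 45/1,728 missing-data share)."""

    model_config = ConfigDict(frozen=True)

    n_total: int = 1728
    seed: int = 0
    missing_rate: float = DEFAULT_MISSING_RATE
    age_band_mix: dict[str, float] = Field(default_factory=_default_age_mix)
    bands: dict[str, BandConfig] = Field(default_factory=_default_bands)
    comorbidity_rates: dict[str, tuple[float, float]] = Field(
        default_factory=_default_comorbidity_rates
    )
    item_model: ItemModel = Field(default_factory=ItemModel)
    theta_concentration: float = THETA_CONCENTRATION
    instrument_params: dict[str, tuple[tuple[float, float], ...]] = Field(
        default_factory=lambda: dict(DEFAULT_INSTRUMENT_PARAMS)
    )

    @model_validator(mode="after")
    def _check(self):
        if self.n_total < 0:
            raise ValueError("n_total must be non-negative")
        if not 0 <= self.missing_rate < 1:
            raise ValueError(f"missing_rate {self.missing_rate} outside [0,1)")
        if set(self.age_band_mix) != set(AGE_BANDS):
            raise ValueError(f"age_band_mix must cover exactly {AGE_BANDS}")
        if abs(sum(self.age_band_mix.values()) - 1.0) > 1e-9:
            raise ValueError("age_band_mix must sum to 1")
        if set(self.bands) != set(AGE_BANDS):
            raise ValueError(f"bands must cover exactly {AGE_BANDS}")
        known = {c.value for c in ExclusionCategory}
        unknown = set(self.comorbidity_rates) - known
        if unknown:
            raise ValueError(f"unknown comorbidity categories {sorted(unknown)}")
        for cat, (pc, ps) in self.comorbidity_rates.items():
            if not (0 <= pc <= 1 and 0 <= ps <= 1 and pc + ps <= 1):
                raise ValueError(f"comorbidity_rates[{cat}] invalid: {(pc, ps)}")
        if self.theta_concentration <= 0:
            raise ValueError("theta_concentration must be positive")
        for name, params in self.instrument_params.items():
            if name not in INSTRUMENT_RANGES:
                raise ValueError(f"unknown instrument {name!r}")
            if len(params) != 4 or any(sd <= 0 for _, sd in params):
                raise ValueError(f"instrument_params[{name}] needs 4 (mean, sd>0) pairs")
        return self


@dataclass
class Participant:
    """One survey subject; latent fields are generator ground truth and are
    ``None`` on real (non-synthetic) records."""

    id: str
    age_years: int
    age_band: str
    gender: str
    education_years: float
    insurance: str
    monthly_income_cny: float
    comorbidities: list[tuple[ExclusionCategory, DiagnosticStatus]]
    item_responses: list  # 12 slots, int 0-3 or None
    sarcf: float
    adl_independence: float
    fesi: float
    hads: float
    gses: float
    ses_income_band: int
    ses_education_band: int
    ses_occupation_band: int
    latent_severity: Optional[float] = None
    latent_band: Optional[str] = None

    @property
    def is_synthetic(self) -> bool:
        return self.latent_severity is not None


# ---------------------------------------------------------------------------
# item-response machinery


def expected_total(theta, item_model: ItemModel) -> np.ndarray:
    """Expected 12-item total at latent severity theta."""
    th = np.asarray(theta, dtype=float)[..., None]
    tau = np.asarray(item_model.thresholds)
    return N_ITEMS * special.expit((th - tau) / item_model.noise_scale).sum(axis=-1)


def latent_band_of_theta(theta, item_model: ItemModel) -> np.ndarray:
    """Ground-truth band: the band whose score range holds E[total | theta]."""
    return np.digitize(expected_total(theta, item_model), _CONT_EDGES)


@lru_cache(maxsize=64)
def _calibrated_mean(
    target_total: float, thresholds: tuple, noise_scale: float, concentration: float
) -> float:
    """Beta mean m such that E[total], theta ~ Beta(m*k, (1-m)*k), equals
    the target.  Gauss-Legendre quadrature + brentq."""
    im = ItemModel(thresholds=thresholds, noise_scale=noise_scale)
    # integrate in quantile space (robust for concentrated Beta shapes):
    # E[f(theta)] = int_0^1 f(F^-1(u)) du
    nodes, wts = np.polynomial.legendre.leggauss(200)
    u = 0.5 * (nodes + 1.0)
    w = 0.5 * wts

    def mean_total(m: float) -> float:
        a, b = m * concentration, (1 - m) * concentration
        theta = stats.beta.ppf(u, a, b)
        return float(np.sum(w * expected_total(theta, im)))

    lo, hi = 1e-3, 1 - 1e-3
    if not mean_total(lo) <= target_total <= mean_total(hi):
        raise ConfigurationError(
            f"mean_total_target {target_total} unreachable under the item model"
        )
    return float(optimize.brentq(lambda m: mean_total(m) - target_total, lo, hi, xtol=1e-10))


def calibrated_band_means(
    item_model: ItemModel, concentration: float = THETA_CONCENTRATION
) -> tuple[float, ...]:
    """Per-band Beta means hitting the band-midpoint expected totals."""
    return tuple(
        _calibrated_mean(t, item_model.thresholds, item_model.noise_scale, concentration)
        for t in BAND_TOTAL_TARGETS
    )


def _truncnorm(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float) -> float:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def _band_of(value: float, cuts: Sequence[float]) -> int:
    return 1 + int(np.digitize(value, cuts))


# ---------------------------------------------------------------------------
# generation


def generate_cohort(config: SimConfig) -> list[Participant]:
    """Generate ``config.n_total`` participants; identical config (including
    seed) yields an identical cohort."""
    try:
        config = SimConfig.model_validate(config)
    except Exception as exc:  # pydantic names the offending field
        raise ConfigurationError(str(exc)) from exc
    rng = np.random.default_rng(config.seed)
    im = config.item_model
    kappa = config.theta_concentration
    band_means = calibrated_band_means(im, kappa)
    tau = np.asarray(im.thresholds)
    cats = list(config.comorbidity_rates.items())

    out: list[Participant] = []
    for idx in range(config.n_total):
        age_band = str(rng.choice(AGE_BANDS, p=[config.age_band_mix[b] for b in AGE_BANDS]))
        bc = config.bands[age_band]
        lo_age, hi_age = AGE_RANGES[age_band]
        age = int(rng.integers(lo_age, hi_age + 1))
        gender = "male" if rng.random() < bc.male_share else "female"
        education = float(np.clip(rng.normal(bc.education_mean, bc.education_sd), 0, 22))
        ins_names = list(bc.insurance_probs)
        insurance = str(rng.choice(ins_names, p=[bc.insurance_probs[k] for k in ins_names]))
        income = float(max(0.0, rng.normal(bc.income_mean, bc.income_sd)))

        if bc.mean_total_target is not None:
            # single calibrated severity distribution; ground truth is the
            # band whose score range holds the expected total at theta
            m = _calibrated_mean(bc.mean_total_target, im.thresholds, im.noise_scale, kappa)
            theta = float(rng.beta(m * kappa, (1 - m) * kappa))
            latent_band = LATENT_BANDS[int(latent_band_of_theta(theta, im))]
        else:
            drawn = int(rng.choice(4, p=list(bc.latent_mix)))
            m = band_means[drawn]
            theta = float(rng.beta(m * kappa, (1 - m) * kappa))
            latent_band = LATENT_BANDS[drawn]

        # one uniform per item realises the ordered graded response
        u = rng.random(N_ITEMS)
        p_ge = special.expit((theta - tau) / im.noise_scale)  # P(item >= k), k=1..3
        items: list = [int((ui < p_ge).sum()) for ui in u]
        for k in range(N_ITEMS):
            if rng.random() < config.missing_rate:
                items[k] = None

        comorbidities = []
        for cat, (pc, ps) in cats:
            r = rng.random()
            if r < pc:
                comorbidities.append((ExclusionCategory(cat), DiagnosticStatus.CONFIRMED))
            elif r < pc + ps:
                comorbidities.append(
                    (ExclusionCategory(cat), DiagnosticStatus.SYMPTOMATIC_UNDIAGNOSED)
                )

        bi = LATENT_BANDS.index(latent_band)
        instr = {}
        for name in INSTRUMENTS:
            mean, sd = config.instrument_params[name][bi]
            lo, hi = INSTRUMENT_RANGES[name]
            instr[name] = round(_truncnorm(rng, mean, sd, lo, hi), 1)

        occ = (
            _band_of(education, SES_EDUCATION_CUTS)
            if rng.random() < 0.7
            else int(rng.integers(1, 4))
        )
        out.append(
            Participant(
                id=f"P{idx + 1:05d}",
                age_years=age,
                age_band=age_band,
                gender=gender,
                education_years=round(education, 1),
                insurance=insurance,
                monthly_income_cny=round(income, 0),
                comorbidities=comorbidities,
                item_responses=items,
                sarcf=instr["sarcf"],
                adl_independence=instr["adl_independence"],
                fesi=instr["fesi"],
                hads=instr["hads"],
                gses=instr["gses"],
                ses_income_band=_band_of(income, SES_INCOME_CUTS),
                ses_education_band=_band_of(education, SES_EDUCATION_CUTS),
                ses_occupation_band=occ,
                latent_severity=theta,
                latent_band=latent_band,
            )
        )
    return out


# ---------------------------------------------------------------------------
# calibration report


def calibration_report(cohort: Sequence[Participant]) -> pd.DataFrame:
    """Per-age-band summary against generator ground truth: complete-response
    mean total, latent band mixture, and comorbidity prevalence.

    Requires a synthetic cohort (latent fields present)."""
    if not cohort:
        raise InputValidationError("cohort is empty")
    if not all(p.is_synthetic for p in cohort):
        raise InputValidationError("calibration_report needs a synthetic cohort (no ground truth)")
    rows = []
    for band in AGE_BANDS:
        members = [p for p in cohort if p.age_band == band]
        if not members:
            continue
        complete = [p for p in members if all(v is not None for v in p.item_responses)]
        totals = [sum(p.item_responses) for p in complete]
        mix = {
            lb: sum(p.latent_band == lb for p in members) / len(members) for lb in LATENT_BANDS
        }
        rows.append(
            {
                "age_band": band,
                "n": len(members),
                "mean_total": float(np.mean(totals)) if totals else float("nan"),
                **{f"share_{lb}": mix[lb] for lb in LATENT_BANDS},
                "comorbidity_prevalence": sum(bool(p.comorbidities) for p in members)
                / len(members),
            }
        )
    return pd.DataFrame(rows).set_index("age_band")


# ---------------------------------------------------------------------------
# CSV round trip

_CSV_COLUMNS = [
    "id", "age_years", "age_band", "gender", "education_years", "insurance",
    "monthly_income_cny", "comorbidities",
    *[f"item_{k}" for k in range(1, N_ITEMS + 1)],
    "sarcf", "adl_independence", "fesi", "hads", "gses",
    "ses_income_band", "ses_education_band", "ses_occupation_band",
    "latent_severity", "latent_band",
]


def cohort_to_dataframe(cohort: Sequence[Participant]) -> pd.DataFrame:
    rows = []
    for p in cohort:
        row = {
            "id": p.id, "age_years": p.age_years, "age_band": p.age_band,
            "gender": p.gender, "education_years": p.education_years,
            "insurance": p.insurance, "monthly_income_cny": p.monthly_income_cny,
            "comorbidities": ";".join(f"{c.value}:{s.value}" for c, s in p.comorbidities),
            "sarcf": p.sarcf, "adl_independence": p.adl_independence,
            "fesi": p.fesi, "hads": p.hads, "gses": p.gses,
            "ses_income_band": p.ses_income_band,
            "ses_education_band": p.ses_education_band,
            "ses_occupation_band": p.ses_occupation_band,
            "latent_severity": p.latent_severity, "latent_band": p.latent_band,
        }
        for k, v in enumerate(p.item_responses, start=1):
            row[f"item_{k}"] = v
        rows.append(row)
    return pd.DataFrame(rows, columns=_CSV_COLUMNS)


def write_cohort_csv(cohort: Sequence[Participant], path, config: SimConfig | None = None) -> None:
    """Write the cohort CSV (missing item = empty cell) and, when the config
    is given, a JSON sidecar recording it."""
    df = cohort_to_dataframe(cohort)
    df.to_csv(path, index=False)
    if config is not None:
        sidecar = str(path) + ".config.json"
        with open(sidecar, "w") as fh:
            json.dump(config.model_dump(mode="json"), fh, indent=2, default=list)


def read_cohort_csv(path) -> list[Participant]:
    df = pd.read_csv(path, dtype={"comorbidities": str}, keep_default_na=True)
    out = []
    for _, r in df.iterrows():
        com = []
        if isinstance(r["comorbidities"], str) and r["comorbidities"]:
            for tok in r["comorbidities"].split(";"):
                cat, st = tok.split(":")
                com.append((ExclusionCategory(cat), DiagnosticStatus(st)))
        items = [
            None if pd.isna(r[f"item_{k}"]) else int(r[f"item_{k}"])
            for k in range(1, N_ITEMS + 1)
        ]
        out.append(
            Participant(
                id=r["id"], age_years=int(r["age_years"]), age_band=r["age_band"],
                gender=r["gender"], education_years=float(r["education_years"]),
                insurance=r["insurance"], monthly_income_cny=float(r["monthly_income_cny"]),
                comorbidities=com, item_responses=items,
                sarcf=float(r["sarcf"]), adl_independence=float(r["adl_independence"]),
                fesi=float(r["fesi"]), hads=float(r["hads"]), gses=float(r["gses"]),
                ses_income_band=int(r["ses_income_band"]),
                ses_education_band=int(r["ses_education_band"]),
                ses_occupation_band=int(r["ses_occupation_band"]),
                latent_severity=None if pd.isna(r["latent_severity"]) else float(r["latent_severity"]),
                latent_band=None if pd.isna(r["latent_band"]) else r["latent_band"],
            )
        )
    return out
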