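"""End-to-end pipeline: simulate -> screen -> score -> stage -> stratify.

One top-level seed is fanned out to per-stage child seeds through
``numpy.random.SeedSequence.spawn``, so each stage is independently
reproducible and two runs with the same config and seed produce
byte-identical output files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import SimConfig, generate_cohort, write_cohort_csv
from .exceptions import ConfigurationError, SarcostageError
from .questionnaire import psychometrics_report, score_items
from .screening import ScreenStatus, run_funnel
from .staging import Stage, assign_stage, ses_score
from .stratification import (
    InstrumentPanel,
    compose_stage_weights,
    intervention_score,
    rate_indicators,
)

log = logging.getLogger("sarcostage")


@dataclass
class RunManifest:
    """Record of one pipeline run, sufficient to reproduce it."""

    seed: int
    config_hash: str
    version: str
    counts: dict
    outputs: dict[str, str]

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "config_hash": self.config_hash,
            "version": self.version,
            "counts": self.counts,
            "outputs": self.outputs,
        }


def child_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-stage seeds derived from the top-level seed."""
    return [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(n)]


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: SimConfig, out_dir, seed: int | None = None) -> RunManifest:
    """Run the five stages on a synthetic cohort and write all reports.

    Outputs in ``out_dir``: cohort.csv (+ config sidecar), scores.csv,
    funnel.json, psychometrics.json, staging.csv, stratification.csv and
    manifest.json.  ``seed`` overrides the config seed when given.
    """
    if seed is not None:
        config = config.model_copy(update={"seed": int(child_seeds(seed, 1)[0])})
    if config.n_total <= 0:
        raise ConfigurationError("n_total must be positive for a pipeline run")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        cfg_json = json.dumps(config.model_dump(mode="json"), sort_keys=True, default=list)
        config_hash = hashlib.sha256(cfg_json.encode()).hexdigest()[:16]

        # 1. simulate
        cohort = generate_cohort(config)
        cohort_path = out / "cohort.csv"
        write_cohort_csv(cohort, cohort_path, config=config)
        written += [cohort_path, Path(str(cohort_path) + ".config.json")]
        log.info("simulate: %d participants", len(cohort))

        # 2. screen
        funnel = run_funnel(cohort)
        funnel_path = out / "funnel.json"
        _write_json(funnel.to_dict(), funnel_path)
        written.append(funnel_path)
        log.info("screen: %d -> %d", funnel.n_surveyed, funnel.n_final)

        # 3. score + psychometrics on the analytic sample (complete
        # responses, before comorbidity exclusion)
        complete = [p for p in cohort if all(v is not None for v in p.item_responses)]
        matrix = np.array([p.item_responses for p in complete], dtype=float)
        psych_path = out / "psychometrics.json"
        _write_json(psychometrics_report(matrix), psych_path)
        written.append(psych_path)

        scores = {p.id: score_items(p.item_responses) for p in complete}
        scores_df = pd.DataFrame(
            [
                {"id": p.id, "total": scores[p.id].total, "band": scores[p.id].band.label}
                for p in complete
            ]
        )
        scores_path = out / "scores.csv"
        scores_df.to_csv(scores_path, index=False)
        written.append(scores_path)
        log.info("score: %d complete responders", len(complete))

        # 4. stage the screened-in participants
        passed = [p for p in cohort if funnel.statuses[p.id].status is ScreenStatus.PASS]
        staging_rows = []
        for p in passed:
            stage = assign_stage(scores[p.id], p.adl_independence)
            ses = ses_score(p.ses_income_band, p.ses_education_band, p.ses_occupation_band)
            staging_rows.append(
                {"id": p.id, "stage": stage.name, "ses_total": ses.total,
                 "ses_group": ses.group.value}
            )
        staging_df = pd.DataFrame(staging_rows)
        staging_path = out / "staging.csv"
        staging_df.to_csv(staging_path, index=False)
        written.append(staging_path)
        log.info("stage: %d participants staged", len(passed))

        # 5. stratify
        weights_by_stage = {s: compose_stage_weights(stage=s) for s in Stage}
        strat_rows = []
        for p, srow in zip(passed, staging_rows):
            stage = Stage[srow["stage"]]
            panel = InstrumentPanel(
                sarcf=p.sarcf, adl_independence=p.adl_independence, fesi=p.fesi,
                hads=p.hads, gses=p.gses, ses_total=srow["ses_total"],
            )
            result = intervention_score(
                rate_indicators(panel, stage), weights_by_stage[stage]
            )
            strat_rows.append(
                {"id": p.id, "stage": stage.name,
                 "total_score": round(result.total_score, 6), "grade": result.grade.value}
            )
        strat_df = pd.DataFrame(strat_rows)
        strat_path = out / "stratification.csv"
        strat_df.to_csv(strat_path, index=False)
        written.append(strat_path)
        log.info("stratify: %d participants graded", len(strat_rows))

        manifest = RunManifest(
            seed=config.seed,
            config_hash=config_hash,
            version=__version__,
            counts={
                **funnel.to_dict(),
                "n_scored": len(complete),
                "n_staged": len(staging_rows),
                "n_stratified": len(strat_rows),
            },
            outputs={p.name: p.name for p in written},
        )
        manifest_path = out / "manifest.json"
        _write_json(manifest.to_dict(), manifest_path)
        return manifest
    except SarcostageError:
        for p in written:  # remove partial outputs on failure
            p.unlink(missing_ok=True)
        raise
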