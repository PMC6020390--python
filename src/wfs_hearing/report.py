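"""Report bundles: cohort descriptives, session-1 tables, effect tables.

``run_report`` drives the whole pipeline from two CSV inputs (cohort
symptom table, long-format audiograms) to a directory of human-readable
tables plus one machine-readable JSON holding every number before
rounding.  All rounding goes through :mod:`wfs_hearing._format`, so the
text tables always equal the JSON after the documented rounding.
"""

from __future__ import annotations

import json
import logging
import os
import shutil
from dataclasses import dataclass, field

import pandas as pd

from ._format import round_db, round_stat, sii_percent
from .audiometry import SiiConstants, ValidationError
from .cohort import (
    SYMPTOMS,
    apply_exclusions,
    hearing_category_counts,
    load_cohort,
    summarize_cohort,
)
from .io import read_audiogram_csv
from .longitudinal import (
    OUTCOMES,
    build_long_table,
    estimate_annual_change,
    fit_random_slope,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated configuration for one report run."""

    cohort_path: str
    audiogram_path: str
    output_dir: str
    sii_constants_path: str | None = None
    subgroup: str = "whole"
    ear_roles: tuple[str, ...] = ("worse", "better")
    outcomes: tuple[str, ...] = OUTCOMES
    include_interaction: bool = True
    include_sex: bool = False
    random_intercept: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for path in (self.cohort_path, self.audiogram_path):
            if not os.path.exists(path):
                raise ValidationError(f"input path does not exist: {path}")
        if self.sii_constants_path and not os.path.exists(self.sii_constants_path):
            raise ValidationError(f"SII constants file not found: {self.sii_constants_path}")
        if self.subgroup not in ("whole", "known_hearing_loss"):
            raise ValidationError(f"unknown subgroup {self.subgroup!r}")
        for role in self.ear_roles:
            if role not in ("worse", "better"):
                raise ValidationError(f"unknown ear role {role!r}")
        for outcome in self.outcomes:
            if outcome not in OUTCOMES:
                raise ValidationError(f"unknown outcome {outcome!r}")


@dataclass
class ReportBundle:
    """Paths to the artifacts written by one run plus the raw numbers."""

    output_dir: str
    cohort_summary_csv: str
    session1_csv: str
    effects_csv: str
    summary_json: str
    exclusions_csv: str
    summary: dict = field(repr=False, default_factory=dict)


class ReportStageError(RuntimeError):
    """A report stage failed; partial outputs were removed."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"report stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _cohort_summary_frame(summary) -> pd.DataFrame:
    rows = []
    for sym in SYMPTOMS:
        n, mean, sd = summary.symptom_stats[sym]
        rows.append(
            {
                "symptom": sym,
                "n_diagnosed": n,
                "onset_mean": None if mean is None else round_db(mean),
                "onset_sd": None if sd is None else round_db(sd),
                "prevalence_pct": round_stat(100.0 * summary.prevalence[sym], 1),
                "first_symptom_count": summary.first_symptom_counts[sym],
            }
        )
    return pd.DataFrame(rows)


def run_report(config: RunConfig) -> ReportBundle:
    """Run the full pipeline and write the report bundle.

    Artifacts: cohort summary (CSV + text), session-1 descriptives per
    ear role, effect tables per outcome/ear role, the exclusion log and
    a machine-readable JSON with everything.  Any stage failure removes
    partial outputs and raises :class:`ReportStageError` naming the
    stage.
    """
    outdir = config.output_dir
    created = not os.path.exists(outdir)
    os.makedirs(outdir, exist_ok=True)
    stage = "setup"
    try:
        stage = "load"
        cohort = load_cohort(config.cohort_path)
        sessions = read_audiogram_csv(config.audiogram_path)
        constants = (
            SiiConstants.from_yaml(config.sii_constants_path)
            if config.sii_constants_path
            else SiiConstants.default()
        )

        stage = "cohort_summary"
        summary = summarize_cohort(cohort)
        cohort_frame = _cohort_summary_frame(summary)
        cohort_csv = os.path.join(outdir, "cohort_summary.csv")
        cohort_frame.to_csv(cohort_csv, index=False)
        chi = summary.chi_square_sex_snhl
        with open(os.path.join(outdir, "cohort_summary.txt"), "w", encoding="utf-8") as fh:
            fh.write(f"Cohort: n = {summary.n_patients} "
                     f"({summary.sex_counts['M']} M / {summary.sex_counts['F']} F), "
                     f"enrollment age {round_db(summary.enrollment_mean)} "
                     f"(SD {round_db(summary.enrollment_sd)})\n")
            fh.write(f"Cochlear implants: {summary.n_cochlear_implant}\n")
            if chi is not None:
                fh.write(f"Sex x SNHL chi-square = {round_stat(chi[0], 1)}, "
                         f"p = {round_stat(chi[1], 2)}\n")
            fh.write(cohort_frame.to_string(index=False) + "\n")

        stage = "exclusions"
        excl = apply_exclusions(sessions, cohort)
        excl_csv = os.path.join(outdir, "exclusions.csv")
        pd.DataFrame(
            [
                {
                    "patient_id": e.patient_id,
                    "session_index": e.session_index,
                    "ear": e.ear or "",
                    "reason": e.reason,
                }
                for e in excl.excluded
            ],
            columns=["patient_id", "session_index", "ear", "reason"],
        ).to_csv(excl_csv, index=False)

        stage = "session1_descriptives"
        session1_rows = []
        datasets = {}
        for role in config.ear_roles:
            data = build_long_table(
                excl.kept, role, constants, cohort=cohort, subgroup=config.subgroup
            )
            datasets[role] = data
            first = data.frame[data.frame["t"] == 0.0]
            for outcome in config.outcomes:
                vals = first[outcome]
                # SII is carried in percent; report integer percent per convention
                rnd = (lambda v: sii_percent(v / 100.0)) if outcome == "sii" else round_db
                session1_rows.append(
                    {
                        "ear_role": role,
                        "outcome": outcome,
                        "n": int(vals.notna().sum()),
                        "mean": rnd(vals.mean()),
                        "sd": rnd(vals.std(ddof=1)),
                        "min": rnd(vals.min()),
                        "max": rnd(vals.max()),
                    }
                )
        session1_csv = os.path.join(outdir, "session1_descriptives.csv")
        pd.DataFrame(session1_rows).to_csv(session1_csv, index=False)

        stage = "mixed_models"
        effect_rows = []
        fits_json = {}
        for role, data in datasets.items():
            for outcome in config.outcomes:
                fit = fit_random_slope(
                    data,
                    outcome=outcome,
                    include_interaction=config.include_interaction,
                    include_sex=config.include_sex,
                    random_intercept=config.random_intercept,
                )
                change = estimate_annual_change(fit)
                for term in fit.terms:
                    if term == "intercept":
                        continue
                    effect_rows.append(
                        {
                            "ear_role": role,
                            "outcome": outcome,
                            "term": term,
                            "F": round_stat(fit.f_stats[term]),
                            "p": round_stat(fit.p_values[term], 4),
                            "annual_change": change.label if term == "time" else "",
                        }
                    )
                fits_json[f"{role}/{outcome}"] = {
                    "params": fit.params,
                    "se": fit.se,
                    "f_stats": fit.f_stats,
                    "p_values": fit.p_values,
                    "slope_var": fit.slope_var,
                    "intercept_var": fit.intercept_var,
                    "resid_var": fit.resid_var,
                    "annual_change": change.value,
                    "annual_change_label": change.label,
                    "n_obs": fit.n_obs,
                    "n_patients": fit.n_patients,
                    "converged": fit.converged,
                    "notes": fit.notes,
                }
        effects_csv = os.path.join(outdir, "effect_tables.csv")
        pd.DataFrame(effect_rows).to_csv(effects_csv, index=False)

        stage = "summary_json"
        payload = {
            "config": {
                "subgroup": config.subgroup,
                "ear_roles": list(config.ear_roles),
                "outcomes": list(config.outcomes),
                "include_interaction": config.include_interaction,
                "include_sex": config.include_sex,
                "random_intercept": config.random_intercept,
                "seed": config.seed,
            },
            "cohort": {
                "n_patients": summary.n_patients,
                "sex_counts": summary.sex_counts,
                "enrollment_mean": summary.enrollment_mean,
                "enrollment_sd": summary.enrollment_sd,
                "n_cochlear_implant": summary.n_cochlear_implant,
                "hearing_categories": hearing_category_counts(cohort),
                "chi_square_sex_snhl": chi,
                "symptoms": {
                    s: {
                        "n": summary.symptom_stats[s][0],
                        "mean": summary.symptom_stats[s][1],
                        "sd": summary.symptom_stats[s][2],
                        "prevalence": summary.prevalence[s],
                        "first_symptom_count": summary.first_symptom_counts[s],
                    }
                    for s in SYMPTOMS
                },
            },
            "exclusions": {
                "n_excluded_records": len(excl.excluded),
                "n_sessions_kept": len(excl.kept),
            },
            "session1": session1_rows,
            "fits": fits_json,
        }
        summary_json = os.path.join(outdir, "summary.json")
        with open(summary_json, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

        return ReportBundle(
            output_dir=outdir,
            cohort_summary_csv=cohort_csv,
            session1_csv=session1_csv,
            effects_csv=effects_csv,
            summary_json=summary_json,
            exclusions_csv=excl_csv,
            summary=payload,
        )
    except Exception as exc:
        logger.error("report stage %s failed: %s", stage, exc)
        if created:
            shutil.rmtree(outdir, ignore_errors=True)
        else:
            for name in (
                "cohort_summary.csv", "cohort_summary.txt", "exclusions.csv",
                "session1_descriptives.csv", "effect_tables.csv", "summary.json",
            ):
                path = os.path.join(outdir, name)
                if os.path.exists(path):
                    os.remove(path)
        raise ReportStageError(stage, exc) from exc
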