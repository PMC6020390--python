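"""Random-slope longitudinal models of audiometric outcomes.

Builds per-ear-role long-format datasets (one row per patient-session)
and fits the linear mixed model

    y_ij = b0 + b1*t_ij + b2*age0c_i + b3*t_ij*age0c_i (+ sex terms)
           + u0_i + u1_i*t_ij + e_ij

where ``t`` is years since the patient's first analyzed session,
``age0c`` is age at that session centered at the sample mean, ``u0``
and ``u1`` are independent patient-level random intercept and slope,
and ``e`` is homoscedastic residual error.  Estimation is profiled REML
(see :mod:`wfs_hearing._reml`); fixed effects are tested with Wald F
statistics (F = (beta/se)^2 with a residual-style denominator df).
Because age is centered, ``b1`` is the estimated average annual change
at the sample's mean entry age, the quantity reported clinically.

Outcomes: ``hfa`` and ``pta`` in dB HL (worsening = increase) and
``sii`` in percentage points (worsening = decrease).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._reml import fit_lmm
from .audiometry import (
    AudiogramSession,
    SiiConstants,
    ValidationError,
    compute_ear_metrics,
    rank_ears,
)
from .cohort import PatientRecord

logger = logging.getLogger(__name__)

OUTCOMES: tuple[str, ...] = ("hfa", "pta", "sii")

#: Sign convention per outcome: +1 means larger values are worse.
WORSENING_SIGN: dict[str, int] = {"hfa": +1, "pta": +1, "sii": -1}

OUTCOME_UNITS: dict[str, str] = {"hfa": "dB", "pta": "dB", "sii": ""}


@dataclass
class LongitudinalDataset:
    """Long-format outcome table for one ear role.

    ``frame`` columns: patient_id, t (years since first analyzed
    session), age0 (age at first analyzed session), sex (may be NA),
    session_index, hfa, pta, sii (percent).
    """

    frame: pd.DataFrame
    ear_role: str  # "worse" | "better"
    subgroup: str = "whole"  # "whole" | "known_hearing_loss"
    skipped: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.ear_role not in ("worse", "better"):
            raise ValidationError(f"ear_role must be worse/better, got {self.ear_role}")
        if len(self.frame) and (self.frame["t"] < 0).any():
            raise ValidationError("time since first session must be non-negative")

    @property
    def n_patients(self) -> int:
        return self.frame["patient_id"].nunique()


def build_long_table(
    sessions: list[AudiogramSession],
    ear_role: str,
    constants: SiiConstants,
    cohort: list[PatientRecord] | None = None,
    subgroup: str = "whole",
    worse_ear_override: dict[str, str] | None = None,
) -> LongitudinalDataset:
    """Assemble the long-format table for one ear role.

    The worse/better assignment is made once per patient, from the first
    analyzed session with two clean ears, and held fixed across that
    patient's sessions (per-session reassignment would splice different
    ears into one trajectory).  Sessions where the assigned ear carries a
    conductive flag contribute no record.  ``subgroup``
    ``known_hearing_loss`` keeps only patients with diagnosed SNHL
    (requires ``cohort``).  ``worse_ear_override`` maps patient id to the
    side treated as worse, bypassing the measurement-based ranking
    (used to separate ranking effects from model behaviour in
    simulation studies).
    """
    by_patient: dict[str, list[AudiogramSession]] = {}
    for s in sorted(sessions, key=lambda s: (s.patient_id, s.age_at_session)):
        by_patient.setdefault(s.patient_id, []).append(s)

    sex_by_id = {r.patient_id: r.sex for r in (cohort or [])}
    if subgroup == "known_hearing_loss":
        if cohort is None:
            raise ValidationError("known_hearing_loss subgroup requires a cohort table")
        keep_ids = {r.patient_id for r in cohort if r.has_snhl}
    elif subgroup == "whole":
        keep_ids = None
    else:
        raise ValidationError(f"unknown subgroup {subgroup!r}")

    rows = []
    skipped: list[str] = []
    for pid, plist in by_patient.items():
        if keep_ids is not None and pid not in keep_ids:
            continue
        ages = [s.age_at_session for s in plist]
        if any(b <= a for a, b in zip(ages, ages[1:])):
            raise ValidationError(f"{pid}: session ages must be strictly increasing")
        if worse_ear_override is not None and pid in worse_ear_override:
            worse_side = worse_ear_override[pid]
        else:
            anchor = next(
                (s for s in plist if not (s.left.conductive_flag or s.right.conductive_flag)),
                None,
            )
            if anchor is None:
                skipped.append(pid)
                logger.info("%s: no session with two clean ears; patient omitted", pid)
                continue
            worse_side = rank_ears(anchor, constants)[0].ear
        assigned_side = worse_side if ear_role == "worse" else (
            "right" if worse_side == "left" else "left"
        )
        age0 = None
        for s in plist:
            ear = s.left if assigned_side == "left" else s.right
            if ear.conductive_flag:
                continue
            if age0 is None:
                age0 = s.age_at_session
            m = compute_ear_metrics(ear, constants)
            rows.append(
                {
                    "patient_id": pid,
                    "session_index": s.session_index,
                    "t": s.age_at_session - age0,
                    "age0": age0,
                    "sex": sex_by_id.get(pid),
                    "hfa": m.hfa,
                    "pta": m.pta,
                    "sii": 100.0 * m.sii,
                }
            )
        if age0 is None:
            skipped.append(pid)

    frame = pd.DataFrame(
        rows,
        columns=["patient_id", "session_index", "t", "age0", "sex", "hfa", "pta", "sii"],
    )
    return LongitudinalDataset(frame=frame, ear_role=ear_role, subgroup=subgroup, skipped=skipped)


@dataclass
class ModelFit:
    """REML fit of the random-slope model for one outcome."""

    outcome: str
    terms: list[str]
    params: dict[str, float]
    se: dict[str, float]
    f_stats: dict[str, float]
    p_values: dict[str, float]
    slope_var: float  # random-slope variance (delta^2)
    intercept_var: float | None  # random-intercept variance (tau^2), None if absent
    resid_var: float  # residual variance (epsilon^2)
    ddf: float
    n_obs: int
    n_patients: int
    converged: bool
    ci_time: tuple[float, float]
    patient_slopes: dict[str, float]
    age0_mean: float
    notes: list[str] = field(default_factory=list)


def _wald_tables(params, bse, terms, ddf):
    f_stats, p_values = {}, {}
    for name in terms:
        f = (params[name] / bse[name]) ** 2
        f_stats[name] = float(f)
        p_values[name] = float(stats.f.sf(f, 1, ddf))
    return f_stats, p_values


def fit_random_slope(
    data: LongitudinalDataset | pd.DataFrame,
    outcome: str = "hfa",
    include_interaction: bool = True,
    include_sex: bool = False,
    random_intercept: bool = True,
) -> ModelFit:
    """Fit the random-slope model for one outcome by REML.

    The default covariance has independent random intercept and random
    slope; ``random_intercept=False`` gives the pure random-slope model.
    A restricted-likelihood search that does not report convergence is
    noted in ``ModelFit.notes`` (estimates are still returned with
    diagnostics rather than discarded).
    """
    frame = data.frame if isinstance(data, LongitudinalDataset) else data
    if outcome not in OUTCOMES:
        raise ValidationError(f"unknown outcome {outcome!r}")
    df = frame.dropna(subset=[outcome]).copy()
    counts = df.groupby("patient_id")["t"].count()
    if (counts >= 2).sum() < 2:
        raise ValidationError(
            "random-slope fit requires at least 2 patients with at least 2 time points"
        )
    age0_mean = float(df.drop_duplicates("patient_id")["age0"].mean())
    df["age0c"] = df["age0"] - age0_mean

    terms = ["intercept", "time", "age0"]
    cols = [np.ones(len(df)), df["t"].to_numpy(), df["age0c"].to_numpy()]
    if include_interaction:
        terms.append("time:age0")
        cols.append(df["t"].to_numpy() * df["age0c"].to_numpy())
    if include_sex:
        if df["sex"].isna().any():
            raise ValidationError("include_sex requires sex for every patient")
        male = (df["sex"] == "M").astype(float).to_numpy()
        terms += ["sex", "time:sex"]
        cols += [male, df["t"].to_numpy() * male]
    X = np.column_stack(cols)
    y = df[outcome].to_numpy(dtype=float)
    groups = df["patient_id"].to_numpy()

    notes: list[str] = []
    t_col = df["t"].to_numpy(dtype=float)
    if random_intercept:
        z_columns = [np.ones(len(df)), t_col]
        slope_col = 1
    else:
        z_columns = [t_col]
        slope_col = 0
    res = fit_lmm(y, X, groups, z_columns)
    if not res.converged:
        notes.append("restricted-likelihood search did not report convergence")
        logger.warning("REML search did not report convergence for %s", outcome)

    params = {t: float(v) for t, v in zip(terms, res.beta)}
    bse = {t: float(v) for t, v in zip(terms, np.sqrt(np.diag(res.cov_beta)))}
    n_obs, n_pat = len(df), int(df["patient_id"].nunique())
    ddf = max(float(n_obs - n_pat - X.shape[1]), 1.0)
    f_stats, p_values = _wald_tables(params, bse, terms, ddf)

    intercept_var = float(res.vcomp[0]) if random_intercept else None
    slope_var = float(res.vcomp[slope_col])

    tcrit = stats.t.ppf(0.975, ddf)
    ci_time = (
        params["time"] - tcrit * bse["time"],
        params["time"] + tcrit * bse["time"],
    )
    patient_slopes = {
        str(pid): params["time"] + float(u[slope_col]) for pid, u in res.ranef.items()
    }
    return ModelFit(
        outcome=outcome,
        terms=terms,
        params=params,
        se=bse,
        f_stats=f_stats,
        p_values=p_values,
        slope_var=slope_var,
        intercept_var=intercept_var,
        resid_var=float(res.sigma2),
        ddf=ddf,
        n_obs=n_obs,
        n_patients=n_pat,
        converged=bool(res.converged),
        ci_time=(float(ci_time[0]), float(ci_time[1])),
        patient_slopes=patient_slopes,
        age0_mean=age0_mean,
        notes=notes,
    )


@dataclass(frozen=True)
class AnnualChangeEstimate:
    """Estimated average change in an outcome over one year."""

    outcome: str
    value: float  # signed model slope (outcome units per year)
    direction: str  # "increase" | "decrease" | "no change"
    label: str


def estimate_annual_change(fit: ModelFit) -> AnnualChangeEstimate:
    """Average annual change at the sample's mean entry age.

    With the age-centered interaction model this is exactly the ``time``
    coefficient.  The label reports the magnitude with an
    increase/decrease direction (HFA/PTA worsen upward, SII downward).
    """
    beta = fit.params["time"]
    unit = OUTCOME_UNITS[fit.outcome]
    unit_sfx = f" {unit}" if unit else ""
    if beta == 0:
        return AnnualChangeEstimate(fit.outcome, 0.0, "no change", f"0.00{unit_sfx} (no change)")
    direction = "increase" if beta > 0 else "decrease"
    label = f"{abs(beta):.2f}{unit_sfx} {direction}"
    return AnnualChangeEstimate(fit.outcome, float(beta), direction, label)
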