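"""Reading and writing the long-format audiogram CSV.

Schema (UTF-8, header required): patient_id, age_at_session,
session_index, ear{left|right}, frequency_hz, threshold_db_hl (empty
when no response), no_response{0|1}, conductive{0|1}, invalid{0|1}.
One row per measured frequency; the QC flags apply to the whole ear at
that session and must agree across its rows.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .audiometry import AudiogramSession, EarAudiogram, Threshold, ValidationError

AUDIOGRAM_COLUMNS = [
    "patient_id",
    "age_at_session",
    "session_index",
    "ear",
    "frequency_hz",
    "threshold_db_hl",
    "no_response",
    "conductive",
    "invalid",
]


def sessions_to_frame(sessions: list[AudiogramSession]) -> pd.DataFrame:
    """Flatten sessions into the long-format audiogram table."""
    rows = []
    for s in sessions:
        for ear in (s.left, s.right):
            for freq in sorted(ear.thresholds):
                thr = ear.thresholds[freq]
                rows.append(
                    {
                        "patient_id": s.patient_id,
                        "age_at_session": s.age_at_session,
                        "session_index": s.session_index,
                        "ear": ear.ear,
                        "frequency_hz": freq,
                        "threshold_db_hl": "" if thr.no_response else thr.level,
                        "no_response": int(thr.no_response),
                        "conductive": int(ear.conductive_flag),
                        "invalid": int(ear.invalid_flag),
                    }
                )
    return pd.DataFrame(rows, columns=AUDIOGRAM_COLUMNS)


def frame_to_sessions(df: pd.DataFrame) -> list[AudiogramSession]:
    """Assemble validated sessions from a long-format audiogram table."""
    missing = set(AUDIOGRAM_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"audiogram table missing columns {sorted(missing)}")
    sessions: list[AudiogramSession] = []
    grouped = df.groupby(["patient_id", "session_index"], sort=True)
    for (pid, sidx), g in grouped:
        ages = g["age_at_session"].astype(float).unique()
        if len(ages) != 1:
            raise ValidationError(f"{pid} session {sidx}: inconsistent ages {ages}")
        ears = {}
        for side, eg in g.groupby("ear"):
            thresholds = {}
            for _, row in eg.iterrows():
                freq = int(row["frequency_hz"])
                nr = bool(int(row["no_response"]))
                raw = row["threshold_db_hl"]
                level = None
                if not nr:
                    if raw is None or (isinstance(raw, float) and np.isnan(raw)) or str(raw).strip() == "":
                        raise ValidationError(
                            f"{pid} session {sidx} {side} {freq} Hz: missing level without no_response"
                        )
                    level = float(raw)
                thresholds[freq] = Threshold(freq, level=level, no_response=nr)
            for flag in ("conductive", "invalid"):
                if eg[flag].astype(int).nunique() != 1:
                    raise ValidationError(
                        f"{pid} session {sidx} {side}: inconsistent {flag} flag"
                    )
            ears[side] = EarAudiogram(
                ear=side,
                thresholds=thresholds,
                conductive_flag=bool(int(eg["conductive"].iloc[0])),
                invalid_flag=bool(int(eg["invalid"].iloc[0])),
            )
        if set(ears) != {"left", "right"}:
            raise ValidationError(f"{pid} session {sidx}: both ears required")
        sessions.append(
            AudiogramSession(
                patient_id=str(pid),
                age_at_session=float(ages[0]),
                session_index=int(sidx),
                left=ears["left"],
                right=ears["right"],
            )
        )
    # enforce strictly increasing ages within each patient
    by_pid: dict[str, list[AudiogramSession]] = {}
    for s in sessions:
        by_pid.setdefault(s.patient_id, []).append(s)
    for pid, plist in by_pid.items():
        plist.sort(key=lambda s: s.session_index)
        ages = [s.age_at_session for s in plist]
        if any(b <= a for a, b in zip(ages, ages[1:])):
            raise ValidationError(f"{pid}: session ages must be strictly increasing")
    return sessions


def read_audiogram_csv(path) -> list[AudiogramSession]:
    return frame_to_sessions(pd.read_csv(path, keep_default_na=False, na_values=[]))


def write_audiogram_csv(sessions: list[AudiogramSession], path) -> None:
    sessions_to_frame(sessions).to_csv(path, index=False)
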