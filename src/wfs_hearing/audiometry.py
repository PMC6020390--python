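"""Audiogram data model and per-ear audiometric metrics.

Implements the measures used to track sensorineural hearing loss in
Wolfram syndrome natural-history cohorts:

* **PTA** — pure-tone average of the air-conduction thresholds at 0.5,
  1 and 2 kHz (dB HL).
* **HFA** — high-frequency average of the 4 and 8 kHz thresholds; a
  no-response at the equipment limit is replaced by 95 dB HL.
* **unaided SII** — octave-band Speech Intelligibility Index, the
  importance-weighted proportion of the speech spectrum that is audible
  given the pure-tone thresholds.
* hearing-status classification (normal vs. hearing loss, with a
  profound flag) and the worse/better ear ranking used to split
  longitudinal analyses by ear role.

Thresholds live on a 5-dB grid between -10 and 120 dB HL; a stimulus at
the equipment limit that is not heard is recorded as ``no_response``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import yaml

logger = logging.getLogger(__name__)

#: Octave frequencies that every analyzable audiogram must contain (Hz).
OCTAVE_FREQUENCIES: tuple[int, ...] = (250, 500, 1000, 2000, 4000, 8000)

#: Frequencies an audiogram may contain (octaves plus inter-octaves, Hz).
VALID_FREQUENCIES: tuple[int, ...] = (
    250, 500, 750, 1000, 1500, 2000, 3000, 4000, 6000, 8000,
)

#: Frequencies entering the pure-tone average (Hz).
PTA_FREQUENCIES: tuple[int, ...] = (500, 1000, 2000)

#: Frequencies entering the high-frequency average (Hz).
HFA_FREQUENCIES: tuple[int, ...] = (4000, 8000)

#: Level substituted for a no-response threshold in PTA/HFA computation.
NO_RESPONSE_SUBSTITUTE: float = 95.0

#: An ear is classified as hearing loss when PTA exceeds this (dB HL) or
#: when more than two measured frequencies exceed it.
NORMAL_LIMIT_DB: float = 20.0

#: PTA at or above this level is profound hearing loss (dB HL).
PROFOUND_PTA_DB: float = 80.0

#: Unaided SII below this proportion suggests significantly compromised
#: speech audibility (amplification-candidacy screen).
SII_COMPROMISE_LIMIT: float = 0.75


class ValidationError(ValueError):
    """An audiogram or parameter set violates a structural requirement."""


class ConfigurationError(ValueError):
    """SII constants are internally inconsistent."""


@dataclass(frozen=True)
class Threshold:
    """One air-conduction threshold.

    ``level`` is present exactly when the tone was heard; ``no_response``
    marks a stimulus at the equipment limit that was not heard.  Levels
    are integer multiples of 5 dB in [-10, 120] (the clinical step size).
    """

    frequency: int
    level: float | None = None
    no_response: bool = False

    def __post_init__(self) -> None:
        if self.frequency not in VALID_FREQUENCIES:
            raise ValidationError(
                f"unsupported audiometric frequency {self.frequency} Hz"
            )
        if self.no_response == (self.level is not None):
            raise ValidationError(
                f"{self.frequency} Hz: exactly one of level / no_response required"
            )
        if self.level is not None:
            if not (-10 <= self.level <= 120):
                raise ValidationError(
                    f"{self.frequency} Hz: level {self.level} dB HL out of range"
                )
            if self.level % 5 != 0:
                raise ValidationError(
                    f"{self.frequency} Hz: level {self.level} is not a multiple of 5 dB"
                )

    def exceeds(self, limit: float) -> bool:
        """True when the threshold is above ``limit`` (no-response always is)."""
        return True if self.no_response else self.level > limit


@dataclass
class EarAudiogram:
    """One ear's thresholds for one session, with QC flags.

    ``conductive_flag`` marks a session with a transient conductive
    component (tympanometry screen); ``invalid_flag`` marks an audiogram
    judged inconsistent with surrounding sessions.  Both exclude the ear
    from sensorineural analysis.
    """

    ear: str
    thresholds: Mapping[int, Threshold]
    conductive_flag: bool = False
    invalid_flag: bool = False

    def __post_init__(self) -> None:
        if self.ear not in ("left", "right"):
            raise ValidationError(f"ear must be 'left' or 'right', got {self.ear!r}")
        missing = [f for f in OCTAVE_FREQUENCIES if f not in self.thresholds]
        if missing:
            raise ValidationError(
                f"{self.ear} ear: missing octave frequencies {missing}"
            )
        for freq, thr in self.thresholds.items():
            if thr.frequency != freq:
                raise ValidationError(
                    f"threshold keyed {freq} Hz carries frequency {thr.frequency} Hz"
                )

    def level_for_average(self, frequency: int) -> tuple[float, bool]:
        """Level used in PTA/HFA at ``frequency``.

        Returns ``(level, substituted)`` where ``substituted`` is True when
        a no-response was replaced by 95 dB HL.
        """
        thr = self.thresholds.get(frequency)
        if thr is None:
            raise ValidationError(
                f"{self.ear} ear: required frequency {frequency} Hz not measured"
            )
        if thr.no_response:
            logger.info(
                "%s ear: no response at %d Hz, substituting %.0f dB HL",
                self.ear, frequency, NO_RESPONSE_SUBSTITUTE,
            )
            return NO_RESPONSE_SUBSTITUTE, True
        return float(thr.level), False


@dataclass
class AudiogramSession:
    """Both ears of one patient at one visit."""

    patient_id: str
    age_at_session: float
    session_index: int
    left: EarAudiogram
    right: EarAudiogram

    def __post_init__(self) -> None:
        if self.session_index < 1:
            raise ValidationError("session_index must be >= 1")
        if self.age_at_session < 0:
            raise ValidationError("age_at_session must be non-negative")


@dataclass
class SiiConstants:
    """Octave-band constants for the unaided SII.

    ``importance`` weights sum to one; ``band_speech_level`` is the
    long-term average speech level per band in dB HL at average vocal
    effort.  A band is fully audible when the threshold sits
    ``peak_offset`` dB below the band level plus the dynamic range, and
    inaudible ``dynamic_range - peak_offset`` dB above the band level.
    """

    bands: Sequence[int]
    importance: Sequence[float]
    band_speech_level: Sequence[float]
    dynamic_range: float = 30.0
    peak_offset: float = 15.0

    def __post_init__(self) -> None:
        if not (len(self.bands) == len(self.importance) == len(self.band_speech_level)):
            raise ConfigurationError("bands/importance/band_speech_level lengths differ")
        if any(w < 0 for w in self.importance):
            raise ConfigurationError("importance weights must be non-negative")
        if abs(sum(self.importance) - 1.0) > 1e-9:
            raise ConfigurationError(
                f"importance weights sum to {sum(self.importance)!r}, expected 1"
            )
        if self.dynamic_range <= 0:
            raise ConfigurationError("dynamic_range must be positive")

    @classmethod
    def from_yaml(cls, path) -> "SiiConstants":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls(
            bands=tuple(raw["bands"]),
            importance=tuple(float(x) for x in raw["importance"]),
            band_speech_level=tuple(float(x) for x in raw["band_speech_level"]),
            dynamic_range=float(raw.get("dynamic_range", 30.0)),
            peak_offset=float(raw.get("peak_offset", 15.0)),
        )

    @classmethod
    def default(cls) -> "SiiConstants":
        from importlib.resources import files

        return cls.from_yaml(files("wfs_hearing.data") / "sii_constants.yaml")


@dataclass
class EarMetrics:
    """Per-ear summary metrics for one session."""

    pta: float
    hfa: float
    sii: float
    category: str  # "normal" | "hearing_loss"
    profound: bool
    amplification_candidate: bool
    substituted_frequencies: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not 0.0 <= self.sii <= 1.0:
            raise ValidationError(f"SII {self.sii} outside [0, 1]")
        if self.profound and self.category != "hearing_loss":
            raise ValidationError("profound loss must be categorized as hearing_loss")


def pta(ear: EarAudiogram) -> float:
    """Pure-tone average of 0.5, 1 and 2 kHz in dB HL (unrounded)."""
    levels = [ear.level_for_average(f)[0] for f in PTA_FREQUENCIES]
    return sum(levels) / len(levels)


def hfa(ear: EarAudiogram) -> float:
    """High-frequency average of 4 and 8 kHz in dB HL (unrounded).

    No-response at either frequency contributes 95 dB HL.
    """
    levels = [ear.level_for_average(f)[0] for f in HFA_FREQUENCIES]
    return sum(levels) / len(levels)


def classify_hearing(ear: EarAudiogram) -> tuple[str, bool]:
    """Classify one ear as ``("normal"|"hearing_loss", profound)``.

    Hearing is abnormal when PTA > 20 dB HL or when more than two of the
    measured frequencies (octaves plus any recorded inter-octaves) exceed
    20 dB HL; a no-response counts as exceeding.  Profound means
    PTA >= 80 dB HL.
    """
    if ear.invalid_flag:
        raise ValidationError(f"{ear.ear} ear flagged invalid: classification refused")
    mean_pta = pta(ear)
    n_above = sum(1 for t in ear.thresholds.values() if t.exceeds(NORMAL_LIMIT_DB))
    loss = mean_pta > NORMAL_LIMIT_DB or n_above >= 3
    profound = mean_pta >= PROFOUND_PTA_DB
    return ("hearing_loss" if loss else "normal"), profound


def band_audibility(threshold: float, band_level: float, constants: SiiConstants) -> float:
    """Audible proportion of one speech band given a pure-tone threshold.

    Linear between the band's speech peak (``band_level + peak_offset``)
    and the bottom of its dynamic range, clipped to [0, 1].  An infinite
    threshold (no response) yields 0.
    """
    if math.isinf(threshold):
        return 0.0
    raw = (band_level + constants.peak_offset - threshold) / constants.dynamic_range
    return min(1.0, max(0.0, raw))


def sii_unaided(ear: EarAudiogram, constants: SiiConstants) -> float:
    """Unaided octave-band SII in [0, 1].

    Importance-weighted sum of per-band audibilities over the six octave
    bands; monotone non-increasing in every threshold.
    """
    total = 0.0
    for freq, weight, level in zip(
        constants.bands, constants.importance, constants.band_speech_level
    ):
        thr = ear.thresholds.get(freq)
        if thr is None:
            raise ValidationError(
                f"{ear.ear} ear: SII band {freq} Hz not measured"
            )
        t = math.inf if thr.no_response else float(thr.level)
        total += weight * band_audibility(t, level, constants)
    # guard against float round-off outside [0, 1]
    return min(1.0, max(0.0, total))


def compute_ear_metrics(ear: EarAudiogram, constants: SiiConstants) -> EarMetrics:
    """All per-ear metrics for one session."""
    substituted = tuple(
        f
        for f in PTA_FREQUENCIES + HFA_FREQUENCIES
        if f in ear.thresholds and ear.thresholds[f].no_response
    )
    category, profound = classify_hearing(ear)
    sii = sii_unaided(ear, constants)
    return EarMetrics(
        pta=pta(ear),
        hfa=hfa(ear),
        sii=sii,
        category=category,
        profound=profound,
        amplification_candidate=sii < SII_COMPROMISE_LIMIT,
        substituted_frequencies=substituted,
    )


def rank_ears(
    session: AudiogramSession, constants: SiiConstants
) -> tuple[EarAudiogram, EarAudiogram]:
    """Return ``(worse, better)`` ear for one session.

    The worse ear has the lower unaided SII; ties fall back to the higher
    HFA, then the higher PTA, and a full tie deterministically designates
    the left ear as worse.
    """
    for ear in (session.left, session.right):
        if ear.invalid_flag:
            raise ValidationError(
                f"session {session.patient_id}/{session.session_index}: "
                f"{ear.ear} ear invalid, cannot rank ears"
            )
    left, right = session.left, session.right
    key_left = (-sii_unaided(left, constants), hfa(left), pta(left))
    key_right = (-sii_unaided(right, constants), hfa(right), pta(right))
    if key_left == key_right:
        logger.info(
            "session %s/%d: ears fully tied, designating left as worse",
            session.patient_id, session.session_index,
        )
        return left, right
    return (left, right) if key_left > key_right else (right, left)


def with_flags(
    ear: EarAudiogram, conductive: bool | None = None, invalid: bool | None = None
) -> EarAudiogram:
    """Copy of ``ear`` with QC flags replaced (convenience for pipelines)."""
    return replace(
        ear,
        conductive_flag=ear.conductive_flag if conductive is None else conductive,
        invalid_flag=ear.invalid_flag if invalid is None else invalid,
    )
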