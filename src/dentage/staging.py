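"""Tooth developmental staging and maturity/sum scores.

Implements the two classical scoring systems for the seven left mandibular
permanent teeth (FDI 31-37):

* **Demirjian**: each tooth is staged into eight crown/root formation stages
  A-H (plus "no calcification", coded ``0``); stages are converted to
  sex-specific self-weighted scores whose sum is a 0-100 maturity score, and
  the maturity score is read against age norms to give a dental age.
* **Nolla**: each tooth is staged on a 0-10 scale, with fractional readings
  on the lattice {k, k+0.2, k+0.5, k+0.7} (k = 0..9) plus 10.0; the seven
  stage values are summed (0-70) and the sum is read against age norms.

The numeric content of the packaged scoring and age-norm tables is a
synthetic surrogate for the original published reference tables (see the
table files and ``docs/methods.md``); the scoring machinery itself is exact.
"""

from __future__ import annotations

import csv
import datetime as _dt
import hashlib
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, NamedTuple

import numpy as np

from .errors import (
    ConfigurationError,
    IncompleteRecordError,
    InvalidIntervalError,
    StageLookupError,
)

#: FDI codes of the seven left mandibular permanent teeth, incisor to molar.
FDI_TEETH: tuple[int, ...] = (31, 32, 33, 34, 35, 36, 37)

#: Demirjian stage vocabulary in developmental order. "0" = no calcification.
DEMIRJIAN_STAGES: tuple[str, ...] = ("0", "A", "B", "C", "D", "E", "F", "G", "H")

_NOLLA_FRACTIONS = (0.0, 0.2, 0.5, 0.7)

#: Admissible Nolla stage readings: k, k+0.2, k+0.5, k+0.7 for k=0..9, and 10.
NOLLA_LATTICE: tuple[float, ...] = tuple(
    round(k + f, 1) for k in range(10) for f in _NOLLA_FRACTIONS
) + (10.0,)

_NOLLA_LATTICE_ARR = np.asarray(NOLLA_LATTICE)
_NOLLA_SET = frozenset(NOLLA_LATTICE)

DAYS_PER_YEAR = 365.25

SEXES = ("male", "female")


def is_nolla_stage(value: float) -> bool:
    """True if *value* is a member of the Nolla stage lattice."""
    return round(float(value), 1) in _NOLLA_SET and math.isclose(
        value, round(value, 1), abs_tol=1e-9
    )


def snap_to_nolla_lattice(value: float) -> float:
    """Nearest admissible Nolla stage to *value* (clipped to [0, 10])."""
    idx = int(np.argmin(np.abs(_NOLLA_LATTICE_ARR - float(value))))
    return NOLLA_LATTICE[idx]


def _normalise_demirjian(symbol: str | None) -> str | None:
    if symbol is None:
        return None
    s = str(symbol).strip()
    if s in ("", "none", "None", "NONE"):
        return "0"
    s = s.upper()
    if s not in DEMIRJIAN_STAGES:
        raise ValueError(f"unknown Demirjian stage {symbol!r}")
    return s


@dataclass(frozen=True)
class ToothStage:
    """Stage assignment for one tooth under either or both systems.

    Parameters
    ----------
    tooth:
        FDI code, one of 31-37.
    demirjian:
        Stage symbol ``0``/``A``-``H`` (``none`` is accepted and normalised
        to ``0``), or None if not assessed.
    nolla:
        Lattice value in {k, k+0.2, k+0.5, k+0.7, 10.0}, or None.
    """

    tooth: int
    demirjian: str | None = None
    nolla: float | None = None

    def __post_init__(self) -> None:
        if self.tooth not in FDI_TEETH:
            raise ValueError(f"tooth {self.tooth} is not one of FDI {FDI_TEETH}")
        object.__setattr__(self, "demirjian", _normalise_demirjian(self.demirjian))
        if self.nolla is not None:
            if not is_nolla_stage(self.nolla):
                raise ValueError(
                    f"Nolla stage {self.nolla!r} is not on the admissible "
                    "lattice {k, k+0.2, k+0.5, k+0.7, 10.0}"
                )
            object.__setattr__(self, "nolla", round(float(self.nolla), 1))


@dataclass(frozen=True)
class StageRecord:
    """One subject: sex, chronological age, and stages for all seven teeth."""

    subject_id: str
    sex: str
    ca_years: float
    stages: tuple[ToothStage, ...]

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if not (math.isfinite(self.ca_years) and 0 < self.ca_years < 25):
            raise ValueError(f"ca_years must be finite in (0, 25), got {self.ca_years}")
        teeth = tuple(s.tooth for s in self.stages)
        if sorted(teeth) != list(FDI_TEETH):
            raise ValueError(
                f"stages must cover each of FDI {FDI_TEETH} exactly once, got {teeth}"
            )
        object.__setattr__(
            self, "stages", tuple(sorted(self.stages, key=lambda s: s.tooth))
        )

    def stage_for(self, tooth: int) -> ToothStage:
        return self.stages[FDI_TEETH.index(tooth)]


class AgeEstimate(NamedTuple):
    """A dental-age readout plus whether it was clamped to a boundary."""

    age: float
    clamped: bool


# ---------------------------------------------------------------------------
# Packaged lookup tables
# ---------------------------------------------------------------------------

_DATA_PACKAGE = "dentage.data"


def _read_packaged_csv(name: str) -> list[dict[str, str]]:
    ref = resources.files(_DATA_PACKAGE).joinpath(name)
    try:
        text = ref.read_text(encoding="utf-8")
    except FileNotFoundError as exc:  # pragma: no cover - packaging defect
        raise ConfigurationError(f"packaged table {name} not found") from exc
    return list(csv.DictReader(text.splitlines()))


def verify_data_manifest() -> dict[str, bool]:
    """Check packaged table files against their recorded SHA-256 digests."""
    manifest = json.loads(
        resources.files(_DATA_PACKAGE).joinpath("manifest.json").read_text()
    )
    out = {}
    for name, digest in manifest["sha256"].items():
        data = resources.files(_DATA_PACKAGE).joinpath(name).read_bytes()
        out[name] = hashlib.sha256(data).hexdigest() == digest
    return out


@dataclass
class ScoreLookup:
    """Scoring and age-norm tables for one (method, sex) combination.

    ``stage_scores`` maps (tooth, stage symbol) to the self-weighted score
    contribution (Demirjian only; empty for Nolla). ``age_norms`` is an
    ordered table of (age, expected score) pairs used for score-to-age
    interpolation.
    """

    method: str
    sex: str
    stage_scores: dict[tuple[int, str], float] = field(default_factory=dict)
    age_norms: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.method not in ("demirjian", "nolla"):
            raise ConfigurationError(f"unknown method {self.method!r}")
        if self.sex not in SEXES:
            raise ConfigurationError(f"unknown sex {self.sex!r}")
        # invariants: stage scores non-decreasing per tooth; norms strictly
        # increasing in age and non-decreasing in score
        for tooth in FDI_TEETH:
            prev = -math.inf
            for stage in DEMIRJIAN_STAGES:
                if (tooth, stage) in self.stage_scores:
                    score = self.stage_scores[(tooth, stage)]
                    if score < prev:
                        raise ConfigurationError(
                            f"stage scores for tooth {tooth} not monotone at {stage}"
                        )
                    prev = score
        ages = [a for a, _ in self.age_norms]
        scores = [s for _, s in self.age_norms]
        if any(a2 <= a1 for a1, a2 in zip(ages, ages[1:])):
            raise ConfigurationError("age_norms ages must be strictly increasing")
        if any(s2 < s1 for s1, s2 in zip(scores, scores[1:])):
            raise ConfigurationError("age_norms scores must be non-decreasing")

    @classmethod
    def load(cls, method: str, sex: str) -> "ScoreLookup":
        """Load the packaged (synthetic surrogate) tables for *method*, *sex*."""
        stage_scores: dict[tuple[int, str], float] = {}
        if method == "demirjian":
            rows = _read_packaged_csv(f"demirjian_scores_{sex}_synthetic.csv")
            for row in rows:
                stage_scores[(int(row["tooth"]), row["stage"])] = float(row["score"])
        norm_rows = _read_packaged_csv(f"{method}_age_norms_{sex}_synthetic.csv")
        norms = tuple(
            (float(r["age_years"]), float(r["score"])) for r in norm_rows
        )
        return cls(method=method, sex=sex, stage_scores=stage_scores, age_norms=norms)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def chronological_age(dob: _dt.date, exam: _dt.date) -> float:
    """Chronological age in decimal years: calendar days / 365.25.

    Raises :class:`InvalidIntervalError` unless *exam* is strictly after
    *dob*. Rounding is left to presentation.
    """
    if exam <= dob:
        raise InvalidIntervalError(
            f"examination date {exam} is not after date of birth {dob}"
        )
    return (exam - dob).days / DAYS_PER_YEAR


def nolla_sum(record: StageRecord) -> float:
    """Sum of the seven Nolla stage values; range [0, 70]."""
    values = []
    for stage in record.stages:
        if stage.nolla is None:
            raise IncompleteRecordError(
                f"subject {record.subject_id}: tooth {stage.tooth} has no Nolla stage"
            )
        values.append(stage.nolla)
    return float(round(sum(values), 10))


def demirjian_maturity(record: StageRecord, lookup: ScoreLookup | None = None) -> float:
    """Sex-specific Demirjian maturity score (0-100) for *record*."""
    if lookup is None:
        lookup = ScoreLookup.load("demirjian", record.sex)
    if lookup.sex != record.sex:
        raise ConfigurationError(
            f"lookup is for {lookup.sex}, record {record.subject_id} is {record.sex}"
        )
    total = 0.0
    for stage in record.stages:
        if stage.demirjian is None:
            raise IncompleteRecordError(
                f"subject {record.subject_id}: tooth {stage.tooth} has no "
                "Demirjian stage"
            )
        key = (stage.tooth, stage.demirjian)
        if key not in lookup.stage_scores:
            raise StageLookupError(f"no score for tooth/stage {key}")
        total += lookup.stage_scores[key]
    return round(total, 10)


def score_to_age_lookup(lookup: ScoreLookup, score: float) -> AgeEstimate:
    """Dental age for *score* by piecewise-linear interpolation in age norms.

    Scores outside the tabulated range clamp to the boundary age and set the
    ``clamped`` flag; no extrapolation is performed.
    """
    if not lookup.age_norms:
        raise ConfigurationError("empty age-norms table")
    ages = np.array([a for a, _ in lookup.age_norms])
    scores = np.array([s for _, s in lookup.age_norms])
    if score < scores[0]:
        return AgeEstimate(float(ages[0]), True)
    if score > scores[-1]:
        return AgeEstimate(float(ages[-1]), True)
    return AgeEstimate(float(np.interp(score, scores, ages)), False)


def estimate_da_original(
    records: Iterable[StageRecord], method: str
) -> list[AgeEstimate]:
    """Dental ages for *records* under the Demirjian or Nolla method."""
    lookups = {sex: ScoreLookup.load(method, sex) for sex in SEXES}
    out = []
    for rec in records:
        score = (
            demirjian_maturity(rec, lookups[rec.sex])
            if method == "demirjian"
            else nolla_sum(rec)
        )
        out.append(score_to_age_lookup(lookups[rec.sex], score))
    return out
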