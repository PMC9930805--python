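"""CSV/JSON/YAML round-tripping for cohorts, models, and reports.

The cohort CSV dialect is one row per subject: ``subject_id``, ``sex``,
``ca_years`` (or ``dob`` and ``exam_date`` ISO dates, from which the
chronological age is computed), ``dem_31``..``dem_37`` and/or
``nolla_31``..``nolla_37``. UTF-8, header required, dot decimal separator.
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from .cohort import CohortCell, CohortDesign, GeneratorConfig
from .errors import ConfigurationError, IncompleteRecordError
from .staging import FDI_TEETH, StageRecord, ToothStage, chronological_age


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    """Read a cohort CSV, deriving ``ca_years`` from dates when needed."""
    frame = pd.read_csv(path)
    if "ca_years" not in frame.columns:
        if not {"dob", "exam_date"} <= set(frame.columns):
            raise ConfigurationError(
                f"{path}: need a ca_years column or dob + exam_date columns"
            )
        frame["ca_years"] = [
            chronological_age(_dt.date.fromisoformat(d), _dt.date.fromisoformat(e))
            for d, e in zip(frame["dob"], frame["exam_date"])
        ]
    return frame


def write_cohort_csv(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, index=False)


def records_from_frame(frame: pd.DataFrame) -> list[StageRecord]:
    """Convert cohort rows into validated :class:`StageRecord` objects."""
    records = []
    for _, row in frame.iterrows():
        stages = []
        for tooth in FDI_TEETH:
            dem = row.get(f"dem_{tooth}")
            nol = row.get(f"nolla_{tooth}")
            if dem is None and nol is None:
                raise IncompleteRecordError(
                    f"subject {row.get('subject_id')}: no stage columns for "
                    f"tooth {tooth}"
                )
            stages.append(
                ToothStage(
                    tooth,
                    demirjian=None if pd.isna(dem) else str(dem),
                    nolla=None if pd.isna(nol) else float(nol),
                )
            )
        records.append(
            StageRecord(
                subject_id=str(row.get("subject_id", "")),
                sex=str(row["sex"]),
                ca_years=float(row["ca_years"]),
                stages=tuple(stages),
            )
        )
    return records


def design_from_obj(obj: Any) -> CohortDesign:
    if obj in (None, "default"):
        return CohortDesign.default()
    cells = tuple(
        CohortCell(
            age_lower=int(c["age_lower"]),
            sex=str(c["sex"]),
            n_train=int(c["n_train"]),
            n_test=int(c["n_test"]),
        )
        for c in obj
    )
    return CohortDesign(cells)


def generator_config_from_yaml(path: str | Path) -> GeneratorConfig:
    """Load a :class:`GeneratorConfig` from a YAML file."""
    try:
        payload = yaml.safe_load(Path(path).read_text()) or {}
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"malformed YAML in {path}: {exc}") from exc
    if not isinstance(payload, dict):
        raise ConfigurationError(f"{path}: top-level YAML must be a mapping")
    kwargs: dict[str, Any] = {}
    kwargs["design"] = design_from_obj(payload.get("design"))
    if "coefficients" in payload:
        kwargs["coefficients"] = {
            sex: tuple(float(v) for v in coef)
            for sex, coef in payload["coefficients"].items()
        }
    for key in ("score_noise_sd", "per_tooth_jitter_sd", "seed", "snap_stages"):
        if key in payload:
            kwargs[key] = payload[key]
    if "tooth_profile" in payload:
        kwargs["tooth_profile"] = tuple(float(w) for w in payload["tooth_profile"])
    return GeneratorConfig(**kwargs)


def generator_provenance(config: GeneratorConfig) -> dict:
    """JSON-serialisable record of the generation parameters."""
    return {
        "seed": config.seed,
        "score_noise_sd": config.score_noise_sd,
        "per_tooth_jitter_sd": config.per_tooth_jitter_sd,
        "tooth_profile": list(config.tooth_profile),
        "snap_stages": config.snap_stages,
        "coefficients": {s: list(c) for s, c in config.coefficients.items()},
        "design": [
            {
                "age_lower": c.age_lower,
                "sex": c.sex,
                "n_train": c.n_train,
                "n_test": c.n_test,
            }
            for c in config.design.cells
        ],
    }
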