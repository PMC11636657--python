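"""CSV readers/writers for the four input tables and the results table.

Schemas (comma-separated, UTF-8, ``.`` decimal, header required; the first
line is a comment carrying the schema version):

* ``vessels.csv``  — subject_id, session_id, vessel_id, vessel_type{A,V},
  sat_pct, diameter_um, distance_um, mbr_au
* ``subjects.csv`` — subject_id, hb_g_dl, po2_mmhg, so2_pct
* ``onh.csv``      — subject_id, session_id, mv_au, mt_au, ma_au
* ``sessions.csv`` — subject_id, session_id, study_day, timepoint, gas
* ``results.csv``  — subject_id, session_id, sat_cra_pct, sat_crv_pct,
  c_cra, c_crv, av_diff, mv_au, ext_o2_au

Saturations are percent in files and fractions in memory; the conversion
happens here and nowhere else. Numeric fields are written with 10
significant digits, so a write/read round trip is lossless well beyond
the 6 significant digits the schemas guarantee.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .errors import SchemaError
from .extraction import ExtractionResult
from .model import (
    BaselinePolicy,
    Gas,
    IccModel,
    OnhFlowMetrics,
    PhysicalConstants,
    Po2Source,
    RunConfig,
    SessionLabel,
    StudyDay,
    SubjectPhysiology,
    Timepoint,
    VesselMeasurement,
    VesselType,
)

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1"
_FLOAT_FMT = "%.10g"

VESSEL_COLUMNS = [
    "subject_id",
    "session_id",
    "vessel_id",
    "vessel_type",
    "sat_pct",
    "diameter_um",
    "distance_um",
    "mbr_au",
]
SUBJECT_COLUMNS = ["subject_id", "hb_g_dl", "po2_mmhg", "so2_pct"]
ONH_COLUMNS = ["subject_id", "session_id", "mv_au", "mt_au", "ma_au"]
SESSION_COLUMNS = ["subject_id", "session_id", "study_day", "timepoint", "gas"]
RESULT_COLUMNS = [
    "subject_id",
    "session_id",
    "sat_cra_pct",
    "sat_crv_pct",
    "c_cra",
    "c_crv",
    "av_diff",
    "mv_au",
    "ext_o2_au",
]


def _read_csv(path: str | Path, table: str, columns: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{table} file not found: {path}")
    try:
        df = pd.read_csv(path, comment="#", dtype={"subject_id": str, "session_id": str, "vessel_id": str})
    except Exception as exc:  # malformed CSV
        raise SchemaError(f"cannot parse {table} file {path}: {exc}") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{table} file {path} is missing columns {missing}")
    return df


def _write_csv(df: pd.DataFrame, path: str | Path, table: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# reox {table} schema v{SCHEMA_VERSION}\n")
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT, lineterminator="\n")


def read_vessel_table(path: str | Path) -> list[VesselMeasurement]:
    """Parse ``vessels.csv`` into measurement records, converting percent
    saturations to fractions. Malformed rows raise errors naming the data
    row number (1-based, header excluded)."""
    df = _read_csv(path, "vessels", VESSEL_COLUMNS)
    records: list[VesselMeasurement] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        if row.vessel_type not in ("A", "V"):
            raise SchemaError(
                f"vessels row {i}: vessel_type must be 'A' or 'V', got {row.vessel_type!r}"
            )
        sat = float(row.sat_pct)
        if not 0.0 <= sat <= 100.0:
            raise SchemaError(f"vessels row {i}: sat_pct {sat} outside [0, 100]")
        try:
            records.append(
                VesselMeasurement(
                    subject_id=str(row.subject_id),
                    session_id=str(row.session_id),
                    vessel_id=str(row.vessel_id),
                    vessel_type=VesselType(row.vessel_type),
                    sat_measured=sat / 100.0,
                    diameter=float(row.diameter_um),
                    distance_L=float(row.distance_um),
                    mbr_Q=float(row.mbr_au),
                )
            )
        except ValueError as exc:
            raise SchemaError(f"vessels row {i}: {exc}") from exc
    return records


def write_vessel_table(records: Iterable[VesselMeasurement], path: str | Path) -> None:
    rows = [
        {
            "subject_id": v.subject_id,
            "session_id": v.session_id,
            "vessel_id": v.vessel_id,
            "vessel_type": v.vessel_type.value,
            "sat_pct": v.sat_measured * 100.0,
            "diameter_um": v.diameter,
            "distance_um": v.distance_L,
            "mbr_au": v.mbr_Q,
        }
        for v in records
    ]
    _write_csv(pd.DataFrame(rows, columns=VESSEL_COLUMNS), path, "vessels")


def read_subject_table(path: str | Path) -> list[SubjectPhysiology]:
    df = _read_csv(path, "subjects", SUBJECT_COLUMNS)
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            out.append(
                SubjectPhysiology(
                    subject_id=str(row.subject_id),
                    hb=float(row.hb_g_dl),
                    po2_systemic=float(row.po2_mmhg),
                    so2_systemic=float(row.so2_pct) / 100.0,
                )
            )
        except ValueError as exc:
            raise SchemaError(f"subjects row {i}: {exc}") from exc
    return out


def write_subject_table(records: Iterable[SubjectPhysiology], path: str | Path) -> None:
    rows = [
        {
            "subject_id": s.subject_id,
            "hb_g_dl": s.hb,
            "po2_mmhg": s.po2_systemic,
            "so2_pct": s.so2_systemic * 100.0,
        }
        for s in records
    ]
    _write_csv(pd.DataFrame(rows, columns=SUBJECT_COLUMNS), path, "subjects")


def read_onh_table(path: str | Path) -> list[OnhFlowMetrics]:
    df = _read_csv(path, "onh", ONH_COLUMNS)
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            out.append(
                OnhFlowMetrics(
                    subject_id=str(row.subject_id),
                    session_id=str(row.session_id),
                    mv=float(row.mv_au),
                    mt=float(row.mt_au),
                    ma=float(row.ma_au),
                )
            )
        except ValueError as exc:
            raise SchemaError(f"onh row {i}: {exc}") from exc
    return out


def write_onh_table(records: Iterable[OnhFlowMetrics], path: str | Path) -> None:
    rows = [
        {"subject_id": m.subject_id, "session_id": m.session_id, "mv_au": m.mv, "mt_au": m.mt, "ma_au": m.ma}
        for m in records
    ]
    _write_csv(pd.DataFrame(rows, columns=ONH_COLUMNS), path, "onh")


def read_session_table(path: str | Path) -> list[SessionLabel]:
    df = _read_csv(path, "sessions", SESSION_COLUMNS)
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            out.append(
                SessionLabel(
                    subject_id=str(row.subject_id),
                    session_id=str(row.session_id),
                    study_day=StudyDay(row.study_day),
                    timepoint=Timepoint(row.timepoint),
                    gas=Gas(row.gas),
                )
            )
        except ValueError as exc:
            raise SchemaError(f"sessions row {i}: {exc}") from exc
    return out


def write_session_table(records: Iterable[SessionLabel], path: str | Path) -> None:
    rows = [
        {
            "subject_id": s.subject_id,
            "session_id": s.session_id,
            "study_day": s.study_day.value,
            "timepoint": s.timepoint.value,
            "gas": s.gas.value,
        }
        for s in records
    ]
    _write_csv(pd.DataFrame(rows, columns=SESSION_COLUMNS), path, "sessions")


def results_to_frame(results: Sequence[ExtractionResult]) -> pd.DataFrame:
    """One row per session: merged saturations (percent), contents,
    arteriovenous difference, MV and extraction."""
    rows = [
        {
            "subject_id": r.subject_id,
            "session_id": r.session_id,
            "sat_cra_pct": r.corrected.sat_cra * 100.0,
            "sat_crv_pct": r.corrected.sat_crv * 100.0,
            "c_cra": r.contents.c_cra,
            "c_crv": r.contents.c_crv,
            "av_diff": r.av_content_difference,
            "mv_au": r.mv,
            "ext_o2_au": r.ext_o2,
        }
        for r in results
    ]
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def write_results(results: Sequence[ExtractionResult] | pd.DataFrame, path: str | Path) -> None:
    """Write ``results.csv``. An empty collection produces a header-only
    file and a warning."""
    if isinstance(results, pd.DataFrame):
        df = results
    else:
        df = results_to_frame(results)
    if df.empty:
        warnings.warn("writing an empty results table (header only)", stacklevel=2)
        df = pd.DataFrame(columns=RESULT_COLUMNS)
    _write_csv(df, path, "results")


def read_results(path: str | Path) -> pd.DataFrame:
    return _read_csv(path, "results", RESULT_COLUMNS)


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration. Every key is optional; omitted keys
    keep their defaults. Layout::

        constants: {huefner: 1.35, o2_solubility: 0.003, jo2_wall: 0.0}
        po2_cra_source: from_saturation   # from_systemic | constant
        po2_cra_constant: 95.0
        icc_model: two_way_mixed_absolute # one_way_random
        baseline_policy: mean_of_two      # first | second
        seed: 0
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise SchemaError(f"config file {path} must contain a mapping")
    try:
        constants = PhysicalConstants(**raw.get("constants", {}))
        return RunConfig(
            constants=constants,
            po2_cra_source=Po2Source(raw.get("po2_cra_source", Po2Source.FROM_SATURATION)),
            po2_cra_constant=float(raw.get("po2_cra_constant", 95.0)),
            icc_model=IccModel(raw.get("icc_model", IccModel.TWO_WAY_MIXED_ABSOLUTE)),
            baseline_policy=BaselinePolicy(raw.get("baseline_policy", BaselinePolicy.MEAN_OF_TWO)),
            seed=int(raw.get("seed", 0)),
        )
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"invalid config {path}: {exc}") from exc


def save_config(config: RunConfig, path: str | Path) -> None:
    data = {
        "constants": dataclasses.asdict(config.constants),
        "po2_cra_source": config.po2_cra_source.value,
        "po2_cra_constant": config.po2_cra_constant,
        "icc_model": config.icc_model.value,
        "baseline_policy": config.baseline_policy.value,
        "seed": config.seed,
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
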