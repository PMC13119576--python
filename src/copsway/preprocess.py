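"""Reading stabilometry trial files and metadata; filtering; velocity.

Trial files are delimited text (comma or whitespace, auto-detected), one row
per sample, with a header row naming the CoP columns.  The column labels,
delimiter and unit scale vary between dataset releases, so they are
configurable through :class:`TrialDialect`.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import signal as sps

from copsway.core import CONDITIONS, CohortSelection, CoPTrial, ParticipantRecord, VelocitySeries

__all__ = [
    "TrialDialect",
    "ReadError",
    "EmptyCohortError",
    "read_trial",
    "write_trial",
    "read_metadata",
    "write_metadata",
    "select_cohort",
    "filter_cop",
    "cop_velocity",
]


class ReadError(ValueError):
    """A trial or metadata file could not be parsed."""


class EmptyCohortError(ValueError):
    """Eligibility screening left no participants."""


@dataclass
class TrialDialect:
    """File-format conventions for trial files.

    ``delimiter=None`` auto-detects comma vs. whitespace.  ``unit_scale``
    multiplies the stored coordinates into cm (1.0 when the file is already
    in cm).  ``duration_s=None`` disables the sample-count check; otherwise
    trials whose length differs from ``fs * duration_s`` by more than one
    sample are rejected.
    """

    ap_col: str = "COP_AP"
    ml_col: str = "COP_ML"
    delimiter: Optional[str] = None
    unit_scale: float = 1.0
    fs: float = 100.0
    duration_s: Optional[float] = 60.0
    #: filename pattern with named groups pid / cond / trial
    filename_pattern: str = r"(?P<pid>.+?)_(?P<cond>EO_firm|EC_firm)_(?P<trial>\d+)\.\w+$"


def _parse_trial_filename(path: Path, dialect: TrialDialect) -> Tuple[str, str, int]:
    m = re.search(dialect.filename_pattern, path.name)
    if m is None:
        raise ReadError(
            f"{path}: filename does not match dialect pattern {dialect.filename_pattern!r}"
        )
    return m.group("pid"), m.group("cond"), int(m.group("trial"))


def read_trial(path, dialect: TrialDialect = TrialDialect()) -> CoPTrial:
    """Read one CoP trial file into cm-scaled arrays.

    Channels are mapped by header name (column order is irrelevant).  Raises
    :class:`ReadError` on missing columns, non-numeric or missing values
    (naming the first offending row), or a sample count inconsistent with
    the declared ``fs * duration``.
    """
    path = Path(path)
    pid, cond, trial_index = _parse_trial_filename(path, dialect)
    try:
        df = pd.read_csv(path, sep=dialect.delimiter, engine="python")
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise ReadError(f"{path}: cannot parse file ({exc})") from exc
    for col in (dialect.ap_col, dialect.ml_col):
        if col not in df.columns:
            raise ReadError(f"{path}: missing column {col!r}; found {list(df.columns)}")
    sub = df[[dialect.ap_col, dialect.ml_col]].apply(pd.to_numeric, errors="coerce")
    bad = sub.isna().any(axis=1)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ReadError(f"{path}: non-numeric or missing value at data row {row}")
    if dialect.duration_s is not None:
        expected = dialect.fs * dialect.duration_s
        if abs(len(sub) - expected) > 1:
            raise ReadError(
                f"{path}: {len(sub)} samples, expected {expected:.0f} "
                f"(fs={dialect.fs} Hz x {dialect.duration_s} s)"
            )
    return CoPTrial(
        participant_id=pid,
        condition=cond,
        trial_index=trial_index,
        fs=dialect.fs,
        cop_ap=sub[dialect.ap_col].to_numpy() * dialect.unit_scale,
        cop_ml=sub[dialect.ml_col].to_numpy() * dialect.unit_scale,
    )


def write_trial(trial: CoPTrial, directory, dialect: TrialDialect = TrialDialect()) -> Path:
    """Write a trial in the dialect the reader consumes; returns the path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / f"{trial.participant_id}_{trial.condition}_{trial.trial_index}.csv"
    sep = dialect.delimiter if dialect.delimiter not in (None, r"\s+") else ","
    df = pd.DataFrame(
        {
            dialect.ap_col: trial.cop_ap / dialect.unit_scale,
            dialect.ml_col: trial.cop_ml / dialect.unit_scale,
        }
    )
    df.to_csv(path, sep=sep, index=False, float_format="%.6f")
    return path


# ---------------------------------------------------------------------------
# Metadata
# ---------------------------------------------------------------------------

_TRUE_LABELS = {"1", "yes", "y", "true", "t"}
_FALSE_LABELS = {"0", "no", "n", "false", "f", "none"}
_MALE_LABELS = {"m", "male", "man", "1"}
_FEMALE_LABELS = {"f", "female", "woman", "0"}

#: default metadata column mapping (canonical field -> file column)
DEFAULT_METADATA_COLUMNS = {
    "participant_id": "participant_id",
    "age": "age",
    "sex": "sex",
    "bmi": "bmi",
    "adl": "adl",
    "illness": "illness",
    "n_medications": "n_medications",
    "disability": "disability",
    "orthosis": "orthosis",
    "falls12m": "falls12m",
}


def _norm_binary(value, fieldname: str) -> int:
    s = str(value).strip().lower()
    if s in _TRUE_LABELS:
        return 1
    if s in _FALSE_LABELS:
        return 0
    raise ValueError(f"cannot interpret {fieldname}={value!r} as binary")


def _norm_sex(value) -> int:
    s = str(value).strip().lower()
    if s in _MALE_LABELS:
        return 1
    if s in _FEMALE_LABELS:
        return 0
    raise ValueError(f"cannot interpret sex={value!r}")


@dataclass
class MetadataResult:
    """Typed participant records plus an exclusion report."""

    records: List[ParticipantRecord]
    exclusions: List[dict] = field(default_factory=list)


def read_metadata(path, columns: Optional[dict] = None, delimiter: Optional[str] = None) -> MetadataResult:
    """Read the participant metadata table.

    Rows with a blank/unparseable fall count or malformed covariates are
    excluded (not fatal) and listed in the exclusion report with a reason.
    """
    cols = dict(DEFAULT_METADATA_COLUMNS)
    if columns:
        cols.update(columns)
    try:
        df = pd.read_csv(path, sep=delimiter, engine="python", dtype=str)
    except Exception as exc:  # noqa: BLE001
        raise ReadError(f"{path}: cannot parse metadata ({exc})") from exc
    missing = [c for c in cols.values() if c not in df.columns]
    if missing:
        raise ReadError(f"{path}: missing metadata columns {missing}")

    records: List[ParticipantRecord] = []
    exclusions: List[dict] = []
    for i, row in df.iterrows():
        pid = str(row[cols["participant_id"]]).strip()
        try:
            falls_raw = row[cols["falls12m"]]
            if pd.isna(falls_raw) or str(falls_raw).strip() == "":
                raise ValueError("fall history missing")
            rec = ParticipantRecord(
                participant_id=pid,
                age=float(row[cols["age"]]),
                sex=_norm_sex(row[cols["sex"]]),
                bmi=float(row[cols["bmi"]]),
                adl=int(float(row[cols["adl"]])),
                illness=_norm_binary(row[cols["illness"]], "illness"),
                n_medications=int(float(row[cols["n_medications"]])),
                disability=_norm_binary(row[cols["disability"]], "disability"),
                orthosis=_norm_binary(row[cols["orthosis"]], "orthosis"),
                falls12m=int(float(falls_raw)),
            )
        except (TypeError, ValueError) as exc:
            exclusions.append({"participant_id": pid, "row": int(i), "reason": str(exc)})
            continue
        records.append(rec)
    return MetadataResult(records=records, exclusions=exclusions)


def write_metadata(records: Iterable[ParticipantRecord], path, delimiter: str = ",") -> Path:
    """Write records in the table layout :func:`read_metadata` consumes."""
    path = Path(path)
    rows = []
    for r in records:
        rows.append(
            {
                "participant_id": r.participant_id,
                "age": r.age,
                "sex": r.sex,
                "bmi": r.bmi,
                "adl": r.adl,
                "illness": r.illness,
                "n_medications": r.n_medications,
                "disability": r.disability,
                "orthosis": r.orthosis,
                "falls12m": "" if r.falls12m is None else r.falls12m,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep=delimiter, index=False)
    return path


# ---------------------------------------------------------------------------
# Cohort selection
# ---------------------------------------------------------------------------

def select_cohort(
    records: Sequence[ParticipantRecord],
    trials: Sequence[CoPTrial],
    min_age: float = 60.0,
) -> CohortSelection:
    """Apply the eligibility screen and label groups.

    Keeps participants aged >= ``min_age`` with a known fall count and at
    least one firm-surface trial in *each* of the eyes-open and eyes-closed
    conditions.  Fallers have >= 1 fall in the past 12 months.  The result
    is independent of input ordering (records are sorted by id).
    """
    by_pid: dict = {}
    for t in trials:
        by_pid.setdefault(t.participant_id, set()).add(t.condition)

    excluded: dict = {"age": [], "missing_falls": [], "incomplete_trials": []}
    eligible: List[ParticipantRecord] = []
    for rec in sorted(records, key=lambda r: r.participant_id):
        if rec.falls12m is None:
            excluded["missing_falls"].append(rec.participant_id)
        elif rec.age < min_age:
            excluded["age"].append(rec.participant_id)
        elif not set(CONDITIONS) <= by_pid.get(rec.participant_id, set()):
            excluded["incomplete_trials"].append(rec.participant_id)
        else:
            eligible.append(rec)
    if not eligible:
        raise EmptyCohortError("no participants satisfy the eligibility criteria")

    ids = {r.participant_id for r in eligible}
    kept_trials = [t for t in trials if t.participant_id in ids and t.condition in CONDITIONS]
    n_fallers = sum(1 for r in eligible if r.falls12m >= 1)
    return CohortSelection(
        records=eligible,
        trials=kept_trials,
        n_fallers=n_fallers,
        n_nonfallers=len(eligible) - n_fallers,
        n_recurrent_fallers=sum(1 for r in eligible if r.falls12m >= 2),
        excluded=excluded,
    )


# ---------------------------------------------------------------------------
# Filtering and velocity
# ---------------------------------------------------------------------------

def filter_cop(trial: CoPTrial, cutoff_hz: float = 20.0, order: int = 2) -> CoPTrial:
    """Zero-phase Butterworth low-pass of both channels (length preserved).

    A second-order design applied forward and backward (effective fourth
    order, zero phase) with reflective edge padding of ``3 * (order + 1)``
    samples.
    """
    padlen = 3 * (order + 1)
    if trial.n_samples <= padlen:
        raise ValueError(f"trial too short to filter: {trial.n_samples} <= padlen {padlen}")
    if not 0 < cutoff_hz < trial.fs / 2:
        raise ValueError("cutoff must lie in (0, fs/2)")
    b, a = sps.butter(order, cutoff_hz, btype="low", fs=trial.fs)
    kw = dict(padtype="even", padlen=padlen)
    return CoPTrial(
        participant_id=trial.participant_id,
        condition=trial.condition,
        trial_index=trial.trial_index,
        fs=trial.fs,
        cop_ap=sps.filtfilt(b, a, trial.cop_ap, **kw),
        cop_ml=sps.filtfilt(b, a, trial.cop_ml, **kw),
    )


def cop_velocity(trial: CoPTrial) -> VelocitySeries:
    """First-difference CoP velocity in cm/s (one sample shorter)."""
    return VelocitySeries(
        vel_ap=np.diff(trial.cop_ap) * trial.fs,
        vel_ml=np.diff(trial.cop_ml) * trial.fs,
        fs=trial.fs,
    )
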