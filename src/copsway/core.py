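"""Core domain containers shared across the pipeline.

Units follow the force-platform dataset convention: CoP coordinates in cm,
velocities in cm/s, areas in cm**2, sampling rate in Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: Quiet-standing conditions analyzed (firm surface only).
CONDITIONS = ("EO_firm", "EC_firm")

#: Canonical metric names of the per-participant, per-condition feature table,
#: in reporting order.  Linear (magnitude) metrics first, then
#: temporal-structure metrics.
FEATURE_NAMES = (
    "velo",
    "area",
    "velo_ap",
    "velo_ml",
    "velo_sd_ap",
    "velo_sd_ml",
    "mfreq_ap",
    "mfreq_ml",
    "mp3",
    "mt3",
    "md3",
    "fd",
    "alpha_ap",
    "alpha_ml",
    "sda_ds",
    "sda_dl",
    "sda_crit",
    "sda_crid",
    "mse1_ap",
    "mse10_ap",
    "mse40_ap",
    "mse1_ml",
    "mse10_ml",
    "mse40_ml",
    "det_ap",
    "det_ml",
    "lam_ap",
    "lam_ml",
)

#: The eight covariates of the propensity-score model, in model order.
PS_COVARIATES = (
    "age",
    "sex",
    "bmi",
    "adl",
    "illness",
    "n_medications",
    "disability",
    "orthosis",
)


@dataclass
class CoPTrial:
    """One 60-s (nominal) two-channel center-of-pressure recording.

    ``cop_ap`` and ``cop_ml`` are the anteroposterior and mediolateral CoP
    coordinates in cm, sampled at ``fs`` Hz.
    """

    participant_id: str
    condition: str
    trial_index: int
    fs: float
    cop_ap: np.ndarray
    cop_ml: np.ndarray

    def __post_init__(self) -> None:
        self.cop_ap = np.asarray(self.cop_ap, dtype=float)
        self.cop_ml = np.asarray(self.cop_ml, dtype=float)
        if self.cop_ap.shape != self.cop_ml.shape or self.cop_ap.ndim != 1:
            raise ValueError("cop_ap and cop_ml must be 1-D arrays of equal length")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}; expected one of {CONDITIONS}")

    @property
    def n_samples(self) -> int:
        return self.cop_ap.shape[0]

    @property
    def duration(self) -> float:
        """Trial duration in seconds."""
        return self.n_samples / self.fs

    def planar(self) -> np.ndarray:
        """Return the (n, 2) planar trajectory with columns (AP, ML)."""
        return np.column_stack([self.cop_ap, self.cop_ml])


@dataclass
class ParticipantRecord:
    """Covariates and 12-month fall count for one subject.

    ``sex``, ``adl``, ``illness``, ``disability`` and ``orthosis`` are binary
    (0/1); ``n_medications`` is a small non-negative integer count.
    ``falls12m`` is the self-reported number of non-intentional falls in the
    previous 12 months; ``None`` marks a missing fall history.
    """

    participant_id: str
    age: float
    sex: int
    bmi: float
    adl: int
    illness: int
    n_medications: int
    disability: int
    orthosis: int
    falls12m: Optional[int]

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValueError("age must be non-negative")
        if self.bmi <= 0:
            raise ValueError("bmi must be positive")
        if self.falls12m is not None and self.falls12m < 0:
            raise ValueError("falls12m must be a non-negative count")

    @property
    def is_faller(self) -> Optional[bool]:
        """Faller = at least one fall in the past 12 months."""
        if self.falls12m is None:
            return None
        return self.falls12m >= 1


@dataclass
class VelocitySeries:
    """Instantaneous CoP velocity per axis, cm/s.

    First-difference convention: one sample shorter than the CoP series it
    was derived from.
    """

    vel_ap: np.ndarray
    vel_ml: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.vel_ap = np.asarray(self.vel_ap, dtype=float)
        self.vel_ml = np.asarray(self.vel_ml, dtype=float)
        if self.vel_ap.shape != self.vel_ml.shape or self.vel_ap.ndim != 1:
            raise ValueError("vel_ap and vel_ml must be 1-D arrays of equal length")


@dataclass
class CohortSelection:
    """Result of eligibility screening: grouped records plus their trials."""

    records: list  # eligible ParticipantRecord, age >= 60, fall history known
    trials: list  # CoPTrial for eligible participants, firm-surface EO/EC
    n_fallers: int
    n_nonfallers: int
    n_recurrent_fallers: int  # falls12m >= 2
    excluded: dict = field(default_factory=dict)  # reason -> list of ids

    @property
    def groups(self) -> dict:
        """participant_id -> 1 (faller) / 0 (non-faller)."""
        return {r.participant_id: int(r.is_faller) for r in self.records}
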