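"""Domain types for paired cardiac-output method-comparison studies.

All cardiac-index values are in L min^-1 m^-2, cardiac output in L min^-1,
heights in cm, weights in kg. Timepoints are labelled 1..5 as in the study
protocol; no 0-based indexing is exposed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .errors import DomainError, IntegrityError

TIMEPOINTS = (1, 2, 3, 4, 5)


@dataclass(frozen=True)
class PatientRecord:
    """Biometrics needed for body-surface-area indexing."""

    patient_id: str
    age: float
    height: float  # cm
    weight: float  # kg
    asa_class: int = 2

    def __post_init__(self) -> None:
        if self.height <= 0:
            raise DomainError(f"height must be > 0, got {self.height}")
        if self.weight <= 0:
            raise DomainError(f"weight must be > 0, got {self.weight}")
        if self.asa_class not in (1, 2, 3):
            raise DomainError(f"asa_class must be in {{1,2,3}}, got {self.asa_class}")


@dataclass(frozen=True)
class EchoMeasurement:
    """One echocardiographic acquisition: diameter plus replicate VTI traces.

    ``vti_sets`` holds three sets of three velocity-time-integral traces (cm),
    mirroring the acquisition protocol; the shape is validated strictly.
    """

    patient_id: str
    timepoint: int
    aortic_diameter: float  # cm
    vti_sets: tuple[tuple[float, ...], ...]
    heart_rate: float  # beats/min

    def __post_init__(self) -> None:
        if self.timepoint not in TIMEPOINTS:
            raise DomainError(f"timepoint must be in 1..5, got {self.timepoint}")
        if self.aortic_diameter <= 0:
            raise DomainError("aortic_diameter must be > 0")
        if len(self.vti_sets) != 3 or any(len(s) != 3 for s in self.vti_sets):
            raise DomainError("vti_sets must be 3 sets of 3 traces")
        if any(t <= 0 for s in self.vti_sets for t in s):
            raise DomainError("all VTI traces must be > 0")
        if self.heart_rate <= 0:
            raise DomainError("heart_rate must be > 0")


@dataclass(frozen=True)
class DeviceReading:
    """A single test-device cardiac-output reading."""

    patient_id: str
    timepoint: int
    cardiac_output: float  # L/min

    def __post_init__(self) -> None:
        if self.timepoint not in TIMEPOINTS:
            raise DomainError(f"timepoint must be in 1..5, got {self.timepoint}")
        if self.cardiac_output <= 0:
            raise DomainError("cardiac_output must be > 0")


@dataclass(frozen=True)
class PairedObservation:
    """One (test, reference) cardiac-index pair at a patient x timepoint.

    ``difference`` (test minus reference) and ``mean_pair`` are derived
    exactly from the two index values at construction time.
    """

    patient_id: str
    timepoint: int
    ci_test: float
    ci_ref: float

    def __post_init__(self) -> None:
        if self.ci_test <= 0 or self.ci_ref <= 0:
            raise DomainError(
                f"cardiac-index values must be > 0, got "
                f"({self.ci_test}, {self.ci_ref})"
            )

    @property
    def difference(self) -> float:
        return self.ci_test - self.ci_ref

    @property
    def mean_pair(self) -> float:
        return (self.ci_test + self.ci_ref) / 2


@dataclass
class StudyDataset:
    """A full study: patients plus paired observations.

    ``orphans`` retains unpaired method rows; the analyses use only complete
    pairs but nothing is silently dropped.
    """

    patients: dict[str, PatientRecord] = field(default_factory=dict)
    observations: list[PairedObservation] = field(default_factory=list)
    orphans: list[tuple[str, int, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[str, int]] = set()
        for obs in self.observations:
            key = (obs.patient_id, obs.timepoint)
            if key in seen:
                raise IntegrityError(
                    f"duplicate observation for patient {obs.patient_id!r} "
                    f"timepoint {obs.timepoint}"
                )
            seen.add(key)
            if self.patients and obs.patient_id not in self.patients:
                raise IntegrityError(
                    f"observation references unknown patient {obs.patient_id!r}"
                )

    @property
    def n_pairs(self) -> int:
        return len(self.observations)

    def differences(self) -> list[float]:
        return [o.difference for o in self.observations]

    def by_patient(self) -> dict[str, list[PairedObservation]]:
        grouped: dict[str, list[PairedObservation]] = {}
        for obs in self.observations:
            grouped.setdefault(obs.patient_id, []).append(obs)
        for obs_list in grouped.values():
            obs_list.sort(key=lambda o: o.timepoint)
        return grouped


def pair_count(n_patients: int, n_timepoints: int, n_lost: int) -> int:
    """Number of analysable pairs after losing ``n_lost`` measurement sets."""
    if n_patients < 0 or n_timepoints < 0 or n_lost < 0:
        raise DomainError("pair_count arguments must be non-negative")
    total = n_patients * n_timepoints
    if n_lost > total:
        raise DomainError(f"n_lost {n_lost} exceeds total sets {total}")
    return total - n_lost


def make_pairs(
    records: Sequence[tuple[str, int, float, float]]
) -> list[PairedObservation]:
    """Build PairedObservations from (patient_id, timepoint, ci_test, ci_ref)."""
    return [PairedObservation(p, t, ct, cr) for p, t, ct, cr in records]
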