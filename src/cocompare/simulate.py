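"""Synthetic paired-study generator with known ground truth.

Emulates the clinical design: a cohort measured at five perioperative
timepoints by two methods, with a patient-level shift inducing within-patient
correlation, per-method measurement noise, an additive (and optionally
proportional) device bias, replicate echo traces, and sporadic missing
measurement sets.

Randomness: one seed feeds a ``numpy.random.SeedSequence`` whose spawned
children drive each component (biometrics, patient levels, reference noise,
test noise, missingness, echo traces) in a fixed documented order, so adding
a feature never shifts existing streams.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datamodel import PairedObservation, PatientRecord, StudyDataset
from .errors import DomainError
from .hemodynamics import aortic_cross_section, mosteller_bsa

# Default per-timepoint reference cardiac-index means (L min^-1 m^-2)
REFERENCE_TIMEPOINT_MEANS = (2.76, 2.38, 2.50, 2.54, 3.02)

# Cohort biometric profile: (mean, sd, low, high)
_HEIGHT = (163.7, 6.3, 149.0, 176.0)
_WEIGHT = (66.5, 11.4, 44.0, 93.0)
_AGE = (44.1, 10.8, 23.0, 77.0)
_ASA_PROBS = (8 / 55, 45 / 55, 2 / 55)

# Floor applied to generated readings so indices stay positive even under
# extreme noise settings (documented distortion, negligible at realistic sds)
_CI_FLOOR = 0.01


@dataclass(frozen=True)
class SyntheticParams:
    """Ground-truth parameterisation of a simulated study."""

    n_patients: int = 55
    timepoint_means: tuple[float, ...] = REFERENCE_TIMEPOINT_MEANS
    sigma_between: float = 0.30
    sigma_ref: float = 0.14
    sigma_test: float = 0.14
    device_bias: float = 0.02
    prop_coefficient: float = 0.0
    replicate_cv: float = 0.03
    missing_rate: float = 2 / 275
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise DomainError("n_patients must be >= 1")
        if len(self.timepoint_means) != 5:
            raise DomainError("exactly 5 timepoint means are required")
        if any(m <= 0 for m in self.timepoint_means):
            raise DomainError("timepoint means must be > 0")
        for name in ("sigma_between", "sigma_ref", "sigma_test", "replicate_cv"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0")
        if not 0 <= self.missing_rate < 1:
            raise DomainError("missing_rate must be in [0, 1)")


@dataclass
class GroundTruth:
    """True per-patient-timepoint cardiac indices plus generating parameters."""

    params: SyntheticParams
    true_ci: dict[tuple[str, int], float] = field(default_factory=dict)
    echo: pd.DataFrame | None = None


def default_study_params(seed: int = 0) -> SyntheticParams:
    """Defaults matching the published study profile.

    55 patients, the reference per-timepoint means, a between-patient shift
    of sd 0.30, per-method noise sds of 0.14 (theoretical MPE about 14.6%),
    a constant device bias of 0.02, and a missing rate of 2/275 sets.
    """
    return SyntheticParams(seed=seed)


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, low: float, high: float, n: int
) -> np.ndarray:
    """Rejection-sample a truncated normal; exact respect of the bounds."""
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=max(n - filled, 16))
        keep = draw[(draw >= low) & (draw <= high)]
        take = min(keep.size, n - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


def generate_biometrics(n: int, seed: int | np.random.Generator) -> list[PatientRecord]:
    """Generate ``n`` patient records from the cohort biometric profile."""
    if n < 1:
        raise DomainError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    heights = _truncated_normal(rng, *_HEIGHT, n)
    weights = _truncated_normal(rng, *_WEIGHT, n)
    ages = _truncated_normal(rng, *_AGE, n)
    asa = rng.choice([1, 2, 3], size=n, p=_ASA_PROBS)
    width = max(3, len(str(n)))
    return [
        PatientRecord(
            patient_id=f"P{i + 1:0{width}d}",
            age=float(ages[i]),
            height=float(heights[i]),
            weight=float(weights[i]),
            asa_class=int(asa[i]),
        )
        for i in range(n)
    ]


def generate_study(
    params: SyntheticParams, with_echo: bool = False
) -> tuple[StudyDataset, GroundTruth]:
    """Simulate a full paired study.

    Model: true CI for patient i at timepoint t is ``timepoint_means[t] +
    b_i`` with ``b_i ~ N(0, sigma_between)``; the reference reading adds
    ``N(0, sigma_ref)``; the test reading adds ``device_bias +
    prop_coefficient * true + N(0, sigma_test)``. Each patient-timepoint set
    is lost independently with probability ``missing_rate``. Readings are
    floored at a small positive value so indices remain valid.
    """
    ss = np.random.SeedSequence(params.seed)
    kids = ss.spawn(6)
    rng_bio = np.random.default_rng(kids[0])
    rng_level = np.random.default_rng(kids[1])
    rng_ref = np.random.default_rng(kids[2])
    rng_test = np.random.default_rng(kids[3])
    rng_miss = np.random.default_rng(kids[4])
    rng_echo = np.random.default_rng(kids[5])

    n = params.n_patients
    records = generate_biometrics(n, rng_bio)
    levels = rng_level.normal(0.0, params.sigma_between, size=n)
    noise_ref = rng_ref.normal(0.0, params.sigma_ref, size=(n, 5))
    noise_test = rng_test.normal(0.0, params.sigma_test, size=(n, 5))
    lost = rng_miss.random(size=(n, 5)) < params.missing_rate

    truth = GroundTruth(params=params)
    observations: list[PairedObservation] = []
    echo_rows: list[dict] = []
    diameters = _truncated_normal(rng_echo, 2.0, 0.15, 1.6, 2.6, n) if with_echo else None

    for i, rec in enumerate(records):
        for t in range(5):
            tp = t + 1
            true_ci = params.timepoint_means[t] + levels[i]
            truth.true_ci[(rec.patient_id, tp)] = true_ci
            if lost[i, t]:
                continue
            ci_ref = max(_CI_FLOOR, true_ci + noise_ref[i, t])
            ci_test = max(
                _CI_FLOOR,
                true_ci
                + params.device_bias
                + params.prop_coefficient * true_ci
                + noise_test[i, t],
            )
            observations.append(PairedObservation(rec.patient_id, tp, ci_test, ci_ref))
            if with_echo:
                bsa = mosteller_bsa(rec.height, rec.weight)
                co_ref = ci_ref * bsa
                hr = float(_truncated_normal(rng_echo, 70.0, 10.0, 40.0, 120.0, 1)[0])
                area = aortic_cross_section(float(diameters[i]))
                base_vti = co_ref / hr * 1000.0 / area
                traces = base_vti * np.clip(
                    1.0 + rng_echo.normal(0.0, params.replicate_cv, size=9), 0.05, None
                )
                for set_idx in range(3):
                    for trace_idx in range(3):
                        echo_rows.append(
                            {
                                "patient_id": rec.patient_id,
                                "timepoint": tp,
                                "aortic_diameter_cm": float(diameters[i]),
                                "set_idx": set_idx + 1,
                                "trace_idx": trace_idx + 1,
                                "vti_cm": float(traces[3 * set_idx + trace_idx]),
                                "heart_rate_bpm": hr,
                            }
                        )

    if with_echo:
        truth.echo = pd.DataFrame(echo_rows)
    dataset = StudyDataset(
        patients={r.patient_id: r for r in records}, observations=observations
    )
    return dataset, truth


def reseeded(params: SyntheticParams, seed: int) -> SyntheticParams:
    """Copy of ``params`` with a different seed."""
    return replace(params, seed=seed)
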