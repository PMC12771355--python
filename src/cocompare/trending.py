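"""Trending-ability analysis: change-pair extraction, four-quadrant
concordance with a central exclusion zone, and polar-plot statistics.

Angle convention: the identity line (test change == reference change) maps to
0 degrees; points whose mean change is negative are rotated by 180 degrees so
all angular statistics live on a single half-circle sheet. Angles are in
(-180, 180], radii in the cardiac-index units of the input deltas.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .datamodel import PairedObservation, StudyDataset
from .errors import DomainError, InsufficientDataError

POLAR_SCALE_DEFAULT = 1.5
ZONE_FRACTION_DEFAULT = 0.15


@dataclass(frozen=True)
class ChangePair:
    """Between-timepoint change measured by both methods for one patient."""

    patient_id: str
    interval: tuple[int, int]
    delta_ref: float
    delta_test: float

    def __post_init__(self) -> None:
        if self.interval[1] <= self.interval[0]:
            raise DomainError(f"interval must increase, got {self.interval}")
        if not (math.isfinite(self.delta_ref) and math.isfinite(self.delta_test)):
            raise DomainError("deltas must be finite")


@dataclass(frozen=True)
class PolarPoint:
    """Polar representation of a change pair: angle from identity, radius."""

    angle: float  # degrees, (-180, 180]
    radius: float

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise DomainError("radius must be >= 0")


@dataclass(frozen=True)
class TrendingResult:
    """Four-quadrant and polar summary of trending agreement."""

    n_total: int
    n_excluded: int
    n_concordant: int
    concordance_rate: float
    mean_polar_angle: float
    polar_sd: float
    radial_loa_lower: float
    radial_loa_upper: float
    zone_quadrant: float
    zone_polar: float
    n_polar_excluded: int


def change_pairs(
    data: StudyDataset | Sequence[PairedObservation], policy: str = "consecutive_only"
) -> list[ChangePair]:
    """Extract per-patient between-timepoint change pairs.

    ``consecutive_only`` keeps only transitions between adjacent timepoints
    present for the patient; ``bridge`` additionally spans single missing
    timepoints (a gap of exactly one).
    """
    if policy not in ("consecutive_only", "bridge"):
        raise DomainError(f"unknown policy {policy!r}")
    observations = data.observations if isinstance(data, StudyDataset) else list(data)
    grouped: dict[str, dict[int, PairedObservation]] = {}
    for obs in observations:
        grouped.setdefault(obs.patient_id, {})[obs.timepoint] = obs
    max_gap = 1 if policy == "consecutive_only" else 2
    changes: list[ChangePair] = []
    for pid in sorted(grouped):
        by_tp = grouped[pid]
        tps = sorted(by_tp)
        for a, b in zip(tps, tps[1:]):
            if b - a <= max_gap:
                changes.append(
                    ChangePair(
                        patient_id=pid,
                        interval=(a, b),
                        delta_ref=by_tp[b].ci_ref - by_tp[a].ci_ref,
                        delta_test=by_tp[b].ci_test - by_tp[a].ci_test,
                    )
                )
    return changes


def exclusion_zone(mean_ci: float, fraction: float = ZONE_FRACTION_DEFAULT) -> float:
    """Small-change exclusion threshold: ``fraction`` of the mean index."""
    if mean_ci <= 0:
        raise DomainError(f"mean_ci must be > 0, got {mean_ci}")
    if not 0 <= fraction < 1:
        raise DomainError(f"fraction must be in [0, 1), got {fraction}")
    return fraction * mean_ci


def concordance_rate(
    changes: Sequence[ChangePair], zone: float
) -> tuple[float, int, int]:
    """Four-quadrant concordance among changes outside the exclusion square.

    A pair is excluded when both |delta| values fall inside the central
    square of half-width ``zone``. Among included pairs, concordance requires
    a strictly positive product of the deltas, so a zero delta on either axis
    counts as discordant.
    """
    if zone < 0:
        raise DomainError("zone must be >= 0")
    included = [
        c for c in changes if not (abs(c.delta_ref) < zone and abs(c.delta_test) < zone)
    ]
    n_excluded = len(changes) - len(included)
    if not included:
        raise InsufficientDataError("no change pairs outside the exclusion zone")
    n_concordant = sum(1 for c in included if c.delta_ref * c.delta_test > 0)
    return (100.0 * n_concordant / len(included), len(included), n_excluded)


def polar_transform(
    delta_ref: float, delta_test: float, radius_convention: str = "mean"
) -> PolarPoint:
    """Map a change pair to (angle from identity line, radius).

    The raw angle is the planar angle of (delta_ref, delta_test) minus 45
    degrees; points with a negative mean change are rotated 180 degrees onto
    the positive half-circle. The radius is the magnitude of the mean change
    (default) or the Euclidean norm divided by sqrt(2) (``"norm"``).
    """
    if delta_ref == 0 and delta_test == 0:
        raise DomainError("polar angle undefined for a (0, 0) change pair")
    if radius_convention not in ("mean", "norm"):
        raise DomainError(f"unknown radius convention {radius_convention!r}")
    angle = math.degrees(math.atan2(delta_test, delta_ref)) - 45.0
    mean_change = (delta_ref + delta_test) / 2.0
    if mean_change < 0:
        angle += 180.0
    # wrap into (-180, 180]
    angle = -((-angle + 180.0) % 360.0 - 180.0)
    if radius_convention == "mean":
        radius = abs(mean_change)
    else:
        radius = math.hypot(delta_ref, delta_test) / math.sqrt(2.0)
    return PolarPoint(angle=angle, radius=radius)


def polar_points(
    changes: Iterable[ChangePair], radius_convention: str = "mean"
) -> list[PolarPoint]:
    """Polar-transform every change pair, skipping exact (0, 0) pairs."""
    points = []
    for c in changes:
        if c.delta_ref == 0 and c.delta_test == 0:
            continue
        points.append(polar_transform(c.delta_ref, c.delta_test, radius_convention))
    return points


def polar_zone(zone_quadrant: float, scale_factor: float = POLAR_SCALE_DEFAULT) -> float:
    """Polar exclusion radius: the four-quadrant zone scaled down."""
    if zone_quadrant < 0:
        raise DomainError("zone_quadrant must be >= 0")
    if scale_factor <= 0:
        raise DomainError("scale_factor must be > 0")
    return zone_quadrant / scale_factor


def polar_stats(
    points: Sequence[PolarPoint],
    zone_polar: float,
    z: float = 1.96,
    radius_weighted: bool = False,
) -> tuple[float, float, tuple[float, float], int]:
    """Angular statistics of points outside the central polar zone.

    Returns (mean angle, sample sd, radial limits of agreement, n excluded).
    The mean is the plain arithmetic mean of angles unless
    ``radius_weighted`` is set.
    """
    included = [p for p in points if p.radius >= zone_polar]
    n_excluded = len(points) - len(included)
    if len(included) < 2:
        raise InsufficientDataError(
            f"need >= 2 points outside the polar zone, got {len(included)}"
        )
    angles = np.asarray([p.angle for p in included])
    if radius_weighted:
        weights = np.asarray([p.radius for p in included])
        mean_angle = float(np.average(angles, weights=weights))
    else:
        mean_angle = float(angles.mean())
    sd = float(angles.std(ddof=1))
    return (mean_angle, sd, (mean_angle - z * sd, mean_angle + z * sd), n_excluded)


def trending_analysis(
    data: StudyDataset | Sequence[PairedObservation],
    mean_ci: float | None = None,
    zone_fraction: float = ZONE_FRACTION_DEFAULT,
    polar_scale: float = POLAR_SCALE_DEFAULT,
    policy: str = "consecutive_only",
    radius_convention: str = "mean",
) -> TrendingResult:
    """End-to-end trending analysis on a paired dataset.

    When ``mean_ci`` is None, the grand mean of the pair means is used to
    size the exclusion zone.
    """
    observations = data.observations if isinstance(data, StudyDataset) else list(data)
    if mean_ci is None:
        if not observations:
            raise InsufficientDataError("empty dataset")
        mean_ci = float(np.mean([o.mean_pair for o in observations]))
    changes = change_pairs(data, policy=policy)
    zone_q = exclusion_zone(mean_ci, zone_fraction)
    rate, n_included, n_excluded = concordance_rate(changes, zone_q)
    n_concordant = round(rate * n_included / 100.0)
    zone_p = polar_zone(zone_q, polar_scale)
    points = polar_points(changes, radius_convention)
    mean_angle, sd, (loa_lo, loa_hi), n_polar_excl = polar_stats(points, zone_p)
    return TrendingResult(
        n_total=len(changes),
        n_excluded=n_excluded,
        n_concordant=n_concordant,
        concordance_rate=rate,
        mean_polar_angle=mean_angle,
        polar_sd=sd,
        radial_loa_lower=loa_lo,
        radial_loa_upper=loa_hi,
        zone_quadrant=zone_q,
        zone_polar=zone_p,
        n_polar_excluded=n_polar_excl,
    )
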