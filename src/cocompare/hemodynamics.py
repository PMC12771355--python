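"""Body surface area, cardiac index, and Doppler stroke-volume arithmetic.

Units at every boundary: heights cm, weights kg, diameters cm, VTI cm,
stroke volume mL, cardiac output L min^-1, BSA m^2, cardiac index
L min^-1 m^-2. Conversions happen only inside these functions.
"""
from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np

from .errors import DomainError


def mosteller_bsa(height: float, weight: float) -> float:
    """Body surface area (m^2) from height (cm) and weight (kg).

    BSA = sqrt(height * weight / 3600).
    """
    if height <= 0 or weight <= 0:
        raise DomainError(f"height and weight must be > 0, got ({height}, {weight})")
    return math.sqrt(height * weight / 3600.0)


def cardiac_index(co: float, bsa: float) -> float:
    """Cardiac index (L min^-1 m^-2) = cardiac output / body surface area."""
    if bsa <= 0:
        raise DomainError(f"bsa must be > 0, got {bsa}")
    return co / bsa


def aortic_cross_section(diameter: float) -> float:
    """Circular cross-sectional area (cm^2) from aortic diameter (cm)."""
    if diameter <= 0:
        raise DomainError(f"diameter must be > 0, got {diameter}")
    return math.pi * (diameter / 2.0) ** 2


def doppler_stroke_volume(diameter: float, vti: float) -> float:
    """Stroke volume (mL) = aortic cross-section (cm^2) x VTI (cm).

    cm^3 and mL are identical, so no numeric conversion is needed.
    """
    if vti <= 0:
        raise DomainError(f"vti must be > 0, got {vti}")
    return aortic_cross_section(diameter) * vti


def tte_cardiac_output(sv: float, hr: float) -> float:
    """Cardiac output (L min^-1) from stroke volume (mL) and heart rate."""
    if sv <= 0 or hr <= 0:
        raise DomainError(f"sv and hr must be > 0, got ({sv}, {hr})")
    return sv * hr / 1000.0


def average_replicates(
    vti_sets: Sequence[Iterable[float]], method: str = "mean"
) -> tuple[list[float], float]:
    """Aggregate replicate trace sets into (per-set means, grand summary).

    Each set is averaged arithmetically; the grand summary is the mean
    (default) or median of the set means. With the balanced 3x3 acquisition
    the mean-of-set-means equals the grand mean of all nine traces.
    """
    if method not in ("mean", "median"):
        raise DomainError(f"unknown aggregation method {method!r}")
    sets = [list(s) for s in vti_sets]
    if not sets or any(len(s) == 0 for s in sets):
        raise DomainError("each replicate set must contain at least one trace")
    if any(t <= 0 for s in sets for t in s):
        raise DomainError("all traces must be > 0")
    set_means = [float(np.mean(s)) for s in sets]
    if method == "mean":
        grand = float(np.mean(set_means))
    else:
        grand = float(np.median(set_means))
    return set_means, grand


def echo_cardiac_index(
    diameter: float,
    vti_sets: Sequence[Iterable[float]],
    hr: float,
    height: float,
    weight: float,
    aggregation: str = "mean",
) -> float:
    """Full echo chain: replicate VTIs -> SV -> CO -> indexed by Mosteller BSA."""
    _, vti = average_replicates(vti_sets, method=aggregation)
    sv = doppler_stroke_volume(diameter, vti)
    co = tte_cardiac_output(sv, hr)
    return cardiac_index(co, mosteller_bsa(height, weight))
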