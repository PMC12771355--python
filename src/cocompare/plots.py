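"""Functional plots: Bland-Altman, four-quadrant, and polar trending views."""
from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .agreement import AgreementResult
from .datamodel import PairedObservation
from .trending import ChangePair, PolarPoint, TrendingResult


def bland_altman_plot(
    pairs: Sequence[PairedObservation], result: AgreementResult, path: str | Path
) -> None:
    """Difference vs pair-mean scatter with bias, LoA, and their CI bands."""
    means = [p.mean_pair for p in pairs]
    diffs = [p.difference for p in pairs]
    fig, ax = plt.subplots(figsize=(6, 4.5))
    ax.scatter(means, diffs, s=14, alpha=0.7)
    for level, ci in (
        (result.bias, result.ci_bias),
        (result.loa_lower, result.ci_loa_lower),
        (result.loa_upper, result.ci_loa_upper),
    ):
        ax.axhline(level, color="k", lw=1, ls="--")
        ax.axhspan(ci[0], ci[1], color="purple", alpha=0.15)
    ax.set_xlabel("Mean of pair (L/min/m$^2$)")
    ax.set_ylabel("Difference, test $-$ reference (L/min/m$^2$)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def four_quadrant_plot(
    changes: Sequence[ChangePair], zone: float, path: str | Path
) -> None:
    """Change-pair scatter with the central square exclusion zone."""
    dr = [c.delta_ref for c in changes]
    dt = [c.delta_test for c in changes]
    lim = max(0.1, 1.1 * max((abs(v) for v in dr + dt), default=1.0))
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.add_patch(
        plt.Rectangle((-zone, -zone), 2 * zone, 2 * zone, color="purple", alpha=0.2)
    )
    ax.scatter(dr, dt, s=14, alpha=0.7)
    ax.plot([-lim, lim], [-lim, lim], color="k", lw=0.8)
    ax.axhline(0, color="grey", lw=0.5)
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlim(-lim, lim)
    ax.set_ylim(-lim, lim)
    ax.set_xlabel("$\\Delta$ reference (L/min/m$^2$)")
    ax.set_ylabel("$\\Delta$ test (L/min/m$^2$)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def polar_plot(
    points: Sequence[PolarPoint], result: TrendingResult, path: str | Path
) -> None:
    """Half-circle polar view with zone disc, mean angle, and radial LoA rays."""
    fig = plt.figure(figsize=(5.5, 4.5))
    ax = fig.add_subplot(projection="polar")
    angles = np.radians([p.angle for p in points])
    radii = [p.radius for p in points]
    ax.scatter(angles, radii, s=14, alpha=0.7)
    rmax = max(radii, default=1.0) * 1.1
    theta_zone = np.linspace(-np.pi, np.pi, 100)
    ax.fill_between(theta_zone, 0, result.zone_polar, color="purple", alpha=0.2)
    for ang, style in (
        (result.mean_polar_angle, "-"),
        (result.radial_loa_lower, "--"),
        (result.radial_loa_upper, "--"),
    ):
        ax.plot([np.radians(ang)] * 2, [0, rmax], color="k", ls=style, lw=1)
    ax.set_thetamin(-90)
    ax.set_thetamax(90)
    ax.set_rmax(rmax)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
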