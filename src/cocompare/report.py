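"""Assembled validation report: agreement plus trending, with verdicts.

Verdicts are pure functions of the numeric summary statistics:

* ``mpe_acceptable`` — mean percentage error strictly below the threshold
  (default 30%).
* ``trending_reliable`` — concordance rate above 90%, absolute mean polar
  angle below 5 degrees, angular sd at most 15 degrees, and radial limits of
  agreement inside +/- 30 degrees.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

from . import __version__
from .agreement import (
    AgreementResult,
    RobustnessChecks,
    bland_altman,
    interchangeability,
    robustness_checks,
)
from .datamodel import StudyDataset
from .errors import DomainError
from .io import read_pairs
from .trending import TrendingResult, change_pairs, polar_points, trending_analysis

logger = logging.getLogger(__name__)


def mpe_acceptable(mpe_value: float, threshold: float = 30.0) -> bool:
    """Interchangeability verdict on the mean percentage error."""
    return interchangeability(mpe_value, threshold)


def trending_reliable(
    concordance: float,
    mean_angle: float,
    angle_sd: float,
    radial_loa_lower: float,
    radial_loa_upper: float,
) -> bool:
    """Combined trending verdict against the conventional criteria."""
    return (
        concordance > 90.0
        and abs(mean_angle) < 5.0
        and angle_sd <= 15.0
        and radial_loa_lower > -30.0
        and radial_loa_upper < 30.0
    )


@dataclass(frozen=True)
class ReportConfig:
    z: float = 1.96
    mpe_threshold: float = 30.0
    zone_fraction: float = 0.15
    polar_scale: float = 1.5
    policy: str = "consecutive_only"
    seed: int | None = None


@dataclass(frozen=True)
class ValidationReport:
    agreement: AgreementResult
    robustness: RobustnessChecks
    trending: TrendingResult
    mpe_acceptable: bool
    trending_reliable: bool
    provenance: dict


def _digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def validate_dataset(
    dataset: StudyDataset, config: ReportConfig = ReportConfig(), provenance: dict | None = None
) -> ValidationReport:
    """Run the full agreement + trending pipeline on an in-memory dataset."""
    agreement = bland_altman(dataset.observations, z=config.z)
    robustness = robustness_checks(dataset.observations, z=config.z)
    trending = trending_analysis(
        dataset,
        zone_fraction=config.zone_fraction,
        polar_scale=config.polar_scale,
        policy=config.policy,
    )
    logger.info(
        "validation: %d pairs, %d orphans, %d change pairs (%d excluded)",
        dataset.n_pairs,
        len(dataset.orphans),
        trending.n_total,
        trending.n_excluded,
    )
    report = ValidationReport(
        agreement=agreement,
        robustness=robustness,
        trending=trending,
        mpe_acceptable=mpe_acceptable(agreement.mpe, config.mpe_threshold),
        trending_reliable=trending_reliable(
            trending.concordance_rate,
            trending.mean_polar_angle,
            trending.polar_sd,
            trending.radial_loa_lower,
            trending.radial_loa_upper,
        ),
        provenance={"version": __version__, "seed": config.seed, **(provenance or {})},
    )
    logger.info(
        "verdicts: mpe_acceptable=%s trending_reliable=%s",
        report.mpe_acceptable,
        report.trending_reliable,
    )
    return report


def run_validation(
    pairs_path: str | Path,
    config: ReportConfig = ReportConfig(),
    out_dir: str | Path | None = None,
) -> ValidationReport:
    """Read a pairs CSV, run the pipeline, and optionally write report + plots."""
    dataset = read_pairs(pairs_path)
    report = validate_dataset(
        dataset, config, provenance={"input_sha256": _digest(pairs_path)}
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(render_report(report, "json"))
        from . import plots

        changes = change_pairs(dataset, policy=config.policy)
        plots.bland_altman_plot(dataset.observations, report.agreement, out / "bland_altman.png")
        plots.four_quadrant_plot(changes, report.trending.zone_quadrant, out / "four_quadrant.png")
        plots.polar_plot(polar_points(changes), report.trending, out / "polar.png")
    return report


def report_to_dict(report: ValidationReport) -> dict:
    d = dataclasses.asdict(report)

    def tuples_to_lists(obj):
        if isinstance(obj, tuple):
            return [tuples_to_lists(v) for v in obj]
        if isinstance(obj, dict):
            return {k: tuples_to_lists(v) for k, v in obj.items()}
        return obj

    return tuples_to_lists(d)


def render_report(report: ValidationReport, format: str = "json") -> str:
    """Render a report as canonical JSON or a human-readable text table.

    Text numbers follow the reporting precision conventions: two decimals for
    index-scale quantities, one decimal for percentages and degrees.
    """
    if format == "json":
        return json.dumps(report_to_dict(report), sort_keys=True, indent=2) + "\n"
    if format != "text":
        raise DomainError(f"unknown report format {format!r}")

    a, r, t = report.agreement, report.robustness, report.trending
    lines = [
        "Agreement (Bland-Altman)",
        f"  pairs analysed        {a.n}",
        f"  bias                  {a.bias:.2f} ({a.ci_bias[0]:.2f} to {a.ci_bias[1]:.2f})",
        f"  precision (sd)        {a.precision:.2f}",
        f"  lower LoA             {a.loa_lower:.2f} ({a.ci_loa_lower[0]:.2f} to {a.ci_loa_lower[1]:.2f})",
        f"  upper LoA             {a.loa_upper:.2f} ({a.ci_loa_upper[0]:.2f} to {a.ci_loa_upper[1]:.2f})",
        f"  MPE                   {a.mpe:.1f}% ({a.ci_mpe[0]:.1f} to {a.ci_mpe[1]:.1f})",
        "Robustness checks",
        f"  Shapiro-Wilk          W={r.shapiro_w:.3f}, p={r.shapiro_p:.3g}",
        f"  percentile LoA        {r.np_loa_lower:.2f} to {r.np_loa_upper:.2f}",
        f"  corrected LoA         {r.corrected_loa_lower:.2f} to {r.corrected_loa_upper:.2f}",
        (
            f"  combined repeatability {r.combined_repeatability:.1f}%"
            if r.combined_repeatability is not None
            else "  combined repeatability n/a (no replicate data)"
        ),
        f"  proportional slope    {r.prop_slope:.3f} (se {r.prop_slope_se:.3f}, p={r.prop_slope_p:.3g})",
        "Trending",
        f"  change pairs          {t.n_total} ({t.n_excluded} excluded, zone {t.zone_quadrant:.2f})",
        f"  concordance rate      {t.concordance_rate:.1f}%",
        f"  mean polar angle      {t.mean_polar_angle:.1f} deg",
        f"  polar sd              {t.polar_sd:.1f} deg",
        f"  radial LoA            {t.radial_loa_lower:.1f} to {t.radial_loa_upper:.1f} deg",
        "Verdicts",
        f"  MPE acceptable        {report.mpe_acceptable}",
        f"  trending reliable     {report.trending_reliable}",
    ]
    return "\n".join(lines) + "\n"
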