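"""CSV input/output for paired studies, plus packaged reference fixtures.

Schemas
-------
``pairs.csv``: long format, one row per method reading::

    patient_id,timepoint,method,co_l_min[,height_cm,weight_kg][,ci_l_min_m2]

``method`` is ``test`` or ``reference``. When biometrics columns are present
the cardiac index is computed as CO / Mosteller BSA; an explicit
``ci_l_min_m2`` column (written by :func:`write_pairs` for lossless
round-trips) takes precedence; with neither, ``co_l_min`` is treated as an
already-indexed value.

``echo.csv``: one row per VTI trace::

    patient_id,timepoint,aortic_diameter_cm,set_idx,trace_idx,vti_cm,heart_rate_bpm
"""
from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import PairedObservation, PatientRecord, StudyDataset
from .errors import IntegrityError, SchemaError
from .hemodynamics import mosteller_bsa

logger = logging.getLogger(__name__)

PAIRS_REQUIRED = ("patient_id", "timepoint", "method", "co_l_min")
METHODS = ("test", "reference")


def _fixture_path(name: str):
    return resources.files("cocompare.fixtures").joinpath(name)


def read_pairs(path: str | Path) -> StudyDataset:
    """Read a long-format pairs CSV into a :class:`StudyDataset`.

    Unpaired rows (a patient-timepoint with only one method) are retained in
    ``dataset.orphans`` and logged, never silently dropped. Missing required
    columns raise :class:`SchemaError`; duplicate (patient, timepoint, method)
    rows raise :class:`IntegrityError`.
    """
    # round_trip parser: shortest-repr floats written by to_csv read back
    # bit-exactly, which the write/read round-trip contract relies on
    df = pd.read_csv(path, float_precision="round_trip")
    for col in PAIRS_REQUIRED:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r} in {path}")
    bad_method = ~df["method"].isin(METHODS)
    if bad_method.any():
        row = df.index[bad_method][0]
        raise SchemaError(
            f"row {row}: method must be one of {METHODS}, "
            f"got {df.loc[row, 'method']!r}"
        )
    dupes = df.duplicated(subset=["patient_id", "timepoint", "method"], keep=False)
    if dupes.any():
        first = df[dupes].iloc[0]
        raise IntegrityError(
            f"duplicate rows for patient {first['patient_id']!r} "
            f"timepoint {first['timepoint']} method {first['method']!r}"
        )

    has_biometrics = {"height_cm", "weight_kg"}.issubset(df.columns)
    has_ci = "ci_l_min_m2" in df.columns

    patients: dict[str, PatientRecord] = {}
    if has_biometrics:
        for pid, grp in df.groupby("patient_id", sort=False):
            h = float(grp["height_cm"].iloc[0])
            w = float(grp["weight_kg"].iloc[0])
            age = float(grp["age_yr"].iloc[0]) if "age_yr" in grp else float("nan")
            patients[str(pid)] = PatientRecord(str(pid), age, h, w)

    def to_ci(row: pd.Series) -> float:
        if has_ci and pd.notna(row.get("ci_l_min_m2")):
            return float(row["ci_l_min_m2"])
        co = float(row["co_l_min"])
        if has_biometrics:
            return co / mosteller_bsa(float(row["height_cm"]), float(row["weight_kg"]))
        return co

    observations: list[PairedObservation] = []
    orphans: list[tuple[str, int, str, float]] = []
    for (pid, tp), grp in df.groupby(["patient_id", "timepoint"], sort=True):
        methods = dict(zip(grp["method"], (to_ci(r) for _, r in grp.iterrows())))
        if set(methods) == set(METHODS):
            observations.append(
                PairedObservation(str(pid), int(tp), methods["test"], methods["reference"])
            )
        else:
            for m, ci in methods.items():
                orphans.append((str(pid), int(tp), str(m), ci))
                logger.warning(
                    "orphan reading: patient %s timepoint %s method %s", pid, tp, m
                )
    return StudyDataset(patients=patients, observations=observations, orphans=orphans)


def write_pairs(dataset: StudyDataset, path: str | Path) -> None:
    """Write a dataset back to the long-format pairs CSV.

    The explicit ``ci_l_min_m2`` column is included so that a subsequent
    :func:`read_pairs` reproduces every difference and pair mean bit-exactly
    (dividing CO by BSA would not round-trip in floating point).
    """
    rows = []
    for obs in dataset.observations:
        rec = dataset.patients.get(obs.patient_id)
        for method, ci in (("test", obs.ci_test), ("reference", obs.ci_ref)):
            row = {
                "patient_id": obs.patient_id,
                "timepoint": obs.timepoint,
                "method": method,
                "ci_l_min_m2": ci,
            }
            if rec is not None:
                bsa = mosteller_bsa(rec.height, rec.weight)
                row["co_l_min"] = ci * bsa
                row["height_cm"] = rec.height
                row["weight_kg"] = rec.weight
            else:
                row["co_l_min"] = ci
            rows.append(row)
    cols = ["patient_id", "timepoint", "method", "co_l_min"]
    if any("height_cm" in r for r in rows):
        cols += ["height_cm", "weight_kg"]
    cols += ["ci_l_min_m2"]
    pd.DataFrame(rows)[cols].to_csv(path, index=False)


def write_echo(echo_rows: pd.DataFrame, path: str | Path) -> None:
    """Write trace-level echo data (one row per VTI trace)."""
    echo_rows.to_csv(path, index=False)


def fixture_table2() -> pd.DataFrame:
    """Per-timepoint cardiac-index summary (n, mean, sd) for both methods.

    Five timepoints x two methods; ``method`` is ``test`` (device) or
    ``reference`` (echocardiography).
    """
    with resources.as_file(_fixture_path("timepoint_summary.csv")) as p:
        return pd.read_csv(p)


def fixture_table1() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cohort biometric summary (continuous variables, ASA class counts)."""
    with resources.as_file(_fixture_path("cohort_characteristics.csv")) as p:
        cont = pd.read_csv(p)
    with resources.as_file(_fixture_path("cohort_asa.csv")) as p:
        asa = pd.read_csv(p)
    return cont, asa


def summary_weighted_bias(summary: pd.DataFrame) -> float:
    """Sample-size-weighted mean of per-timepoint (test - reference) means."""
    wide = summary.pivot(index="timepoint", columns="method", values="mean")
    n = summary.pivot(index="timepoint", columns="method", values="n")["test"]
    diffs = wide["test"] - wide["reference"]
    return float(np.average(diffs, weights=n))


def summary_pooled_mean(summary: pd.DataFrame) -> float:
    """Sample-size-weighted grand mean over all method x timepoint cells."""
    return float(np.average(summary["mean"], weights=summary["n"]))
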