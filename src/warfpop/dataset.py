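"""Tabular dataset contracts: the three-CSV layout and its validation.

A study dataset is three comma-delimited UTF-8 tables:

* ``dosing.csv``       — patient_id, time_h, dose_mg (racemic)
* ``observations.csv`` — patient_id, time_h, obs_type {CP, NPT, INR}, value
* ``covariates.csv``   — patient_id plus one column per covariate

Synthetic cohorts add ``truth.csv`` (true individual parameters and
random-effect draws) for parameter-recovery scoring; it is optional on read.

Pre-treatment observations carry negative ``time_h`` (hours before the first
warfarin dose).  Patients whose baseline NPT (``npt0``) is missing are kept
in the dataset but flagged, and the PD stages exclude them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from warfpop.structural import CovariateSet, GenotypeProfile

logger = logging.getLogger("warfpop")

OBS_TYPES = ("CP", "NPT", "INR")

COVARIATE_COLUMNS = [
    "patient_id", "protocol", "age", "weight", "height", "bsa", "bmi", "sex_female",
    "npt0", "inr_base", "alt", "ast", "clcr",
    "cyp2c9_star3", "vkorc1_star1", "cyp4f2_star3_carrier",
    "diabetes", "hypertension", "hepatic_disease", "ckd", "chf",
    "alcohol", "smoking", "atrial_fibrillation", "stroke", "dvt",
]

DOSING_COLUMNS = ["patient_id", "time_h", "dose_mg"]
OBSERVATION_COLUMNS = ["patient_id", "time_h", "obs_type", "value"]


class DatasetError(ValueError):
    """Schema or cross-reference violation in an input dataset."""


@dataclass
class Dataset:
    """Validated in-memory study dataset."""

    covariates: pd.DataFrame
    dosing: pd.DataFrame
    observations: pd.DataFrame
    truth: pd.DataFrame | None = None

    @property
    def patient_ids(self) -> list[int]:
        return list(self.covariates["patient_id"])

    @property
    def n_patients(self) -> int:
        return len(self.covariates)

    def missing_npt0_ids(self) -> list[int]:
        m = self.covariates["npt0"].isna()
        return list(self.covariates.loc[m, "patient_id"])

    def pd_patient_ids(self) -> list[int]:
        """Patients eligible for the PD stages (baseline NPT present)."""
        m = self.covariates["npt0"].notna()
        return list(self.covariates.loc[m, "patient_id"])

    def covariate_set(self, patient_id: int) -> CovariateSet:
        row = self.covariates.set_index("patient_id").loc[patient_id]
        geno = GenotypeProfile(int(row["cyp2c9_star3"]), int(row["vkorc1_star1"]),
                               int(row["cyp4f2_star3_carrier"]))
        return CovariateSet(
            bsa=float(row["bsa"]), npt0=float(row["npt0"]),
            inr_base=float(row["inr_base"]), genotype=geno,
            age=float(row["age"]), weight=float(row["weight"]),
            height=float(row["height"]), sex_female=int(row["sex_female"]),
            alt=float(row["alt"]), ast=float(row["ast"]), clcr=float(row["clcr"]),
            diabetes=int(row["diabetes"]), hypertension=int(row["hypertension"]),
            hepatic_disease=int(row["hepatic_disease"]), ckd=int(row["ckd"]),
            chf=int(row["chf"]), alcohol=int(row["alcohol"]),
            smoking=int(row["smoking"]),
            atrial_fibrillation=int(row["atrial_fibrillation"]),
            stroke=int(row["stroke"]), dvt=int(row["dvt"]),
        )

    def obs(self, obs_type: str) -> pd.DataFrame:
        if obs_type not in OBS_TYPES:
            raise DatasetError(f"unknown observation type {obs_type!r}")
        return self.observations[self.observations["obs_type"] == obs_type]

    def subset(self, patient_ids, renumber: bool = False) -> "Dataset":
        """Dataset restricted to ``patient_ids`` (with repeats, for bootstrap).

        With ``renumber=True`` resampled patients get fresh sequential ids so a
        patient drawn twice contributes two independent individuals.
        """
        cov = self.covariates.set_index("patient_id", drop=False)
        dos = {pid: g for pid, g in self.dosing.groupby("patient_id")}
        obs = {pid: g for pid, g in self.observations.groupby("patient_id")}
        cov_rows, dos_rows, obs_rows = [], [], []
        for new_id, pid in enumerate(patient_ids, start=1):
            if pid not in cov.index:
                raise DatasetError(f"unknown patient id {pid!r}")
            out_id = new_id if renumber else pid
            c = cov.loc[pid].copy()
            c["patient_id"] = out_id
            cov_rows.append(c)
            for src, sink in ((dos, dos_rows), (obs, obs_rows)):
                g = src.get(pid)
                if g is not None:
                    g = g.copy()
                    g["patient_id"] = out_id
                    sink.append(g)
        return Dataset(
            covariates=pd.DataFrame(cov_rows).reset_index(drop=True),
            dosing=pd.concat(dos_rows, ignore_index=True) if dos_rows else
                self.dosing.iloc[0:0].copy(),
            observations=pd.concat(obs_rows, ignore_index=True) if obs_rows else
                self.observations.iloc[0:0].copy(),
        )


def _require_columns(df: pd.DataFrame, cols, name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise DatasetError(f"{name}: missing column(s) {missing}")


def validate_dataset(ds: Dataset) -> Dataset:
    """Schema checks and cross-referencing; returns the dataset on success."""
    _require_columns(ds.covariates, COVARIATE_COLUMNS, "covariates")
    _require_columns(ds.dosing, DOSING_COLUMNS, "dosing")
    _require_columns(ds.observations, OBSERVATION_COLUMNS, "observations")
    ids = set(ds.covariates["patient_id"])
    if len(ids) != len(ds.covariates):
        raise DatasetError("covariates: duplicated patient_id")
    for name, df in (("dosing", ds.dosing), ("observations", ds.observations)):
        unknown = set(df["patient_id"]) - ids
        if unknown:
            raise DatasetError(f"{name}: unknown patient id {sorted(unknown)[0]!r}")
    bad = set(ds.observations["obs_type"]) - set(OBS_TYPES)
    if bad:
        raise DatasetError(f"observations: invalid obs_type {sorted(bad)[0]!r}")
    if len(ds.dosing) and (ds.dosing["time_h"] < 0).any():
        raise DatasetError("dosing: negative time_h")
    if len(ds.dosing) and (ds.dosing["dose_mg"] <= 0).any():
        raise DatasetError("dosing: non-positive dose_mg")
    n_missing = len(ds.missing_npt0_ids())
    if n_missing:
        logger.info("%d patient(s) lack baseline NPT and are excluded from the PD stages",
                    n_missing)
    return ds


def write_dataset(ds: Dataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the CSV tables; returns the written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "covariates": out / "covariates.csv",
        "dosing": out / "dosing.csv",
        "observations": out / "observations.csv",
    }
    ds.covariates.to_csv(paths["covariates"], index=False)
    ds.dosing.to_csv(paths["dosing"], index=False)
    ds.observations.to_csv(paths["observations"], index=False)
    if ds.truth is not None:
        paths["truth"] = out / "truth.csv"
        ds.truth.to_csv(paths["truth"], index=False)
    return paths


def read_dataset(in_dir: str | Path) -> Dataset:
    """Read and validate a dataset directory written by :func:`write_dataset`."""
    d = Path(in_dir)
    for fname in ("covariates.csv", "dosing.csv", "observations.csv"):
        if not (d / fname).exists():
            raise DatasetError(f"missing input file {d / fname}")
    kwargs = dict(comment=None)
    ds = Dataset(
        covariates=pd.read_csv(d / "covariates.csv"),
        dosing=pd.read_csv(d / "dosing.csv"),
        observations=pd.read_csv(d / "observations.csv"),
        truth=pd.read_csv(d / "truth.csv") if (d / "truth.csv").exists() else None,
    )
    return validate_dataset(ds)
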