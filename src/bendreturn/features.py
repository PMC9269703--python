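"""Statistical describers and feature-table assembly.

Every recorded channel of every sensor is treated as an independent time
series and condensed into seven describers — max, min, mean, median, Q1, Q3
and SD — giving 3 sensors x 6 channels x 7 = 126 "raw data" features per
participant.  Entropy columns (per-channel SampEn, or the two complexity
factors LCF/HCF) can be added or used on their own.

Two granularities are supported: *whole* mode (one row per participant,
describers over the full 60 s analysis window) and *cycle* mode (one row per
segmented, length-normalised cycle, each still tagged with its participant so
cross-validation can split leakage-safely by subject).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .entropy import SampEnParams, complexity_factors, sample_entropy
from .imu_io import RECORDED_CHANNELS, Recording, SensorId
from .segmentation import CycleSet

__all__ = [
    "DESCRIBERS",
    "FeatureTable",
    "describe_series",
    "build_feature_table",
    "cycle_feature_table",
]

#: Canonical describer order used in column names.
DESCRIBERS = ("max", "min", "mean", "median", "Q1", "Q3", "SD")


def describe_series(x: np.ndarray) -> dict[str, float]:
    """The seven statistical describers of one series.

    Quartiles use linear interpolation between order statistics; SD is the
    sample standard deviation (ddof=1), hence the length >= 2 requirement.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError(f"need >= 2 samples for describers, got {x.size}")
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return {
        "max": float(x.max()),
        "min": float(x.min()),
        "mean": float(x.mean()),
        "median": float(med),
        "Q1": float(q1),
        "Q3": float(q3),
        "SD": float(x.std(ddof=1)),
    }


@dataclass
class FeatureTable:
    """Features x rows with aligned labels and subject grouping.

    ``data`` holds one named scalar column per feature ("Gyr Y SENS2 min",
    "LCF", ...); ``labels`` the clinical group per row; ``groups`` the
    subject each row came from (rows == subjects in whole mode, but several
    rows share a subject in cycle mode).  Missing values can arise only from
    undefined SampEn and propagate as NaN.
    """

    data: pd.DataFrame
    labels: pd.Series
    groups: pd.Series
    mode: str = "whole"

    def __post_init__(self) -> None:
        if self.data.columns.duplicated().any():
            dupes = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValueError(f"duplicate feature columns: {dupes}")
        if not (len(self.data) == len(self.labels) == len(self.groups)):
            raise ValueError("data, labels and groups must align row-wise")

    @property
    def X(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.labels.to_numpy()

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    def __len__(self) -> int:
        return len(self.data)

    def select(self, columns: list[str]) -> "FeatureTable":
        return FeatureTable(
            data=self.data[columns].copy(),
            labels=self.labels,
            groups=self.groups,
            mode=self.mode,
        )

    def to_csv(self, path, *, sep: str = ",") -> None:
        out = self.data.copy()
        out.insert(0, "subject", self.groups.to_numpy())
        out.insert(1, "group", self.labels.to_numpy())
        out.to_csv(path, sep=sep, index=False)

    @staticmethod
    def from_csv(path, *, sep: str = ",", mode: str = "whole") -> "FeatureTable":
        df = pd.read_csv(path, sep=sep)
        return FeatureTable(
            data=df.drop(columns=["subject", "group"]),
            labels=df["group"],
            groups=df["subject"],
            mode=mode,
        )


def _raw_feature_row(rec: Recording, include_derived: bool) -> dict[str, float]:
    row: dict[str, float] = {}
    for sid, name, series in rec.iter_channels(include_derived=include_derived):
        desc = describe_series(series)
        for dname, val in desc.items():
            row[f"{name} {sid.value} {dname}"] = val
    return row


def _entropy_columns(
    rec: Recording, params: SampEnParams
) -> dict[str, float]:
    row: dict[str, float] = {}
    for sid, name, series in rec.iter_channels():
        res = sample_entropy(series, params)
        row[f"{name} {sid.value} SampEn"] = res.value if res.defined else np.nan
    return row


def _cf_columns(rec: Recording, params: SampEnParams) -> dict[str, float]:
    cf = complexity_factors(rec, params)
    return {
        "LCF": cf.lcf.value if cf.lcf.defined else np.nan,
        "HCF": cf.hcf.value if cf.hcf.defined else np.nan,
    }


def build_feature_table(
    recordings: list[Recording],
    *,
    feature_set: str = "raw",
    include_derived: bool = False,
    sampen_params: SampEnParams | None = None,
) -> FeatureTable:
    """Whole-sequence feature table: one row per participant.

    ``feature_set`` selects the columns: ``"raw"`` (the describers; 126
    columns by default), ``"sampen"`` (18 per-channel SampEn values),
    ``"cf"`` (LCF and HCF only), or ``"raw+sampen"`` / ``"raw+sampen+cf"``
    combinations.
    """
    parts = feature_set.split("+")
    unknown = set(parts) - {"raw", "sampen", "cf"}
    if unknown:
        raise ValueError(f"unknown feature set component(s): {sorted(unknown)}")
    p = sampen_params or SampEnParams()

    rows = []
    for rec in recordings:
        row: dict[str, float] = {}
        if "raw" in parts:
            row.update(_raw_feature_row(rec, include_derived))
        if "sampen" in parts:
            row.update(_entropy_columns(rec, p))
        if "cf" in parts:
            row.update(_cf_columns(rec, p))
        rows.append(row)

    data = pd.DataFrame(rows)
    if data.isna().all(axis=None):
        raise ValueError("empty feature table")
    first_cols = list(data.columns)
    for row in rows[1:]:
        if list(row) != first_cols:
            raise ValueError("recordings yield mixed channel/feature sets")
    return FeatureTable(
        data=data,
        labels=pd.Series([r.group.value for r in recordings], name="group"),
        groups=pd.Series([r.subject_id for r in recordings], name="subject"),
        mode="whole",
    )


def cycle_feature_table(
    cycle_sets: list[CycleSet],
    *,
    channels: tuple[str, ...] = RECORDED_CHANNELS,
) -> FeatureTable:
    """Cycle-mode feature table: one row per normalised cycle.

    Each cycle contributes the seven describers of each channel; rows keep
    their subject tag so the ML protocol can split subject-wise.
    """
    rows, labels, groups = [], [], []
    ref_cols: list[str] | None = None
    for cs in cycle_sets:
        for k in range(cs.n_cycles):
            row: dict[str, float] = {}
            for sid in SensorId:
                for name in channels:
                    seg = cs.channel(sid, name)[k]
                    for dname, val in describe_series(seg).items():
                        row[f"{name} {sid.value} {dname}"] = val
            if ref_cols is None:
                ref_cols = list(row)
            elif list(row) != ref_cols:
                raise ValueError("cycle sets yield mixed channel sets")
            rows.append(row)
            labels.append(cs.group)
            groups.append(cs.subject_id)
    if not rows:
        raise ValueError("no cycles to tabulate")
    return FeatureTable(
        data=pd.DataFrame(rows),
        labels=pd.Series(labels, name="group"),
        groups=pd.Series(groups, name="subject"),
        mode="cycle",
    )
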