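"""Experimental time-course datasets and their tidy CSV schema.

A dataset is one observable measured under one stimulus protocol at a set
of time points, in arbitrary units, with optional per-point measurement
errors.  The on-disk format is a tidy CSV with columns::

    dataset_id, observable, dose_Gy, duration_s, k_dnab, ab,
    time_s, value, sigma

``k_dnab`` is empty for dose-derived protocols and carries the fitted
binding-site generation rate for microirradiation datasets; ``ab`` is the
catalytic-activity switch (0 marks E988K-variant data).  ``sigma`` may be
empty, in which case the error model is profiled during inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .stimulus import StimulusProtocol

__all__ = ["ExperimentalDataset", "load_datasets", "save_datasets"]

_COLUMNS = ["dataset_id", "observable", "dose_Gy", "duration_s", "k_dnab", "ab",
            "time_s", "value", "sigma"]


@dataclass
class ExperimentalDataset:
    """One observable's time course under one stimulus protocol."""

    dataset_id: str
    observable_id: str
    protocol: StimulusProtocol
    times: np.ndarray                 # s
    values: np.ndarray                # arbitrary units
    sigmas: np.ndarray | None = None  # same units; None -> profiled
    ab: float = 1.0                   # 0 for the catalytically dead variant
    provenance: str = ""
    truth: dict = field(default_factory=dict)  # generator ground truth, if synthetic

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.sigmas is not None:
            self.sigmas = np.asarray(self.sigmas, dtype=float)
            if np.any(self.sigmas <= 0):
                raise ValueError("measurement errors must be positive where given")
            if self.sigmas.shape != self.times.shape:
                raise ValueError("sigmas must match times in shape")
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have the same shape")
        if np.any(self.times < 0):
            raise ValueError("times must be nonnegative")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")
        if self.ab not in (0.0, 1.0):
            raise ValueError("ab must be 0 or 1")

    @property
    def n_points(self) -> int:
        return int(self.times.size)

    def to_frame(self) -> pd.DataFrame:
        micro = self.protocol.dose == 0.0
        return pd.DataFrame({
            "dataset_id": self.dataset_id,
            "observable": self.observable_id,
            "dose_Gy": self.protocol.dose,
            "duration_s": self.protocol.duration,
            "k_dnab": self.protocol.k_dnab if micro else np.nan,
            "ab": self.ab,
            "time_s": self.times,
            "value": self.values,
            "sigma": self.sigmas if self.sigmas is not None else np.nan,
        })


def save_datasets(datasets: list[ExperimentalDataset], path: str | Path) -> None:
    """Write datasets to one tidy CSV."""
    frame = pd.concat([ds.to_frame() for ds in datasets], ignore_index=True)
    frame.to_csv(path, index=False, columns=_COLUMNS, float_format="%.10g")


def load_datasets(path: str | Path) -> list[ExperimentalDataset]:
    """Read datasets from a tidy CSV written by :func:`save_datasets`."""
    frame = pd.read_csv(path)
    missing = set(_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"dataset file {path} lacks columns: {sorted(missing)}")
    out = []
    for ds_id, grp in frame.groupby("dataset_id", sort=False):
        row = grp.iloc[0]
        if np.isfinite(row.k_dnab):
            proto = StimulusProtocol.microirradiation(
                k_dnab=float(row.k_dnab), duration=float(row.duration_s))
        else:
            proto = StimulusProtocol.from_dose(
                float(row.dose_Gy), duration=float(row.duration_s))
        sigmas = grp.sigma.to_numpy(dtype=float)
        out.append(ExperimentalDataset(
            dataset_id=str(ds_id),
            observable_id=str(row.observable),
            protocol=proto,
            times=grp.time_s.to_numpy(dtype=float),
            values=grp.value.to_numpy(dtype=float),
            sigmas=None if np.all(np.isnan(sigmas)) else sigmas,
            ab=float(row.ab),
        ))
    return out
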