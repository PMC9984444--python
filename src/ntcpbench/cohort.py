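"""Patient records and cohorts: the unit of NTCP model fitting.

A :class:`PatientRecord` ties one organ DVH to a binary toxicity label
(grade >= 2 complication at follow-up), a treatment-center/batch id and
optional clinical covariates.  A :class:`Cohort` is an ordered collection of
records with unique patient ids; it caches padded dose/volume matrices so
the generalized mean dose of every patient can be evaluated vectorized —
the inner loop of likelihood-based fitting.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .dvh import (
    N_FLOOR,
    DoseVolumeHistogram,
    DVHValidationError,
    GMDDomainError,
)


@dataclasses.dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    dvh: DoseVolumeHistogram
    toxicity: int
    batch: str
    covariates: Mapping[str, object] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.toxicity not in (0, 1):
            raise ValueError(f"toxicity label must be 0 or 1, got {self.toxicity!r}")


class Cohort:
    """Ordered set of patient records with unique ids."""

    def __init__(self, records: Iterable[PatientRecord]):
        self.records: list[PatientRecord] = list(records)
        if not self.records:
            raise ValueError("a cohort must contain at least one patient")
        ids = [r.patient_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate patient ids in cohort")
        self._log_doses: np.ndarray | None = None
        self._log_volumes: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def patient_ids(self) -> list[str]:
        return [r.patient_id for r in self.records]

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.toxicity for r in self.records], dtype=int)

    @property
    def batches(self) -> list[str]:
        return [r.batch for r in self.records]

    def _log_matrices(self) -> tuple[np.ndarray, np.ndarray]:
        """Padded (N, B) matrices of log dose and log volume; padding is -inf."""
        if self._log_doses is None:
            width = max(r.dvh.n_bins for r in self.records)
            log_d = np.full((len(self.records), width), -np.inf)
            log_v = np.full((len(self.records), width), -np.inf)
            with np.errstate(divide="ignore"):
                for i, rec in enumerate(self.records):
                    keep = (rec.dvh.volumes > 0) & (rec.dvh.doses > 0)
                    k = int(keep.sum())
                    log_d[i, :k] = np.log(rec.dvh.doses[keep])
                    log_v[i, :k] = np.log(rec.dvh.volumes[keep])
            self._log_doses = log_d
            self._log_volumes = log_v
        return self._log_doses, self._log_volumes

    def gmd(self, n: float, *, n_floor: float = N_FLOOR) -> np.ndarray:
        """Generalized mean dose of every patient at exponent parameter ``n``.

        Vectorized log-sum-exp over the padded bin matrices; identical to
        calling :func:`ntcpbench.dvh.generalized_mean_dose` per record.
        """
        if not np.isfinite(n) or n < n_floor:
            raise GMDDomainError(
                f"dose-volume exponent n={n!r} below the safe floor {n_floor}"
            )
        log_d, log_v = self._log_matrices()
        terms = log_v + log_d / n
        peak = terms.max(axis=1)
        # rows with no positive-dose mass have peak -inf -> GMD 0 by convention
        out = np.zeros(len(self.records))
        ok = np.isfinite(peak)
        if ok.any():
            shifted = np.exp(terms[ok] - peak[ok, None])
            out[ok] = np.exp(n * (peak[ok] + np.log(shifted.sum(axis=1))))
        return out

    def mean_doses(self) -> np.ndarray:
        return np.array([float(np.dot(r.dvh.volumes, r.dvh.doses)) for r in self.records])

    def covariate_frame(self) -> pd.DataFrame:
        """Covariates as a DataFrame indexed by patient id (may be empty)."""
        rows = [dict(r.covariates) for r in self.records]
        frame = pd.DataFrame(rows, index=self.patient_ids)
        frame.index.name = "patient_id"
        return frame

    # ------------------------------------------------------------------ I/O

    def write(self, directory: Union[str, Path]) -> None:
        """Write ``cohort.csv`` (labels, batches, covariates) and ``dvhs.csv``
        (long-format differential DVHs) into ``directory``."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = self.covariate_frame()
        meta.insert(0, "batch", self.batches)
        meta.insert(1, "toxicity", self.labels)
        meta.to_csv(directory / "cohort.csv", float_format="%.12g")
        chunks = []
        for rec in self.records:
            chunks.append(
                pd.DataFrame(
                    {
                        "patient_id": rec.patient_id,
                        "dose_gy": rec.dvh.doses,
                        "volume": rec.dvh.volumes,
                    }
                )
            )
        pd.concat(chunks, ignore_index=True).to_csv(
            directory / "dvhs.csv", index=False, float_format="%.12g"
        )

    @classmethod
    def read(cls, directory: Union[str, Path]) -> "Cohort":
        """Read a cohort written by :meth:`write`."""
        directory = Path(directory)
        meta = pd.read_csv(directory / "cohort.csv", index_col="patient_id")
        dvhs = pd.read_csv(directory / "dvhs.csv")
        missing = {"patient_id", "dose_gy", "volume"} - set(dvhs.columns)
        if missing:
            raise DVHValidationError(f"dvhs.csv missing columns {sorted(missing)}")
        grouped = dict(tuple(dvhs.groupby("patient_id", sort=False)))
        records = []
        covariate_cols = [c for c in meta.columns if c not in ("batch", "toxicity")]
        for pid, row in meta.iterrows():
            pid = str(pid)
            if pid not in grouped:
                raise DVHValidationError(f"no DVH rows for patient {pid}")
            part = grouped[pid]
            dvh = DoseVolumeHistogram(
                doses=part["dose_gy"].to_numpy(float),
                volumes=part["volume"].to_numpy(float),
            )
            records.append(
                PatientRecord(
                    patient_id=pid,
                    dvh=dvh,
                    toxicity=int(row["toxicity"]),
                    batch=str(row["batch"]),
                    covariates={c: row[c] for c in covariate_cols},
                )
            )
        return cls(records)


def check_disjoint(train: Cohort, test: Cohort) -> None:
    """Raise if the two cohorts share patient ids (train/test leakage)."""
    shared = set(train.patient_ids) & set(test.patient_ids)
    if shared:
        raise ValueError(f"train and test cohorts share patient ids: {sorted(shared)[:5]}")
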