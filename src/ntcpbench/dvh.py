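"""Dose-volume histograms and the generalized mean dose.

A differential dose-volume histogram (DVH) records, for one organ of one
patient, the fraction of organ volume receiving dose within each dose bin.
The generalized mean dose (GMD, equivalently the equivalent uniform dose,
EUD) collapses the histogram to a single effective dose

    GMD(n) = ( sum_i  v_i * D_i^(1/n) )^n

i.e. the power mean of the bin doses with exponent ``1/n``.  ``n`` encodes
the dose-volume dependence (seriality) of the tissue: ``n = 1`` gives the
plain mean dose (parallel organ), while ``n -> 0`` approaches the maximum
dose (serial organ).

For small ``n`` a naive evaluation of ``D_i^(1/n)`` overflows (``70**100``
is far beyond float range), so the sum is evaluated in log space with a
log-sum-exp; the evaluation refuses ``n`` below a hard floor rather than
silently clamping, because exponents that extreme are a known source of
numerical infinities in tissue-complication fitting.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
from scipy.special import logsumexp

#: hard evaluation floor for the dose-volume exponent n
N_FLOOR = 1e-3
#: tolerance on sum(volumes) == 1 for an already-valid DVH
VOLUME_SUM_TOL = 1e-6
#: volumes whose sum deviates from 1 by less than this are renormalized on read
RENORMALIZE_TOL = 0.01


class DVHValidationError(ValueError):
    """A dose-volume histogram violates its structural invariants."""


class GMDDomainError(ValueError):
    """The requested dose-volume exponent is outside the numerically safe domain."""


@dataclasses.dataclass(frozen=True)
class DoseVolumeHistogram:
    """Differential DVH: bin-center doses in Gy and fractional volumes.

    Invariants enforced at construction: doses strictly increasing and
    non-negative, volumes non-negative and summing to 1 within ``1e-6``,
    at least one bin.
    """

    doses: np.ndarray
    volumes: np.ndarray

    def __post_init__(self) -> None:
        doses = np.asarray(self.doses, dtype=float)
        volumes = np.asarray(self.volumes, dtype=float)
        object.__setattr__(self, "doses", doses)
        object.__setattr__(self, "volumes", volumes)
        if doses.ndim != 1 or volumes.ndim != 1:
            raise DVHValidationError("doses and volumes must be one-dimensional")
        if doses.size < 1:
            raise DVHValidationError("a DVH needs at least one bin")
        if doses.size != volumes.size:
            raise DVHValidationError(
                f"doses ({doses.size}) and volumes ({volumes.size}) differ in length"
            )
        if not np.all(np.isfinite(doses)) or not np.all(np.isfinite(volumes)):
            raise DVHValidationError("doses and volumes must be finite")
        if np.any(doses < 0):
            raise DVHValidationError("negative dose bin")
        if np.any(np.diff(doses) <= 0):
            raise DVHValidationError("doses must be strictly increasing")
        if np.any(volumes < 0):
            raise DVHValidationError("negative volume")
        total = volumes.sum()
        if abs(total - 1.0) > VOLUME_SUM_TOL:
            raise DVHValidationError(
                f"fractional volumes must sum to 1 (got {total:.6g}); "
                "renormalize on read or rescale before constructing"
            )

    @property
    def n_bins(self) -> int:
        return int(self.doses.size)

    def max_dose(self) -> float:
        """Highest bin dose carrying positive volume, in Gy."""
        positive = self.volumes > 0
        return float(self.doses[positive].max())

    def min_dose(self) -> float:
        """Lowest bin dose carrying positive volume, in Gy."""
        positive = self.volumes > 0
        return float(self.doses[positive].min())


def mean_dose(dvh: DoseVolumeHistogram) -> float:
    """Volume-weighted mean dose, Gy — the GMD at ``n = 1``."""
    return float(np.dot(dvh.volumes, dvh.doses))


def generalized_mean_dose(
    dvh: DoseVolumeHistogram, n: float, *, n_floor: float = N_FLOOR
) -> float:
    """Power mean of bin doses with exponent ``1/n``, evaluated in log space.

    Zero-dose bins contribute nothing to the power sum (the limit of
    ``v * D**(1/n)`` as ``D -> 0`` is 0 for ``n > 0``) and are excluded; a
    DVH whose entire volume sits at zero dose returns 0 by convention.

    Raises
    ------
    GMDDomainError
        If ``n`` is below ``n_floor`` (default 1e-3): exponents this large
        are numerically hazardous and are refused rather than clamped.
    """
    if not np.isfinite(n) or n < n_floor:
        raise GMDDomainError(
            f"dose-volume exponent n={n!r} below the safe floor {n_floor}; "
            "very small n causes numerical infinities in the power mean"
        )
    keep = (dvh.volumes > 0) & (dvh.doses > 0)
    if not keep.any():
        return 0.0
    log_terms = np.log(dvh.volumes[keep]) + np.log(dvh.doses[keep]) / n
    return float(np.exp(n * logsumexp(log_terms)))


def read_dvh(path: Union[str, Path], dialect: str = "differential") -> DoseVolumeHistogram:
    """Read a per-patient DVH CSV with header columns ``dose_gy,volume``.

    ``dialect="differential"`` reads (bin dose, fractional volume) pairs
    directly.  ``dialect="cumulative"`` expects volume non-increasing and
    starting at 1.0; successive differences are assigned to bin midpoints.
    Volumes are renormalized if their sum is within 1 % of 1, otherwise a
    :class:`DVHValidationError` is raised.
    """
    if dialect not in ("differential", "cumulative"):
        raise ValueError(f"unknown DVH dialect {dialect!r}")
    try:
        table = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise DVHValidationError(f"malformed DVH CSV {path}: {exc}") from exc
    missing = {"dose_gy", "volume"} - set(table.columns)
    if missing:
        raise DVHValidationError(f"DVH CSV {path} missing columns {sorted(missing)}")
    doses = table["dose_gy"].to_numpy(dtype=float)
    volumes = table["volume"].to_numpy(dtype=float)
    if dialect == "cumulative":
        doses, volumes = _cumulative_to_differential(doses, volumes)
    return _build_normalized(doses, volumes)


def _cumulative_to_differential(
    doses: np.ndarray, cum_volumes: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    if doses.size < 2:
        raise DVHValidationError("a cumulative DVH needs at least two rows")
    if np.any(np.diff(doses) <= 0):
        raise DVHValidationError("cumulative DVH doses must be strictly increasing")
    if abs(cum_volumes[0] - 1.0) > RENORMALIZE_TOL:
        raise DVHValidationError(
            f"cumulative DVH must start at volume 1.0 (got {cum_volumes[0]:.6g})"
        )
    if np.any(np.diff(cum_volumes) > 0):
        raise DVHValidationError("cumulative DVH volumes must be non-increasing")
    midpoints = 0.5 * (doses[:-1] + doses[1:])
    volumes = -np.diff(cum_volumes)
    # residual volume at or beyond the last recorded dose is attributed there
    if cum_volumes[-1] > 0:
        midpoints = np.append(midpoints, doses[-1])
        volumes = np.append(volumes, cum_volumes[-1])
    return midpoints, volumes


def _build_normalized(doses: np.ndarray, volumes: np.ndarray) -> DoseVolumeHistogram:
    if np.any(volumes < 0) or np.any(doses < 0):
        raise DVHValidationError("negative dose or volume in DVH file")
    total = volumes.sum()
    if abs(total - 1.0) > RENORMALIZE_TOL:
        raise DVHValidationError(
            f"fractional volumes sum to {total:.6g}, more than 1% away from 1; "
            "refusing to renormalize"
        )
    if total != 1.0:
        volumes = volumes / total
    return DoseVolumeHistogram(doses=doses, volumes=volumes)


def write_dvh(dvh: DoseVolumeHistogram, path: Union[str, Path]) -> None:
    """Write a differential DVH as a ``dose_gy,volume`` CSV."""
    pd.DataFrame({"dose_gy": dvh.doses, "volume": dvh.volumes}).to_csv(
        path, index=False, float_format="%.12g"
    )
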