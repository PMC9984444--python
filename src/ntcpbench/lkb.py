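"""The Lyman-Kutcher-Burman (LKB) NTCP model and its fitting machinery.

The model maps a generalized mean dose (GMD) to a complication probability
through a probit link:

    NTCP = Phi( (GMD - D50) / (m * D50) )
         = 1/2 * [ 1 + erf( (GMD - D50) / (sqrt(2) * m * D50) ) ]

with three parameters: ``n`` (dose-volume dependence, entering through the
GMD), ``m`` (relative slope) and ``D50`` (dose giving 50 % complication
probability).  The cohort objective is the mean binary cross-entropy
(log-loss) of the predicted probabilities against observed toxicity labels.

The log-loss surface in (n, m, D50) is non-convex with multiple basins, so
besides a bound-constrained quasi-Newton local optimizer ("gradient
descent" in the radiotherapy literature; the loss gradient has no known
analytic form and is obtained by central finite differences) the module
exposes two seeded global optimizers, dual annealing and differential
evolution.  A loss/gradient landscape grid over (n, D50) supports
visualising the competing gradient basins.
"""

from __future__ import annotations

import dataclasses
import json
import time
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import ndtr

from .cohort import Cohort
from .dvh import GMDDomainError

#: evaluation floor for the slope parameter m (m -> 0 degenerates to a step)
M_EVAL_FLOOR = 1e-6
#: clipping of predicted probabilities inside the log-loss
LOGLOSS_EPS = 1e-15
#: fitting bounds below this value of n are refused (numerical-infinity hazard)
N_FIT_FLOOR = 0.01

LOCAL_METHOD = "gradient_descent"
GLOBAL_METHODS = ("dual_annealing", "differential_evolution")
FIT_METHODS = (LOCAL_METHOD,) + GLOBAL_METHODS


class LKBDomainError(ValueError):
    """Parameter outside the numerically meaningful domain of the model."""


@dataclasses.dataclass(frozen=True)
class LKBParameters:
    """The (n, m, D50) triple of the LKB dose-response model.

    n : dose-volume dependence (unitless), n=1 -> mean dose
    m : relative slope (unitless); smaller m = steeper dose response
    d50 : dose at 50 % complication probability, Gy
    """

    n: float
    m: float
    d50: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.n) or not np.isfinite(self.m) or not np.isfinite(self.d50):
            raise LKBDomainError("LKB parameters must be finite")
        if self.d50 <= 0:
            raise LKBDomainError(f"D50 must be positive, got {self.d50}")

    def as_array(self) -> np.ndarray:
        return np.array([self.n, self.m, self.d50])

    def to_dict(self) -> dict:
        return {"n": self.n, "m": self.m, "d50": self.d50}


@dataclasses.dataclass(frozen=True)
class ParameterBounds:
    """Box constraints for fitting, as (low, high) pairs."""

    n: tuple[float, float] = (N_FIT_FLOOR, 4.0)
    m: tuple[float, float] = (0.0, 1.0)
    d50: tuple[float, float] = (1e-2, 120.0)

    def as_list(self) -> list[tuple[float, float]]:
        return [self.n, self.m, self.d50]

    def contains(self, params: LKBParameters) -> bool:
        x = params.as_array()
        for value, (lo, hi) in zip(x, self.as_list()):
            if not (lo <= value <= hi):
                return False
        return True

    def validate_safe(self, unsafe: bool = False) -> None:
        if self.n[0] < N_FIT_FLOOR and not unsafe:
            raise LKBDomainError(
                f"bounds permit n < {N_FIT_FLOOR}: very small n causes numerical "
                "infinities during GMD evaluation; pass unsafe=True to override"
            )

    def to_dict(self) -> dict:
        return {"n": list(self.n), "m": list(self.m), "d50": list(self.d50)}


DEFAULT_BOUNDS = ParameterBounds()


@dataclasses.dataclass(frozen=True)
class FitResult:
    params: LKBParameters
    loss: float
    converged: bool
    optimizer: str
    n_evaluations: int
    elapsed: float
    seed: Optional[int]
    bounds: ParameterBounds
    n_free_parameters: int
    message: str = ""

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "loss": self.loss,
            "converged": self.converged,
            "optimizer": self.optimizer,
            "n_evaluations": self.n_evaluations,
            "elapsed": self.elapsed,
            "seed": self.seed,
            "bounds": self.bounds.to_dict(),
            "n_free_parameters": self.n_free_parameters,
            "message": self.message,
        }

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def ntcp(gmd, params: LKBParameters):
    """Complication probability at generalized mean dose ``gmd`` (Gy).

    Equals the standard normal CDF at ``t = (gmd - D50) / (m * D50)``.
    ``gmd`` may be a scalar or array; a scalar input returns a float.
    Raises :class:`LKBDomainError` when ``m`` is below the evaluation floor
    (the response would degenerate to a step function).
    """
    if params.m < M_EVAL_FLOOR:
        raise LKBDomainError(
            f"m={params.m} below evaluation floor {M_EVAL_FLOOR}: step-function degeneracy"
        )
    gmd_arr = np.asarray(gmd, dtype=float)
    if np.any(gmd_arr < 0):
        raise LKBDomainError("gmd must be non-negative")
    t = (gmd_arr - params.d50) / (params.m * params.d50)
    p = ndtr(t)
    return float(p) if np.isscalar(gmd) or gmd_arr.ndim == 0 else p


def _predict_probabilities(cohort: Cohort, params: LKBParameters) -> np.ndarray:
    """NTCP per patient with the slope floored internally (fitting may probe m=0)."""
    m_eff = max(params.m, M_EVAL_FLOOR)
    gmd = cohort.gmd(params.n)
    return ndtr((gmd - params.d50) / (m_eff * params.d50))


def cohort_log_loss(
    cohort: Cohort, params: LKBParameters, *, eps: float = LOGLOSS_EPS
) -> float:
    """Mean binary cross-entropy (nats) of LKB predictions on a cohort.

    Probabilities are clipped to ``[eps, 1 - eps]`` so the loss stays finite
    over the whole fitting box, including the m -> 0 step-function limit.
    """
    p = np.clip(_predict_probabilities(cohort, params), eps, 1.0 - eps)
    y = cohort.labels
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log1p(-p)))


def predict(cohort: Cohort, params: LKBParameters) -> np.ndarray:
    """Per-patient NTCP for scoring (m must be above the evaluation floor)."""
    if params.m < M_EVAL_FLOOR:
        raise LKBDomainError(f"m={params.m} below evaluation floor {M_EVAL_FLOOR}")
    return _predict_probabilities(cohort, params)


#: tolerance (as a fraction of each bound's range) by which a returned
#: parameter may sit outside the box and still count as in-bounds
_BOUNDS_TOL = 1e-9


def _within_bounds(x: np.ndarray, bounds: Sequence[tuple[float, float]]) -> bool:
    for value, (lo, hi) in zip(x, bounds):
        tol = _BOUNDS_TOL * (hi - lo)
        if not (lo - tol <= value <= hi + tol):
            return False
    return True


def fit(
    cohort: Cohort,
    method: str = "dual_annealing",
    initial: Optional[LKBParameters] = None,
    bounds: ParameterBounds = DEFAULT_BOUNDS,
    seed: Optional[int] = 0,
    fix_n: Optional[float] = None,
    unsafe_bounds: bool = False,
) -> FitResult:
    """Fit LKB parameters to a cohort by minimizing the mean log-loss.

    Parameters
    ----------
    method
        ``gradient_descent`` — bounded L-BFGS-B with central-difference
        gradients; requires ``initial``.  ``dual_annealing`` /
        ``differential_evolution`` — seeded global optimizers.
    initial
        Starting point; required for the local method, optional seed point
        for dual annealing, ignored by differential evolution.
    fix_n
        When given, ``n`` is held at this value and only (m, D50) are free:
        the fit has two degrees of freedom (the classical mean-dose
        reduction when ``n = 1``).
    seed
        Seeds the global optimizers; runs are reproducible per seed.

    Convergence is defined as: the optimizer reports success, the final
    loss is finite, and every free parameter lies within its bounds (up to
    a tiny tolerance).  The local method's success flag is the L-BFGS-B
    termination status, so abnormal line-search terminations on the
    plateaued or multi-basin parts of the loss surface register as
    non-converged runs.
    """
    if method not in FIT_METHODS:
        raise ValueError(f"unknown fit method {method!r}; choose from {FIT_METHODS}")
    bounds.validate_safe(unsafe=unsafe_bounds)
    if fix_n is not None and not (bounds.n[0] <= fix_n <= bounds.n[1]):
        raise LKBDomainError(f"fix_n={fix_n} outside n bounds {bounds.n}")

    box = bounds.as_list() if fix_n is None else bounds.as_list()[1:]
    n_free = len(box)

    def unpack(x: np.ndarray) -> LKBParameters:
        if fix_n is None:
            return LKBParameters(n=float(x[0]), m=float(x[1]), d50=float(x[2]))
        return LKBParameters(n=float(fix_n), m=float(x[0]), d50=float(x[1]))

    counter = {"evals": 0}

    def objective(x: np.ndarray) -> float:
        counter["evals"] += 1
        try:
            return cohort_log_loss(cohort, unpack(x))
        except (GMDDomainError, LKBDomainError):
            return np.inf

    x0 = None
    if initial is not None:
        if not bounds.contains(initial):
            raise LKBDomainError(f"initial point {initial} outside bounds {bounds}")
        full = initial.as_array()
        x0 = full if fix_n is None else full[1:]

    start = time.perf_counter()
    if method == LOCAL_METHOD:
        if x0 is None:
            raise ValueError("gradient_descent requires an initial point")
        result = optimize.minimize(
            objective,
            x0,
            method="L-BFGS-B",
            jac="3-point",
            bounds=box,
            options={"finite_diff_rel_step": 1e-6},
        )
    elif method == "dual_annealing":
        result = optimize.dual_annealing(
            objective, bounds=box, seed=seed, maxiter=1000, maxfun=20000, x0=x0
        )
    else:  # differential_evolution
        result = optimize.differential_evolution(
            objective, bounds=box, seed=seed, maxiter=1000, popsize=15, polish=True
        )
    elapsed = time.perf_counter() - start

    x_final = np.asarray(result.x, dtype=float)
    params = unpack(x_final)
    loss = float(result.fun)
    converged = bool(result.success) and np.isfinite(loss) and _within_bounds(x_final, box)
    return FitResult(
        params=params,
        loss=loss,
        converged=converged,
        optimizer=method,
        n_evaluations=counter["evals"],
        elapsed=elapsed,
        seed=seed,
        bounds=bounds,
        n_free_parameters=n_free,
        message=str(getattr(result, "message", "")),
    )


def loss_landscape(
    cohort: Cohort,
    n_grid: Sequence[float],
    d50_grid: Sequence[float],
    m_fixed: float,
    bounds: ParameterBounds = DEFAULT_BOUNDS,
    rel_step: float = 1e-5,
) -> pd.DataFrame:
    """Loss and central-difference gradients over an (n, D50) grid at fixed m.

    Returns a long-format table with columns ``n, d50, loss, grad_n,
    grad_d50``, one row per grid node — directly renderable as a quiver or
    heat map of the competing gradient basins.
    """
    n_grid = np.asarray(n_grid, dtype=float)
    d50_grid = np.asarray(d50_grid, dtype=float)
    if n_grid.size == 0 or d50_grid.size == 0:
        raise ValueError("grids must be non-empty")
    if not (0 < m_fixed <= 1):
        raise LKBDomainError(f"m_fixed={m_fixed} outside (0, 1]")
    bad = [float(v) for v in n_grid if not (bounds.n[0] <= v <= bounds.n[1])]
    bad += [float(v) for v in d50_grid if not (bounds.d50[0] <= v <= bounds.d50[1])]
    if bad:
        raise ValueError(f"grid nodes outside bounds: {bad}")

    def loss_at(n: float, d50: float) -> float:
        return cohort_log_loss(cohort, LKBParameters(n=n, m=m_fixed, d50=d50))

    rows = []
    for n in n_grid:
        h_n = rel_step * max(abs(n), 1.0)
        for d50 in d50_grid:
            h_d = rel_step * max(abs(d50), 1.0)
            loss = loss_at(n, d50)
            grad_n = (loss_at(n + h_n, d50) - loss_at(n - h_n, d50)) / (2 * h_n)
            grad_d50 = (loss_at(n, d50 + h_d) - loss_at(n, d50 - h_d)) / (2 * h_d)
            rows.append((n, d50, loss, grad_n, grad_d50))
    return pd.DataFrame(rows, columns=["n", "d50", "loss", "grad_n", "grad_d50"])
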