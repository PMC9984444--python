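"""Multi-start convergence study of the local LKB fitter.

The LKB log-loss surface has competing gradient basins, so a local
bound-constrained optimizer started at a random point may (a) fail to
converge (abnormal termination, non-finite loss, or a parameter pinned at
the box edge), (b) converge to a model that is not predictive on held-out
patients (test ROC-AUC below a threshold), or (c) converge to a predictive
model.  This module samples initial guesses uniformly over the bounds box,
fits each with the local method, and reports the fractions of the three
disjoint outcome classes — the desk-scale analogue of a million-start
sweep.
"""

from __future__ import annotations

import dataclasses
import json
import time
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from . import lkb
from .cohort import Cohort, check_disjoint
from .metrics import roc_auc

CLASS_FAILED = "failed"
CLASS_NONPREDICTIVE = "nonpredictive"
CLASS_PREDICTIVE = "predictive"


class SweepBudgetError(RuntimeError):
    """Projected sweep runtime exceeds the configured budget."""


@dataclasses.dataclass(frozen=True)
class SweepResult:
    n_starts: int
    frac_failed: float
    frac_nonpredictive: float
    frac_predictive: float
    best_loss: float
    auc_min: float
    auc_median: float
    auc_max: float
    seed: int
    predictive_threshold: float
    start_distribution: str = "uniform-over-bounds-box"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def sample_starts(
    n_starts: int, bounds: lkb.ParameterBounds, seed: int
) -> np.ndarray:
    """Uniform starting points over the bounds box, (n_starts, 3)."""
    rng = np.random.default_rng(seed)
    box = np.array(bounds.as_list())
    return rng.uniform(box[:, 0], box[:, 1], size=(n_starts, 3))


def run_sweep(
    train: Cohort,
    test: Cohort,
    n_starts: int = 1000,
    bounds: lkb.ParameterBounds = lkb.DEFAULT_BOUNDS,
    predictive_threshold: float = 0.7,
    seed: int = 0,
    runtime_budget: Optional[float] = None,
    override_budget: bool = False,
    per_start_csv: Optional[Union[str, Path]] = None,
) -> SweepResult:
    """Fit the local optimizer from ``n_starts`` random initial guesses.

    Classification per start (disjoint classes):
      * ``failed`` — the fit did not converge (see :func:`ntcpbench.lkb.fit`);
      * ``nonpredictive`` — converged but test ROC-AUC < ``predictive_threshold``;
      * ``predictive`` — converged with test ROC-AUC >= the threshold.

    ``best_loss`` is the minimum training loss over converged fits.  When
    ``runtime_budget`` (seconds) is set, a handful of pilot fits project the
    total runtime and the sweep is refused if the projection exceeds the
    budget (``override_budget=True`` proceeds anyway).  Deterministic per
    seed.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    check_disjoint(train, test)
    starts = sample_starts(n_starts, bounds, seed)

    def fit_one(x0: np.ndarray):
        initial = lkb.LKBParameters(n=float(x0[0]), m=float(x0[1]), d50=float(x0[2]))
        result = lkb.fit(
            train, method=lkb.LOCAL_METHOD, initial=initial, bounds=bounds, seed=None
        )
        test_auc = np.nan
        if result.converged:
            probs = lkb.predict(
                test,
                lkb.LKBParameters(
                    n=result.params.n,
                    m=max(result.params.m, lkb.M_EVAL_FLOOR),
                    d50=result.params.d50,
                ),
            )
            test_auc = roc_auc(probs, test.labels)
        return result, test_auc

    if runtime_budget is not None and not override_budget:
        n_pilot = min(5, n_starts)
        tic = time.perf_counter()
        for x0 in starts[:n_pilot]:
            fit_one(x0)
        projected = (time.perf_counter() - tic) / n_pilot * n_starts
        if projected > runtime_budget:
            raise SweepBudgetError(
                f"projected sweep runtime {projected:.1f}s exceeds budget "
                f"{runtime_budget:.1f}s for {n_starts} starts; "
                "pass override_budget=True to run anyway"
            )

    rows = []
    for x0 in starts:
        result, test_auc = fit_one(x0)
        if not result.converged:
            label = CLASS_FAILED
        elif test_auc < predictive_threshold:
            label = CLASS_NONPREDICTIVE
        else:
            label = CLASS_PREDICTIVE
        rows.append(
            {
                "start_n": x0[0],
                "start_m": x0[1],
                "start_d50": x0[2],
                "converged": result.converged,
                "loss": result.loss,
                "test_auc": test_auc,
                "classification": label,
            }
        )
    table = pd.DataFrame(rows)
    if per_start_csv is not None:
        table.to_csv(per_start_csv, index=False, float_format="%.10g")

    counts = table["classification"].value_counts()
    converged_losses = table.loc[table["converged"], "loss"]
    aucs = table.loc[table["converged"], "test_auc"].dropna()
    return SweepResult(
        n_starts=n_starts,
        frac_failed=float(counts.get(CLASS_FAILED, 0)) / n_starts,
        frac_nonpredictive=float(counts.get(CLASS_NONPREDICTIVE, 0)) / n_starts,
        frac_predictive=float(counts.get(CLASS_PREDICTIVE, 0)) / n_starts,
        best_loss=float(converged_losses.min()) if len(converged_losses) else float("nan"),
        auc_min=float(aucs.min()) if len(aucs) else float("nan"),
        auc_median=float(aucs.median()) if len(aucs) else float("nan"),
        auc_max=float(aucs.max()) if len(aucs) else float("nan"),
        seed=seed,
        predictive_threshold=predictive_threshold,
    )
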