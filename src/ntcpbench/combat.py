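"""Parametric empirical-Bayes ComBat harmonization of scalar features.

Treatment-center effects behave like the batch effects of microarray
studies: per feature, each batch shifts the location and inflates or
deflates the scale.  ComBat standardizes each feature against a
size-weighted grand mean and pooled variance, estimates per-batch additive
(gamma) and multiplicative (delta) effects, shrinks them toward common
priors by empirical Bayes (normal prior on gamma, inverse-gamma on delta,
estimated by moment matching and refined by fixed-point iteration), and
removes the shrunken effects:

    x*_ijg = sqrt(pooled var_g) * (z_ijg - gamma*_ig) / sqrt(delta*_ig) + grand mean_g

for sample j of batch i, feature g, where z is the standardized value.

Only scalar numerical features are harmonized — a whole DVH curve is not a
valid input (its bins are not exchangeable features in this sense); pass
summary doses such as the mean parotid dose instead.  The outcome label
must never enter the standardization design (leakage); an optional hook
accepts non-outcome covariates.

The arithmetic mirrors the standard parametric ComBat reference
(Johnson, Li & Rabinovic 2007, as implemented in Bioconductor's sva),
including its fixed-point stopping rule, so results agree element-wise
with that implementation.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd


class CombatError(ValueError):
    """Invalid input for ComBat harmonization."""


@dataclasses.dataclass(frozen=True)
class CombatModel:
    """Fitted ComBat correction for a fixed feature set and batch set."""

    feature_names: tuple[str, ...]
    batch_ids: tuple[str, ...]
    grand_mean: np.ndarray        # (F,)
    var_pooled: np.ndarray        # (F,)
    gamma_star: np.ndarray        # (B, F) additive batch effects, standardized scale
    delta_star: np.ndarray        # (B, F) multiplicative batch effects, > 0
    n_iterations: tuple[int, ...] = ()

    def to_dict(self) -> dict:
        return {
            "feature_names": list(self.feature_names),
            "batch_ids": list(self.batch_ids),
            "grand_mean": self.grand_mean.tolist(),
            "var_pooled": self.var_pooled.tolist(),
            "gamma_star": self.gamma_star.tolist(),
            "delta_star": self.delta_star.tolist(),
            "n_iterations": list(self.n_iterations),
        }

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, payload: dict) -> "CombatModel":
        return cls(
            feature_names=tuple(payload["feature_names"]),
            batch_ids=tuple(payload["batch_ids"]),
            grand_mean=np.asarray(payload["grand_mean"], float),
            var_pooled=np.asarray(payload["var_pooled"], float),
            gamma_star=np.asarray(payload["gamma_star"], float),
            delta_star=np.asarray(payload["delta_star"], float),
            n_iterations=tuple(payload.get("n_iterations", ())),
        )


def _check_inputs(features: pd.DataFrame, batch: Sequence) -> tuple[np.ndarray, np.ndarray]:
    if not isinstance(features, pd.DataFrame):
        features = pd.DataFrame(features)
    x = features.to_numpy(dtype=float)
    if x.ndim != 2 or x.shape[0] == 0 or x.shape[1] == 0:
        raise CombatError("feature table must be a non-empty 2-d table")
    if np.isnan(x).any():
        raise CombatError("missing values in feature table")
    b = np.asarray([str(v) for v in batch])
    if b.size != x.shape[0]:
        raise CombatError("batch vector length must match number of patients")
    return x, b


def _eb_fixed_point(
    s_batch: np.ndarray,
    gamma_hat: np.ndarray,
    delta_hat: np.ndarray,
    gamma_bar: float,
    t2: float,
    a_prior: float,
    b_prior: float,
    conv: float = 1e-4,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Iterate the coupled posterior means of (gamma, delta) to a fixed point."""
    n = s_batch.shape[0]
    g_old = gamma_hat.copy()
    d_old = delta_hat.copy()
    count = 0
    while True:
        g_new = (t2 * n * gamma_hat + d_old * gamma_bar) / (t2 * n + d_old)
        sum2 = ((s_batch - g_new[None, :]) ** 2).sum(axis=0)
        d_new = (0.5 * sum2 + b_prior) / (n / 2.0 + a_prior - 1.0)
        # relative-change stopping rule of the reference implementation
        change = max(
            np.max(np.abs(g_new - g_old) / g_old), np.max(np.abs(d_new - d_old) / d_old)
        )
        g_old, d_old = g_new, d_new
        count += 1
        if change < conv:
            break
    return g_old, d_old, count


def combat_fit(
    features: pd.DataFrame,
    batch: Sequence,
    covariates: Optional[pd.DataFrame] = None,
) -> CombatModel:
    """Estimate EB-shrunken location/scale batch effects per feature.

    Requires at least two batches with at least three patients each, no
    missing values, and positive within-batch variance for every feature.
    ``covariates`` is a hook for non-outcome adjustment variables; it is
    currently not part of the standardization design (the default design
    uses batch indicators only) and is rejected if supplied.
    """
    if covariates is not None:
        raise NotImplementedError(
            "covariate-adjusted standardization is not implemented; "
            "never pass the outcome label here in any case"
        )
    x, b = _check_inputs(features, batch)
    feature_names = tuple(str(c) for c in features.columns)
    batch_ids = tuple(pd.unique(b))
    if len(batch_ids) < 2:
        raise CombatError("single batch: nothing to correct")
    n_total, n_features = x.shape
    masks = {bid: b == bid for bid in batch_ids}
    for bid, mask in masks.items():
        if mask.sum() < 3:
            raise CombatError(f"batch {bid!r} has fewer than 3 patients")
        batch_var = x[mask].var(axis=0, ddof=1)
        for g, v in zip(feature_names, batch_var):
            if v <= 0:
                raise CombatError(f"zero variance in batch {bid!r}, feature {g!r}")

    # standardization: size-weighted grand mean, pooled residual variance
    batch_means = np.stack([x[masks[bid]].mean(axis=0) for bid in batch_ids])
    sizes = np.array([masks[bid].sum() for bid in batch_ids], dtype=float)
    grand_mean = (sizes / n_total) @ batch_means
    fitted = np.empty_like(x)
    for i, bid in enumerate(batch_ids):
        fitted[masks[bid]] = batch_means[i]
    var_pooled = ((x - fitted) ** 2).mean(axis=0)
    s = (x - grand_mean) / np.sqrt(var_pooled)

    gamma_hat = np.stack([s[masks[bid]].mean(axis=0) for bid in batch_ids])
    delta_hat = np.stack([s[masks[bid]].var(axis=0, ddof=1) for bid in batch_ids])

    gamma_star = np.empty_like(gamma_hat)
    delta_star = np.empty_like(delta_hat)
    iterations = []
    if n_features < 2:
        # the priors are moment-matched across features; with a single
        # feature there is nothing to shrink toward, so the per-batch
        # estimates are used directly
        gamma_star[:] = gamma_hat
        delta_star[:] = delta_hat
        iterations = [0] * len(batch_ids)
    else:
        gamma_bar = gamma_hat.mean(axis=1)
        t2 = gamma_hat.var(axis=1, ddof=1)
        d_mean = delta_hat.mean(axis=1)
        d_var = delta_hat.var(axis=1, ddof=1)
        a_prior = (2 * d_var + d_mean**2) / d_var
        b_prior = (d_mean * d_var + d_mean**3) / d_var
        for i, bid in enumerate(batch_ids):
            g, d, count = _eb_fixed_point(
                s[masks[bid]],
                gamma_hat[i],
                delta_hat[i],
                gamma_bar[i],
                t2[i],
                a_prior[i],
                b_prior[i],
            )
            gamma_star[i] = g
            delta_star[i] = d
            iterations.append(count)

    return CombatModel(
        feature_names=feature_names,
        batch_ids=batch_ids,
        grand_mean=grand_mean,
        var_pooled=var_pooled,
        gamma_star=gamma_star,
        delta_star=delta_star,
        n_iterations=tuple(iterations),
    )


def combat_apply(
    model: CombatModel, features: pd.DataFrame, batch: Sequence
) -> pd.DataFrame:
    """Remove the fitted batch effects from a feature table.

    Every batch id must have been seen at fit time (no reference-batch
    fallback) and the feature columns must match the fitted model.
    """
    x, b = _check_inputs(features, batch)
    if tuple(str(c) for c in features.columns) != model.feature_names:
        raise CombatError(
            f"feature columns {list(features.columns)} do not match the fitted "
            f"model's {list(model.feature_names)}"
        )
    unseen = sorted(set(b) - set(model.batch_ids))
    if unseen:
        raise CombatError(f"batch ids not seen at fit time: {unseen}")
    z = (x - model.grand_mean) / np.sqrt(model.var_pooled)
    out = np.empty_like(x)
    for i, bid in enumerate(model.batch_ids):
        mask = b == bid
        if not mask.any():
            continue
        out[mask] = (
            np.sqrt(model.var_pooled)
            * (z[mask] - model.gamma_star[i])
            / np.sqrt(model.delta_star[i])
            + model.grand_mean
        )
    return pd.DataFrame(out, index=features.index, columns=features.columns)
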