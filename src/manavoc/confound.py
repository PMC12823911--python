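"""Body-size confound removal by regularized ANCOVA residualization.

Body size correlates with age (and weakly with the vocal envelope), so a
classifier could exploit size-driven feature variance instead of genuine
demographic signal.  Before classification, each feature is regressed —
on the training fold only — against centred body size plus the auxiliary
demographic covariate (sex when classifying age, age when classifying
sex), and only the size component is subtracted:

    residual_j = feature_j - b_j * (size - mean(train size))

The auxiliary covariate de-biases the size slope but is never subtracted,
so class signal survives residualization.  The size slope is shrunk by
ridge regularization acting on the slope alone (the de-biased OLS slope
scaled by 1/(1 + tau)): tau -> 0 recovers OLS residuals
orthogonal to size, tau -> infinity leaves the centred features
untouched.  tau may be fixed (default 1.2) or adaptive, 2p/n by default;
an alternative 2*log(p/n) convention exists behind a switch but is
negative whenever p < n and is floored at zero with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ResidualModel",
    "adaptive_tau",
    "fit_residualizer",
    "apply_residualizer",
    "variance_retained",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ResidualModel:
    feature_names: tuple[str, ...]
    size_slope: np.ndarray  # acting (total, shrunk) slope, one per feature
    direct_slope: np.ndarray  # de-biased direct slope, before mediation/shrinkage
    aux_coef: np.ndarray  # (n_aux_levels - 1, n_features), adjusters only
    intercept: np.ndarray
    tau: float
    train_size_mean: float
    aux_levels: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "feature_names": list(self.feature_names),
            "size_slope": self.size_slope.tolist(),
            "direct_slope": self.direct_slope.tolist(),
            "aux_coef": self.aux_coef.tolist(),
            "intercept": self.intercept.tolist(),
            "tau": self.tau,
            "train_size_mean": self.train_size_mean,
            "aux_levels": list(self.aux_levels),
        }


def adaptive_tau(p: int, n: int, convention: str = "ratio") -> float:
    """Adaptive regularization strength from fold dimensions.

    ``ratio`` (primary): tau = 2p/n.  ``log``: tau = 2*log(p/n), an
    alternative convention that is negative for p < n and therefore
    floored at 0 with a warning.
    """
    if p <= 0:
        raise ValueError("feature count p must be positive")
    if n <= 0:
        raise ValueError("training sample count n must be positive")
    if convention == "ratio":
        return 2.0 * p / n
    if convention == "log":
        tau = 2.0 * float(np.log(p / n))
        if tau < 0:
            log.warning("log-convention tau=%.3f is negative; floored to 0", tau)
            return 0.0
        return tau
    raise ValueError(f"unknown tau convention {convention!r}")


def _design(size_c: np.ndarray, aux: np.ndarray, levels: tuple[str, ...]) -> np.ndarray:
    cols = [np.ones_like(size_c), size_c]
    for lev in levels[1:]:  # treatment coding, first level is reference
        cols.append((aux == lev).astype(float))
    return np.column_stack(cols)


def fit_residualizer(
    train_features: pd.DataFrame,
    size_m: np.ndarray,
    auxiliary: np.ndarray,
    tau: float,
) -> ResidualModel:
    """Fit the per-feature size model on training rows only.

    For all features jointly, an ordinary least-squares fit on an
    intercept, centred size, and auxiliary-class indicators estimates the
    de-biased *direct* size slope.  Because the auxiliary demographic is
    itself associated with size in realistic cohorts, the subtracted
    component is the *total* size projection, recomposed from the direct
    slope plus the covariate-mediated path (direct + aux_coef . gamma,
    where gamma are the regressions of the indicators on centred size);
    this makes the tau -> 0 residuals exactly orthogonal to size.  The
    acting slope is then shrunk by ``1/(1 + tau)``.  The stored model
    keeps the decomposition (``direct_slope``, ``aux_coef``) for audit.
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    Y = np.asarray(train_features, dtype=float)
    n, p = Y.shape
    if n < 3:
        raise ValueError("need at least 3 training rows")
    size = np.asarray(size_m, dtype=float)
    aux = np.asarray(auxiliary)
    if len(size) != n or len(aux) != n:
        raise ValueError("covariate length mismatch")
    if float(np.var(size)) <= 0:
        raise ValueError("covariate degenerate: body size is constant in training fold")

    size_mean = float(size.mean())
    size_c = size - size_mean
    levels = tuple(sorted(pd.unique(aux).tolist()))
    X = _design(size_c, aux, levels)
    B = np.linalg.lstsq(X, Y, rcond=None)[0]
    sxx = float(np.sum(size_c**2))
    # regression of each auxiliary indicator on centred size (the
    # covariate-mediated path of the size association)
    gamma = np.array([np.sum((aux == lev) * size_c) / sxx for lev in levels[1:]])
    total_slope = B[1] + gamma @ B[2:] if len(gamma) else B[1]

    return ResidualModel(
        feature_names=tuple(train_features.columns),
        size_slope=total_slope / (1.0 + tau),
        direct_slope=B[1].copy(),
        aux_coef=B[2:].copy(),
        intercept=B[0].copy(),
        tau=float(tau),
        train_size_mean=size_mean,
        aux_levels=levels,
    )


def apply_residualizer(
    model: ResidualModel, features: pd.DataFrame, size_m: np.ndarray
) -> pd.DataFrame:
    """Subtract the fitted size component; shape is preserved.

    Only the size term is removed — auxiliary-class offsets were adjusters
    during fitting and stay in the features, so demographic signal is not
    stripped.  Works identically for training and held-out rows; the fit
    never sees the rows passed here.
    """
    if tuple(features.columns) != model.feature_names:
        raise ValueError("feature columns do not match the fitted model")
    size_c = np.asarray(size_m, dtype=float) - model.train_size_mean
    resid = np.asarray(features, dtype=float) - np.outer(size_c, model.size_slope)
    return pd.DataFrame(resid, index=features.index, columns=features.columns)


def variance_retained(
    model: ResidualModel, features: pd.DataFrame, size_m: np.ndarray
) -> float:
    """Pooled fraction of total (centred) feature variance surviving
    residualization: sum_j var(residual_j) / sum_j var(feature_j)."""
    resid = apply_residualizer(model, features, size_m)
    v_orig = np.asarray(features, dtype=float).var(axis=0).sum()
    v_res = np.asarray(resid, dtype=float).var(axis=0).sum()
    return float(v_res / v_orig)
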