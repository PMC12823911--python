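"""Class balancing by SMOTE stratified on the auxiliary demographic.

Plain SMOTE on the target class would distort the joint demographic
distribution: in this study system adults are overwhelmingly female and
juveniles overwhelmingly male, so synthesizing minority-sex samples
without regard to age would teach the classifier a spurious age-sex
association.  Synthetic rows are therefore generated inside
(target x auxiliary) cells, with the deficit allocated across cells by
the largest-remainder method so the auxiliary distribution within the
minority class is preserved up to integer rounding.

Within a cell, neighbours are found by Euclidean distance (features are
expected to arrive standardized); k falls back to cell_size - 1 with a
floor of 1, and singleton cells are replicated verbatim.  Applied to
training folds only — test folds keep their natural distributions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

__all__ = ["SmoteConfig", "smote_interpolate", "stratified_smote"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SmoteConfig:
    k_neighbors: int = 5
    seed: int = 0
    target_ratio: float = 1.0  # minority:majority after augmentation

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if not (0 < self.target_ratio <= 1.0):
            raise ValueError("target_ratio must be in (0, 1]")


def smote_interpolate(
    x: np.ndarray, neighbor: np.ndarray, u: float
) -> np.ndarray:
    """Componentwise interpolation ``x + u * (neighbor - x)``, u in [0, 1]."""
    x = np.asarray(x, dtype=float)
    neighbor = np.asarray(neighbor, dtype=float)
    if x.shape != neighbor.shape:
        raise ValueError("dimension mismatch between sample and neighbor")
    return x + u * (neighbor - x)


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation of ``total`` proportional to ``weights``."""
    if total == 0:
        return np.zeros(len(weights), dtype=int)
    quota = weights / weights.sum() * total
    base = np.floor(quota).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(quota - base), kind="stable")
    base[order[:rem]] += 1
    return base


def stratified_smote(
    features: pd.DataFrame,
    target: np.ndarray,
    auxiliary: np.ndarray,
    config: SmoteConfig = SmoteConfig(),
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray, np.ndarray]:
    """Oversample the minority target class toward 1:1, cell by cell.

    Returns ``(features_aug, target_aug, auxiliary_aug, is_synthetic)``.
    Original rows are passed through unchanged and come first; synthetic
    rows are flagged.  Already balanced input is returned as-is.
    """
    target = np.asarray(target)
    auxiliary = np.asarray(auxiliary)
    if not (len(features) == len(target) == len(auxiliary)):
        raise ValueError("features/target/auxiliary length mismatch")

    classes, counts = np.unique(target, return_counts=True)
    if len(classes) != 2:
        raise ValueError("stratified_smote expects a binary target")
    minority = classes[np.argmin(counts)]
    majority = classes[np.argmax(counts)]
    n_min, n_maj = counts.min(), counts.max()
    if n_min == 0:
        raise ValueError("empty minority class")
    deficit = int(round(config.target_ratio * n_maj)) - n_min
    if deficit <= 0:
        return (
            features.copy(),
            target.copy(),
            auxiliary.copy(),
            np.zeros(len(features), dtype=bool),
        )

    min_mask = target == minority
    aux_levels, aux_counts = np.unique(auxiliary[min_mask], return_counts=True)
    alloc = _largest_remainder(aux_counts.astype(float), deficit)

    rng = np.random.default_rng(config.seed)
    X = np.asarray(features, dtype=float)
    synth_rows = []
    synth_aux = []
    for lev, n_new in zip(aux_levels, alloc):
        if n_new == 0:
            continue
        cell_idx = np.flatnonzero(min_mask & (auxiliary == lev))
        cell = X[cell_idx]
        if len(cell) == 1:
            # singleton cell: jitterless replication keeps the auxiliary
            # distribution intact (the k=1 fallback degenerates here)
            synth_rows.append(np.repeat(cell, n_new, axis=0))
            synth_aux.extend([lev] * n_new)
            continue
        k = max(1, min(config.k_neighbors, len(cell) - 1))
        nn = NearestNeighbors(n_neighbors=k + 1).fit(cell)
        _, nbr = nn.kneighbors(cell)  # first column is the point itself
        base = rng.integers(0, len(cell), size=n_new)
        pick = rng.integers(1, k + 1, size=n_new)
        u = rng.uniform(0.0, 1.0, size=n_new)
        neigh = nbr[base, pick]
        synth_rows.append(cell[base] + u[:, None] * (cell[neigh] - cell[base]))
        synth_aux.extend([lev] * n_new)

    S = np.vstack(synth_rows)
    feats_aug = pd.DataFrame(
        np.vstack([X, S]), columns=features.columns
    )
    target_aug = np.concatenate([target, np.full(len(S), minority, dtype=target.dtype)])
    aux_aug = np.concatenate([auxiliary, np.asarray(synth_aux, dtype=auxiliary.dtype)])
    is_synth = np.concatenate(
        [np.zeros(len(X), dtype=bool), np.ones(len(S), dtype=bool)]
    )
    realized = (target_aug == minority).sum()
    if abs(realized - int(round(config.target_ratio * n_maj))) > 1:
        log.info(
            "stratification constraints prevented exact balance: %d vs %d",
            realized,
            n_maj,
        )
    return feats_aug, target_aug, aux_aug, is_synth
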