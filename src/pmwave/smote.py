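"""Synthetic minority oversampling for high-concentration training rows.

Regression tables of ambient PM2.5 are heavily skewed: hours above the
regulatory short-term benchmark are rare, and tree ensembles trained on the
raw table systematically under-predict them.  This module oversamples the
high-concentration "minority" rows SMOTE-style: each synthetic row is drawn
uniformly on the segment between a minority seed row and one of its k
nearest minority neighbors, applied jointly to predictors and target, so
every synthetic row is a convex combination of two real high-PM2.5 rows.

Neighbor search runs in standardized (z-scored) predictor space so that
predictors with large units do not dominate the metric.  Oversampling must
happen inside each cross-validation training fold, never before splitting;
the fold drivers in :mod:`pmwave.validation` do exactly that.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = ["SmoteConfig", "identify_minority", "smote"]


@dataclass(frozen=True)
class SmoteConfig:
    """Oversampling parameters.

    minority_threshold : ug/m3; rows with target at or above it are minority
        (default 35, a standard short-term regulatory benchmark).
    k_neighbors : nearest minority neighbors to interpolate toward.
    target_minority_fraction : synthesize until minority rows (real +
        synthetic) are this fraction of the table.
    """

    minority_threshold: float = 35.0
    k_neighbors: int = 5
    target_minority_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.k_neighbors < 1:
            raise ValueError(f"k_neighbors must be >= 1, got {self.k_neighbors}")
        if not 0.0 < self.target_minority_fraction < 1.0:
            raise ValueError(
                f"target_minority_fraction must be in (0, 1), got {self.target_minority_fraction}"
            )


def identify_minority(target: pd.Series | np.ndarray, threshold: float) -> np.ndarray:
    """Boolean flags for rows whose target is at or above the threshold."""
    target = np.asarray(target, dtype=float)
    if target.size == 0:
        raise ValueError("empty table")
    return target >= threshold


def smote(frame: pd.DataFrame, predictors: list[str], target: str,
          flags: np.ndarray, config: SmoteConfig) -> pd.DataFrame:
    """Append synthetic minority rows until the minority fraction is reached.

    Original rows are preserved verbatim and keep ``synthetic = False``;
    appended rows carry ``synthetic = True``.  If the minority fraction
    already meets the request, the table is returned unchanged (a copy).

    Raises if the minority count does not exceed ``k_neighbors`` -- with
    fewer points than neighbors the interpolation set is ill-defined.
    """
    flags = np.asarray(flags, dtype=bool)
    if len(flags) != len(frame):
        raise ValueError("flags length does not match table")
    n_minority = int(flags.sum())
    if n_minority <= config.k_neighbors:
        raise ValueError(
            f"minority count {n_minority} must exceed k_neighbors={config.k_neighbors}"
        )
    out = frame.copy()
    if "synthetic" not in out.columns:
        out["synthetic"] = False

    n_total = len(frame)
    frac = config.target_minority_fraction
    # solve (n_minority + s) / (n_total + s) >= frac for synthetic count s
    needed = int(np.ceil((frac * n_total - n_minority) / (1.0 - frac)))
    if needed <= 0:
        return out

    cols = list(predictors) + [target]
    minority = frame.loc[flags, cols].to_numpy(dtype=float)
    X = frame.loc[flags, predictors].to_numpy(dtype=float)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    k = min(config.k_neighbors, n_minority - 1)
    _, nn = cKDTree(Z).query(Z, k=k + 1)  # first neighbor is the point itself
    nn = np.atleast_2d(nn)[:, 1:]

    rng = np.random.default_rng(config.seed)
    seeds = rng.integers(0, n_minority, size=needed)
    picks = rng.integers(0, k, size=needed)
    u = rng.uniform(0.0, 1.0, size=needed)
    neighbor_rows = nn[seeds, picks]
    synth = minority[seeds] + u[:, None] * (minority[neighbor_rows] - minority[seeds])

    synth_df = pd.DataFrame(synth, columns=cols)
    synth_df["synthetic"] = True
    # carry bookkeeping columns so the augmented table stays rectangular
    for c in frame.columns:
        if c not in synth_df.columns:
            synth_df[c] = pd.NA
    synth_df = synth_df[list(out.columns)]
    return pd.concat([out, synth_df], ignore_index=True)
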