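"""Global Moran's I and local indicators of spatial autocorrelation (LISA).

Global Moran's I measures whether similar attribute values cluster in
space:

    I = (n / S0) * sum_ij w_ij z_i z_j / sum_i z_i^2,

with z the centered attribute and S0 the sum of all weights. Its null
expectation is -1/(n-1); for row-standardized weights it lies
(approximately) in [-1, 1]. Inference is by conditional permutation: the
attribute values are shuffled over the locations, and the pseudo p-value is
(exceedances + 1) / (permutations + 1), one-sided toward the observed sign
of the departure from expectation. Because the statistic is computed on
z-scores, it is invariant to affine transforms of the attribute.

The local statistic decomposes I by unit:

    I_i = z_i * lag_i / m2,   m2 = sum_k z_k^2 / n,

so that for row-standardized weights sum_i I_i = n * I. Each unit is
classified by the signs of (z_i, lag_i) into HH (high value among high
neighbors), HL (high among low), LH (low among high) and LL; labels are
assigned only where the per-unit conditional-permutation p-value clears the
significance level, otherwise "ns". No multiple-testing correction is
applied by default (an optional Benjamini-Hochberg FDR flag is available).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .weights import SpatialWeights

__all__ = ["MoranResult", "LisaResult", "global_moran", "lisa"]

QUADRANTS = ("HH", "HL", "LH", "LL")


@dataclass(frozen=True)
class MoranResult:
    I: float
    expected_i: float
    p_value: float
    permutations: int
    seed: Optional[int]
    sim_mean: float
    sim_sd: float

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"permutation p-value {self.p_value} outside (0, 1]")


@dataclass(frozen=True)
class LisaResult:
    local_i: np.ndarray
    quadrant: np.ndarray  # raw quadrant per unit (always assigned)
    label: np.ndarray  # quadrant where significant, else "ns"
    p_value: np.ndarray
    significant: np.ndarray
    alpha: float
    permutations: int
    seed: Optional[int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "local_i": self.local_i,
                "quadrant": self.quadrant,
                "label": self.label,
                "p_value": self.p_value,
                "significant": self.significant,
            }
        )


def _center(values: np.ndarray) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise ValueError("attribute must be one-dimensional")
    z = v - v.mean()
    if np.allclose(z, 0.0):
        raise ValueError("zero variance: attribute is constant")
    return z


def global_moran(
    values: np.ndarray,
    weights: SpatialWeights,
    permutations: int = 999,
    seed: Optional[int] = None,
) -> MoranResult:
    """Global Moran's I with conditional-permutation inference."""
    if permutations < 99:
        raise ValueError(f"permutations must be >= 99, got {permutations}")
    z = _center(values)
    n = weights.n
    if len(z) != n:
        raise ValueError("attribute length does not match weights")
    if np.any(weights.cardinalities == 0):
        raise ValueError("isolated unit: every unit needs >= 1 neighbor")
    W = weights.to_sparse()
    s0 = weights.s0
    ssz = float(z @ z)
    i_obs = float(n / s0 * (z @ (W @ z)) / ssz)

    rng = np.random.default_rng(seed)
    # permute values over locations; I is invariant to which copy we shuffle
    zperm = np.tile(z, (permutations, 1))
    zperm = rng.permuted(zperm, axis=1)
    lag = (W @ zperm.T).T
    i_sim = n / s0 * np.einsum("ij,ij->i", zperm, lag) / ssz

    e_i = -1.0 / (n - 1)
    if i_obs >= e_i:
        exceed = int(np.sum(i_sim >= i_obs))
    else:
        exceed = int(np.sum(i_sim <= i_obs))
    p = (exceed + 1) / (permutations + 1)
    return MoranResult(
        I=i_obs,
        expected_i=e_i,
        p_value=float(p),
        permutations=permutations,
        seed=seed,
        sim_mean=float(i_sim.mean()),
        sim_sd=float(i_sim.std(ddof=1)),
    )


def lisa(
    values: np.ndarray,
    weights: SpatialWeights,
    permutations: int = 999,
    seed: Optional[int] = None,
    alpha: float = 0.05,
    fdr: bool = False,
) -> LisaResult:
    """Local Moran statistics with quadrant labels and permutation p-values."""
    if permutations < 99:
        raise ValueError(f"permutations must be >= 99, got {permutations}")
    if not (0.0 <= alpha <= 1.0):
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    z = _center(values)
    n = weights.n
    if len(z) != n:
        raise ValueError("attribute length does not match weights")
    if np.any(weights.cardinalities == 0):
        raise ValueError("isolated unit: every unit needs >= 1 neighbor")
    m2 = float(z @ z) / n
    lag = weights.lag(z)
    local_i = z * lag / m2

    quadrant = np.where(
        z >= 0,
        np.where(lag >= 0, "HH", "HL"),
        np.where(lag >= 0, "LH", "LL"),
    ).astype(object)

    rng = np.random.default_rng(seed)
    p = np.empty(n)
    others_idx = np.arange(n)
    for i in range(n):
        nb = np.asarray(weights.neighbors[i], dtype=int)
        w = np.asarray(weights.weights[i], dtype=float)
        others = np.delete(others_idx, i)
        k = len(nb)
        # conditional permutation: hold z_i, draw k neighbor values without
        # replacement from the remaining units
        keys = rng.random((permutations, n - 1))
        draw = np.argpartition(keys, k - 1, axis=1)[:, :k]
        sim_lag = z[others[draw]] @ w
        sim_i = z[i] * sim_lag / m2
        if local_i[i] >= 0:
            exceed = int(np.sum(sim_i >= local_i[i]))
        else:
            exceed = int(np.sum(sim_i <= local_i[i]))
        p[i] = (exceed + 1) / (permutations + 1)

    if fdr:
        from statsmodels.stats.multitest import multipletests

        significant = multipletests(p, alpha=alpha, method="fdr_bh")[0]
    else:
        significant = p <= alpha
    label = np.where(significant, quadrant, "ns").astype(object)
    return LisaResult(
        local_i=local_i,
        quadrant=quadrant,
        label=label,
        p_value=p,
        significant=significant,
        alpha=alpha,
        permutations=permutations,
        seed=seed,
    )
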