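"""Connectivity learning (CL): learnable Gaussian-kernel map from ROI series to a FBN.

The connectivity between ROIs i and j is
``A(i, j) = exp(-||(F_i - F_j) W||^2 / (2 sigma^2))`` where W is a learnable
q x q "time series transformable" matrix and sigma the kernel bandwidth
(default 2, controlling sparsity).  Entries lie in (0, 1] with unit
diagonal, and the matrix is symmetric by construction.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import pdist, squareform

from ._autodiff import Parameter, Tensor
from ._nn import DTYPE, Module

__all__ = ["gaussian_connectivity", "ConnectivityLearner"]


def gaussian_connectivity(series: np.ndarray, weight: np.ndarray | None = None,
                          sigma: float = 2.0) -> np.ndarray:
    """Gaussian-kernel connectivity of an (N, q) series matrix (pure numpy).

    Each unordered pair is evaluated once, so symmetry is exact; the diagonal
    is exactly 1.
    """
    if sigma <= 0:
        raise ValueError("kernel bandwidth sigma must be positive")
    series = np.asarray(series, dtype=np.float64)
    if series.ndim != 2:
        raise ValueError("series must be an N x q matrix")
    mapped = series if weight is None else series @ np.asarray(weight, dtype=np.float64)
    d2 = pdist(mapped, metric="sqeuclidean")
    a = squareform(np.exp(-d2 / (2.0 * sigma ** 2)))
    np.fill_diagonal(a, 1.0)
    return a


class ConnectivityLearner(Module):
    """Differentiable Gaussian-kernel connectivity with learnable transform W."""

    def __init__(self, n_timepoints: int, rng: np.random.Generator,
                 sigma: float = 2.0, init_noise_sd: float = 0.01):
        super().__init__()
        if sigma <= 0:
            raise ValueError("kernel bandwidth sigma must be positive")
        self.sigma = sigma
        # Scale-aware start: W = (I + noise) / sqrt(q) makes the initial kernel
        # argument ||(F_i - F_j) W||^2 ~ 2 (1 - r), independent of the series
        # length.  A plain identity start would put squared distances at
        # O(q) and collapse every off-diagonal kernel value to ~0.
        w0 = (np.eye(n_timepoints) + init_noise_sd * rng.standard_normal(
            (n_timepoints, n_timepoints))) / np.sqrt(n_timepoints)
        self.weight = Parameter(w0.astype(DTYPE))

    def __call__(self, series: Tensor) -> Tensor:
        n = series.shape[0]
        mapped = series @ self.weight
        sq = (mapped * mapped).sum(axis=1, keepdims=True)          # (N, 1)
        d2 = (sq + sq.transpose(1, 0) - 2.0 * (mapped @ mapped.transpose(1, 0))).relu()
        a = (d2 * (-1.0 / (2.0 * self.sigma ** 2))).exp()
        a = (a + a.transpose(1, 0)) * 0.5                          # exact symmetry
        off = 1.0 - np.eye(n, dtype=a.data.dtype)
        return a * off + np.eye(n, dtype=a.data.dtype)             # exact unit diagonal
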