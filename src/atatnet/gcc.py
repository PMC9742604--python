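"""Global-local connectivity classifier (GCC).

Graph convolutions over the functional brain network with ROI time series as
node features, in the symmetric-normalized-adjacency formulation: three
graph-convolution layers halve the feature width per layer
(q -> q/2 -> q/4 -> q/8), a graph pooling layer averages features per ROI to
one value, and a three-layer perceptron (N -> 32 -> 16 -> classes) with a
softmax head emits class probabilities.  The classifier accepts either the
learned (A_g, F_g) pair or the empirical (A_e, F_e) pair; empirical Pearson
adjacencies are first rescaled to [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor, softmax
from ._nn import DTYPE, Linear, Module

__all__ = ["GCCConfig", "GCC", "normalize_adjacency", "rescale_pearson"]

_DEGREE_FLOOR = 1e-8


@dataclass
class GCCConfig:
    n_rois: int
    n_timepoints: int
    n_classes: int = 2
    mlp_widths: tuple[int, int] = (32, 16)


def rescale_pearson(a: np.ndarray) -> np.ndarray:
    """Map off-diagonal Pearson values from [-1, 1] to [0, 1]; diagonal stays 1."""
    out = (np.asarray(a, dtype=np.float64) + 1.0) / 2.0
    np.fill_diagonal(out, 1.0)
    return np.clip(out, 0.0, 1.0)


def normalize_adjacency(a: np.ndarray | Tensor):
    """Symmetric degree normalization D^{-1/2} (A + I) D^{-1/2}.

    ``D`` is the degree matrix of A + I.  Works on plain arrays and on
    autodiff tensors (so gradients can flow into a learned adjacency).
    Zero-degree nodes are floored at 1e-8.
    """
    if isinstance(a, Tensor):
        n = a.shape[0]
        at = a + np.eye(n, dtype=a.data.dtype)
        deg = at.sum(axis=1)
        deg = (deg - _DEGREE_FLOOR).relu() + _DEGREE_FLOOR
        dinv = deg ** -0.5
        return at * dinv.reshape(n, 1) * dinv.reshape(1, n)
    a = np.asarray(a, dtype=np.float64)
    at = a + np.eye(a.shape[0])
    deg = at.sum(axis=1)
    if (deg <= _DEGREE_FLOOR).any():
        warnings.warn("zero-degree node; degree floored at 1e-8", RuntimeWarning,
                      stacklevel=2)
        deg = np.maximum(deg, _DEGREE_FLOOR)
    dinv = deg ** -0.5
    return at * dinv[:, None] * dinv[None, :]


class GCC(Module):
    def __init__(self, config: GCCConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        q = config.n_timepoints
        widths = [q, q // 2, q // 4, q // 8]
        if widths[-1] < 1:
            raise ValueError("q too small for three halving graph convolutions")
        self.gconvs = [Linear(a, b, rng, init="he") for a, b in zip(widths[:-1], widths[1:])]
        mlp_widths = [config.n_rois, *config.mlp_widths, config.n_classes]
        self.mlp = [Linear(a, b, rng) for a, b in zip(mlp_widths[:-1], mlp_widths[1:])]

    def __call__(self, adjacency: Tensor | np.ndarray,
                 features: Tensor | np.ndarray,
                 pre_normalized: bool = False) -> Tensor:
        """Class probability vector for one (FBN, series) pair."""
        if not isinstance(features, Tensor):
            features = Tensor(np.ascontiguousarray(features, dtype=DTYPE))
        if not pre_normalized:
            adjacency = normalize_adjacency(adjacency)
        if not isinstance(adjacency, Tensor):
            adjacency = Tensor(np.ascontiguousarray(adjacency, dtype=DTYPE))
        h = features
        for gc in self.gconvs:
            h = gc(adjacency @ h).relu()
        pooled = h.mean(axis=1)                      # one value per ROI
        # the perceptron head learns a linear mapping of the pooled vector
        x = pooled.reshape(1, self.config.n_rois)
        for layer in self.mlp[:-1]:
            x = layer(x)
        logits = self.mlp[-1](x)
        return softmax(logits, axis=-1).reshape(self.config.n_classes)
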