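"""Multi-channel temporal discriminator (MTD).

N independent per-ROI networks; channel i consumes ROI i's time series and
emits one real-valued score through hidden widths floor(q/2), q, floor(q/2)
(leaky-ReLU, slope 0.2) and a final scalar output layer.  The discriminator
result is the arithmetic mean of the N channel scores.  Outputs are left
un-squashed because the adversarial losses are least-squares.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import Parameter, Tensor
from ._nn import DTYPE, Module, glorot

__all__ = ["MTD"]


class MTD(Module):
    def __init__(self, n_rois: int, n_timepoints: int, rng: np.random.Generator,
                 slope: float = 0.2):
        super().__init__()
        self.n_rois = n_rois
        self.n_timepoints = n_timepoints
        self.slope = slope
        widths = [n_timepoints, n_timepoints // 2, n_timepoints,
                  n_timepoints // 2, 1]
        self.weights: list[Parameter] = []
        self.biases: list[Parameter] = []
        for n_in, n_out in zip(widths[:-1], widths[1:]):
            w = np.stack([glorot(rng, (n_in, n_out), n_in, n_out)
                          for _ in range(n_rois)])          # (N, n_in, n_out)
            self.weights.append(Parameter(w))
            self.biases.append(Parameter(np.zeros((n_rois, 1, n_out), dtype=DTYPE)))

    def channel_scores(self, series: Tensor | np.ndarray) -> Tensor:
        if not isinstance(series, Tensor):
            series = Tensor(np.ascontiguousarray(series, dtype=DTYPE))
        if series.shape != (self.n_rois, self.n_timepoints):
            raise ValueError(f"series shape {series.shape} != "
                             f"({self.n_rois}, {self.n_timepoints})")
        x = series.reshape(self.n_rois, 1, self.n_timepoints)
        last = len(self.weights) - 1
        for layer, (w, b) in enumerate(zip(self.weights, self.biases)):
            x = x @ w + b
            if layer < last:
                x = x.leaky_relu(self.slope)
        return x.reshape(self.n_rois)

    def __call__(self, series: Tensor | np.ndarray) -> Tensor:
        return self.channel_scores(series).mean()
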