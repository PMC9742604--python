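"""Region-guided feature learning network (RFLNet).

A 3-D convolutional front end that maps each fMRI frame to a rough per-ROI
feature, conditioned on normalized ROI embeddings (center location and
volume).  Each frame passes through a stack of conv -> average-pool ->
batch-norm -> ReLU blocks, then a 1x1x1 convolution raises the channel count
to N (one channel per ROI) followed by a sigmoid.  The sigmoid output is
flattened (all N channels by all pooled cells), concatenated with the
flattened embedding table, and a single linear projection shared across
frames maps it to N values, one per ROI.  Stacking over frames yields the
rough feature F1 of shape N x q.

Giving every ROI its own projection row is what lets the network select
*where* in the pooled map each ROI's signal lives; convolution weights alone
are spatially shared and cannot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor, concat
from ._nn import DTYPE, BatchNorm3d, Conv3d, Linear, Module, avg_pool3d

__all__ = ["RFLNetConfig", "RFLNet"]


@dataclass
class RFLNetConfig:
    grid_shape: tuple[int, int, int]
    n_rois: int
    n_timepoints: int
    n_blocks: int = 4
    channels: tuple[int, ...] = (8, 16, 32, 64)

    def __post_init__(self):
        if self.n_blocks > len(self.channels):
            raise ValueError("not enough channel counts for the requested blocks")
        self.channels = tuple(self.channels[: self.n_blocks])
        if any(c <= 0 for c in self.channels) or list(self.channels) != sorted(self.channels):
            raise ValueError("channel counts must be positive and non-decreasing")
        factor = 2 ** self.n_blocks
        if any(d % factor for d in self.grid_shape):
            raise ValueError(
                f"grid dims {self.grid_shape} must divide by 2^{self.n_blocks}")

    @property
    def pooled_shape(self) -> tuple[int, int, int]:
        f = 2 ** self.n_blocks
        return tuple(d // f for d in self.grid_shape)  # type: ignore[return-value]

    @property
    def flat_size(self) -> int:
        return int(np.prod(self.pooled_shape))


class RFLNet(Module):
    def __init__(self, config: RFLNetConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        self.convs: list[Conv3d] = []
        self.norms: list[BatchNorm3d] = []
        c_in = 1
        for c_out in config.channels:
            self.convs.append(Conv3d(c_in, c_out, 3, rng))
            self.norms.append(BatchNorm3d(c_out))
            c_in = c_out
        self.roi_conv = Conv3d(c_in, config.n_rois, 1, rng, padding=0)
        n = config.n_rois
        self.proj = Linear(n * config.flat_size + 4 * n, n, rng)

    def __call__(self, volume: np.ndarray, embeddings: np.ndarray) -> Tensor:
        """Map an (X, Y, Z, T) volume + (N, 4) embeddings to F1 of shape (N, T)."""
        cfg = self.config
        if volume.shape[:3] != cfg.grid_shape:
            raise ValueError(f"volume grid {volume.shape[:3]} != config {cfg.grid_shape}")
        if volume.shape[3] != cfg.n_timepoints:
            raise ValueError(f"volume has {volume.shape[3]} frames, config expects "
                             f"{cfg.n_timepoints}")
        if embeddings.shape != (cfg.n_rois, 4):
            raise ValueError(f"embeddings shape {embeddings.shape} != ({cfg.n_rois}, 4)")
        # frames form the batch axis: (T, 1, X, Y, Z)
        x = Tensor(np.ascontiguousarray(volume.transpose(3, 0, 1, 2), dtype=DTYPE)
                   .reshape(cfg.n_timepoints, 1, *cfg.grid_shape))
        for conv, norm in zip(self.convs, self.norms):
            x = norm(avg_pool3d(conv(x)))
            x = x.relu()
        x = self.roi_conv(x).sigmoid()                     # (T, N, xs, ys, zs)
        T, N = cfg.n_timepoints, cfg.n_rois
        flat = x.reshape(T, N * cfg.flat_size)
        # embeddings appended column-wise: all ex, then ey, ez, ev
        emb = np.broadcast_to(
            np.ascontiguousarray(embeddings.T, dtype=DTYPE).reshape(-1), (T, 4 * N))
        feat = concat([flat, Tensor(np.ascontiguousarray(emb))], axis=1)
        f1 = self.proj(feat)                               # (T, N), one row per frame
        return f1.transpose(1, 0)                          # (N, T)
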