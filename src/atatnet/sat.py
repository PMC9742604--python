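"""Spatial-temporal aligned transformer (SAT).

Refines the rough per-ROI feature F1 into the generated ROI time series F_g.
Every ROI is a token.  The spatial multi-head central attention (SMCA)
projects F1 to queries and the embedding-augmented F1 to keys/values,
applies scaled-dot-product attention per head, concatenates heads, projects,
adds the F1 residual and layer-normalizes each ROI row.  The temporal
aligned feed-forward (TAFF) block then down-maps each row from q to
floor(q/2) features with a ReLU, up-maps back to q, and adds the SMCA
residual.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor, concat, softmax
from ._nn import DTYPE, LayerNorm, Linear, Module

__all__ = ["SATConfig", "SAT", "central_attention", "head_slices"]


@dataclass
class SATConfig:
    n_timepoints: int
    n_heads: int = 11

    def __post_init__(self):
        if self.n_heads < 1 or self.n_heads > self.n_timepoints:
            raise ValueError("head count must be in [1, q]")

    @property
    def head_widths(self) -> list[int]:
        """floor(q/h) per head, remainder assigned to the last head."""
        q, h = self.n_timepoints, self.n_heads
        base = q // h
        widths = [base] * h
        widths[-1] += q - base * h
        return widths

    @property
    def hidden_width(self) -> int:
        return self.n_timepoints // 2


def head_slices(config: SATConfig) -> list[slice]:
    slices, start = [], 0
    for w in config.head_widths:
        slices.append(slice(start, start + w))
        start += w
    return slices


def central_attention(q_i: Tensor, k_i: Tensor, v_i: Tensor,
                      return_weights: bool = False):
    """softmax(Q_i K_i^T / sqrt(d)) V_i for one head; rows sum to 1."""
    d = q_i.shape[-1]
    scores = (q_i @ k_i.transpose(1, 0)) * (1.0 / np.sqrt(d))
    attn = softmax(scores, axis=-1)
    out = attn @ v_i
    if return_weights:
        return out, attn.data
    return out


class SAT(Module):
    def __init__(self, config: SATConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        q = config.n_timepoints
        self.w_q = Linear(q, q, rng)
        self.w_k = Linear(q + 4, q, rng)
        self.w_v = Linear(q + 4, q, rng)
        self.w_o = Linear(q, q, rng)
        self.norm = LayerNorm(q)
        self.down = Linear(q, config.hidden_width, rng, init="he")
        # zero-init up-map: the residual branch starts as the identity
        self.up = Linear(config.hidden_width, q, rng, init="zeros")

    def project_qkv(self, f1: Tensor, embeddings: np.ndarray
                    ) -> tuple[Tensor, Tensor, Tensor]:
        emb = Tensor(np.ascontiguousarray(embeddings, dtype=DTYPE))
        augmented = concat([f1, emb], axis=1)  # (N, q + 4)
        return self.w_q(f1), self.w_k(augmented), self.w_v(augmented)

    def smca(self, f1: Tensor, embeddings: np.ndarray,
             return_attention: bool = False):
        q_m, k_m, v_m = self.project_qkv(f1, embeddings)
        heads, weights = [], []
        for sl in head_slices(self.config):
            res = central_attention(q_m[:, sl], k_m[:, sl], v_m[:, sl],
                                    return_weights=return_attention)
            if return_attention:
                out, w = res
                weights.append(w)
            else:
                out = res
            heads.append(out)
        merged = self.w_o(concat(heads, axis=1)) + f1
        normed = self.norm(merged)
        if return_attention:
            return normed, weights
        return normed

    def taff(self, smca: Tensor) -> Tensor:
        return self.up(self.down(smca).relu()) + smca

    def __call__(self, f1: Tensor, embeddings: np.ndarray,
                 return_attention: bool = False):
        if return_attention:
            smca_out, weights = self.smca(f1, embeddings, return_attention=True)
            return self.taff(smca_out), weights
        return self.taff(self.smca(f1, embeddings))
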