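"""Integrated-gradients attribution on self-attention score matrices.

For a trained classifier F and a sequence with post-softmax attention score
matrices S (all heads), the attention attribute matrix is the Riemann
approximation of integrated gradients along the straight path from the zero
matrix to S:

    G = (S / a) * sum_{k=1..a} dF((k/a) S) / dS

with ``a`` interpolation steps (default 100) and the gradient taken with
respect to S as an independent input at the scaled point (the value
projections and all layers below stay fixed at their inference values).
F is the classifier's pre-sigmoid score: the final sigmoid saturates for
confidently classified sequences and would flatten exactly the gradients
the attribution aggregates, so the path integral is taken on the margin.
The per-head matrices are reduced by a position-wise maximum to G^max, the
quantity used to link motif pairs downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class AttentionAttribution:
    """Per-sequence attention attributions.

    ``g_heads`` has shape (H, m, m); ``g_max`` is the position-wise maximum
    over heads; ``score`` is the model's sigmoid output for the sequence.
    """

    seq_id: str
    g_heads: np.ndarray
    g_max: np.ndarray
    score: float


def max_over_heads(g_heads: np.ndarray | list[np.ndarray]) -> np.ndarray:
    """Position-wise maximum over per-head attribution matrices."""
    if isinstance(g_heads, (list, tuple)):
        shapes = {g.shape for g in g_heads}
        if len(shapes) > 1:
            raise ValueError(f"head matrices differ in shape: {shapes}")
        g_heads = np.stack(g_heads)
    if g_heads.ndim != 3:
        raise ValueError(f"expected (H, m, m) array, got shape {g_heads.shape}")
    return g_heads.max(axis=0)


def _ig_on_state(model, s: np.ndarray, v: np.ndarray, steps: int,
                 step_chunk: int = 25) -> np.ndarray:
    """Riemann-sum IG for a batch of attention states.

    ``s``: (B, H, m, m) post-softmax scores, ``v``: (B, H, m, d).  All heads
    are scaled jointly by k/a, matching a single path integral over the full
    score tensor.  Returns G of shape (B, H, m, m).
    """
    b = s.shape[0]
    total = np.zeros_like(s)
    scales = np.arange(1, steps + 1) / steps
    for k0 in range(0, steps, step_chunk):
        sc = scales[k0:k0 + step_chunk]
        t = sc[:, None, None, None, None] * s[None]          # (c,B,H,m,m)
        flat_t = t.reshape(-1, *s.shape[1:])
        flat_v = np.broadcast_to(v[None], (len(sc), *v.shape)
                                 ).reshape(-1, *v.shape[1:])
        _, ds = model.grad_wrt_attention(flat_t, flat_v)
        total += ds.reshape(len(sc), b, *s.shape[1:]).sum(axis=0)
    return s / steps * total


def integrated_gradients_attention(model, feature_maps: np.ndarray,
                                   steps: int = 100,
                                   seq_ids: list[str] | None = None,
                                   seq_chunk: int = 8,
                                   ) -> list[AttentionAttribution]:
    """Attention attributions for a batch of sequences.

    ``feature_maps`` is (B, input_len, n_features) from the frozen conv
    stage (a single (input_len, n_features) map is also accepted).
    Deterministic given a checkpoint and its inputs.
    """
    if steps < 1:
        raise ValueError(f"steps must be >= 1, got {steps}")
    if feature_maps.ndim == 2:
        feature_maps = feature_maps[None]
    n = feature_maps.shape[0]
    if seq_ids is None:
        seq_ids = [str(i) for i in range(n)]
    if len(seq_ids) != n:
        raise ValueError("seq_ids length does not match batch size")
    out: list[AttentionAttribution] = []
    for c0 in range(0, n, seq_chunk):
        c1 = min(c0 + seq_chunk, n)
        prob, s, v = model.attention_state(feature_maps[c0:c1])
        g = _ig_on_state(model, s, v, steps)
        if not np.all(np.isfinite(g)):
            bad = [seq_ids[c0 + i] for i in range(c1 - c0)
                   if not np.all(np.isfinite(g[i]))]
            raise FloatingPointError(
                f"non-finite attribution for sequence(s) {bad}")
        for i in range(c1 - c0):
            out.append(AttentionAttribution(
                seq_id=seq_ids[c0 + i], g_heads=g[i],
                g_max=max_over_heads(g[i]), score=float(prob[i])))
    return out


def completeness_gap(model, feature_map: np.ndarray, steps: int = 100
                     ) -> tuple[float, float]:
    """Return (sum of attributions, F(S) - F(0)) for one sequence.

    The two agree up to the Riemann discretization error; this is the
    standard completeness diagnostic for integrated gradients.
    """
    if feature_map.ndim == 2:
        feature_map = feature_map[None]
    prob, s, v = model.attention_state(feature_map)
    g = _ig_on_state(model, s, v, steps)
    f_s = model.margin_from_attention(s, v)
    f_0 = model.margin_from_attention(np.zeros_like(s), v)
    return float(g.sum()), float(f_s[0] - f_0[0])
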