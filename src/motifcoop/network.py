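"""Attention-based binary sequence classifier with fixed motif filters.

Architecture (in order): one-dimensional convolution whose filters are the
library PSSMs and their reverse complements (frozen, linear activation, so
activations are true log-odds scores comparable to the motif thresholds) ->
vertical max-pool of size 2 merging each forward/reverse-complement filter
pair -> batch normalization -> horizontal max-pool of size 4 -> additive
sin/cos positional encoding -> one multi-head self-attention layer (4 heads)
-> flatten -> fully connected 256 -> 64 -> sigmoid.

The network is implemented directly on NumPy arrays with explicit forward
and backward passes and an Adam optimizer; because the convolution filters
are frozen, the convolution + strand-pool feature maps are precomputed once
per dataset and training only touches the layers above them.  The attention
score matrices S_h (post-softmax) are exposed for the attribution module,
which needs forward passes and gradients with S replaced by a scaled copy.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.metrics import roc_auc_score

from .motifs import MotifLibrary

NEG_INF = -np.inf


@dataclass
class ModelConfig:
    """Hyperparameters of the classifier.

    ``n_motifs`` is the library size; the conv layer has ``2*n_motifs``
    filters.  With ``compute_rc=False`` (default) forward and reverse
    complement scores are merged by the vertical pool and the attended
    feature count is ``n_motifs``; with ``compute_rc=True`` strands are kept
    separate and the feature count doubles.  ``input_len / horizontal_pool``
    attended positions; feature count must be divisible by ``n_heads``.
    """

    n_motifs: int = 224
    input_len: int = 200
    vertical_pool: int = 2
    horizontal_pool: int = 4
    n_heads: int = 4
    fc_units: tuple[int, ...] = (256, 64)
    epochs: int = 50
    compute_rc: bool = False
    pe_n: float = 10000.0
    batch_size: int = 16
    learning_rate: float = 1e-3
    seed: int = 0
    bn_momentum: float = 0.99
    bn_eps: float = 1e-5
    head_dim: int | None = None  # default: n_features / n_heads
    weight_decay: float = 0.0
    lr_decay_at: float = 0.75  # fraction of epochs after which lr drops 10x
    fc_activation: str = "relu"  # "relu" | "linear"
    dropout: float = 0.0  # on FC hidden layers, training only
    restore_best: bool = True  # keep the best held-out-AUC checkpoint

    @property
    def n_filters(self) -> int:
        return 2 * self.n_motifs

    @property
    def n_features(self) -> int:
        return 2 * self.n_motifs if self.compute_rc else self.n_motifs

    @property
    def m_positions(self) -> int:
        return self.input_len // self.horizontal_pool

    @property
    def d_k(self) -> int:
        if self.head_dim is not None:
            return self.head_dim
        return self.n_features // self.n_heads

    @property
    def attn_out(self) -> int:
        return self.n_heads * self.d_k

    def validate(self) -> None:
        if self.input_len > 1000:
            raise ValueError("input sequences up to 1000 bp are supported")
        if self.input_len % self.horizontal_pool:
            raise ValueError("input_len must be divisible by horizontal_pool")
        if self.head_dim is None and self.n_features % self.n_heads:
            raise ValueError(
                f"feature count {self.n_features} not divisible by "
                f"{self.n_heads} attention heads; set head_dim explicitly")
        if self.vertical_pool != 2:
            raise ValueError("vertical pool merges strand pairs; size must be 2")


def conv_scan(onehot: np.ndarray, filters: np.ndarray,
              motif_lengths: np.ndarray | None = None,
              mask_incomplete: bool = True,
              chunk: int = 256) -> np.ndarray:
    """Scan one-hot sequences with PSSM filters.

    ``onehot`` is ``(L, 4)`` or ``(B, L, 4)``; ``filters`` is ``(F, 4, W)``
    with each motif right-aligned in its filter.  Entry ``(i, k)`` of the
    output is the score of the window *ending* at base ``i`` (the input is
    zero-padded on the left by ``W - 1``), so output length equals input
    length.  With ``mask_incomplete``, positions ``i < length_k - 1`` where
    filter ``k``'s motif would overhang the sequence start are set to -inf.
    """
    single = onehot.ndim == 2
    x = onehot[None] if single else onehot
    b, length, _ = x.shape
    n_filters, _, w = filters.shape
    if motif_lengths is not None and length < int(np.max(motif_lengths)):
        raise ValueError(
            f"sequence length {length} shorter than longest motif "
            f"{int(np.max(motif_lengths))}")
    flat_filters = filters.transpose(1, 2, 0).reshape(4 * w, n_filters)
    out = np.empty((b, length, n_filters))
    padded = np.zeros((b, length + w - 1, 4))
    for c0 in range(0, b, chunk):
        c1 = min(c0 + chunk, b)
        padded[c0:c1, w - 1:, :] = x[c0:c1]
        win = sliding_window_view(padded[c0:c1], w, axis=1)  # (c,L,4,W)
        out[c0:c1] = win.reshape(c1 - c0, length, 4 * w) @ flat_filters
    if mask_incomplete and motif_lengths is not None:
        lengths = np.asarray(motif_lengths)
        if lengths.size * 2 == n_filters:
            lengths = np.concatenate([lengths, lengths])
        for k, lk in enumerate(lengths):
            out[:, : int(lk) - 1, k] = NEG_INF
    return out[0] if single else out


def vertical_pool(score_map: np.ndarray, compute_rc: bool = False) -> np.ndarray:
    """Merge each forward/reverse-complement filter pair by elementwise max.

    Filters are laid out in two blocks (all forward, then all reverse
    complements), so the pool pairs column ``k`` with ``k + n_motifs``.
    With ``compute_rc=True`` the map passes through unchanged (strands are
    analysed separately).
    """
    if compute_rc:
        return score_map
    n = score_map.shape[-1]
    if n % 2:
        raise ValueError(f"odd filter count {n}; expected forward/rc pairs")
    return np.maximum(score_map[..., : n // 2], score_map[..., n // 2:])


def horizontal_pool(feature_map: np.ndarray, pool: int = 4,
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Non-overlapping max pool of size ``pool`` along the position axis.

    Returns the pooled map and the within-window bp argmax (absolute base
    coordinate, lowest index on ties) retained for interpretation.
    """
    *lead, length, f = feature_map.shape
    if length % pool:
        raise ValueError(f"length {length} not divisible by pool {pool}")
    r = feature_map.reshape(*lead, length // pool, pool, f)
    arg = r.argmax(axis=-2)
    pooled = np.take_along_axis(r, arg[..., None, :], axis=-2).squeeze(-2)
    offsets = np.arange(length // pool)[:, None] * pool
    return pooled, arg + offsets


def positional_encoding(m: int, f: int, n: float = 10000.0) -> np.ndarray:
    """Sin/cos positional encoding matrix P of shape ``(m, f)``.

    ``P[i, 2j] = sin(i / n**(2j/f))``, ``P[i, 2j+1] = cos(i / n**(2j/f))``.
    """
    if m < 1 or f < 1:
        raise ValueError("m and f must be >= 1")
    pos = np.arange(m, dtype=float)[:, None]
    even = np.arange(0, f, 2, dtype=float)
    div = n ** (even / f)
    p = np.zeros((m, f))
    p[:, 0::2] = np.sin(pos / div)
    p[:, 1::2] = np.cos(pos / div[: p[:, 1::2].shape[1]])
    return p


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[-2], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def compute_feature_maps(onehots: np.ndarray, library: MotifLibrary,
                         config: ModelConfig, chunk: int = 256) -> np.ndarray:
    """Frozen part of the network: conv scan + vertical pool.

    Returns ``(B, input_len, n_features)`` maps used as classifier input.
    Incomplete windows are not masked here (their partial scores are finite
    and harmless to the classifier); interpretation-time motif calls use the
    masked scan instead.
    """
    filters = library.filter_tensor()
    maps = np.empty((onehots.shape[0], config.input_len, config.n_features))
    for c0 in range(0, onehots.shape[0], chunk):
        c1 = min(c0 + chunk, onehots.shape[0])
        raw = conv_scan(onehots[c0:c1].astype(float), filters,
                        motif_lengths=library.motif_lengths,
                        mask_incomplete=False)
        maps[c0:c1] = vertical_pool(raw, config.compute_rc)
    return maps


class AttentionClassifier:
    """The trainable stack above the frozen convolution.

    Operates on precomputed feature maps ``(B, input_len, n_features)``.
    All randomness (weight init, shuffling) derives from ``config.seed``.
    """

    def __init__(self, library: MotifLibrary, config: ModelConfig):
        config.validate()
        if config.n_motifs != len(library):
            raise ValueError(
                f"config.n_motifs={config.n_motifs} but library has "
                f"{len(library)} motifs")
        self.library = library
        self.config = config
        f, m = config.n_features, config.m_positions
        h, dk = config.n_heads, config.d_k
        rng = np.random.default_rng(config.seed)
        self.params: dict[str, np.ndarray] = {
            "gamma": np.ones(f), "beta": np.zeros(f),
            "Wq": _glorot(rng, (h, f, dk)),
            "Wk": _glorot(rng, (h, f, dk)),
            "Wv": _glorot(rng, (h, f, dk)),
            "W1": _glorot(rng, (m * config.attn_out, config.fc_units[0])),
            "b1": np.zeros(config.fc_units[0]),
            "W2": _glorot(rng, (config.fc_units[0], config.fc_units[1])),
            "b2": np.zeros(config.fc_units[1]),
            "W3": _glorot(rng, (config.fc_units[1], 1)),
            "b3": np.zeros(1),
        }
        self.run_mean = np.zeros(f)
        self.run_var = np.ones(f)
        self.pe = positional_encoding(m, f, config.pe_n)
        self.history: list[dict] = []
        self._drop_rng = np.random.default_rng(config.seed + 2)
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    # ---------------- forward pieces ----------------

    def _batch_norm(self, maps: np.ndarray, training: bool):
        cfg = self.config
        if training:
            mu = maps.mean(axis=(0, 1))
            var = maps.var(axis=(0, 1))
            mom = cfg.bn_momentum
            self.run_mean = mom * self.run_mean + (1 - mom) * mu
            self.run_var = mom * self.run_var + (1 - mom) * var
        else:
            mu, var = self.run_mean, self.run_var
        xhat = (maps - mu) / np.sqrt(var + cfg.bn_eps)
        return self.params["gamma"] * xhat + self.params["beta"], xhat

    def _attend(self, x: np.ndarray):
        """Multi-head attention on ``x`` of shape (B, m, f)."""
        p = self.params
        h, dk = self.config.n_heads, self.config.d_k
        q = np.einsum("bmf,hfd->bhmd", x, p["Wq"])
        k = np.einsum("bmf,hfd->bhmd", x, p["Wk"])
        v = np.einsum("bmf,hfd->bhmd", x, p["Wv"])
        logits = q @ k.transpose(0, 1, 3, 2) / np.sqrt(dk)
        logits -= logits.max(axis=-1, keepdims=True)
        e = np.exp(logits)
        s = e / e.sum(axis=-1, keepdims=True)
        return q, k, v, s

    def _head_concat(self, s: np.ndarray, v: np.ndarray) -> np.ndarray:
        """(B,H,m,m) x (B,H,m,d) -> concatenated (B, m, n_heads*d_k)."""
        a = s @ v  # (B,H,m,d)
        b, h, m, dk = a.shape
        return a.transpose(0, 2, 1, 3).reshape(b, m, h * dk)

    def _attn_output(self, s: np.ndarray, v: np.ndarray):
        """Concatenated head outputs flattened to the classifier head's
        input vector (the MHA output feeds the flatten layer directly)."""
        a_cat = self._head_concat(s, v)
        return a_cat.reshape(s.shape[0], -1), a_cat

    def _mlp(self, y: np.ndarray, training: bool = False):
        p = self.params
        relu = self.config.fc_activation == "relu"
        drop = self.config.dropout if training else 0.0
        z1 = y @ p["W1"] + p["b1"]
        r1 = np.maximum(z1, 0.0) if relu else z1
        if drop:
            m1 = (self._drop_rng.random(r1.shape) >= drop) / (1.0 - drop)
            r1 = r1 * m1
        else:
            m1 = None
        z2 = r1 @ p["W2"] + p["b2"]
        r2 = np.maximum(z2, 0.0) if relu else z2
        if drop:
            m2 = (self._drop_rng.random(r2.shape) >= drop) / (1.0 - drop)
            r2 = r2 * m2
        else:
            m2 = None
        z3 = (r2 @ p["W3"] + p["b3"]).ravel()
        return z3, (y, z1, r1, z2, r2, m1, m2)

    def _forward(self, maps: np.ndarray, training: bool):
        bn_out, xhat = self._batch_norm(maps, training)
        pooled, arg = horizontal_pool(bn_out, self.config.horizontal_pool)
        x = pooled + self.pe
        q, k, v, s = self._attend(x)
        y, a_cat = self._attn_output(s, v)
        z3, mlp_cache = self._mlp(y, training=training)
        prob = _sigmoid(z3)
        cache = dict(xhat=xhat, arg=arg, x=x, q=q, k=k, v=v, s=s,
                     a_cat=a_cat, mlp=mlp_cache, z3=z3, prob=prob)
        return prob, cache

    # ---------------- backward ----------------

    def _mlp_backward(self, dz3: np.ndarray, mlp_cache, grads: dict | None):
        """Backprop dz3 (B,) through the FC stack; returns dF/dy (B, m*f)."""
        p = self.params
        y, z1, r1, z2, r2, m1, m2 = mlp_cache
        dz3 = dz3[:, None]
        if grads is not None:
            grads["W3"] += r2.T @ dz3
            grads["b3"] += dz3.sum(axis=0)
        relu = self.config.fc_activation == "relu"
        dr2 = dz3 @ p["W3"].T
        if m2 is not None:
            dr2 = dr2 * m2
        dz2 = dr2 * (z2 > 0) if relu else dr2
        if grads is not None:
            grads["W2"] += r1.T @ dz2
            grads["b2"] += dz2.sum(axis=0)
        dr1 = dz2 @ p["W2"].T
        if m1 is not None:
            dr1 = dr1 * m1
        dz1 = dr1 * (z1 > 0) if relu else dr1
        if grads is not None:
            grads["W1"] += y.T @ dz1
            grads["b1"] += dz1.sum(axis=0)
        return dz1 @ p["W1"].T

    def _attention_backward(self, do_flat: np.ndarray, cache, grads: dict):
        """Backprop the gradient at the flattened MHA output through the
        heads, softmax and QKV projections; returns dx (B, m, f)."""
        p = self.params
        h, dk = self.config.n_heads, self.config.d_k
        m = self.config.m_positions
        x, q, k, v, s = cache["x"], cache["q"], cache["k"], cache["v"], cache["s"]
        b = do_flat.shape[0]
        da_cat = do_flat.reshape(b, m, self.config.attn_out)
        da = da_cat.reshape(b, m, h, dk).transpose(0, 2, 1, 3)  # (B,H,m,d)
        ds = da @ v.transpose(0, 1, 3, 2)                       # (B,H,m,m)
        dv = s.transpose(0, 1, 3, 2) @ da                       # (B,H,m,d)
        dlog = s * (ds - (ds * s).sum(axis=-1, keepdims=True))
        scale = 1.0 / np.sqrt(dk)
        dq = dlog @ k * scale
        dkk = dlog.transpose(0, 1, 3, 2) @ q * scale
        grads["Wq"] += np.einsum("bmf,bhmd->hfd", x, dq)
        grads["Wk"] += np.einsum("bmf,bhmd->hfd", x, dkk)
        grads["Wv"] += np.einsum("bmf,bhmd->hfd", x, dv)
        dx = (np.einsum("bhmd,hfd->bmf", dq, p["Wq"])
              + np.einsum("bhmd,hfd->bmf", dkk, p["Wk"])
              + np.einsum("bhmd,hfd->bmf", dv, p["Wv"]))
        return dx

    def _backward(self, labels: np.ndarray, cache) -> dict[str, np.ndarray]:
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        b = labels.shape[0]
        dz3 = (cache["prob"] - labels) / b  # BCE-with-logits gradient
        dy = self._mlp_backward(dz3, cache["mlp"], grads)
        dx = self._attention_backward(dy, cache, grads)
        m = self.config.m_positions
        # positional encoding is additive -> dx passes through to the pooled map
        dpooled = dx
        # scatter through the horizontal max pool back to the BN output
        pool = self.config.horizontal_pool
        dr = np.zeros((b, m, pool, self.config.n_features))
        np.put_along_axis(dr, (cache["arg"] % pool)[..., None, :],
                          dpooled[..., None, :], axis=-2)
        dbn = dr.reshape(b, m * pool, self.config.n_features)
        grads["gamma"] += (dbn * cache["xhat"]).sum(axis=(0, 1))
        grads["beta"] += dbn.sum(axis=(0, 1))
        # conv filters below BN are frozen: no further propagation needed
        return grads

    def _adam_step(self, grads: dict[str, np.ndarray]):
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        self._adam_t += 1
        lr = getattr(self, "_lr", self.config.learning_rate)
        for key, g in grads.items():
            self._adam_m[key] = beta1 * self._adam_m[key] + (1 - beta1) * g
            self._adam_v[key] = beta2 * self._adam_v[key] + (1 - beta2) * g * g
            mhat = self._adam_m[key] / (1 - beta1 ** self._adam_t)
            vhat = self._adam_v[key] / (1 - beta2 ** self._adam_t)
            self.params[key] -= lr * mhat / (np.sqrt(vhat) + eps)

    # ---------------- public API ----------------

    def fit(self, maps: np.ndarray, labels: np.ndarray,
            train_idx: np.ndarray, test_idx: np.ndarray,
            epochs: int | None = None, log_fn=None) -> list[dict]:
        """Train with minibatch Adam on binary cross-entropy.

        Records per-epoch mean training loss and held-out AUC in
        ``self.history``.  Conv filters live outside this class entirely, so
        freezing holds by construction.
        """
        cfg = self.config
        epochs = cfg.epochs if epochs is None else epochs
        rng = np.random.default_rng(cfg.seed + 1)
        labels = np.asarray(labels, dtype=float)
        train_idx = np.asarray(train_idx)
        base_lr = cfg.learning_rate
        best = None
        for epoch in range(epochs):
            self._lr = base_lr * (0.1 if epoch >= cfg.lr_decay_at * epochs
                                  else 1.0)
            order = rng.permutation(len(train_idx))
            losses = []
            for b0 in range(0, len(order), cfg.batch_size):
                sel = train_idx[order[b0:b0 + cfg.batch_size]]
                prob, cache = self._forward(maps[sel], training=True)
                eps = 1e-12
                loss = -np.mean(labels[sel] * np.log(prob + eps)
                                + (1 - labels[sel]) * np.log(1 - prob + eps))
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch}: {loss}; "
                        f"prob range [{prob.min()}, {prob.max()}]")
                losses.append(loss)
                grads = self._backward(labels[sel], cache)
                if cfg.weight_decay:
                    for key in ("Wq", "Wk", "Wv", "W1", "W2", "W3"):
                        grads[key] = grads[key] + cfg.weight_decay * self.params[key]
                self._adam_step(grads)
            test_prob = self.predict(maps[test_idx])
            auc = roc_auc_score(labels[test_idx], test_prob)
            row = {"epoch": epoch + 1, "train_loss": float(np.mean(losses)),
                   "test_auc": float(auc)}
            self.history.append(row)
            if log_fn is not None:
                log_fn(row)
            if cfg.restore_best and (best is None or auc > best[0]):
                best = (auc, {k: v.copy() for k, v in self.params.items()},
                        self.run_mean.copy(), self.run_var.copy(), epoch + 1)
        if cfg.restore_best and best is not None:
            auc, params, run_mean, run_var, best_epoch = best
            self.params, self.run_mean, self.run_var = params, run_mean, run_var
            self.history.append({"epoch": best_epoch,
                                 "train_loss": float("nan"),
                                 "test_auc": float(auc)})
        return self.history

    @property
    def test_auc(self) -> float:
        if not self.history:
            raise RuntimeError("model has not been trained")
        return self.history[-1]["test_auc"]

    def predict(self, maps: np.ndarray, chunk: int = 1024) -> np.ndarray:
        """Sigmoid scores in (0, 1), one per feature map, order preserved."""
        if maps.shape[1] != self.config.input_len:
            raise ValueError(
                f"expected input length {self.config.input_len}, "
                f"got {maps.shape[1]}")
        out = np.empty(maps.shape[0])
        for c0 in range(0, maps.shape[0], chunk):
            prob, _ = self._forward(maps[c0:c0 + chunk], training=False)
            out[c0:c0 + chunk] = prob
        return out

    def predict_sequences(self, onehots: np.ndarray) -> np.ndarray:
        return self.predict(compute_feature_maps(onehots, self.library,
                                                 self.config))

    def attention_state(self, maps: np.ndarray):
        """Inference-mode forward exposing the attention internals.

        Returns ``(prob, S, V)`` with ``S`` of shape (B, H, m, m) (each row
        of each head a softmax distribution) and ``V`` (B, H, m, d_k).
        """
        prob, cache = self._forward(maps, training=False)
        return prob, cache["s"], cache["v"]

    def classify_from_attention(self, s: np.ndarray, v: np.ndarray) -> np.ndarray:
        """Classifier output F when the attention scores are replaced by
        ``s`` while the value projections (and everything below) stay fixed."""
        y, _ = self._attn_output(s, v)
        z3, _ = self._mlp(y)
        return _sigmoid(z3)

    def margin_from_attention(self, s: np.ndarray, v: np.ndarray) -> np.ndarray:
        """Pre-sigmoid classification score from an attention state; the
        quantity whose integrated gradients the attribution module computes."""
        y, _ = self._attn_output(s, v)
        z3, _ = self._mlp(y)
        return z3

    def grad_wrt_attention(self, s: np.ndarray, v: np.ndarray):
        """Per-sample gradient of the classification score F with respect to
        the attention score matrix ``s`` (treated as an independent input;
        the value matrices ``v`` are held fixed).  Returns ``(F, dF/dS)``.

        F is the pre-sigmoid score: the sigmoid is a monotone rescaling that
        saturates for confident sequences and would flatten the gradients
        attribution is built from, so attribution is computed on the margin
        itself.
        """
        b = s.shape[0]
        y, _ = self._attn_output(s, v)
        z3, mlp_cache = self._mlp(y)
        dy = self._mlp_backward(np.ones_like(z3), mlp_cache, grads=None)
        h, dk = self.config.n_heads, self.config.d_k
        m = self.config.m_positions
        da = dy.reshape(b, m, h, dk).transpose(0, 2, 1, 3)
        ds = da @ v.transpose(0, 1, 3, 2)
        return z3, ds

    # ---------------- persistence ----------------

    def save(self, path) -> None:
        meta = {"config": {**asdict(self.config),
                           "fc_units": list(self.config.fc_units)},
                "library_hash": self.library.manifest_hash(),
                "history": self.history}
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8),
            run_mean=self.run_mean, run_var=self.run_var, **self.params)

    @classmethod
    def load(cls, path, library: MotifLibrary) -> "AttentionClassifier":
        with np.load(path) as npz:
            meta = json.loads(bytes(npz["__meta__"]).decode())
            cfg_d = meta["config"]
            cfg_d["fc_units"] = tuple(cfg_d["fc_units"])
            config = ModelConfig(**cfg_d)
            model = cls(library, config)
            if meta["library_hash"] != library.manifest_hash():
                raise ValueError("checkpoint was trained with a different "
                                 "motif library")
            for key in model.params:
                model.params[key] = npz[key]
            model.run_mean = npz["run_mean"]
            model.run_var = npz["run_var"]
            model.history = meta["history"]
        return model
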