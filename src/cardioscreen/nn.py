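"""Minimal recurrent network for frame-sequence classification, in pure numpy.

A (optionally bidirectional, multi-layer) GRU reads the Mel-spectrogram
frames of one recording, a linear head scores every frame, and the frame
scores are pooled (mean, max, or attention over frames) into one logit whose
sigmoid is the recording-level probability.  Forward, backpropagation
through time and the Adam optimiser are implemented directly so training is
single-threaded and bit-reproducible; analytic gradients are verified
against central finite differences in the test suite.

Batches must be rectangular: all sequences in one batch share a length
(the trainer groups recordings by frame count).
"""

from __future__ import annotations

import numpy as np

__all__ = ["RecurrentScorer", "Adam", "sigmoid", "bce_loss"]


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def bce_loss(logits: np.ndarray, y: np.ndarray, weights: np.ndarray | None = None
             ) -> tuple[float, np.ndarray]:
    """Weighted binary cross-entropy on logits; returns (loss, dloss/dlogits)."""
    y = np.asarray(y, dtype=np.float64)
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=np.float64)
    # log(1+e^x) computed stably
    ll = np.logaddexp(0.0, logits) - y * logits
    loss = float(np.sum(w * ll) / np.sum(w))
    dlogits = w * (sigmoid(logits) - y) / np.sum(w)
    return loss, dlogits


def _gru_forward(X: np.ndarray, Wx: np.ndarray, Wh: np.ndarray, bx: np.ndarray, bh: np.ndarray):
    """One GRU direction over (T, B, D) input; returns hidden states and cache."""
    T, B, _ = X.shape
    H = Wh.shape[0]
    GX = X @ Wx + bx  # (T, B, 3H)
    h = np.zeros((B, H))
    Hout = np.empty((T, B, H))
    R = np.empty((T, B, H)); Z = np.empty((T, B, H))
    N = np.empty((T, B, H)); HN = np.empty((T, B, H)); HP = np.empty((T, B, H))
    for t in range(T):
        gh = h @ Wh + bh
        r = sigmoid(GX[t, :, :H] + gh[:, :H])
        z = sigmoid(GX[t, :, H:2 * H] + gh[:, H:2 * H])
        hn = gh[:, 2 * H:]
        n = np.tanh(GX[t, :, 2 * H:] + r * hn)
        HP[t] = h
        h = (1.0 - z) * n + z * h
        Hout[t] = h; R[t] = r; Z[t] = z; N[t] = n; HN[t] = hn
    cache = (X, R, Z, N, HN, HP, Wx, Wh)
    return Hout, cache


def _gru_backward(dHout: np.ndarray, cache):
    """BPTT for one direction; dHout is the gradient w.r.t. every hidden state."""
    X, R, Z, N, HN, HP, Wx, Wh = cache
    T, B, H = dHout.shape
    dGX = np.empty((T, B, 3 * H))
    dWh = np.zeros_like(Wh)
    dbh = np.zeros(3 * H)
    dh = np.zeros((B, H))
    for t in range(T - 1, -1, -1):
        dht = dh + dHout[t]
        r, z, n, hn, hp = R[t], Z[t], N[t], HN[t], HP[t]
        dz = dht * (hp - n) * z * (1.0 - z)
        dn_pre = dht * (1.0 - z) * (1.0 - n * n)
        dr_pre = dn_pre * hn * r * (1.0 - r)
        dgh = np.concatenate([dr_pre, dz, dn_pre * r], axis=1)
        dGX[t, :, :H] = dr_pre
        dGX[t, :, H:2 * H] = dz
        dGX[t, :, 2 * H:] = dn_pre
        dWh += hp.T @ dgh
        dbh += dgh.sum(axis=0)
        dh = dht * z + dgh @ Wh.T
    Xf = X.reshape(T * B, -1)
    dGXf = dGX.reshape(T * B, -1)
    dWx = Xf.T @ dGXf
    dbx = dGXf.sum(axis=0)
    dX = dGX @ Wx.T
    return dX, dWx, dWh, dbx, dbh


class Adam:
    """Standard Adam over a dict of parameter arrays."""

    def __init__(self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        if self.lr == 0.0:
            return
        self.t += 1
        for k, g in grads.items():
            if k not in self.m:
                self.m[k] = np.zeros_like(g)
                self.v[k] = np.zeros_like(g)
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            mhat = self.m[k] / (1 - self.beta1 ** self.t)
            vhat = self.v[k] / (1 - self.beta2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class RecurrentScorer:
    """GRU frame encoder + linear frame head + temporal pooling + sigmoid.

    pooling:
      * ``mean_logit`` -- average of frame logits (default)
      * ``max_logit``  -- maximum frame logit
      * ``attention``  -- softmax attention over frames, learned query vector

    The head is zero-initialised, so an untrained model outputs exactly 0.5.
    """

    POOLINGS = ("mean_logit", "max_logit", "attention")

    def __init__(self, input_dim: int, hidden_size: int = 32, n_layers: int = 1,
                 bidirectional: bool = True, pooling: str = "mean_logit",
                 dropout: float = 0.0, seed: int = 0):
        if pooling not in self.POOLINGS:
            raise ValueError(f"pooling must be one of {self.POOLINGS}")
        if not 0.0 <= dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        self.input_dim = input_dim
        self.hidden_size = hidden_size
        self.n_layers = n_layers
        self.bidirectional = bidirectional
        self.pooling = pooling
        self.dropout = dropout
        rng = np.random.default_rng(seed)
        H = hidden_size
        k = 1.0 / np.sqrt(H)
        self.params: dict[str, np.ndarray] = {}
        dirs = ("f", "b") if bidirectional else ("f",)
        for layer in range(n_layers):
            d_in = input_dim if layer == 0 else H * len(dirs)
            for d in dirs:
                pre = f"l{layer}{d}_"
                self.params[pre + "Wx"] = rng.uniform(-k, k, (d_in, 3 * H))
                self.params[pre + "Wh"] = rng.uniform(-k, k, (H, 3 * H))
                self.params[pre + "bx"] = np.zeros(3 * H)
                self.params[pre + "bh"] = np.zeros(3 * H)
        d_out = H * len(dirs)
        self.params["head_w"] = np.zeros(d_out)
        self.params["head_b"] = np.zeros(1)
        if pooling == "attention":
            self.params["attn_v"] = rng.uniform(-k, k, d_out)

    # -- forward -----------------------------------------------------------

    def _encode(self, X: np.ndarray, train_rng: np.random.Generator | None = None):
        """Run the GRU stack; X is (T, B, D).  Returns (T, B, d_out) + caches."""
        caches = []
        cur = X
        dirs = ("f", "b") if self.bidirectional else ("f",)
        for layer in range(self.n_layers):
            outs = []
            layer_caches = []
            for d in dirs:
                pre = f"l{layer}{d}_"
                inp = cur[::-1] if d == "b" else cur
                Hout, cache = _gru_forward(
                    inp, self.params[pre + "Wx"], self.params[pre + "Wh"],
                    self.params[pre + "bx"], self.params[pre + "bh"])
                outs.append(Hout[::-1] if d == "b" else Hout)
                layer_caches.append((pre, cache))
            cur = np.concatenate(outs, axis=2) if len(outs) > 1 else outs[0]
            mask = None
            if train_rng is not None and self.dropout > 0.0 and layer < self.n_layers - 1:
                mask = (train_rng.random(cur.shape) >= self.dropout) / (1.0 - self.dropout)
                cur = cur * mask
            caches.append((layer_caches, mask))
        return cur, caches

    def forward(self, X: np.ndarray, train_rng: np.random.Generator | None = None):
        """Probabilities for a rectangular batch (T, B, D); returns (p, cache)."""
        Henc, caches = self._encode(X, train_rng)
        T, B, _ = Henc.shape
        L = Henc @ self.params["head_w"] + self.params["head_b"][0]  # (T, B)
        if self.pooling == "mean_logit":
            pooled = L.mean(axis=0)
            pool_cache = None
        elif self.pooling == "max_logit":
            arg = L.argmax(axis=0)
            pooled = L[arg, np.arange(B)]
            pool_cache = arg
        else:  # attention
            s = Henc @ self.params["attn_v"]  # (T, B)
            s = s - s.max(axis=0, keepdims=True)
            a = np.exp(s)
            a /= a.sum(axis=0, keepdims=True)
            pooled = (a * L).sum(axis=0)
            pool_cache = a
        p = sigmoid(pooled)
        return p, (X, Henc, caches, L, pooled, pool_cache)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Inference-mode probabilities for a rectangular batch (T, B, D)."""
        p, _ = self.forward(X, train_rng=None)
        return p

    # -- backward ----------------------------------------------------------

    def loss_and_grads(self, X: np.ndarray, y: np.ndarray,
                       weights: np.ndarray | None = None,
                       train_rng: np.random.Generator | None = None):
        """Weighted BCE loss and gradients for a rectangular batch."""
        p, cache = self.forward(X, train_rng)
        _, Henc, caches, L, pooled, pool_cache = cache
        loss, dpooled = bce_loss(pooled, y, weights)
        T, B, _ = Henc.shape

        if self.pooling == "mean_logit":
            dL = np.broadcast_to(dpooled / T, (T, B)).copy()
            dHenc_extra = 0.0
            dattn = None
        elif self.pooling == "max_logit":
            dL = np.zeros((T, B))
            dL[pool_cache, np.arange(B)] = dpooled
            dHenc_extra = 0.0
            dattn = None
        else:
            a = pool_cache
            dL = a * dpooled
            # d s_t = a_t (L_t - pooled) dpooled ; s = Henc @ v
            ds = a * (L - pooled) * dpooled
            dattn = np.einsum("tbd,tb->d", Henc, ds)
            dHenc_extra = ds[:, :, None] * self.params["attn_v"][None, None, :]

        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        grads["head_w"] = np.einsum("tbd,tb->d", Henc, dL)
        grads["head_b"] = np.array([dL.sum()])
        dHenc = dL[:, :, None] * self.params["head_w"][None, None, :] + dHenc_extra
        if self.pooling == "attention":
            grads["attn_v"] = dattn

        dirs = ("f", "b") if self.bidirectional else ("f",)
        dcur = dHenc
        for layer in range(self.n_layers - 1, -1, -1):
            layer_caches, mask = caches[layer]
            if mask is not None:
                dcur = dcur * mask
            H = self.hidden_size
            dX_total = None
            for i, (pre, c) in enumerate(layer_caches):
                d = dirs[i]
                dpart = dcur[:, :, i * H:(i + 1) * H]
                if d == "b":
                    dpart = dpart[::-1]
                dX, dWx, dWh, dbx, dbh = _gru_backward(np.ascontiguousarray(dpart), c)
                if d == "b":
                    dX = dX[::-1]
                grads[pre + "Wx"] += dWx
                grads[pre + "Wh"] += dWh
                grads[pre + "bx"] += dbx
                grads[pre + "bh"] += dbh
                dX_total = dX if dX_total is None else dX_total + dX
            dcur = dX_total
        return loss, grads, p

    # -- (de)serialisation -------------------------------------------------

    def get_weights(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = np.asarray(weights[k], dtype=np.float64).copy()

    def clone(self) -> "RecurrentScorer":
        m = RecurrentScorer(self.input_dim, self.hidden_size, self.n_layers,
                            self.bidirectional, self.pooling, self.dropout)
        m.set_weights(self.get_weights())
        return m
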