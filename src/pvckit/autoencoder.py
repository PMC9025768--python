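"""LSTM auto-encoder for per-beat feature extraction.

Each heartbeat window is fed to a single-layer LSTM encoder as a univariate
sequence (one time step per sample); the encoder's final hidden state h (the
*feature number*-dimensional embedding, default 32) summarises the beat.  A
single-layer LSTM decoder receives that embedding as its input at every step
and a linear read-out reconstructs the waveform.  Training minimises the mean
squared error between the reconstruction and the *band-pass-filtered* version
of the beat while the encoder consumes the raw beat — the filtered target
acts as a denoising teacher.

The network is implemented directly in numpy (forward pass, full
backpropagation through time, Adam optimiser), which keeps training exactly
reproducible from a seed and dependency-light; beats are short (a few hundred
samples) and segments hold a few thousand beats, so CPU training is adequate.

LSTM cell, with σ the logistic function and ∗ elementwise product:

    f_t = σ(W_f·[h_{t-1}, x_t] + b_f)          (forget gate)
    i_t = σ(W_i·[h_{t-1}, x_t] + b_i)          (input gate)
    ĉ_t = tanh(W_C·[h_{t-1}, x_t] + b_C)       (candidate state)
    C_t = f_t ∗ C_{t-1} + i_t ∗ ĉ_t
    o_t = σ(W_o·[h_{t-1}, x_t] + b_o)          (output gate)
    h_t = o_t ∗ tanh(C_t)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AEConfig", "AEModel", "train_autoencoder", "encode",
           "hyperparameter_sweep"]


@dataclass
class AEConfig:
    feature_number: int = 32
    batch_size: int = 128
    epochs: int = 100
    learning_rate: float = 1e-3
    seed: int = 0
    dtype: str = "float32"


def _sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class _LSTMLayer:
    """One LSTM layer over batched sequences, with manual BPTT.

    Weights are stored fused as ``Wx (D,4H)``, ``Wh (H,4H)``, ``b (4H,)``
    with gate order (i, f, g, o); the forget-gate bias starts at +1.
    """

    def __init__(self, input_dim: int, hidden: int, rng: np.random.Generator,
                 dtype):
        k = 1.0 / np.sqrt(hidden)
        self.Wx = rng.uniform(-k, k, size=(input_dim, 4 * hidden)).astype(dtype)
        self.Wh = rng.uniform(-k, k, size=(hidden, 4 * hidden)).astype(dtype)
        self.b = np.zeros(4 * hidden, dtype=dtype)
        self.b[hidden:2 * hidden] = 1.0
        self.H = hidden
        self.D = input_dim

    @property
    def params(self):
        return [self.Wx, self.Wh, self.b]

    def forward(self, X, x_constant=False, cache=False):
        """Run the layer over ``X``.

        ``X`` is ``(B, T, D)``; with ``x_constant`` it is ``(B, D)`` and the
        same input is applied at every of ``T`` steps (pass T explicitly via
        ``self._T``).  Returns ``(H_seq, h_T)`` and, if caching, keeps the
        intermediates needed for :meth:`backward`.
        """
        H = self.H
        if x_constant:
            B, T = X.shape[0], self._T
            x_proj = X @ self.Wx + self.b
        else:
            B, T, _ = X.shape
            x_proj = X @ self.Wx + self.b  # (B,T,4H)
        h = np.zeros((B, H), dtype=self.Wx.dtype)
        c = np.zeros((B, H), dtype=self.Wx.dtype)
        H_seq = np.empty((T, B, H), dtype=self.Wx.dtype)
        if cache:
            gates = np.empty((T, B, 4 * H), dtype=self.Wx.dtype)
            cs = np.empty((T, B, H), dtype=self.Wx.dtype)
            tcs = np.empty((T, B, H), dtype=self.Wx.dtype)
        for t in range(T):
            z = (x_proj if x_constant else x_proj[:, t]) + h @ self.Wh
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = _sigmoid(z[:, 3 * H:])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            if cache:
                gates[t, :, :H] = i
                gates[t, :, H:2 * H] = f
                gates[t, :, 2 * H:3 * H] = g
                gates[t, :, 3 * H:] = o
                cs[t] = c
                tcs[t] = tc
            h, c = h_new, c_new
            H_seq[t] = h
        if cache:
            self._cache = (X, x_constant, gates, cs, tcs, H_seq)
        return H_seq, h

    def backward(self, dH_seq=None, dh_last=None):
        """Backprop through time.

        ``dH_seq`` is ``(T, B, H)`` gradients w.r.t. each hidden state,
        ``dh_last`` an extra gradient for the final state.  Returns
        ``(grads, dX)`` where ``dX`` matches the forward input shape
        (summed over steps for a constant input).
        """
        X, x_constant, gates, cs, tcs, H_seq = self._cache
        H = self.H
        T, B, _ = H_seq.shape
        dtype = self.Wx.dtype
        dWx = np.zeros_like(self.Wx)
        dWh = np.zeros_like(self.Wh)
        db = np.zeros_like(self.b)
        dh = np.zeros((B, H), dtype=dtype) if dh_last is None else dh_last.astype(dtype)
        dc = np.zeros((B, H), dtype=dtype)
        dZ_sum = np.zeros((B, 4 * H), dtype=dtype) if x_constant else None
        dX = np.zeros_like(X) if not x_constant else None
        for t in range(T - 1, -1, -1):
            if dH_seq is not None:
                dh = dh + dH_seq[t]
            i = gates[t, :, :H]
            f = gates[t, :, H:2 * H]
            g = gates[t, :, 2 * H:3 * H]
            o = gates[t, :, 3 * H:]
            tc = tcs[t]
            c_prev = cs[t]
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc * tc)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate([
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g * g),
                do * o * (1.0 - o),
            ], axis=1)
            h_prev = H_seq[t - 1] if t > 0 else np.zeros((B, H), dtype=dtype)
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            if x_constant:
                dZ_sum += dz
            else:
                dWx += X[:, t].T @ dz
                dX[:, t] = dz @ self.Wx.T
            dh = dz @ self.Wh.T
            dc = dc * f
        if x_constant:
            dWx = X.T @ dZ_sum
            dX = dZ_sum @ self.Wx.T
        return [dWx, dWh, db], dX


class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2 ** self.t) / (1 - self.b1 ** self.t)
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= lr_t * m / (np.sqrt(v) + self.eps)


class AEModel:
    """Trained LSTM auto-encoder (encoder + decoder + linear read-out)."""

    def __init__(self, config: AEConfig, seq_len: int, rng=None):
        self.config = config
        self.seq_len = seq_len
        H = config.feature_number
        dtype = np.dtype(config.dtype)
        if rng is None:
            rng = np.random.default_rng(config.seed)
        self.encoder = _LSTMLayer(1, H, rng, dtype)
        self.decoder = _LSTMLayer(H, H, rng, dtype)
        k = 1.0 / np.sqrt(H)
        self.Wy = rng.uniform(-k, k, size=(H, 1)).astype(dtype)
        self.by = np.zeros(1, dtype=dtype)
        self.loss_history: list[float] = []

    @property
    def params(self):
        return self.encoder.params + self.decoder.params + [self.Wy, self.by]

    # -- forward / backward -------------------------------------------------
    def _forward(self, X, cache=False):
        """X: (B,T). Returns (reconstruction (B,T), embeddings (B,H))."""
        B, T = X.shape
        _, h_enc = self.encoder.forward(X[:, :, None], cache=cache)
        self.decoder._T = T
        Hdec, _ = self.decoder.forward(h_enc, x_constant=True, cache=cache)
        Y = (Hdec @ self.Wy)[:, :, 0].T  # (B,T)
        if cache:
            self._Hdec = Hdec
        return Y + self.by, h_enc

    def _backward(self, X, dY):
        """dY: (B,T) gradient of loss w.r.t. reconstruction."""
        T, B = dY.shape[1], dY.shape[0]
        dHdec = (dY.T[:, :, None] * self.Wy[None, None, :, 0]).astype(self.Wy.dtype)
        dWy = np.einsum("tbh,bt->h", self._Hdec, dY)[:, None]
        dby = np.array([dY.sum()], dtype=self.by.dtype)
        dec_grads, dh_enc = self.decoder.backward(dH_seq=dHdec)
        enc_grads, _ = self.encoder.backward(dh_last=dh_enc)
        return enc_grads + dec_grads + [dWy.astype(self.Wy.dtype), dby]

    # -- persistence --------------------------------------------------------
    def save(self, path) -> None:
        np.savez(path, seq_len=self.seq_len,
                 feature_number=self.config.feature_number,
                 dtype=self.config.dtype,
                 enc_Wx=self.encoder.Wx, enc_Wh=self.encoder.Wh,
                 enc_b=self.encoder.b, dec_Wx=self.decoder.Wx,
                 dec_Wh=self.decoder.Wh, dec_b=self.decoder.b,
                 Wy=self.Wy, by=self.by)

    @classmethod
    def load(cls, path) -> "AEModel":
        z = np.load(path, allow_pickle=False)
        cfg = AEConfig(feature_number=int(z["feature_number"]),
                       dtype=str(z["dtype"]))
        model = cls(cfg, int(z["seq_len"]))
        model.encoder.Wx, model.encoder.Wh, model.encoder.b = (
            z["enc_Wx"], z["enc_Wh"], z["enc_b"])
        model.decoder.Wx, model.decoder.Wh, model.decoder.b = (
            z["dec_Wx"], z["dec_Wh"], z["dec_b"])
        model.Wy, model.by = z["Wy"], z["by"]
        return model


def _stack(beats) -> np.ndarray:
    return np.stack([np.asarray(b.hw, dtype=float) for b in beats])


def train_autoencoder(beats_raw, beats_filtered, config: AEConfig | None = None
                      ) -> AEModel:
    """Train the auto-encoder on one segment's beats.

    The encoder input is the raw (unfiltered) beat; the reconstruction loss
    is measured against the band-pass-filtered beat.  Raw and filtered lists
    must be aligned beat-for-beat.
    """
    config = config or AEConfig()
    if len(beats_raw) != len(beats_filtered):
        raise ValueError("raw and filtered beat lists must be aligned")
    if len(beats_raw) < 8:
        raise ValueError("need at least 8 beats to train")
    for br, bf in zip(beats_raw, beats_filtered):
        if br.r_sample != bf.r_sample or len(br.hw) != len(bf.hw):
            raise ValueError("raw and filtered beat lists must be aligned")

    dtype = np.dtype(config.dtype)
    X = _stack(beats_raw).astype(dtype)
    Ytgt = _stack(beats_filtered).astype(dtype)
    n, T = X.shape

    rng = np.random.default_rng(config.seed)
    model = AEModel(config, T, rng=rng)
    opt = _Adam(model.params, config.learning_rate)

    B = min(config.batch_size, n)
    for _ in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, B):
            idx = order[start:start + B]
            xb, yb = X[idx], Ytgt[idx]
            Y, _ = model._forward(xb, cache=True)
            err = Y - yb
            loss = float(np.mean(err ** 2))
            dY = (2.0 / err.size) * err
            grads = model._backward(xb, dY)
            opt.step(grads)
            epoch_loss += loss * len(idx)
        model.loss_history.append(epoch_loss / n)
    return model


def encode(model: AEModel, beats) -> np.ndarray:
    """Embed beats with the trained encoder: returns ``(n, feature_number)``."""
    if len(beats) == 0:
        return np.empty((0, model.config.feature_number))
    X = _stack(beats)
    if X.shape[1] != model.seq_len:
        raise ValueError(
            f"beat length {X.shape[1]} does not match training length "
            f"{model.seq_len}")
    _, h = model._forward(X.astype(model.Wy.dtype), cache=False)
    return np.asarray(h, dtype=float)


def reconstruct(model: AEModel, beats) -> np.ndarray:
    """Decode beats back to waveforms (mainly for diagnostics/tests)."""
    X = _stack(beats).astype(model.Wy.dtype)
    Y, _ = model._forward(X, cache=False)
    return np.asarray(Y, dtype=float)


def hyperparameter_sweep(beats_raw, beats_filtered, labels_fn,
                         batch_sizes=(64, 128, 256), features=(16, 32, 64),
                         epochs: int = 20, seed: int = 0):
    """Grid-train over batch size x feature number; score with ``labels_fn``.

    ``labels_fn(embeddings) -> float`` maps the embedding matrix to a score
    (e.g. downstream classification accuracy).  Returns a dict keyed by
    ``(batch, features)``.
    """
    results = {}
    for bs in batch_sizes:
        for ft in features:
            cfg = AEConfig(feature_number=ft, batch_size=bs, epochs=epochs,
                           seed=seed)
            model = train_autoencoder(beats_raw, beats_filtered, cfg)
            results[(bs, ft)] = float(labels_fn(encode(model, beats_raw)))
    return results
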