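"""Minimal NumPy neural-network core for the chemical language model.

Implements exactly the pieces the model needs — batch normalization,
LSTM layers with full backpropagation through time, a per-step dense
softmax head, and the Adam optimizer — with deterministic, seedable
initialization. Shapes follow the time-major-batch convention
``(batch, time, features)``; padding is at the end of each sequence and
masked positions carry zero loss.

Parameter layout matches the usual framework conventions so closed-form
parameter counts transfer: an LSTM with input dimension D and H units has
``Wx (D, 4H)``, ``Wh (H, 4H)``, ``b (4H,)``; batch normalization carries
gamma, beta and the (non-trainable) moving mean and variance.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - np.max(z, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / np.sum(e, axis=axis, keepdims=True)


def log_softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - np.max(z, axis=axis, keepdims=True)
    return z - np.log(np.sum(np.exp(z), axis=axis, keepdims=True))


def _glorot(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    lim = np.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-lim, lim, size=shape).astype(DTYPE)


def _orthogonal(rng: np.random.Generator, n: int) -> np.ndarray:
    a = rng.standard_normal((n, n))
    q, r = np.linalg.qr(a)
    return (q * np.sign(np.diag(r))).astype(DTYPE)


class BatchNorm:
    """Per-feature batch normalization over all unmasked (batch, time) positions."""

    def __init__(self, n_features: int, momentum: float = 0.9, eps: float = 1e-3):
        self.n_features = n_features
        self.momentum = momentum
        self.eps = eps
        self.gamma = np.ones(n_features, dtype=DTYPE)
        self.beta = np.zeros(n_features, dtype=DTYPE)
        self.moving_mean = np.zeros(n_features, dtype=DTYPE)
        self.moving_var = np.ones(n_features, dtype=DTYPE)
        self._cache = None

    def params(self) -> dict[str, np.ndarray]:
        return {
            "gamma": self.gamma,
            "beta": self.beta,
            "moving_mean": self.moving_mean,
            "moving_var": self.moving_var,
        }

    trainable = ("gamma", "beta")

    def forward(
        self,
        x: np.ndarray,
        mask: np.ndarray | None,
        training: bool,
        frozen: bool = False,
    ) -> np.ndarray:
        """``frozen=True`` trains through the layer with the moving statistics
        (no update): batch statistics of very small fine-tuning batches are
        degenerate, so transfer learning freezes them."""
        if training and not frozen:
            if mask is None:
                mask = np.ones(x.shape[:-1], dtype=DTYPE)
            w = mask[..., None].astype(DTYPE)
            n = w.sum()
            mean = (x * w).sum(axis=(0, 1)) / n
            var = (((x - mean) ** 2) * w).sum(axis=(0, 1)) / n
            m = self.momentum
            self.moving_mean = (m * self.moving_mean + (1 - m) * mean).astype(DTYPE)
            self.moving_var = (m * self.moving_var + (1 - m) * var).astype(DTYPE)
        else:
            mean, var = self.moving_mean, self.moving_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        y = self.gamma * xhat + self.beta
        if training and not frozen:
            self._cache = (xhat, inv, w, n)
        else:
            self._cache = (xhat, inv, None, None)
        return y.astype(DTYPE)

    def forward_step(self, x: np.ndarray) -> np.ndarray:
        """Inference-mode normalization of a single step ``(batch, features)``."""
        inv = 1.0 / np.sqrt(self.moving_var + self.eps)
        return (self.gamma * (x - self.moving_mean) * inv + self.beta).astype(DTYPE)

    def backward(self, dy: np.ndarray) -> tuple[np.ndarray, dict[str, np.ndarray]]:
        xhat, inv, w, n = self._cache
        if w is None:  # inference-mode stats: no coupling through the batch
            dgamma = (dy * xhat).sum(axis=(0, 1))
            dbeta = dy.sum(axis=(0, 1))
            dx = dy * self.gamma * inv
            return dx, {"gamma": dgamma, "beta": dbeta}
        dyw = dy * w
        dgamma = (dyw * xhat).sum(axis=(0, 1))
        dbeta = dyw.sum(axis=(0, 1))
        dxhat = dyw * self.gamma
        mean_dxhat = dxhat.sum(axis=(0, 1)) / n
        mean_dxhat_xhat = (dxhat * xhat).sum(axis=(0, 1)) / n
        dx = (inv * (dxhat - mean_dxhat - xhat * mean_dxhat_xhat)) * w
        return dx.astype(DTYPE), {"gamma": dgamma, "beta": dbeta}


class LSTM:
    """Standard LSTM layer (gates ordered i, f, g, o) with BPTT."""

    trainable = ("Wx", "Wh", "b")

    def __init__(self, input_dim: int, units: int, rng: np.random.Generator):
        self.input_dim = input_dim
        self.units = units
        self.Wx = _glorot(rng, (input_dim, 4 * units))
        self.Wh = np.concatenate(
            [_orthogonal(rng, units) for _ in range(4)], axis=1
        ).astype(DTYPE)
        b = np.zeros(4 * units, dtype=DTYPE)
        b[units : 2 * units] = 1.0  # forget-gate bias
        self.b = b
        self._cache = None

    def params(self) -> dict[str, np.ndarray]:
        return {"Wx": self.Wx, "Wh": self.Wh, "b": self.b}

    def _gates(self, z: np.ndarray) -> tuple[np.ndarray, ...]:
        H = self.units
        i = 1.0 / (1.0 + np.exp(-z[:, :H]))
        f = 1.0 / (1.0 + np.exp(-z[:, H : 2 * H]))
        g = np.tanh(z[:, 2 * H : 3 * H])
        o = 1.0 / (1.0 + np.exp(-z[:, 3 * H :]))
        return i, f, g, o

    def forward(self, x: np.ndarray, cache: bool = True) -> np.ndarray:
        """Run the full sequence ``x (B, T, D)``; returns hidden states (B, T, H)."""
        B, T, _ = x.shape
        H = self.units
        h = np.zeros((B, H), dtype=DTYPE)
        c = np.zeros((B, H), dtype=DTYPE)
        out = np.empty((B, T, H), dtype=DTYPE)
        steps = []
        for t in range(T):
            xt = x[:, t, :]
            z = xt @ self.Wx + h @ self.Wh + self.b
            i, f, g, o = self._gates(z)
            c_prev = c
            c = f * c + i * g
            tc = np.tanh(c)
            h_prev = h
            h = o * tc
            out[:, t, :] = h
            if cache:
                steps.append((xt, h_prev, c_prev, i, f, g, o, c, tc))
        self._cache = steps if cache else None
        return out

    def step(self, xt: np.ndarray, state: tuple[np.ndarray, np.ndarray]):
        """Single inference step; state is ``(h, c)``."""
        h, c = state
        z = xt @ self.Wx + h @ self.Wh + self.b
        i, f, g, o = self._gates(z)
        c = f * c + i * g
        h = o * np.tanh(c)
        return h, (h, c)

    def backward(self, dout: np.ndarray) -> tuple[np.ndarray, dict[str, np.ndarray]]:
        steps = self._cache
        B, T, _ = dout.shape
        H = self.units
        dWx = np.zeros_like(self.Wx)
        dWh = np.zeros_like(self.Wh)
        db = np.zeros_like(self.b)
        dx = np.empty((B, T, self.input_dim), dtype=DTYPE)
        dh_next = np.zeros((B, H), dtype=DTYPE)
        dc_next = np.zeros((B, H), dtype=DTYPE)
        dz = np.empty((B, 4 * H), dtype=DTYPE)
        for t in range(T - 1, -1, -1):
            xt, h_prev, c_prev, i, f, g, o, c, tc = steps[t]
            dh = dout[:, t, :] + dh_next
            dc = dc_next + dh * o * (1.0 - tc * tc)
            dz[:, :H] = dc * g * i * (1.0 - i)
            dz[:, H : 2 * H] = dc * c_prev * f * (1.0 - f)
            dz[:, 2 * H : 3 * H] = dc * i * (1.0 - g * g)
            dz[:, 3 * H :] = dh * tc * o * (1.0 - o)
            dWx += xt.T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, t, :] = dz @ self.Wx.T
            dh_next = dz @ self.Wh.T
            dc_next = dc * f
        return dx, {"Wx": dWx, "Wh": dWh, "b": db}


class Dense:
    """Per-step affine map ``(B, T, H) -> (B, T, V)``."""

    trainable = ("W", "b")

    def __init__(self, input_dim: int, units: int, rng: np.random.Generator):
        self.W = _glorot(rng, (input_dim, units))
        self.b = np.zeros(units, dtype=DTYPE)
        self._cache = None

    def params(self) -> dict[str, np.ndarray]:
        return {"W": self.W, "b": self.b}

    def forward(self, x: np.ndarray, cache: bool = True) -> np.ndarray:
        if cache:
            self._cache = x
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray) -> tuple[np.ndarray, dict[str, np.ndarray]]:
        x = self._cache
        dW = np.tensordot(x, dy, axes=([0, 1], [0, 1]))
        db = dy.sum(axis=(0, 1))
        dx = dy @ self.W.T
        return dx, {"W": dW, "b": db}


class SequenceNetwork:
    """batch norm -> LSTM -> LSTM -> batch norm -> per-step dense softmax.

    The network consumes one-hot token sequences whose position 0 is the
    start token and predicts the distribution of the next token at every
    step.
    """

    def __init__(
        self,
        vocab_size: int,
        lstm1_units: int,
        lstm2_units: int,
        rng: np.random.Generator,
    ):
        self.vocab_size = vocab_size
        self.bn_frozen = False  # set during fine-tuning (tiny batches)
        self.bn_in = BatchNorm(vocab_size)
        self.lstm1 = LSTM(vocab_size, lstm1_units, rng)
        self.lstm2 = LSTM(lstm1_units, lstm2_units, rng)
        self.bn_out = BatchNorm(lstm2_units)
        self.dense = Dense(lstm2_units, vocab_size, rng)
        self._layer_map = {
            "bn_in": self.bn_in,
            "lstm1": self.lstm1,
            "lstm2": self.lstm2,
            "bn_out": self.bn_out,
            "dense": self.dense,
        }

    # --- parameter bookkeeping -------------------------------------------
    def parameters(self) -> dict[str, np.ndarray]:
        """All parameter arrays, including batch-norm moving statistics."""
        out = {}
        for lname, layer in self._layer_map.items():
            for pname, arr in layer.params().items():
                out[f"{lname}.{pname}"] = arr
        return out

    def trainable_names(self) -> list[str]:
        return [
            f"{lname}.{pname}"
            for lname, layer in self._layer_map.items()
            for pname in layer.trainable
        ]

    def n_parameters(self) -> int:
        return sum(int(a.size) for a in self.parameters().values())

    def set_parameters(self, values: dict[str, np.ndarray]) -> None:
        for name, arr in values.items():
            lname, pname = name.split(".")
            layer = self._layer_map[lname]
            current = getattr(layer, pname)
            if current.shape != arr.shape:
                raise ValueError(f"shape mismatch for {name}")
            setattr(layer, pname, arr.astype(DTYPE))

    # --- forward / backward ----------------------------------------------
    def one_hot(self, tokens: np.ndarray) -> np.ndarray:
        B, T = tokens.shape
        x = np.zeros((B, T, self.vocab_size), dtype=DTYPE)
        x[np.arange(B)[:, None], np.arange(T)[None, :], tokens] = 1.0
        return x

    def forward(
        self, tokens: np.ndarray, mask: np.ndarray | None, training: bool
    ) -> np.ndarray:
        x = self.one_hot(tokens)
        x = self.bn_in.forward(x, mask, training, frozen=self.bn_frozen)
        h = self.lstm1.forward(x, cache=training)
        h = self.lstm2.forward(h, cache=training)
        h = self.bn_out.forward(h, mask, training, frozen=self.bn_frozen)
        return self.dense.forward(h, cache=training)

    def loss_and_grads(
        self, tokens_in: np.ndarray, targets: np.ndarray, mask: np.ndarray
    ) -> tuple[float, dict[str, np.ndarray]]:
        """Mean masked cross-entropy and gradients for all trainable parameters."""
        logits = self.forward(tokens_in, mask, training=True)
        B, T = targets.shape
        logp = log_softmax(logits)
        n_valid = mask.sum()
        picked = logp[np.arange(B)[:, None], np.arange(T)[None, :], targets]
        loss = -float((picked * mask).sum() / n_valid)

        p = np.exp(logp)
        dlogits = p
        dlogits[np.arange(B)[:, None], np.arange(T)[None, :], targets] -= 1.0
        dlogits *= (mask / n_valid)[..., None]

        grads: dict[str, np.ndarray] = {}
        d, g = self.dense.backward(dlogits)
        grads.update({f"dense.{k}": v for k, v in g.items()})
        d, g = self.bn_out.backward(d)
        grads.update({f"bn_out.{k}": v for k, v in g.items()})
        d, g = self.lstm2.backward(d)
        grads.update({f"lstm2.{k}": v for k, v in g.items()})
        d, g = self.lstm1.backward(d)
        grads.update({f"lstm1.{k}": v for k, v in g.items()})
        _, g = self.bn_in.backward(d)
        grads.update({f"bn_in.{k}": v for k, v in g.items()})
        return loss, grads

    def sequence_loss(self, tokens_in, targets, mask) -> float:
        """Mean masked cross-entropy without gradient bookkeeping (evaluation)."""
        logits = self.forward(tokens_in, mask, training=False)
        B, T = targets.shape
        logp = log_softmax(logits)
        picked = logp[np.arange(B)[:, None], np.arange(T)[None, :], targets]
        return -float((picked * mask).sum() / mask.sum())

    # --- stepwise inference (sampling / beam search) ----------------------
    def init_state(self, batch: int):
        z1 = np.zeros((batch, self.lstm1.units), dtype=DTYPE)
        z2 = np.zeros((batch, self.lstm2.units), dtype=DTYPE)
        return ((z1, z1.copy()), (z2, z2.copy()))

    def step(self, tokens: np.ndarray, state):
        """One inference step: tokens ``(B,)`` -> logits ``(B, V)`` and new state."""
        (s1, s2) = state
        x = np.zeros((tokens.shape[0], self.vocab_size), dtype=DTYPE)
        x[np.arange(tokens.shape[0]), tokens] = 1.0
        x = self.bn_in.forward_step(x)
        h1, s1 = self.lstm1.step(x, s1)
        h2, s2 = self.lstm2.step(h1, s2)
        h2 = self.bn_out.forward_step(h2)
        logits = h2 @ self.dense.W + self.dense.b
        return logits, (s1, s2)


class Adam:
    """Adam optimizer with global-norm gradient clipping."""

    def __init__(
        self,
        params: dict[str, np.ndarray],
        lr: float = 1e-4,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
        clip_norm: float | None = 5.0,
    ):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        if self.clip_norm is not None:
            total = np.sqrt(
                sum(float(np.sum(grads[k].astype(np.float64) ** 2)) for k in self.params)
            )
            if total > self.clip_norm:
                scale = self.clip_norm / (total + 1e-12)
                grads = {k: g * scale for k, g in grads.items()}
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for k, p in self.params.items():
            g = grads[k].astype(DTYPE)
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * (g * g)
            mhat = self.m[k] / bias1
            vhat = self.v[k] / bias2
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(DTYPE)
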