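"""From-scratch NumPy neural-network primitives with backpropagation.

Provides both the small functional operations used throughout the package
(`conv2d`, `relu`, `max_pool`, `batch_norm`, `softmax`, `modified_ce_loss`,
`bilstm`) and the layer classes (with `forward`/`backward` and an Adam
optimizer) that the CNN + Bi-LSTM classifier is assembled from.

Conventions: image batches are [N, C, H, W]; sequences are [T, N, F];
convolution is cross-correlation (no kernel flip).
"""

from __future__ import annotations

import copy
import math

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "conv2d",
    "relu",
    "max_pool",
    "batch_norm",
    "softmax",
    "modified_ce_loss",
    "modified_ce_loss_grad",
    "bilstm",
    "Conv2D",
    "BatchNorm2D",
    "ReLULayer",
    "MaxPool2D",
    "Dropout",
    "LSTM",
    "BiLSTMLayer",
    "Attention",
    "Dense",
    "Adam",
]

_P_CLAMP = 1e-7


# ---------------------------------------------------------------------------
# Functional operations
# ---------------------------------------------------------------------------

def conv2d(input: np.ndarray, kernel: np.ndarray, stride: int = 1, padding: int = 0) -> np.ndarray:
    """2-D valid cross-correlation f(p,q) = sum_mn s(p+m, q+n) k(m,n).

    ``padding`` zero-pads the input symmetrically before correlating.
    """
    x = np.asarray(input, dtype=np.float64)
    k = np.asarray(kernel, dtype=np.float64)
    if x.ndim != 2 or k.ndim != 2:
        raise ValueError("conv2d expects 2-D input and kernel")
    if stride < 1:
        raise ValueError(f"stride must be >= 1, got {stride}")
    if padding:
        x = np.pad(x, padding)
    if k.shape[0] > x.shape[0] or k.shape[1] > x.shape[1]:
        raise ValueError(f"kernel {k.shape} does not fit in input {x.shape}")
    windows = sliding_window_view(x, k.shape)[::stride, ::stride]
    if windows.shape[0] == 0 or windows.shape[1] == 0:
        raise ValueError("stride produces an empty output")
    return np.einsum("ijmn,mn->ij", windows, k)


def relu(x: np.ndarray) -> np.ndarray:
    """Elementwise max(0, x)."""
    return np.maximum(0, np.asarray(x))


def max_pool(x: np.ndarray, window: int = 2) -> np.ndarray:
    """Per-window maxima over non-overlapping window x window blocks.

    Dimensions not divisible by the window are padded with -inf first
    (pad-then-pool), so every input pixel belongs to exactly one block.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("max_pool expects a 2-D matrix")
    h, w = x.shape
    ph = (-h) % window
    pw = (-w) % window
    if ph or pw:
        x = np.pad(x, ((0, ph), (0, pw)), constant_values=-np.inf)
    h, w = x.shape
    return x.reshape(h // window, window, w // window, window).max(axis=(1, 3))


def batch_norm(
    batch: np.ndarray,
    eps: float = 1e-5,
    scale: float | np.ndarray = 1.0,
    shift: float | np.ndarray = 0.0,
    mode: str = "train",
    running_mean=None,
    running_var=None,
) -> np.ndarray:
    """Batch normalization over axis 0.

    Train mode normalizes with the batch mean and (biased) variance:
    ``(x - mean) / sqrt(var + eps)``, then applies scale and shift.  Eval
    mode uses the supplied running statistics instead.
    """
    x = np.asarray(batch, dtype=np.float64)
    if mode == "train":
        if x.shape[0] < 2:
            raise ValueError(f"train-mode batch_norm needs batch size >= 2, got {x.shape[0]}")
        mean = x.mean(axis=0)
        var = x.var(axis=0)
    elif mode == "eval":
        if running_mean is None or running_var is None:
            raise ValueError("eval-mode batch_norm requires running statistics")
        mean, var = running_mean, running_var
    else:
        raise ValueError(f"mode must be 'train' or 'eval', got {mode!r}")
    xhat = (x - mean) / np.sqrt(var + eps)
    return scale * xhat + shift


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically stabilized exp-normalization along ``axis``."""
    z = np.asarray(logits, dtype=np.float64)
    if not np.all(np.isfinite(z)):
        raise ValueError("logits must be finite")
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _check_probs(pred) -> np.ndarray:
    p = np.asarray(pred, dtype=np.float64)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("predicted probabilities must lie in [0, 1]")
    return np.clip(p, _P_CLAMP, 1.0 - _P_CLAMP)


def modified_ce_loss(pred, target, t: float = 0.75, eta: float = 2.0, reduce: str = "mean"):
    """Imbalance-aware focal-style cross-entropy.

    Elementwise ``L = -t * x * (1-x')^eta * log x' - (1-x) * log(1-x')`` for
    target ``x`` in {0,1} and predicted probability ``x'`` (clamped at 1e-7).
    With ``t=1, eta=0`` this is exactly binary cross-entropy.  The multiclass
    training loss applies this one-vs-rest over the softmax outputs, summing
    classes and averaging the batch.  ``reduce``: 'mean', 'sum' or 'none'.
    """
    p = _check_probs(pred)
    x = np.asarray(target, dtype=np.float64)
    loss = -t * x * (1.0 - p) ** eta * np.log(p) - (1.0 - x) * np.log1p(-p)
    if reduce == "none":
        return loss
    if reduce == "sum":
        return float(np.sum(loss))
    if reduce == "mean":
        return float(np.mean(loss))
    raise ValueError(f"unknown reduce {reduce!r}")


def modified_ce_loss_grad(pred, target, t: float = 0.75, eta: float = 2.0) -> np.ndarray:
    """Elementwise dL/dx' of :func:`modified_ce_loss` (no reduction)."""
    p = _check_probs(pred)
    x = np.asarray(target, dtype=np.float64)
    pos = t * (eta * (1.0 - p) ** (eta - 1.0) * np.log(p) - (1.0 - p) ** eta / p) if eta > 0 \
        else -t / p
    neg = 1.0 / (1.0 - p)
    return x * pos + (1.0 - x) * neg


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

class Layer:
    """Base layer: named parameters, gradients, forward/backward."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x, train: bool = True):
        raise NotImplementedError

    def backward(self, dout):
        raise NotImplementedError


class Conv2D(Layer):
    """Strided valid cross-correlation, [N, C, H, W] -> [N, F, Ho, Wo]."""

    def __init__(self, c_in, c_out, k, stride=1, pad=0, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * k * k
        self.params = {
            "W": rng.normal(0.0, math.sqrt(2.0 / fan_in), size=(c_out, fan_in)),
            "b": np.zeros(c_out),
        }
        self.k, self.stride, self.pad = k, stride, pad
        self.c_in, self.c_out = c_in, c_out

    def out_shape(self, h, w):
        ho = (h + 2 * self.pad - self.k) // self.stride + 1
        wo = (w + 2 * self.pad - self.k) // self.stride + 1
        return ho, wo

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        if self.pad:
            x = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad), (self.pad, self.pad)))
        ho, wo = self.out_shape(h, w)
        if ho < 1 or wo < 1:
            raise ValueError(f"Conv2D: kernel {self.k} does not fit input {h}x{w}")
        win = sliding_window_view(x, (self.k, self.k), axis=(2, 3))[:, :, :: self.stride, :: self.stride]
        # [N, C, Ho, Wo, k, k] -> [N*Ho*Wo, C*k*k]
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * self.k * self.k)
        out = cols @ self.params["W"].T + self.params["b"]
        self._cache = (cols, (n, c, h, w), (ho, wo))
        return out.reshape(n, ho, wo, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dout):
        cols, (n, c, h, w), (ho, wo) = self._cache
        dcols_flat = dout.transpose(0, 2, 3, 1).reshape(n * ho * wo, self.c_out)
        self.grads["W"] = dcols_flat.T @ cols
        self.grads["b"] = dcols_flat.sum(axis=0)
        dcols = (dcols_flat @ self.params["W"]).reshape(n, ho, wo, c, self.k, self.k)
        hp, wp = h + 2 * self.pad, w + 2 * self.pad
        dx_pad = np.zeros((n, c, hp, wp))
        s = self.stride
        for dy in range(self.k):
            for dx in range(self.k):
                dx_pad[:, :, dy : dy + s * ho : s, dx : dx + s * wo : s] += dcols[
                    :, :, :, :, dy, dx
                ].transpose(0, 3, 1, 2)
        if self.pad:
            return dx_pad[:, :, self.pad : -self.pad, self.pad : -self.pad]
        return dx_pad


class BatchNorm2D(Layer):
    """Per-channel batch norm over (N, H, W) with running statistics."""

    def __init__(self, channels, eps=1e-5, momentum=0.1):
        super().__init__()
        self.params = {"gamma": np.ones(channels), "beta": np.zeros(channels)}
        self.eps, self.momentum = eps, momentum
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x, train=True):
        if train:
            if x.shape[0] < 2:
                raise ValueError("BatchNorm2D needs batch size >= 2 in train mode")
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        m, v = mean[None, :, None, None], var[None, :, None, None]
        inv = 1.0 / np.sqrt(v + self.eps)
        xhat = (x - m) * inv
        self._cache = (xhat, inv, x.shape)
        return self.params["gamma"][None, :, None, None] * xhat + self.params["beta"][None, :, None, None]

    def backward(self, dout):
        xhat, inv, shape = self._cache
        n_eff = shape[0] * shape[2] * shape[3]
        self.grads["gamma"] = (dout * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] = dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.params["gamma"][None, :, None, None]
        # standard batch-norm backward (through batch statistics)
        term1 = dxhat
        term2 = dxhat.mean(axis=(0, 2, 3), keepdims=True)
        term3 = xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        return inv * (term1 - term2 - term3)


class ReLULayer(Layer):
    def forward(self, x, train=True):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool2D(Layer):
    """2x2 (or w x w) max pooling with -inf pad-then-pool on odd dims."""

    def __init__(self, window=2):
        super().__init__()
        self.w = window

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        ph, pw = (-h) % self.w, (-w) % self.w
        if ph or pw:
            x = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)), constant_values=-np.inf)
        hp, wp = x.shape[2], x.shape[3]
        ho, wo = hp // self.w, wp // self.w
        blocks = x.reshape(n, c, ho, self.w, wo, self.w).transpose(0, 1, 2, 4, 3, 5)
        flat = blocks.reshape(n, c, ho, wo, self.w * self.w)
        arg = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
        self._cache = (arg, (n, c, h, w), (hp, wp), (ho, wo))
        return out

    def backward(self, dout):
        arg, (n, c, h, w), (hp, wp), (ho, wo) = self._cache
        dflat = np.zeros((n, c, ho, wo, self.w * self.w))
        np.put_along_axis(dflat, arg[..., None], dout[..., None], axis=-1)
        dx = (
            dflat.reshape(n, c, ho, wo, self.w, self.w)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, hp, wp)
        )
        return dx[:, :, :h, :w]


class Dropout(Layer):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, p, rng):
        super().__init__()
        self.p, self.rng = p, rng

    def forward(self, x, train=True):
        if not train or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class LSTM(Layer):
    """Unidirectional LSTM over [T, N, F] -> hidden states [T, N, H].

    Standard gate structure (input/forget/cell/output gates, forget-gate
    bias initialized to 1).
    """

    def __init__(self, input_dim, hidden, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        s = math.sqrt(1.0 / hidden)
        self.params = {
            "Wx": rng.uniform(-s, s, size=(input_dim, 4 * hidden)),
            "Wh": rng.uniform(-s, s, size=(hidden, 4 * hidden)),
            "b": np.zeros(4 * hidden),
        }
        self.params["b"][hidden : 2 * hidden] = 1.0  # forget-gate bias
        self.hidden = hidden

    def forward(self, x, train=True):
        T, n, _ = x.shape
        H = self.hidden
        h = np.zeros((n, H))
        c = np.zeros((n, H))
        caches, hs = [], []
        for t in range(T):
            z = x[t] @ self.params["Wx"] + h @ self.params["Wh"] + self.params["b"]
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c_new = f * c + i * g
            tanh_c = np.tanh(c_new)
            h = o * tanh_c
            caches.append((x[t], h.copy(), c, i, f, g, o, c_new, tanh_c))
            c = c_new
            hs.append(h)
        self._cache = (caches, x.shape)
        return np.stack(hs)

    def backward(self, dout):
        caches, (T, n, fdim) = self._cache
        H = self.hidden
        dWx = np.zeros_like(self.params["Wx"])
        dWh = np.zeros_like(self.params["Wh"])
        db = np.zeros_like(self.params["b"])
        dx = np.zeros((T, n, fdim))
        dh_next = np.zeros((n, H))
        dc_next = np.zeros((n, H))
        for t in range(T - 1, -1, -1):
            xt, _, c_prev, i, f, g, o, c_new, tanh_c = caches[t]
            dh = dout[t] + dh_next
            do = dh * tanh_c
            dc = dh * o * (1 - tanh_c**2) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dc_next = dc * f
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g**2), do * o * (1 - o)],
                axis=1,
            )
            dWx += xt.T @ dz
            db += dz.sum(axis=0)
            h_prev = caches[t - 1][1] if t > 0 else np.zeros((n, H))
            dWh += h_prev.T @ dz
            dx[t] = dz @ self.params["Wx"].T
            dh_next = dz @ self.params["Wh"].T
        self.grads = {"Wx": dWx, "Wh": dWh, "b": db}
        return dx


class BiLSTMLayer(Layer):
    """Bidirectional LSTM with explicit per-unit direction weights.

    Per-step output ``y_t = w5 * h_fwd_t + w6 * h_bwd_t`` where ``w5`` and
    ``w6`` are learned vectors combining the forward pass over t = 1..T and
    the backward pass over the reversed sequence.
    """

    def __init__(self, input_dim, hidden, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.fwd = LSTM(input_dim, hidden, rng)
        self.bwd = LSTM(input_dim, hidden, rng)
        self.params = {"w5": np.full(hidden, 0.5), "w6": np.full(hidden, 0.5)}
        self.hidden = hidden

    def forward(self, x, train=True):
        hf = self.fwd.forward(x, train)
        hb = self.bwd.forward(x[::-1], train)[::-1]
        self._cache = (hf, hb)
        return self.params["w5"] * hf + self.params["w6"] * hb

    def backward(self, dout):
        hf, hb = self._cache
        self.grads = {
            "w5": (dout * hf).sum(axis=(0, 1)),
            "w6": (dout * hb).sum(axis=(0, 1)),
        }
        dxf = self.fwd.backward(dout * self.params["w5"])
        dxb = self.bwd.backward((dout * self.params["w6"])[::-1])[::-1]
        return dxf + dxb

    @property
    def children(self):
        return [self.fwd, self.bwd]


class Attention(Layer):
    """Additive attention pooling over time: [T, N, H] -> [N, H]."""

    def __init__(self, hidden, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        s = math.sqrt(1.0 / hidden)
        self.params = {
            "Wa": rng.uniform(-s, s, size=(hidden, hidden)),
            "ba": np.zeros(hidden),
            "va": rng.uniform(-s, s, size=hidden),
        }

    def forward(self, x, train=True):
        u = np.tanh(x @ self.params["Wa"] + self.params["ba"])  # [T,N,H]
        e = u @ self.params["va"]  # [T,N]
        alpha = softmax(e, axis=0)
        ctx = (alpha[:, :, None] * x).sum(axis=0)
        self._cache = (x, u, alpha)
        return ctx

    def backward(self, dout):
        x, u, alpha = self._cache
        dalpha = (dout[None, :, :] * x).sum(axis=2)  # [T,N]
        dx = alpha[:, :, None] * dout[None, :, :]
        de = alpha * (dalpha - (dalpha * alpha).sum(axis=0, keepdims=True))
        du = de[:, :, None] * self.params["va"]
        dpre = du * (1 - u**2)
        self.grads = {
            "Wa": np.einsum("tnh,tnk->hk", x, dpre),
            "ba": dpre.sum(axis=(0, 1)),
            "va": (u * de[:, :, None]).sum(axis=(0, 1)),
        }
        dx += np.einsum("tnk,hk->tnh", dpre, self.params["Wa"])
        return dx


class MeanPoolTime(Layer):
    """Mean over the time axis: [T, N, H] -> [N, H]."""

    def forward(self, x, train=True):
        self._T = x.shape[0]
        return x.mean(axis=0)

    def backward(self, dout):
        return np.repeat(dout[None], self._T, axis=0) / self._T


class Dense(Layer):
    def __init__(self, d_in, d_out, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.params = {
            "W": rng.normal(0.0, math.sqrt(2.0 / d_in), size=(d_in, d_out)),
            "b": np.zeros(d_out),
        }

    def forward(self, x, train=True):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads = {"W": self._x.T @ dout, "b": dout.sum(axis=0)}
        return dout @ self.params["W"].T


def bilstm(sequence: np.ndarray, layer: BiLSTMLayer) -> np.ndarray:
    """Functional Bi-LSTM: run ``layer`` over a [T, N, F] (or [T, F]) sequence."""
    seq = np.asarray(sequence, dtype=np.float64)
    if seq.size == 0:
        raise ValueError("sequence is empty")
    squeeze = seq.ndim == 2
    if squeeze:
        seq = seq[:, None, :]
    if seq.shape[2] != layer.fwd.params["Wx"].shape[0]:
        raise ValueError(
            f"feature dimension {seq.shape[2]} does not match layer input "
            f"{layer.fwd.params['Wx'].shape[0]}"
        )
    out = layer.forward(seq, train=False)
    return out[:, 0, :] if squeeze else out


class Adam:
    """Adam optimizer over a flat list of (layer, param-name) entries."""

    def __init__(self, layers, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.entries = []
        for layer in _flatten_layers(layers):
            for name in layer.params:
                self.entries.append((layer, name))
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(l.params[n]) for l, n in self.entries]
        self.v = [np.zeros_like(l.params[n]) for l, n in self.entries]
        self.t = 0

    def step(self):
        self.t += 1
        for i, (layer, name) in enumerate(self.entries):
            g = layer.grads.get(name)
            if g is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            layer.params[name] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _flatten_layers(layers):
    out = []
    for layer in layers:
        out.append(layer)
        if hasattr(layer, "children"):
            out.extend(layer.children)
    return out


def snapshot_params(layers):
    """Deep-copy all parameters and BN running stats of a layer stack."""
    state = []
    for layer in _flatten_layers(layers):
        entry = {"params": copy.deepcopy(layer.params)}
        if isinstance(layer, BatchNorm2D):
            entry["running_mean"] = layer.running_mean.copy()
            entry["running_var"] = layer.running_var.copy()
        state.append(entry)
    return state


def restore_params(layers, state):
    for layer, entry in zip(_flatten_layers(layers), state):
        layer.params = copy.deepcopy(entry["params"])
        if isinstance(layer, BatchNorm2D):
            layer.running_mean = entry["running_mean"].copy()
            layer.running_var = entry["running_var"].copy()
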