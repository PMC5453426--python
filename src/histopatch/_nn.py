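"""Minimal seeded NumPy neural-network backend.

Implements exactly what the default architecture needs: stride-1 square
convolutions (valid/same) via im2col + BLAS matmul, max-pooling with stride
equal to the pooling size, fully-connected layers, ReLU, softmax
cross-entropy, and Adam.  Everything is float32 and fully deterministic for
a fixed seed.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Sequential", "Adam", "softmax"]


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _im2col(x: np.ndarray, k: int) -> tuple[np.ndarray, int, int]:
    """(N, H, W, C) -> ((N*oh*ow, k*k*C) patch matrix, oh, ow), stride-1 windows."""
    n = x.shape[0]
    win = sliding_window_view(x, (k, k), axis=(1, 2))  # (N, oh, ow, C, k, k)
    win = win.transpose(0, 1, 2, 4, 5, 3)  # (N, oh, ow, k, k, C)
    oh, ow = win.shape[1], win.shape[2]
    return win.reshape(n * oh * ow, -1), oh, ow


class _Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class InputScale(_Layer):
    """Multiply inputs by a constant (maps 8-bit pixel scale to ~unit range)."""

    def __init__(self, scale: float) -> None:
        super().__init__()
        self.scale = np.float32(scale)

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x * self.scale

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self.scale


class Conv2D(_Layer):
    """Stride-1 square convolution, padding 'valid' or 'same', optional ReLU."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, padding: str,
                 relu: bool, rng: np.random.Generator) -> None:
        super().__init__()
        if padding not in ("valid", "same"):
            raise ValueError(padding)
        self.k = kernel
        self.pad = (kernel - 1) // 2 if padding == "same" else 0
        self.relu = relu
        fan_in = kernel * kernel * in_ch
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(kernel * kernel * in_ch, out_ch))
        self.params = [w.astype(np.float32), np.zeros(out_ch, dtype=np.float32)]
        self.grads = [np.zeros_like(p) for p in self.params]

    def _padded(self, x: np.ndarray, pad: int) -> np.ndarray:
        if pad == 0:
            return x
        return np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        w, b = self.params
        xp = self._padded(x, self.pad)
        cols, oh, ow = _im2col(xp, self.k)
        out = (cols @ w + b).reshape(x.shape[0], oh, ow, -1)
        if self.relu:
            self._mask = out > 0
            out = np.where(self._mask, out, 0.0)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self.relu:
            dout = np.where(self._mask, dout, 0.0)
        w, _ = self.params
        n, oh, ow, f = dout.shape
        dflat = dout.reshape(-1, f)
        xp = self._padded(self._x, self.pad)
        cols, _, _ = _im2col(xp, self.k)
        self.grads[0][...] = cols.T @ dflat
        self.grads[1][...] = dflat.sum(axis=0)
        # dx: full correlation of dout with the flipped kernel
        k = self.k
        in_ch = self._x.shape[3]
        w4 = w.reshape(k, k, in_ch, f)
        w_rot = w4[::-1, ::-1].transpose(0, 1, 3, 2).reshape(k * k * f, in_ch)
        dpad = self._padded(dout, k - 1 - self.pad)
        dcols, dh, dw_ = _im2col(dpad, k)
        dx = (dcols @ w_rot).reshape(n, dh, dw_, in_ch)
        return dx


class MaxPool2D(_Layer):
    """Max pooling with stride equal to the pooling size (excess rows cropped)."""

    def __init__(self, size: int) -> None:
        super().__init__()
        self.s = size

    def forward(self, x: np.ndarray) -> np.ndarray:
        s = self.s
        n, h, w, c = x.shape
        oh, ow = h // s, w // s
        xc = x[:, : oh * s, : ow * s, :]
        win = xc.reshape(n, oh, s, ow, s, c).transpose(0, 1, 3, 5, 2, 4).reshape(
            n, oh, ow, c, s * s
        )
        self._arg = win.argmax(axis=-1)
        self._in_shape = x.shape
        return np.take_along_axis(win, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        s = self.s
        n, oh, ow, c = dout.shape
        dwin = np.zeros((n, oh, ow, c, s * s), dtype=dout.dtype)
        np.put_along_axis(dwin, self._arg[..., None], dout[..., None], axis=-1)
        dx_c = dwin.reshape(n, oh, ow, c, s, s).transpose(0, 1, 4, 2, 5, 3).reshape(
            n, oh * s, ow * s, c
        )
        dx = np.zeros(self._in_shape, dtype=dout.dtype)
        dx[:, : oh * s, : ow * s, :] = dx_c
        return dx


class Flatten(_Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Dense(_Layer):
    def __init__(self, n_in: int, n_out: int, relu: bool, rng: np.random.Generator) -> None:
        super().__init__()
        self.relu = relu
        w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.params = [w.astype(np.float32), np.zeros(n_out, dtype=np.float32)]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        w, b = self.params
        out = x @ w + b
        if self.relu:
            self._mask = out > 0
            out = np.where(self._mask, out, 0.0)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self.relu:
            dout = np.where(self._mask, dout, 0.0)
        w, _ = self.params
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ w.T


class Adam:
    """Adam optimizer; a standard per-parameter adaptive-learning-rate scheme."""

    def __init__(self, learning_rate: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.lr = learning_rate
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self._m: dict[int, np.ndarray] = {}
        self._v: dict[int, np.ndarray] = {}
        self._t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self._t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (p, g) in enumerate(zip(params, grads)):
            m = self._m.setdefault(i, np.zeros_like(p))
            v = self._v.setdefault(i, np.zeros_like(p))
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            mhat = m / (1 - b1 ** self._t)
            vhat = v / (1 - b2 ** self._t)
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)


class Sequential:
    """A feed-forward stack built from an :class:`ArchitectureSpec`.

    The final dense layer emits logits; :meth:`predict_proba` applies the
    softmax.  ``spec_layer_ends[i]`` is the index (exclusive) into
    ``self.layers`` at which spec layer ``i`` finishes, so activations can be
    read out per spec layer (e.g. the second fully-connected layer).
    """

    def __init__(self, layers: list[_Layer], spec, spec_layer_ends: list[int]) -> None:
        self.layers = layers
        self.spec = spec
        self.spec_layer_ends = spec_layer_ends

    @classmethod
    def from_spec(cls, spec, seed: int) -> "Sequential":
        from histopatch.network_architecture import propagate_shapes

        rng = np.random.default_rng(seed)
        traces, _ = propagate_shapes(spec)
        # centered 8-bit inputs arrive at +/- ~255; bring them to unit range
        layers: list[_Layer] = [InputScale(1.0 / 255.0)]
        ends: list[int] = []
        in_ch = spec.input_shape[2]
        flat_in: int | None = None
        prev_shape = (spec.input_shape[2], spec.input_shape[0], spec.input_shape[1])
        for trace in traces:
            ls = trace.spec
            if ls.kind == "conv":
                layers.append(
                    Conv2D(in_ch, ls.maps_or_units, ls.kernel, ls.padding,
                           relu=(ls.activation == "relu"), rng=rng)
                )
                in_ch = ls.maps_or_units
            elif ls.kind == "maxpool":
                layers.append(MaxPool2D(ls.kernel))
            else:
                if flat_in is None:
                    flat_in = int(np.prod(prev_shape))
                    layers.append(Flatten())
                layers.append(
                    Dense(flat_in, ls.maps_or_units, relu=(ls.activation == "relu"), rng=rng)
                )
                flat_in = ls.maps_or_units
            prev_shape = trace.output_shape
            ends.append(len(layers))
        return cls(layers, spec, ends)

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def predict_proba(self, x: np.ndarray, batch_size: int = 16) -> np.ndarray:
        outs = []
        for i in range(0, x.shape[0], batch_size):
            outs.append(softmax(self.forward(x[i : i + batch_size].astype(np.float32))))
        return np.concatenate(outs, axis=0)

    def activations_at_spec_layer(self, x: np.ndarray, spec_layer_index: int,
                                  batch_size: int = 16) -> np.ndarray:
        """Post-activation output of spec layer ``spec_layer_index`` (0-based)."""
        end = self.spec_layer_ends[spec_layer_index]
        outs = []
        for i in range(0, x.shape[0], batch_size):
            h = x[i : i + batch_size].astype(np.float32)
            for layer in self.layers[:end]:
                h = layer.forward(h)
            outs.append(h)
        return np.concatenate(outs, axis=0)

    def train_batch(self, x: np.ndarray, y: np.ndarray, optimizer: Adam) -> float:
        """One gradient step on (x, y); returns the batch cross-entropy loss."""
        logits = self.forward(x.astype(np.float32))
        probs = softmax(logits)
        n = x.shape[0]
        eps = 1e-12
        loss = float(-np.log(probs[np.arange(n), y] + eps).mean())
        dlogits = probs.copy()
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n
        grad = dlogits.astype(np.float32)
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        params = [p for l in self.layers for p in l.params]
        grads = [g for l in self.layers for g in l.grads]
        optimizer.step(params, grads)
        return loss

    def loss_only(self, x: np.ndarray, y: np.ndarray) -> float:
        probs = self.predict_proba(x)
        return float(-np.log(probs[np.arange(x.shape[0]), y] + 1e-12).mean())

    # -- weights ------------------------------------------------------------

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for l in self.layers for p in l.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        flat = [p for l in self.layers for p in l.params]
        if len(flat) != len(weights):
            raise ValueError("weight count mismatch")
        for p, w in zip(flat, weights):
            p[...] = w

    def shape_trace(self) -> list[tuple[int, ...]]:
        """Per-spec-layer output shapes measured by a dummy forward pass."""
        h, w, c = self.spec.input_shape
        x = np.zeros((1, h, w, c), dtype=np.float32)
        shapes: list[tuple[int, ...]] = []
        idx = 0
        for end in self.spec_layer_ends:
            for layer in self.layers[idx:end]:
                x = layer.forward(x)
            idx = end
            if x.ndim == 4:
                shapes.append((x.shape[3], x.shape[1], x.shape[2]))
            else:
                shapes.append((x.shape[1],))
        return shapes
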