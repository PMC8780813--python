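"""A compact numpy convolutional network for expression images.

Layer pattern: two valid-padded convolutions with ReLU, one max-pool
subsampling layer, one fully-connected ReLU layer, and a softmax output —
trained with minibatch SGD + momentum on cross-entropy. Kernels larger
than the current feature map are clipped to it so degenerate inputs
(e.g. single-gene 1×1 images) still train.

Everything is deterministic given the seed: He-normal initialisation and
minibatch shuffling both come from one ``numpy.random.default_rng``.
"""

from __future__ import annotations

import numpy as np

from .errors import ArgumentError


def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """(N, C, H, W) → (N, out_h, out_w, C*kh*kw) patch matrix, stride 1."""
    n, c, h, w = x.shape
    out_h, out_w = h - kh + 1, w - kw + 1
    s0, s1, s2, s3 = x.strides
    patches = np.lib.stride_tricks.as_strided(
        x, shape=(n, c, out_h, out_w, kh, kw),
        strides=(s0, s1, s2, s3, s2, s3), writeable=False,
    )
    return patches.transpose(0, 2, 3, 1, 4, 5).reshape(n, out_h, out_w, c * kh * kw)


class _Conv:
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        fan_in = c_in * k * k
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, k, k))
        self.b = np.zeros(c_out)
        self.k = k
        self.vw = np.zeros_like(self.w)
        self.vb = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self.x_shape = x.shape
        self.cols = _im2col(x, self.k, self.k)  # (N, oh, ow, C*k*k)
        wm = self.w.reshape(self.w.shape[0], -1)  # (c_out, C*k*k)
        out = self.cols @ wm.T + self.b  # (N, oh, ow, c_out)
        return out.transpose(0, 3, 1, 2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        # grad: (N, c_out, oh, ow)
        g = grad.transpose(0, 2, 3, 1)  # (N, oh, ow, c_out)
        wm = self.w.reshape(self.w.shape[0], -1)
        self.gw = np.tensordot(g, self.cols, axes=([0, 1, 2], [0, 1, 2])).reshape(
            self.w.shape
        )
        self.gb = g.sum(axis=(0, 1, 2))
        gcols = g @ wm  # (N, oh, ow, C*k*k)
        n, c, h, w = self.x_shape
        oh, ow = h - self.k + 1, w - self.k + 1
        gx = np.zeros((n, c, h, w))
        gcols = gcols.reshape(n, oh, ow, c, self.k, self.k)
        for di in range(self.k):
            for dj in range(self.k):
                gx[:, :, di : di + oh, dj : dj + ow] += gcols[
                    :, :, :, :, di, dj
                ].transpose(0, 3, 1, 2)
        return gx

    def step(self, lr: float, momentum: float) -> None:
        self.vw = momentum * self.vw - lr * self.gw
        self.vb = momentum * self.vb - lr * self.gb
        self.w += self.vw
        self.b += self.vb


class _MaxPool:
    def __init__(self, window: int, stride: int):
        self.window, self.stride = window, stride

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        k, s = self.window, self.stride
        oh, ow = (h - k) // s + 1, (w - k) // s + 1
        self.x_shape = x.shape
        s0, s1, s2, s3 = x.strides
        win = np.lib.stride_tricks.as_strided(
            x, shape=(n, c, oh, ow, k, k),
            strides=(s0, s1, s2 * s, s3 * s, s2, s3), writeable=False,
        ).reshape(n, c, oh, ow, k * k)
        self.argmax = win.argmax(axis=-1)
        return win.max(axis=-1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self.x_shape
        k, s = self.window, self.stride
        oh, ow = grad.shape[2], grad.shape[3]
        gx = np.zeros((n, c, h, w))
        di, dj = np.divmod(self.argmax, k)
        ii = np.arange(oh)[None, None, :, None] * s + di
        jj = np.arange(ow)[None, None, None, :] * s + dj
        nn = np.arange(n)[:, None, None, None]
        cc = np.arange(c)[None, :, None, None]
        np.add.at(gx, (nn, cc, ii, jj), grad)
        return gx


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.vw = np.zeros_like(self.w)
        self.vb = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self.x = x
        return x @ self.w + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.gw = self.x.T @ grad
        self.gb = grad.sum(axis=0)
        return grad @ self.w.T

    def step(self, lr: float, momentum: float) -> None:
        self.vw = momentum * self.vw - lr * self.gw
        self.vb = momentum * self.vb - lr * self.gb
        self.w += self.vw
        self.b += self.vb


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class ConvNet:
    """conv-ReLU → conv-ReLU → max-pool → dense-ReLU → softmax."""

    def __init__(
        self,
        side: int,
        n_classes: int,
        conv_layers: tuple[tuple[int, int], ...] = ((5, 8), (3, 16)),
        pool: tuple[int, int] = (2, 2),
        dense_size: int = 120,
        seed: int = 0,
    ):
        if side < 1:
            raise ArgumentError("image side must be >= 1")
        if n_classes < 2:
            raise ArgumentError("need at least 2 classes")
        rng = np.random.default_rng(seed)
        self.side, self.n_classes = side, n_classes
        self.convs: list[_Conv] = []
        c_in, spatial = 1, side
        for k, c_out in conv_layers:
            k_eff = min(k, spatial)  # clip kernels on tiny feature maps
            self.convs.append(_Conv(c_in, c_out, k_eff, rng))
            spatial = spatial - k_eff + 1
            c_in = c_out
        pw, ps = pool
        if spatial >= pw:
            self.pool: _MaxPool | None = _MaxPool(pw, ps)
            spatial = (spatial - pw) // ps + 1
        else:
            self.pool = None
        flat = c_in * spatial * spatial
        self.fc1 = _Dense(flat, dense_size, rng)
        self.fc2 = _Dense(dense_size, n_classes, rng)
        self._rng = rng

    def _forward(self, x: np.ndarray, keep: bool = True) -> np.ndarray:
        h = x
        self._relu_masks = []
        for conv in self.convs:
            h = conv.forward(h)
            mask = h > 0
            h = h * mask
            self._relu_masks.append(mask)
        if self.pool is not None:
            h = self.pool.forward(h)
        self._pre_flat_shape = h.shape
        h = h.reshape(h.shape[0], -1)
        h = self.fc1.forward(h)
        self._fc_mask = h > 0
        h = h * self._fc_mask
        return self.fc2.forward(h)

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        x = self._as_input(images)
        return _softmax(self._forward(x))

    def _as_input(self, images: np.ndarray) -> np.ndarray:
        x = np.asarray(images, dtype=float)
        if x.ndim == 3:
            x = x[:, None, :, :]
        if x.shape[2] != self.side or x.shape[3] != self.side:
            raise ArgumentError(
                f"expected {self.side}x{self.side} images, got "
                f"{x.shape[2]}x{x.shape[3]}"
            )
        return x

    def fit(
        self,
        images: np.ndarray,
        y: np.ndarray,
        epochs: int,
        learning_rate: float,
        momentum: float = 0.9,
        batch_size: int = 32,
    ) -> list[dict]:
        """Train; returns a per-epoch log of loss and training accuracy."""
        if epochs < 1:
            raise ArgumentError("epochs must be >= 1")
        x = self._as_input(images)
        y = np.asarray(y, dtype=int)
        n = x.shape[0]
        onehot = np.eye(self.n_classes)[y]
        log: list[dict] = []
        for epoch in range(epochs):
            order = self._rng.permutation(n)
            losses = []
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                xb, yb = x[idx], onehot[idx]
                logits = self._forward(xb)
                p = _softmax(logits)
                losses.append(-np.mean(np.log(p[np.arange(len(idx)), y[idx]] + 1e-12)))
                grad = (p - yb) / len(idx)
                g = self.fc2.backward(grad)
                g = g * self._fc_mask
                g = self.fc1.backward(g)
                g = g.reshape(self._pre_flat_shape)
                if self.pool is not None:
                    g = self.pool.backward(g)
                for conv, mask in zip(reversed(self.convs), reversed(self._relu_masks)):
                    g = g * mask
                    g = conv.backward(g)
                for layer in (*self.convs, self.fc1, self.fc2):
                    layer.step(learning_rate, momentum)
            acc = float(np.mean(self.predict_proba(x).argmax(axis=1) == y))
            log.append({"epoch": epoch + 1, "loss": float(np.mean(losses)),
                        "train_accuracy": acc})
        return log
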