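"""A compact convolutional network for posture-image classification.

The classification task here is small and well-conditioned - tens-of-
pixels grey-scale images of three clearly distinct pressure distributions
- so a deliberately small network suffices: one 3x3 valid convolution,
ReLU, 2x2 max-pooling, one hidden dense layer and a softmax output,
trained with Adam on cross-entropy.  The implementation is plain numpy
with explicit forward/backward passes, which keeps training bit-
reproducible from a seed and lets the gradients be checked numerically in
the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .frames import ValidationError


@dataclass(frozen=True)
class CNNConfig:
    """Architecture and training hyper-parameters.

    Defaults are sized for CPU training in seconds to minutes; none of
    them encodes anything about the source data beyond "small grey-scale
    images, few classes".
    """

    channels: int = 8
    kernel: int = 3
    hidden: int = 32
    epochs: int = 20
    batch_size: int = 32
    learning_rate: float = 1e-3


class SmallCNN:
    """conv(k x k, C) -> ReLU -> maxpool(2x2) -> dense(H) -> ReLU -> softmax.

    Images smaller than the pooling window in either direction skip the
    pooling step, so the network accepts any input from (kernel+1)^2 up.
    All randomness (init, batch order) flows from ``seed``.
    """

    def __init__(
        self,
        input_shape: tuple[int, int],
        n_classes: int,
        config: CNNConfig | None = None,
        seed: int = 0,
    ) -> None:
        self.config = config or CNNConfig()
        self.input_shape = tuple(input_shape)
        self.n_classes = int(n_classes)
        k, c = self.config.kernel, self.config.channels
        h_in, w_in = self.input_shape
        if h_in < k or w_in < k:
            raise ValidationError(
                f"input {self.input_shape} smaller than the {k}x{k} kernel"
            )
        self.conv_out = (h_in - k + 1, w_in - k + 1)
        ho, wo = self.conv_out
        self.do_pool = ho >= 2 and wo >= 2
        self.pool_out = (ho // 2, wo // 2) if self.do_pool else (ho, wo)
        n_flat = self.pool_out[0] * self.pool_out[1] * c

        self.rng = np.random.default_rng(seed)
        rng = self.rng
        self.params = {
            "Wc": rng.normal(0.0, np.sqrt(2.0 / (k * k)), size=(k * k, c)),
            "bc": np.zeros(c),
            "W1": rng.normal(0.0, np.sqrt(2.0 / n_flat), size=(n_flat, self.config.hidden)),
            "b1": np.zeros(self.config.hidden),
            "W2": rng.normal(
                0.0, np.sqrt(2.0 / self.config.hidden),
                size=(self.config.hidden, self.n_classes),
            ),
            "b2": np.zeros(self.n_classes),
        }
        self._adam_m = {k_: np.zeros_like(v) for k_, v in self.params.items()}
        self._adam_v = {k_: np.zeros_like(v) for k_, v in self.params.items()}
        self._adam_t = 0

    # ---- forward / backward -------------------------------------------------

    def _forward(self, x: np.ndarray) -> dict:
        k = self.config.kernel
        cols = sliding_window_view(x, (k, k), axis=(1, 2))
        n, ho, wo = cols.shape[:3]
        cols = cols.reshape(n, ho, wo, k * k)
        conv_pre = cols @ self.params["Wc"] + self.params["bc"]
        conv = np.maximum(conv_pre, 0.0)
        if self.do_pool:
            hp, wp = self.pool_out
            windows = (
                conv[:, : hp * 2, : wp * 2, :]
                .reshape(n, hp, 2, wp, 2, -1)
                .transpose(0, 1, 3, 2, 4, 5)
                .reshape(n, hp, wp, 4, -1)
            )
            argmax = windows.argmax(axis=3)
            pooled = np.take_along_axis(windows, argmax[:, :, :, None, :], axis=3)[
                :, :, :, 0, :
            ]
        else:
            windows = argmax = None
            pooled = conv
        flat = pooled.reshape(n, -1)
        z1 = flat @ self.params["W1"] + self.params["b1"]
        h = np.maximum(z1, 0.0)
        logits = h @ self.params["W2"] + self.params["b2"]
        logits = logits - logits.max(axis=1, keepdims=True)
        exp = np.exp(logits)
        proba = exp / exp.sum(axis=1, keepdims=True)
        return {
            "cols": cols,
            "conv_pre": conv_pre,
            "argmax": argmax,
            "flat": flat,
            "z1": z1,
            "h": h,
            "proba": proba,
        }

    def loss_and_grads(
        self, x: np.ndarray, y: np.ndarray
    ) -> tuple[float, dict[str, np.ndarray]]:
        """Mean cross-entropy and its gradient w.r.t. every parameter."""
        n = len(x)
        cache = self._forward(x)
        proba = cache["proba"]
        eps = 1e-12
        loss = -float(np.mean(np.log(proba[np.arange(n), y] + eps)))

        dlogits = proba.copy()
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n

        grads = {}
        grads["W2"] = cache["h"].T @ dlogits
        grads["b2"] = dlogits.sum(axis=0)
        dh = dlogits @ self.params["W2"].T
        dz1 = dh * (cache["z1"] > 0)
        grads["W1"] = cache["flat"].T @ dz1
        grads["b1"] = dz1.sum(axis=0)
        dflat = dz1 @ self.params["W1"].T

        c = self.config.channels
        hp, wp = self.pool_out
        dpooled = dflat.reshape(n, hp, wp, c)
        if self.do_pool:
            ho, wo = self.conv_out
            dwindows = np.zeros((n, hp, wp, 4, c))
            np.put_along_axis(
                dwindows, cache["argmax"][:, :, :, None, :], dpooled[:, :, :, None, :], axis=3
            )
            dconv = np.zeros((n, ho, wo, c))
            dconv[:, : hp * 2, : wp * 2, :] = (
                dwindows.reshape(n, hp, wp, 2, 2, c)
                .transpose(0, 1, 3, 2, 4, 5)
                .reshape(n, hp * 2, wp * 2, c)
            )
        else:
            dconv = dpooled
        dconv_pre = dconv * (cache["conv_pre"] > 0)
        k = self.config.kernel
        cols_flat = cache["cols"].reshape(-1, k * k)
        grads["Wc"] = cols_flat.T @ dconv_pre.reshape(-1, c)
        grads["bc"] = dconv_pre.reshape(-1, c).sum(axis=0)
        return loss, grads

    # ---- training / inference -----------------------------------------------

    def _adam_step(self, grads: dict[str, np.ndarray]) -> None:
        self._adam_t += 1
        lr, b1, b2, eps = self.config.learning_rate, 0.9, 0.999, 1e-8
        for name, g in grads.items():
            m = self._adam_m[name] = b1 * self._adam_m[name] + (1 - b1) * g
            v = self._adam_v[name] = b2 * self._adam_v[name] + (1 - b2) * g * g
            m_hat = m / (1 - b1**self._adam_t)
            v_hat = v / (1 - b2**self._adam_t)
            self.params[name] -= lr * m_hat / (np.sqrt(v_hat) + eps)

    def fit(self, x: np.ndarray, y: np.ndarray) -> "SmallCNN":
        """Train on images ``x`` (N, H, W), scaled to [0, 1], labels ``y``."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=int)
        if x.ndim != 3 or x.shape[1:] != self.input_shape:
            raise ValidationError(
                f"expected images of shape {self.input_shape}, got {x.shape}"
            )
        n = len(x)
        for _ in range(self.config.epochs):
            order = self.rng.permutation(n)
            for start in range(0, n, self.config.batch_size):
                idx = order[start : start + self.config.batch_size]
                _, grads = self.loss_and_grads(x[idx], y[idx])
                self._adam_step(grads)
        return self

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        # bound peak memory on large inputs
        out = [self._forward(x[i : i + 256])["proba"] for i in range(0, len(x), 256)]
        return np.concatenate(out)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.predict_proba(x).argmax(axis=1)
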