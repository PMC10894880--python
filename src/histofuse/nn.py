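"""Minimal numpy CNN used as the default desk-scale patch backbone.

Three 3x3 convolution blocks, global average pooling, and a linear softmax
head, with hand-written backpropagation.  The convolutional stack is the
"backbone" parameter group and the linear head the "task" group, so the two
learning-rate schedules can drive them independently.  Deliberately small:
it exists so the full training/prediction/Grad-CAM contract runs on one CPU
in seconds, not to compete with large pretrained architectures.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

__all__ = ["SmallCNN", "softmax", "cross_entropy"]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(probs: np.ndarray, y: np.ndarray) -> float:
    return float(-np.log(np.maximum(probs[np.arange(len(y)), y], 1e-12)).mean())


def _im2col(x: np.ndarray, k: int = 3, pad: int = 1) -> np.ndarray:
    """(N,C,H,W) -> (N, H*W, C*k*k) patch matrix for stride-1 convolution."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    # win: (N, C, H, W, k, k) -> (N, H, W, C, k, k)
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(n, h * w, c * k * k)


class _Conv:
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, k: int = 3):
        self.k = k
        scale = np.sqrt(2.0 / (c_in * k * k))  # He init
        self.W = rng.standard_normal((c_out, c_in * k * k)) * scale
        self.b = np.zeros(c_out)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self.x_shape = x.shape
        self.cols = _im2col(x, self.k, self.k // 2)
        n, _, h, w = x.shape
        out = self.cols @ self.W.T + self.b  # (N, HW, C_out)
        return out.transpose(0, 2, 1).reshape(n, -1, h, w)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c_in, h, w = self.x_shape
        k, pad = self.k, self.k // 2
        d2 = dout.reshape(n, -1, h * w).transpose(0, 2, 1)  # (N, HW, C_out)
        self.dW = np.einsum("npf,npc->fc", d2, self.cols)
        self.db = d2.sum(axis=(0, 1))
        dcols = (d2 @ self.W).reshape(n, h, w, c_in, k, k)
        dxp = np.zeros((n, c_in, h + 2 * pad, w + 2 * pad))
        for di in range(k):
            for dj in range(k):
                dxp[:, :, di:di + h, dj:dj + w] += dcols[:, :, :, :, di, dj].transpose(
                    0, 3, 1, 2)
        return dxp[:, :, pad:pad + h, pad:pad + w]


class _ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self.mask = x > 0
        return x * self.mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self.mask


class _MaxPool2:
    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        self.x_shape = x.shape
        xw = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xw = xw.reshape(n, c, h // 2, w // 2, 4)
        self.am = xw.argmax(axis=-1)
        return np.take_along_axis(xw, self.am[..., None], axis=-1)[..., 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self.x_shape
        dxw = np.zeros((n, c, h // 2, w // 2, 4))
        np.put_along_axis(dxw, self.am[..., None], dout[..., None], axis=-1)
        dxw = dxw.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dxw.reshape(n, c, h, w)


class SmallCNN:
    """conv-relu-pool ×2, conv-relu, GAP, linear — softmax classifier.

    The post-ReLU output of the last convolution is the Grad-CAM target
    activation; with GAP + linear on top, the class gradient at that layer
    is constant per channel, which keeps Grad-CAM exact and cheap.
    """

    def __init__(self, n_classes: int, input_size: int = 32,
                 channels: tuple[int, int, int] = (8, 16, 32), seed: int = 0):
        if input_size % 4 != 0:
            raise ValueError("input_size must be divisible by 4")
        rng = np.random.default_rng(seed)
        self.n_classes = n_classes
        self.input_size = input_size
        self.channels = tuple(channels)
        c1, c2, c3 = channels
        self.conv1, self.conv2, self.conv3 = (
            _Conv(3, c1, rng), _Conv(c1, c2, rng), _Conv(c2, c3, rng))
        self.relu1, self.relu2, self.relu3 = _ReLU(), _ReLU(), _ReLU()
        self.pool1, self.pool2 = _MaxPool2(), _MaxPool2()
        # Zero-init head + frozen feature standardization: conditions the
        # linear problem so plain SGD converges while the backbone is frozen.
        self.head_W = np.zeros((n_classes, c3))
        self.head_b = np.zeros(n_classes)
        self.feat_mu = np.zeros(c3)
        self.feat_sd = np.ones(c3)

    # -- forward / backward --------------------------------------------------

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (N, H, W, 3) float in [0,1] (or standardized) -> logits (N, K)."""
        z = np.ascontiguousarray(x.transpose(0, 3, 1, 2), dtype=float)
        z = self.pool1.forward(self.relu1.forward(self.conv1.forward(z)))
        z = self.pool2.forward(self.relu2.forward(self.conv2.forward(z)))
        self.last_conv = self.relu3.forward(self.conv3.forward(z))  # (N,C3,h,w)
        self.gap = (self.last_conv.mean(axis=(2, 3)) - self.feat_mu) / self.feat_sd
        return self.gap @ self.head_W.T + self.head_b

    def backward(self, dlogits: np.ndarray) -> None:
        self.d_head_W = dlogits.T @ self.gap
        self.d_head_b = dlogits.sum(axis=0)
        n, c, h, w = self.last_conv.shape
        dgap = (dlogits @ self.head_W) / self.feat_sd
        dconv = np.broadcast_to(dgap[:, :, None, None] / (h * w), (n, c, h, w))
        d = self.conv3.backward(self.relu3.backward(dconv))
        d = self.conv2.backward(self.relu2.backward(self.pool2.backward(d)))
        self.conv1.backward(self.relu1.backward(self.pool1.backward(d)))

    def sgd_step(self, lr_task: float, lr_backbone: float,
                 momentum: float = 0.9, max_grad_norm: float = 1.0) -> None:
        if not hasattr(self, "_vel"):
            self._vel = {}
        grads = [self.conv1.dW, self.conv1.db, self.conv2.dW, self.conv2.db,
                 self.conv3.dW, self.conv3.db, self.d_head_W, self.d_head_b]
        gnorm = np.sqrt(sum(float((g * g).sum()) for g in grads))
        clip = min(1.0, max_grad_norm / gnorm) if gnorm > 0 else 1.0
        for name, p, g, lr in (
            [(f"conv{i}W", c.W, c.dW, lr_backbone)
             for i, c in enumerate((self.conv1, self.conv2, self.conv3))]
            + [(f"conv{i}b", c.b, c.db, lr_backbone)
               for i, c in enumerate((self.conv1, self.conv2, self.conv3))]
            + [("headW", self.head_W, self.d_head_W, lr_task),
               ("headb", self.head_b, self.d_head_b, lr_task)]
        ):
            if lr == 0.0:
                continue  # frozen group: no step, no velocity accumulation
            v = self._vel.get(name)
            if v is None:
                v = np.zeros_like(p)
            v = momentum * v + clip * g
            self._vel[name] = v
            p -= lr * v

    def fit_feature_norm(self, x: np.ndarray, batch_size: int = 128) -> None:
        """Freeze GAP-feature mean/std from (a sample of) the training set."""
        self.feat_mu = np.zeros(self.channels[-1])
        self.feat_sd = np.ones(self.channels[-1])
        feats = []
        for i in range(0, len(x), batch_size):
            self.forward(x[i:i + batch_size])
            feats.append(self.gap.copy())
        f = np.vstack(feats)
        # Per-channel centering with one global scale: whitening individual
        # near-dead channels would amplify their gradients unboundedly.
        self.feat_mu = f.mean(axis=0)
        scale = max(float((f - self.feat_mu).std()), 1e-6)
        self.feat_sd = np.full(f.shape[1], scale)

    # -- inference helpers ---------------------------------------------------

    def predict_proba(self, x: np.ndarray, batch_size: int = 128) -> np.ndarray:
        out = [softmax(self.forward(x[i:i + batch_size]))
               for i in range(0, len(x), batch_size)]
        return np.vstack(out)

    def gradcam(self, x: np.ndarray, target_class: int) -> np.ndarray:
        """Class-activation map at the last conv layer for one image.

        Returns the (h, w) non-negative map before upsampling, max-normalized
        to [0, 1] when non-zero.
        """
        self.forward(x[None] if x.ndim == 3 else x)
        acts = self.last_conv[0]                      # (C3, h, w)
        h, w = acts.shape[1:]
        # d logit_c / d act_k is head_W[c, k] / (feat_sd_k * h * w) everywhere
        # (GAP + frozen standardization + linear).
        alpha = self.head_W[target_class] / (self.feat_sd * h * w)
        cam = np.maximum((alpha[:, None, None] * acts).sum(axis=0), 0.0)
        if cam.max() > 0:
            cam = cam / cam.max()
        return cam

    # -- serialization -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = {
            "conv1_W": self.conv1.W, "conv1_b": self.conv1.b,
            "conv2_W": self.conv2.W, "conv2_b": self.conv2.b,
            "conv3_W": self.conv3.W, "conv3_b": self.conv3.b,
            "head_W": self.head_W, "head_b": self.head_b,
            "feat_mu": self.feat_mu, "feat_sd": self.feat_sd,
        }
        np.savez(path.with_suffix(".npz"), **arrays)
        meta = {"n_classes": self.n_classes, "input_size": self.input_size,
                "channels": list(self.channels)}
        path.with_suffix(".json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path: str | Path) -> "SmallCNN":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        model = cls(meta["n_classes"], meta["input_size"], tuple(meta["channels"]))
        with np.load(path.with_suffix(".npz")) as z:
            model.conv1.W, model.conv1.b = z["conv1_W"], z["conv1_b"]
            model.conv2.W, model.conv2.b = z["conv2_W"], z["conv2_b"]
            model.conv3.W, model.conv3.b = z["conv3_W"], z["conv3_b"]
            model.head_W, model.head_b = z["head_W"], z["head_b"]
            model.feat_mu, model.feat_sd = z["feat_mu"], z["feat_sd"]
        return model
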