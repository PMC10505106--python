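"""A small convolutional encoder-decoder with a non-negative evidence head.

Pure-numpy implementation with hand-written backpropagation.  All spatial
operators are expressed as matrix multiplications (im2col patches for the
3x3 convolutions; the input gradient of a convolution is itself a
convolution with the flipped, transposed kernel), so no scatter-add is
needed and the whole pass stays vectorized.

The architecture is a three-level U-Net: two 3x3 conv + ReLU blocks per
level, 2x average pooling down, nearest-neighbour upsampling with skip
concatenation up, and a final 1x1 convolution through a ReLU — the evidence
head.  There is no softmax or sigmoid anywhere on the output path: the head
emits non-negative evidence per class, which parameterizes the voxelwise
Dirichlet distribution downstream.
"""

from __future__ import annotations

import numpy as np

__all__ = ["EvidenceNet", "Adam"]


def _conv3_fwd(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """Same-padded 3x3 convolution. x: (C,H,W), w: (O,C,3,3) -> (O,H,W)."""
    c, h, wd = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1)))
    patches = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(1, 2))
    cols = patches.transpose(1, 2, 0, 3, 4).reshape(h * wd, c * 9)
    out = cols @ w.reshape(w.shape[0], -1).T + b
    return out.reshape(h, wd, -1).transpose(2, 0, 1), cols


def _conv3_bwd(gout: np.ndarray, cols: np.ndarray, w: np.ndarray, need_gx: bool = True):
    """Gradients of the same-padded 3x3 convolution."""
    o, h, wd = gout.shape
    g2 = gout.reshape(o, -1).T  # (HW, O)
    gw = (g2.T @ cols).reshape(w.shape)
    gb = g2.sum(axis=0)
    gx = None
    if need_gx:
        w_flip = np.ascontiguousarray(w[:, :, ::-1, ::-1].transpose(1, 0, 2, 3))
        gx, _ = _conv3_fwd(gout, w_flip, np.zeros(w_flip.shape[0], dtype=w.dtype))
    return gx, gw, gb


def _pool2(x: np.ndarray) -> np.ndarray:
    c, h, w = x.shape
    return x.reshape(c, h // 2, 2, w // 2, 2).mean(axis=(2, 4))


def _pool2_bwd(g: np.ndarray) -> np.ndarray:
    c, h, w = g.shape
    return np.repeat(np.repeat(g, 2, axis=1), 2, axis=2) * 0.25


def _up2(x: np.ndarray) -> np.ndarray:
    return np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)


def _up2_bwd(g: np.ndarray) -> np.ndarray:
    c, h, w = g.shape
    return g.reshape(c, h // 2, 2, w // 2, 2).sum(axis=(2, 4))


class EvidenceNet:
    """Three-level 2D encoder-decoder emitting K non-negative evidence maps."""

    def __init__(self, in_channels: int, n_classes: int, width: int = 8, seed: int = 0):
        if n_classes < 2:
            raise ValueError("need at least 2 output classes")
        if width < 1:
            raise ValueError("width must be positive")
        self.in_channels = in_channels
        self.n_classes = n_classes
        self.width = width
        w = width
        # (name, in_ch, out_ch, kernel)
        self._spec = [
            ("enc1a", in_channels, w, 3),
            ("enc1b", w, w, 3),
            ("enc2a", w, 2 * w, 3),
            ("enc2b", 2 * w, 2 * w, 3),
            ("botta", 2 * w, 4 * w, 3),
            ("bottb", 4 * w, 4 * w, 3),
            ("dec2a", 6 * w, 2 * w, 3),
            ("dec2b", 2 * w, 2 * w, 3),
            ("dec1a", 3 * w, w, 3),
            ("dec1b", w, w, 3),
            ("head", w, n_classes, 1),
        ]
        rng = np.random.default_rng(seed)
        self.params = {}
        for name, cin, cout, k in self._spec:
            fan_in = cin * k * k
            scale = np.sqrt(2.0 / fan_in)
            self.params[name] = [
                (rng.standard_normal((cout, cin, k, k)) * scale).astype(np.float32),
                np.zeros(cout, dtype=np.float32),
            ]

    # -- persistence -------------------------------------------------------
    def state_dict(self) -> dict:
        return {k: [w.copy(), b.copy()] for k, (w, b) in self.params.items()}

    def load_state_dict(self, state: dict) -> None:
        for k in self.params:
            self.params[k] = [state[k][0].copy(), state[k][1].copy()]

    def checksum(self) -> str:
        import hashlib

        h = hashlib.sha256()
        for k in sorted(self.params):
            h.update(self.params[k][0].tobytes())
            h.update(self.params[k][1].tobytes())
        return h.hexdigest()

    # -- forward / backward ------------------------------------------------
    def _block(self, x, name, cache):
        w, b = self.params[name]
        z, cols = _conv3_fwd(x, w, b)
        a = np.maximum(z, 0.0)
        cache[name] = (cols, z > 0)
        return a

    def forward(self, x: np.ndarray, cache: dict | None = None) -> np.ndarray:
        """x: (C, H, W) with H, W divisible by 4 -> evidence (K, H, W)."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 3 or x.shape[0] != self.in_channels:
            raise ValueError(
                f"expected input ({self.in_channels}, H, W), got {x.shape}"
            )
        if x.shape[1] % 4 or x.shape[2] % 4:
            raise ValueError("spatial dimensions must be divisible by 4")
        record = cache is not None
        c = cache if record else {}
        e1 = self._block(self._block(x, "enc1a", c), "enc1b", c)
        p1 = _pool2(e1)
        e2 = self._block(self._block(p1, "enc2a", c), "enc2b", c)
        p2 = _pool2(e2)
        bt = self._block(self._block(p2, "botta", c), "bottb", c)
        u2 = np.concatenate([_up2(bt), e2], axis=0)
        d2 = self._block(self._block(u2, "dec2a", c), "dec2b", c)
        u1 = np.concatenate([_up2(d2), e1], axis=0)
        d1 = self._block(self._block(u1, "dec1a", c), "dec1b", c)
        wh, bh = self.params["head"]
        zh = np.einsum("chw,oc->ohw", d1, wh[:, :, 0, 0]) + bh[:, None, None]
        if record:
            c["head_in"] = d1
            c["head_mask"] = zh > 0
        return np.maximum(zh, 0.0)

    def backward(self, cache: dict, g_evidence: np.ndarray) -> dict:
        """Backpropagate d(loss)/d(evidence) to parameter gradients."""
        grads = {}
        w4 = self.width * 4
        w2 = self.width * 2

        gz = (g_evidence * cache["head_mask"]).astype(np.float32)
        d1 = cache["head_in"]
        wh = self.params["head"][0][:, :, 0, 0]
        grads["head"] = [
            np.einsum("ohw,chw->oc", gz, d1)[:, :, None, None],
            gz.sum(axis=(1, 2)),
        ]
        g = np.einsum("ohw,oc->chw", gz, wh)

        def back_block(name, g, need_gx=True):
            cols, mask = cache[name]
            gz = g * mask
            gx, gw, gb = _conv3_bwd(gz, cols, self.params[name][0], need_gx)
            grads[name] = [gw, gb]
            return gx

        g = back_block("dec1b", g)
        g = back_block("dec1a", g)
        g_up, g_e1 = g[:w2], g[w2:]
        g_d2 = _up2_bwd(g_up)
        g = back_block("dec2b", g_d2)
        g = back_block("dec2a", g)
        g_up, g_e2 = g[:w4], g[w4:]
        g_bt = _up2_bwd(g_up)
        g = back_block("bottb", g_bt)
        g = back_block("botta", g)
        g_p2 = _pool2_bwd(g) + g_e2
        g = back_block("enc2b", g_p2)
        g = back_block("enc2a", g)
        g_p1 = _pool2_bwd(g) + g_e1
        g = back_block("enc1b", g_p1)
        back_block("enc1a", g, need_gx=False)
        return grads


class Adam:
    """Adam optimizer over an EvidenceNet's parameter dict."""

    def __init__(self, params: dict, lr: float = 3e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: [np.zeros_like(w), np.zeros_like(b)] for k, (w, b) in params.items()}
        self.v = {k: [np.zeros_like(w), np.zeros_like(b)] for k, (w, b) in params.items()}

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for k, pair in params.items():
            for i in range(2):
                g = grads[k][i].astype(pair[i].dtype)
                self.m[k][i] = self.b1 * self.m[k][i] + (1 - self.b1) * g
                self.v[k][i] = self.b2 * self.v[k][i] + (1 - self.b2) * g * g
                mhat = self.m[k][i] / bc1
                vhat = self.v[k][i] / bc2
                pair[i] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
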