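"""Minimal NumPy neural-network engine for the window classifiers.

Implements exactly what the model families need: dense and convolutional
layers (stride-1 convolutions, odd or even kernels, 'same'/'valid'
padding), max pooling, dropout, softmax cross-entropy, and the capsule
machinery (squash nonlinearity, dynamic routing, margin loss) with manual
backpropagation and Adam updates.  All randomness (weight init, dropout
masks) flows through generators passed in by the caller, so training is
bit-reproducible for a fixed seed.

Shapes are batch-first: dense (B, D); 1D conv (B, C, L); 2D conv
(B, C, H, W).  During routing, coupling coefficients are treated as
constants of the backward pass (gradients flow through the weighted sums
and the squash only); with few routing iterations this is the standard
cheap approximation and keeps the backward pass linear in the forward
cost.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

# ---------------------------------------------------------------------------
# convolution primitives (stride 1)


def _conv1d_valid(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """x (B,C,L), w (F,C,K) -> (B,F,L-K+1)."""
    win = sliding_window_view(x, w.shape[2], axis=2)
    return np.einsum("bclk,fck->bfl", win, w, optimize=True)


def _conv2d_valid(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """x (B,C,H,W), w (F,C,KH,KW) -> (B,F,H-KH+1,W-KW+1)."""
    win = sliding_window_view(x, w.shape[2:], axis=(2, 3))
    return np.einsum("bchwij,fcij->bfhw", win, w, optimize=True)


def _same_pads(k: int) -> tuple[int, int]:
    return (k - 1) // 2, k // 2


# ---------------------------------------------------------------------------
# layers


class Layer:
    """Forward/backward pair; params and grads exposed for the optimiser."""

    params: dict[str, np.ndarray]
    grads: dict[str, np.ndarray]

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p in self.params.values())


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(2.0 / d_in)
        self.params = {"w": rng.normal(0, scale, (d_in, d_out)), "b": np.zeros(d_out)}

    def forward(self, x, train=False):
        self._x = x
        return x @ self.params["w"] + self.params["b"]

    def backward(self, dout):
        self.grads = {"w": self._x.T @ dout, "b": dout.sum(axis=0)}
        return dout @ self.params["w"].T


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Dropout(Layer):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0 <= p < 1:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1 - self.p)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(len(x), -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Conv1d(Layer):
    """Stride-1 1D convolution, padding 'same' or 'valid'."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 padding: str = "same"):
        super().__init__()
        scale = np.sqrt(2.0 / (c_in * kernel))
        self.params = {"w": rng.normal(0, scale, (c_out, c_in, kernel)), "b": np.zeros(c_out)}
        self.kernel = kernel
        self.pads = _same_pads(kernel) if padding == "same" else (0, 0)

    def forward(self, x, train=False):
        pl, pr = self.pads
        self._xp = np.pad(x, ((0, 0), (0, 0), (pl, pr)))
        return _conv1d_valid(self._xp, self.params["w"]) + self.params["b"][None, :, None]

    def backward(self, dout):
        w = self.params["w"]
        k = self.kernel
        win = sliding_window_view(self._xp, k, axis=2)
        self.grads = {
            "w": np.einsum("bclk,bfl->fck", win, dout, optimize=True),
            "b": dout.sum(axis=(0, 2)),
        }
        pl, pr = self.pads
        dpad = np.pad(dout, ((0, 0), (0, 0), (k - 1 - pl, k - 1 - pr)))
        # transposed convolution: flipped kernel, in/out channels swapped
        dxp = _conv1d_valid(dpad, w[:, :, ::-1].swapaxes(0, 1))
        return dxp


class Conv2d(Layer):
    """Stride-1 2D convolution, padding 'same' or 'valid'."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 padding: str = "same"):
        super().__init__()
        scale = np.sqrt(2.0 / (c_in * kernel * kernel))
        self.params = {
            "w": rng.normal(0, scale, (c_out, c_in, kernel, kernel)),
            "b": np.zeros(c_out),
        }
        self.kernel = kernel
        self.pads = _same_pads(kernel) if padding == "same" else (0, 0)

    def forward(self, x, train=False):
        pl, pr = self.pads
        self._xp = np.pad(x, ((0, 0), (0, 0), (pl, pr), (pl, pr)))
        return _conv2d_valid(self._xp, self.params["w"]) + self.params["b"][None, :, None, None]

    def backward(self, dout):
        w = self.params["w"]
        k = self.kernel
        win = sliding_window_view(self._xp, (k, k), axis=(2, 3))
        self.grads = {
            "w": np.einsum("bchwij,bfhw->fcij", win, dout, optimize=True),
            "b": dout.sum(axis=(0, 2, 3)),
        }
        pl, pr = self.pads
        dpad = np.pad(dout, ((0, 0), (0, 0), (k - 1 - pl, k - 1 - pr), (k - 1 - pl, k - 1 - pr)))
        return _conv2d_valid(dpad, w[:, :, ::-1, ::-1].swapaxes(0, 1))


class MaxPool1d(Layer):
    def __init__(self, kernel: int, stride: int):
        super().__init__()
        self.kernel, self.stride = kernel, stride

    def forward(self, x, train=False):
        self._xshape = x.shape
        k = min(self.kernel, x.shape[2])
        win = sliding_window_view(x, k, axis=2)[:, :, :: self.stride, :]
        self._k, self._arg = k, win.argmax(axis=3)
        return win.max(axis=3)

    def backward(self, dout):
        dx = np.zeros(self._xshape)
        b, c, L = dout.shape
        starts = np.arange(L) * self.stride
        src = starts[None, None, :] + self._arg
        bi = np.arange(b)[:, None, None]
        ci = np.arange(c)[None, :, None]
        np.add.at(dx, (bi, ci, src), dout)
        return dx


class MaxPool2d(Layer):
    """Max pooling with the kernel clamped to the input height/width."""

    def __init__(self, kernel: int, stride: int):
        super().__init__()
        self.kernel, self.stride = kernel, stride

    def forward(self, x, train=False):
        self._xshape = x.shape
        kh = min(self.kernel, x.shape[2])
        kw = min(self.kernel, x.shape[3])
        win = sliding_window_view(x, (kh, kw), axis=(2, 3))[
            :, :, :: self.stride, :: self.stride, :, :
        ]
        b, c, H, W = win.shape[:4]
        flat = win.reshape(b, c, H, W, kh * kw)
        self._kh, self._kw = kh, kw
        self._arg = flat.argmax(axis=4)
        return flat.max(axis=4)

    def backward(self, dout):
        dx = np.zeros(self._xshape)
        b, c, H, W = dout.shape
        hi = (np.arange(H) * self.stride)[None, None, :, None] + self._arg // self._kw
        wi = (np.arange(W) * self.stride)[None, None, None, :] + self._arg % self._kw
        bi = np.arange(b)[:, None, None, None]
        ci = np.arange(c)[None, :, None, None]
        np.add.at(dx, (bi, ci, hi, wi), dout)
        return dx


# ---------------------------------------------------------------------------
# capsules


def squash(s: np.ndarray, axis: int = -1) -> np.ndarray:
    """v = (r² / (1 + r²)) · s / r with r = ‖s‖; squash(0) = 0.

    Preserves direction and maps the norm monotonically into [0, 1).
    """
    sq = np.sum(np.square(s), axis=axis, keepdims=True)
    r = np.sqrt(sq)
    safe_r = np.where(r == 0, 1.0, r)
    return (sq / (1.0 + sq)) * (s / safe_r)


def _squash_backward(s: np.ndarray, dv: np.ndarray, axis: int = -1) -> np.ndarray:
    # v = g(r)·s with g(r) = r/(1+r²);  ds = g·dv + (g'/r)(s·dv)s
    sq = np.sum(np.square(s), axis=axis, keepdims=True)
    r = np.sqrt(sq)
    safe = np.where(r == 0, 1.0, r)
    g = r / (1.0 + sq)
    gp = (1.0 - sq) / (1.0 + sq) ** 2
    s_dot_dv = np.sum(s * dv, axis=axis, keepdims=True)
    return g * dv + np.where(r == 0, 0.0, gp / safe) * s_dot_dv * s


def dynamic_routing(
    u_hat: np.ndarray, iterations: int = 3, return_coupling: bool = False
):
    """Routing-by-agreement between primary and class capsules.

    ``u_hat`` has shape (..., N, J, D): prediction of each of N primary
    capsules for each of J class capsules.  Logits start at zero; each
    iteration takes the softmax over class capsules, forms the weighted sum
    s_j = Σ_i c_ij û_ij, squashes it, and adds the agreement û_ij·v_j to the
    logits.  Per primary capsule the couplings sum to 1 at every iteration.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    u_hat = np.asarray(u_hat, dtype=float)
    b = np.zeros(u_hat.shape[:-1])
    for _ in range(iterations):
        b_shift = b - b.max(axis=-1, keepdims=True)
        c = np.exp(b_shift)
        c /= c.sum(axis=-1, keepdims=True)
        s = np.einsum("...nj,...njd->...jd", c, u_hat, optimize=True)
        v = squash(s)
        b = b + np.einsum("...njd,...jd->...nj", u_hat, v, optimize=True)
    if return_coupling:
        return v, c
    return v


class PrimaryCaps1d(Layer):
    """Group a (B, C, L) conv map into squashed capsule vectors (B, N, D).

    C must be divisible by the capsule dimension; positions are subsampled
    with the given spatial stride before grouping.
    """

    def __init__(self, caps_dim: int = 8, stride: int = 2):
        super().__init__()
        self.caps_dim, self.stride = caps_dim, stride

    def forward(self, x, train=False):
        b, c, L = x.shape
        xs = x[:, :, :: self.stride]
        self._in_shape, self._sub_shape = x.shape, xs.shape
        n_types = c // self.caps_dim
        # (B, types, D, L') -> (B, types*L', D)
        caps = xs.reshape(b, n_types, self.caps_dim, -1).transpose(0, 1, 3, 2)
        self._caps_shape = caps.shape
        self._s = caps.reshape(b, -1, self.caps_dim)
        return squash(self._s)

    def backward(self, dout):
        ds = _squash_backward(self._s, dout)
        b = self._in_shape[0]
        n_types, Lp, _ = self._caps_shape[1:]
        dxs = ds.reshape(b, n_types, Lp, self.caps_dim).transpose(0, 1, 3, 2).reshape(
            self._sub_shape
        )
        dx = np.zeros(self._in_shape)
        dx[:, :, :: self.stride] = dxs
        return dx


class PrimaryCaps2d(Layer):
    """As :class:`PrimaryCaps1d` for (B, C, H, W) maps; stride on width only."""

    def __init__(self, caps_dim: int = 8, stride: int = 2):
        super().__init__()
        self.caps_dim, self.stride = caps_dim, stride

    def forward(self, x, train=False):
        b, c, H, W = x.shape
        xs = x[:, :, :, :: self.stride]
        self._in_shape, self._sub_shape = x.shape, xs.shape
        n_types = c // self.caps_dim
        caps = xs.reshape(b, n_types, self.caps_dim, -1).transpose(0, 1, 3, 2)
        self._caps_shape = caps.shape
        self._s = caps.reshape(b, -1, self.caps_dim)
        return squash(self._s)

    def backward(self, dout):
        ds = _squash_backward(self._s, dout)
        b = self._in_shape[0]
        n_types, P, _ = self._caps_shape[1:]
        dxs = ds.reshape(b, n_types, P, self.caps_dim).transpose(0, 1, 3, 2).reshape(
            self._sub_shape
        )
        dx = np.zeros(self._in_shape)
        dx[:, :, :, :: self.stride] = dxs
        return dx


class CapsuleRouting(Layer):
    """Linear capsule transform followed by dynamic routing.

    Input (B, N, D_in) primary capsules; output (B, J, D_out) class
    capsules.  Coupling coefficients are recomputed every forward pass and
    held fixed in the backward pass.
    """

    def __init__(self, n_in: int, d_in: int, n_out: int, d_out: int,
                 iterations: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(1.0 / d_in)
        self.params = {"w": rng.normal(0, scale, (n_in, n_out, d_out, d_in))}
        self.iterations = iterations

    def forward(self, x, train=False):
        self._x = x
        self._u_hat = np.einsum("bnd,njod->bnjo", x, self.params["w"], optimize=True)
        b = np.zeros(self._u_hat.shape[:-1])
        for _ in range(self.iterations):
            bs = b - b.max(axis=-1, keepdims=True)
            c = np.exp(bs)
            c /= c.sum(axis=-1, keepdims=True)
            s = np.einsum("bnj,bnjd->bjd", c, self._u_hat, optimize=True)
            v = squash(s)
            b = b + np.einsum("bnjd,bjd->bnj", self._u_hat, v, optimize=True)
        self._c, self._s = c, s
        return v

    def backward(self, dout):
        ds = _squash_backward(self._s, dout)  # (B, J, D_out)
        du_hat = self._c[..., None] * ds[:, None, :, :]  # couplings fixed
        self.grads = {"w": np.einsum("bnjo,bnd->njod", du_hat, self._x, optimize=True)}
        return np.einsum("bnjo,njod->bnd", du_hat, self.params["w"], optimize=True)


# ---------------------------------------------------------------------------
# losses


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean softmax cross-entropy and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = len(labels)
    loss = -float(np.mean(np.log(p[np.arange(n), labels] + 1e-12)))
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n


def margin_loss(
    v: np.ndarray,
    labels: np.ndarray,
    m_pos: float = 0.9,
    m_neg: float = 0.1,
    lam: float = 0.5,
) -> tuple[float, np.ndarray]:
    """Capsule margin loss on class-capsule norms, and its gradient w.r.t. v.

    L = Σ_j T_j max(0, m⁺−‖v_j‖)² + λ(1−T_j) max(0, ‖v_j‖−m⁻)², averaged
    over the batch.
    """
    norms = np.linalg.norm(v, axis=-1)  # (B, J)
    n, J = norms.shape
    T = np.zeros((n, J))
    T[np.arange(n), labels] = 1.0
    pos = np.maximum(0.0, m_pos - norms)
    neg = np.maximum(0.0, norms - m_neg)
    loss = float(np.mean(np.sum(T * pos**2 + lam * (1 - T) * neg**2, axis=1)))
    dnorm = (-2.0 * T * pos + 2.0 * lam * (1 - T) * neg) / n
    safe = np.where(norms == 0, 1.0, norms)
    dv = (dnorm / safe)[..., None] * v
    return loss, dv


# ---------------------------------------------------------------------------
# network container and optimiser


class Adam:
    def __init__(self, layers: list[Layer], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.layers, self.lr = layers, lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(p) for k, p in lay.params.items()} for lay in layers]
        self.v = [{k: np.zeros_like(p) for k, p in lay.params.items()} for lay in layers]

    def step(self) -> None:
        self.t += 1
        for lay, m, v in zip(self.layers, self.m, self.v):
            for k, p in lay.params.items():
                g = lay.grads.get(k)
                if g is None:
                    continue
                m[k] = self.beta1 * m[k] + (1 - self.beta1) * g
                v[k] = self.beta2 * v[k] + (1 - self.beta2) * g * g
                mhat = m[k] / (1 - self.beta1**self.t)
                vhat = v[k] / (1 - self.beta2**self.t)
                p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for lay in self.layers:
            x = lay.forward(x, train=train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for lay in reversed(self.layers):
            dout = lay.backward(dout)
        return dout

    @property
    def n_parameters(self) -> int:
        return sum(lay.n_parameters for lay in self.layers)
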