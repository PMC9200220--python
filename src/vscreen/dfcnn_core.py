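"""Densely connected binding classifier and a 1-D CNN alternative.

Both models map a concatenated (pocket ++ ligand) feature vector to a
binding probability in (0, 1).  "Densely connected" means hidden block i
consumes the concatenation of the (normalized) input and the outputs of
all previous blocks, so block widths grow arithmetically.  Everything is
plain NumPy: forward, backward, Adam/RMSprop, seeded initialization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .errors import ConfigError, ShapeError

_SCORE_EPS = 1e-12
_MODEL_VERSION = "vscreen-model-v1"


@dataclass(frozen=True)
class PairSample:
    """One training pair: pocket vector, ligand vector, binary label."""

    pocket: np.ndarray
    ligand: np.ndarray
    label: int
    provenance: str = "positive"  # "positive" | "cross_combination"


def pairs_to_arrays(samples: Sequence[PairSample]) -> tuple[np.ndarray, np.ndarray]:
    """Stack pair samples into (X, y); rows are pocket ++ ligand."""
    X = np.array([np.concatenate([s.pocket, s.ligand]) for s in samples])
    y = np.array([s.label for s in samples], dtype=float)
    return X, y


# ---------------------------------------------------------------------------
# input normalization
# ---------------------------------------------------------------------------


@dataclass
class Normalizer:
    mean: np.ndarray
    std: np.ndarray

    STD_FLOOR = 1e-8

    @classmethod
    def fit(cls, features: np.ndarray) -> "Normalizer":
        """Per-feature mean/population-std; constant columns get a floored std."""
        mean = features.mean(axis=0)
        std = features.std(axis=0)
        std = np.maximum(std, cls.STD_FLOOR)
        return cls(mean=mean, std=std)

    def transform(self, features: np.ndarray) -> np.ndarray:
        return (features - self.mean) / self.std


def fit_normalizer(features: np.ndarray) -> Normalizer:
    return Normalizer.fit(np.asarray(features, dtype=float))


# ---------------------------------------------------------------------------
# DFCNN
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DFCNNConfig:
    input_dim: int = 600
    n_dense_blocks: int = 10
    block_units: int = 100
    activation: str = "relu"
    head_activation: str = "sigmoid"
    optimizer: str = "adam"
    loss: str = "bce"
    seed: int = 0
    include_input: bool = True  # block input includes the raw normalized features
    dropout: float = 0.0

    def __post_init__(self):
        if self.n_dense_blocks < 1:
            raise ConfigError("n_dense_blocks must be >= 1")
        if self.input_dim < 1 or self.block_units < 1:
            raise ConfigError("input_dim and block_units must be >= 1")
        if self.activation != "relu" or self.head_activation != "sigmoid":
            raise ConfigError("only relu hidden / sigmoid head activations are supported")
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigError("dropout must be in [0, 1)")

    def block_input_width(self, i: int) -> int:
        """Input width of 1-based block i under dense connectivity."""
        if self.include_input:
            return self.input_dim + (i - 1) * self.block_units
        return self.input_dim if i == 1 else (i - 1) * self.block_units

    @property
    def head_input_width(self) -> int:
        if self.include_input:
            return self.input_dim + self.n_dense_blocks * self.block_units
        return self.n_dense_blocks * self.block_units

    @property
    def n_parameters(self) -> int:
        n = 0
        for i in range(1, self.n_dense_blocks + 1):
            n += self.block_input_width(i) * self.block_units + self.block_units
        n += self.head_input_width + 1
        return n


@dataclass
class DFCNNParams:
    config: DFCNNConfig
    weights: list[np.ndarray]  # per block, shape (in_width, block_units)
    biases: list[np.ndarray]
    head_w: np.ndarray  # (head_in, 1)
    head_b: np.ndarray  # (1,)
    normalizer: Normalizer | None = None
    training_log: dict = field(default_factory=dict)

    def n_parameters(self) -> int:
        n = sum(w.size + b.size for w, b in zip(self.weights, self.biases))
        return n + self.head_w.size + self.head_b.size


def _he_uniform(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape)


def build_dfcnn(cfg: DFCNNConfig = DFCNNConfig()) -> DFCNNParams:
    """Allocate seeded He-uniform weights satisfying the dense-width invariant."""
    rng = np.random.default_rng(cfg.seed)
    weights, biases = [], []
    for i in range(1, cfg.n_dense_blocks + 1):
        w_in = cfg.block_input_width(i)
        weights.append(_he_uniform(rng, w_in, (w_in, cfg.block_units)))
        biases.append(np.zeros(cfg.block_units))
    head_in = cfg.head_input_width
    head_w = _he_uniform(rng, head_in, (head_in, 1))
    head_b = np.zeros(1)
    params = DFCNNParams(cfg, weights, biases, head_w, head_b)
    assert params.n_parameters() == cfg.n_parameters
    return params


def _forward(
    params: DFCNNParams,
    x_norm: np.ndarray,
    keep_cache: bool = False,
    dropout: float = 0.0,
    rng: np.random.Generator | None = None,
):
    """Forward pass; dropout masks are applied only when training supplies
    an rng (scoring is always deterministic)."""
    cfg = params.config
    acts = []  # block outputs (post-relu, post-dropout)
    zs = []
    masks = []
    for i in range(cfg.n_dense_blocks):
        parts = ([x_norm] if cfg.include_input else ([x_norm] if i == 0 else []))
        parts += acts
        c = np.concatenate(parts, axis=1) if len(parts) > 1 else parts[0]
        z = c @ params.weights[i] + params.biases[i]
        a = np.maximum(z, 0.0)
        if dropout > 0.0 and rng is not None:
            mask = (rng.random(a.shape) >= dropout) / (1.0 - dropout)
            a = a * mask
        else:
            mask = None
        acts.append(a)
        if keep_cache:
            zs.append(z)
            masks.append(mask)
    head_parts = ([x_norm] + acts) if cfg.include_input else acts
    c_head = np.concatenate(head_parts, axis=1)
    logit = np.clip((c_head @ params.head_w + params.head_b).ravel(), -500, 500)
    prob = 1.0 / (1.0 + np.exp(-logit))
    if keep_cache:
        return prob, acts, zs, masks, c_head
    return prob


def score(params: DFCNNParams, batch: np.ndarray) -> np.ndarray:
    """Score a batch of (n, input_dim) concatenated vectors; output in (0, 1)."""
    batch = np.atleast_2d(np.asarray(batch, dtype=float))
    if batch.shape[1] != params.config.input_dim:
        raise ShapeError(
            f"batch width {batch.shape[1]} != model input_dim {params.config.input_dim}"
        )
    x = params.normalizer.transform(batch) if params.normalizer is not None else batch
    prob = _forward(params, x)
    return np.clip(prob, _SCORE_EPS, 1.0 - _SCORE_EPS)


def _bce(prob: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(prob, _SCORE_EPS, 1.0 - _SCORE_EPS)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


class _Adam:
    def __init__(self, shapes, lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class _RMSprop:
    def __init__(self, shapes, lr: float):
        self.lr = lr
        self.rho, self.eps = 0.9, 1e-8
        self.cache = [np.zeros(s) for s in shapes]

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        for i, (p, g) in enumerate(zip(params, grads)):
            self.cache[i] = self.rho * self.cache[i] + (1 - self.rho) * g * g
            p -= self.lr * g / (np.sqrt(self.cache[i]) + self.eps)


def _dfcnn_backward(params: DFCNNParams, x_norm, y, prob, acts, zs, masks, c_head):
    """Gradients of mean BCE wrt all weights. Returns (grads, loss)."""
    cfg = params.config
    n = len(y)
    dz_head = (prob - y)[:, None] / n  # (n, 1)
    g_head_w = c_head.T @ dz_head
    g_head_b = dz_head.sum(axis=0)
    g_c = dz_head @ params.head_w.T  # (n, head_in)

    D = cfg.input_dim
    U = cfg.block_units
    L = cfg.n_dense_blocks
    # split head-input gradient into per-component pieces
    if cfg.include_input:
        g_x = g_c[:, :D].copy()
        g_a = [g_c[:, D + j * U : D + (j + 1) * U].copy() for j in range(L)]
    else:
        g_x = np.zeros_like(x_norm)
        g_a = [g_c[:, j * U : (j + 1) * U].copy() for j in range(L)]

    gW = [None] * L
    gB = [None] * L
    for i in reversed(range(L)):
        g = g_a[i] * masks[i] if masks[i] is not None else g_a[i]
        dz = g * (zs[i] > 0)
        if cfg.include_input:
            parts = [x_norm] + acts[:i]
        else:
            parts = [x_norm] if i == 0 else acts[:i]
        c = np.concatenate(parts, axis=1) if len(parts) > 1 else parts[0]
        gW[i] = c.T @ dz
        gB[i] = dz.sum(axis=0)
        back = dz @ params.weights[i].T
        if cfg.include_input:
            g_x += back[:, :D]
            off = D
            for j in range(i):
                g_a[j] += back[:, off : off + U]
                off += U
        else:
            if i == 0:
                g_x += back
            else:
                off = 0
                for j in range(i):
                    g_a[j] += back[:, off : off + U]
                    off += U
    return gW, gB, g_head_w, g_head_b


def fit(
    params: DFCNNParams,
    train: Sequence[PairSample],
    val: Sequence[PairSample] | None = None,
    epochs: int = 50,
    batch_size: int = 128,
    lr: float = 1e-3,
    seed: int = 0,
) -> DFCNNParams:
    """Train in place with Adam on mean binary cross-entropy.

    The input normalizer is fitted on the training features only.  Appends
    per-epoch train/val losses to params.training_log.  Deterministic for a
    fixed seed.
    """
    X, y = pairs_to_arrays(train)
    if X.shape[1] != params.config.input_dim:
        raise ShapeError(f"pair width {X.shape[1]} != input_dim {params.config.input_dim}")
    if len(np.unique(y)) < 2:
        raise ConfigError("training set must contain both classes")
    params.normalizer = fit_normalizer(X)
    Xn = params.normalizer.transform(X)
    if val is not None and len(val) > 0:
        Xv, yv = pairs_to_arrays(val)
        Xvn = params.normalizer.transform(Xv)
    else:
        Xvn = yv = None

    flat = params.weights + params.biases + [params.head_w, params.head_b]
    opt = _Adam([p.shape for p in flat], lr)
    rng = np.random.default_rng(seed)
    log = {"train_loss": [], "val_loss": []}
    n = len(y)
    for _ in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            sel = order[start : start + batch_size]
            xb, yb = Xn[sel], y[sel]
            prob, acts, zs, masks, c_head = _forward(
                params, xb, keep_cache=True,
                dropout=params.config.dropout, rng=rng,
            )
            gW, gB, g_hw, g_hb = _dfcnn_backward(
                params, xb, yb, prob, acts, zs, masks, c_head
            )
            opt.step(flat, gW + gB + [g_hw, g_hb])
        log["train_loss"].append(_bce(_forward(params, Xn), y))
        if Xvn is not None:
            log["val_loss"].append(_bce(_forward(params, Xvn), yv))
    for k, v in log.items():
        params.training_log.setdefault(k, []).extend(v)
    return params


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def save_params(params: DFCNNParams, path) -> None:
    """Persist weights + config + normalizer in one NPZ container."""
    arrays = {"__version__": np.array(_MODEL_VERSION)}
    arrays["config_json"] = np.array(json.dumps(asdict(params.config)))
    for i, (w, b) in enumerate(zip(params.weights, params.biases)):
        arrays[f"w{i}"] = w
        arrays[f"b{i}"] = b
    arrays["head_w"] = params.head_w
    arrays["head_b"] = params.head_b
    if params.normalizer is not None:
        arrays["norm_mean"] = params.normalizer.mean
        arrays["norm_std"] = params.normalizer.std
    np.savez(path, **arrays)


def load_params(path) -> DFCNNParams:
    data = np.load(path, allow_pickle=False)
    if "__version__" not in data or str(data["__version__"]) != _MODEL_VERSION:
        raise ConfigError(f"not a recognized model container: {path}")
    cfg = DFCNNConfig(**json.loads(str(data["config_json"])))
    weights = [data[f"w{i}"] for i in range(cfg.n_dense_blocks)]
    biases = [data[f"b{i}"] for i in range(cfg.n_dense_blocks)]
    norm = None
    if "norm_mean" in data:
        norm = Normalizer(mean=data["norm_mean"], std=data["norm_std"])
    return DFCNNParams(
        config=cfg, weights=weights, biases=biases,
        head_w=data["head_w"], head_b=data["head_b"], normalizer=norm,
    )


# ---------------------------------------------------------------------------
# 1-D CNN alternative
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CNNConfig:
    input_dim: int = 600
    conv_filters: tuple[int, int] = (16, 32)  # filters per block
    kernel_size: int = 3
    pool_size: int = 2
    dropout_rate: float = 0.25
    dense_units: int = 256
    optimizer: str = "rmsprop"
    loss: str = "bce"
    seed: int = 0


class CNNParams:
    """Two conv blocks (two conv layers + max-pool + dropout each), then
    dense-256 + dropout + sigmoid head."""

    def __init__(self, cfg: CNNConfig):
        self.config = cfg
        rng = np.random.default_rng(cfg.seed)
        k = cfg.kernel_size
        f1, f2 = cfg.conv_filters
        self.conv_w = [
            _he_uniform(rng, k * 1, (k, 1, f1)),
            _he_uniform(rng, k * f1, (k, f1, f1)),
            _he_uniform(rng, k * f1, (k, f1, f2)),
            _he_uniform(rng, k * f2, (k, f2, f2)),
        ]
        self.conv_b = [np.zeros(f1), np.zeros(f1), np.zeros(f2), np.zeros(f2)]
        flat_len = self._flat_len()
        self.dense_w = _he_uniform(rng, flat_len, (flat_len, cfg.dense_units))
        self.dense_b = np.zeros(cfg.dense_units)
        self.head_w = _he_uniform(rng, cfg.dense_units, (cfg.dense_units, 1))
        self.head_b = np.zeros(1)
        self.normalizer: Normalizer | None = None
        self.training_log: dict = {"train_loss": [], "val_loss": []}

    def _flat_len(self) -> int:
        cfg = self.config
        L = cfg.input_dim
        for blk in range(2):
            L = L - cfg.kernel_size + 1
            L = L - cfg.kernel_size + 1
            L = L // cfg.pool_size
        return L * cfg.conv_filters[1]

    def flat_params(self) -> list[np.ndarray]:
        return self.conv_w + self.conv_b + [self.dense_w, self.dense_b, self.head_w, self.head_b]


def _conv1d_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    # x: (n, L, Cin); w: (k, Cin, Cout)
    k = w.shape[0]
    win = np.lib.stride_tricks.sliding_window_view(x, k, axis=1)  # (n, Lo, Cin, k)
    z = np.einsum("nlik,kio->nlo", win, w) + b
    return z, win


def _maxpool_forward(x: np.ndarray, size: int):
    n, L, C = x.shape
    Lo = L // size
    xr = x[:, : Lo * size].reshape(n, Lo, size, C)
    idx = xr.argmax(axis=2)
    out = xr.max(axis=2)
    return out, (idx, L, size)


def _cnn_forward(p: CNNParams, x_norm: np.ndarray, training: bool, rng=None):
    cfg = p.config
    h = x_norm[:, :, None]  # (n, L, 1)
    cache = []
    li = 0
    for blk in range(2):
        for _ in range(2):
            z, win = _conv1d_forward(h, p.conv_w[li], p.conv_b[li])
            a = np.maximum(z, 0.0)
            cache.append(("conv", win, z, h.shape))
            h = a
            li += 1
        h, pool_cache = _maxpool_forward(h, cfg.pool_size)
        cache.append(("pool", pool_cache))
        if training and cfg.dropout_rate > 0:
            mask = (rng.random(h.shape) >= cfg.dropout_rate) / (1 - cfg.dropout_rate)
            h = h * mask
            cache.append(("drop", mask))
        else:
            cache.append(("drop", None))
    n = h.shape[0]
    flat_shape = h.shape
    flat = h.reshape(n, -1)
    zd = flat @ p.dense_w + p.dense_b
    ad = np.maximum(zd, 0.0)
    if training and cfg.dropout_rate > 0:
        dmask = (rng.random(ad.shape) >= cfg.dropout_rate) / (1 - cfg.dropout_rate)
        ad_used = ad * dmask
    else:
        dmask = None
        ad_used = ad
    logit = np.clip((ad_used @ p.head_w + p.head_b).ravel(), -500, 500)
    prob = 1.0 / (1.0 + np.exp(-logit))
    return prob, (cache, flat, flat_shape, zd, ad, dmask, ad_used)


def build_cnn(cfg: CNNConfig = CNNConfig()) -> CNNParams:
    return CNNParams(cfg)


def score_cnn(p: CNNParams, batch: np.ndarray) -> np.ndarray:
    batch = np.atleast_2d(np.asarray(batch, dtype=float))
    if batch.shape[1] != p.config.input_dim:
        raise ShapeError(
            f"batch width {batch.shape[1]} != model input_dim {p.config.input_dim}"
        )
    x = p.normalizer.transform(batch) if p.normalizer is not None else batch
    prob, _ = _cnn_forward(p, x, training=False)
    return np.clip(prob, _SCORE_EPS, 1.0 - _SCORE_EPS)


def _cnn_backward(p: CNNParams, y: np.ndarray, prob: np.ndarray, fwd_cache):
    cache, flat, flat_shape, zd, ad, dmask, ad_used = fwd_cache
    n = len(y)
    dz_head = (prob - y)[:, None] / n
    g_head_w = ad_used.T @ dz_head
    g_head_b = dz_head.sum(axis=0)
    d_ad = dz_head @ p.head_w.T
    if dmask is not None:
        d_ad = d_ad * dmask
    d_zd = d_ad * (zd > 0)
    g_dense_w = flat.T @ d_zd
    g_dense_b = d_zd.sum(axis=0)
    dh = (d_zd @ p.dense_w.T).reshape(flat_shape)

    g_conv_w = [None] * 4
    g_conv_b = [None] * 4
    li = 3
    for entry in reversed(cache):
        kind = entry[0]
        if kind == "drop":
            if entry[1] is not None:
                dh = dh * entry[1]
        elif kind == "pool":
            idx, L, size = entry[1]
            nb, Lo, C = dh.shape
            up = np.zeros((nb, Lo, size, C))
            n_idx = np.arange(nb)[:, None, None]
            l_idx = np.arange(Lo)[None, :, None]
            c_idx = np.arange(C)[None, None, :]
            up[n_idx, l_idx, idx, c_idx] = dh
            full = np.zeros((nb, L, C))
            full[:, : Lo * size] = up.reshape(nb, Lo * size, C)
            dh = full
        else:  # conv
            _, win, z, in_shape = entry
            dz = dh * (z > 0)
            g_conv_w[li] = np.einsum("nlik,nlo->kio", win, dz)
            g_conv_b[li] = dz.sum(axis=(0, 1))
            w = p.conv_w[li]
            k = w.shape[0]
            dx = np.zeros(in_shape)
            Lo = dz.shape[1]
            for j in range(k):
                dx[:, j : j + Lo, :] += np.einsum("nlo,io->nli", dz, w[j])
            dh = dx
            li -= 1
    return g_conv_w + g_conv_b + [g_dense_w, g_dense_b, g_head_w, g_head_b]


def fit_cnn(
    p: CNNParams,
    train: Sequence[PairSample],
    val: Sequence[PairSample] | None = None,
    epochs: int = 20,
    batch_size: int = 128,
    lr: float = 1e-3,
    seed: int = 0,
) -> CNNParams:
    """RMSprop training on mean binary cross-entropy; dropout active only here."""
    X, y = pairs_to_arrays(train)
    if X.shape[1] != p.config.input_dim:
        raise ShapeError(f"pair width {X.shape[1]} != input_dim {p.config.input_dim}")
    if len(np.unique(y)) < 2:
        raise ConfigError("training set must contain both classes")
    p.normalizer = fit_normalizer(X)
    Xn = p.normalizer.transform(X)
    if val is not None and len(val) > 0:
        Xv, yv = pairs_to_arrays(val)
        Xvn = p.normalizer.transform(Xv)
    else:
        Xvn = yv = None

    flat = p.flat_params()
    opt = _RMSprop([a.shape for a in flat], lr)
    rng = np.random.default_rng(seed)
    n = len(y)
    for _ in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            sel = order[start : start + batch_size]
            prob, fwd = _cnn_forward(p, Xn[sel], training=True, rng=rng)
            grads = _cnn_backward(p, y[sel], prob, fwd)
            opt.step(flat, grads)
        p.training_log["train_loss"].append(_bce(_cnn_forward(p, Xn, training=False)[0], y))
        if Xvn is not None:
            p.training_log["val_loss"].append(
                _bce(_cnn_forward(p, Xvn, training=False)[0], yv)
            )
    return p
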