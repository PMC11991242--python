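"""Stacked-GRU sequence classifier and hardware feasibility planning.

The classifier is a cascade of ``L`` GRU layers of ``W`` units each, fed
with the ``C``-channel descriptor sequence, followed by a two-neuron fully
connected head read from the final time step.  Architectures are encoded as
``C{c}-W{w}-L{l}[-X]`` where the ``-X`` suffix enables input batch
normalization and inter-layer dropout during training.

Gate convention (one of the two standard ones; biases both on the input and
the recurrent path, i.e. two bias vectors per gate):

    r  = sigmoid(W_r x + b_r + U_r h + c_r)
    z  = sigmoid(W_z x + b_z + U_z h + c_z)
    h~ = tanh(W_h x + b_h + r * (U_h h + c_h))
    h' = (1 - z) * h + z * h~

Everything is plain NumPy: the module provides the forward pass, a cached
forward plus full backpropagation-through-time used by the trainer, exact
parameter counting, and `fanin_plan`, which decomposes a dot product into a
tree of partial-sum units so that no physical neuron exceeds the analog
fan-in limit of six inputs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

__all__ = [
    "NetworkConfig",
    "GATES",
    "init_params",
    "gru_cell_step",
    "forward",
    "forward_batch",
    "backward_batch",
    "count_params",
    "FaninPlan",
    "fanin_plan",
    "iter_neuron_rows",
    "set_neuron_row",
    "TABLE2_ARCHS",
]

GATES = ("r", "z", "h")
_BN_EPS = 1e-5

#: The seven architectures retained for the quantization experiments.
TABLE2_ARCHS = (
    "C1-W6-L3-X", "C1-W8-L3-X", "C1-W6-L5-X", "C3-W8-L3-X",
    "C3-W6-L7-X", "C3-W8-L5-X", "C12-W16-L3-X",
)

_ARCH_RE = re.compile(r"^C(\d+)-W(\d+)-L(\d+)(-X)?$")


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters: channels, width, depth, regularization."""

    c: int
    w: int
    l: int
    use_bn_dropout: bool = True
    dropout_p: float = 0.3

    def __post_init__(self):
        if self.c < 1 or self.w < 1 or self.l < 1:
            raise ValueError("C, W and L must all be >= 1")
        if not (0 <= self.dropout_p < 1):
            raise ValueError("dropout_p must lie in [0, 1)")

    @property
    def arch(self) -> str:
        s = f"C{self.c}-W{self.w}-L{self.l}"
        return s + "-X" if self.use_bn_dropout else s

    @classmethod
    def from_arch(cls, arch: str, dropout_p: float = 0.3) -> "NetworkConfig":
        m = _ARCH_RE.match(arch.strip())
        if not m:
            raise ValueError(f"cannot parse architecture string {arch!r}")
        return cls(
            c=int(m.group(1)), w=int(m.group(2)), l=int(m.group(3)),
            use_bn_dropout=m.group(4) is not None, dropout_p=dropout_p,
        )

    def layer_input_sizes(self) -> list[int]:
        return [self.c] + [self.w] * (self.l - 1)


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------


def _orthogonal(n: int, rng: np.random.Generator) -> np.ndarray:
    q, r = np.linalg.qr(rng.normal(size=(n, n)))
    return q * np.sign(np.diag(r))  # unique, uniformly distributed Q


def init_params(config: NetworkConfig, seed: int) -> dict:
    """Seeded init: input weights and biases uniform in +-1/sqrt(fan-in),
    recurrent matrices orthogonal (the standard recipe for stable recurrent
    gradient propagation); BN starts as identity."""
    rng = np.random.default_rng(seed)
    params: dict = {"layers": [], "fc": {}}
    if config.use_bn_dropout:
        params["bn"] = {
            "gamma": np.ones(config.c),
            "beta": np.zeros(config.c),
            "running_mean": np.zeros(config.c),
            "running_var": np.ones(config.c),
        }
    for I in config.layer_input_sizes():
        W = config.w
        s = 1.0 / np.sqrt(I + W + 2)
        layer = {}
        for g in GATES:
            layer[f"W_{g}"] = rng.uniform(-s, s, (W, I))
            layer[f"U_{g}"] = _orthogonal(W, rng)
            layer[f"b_{g}"] = rng.uniform(-s, s, W)
            layer[f"c_{g}"] = rng.uniform(-s, s, W)
        params["layers"].append(layer)
    s = 1.0 / np.sqrt(config.w + 1)
    params["fc"] = {
        "V": rng.uniform(-s, s, (2, config.w)),
        "d": rng.uniform(-s, s, 2),
    }
    return params


def count_params(config: NetworkConfig) -> int:
    """Trainable scalar count: 3 gates x W x (I + W + 2) per layer, a
    2 x (W + 1) head, and 2C batch-norm parameters when enabled."""
    n = sum(3 * config.w * (I + config.w + 2) for I in config.layer_input_sizes())
    n += 2 * (config.w + 1)
    if config.use_bn_dropout:
        n += 2 * config.c
    return n


from scipy.special import expit as _sigmoid  # numerically stable sigmoid


def gru_cell_step(layer: dict, x: np.ndarray, h: np.ndarray) -> np.ndarray:
    """One GRU step for a single layer; ``x`` and ``h`` may be batched."""
    x = np.atleast_2d(np.asarray(x, float))
    h = np.atleast_2d(np.asarray(h, float))
    if x.shape[1] != layer["W_r"].shape[1] or h.shape[1] != layer["U_r"].shape[1]:
        raise ValueError("input/state dimensions do not match layer parameters")
    r = _sigmoid(x @ layer["W_r"].T + layer["b_r"] + h @ layer["U_r"].T + layer["c_r"])
    z = _sigmoid(x @ layer["W_z"].T + layer["b_z"] + h @ layer["U_z"].T + layer["c_z"])
    inner = h @ layer["U_h"].T + layer["c_h"]
    hb = np.tanh(x @ layer["W_h"].T + layer["b_h"] + r * inner)
    out = (1.0 - z) * h + z * hb
    return out[0] if np.asarray(x).ndim == 1 else out


# ---------------------------------------------------------------------------
# forward / backward
# ---------------------------------------------------------------------------


def _apply_input_norm(params: dict, X: np.ndarray, train: bool, cache: dict):
    """Input batch normalization (or a quantized input affine map)."""
    if "input_affine" in params:
        ia = params["input_affine"]
        return X * ia["a"] + ia["b"]
    if "bn" not in params:
        return X
    bn = params["bn"]
    if train and not bn.get("frozen_stats", False):
        mu = X.mean(axis=(0, 1))
        var = X.var(axis=(0, 1))
        bn["running_mean"] = 0.9 * bn["running_mean"] + 0.1 * mu
        bn["running_var"] = 0.9 * bn["running_var"] + 0.1 * var
    else:
        # descriptor energies are heavy-tailed, so per-batch statistics swing
        # wildly at small batch sizes; the trainer pins the statistics to the
        # training set once and lets only gamma/beta learn
        mu, var = bn["running_mean"], bn["running_var"]
    xhat = (X - mu) / np.sqrt(var + _BN_EPS)
    cache["bn"] = (xhat, var)
    return bn["gamma"] * xhat + bn["beta"]


def forward_batch(
    config: NetworkConfig,
    params: dict,
    X: np.ndarray,
    train: bool = False,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, dict]:
    """Run a ``[B, T, C]`` batch through the network.

    Returns ``(logits [B, 2], cache)``; the cache carries everything
    `backward_batch` needs.  Dropout masks are drawn from ``rng`` only when
    ``train`` is true and the architecture has the ``-X`` suffix.
    """
    X = np.asarray(X, float)
    if X.ndim == 2:
        X = X[None]
    B, T, C = X.shape
    if C != config.c:
        raise ValueError(f"window has {C} channels, network expects {config.c}")
    cache: dict = {"X_raw": X, "train": train}
    inp = _apply_input_norm(params, X, train, cache)

    use_dropout = train and config.use_bn_dropout and config.dropout_p > 0
    if use_dropout and rng is None:
        rng = np.random.default_rng()

    layer_caches = []
    for li, layer in enumerate(params["layers"]):
        W = config.w
        h = np.zeros((B, W))
        steps = []
        out = np.empty((B, T, W))
        for t in range(T):
            x = inp[:, t, :]
            r = _sigmoid(x @ layer["W_r"].T + layer["b_r"] + h @ layer["U_r"].T + layer["c_r"])
            z = _sigmoid(x @ layer["W_z"].T + layer["b_z"] + h @ layer["U_z"].T + layer["c_z"])
            inner = h @ layer["U_h"].T + layer["c_h"]
            hb = np.tanh(x @ layer["W_h"].T + layer["b_h"] + r * inner)
            h_new = (1.0 - z) * h + z * hb
            steps.append((x, h, r, z, inner, hb))
            h = h_new
            out[:, t, :] = h
        mask = None
        if use_dropout and li < config.l - 1:
            keep = 1.0 - config.dropout_p
            mask = (rng.random(out.shape) < keep) / keep
            out = out * mask
        layer_caches.append({"steps": steps, "mask": mask})
        inp = out
    # the top layer is never dropped, so this is its final hidden state
    h_last = inp[:, -1, :]
    logits = h_last @ params["fc"]["V"].T + params["fc"]["d"]
    cache["layers"] = layer_caches
    cache["h_last"] = h_last
    cache["T"] = T
    return logits, cache


def forward(
    config: NetworkConfig,
    params: dict,
    window,
    train: bool = False,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Logits ``[no-humans score, humans score]`` for one descriptor window."""
    values = getattr(window, "values", window)
    logits, _ = forward_batch(config, params, np.asarray(values, float), train, rng)
    return logits[0]


def backward_batch(
    config: NetworkConfig, params: dict, cache: dict, dlogits: np.ndarray
) -> dict:
    """Backpropagation through time; returns grads shaped like ``params``."""
    B, T = cache["X_raw"].shape[0], cache["T"]
    grads: dict = {"layers": [], "fc": {}}
    grads["fc"]["V"] = dlogits.T @ cache["h_last"]
    grads["fc"]["d"] = dlogits.sum(axis=0)

    # gradient flowing into each layer's output sequence
    dout = np.zeros((B, T, config.w))
    dout[:, -1, :] = dlogits @ params["fc"]["V"]

    for li in range(config.l - 1, -1, -1):
        layer = params["layers"][li]
        lc = cache["layers"][li]
        if lc["mask"] is not None:
            dout = dout * lc["mask"]
        I = layer["W_r"].shape[1]
        g = {k: np.zeros_like(v) for k, v in layer.items()}
        dinp = np.zeros((B, T, I))
        dh = np.zeros((B, config.w))
        for t in range(T - 1, -1, -1):
            dh = dh + dout[:, t, :]
            x, h_prev, r, z, inner, hb = lc["steps"][t]
            dz = dh * (hb - h_prev)
            dhb = dh * z
            dh_prev = dh * (1.0 - z)
            da_h = dhb * (1.0 - hb**2)
            dr = da_h * inner
            dinner = da_h * r
            da_r = dr * r * (1.0 - r)
            da_z = dz * z * (1.0 - z)
            g["W_r"] += da_r.T @ x
            g["U_r"] += da_r.T @ h_prev
            g["b_r"] += da_r.sum(axis=0)
            g["c_r"] += da_r.sum(axis=0)
            g["W_z"] += da_z.T @ x
            g["U_z"] += da_z.T @ h_prev
            g["b_z"] += da_z.sum(axis=0)
            g["c_z"] += da_z.sum(axis=0)
            g["W_h"] += da_h.T @ x
            g["b_h"] += da_h.sum(axis=0)
            g["U_h"] += dinner.T @ h_prev
            g["c_h"] += dinner.sum(axis=0)
            dh_prev += da_r @ layer["U_r"] + da_z @ layer["U_z"] + dinner @ layer["U_h"]
            dinp[:, t, :] = da_r @ layer["W_r"] + da_z @ layer["W_z"] + da_h @ layer["W_h"]
            dh = dh_prev
        grads["layers"].insert(0, g)
        dout = dinp

    if "bn" in params and "bn" in cache:
        xhat, var = cache["bn"]
        dy = dout  # gradient wrt BN output
        N = B * T
        grads["bn"] = {
            "gamma": (dy * xhat).sum(axis=(0, 1)),
            "beta": dy.sum(axis=(0, 1)),
        }
        if cache["train"]:
            gamma = params["bn"]["gamma"]
            inv = 1.0 / np.sqrt(var + _BN_EPS)
            mean_dy = dy.mean(axis=(0, 1))
            mean_dyx = (dy * xhat).mean(axis=(0, 1))
            # dX not propagated further (input layer), kept for completeness
            grads["dX"] = gamma * inv * (dy - mean_dy - xhat * mean_dyx)
    return grads


# ---------------------------------------------------------------------------
# neuron-row access (used by the quantization machinery)
# ---------------------------------------------------------------------------


def iter_neuron_rows(params: dict) -> Iterator[tuple[tuple, np.ndarray]]:
    """Yield ``(location, row)`` for every hardware neuron.

    A GRU gate neuron's row is ``[W_g[u, :], U_g[u, :], b_g[u], c_g[u]]``
    (biases appended as weights on constant-1 inputs); an FC neuron's row is
    ``[V[u, :], d[u]]``.  Locations are ``("layer", li, gate, u)`` or
    ``("fc", u)``.
    """
    for li, layer in enumerate(params["layers"]):
        for g in GATES:
            for u in range(layer[f"W_{g}"].shape[0]):
                row = np.concatenate([
                    layer[f"W_{g}"][u], layer[f"U_{g}"][u],
                    [layer[f"b_{g}"][u]], [layer[f"c_{g}"][u]],
                ])
                yield ("layer", li, g, u), row
    for u in range(params["fc"]["V"].shape[0]):
        yield ("fc", u), np.concatenate([params["fc"]["V"][u], [params["fc"]["d"][u]]])


def set_neuron_row(params: dict, loc: tuple, row: np.ndarray) -> None:
    """Write a (possibly reconstructed) neuron row back into ``params``."""
    row = np.asarray(row, float)
    if loc[0] == "fc":
        u = loc[1]
        w = params["fc"]["V"].shape[1]
        params["fc"]["V"][u] = row[:w]
        params["fc"]["d"][u] = row[w]
        return
    _, li, g, u = loc
    layer = params["layers"][li]
    I = layer[f"W_{g}"].shape[1]
    W = layer[f"U_{g}"].shape[1]
    layer[f"W_{g}"][u] = row[:I]
    layer[f"U_{g}"][u] = row[I : I + W]
    layer[f"b_{g}"][u] = row[I + W]
    layer[f"c_{g}"][u] = row[I + W + 1]


# ---------------------------------------------------------------------------
# fan-in planning
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FaninPlan:
    """Partial-sum tree realizing an ``n_inputs``-wide dot product with
    physical units of fan-in <= ``max_fanin``.

    ``levels[0]`` lists the input chunk sizes (units multiplying weights);
    deeper levels list combiner fan-ins summing previous-level outputs.
    """

    n_inputs: int
    max_fanin: int
    levels: tuple[tuple[int, ...], ...]

    @property
    def depth(self) -> int:
        return len(self.levels)

    @property
    def max_fanin_used(self) -> int:
        return max(max(lv) for lv in self.levels)

    @property
    def n_units(self) -> int:
        return sum(len(lv) for lv in self.levels)

    def evaluate(self, w: np.ndarray, x: np.ndarray) -> float:
        """Run the tree on weights ``w`` and inputs ``x``."""
        w = np.asarray(w, float)
        x = np.asarray(x, float)
        if w.shape != (self.n_inputs,) or x.shape != (self.n_inputs,):
            raise ValueError("weight/input length must equal n_inputs")
        vals = w * x
        for lv in self.levels:
            nxt, k = [], 0
            for size in lv:
                nxt.append(vals[k : k + size].sum())
                k += size
            vals = np.asarray(nxt)
        return float(vals[0])


def fanin_plan(n_inputs: int, max_fanin: int = 6) -> FaninPlan:
    """Decompose an ``n_inputs``-wide dot product for fan-in-limited units.

    Produces a two-level tree whenever ``ceil(n/max) <= max`` and recurses
    deeper otherwise; the composed linear map equals the direct dot product.
    """
    if n_inputs < 1:
        raise ValueError("n_inputs must be >= 1")
    if max_fanin < 2:
        raise ValueError("max_fanin must be >= 2")
    levels = []
    m = n_inputs
    while True:
        sizes = tuple(
            min(max_fanin, m - k * max_fanin)
            for k in range(-(-m // max_fanin))
        )
        levels.append(sizes)
        m = len(sizes)
        if m == 1:
            break
    return FaninPlan(n_inputs=n_inputs, max_fanin=max_fanin, levels=tuple(levels))
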