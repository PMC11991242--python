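"""Weight quantization for analog hardware: loss, renormalization, codebook.

The target hardware stores each synaptic weight with 4-bit-plus-sign
resolution, i.e. on the uniform codebook

    { m / M : m = -M .. M },   M = 2^B - 1 - (B mod 2),   B = 4  =>  M = 15

(31 signed levels, 16 distinct magnitudes).  Training pulls weights toward
that grid with a periodic regularizer,

    L_Q = sum_i | sin(M * pi * w_i) |,

which vanishes exactly on the grid and peaks midway between adjacent
levels.  The total training loss is ``L_CCE + lambda * L_Q``, with the
quantization term activated only after the network has learned some
discrimination (epoch 6 of 20 by default).

Because a handful of admissible weight values would otherwise strangle
capacity, each neuron's weight vector ``w`` is renormalized to [-1, 1],

    w_hat_j = (2 w_j - w_max - w_min) / (w_max - w_min),

and only ``w_hat`` is quantized; the neuron-specific scale
``k = (w_max - w_min)/2`` and offset ``B = (w_max + w_min)/2`` restore the
original dot product exactly through

    x^T w = k * (x^T w_hat) + B * sum_j x_j

(the offset acts as one extra synapse on a constant-1 input, which is how
the hardware realizes it).  Scales and offsets are themselves quantized —
already during training, so the network adapts to them — on a sign-plus-
4-bit logarithmic codebook relative to per-layer reference values, the
natural representation for amplifier gains.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .grunet import (
    GATES,
    NetworkConfig,
    init_params,
    iter_neuron_rows,
    set_neuron_row,
)

__all__ = [
    "QuantConfig",
    "NeuronAffine",
    "quant_grid",
    "quant_loss",
    "quant_loss_grad",
    "cross_entropy",
    "total_loss",
    "normalize_neuron",
    "affine_dot",
    "hard_quantize",
    "normalized_weight_vector",
    "quant_reg_grads",
    "QuantizedNetwork",
    "quantize_network",
    "project_scales",
    "naive_quantize",
]

_BN_EPS = 1e-5


@dataclass(frozen=True)
class QuantConfig:
    """Codebook resolution and training-schedule parameters.

    ``bit_depth`` counts magnitude bits (the sign is extra); odd depths are
    permitted but only B=2 and B=4 correspond to validated hardware.
    ``lam`` weighs the quantization pull against the task loss: the
    regularizer's gradient step per weight is ``lr * lam * |dL_Q/dw|``
    (the trainer applies it as a separate splitting step after Adam), and
    the default is calibrated so classification accuracy keeps improving
    after the activation epoch while normalized weights converge onto the
    codebook.
    """

    bit_depth: int = 4
    lam: float = 3e-4
    activation_epoch: int = 6

    def __post_init__(self):
        if self.bit_depth < 2:
            raise ValueError("bit_depth must be >= 2")
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")

    @property
    def multiplier(self) -> int:
        return 2**self.bit_depth - 1 - (self.bit_depth % 2)


def quant_grid(B: int) -> np.ndarray:
    """Admissible weight levels ``{m/M : m = -M..M}`` for bit depth ``B``."""
    if B < 2:
        raise ValueError("bit depth must be >= 2")
    M = 2**B - 1 - (B % 2)
    return np.arange(-M, M + 1) / M


def quant_loss(weights, B: int) -> float:
    """Periodic quantization loss ``sum |sin(M pi w)|``; zero on the grid."""
    w = np.asarray(weights, float).ravel()
    if not np.all(np.isfinite(w)):
        raise ValueError("weights must be finite")
    M = 2**B - 1 - (B % 2)
    return float(np.abs(np.sin(M * np.pi * w)).sum())


def quant_loss_grad(weights, B: int) -> np.ndarray:
    """d/dw of `quant_loss` (zero at grid points and at loss maxima).

    Grid points are detected with a small tolerance: sin(M*pi*w) carries a
    ~1e-13 floating-point residue at exact levels (notably w = +-1, which
    every normalized row attains), and its sign would otherwise inject a
    spurious +-M*pi gradient there.
    """
    w = np.asarray(weights, float)
    M = 2**B - 1 - (B % 2)
    s = np.sin(M * np.pi * w)
    g = M * np.pi * np.cos(M * np.pi * w) * np.sign(s)
    return np.where(np.abs(s) < 1e-9, 0.0, g)


def cross_entropy(logits: np.ndarray, labels: np.ndarray) -> float:
    """Mean categorical cross-entropy of two-class logits."""
    logits = np.atleast_2d(logits)
    labels = np.atleast_1d(labels).astype(int)
    m = logits.max(axis=1, keepdims=True)
    logz = m[:, 0] + np.log(np.exp(logits - m).sum(axis=1))
    return float(np.mean(logz - logits[np.arange(len(labels)), labels]))


def total_loss(logits, labels, quantizable_weights, qc: QuantConfig, epoch: int) -> float:
    """Two-component loss: CCE alone before the activation epoch, then
    ``CCE + lambda * L_Q`` over the (normalized) quantizable weights."""
    if epoch < 1:
        raise ValueError("epochs are 1-based")
    loss = cross_entropy(logits, labels)
    if epoch >= qc.activation_epoch and qc.lam > 0:
        loss += qc.lam * quant_loss(quantizable_weights, qc.bit_depth)
    return loss


# ---------------------------------------------------------------------------
# per-neuron renormalization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NeuronAffine:
    """Normalized weights plus the affine pair that restores the original."""

    w_hat: np.ndarray
    scale: float
    offset: float


def normalize_neuron(w) -> NeuronAffine:
    """Map a weight vector onto [-1, 1] with its restoring scale and offset.

    Constant vectors degenerate to ``w_hat = 0, scale = 0, offset = w_max``.
    """
    w = np.asarray(w, float)
    wmax, wmin = float(w.max()), float(w.min())
    if wmax == wmin:
        return NeuronAffine(np.zeros_like(w), 0.0, wmax)
    w_hat = (2 * w - wmax - wmin) / (wmax - wmin)
    return NeuronAffine(w_hat, (wmax - wmin) / 2.0, (wmax + wmin) / 2.0)


def affine_dot(x, na: NeuronAffine) -> float:
    """``scale * (x . w_hat) + offset * sum(x)``; equals ``x . w`` exactly
    before quantization."""
    x = np.asarray(x, float)
    if x.shape != na.w_hat.shape:
        raise ValueError("input length does not match weight length")
    return float(na.scale * (x @ na.w_hat) + na.offset * x.sum())


def hard_quantize(values, grid) -> np.ndarray:
    """Snap each value to the nearest grid level; ties round away from zero."""
    grid = np.asarray(grid, float)
    if grid.size == 0:
        raise ValueError("empty grid")
    v = np.asarray(values, float)
    scalar = v.ndim == 0
    v = np.atleast_1d(v)
    idx = np.searchsorted(grid, v)
    lo = np.clip(idx - 1, 0, grid.size - 1)
    hi = np.clip(idx, 0, grid.size - 1)
    dlo = np.abs(v - grid[lo])
    dhi = np.abs(grid[hi] - v)
    pick_hi = dhi < dlo
    tie = np.isclose(dlo, dhi, rtol=0.0, atol=1e-15)
    away = np.abs(grid[hi]) >= np.abs(grid[lo])
    pick_hi = np.where(tie, away, pick_hi)
    out = np.where(pick_hi, grid[hi], grid[lo])
    return float(out[0]) if scalar else out


def normalized_weight_vector(params: dict) -> np.ndarray:
    """Concatenated ``w_hat`` of every neuron row — the quantity L_Q sees."""
    return np.concatenate(
        [normalize_neuron(row).w_hat for _, row in iter_neuron_rows(params)]
    )


def snapshot_frames(params: dict) -> dict:
    """Per-neuron (w_min, w_max) normalization frames at this instant."""
    return {
        loc: (float(row.min()), float(row.max()))
        for loc, row in iter_neuron_rows(params)
    }


def quant_reg_grads(params: dict, qc: QuantConfig, frames: dict | None = None) -> dict:
    """Gradient of ``L_Q(w_hat)`` with respect to the raw parameters.

    The normalization frame (per-neuron min/max) is treated as a constant
    (straight-through), so ``d w_hat_j / d w_j = 2 / (w_max - w_min)``.
    When ``frames`` is given (a `snapshot_frames` result) the normalized
    coordinates are measured against that frozen frame instead of the
    current row extremes: every task update to an extreme weight rescales
    the whole row, so a per-step frame makes the periodic attraction chase
    a moving grid; the trainer refreshes the frame once per epoch, which is
    slow enough for interior weights to lock onto stable levels and fresh
    enough to track the row's drift.  Returned in the params layout (zero
    for BN).
    """
    grads: dict = {
        "layers": [
            {k: np.zeros_like(v) for k, v in layer.items()}
            for layer in params["layers"]
        ],
        "fc": {k: np.zeros_like(v) for k, v in params["fc"].items()},
    }
    for loc, row in iter_neuron_rows(params):
        if frames is not None and loc in frames:
            wmin, wmax = frames[loc]
        else:
            wmin, wmax = float(row.min()), float(row.max())
        if wmax == wmin:
            continue
        w_hat = (2 * row - wmax - wmin) / (wmax - wmin)
        g = quant_loss_grad(w_hat, qc.bit_depth) * (2.0 / (wmax - wmin))
        set_neuron_row(grads, loc, g)
    return grads


# ---------------------------------------------------------------------------
# quantized network
# ---------------------------------------------------------------------------


@dataclass
class QuantizedNeuron:
    loc: tuple
    codes: np.ndarray  # int8 in [-M, M]
    k_code: int
    b_code: int


@dataclass
class QuantizedGroup:
    """One hardware layer sharing reference scale/offset magnitudes."""

    key: tuple
    k_ref: float
    b_ref: float
    neurons: list = field(default_factory=list)


@dataclass
class QuantizedNetwork:
    """All-integer network: per-neuron codebook indices, per-neuron quantized
    scale/offset codes, per-layer float references."""

    config: NetworkConfig
    qc: QuantConfig
    groups: dict

    @property
    def multiplier(self) -> int:
        return self.qc.multiplier

    def to_float_params(self) -> dict:
        """Reconstruct effective float parameters for inference."""
        M = self.multiplier
        params = init_params(self.config, seed=0)
        params.pop("bn", None)
        for layer in params["layers"]:
            for k in layer:
                layer[k][...] = 0.0
        for k in params["fc"]:
            params["fc"][k][...] = 0.0
        for key, grp in self.groups.items():
            for qn in grp.neurons:
                k_q = float(_log_decode(np.array(qn.k_code), grp.k_ref))
                b_q = float(_log_decode(np.array(qn.b_code), grp.b_ref))
                row = qn.codes.astype(float) / M * k_q + b_q
                if key == ("input_affine",):
                    params.setdefault("input_affine", {})[qn.loc[1]] = row
                else:
                    set_neuron_row(params, qn.loc, row)
        return params


def _quantize_row(row: np.ndarray, M: int, grid: np.ndarray):
    na = normalize_neuron(row)
    codes = np.rint(hard_quantize(na.w_hat, grid) * M).astype(np.int8)
    return codes, na.scale, na.offset


#: Step ratio of the logarithmic scale/offset codebook.  Per-neuron gains
#: and offsets span orders of magnitude within one layer, so a linear code
#: would leave small-gain neurons with huge relative error; amplifier gains
#: are programmed in dB-like steps anyway.  15 magnitudes at ratio r cover
#: r^14 ~ 1/100 of the layer reference with a constant relative error of
#: about (1 - sqrt(r)) ~ 15%.
_LOG_STEP = 10 ** (-2 / 14)


def _log_code(vals: np.ndarray, ref: float) -> np.ndarray:
    """Sign-and-4-bit log codes: |v| = ref * r^(15 - |code|), code 0 = 0."""
    vals = np.asarray(vals, float)
    codes = np.zeros(vals.shape, dtype=int)
    nz = vals != 0.0
    steps = np.round(np.log(np.abs(vals[nz]) / ref) / np.log(_LOG_STEP))
    mag = 15 - steps
    # below the smallest level by more than half a (log) step: silence
    mag = np.where(mag < 1, 0, np.clip(mag, 0, 15))
    codes[nz] = (np.sign(vals[nz]) * mag).astype(int)
    return codes


def _log_decode(codes: np.ndarray, ref: float) -> np.ndarray:
    codes = np.asarray(codes, int)
    mag = np.where(codes == 0, 0.0, ref * _LOG_STEP ** (15 - np.abs(codes)))
    return np.sign(codes) * mag


def _quantize_refs(vals: np.ndarray, M: int, grid: np.ndarray):
    ref = float(np.max(np.abs(vals)))
    if ref == 0.0:
        return 0.0, np.zeros(len(vals), dtype=int)
    return ref, _log_code(vals, ref)


def quantize_network(
    model, config: NetworkConfig | None = None, qc: QuantConfig | None = None
) -> QuantizedNetwork:
    """Quantize trained parameters to the B-bit-plus-sign codebook.

    Per neuron: renormalize, snap ``w_hat`` to the grid, then quantize the
    scale and offset against per-layer references (the largest magnitude in
    the layer maps to code +-M).  Batch-norm statistics are folded into a
    per-channel input affine map quantized the same way.  Accepts either a
    float parameter dict (with ``config`` and ``qc``) or an existing
    `QuantizedNetwork` (idempotent re-quantization).
    """
    if isinstance(model, QuantizedNetwork):
        return quantize_network(model.to_float_params(), model.config, model.qc)
    params = model
    if config is None or qc is None:
        raise ValueError("config and qc are required when quantizing raw params")
    M = qc.multiplier
    grid = quant_grid(qc.bit_depth)

    raw: dict[tuple, list] = {}
    for loc, row in iter_neuron_rows(params):
        key = ("layer", loc[1]) if loc[0] == "layer" else ("fc",)
        codes, k, b = _quantize_row(row, M, grid)
        raw.setdefault(key, []).append((loc, codes, k, b))

    if "bn" in params:
        bn = params["bn"]
        inv = 1.0 / np.sqrt(bn["running_var"] + _BN_EPS)
        a = bn["gamma"] * inv
        b = bn["beta"] - bn["gamma"] * bn["running_mean"] * inv
        for name, vec in (("a", a), ("b", b)):
            codes, k, off = _quantize_row(np.asarray(vec, float), M, grid)
            raw.setdefault(("input_affine",), []).append(
                (("input_affine", name), codes, k, off)
            )
    elif "input_affine" in params:
        for name in ("a", "b"):
            vec = np.asarray(params["input_affine"][name], float)
            codes, k, off = _quantize_row(vec, M, grid)
            raw.setdefault(("input_affine",), []).append(
                (("input_affine", name), codes, k, off)
            )

    groups = {}
    for key, rows in raw.items():
        ks = np.array([r[2] for r in rows])
        bs = np.array([r[3] for r in rows])
        k_ref, k_codes = _quantize_refs(ks, M, grid)
        b_ref, b_codes = _quantize_refs(bs, M, grid)
        grp = QuantizedGroup(key=key, k_ref=k_ref, b_ref=b_ref)
        for (loc, codes, _, _), kc, bc in zip(rows, k_codes, b_codes):
            grp.neurons.append(
                QuantizedNeuron(loc=loc, codes=codes, k_code=int(kc), b_code=int(bc))
            )
        groups[key] = grp
    return QuantizedNetwork(config=config, qc=qc, groups=groups)


def project_scales(params: dict, qc: QuantConfig) -> None:
    """Hard-quantize every neuron's scale and offset in place, keeping the
    normalized weights float.

    Scales and offsets are subject to hard quantization already during
    training, so the network adapts to the codes it will deploy with; the
    final quantization step then only snaps the normalized weights, whose
    rounding error is benign.  The projection rewrites each row as
    ``w_hat * k_q + B_q`` with ``(k_q, B_q)`` decoded from the same
    per-layer log codebook `quantize_network` uses.
    """
    M = qc.multiplier
    raw: dict[tuple, list] = {}
    for loc, row in iter_neuron_rows(params):
        key = ("layer", loc[1]) if loc[0] == "layer" else ("fc",)
        na = normalize_neuron(row)
        raw.setdefault(key, []).append((loc, na))
    for key, rows in raw.items():
        ks = np.array([na.scale for _, na in rows])
        bs = np.array([na.offset for _, na in rows])
        k_ref = float(np.max(np.abs(ks)))
        b_ref = float(np.max(np.abs(bs)))
        k_q = _log_decode(_log_code(ks, k_ref), k_ref) if k_ref else ks
        b_q = _log_decode(_log_code(bs, b_ref), b_ref) if b_ref else bs
        for (loc, na), kq, bq in zip(rows, k_q, b_q):
            set_neuron_row(params, loc, na.w_hat * kq + bq)
    if "bn" in params:
        # fold BN into the input affine, quantize it, unfold — the network
        # then trains against the exact affine it will deploy with
        bn = params["bn"]
        sig = np.sqrt(np.asarray(bn["running_var"], float) + 1e-5)
        mu = np.asarray(bn["running_mean"], float)
        a = bn["gamma"] / sig
        b = bn["beta"] - bn["gamma"] * mu / sig
        grid = quant_grid(qc.bit_depth)
        nas = [normalize_neuron(np.atleast_1d(v)) for v in (a, b)]
        k_ref = max(abs(na.scale) for na in nas)
        b_ref = max(abs(na.offset) for na in nas)
        out = []
        for na in nas:
            kq = (float(_log_decode(_log_code(np.array([na.scale]), k_ref), k_ref)[0])
                  if k_ref else na.scale)
            bq = (float(_log_decode(_log_code(np.array([na.offset]), b_ref), b_ref)[0])
                  if b_ref else na.offset)
            out.append(hard_quantize(na.w_hat, grid) * kq + bq)
        a_q, b_q = out
        bn["gamma"] = a_q * sig
        bn["beta"] = b_q + a_q * mu


def naive_quantize(params: dict, qc: QuantConfig) -> dict:
    """Post-hoc rounding of every raw weight to the codebook, no
    renormalization — the baseline the diversification scheme replaces.
    Weights outside [-1, 1] clip to the extreme levels."""
    grid = quant_grid(qc.bit_depth)
    out = copy.deepcopy(params)
    for layer in out["layers"]:
        for k in layer:
            layer[k] = hard_quantize(np.clip(layer[k], -1, 1), grid).reshape(
                layer[k].shape
            )
    for k in out["fc"]:
        arr = np.asarray(out["fc"][k], float)
        out["fc"][k] = hard_quantize(np.clip(arr, -1, 1), grid).reshape(arr.shape)
    if "bn" in out:
        for k in ("gamma", "beta"):
            arr = np.asarray(out["bn"][k], float)
            out["bn"][k] = hard_quantize(np.clip(arr, -1, 1), grid).reshape(arr.shape)
    return out
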