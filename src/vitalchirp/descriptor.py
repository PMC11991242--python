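"""Differential-chirp energy descriptor.

The feature extractor summarizes the motion occurring in a radar-monitored
space between two acquisition instants separated by a delay ``delta_t``:

1. each train of consecutive scans is averaged element-wise (a low-pass
   filter suppressing Gaussian acquisition noise), giving filtered vectors
   ``p_bar_t`` and ``q_bar_t``;
2. differential chirps are formed by subtraction,
   ``dp_t = p_bar_t - p_bar_{t - delta_t}`` (and likewise ``dq_t``);
3. the descriptor is the mean energy of the differential pair,

       f_t = (1/n) * sum_j (dp_{t,j}^2 + dq_{t,j}^2).

For a single reflector of amplitude ``A`` whose phase changed by
``delta_phi`` over the delay (fixed IF), the descriptor has the closed form
``4 A^2 sin^2(delta_phi / 2)`` — `analytic_descriptor` — which serves as an
independent oracle for the numeric pipeline.  With several channels the
descriptor is a vector with one component per channel.

Sequences of descriptors are cut into non-overlapping observation windows
(2, 6 or 12 s) which form the classifier inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as _sig

from .radar_sim import Recording

__all__ = [
    "FilteredScan",
    "DescriptorWindow",
    "lpf_average",
    "differential_pair",
    "energy",
    "analytic_descriptor",
    "descriptor_sequence",
    "descriptor_series",
    "bandpass",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilteredScan:
    """Train-averaged (p_bar, q_bar) pair for one channel at time ``t``."""

    p_bar: np.ndarray
    q_bar: np.ndarray
    t: float = 0.0


@dataclass
class DescriptorWindow:
    """One observation window of the C-channel descriptor sequence.

    ``values`` has shape ``[n_steps, C]`` with ``n_steps = window_s / ts``;
    all entries are non-negative.
    """

    values: np.ndarray
    window_s: float
    delta_t_s: float
    label: int
    source_id: str
    start_index: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be [n_steps, C]")
        if np.any(self.values < -1e-12):
            raise ValueError("descriptor values must be non-negative")

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]


def lpf_average(train) -> FilteredScan:
    """Element-wise mean of a train of scans (the LPF stage).

    ``train`` is a sequence of ``(p, q)`` pairs or objects with ``p``/``q``
    attributes; all vectors must share one length.
    """
    ps, qs, t = [], [], 0.0
    for s in train:
        if hasattr(s, "p"):
            ps.append(np.asarray(s.p, float))
            qs.append(np.asarray(s.q, float))
            t = getattr(s, "t", t)
        else:
            p, q = s
            ps.append(np.asarray(p, float))
            qs.append(np.asarray(q, float))
    if not ps:
        raise ValueError("empty train")
    n = ps[0].shape
    if any(p.shape != n for p in ps) or any(q.shape != n for q in qs):
        raise ValueError("ragged scan lengths in train")
    return FilteredScan(np.mean(ps, axis=0), np.mean(qs, axis=0), t)


def differential_pair(
    curr: FilteredScan, prev: FilteredScan
) -> tuple[np.ndarray, np.ndarray]:
    """Differential chirps: element-wise ``curr - prev`` for p and q."""
    if curr.p_bar.shape != prev.p_bar.shape or curr.q_bar.shape != prev.q_bar.shape:
        raise ValueError("filtered scan lengths do not match")
    return curr.p_bar - prev.p_bar, curr.q_bar - prev.q_bar


def energy(dp: np.ndarray, dq: np.ndarray) -> float:
    """Mean energy of a differential chirp pair: (1/n) sum (dp^2 + dq^2)."""
    dp = np.asarray(dp, float)
    dq = np.asarray(dq, float)
    if dp.size == 0 or dq.size == 0:
        raise ValueError("empty differential vectors")
    if dp.shape != dq.shape:
        raise ValueError("dp and dq lengths differ")
    return float(np.mean(dp**2 + dq**2))


def analytic_descriptor(A: float, delta_phi: float) -> float:
    """Closed-form descriptor for one reflector: ``4 A^2 sin^2(delta_phi/2)``.

    Oracle for `energy` on single-reflector noise-free scenes with fixed IF.
    """
    return float(4.0 * A**2 * np.sin(delta_phi / 2.0) ** 2)


def _filtered_trains(rec: Recording) -> np.ndarray:
    """Train-averaged scans as ``[n_trains, C, n]``."""
    tl = rec.config.train_len
    n_trains = rec.p.shape[0] // tl
    shape = (n_trains, tl) + rec.p.shape[1:]
    p_bar = rec.p[: n_trains * tl].reshape(shape).mean(axis=1)
    q_bar = rec.q[: n_trains * tl].reshape(shape).mean(axis=1)
    return p_bar, q_bar


def descriptor_series(
    rec: Recording, delta_t: float, channel_mode: int | None = None
) -> np.ndarray:
    """Full descriptor sequence ``[n_trains - delta_steps, C]`` of a recording.

    The first ``delta_t/ts`` trains have no subtraction partner and are
    consumed as warm-up.  ``channel_mode`` of 1, 3 or 12 selects the leading
    channels of the recording (so mode 1 is the first component of mode 12);
    None keeps all recorded channels.
    """
    ts = rec.config.ts
    ratio = delta_t / ts
    delta_steps = int(round(ratio))
    if delta_steps < 1 or abs(ratio - delta_steps) > 1e-9:
        raise ValueError(
            f"delta_t={delta_t} must be a positive integer multiple of ts={ts}"
        )
    p_bar, q_bar = _filtered_trains(rec)
    if channel_mode is not None:
        if channel_mode > p_bar.shape[1]:
            raise ValueError(
                f"channel_mode={channel_mode} exceeds recorded channels "
                f"({p_bar.shape[1]})"
            )
        p_bar = p_bar[:, :channel_mode]
        q_bar = q_bar[:, :channel_mode]
    dp = p_bar[delta_steps:] - p_bar[:-delta_steps]
    dq = q_bar[delta_steps:] - q_bar[:-delta_steps]
    return (dp**2 + dq**2).mean(axis=2)


def descriptor_sequence(
    rec: Recording,
    delta_t: float,
    window_s: float,
    channel_mode: int | None = None,
    bpf_band: tuple[float, float] | None = None,
    source_id: str | None = None,
) -> list[DescriptorWindow]:
    """Cut a recording's descriptor sequence into non-overlapping windows.

    ``bpf_band`` optionally applies a zero-phase band-pass (in Hz) to each
    channel's sequence before windowing; the default pipeline leaves it off.
    Returns an empty list (with a logged warning) when the recording is
    shorter than warm-up plus one window.
    """
    ts = rec.config.ts
    f = descriptor_series(rec, delta_t, channel_mode)
    if bpf_band is not None:
        f = bandpass(f, bpf_band[0], bpf_band[1], fs=1.0 / ts)
    wsteps = int(round(window_s / ts))
    if abs(window_s / ts - wsteps) > 1e-9 or wsteps < 1:
        raise ValueError("window_s must be a positive integer multiple of ts")
    n_windows = f.shape[0] // wsteps
    if n_windows == 0:
        logger.warning(
            "recording %s too short for a %gs window after %gs warm-up",
            source_id or rec.scene_name, window_s, delta_t,
        )
        return []
    sid = source_id or f"{rec.scene_name}-{rec.seed}"
    out = []
    for w in range(n_windows):
        vals = f[w * wsteps : (w + 1) * wsteps]
        if bpf_band is not None:
            # keep the non-negativity contract after filtering
            vals = vals - vals.min(axis=0, keepdims=True)
        out.append(
            DescriptorWindow(
                values=vals,
                window_s=window_s,
                delta_t_s=delta_t,
                label=rec.label,
                source_id=sid,
                start_index=w * wsteps,
            )
        )
    return out


def bandpass(seq: np.ndarray, low: float, high: float, fs: float) -> np.ndarray:
    """Zero-phase Butterworth band-pass along axis 0 of ``[T, C]`` data."""
    if not (0 < low < high < fs / 2):
        raise ValueError(
            f"band ({low}, {high}) Hz invalid for sampling rate {fs} Hz"
        )
    sos = _sig.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    return _sig.sosfiltfilt(sos, np.asarray(seq, float), axis=0)
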