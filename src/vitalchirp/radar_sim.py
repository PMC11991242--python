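"""Synthetic FMCW radar scan generation.

An FMCW radar repeatedly emits linear frequency sweeps (chirps) and mixes
the echo with the emitted signal.  For a static scene the mixer output is a
superposition of intermediate-frequency (IF) tones, one per reflective
surface, whose frequency encodes the reflector's distance and whose phase
tracks sub-wavelength displacements through the linear relation

    delta_phi = 4 * pi * f * delta_d / c

with ``f`` the carrier frequency and ``c`` the wave speed.  Each acquisition
yields an in-phase vector ``p`` and a quadrature vector ``q`` of ``n``
samples:

    p_j = sum_i A_i * cos(2*pi*df_i*j + phi_i) + N_j
    q_j = sum_i A_i * sin(2*pi*df_i*j + phi_i) + N_j      j = 1..n

where ``df_i`` is the IF in cycles/sample, ``A_i`` the component amplitude,
``phi_i`` the (motion-modulated) phase and ``N_j`` i.i.d. Gaussian
acquisition noise.  Chirps are acquired in short trains (for low-pass
averaging) whose start times are spaced ``Ts`` apart; ``Ts`` sets the
sampling period of everything downstream.

Displacement is modulated per reflector by a :class:`Trajectory`: sinusoidal
chest motion for breathing, a sawtooth for a rotating fan, a triangle wave
for a reciprocating robotic arm, a clipped Gaussian random walk for curtains,
or zero for static clutter.  Distractor rates and amplitudes are drawn from
the same intervals as breathing so that motion rate alone cannot separate
the classes; the waveform shape is the discriminative feature.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "C_LIGHT",
    "CANONICAL_CHANNELS",
    "RadarConfig",
    "Trajectory",
    "Reflector",
    "Scene",
    "ScanFrame",
    "Recording",
    "trajectory_displacement",
    "synth_scan",
    "simulate_recording",
    "scene_preset",
    "SCENE_PRESETS",
]

C_LIGHT = 2.99792458e8

#: The 12 TX-RX antenna pairings of a 4-TX / 3-RX radar front end, in a fixed
#: order.  The three-channel acquisition mode uses TX1-RX3, TX4-RX1, TX2-RX2
#: and the single-channel mode TX1-RX1.
CANONICAL_CHANNELS: tuple[str, ...] = tuple(
    f"TX{i}-RX{j}" for i in range(1, 5) for j in range(1, 4)
)

THREE_CHANNEL_SET: tuple[str, ...] = ("TX1-RX3", "TX4-RX1", "TX2-RX2")
SINGLE_CHANNEL_SET: tuple[str, ...] = ("TX1-RX1",)


def default_channels(n: int) -> tuple[str, ...]:
    """Channel list for the 1-, 3- or 12-channel acquisition mode."""
    if n == 1:
        return SINGLE_CHANNEL_SET
    if n == 3:
        return THREE_CHANNEL_SET
    if n == 12:
        return CANONICAL_CHANNELS
    raise ValueError(f"channel count must be 1, 3 or 12, got {n}")


def _subseed(seed: int, *tags) -> np.random.SeedSequence:
    """Derive an independent seed stream from a global seed and string tags."""
    h = hashlib.sha256(("/".join(map(str, tags))).encode()).digest()
    salt = int.from_bytes(h[:4], "little")
    return np.random.SeedSequence(entropy=[int(seed) % (2**31), salt])


@dataclass(frozen=True)
class RadarConfig:
    """Acquisition geometry and timing of the simulated radar.

    ``ts`` is the interval between chirp-train start times and therefore the
    sampling period of the descriptor sequence; every differential delay
    used downstream must be an integer multiple of it.
    """

    carrier_freq: float = 79e9
    n_samples: int = 512
    scan_rate: float = 1000.0
    train_len: int = 3
    ts: float = 0.05
    channels: tuple[str, ...] = THREE_CHANNEL_SET
    noise_sigma: float = 0.1
    wave_speed: float = C_LIGHT
    full_physics: bool = False

    def __post_init__(self):
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.train_len < 1:
            raise ValueError("train_len must be >= 1")
        if self.ts <= self.train_len / self.scan_rate:
            raise ValueError("ts must exceed the train duration train_len/scan_rate")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if len(self.channels) == 0:
            raise ValueError("at least one channel required")
        object.__setattr__(self, "channels", tuple(self.channels))

    def to_json(self) -> str:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["channels"] = list(d["channels"])
        return json.dumps(d)

    @classmethod
    def from_json(cls, s: str) -> "RadarConfig":
        d = json.loads(s)
        d["channels"] = tuple(d["channels"])
        return cls(**d)


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

TRAJECTORY_KINDS = ("breathing", "fan", "arm", "curtain", "static")

#: Internal sampling step of the curtain random walk [s]; values between grid
#: points are linearly interpolated.
_WALK_DT = 0.05


@dataclass(frozen=True)
class Trajectory:
    """Displacement-versus-time model for one reflector.

    kind-specific ``params``:

    - ``breathing``: ``rate`` [Hz, 0.125-0.5], ``amplitude`` [m], ``phase``
      [rad]; optional ``rate_jitter`` / ``amp_jitter`` (relative std of the
      slow cycle-to-cycle modulation) and ``jitter_seed`` fixing its
      realization — chest motion is irregular breath to breath, unlike the
      mechanically regular distractors
    - ``fan``: ``period`` [s], ``amplitude`` [m]  (sawtooth)
    - ``arm``: ``period`` [s], ``amplitude`` [m]  (triangle)
    - ``curtain``: ``step_std`` [m per step], ``clip`` [m]
    - ``static``: none
    """

    kind: str
    params: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in TRAJECTORY_KINDS:
            raise ValueError(
                f"unknown trajectory kind {self.kind!r}; valid: {TRAJECTORY_KINDS}"
            )
        object.__setattr__(self, "params", dict(self.params))
        if self.kind == "breathing" and not (0 < self.params["rate"] <= 1.0):
            raise ValueError("breathing rate must be in (0, 1] Hz")


def trajectory_displacement(traj: Trajectory, t, seed: int = 0):
    """Reflector displacement [m] at time(s) ``t``, deterministic per seed.

    Accepts a scalar or array of times; returns the same shape.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    p = traj.params
    if traj.kind == "static":
        return np.zeros_like(t) if t.ndim else 0.0
    if traj.kind == "breathing":
        out = _breathing_displacement(p, t)
    elif traj.kind == "fan":
        # rotating blade: repeating linear ramp over one revolution
        frac = np.mod(t / p["period"], 1.0)
        out = p["amplitude"] * (2.0 * frac - 1.0)
    elif traj.kind == "arm":
        # reciprocating motion: symmetric triangle, peak at period/4
        out = p["amplitude"] * (2 / np.pi) * np.arcsin(
            np.sin(2 * np.pi * t / p["period"])
        )
    elif traj.kind == "curtain":
        out = _curtain_walk(p, t, seed)
    else:  # pragma: no cover - guarded by Trajectory.__post_init__
        raise ValueError(traj.kind)
    return out if t.ndim else float(out)


#: Control-point spacing [s] of the slow physiological modulation and the
#: dense grid step [s] on which the breathing phase is integrated.
_MOD_DT = 2.0
_PHASE_DT = 0.1


def _smooth_modulation(tmax: float, rel_std: float, rng) -> tuple[np.ndarray, np.ndarray]:
    """Multiplicative modulation (1 + jitter) interpolated between control
    points a couple of seconds apart."""
    n_ctrl = int(np.floor(tmax / _MOD_DT)) + 2
    ctrl = 1.0 + rng.normal(0.0, rel_std, n_ctrl)
    ctrl = np.clip(ctrl, 0.5, 1.5)
    t_ctrl = np.arange(n_ctrl) * _MOD_DT
    grid = np.arange(int(np.floor(tmax / _PHASE_DT)) + 2) * _PHASE_DT
    return grid, np.interp(grid, t_ctrl, ctrl)


def _breathing_displacement(p: Mapping[str, float], t: np.ndarray) -> np.ndarray:
    """Sinusoidal chest motion with optional cycle-to-cycle irregularity.

    With jitter the instantaneous rate and depth wander slowly (each a
    smoothed seeded process), so no two breathing cycles are identical —
    the feature separating humans from mechanically periodic distractors.
    """
    rate_j = p.get("rate_jitter", 0.0)
    amp_j = p.get("amp_jitter", 0.0)
    if rate_j == 0.0 and amp_j == 0.0:
        return p["amplitude"] * np.sin(
            2 * np.pi * p["rate"] * t + p.get("phase", 0.0)
        )
    rng = np.random.default_rng(_subseed(int(p.get("jitter_seed", 0)), "breath"))
    tmax = float(np.max(t)) if t.size else 0.0
    grid, rate_mod = _smooth_modulation(tmax, rate_j, rng)
    _, amp_mod = _smooth_modulation(tmax, amp_j, rng)
    # phase accumulates the wandering instantaneous rate
    phi = np.concatenate([
        [0.0],
        np.cumsum(
            2 * np.pi * p["rate"] * 0.5 * (rate_mod[1:] + rate_mod[:-1]) * _PHASE_DT
        ),
    ])
    phi_t = np.interp(t, grid, phi)
    amp_t = p["amplitude"] * np.interp(t, grid, amp_mod)
    return amp_t * np.sin(phi_t + p.get("phase", 0.0))


def _curtain_walk(p: Mapping[str, float], t: np.ndarray, seed: int) -> np.ndarray:
    """Clipped Gaussian random walk sampled on a fixed grid, interpolated."""
    tmax = float(np.max(t)) if t.size else 0.0
    nsteps = int(np.floor(tmax / _WALK_DT)) + 2
    rng = np.random.default_rng(_subseed(seed, "curtain"))
    steps = rng.normal(0.0, p["step_std"], size=nsteps)
    walk = np.empty(nsteps + 1)
    walk[0] = 0.0
    # clip keeps the curtain within its physical travel range
    clip = p["clip"]
    np.cumsum(steps, out=walk[1:])
    walk = np.clip(walk, -clip, clip)
    grid = np.arange(nsteps + 1) * _WALK_DT
    return np.interp(t, grid, walk)


# ---------------------------------------------------------------------------
# scene model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Reflector:
    """One reflective surface: an IF tone with motion-modulated phase."""

    amplitude: float
    if_freq: float  # cycles/sample, in (0, 0.5)
    trajectory: Trajectory
    phase0: float = 0.0
    base_distance: float = 1.0  # m, used only by the full-physics IF shift
    channel_phase_offsets: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not np.isfinite(self.amplitude) or self.amplitude <= 0:
            raise ValueError("amplitude must be finite and > 0")
        if not (0 < self.if_freq < 0.5):
            raise ValueError("if_freq must lie in (0, 0.5) cycles/sample")
        object.__setattr__(
            self, "channel_phase_offsets", dict(self.channel_phase_offsets)
        )


@dataclass(frozen=True)
class Scene:
    reflectors: tuple[Reflector, ...]
    label: int
    name: str = ""

    def __post_init__(self):
        object.__setattr__(self, "reflectors", tuple(self.reflectors))
        has_breathing = any(
            r.trajectory.kind == "breathing" for r in self.reflectors
        )
        if has_breathing and self.label != 1:
            raise ValueError("scenes containing breathing motion must carry label 1")


class ScanFrame:
    """One (p, q) scan pair for one channel at one acquisition instant."""

    __slots__ = ("t", "channel", "p", "q")

    def __init__(self, t: float, channel: str, p: np.ndarray, q: np.ndarray):
        self.t, self.channel, self.p, self.q = t, channel, p, q


@dataclass
class Recording:
    """Time-ordered multi-channel scan arrays plus provenance.

    ``p`` and ``q`` have shape ``[n_scans, n_channels, n_samples]``; ``times``
    holds the acquisition instant of each scan.  Scans are grouped in trains
    of ``config.train_len`` at ``1/config.scan_rate`` spacing, train starts
    ``config.ts`` apart.
    """

    p: np.ndarray
    q: np.ndarray
    times: np.ndarray
    config: RadarConfig
    scene_name: str
    label: int
    seed: int

    @property
    def n_trains(self) -> int:
        return self.p.shape[0] // self.config.train_len

    @property
    def duration(self) -> float:
        return self.n_trains * self.config.ts

    def frames(self) -> Iterator[ScanFrame]:
        for k, t in enumerate(self.times):
            for c, ch in enumerate(self.config.channels):
                yield ScanFrame(float(t), ch, self.p[k, c], self.q[k, c])

    def __eq__(self, other) -> bool:
        if not isinstance(other, Recording):
            return NotImplemented
        return (
            np.array_equal(self.p, other.p)
            and np.array_equal(self.q, other.q)
            and np.array_equal(self.times, other.times)
            and self.config == other.config
            and self.scene_name == other.scene_name
            and self.label == other.label
            and self.seed == other.seed
        )


# ---------------------------------------------------------------------------
# scan synthesis
# ---------------------------------------------------------------------------


def _phase_at(
    refl: Reflector, config: RadarConfig, t, channel: str, seed: int
) -> np.ndarray:
    """Total phase of one reflector's IF component at time(s) t."""
    disp = trajectory_displacement(refl.trajectory, t, seed=seed)
    return (
        refl.phase0
        + refl.channel_phase_offsets.get(channel, 0.0)
        + 4 * np.pi * config.carrier_freq * np.asarray(disp) / config.wave_speed
    )


def _if_freq_at(refl: Reflector, config: RadarConfig, t, seed: int):
    if not config.full_physics:
        return refl.if_freq
    disp = trajectory_displacement(refl.trajectory, t, seed=seed)
    return refl.if_freq * (1.0 + np.asarray(disp) / refl.base_distance)


def synth_scan(
    scene: Scene,
    config: RadarConfig,
    t: float,
    channel: str,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthesize one (p, q) scan pair for one channel at time ``t``.

    Straightforward per-reflector superposition; `simulate_recording` uses an
    algebraically identical vectorized path for long recordings.
    """
    if channel not in config.channels:
        raise ValueError(f"channel {channel!r} not in config.channels")
    j = np.arange(1, config.n_samples + 1)
    p = np.zeros(config.n_samples)
    q = np.zeros(config.n_samples)
    for i, refl in enumerate(scene.reflectors):
        phi = _phase_at(refl, config, t, channel, seed=_refl_seed(seed, i))
        df = _if_freq_at(refl, config, t, seed=_refl_seed(seed, i))
        arg = 2 * np.pi * df * j + phi
        p += refl.amplitude * np.cos(arg)
        q += refl.amplitude * np.sin(arg)
    if config.noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng(_subseed(seed, "scan-noise", t, channel))
        p += rng.normal(0.0, config.noise_sigma, config.n_samples)
        q += rng.normal(0.0, config.noise_sigma, config.n_samples)
    return p, q


def _refl_seed(seed: int, i: int) -> int:
    # stable per-reflector stream for stochastic trajectories
    return int(_subseed(seed, "reflector", i).generate_state(1)[0] % (2**31))


def simulate_recording(
    scene: Scene,
    config: RadarConfig,
    duration: float,
    seed: int,
    dtype=np.float64,
) -> Recording:
    """Simulate ``duration`` seconds of chirp trains for every channel.

    Emits ``floor(duration/ts)`` trains of ``train_len`` scans spaced
    ``1/scan_rate`` apart.  Bit-reproducible from ``seed``.  ``dtype``
    controls the stored scan precision (float32 halves the footprint of
    long recordings; synthesis itself always runs in float64).
    """
    if duration < config.ts:
        raise ValueError("duration must be at least one train interval ts")
    n_trains = int(np.floor(duration / config.ts + 1e-9))
    tl = config.train_len
    times = (
        np.arange(n_trains)[:, None] * config.ts
        + np.arange(tl)[None, :] / config.scan_rate
    ).ravel()
    n_scans, n_ch, n = times.size, len(config.channels), config.n_samples

    p = np.zeros((n_scans, n_ch, n), dtype=np.float64)
    q = np.zeros((n_scans, n_ch, n), dtype=np.float64)
    j = np.arange(1, n + 1)

    for i, refl in enumerate(scene.reflectors):
        rs = _refl_seed(seed, i)
        disp = trajectory_displacement(refl.trajectory, times, seed=rs)
        dphi = 4 * np.pi * config.carrier_freq * disp / config.wave_speed
        if config.full_physics:
            df = refl.if_freq * (1.0 + disp / refl.base_distance)  # [n_scans]
            arg_t = 2 * np.pi * np.outer(df, j)  # [n_scans, n]
            for c, ch in enumerate(config.channels):
                phi = refl.phase0 + refl.channel_phase_offsets.get(ch, 0.0) + dphi
                arg = arg_t + phi[:, None]
                p[:, c, :] += refl.amplitude * np.cos(arg)
                q[:, c, :] += refl.amplitude * np.sin(arg)
        else:
            # fixed IF: cos(a_j + phi_t) factorizes into a rank-2 product,
            # so the whole reflector is two outer products per channel
            a = 2 * np.pi * refl.if_freq * j
            cos_a, sin_a = np.cos(a), np.sin(a)
            for c, ch in enumerate(config.channels):
                phi = refl.phase0 + refl.channel_phase_offsets.get(ch, 0.0) + dphi
                cphi = refl.amplitude * np.cos(phi)
                sphi = refl.amplitude * np.sin(phi)
                p[:, c, :] += np.outer(cphi, cos_a) - np.outer(sphi, sin_a)
                q[:, c, :] += np.outer(sphi, cos_a) + np.outer(cphi, sin_a)

    if config.noise_sigma > 0:
        rng = np.random.default_rng(_subseed(seed, "noise"))
        p += rng.normal(0.0, config.noise_sigma, p.shape)
        q += rng.normal(0.0, config.noise_sigma, q.shape)

    if dtype is not np.float64:
        p = p.astype(dtype)
        q = q.astype(dtype)
    return Recording(
        p=p, q=q, times=times, config=config,
        scene_name=scene.name, label=scene.label, seed=int(seed),
    )


# ---------------------------------------------------------------------------
# scene presets
# ---------------------------------------------------------------------------

SCENE_PRESETS = (
    "human_single", "human_multi", "human_hidden",
    "empty", "fan", "arm", "curtain",
)

# breathing cycles last 2-8 s, i.e. rates 0.125-0.5 Hz; distractor periods and
# amplitudes are drawn from the same intervals so rate alone cannot separate
# the classes
_RATE_RANGE = (0.125, 0.5)
_AMP_RANGE = (0.002, 0.006)  # m, chest-wall displacement scale
_HIDDEN_ATTENUATION = 0.3


def _rand_reflector(rng, traj, amp_range=(0.5, 1.5)) -> Reflector:
    return Reflector(
        amplitude=float(rng.uniform(*amp_range)),
        if_freq=float(rng.uniform(0.02, 0.45)),
        trajectory=traj,
        phase0=float(rng.uniform(0, 2 * np.pi)),
        base_distance=float(rng.uniform(0.5, 5.0)),
        channel_phase_offsets={
            ch: float(rng.uniform(0, 2 * np.pi)) for ch in CANONICAL_CHANNELS
        },
    )


#: Relative std of the slow cycle-to-cycle wander of breathing rate and depth.
_RATE_JITTER = 0.15
_AMP_JITTER = 0.2


def _breathing_traj(rng, amp_scale: float = 1.0) -> Trajectory:
    return Trajectory("breathing", {
        "rate": float(rng.uniform(*_RATE_RANGE)),
        "amplitude": amp_scale * float(rng.uniform(*_AMP_RANGE)),
        "phase": float(rng.uniform(0, 2 * np.pi)),
        "rate_jitter": _RATE_JITTER,
        "amp_jitter": _AMP_JITTER,
        # one realization per torso: patches share the waveform
        "jitter_seed": int(rng.integers(0, 2**31)),
    })


def _clutter(rng, k: int) -> list[Reflector]:
    return [
        _rand_reflector(rng, Trajectory("static"), amp_range=(0.3, 1.0))
        for _ in range(k)
    ]


#: Moving objects are spatially extended: a torso, a fan, an arm reflect from
#: several patches whose displacements share one waveform but differ in
#: magnitude.  Summing the resulting differently-wrapped energy terms is what
#: lets the descriptor partially compensate phase wrapping, so scenes model it.
_PATCH_SCALE_RANGE = (0.2, 1.0)


def _patched(rng, traj: Trajectory, n_patches: int, amp_range=(0.5, 1.5)) -> list[Reflector]:
    """Reflector patches sharing one motion waveform at scaled magnitudes."""
    out = []
    for k in range(n_patches):
        s = 1.0 if k == 0 else float(rng.uniform(*_PATCH_SCALE_RANGE))
        p = dict(traj.params)
        if traj.kind == "curtain":
            p["step_std"] *= s
        else:
            p["amplitude"] *= s
        out.append(_rand_reflector(rng, Trajectory(traj.kind, p), amp_range))
    return out


def scene_preset(name: str, seed: int) -> Scene:
    """Build a randomized scene from one of the benchmark presets.

    Human presets contain one or more breathing reflectors (label 1);
    distractor presets contain fan / arm / curtain motion whose periods and
    amplitudes match the breathing ranges (label 0).  Every preset includes
    static clutter emulating walls and furniture.
    """
    if name not in SCENE_PRESETS:
        raise ValueError(
            f"unknown preset {name!r}; valid presets: {', '.join(SCENE_PRESETS)}"
        )
    rng = np.random.default_rng(_subseed(seed, "preset", name))
    clutter = _clutter(rng, int(rng.integers(2, 5)))

    if name == "human_single":
        refl = _patched(rng, _breathing_traj(rng), int(rng.integers(4, 7)))
        return Scene(tuple(refl + clutter), label=1, name=name)
    if name == "human_multi":
        refl = []
        for _ in range(int(rng.integers(2, 4))):
            refl += _patched(rng, _breathing_traj(rng), int(rng.integers(3, 6)))
        return Scene(tuple(refl + clutter), label=1, name=name)
    if name == "human_hidden":
        refl = _patched(rng, _breathing_traj(rng), int(rng.integers(4, 7)))
        refl = [replace(r, amplitude=r.amplitude * _HIDDEN_ATTENUATION)
                for r in refl]
        return Scene(tuple(refl + clutter), label=1, name=name)
    if name == "empty":
        return Scene(tuple(clutter), label=0, name=name)

    period = float(1.0 / rng.uniform(*_RATE_RANGE))  # 2-8 s, as for breathing
    amp = float(rng.uniform(*_AMP_RANGE))
    if name == "fan":
        traj = Trajectory("fan", {"period": period, "amplitude": amp})
        moving = _patched(rng, traj, int(rng.integers(3, 6)))
    elif name == "arm":
        traj = Trajectory("arm", {"period": period, "amplitude": amp})
        moving = _patched(rng, traj, int(rng.integers(2, 4)))
    else:  # curtain
        traj = Trajectory("curtain", {
            # step std chosen so the RMS excursion over one breathing cycle
            # matches the breathing amplitude scale
            "step_std": amp / 4.0,
            "clip": 2 * amp,
        })
        moving = _patched(rng, traj, int(rng.integers(3, 6)))
    return Scene(tuple(moving + clutter), label=0, name=name)
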