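"""Synthetic peri-saccadic LFP session generator.

The original recordings (multi-electrode V1 LFPs around 7-deg outside-in
saccades in 12 directions) are not publicly deposited, so this module
generates trial sets with the statistical structure the analysis assumes:

* eye traces with a single ballistic saccade of configurable amplitude and
  duration ending at t = 0 (fixation onset), plus fixational position noise;
* direction-tuned saccade-locked LFP templates — a small dip near fixation
  onset, a peak around 30–40 ms, and a second dip around 60–70 ms — whose
  shape varies smoothly with saccade direction so that neighboring directions
  are more similar than opposite ones;
* 1/f^alpha background noise with per-channel gain variation;
* a null mode (snr = 0) with no saccade-locked signal at all, for
  calibration of the downstream classifiers under chance conditions.

The saccade speed profile is a raised cosine: the position displacement has
the closed form A·(s/D − sin(2πs/D)/(2π))·2/… (see
:func:`saccade_displacement`), so the generated amplitude is exact rather
than quadrature-approximate.  Amplitude and duration are honoured exactly;
the peak speed is then 2·A/D (≈ 467 deg/s for 7 deg / 30 ms).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import TrialSet
from .errors import InvalidConfigError

__all__ = [
    "TemplateParams",
    "SynthConfig",
    "GroundTruth",
    "raised_cosine_speed",
    "saccade_displacement",
    "gen_eye_trace",
    "gen_template",
    "gen_noise",
    "gen_trialset",
]

# fixed stream labels so each random ingredient has its own child seed
_STREAM_TEMPLATE = 0
_STREAM_NOISE = 1
_STREAM_JITTER = 2
_STREAM_EYE = 3
_STREAM_GAIN = 4


@dataclass(frozen=True)
class TemplateParams:
    """Shape parameters of the dip/peak/dip saccade-locked LFP template.

    The template is a sum of three Gaussian lobes at ``latencies_ms`` with
    widths ``widths_ms`` and signed ``amplitudes`` (dip, peak, dip), windowed
    to zero outside ``support_ms``.  Direction tuning multiplies each lobe by
    a von-Mises bump of the angle between the saccade direction and the
    channel's preferred direction (concentration ``kappa``, floor
    ``tuning_floor``), and shifts lobe latencies by up to
    ``latency_dirmod_ms`` as direction rotates, so LFP *shape* — not just
    gain — depends on direction.
    """

    latencies_ms: tuple[float, float, float] = (5.0, 35.0, 65.0)
    widths_ms: tuple[float, float, float] = (8.0, 10.0, 12.0)
    amplitudes: tuple[float, float, float] = (-0.6, 1.0, -0.5)
    kappa: float = 2.0
    tuning_floor: float = 0.2
    latency_dirmod_ms: float = 6.0
    support_ms: tuple[float, float] = (-30.0, 100.0)
    scale: float = 1.0


@dataclass(frozen=True)
class SynthConfig:
    """Study-condition parameters of a synthetic session.

    Defaults mirror the original task: 12 saccade directions in 30-deg steps,
    7-deg saccades of ~30 ms duration, LFP at 1 kHz, trials spanning well
    beyond the pre-saccadic (−300…−201 ms) and post-saccadic (+200…+299 ms)
    fixation windows.
    """

    n_directions: int = 12
    trials_per_direction: int = 42
    n_channels: int = 16
    sample_rate_lfp: float = 1000.0
    eye_sample_rate: float = 1000.0
    trial_span: tuple[int, int] = (-400, 400)
    saccade_amplitude: float = 7.0
    saccade_duration: float = 30.0
    peak_speed: float | None = None  # derived from amplitude/duration if None
    template_params: TemplateParams = field(default_factory=TemplateParams)
    snr: float = 1.0
    channel_gain_spread: float = 0.3
    noise_exponent: float = 1.0
    latency_jitter_sd: float = 3.0
    latency_jitter_max: float = 10.0
    eye_noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_directions < 1 or self.trials_per_direction < 1:
            raise InvalidConfigError("need at least one direction and trial")
        if self.n_directions * self.trials_per_direction < 2:
            raise InvalidConfigError("need >= 2 trials overall")
        if self.sample_rate_lfp <= 0 or self.eye_sample_rate <= 0:
            raise InvalidConfigError("sample rates must be positive")
        if self.saccade_amplitude <= 0 or self.saccade_duration <= 0:
            raise InvalidConfigError("saccade amplitude and duration must be positive")
        if self.snr < 0:
            raise InvalidConfigError("snr must be >= 0 (0 selects null mode)")
        lo, hi = self.trial_span
        margin = self.latency_jitter_max
        if lo > -(300 + margin) or hi < 300 + margin:
            raise InvalidConfigError(
                "trial_span must contain the fixation windows (at least "
                f"[-{300 + margin:.0f}, +{300 + margin:.0f}] ms around t = 0)"
            )

    @property
    def directions(self) -> np.ndarray:
        """The configured direction set in degrees, e.g. 0, 30, …, 330."""
        return np.arange(self.n_directions) * (360.0 / self.n_directions)

    def time_axis(self) -> np.ndarray:
        """Integer-ms LFP time axis covering ``trial_span`` (end exclusive)."""
        return np.arange(self.trial_span[0], self.trial_span[1])


@dataclass
class GroundTruth:
    """Per-trial true event times plus the noise-free templates used."""

    events: pd.DataFrame  # trial_id, onset_ms, end_ms, direction_deg
    templates: np.ndarray  # (n_channels, n_directions, n_time), snr-scaled
    channel_gains: np.ndarray


def raised_cosine_speed(
    t_ms: np.ndarray,
    duration_ms: float,
    amplitude_deg: float | None = None,
    peak_deg_s: float | None = None,
    t_start_ms: float = 0.0,
) -> np.ndarray:
    """Raised-cosine speed pulse (deg/s) supported on [t_start, t_start + D].

    Exactly one of ``amplitude_deg`` (the pulse integral, i.e. saccade
    amplitude) or ``peak_deg_s`` must be given; the other is derived via
    peak = 2·A/D.
    """
    if duration_ms <= 0:
        raise InvalidConfigError("duration must be positive")
    if (amplitude_deg is None) == (peak_deg_s is None):
        raise InvalidConfigError("give exactly one of amplitude_deg or peak_deg_s")
    if peak_deg_s is None:
        if amplitude_deg <= 0:
            raise InvalidConfigError("amplitude must be positive")
        peak_deg_s = 2.0 * amplitude_deg / (duration_ms / 1000.0)
    t = np.asarray(t_ms, dtype=float)
    s = t - t_start_ms
    inside = (s >= 0) & (s <= duration_ms)
    out = np.zeros_like(t)
    out[inside] = peak_deg_s * 0.5 * (1.0 - np.cos(2.0 * np.pi * s[inside] / duration_ms))
    return out


def saccade_displacement(
    t_ms: np.ndarray,
    duration_ms: float,
    amplitude_deg: float,
    t_start_ms: float = 0.0,
) -> np.ndarray:
    """Closed-form displacement (deg) of the raised-cosine saccade profile.

    0 before the saccade, exactly ``amplitude_deg`` after it.
    """
    t = np.asarray(t_ms, dtype=float)
    s = np.clip(t - t_start_ms, 0.0, duration_ms)
    phase = s / duration_ms
    return amplitude_deg * (phase - np.sin(2.0 * np.pi * phase) / (2.0 * np.pi))


def gen_eye_trace(
    direction: float,
    cfg: SynthConfig,
    rng: np.random.Generator | None = None,
    end_ms: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Eye position (2, n) in deg and speed (n,) in deg/s for one trial.

    The trial starts on the eccentric fixation point and makes one saccade of
    the configured amplitude along ``direction`` (so direction 0 displaces the
    eye horizontally), ending at ``end_ms`` (default t = 0, fixation onset).
    Fixational noise of SD ``cfg.eye_noise_sd`` deg (smoothed white noise) is
    added to both position components when an ``rng`` is supplied.
    """
    dt = 1000.0 / cfg.eye_sample_rate
    t = np.arange(cfg.trial_span[0], cfg.trial_span[1], dt)
    amp, dur = cfg.saccade_amplitude, cfg.saccade_duration
    disp = saccade_displacement(t, dur, amp, t_start_ms=end_ms - dur)
    theta = np.deg2rad(direction)
    u = np.array([np.cos(theta), np.sin(theta)])
    # outside-in: start at -A*u (the eccentric point), land on the origin
    pos = (disp - amp)[None, :] * u[:, None]
    if rng is not None and cfg.eye_noise_sd > 0:
        noise = rng.normal(0.0, cfg.eye_noise_sd, size=(2, t.size))
        kernel = np.ones(9) / 9.0
        noise = np.apply_along_axis(
            lambda x: np.convolve(np.pad(x, 4, mode="edge"), kernel, mode="valid"),
            -1,
            noise,
        )
        pos = pos + noise
    vel = np.gradient(pos, axis=-1) * (cfg.eye_sample_rate)
    speed = np.sqrt(np.sum(vel**2, axis=0))
    return pos, speed


def _channel_tuning(cfg: SynthConfig, n_channels: int) -> dict[str, np.ndarray]:
    """Deterministic per-channel tuning draws (independent of trial noise)."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, _STREAM_TEMPLATE]))
    return {
        # spread preferred directions around the circle with jitter so a
        # multi-channel array covers all saccade directions
        "preferred_deg": (
            np.arange(n_channels) * (360.0 / max(n_channels, 1))
            + rng.uniform(-15.0, 15.0, n_channels)
        )
        % 360.0,
        "lobe_offset_deg": rng.normal(0.0, 25.0, size=(n_channels, 3)),
        "latency_jit_ms": rng.normal(0.0, 2.0, size=(n_channels, 3)),
    }


def _raw_template(
    direction: float, channel: int, cfg: SynthConfig, tuning: dict[str, np.ndarray]
) -> np.ndarray:
    p = cfg.template_params
    t = cfg.time_axis().astype(float)
    pref = tuning["preferred_deg"][channel]
    wave = np.zeros_like(t)
    for j in range(3):
        dtheta = np.deg2rad(direction - pref - tuning["lobe_offset_deg"][channel, j])
        tune = p.tuning_floor + (1.0 - p.tuning_floor) * np.exp(
            p.kappa * (np.cos(dtheta) - 1.0)
        )
        mu = (
            p.latencies_ms[j]
            + tuning["latency_jit_ms"][channel, j]
            + p.latency_dirmod_ms * np.sin(dtheta)
        )
        wave += (
            p.amplitudes[j] * tune * np.exp(-0.5 * ((t - mu) / p.widths_ms[j]) ** 2)
        )
    # enforce exact zeros outside the peri-saccadic support, with 10 ms
    # cosine ramps so the windowing does not add sharp edges
    lo, hi = p.support_ms
    ramp = 10.0
    mask = np.zeros_like(t)
    core = (t >= lo + ramp) & (t <= hi - ramp)
    mask[core] = 1.0
    rise = (t >= lo) & (t < lo + ramp)
    mask[rise] = 0.5 * (1 - np.cos(np.pi * (t[rise] - lo) / ramp))
    fall = (t > hi - ramp) & (t <= hi)
    mask[fall] = 0.5 * (1 - np.cos(np.pi * (hi - t[fall]) / ramp))
    return wave * mask * p.scale


def _template_norm(cfg: SynthConfig, tuning: dict[str, np.ndarray], channel: int) -> float:
    """Direction-averaged RMS over the support, used to put templates on the
    snr scale (snr = template RMS / noise RMS, noise RMS = 1)."""
    p = cfg.template_params
    lo, hi = p.support_ms
    t = cfg.time_axis()
    sup = (t >= lo) & (t <= hi)
    rms = [
        np.sqrt(np.mean(_raw_template(d, channel, cfg, tuning)[sup] ** 2))
        for d in cfg.directions
    ]
    return float(np.mean(rms))


def gen_template(direction: float, channel: int, cfg: SynthConfig) -> np.ndarray:
    """Noise-free saccade-locked LFP template on the trial time axis.

    Deterministic given (direction, channel, cfg); fixation-aligned (the dip/
    peak/dip morphology sits just after t = 0); identically zero outside the
    configured support.  Scaled so the direction-averaged RMS over the support
    is 1 (the session generator multiplies by snr and channel gain).
    """
    tuning = _channel_tuning(cfg, cfg.n_channels)
    wave = _raw_template(direction, channel, cfg, tuning)
    if cfg.template_params.scale == 0:
        return wave
    norm = _template_norm(cfg, tuning, channel)
    return wave / norm if norm > 0 else wave


def gen_noise(
    rng: np.random.Generator, shape: tuple[int, ...], alpha: float
) -> np.ndarray:
    """Gaussian 1/f^alpha noise with unit variance along the last axis."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n)
    gain = np.ones_like(f)
    gain[1:] = f[1:] ** (-alpha / 2.0)
    gain[0] = 0.0
    shaped = np.fft.irfft(spec * gain, n=n, axis=-1)
    sd = shaped.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return shaped / sd


def gen_trialset(cfg: SynthConfig) -> tuple[TrialSet, GroundTruth]:
    """Generate a full synthetic session.

    Each trial is 1/f^alpha background noise (unit SD per channel) plus the
    direction- and channel-specific template, scaled by snr and a per-channel
    gain, inserted at the trial's true fixation onset.  The true onset is
    jittered trial-to-trial by a truncated Gaussian (SD
    ``latency_jitter_sd`` ms, clipped at ±``latency_jitter_max`` ms, rounded
    to the 1 ms grid).  snr = 0 produces the null mode: pure noise, with
    events metadata still present.

    Returns
    -------
    (TrialSet, GroundTruth)
        Reproducible bit-for-bit under a fixed ``cfg.seed``.
    """
    root = np.random.SeedSequence(cfg.seed)
    rng_noise = np.random.default_rng(np.random.SeedSequence([cfg.seed, _STREAM_NOISE]))
    rng_jit = np.random.default_rng(np.random.SeedSequence([cfg.seed, _STREAM_JITTER]))
    rng_eye = np.random.default_rng(np.random.SeedSequence([cfg.seed, _STREAM_EYE]))
    rng_gain = np.random.default_rng(np.random.SeedSequence([cfg.seed, _STREAM_GAIN]))
    del root

    n_trials = cfg.n_directions * cfg.trials_per_direction
    time_ms = cfg.time_axis()
    n_time = time_ms.size
    dirs = cfg.directions

    gains = np.exp(rng_gain.normal(0.0, cfg.channel_gain_spread, cfg.n_channels))
    templates = np.stack(
        [
            np.stack([gen_template(d, ch, cfg) for d in dirs])
            for ch in range(cfg.n_channels)
        ]
    )  # (n_channels, n_directions, n_time)

    # truncated-Gaussian latency jitter on the 1 ms grid
    jit = rng_jit.normal(0.0, cfg.latency_jitter_sd, n_trials)
    jit = np.clip(jit, -cfg.latency_jitter_max, cfg.latency_jitter_max)
    jit = np.round(jit).astype(int)
    if cfg.latency_jitter_sd == 0:
        jit[:] = 0

    lfp = gen_noise(rng_noise, (n_trials, cfg.n_channels, n_time), cfg.noise_exponent)
    eye = np.empty((n_trials, 2, n_time))
    rows = []
    for trial in range(n_trials):
        d_idx = trial % cfg.n_directions
        direction = dirs[d_idx]
        if cfg.snr > 0:
            shifted = _shift(templates[:, d_idx, :], jit[trial])
            lfp[trial] += cfg.snr * gains[:, None] * shifted
        pos, _speed = gen_eye_trace(direction, cfg, rng_eye, end_ms=float(jit[trial]))
        eye[trial] = pos
        end = int(jit[trial])
        rows.append(
            {
                "trial_id": trial,
                "onset_ms": end - cfg.saccade_duration,
                "end_ms": end,
                "direction_deg": direction,
            }
        )
    events = pd.DataFrame(rows)

    meta = {"generator": "perisacc.synth", "config": asdict(cfg), "seed": cfg.seed}
    trialset = TrialSet(
        lfp=lfp,
        eye=eye,
        time_ms=time_ms,
        events=events,
        sample_rate=cfg.sample_rate_lfp,
        eye_sample_rate=cfg.eye_sample_rate,
        meta=meta,
    )
    truth = GroundTruth(
        events=events.copy(),
        templates=cfg.snr * gains[:, None, None] * templates,
        channel_gains=gains,
    )
    return trialset, truth


def _shift(waves: np.ndarray, shift_ms: int) -> np.ndarray:
    """Shift waveforms along the last axis by an integer ms, zero-filling."""
    if shift_ms == 0:
        return waves
    out = np.zeros_like(waves)
    if shift_ms > 0:
        out[..., shift_ms:] = waves[..., :-shift_ms]
    else:
        out[..., :shift_ms] = waves[..., -shift_ms:]
    return out
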