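"""Synthetic 8-channel FMG gait trials with ground-truth phase events.

Each gait cycle produces a quasi-periodic force envelope per channel: the
amplitude rises monotonically from Initial-Contact through Mid-Stance and
Pre-Swing, peaks late in Pre-Swing, drops sharply within the first tenth
of Swing (toe-off unloads the ankle band) and stays near baseline for the
rest of Swing.  Channels differ by random gain and a small random offset
of the peak position; cycle durations are lognormal around the configured
stride length; additive white Gaussian noise and a slow sinusoidal
baseline drift emulate FSR sensor behaviour.

The default stride duration of 2.60 s corresponds to slow treadmill
walking at 1-2 km/h; the per-speed defaults (3.0 / 2.6 / 2.2 s for 1, 1.5
and 2 km/h) bracket it.  Phase fractions follow standard gait-cycle
proportions (stance ~60% of the cycle).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import PchipInterpolator

from .io import EventList, FMGRecording

DEFAULT_SPEED_CYCLES = {"speed1": 3.0, "speed2": 2.6, "speed3": 2.2}


class SimulationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Trial-generation parameters.

    ``noise_sd`` and ``drift_amplitude`` are relative to the unit peak
    envelope amplitude; ``cycle_jitter_cv`` is the coefficient of
    variation of the lognormal cycle-duration distribution.
    """

    fs: float = 500.0
    n_channels: int = 8
    trial_s: float = 60.0
    cycle_s: float = 2.60
    phase_fractions: tuple = (0.12, 0.28, 0.20, 0.40)   # IC, MSt, PS, Sw
    cycle_jitter_cv: float = 0.05
    gain_range: tuple = (0.8, 1.2)
    peak_offset_sd: float = 0.02     # channel-specific shift of the peak, cycle fraction
    amp_jitter_sd: float = 0.03      # per-cycle amplitude factor SD
    noise_sd: float = 0.05
    drift_amplitude: float = 0.05
    drift_freq_hz: float = 0.3
    baseline: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        fr = np.asarray(self.phase_fractions, float)
        if fr.shape != (4,) or np.any(fr <= 0) or abs(fr.sum() - 1.0) > 1e-9:
            raise SimulationError("phase_fractions must be 4 positives summing to 1")
        if self.cycle_s <= 0 or self.fs <= 0 or self.n_channels < 1:
            raise SimulationError("fs, cycle_s and n_channels must be positive")
        if min(self.noise_sd, self.cycle_jitter_cv, self.drift_amplitude) < 0:
            raise SimulationError("noise/jitter/drift magnitudes must be >= 0")
        if self.trial_s < self.cycle_s:
            raise SimulationError("trial must be at least one cycle long")
        self.phase_fractions = tuple(fr.tolist())


def _cycle_durations(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Lognormal durations with mean cycle_s and CV cycle_jitter_cv,
    enough to cover the trial."""
    n_max = int(np.ceil(cfg.trial_s / cfg.cycle_s * 2)) + 4
    if cfg.cycle_jitter_cv == 0:
        durs = np.full(n_max, cfg.cycle_s)
    else:
        sigma2 = np.log1p(cfg.cycle_jitter_cv ** 2)
        mu = np.log(cfg.cycle_s) - sigma2 / 2.0
        durs = rng.lognormal(mu, np.sqrt(sigma2), size=n_max)
    keep = np.searchsorted(np.cumsum(durs), cfg.trial_s + durs[0]) + 1
    return durs[:keep]


def _channel_template(cfg: SimConfig, rng: np.random.Generator) -> PchipInterpolator:
    """Monotone piecewise-cubic envelope over one normalized cycle."""
    f1, f2, f3, f4 = cfg.phase_fractions
    b = cfg.baseline
    mid1 = b + (0.35 - b) * (1 + rng.normal(0, 0.08))
    mid2 = mid1 + (0.60 - mid1) * (1 + rng.normal(0, 0.08))
    peak_u = f1 + f2 + 0.9 * f3 + rng.normal(0, cfg.peak_offset_sd)
    peak_u = float(np.clip(peak_u, f1 + f2 + 0.5 * f3, f1 + f2 + 0.98 * f3))
    knots_u = [0.0, f1, f1 + f2, peak_u, f1 + f2 + f3,
               f1 + f2 + f3 + 0.1 * f4, 1.0]
    knots_a = [b, mid1, mid2, 1.0, 0.95, b, b]
    return PchipInterpolator(knots_u, knots_a)


def simulate_trial(cfg: SimConfig, rng: np.random.Generator | int | None = None,
                   **meta) -> tuple[FMGRecording, EventList]:
    """Generate one trial: a noisy 8-channel recording plus the exact
    ground-truth phase-transition events."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(cfg.seed if rng is None else rng)
    durs = _cycle_durations(cfg, rng)
    # recording begins at a random position within a gait cycle, as a
    # treadmill acquisition would; the cycle in progress started at -tau
    tau = rng.uniform(0.0, 1.0) * durs[0]
    starts = np.r_[0.0, np.cumsum(durs)] - tau

    fr = np.asarray(cfg.phase_fractions)
    ev_times, ev_phases = [], []
    for t0, D in zip(starts[:-1], durs):
        bounds = t0 + np.r_[0.0, np.cumsum(fr[:3])] * D
        for tb, ph in zip(bounds, (1, 2, 3, 4)):
            if 0.0 < tb < cfg.trial_s:
                ev_times.append(tb)
                ev_phases.append(ph)
    # state marker: the phase already in progress at t = 0
    u0 = tau / durs[0]
    phase0 = 1 + int(np.searchsorted(np.cumsum(fr[:3]), u0, side="right"))
    events = EventList(np.r_[0.0, ev_times], np.r_[phase0, ev_phases])

    n = int(round(cfg.trial_s * cfg.fs))
    t = np.arange(n) / cfg.fs
    idx = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, len(durs) - 1)
    u = (t - starts[idx]) / durs[idx]

    gains = rng.uniform(*cfg.gain_range, size=cfg.n_channels)
    templates = [_channel_template(cfg, rng) for _ in range(cfg.n_channels)]
    cyc_gain = 1.0 + rng.normal(0, cfg.amp_jitter_sd, size=len(durs))
    drift_f = rng.uniform(0.5, 1.0, size=cfg.n_channels) * cfg.drift_freq_hz
    drift_phi = rng.uniform(0, 2 * np.pi, size=cfg.n_channels)

    signal = np.empty((n, cfg.n_channels))
    for c in range(cfg.n_channels):
        env = templates[c](u) * cyc_gain[idx] * gains[c]
        drift = cfg.drift_amplitude * np.sin(2 * np.pi * drift_f[c] * t
                                             + drift_phi[c])
        noise = rng.normal(0, cfg.noise_sd, size=n) if cfg.noise_sd > 0 else 0.0
        signal[:, c] = env + drift + noise
    return FMGRecording(signal, fs=cfg.fs, **meta), events


def simulate_protocol(base_cfg: SimConfig | None = None, *,
                      n_subjects: int = 1, n_trials: int = 5,
                      speed_cycles: dict | None = None,
                      seed: int = 0) -> list[tuple[FMGRecording, EventList]]:
    """Simulate the walking protocol: ``n_trials`` trials at each of the
    configured speeds for each subject (defaults: 3 speeds x 5 trials).

    Every trial draws from an independent, reproducible child stream of
    ``seed``; recordings carry subject/trial/speed metadata.
    """
    base_cfg = base_cfg or SimConfig()
    speed_cycles = speed_cycles or DEFAULT_SPEED_CYCLES
    out = []
    streams = np.random.SeedSequence(seed).spawn(
        n_subjects * len(speed_cycles) * n_trials)
    k = 0
    for s in range(n_subjects):
        for speed, cyc in speed_cycles.items():
            for tr in range(n_trials):
                cfg = replace(base_cfg, cycle_s=cyc)
                rec, events = simulate_trial(
                    cfg, np.random.default_rng(streams[k]),
                    subject_id=f"S{s+1}", trial_id=f"T{tr+1}",
                    speed_label=speed)
                out.append((rec, events))
                k += 1
    return out
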