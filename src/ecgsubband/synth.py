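"""Seeded synthetic three-class ECG generator (AF / CHF / NSR).

Beats are rendered as sums of Gaussian bumps for the P, Q, R, S and T
waves — a standard phenomenological ECG model — on top of class-specific
rhythm statistics:

* NSR: regular RR intervals (low coefficient of variation), full P-QRS-T
  morphology, low noise.
* AF: short, highly irregular RR intervals, suppressed P wave, plus a
  band-limited 4-10 Hz fibrillatory baseline oscillation.
* CHF: low RR variability with reduced R amplitude, broadened/raised T
  wave and a higher additive-noise floor.

The generator provides desk-scale, download-free fixtures with the
statistical class structure the feature pipeline assumes (separable
Hjorth/entropy features), not physiological fidelity. Default model
parameters are committed constants; records are deterministic functions
of (model, duration, fs, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal_io import ECGSignal


@dataclass(frozen=True)
class Wave:
    """One Gaussian bump: center offset from the R peak (s), width (s), amplitude."""

    offset_s: float
    width_s: float
    amplitude: float


@dataclass(frozen=True)
class RhythmModel:
    """Class-specific waveform morphology and rhythm statistics."""

    label: str
    rr_mean_s: float
    rr_cv: float
    waves: dict  # name -> Wave for P, Q, R, S, T
    fib_amplitude: float = 0.0  # RMS of the fibrillatory oscillation
    fib_band_hz: tuple = (4.0, 10.0)
    noise_sd: float = 0.01

    def __post_init__(self) -> None:
        if not self.rr_mean_s > 0.3:
            raise ValueError("RR mean must exceed 0.3 s")
        if any(not w.width_s > 0 for w in self.waves.values()):
            raise ValueError("wave widths must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be non-negative")


def _waves(p_amp, q_amp, r_amp, s_amp, t_amp, t_width=0.06):
    return {
        "P": Wave(-0.20, 0.025, p_amp),
        "Q": Wave(-0.04, 0.010, q_amp),
        "R": Wave(0.00, 0.012, r_amp),
        "S": Wave(0.04, 0.010, s_amp),
        "T": Wave(0.25, t_width, t_amp),
    }


# Frozen defaults: tuned once for class-separable sub-band features and the
# qualitative ordering activity(NSR) < activity(AF) < activity(CHF) with NSR
# having the lowest mobility.
DEFAULT_MODELS: dict[str, RhythmModel] = {
    "NSR": RhythmModel(
        label="NSR", rr_mean_s=0.80, rr_cv=0.04,
        waves=_waves(0.15, -0.08, 1.00, -0.12, 0.30),
        fib_amplitude=0.0, noise_sd=0.010,
    ),
    "AF": RhythmModel(
        label="AF", rr_mean_s=0.55, rr_cv=0.22,
        waves=_waves(0.00, -0.08, 0.90, -0.12, 0.25),
        fib_amplitude=0.12, fib_band_hz=(4.0, 10.0), noise_sd=0.020,
    ),
    "CHF": RhythmModel(
        label="CHF", rr_mean_s=0.95, rr_cv=0.03,
        waves=_waves(0.08, -0.06, 0.45, -0.10, 0.35, t_width=0.09),
        fib_amplitude=0.0, noise_sd=0.060,
    ),
}


def _band_limited_noise(n: int, fs: float, band: tuple, rms: float,
                        rng: np.random.Generator) -> np.ndarray:
    """White noise FFT-masked to ``band`` Hz and rescaled to the target RMS."""
    w = rng.standard_normal(n)
    spec = np.fft.rfft(w)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[(freqs < band[0]) | (freqs > band[1])] = 0.0
    y = np.fft.irfft(spec, n=n)
    sd = y.std()
    return y * (rms / sd) if sd > 0 else y


def generate_record(model: RhythmModel, duration_s: float = 2.0, fs: float = 250.0,
                    seed: int = 0, record_id: str | None = None) -> ECGSignal:
    """Render one deterministic synthetic segment for a rhythm model.

    Beat onsets are drawn from the class RR distribution (normal, clipped
    at 0.3 s); every beat renders the five-bump template; AF adds the
    band-limited fibrillatory oscillation; white noise at the class SD is
    superimposed.
    """
    if duration_s < 2 * model.rr_mean_s:
        raise ValueError(
            f"duration {duration_s} s too short for two beats at RR {model.rr_mean_s} s"
        )
    rng = np.random.default_rng(seed)
    n = round(duration_s * fs)
    t = np.arange(n) / fs
    x = np.zeros(n)
    # beat train: start slightly before the window so edge beats are partial
    beat_t = -model.rr_mean_s * rng.uniform(0.0, 1.0)
    margin = 0.5
    while beat_t < duration_s + margin:
        if beat_t > -margin:
            for w in model.waves.values():
                if w.amplitude != 0.0:
                    c = beat_t + w.offset_s
                    x += w.amplitude * np.exp(-((t - c) ** 2) / (2.0 * w.width_s**2))
        rr = rng.normal(model.rr_mean_s, model.rr_cv * model.rr_mean_s)
        beat_t += max(rr, 0.3)
    if model.fib_amplitude > 0:
        x += _band_limited_noise(n, fs, model.fib_band_hz, model.fib_amplitude, rng)
    if model.noise_sd > 0:
        x += model.noise_sd * rng.standard_normal(n)
    return ECGSignal(x, fs=fs, label=model.label, record_id=record_id or f"{model.label}_{seed}")


def generate_dataset(n_per_class: int = 50, duration_s: float = 2.0, fs: float = 250.0,
                     seed: int = 0,
                     models: dict[str, RhythmModel] | None = None) -> list[ECGSignal]:
    """3 * n_per_class records (default 150, 50 per class) from one master seed.

    Per-record seeds are spawned deterministically from the master seed, so
    the full dataset is a pure function of its arguments.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    models = models or DEFAULT_MODELS
    records = []
    for ci, cls in enumerate(sorted(models)):
        for i in range(n_per_class):
            child = int(np.random.SeedSequence(entropy=seed, spawn_key=(ci, i))
                        .generate_state(1)[0] % (2**31))
            records.append(
                generate_record(models[cls], duration_s=duration_s, fs=fs,
                                seed=child, record_id=f"{cls}_{i:03d}")
            )
    return records
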