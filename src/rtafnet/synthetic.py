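"""Synthetic single-lead ECG rhythm simulator.

Generates labeled ECG records whose statistical structure carries the
clinical signatures an AF classifier exploits:

* **NSR** — regular RR intervals (low coefficient of variation) with a
  visible P wave before every QRS complex;
* **AF** — serially irregular RR intervals (i.i.d. Gamma-distributed,
  high CV), absent P waves, and a low-amplitude fibrillatory (f-wave)
  baseline around 6 Hz;
* **AFL** — saw-tooth flutter waves at the atrial rate with a variable
  AV block, so the ventricular rhythm is an integer multiple of the
  atrial cycle.

Each beat is rendered as a sum of five Gaussian kernels (P, Q, R, S, T)
placed relative to the R-peak time; baseline wander and white measurement
noise are added on top.  Two independent RNG streams (rhythm process,
noise) are derived from the master seed so that changing the noise level
never changes beat times.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "RhythmSpec",
    "SynthConfig",
    "ECGRecord",
    "DEFAULT_BEAT_WAVES",
    "default_rhythm_specs",
    "generate_rr_train",
    "render_ecg",
    "generate_record",
    "generate_dataset",
]

# Gaussian beat-kernel constants: wave -> (amplitude mV, width s, offset s
# relative to the R peak).  Amplitudes/widths are ballpark adult lead-II
# morphology; the classifier only needs the P/QRS/T geometry, not
# vectorcardiographic fidelity.
DEFAULT_BEAT_WAVES: dict[str, tuple[float, float, float]] = {
    "P": (0.15, 0.040, -0.160),
    "Q": (-0.10, 0.015, -0.040),
    "R": (1.00, 0.025, 0.000),
    "S": (-0.15, 0.015, 0.040),
    "T": (0.30, 0.070, 0.300),
}


@dataclass(frozen=True)
class RhythmSpec:
    """Statistical description of one rhythm class.

    Parameters
    ----------
    rhythm_class : {"NSR", "AF", "AFL"}
    mean_hr : float
        Mean ventricular rate, beats/min; must lie in [30, 220].
    rr_cv : float
        Coefficient of variation of the RR-interval process.
    p_amplitude : float
        P-wave amplitude in mV; forced to 0 for non-NSR rhythms.
    fwave_amplitude : float
        Fibrillatory/flutter baseline amplitude in mV; 0 for NSR.
    fwave_freq : float
        Fibrillatory/flutter wave frequency in Hz.
    """

    rhythm_class: str
    mean_hr: float = 70.0
    rr_cv: float = 0.05
    p_amplitude: float = 0.15
    fwave_amplitude: float = 0.0
    fwave_freq: float = 6.0

    def __post_init__(self) -> None:
        if self.rhythm_class not in ("NSR", "AF", "AFL"):
            raise ValueError(f"unknown rhythm class {self.rhythm_class!r}")
        if not 30.0 <= self.mean_hr <= 220.0:
            raise ValueError("mean_hr must lie in [30, 220] bpm")
        if self.rr_cv < 0:
            raise ValueError("rr_cv must be non-negative")
        if self.rhythm_class != "NSR" and self.p_amplitude != 0.0:
            object.__setattr__(self, "p_amplitude", 0.0)
        if self.rhythm_class == "NSR" and self.fwave_amplitude != 0.0:
            object.__setattr__(self, "fwave_amplitude", 0.0)


@dataclass(frozen=True)
class SynthConfig:
    """Rendering configuration shared by all rhythm classes."""

    fs: float = 400.0
    duration: float = 60.0
    beat_wave_params: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BEAT_WAVES)
    )
    noise_sd: float = 0.03
    wander_amplitude: float = 0.05
    wander_freq: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        # Nyquist guard: widest spectral content is the narrow Q/S kernels
        # (~1/(2*pi*width) Hz bandwidth) and the f-waves.
        if self.fs < 2 * max(self.wander_freq, 20.0):
            raise ValueError("fs too low for the generated frequency content")


@dataclass
class ECGRecord:
    """A raw (multi-)channel ECG record with rhythm-interval annotations.

    ``signal`` has shape (channels, samples) in mV; ``rhythm_intervals`` is a
    list of ``(start_s, end_s, tag)`` half-open intervals that tile
    ``[0, duration]`` exactly once, ordered and non-overlapping.
    """

    record_id: str
    signal: np.ndarray
    fs: float
    lead_names: list[str]
    rhythm_intervals: list[tuple[float, float, str]]

    def __post_init__(self) -> None:
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=float))
        self.validate()

    @property
    def duration(self) -> float:
        return self.signal.shape[1] / self.fs

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    def validate(self) -> None:
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2-D (channels x samples)")
        if len(self.lead_names) != self.signal.shape[0]:
            raise ValueError("one lead name per channel required")
        ivs = self.rhythm_intervals
        if ivs:
            if any(e <= s for s, e, _ in ivs):
                raise ValueError("rhythm intervals must have positive length")
            for (s0, e0, _), (s1, e1, _) in zip(ivs, ivs[1:]):
                if not np.isclose(e0, s1):
                    raise ValueError("rhythm intervals must tile the record")
            if not np.isclose(ivs[0][0], 0.0) or not np.isclose(
                ivs[-1][1], self.duration, atol=1.0 / self.fs
            ):
                raise ValueError("rhythm intervals must cover [0, duration]")


def default_rhythm_specs() -> dict[str, RhythmSpec]:
    """Per-class default specs used across the test-bench experiments."""
    return {
        "NSR": RhythmSpec("NSR", mean_hr=70.0, rr_cv=0.03, p_amplitude=0.15),
        "AF": RhythmSpec(
            "AF", mean_hr=95.0, rr_cv=0.25, p_amplitude=0.0,
            fwave_amplitude=0.08, fwave_freq=6.0,
        ),
        "AFL": RhythmSpec(
            "AFL", mean_hr=100.0, rr_cv=0.15, p_amplitude=0.0,
            fwave_amplitude=0.15, fwave_freq=5.0,
        ),
    }


def generate_rr_train(
    spec: RhythmSpec, duration: float, seed: int | np.random.Generator
) -> np.ndarray:
    """Generate R-peak times (s) on ``[0, duration)`` for one rhythm.

    NSR draws RR intervals from a low-CV Gaussian (an AR-free stand-in for
    respiratory sinus variability); AF draws i.i.d. positive Gamma intervals
    at the configured CV; AFL produces RR = k x atrial cycle with k a random
    small integer (variable AV block).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    mean_rr = 60.0 / spec.mean_hr
    n_max = int(np.ceil(duration / mean_rr * 2.5)) + 8

    if spec.rhythm_class == "NSR":
        rr = rng.normal(mean_rr, spec.rr_cv * mean_rr, size=n_max)
        rr = np.clip(rr, 0.25 * mean_rr, 2.0 * mean_rr)
    elif spec.rhythm_class == "AF":
        cv = max(spec.rr_cv, 1e-6)
        shape = 1.0 / cv**2
        rr = rng.gamma(shape, mean_rr / shape, size=n_max)
        rr = np.clip(rr, 0.2, 2.5)
    else:  # AFL: variable AV conduction over a fixed atrial cycle
        atrial_cycle = 1.0 / spec.fwave_freq
        k_mean = max(mean_rr / atrial_cycle, 1.0)
        base = int(np.floor(k_mean))
        # mix of base and base+1 blocks so the mean conduction ratio is hit
        p_hi = np.clip(k_mean - base, 0.0, 1.0)
        ks = base + (rng.random(n_max) < p_hi)
        rr = ks * atrial_cycle

    times = np.cumsum(rr) - rr[0] + 0.5 * mean_rr
    return times[times < duration]


def _fwave_baseline(
    t: np.ndarray, spec: RhythmSpec, rng: np.random.Generator
) -> np.ndarray:
    """Sinusoid at fwave_freq with slow per-cycle amplitude/phase jitter."""
    if spec.fwave_amplitude == 0.0:
        return np.zeros_like(t)
    # jitter sampled on a per-cycle grid then interpolated
    n_cycles = int(np.ceil(t[-1] * spec.fwave_freq)) + 2 if t.size else 2
    amp_knots = spec.fwave_amplitude * (1.0 + 0.3 * rng.standard_normal(n_cycles))
    ph_knots = np.cumsum(0.4 * rng.standard_normal(n_cycles))
    knot_t = np.arange(n_cycles) / spec.fwave_freq
    amp = np.interp(t, knot_t, amp_knots)
    phase = np.interp(t, knot_t, ph_knots)
    wave = amp * np.sin(2 * np.pi * spec.fwave_freq * t + phase)
    if spec.rhythm_class == "AFL":
        # saw-tooth flavour: add a harmonic to sharpen the flutter waves
        wave = wave + 0.5 * amp * np.sin(4 * np.pi * spec.fwave_freq * t + 2 * phase)
    return wave


def render_ecg(
    rr_times: np.ndarray,
    spec: RhythmSpec,
    config: SynthConfig,
    record_id: str = "synthetic",
    noise_rng: np.random.Generator | None = None,
) -> ECGRecord:
    """Render R-peak times into a single-lead annotated :class:`ECGRecord`.

    Each beat is a sum of Gaussian P/Q/R/S/T kernels placed relative to its
    R time; the P kernel is omitted when ``spec.p_amplitude`` is 0.  AF/AFL
    add the fibrillatory baseline; wander and white noise are controlled by
    ``config`` and drawn from a dedicated noise stream.
    """
    rr_times = np.asarray(rr_times, dtype=float)
    if rr_times.size and (rr_times.min() < 0 or rr_times.max() >= config.duration):
        raise ValueError("rr_times must lie within [0, duration)")
    if np.any(np.diff(rr_times) < 0):
        raise ValueError("rr_times must be sorted")
    rng = (
        noise_rng
        if noise_rng is not None
        else np.random.default_rng(config.seed)
    )
    n = int(round(config.fs * config.duration))
    t = np.arange(n) / config.fs
    sig = np.zeros(n)

    for name, (amp, width, offset) in config.beat_wave_params.items():
        if name == "P":
            if spec.p_amplitude == 0.0:
                continue
            amp = spec.p_amplitude
        for r in rr_times:
            c = r + offset
            lo = max(0, int((c - 5 * width) * config.fs))
            hi = min(n, int((c + 5 * width) * config.fs) + 1)
            if hi > lo:
                sig[lo:hi] += amp * np.exp(-0.5 * ((t[lo:hi] - c) / width) ** 2)

    sig += _fwave_baseline(t, spec, rng)
    if config.wander_amplitude > 0:
        wander_phase = rng.uniform(0, 2 * np.pi)
        sig += config.wander_amplitude * np.sin(
            2 * np.pi * config.wander_freq * t + wander_phase
        )
    if config.noise_sd > 0:
        sig += config.noise_sd * rng.standard_normal(n)

    return ECGRecord(
        record_id=record_id,
        signal=sig[None, :],
        fs=config.fs,
        lead_names=["II"],
        rhythm_intervals=[(0.0, config.duration, spec.rhythm_class)],
    )


def generate_record(
    spec: RhythmSpec, config: SynthConfig, record_id: str = "synthetic"
) -> ECGRecord:
    """Generate one record: RR train + rendering, with independent
    rhythm/noise RNG streams spawned from ``config.seed``."""
    ss = np.random.SeedSequence(config.seed)
    rhythm_ss, noise_ss = ss.spawn(2)
    rr = generate_rr_train(spec, config.duration, np.random.default_rng(rhythm_ss))
    return render_ecg(
        rr, spec, config, record_id=record_id,
        noise_rng=np.random.default_rng(noise_ss),
    )


def generate_dataset(
    n_per_class: int,
    specs: dict[str, RhythmSpec] | None = None,
    config: SynthConfig | None = None,
) -> list[ECGRecord]:
    """Generate ``n_per_class`` records per rhythm class.

    Record seeds are derived deterministically from the master seed in
    ``config.seed``, so the whole dataset is reproducible bit-for-bit.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if specs is None:
        specs = {k: v for k, v in default_rhythm_specs().items() if k != "AFL"}
    if config is None:
        config = SynthConfig()
    master = np.random.SeedSequence(config.seed)
    child_seeds = master.generate_state(len(specs) * n_per_class) % (2**31)
    records: list[ECGRecord] = []
    i = 0
    for cls in specs:
        for j in range(n_per_class):
            cfg = replace(config, seed=int(child_seeds[i]))
            records.append(
                generate_record(specs[cls], cfg, record_id=f"{cls}_{j:03d}")
            )
            i += 1
    return records
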