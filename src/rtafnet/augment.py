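"""Class-selective training-set augmentation.

Only the minority AF class in the *training* split is augmented: each AF
window gains ``ratio - 1`` copies, each produced by adding Gaussian noise at
2% of the window's standard deviation and then masking one contiguous
interior span of 2-10% of the samples with linear interpolation.  The
default ratio of 2.0 doubles the AF count; non-target windows pass through
byte-for-byte untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .preprocess import AF, Window

__all__ = [
    "AugmentConfig",
    "add_gaussian_noise",
    "random_mask",
    "augment_training_set",
]


@dataclass(frozen=True)
class AugmentConfig:
    noise_frac: float = 0.02
    mask_frac_range: tuple[float, float] = (0.02, 0.10)
    ratio: float = 2.0
    target_class: str = AF
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.mask_frac_range
        if self.noise_frac < 0:
            raise ValueError("noise_frac must be >= 0")
        if not 0 <= lo <= hi < 1:
            raise ValueError("need 0 <= mask lower <= upper < 1")
        if self.ratio < 1:
            raise ValueError("ratio must be >= 1")


def add_gaussian_noise(
    samples: np.ndarray, noise_frac: float, seed: int | np.random.Generator
) -> np.ndarray:
    """Add i.i.d. zero-mean Gaussian noise with SD = noise_frac x SD(input)."""
    samples = np.asarray(samples, dtype=float)
    if noise_frac == 0:
        return samples.copy()
    sd = samples.std()
    if sd == 0:
        raise ValueError("cannot scale noise to a constant window")
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    return samples + rng.normal(0.0, noise_frac * sd, size=samples.shape)


def random_mask(
    samples: np.ndarray,
    mask_frac_range: tuple[float, float] = (0.02, 0.10),
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Replace one contiguous interior span by linear interpolation.

    The span length is uniform in ``[lo, hi]`` fractions of the window; the
    span never touches the first or last sample, so both interpolation
    endpoints always exist and are preserved.
    """
    samples = np.asarray(samples, dtype=float)
    n = samples.size
    if n < 3:
        raise ValueError("window too short to mask")
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    lo, hi = mask_frac_range
    span = int(round(rng.uniform(lo, hi) * n))
    span = max(1, min(span, n - 2))
    start = int(rng.integers(1, n - span))  # interior: [1, n-1-span]
    out = samples.copy()
    a, b = out[start - 1], out[start + span]
    # affine fill strictly between the flanking samples
    out[start : start + span] = a + (b - a) * np.arange(1, span + 1) / (span + 1)
    return out


def augment_training_set(
    windows: list[Window], config: AugmentConfig = AugmentConfig()
) -> list[Window]:
    """Expand the target class to ``round(ratio x count)`` windows.

    Every augmented copy applies noise then masking with fresh seeds and is
    flagged ``is_augmented`` while keeping the source window's provenance.
    Refuses windows already flagged augmented (guards against applying the
    operation to anything but the raw training split).
    """
    if any(w.is_augmented for w in windows):
        raise ValueError("input already contains augmented windows")
    n_copies_total = 0
    targets = [w for w in windows if w.label == config.target_class]
    if targets:
        n_copies_total = int(round(config.ratio * len(targets))) - len(targets)
    ss = np.random.SeedSequence(config.seed)
    out = list(windows)
    if n_copies_total <= 0:
        return out
    streams = ss.spawn(n_copies_total)
    k = 0
    # round-robin over target windows so copies are spread evenly
    while k < n_copies_total:
        src = targets[k % len(targets)]
        rng = np.random.default_rng(streams[k])
        x = add_gaussian_noise(src.samples, config.noise_frac, rng)
        x = random_mask(x, config.mask_frac_range, rng)
        out.append(replace(src, samples=x, is_augmented=True))
        k += 1
    return out
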