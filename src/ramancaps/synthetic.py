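"""Synthetic Raman spectra with class-dependent crest signatures.

Real grain spectra sit on a broad fluorescence baseline with starch and
sugar bands at the seven reference shifts.  The generator emulates that
structure: a smooth baseline (low-order polynomial plus a broad
sinusoid), Gaussian bands at the reference shifts whose amplitudes
jitter lognormally around class-specific means, and white detector
noise, clipped at zero.  The three growth-duration classes differ in the
relative amplitudes of the starch/sugar crests (480, 941 and 1129
cm^-1), so classes are separable through band ratios that survive the
per-spectrum min-max normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .imaging import REFERENCE_SHIFTS
from .io import DEFAULT_CLASS_NAMES, VARIETY_LABELS, RamanSpectrum, SampleSet, default_axis

#: Indices (into REFERENCE_SHIFTS) of the crests that carry the class
#: signal: the starch/sugar bands at 480, 941 and 1129 cm^-1.
DISCRIMINATIVE_CRESTS = (0, 2, 3)

#: Mean band amplitudes (a.u.) shared by all classes before class scaling.
BASE_AMPLITUDES = (950.0, 520.0, 1350.0, 820.0, 430.0, 470.0, 1100.0)

#: Multiplier applied to the discriminative crests per class; adjacent
#: classes differ by ~20% in those band amplitudes.
CLASS_MULTIPLIERS = {0: 1.0, 1: 1.2, 2: 1.0 / 1.2}


@dataclass(frozen=True)
class ClassProfile:
    """Statistical description of one class's spectra."""

    label: int
    peak_amplitudes: tuple[float, ...]
    peak_width_sigma: float = 8.0  # cm^-1, ~19 cm^-1 FWHM Raman bands
    amplitude_cv: float = 0.03
    intensity_cv: float = 0.10
    baseline_scale: float = 300.0
    noise_sigma: float = 6.0

    def __post_init__(self) -> None:
        if len(self.peak_amplitudes) != len(REFERENCE_SHIFTS):
            raise ValueError("one amplitude per reference crest is required")
        if min(self.peak_amplitudes) <= 0 or self.peak_width_sigma <= 0:
            raise ValueError("amplitudes and widths must be positive")
        if self.amplitude_cv < 0:
            raise ValueError("amplitude_cv must be non-negative")


def class_profile(label: int, **overrides) -> ClassProfile:
    """Default profile for one growth-duration class."""
    mult = CLASS_MULTIPLIERS[label]
    amps = tuple(
        a * (mult if k in DISCRIMINATIVE_CRESTS else 1.0)
        for k, a in enumerate(BASE_AMPLITUDES)
    )
    return ClassProfile(label=label, peak_amplitudes=amps, **overrides)


@dataclass(frozen=True)
class SynthConfig:
    """Dataset-level template: varieties, per-variety sizes, axis, seed.

    The default mirrors the field study: 7 varieties x 35 grains with the
    variety -> class mapping LJ47/KY131/LJ11/HH311 -> 0, QJ1 -> 1,
    SJ13/HJ313 -> 2 (245 spectra in total).
    """

    varieties: tuple[tuple[str, ClassProfile, int], ...]
    axis_start: float = 200.0
    axis_stop: float = 3400.0
    axis_step: float = 1.4
    master_seed: int = 7
    variety_jitter_cv: float = 0.02

    def axis(self) -> np.ndarray:
        return default_axis(self.axis_start, self.axis_stop, self.axis_step)

    def __post_init__(self) -> None:
        axis = self.axis()
        margin = 60 * self.axis_step
        for shift in REFERENCE_SHIFTS:
            if not (axis[0] + margin <= shift <= axis[-1] - margin):
                raise ValueError(
                    f"axis must cover crest {shift} cm^-1 with >= 60 grid points margin"
                )


def default_config(master_seed: int = 7, n_per_variety: int = 35, **profile_overrides) -> SynthConfig:
    """The standard 7 x 35 three-class dataset template."""
    varieties = tuple(
        (name, class_profile(label, **profile_overrides), n_per_variety)
        for name, label in VARIETY_LABELS.items()
    )
    return SynthConfig(varieties=varieties, master_seed=master_seed)


def degenerate_config(master_seed: int = 7, n_per_variety: int = 35) -> SynthConfig:
    """Negative control: all classes share one profile (no class signal)."""
    varieties = tuple(
        (name, replace(class_profile(0), label=label), n_per_variety)
        for name, label in VARIETY_LABELS.items()
    )
    return SynthConfig(varieties=varieties, master_seed=master_seed)


def _lognormal_unit_mean(rng: np.random.Generator, cv: float) -> float:
    """Lognormal draw with mean 1 and the given coefficient of variation."""
    if cv <= 0:
        return 1.0
    s = np.sqrt(np.log1p(cv**2))
    return float(rng.lognormal(-0.5 * s**2, s))


def _baseline(axis: np.ndarray, scale: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth fluorescence-like baseline: quadratic trend + broad sinusoid.

    The sinusoid period (4500 cm^-1) is far above the first filter's
    cutoff wavelength (~1400 cm^-1 at wn = 0.002 on the 1.4 cm^-1 grid),
    so the first zero-phase pass tracks the whole baseline (leakage into
    the difference signal < 1%) and the difference step removes it, as
    the preprocessing scheme assumes of real fluorescence backgrounds.
    Phase and amplitudes vary per sample.
    """
    t = (axis - axis[0]) / (axis[-1] - axis[0])
    phase = rng.uniform(0, 2 * np.pi)
    trend_amp = rng.uniform(0.8, 1.2)
    wave_amp = 0.25 * rng.uniform(0.6, 1.4)
    trend = trend_amp * (0.6 + 0.5 * t - 0.35 * t**2)
    wave = wave_amp * np.sin(2 * np.pi * (axis - axis[0]) / 4500.0 + phase)
    return scale * (trend + wave)


def generate_spectrum(
    profile: ClassProfile,
    axis: np.ndarray,
    seed: int | np.random.SeedSequence,
    sample_id: str = "synthetic",
    variety: str = "",
    amplitude_multipliers: np.ndarray | None = None,
) -> RamanSpectrum:
    """Draw one spectrum from a class profile. Deterministic per seed."""
    rng = np.random.default_rng(seed)
    axis = np.asarray(axis, dtype=float)
    intensity = _baseline(axis, profile.baseline_scale, rng)
    # one overall scattering-intensity factor per grain (focus, grain
    # position); band *ratios* jitter much less, as in real Raman spectra
    global_factor = _lognormal_unit_mean(rng, profile.intensity_cv)
    cv = profile.amplitude_cv
    for k, (center, amp) in enumerate(zip(REFERENCE_SHIFTS, profile.peak_amplitudes)):
        if amplitude_multipliers is not None:
            amp = amp * amplitude_multipliers[k]
        amp = amp * global_factor * _lognormal_unit_mean(rng, cv)
        intensity += amp * np.exp(-0.5 * ((axis - center) / profile.peak_width_sigma) ** 2)
    if profile.noise_sigma > 0:
        intensity += rng.normal(0.0, profile.noise_sigma, size=len(axis))
    return RamanSpectrum(
        sample_id=sample_id,
        variety=variety,
        label=profile.label,
        shifts=axis,
        intensities=np.clip(intensity, 0.0, None),
        n_scans=1,
    )


def generate_dataset(cfg: SynthConfig | None = None) -> SampleSet:
    """Generate the full synthetic SampleSet.

    Seeds are spawned hierarchically (master -> variety -> sample), so
    changing one variety's branch leaves every other variety's spectra
    untouched.  Each variety carries a small deterministic multiplier on
    the band amplitudes (lognormal, ``variety_jitter_cv``) emulating
    variety-level biological variation within a class.
    """
    cfg = cfg or default_config()
    axis = cfg.axis()
    spectra = []
    for vi, (name, profile, n_samples) in enumerate(cfg.varieties):
        vseq = np.random.SeedSequence(entropy=(cfg.master_seed, vi))
        vrng = np.random.default_rng(vseq)
        if cfg.variety_jitter_cv > 0:
            s = np.sqrt(np.log1p(cfg.variety_jitter_cv**2))
            mult = vrng.lognormal(-0.5 * s**2, s, size=len(REFERENCE_SHIFTS))
        else:
            mult = np.ones(len(REFERENCE_SHIFTS))
        for si in range(n_samples):
            spectra.append(
                generate_spectrum(
                    profile,
                    axis,
                    seed=np.random.SeedSequence(entropy=(cfg.master_seed, vi, si)),
                    sample_id=f"{name}_{si:03d}",
                    variety=name,
                    amplitude_multipliers=mult,
                )
            )
    return SampleSet(spectra=spectra, class_names=dict(DEFAULT_CLASS_NAMES))
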