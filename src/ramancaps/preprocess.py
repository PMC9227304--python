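"""Spectral preprocessing: zero-phase low-pass filtering and baseline
removal by differencing.

The scheme has three stages.  A low-order Butterworth low-pass filter is
applied forward and backward (zero phase) to the min-max-normalized
spectrum; at a very low cutoff (``wn = 0.002`` of Nyquist) the filtered
trace ``y1`` tracks the broad fluorescence baseline.  The difference
``X = x - y1`` then isolates the vibrational crests.  A second, wider
zero-phase pass (``wn = 0.03``) smooths residual clutter; its output
``Xs`` is the signal from which crest windows are cut.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal

from .io import RamanSpectrum


class DegenerateRangeError(ValueError):
    """Raised when a constant signal is min-max normalized."""


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth low-pass design parameters.

    ``wn`` is the critical frequency as a fraction of Nyquist
    (wn = 2 x cutoff frequency / sampling frequency).
    """

    N: int = 2
    wn: float = 0.002

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError(f"filter order must be >= 1, got {self.N}")
        if not 0.0 < self.wn < 1.0:
            raise ValueError(f"wn must lie in (0, 1), got {self.wn}")


@dataclass(frozen=True)
class FilterCoefficients:
    """Transfer-function coefficients ``b`` (numerator) and ``a`` (denominator)."""

    b: np.ndarray
    a: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "b", np.asarray(self.b, dtype=float))
        object.__setattr__(self, "a", np.asarray(self.a, dtype=float))
        if self.b.shape != self.a.shape:
            raise ValueError("b and a must have equal length")
        if self.a[0] == 0:
            raise ValueError("a[0] must be nonzero")
        dc = self.b.sum() / self.a.sum()
        if abs(dc - 1.0) >= 1e-9:
            raise ValueError(f"low-pass DC gain must be 1, got {dc!r}")

    @property
    def order(self) -> int:
        return len(self.b) - 1


@dataclass
class ProcessedSignal:
    """All intermediate products of the preprocessing chain.

    ``x`` is the (normalized) input to the difference step, so the
    conservation identity ``x == X + y1`` holds exactly.  ``x_raw`` keeps
    the untouched intensities for reference.
    """

    shifts: np.ndarray
    x: np.ndarray
    y1: np.ndarray
    X: np.ndarray
    Xs: np.ndarray
    x_raw: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.shifts)
        for name in ("x", "y1", "X", "Xs"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length differs from the shift axis")
        if self.x_raw is None:
            self.x_raw = self.x


def design_lowpass(spec: FilterSpec) -> FilterCoefficients:
    """Design a Butterworth low-pass filter for the given order and cutoff."""
    b, a = sp_signal.butter(spec.N, spec.wn, btype="low")
    return FilterCoefficients(b=b, a=a)


def zero_phase_filter(x: np.ndarray, coeffs: FilterCoefficients) -> np.ndarray:
    """Apply the filter forward then backward so the output has no phase lag.

    Uses odd-reflection padding of length ``3 * (order + 1)`` at each end,
    which keeps the endpoints stable and makes results reproducible
    bit-for-bit.
    """
    x = np.asarray(x, dtype=float)
    padlen = 3 * (coeffs.order + 1)
    if len(x) <= padlen:
        raise ValueError(
            f"signal of length {len(x)} is too short for zero-phase filtering "
            f"(needs more than {padlen} samples)"
        )
    return sp_signal.filtfilt(coeffs.b, coeffs.a, x, padtype="odd", padlen=padlen)


def minmax_normalize(x: np.ndarray) -> np.ndarray:
    """Map a signal affinely onto [0, 1] to remove the intensity dimension."""
    x = np.asarray(x, dtype=float)
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise DegenerateRangeError("cannot min-max normalize a constant signal")
    return (x - lo) / (hi - lo)


def peak_signal(
    spectrum: RamanSpectrum,
    first: FilterSpec = FilterSpec(2, 0.002),
    second: FilterSpec = FilterSpec(2, 0.03),
    normalize: bool = True,
) -> ProcessedSignal:
    """Run the full preprocessing chain on one spectrum.

    ``y1`` is the first zero-phase pass over the normalized intensities,
    ``X = x - y1`` is the baseline-free difference signal, and ``Xs`` is
    ``X`` after the second, wider zero-phase pass.
    """
    x_raw = spectrum.intensities
    x = minmax_normalize(x_raw) if normalize else np.asarray(x_raw, dtype=float)
    y1 = zero_phase_filter(x, design_lowpass(first))
    X = x - y1
    Xs = zero_phase_filter(X, design_lowpass(second))
    return ProcessedSignal(shifts=spectrum.shifts, x=x, y1=y1, X=X, Xs=Xs, x_raw=x_raw)


def detect_peaks(x: np.ndarray, min_prominence_frac: float = 0.05) -> list[int]:
    """Find local maxima whose topographic prominence exceeds a fraction of
    the signal maximum.

    Diagnostic only: the imaging pipeline uses the fixed reference crests,
    not rediscovered ones.
    """
    x = np.asarray(x, dtype=float)
    if not 0.0 < min_prominence_frac < 1.0:
        raise ValueError("min_prominence_frac must lie in (0, 1)")
    if x.max() == x.min():
        raise ValueError("cannot detect peaks in a constant signal")
    idx, _ = sp_signal.find_peaks(x, prominence=min_prominence_frac * x.max())
    return sorted(int(i) for i in idx)
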