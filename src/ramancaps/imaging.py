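"""Folding the processed spectrum into a 28x28 pseudo-image.

Seven fixed reference crests (starch/sugar bands) are each cut from the
twice-filtered difference signal as a 112-point window: 56 points before
the crest center and 55 after, center included.  Each window is split
into 4 consecutive 28-point segments; the segments are stacked side by
side so every crest contributes a 28x4 block, and the seven blocks
concatenate into a 28x28 matrix.  The fold is a pure rearrangement of the
7 x 112 = 784 extracted values and is exactly invertible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import RamanSpectrum
from .preprocess import FilterSpec, ProcessedSignal, peak_signal

#: Reference crest positions (cm^-1), bands of amylum (starch) and sugars.
REFERENCE_SHIFTS = (480.0, 865.0, 941.0, 1129.0, 1339.0, 1461.0, 2910.0)


class WindowBoundsError(ValueError):
    """A crest window would fall off the edge of the signal."""


@dataclass(frozen=True)
class CrestConfig:
    """Geometry of the crest-window extraction and image fold."""

    reference_shifts: tuple[float, ...] = REFERENCE_SHIFTS
    points_before: int = 56
    points_after: int = 55
    segment_length: int = 28
    segments_per_window: int = 4

    def __post_init__(self) -> None:
        if self.points_before + self.points_after + 1 != self.window_length:
            raise ValueError(
                "points_before + points_after + 1 must equal "
                "segment_length * segments_per_window"
            )
        if len(self.reference_shifts) * self.segments_per_window != self.image_side:
            raise ValueError(
                "number of crests x segments_per_window must equal the image side"
            )

    @property
    def window_length(self) -> int:
        return self.segment_length * self.segments_per_window

    @property
    def image_side(self) -> int:
        return self.segment_length

    @property
    def n_crests(self) -> int:
        return len(self.reference_shifts)


@dataclass
class PeakWindow:
    """A fixed-length slice of the processed signal around one crest."""

    center_shift: float
    center_index: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("window values must be 1-D")


@dataclass
class SampleImage:
    """A 28x28 pseudo-image for one sample, the capsule network's input."""

    pixels: np.ndarray
    sample_id: str = ""
    label: int = 0
    variety: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError(f"image must be square 2-D, got shape {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image contains non-finite values")


def shift_to_index(shifts: np.ndarray, target: float) -> int:
    """Index of the axis value nearest ``target``; ties break low."""
    shifts = np.asarray(shifts, dtype=float)
    if not shifts[0] <= target <= shifts[-1]:
        raise ValueError(
            f"target {target} cm^-1 outside axis range "
            f"[{shifts[0]}, {shifts[-1]}] cm^-1"
        )
    return int(np.argmin(np.abs(shifts - target)))


def extract_window(
    processed: ProcessedSignal | np.ndarray,
    center_index: int,
    cfg: CrestConfig = CrestConfig(),
    center_shift: float = float("nan"),
) -> PeakWindow:
    """Cut the 112-point window ``[center - 56, center + 55]`` (inclusive)
    from the twice-filtered difference signal."""
    sig = processed.Xs if isinstance(processed, ProcessedSignal) else np.asarray(processed)
    lo = center_index - cfg.points_before
    hi = center_index + cfg.points_after
    if lo < 0 or hi >= len(sig):
        raise WindowBoundsError(
            f"crest at index {center_index} (shift {center_shift} cm^-1) needs "
            f"signal indices [{lo}, {hi}] but the signal has length {len(sig)}"
        )
    if isinstance(processed, ProcessedSignal) and np.isnan(center_shift):
        center_shift = float(processed.shifts[center_index])
    return PeakWindow(
        center_shift=center_shift,
        center_index=center_index,
        values=sig[lo : hi + 1].copy(),
    )


def fold_sample(
    windows: list[PeakWindow],
    cfg: CrestConfig = CrestConfig(),
    sample_id: str = "",
    label: int = 0,
    variety: str = "",
) -> SampleImage:
    """Superpose the 4 segments of every crest window into one image.

    Layout: crest ``w`` occupies columns ``4w .. 4w+3``; its segment ``s``
    is column ``4w + s`` with the segment's 28 values running down the
    rows, i.e. ``pixels[r, 4w + s] = windows[w].values[28 s + r]``.
    """
    if len(windows) != cfg.n_crests:
        raise ValueError(f"expected {cfg.n_crests} windows, got {len(windows)}")
    for w in windows:
        if len(w.values) != cfg.window_length:
            raise ValueError(
                f"window at {w.center_shift} cm^-1 has {len(w.values)} values, "
                f"expected {cfg.window_length}"
            )
    vals = np.stack([w.values for w in windows])  # (7, 112)
    blocks = vals.reshape(cfg.n_crests, cfg.segments_per_window, cfg.segment_length)
    pixels = blocks.transpose(2, 0, 1).reshape(cfg.image_side, cfg.image_side)
    return SampleImage(pixels=pixels, sample_id=sample_id, label=label, variety=variety)


def unfold_image(image: SampleImage | np.ndarray, cfg: CrestConfig = CrestConfig()) -> np.ndarray:
    """Invert :func:`fold_sample`: recover the (n_crests, 112) window values."""
    pixels = image.pixels if isinstance(image, SampleImage) else np.asarray(image)
    side = cfg.image_side
    if pixels.shape != (side, side):
        raise ValueError(f"expected a {side}x{side} image, got {pixels.shape}")
    blocks = pixels.reshape(side, cfg.n_crests, cfg.segments_per_window)
    return blocks.transpose(1, 2, 0).reshape(cfg.n_crests, cfg.window_length)


def image_from_spectrum(
    spectrum: RamanSpectrum,
    cfg: CrestConfig = CrestConfig(),
    first: FilterSpec = FilterSpec(2, 0.002),
    second: FilterSpec = FilterSpec(2, 0.03),
    normalize: bool = True,
) -> SampleImage:
    """Full chain: preprocess, window the 7 crests, fold to 28x28."""
    processed = peak_signal(spectrum, first=first, second=second, normalize=normalize)
    windows = []
    for shift in cfg.reference_shifts:
        center = shift_to_index(processed.shifts, shift)
        windows.append(extract_window(processed, center, cfg, center_shift=shift))
    return fold_sample(
        windows,
        cfg,
        sample_id=spectrum.sample_id,
        label=spectrum.label,
        variety=spectrum.variety,
    )


def export_png(image: SampleImage, path) -> None:
    """Save a viridis pseudocolor rendering of the image for inspection."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(3, 3))
    ax.imshow(image.pixels, cmap="viridis")
    ax.set_title(f"{image.sample_id} (class {image.label})", fontsize=8)
    ax.axis("off")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
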