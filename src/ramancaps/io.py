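"""Reading and writing Raman spectra and sample manifests.

Spectra live on disk as PRN-style two-column numeric text (Raman shift in
cm^-1, intensity in a.u.), optionally with non-numeric header lines and
optionally with several intensity columns (one per co-added scan).  A
dataset is a directory of such files plus a delimited manifest mapping
``sample_id, variety, label, path``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Default Raman-shift axis: 200-3400 cm^-1 at 1.4 cm^-1 resolution.
DEFAULT_AXIS_START = 200.0
DEFAULT_AXIS_STOP = 3400.0
DEFAULT_AXIS_STEP = 1.4

#: Growth-duration class descriptions, keyed by integer label.  Label 0 is
#: the short-duration group (third accumulated-temperature zone), label 1
#: the long-duration group (first zone), label 2 the medium group (second
#: zone).
DEFAULT_CLASS_NAMES = {
    0: "third accumulated-temperature zone (short growth duration)",
    1: "first accumulated-temperature zone (long growth duration)",
    2: "second accumulated-temperature zone (medium growth duration)",
}

VALID_LABELS = frozenset(DEFAULT_CLASS_NAMES)

#: Variety -> growth-duration class label.
VARIETY_LABELS = {
    "LJ47": 0,
    "KY131": 0,
    "LJ11": 0,
    "HH311": 0,
    "QJ1": 1,
    "SJ13": 2,
    "HJ313": 2,
}


class SpectrumParseError(ValueError):
    """A spectrum file contained a row that does not parse to numbers."""


class AxisValidationError(ValueError):
    """A shift axis violates the monotone / uniform-spacing contract."""


def default_axis(
    start: float = DEFAULT_AXIS_START,
    stop: float = DEFAULT_AXIS_STOP,
    step: float = DEFAULT_AXIS_STEP,
) -> np.ndarray:
    """Return the canonical acquisition grid (2287 points by default).

    Both endpoints are included: the number of points is the rounded span
    over the nominal step plus one, and the actual spacing is the span
    divided evenly (1.39983 cm^-1 for the default grid, i.e. the nominal
    1.4 cm^-1 resolution).
    """
    n = int(round((stop - start) / step)) + 1
    return np.linspace(start, stop, n)


def _validate_axis(shifts: np.ndarray) -> None:
    diffs = np.diff(shifts)
    if len(shifts) < 2:
        raise AxisValidationError("shift axis needs at least two points")
    if np.any(diffs <= 0):
        raise AxisValidationError("shift axis must be strictly increasing")
    med = np.median(diffs)
    if np.max(np.abs(diffs - med)) >= 0.1 * med:
        raise AxisValidationError(
            "shift spacing deviates more than 10% from the median spacing"
        )


@dataclass
class RamanSpectrum:
    """One grain's Raman spectrum with identity and label metadata.

    Parameters
    ----------
    sample_id : str
        Unique sample identifier.
    variety : str
        Rice variety name (e.g. ``"LJ47"``).
    label : int
        Growth-duration class in ``{0, 1, 2}``.
    shifts : ndarray
        Strictly increasing Raman shifts (cm^-1) on an approximately
        uniform grid.
    intensities : ndarray
        Non-negative scattering intensities (a.u.), same length as
        ``shifts``.
    n_scans : int
        Number of co-added scans behind ``intensities``.
    """

    sample_id: str
    variety: str
    label: int
    shifts: np.ndarray
    intensities: np.ndarray
    n_scans: int = 1

    def __post_init__(self) -> None:
        self.shifts = np.asarray(self.shifts, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.shifts.shape != self.intensities.shape or self.shifts.ndim != 1:
            raise ValueError("shifts and intensities must be equal-length 1-D")
        if self.label not in VALID_LABELS:
            raise ValueError(f"label must be one of {sorted(VALID_LABELS)}, got {self.label}")
        if self.n_scans < 1:
            raise ValueError("n_scans must be a positive integer")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")
        _validate_axis(self.shifts)

    def __len__(self) -> int:
        return len(self.shifts)


@dataclass
class SampleSet:
    """A collection of spectra sharing one shift axis."""

    spectra: list[RamanSpectrum]
    class_names: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_CLASS_NAMES))

    def __post_init__(self) -> None:
        if self.spectra:
            axis = self.spectra[0].shifts
            for sp in self.spectra[1:]:
                if sp.shifts.shape != axis.shape or not np.array_equal(sp.shifts, axis):
                    raise AxisValidationError(
                        f"spectrum {sp.sample_id!r} is not on the shared shift axis"
                    )
        for sp in self.spectra:
            if sp.label not in self.class_names:
                raise ValueError(
                    f"spectrum {sp.sample_id!r} has label {sp.label} "
                    f"outside class_names keys {sorted(self.class_names)}"
                )

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)

    @property
    def shifts(self) -> np.ndarray:
        if not self.spectra:
            raise ValueError("empty SampleSet has no axis")
        return self.spectra[0].shifts

    @property
    def labels(self) -> np.ndarray:
        return np.array([sp.label for sp in self.spectra], dtype=int)

    @property
    def varieties(self) -> list[str]:
        return [sp.variety for sp in self.spectra]


def read_spectrum(
    path: str | Path,
    dialect: str = "auto",
    sample_id: str | None = None,
    variety: str = "",
    label: int = 0,
) -> RamanSpectrum:
    """Read a PRN-style spectrum file.

    The file is whitespace- or comma-delimited numeric text with one row
    per grid point: the first column is the Raman shift, the remaining
    column(s) are intensities.  Leading non-numeric lines are skipped as a
    header; after the first numeric row any unparseable row is an error.
    Multiple intensity columns (one per scan) are averaged and counted in
    ``n_scans``.  Rows are sorted by shift before validation.

    Parameters
    ----------
    dialect : {"auto", "two-column-text", "delimited-with-header"}
        Kept for explicitness; all three parse identically because header
        detection is automatic.
    """
    if dialect not in ("auto", "two-column-text", "delimited-with-header"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    rows: list[list[float]] = []
    in_data = False
    n_cols = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            parts = stripped.replace(",", " ").split()
            try:
                values = [float(p) for p in parts]
            except ValueError:
                if in_data:
                    raise SpectrumParseError(
                        f"{path}: line {lineno}: cannot parse {stripped!r} as numbers"
                    ) from None
                continue  # header line
            if len(values) < 2:
                raise SpectrumParseError(
                    f"{path}: line {lineno}: expected at least 2 columns, got {len(values)}"
                )
            if n_cols is None:
                n_cols = len(values)
            elif len(values) != n_cols:
                raise SpectrumParseError(
                    f"{path}: line {lineno}: inconsistent column count"
                )
            in_data = True
            rows.append(values)
    if not rows:
        raise SpectrumParseError(f"{path}: no numeric data rows")
    data = np.array(rows)
    order = np.argsort(data[:, 0], kind="stable")
    data = data[order]
    shifts = data[:, 0]
    if np.any(np.diff(shifts) == 0):
        raise AxisValidationError(f"{path}: duplicate shift values after sorting")
    n_scans = data.shape[1] - 1
    intensities = data[:, 1:].mean(axis=1)
    return RamanSpectrum(
        sample_id=sample_id or path.stem,
        variety=variety,
        label=label,
        shifts=shifts,
        intensities=intensities,
        n_scans=n_scans,
    )


def write_spectrum(spectrum: RamanSpectrum, path: str | Path) -> None:
    """Write a spectrum as two-column text with float-exact precision."""
    data = np.column_stack([spectrum.shifts, spectrum.intensities])
    np.savetxt(path, data, fmt="%.17g", delimiter="\t")


def read_manifest(path: str | Path, class_names: dict[int, str] | None = None) -> SampleSet:
    """Load a sample manifest and every spectrum it names.

    The manifest is delimited text (CSV or TSV, sniffed by pandas) with
    columns ``sample_id, variety, label, path``; spectrum paths are
    resolved relative to the manifest's directory.
    """
    path = Path(path)
    table = pd.read_csv(path, sep=None, engine="python")
    required = {"sample_id", "variety", "label", "path"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"{path}: manifest missing columns {sorted(missing)}")
    if table.empty:
        warnings.warn(f"{path}: empty manifest", stacklevel=2)
        logger.warning("%s: empty manifest", path)
        return SampleSet(spectra=[], class_names=class_names or dict(DEFAULT_CLASS_NAMES))
    spectra = []
    for row in table.itertuples(index=False):
        label = int(row.label)
        if label not in VALID_LABELS:
            raise ValueError(
                f"{path}: sample {row.sample_id!r} has label {label}, "
                f"expected one of {sorted(VALID_LABELS)}"
            )
        spec_path = path.parent / str(row.path)
        if not spec_path.exists():
            raise FileNotFoundError(f"{path}: spectrum file {spec_path} not found")
        spectra.append(
            read_spectrum(
                spec_path,
                sample_id=str(row.sample_id),
                variety=str(row.variety),
                label=label,
            )
        )
    return SampleSet(spectra=spectra, class_names=class_names or dict(DEFAULT_CLASS_NAMES))


def write_dataset(samples: SampleSet, directory: str | Path) -> Path:
    """Write a SampleSet as PRN-style files plus ``manifest.csv``.

    Returns the manifest path.  The layout round-trips through
    :func:`read_manifest` exactly.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    records = []
    for sp in samples:
        fname = f"{sp.sample_id}.prn"
        write_spectrum(sp, directory / fname)
        records.append(
            {"sample_id": sp.sample_id, "variety": sp.variety, "label": sp.label, "path": fname}
        )
    manifest = directory / "manifest.csv"
    pd.DataFrame(records, columns=["sample_id", "variety", "label", "path"]).to_csv(
        manifest, index=False
    )
    return manifest


def save_image_text(pixels: np.ndarray, path: str | Path) -> None:
    """Write a 28x28 image matrix as delimited text at 9 significant digits."""
    np.savetxt(path, np.asarray(pixels, dtype=float), fmt="%.9g", delimiter="\t")


def load_image_text(path: str | Path) -> np.ndarray:
    return np.loadtxt(path, delimiter="\t", ndmin=2)
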