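"""ppm-axis model, spectral windows, alignment, and spectra I/O.

The calibration features are two fixed slices of the processed grid:

* TG window — 1746 consecutive points starting at the grid point at
  1.4 ppm and running upfield (methylene + methyl lipid signals,
  1.4 -> ~0.6 ppm);
* CH window — the final 961 points of the TG window (the methyl-only
  segment, ~1.04 -> ~0.6 ppm).

The two printed point counts are not exactly proportional to closed ppm
intervals on one uniform grid, so the windows are defined by start point
and count; this reproduces both counts exactly and keeps CH a suffix of
TG. Grid spacing is fixed at 0.8/1746 ppm per point.

Axes follow the NMR convention of strictly descending ppm.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "PpmAxis",
    "Spectrum",
    "SpectralWindow",
    "TG_WINDOW",
    "CH_WINDOW",
    "SELECTION_WINDOW",
    "DEFAULT_SPACING",
    "default_axis",
    "extract_window",
    "window_bounds",
    "align_to_reference",
    "read_spectra",
    "write_spectra",
]

DEFAULT_SPACING = 0.8 / 1746  # ppm per point
_UNIFORM_TOL = 1e-9


@dataclass(frozen=True)
class PpmAxis:
    """Uniform, strictly descending chemical-shift axis."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("axis needs at least two points")
        d = np.diff(v)
        if not (d < 0).all():
            raise ValueError("axis must be strictly descending (NMR convention)")
        if np.ptp(d) > _UNIFORM_TOL:
            raise ValueError("axis spacing not uniform")

    @property
    def spacing(self) -> float:
        return float(self.values[0] - self.values[1])

    def __len__(self) -> int:
        return len(self.values)

    def index_of(self, ppm: float) -> int:
        """Index of the grid point nearest ``ppm``."""
        return int(np.argmin(np.abs(self.values - ppm)))


@dataclass
class Spectrum:
    """One sample's intensity vector on a ppm axis."""

    sample_id: str
    axis: PpmAxis
    intensity: np.ndarray
    kind: str = "diffusion_edited"  # or "noesy"

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, float)
        if self.intensity.shape != (len(self.axis),):
            raise ValueError("intensity length must match axis length")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")


@dataclass(frozen=True)
class SpectralWindow:
    """A named contiguous slice: ``n_points`` starting at ``start_ppm``."""

    name: str
    start_ppm: float
    n_points: int


TG_WINDOW = SpectralWindow("TG_window", start_ppm=1.4, n_points=1746)
CH_WINDOW = SpectralWindow("CH_window", start_ppm=1.4 - 785 * DEFAULT_SPACING, n_points=961)
# PCA-based representative-sample selection uses the methyl region 0.6-1.04 ppm.
SELECTION_WINDOW = SpectralWindow(
    "selection_window", start_ppm=1.04, n_points=int(round((1.04 - 0.6) / DEFAULT_SPACING)) + 1
)


def default_axis(max_ppm: float = 4.0, min_ppm: float = 0.0,
                 spacing: float = DEFAULT_SPACING) -> PpmAxis:
    """Descending uniform grid containing 1.4 ppm exactly.

    The grid is anchored so that 1.4 ppm is a grid point (the TG window
    start) and spans at least [min_ppm, max_ppm] so the alanine region
    (1.49 ppm) exists for alignment.
    """
    n_up = int(np.ceil((max_ppm - 1.4) / spacing))
    n_down = int(np.ceil((1.4 - min_ppm) / spacing))
    k = np.arange(n_up, -n_down - 1, -1)
    return PpmAxis(1.4 + k * spacing)


def _window_slice(axis: PpmAxis, window: SpectralWindow) -> slice:
    start = axis.index_of(window.start_ppm)
    if abs(axis.values[start] - window.start_ppm) > axis.spacing / 2 + 1e-12:
        raise ValueError(f"axis does not contain the {window.name} start point")
    stop = start + window.n_points
    if stop > len(axis):
        raise ValueError(f"axis does not cover {window.name} ({window.n_points} points)")
    return slice(start, stop)


def extract_window(spectrum: Spectrum, window: SpectralWindow) -> np.ndarray:
    """Feature vector: the window's contiguous slice of the intensity."""
    return spectrum.intensity[_window_slice(spectrum.axis, window)].copy()


def window_bounds(axis: PpmAxis, window: SpectralWindow) -> tuple[float, float]:
    """(high, low) ppm bounds of the window on this axis."""
    sl = _window_slice(axis, window)
    return float(axis.values[sl.start]), float(axis.values[sl.stop - 1])


def align_to_reference(spectrum: Spectrum, reference_ppm: float = 1.49,
                       search_halfwidth: float = 0.008) -> tuple[Spectrum, int]:
    """Circularly shift so the local maximum near ``reference_ppm`` sits
    at the grid point nearest the reference.

    Emulates alignment to the left line of the alanine doublet at
    1.49 ppm; the default half-width covers that line but not its
    doublet partner 0.012 ppm upfield. Integer-point circular shift, no
    interpolation. Raises for flat or featureless input: the peak must
    be interior to the region and its prominence must exceed five times
    the point-noise level (estimated from second differences, which
    cancel smooth line shape and baseline).
    """
    axis = spectrum.axis
    target = axis.index_of(reference_ppm)
    half = max(1, int(round(search_halfwidth / axis.spacing)))
    lo, hi = max(0, target - half), min(len(axis), target + half + 1)
    region = spectrum.intensity[lo:hi]
    peak_local = int(np.argmax(region))
    interior = 0 < peak_local < len(region) - 1
    d2 = np.diff(region, n=2)
    sigma = 1.4826 * float(np.median(np.abs(d2 - np.median(d2)))) / np.sqrt(6.0) if d2.size else 0.0
    prominence = float(region[peak_local] - region.min())
    if not interior or prominence <= 5.0 * sigma:
        raise ValueError("no local maximum above noise floor in the search region")
    shift = target - (lo + peak_local)
    out = Spectrum(spectrum.sample_id, axis, np.roll(spectrum.intensity, shift), spectrum.kind)
    return out, shift


def write_spectra(spectra: list[Spectrum], path: str | Path) -> None:
    """CSV: header row ``ppm`` + axis values; one row per sample."""
    if not spectra:
        raise ValueError("no spectra to write")
    axis = spectra[0].axis
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["ppm"] + [f"{float(v):.17g}" for v in axis.values])
        for s in spectra:
            if len(s.axis) != len(axis) or not np.allclose(s.axis.values, axis.values):
                raise ValueError("all spectra must share one axis")
            w.writerow([s.sample_id] + [f"{float(v):.17g}" for v in s.intensity])


def read_spectra(path: str | Path) -> list[Spectrum]:
    """Inverse of :func:`write_spectra`; validates axis and row shapes."""
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise ValueError(f"{path}: empty spectra file")
    header = rows[0]
    if len(header) < 3 or header[0] != "ppm":
        raise ValueError(f"{path}: line 1: expected 'ppm' header row")
    axis = PpmAxis(np.array([float(x) for x in header[1:]]))
    spectra = []
    for i, row in enumerate(rows[1:], start=2):
        if len(row) != len(header):
            raise ValueError(
                f"{path}: line {i}: row has {len(row) - 1} values, expected {len(axis)}"
            )
        spectra.append(Spectrum(row[0], axis, np.array([float(x) for x in row[1:]])))
    if not spectra:
        raise ValueError(f"{path}: no sample rows")
    return spectra
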