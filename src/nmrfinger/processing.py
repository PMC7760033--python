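"""Spectral processing: FID -> spectrum -> calibrated, binned, normalized fingerprint.

The fingerprint pipeline converts one 1D 1H spectrum per subject into a row of
a subjects x bins feature matrix:

1. (optional, FID input) exponential apodization + Fourier transform,
   zero-order phasing and polynomial baseline subtraction;
2. chemical-shift calibration on the anomeric glucose doublet at 5.24 ppm;
3. integration into fixed 0.02 ppm bins over 10.00-0.2 ppm (490 bins);
4. removal of the residual-water bins (4.50-5.00 ppm, 25 bins) and
   normalization of each subject to unit total spectral area (465 bins).

Spectra are stored on a descending ppm axis, the plotting convention of the
field. Bins are left-closed/right-open on that descending axis (a point lying
exactly on an edge belongs to the higher-ppm bin) and anchored at 10.00 ppm.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = [
    "FID",
    "Spectrum",
    "BinnedMatrix",
    "CalibrationError",
    "apodize_transform",
    "phase_correct",
    "baseline_correct",
    "calibrate",
    "bin_edges",
    "bin_spectrum",
    "bin_spectra",
    "normalize_matrix",
    "read_spectrum_txt",
    "write_spectrum_txt",
]

FINGERPRINT_REGION = (0.2, 10.0)   # ppm
BIN_WIDTH = 0.02                   # ppm
WATER_REGION = (4.50, 5.00)        # ppm, excluded from the fingerprint
GLUCOSE_DOUBLET_PPM = 5.24         # calibration reference


class CalibrationError(ValueError):
    """No usable reference peak found in the calibration search window."""


@dataclass(frozen=True)
class FID:
    """Raw free induction decay for one acquisition.

    points            complex time-domain samples
    dwell_time        sampling interval in s (1 / spectral width)
    carrier_mhz       spectrometer proton Larmor frequency in MHz
    reference_ppm     chemical shift of the carrier (centre of the spectrum)
    """

    points: np.ndarray
    dwell_time: float
    carrier_mhz: float = 600.13
    reference_ppm: float = 4.7
    subject_id: str = ""

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=complex)
        object.__setattr__(self, "points", pts)
        if pts.size < 2:
            raise ValueError("FID needs at least 2 points")
        if self.dwell_time <= 0:
            raise ValueError("dwell_time must be positive")

    @property
    def spectral_width_hz(self) -> float:
        return 1.0 / self.dwell_time

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.points.size) * self.dwell_time


@dataclass(frozen=True)
class Spectrum:
    """Real 1D spectrum on a strictly descending ppm axis."""

    ppm: np.ndarray
    intensity: np.ndarray
    subject_id: str = ""
    experiment: str = "noesy"

    def __post_init__(self) -> None:
        ppm = np.asarray(self.ppm, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if ppm.shape != inten.shape or ppm.ndim != 1:
            raise ValueError("ppm and intensity must be equal-length 1D arrays")
        d = np.diff(ppm)
        if np.all(d < 0):
            pass
        elif np.all(d > 0):  # accept ascending input, store descending
            ppm, inten = ppm[::-1], inten[::-1]
        else:
            raise ValueError("ppm axis must be strictly monotone")
        object.__setattr__(self, "ppm", ppm)
        object.__setattr__(self, "intensity", inten)

    def shifted(self, delta_ppm: float) -> "Spectrum":
        return replace(self, ppm=self.ppm + delta_ppm)

    def covers(self, lo: float, hi: float) -> bool:
        return self.ppm[-1] <= lo and self.ppm[0] >= hi


@dataclass
class BinnedMatrix:
    """Subjects x bins feature table with explicit ppm bin edges.

    ``left_edges``/``right_edges`` follow the descending-axis convention:
    left > right for every bin, bins ordered from high to low ppm.
    """

    subject_ids: list[str]
    left_edges: np.ndarray
    right_edges: np.ndarray
    values: np.ndarray
    water_excluded: bool = False
    normalized: bool = False
    experiment: str = "noesy"

    def __post_init__(self) -> None:
        self.left_edges = np.asarray(self.left_edges, dtype=float)
        self.right_edges = np.asarray(self.right_edges, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.subject_ids), self.left_edges.size):
            raise ValueError("values shape does not match subjects x bins")
        if np.any(self.left_edges <= self.right_edges):
            raise ValueError("bins must satisfy left_edge > right_edge (descending axis)")

    @property
    def n_bins(self) -> int:
        return self.left_edges.size

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.left_edges + self.right_edges)

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{l:.10g}_{r:.10g}" for l, r in zip(self.left_edges, self.right_edges)]
        return pd.DataFrame(self.values, index=self.subject_ids, columns=cols)

    def to_csv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = f"subject_id;water_excluded={int(self.water_excluded)};normalized={int(self.normalized)};experiment={self.experiment}"
        df.to_csv(path, float_format="%.17g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "BinnedMatrix":
        df = pd.read_csv(path, index_col=0)
        meta = {"water_excluded": "0", "normalized": "0", "experiment": "noesy"}
        idx_name = df.index.name or "subject_id"
        for part in idx_name.split(";")[1:]:
            k, _, v = part.partition("=")
            meta[k] = v
        edges = np.array([[float(a) for a in c.split("_")] for c in df.columns])
        return cls(
            subject_ids=[str(s) for s in df.index],
            left_edges=edges[:, 0],
            right_edges=edges[:, 1],
            values=df.to_numpy(float),
            water_excluded=meta["water_excluded"] == "1",
            normalized=meta["normalized"] == "1",
            experiment=meta["experiment"],
        )


# ---------------------------------------------------------------------------
# FID path

def apodize_transform(fid: FID, line_broadening: float = 0.3) -> Spectrum:
    """Exponential apodization followed by Fourier transform.

    The time-domain points are multiplied by ``exp(-pi * lb * t)`` (an ``lb``
    Hz Lorentzian line-broadening window) before the discrete Fourier
    transform; the real part is returned on a descending ppm axis derived from
    the spectral width, carrier frequency and reference offset. The first
    point is halved before transformation so that a pure exponential decay
    gives a flat-baseline Lorentzian.
    """
    if line_broadening < 0:
        raise ValueError("line_broadening must be >= 0")
    pts = fid.points.copy()
    pts *= np.exp(-np.pi * line_broadening * fid.times)
    pts[0] *= 0.5
    spec = np.fft.fftshift(np.fft.fft(pts))
    n = pts.size
    freq_hz = np.fft.fftshift(np.fft.fftfreq(n, d=fid.dwell_time))
    ppm = fid.reference_ppm + freq_hz / fid.carrier_mhz
    # descending axis
    return Spectrum(ppm=ppm[::-1], intensity=spec.real[::-1], subject_id=fid.subject_id)


def phase_correct(spectrum: Spectrum, complex_intensity: np.ndarray | None = None,
                  n_grid: int = 360) -> Spectrum:
    """Zero-order phase correction maximizing real-part positivity.

    When the complex spectrum is available it is rotated by the angle (on an
    ``n_grid``-point circle) that minimizes the summed negative real part.
    Real-only input is returned unchanged.
    """
    if complex_intensity is None:
        return spectrum
    z = np.asarray(complex_intensity, dtype=complex)
    phis = np.linspace(0, 2 * np.pi, n_grid, endpoint=False)
    neg = [np.minimum((z * np.exp(1j * phi)).real, 0.0).sum() for phi in phis]
    best = phis[int(np.argmax(neg))]  # least-negative
    return replace(spectrum, intensity=(z * np.exp(1j * best)).real)


def baseline_correct(spectrum: Spectrum, order: int = 3,
                     signal_free: Sequence[tuple[float, float]] = ((9.0, 10.0), (-0.5, 0.1))) -> Spectrum:
    """Subtract a low-order polynomial fitted to signal-free ppm regions."""
    mask = np.zeros(spectrum.ppm.size, bool)
    for lo, hi in signal_free:
        mask |= (spectrum.ppm >= lo) & (spectrum.ppm <= hi)
    if mask.sum() < order + 1:
        raise ValueError("not enough signal-free points for baseline fit")
    coef = np.polynomial.polynomial.polyfit(spectrum.ppm[mask], spectrum.intensity[mask], order)
    base = np.polynomial.polynomial.polyval(spectrum.ppm, coef)
    return replace(spectrum, intensity=spectrum.intensity - base)


# ---------------------------------------------------------------------------
# Calibration

def calibrate(spectrum: Spectrum, reference_ppm: float = GLUCOSE_DOUBLET_PPM,
              search_window: tuple[float, float] = (5.15, 5.35),
              prominence_frac: float = 0.1,
              doublet_span: float = 0.03) -> tuple[Spectrum, float]:
    """Shift the ppm axis so the glucose anomeric doublet sits at 5.24 ppm.

    The doublet centre is the midpoint of the two most prominent local maxima
    in ``search_window`` (the single maximum if only one is found, or if the
    two are further apart than ``doublet_span`` ppm, i.e. not one doublet).
    Returns the calibrated spectrum and the applied shift in ppm.

    Raises :class:`CalibrationError` when no peak with prominence of at least
    ``prominence_frac`` times the window's dynamic range exists (e.g. a flat
    or signal-free window); the caller decides whether to drop the subject.
    """
    lo, hi = min(search_window), max(search_window)
    sel = (spectrum.ppm >= lo) & (spectrum.ppm <= hi)
    if sel.sum() < 3:
        raise CalibrationError(f"search window [{lo}, {hi}] ppm not covered by spectrum")
    # work on ascending axis for find_peaks
    win_ppm = spectrum.ppm[sel][::-1]
    win_int = spectrum.intensity[sel][::-1]
    dyn = win_int.max() - win_int.min()
    if dyn <= 0:
        raise CalibrationError("flat calibration window")
    idx, props = find_peaks(win_int, prominence=prominence_frac * dyn)
    if idx.size == 0:
        raise CalibrationError(
            f"no peak with prominence >= {prominence_frac:g} x window range in "
            f"[{lo}, {hi}] ppm")
    order = np.argsort(props["prominences"])[::-1]
    if idx.size >= 2:
        a, b = win_ppm[idx[order[0]]], win_ppm[idx[order[1]]]
        center = 0.5 * (a + b) if abs(a - b) <= doublet_span else win_ppm[idx[order[0]]]
    else:
        center = win_ppm[idx[order[0]]]
    shift = reference_ppm - center
    return spectrum.shifted(shift), shift


# ---------------------------------------------------------------------------
# Binning and normalization

def bin_edges(region: tuple[float, float] = FINGERPRINT_REGION,
              width: float = BIN_WIDTH) -> tuple[np.ndarray, np.ndarray]:
    """Left (high) and right (low) ppm edges, anchored at the top of the region.

    The number of bins is ``round((hi - lo) / width)``; for the default
    10.00-0.2 ppm region at 0.02 ppm this is 490 bins.
    """
    lo, hi = min(region), max(region)
    n = int(round((hi - lo) / width))
    if n < 1:
        raise ValueError("region narrower than one bin")
    left = hi - width * np.arange(n)
    right = hi - width * np.arange(1, n + 1)
    return left, right


def bin_spectrum(spectrum: Spectrum, region: tuple[float, float] = FINGERPRINT_REGION,
                 width: float = BIN_WIDTH) -> np.ndarray:
    """Trapezoidal integral of intensity over each bin's ppm interval.

    Implemented as differences of the cumulative trapezoid interpolated at the
    bin edges, so partial grid steps at the edges are handled exactly (in the
    piecewise-linear sense).
    """
    lo, hi = min(region), max(region)
    if not spectrum.covers(lo, hi):
        raise ValueError(
            f"spectrum [{spectrum.ppm[-1]:.3f}, {spectrum.ppm[0]:.3f}] ppm does not "
            f"cover the binning region [{lo}, {hi}]")
    asc_ppm = spectrum.ppm[::-1]
    asc_int = spectrum.intensity[::-1]
    cum = np.concatenate([[0.0], np.cumsum(np.diff(asc_ppm) * 0.5 * (asc_int[1:] + asc_int[:-1]))])
    left, right = bin_edges((lo, hi), width)
    cum_at = np.interp(np.concatenate([right[::-1], [left[0]]]), asc_ppm, cum)
    areas_asc = np.diff(cum_at)  # ascending bin order
    return areas_asc[::-1]


def bin_spectra(spectra: Iterable[Spectrum], region: tuple[float, float] = FINGERPRINT_REGION,
                width: float = BIN_WIDTH, experiment: str = "noesy") -> BinnedMatrix:
    spectra = list(spectra)
    left, right = bin_edges(region, width)
    values = np.vstack([bin_spectrum(s, region, width) for s in spectra])
    ids = [s.subject_id or f"S{i:03d}" for i, s in enumerate(spectra)]
    return BinnedMatrix(ids, left, right, values, experiment=experiment)


def normalize_matrix(matrix: BinnedMatrix,
                     water_region: tuple[float, float] = WATER_REGION) -> BinnedMatrix:
    """Drop water bins, then scale each subject to unit total spectral area.

    A bin is dropped when its open ppm interval overlaps the open water
    interval, so bins merely touching 4.50 or 5.00 at an edge are kept; for
    the default 490-bin layout exactly 25 bins are removed. Subjects whose
    remaining total area is not positive are rejected by name.
    """
    if matrix.normalized:
        raise ValueError("matrix is already normalized")
    wlo, whi = min(water_region), max(water_region)
    tol = 1e-9  # guard against float noise on edges exactly at 4.50 / 5.00
    keep = ~((matrix.right_edges < whi - tol) & (matrix.left_edges > wlo + tol))
    vals = matrix.values[:, keep]
    totals = vals.sum(axis=1)
    bad = [sid for sid, t in zip(matrix.subject_ids, totals) if t <= 0]
    if bad:
        raise ValueError(f"non-positive total spectral area for subjects: {', '.join(bad)}")
    return BinnedMatrix(
        subject_ids=list(matrix.subject_ids),
        left_edges=matrix.left_edges[keep],
        right_edges=matrix.right_edges[keep],
        values=vals / totals[:, None],
        water_excluded=True,
        normalized=True,
        experiment=matrix.experiment,
    )


# ---------------------------------------------------------------------------
# Plain-text I/O

def read_spectrum_txt(path: str | Path, subject_id: str | None = None,
                      experiment: str = "noesy") -> Spectrum:
    """Read a two-column ppm/intensity text file (whitespace or comma separated)."""
    text = Path(path).read_text()
    arr = np.loadtxt(io.StringIO(text.replace(",", " ")))
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (ppm, intensity)")
    sid = subject_id if subject_id is not None else Path(path).stem
    return Spectrum(ppm=arr[:, 0], intensity=arr[:, 1], subject_id=sid, experiment=experiment)


def write_spectrum_txt(spectrum: Spectrum, path: str | Path) -> None:
    np.savetxt(path, np.column_stack([spectrum.ppm, spectrum.intensity]), fmt="%.10g")
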