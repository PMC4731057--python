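"""Five-step fingerprint preprocessing and the intensity-threshold peak filter.

The chain turns raw intact-cell MALDI-TOF spectra acquired on irregular
m/z axes into a common fingerprint matrix:

(i)   resampling onto a uniform m/z grid (default 30000 points over
      2000-20000 Da/e) by linear interpolation,
(ii)  alignment of the set by an integer-bin shift maximizing the
      cross-correlation with the element-wise median reference spectrum,
(iii) baseline subtraction (rolling minimum smoothed by a moving average),
(iv)  Savitzky-Golay smoothing,
(v)   normalization to sum 1 (total-ion-current normalization; an L2 mode
      is available).

After stacking into a matrix (rows = spectra, in manifest order), columns
whose maximum intensity never exceeds a small threshold (default 1e-3 of
the normalized signal) are discarded as latent noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import minimum_filter1d, uniform_filter1d
from scipy.signal import savgol_filter

from .errors import (
    DegenerateInputError,
    EmptyResultError,
    LinkageError,
    ParameterError,
    ValidationError,
)
from .io import SampleManifest, Spectrum, STAGES


@dataclass(frozen=True)
class MzGrid:
    """Uniform m/z grid; bin i sits at lo + i*(hi-lo)/(n_bins-1)."""

    lo: float = 2000.0
    hi: float = 20000.0
    n_bins: int = 30000

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ParameterError(f"grid requires lo < hi, got [{self.lo}, {self.hi}]")
        if self.n_bins < 2:
            raise ParameterError("grid needs at least 2 bins")

    @property
    def centers(self) -> np.ndarray:
        return np.linspace(self.lo, self.hi, self.n_bins)

    @property
    def step(self) -> float:
        return (self.hi - self.lo) / (self.n_bins - 1)


@dataclass
class IntensityMatrix:
    """m x n fingerprint matrix: one row per spectrum, one column per m/z bin
    (or selected peak).  Row order matches the manifest."""

    values: np.ndarray
    row_ids: list[str]
    col_mz: np.ndarray
    stage: str = "normalized"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.col_mz = np.asarray(self.col_mz, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("matrix values must be 2-D")
        m, n = self.values.shape
        if len(self.row_ids) != m:
            raise ValidationError(f"{len(self.row_ids)} row ids for {m} rows")
        if len(self.col_mz) != n:
            raise ValidationError(f"{len(self.col_mz)} m/z labels for {n} columns")
        if self.stage not in STAGES:
            raise ValidationError(f"unknown stage {self.stage!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def select_columns(self, idx: np.ndarray, stage: str | None = None) -> "IntensityMatrix":
        return IntensityMatrix(
            values=self.values[:, idx],
            row_ids=list(self.row_ids),
            col_mz=self.col_mz[idx],
            stage=stage or self.stage,
        )


def resample(spectrum: Spectrum, grid: MzGrid) -> Spectrum:
    """Linear-interpolation resampling onto the grid centers.

    Input points outside [grid.lo, grid.hi] are dropped; grid points outside
    the support of the (clipped) input are set to 0.
    """
    inside = (spectrum.mz >= grid.lo) & (spectrum.mz <= grid.hi)
    if not inside.any():
        raise DegenerateInputError(
            f"spectrum {spectrum.sample_id!r} has no points in "
            f"[{grid.lo}, {grid.hi}]"
        )
    mz, inten = spectrum.mz[inside], spectrum.intensity[inside]
    values = np.interp(grid.centers, mz, inten, left=0.0, right=0.0)
    return spectrum.with_(mz=grid.centers, intensity=values, stage="resampled")


def _best_shift(x: np.ndarray, ref: np.ndarray, max_shift: int) -> int:
    """Integer shift s (|s| <= max_shift) maximizing corr(roll(x, s), ref).

    Ties prefer the smallest |s| (then the negative one), which makes
    alignment of an already-aligned set a no-op.
    """
    lags = sorted(range(-max_shift, max_shift + 1), key=lambda s: (abs(s), s))
    best_s, best_c = 0, -np.inf
    n = len(x)
    for s in lags:
        # corr of x shifted by +s against ref, over the overlap
        if s >= 0:
            c = float(np.dot(x[: n - s], ref[s:])) if s < n else -np.inf
        else:
            c = float(np.dot(x[-s:], ref[: n + s]))
        # strict > with lags in (|s|, s) order: exact ties keep the
        # smallest shift, so aligning an aligned set is a no-op
        if c > best_c:
            best_s, best_c = s, c
    return best_s


def _roll_zero(x: np.ndarray, s: int) -> np.ndarray:
    """Shift by s bins, filling vacated bins with 0."""
    out = np.zeros_like(x)
    if s == 0:
        out[:] = x
    elif s > 0:
        out[s:] = x[:-s]
    else:
        out[:s] = x[-s:]
    return out


def align_set(
    spectra: list[Spectrum], max_shift_bins: int = 50
) -> tuple[list[Spectrum], np.ndarray]:
    """Remove systematic m/z shifts across repeated acquisitions.

    Each spectrum is shifted by the integer bin offset (|offset| <=
    max_shift_bins) that maximizes its cross-correlation with the
    element-wise median reference spectrum.  Returns the aligned spectra
    and the applied offsets.
    """
    if not spectra:
        return [], np.zeros(0, dtype=int)
    n = len(spectra[0])
    if max_shift_bins >= n:
        raise ParameterError(
            f"max_shift_bins={max_shift_bins} must be < spectrum length {n}"
        )
    if max_shift_bins < 0:
        raise ParameterError("max_shift_bins must be >= 0")
    grid_mz = spectra[0].mz
    for s in spectra:
        if len(s) != n or not np.allclose(s.mz, grid_mz, atol=1e-9):
            raise ValidationError("all spectra must share one grid before alignment")
    ref = np.median(np.stack([s.intensity for s in spectra]), axis=0)
    out, offsets = [], []
    for s in spectra:
        off = _best_shift(s.intensity, ref, max_shift_bins)
        out.append(s.with_(intensity=_roll_zero(s.intensity, off), stage="aligned"))
        offsets.append(off)
    return out, np.asarray(offsets, dtype=int)


def align_to_reference(
    spectrum: Spectrum, reference: np.ndarray, max_shift_bins: int = 50
) -> tuple[Spectrum, int]:
    """Align one spectrum against a stored reference (for prediction-time
    preprocessing of new samples on a calibrated grid)."""
    if max_shift_bins >= len(spectrum):
        raise ParameterError("max_shift_bins must be < spectrum length")
    off = _best_shift(spectrum.intensity, np.asarray(reference, float), max_shift_bins)
    return spectrum.with_(intensity=_roll_zero(spectrum.intensity, off), stage="aligned"), off


def subtract_baseline(spectrum: Spectrum, half_window_bins: int = 250) -> Spectrum:
    """Rolling-minimum baseline, smoothed by a moving average of the same
    window, subtracted and clipped at zero.  The baseline never exceeds the
    signal, so output <= input elementwise."""
    if half_window_bins < 1:
        raise ParameterError("half_window_bins must be >= 1")
    size = 2 * half_window_bins + 1
    floor = minimum_filter1d(spectrum.intensity, size=size, mode="nearest")
    baseline = uniform_filter1d(floor, size=size, mode="nearest")
    out = np.clip(spectrum.intensity - baseline, 0.0, None)
    return spectrum.with_(intensity=out, stage="baselined")


def smooth(spectrum: Spectrum, window_bins: int = 21, polyorder: int = 3) -> Spectrum:
    """Savitzky-Golay smoothing; reproduces polynomials of degree <=
    polyorder exactly.  Small negative excursions are clipped to zero to
    keep the post-baseline non-negativity invariant."""
    if window_bins % 2 == 0:
        raise ParameterError(f"window_bins must be odd, got {window_bins}")
    if polyorder >= window_bins:
        raise ParameterError("polyorder must be < window_bins")
    out = savgol_filter(spectrum.intensity, window_bins, polyorder, mode="interp")
    return spectrum.with_(intensity=np.clip(out, 0.0, None), stage="smoothed")


def normalize(spectrum: Spectrum, mode: str = "l1") -> Spectrum:
    """Normalize the fingerprint: default divides by the intensity sum
    (sum X_i = 1); mode='l2' divides by the Euclidean norm instead."""
    if mode == "l1":
        denom = float(spectrum.intensity.sum())
    elif mode == "l2":
        denom = float(np.linalg.norm(spectrum.intensity))
    else:
        raise ParameterError(f"unknown normalization mode {mode!r}")
    if denom <= 0:
        raise DegenerateInputError(
            f"spectrum {spectrum.sample_id!r} is all-zero; cannot normalize"
        )
    return spectrum.with_(intensity=spectrum.intensity / denom, stage="normalized")


def preprocess_spectra(
    spectra: list[Spectrum],
    grid: MzGrid | None = None,
    max_shift_bins: int = 50,
    baseline_half_window: int = 250,
    smooth_window: int = 21,
    smooth_polyorder: int = 3,
    norm_mode: str = "l1",
) -> tuple[list[Spectrum], np.ndarray]:
    """Run the full (i)-(v) chain on a set of raw spectra.

    Returns the normalized spectra (in input order) and the alignment
    offsets applied at step (ii).
    """
    grid = grid or MzGrid()
    resampled = [resample(s, grid) for s in spectra]
    aligned, offsets = align_set(resampled, max_shift_bins)
    done = []
    for s in aligned:
        s = subtract_baseline(s, baseline_half_window)
        s = smooth(s, smooth_window, smooth_polyorder)
        done.append(normalize(s, norm_mode))
    return done, offsets


def build_matrix(spectra: list[Spectrum], manifest: SampleManifest) -> IntensityMatrix:
    """Stack normalized spectra into the fingerprint matrix in manifest order."""
    if not spectra:
        raise ValidationError("no spectra to stack")
    by_key = {}
    for s in spectra:
        if s.stage != "normalized":
            raise ValidationError(
                f"spectrum {s.sample_id!r} is at stage {s.stage!r}, expected 'normalized'"
            )
        by_key[(s.sample_id, int(s.replicate))] = s
    grid_mz = spectra[0].mz
    for s in spectra:
        if len(s.mz) != len(grid_mz) or not np.allclose(s.mz, grid_mz, atol=1e-9):
            raise ValidationError("spectra are on mismatched grids")
    rows, row_ids = [], []
    for _, rec in manifest.table.iterrows():
        key = (rec["sample_id"], int(rec["replicate"]))
        if key not in by_key:
            raise LinkageError(
                f"manifest row ({key[0]}, replicate {key[1]}) has no spectrum"
            )
        rows.append(by_key[key].intensity)
        row_ids.append(f"{key[0]}#r{key[1]}")
    return IntensityMatrix(
        values=np.stack(rows), row_ids=row_ids, col_mz=grid_mz, stage="normalized"
    )


def threshold_filter(matrix: IntensityMatrix, threshold: float = 1e-3) -> IntensityMatrix:
    """Keep columns whose maximum over rows is strictly greater than the
    threshold; discards bins that never rise above latent noise."""
    if threshold < 0:
        raise ParameterError("threshold must be >= 0")
    keep = np.flatnonzero(matrix.values.max(axis=0) > threshold)
    if keep.size == 0:
        raise EmptyResultError(
            f"no column exceeds threshold {threshold}; nothing to keep"
        )
    return matrix.select_columns(keep, stage="thresholded")
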