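"""Nuisance denoising of voxel time series.

The driver applies, in order: removal of initial equilibration volumes,
framewise-displacement outlier detection (spike regressors), subject-level
motion-exclusion screening, Gaussian smoothing, confound regression
(6 motion parameters + their first derivatives + 5 aCompCor components +
one indicator per outlier volume), then linear detrending and band-pass
filtering.

Framewise displacement uses the sum-of-absolute-differences convention:
FD(t) = Σ|Δtranslation| + r·(π/180)·Σ|Δrotation°| with rotations converted
to arc length on a sphere of radius r = 50 mm.  Volume 0 has FD = 0.

The band-pass is zero-phase frequency-domain masking with raised-cosine
transitions, so its frequency response is exactly characterizable.  The
default band is 0.008–0.09 Hz.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, ndimage

from .io_cohort import LabeledMaskSet, VoxelTimeSeriesImage

logger = logging.getLogger(__name__)

ROTATION_SPHERE_RADIUS_MM = 50.0
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class MotionTrace:
    """Per-volume rigid-body motion: 3 translations (mm), 3 rotations (deg)."""

    params: np.ndarray  # (n_volumes, 6)

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=np.float64)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError("motion parameters must be (n_volumes, 6)")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "MotionTrace":
        cols = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]
        return cls(df[cols].to_numpy(dtype=np.float64))

    @property
    def n_volumes(self) -> int:
        return self.params.shape[0]

    @property
    def translations(self) -> np.ndarray:
        return self.params[:, :3]

    @property
    def rotations_deg(self) -> np.ndarray:
        return self.params[:, 3:]


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass specification in Hz, with optional linear detrending."""

    low_cutoff_hz: float = 0.008
    high_cutoff_hz: float = 0.09
    detrend: bool = True
    transition_fraction: float = 0.25  # raised-cosine half-width / cutoff

    def validate(self, repetition_time: float) -> None:
        nyquist = 1.0 / (2.0 * repetition_time)
        if not (0 <= self.low_cutoff_hz < self.high_cutoff_hz):
            raise ValueError("need 0 <= low_cutoff < high_cutoff")
        if self.high_cutoff_hz >= nyquist:
            raise ValueError(
                f"high cutoff {self.high_cutoff_hz} Hz at or above Nyquist "
                f"{nyquist:.4f} Hz"
            )


@dataclass
class ConfoundMatrix:
    """Per-volume nuisance design: labelled columns, one row per volume."""

    values: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.labels):
            raise ValueError("values must be (n_volumes, n_labels)")

    @property
    def n_volumes(self) -> int:
        return self.values.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.labels)


def framewise_displacement(trace: MotionTrace) -> np.ndarray:
    """Per-volume framewise displacement in mm (volume 0 = 0)."""
    dt = np.abs(np.diff(trace.translations, axis=0)).sum(axis=1)
    dr_deg = np.abs(np.diff(trace.rotations_deg, axis=0)).sum(axis=1)
    dr_mm = ROTATION_SPHERE_RADIUS_MM * np.deg2rad(dr_deg)
    fd = np.concatenate([[0.0], dt + dr_mm])
    return fd


def detect_outlier_volumes(
    displacement: np.ndarray, threshold_mm: float = 0.09
) -> np.ndarray:
    """Indices of volumes whose displacement strictly exceeds the threshold."""
    if threshold_mm <= 0:
        raise ValueError("threshold_mm must be > 0")
    return np.where(np.asarray(displacement) > threshold_mm)[0]


def exclusion_check(
    trace: MotionTrace,
    max_translation_mm: float = 3.0,
    max_rotation_deg: float = 3.0,
) -> str:
    """Subject-level motion screen: ``"exclude"`` iff any translation
    magnitude exceeds 3 mm or any rotation magnitude exceeds 3° relative to
    the reference (first) volume, else ``"keep"``."""
    rel = trace.params - trace.params[0]
    if np.any(np.abs(rel[:, :3]) > max_translation_mm):
        return "exclude"
    if np.any(np.abs(rel[:, 3:]) > max_rotation_deg):
        return "exclude"
    return "keep"


def acompcor_components(
    image: VoxelTimeSeriesImage,
    noise_masks: LabeledMaskSet,
    n_components: int = 5,
) -> np.ndarray:
    """Anatomical CompCor: top principal components of the noise-compartment
    (WM/CSF) voxel time series.

    Voxel series are demeaned and variance-normalized before the PCA; the
    returned columns (n_volumes × n_components) are mutually orthogonal with
    unit norm.
    """
    union = noise_masks.union()
    series = image.data[union]  # (n_voxels, T)
    if series.shape[0] < n_components:
        raise ValueError(
            f"too few noise voxels ({series.shape[0]}) for "
            f"{n_components} components"
        )
    series = series - series.mean(axis=1, keepdims=True)
    sd = series.std(axis=1)
    if np.all(sd == 0):
        raise ValueError("zero-variance noise region")
    keep = sd > 0
    series = series[keep] / sd[keep, None]
    # PCA over time: left singular vectors of the (T x voxels) matrix
    u, s, _ = np.linalg.svd(series.T, full_matrices=False)
    return u[:, :n_components]


def build_confound_matrix(
    trace: MotionTrace,
    compcor: np.ndarray | None = None,
    outlier_indices: np.ndarray | None = None,
) -> ConfoundMatrix:
    """Assemble the nuisance design: 6 motion parameters, their first
    temporal derivatives (first row defined as 0), aCompCor columns, and a
    one-hot spike column per outlier volume."""
    T = trace.n_volumes
    cols = [trace.params]
    labels = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]
    deriv = np.vstack([np.zeros((1, 6)), np.diff(trace.params, axis=0)])
    cols.append(deriv)
    labels += [f"d_{l}" for l in labels[:6]]
    if compcor is not None:
        compcor = np.asarray(compcor, dtype=np.float64)
        if compcor.shape[0] != T:
            raise ValueError("compcor rows must equal n_volumes")
        cols.append(compcor)
        labels += [f"acompcor_{i:02d}" for i in range(compcor.shape[1])]
    if outlier_indices is not None:
        for idx in np.asarray(outlier_indices, dtype=int):
            col = np.zeros((T, 1))
            col[idx, 0] = 1.0
            cols.append(col)
            labels.append(f"outlier_{idx:04d}")
    return ConfoundMatrix(np.hstack(cols), labels)


def regress_confounds(
    image: VoxelTimeSeriesImage, confounds: ConfoundMatrix
) -> VoxelTimeSeriesImage:
    """Voxelwise least-squares removal of the confound columns (plus an
    intercept); residuals are orthogonal to every retained column.

    Collinear columns are dropped with a logged warning (QR with column
    pivoting).
    """
    T = image.n_volumes
    if confounds.n_volumes != T:
        raise ValueError("confound rows must equal n_volumes")
    X = np.column_stack([np.ones(T), confounds.values])
    q, r, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = max(X.shape) * np.finfo(float).eps * (diag[0] if diag.size else 1.0)
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        dropped = [
            (["intercept"] + confounds.labels)[j] for j in piv[rank:]
        ]
        logger.warning("dropping %d collinear confound column(s): %s",
                       len(dropped), dropped)
        X = X[:, np.sort(piv[:rank])]
        q, _ = np.linalg.qr(X)
    flat = image.data.reshape(-1, T)
    mask_idx = np.where(image.brain_mask.reshape(-1))[0]
    y = flat[mask_idx].T  # (T, n_voxels)
    resid = y - q @ (q.T @ y)
    out = np.zeros_like(flat)
    out[mask_idx] = resid.T
    return image.with_data(out.reshape(image.data.shape))


def _bandpass_gain(freqs: np.ndarray, filt: FilterSpec) -> np.ndarray:
    """Raised-cosine band-pass gain at the given frequencies (Hz).

    The gain ramps from 0 to 1 over [f·(1−a), f·(1+a)] around each cutoff
    f, with a = ``transition_fraction``; it is exactly 1 in the interior
    passband and exactly 0 in the far stopband.
    """
    a = filt.transition_fraction
    gain = np.ones_like(freqs)

    def ramp_up(f, lo, hi):
        g = np.zeros_like(f)
        g[f >= hi] = 1.0
        mid = (f > lo) & (f < hi)
        g[mid] = 0.5 * (1 - np.cos(np.pi * (f[mid] - lo) / (hi - lo)))
        return g

    if filt.low_cutoff_hz > 0:
        lo = filt.low_cutoff_hz * (1 - a)
        hi = filt.low_cutoff_hz * (1 + a)
        gain = gain * ramp_up(freqs, lo, hi)
    lo2 = filt.high_cutoff_hz * (1 - a)
    hi2 = filt.high_cutoff_hz * (1 + a)
    gain = gain * (1.0 - ramp_up(freqs, lo2, hi2))
    return gain


def detrend_and_bandpass(
    image: VoxelTimeSeriesImage, filt: FilterSpec
) -> VoxelTimeSeriesImage:
    """Linear detrend (optional) followed by zero-phase FFT band-pass."""
    filt.validate(image.meta.repetition_time)
    T = image.n_volumes
    flat = image.data.reshape(-1, T)
    mask_idx = np.where(image.brain_mask.reshape(-1))[0]
    y = flat[mask_idx]
    if filt.detrend:
        t = np.arange(T, dtype=np.float64)
        t = (t - t.mean()) / t.std()
        y = y - y.mean(axis=1, keepdims=True)
        slope = (y @ t) / (t @ t)
        y = y - slope[:, None] * t
    freqs = np.fft.rfftfreq(T, d=image.meta.repetition_time)
    gain = _bandpass_gain(freqs, filt)
    y = np.fft.irfft(np.fft.rfft(y, axis=1) * gain, n=T, axis=1)
    out = np.zeros_like(flat)
    out[mask_idx] = y
    return image.with_data(out.reshape(image.data.shape))


def gaussian_smooth(
    image: VoxelTimeSeriesImage, fwhm_mm: float = 6.0
) -> VoxelTimeSeriesImage:
    """Volume-wise 3D Gaussian smoothing with σ = FWHM/(2√(2 ln 2)) in
    voxel units per axis.  Edge-replication boundary handling: constant
    volumes pass through unchanged, and the per-volume sum is preserved
    away from the array edges."""
    if fwhm_mm < 0:
        raise ValueError("fwhm must be >= 0")
    if fwhm_mm == 0:
        return image.with_data(image.data.copy())
    sigmas = [
        fwhm_mm * FWHM_TO_SIGMA / v for v in image.meta.voxel_size
    ]
    out = ndimage.gaussian_filter(
        image.data, sigma=sigmas + [0.0], mode="nearest"
    )
    return image.with_data(out, smoothing_fwhm=fwhm_mm)


@dataclass
class PreprocessResult:
    """Denoised image plus the quality-control facts that produced it."""

    image: VoxelTimeSeriesImage
    confounds: ConfoundMatrix
    framewise_displacement: np.ndarray
    outlier_volumes: np.ndarray
    exclusion: str
    n_dropped_initial: int


def preprocess_subject(
    image: VoxelTimeSeriesImage,
    motion: MotionTrace,
    noise_masks: LabeledMaskSet,
    filt: FilterSpec | None = None,
    smoothing_fwhm_mm: float = 6.0,
    n_drop_initial: int = 5,
    outlier_threshold_mm: float = 0.09,
    n_compcor: int = 5,
    max_translation_mm: float = 3.0,
    max_rotation_deg: float = 3.0,
) -> PreprocessResult:
    """Full denoising driver in the pipeline's fixed order.

    Order: drop initial volumes → framewise displacement / outlier scan /
    exclusion screen → Gaussian smoothing → confound construction (motion,
    derivatives, aCompCor, spikes) → confound regression → linear detrend +
    band-pass.  An excluded subject is still processed; ``exclusion``
    carries the verdict for the caller to act on.
    """
    if filt is None:
        filt = FilterSpec()
    if motion.n_volumes != image.n_volumes:
        raise ValueError("motion trace length must equal n_volumes")
    if n_drop_initial:
        image = image.with_data(image.data[..., n_drop_initial:])
        motion = MotionTrace(motion.params[n_drop_initial:])

    fd = framewise_displacement(motion)
    outliers = detect_outlier_volumes(fd, outlier_threshold_mm)
    verdict = exclusion_check(motion, max_translation_mm, max_rotation_deg)

    image = gaussian_smooth(image, smoothing_fwhm_mm)
    compcor = acompcor_components(image, noise_masks, n_compcor)
    confounds = build_confound_matrix(motion, compcor, outliers)
    image = regress_confounds(image, confounds)
    image = detrend_and_bandpass(image, filt)

    return PreprocessResult(
        image=image, confounds=confounds, framewise_displacement=fd,
        outlier_volumes=outliers, exclusion=verdict,
        n_dropped_initial=n_drop_initial,
    )
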