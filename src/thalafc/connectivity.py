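"""Per-nucleus seed-to-voxel functional-connectivity maps.

For each subject, condition and thalamic nucleus, the seed's mean time
series is correlated with every brain voxel (the Pearson r, equivalently
the standardized GLM slope).  Fisher's arctanh transform stabilizes the
variance for group statistics; the value convention (r / fisher_z) is
threaded through every map so downstream stages can report which was used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .io_cohort import NUCLEUS_LABELS, LabeledMaskSet, VoxelTimeSeriesImage

logger = logging.getLogger(__name__)

#: |r| at or beyond this bound is clipped before arctanh.
FISHER_CLIP = 1.0 - 1e-7


@dataclass
class FCMap:
    """Whole-brain connectivity map for one (subject, condition, nucleus).

    ``values`` is a 3D array, NaN outside ``brain_mask`` and at voxels
    whose correlation is undefined (zero temporal variance).  ``seed_mask``
    flags the seed's own voxels, which self-correlate near 1 and are
    excluded from whole-brain averaging downstream.
    """

    subject_id: str
    condition: str
    nucleus: str
    values: np.ndarray
    brain_mask: np.ndarray
    seed_mask: np.ndarray
    value_kind: str = "r"

    def __post_init__(self) -> None:
        if self.value_kind not in ("r", "fisher_z", "beta"):
            raise ValueError(f"unknown value_kind {self.value_kind!r}")
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.value_kind == "r":
            valid = np.isfinite(self.values)
            if valid.any() and (np.abs(self.values[valid]) > 1 + 1e-12).any():
                raise ValueError("r values must lie in [-1, 1]")


def extract_seed_timeseries(
    image: VoxelTimeSeriesImage, seed: np.ndarray
) -> np.ndarray:
    """Unweighted mean time series across the seed's voxels."""
    seed = np.asarray(seed, dtype=bool)
    if not seed.any():
        raise ValueError("empty seed mask")
    if not np.all(image.brain_mask[seed]):
        raise ValueError("seed extends outside brain_mask")
    return image.data[seed].mean(axis=0)


def seed_to_voxel_fc(
    image: VoxelTimeSeriesImage,
    seed_series: np.ndarray,
    subject_id: str = "",
    condition: str = "",
    nucleus: str = "",
    seed_mask: np.ndarray | None = None,
) -> FCMap:
    """Pearson correlation between the seed series and every brain voxel.

    Zero-variance voxels receive NaN (a defined missing value), never 0.
    """
    seed_series = np.asarray(seed_series, dtype=np.float64)
    T = image.n_volumes
    if seed_series.shape != (T,):
        raise ValueError("seed series length must equal n_volumes")
    if T < 4:
        raise ValueError("need at least 4 volumes")
    s = seed_series - seed_series.mean()
    s_norm = np.sqrt(s @ s)
    if s_norm == 0:
        raise ValueError("zero-variance seed series")
    mask_idx = np.where(image.brain_mask.reshape(-1))[0]
    y = image.data.reshape(-1, T)[mask_idx]
    y = y - y.mean(axis=1, keepdims=True)
    y_norm = np.sqrt((y * y).sum(axis=1))
    r = np.full(mask_idx.size, np.nan)
    ok = y_norm > 0
    r[ok] = (y[ok] @ s) / (y_norm[ok] * s_norm)
    np.clip(r, -1.0, 1.0, out=r)
    values = np.full(image.spatial_shape, np.nan).reshape(-1)
    values[mask_idx] = r
    if seed_mask is None:
        seed_mask = np.zeros(image.spatial_shape, dtype=bool)
    return FCMap(
        subject_id=subject_id, condition=condition, nucleus=nucleus,
        values=values.reshape(image.spatial_shape),
        brain_mask=image.brain_mask.copy(),
        seed_mask=np.asarray(seed_mask, dtype=bool),
        value_kind="r",
    )


def fisher_z(fc_map: FCMap) -> FCMap:
    """arctanh variance-stabilizing transform of a correlation map.

    |r| at or beyond 1 − 1e−7 is clipped first; the number of clipped
    voxels is logged.
    """
    if fc_map.value_kind != "r":
        raise ValueError("fisher_z expects an r-valued map")
    values = fc_map.values.copy()
    valid = np.isfinite(values)
    n_clipped = int((np.abs(values[valid]) >= FISHER_CLIP).sum())
    if n_clipped:
        logger.warning("fisher_z: clipping %d voxel(s) with |r| >= %g",
                       n_clipped, FISHER_CLIP)
    values[valid] = np.arctanh(np.clip(values[valid], -FISHER_CLIP, FISHER_CLIP))
    return replace(fc_map, values=values, value_kind="fisher_z")


def fc_stack(
    images: dict[str, dict[str, VoxelTimeSeriesImage]],
    nuclei: LabeledMaskSet,
    value_kind: str = "fisher_z",
) -> dict[tuple[str, str, str], FCMap]:
    """Seed-to-voxel maps for every (subject, condition, nucleus).

    ``images`` maps subject id → condition → preprocessed image; all
    subjects must share the nuclei grid.  The returned mapping is ordered
    by (subject id, condition, canonical nucleus order) and is independent
    of the input iteration order.
    """
    if value_kind not in ("r", "fisher_z"):
        raise ValueError(f"unsupported value_kind {value_kind!r}")
    conditions_seen = sorted({c for conds in images.values() for c in conds})
    out: dict[tuple[str, str, str], FCMap] = {}
    for subject_id in sorted(images):
        conds = images[subject_id]
        missing = set(conditions_seen) - set(conds)
        if missing:
            raise ValueError(
                f"subject {subject_id!r} missing condition(s) {sorted(missing)}"
            )
        for condition in conditions_seen:
            image = conds[condition]
            if image.spatial_shape != tuple(nuclei.grid_shape):
                raise ValueError(
                    f"subject {subject_id!r} not on the nuclei grid"
                )
            for nucleus in NUCLEUS_LABELS:
                seed = nuclei.masks[nucleus]
                series = extract_seed_timeseries(image, seed)
                fc = seed_to_voxel_fc(
                    image, series, subject_id=subject_id,
                    condition=condition, nucleus=nucleus, seed_mask=seed,
                )
                if value_kind == "fisher_z":
                    fc = fisher_z(fc)
                out[(subject_id, condition, nucleus)] = fc
    return out
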