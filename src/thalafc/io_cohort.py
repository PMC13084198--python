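"""Image/mask I/O, atlas resampling and cohort bookkeeping.

Volumetric data are NIfTI-1 files handled through nibabel; the participants
table is a TSV mirroring the demographics table of a disorders-of-
consciousness cohort (22 patients with MCS/UWS diagnoses and imagery-task
response labels), shipped with the package as its only non-synthetic data.

Conventions: 0-based voxel indices and half-open ranges everywhere; masks
are boolean arrays on a shared 3D grid.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

#: Canonical bilateral thalamic seed labels (7 clusters of a diffusion-MRI
#: thalamic parcellation: pulvinar, anterior, mediodorsal,
#: ventral-latero-dorsal, the central-lateral/lateral-posterior/medial-
#: pulvinar conglomerate, ventral-anterior, ventral-latero-ventral).
NUCLEUS_LABELS: tuple[str, ...] = ("Pu", "Ant", "MD", "VLD", "CL-LP-MPu", "VA", "VLV")

#: Canonical 10-network resting-state atlas labels, in atlas order.
ICN_LABELS: tuple[str, ...] = (
    "VN1", "VN2", "VN3", "DMN", "CN", "SMN", "AUDN", "ECN", "FPN1", "FPN2",
)

#: Higher-order (associative) networks, contrasted with sensory/motor/
#: cerebellar lower-order networks.
HIGHER_ORDER_ICNS: tuple[str, ...] = ("DMN", "ECN", "FPN1", "FPN2")

DIAGNOSES = ("MCS+", "MCS-", "UWS", "control")
TASK_RESPONSES = ("positive", "negative", "n/a")

PARTICIPANT_COLUMNS = (
    "id", "gender", "age", "aetiology", "months_post_injury",
    "diagnosis", "crs_r", "task_response",
)


class CorruptInputError(ValueError):
    """Raised when an on-disk input violates its format contract."""


@dataclass(frozen=True)
class AcquisitionMeta:
    """Scan acquisition metadata.

    Parameters
    ----------
    repetition_time : float
        Seconds per volume (TR).
    voxel_size : tuple of float
        Physical edge length of a voxel along each axis, millimetres.
    n_volumes : int
        Number of time points.
    smoothing_fwhm : float
        Full width at half maximum of any applied Gaussian smoothing, mm
        (0 = unsmoothed).
    """

    repetition_time: float
    voxel_size: tuple[float, float, float]
    n_volumes: int
    smoothing_fwhm: float = 0.0

    def __post_init__(self) -> None:
        if not self.repetition_time > 0:
            raise ValueError("repetition_time must be > 0")
        if self.n_volumes < 1:
            raise ValueError("n_volumes must be >= 1")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size components must be > 0")
        if self.smoothing_fwhm < 0:
            raise ValueError("smoothing_fwhm must be >= 0")


@dataclass
class VoxelTimeSeriesImage:
    """A 4D BOLD-like scalar field (x, y, z, t) with acquisition metadata.

    ``brain_mask`` marks voxels that participate in analysis; values inside
    the mask must be finite at every time point.
    """

    data: np.ndarray
    meta: AcquisitionMeta
    brain_mask: np.ndarray
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise CorruptInputError(
                f"not a time series: expected 4D data, got {self.data.ndim}D"
            )
        self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
        if self.brain_mask.shape != self.data.shape[:3]:
            raise ValueError("brain_mask shape must equal spatial shape of data")
        if self.data.shape[3] != self.meta.n_volumes:
            raise ValueError("meta.n_volumes inconsistent with data")
        if not np.all(np.isfinite(self.data[self.brain_mask])):
            raise CorruptInputError("non-finite values inside brain_mask")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    def with_data(self, data: np.ndarray, **meta_updates) -> "VoxelTimeSeriesImage":
        """Return a copy carrying new data (and optionally updated meta)."""
        meta = replace(self.meta, n_volumes=data.shape[3], **meta_updates)
        return VoxelTimeSeriesImage(
            data=data, meta=meta, brain_mask=self.brain_mask.copy(),
            affine=None if self.affine is None else self.affine.copy(),
        )


@dataclass
class LabeledMaskSet:
    """Named 3D boolean region masks sharing one grid.

    ``kind`` is one of ``{"nuclei", "icn", "noise_compartment"}``.  Nuclei
    mask sets must carry exactly the 7 canonical seed labels and be pairwise
    disjoint.
    """

    grid_shape: tuple[int, int, int]
    masks: dict[str, np.ndarray]
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in ("nuclei", "icn", "noise_compartment"):
            raise ValueError(f"unknown mask-set kind {self.kind!r}")
        self.masks = {
            label: np.asarray(m, dtype=bool) for label, m in self.masks.items()
        }
        for label, m in self.masks.items():
            if m.shape != tuple(self.grid_shape):
                raise ValueError(f"mask {label!r} does not match grid_shape")
            if not m.any():
                raise ValueError(f"mask {label!r} is empty")
        if self.kind == "nuclei":
            if tuple(self.masks) != NUCLEUS_LABELS:
                raise ValueError(
                    "nuclei mask set must carry exactly the canonical labels "
                    f"{NUCLEUS_LABELS} in order"
                )
            self._check_disjoint()

    def _check_disjoint(self) -> None:
        total = np.zeros(self.grid_shape, dtype=np.int32)
        for m in self.masks.values():
            total += m
        if total.max() > 1:
            raise ValueError("masks are not pairwise disjoint")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.masks)

    def union(self) -> np.ndarray:
        out = np.zeros(self.grid_shape, dtype=bool)
        for m in self.masks.values():
            out |= m
        return out

    def to_label_volume(self) -> tuple[np.ndarray, dict[int, str]]:
        """Encode as an integer volume (0 = background, i+1 = i-th label).

        Overlapping masks (only possible for non-nuclei kinds) resolve to
        the later label; nuclei sets are disjoint by invariant.
        """
        vol = np.zeros(self.grid_shape, dtype=np.int16)
        legend: dict[int, str] = {}
        for i, (label, m) in enumerate(self.masks.items(), start=1):
            vol[m] = i
            legend[i] = label
        return vol, legend


@dataclass(frozen=True)
class ParticipantRecord:
    """One row of the cohort demographics table."""

    id: str
    gender: str
    age: int
    aetiology: str
    months_post_injury: int | None
    diagnosis: str
    crs_r: int | None
    task_response: str

    def __post_init__(self) -> None:
        if self.diagnosis not in DIAGNOSES:
            raise ValueError(
                f"participant {self.id!r}: diagnosis {self.diagnosis!r} "
                f"not in {DIAGNOSES}"
            )
        if self.task_response not in TASK_RESPONSES:
            raise ValueError(
                f"participant {self.id!r}: task_response "
                f"{self.task_response!r} not in {TASK_RESPONSES}"
            )
        if self.crs_r is not None and self.crs_r < 0:
            raise ValueError(f"participant {self.id!r}: crs_r must be >= 0")


@dataclass
class ParticipantTable:
    """Ordered collection of participant records with unique ids."""

    records: list[ParticipantRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate participant ids: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def subset(self, predicate: Callable[[ParticipantRecord], bool]) -> "ParticipantTable":
        return ParticipantTable([r for r in self.records if predicate(r)])

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append({
                "id": r.id, "gender": r.gender, "age": r.age,
                "aetiology": r.aetiology,
                "months_post_injury": (
                    "Unknown" if r.months_post_injury is None
                    else r.months_post_injury
                ),
                "diagnosis": r.diagnosis,
                "crs_r": "" if r.crs_r is None else r.crs_r,
                "task_response": r.task_response,
            })
        return pd.DataFrame(rows, columns=list(PARTICIPANT_COLUMNS))


# ---------------------------------------------------------------------------
# image I/O


def read_timeseries_image(
    path: str | Path, repetition_time: float | None = None
) -> VoxelTimeSeriesImage:
    """Load a 4D NIfTI file into a :class:`VoxelTimeSeriesImage`.

    The brain mask defaults to voxels with nonzero temporal variance and no
    non-finite values.  TR is taken from the NIfTI header's 4th zoom unless
    overridden.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if data.ndim == 3:
        raise CorruptInputError(f"{path}: not a time series (3D image)")
    if data.ndim != 4:
        raise CorruptInputError(f"{path}: expected 4D image, got {data.ndim}D")
    zooms = img.header.get_zooms()
    voxel_size = tuple(float(z) for z in zooms[:3])
    tr = repetition_time if repetition_time is not None else float(zooms[3])
    if tr <= 0:
        raise CorruptInputError(f"{path}: non-positive TR in header; pass repetition_time")
    finite = np.all(np.isfinite(data), axis=3)
    variance = np.zeros(data.shape[:3])
    variance[finite] = data[finite].var(axis=-1)
    brain_mask = finite & (variance > 0)
    meta = AcquisitionMeta(
        repetition_time=tr, voxel_size=voxel_size, n_volumes=data.shape[3]
    )
    # NaNs live only outside the mask by construction; zero them so that
    # downstream whole-volume array ops stay finite.
    data[~finite] = 0.0
    return VoxelTimeSeriesImage(
        data=data, meta=meta, brain_mask=brain_mask, affine=np.asarray(img.affine)
    )


def write_timeseries_image(image: VoxelTimeSeriesImage, path: str | Path) -> None:
    """Write a :class:`VoxelTimeSeriesImage` as NIfTI-1 (.nii/.nii.gz)."""
    affine = image.affine
    if affine is None:
        affine = np.diag(list(image.meta.voxel_size) + [1.0])
    img = nib.Nifti1Image(image.data.astype(np.float64), affine)
    zooms = tuple(image.meta.voxel_size) + (image.meta.repetition_time,)
    img.header.set_zooms(zooms)
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def write_mask_set(mask_set: LabeledMaskSet, path: str | Path) -> None:
    """Write a mask set as an integer-label NIfTI plus a JSON legend sidecar."""
    vol, legend = mask_set.to_label_volume()
    img = nib.Nifti1Image(vol.astype(np.int16), np.eye(4))
    nib.save(img, str(path))
    sidecar = Path(str(path).removesuffix(".gz").removesuffix(".nii") + ".json")
    sidecar.write_text(json.dumps(
        {"kind": mask_set.kind, "labels": {str(k): v for k, v in legend.items()}},
        indent=2,
    ))


def read_mask_set(path: str | Path) -> LabeledMaskSet:
    """Read a mask set written by :func:`write_mask_set`."""
    img = nib.load(str(path))
    vol = np.asarray(img.dataobj).astype(np.int64)
    sidecar = Path(str(path).removesuffix(".gz").removesuffix(".nii") + ".json")
    info = json.loads(sidecar.read_text())
    masks = {label: vol == int(k) for k, label in info["labels"].items()}
    return LabeledMaskSet(grid_shape=vol.shape, masks=masks, kind=info["kind"])


# ---------------------------------------------------------------------------
# mask resampling


def resample_mask_nearest(
    mask_set: LabeledMaskSet,
    target_shape: tuple[int, int, int],
    transform: Callable[[np.ndarray], np.ndarray],
) -> LabeledMaskSet:
    """Resample masks onto a new grid with nearest-neighbour interpolation.

    ``transform`` maps an array of target voxel indices, shape (N, 3), to
    source-grid coordinates, shape (N, 3).  Each target voxel takes the
    label of its nearest source voxel, so no fractional labels can arise
    and disjoint source masks stay disjoint.

    Raises
    ------
    ValueError
        If any mask maps to the empty set ("seed lost in resampling").
    """
    target_shape = tuple(int(s) for s in target_shape)
    idx = np.indices(target_shape).reshape(3, -1).T.astype(np.float64)
    coords = np.asarray(transform(idx), dtype=np.float64)
    if coords.shape != idx.shape:
        raise ValueError("transform must return one source coordinate per target voxel")
    out_masks: dict[str, np.ndarray] = {}
    for label, mask in mask_set.masks.items():
        sampled = ndimage.map_coordinates(
            mask.astype(np.float32), coords.T, order=0, mode="constant", cval=0.0
        )
        resampled = (sampled > 0.5).reshape(target_shape)
        if not resampled.any():
            raise ValueError(f"seed lost in resampling: mask {label!r} became empty")
        out_masks[label] = resampled
    return LabeledMaskSet(grid_shape=target_shape, masks=out_masks, kind=mask_set.kind)


# ---------------------------------------------------------------------------
# participants


def _parse_optional_int(value, what: str, row: str):
    if value is None:
        return None
    text = str(value).strip()
    if text == "" or text.lower() in ("unknown", "na", "n/a", "nan", "none"):
        return None
    try:
        return int(float(text))
    except ValueError as exc:
        raise ValueError(f"row {row!r}: cannot parse {what} value {value!r}") from exc


def read_participants(path: str | Path) -> ParticipantTable:
    """Read a participants TSV into a validated :class:`ParticipantTable`.

    The header must contain at least ``id``, ``diagnosis`` and
    ``task_response``.  An unknown time post-injury is parsed as missing,
    never as zero.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"id", "diagnosis", "task_response"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"participants table missing columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        rid = str(row["id"]).strip()
        records.append(ParticipantRecord(
            id=rid,
            gender=str(row.get("gender", "")).strip(),
            age=_parse_optional_int(row.get("age"), "age", rid) or 0,
            aetiology=str(row.get("aetiology", "")).strip(),
            months_post_injury=_parse_optional_int(
                row.get("months_post_injury"), "months_post_injury", rid
            ),
            diagnosis=str(row["diagnosis"]).strip(),
            crs_r=_parse_optional_int(row.get("crs_r"), "crs_r", rid),
            task_response=str(row["task_response"]).strip(),
        ))
    return ParticipantTable(records)


def write_participants(table: ParticipantTable, path: str | Path) -> None:
    table.to_dataframe().to_csv(path, sep="\t", index=False)


def packaged_participants() -> ParticipantTable:
    """The package's transcription of the 22-patient DOC demographics table."""
    ref = importlib.resources.files("thalafc") / "data" / "doc_participants.tsv"
    with importlib.resources.as_file(ref) as path:
        return read_participants(path)


def cohort_counts(table: ParticipantTable) -> dict[str, int]:
    """Cohort bookkeeping counts.

    Returns counts for the total cohort, MCS (MCS+ plus MCS−) and its
    subtypes, UWS, controls, imagery-task responders/non-responders, and
    MCS patients among the non-responders.  For a patient-only table,
    MCS + UWS equals the total.
    """
    recs = list(table)
    counts = {
        "total": len(recs),
        "mcs": sum(r.diagnosis in ("MCS+", "MCS-") for r in recs),
        "mcs_plus": sum(r.diagnosis == "MCS+" for r in recs),
        "mcs_minus": sum(r.diagnosis == "MCS-" for r in recs),
        "uws": sum(r.diagnosis == "UWS" for r in recs),
        "control": sum(r.diagnosis == "control" for r in recs),
        "task_positive": sum(r.task_response == "positive" for r in recs),
        "task_negative": sum(r.task_response == "negative" for r in recs),
        "mcs_task_negative": sum(
            r.diagnosis in ("MCS+", "MCS-") and r.task_response == "negative"
            for r in recs
        ),
    }
    return counts
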