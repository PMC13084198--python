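"""Synthetic phantom cohorts with known thalamocortical ground truth.

The generator emulates the two study designs of the analysis: a
within-subject anaesthesia design (each subject scanned awake and under
deep sedation) and a between-group design (patients versus awake healthy
controls).  Ground truth is a latent-signal loading model: every intrinsic
connectivity network (ICN) region shares an AR(1) latent signal, every
thalamic nucleus carries a loading-weighted sum of network latents, and one
designated nucleus's loadings onto a "higher-order" network subset shift
additively in the unconscious condition/group.  Nuisance structure —
per-voxel Gaussian noise, low-frequency drift, a shared WM/CSF compartment
signal partially leaked into all brain voxels, and motion spikes with
matching image glitches — gives every denoising stage something real to
remove.

All randomness flows from integer seeds through ``numpy.random.default_rng``;
regenerating with the same seed reproduces cohorts exactly.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_cohort import (
    HIGHER_ORDER_ICNS,
    ICN_LABELS,
    NUCLEUS_LABELS,
    AcquisitionMeta,
    LabeledMaskSet,
    ParticipantRecord,
    ParticipantTable,
    VoxelTimeSeriesImage,
    packaged_participants,
    read_mask_set,
    read_participants,
    read_timeseries_image,
    write_mask_set,
    write_participants,
    write_timeseries_image,
)

MOTION_COLUMNS = ("trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and acquisition parameters of the phantom.

    The default grid (24³ voxels of 3 mm) is a desk-scale stand-in for an
    EPI volume; 256 volumes at TR = 2 s matches an 8-minute resting-state
    run.  Shell bounds are fractions of the brain-envelope radius.
    """

    grid_shape: tuple[int, int, int] = (24, 24, 24)
    n_volumes: int = 256
    repetition_time: float = 2.0
    voxel_size_mm: float = 3.0
    wm_shell: tuple[float, float] = (0.82, 0.88)
    csf_shell: tuple[float, float] = (0.93, 1.0)

    def __post_init__(self) -> None:
        if self.n_volumes < 50:
            raise ValueError("n_volumes must be >= 50 for any statistical use")
        if self.repetition_time <= 0:
            raise ValueError("repetition_time must be > 0")
        if len(self.grid_shape) != 3 or any(s < 1 for s in self.grid_shape):
            raise ValueError("grid_shape must be a positive 3D shape")

    @property
    def meta(self) -> AcquisitionMeta:
        v = self.voxel_size_mm
        return AcquisitionMeta(
            repetition_time=self.repetition_time,
            voxel_size=(v, v, v),
            n_volumes=self.n_volumes,
        )


@dataclass(frozen=True)
class CouplingModel:
    """Generative nucleus → network coupling with condition modulation.

    ``base_coupling`` is a 7 × 10 loading matrix (nuclei × ICNs, canonical
    order).  Under an effect-carrying condition the loadings of
    ``target_nucleus`` onto ``modulated_icns`` shift by ``effect_size``
    (optionally scaled per subject, e.g. boosted for task non-responders).
    Latent network signals and the WM/CSF compartment signal are AR(1) with
    unit marginal variance; voxel noise is iid Gaussian.
    """

    base_coupling: np.ndarray
    target_nucleus: str = "Pu"
    modulated_icns: tuple[str, ...] = HIGHER_ORDER_ICNS
    effect_size: float = 0.8
    ar1_coefficient: float = 0.3
    noise_sd: float = 1.0
    drift_amplitude: float = 0.5
    motion_spike_probability: float = 0.02
    compartment_leak: float = 0.3
    negative_subgroup_boost: float = 0.0

    def __post_init__(self) -> None:
        base = np.asarray(self.base_coupling, dtype=np.float64)
        if base.shape != (len(NUCLEUS_LABELS), len(ICN_LABELS)):
            raise ValueError("base_coupling must be 7 x 10 (nuclei x ICNs)")
        if not np.all(np.isfinite(base)):
            raise ValueError("loadings must be finite")
        object.__setattr__(self, "base_coupling", base)
        if self.target_nucleus not in NUCLEUS_LABELS:
            raise ValueError(f"unknown target nucleus {self.target_nucleus!r}")
        unknown = set(self.modulated_icns) - set(ICN_LABELS)
        if unknown:
            raise ValueError(f"unknown modulated ICNs {sorted(unknown)}")
        if not 0 <= self.ar1_coefficient < 1:
            raise ValueError("ar1_coefficient must be in [0, 1)")

    def loadings(self, with_effect: bool, effect_scale: float = 1.0) -> np.ndarray:
        """The 7 × 10 loading matrix for one condition."""
        L = self.base_coupling.copy()
        if with_effect and self.effect_size != 0.0:
            i = NUCLEUS_LABELS.index(self.target_nucleus)
            for icn in self.modulated_icns:
                L[i, ICN_LABELS.index(icn)] += self.effect_size * effect_scale
        return L

    def to_json_dict(self) -> dict:
        d = {
            "base_coupling": self.base_coupling.tolist(),
            "target_nucleus": self.target_nucleus,
            "modulated_icns": list(self.modulated_icns),
            "effect_size": self.effect_size,
            "ar1_coefficient": self.ar1_coefficient,
            "noise_sd": self.noise_sd,
            "drift_amplitude": self.drift_amplitude,
            "motion_spike_probability": self.motion_spike_probability,
            "compartment_leak": self.compartment_leak,
            "negative_subgroup_boost": self.negative_subgroup_boost,
        }
        return d


def preset_coupling(name: str) -> CouplingModel:
    """Named ground-truth presets.

    ``anaesthesia_like`` modulates the pulvinar (Pu), ``doc_like`` the
    ventral-latero-ventral nucleus (VLV) — the nuclei with maximal FC
    change in pharmacological and pathological loss of consciousness
    respectively; ``doc_like`` additionally boosts the effect in
    task-non-responder patients.  ``null`` plants no effect.

    The strong setting (loading shift 0.9 on a weak 0.1 base, voxel noise
    sd 0.7) is sized so that the planted per-voxel Fisher-z change is
    roughly twice its sampling standard deviation at ~100 effective
    volumes — i.e. individually detectable at small group sizes, as a
    planted-truth phantom should be.
    """
    base = np.full((len(NUCLEUS_LABELS), len(ICN_LABELS)), 0.1)
    common = dict(
        base_coupling=base,
        modulated_icns=HIGHER_ORDER_ICNS,
        effect_size=0.9,
        ar1_coefficient=0.3,
        noise_sd=0.7,
        drift_amplitude=0.5,
        motion_spike_probability=0.02,
        compartment_leak=0.3,
    )
    if name == "anaesthesia_like":
        return CouplingModel(target_nucleus="Pu", **common)
    if name == "doc_like":
        return CouplingModel(
            target_nucleus="VLV", negative_subgroup_boost=0.6, **common
        )
    if name == "null":
        return CouplingModel(target_nucleus="Pu", **{**common, "effect_size": 0.0})
    raise ValueError(f"unknown preset {name!r}")


@dataclass
class PhantomGeometry:
    """Region layout of the phantom: nuclei, ICNs, noise compartments.

    ``brain_mask`` is the analysis envelope (grey-matter-like sphere
    containing nuclei, ICN regions and unstructured background voxels);
    the WM/CSF compartments sit outside it, as real noise compartments sit
    outside the grey-matter analysis mask.
    """

    nuclei: LabeledMaskSet
    icns: LabeledMaskSet
    noise: LabeledMaskSet
    brain_mask: np.ndarray

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.nuclei.grid_shape

    def envelope(self) -> np.ndarray:
        """All voxels carrying any signal (brain plus compartments)."""
        return self.brain_mask | self.noise.union()


def _fibonacci_directions(n: int) -> np.ndarray:
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    s = np.sqrt(1.0 - z**2)
    return np.stack([s * np.cos(phi), s * np.sin(phi), z], axis=1)


def build_phantom_geometry(spec: PhantomSpec, seed: int = 0) -> PhantomGeometry:
    """Lay out 7 central nucleus blobs, 10 peripheral ICN blobs and WM/CSF
    shells on the phantom grid.

    The layout is deterministic for a given spec (``seed`` is accepted for
    interface symmetry with the simulators).  Raises ``ValueError`` when
    the grid is too small to host all 19 regions disjointly.
    """
    shape = tuple(int(s) for s in spec.grid_shape)
    center = (np.array(shape, dtype=np.float64) - 1.0) / 2.0
    radius_max = 0.48 * (min(shape) - 1)
    grid = np.indices(shape).reshape(3, -1).T.astype(np.float64)
    rel = grid - center
    dist_center = np.linalg.norm(rel, axis=1)

    def sphere(c: np.ndarray, r: float) -> np.ndarray:
        return (np.linalg.norm(grid - c, axis=1) <= r).reshape(shape)

    # thalamus-like central cluster: one blob at the centre, six on the axes
    d_n = 0.28 * radius_max
    r_n = 0.135 * radius_max
    offsets = np.array([
        [0, 0, 0], [1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0],
        [0, 0, 1], [0, 0, -1],
    ], dtype=np.float64) * d_n
    nucleus_masks = {
        label: sphere(center + off, r_n)
        for label, off in zip(NUCLEUS_LABELS, offsets)
    }

    # peripheral cortical-network blobs on a spherical Fibonacci lattice
    rho = 0.615 * radius_max
    r_i = 0.16 * radius_max
    directions = _fibonacci_directions(len(ICN_LABELS))
    icn_masks = {
        label: sphere(center + rho * d, r_i)
        for label, d in zip(ICN_LABELS, directions)
    }

    def shell(bounds: tuple[float, float]) -> np.ndarray:
        lo, hi = (b * radius_max for b in bounds)
        return ((dist_center >= lo) & (dist_center <= hi)).reshape(shape)

    noise_masks = {"WM": shell(spec.wm_shell), "CSF": shell(spec.csf_shell)}

    all_masks = {**nucleus_masks, **icn_masks, **noise_masks}
    occupancy = np.zeros(shape, dtype=np.int32)
    for label, m in all_masks.items():
        if not m.any():
            raise ValueError(
                f"grid {shape} too small: region {label!r} is empty"
            )
        occupancy += m
    if occupancy.max() > 1:
        raise ValueError(f"grid {shape} too small: regions overlap")

    brain_mask = (dist_center <= 0.79 * radius_max).reshape(shape)

    return PhantomGeometry(
        nuclei=LabeledMaskSet(shape, nucleus_masks, "nuclei"),
        icns=LabeledMaskSet(shape, icn_masks, "icn"),
        noise=LabeledMaskSet(shape, noise_masks, "noise_compartment"),
        brain_mask=brain_mask,
    )


@dataclass
class SyntheticSubject:
    """One phantom subject: images, motion traces and generative truth."""

    participant: ParticipantRecord
    images: dict[str, VoxelTimeSeriesImage]
    motion: dict[str, pd.DataFrame]
    truth: CouplingModel
    effect_conditions: tuple[str, ...] = ()
    effect_scale: float = 1.0


def _ar1_series(rng: np.random.Generator, n_series: int, n_t: int, phi: float) -> np.ndarray:
    """AR(1) series with unit marginal variance, shape (n_series, n_t)."""
    x = np.empty((n_series, n_t))
    x[:, 0] = rng.standard_normal(n_series)
    innov_sd = np.sqrt(1.0 - phi**2)
    eps = rng.standard_normal((n_series, n_t)) * innov_sd
    for t in range(1, n_t):
        x[:, t] = phi * x[:, t - 1] + eps[:, t]
    return x


def simulate_subject(
    spec: PhantomSpec,
    coupling: CouplingModel,
    geometry: PhantomGeometry,
    conditions: Sequence[str],
    effect_conditions: Iterable[str],
    seed: int,
    participant: ParticipantRecord | None = None,
    effect_scale: float = 1.0,
) -> SyntheticSubject:
    """Simulate one subject's image and motion trace per condition.

    ``effect_conditions`` names the conditions in which the planted loading
    shift applies (e.g. ``{"deep"}`` for the within-subject design, or the
    single resting condition of a patient in the between-group design).
    """
    conditions = list(conditions)
    if not conditions:
        raise ValueError("condition_labels must be nonempty")
    effect_conditions = set(effect_conditions)
    unknown = effect_conditions - set(conditions)
    if unknown:
        raise ValueError(f"unknown condition label(s): {sorted(unknown)}")
    if participant is None:
        participant = ParticipantRecord(
            id=f"sub-{seed:05d}", gender="M", age=30, aetiology="n/a",
            months_post_injury=None, diagnosis="control", crs_r=None,
            task_response="n/a",
        )

    T = spec.n_volumes
    envelope = geometry.envelope()
    env_idx = np.where(envelope.reshape(-1))[0]
    brain = geometry.brain_mask
    images: dict[str, VoxelTimeSeriesImage] = {}
    motions: dict[str, pd.DataFrame] = {}

    for ci, cond in enumerate(conditions):
        rng = np.random.default_rng([int(seed) % (2**31), ci])
        phi = coupling.ar1_coefficient
        latents = _ar1_series(rng, len(ICN_LABELS), T, phi)
        compartment = _ar1_series(rng, 1, T, phi)[0]

        flat = np.zeros((np.prod(spec.grid_shape), T))
        flat[env_idx] = coupling.noise_sd * rng.standard_normal((env_idx.size, T))
        data = flat.reshape(spec.grid_shape + (T,))

        for k, label in enumerate(ICN_LABELS):
            data[geometry.icns.masks[label]] += latents[k]

        L = coupling.loadings(cond in effect_conditions, effect_scale)
        for i, label in enumerate(NUCLEUS_LABELS):
            data[geometry.nuclei.masks[label]] += L[i] @ latents

        for m in geometry.noise.masks.values():
            data[m] += compartment
        data[brain] += coupling.compartment_leak * compartment

        if coupling.drift_amplitude > 0:
            ramp = np.linspace(-0.5, 0.5, T)
            slow = np.cos(np.pi * np.arange(T) / (T - 1))
            amp = coupling.drift_amplitude * rng.standard_normal((env_idx.size, 2))
            drift = amp[:, :1] * ramp + amp[:, 1:] * slow
            flat = data.reshape(-1, T)
            flat[env_idx] += drift

        # motion: slow random walk plus occasional spikes mirrored by a
        # one-volume image glitch (what spike regressors should absorb)
        trace = np.cumsum(rng.normal(0.0, 0.005, size=(T, 6)), axis=0)
        spikes = rng.random(T) < coupling.motion_spike_probability
        spikes[0] = False
        for t in np.where(spikes)[0]:
            axis = rng.integers(0, 6)
            trace[t:, axis] += rng.choice([-0.3, 0.3])
            glitch = 3.0 * coupling.noise_sd * rng.standard_normal(env_idx.size)
            flat = data.reshape(-1, T)
            flat[env_idx, t] += glitch

        images[cond] = VoxelTimeSeriesImage(
            data=data, meta=spec.meta, brain_mask=brain.copy()
        )
        motions[cond] = pd.DataFrame(trace, columns=list(MOTION_COLUMNS))

    return SyntheticSubject(
        participant=participant, images=images, motion=motions,
        truth=coupling, effect_conditions=tuple(sorted(effect_conditions)),
        effect_scale=effect_scale,
    )


def implied_correlation(
    coupling: CouplingModel,
    nucleus: str,
    icn: str,
    n_seed_voxels: int,
    with_effect: bool = False,
    effect_scale: float = 1.0,
    against: str = "voxel",
) -> float:
    """Model-implied correlation between a nucleus mean series and an ICN
    signal, from the generative covariance (drift and spikes excluded).

    ``against="latent"`` correlates with the network latent itself,
    ``against="voxel"`` with a single ICN-region voxel (latent + noise).
    The seed mean averages voxel noise down to ``noise_sd² / n_seed_voxels``.
    The leaked compartment signal contributes a shared term to both sides.
    """
    L = coupling.loadings(with_effect, effect_scale)
    i = NUCLEUS_LABELS.index(nucleus)
    k = ICN_LABELS.index(icn)
    lam = coupling.compartment_leak
    s2 = coupling.noise_sd**2
    var_seed = float(L[i] @ L[i]) + lam**2 + s2 / n_seed_voxels
    cov = float(L[i, k]) + lam**2
    if against == "latent":
        var_other = 1.0
        cov = float(L[i, k])  # the latent itself carries no leak
    elif against == "voxel":
        var_other = 1.0 + lam**2 + s2
    else:
        raise ValueError("against must be 'latent' or 'voxel'")
    return cov / np.sqrt(var_seed * var_other)


@dataclass
class Cohort:
    """A simulated cohort plus the generative truth that produced it."""

    design: str
    spec: PhantomSpec
    coupling: CouplingModel
    geometry: PhantomGeometry
    subjects: list[SyntheticSubject]
    participants: ParticipantTable
    master_seed: int
    conditions: tuple[str, ...]


def _control_record(i: int) -> ParticipantRecord:
    return ParticipantRecord(
        id=f"C{i + 1:02d}", gender="M" if i % 2 == 0 else "F", age=25 + i,
        aetiology="n/a", months_post_injury=None, diagnosis="control",
        crs_r=None, task_response="n/a",
    )


def generate_cohort(
    spec: PhantomSpec,
    coupling: CouplingModel,
    design: str,
    n_per_group: Mapping[str, int] | None = None,
    master_seed: int = 0,
    out_dir: str | Path | None = None,
    overwrite: bool = False,
) -> Cohort:
    """Generate a phantom cohort for one of the two study designs.

    ``within_subject``: each subject is scanned ``awake`` and ``deep``,
    with the planted effect in ``deep`` (default n = 16, the anaesthesia
    cohort size).  ``between_group``: patients (default n = 22, carrying
    the packaged demographics when exactly 22) and awake controls
    (default n = 16), single ``rest`` condition, effect planted in the
    patient group; task non-responders receive the coupling's
    ``negative_subgroup_boost``.

    Per-subject seeds derive deterministically from ``master_seed``.  When
    ``out_dir`` is given, a BIDS-like file tree is written.
    """
    if design not in ("within_subject", "between_group"):
        raise ValueError(f"unknown design {design!r}")
    n_per_group = dict(n_per_group or {})
    if any(n <= 0 for n in n_per_group.values()):
        raise ValueError("n_per_group entries must be positive")
    geometry = build_phantom_geometry(spec, seed=master_seed)
    seed_root = np.random.SeedSequence(int(master_seed) % (2**31))

    subjects: list[SyntheticSubject] = []
    if design == "within_subject":
        n = int(n_per_group.get("subjects", 16))
        conditions = ("awake", "deep")
        for i in range(n):
            sub_seed = int(seed_root.spawn(1)[0].generate_state(1)[0] % (2**31))
            rec = _control_record(i)
            subjects.append(simulate_subject(
                spec, coupling, geometry, conditions,
                effect_conditions={"deep"}, seed=sub_seed, participant=rec,
            ))
    else:
        n_pat = int(n_per_group.get("patients", 22))
        n_ctl = int(n_per_group.get("controls", 16))
        conditions = ("rest",)
        packaged = list(packaged_participants())
        pat_records = [
            packaged[i] if i < len(packaged) else replace_id(packaged[i % len(packaged)], i)
            for i in range(n_pat)
        ]
        for rec in pat_records:
            sub_seed = int(seed_root.spawn(1)[0].generate_state(1)[0] % (2**31))
            scale = 1.0
            if rec.task_response == "negative":
                scale += coupling.negative_subgroup_boost
            subjects.append(simulate_subject(
                spec, coupling, geometry, conditions,
                effect_conditions={"rest"}, seed=sub_seed, participant=rec,
                effect_scale=scale,
            ))
        for i in range(n_ctl):
            sub_seed = int(seed_root.spawn(1)[0].generate_state(1)[0] % (2**31))
            rec = _control_record(i)
            subjects.append(simulate_subject(
                spec, coupling, geometry, conditions,
                effect_conditions=set(), seed=sub_seed, participant=rec,
            ))

    participants = ParticipantTable([s.participant for s in subjects])
    cohort = Cohort(
        design=design, spec=spec, coupling=coupling, geometry=geometry,
        subjects=subjects, participants=participants,
        master_seed=int(master_seed), conditions=conditions,
    )
    if out_dir is not None:
        write_cohort(cohort, out_dir, overwrite=overwrite)
    return cohort


def replace_id(record: ParticipantRecord, i: int) -> ParticipantRecord:
    """Clone a participant record under a fresh unique id (used when a
    requested patient group is larger than the packaged table)."""
    from dataclasses import replace as dc_replace

    return dc_replace(record, id=f"{record.id}x{i:02d}")


def write_cohort(cohort: Cohort, out_dir: str | Path, overwrite: bool = False) -> Path:
    """Write a cohort as a BIDS-like tree.

    Layout::

        <out_dir>/participants.tsv
        <out_dir>/TRUTH.json
        <out_dir>/masks/{nuclei,icns,noise}.nii  (+ .json legends)
        <out_dir>/sub-<id>/cond-<label>_bold.nii.gz
        <out_dir>/sub-<id>/cond-<label>_motion.tsv
    """
    out = Path(out_dir)
    if out.exists():
        if not overwrite:
            raise FileExistsError(f"{out} exists; pass overwrite=True")
        shutil.rmtree(out)
    out.mkdir(parents=True)
    write_participants(cohort.participants, out / "participants.tsv")
    truth = {
        "design": cohort.design,
        "master_seed": cohort.master_seed,
        "conditions": list(cohort.conditions),
        "coupling": cohort.coupling.to_json_dict(),
        "spec": {
            "grid_shape": list(cohort.spec.grid_shape),
            "n_volumes": cohort.spec.n_volumes,
            "repetition_time": cohort.spec.repetition_time,
            "voxel_size_mm": cohort.spec.voxel_size_mm,
        },
        "subject_effect_scales": {
            s.participant.id: s.effect_scale for s in cohort.subjects
        },
    }
    (out / "TRUTH.json").write_text(json.dumps(truth, indent=2))
    masks_dir = out / "masks"
    masks_dir.mkdir()
    write_mask_set(cohort.geometry.nuclei, masks_dir / "nuclei.nii")
    write_mask_set(cohort.geometry.icns, masks_dir / "icns.nii")
    write_mask_set(cohort.geometry.noise, masks_dir / "noise.nii")
    for sub in cohort.subjects:
        sub_dir = out / f"sub-{sub.participant.id}"
        sub_dir.mkdir()
        for cond, img in sub.images.items():
            write_timeseries_image(img, sub_dir / f"cond-{cond}_bold.nii.gz")
            sub.motion[cond].to_csv(
                sub_dir / f"cond-{cond}_motion.tsv", sep="\t", index=False
            )
    return out


def read_cohort(in_dir: str | Path) -> Cohort:
    """Load a cohort previously written by :func:`write_cohort`.

    The TRUTH sidecar restores the generative parameters; images are read
    back with the analysis brain mask taken from the written geometry.
    """
    root = Path(in_dir)
    truth = json.loads((root / "TRUTH.json").read_text())
    spec = PhantomSpec(
        grid_shape=tuple(truth["spec"]["grid_shape"]),
        n_volumes=truth["spec"]["n_volumes"],
        repetition_time=truth["spec"]["repetition_time"],
        voxel_size_mm=truth["spec"]["voxel_size_mm"],
    )
    c = truth["coupling"]
    coupling = CouplingModel(
        base_coupling=np.asarray(c["base_coupling"]),
        target_nucleus=c["target_nucleus"],
        modulated_icns=tuple(c["modulated_icns"]),
        effect_size=c["effect_size"],
        ar1_coefficient=c["ar1_coefficient"],
        noise_sd=c["noise_sd"],
        drift_amplitude=c["drift_amplitude"],
        motion_spike_probability=c["motion_spike_probability"],
        compartment_leak=c["compartment_leak"],
        negative_subgroup_boost=c["negative_subgroup_boost"],
    )
    geometry = build_phantom_geometry(spec, seed=truth["master_seed"])
    participants = read_participants(root / "participants.tsv")
    design = truth["design"]
    conditions = tuple(truth["conditions"])
    scales = truth.get("subject_effect_scales", {})
    subjects = []
    for rec in participants:
        sub_dir = root / f"sub-{rec.id}"
        images, motions = {}, {}
        for cond in conditions:
            img = read_timeseries_image(
                sub_dir / f"cond-{cond}_bold.nii.gz",
                repetition_time=spec.repetition_time,
            )
            # analysis mask comes from the geometry, not the data heuristics
            img.brain_mask = geometry.brain_mask.copy()
            images[cond] = img
            motions[cond] = pd.read_csv(
                sub_dir / f"cond-{cond}_motion.tsv", sep="\t"
            )
        if design == "within_subject":
            effect_conditions = ("deep",)
        else:
            effect_conditions = (
                ("rest",) if rec.diagnosis != "control" else ()
            )
        subjects.append(SyntheticSubject(
            participant=rec, images=images, motion=motions, truth=coupling,
            effect_conditions=effect_conditions,
            effect_scale=float(scales.get(rec.id, 1.0)),
        ))
    return Cohort(
        design=design, spec=spec, coupling=coupling, geometry=geometry,
        subjects=subjects, participants=participants,
        master_seed=int(truth["master_seed"]), conditions=conditions,
    )
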