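"""Group-level voxelwise inference on connectivity maps.

Paired, two-sample and one-sample t maps, voxel-forming threshold
p < 0.005 (two-sided, uncorrected), and cluster-extent family-wise-error
control at p < 0.05 via permutation of the maximum cluster extent:
sign-flipping for paired/one-sample designs, group-label shuffling for
two-sample designs.  When the full sign-flip group (2^n) is no larger than
the requested permutation count, the enumeration is exhaustive and the
corrected p values are exact under exchangeability.

Clusters are maximal face-connected (6-connectivity) components of
suprathreshold |t| voxels; 18- and 26-connectivity are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .connectivity import FCMap

VOXEL_P_DEFAULT = 0.005
CLUSTER_FWE_P_DEFAULT = 0.05


@dataclass
class Cluster:
    """One suprathreshold cluster with its permutation-corrected p."""

    voxels: np.ndarray  # (k, 3) integer coordinates
    extent: int
    peak_voxel: tuple[int, int, int]
    peak_t: float
    corrected_p: float | None = None


@dataclass
class GroupStatMap:
    """Voxelwise t/p maps for one contrast, with optional surviving clusters."""

    contrast: str
    t_values: np.ndarray
    p_values: np.ndarray
    df: int
    brain_mask: np.ndarray
    voxel_p: float = VOXEL_P_DEFAULT
    cluster_fwe_p: float = CLUSTER_FWE_P_DEFAULT
    clusters: list[Cluster] = field(default_factory=list)
    n_zero_variance: int = 0

    def suprathreshold_mask(self) -> np.ndarray:
        """Voxels with two-sided uncorrected p below the voxel threshold."""
        return (
            self.brain_mask
            & np.isfinite(self.p_values)
            & (self.p_values < self.voxel_p)
        )

    def surviving_mask(self) -> np.ndarray:
        """Union of clusters surviving the FWE threshold."""
        out = np.zeros(self.t_values.shape, dtype=bool)
        for c in self.clusters:
            if c.corrected_p is not None and c.corrected_p < self.cluster_fwe_p:
                out[tuple(c.voxels.T)] = True
        return out


def _connectivity_structure(connectivity: int) -> np.ndarray:
    rank = {6: 1, 18: 2, 26: 3}.get(connectivity)
    if rank is None:
        raise ValueError("connectivity must be 6, 18 or 26")
    return ndimage.generate_binary_structure(3, rank)


def _stack_values(maps: list[FCMap]) -> tuple[np.ndarray, np.ndarray]:
    """Stack map values to (n, V) over the shared in-mask voxel index."""
    if not maps:
        raise ValueError("empty map list")
    mask = maps[0].brain_mask
    for m in maps[1:]:
        if m.brain_mask.shape != mask.shape:
            raise ValueError("maps do not share a grid")
    data = np.stack([m.values[mask] for m in maps])
    return data, mask


def _one_sample_t(data: np.ndarray) -> tuple[np.ndarray, int]:
    """Voxelwise one-sample t against 0 over axis 0.

    Degenerate voxels: sd = 0 with zero mean gives t = 0 (no evidence
    either way); sd = 0 with nonzero mean (t → ±∞) is flagged missing.
    """
    n = data.shape[0]
    mean = np.nanmean(data, axis=0)
    sd = np.nanstd(data, axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[(sd == 0) & (mean == 0)] = 0.0
    t[(sd == 0) & (mean != 0)] = np.nan
    return t, n - 1


def _fill_map(
    contrast: str, t_flat: np.ndarray, df: int, mask: np.ndarray,
    voxel_p: float,
) -> GroupStatMap:
    t_vol = np.full(mask.shape, np.nan)
    p_vol = np.full(mask.shape, np.nan)
    t_vol[mask] = t_flat
    with np.errstate(invalid="ignore"):
        p_flat = 2.0 * stats.t.sf(np.abs(t_flat), df)
    p_vol[mask] = p_flat
    n_zero = int(np.isnan(t_flat).sum())
    return GroupStatMap(
        contrast=contrast, t_values=t_vol, p_values=p_vol, df=df,
        brain_mask=mask, voxel_p=voxel_p, n_zero_variance=n_zero,
    )


def one_sample_group_map(
    maps: list[FCMap], contrast: str = "one_sample",
    voxel_p: float = VOXEL_P_DEFAULT,
) -> GroupStatMap:
    """Voxelwise one-sample t of the individual maps against 0.

    Degenerate voxels (zero variance across subjects) are flagged missing
    (NaN t and p) and counted in ``n_zero_variance``.
    """
    if len(maps) < 3:
        raise ValueError("need at least 3 maps")
    data, mask = _stack_values(maps)
    t, df = _one_sample_t(data)
    return _fill_map(contrast, t, df, mask, voxel_p)


def paired_t_map(
    maps_a: list[FCMap], maps_b: list[FCMap],
    contrast: str = "paired", voxel_p: float = VOXEL_P_DEFAULT,
) -> GroupStatMap:
    """Paired t map of condition a minus condition b.

    Exactly the one-sample t applied to within-subject difference maps;
    subjects must match one-to-one (checked by id).
    """
    if len(maps_a) != len(maps_b) or len(maps_a) < 3:
        raise ValueError("need matched lists with n >= 3")
    ids_a = [m.subject_id for m in maps_a]
    ids_b = [m.subject_id for m in maps_b]
    if ids_a != ids_b:
        raise ValueError("subject mismatch between conditions")
    data_a, mask = _stack_values(maps_a)
    data_b, _ = _stack_values(maps_b)
    t, df = _one_sample_t(data_a - data_b)
    return _fill_map(contrast, t, df, mask, voxel_p)


def two_sample_t_map(
    maps_g1: list[FCMap], maps_g2: list[FCMap],
    contrast: str = "two_sample", voxel_p: float = VOXEL_P_DEFAULT,
) -> GroupStatMap:
    """Pooled-variance two-sample t map (group 1 minus group 2),
    df = n1 + n2 − 2."""
    n1, n2 = len(maps_g1), len(maps_g2)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    d1, mask = _stack_values(maps_g1)
    d2, _ = _stack_values(maps_g2)
    t = _two_sample_t_flat(d1, d2)
    return _fill_map(contrast, t, n1 + n2 - 2, mask, voxel_p)


def _two_sample_t_flat(d1: np.ndarray, d2: np.ndarray) -> np.ndarray:
    n1, n2 = d1.shape[0], d2.shape[0]
    m1, m2 = d1.mean(axis=0), d2.mean(axis=0)
    ss1 = ((d1 - m1) ** 2).sum(axis=0)
    ss2 = ((d2 - m2) ** 2).sum(axis=0)
    sp2 = (ss1 + ss2) / (n1 + n2 - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    t[(sp2 == 0) & (m1 == m2)] = 0.0
    t[(sp2 == 0) & (m1 != m2)] = np.nan
    return t


def _clusters_from_t(
    t_vol: np.ndarray, mask: np.ndarray, t_crit: float, structure: np.ndarray
) -> list[Cluster]:
    supra = mask & np.isfinite(t_vol) & (np.abs(t_vol) > t_crit)
    labeled, n = ndimage.label(supra, structure=structure)
    clusters = []
    for lab in range(1, n + 1):
        vox = np.argwhere(labeled == lab)
        ts = t_vol[tuple(vox.T)]
        peak = int(np.argmax(np.abs(ts)))
        clusters.append(Cluster(
            voxels=vox, extent=vox.shape[0],
            peak_voxel=tuple(int(v) for v in vox[peak]),
            peak_t=float(ts[peak]),
        ))
    clusters.sort(key=lambda c: -c.extent)
    return clusters


def _max_extent(supra_flat: np.ndarray, mask: np.ndarray,
                structure: np.ndarray) -> int:
    vol = np.zeros(mask.shape, dtype=bool)
    vol[mask] = supra_flat
    labeled, n = ndimage.label(vol, structure=structure)
    if n == 0:
        return 0
    return int(np.bincount(labeled.reshape(-1))[1:].max())


def _sign_matrix(n: int, n_permutations: int, rng: np.random.Generator
                 ) -> tuple[np.ndarray, bool]:
    """Sign-flip matrix (P, n); exhaustive when 2^n <= n_permutations."""
    if 2**n <= n_permutations:
        bits = np.arange(2**n)[:, None] >> np.arange(n)[None, :] & 1
        return np.where(bits == 1, -1.0, 1.0), True
    signs = rng.choice([-1.0, 1.0], size=(n_permutations, n))
    signs[0] = 1.0  # include the identity, standard Monte-Carlo convention
    return signs, False


def permutation_cluster_fwe(
    stat_map: GroupStatMap,
    data: np.ndarray,
    design: str = "one_sample",
    group_sizes: tuple[int, int] | None = None,
    n_permutations: int = 5000,
    seed: int | None = 0,
    connectivity: int = 6,
) -> GroupStatMap:
    """Attach permutation-corrected cluster p values to a thresholded map.

    ``data`` holds the per-subject values behind the map: for
    ``one_sample`` (and paired designs, via difference maps) an (n, V)
    array over the in-mask voxels, sign-flipped under the null; for
    ``two_sample`` the stacked groups (n1+n2, V) with ``group_sizes``,
    label-shuffled under the null.  The corrected p of an observed cluster
    is the proportion of permutation maximum extents at least as large.
    Exhaustive sign-flip enumeration (exact p) is used whenever
    2^n ≤ ``n_permutations``.
    """
    if n_permutations < 100:
        raise ValueError("refusing fewer than 100 permutations")
    structure = _connectivity_structure(connectivity)
    mask = stat_map.brain_mask
    data = np.asarray(data, dtype=np.float64)
    rng = np.random.default_rng(seed)
    t_crit = float(stats.t.isf(stat_map.voxel_p / 2.0, stat_map.df))

    observed = _clusters_from_t(stat_map.t_values, mask, t_crit, structure)
    if not observed:
        stat_map.clusters = []
        return stat_map

    if design == "one_sample":
        n = data.shape[0]
        signs, exhaustive = _sign_matrix(n, n_permutations, rng)
        ss = (data**2).sum(axis=0)  # invariant under sign flips
        max_extents = np.empty(signs.shape[0], dtype=np.int64)
        for p_i, s in enumerate(signs):
            mean = (s @ data) / n
            var = (ss / n - mean**2) * (n / (n - 1))
            with np.errstate(divide="ignore", invalid="ignore"):
                t = mean / np.sqrt(var / n)
            supra = np.isfinite(t) & (np.abs(t) > t_crit)
            max_extents[p_i] = _max_extent(supra, mask, structure)
        denom = signs.shape[0]
    elif design == "two_sample":
        if group_sizes is None:
            raise ValueError("two_sample design requires group_sizes")
        n1, n2 = group_sizes
        if n1 + n2 != data.shape[0]:
            raise ValueError("group_sizes inconsistent with data")
        exhaustive = False
        max_extents = np.empty(n_permutations, dtype=np.int64)
        perm = np.arange(n1 + n2)
        for p_i in range(n_permutations):
            if p_i > 0:
                rng.shuffle(perm)
            t = _two_sample_t_flat(data[perm[:n1]], data[perm[n1:]])
            supra = np.isfinite(t) & (np.abs(t) > t_crit)
            max_extents[p_i] = _max_extent(supra, mask, structure)
        denom = n_permutations
    else:
        raise ValueError(f"unknown design {design!r}")

    for cluster in observed:
        cluster.corrected_p = float((max_extents >= cluster.extent).sum() / denom)
    stat_map.clusters = observed
    return stat_map
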