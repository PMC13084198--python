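"""ICN spatial-involvement profiles and hierarchical clustering.

Each nucleus's group contrast map is scored against the 10 canonical
intrinsic connectivity networks.  The default involvement metric is the
suprathreshold fraction — the share of a network's voxels that exceed the
map's voxel-forming threshold — mirroring a voxel-overlap readout; a
weighted mode (mean |t| over the network) serves unthresholded maps, and a
signed companion (mean signed t) captures direction ("opposite FC
changes").  The 7 × 10 nucleus × network matrix is then clustered
agglomeratively with Euclidean distance and complete linkage, on rows
(nuclei) and columns (networks) separately.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .group_stats import GroupStatMap
from .io_cohort import ICN_LABELS, NUCLEUS_LABELS, LabeledMaskSet


@dataclass
class InvolvementMatrix:
    """Nucleus × ICN involvement scores with provenance metadata."""

    values: pd.DataFrame  # rows: 7 nuclei, columns: 10 ICNs
    mode: str
    signed: pd.DataFrame | None = None  # mean signed t companion

    def __post_init__(self) -> None:
        if list(self.values.index) != list(NUCLEUS_LABELS):
            raise ValueError("rows must be the canonical nuclei in order")
        if list(self.values.columns) != list(ICN_LABELS):
            raise ValueError("columns must be the canonical ICNs in order")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("involvement scores must be finite")


@dataclass
class ClusteringResult:
    """Agglomerative merge tree over one axis of the involvement matrix."""

    labels: list[str]
    linkage: np.ndarray  # scipy linkage matrix (n-1, 4)
    leaf_order: list[str]
    flat_labels: dict[str, int]
    cophenetic: np.ndarray  # condensed cophenetic distances
    newick: str

    def cut(self, k: int) -> dict[str, int]:
        assign = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.labels, (int(a) for a in assign)))

    def merge_table(self) -> pd.DataFrame:
        """Merge events as (item_i, item_j, height, size) with original
        items named and internal nodes numbered."""
        n = len(self.labels)

        def name(idx: int) -> str:
            return self.labels[idx] if idx < n else f"node{idx}"

        rows = [
            {
                "item_i": name(int(a)), "item_j": name(int(b)),
                "height": float(h), "size": int(s),
            }
            for a, b, h, s in self.linkage
        ]
        return pd.DataFrame(rows)


def icn_involvement(
    stat_map: GroupStatMap,
    icns: LabeledMaskSet,
    mode: str = "suprathreshold_fraction",
) -> tuple[dict[str, float], dict[str, float]]:
    """Per-ICN involvement of a contrast map.

    Returns ``(scores, signed)``: the unsigned involvement per the chosen
    mode, and the mean signed t over each network (the directionality
    companion).  ``suprathreshold_fraction`` counts the network's voxels
    exceeding the map's voxel threshold, as a fraction of the network;
    ``weighted`` averages |t| over the network.
    """
    if tuple(icns.grid_shape) != stat_map.t_values.shape:
        raise ValueError("stat map and ICN masks do not share a grid")
    supra = stat_map.suprathreshold_mask()
    scores: dict[str, float] = {}
    signed: dict[str, float] = {}
    for label, mask in icns.masks.items():
        n_vox = int(mask.sum())
        if n_vox == 0:
            raise ValueError(f"empty ICN mask {label!r}")
        t_vals = stat_map.t_values[mask]
        finite = np.isfinite(t_vals)
        signed[label] = float(t_vals[finite].mean()) if finite.any() else 0.0
        if mode == "suprathreshold_fraction":
            scores[label] = float((supra & mask).sum() / n_vox)
        elif mode == "weighted":
            scores[label] = (
                float(np.abs(t_vals[finite]).mean()) if finite.any() else 0.0
            )
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return scores, signed


def involvement_matrix(
    stat_maps: dict[str, GroupStatMap],
    icns: LabeledMaskSet,
    mode: str = "suprathreshold_fraction",
) -> InvolvementMatrix:
    """Assemble the 7 × 10 nucleus × network involvement matrix.

    ``stat_maps`` maps nucleus label → group contrast map; exactly the 7
    canonical nuclei are required.  Output ordering is canonical on both
    axes and independent of the input iteration order.
    """
    missing = set(NUCLEUS_LABELS) - set(stat_maps)
    if missing:
        raise ValueError(f"missing nucleus map(s): {sorted(missing)}")
    rows, signed_rows = [], []
    for nucleus in NUCLEUS_LABELS:
        scores, signed = icn_involvement(stat_maps[nucleus], icns, mode)
        rows.append([scores[icn] for icn in ICN_LABELS])
        signed_rows.append([signed[icn] for icn in ICN_LABELS])
    values = pd.DataFrame(rows, index=list(NUCLEUS_LABELS), columns=list(ICN_LABELS))
    signed_df = pd.DataFrame(
        signed_rows, index=list(NUCLEUS_LABELS), columns=list(ICN_LABELS)
    )
    return InvolvementMatrix(values=values, mode=mode, signed=signed_df)


def _to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    n = len(labels)
    nodes: dict[int, str] = {i: labels[i] for i in range(n)}
    heights: dict[int, float] = {i: 0.0 for i in range(n)}
    for i, (a, b, h, _) in enumerate(linkage):
        a, b = int(a), int(b)
        la = h - heights[a]
        lb = h - heights[b]
        nodes[n + i] = f"({nodes[a]}:{la:.6g},{nodes[b]}:{lb:.6g})"
        heights[n + i] = float(h)
    return nodes[n + len(linkage) - 1] + ";"


def hierarchical_cluster(
    matrix: InvolvementMatrix,
    axis: str = "rows",
    n_flat_clusters: int = 2,
    use_signed: bool = False,
) -> ClusteringResult:
    """Complete-linkage agglomerative clustering with Euclidean distance.

    ``axis="rows"`` clusters nuclei by their network profiles,
    ``axis="columns"`` clusters networks by their nucleus profiles.  Items
    enter in canonical order, which fixes tie-breaking deterministically.
    ``use_signed`` clusters the signed-involvement companion instead (the
    matrix that carries the direction of FC change).
    """
    source = matrix.signed if (use_signed and matrix.signed is not None) else matrix.values
    if axis == "rows":
        data = source.to_numpy(dtype=np.float64)
        labels = list(source.index)
    elif axis == "columns":
        data = source.to_numpy(dtype=np.float64).T
        labels = list(source.columns)
    else:
        raise ValueError("axis must be 'rows' or 'columns'")
    return complete_linkage_tree(data, labels, n_flat_clusters)


def complete_linkage_tree(
    data: np.ndarray, labels: list[str], n_flat_clusters: int = 2
) -> ClusteringResult:
    """Complete-linkage Euclidean agglomeration of arbitrary labelled items
    (one row per item); the clustering core behind
    :func:`hierarchical_cluster`."""
    data = np.asarray(data, dtype=np.float64)
    if len(labels) != data.shape[0]:
        raise ValueError("one label per item required")
    if len(labels) < 2:
        raise ValueError("need at least 2 items to cluster")
    if not np.isfinite(data).all():
        raise ValueError("non-finite values in clustering input")
    Z = hierarchy.linkage(data, method="complete", metric="euclidean")
    leaf_idx = hierarchy.leaves_list(Z)
    coph = hierarchy.cophenet(Z)
    flat = hierarchy.fcluster(Z, t=n_flat_clusters, criterion="maxclust")
    return ClusteringResult(
        labels=list(labels),
        linkage=Z,
        leaf_order=[labels[i] for i in leaf_idx],
        flat_labels=dict(zip(labels, (int(f) for f in flat))),
        cophenetic=coph,
        newick=_to_newick(Z, labels),
    )


def export_radar_and_heatmap(
    matrix: InvolvementMatrix,
    row_clustering: ClusteringResult,
    column_clustering: ClusteringResult,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write plot-ready involvement data.

    Emits the involvement matrix as TSV, per-nucleus radar series plus
    dendrogram leaf orders as JSON, and both merge trees as Newick and
    TSV merge tables.  Rendering itself is left to the caller.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["matrix"] = out / "involvement_matrix.tsv"
    matrix.values.to_csv(paths["matrix"], sep="\t")
    if matrix.signed is not None:
        paths["signed_matrix"] = out / "involvement_signed.tsv"
        matrix.signed.to_csv(paths["signed_matrix"], sep="\t")

    radar = {
        "mode": matrix.mode,
        "icns": list(matrix.values.columns),
        "series": {n: list(matrix.values.loc[n]) for n in matrix.values.index},
        "row_order": row_clustering.leaf_order,
        "column_order": column_clustering.leaf_order,
    }
    paths["radar"] = out / "radar.json"
    paths["radar"].write_text(json.dumps(radar, indent=2))

    for name, cl in (("rows", row_clustering), ("columns", column_clustering)):
        p_newick = out / f"dendrogram_{name}.nwk"
        p_newick.write_text(cl.newick + "\n")
        paths[f"newick_{name}"] = p_newick
        p_table = out / f"merges_{name}.tsv"
        cl.merge_table().to_csv(p_table, sep="\t", index=False)
        paths[f"merges_{name}"] = p_table
    return paths
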