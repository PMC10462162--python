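"""Sphere-based brain parcellation and its partition into functional networks.

The default atlas follows the 264-ROI resting-state parcellation in which each
region of interest (ROI) is a 5 mm-radius sphere in MNI space and the ROIs are
grouped into 14 functional networks (somatomotor hand/mouth, cinguloopercular,
auditory, default mode, memory, visual, frontoparietal, salience, subcortical,
ventral/dorsal attention, cerebellar, and an "uncertain" remainder).

The packaged coordinate table is *synthetic*: it preserves the published
network labels and ROI index ranges, which is all the network-level statistics
in this package depend on, but places the spheres on an arbitrary
non-overlapping grid.  Any user-supplied atlas in the same TSV format
(columns ``roi_id  x_mm  y_mm  z_mm  radius_mm  network_label  network_name``)
is accepted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, GeometryError

log = logging.getLogger(__name__)

#: Number of functional networks in the full parcellation.
N_NETWORKS = 14

#: Canonical short names per network label.  Labels 0 and 1 are both
#: somatomotor (hand and mouth) and share the SMT abbreviation.
LABEL_ABBREV: Mapping[int, str] = {
    0: "SMT", 1: "SMT", 2: "CNG", 3: "AUD", 4: "DMN", 5: "MEM", 6: "VIS",
    7: "FRNT", 8: "SAL", 9: "SUB", 10: "VTRL", 11: "DRSL", 12: "CB", 13: "UNK",
}

ATLAS_COLUMNS = (
    "roi_id", "x_mm", "y_mm", "z_mm", "radius_mm", "network_label", "network_name",
)

#: A canonical (a, b) network-label pair with a <= b.  Within-network blocks
#: (a == b) are valid keys.
BlockKey = tuple[int, int]


@dataclass(frozen=True)
class Atlas:
    """A sphere parcellation: per-ROI centers, radii and network labels.

    ROI ids are implicit row indices 0..N-1.
    """

    centers_mm: np.ndarray      # (N, 3) float, MNI mm
    radii_mm: np.ndarray        # (N,) float, > 0
    network_labels: np.ndarray  # (N,) int in 0..13
    network_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        centers = np.asarray(self.centers_mm, dtype=float)
        radii = np.asarray(self.radii_mm, dtype=float)
        labels = np.asarray(self.network_labels, dtype=int)
        object.__setattr__(self, "centers_mm", centers)
        object.__setattr__(self, "radii_mm", radii)
        object.__setattr__(self, "network_labels", labels)
        if centers.ndim != 2 or centers.shape[1] != 3:
            raise FormatError("centers_mm must be an (N, 3) array")
        n = centers.shape[0]
        if radii.shape != (n,) or labels.shape != (n,):
            raise FormatError("radii_mm and network_labels must have one entry per ROI")
        if n and not np.all(radii > 0):
            raise FormatError("all radii must be positive")
        if n and (labels.min() < 0 or labels.max() >= N_NETWORKS):
            raise FormatError(
                f"network labels must lie in 0..{N_NETWORKS - 1}, "
                f"got range [{labels.min()}, {labels.max()}]"
            )
        if self.network_names and len(self.network_names) != n:
            raise FormatError("network_names must have one entry per ROI")

    @property
    def n_rois(self) -> int:
        return self.centers_mm.shape[0]

    @property
    def labels(self) -> np.ndarray:
        """Sorted unique network labels present in the atlas."""
        return np.unique(self.network_labels)

    def subset(self, roi_ids: Sequence[int]) -> "Atlas":
        """New atlas restricted to ``roi_ids`` (re-indexed 0..m-1, labels kept)."""
        idx = np.asarray(roi_ids, dtype=int)
        names = tuple(self.network_names[i] for i in idx) if self.network_names else ()
        return Atlas(self.centers_mm[idx], self.radii_mm[idx],
                     self.network_labels[idx], names)


@dataclass(frozen=True)
class NetworkPartition:
    """Ordered mapping network label -> ROI ids; disjoint and covering."""

    rois_by_label: Mapping[int, np.ndarray]
    n_rois: int = field(default=0)

    def __post_init__(self) -> None:
        seen: set[int] = set()
        total = 0
        for label, rois in self.rois_by_label.items():
            rois = np.asarray(rois, dtype=int)
            if rois.size == 0:
                raise FormatError(f"network {label} has no ROIs")
            if seen & set(rois.tolist()):
                raise FormatError("network ROI lists overlap")
            seen.update(rois.tolist())
            total += rois.size
        n = self.n_rois or total
        object.__setattr__(self, "n_rois", n)
        if seen != set(range(n)):
            raise FormatError("networks must jointly cover ROI ids 0..N-1")

    @property
    def labels(self) -> list[int]:
        return sorted(self.rois_by_label)

    @property
    def n_networks(self) -> int:
        return len(self.rois_by_label)

    def rois(self, label: int) -> np.ndarray:
        return np.asarray(self.rois_by_label[label], dtype=int)

    def roi_labels(self) -> np.ndarray:
        """Per-ROI network label, shape (n_rois,)."""
        out = np.empty(self.n_rois, dtype=int)
        for label, rois in self.rois_by_label.items():
            out[np.asarray(rois, dtype=int)] = label
        return out

    def abbrev(self, label: int) -> str:
        return LABEL_ABBREV.get(label, f"N{label}")

    def block_name(self, key: BlockKey) -> str:
        a, b = key
        return f"{self.abbrev(a)}-{self.abbrev(b)}"


def load_atlas(path) -> Atlas:
    """Read an atlas from a TSV file (see module docstring for the columns).

    Row order must agree with ``roi_id`` order, and the ids must be the
    contiguous range 0..N-1.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in ATLAS_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"atlas file {path} lacks required columns: {missing}")
    ids = df["roi_id"].to_numpy()
    if len(np.unique(ids)) != len(ids):
        dup = int(ids[pd.Series(ids).duplicated()][0])
        raise FormatError(f"duplicate roi_id {dup} in atlas file {path}")
    if not np.array_equal(np.sort(ids), np.arange(len(ids))):
        raise FormatError(f"roi_ids in {path} must be the contiguous range 0..N-1")
    df = df.sort_values("roi_id", kind="stable")
    return Atlas(
        centers_mm=df[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float),
        radii_mm=df["radius_mm"].to_numpy(dtype=float),
        network_labels=df["network_label"].to_numpy(dtype=int),
        network_names=tuple(df["network_name"].astype(str)),
    )


def default_atlas() -> Atlas:
    """The packaged 264-ROI / 14-network atlas (synthetic coordinates)."""
    ref = resources.files("fclong.data") / "power264_synthetic_atlas.tsv"
    with resources.as_file(ref) as path:
        return load_atlas(path)


def reduce_atlas(
    atlas: Atlas,
    networks: Iterable[int] | None = None,
    max_rois_per_network: int | None = None,
) -> Atlas:
    """Restrict an atlas to selected networks and/or cap ROIs per network.

    Useful for fast simulations that only exercise particular network blocks;
    network labels are preserved so block keys remain comparable.
    """
    keep_labels = set(atlas.labels.tolist() if networks is None else networks)
    keep: list[int] = []
    for label in sorted(keep_labels):
        rois = np.flatnonzero(atlas.network_labels == label)
        if max_rois_per_network is not None:
            rois = rois[:max_rois_per_network]
        keep.extend(rois.tolist())
    if not keep:
        raise FormatError("atlas reduction removed every ROI")
    return atlas.subset(keep)


def network_partition(atlas: Atlas, merge_somatomotor: bool = False) -> NetworkPartition:
    """Partition ROI ids by network label.

    With ``merge_somatomotor`` the hand (0) and mouth (1) somatomotor networks
    are pooled under label 0, matching analyses that treat SMT as one network.
    """
    labels = atlas.network_labels.copy()
    if merge_somatomotor:
        labels[labels == 1] = 0
    mapping = {
        int(label): np.flatnonzero(labels == label) for label in np.unique(labels)
    }
    return NetworkPartition(mapping, n_rois=atlas.n_rois)


def block_pairs(partition: NetworkPartition) -> list[BlockKey]:
    """All canonical network-pair keys in (a, b) lexicographic order.

    For K networks this enumerates the complete graph with self-loops:
    K(K+1)/2 keys; 14 networks give the 105 inter-network connections
    (within-network blocks included).
    """
    labels = partition.labels
    return [(a, b) for i, a in enumerate(labels) for b in labels[i:]]


def roi_sphere_mask(
    atlas: Atlas,
    roi_id: int,
    shape: tuple[int, int, int],
    affine: np.ndarray,
) -> np.ndarray:
    """Voxel indices (m, 3) whose centers lie within the ROI sphere.

    Membership is center-in-sphere with a non-strict inequality on the
    Euclidean distance, which is deterministic and independent of grid
    resolution.  An ROI entirely outside the grid yields an empty mask and a
    logged warning.
    """
    affine = np.asarray(affine, dtype=float)
    try:
        inv = np.linalg.inv(affine)
    except np.linalg.LinAlgError as exc:
        raise GeometryError(f"non-invertible affine: {exc}") from exc
    center = atlas.centers_mm[roi_id]
    radius = float(atlas.radii_mm[roi_id])

    # Bounding box of the sphere in voxel coordinates: transform the 8 corners
    # of the world-space bounding cube.
    corners = center + radius * np.array(
        [[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)]
    )
    vox = (inv[:3, :3] @ corners.T).T + inv[:3, 3]
    lo = np.maximum(np.floor(vox.min(axis=0)).astype(int), 0)
    hi = np.minimum(np.ceil(vox.max(axis=0)).astype(int), np.asarray(shape) - 1)
    if np.any(hi < lo):
        log.warning("ROI %d sphere lies outside the image grid; empty mask", roi_id)
        return np.empty((0, 3), dtype=int)

    ii, jj, kk = np.meshgrid(
        *(np.arange(lo[d], hi[d] + 1) for d in range(3)), indexing="ij"
    )
    idx = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    world = (affine[:3, :3] @ idx.T).T + affine[:3, 3]
    dist2 = np.sum((world - center) ** 2, axis=1)
    mask = idx[dist2 <= radius**2 + 1e-9]
    if mask.shape[0] == 0:
        log.warning("ROI %d sphere contains no voxel centers", roi_id)
    return mask


def roi_masks(
    atlas: Atlas, shape: tuple[int, int, int], affine: np.ndarray
) -> list[np.ndarray]:
    """Sphere masks for every ROI.  Overlap is allowed: a voxel may belong to
    several ROIs and each ROI mean is computed independently."""
    return [roi_sphere_mask(atlas, r, shape, affine) for r in range(atlas.n_rois)]
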