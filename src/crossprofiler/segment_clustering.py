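"""Single-pass (leader) clustering of dihedral segments.

Segments are processed in input order: each joins the nearest existing
cluster centroid if the angular distance is within ``D_th`` (30 degrees by
default), otherwise it founds a new cluster.  Centroids are circular running
means, updated after every join, so the result is deterministic for a fixed
input order — the order is part of reproducibility and is recorded by the
CLI manifest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure_io import DihedralSegment


@dataclass
class ClusteringConfig:
    d_th: float = 30.0       # angular similarity threshold, degrees
    min_members: int = 80    # floor applied downstream, when building profiles
    L: int = 15

    def __post_init__(self) -> None:
        if self.d_th <= 0:
            raise ValueError("d_th must be > 0")
        if self.min_members < 1:
            raise ValueError("min_members must be >= 1")


def _wrapped_diff(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Angular difference in [-180, 180]."""
    d = (np.asarray(a, dtype=float) - np.asarray(b, dtype=float) + 180.0) % 360.0 - 180.0
    return d


def dihedral_distance_angles(a: np.ndarray, b: np.ndarray) -> float:
    """RMS wrapped difference over interleaved (phi, psi) vectors of length 2L.

    D = sqrt( (1/(2L)) * sum(delta^2) ), with delta the wrapped angular
    difference; symmetric, bounded by 180.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("length mismatch")
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("undefined angle")
    d = _wrapped_diff(a, b)
    return float(np.sqrt(np.mean(d * d)))


def dihedral_distance(a: DihedralSegment, b: DihedralSegment) -> float:
    """Structural distance between two equal-length segments, degrees."""
    if a.L != b.L:
        raise ValueError("length mismatch")
    return dihedral_distance_angles(a.angles, b.angles)


@dataclass
class SegmentCluster:
    cluster_id: int
    member_indices: list[int] = field(default_factory=list)
    centroid: np.ndarray | None = None      # interleaved (phi, psi), degrees
    medoid_index: int | None = None
    # running circular-mean state
    _sin: np.ndarray | None = None
    _cos: np.ndarray | None = None

    @property
    def size(self) -> int:
        return len(self.member_indices)

    def _add(self, index: int, angles: np.ndarray) -> None:
        rad = np.radians(angles)
        if self._sin is None:
            self._sin = np.sin(rad)
            self._cos = np.cos(rad)
        else:
            self._sin += np.sin(rad)
            self._cos += np.cos(rad)
        self.member_indices.append(index)
        cent = np.degrees(np.arctan2(self._sin, self._cos))
        self.centroid = np.where(cent <= -180.0, 180.0, cent)


def single_pass_cluster(segments: list[DihedralSegment],
                        config: ClusteringConfig | None = None) -> list[SegmentCluster]:
    """Leader clustering in input order with incremental circular centroids.

    Ties on the nearest centroid break toward the lowest cluster id.
    Medoids are assigned afterwards via :func:`select_medoid`.
    """
    config = config or ClusteringConfig()
    clusters: list[SegmentCluster] = []
    for i, seg in enumerate(segments):
        ang = seg.angles
        best = None
        best_d = None
        for cl in clusters:
            d = dihedral_distance_angles(ang, cl.centroid)
            if best_d is None or d < best_d:
                best, best_d = cl, d
        if best is not None and best_d <= config.d_th:
            best._add(i, ang)
        else:
            cl = SegmentCluster(cluster_id=len(clusters) + 1)
            cl._add(i, ang)
            clusters.append(cl)
    for cl in clusters:
        cl.medoid_index = select_medoid(cl, segments)
    return clusters


def select_medoid(cluster: SegmentCluster, segments: list[DihedralSegment]) -> int:
    """Member minimising summed distance to co-members; lowest index on ties."""
    if cluster.size == 0:
        raise ValueError("empty cluster")
    members = sorted(cluster.member_indices)
    if len(members) == 1:
        return members[0]
    angles = np.array([segments[i].angles for i in members])
    best_i, best_sum = members[0], None
    for row, i in enumerate(members):
        total = sum(
            dihedral_distance_angles(angles[row], angles[other])
            for other in range(len(members)) if other != row
        )
        if best_sum is None or total < best_sum - 1e-12:
            best_i, best_sum = i, total
    return best_i


def assignments_to_tsv(clusters: list[SegmentCluster],
                       segments: list[DihedralSegment]) -> str:
    """Per-segment TSV: [segment_id, cluster_id, is_medoid, distance_to_centroid]."""
    lines = ["segment_id\tcluster_id\tis_medoid\tdistance_to_centroid"]
    owner = {}
    for cl in clusters:
        for i in cl.member_indices:
            owner[i] = cl
    for i in range(len(segments)):
        cl = owner[i]
        d = dihedral_distance_angles(segments[i].angles, cl.centroid)
        lines.append(f"{i}\t{cl.cluster_id}\t{int(i == cl.medoid_index)}\t{d:.6f}")
    return "\n".join(lines) + "\n"


def summary_to_tsv(clusters: list[SegmentCluster]) -> str:
    """Per-cluster TSV: [cluster_id, n_members, medoid_segment_id]."""
    lines = ["cluster_id\tn_members\tmedoid_segment_id"]
    for cl in clusters:
        lines.append(f"{cl.cluster_id}\t{cl.size}\t{cl.medoid_index}")
    return "\n".join(lines) + "\n"
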