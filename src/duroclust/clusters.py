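"""Cluster identification, size statistics, and shape anisotropy.

A cluster is a connected component of the graph joining any two cells
whose (optionally periodic minimal-image) distance is strictly below the
cutoff — 2 length units, i.e. 50 um.  The cluster numbers are

    S1 = q1/q0,   S2 = q2/q1,   q_k = sum_m m^k n_m,

with ``n_m`` the number of clusters of ``m`` cells: S1 is the mean size
of a randomly chosen cluster, S2 the mean size of the cluster of a
randomly chosen cell, and S1 <= S2 by Cauchy-Schwarz with equality iff
all clusters share one size.

Shape metrics operate on positions unwrapped to a common periodic
image.  The major axis is found two independent ways — minimizing the
summed point-to-line distance through the centroid, and the leading
eigenvector of the position scatter matrix — and the cluster length and
width are the extents of the member projections on the major/minor axis,
padded by one cell diameter so a collinear pair has width d rather
than 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "ClusterPartition",
    "ClusterShape",
    "find_clusters",
    "cluster_numbers",
    "connectivity_index",
    "unwrap_positions",
    "cluster_axes_geometric",
    "cluster_axes_covariance",
    "cluster_length_width",
    "cluster_area_histogram",
    "analyze_partition",
]


@dataclass
class ClusterPartition:
    """Assignment of cells to clusters at a distance cutoff."""

    labels: np.ndarray                 # cluster id per cell
    clusters: list[np.ndarray]         # member index arrays
    cutoff: float
    positions: np.ndarray              # the analyzed (Nc, 2) positions
    periodic: bool
    Lstar: float | None

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def sizes(self) -> np.ndarray:
        return np.array([len(c) for c in self.clusters], dtype=int)


@dataclass
class ClusterShape:
    """Shape metrics of a single cluster."""

    major_axis_geometric: np.ndarray
    major_axis_covariance: np.ndarray
    length: float
    width: float
    aspect_ratio: float
    connectivity_index: float | None
    area: float
    size: int
    isotropic: bool


def _pairwise_distances(positions: np.ndarray, periodic: bool, Lstar: float | None) -> np.ndarray:
    diff = positions[:, None, :] - positions[None, :, :]
    if periodic:
        if not Lstar or Lstar <= 0:
            raise ValueError("periodic distances require a positive Lstar")
        diff -= Lstar * np.round(diff / Lstar)
    return np.sqrt((diff**2).sum(axis=-1))


def find_clusters(
    positions: np.ndarray,
    cutoff: float = 2.0,
    periodic: bool = False,
    Lstar: float | None = None,
) -> ClusterPartition:
    """Partition a point set into clusters at a strict distance cutoff.

    Two cells are neighbors when their distance is strictly less than
    ``cutoff`` ("less than 50 um"); clusters are the connected
    components of the neighbor graph.
    """
    if not cutoff > 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    if positions.size == 0:
        return ClusterPartition(
            np.empty(0, dtype=int), [], cutoff, positions.reshape(0, 2), periodic, Lstar
        )
    if positions.shape[1] != 2:
        raise ValueError("positions must have shape (n, 2)")
    dist = _pairwise_distances(positions, periodic, Lstar)
    adj = (dist < cutoff) & ~np.eye(len(positions), dtype=bool)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    clusters = [np.flatnonzero(labels == k) for k in range(n_comp)]
    return ClusterPartition(labels, clusters, cutoff, positions, periodic, Lstar)


def cluster_numbers(partition: ClusterPartition) -> tuple[float, float]:
    """The cluster numbers ``(S1, S2)`` of a partition."""
    sizes = partition.sizes()
    if sizes.size == 0:
        raise ValueError("cannot compute cluster numbers of an empty partition")
    q0 = float(sizes.size)
    q1 = float(sizes.sum())
    q2 = float((sizes.astype(float) ** 2).sum())
    return q1 / q0, q2 / q1


def connectivity_index(
    positions: np.ndarray,
    cutoff: float = 2.0,
    periodic: bool = False,
    Lstar: float | None = None,
) -> float:
    """Mean number of within-cluster neighbors (distance < cutoff) per cell."""
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    if len(positions) < 2:
        raise ValueError("connectivity index requires a cluster of at least 2 cells")
    dist = _pairwise_distances(positions, periodic, Lstar)
    neighbor_counts = ((dist < cutoff) & ~np.eye(len(positions), dtype=bool)).sum(axis=1)
    return float(neighbor_counts.mean())


def unwrap_positions(
    positions: np.ndarray,
    cutoff: float,
    Lstar: float,
) -> np.ndarray:
    """Map periodic cluster members to one consistent image.

    Starting from the first member, each cell reachable through the
    neighbor graph is placed at the periodic image closest to its
    already-placed neighbor, so shape analysis never straddles a seam.
    """
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    out = positions.copy()
    placed = np.zeros(n, dtype=bool)
    placed[0] = True
    frontier = [0]
    while frontier:
        new_frontier = []
        for i in frontier:
            diff = positions - out[i]
            diff -= Lstar * np.round(diff / Lstar)
            dist = np.hypot(diff[:, 0], diff[:, 1])
            for j in np.flatnonzero((dist < cutoff) & ~placed):
                out[j] = out[i] + diff[j]
                placed[j] = True
                new_frontier.append(j)
        frontier = new_frontier
    if not placed.all():
        # not a single connected cluster; anchor remaining members to
        # the image nearest the running centroid
        center = out[placed].mean(axis=0)
        for j in np.flatnonzero(~placed):
            diff = positions[j] - center
            diff -= Lstar * np.round(diff / Lstar)
            out[j] = center + diff
    return out


def _line_distance_sum(theta: float, centered: np.ndarray) -> float:
    # distance of each point to the line through the origin at angle theta
    return float(np.abs(-math.sin(theta) * centered[:, 0] + math.cos(theta) * centered[:, 1]).sum())


def cluster_axes_geometric(positions: np.ndarray, scan_deg: float = 0.1) -> np.ndarray:
    """Major axis minimizing the summed absolute point-line distance.

    The line is constrained through the centroid; the angle is located
    by a dense scan over ``[0, pi)`` followed by golden-section
    refinement (the objective is piecewise smooth, not differentiable).
    Ties (isotropic clusters) resolve to the smallest angle scanned.
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    if len(positions) < 2:
        raise ValueError("axis of a cluster needs at least 2 members")
    centered = positions - positions.mean(axis=0)
    if np.allclose(centered, 0.0):
        raise ValueError("all cluster members coincide; axis undefined")
    thetas = np.arange(0.0, math.pi, math.radians(scan_deg))
    values = np.abs(
        -np.sin(thetas)[:, None] * centered[:, 0] + np.cos(thetas)[:, None] * centered[:, 1]
    ).sum(axis=1)
    k = int(np.argmin(values))
    span = math.radians(scan_deg)
    lo, hi = thetas[k] - span, thetas[k] + span
    result = optimize.minimize_scalar(
        _line_distance_sum, args=(centered,), bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-10},
    )
    theta = float(result.x) if result.fun <= values[k] else float(thetas[k])
    theta %= math.pi
    return np.array([math.cos(theta), math.sin(theta)])


def cluster_axes_covariance(positions: np.ndarray) -> tuple[np.ndarray, bool]:
    """Major axis from the leading eigenvector of the scatter matrix.

    Returns ``(axis, isotropic)``; the sign is fixed to a nonnegative x
    component (nonnegative y if x vanishes).  When the two eigenvalues
    coincide, the direction is degenerate: the tie resolves as in the
    geometric method (smallest angle, the x axis) and the cluster is
    flagged isotropic.
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    if len(positions) < 2:
        raise ValueError("axis of a cluster needs at least 2 members")
    centered = positions - positions.mean(axis=0)
    scatter = centered.T @ centered
    if np.allclose(scatter, 0.0):
        raise ValueError("all cluster members coincide; axis undefined")
    eigvals, eigvecs = np.linalg.eigh(scatter)
    scale = max(eigvals[-1], 1e-300)
    if (eigvals[-1] - eigvals[0]) <= 1e-9 * scale:
        return np.array([1.0, 0.0]), True
    axis = eigvecs[:, -1]
    if axis[0] < 0 or (axis[0] == 0 and axis[1] < 0):
        axis = -axis
    return axis, False


def cluster_length_width(
    positions: np.ndarray,
    major_axis: np.ndarray,
    d: float,
) -> tuple[float, float, float]:
    """Cluster length, width and aspect ratio along the major/minor axes.

    Length (width) is the extent of the member projections on the major
    (minor) axis plus one cell diameter ``d``, accounting for the finite
    cell footprint; the extents are ordered so the aspect ratio is
    always >= 1.
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    major_axis = np.asarray(major_axis, dtype=float)
    norm = np.hypot(*major_axis)
    if not np.isfinite(norm) or norm == 0:
        raise ValueError("major axis must be a nonzero vector")
    major = major_axis / norm
    minor = np.array([-major[1], major[0]])
    proj_major = positions @ major
    proj_minor = positions @ minor
    length = float(proj_major.max() - proj_major.min()) + d
    width = float(proj_minor.max() - proj_minor.min()) + d
    if width > length:
        length, width = width, length
    return length, width, length / width


def cluster_area_histogram(
    sizes: "np.ndarray | list[int]",
    d: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Proportion of clusters per area bin, one cell footprint per bin.

    A simulated cluster of ``m`` rigid disc-shaped cells has area
    ``m * pi * (d/2)^2``; the bin width is the single-cell disc area, so
    bin ``k`` (1-based) collects clusters of exactly ``k`` cells.
    Returns ``(bin_edges, proportions)`` with proportions summing to 1.
    """
    sizes = np.asarray(sizes, dtype=int)
    if sizes.size == 0:
        raise ValueError("no clusters to histogram")
    cell_area = math.pi * (0.5 * d) ** 2
    max_m = int(sizes.max())
    counts = np.bincount(sizes, minlength=max_m + 1)[1:]
    proportions = counts / counts.sum()
    edges = cell_area * np.arange(0, max_m + 1, dtype=float)
    return edges, proportions


def analyze_partition(
    partition: ClusterPartition,
    d: float,
    min_size: int = 2,
    connectivity_min_size: int = 4,
) -> list[ClusterShape]:
    """Shape metrics for every cluster with at least ``min_size`` members.

    The connectivity index is reported only for clusters of at least
    ``connectivity_min_size`` cells (None otherwise), matching how the
    index is tabulated for simulated ensembles.
    """
    shapes: list[ClusterShape] = []
    cell_area = math.pi * (0.5 * d) ** 2
    for members in partition.clusters:
        if len(members) < min_size:
            continue
        pos = partition.positions[members]
        if partition.periodic:
            pos = unwrap_positions(pos, partition.cutoff, partition.Lstar)
        axis_geo = cluster_axes_geometric(pos)
        axis_cov, isotropic = cluster_axes_covariance(pos)
        length, width, aspect = cluster_length_width(pos, axis_cov if not isotropic else axis_geo, d)
        conn = None
        if len(members) >= connectivity_min_size:
            conn = connectivity_index(pos, partition.cutoff)
        shapes.append(
            ClusterShape(
                major_axis_geometric=axis_geo,
                major_axis_covariance=axis_cov,
                length=length,
                width=width,
                aspect_ratio=aspect,
                connectivity_index=conn,
                area=len(members) * cell_area,
                size=len(members),
                isotropic=isotropic,
            )
        )
    return shapes
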