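"""The µCT pipeline: crystalline-cone point clouds to per-ommatidium optics.

Stages (each a function, composable via :func:`run_pipeline`):

1. :func:`load_stack` — voxels in a density range become a point cloud in µm;
2. :func:`fit_sphere` — least-squares sphere through the cone layer;
3. :func:`make_cross_section` — spherical coordinates about the fitted
   centre, a smooth radius(elevation, azimuth) surface, and the shell of
   points within the central 50% of residuals;
4. :func:`rasterize_and_detect` — 2D angular histograms of the shell are
   run through the 2D lattice detector to find approximate lens centres;
5. :func:`assign_clusters` / :func:`correct_problem_clusters` — nearest-
   centre segmentation of the cloud into per-ommatidium clusters, with a
   seeded differential-evolution repair step for skew-induced errors;
6. :func:`measure_ommatidia` / :func:`measure_io_pairs` — lens diameter,
   ideal and anatomical axes, skewness, and interommatidial (IO) angle
   components per adjacent pair;
7. :func:`export_spreadsheets` — the two per-cone / per-pair CSV tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator
from scipy.optimize import differential_evolution
from scipy.spatial import cKDTree

from .errors import (
    EmptySelectionError,
    IllConditionedError,
    LatticeNotFoundError,
    OmmatidiaError,
)
from .oda2d import run_oda

logger = logging.getLogger(__name__)

__all__ = [
    "EyePointCloud",
    "SphereFit",
    "CrossSection",
    "ClusterSet",
    "OmmatidiumRecord",
    "PairRecord",
    "load_stack",
    "cloud_from_stack",
    "fit_sphere",
    "make_cross_section",
    "rasterize_and_detect",
    "assign_clusters",
    "correct_problem_clusters",
    "partition_objective",
    "measure_ommatidia",
    "measure_io_pairs",
    "export_spreadsheets",
    "summarize",
    "run_pipeline",
]


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass
class EyePointCloud:
    """Points from the crystalline-cone layer, in µm."""

    coords: np.ndarray                      # (N, 3) x, y, z
    density: Optional[np.ndarray] = None    # (N,) scan values
    provenance: Optional[np.ndarray] = None  # (N,) source slice index

    def __post_init__(self):
        self.coords = np.asarray(self.coords, float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise OmmatidiaError("coords must be an (N, 3) array")
        if not np.all(np.isfinite(self.coords)):
            raise OmmatidiaError("coordinates must be finite")

    def __len__(self) -> int:
        return len(self.coords)


@dataclass
class SphereFit:
    """Least-squares sphere through the cone layer."""

    center: np.ndarray
    radius: float
    residuals: np.ndarray   # per-point |p - center| - radius

    def __post_init__(self):
        if self.radius <= 0:
            raise OmmatidiaError("sphere radius must be positive")


@dataclass
class CrossSection:
    """Spherical view of the cloud and the central-residual shell.

    The cloud is rotated so its centroid direction (from the sphere centre)
    points along +x; elevation is measured from the x-y plane toward +z
    (range [-90, 90] deg) and azimuth in the x-y plane from +x (range
    (-180, 180] deg). ``members`` indexes the points whose residual from
    the fitted radius surface lies in the central 50% band.
    """

    cloud: EyePointCloud
    sphere: SphereFit
    rotation: np.ndarray        # (3, 3): section frame = rotation @ (p - center)
    elev_deg: np.ndarray        # (N,) all points
    azim_deg: np.ndarray
    radius_um: np.ndarray
    surface_residuals: np.ndarray
    members: np.ndarray         # indices of the central 50% shell

    def to_frame(self, points: np.ndarray) -> np.ndarray:
        """World points -> section frame (eye looking along +x)."""
        return (np.atleast_2d(points) - self.sphere.center) @ self.rotation.T

    def rotate_vectors(self, vectors: np.ndarray) -> np.ndarray:
        return np.atleast_2d(vectors) @ self.rotation.T

    def angles_of(self, points: np.ndarray):
        """(elev_deg, azim_deg, radius) of world points in the section frame."""
        v = self.to_frame(points)
        r = np.linalg.norm(v, axis=1)
        elev = np.degrees(np.arcsin(np.clip(v[:, 2] / r, -1, 1)))
        azim = np.degrees(np.arctan2(v[:, 1], v[:, 0]))
        return elev, azim, r


@dataclass
class ClusterSet:
    """Per-point cluster labels and per-cluster centroids."""

    labels: np.ndarray          # (N,) cluster id, -1 = unassigned
    centroids: np.ndarray       # (K, 3)
    problematic: np.ndarray     # (K,) bool

    @property
    def n_clusters(self) -> int:
        return len(self.centroids)


@dataclass
class OmmatidiumRecord:
    """Measurements for one crystalline-cone cluster."""

    id: int
    centroid: np.ndarray
    n_points: int
    diameter_um: float
    adjusted_diameter_um: float     # D * cos(skewness)
    ideal_axis: np.ndarray          # outward unit surface normal estimate
    anatomical_axis: np.ndarray     # outward unit cone axis (SVD)
    averaged_axis: np.ndarray       # neighbourhood-averaged anatomical axis
    skewness_deg: float
    elev_deg: float
    azim_deg: float
    radius_um: float
    neighbors: tuple = ()
    flagged: bool = False           # too few points for an anatomical axis


@dataclass
class PairRecord:
    """IO angle components for one adjacent cone pair."""

    cone_i: int
    cone_j: int
    orientation_deg: float      # displacement on the eye surface, 0 = horizontal
    io_h_deg: float             # horizontal component
    io_v_deg: float             # vertical component
    io_total_deg: float         # hypotenuse of the two components
    outlier: bool = False


# --------------------------------------------------------------------------
# Stage 1: loading
# --------------------------------------------------------------------------

def cloud_from_stack(
    stack: np.ndarray,
    voxel_size: float,
    density_range: Optional[tuple] = None,
) -> EyePointCloud:
    """Select voxels in a density range and scale indices to µm.

    ``stack`` is (slice, row, col); coordinates come out as
    ``(x, y, z) = (col, row, slice) * voxel_size``.
    """
    if voxel_size <= 0:
        raise OmmatidiaError("voxel_size must be positive")
    stack = np.asarray(stack)
    if density_range is None:
        sel = stack > 0
    else:
        lo, hi = density_range
        sel = (stack >= lo) & (stack <= hi)
    if not sel.any():
        raise EmptySelectionError(
            f"no voxels with density in {density_range}; "
            f"stack range is [{stack.min()}, {stack.max()}]"
        )
    zz, yy, xx = np.nonzero(sel)
    coords = np.column_stack([xx, yy, zz]).astype(float) * voxel_size
    return EyePointCloud(coords=coords, density=stack[zz, yy, xx].astype(float),
                         provenance=zz.astype(int))


def load_stack(directory, voxel_size: float, density_range=None) -> EyePointCloud:
    """Read a TIFF slice directory and filter it to a point cloud."""
    from .io import read_stack

    return cloud_from_stack(read_stack(directory), voxel_size, density_range)


# --------------------------------------------------------------------------
# Stage 2: sphere fit
# --------------------------------------------------------------------------

def fit_sphere(cloud) -> SphereFit:
    """Least-squares sphere: linearized algebraic fit plus one geometric
    Gauss-Newton refinement pass.

    Raises :class:`IllConditionedError` for coplanar or otherwise degenerate
    point sets (a sphere through coplanar points is underdetermined).
    """
    coords = cloud.coords if isinstance(cloud, EyePointCloud) else np.asarray(cloud, float)
    if len(coords) < 4:
        raise IllConditionedError("need at least 4 points to fit a sphere")
    centered = coords - coords.mean(axis=0)
    svals = np.linalg.svd(centered, compute_uv=False)
    if svals[2] < 1e-9 * svals[0]:
        raise IllConditionedError("points are (nearly) coplanar")

    # algebraic: |p|^2 = 2 p.c + (R^2 - |c|^2)
    A = np.column_stack([2 * coords, np.ones(len(coords))])
    b = (coords**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:3]
    radius = np.sqrt(sol[3] + center @ center)

    # one Gauss-Newton pass on the geometric residuals
    diff = coords - center
    dist = np.linalg.norm(diff, axis=1)
    J = np.column_stack([-diff / dist[:, None], -np.ones(len(coords))])
    step, *_ = np.linalg.lstsq(J, -(dist - radius), rcond=None)
    center = center + step[:3]
    radius = radius + step[3]

    dist = np.linalg.norm(coords - center, axis=1)
    return SphereFit(center=center, radius=float(radius), residuals=dist - radius)


# --------------------------------------------------------------------------
# Stage 3: cross-section shell
# --------------------------------------------------------------------------

def _rotation_to_x(direction: np.ndarray) -> np.ndarray:
    """Rotation matrix taking ``direction`` to the +x axis."""
    u = direction / np.linalg.norm(direction)
    x = np.array([1.0, 0.0, 0.0])
    v = np.cross(u, x)
    s, c = np.linalg.norm(v), float(u @ x)
    if s < 1e-12:
        return np.eye(3) if c > 0 else np.diag([-1.0, -1.0, 1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)


def make_cross_section(
    cloud: EyePointCloud,
    sphere: SphereFit,
    grid_step_deg: Optional[float] = None,
    smooth_bins: int = 3,
) -> CrossSection:
    """Fit radius(elevation, azimuth) and keep the central 50% of residuals.

    The cloud is first rotated so its centroid direction sits at
    (elevation 0, azimuth 0), keeping the eye away from the spherical poles.
    The roll about the viewing axis is then fixed from the data (the point
    farthest in angle from the axis is rolled to azimuth +90), so the
    section frame — and everything derived from it — is equivariant under
    rigid motions of the input cloud.
    The radius surface is a median-binned angular grid, box-smoothed and
    bilinearly interpolated (constant beyond the grid). Membership is
    rank-based: exactly the central ``floor(N/2)`` residuals, ties broken
    by point index, so the member fraction is 0.5 within 1/N on any input.
    If the surface fit is unusable (degenerate angular extent) the constant
    ``sphere.radius`` surface is used instead, with a logged warning.
    """
    rotation = _rotation_to_x(cloud.coords.mean(axis=0) - sphere.center)
    v = (cloud.coords - sphere.center) @ rotation.T
    # canonicalize the roll about the viewing axis: the most off-axis point
    # goes to azimuth +90 (the +y half-plane), making the frame a pure
    # function of the cloud's geometry
    u = v / np.linalg.norm(v, axis=1)[:, None]
    far = np.argmax(np.hypot(u[:, 1], u[:, 2]))
    roll = np.arctan2(u[far, 2], u[far, 1])  # current angle of that point
    c, s = np.cos(roll), np.sin(roll)
    rx = np.array([[1.0, 0.0, 0.0], [0.0, c, s], [0.0, -s, c]])
    rotation = rx @ rotation
    v = (cloud.coords - sphere.center) @ rotation.T
    r = np.linalg.norm(v, axis=1)
    elev = np.degrees(np.arcsin(np.clip(v[:, 2] / r, -1, 1)))
    azim = np.degrees(np.arctan2(v[:, 1], v[:, 0]))

    surface_r = None
    try:
        if grid_step_deg is None:
            span = max(np.ptp(elev), np.ptp(azim))
            grid_step_deg = max(span / 40.0, 1e-3)
        e_edges = np.arange(elev.min(), elev.max() + grid_step_deg, grid_step_deg)
        a_edges = np.arange(azim.min(), azim.max() + grid_step_deg, grid_step_deg)
        if len(e_edges) < 3 or len(a_edges) < 3:
            raise ValueError("angular extent too small for a surface grid")
        ei = np.clip(np.digitize(elev, e_edges) - 1, 0, len(e_edges) - 2)
        ai = np.clip(np.digitize(azim, a_edges) - 1, 0, len(a_edges) - 2)
        flat = ei * (len(a_edges) - 1) + ai
        grid = np.full((len(e_edges) - 1) * (len(a_edges) - 1), np.nan)
        order = np.argsort(flat, kind="stable")
        bounds = np.searchsorted(flat[order], np.arange(grid.size + 1))
        for k in range(grid.size):
            seg = order[bounds[k] : bounds[k + 1]]
            if seg.size:
                grid[k] = np.median(r[seg])
        grid = grid.reshape(len(e_edges) - 1, len(a_edges) - 1)
        # fill empty bins from the nearest filled bin, then box-smooth
        if np.isnan(grid).any():
            filled = np.argwhere(~np.isnan(grid))
            if len(filled) == 0:
                raise ValueError("no filled bins")
            empty = np.argwhere(np.isnan(grid))
            tree = cKDTree(filled)
            _, nearest = tree.query(empty)
            grid[tuple(empty.T)] = grid[tuple(filled[nearest].T)]
        grid = ndimage.uniform_filter(grid, size=smooth_bins, mode="nearest")
        e_mid = 0.5 * (e_edges[:-1] + e_edges[1:])
        a_mid = 0.5 * (a_edges[:-1] + a_edges[1:])
        interp = RegularGridInterpolator(
            (e_mid, a_mid), grid, bounds_error=False, fill_value=None
        )
        surface_r = interp(
            np.column_stack([np.clip(elev, e_mid[0], e_mid[-1]),
                             np.clip(azim, a_mid[0], a_mid[-1])])
        )
    except Exception as exc:  # degenerate surface: constant-radius fallback
        logger.warning("radius surface fit failed (%s); using constant radius", exc)
        surface_r = np.full(len(r), sphere.radius)

    residuals = r - surface_r
    n = len(residuals)
    ranks = np.empty(n, dtype=int)
    ranks[np.argsort(residuals, kind="stable")] = np.arange(n)
    lo = n // 4
    members = np.flatnonzero((ranks >= lo) & (ranks < lo + n // 2))
    return CrossSection(
        cloud=cloud,
        sphere=sphere,
        rotation=rotation,
        elev_deg=elev,
        azim_deg=azim,
        radius_um=r,
        surface_residuals=residuals,
        members=members,
    )


# --------------------------------------------------------------------------
# Stage 4: rasterize + 2D detection
# --------------------------------------------------------------------------

def _estimate_angular_diameter(section: CrossSection, n_fundamentals: int) -> float:
    """First-pass lattice spacing estimate (degrees) from a coarse histogram."""
    elev = section.elev_deg[section.members]
    azim = section.azim_deg[section.members]
    bins = 256
    hist, e_edges, a_edges = np.histogram2d(elev, azim, bins=bins)
    res = run_oda(hist, n_fundamentals=n_fundamentals)
    # fft diameter is the row spacing of a hexagonal lattice; convert to the
    # centre spacing and to degrees
    step = max(e_edges[1] - e_edges[0], a_edges[1] - a_edges[0])
    return res.fundamentals.fft_diameter_px * (2 / np.sqrt(3)) * step


def rasterize_and_detect(
    section: CrossSection,
    window_deg: float = 90.0,
    ang_diameter_deg: Optional[float] = None,
    n_fundamentals: int = 3,
    min_segment_points: int = 50,
    **oda_kwargs,
) -> np.ndarray:
    """Approximate 3D lens centres from angular histograms of the shell.

    The shell is processed in half-overlapping ``window_deg`` x
    ``window_deg`` angular segments (so lattice regions that straddle or
    fall awkwardly in one window are covered whole by a neighbour); each
    segment is recentred (rotated so its centroid faces azimuth 0,
    elevation 0) before forming the 2D count histogram, avoiding extreme
    spherical warping away from the projection equator. Histogram
    bins are a quarter of the expected angular lens diameter (estimated
    from a first coarse pass when not given). Detected maxima map back to
    3D through the nearest shell point in the projected plane; centres from
    different segments closer than half a lens diameter merge.
    """
    members = section.members
    if len(members) == 0:
        return np.empty((0, 3))
    if ang_diameter_deg is None:
        ang_diameter_deg = _estimate_angular_diameter(section, n_fundamentals)
    bin_deg = ang_diameter_deg / 4.0

    elev = section.elev_deg[members]
    azim = section.azim_deg[members]
    coords = section.cloud.coords[members]

    def _windows(lo, hi):
        """Half-overlapping windows of ``window_deg`` covering [lo, hi]."""
        span = hi - lo
        if span <= window_deg:
            return [(lo, hi + 1e-9)]
        starts = np.arange(lo, hi - window_deg / 2, window_deg / 2)
        return [(s, min(s + window_deg, hi) + 1e-9) for s in starts]

    e_windows = _windows(elev.min(), elev.max())
    a_windows = _windows(azim.min(), azim.max())

    centers_3d = []
    for i, (e_lo, e_hi) in enumerate(e_windows):
        for j, (a_lo, a_hi) in enumerate(a_windows):
            in_seg = (
                (elev >= e_lo) & (elev < e_hi)
                & (azim >= a_lo) & (azim < a_hi)
            )
            if in_seg.sum() < min_segment_points:
                if in_seg.any():
                    logger.warning(
                        "segment (%d, %d) has only %d points; skipped",
                        i, j, int(in_seg.sum()),
                    )
                continue
            seg_pts = coords[in_seg]
            # recentre within the (canonical) section frame: segment
            # centroid direction -> +x, so segments inherit equivariance
            vs = section.to_frame(seg_pts)
            rot = _rotation_to_x(vs.mean(axis=0))
            v = vs @ rot.T
            r = np.linalg.norm(v, axis=1)
            se = np.degrees(np.arcsin(np.clip(v[:, 2] / r, -1, 1)))
            sa = np.degrees(np.arctan2(v[:, 1], v[:, 0]))
            e_bins = np.arange(se.min(), se.max() + bin_deg, bin_deg)
            a_bins = np.arange(sa.min(), sa.max() + bin_deg, bin_deg)
            if len(e_bins) < 9 or len(a_bins) < 9:
                logger.warning("segment (%d, %d) too small to rasterize", i, j)
                continue
            hist, _, _ = np.histogram2d(se, sa, bins=(e_bins, a_bins))
            try:
                res = run_oda(hist, n_fundamentals=n_fundamentals, **oda_kwargs)
            except (LatticeNotFoundError, OmmatidiaError) as exc:
                logger.warning("segment (%d, %d): no lattice (%s)", i, j, exc)
                continue
            if res.count == 0:
                continue
            det_e = e_bins[0] + (res.centers[:, 0] + 0.5) * bin_deg
            det_a = a_bins[0] + (res.centers[:, 1] + 0.5) * bin_deg
            tree = cKDTree(np.column_stack([se, sa]))
            _, nearest = tree.query(np.column_stack([det_e, det_a]))
            centers_3d.append(seg_pts[nearest])
    if not centers_3d:
        return np.empty((0, 3))
    centers = np.vstack(centers_3d)

    # merge duplicate detections of the same cone from overlapping
    # segments; merging happens in the projected angular plane because two
    # detections of one cone can sit anywhere along its (radial) length
    plane = _projected_plane(section, centers)
    tree = cKDTree(plane)
    keep = np.ones(len(centers), dtype=bool)
    for a, b in sorted(tree.query_pairs(0.5 * ang_diameter_deg)):
        if keep[a] and keep[b]:
            keep[b] = False
    return centers[keep]


# --------------------------------------------------------------------------
# Stage 5: clustering
# --------------------------------------------------------------------------

def _projected_plane(section: CrossSection, points: np.ndarray) -> np.ndarray:
    """(azim * cos(elev), elev) coordinates in degrees: a locally metric
    chart of the eye surface."""
    elev, azim, _ = section.angles_of(points)
    return np.column_stack([azim * np.cos(np.deg2rad(elev)), elev])


def assign_clusters(section: CrossSection, centers: np.ndarray) -> ClusterSet:
    """Label every point of the cloud by its nearest centre in the
    projected (elevation, azimuth) plane; centroids are 3D means."""
    if len(centers) == 0:
        raise OmmatidiaError("need at least one centre to assign clusters")
    pt_plane = _projected_plane(section, section.cloud.coords)
    ct_plane = _projected_plane(section, centers)
    _, labels = cKDTree(ct_plane).query(pt_plane)
    centroids = np.stack(
        [
            section.cloud.coords[labels == k].mean(axis=0)
            if (labels == k).any()
            else centers[k]
            for k in range(len(centers))
        ]
    )
    return ClusterSet(
        labels=labels,
        centroids=centroids,
        problematic=np.zeros(len(centers), dtype=bool),
    )


def _misneighbor_fractions(coords, labels, n_clusters):
    """Per-cluster fraction of points whose 3D nearest neighbour belongs to
    a different cluster."""
    _, nn = cKDTree(coords).query(coords, k=2)
    mis = labels[nn[:, 1]] != labels
    frac = np.zeros(n_clusters)
    for k in range(n_clusters):
        m = labels == k
        if m.any():
            frac[k] = mis[m].mean()
    return frac


def partition_objective(points: np.ndarray, labels: np.ndarray,
                        direction: np.ndarray) -> float:
    """Two-term clustering objective for a candidate projection direction.

    Points project onto the plane orthogonal to ``direction``; the objective
    is the mean projected distance of each point to its cluster's projected
    centre plus the mean cluster aspect ratio (longest / shortest 3D
    semi-axis). A single cluster of points equidistant from their centre
    with isotropic spread scores ``mean distance + 1``.
    """
    direction = np.asarray(direction, float)
    direction = direction / np.linalg.norm(direction)
    # orthonormal plane basis
    helper = np.array([0.0, 0.0, 1.0])
    if abs(direction @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(direction, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(direction, e1)
    proj = points @ np.column_stack([e1, e2])

    dist_sum, n_pts, aspects = 0.0, 0, []
    for k in np.unique(labels):
        m = labels == k
        sub2, sub3 = proj[m], points[m]
        dist_sum += np.linalg.norm(sub2 - sub2.mean(axis=0), axis=1).sum()
        n_pts += int(m.sum())
        if m.sum() >= 4:
            svals = np.linalg.svd(sub3 - sub3.mean(axis=0), compute_uv=False)
            aspects.append(svals[0] / max(svals[2], 1e-9))
        else:
            aspects.append(1.0)
    return dist_sum / max(n_pts, 1) + float(np.mean(aspects))


def _replan_labels(points, centroids, direction, iters=5):
    """Nearest-centre partition in the plane orthogonal to ``direction``,
    refined by a few 2D k-means iterations. Cluster order follows the
    input centroids, so cluster k keeps identity k."""
    direction = direction / np.linalg.norm(direction)
    helper = np.array([0.0, 0.0, 1.0])
    if abs(direction @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(direction, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(direction, e1)
    basis = np.column_stack([e1, e2])
    proj = points @ basis
    cent2 = centroids @ basis
    for _ in range(iters):
        _, labels = cKDTree(cent2).query(proj)
        for k in range(len(cent2)):
            m = labels == k
            if m.any():
                cent2[k] = proj[m].mean(axis=0)
    return labels


def correct_problem_clusters(
    clusters: ClusterSet,
    section: CrossSection,
    seed: int = 0,
    flag_threshold: float = 0.10,
    accept_threshold: float = 0.05,
    maxiter: int = 20,
    popsize: int = 10,
) -> ClusterSet:
    """Repair clusters broken by ommatidial skew.

    A cluster is *problematic* when at least ``flag_threshold`` (10%) of its
    points have their 3D nearest neighbour in a different cluster. For each
    such cluster, its neighbourhood of the 6 nearest clusters is
    re-partitioned by projecting onto a plane whose orientation (two
    angles) is optimized with a seeded differential-evolution search to
    minimize :func:`partition_objective`. Because skewed cones in a small
    neighbourhood are nearly parallel and elongated, the optimum is close
    to the plane orthogonal to their shared axis, where projected clusters
    are compact. The repair is committed only when it leaves fewer than
    ``accept_threshold`` (5%) problematic elements in the neighbourhood;
    otherwise the original labels stay.
    """
    coords = section.cloud.coords
    labels = clusters.labels.copy()
    k_total = clusters.n_clusters
    frac = _misneighbor_fractions(coords, labels, k_total)
    flagged_ids = np.flatnonzero(frac >= flag_threshold)
    logger.info("clusters flagged problematic: %d / %d", len(flagged_ids), k_total)
    if len(flagged_ids) == 0:
        return ClusterSet(labels=labels, centroids=clusters.centroids.copy(),
                          problematic=frac >= flag_threshold)

    centroids = clusters.centroids.copy()
    ct_tree = cKDTree(centroids)
    rng_seed = int(seed)
    for fid in flagged_ids:
        _, hood = ct_tree.query(centroids[fid], k=min(7, k_total))
        hood = np.atleast_1d(hood)
        in_hood = np.isin(labels, hood)
        # work in the canonical section frame so the search (and hence the
        # outcome) is equivariant under rigid motions of the input cloud
        pts = section.to_frame(coords[in_hood])
        sub_labels = labels[in_hood]
        loc_cent = section.to_frame(centroids[hood])

        def objective(angles, pts=pts, loc_cent=loc_cent):
            t, p = angles
            d = np.array(
                [np.sin(t) * np.cos(p), np.sin(t) * np.sin(p), np.cos(t)]
            )
            lab = _replan_labels(pts, loc_cent, d, iters=3)
            return partition_objective(pts, lab, d)

        try:
            opt = differential_evolution(
                objective,
                bounds=[(0.0, np.pi), (0.0, np.pi)],
                seed=rng_seed + int(fid),
                maxiter=maxiter,
                popsize=popsize,
                tol=1e-3,
                polish=False,
            )
        except Exception as exc:
            logger.warning("optimizer failed for cluster %d (%s)", fid, exc)
            continue
        t, p = opt.x
        d = np.array([np.sin(t) * np.cos(p), np.sin(t) * np.sin(p), np.cos(t)])
        new_loc = _replan_labels(pts, loc_cent, d, iters=5)
        # evaluate problematic fraction within the neighbourhood
        _, nn = cKDTree(pts).query(pts, k=2)
        old_frac = (sub_labels[nn[:, 1]] != sub_labels).mean()
        new_sub = hood[new_loc]
        new_frac = (new_sub[nn[:, 1]] != new_sub).mean()
        if new_frac < accept_threshold and new_frac < old_frac:
            labels[in_hood] = new_sub
            for g in hood:
                m = labels == g
                if m.any():
                    centroids[g] = coords[m].mean(axis=0)

    frac = _misneighbor_fractions(coords, labels, k_total)
    logger.info(
        "clusters still problematic after correction: %d / %d",
        int((frac >= flag_threshold).sum()), k_total,
    )
    return ClusterSet(labels=labels, centroids=centroids,
                      problematic=frac >= flag_threshold)


# --------------------------------------------------------------------------
# Stage 6: measurements
# --------------------------------------------------------------------------

def measure_ommatidia(
    clusters: ClusterSet,
    section: CrossSection,
    neighborhood_radius: float = 5.0,
    adjacency_factor: float = 1.5,
) -> list:
    """Per-cone lens diameter, axes and skewness.

    * adjacency: centroids within ``adjacency_factor`` times the median
      nearest-centroid distance;
    * lens diameter D: mean distance to adjacent centroids;
    * ideal axis: average outward normal of every centroid triplet among
      the cone and its adjacent neighbours (the local surface normal);
    * anatomical axis: the principal ellipsoid semi-axis of the cluster's
      points (SVD) closest in angle to the ideal axis, oriented outward;
    * skewness: the angle between the two axes;
    * averaged axis: mean anatomical axis over clusters within
      ``neighborhood_radius`` lens diameters — used downstream for IO
      angles, while raw axes serve the projected field of view.

    Clusters with fewer than 4 points get the ideal axis as a stand-in
    anatomical axis and are flagged.
    """
    centroids = clusters.centroids
    k = len(centroids)
    if k < 7:
        raise OmmatidiaError("need at least 7 clusters for neighbourhood measures")
    coords = section.cloud.coords
    labels = clusters.labels
    tree = cKDTree(centroids)
    nn_dist, _ = tree.query(centroids, k=2)
    median_nn = float(np.median(nn_dist[:, 1]))
    adjacency = tree.query_ball_point(centroids, adjacency_factor * median_nn)
    adjacency = [
        tuple(j for j in neigh if j != i) for i, neigh in enumerate(adjacency)
    ]

    outward = centroids - section.sphere.center
    outward /= np.linalg.norm(outward, axis=1)[:, None]

    ideal_axes = np.empty((k, 3))
    for i in range(k):
        group = (i, *adjacency[i])
        if len(group) < 3:
            ideal_axes[i] = outward[i]
            continue
        pts = centroids[list(group)]
        normals = []
        for a, b, c in combinations(range(len(group)), 3):
            n = np.cross(pts[b] - pts[a], pts[c] - pts[a])
            if np.linalg.norm(n) < 1e-9:
                continue
            if n @ outward[i] < 0:
                n = -n
            # area-weighted (unnormalized) so near-collinear triplets,
            # whose normal direction is noise-dominated, barely contribute
            normals.append(n)
        if normals:
            mean_n = np.mean(normals, axis=0)
            ideal_axes[i] = mean_n / np.linalg.norm(mean_n)
        else:
            ideal_axes[i] = outward[i]

    anatomical = np.empty((k, 3))
    skew = np.empty(k)
    n_points = np.zeros(k, dtype=int)
    flagged = np.zeros(k, dtype=bool)
    for i in range(k):
        m = labels == i
        n_points[i] = int(m.sum())
        if n_points[i] < 4:
            anatomical[i] = ideal_axes[i]
            skew[i] = np.nan
            flagged[i] = True
            continue
        sub = coords[m]
        _, _, vt = np.linalg.svd(sub - sub.mean(axis=0), full_matrices=False)
        best = np.argmax(np.abs(vt @ ideal_axes[i]))
        axis = vt[best]
        if axis @ ideal_axes[i] < 0:
            axis = -axis
        anatomical[i] = axis
        skew[i] = np.degrees(
            np.arccos(np.clip(axis @ ideal_axes[i], -1.0, 1.0))
        )

    diameters = np.array(
        [
            np.mean(np.linalg.norm(centroids[list(adj)] - centroids[i], axis=1))
            if adj
            else median_nn
            for i, adj in enumerate(adjacency)
        ]
    )
    median_d = float(np.median(diameters))
    hood_lists = tree.query_ball_point(centroids, neighborhood_radius * median_d)
    averaged = np.empty((k, 3))
    for i, hood in enumerate(hood_lists):
        mean_a = anatomical[hood].mean(axis=0)
        averaged[i] = mean_a / np.linalg.norm(mean_a)

    elev, azim, radius = section.angles_of(centroids)
    records = []
    for i in range(k):
        cos_s = np.cos(np.deg2rad(skew[i])) if np.isfinite(skew[i]) else 1.0
        records.append(
            OmmatidiumRecord(
                id=i,
                centroid=centroids[i],
                n_points=n_points[i],
                diameter_um=float(diameters[i]),
                adjusted_diameter_um=float(diameters[i] * cos_s),
                ideal_axis=ideal_axes[i],
                anatomical_axis=anatomical[i],
                averaged_axis=averaged[i],
                skewness_deg=float(skew[i]),
                elev_deg=float(elev[i]),
                azim_deg=float(azim[i]),
                radius_um=float(radius[i]),
                neighbors=adjacency[i],
                flagged=bool(flagged[i]),
            )
        )
    return records


def measure_io_pairs(
    records: Sequence[OmmatidiumRecord],
    section: CrossSection,
    section_width: float = 1.0,
    outlier_factor: float = 5.0,
    vertical_axis=(0.0, 0.0, 1.0),
) -> list:
    """IO angle components for every adjacent cone pair.

    The total anatomical IO angle is the exact 3D angle between the two
    neighbourhood-averaged axes, so it does not depend on any reference
    frame. Its horizontal and vertical components split that angle along
    the local tangent directions defined by ``vertical_axis`` (the scan's
    anatomical up, default +z): the axis-difference vector is projected
    onto the local horizontal and vertical tangent directions of the eye
    surface, and the components are scaled so that the total is exactly
    their hypotenuse. Working slab by slab (``section_width`` lens
    diameters per section) and projecting each slab onto its plane yields
    the same projected angles to first order; the decomposition here keeps
    the hypotenuse identity exact. Pair orientation is the direction of
    the centroid displacement in the same tangent basis (0 = horizontal),
    folded to (-90, 90].

    Pairs with a total angle above ``outlier_factor`` times the median are
    marked as outliers (kept in the table, excluded from summaries).
    """
    centroids = np.stack([r.centroid for r in records])
    axes = np.stack([r.averaged_axis for r in records])
    up = np.asarray(vertical_axis, float)
    up = up / np.linalg.norm(up)
    center = section.sphere.center

    pairs = sorted(
        {(r.id, j) if r.id < j else (j, r.id) for r in records for j in r.neighbors}
    )
    out = []
    for i, j in pairs:
        ai, aj = axes[i], axes[j]
        total = np.degrees(
            np.arccos(np.clip(ai @ aj, -1.0, 1.0))
        )
        mid = 0.5 * (centroids[i] + centroids[j]) - center
        rhat = mid / np.linalg.norm(mid)
        e_v = up - (up @ rhat) * rhat
        e_v /= np.linalg.norm(e_v)
        e_h = np.cross(e_v, rhat)
        diff = aj - ai
        dh, dv = diff @ e_h, diff @ e_v
        norm = np.hypot(dh, dv)
        if norm < 1e-15 or total == 0.0:
            h = v = 0.0
        else:
            h = total * abs(dh) / norm
            v = total * abs(dv) / norm
        disp = centroids[j] - centroids[i]
        orient = np.degrees(np.arctan2(disp @ e_v, disp @ e_h))
        if orient > 90:
            orient -= 180
        elif orient <= -90:
            orient += 180
        out.append(
            PairRecord(
                cone_i=i,
                cone_j=j,
                orientation_deg=float(orient),
                io_h_deg=float(h),
                io_v_deg=float(v),
                io_total_deg=float(total),
            )
        )
    totals = np.array([p.io_total_deg for p in out])
    if len(totals):
        cutoff = outlier_factor * np.median(totals)
        for p in out:
            p.outlier = bool(p.io_total_deg > cutoff)
    return out


# --------------------------------------------------------------------------
# Stage 7: export + summary
# --------------------------------------------------------------------------

def export_spreadsheets(records, pairs, out_prefix) -> tuple:
    """Write the per-cone and per-pair CSV tables; returns the two paths."""
    import pandas as pd

    from .io import write_csv

    cone_rows = []
    for r in records:
        cone_rows.append(
            {
                "cone": r.id,
                "x": r.centroid[0],
                "y": r.centroid[1],
                "z": r.centroid[2],
                "elevation_deg": r.elev_deg,
                "azimuth_deg": r.azim_deg,
                "radius_um": r.radius_um,
                "n_points": r.n_points,
                "diameter_um": r.diameter_um,
                "adjusted_diameter_um": r.adjusted_diameter_um,
                "ideal_axis_x": r.ideal_axis[0],
                "ideal_axis_y": r.ideal_axis[1],
                "ideal_axis_z": r.ideal_axis[2],
                "anatomical_axis_x": r.anatomical_axis[0],
                "anatomical_axis_y": r.anatomical_axis[1],
                "anatomical_axis_z": r.anatomical_axis[2],
                "skewness_deg": r.skewness_deg,
            }
        )
    pair_rows = []
    cent = {r.id: r.centroid for r in records}
    for p in pairs:
        pair_rows.append(
            {
                "cone_i": p.cone_i,
                "cone_j": p.cone_j,
                "centroid_i_x": cent[p.cone_i][0],
                "centroid_i_y": cent[p.cone_i][1],
                "centroid_i_z": cent[p.cone_i][2],
                "centroid_j_x": cent[p.cone_j][0],
                "centroid_j_y": cent[p.cone_j][1],
                "centroid_j_z": cent[p.cone_j][2],
                "orientation_deg": p.orientation_deg,
                "io_h_deg": p.io_h_deg,
                "io_v_deg": p.io_v_deg,
                "io_total_deg": p.io_total_deg,
                "outlier": p.outlier,
            }
        )
    cone_path = f"{out_prefix}_ommatidia.csv"
    pair_path = f"{out_prefix}_pairs.csv"
    write_csv(pd.DataFrame(cone_rows), cone_path)
    write_csv(pd.DataFrame(pair_rows), pair_path)
    return cone_path, pair_path


def summarize(records, pairs, visual_field=None) -> dict:
    """Headline statistics: count, diameter mean ± sd, skewness and IO angle
    medians with interquartile ranges (angular distributions are skewed, so
    medians are the robust summary), and the field of view if supplied."""
    diameters = np.array([r.diameter_um for r in records])
    skews = np.array([r.skewness_deg for r in records])
    skews = skews[np.isfinite(skews)]
    totals = np.array([p.io_total_deg for p in pairs if not p.outlier])

    def iqr(x):
        return float(np.percentile(x, 75) - np.percentile(x, 25)) if len(x) else float("nan")

    summary = {
        "count": int(len(records)),
        "diameter_mean_um": float(diameters.mean()) if len(diameters) else float("nan"),
        "diameter_sd_um": float(diameters.std()) if len(diameters) else float("nan"),
        "skewness_median_deg": float(np.median(skews)) if len(skews) else float("nan"),
        "skewness_iqr_deg": iqr(skews),
        "io_angle_median_deg": float(np.median(totals)) if len(totals) else float("nan"),
        "io_angle_iqr_deg": iqr(totals),
        "fov_horizontal_deg": float(visual_field.fov_horizontal_deg) if visual_field else float("nan"),
        "fov_vertical_deg": float(visual_field.fov_vertical_deg) if visual_field else float("nan"),
    }
    return summary


def run_pipeline(cloud: EyePointCloud, config=None, correct_clusters: bool = True):
    """Run stages 2-6 on a loaded point cloud.

    Returns ``(records, pairs, section, clusters)``. ``config`` is a
    :class:`~ommatidia.config.RunConfig` (defaults used when omitted).
    """
    from .config import RunConfig

    cfg = config or RunConfig()
    if len(cloud) < 100:
        raise OmmatidiaError(f"point cloud too small for the pipeline ({len(cloud)})")
    sphere = fit_sphere(cloud)
    logger.info("sphere fit: radius %.1f µm, %d points", sphere.radius, len(cloud))
    section = make_cross_section(cloud, sphere)
    logger.info("cross-section: %d / %d points in the central shell",
                len(section.members), len(cloud))
    ang_diam = None
    if cfg.lens_diameter_guess_um:
        ang_diam = np.degrees(cfg.lens_diameter_guess_um / sphere.radius)
    centers = rasterize_and_detect(
        section,
        window_deg=cfg.window_deg,
        ang_diameter_deg=ang_diam,
        n_fundamentals=cfg.n_fundamentals,
    )
    logger.info("detected %d approximate lens centres", len(centers))
    clusters = assign_clusters(section, centers)
    if correct_clusters:
        clusters = correct_problem_clusters(clusters, section, seed=cfg.seed)
    records = measure_ommatidia(
        clusters, section, neighborhood_radius=cfg.neighborhood_radius
    )
    pairs = measure_io_pairs(
        records, section, section_width=cfg.section_width,
        vertical_axis=cfg.vertical_axis,
    )
    logger.info("measured %d cones, %d adjacent pairs", len(records), len(pairs))
    return records, pairs, section, clusters
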