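"""Ground-truth generators: gratings, lattice images, and 3D synthetic eyes.

Every generator is deterministic given its seed and returns its ground truth
in the same units and frames as the pipeline outputs, so recovery tests are
direct comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Union

import numpy as np

from .errors import OmmatidiaError


# --------------------------------------------------------------------------
# 2D generators
# --------------------------------------------------------------------------

def make_grating(
    size: Union[int, tuple],
    freq: float,
    orientation: float,
    amplitude: float = 0.5,
    offset: float = 0.5,
) -> np.ndarray:
    """Render a 2D sinusoidal grating.

    ``image[r, c] = offset + amplitude * sin(2*pi*freq*(c*cos(t) + r*sin(t)))``
    with ``t = orientation`` in degrees. ``freq`` is in cycles per pixel and
    must lie below the Nyquist frequency of 0.5 cyc/px. The orientation is the
    direction of intensity variation (perpendicular to the wavefronts), so a
    45-degree grating varies along the image diagonal.
    """
    if not 0 < freq < 0.5:
        raise OmmatidiaError(f"grating frequency {freq} outside (0, 0.5) cyc/px")
    shape = (size, size) if np.isscalar(size) else tuple(size)
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    t = np.deg2rad(orientation)
    phase = 2 * np.pi * freq * (cols * np.cos(t) + rows * np.sin(t))
    return offset + amplitude * np.sin(phase)


def _render_spots(shape, centers, sigma, amplitude=1.0):
    """Sum of unit Gaussians at (row, col) positions, clipped to the frame."""
    img = np.zeros(shape, dtype=float)
    half = max(2, int(np.ceil(4 * sigma)))
    for r0, c0 in centers:
        r_lo, r_hi = int(np.floor(r0)) - half, int(np.floor(r0)) + half + 1
        c_lo, c_hi = int(np.floor(c0)) - half, int(np.floor(c0)) + half + 1
        r_lo, r_hi = max(r_lo, 0), min(r_hi, shape[0])
        c_lo, c_hi = max(c_lo, 0), min(c_hi, shape[1])
        if r_lo >= r_hi or c_lo >= c_hi:
            continue
        rr = np.arange(r_lo, r_hi)[:, None] - r0
        cc = np.arange(c_lo, c_hi)[None, :] - c0
        img[r_lo:r_hi, c_lo:c_hi] += amplitude * np.exp(
            -(rr**2 + cc**2) / (2 * sigma**2)
        )
    return img


def _lattice_nodes(shape, basis, orientation, margin):
    """Enumerate lattice nodes of ``i*b0 + j*b1`` covering ``shape``.

    The lattice is rotated by ``orientation`` degrees about the frame centre.
    Returns an (N, 2) float array of (row, col) node positions at least
    ``margin`` px from every border.
    """
    h, w = shape
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    t = np.deg2rad(orientation)
    rot = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
    b0, b1 = (rot @ np.asarray(b) for b in basis)
    # enough lattice indices to cover the frame diagonal in any orientation
    reach = int(np.ceil(np.hypot(h, w) / min(np.linalg.norm(b0), np.linalg.norm(b1)))) + 2
    ij = np.mgrid[-reach : reach + 1, -reach : reach + 1].reshape(2, -1).T
    nodes = center + ij[:, :1] * b0 + ij[:, 1:] * b1
    keep = (
        (nodes[:, 0] >= margin)
        & (nodes[:, 0] <= h - 1 - margin)
        & (nodes[:, 1] >= margin)
        & (nodes[:, 1] <= w - 1 - margin)
    )
    nodes = nodes[keep]
    order = np.lexsort((nodes[:, 1], nodes[:, 0]))
    return nodes[order]


def make_hex_lattice_image(
    size: Union[int, tuple],
    spacing: float,
    orientation: float = 0.0,
    spot_sigma: Optional[float] = None,
    contrast: float = 1.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
    margin: Optional[float] = None,
):
    """Hexagonal lattice of bright Gaussian spots on a dark background.

    Emulates a compound-eye image where each ommatidium shows a sharp bright
    spot at its centre. ``spacing`` is the centre-to-centre distance in px
    (the lens diameter); rows are ``sqrt(3)/2 * spacing`` apart. Returns
    ``(image, true_centers)`` where centers are exact (row, col) node
    positions at least ``margin`` px (default: half a spacing, so border
    spots are neither clipped nor continued past the frame) from the border. Deterministic per seed; the seed only affects the noise.
    """
    if spacing < 3:
        raise OmmatidiaError("hexagonal spacing below 3 px is unresolvable")
    shape = (size, size) if np.isscalar(size) else tuple(size)
    if spot_sigma is None:
        spot_sigma = spacing / 5.0
    if margin is None:
        margin = spacing / 2.0
    basis = ([np.sqrt(3) / 2 * spacing, spacing / 2.0], [0.0, spacing])
    nodes = _lattice_nodes(shape, basis, orientation, margin)
    img = contrast * _render_spots(shape, nodes, spot_sigma)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sigma * contrast, shape)
    return img, nodes


def make_square_lattice_image(
    size: Union[int, tuple],
    spacing: float,
    orientation: float = 0.0,
    spot_sigma: Optional[float] = None,
    contrast: float = 1.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
    margin: Optional[float] = None,
):
    """Square lattice of bright spots (two orthogonal axes).

    Emulates ommatidia arranged in a square lattice, as in the reflecting
    superposition eyes of decapod crustaceans. Same contract as
    :func:`make_hex_lattice_image`.
    """
    if spacing < 3:
        raise OmmatidiaError("square spacing below 3 px is unresolvable")
    shape = (size, size) if np.isscalar(size) else tuple(size)
    if spot_sigma is None:
        spot_sigma = spacing / 5.0
    if margin is None:
        margin = spacing / 2.0
    basis = ([spacing, 0.0], [0.0, spacing])
    nodes = _lattice_nodes(shape, basis, orientation, margin)
    img = contrast * _render_spots(shape, nodes, spot_sigma)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sigma * contrast, shape)
    return img, nodes


# --------------------------------------------------------------------------
# 3D synthetic eyes
# --------------------------------------------------------------------------

SkewField = Callable[[float, float], float]  # (elev_deg, azim_deg) -> tilt deg


@dataclass
class SyntheticEyeSpec:
    """Parameters of a synthetic crystalline-cone shell.

    The eye surface is a toroidal patch looking along +x: vertical arcs
    (in planes containing the z axis) have radius of curvature ``radius_v``
    and the equatorial horizontal arc has radius ``radius_h``.
    ``radius_h == radius_v`` gives a sphere centred at the origin. Cones sit
    at hexagonal angular spacing ``lens_diameter / R`` and extend inward
    along their (optionally skewed) axis.

    ``skew`` is either a constant tilt in degrees (applied about the local
    azimuthal tangent, i.e. tilting axes vertically) or a callable
    ``(elev_deg, azim_deg) -> tilt_deg``. ``skew_target``, if given, instead
    tilts each axis toward (positive skew) that 3D point by the field value.
    """

    lens_diameter: float = 20.0          # µm, centre-to-centre spacing
    radius_h: float = 1000.0             # µm, horizontal radius of curvature
    radius_v: float = 1000.0             # µm, vertical radius of curvature
    extent_deg: tuple = (60.0, 60.0)     # (azimuth span, elevation span)
    cone_length: float = 40.0            # µm, along the ommatidial axis
    points_per_cone: int = 30
    skew: Union[float, SkewField] = 0.0
    skew_target: Optional[tuple] = None
    noise_sigma: float = 1.0             # µm, isotropic positional noise
    seed: int = 0

    def __post_init__(self):
        if min(self.lens_diameter, self.radius_h, self.radius_v) <= 0:
            raise OmmatidiaError("lens diameter and radii must be positive")


@dataclass
class SyntheticEye3D:
    """A generated eye with its ground truth."""

    spec: SyntheticEyeSpec
    points: np.ndarray          # (M, 3) µm
    labels: np.ndarray          # (M,) cone index per point
    bases: np.ndarray           # (N, 3) lens positions on the surface
    centroids: np.ndarray       # (N, 3) true cone centroids
    axes: np.ndarray            # (N, 3) unit outward cone axes
    normals: np.ndarray         # (N, 3) unit outward surface normals
    elev_deg: np.ndarray        # (N,) surface elevation angle of each cone
    azim_deg: np.ndarray        # (N,) surface azimuth angle of each cone

    @property
    def n_cones(self) -> int:
        return len(self.bases)


def _rotate_about(v, axis, angle_rad):
    """Rodrigues rotation of vectors ``v`` about unit ``axis``."""
    axis = axis / np.linalg.norm(axis)
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return v * c + np.cross(axis, v) * s + axis * np.dot(axis, v) * (1 - c)


def make_synthetic_eye3d(spec: SyntheticEyeSpec) -> SyntheticEye3D:
    """Place cones on the eye surface and render them as point clouds.

    Rows of cones are ``(sqrt(3)/2) * D`` apart along the vertical arc and
    staggered, with the azimuthal step widened at high elevation so the
    physical centre-to-centre spacing stays ``D`` everywhere. Each cone is a
    line segment of ``points_per_cone`` points running inward from the
    surface along its axis, with isotropic Gaussian jitter.
    """
    D, Rh, Rv = spec.lens_diameter, spec.radius_h, spec.radius_v
    az_span, el_span = np.deg2rad(spec.extent_deg[0]), np.deg2rad(spec.extent_deg[1])
    d_elev = (np.sqrt(3) / 2) * D / Rv
    n_rows = int(np.floor(el_span / d_elev / 2))
    if n_rows < 1 or az_span <= D / Rh:
        raise OmmatidiaError("angular extent too small for the lattice spacing")

    if callable(spec.skew):
        skew_fn = spec.skew
    else:
        skew_fn = lambda e, a: float(spec.skew)  # noqa: E731

    rng = np.random.default_rng(spec.seed)
    bases, axes, normals, elevs, azims = [], [], [], [], []
    for j in range(-n_rows, n_rows + 1):
        theta = j * d_elev
        # local horizontal circle radius of the toroidal patch
        rho = Rh - Rv * (1 - np.cos(theta))
        if rho <= D:
            continue
        d_azim = D / rho
        n_cols = int(np.floor((az_span / 2 - (j % 2) * d_azim / 2) / d_azim))
        phis = (np.arange(-n_cols, n_cols + 1) + (j % 2) * 0.5) * d_azim
        for phi in phis:
            ct, st = np.cos(theta), np.sin(theta)
            cp, sp = np.cos(phi), np.sin(phi)
            # vertical arc point in the x-z plane, then rotate about z
            v = np.array([(Rh - Rv) + Rv * ct, 0.0, Rv * st])
            normal = np.array([ct, 0.0, st])
            rot_z = np.array([[cp, -sp, 0.0], [sp, cp, 0.0], [0.0, 0.0, 1.0]])
            base, normal = rot_z @ v, rot_z @ normal
            elev_deg, azim_deg = np.degrees(theta), np.degrees(phi)
            tilt = np.deg2rad(skew_fn(elev_deg, azim_deg))
            axis = normal
            if abs(tilt) > 0:
                if spec.skew_target is not None:
                    toward = np.asarray(spec.skew_target, float) - base
                    pivot = np.cross(normal, toward)
                    if np.linalg.norm(pivot) < 1e-12:
                        pivot = rot_z @ np.array([0.0, 1.0, 0.0])
                else:
                    pivot = rot_z @ np.array([0.0, 1.0, 0.0])  # azimuthal tangent
                axis = _rotate_about(normal, pivot, tilt)
            bases.append(base)
            axes.append(axis / np.linalg.norm(axis))
            normals.append(normal)
            elevs.append(elev_deg)
            azims.append(azim_deg)

    bases = np.asarray(bases)
    axes = np.asarray(axes)
    n = len(bases)
    depth = np.linspace(0.0, spec.cone_length, spec.points_per_cone)
    pts = bases[:, None, :] - axes[:, None, :] * depth[None, :, None]
    pts = pts.reshape(-1, 3)
    if spec.noise_sigma > 0:
        pts = pts + rng.normal(0.0, spec.noise_sigma, pts.shape)
    labels = np.repeat(np.arange(n), spec.points_per_cone)
    centroids = bases - axes * (spec.cone_length / 2.0)
    return SyntheticEye3D(
        spec=spec,
        points=pts,
        labels=labels,
        bases=bases,
        centroids=centroids,
        axes=axes,
        normals=np.asarray(normals),
        elev_deg=np.asarray(elevs),
        azim_deg=np.asarray(azims),
    )


def peripheral_skew(max_deg: float, extent_deg: tuple) -> SkewField:
    """Skew field growing linearly from 0 at the eye centre to ``max_deg``
    at the edge of the angular extent."""
    half_az, half_el = extent_deg[0] / 2.0, extent_deg[1] / 2.0

    def field(elev_deg: float, azim_deg: float) -> float:
        frac = np.hypot(azim_deg / half_az, elev_deg / half_el) / np.sqrt(2)
        return max_deg * min(frac, 1.0)

    return field


def voxelize(points: np.ndarray, voxel_size: float, foreground: int = 200,
             background: int = 10, pad: int = 2):
    """Rasterize a point cloud into an 8-bit image stack.

    Returns ``(stack, origin)`` where ``stack[z, y, x]`` holds ``foreground``
    in voxels containing at least one point and ``background`` elsewhere, and
    ``origin`` is the world coordinate of voxel index (0, 0, 0) so that
    ``world = origin + index * voxel_size`` (x, y, z order).
    """
    pts = np.asarray(points, float)
    lo = pts.min(axis=0) - pad * voxel_size
    idx = np.floor((pts - lo) / voxel_size).astype(int)
    dims = idx.max(axis=0) + 1 + pad
    stack = np.full((dims[2], dims[1], dims[0]), background, dtype=np.uint8)
    stack[idx[:, 2], idx[:, 1], idx[:, 0]] = foreground
    return stack, lo
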