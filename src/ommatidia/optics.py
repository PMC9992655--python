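"""Closed-form compound-eye optics shared by the 2D and 3D pipelines.

For a spherical eye the interommatidial (IO) angle, lens diameter and
radius of curvature are linked by ``delta_phi = D / R`` (radians): the
anatomy visible from outside fixes the optics. Skewed ommatidia reduce the
effective aperture by the cosine of the skew angle, and non-spherical
(oval) eyes separate the IO angle into independent horizontal and vertical
components whose hypotenuse is the total anatomical IO angle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import OmmatidiaError

__all__ = [
    "spherical_io_angle",
    "radius_from_io",
    "adjusted_diameter",
    "total_io_angle",
    "eye_parameter",
    "OvalEyeSummary",
    "oval_eye_analysis",
    "VisualField",
    "world_project",
]


def spherical_io_angle(diameter: float, radius: float) -> float:
    """IO angle (degrees) of a spherical eye: ``D / R`` radians."""
    if radius <= 0:
        raise OmmatidiaError("radius of curvature must be positive")
    if diameter < 0:
        raise OmmatidiaError("lens diameter cannot be negative")
    return float(np.degrees(diameter / radius))


def radius_from_io(diameter: float, io_angle_deg: float) -> float:
    """Radius of curvature/intersection (same units as D): ``R = D / Δφ``."""
    if io_angle_deg <= 0:
        raise OmmatidiaError("IO angle must be positive")
    if diameter < 0:
        raise OmmatidiaError("lens diameter cannot be negative")
    return float(diameter / np.radians(io_angle_deg))


def adjusted_diameter(diameter: float, skew_deg: float) -> float:
    """Effective lens aperture ``D * cos(skew)``; skew in [0, 90] degrees."""
    if not 0 <= skew_deg <= 90:
        raise OmmatidiaError("skew angle must lie in [0, 90] degrees")
    return float(diameter * np.cos(np.radians(skew_deg)))


def total_io_angle(h_deg: float, v_deg: float) -> float:
    """Total anatomical IO angle: hypotenuse of the horizontal and vertical
    components."""
    if h_deg < 0 or v_deg < 0:
        raise OmmatidiaError("angle components must be non-negative")
    return float(np.hypot(h_deg, v_deg))


def eye_parameter(diameter_um: float, io_angle_deg: float) -> float:
    """Eye parameter p = D * Δφ (µm · rad), a diffraction/sensitivity
    trade-off descriptor. Provided for convenience; not validated here."""
    return float(diameter_um * np.radians(io_angle_deg))


# --------------------------------------------------------------------------
# Oval-eye lattice analysis
# --------------------------------------------------------------------------

@dataclass
class OvalEyeSummary:
    """Per-orientation-mode IO statistics of a (possibly oval) eye.

    For ommatidia in a regular hexagonal lattice, pair orientations fall
    into three modes: horizontal pairs near 0 deg and diagonal pairs near
    +/-60 deg. The horizontal angle of horizontal pairs is ``2*delta_phi_h``
    while diagonal pairs contribute ``delta_phi_h`` horizontally and
    ``delta_phi_v`` vertically; on an oval eye the two components map to
    different intersection radii.
    """

    mode_orientations_deg: np.ndarray     # up to 3 modes
    mode_h_deg: np.ndarray                # mean |horizontal| component per mode
    mode_v_deg: np.ndarray                # mean |vertical| component per mode
    mode_radius_um: np.ndarray            # Eq. R = D / Δφ per mode (total angle)
    delta_phi_h_deg: float                # combined horizontal IO component
    delta_phi_v_deg: float                # combined vertical IO component
    radius_horizontal_um: float           # from horizontal pairs
    radius_diagonal_um: float             # mean of the diagonal modes
    radius_h_component_um: float          # D/2 displacement / Δφ_h
    radius_v_component_um: float          # sqrt(3)/2 D displacement / Δφ_v
    n_pairs_per_mode: np.ndarray
    complete: bool                        # all three modes found

    @property
    def radius_ratio(self) -> float:
        """R_diagonal / R_horizontal (1 for a spherical eye)."""
        return self.radius_diagonal_um / self.radius_horizontal_um

    @property
    def component_ratio(self) -> float:
        """Δφ_v / Δφ_h (1/sqrt(3) for a regular hexagonal lattice)."""
        return self.delta_phi_v_deg / self.delta_phi_h_deg


def _orientation_modes(orientations: np.ndarray, n_modes: int = 3,
                       bin_deg: float = 2.0, smooth_deg: float = 6.0,
                       min_sep_deg: float = 30.0) -> np.ndarray:
    """Peaks of a kernel-smoothed orientation histogram on (-90, 90] with
    wraparound (orientation is defined modulo 180 degrees)."""
    edges = np.arange(-90, 90 + bin_deg, bin_deg)
    hist, _ = np.histogram(orientations, bins=edges)
    k_half = int(np.ceil(3 * smooth_deg / bin_deg))
    x = np.arange(-k_half, k_half + 1) * bin_deg
    kernel = np.exp(-0.5 * (x / smooth_deg) ** 2)
    kernel /= kernel.sum()
    padded = np.concatenate([hist[-k_half:], hist, hist[:k_half]])
    smoothed = np.convolve(padded, kernel, mode="same")[k_half:-k_half]
    mids = 0.5 * (edges[:-1] + edges[1:])

    order = np.argsort(-smoothed)
    modes = []
    for idx in order:
        cand = mids[idx]
        if all(
            min(abs(cand - m), 180 - abs(cand - m)) >= min_sep_deg for m in modes
        ):
            modes.append(float(cand))
        if len(modes) == n_modes:
            break
    return np.array(sorted(modes, key=abs))


def oval_eye_analysis(pairs: Sequence, mode_halfwidth_deg: float = 15.0,
                      mean_diameter_um: Optional[float] = None) -> OvalEyeSummary:
    """Orientation-mode analysis of adjacent-pair IO angles.

    Finds the (up to) three orientation modes of the pair population,
    selects pairs within ``mode_halfwidth_deg`` of each mode, and averages
    their horizontal and vertical angle components. The combined horizontal
    component pools the horizontal angle of diagonal pairs with *half* the
    horizontal angle of horizontal pairs (which subtend twice the column
    spacing); the combined vertical component pools the vertical angles of
    diagonal pairs. Radii of intersection come from ``R = D / Δφ`` using
    the pooled mean lens diameter of the contributing pairs.

    ``pairs`` may be :class:`~ommatidia.oda3d.PairRecord` objects or any
    objects with ``orientation_deg``, ``io_h_deg``, ``io_v_deg``,
    ``io_total_deg`` attributes; outlier-marked pairs are ignored. When the
    pairs carry no diameter information, ``mean_diameter_um`` supplies D
    for the radius computations.
    """
    usable = [p for p in pairs if not getattr(p, "outlier", False)]
    if not usable:
        raise OmmatidiaError("no usable pairs for oval-eye analysis")
    orient = np.array([p.orientation_deg for p in usable])
    h = np.array([p.io_h_deg for p in usable])
    v = np.array([p.io_v_deg for p in usable])
    total = np.array([p.io_total_deg for p in usable])

    modes = _orientation_modes(orient)
    complete = len(modes) == 3
    mode_h, mode_v, mode_r, n_per = [], [], [], []
    d_mean = mean_diameter_um if mean_diameter_um else float("nan")
    horiz_halves, diag_h, diag_v = [], [], []
    for m in modes:
        dist = np.abs(orient - m)
        dist = np.minimum(dist, 180 - dist)
        sel = dist <= mode_halfwidth_deg
        n_per.append(int(sel.sum()))
        mh = float(np.mean(h[sel])) if sel.any() else float("nan")
        mv = float(np.mean(v[sel])) if sel.any() else float("nan")
        mt = float(np.mean(total[sel])) if sel.any() else float("nan")
        mode_h.append(mh)
        mode_v.append(mv)
        mode_r.append(radius_from_io(d_mean, mt) if mt > 0 else float("nan"))
        if abs(m) < 30:   # horizontal mode
            horiz_halves.extend(0.5 * h[sel])
        else:             # diagonal modes
            diag_h.extend(h[sel])
            diag_v.extend(v[sel])

    delta_h = float(np.mean(horiz_halves + diag_h)) if (horiz_halves or diag_h) else float("nan")
    delta_v = float(np.mean(diag_v)) if diag_v else float("nan")
    is_horiz = np.abs(modes) < 30
    r_horiz = float(np.nanmean(np.array(mode_r)[is_horiz])) if is_horiz.any() else float("nan")
    r_diag = float(np.nanmean(np.array(mode_r)[~is_horiz])) if (~is_horiz).any() else float("nan")
    # displacement-over-component radii: diagonal pairs are offset half a
    # diameter horizontally and sqrt(3)/2 of a diameter vertically
    r_h_comp = radius_from_io(d_mean / 2.0, delta_h) if delta_h > 0 else float("nan")
    r_v_comp = (
        radius_from_io(np.sqrt(3) / 2.0 * d_mean, delta_v) if delta_v > 0 else float("nan")
    )
    return OvalEyeSummary(
        mode_orientations_deg=modes,
        mode_h_deg=np.array(mode_h),
        mode_v_deg=np.array(mode_v),
        mode_radius_um=np.array(mode_r),
        delta_phi_h_deg=delta_h,
        delta_phi_v_deg=delta_v,
        radius_horizontal_um=r_horiz,
        radius_diagonal_um=r_diag,
        radius_h_component_um=r_h_comp,
        radius_v_component_um=r_v_comp,
        n_pairs_per_mode=np.array(n_per),
        complete=complete,
    )


# --------------------------------------------------------------------------
# World-referenced field of view
# --------------------------------------------------------------------------

@dataclass
class VisualField:
    """World-referenced viewing directions and field-of-view extents."""

    directions: np.ndarray          # (N, 3) unit vectors from the eye centre
    fov_horizontal_deg: float
    fov_vertical_deg: float
    projection_radius_um: float
    n_excluded: int = 0             # rays that miss the projection sphere

    def __post_init__(self):
        if not (0 <= self.fov_horizontal_deg < 360 and 0 <= self.fov_vertical_deg < 360):
            raise OmmatidiaError("FOV must lie in [0, 360) degrees")


def world_project(
    records: Sequence,
    eye_center: np.ndarray,
    projection_radius_um: float = 1e5,
    use_raw_axes: bool = True,
) -> VisualField:
    """Project ommatidial axes onto a distant sphere and measure the FOV.

    Each ommatidial axis ray (from the cone centroid, outward) intersects
    the sphere of ``projection_radius_um`` (default 10 cm, a behaviourally
    relevant fixation distance) about ``eye_center``; the angular spread of
    the intersection directions is the world-referenced field of view:
    horizontal FOV from azimuths, vertical FOV from elevations. Raw
    anatomical axes are used by default (neighbourhood averaging drags
    border axes inward and would shrink the FOV). Rays that miss the
    sphere are excluded and counted.
    """
    eye_center = np.asarray(eye_center, float)
    starts = np.stack([r.centroid for r in records])
    axes = np.stack(
        [r.anatomical_axis if use_raw_axes else r.averaged_axis for r in records]
    )
    rel = starts - eye_center
    b = np.einsum("ij,ij->i", rel, axes)
    c = np.einsum("ij,ij->i", rel, rel) - projection_radius_um**2
    disc = b**2 - c
    ok = disc >= 0
    t = -b + np.sqrt(np.where(ok, disc, 0.0))
    ok &= t > 0
    hits = rel[ok] + t[ok, None] * axes[ok]
    dirs = hits / np.linalg.norm(hits, axis=1)[:, None]
    if len(dirs) == 0:
        return VisualField(
            directions=dirs, fov_horizontal_deg=0.0, fov_vertical_deg=0.0,
            projection_radius_um=projection_radius_um, n_excluded=int((~ok).sum()),
        )
    azim = np.degrees(np.arctan2(dirs[:, 1], dirs[:, 0]))
    elev = np.degrees(np.arcsin(np.clip(dirs[:, 2], -1, 1)))
    return VisualField(
        directions=dirs,
        fov_horizontal_deg=float(azim.max() - azim.min()),
        fov_vertical_deg=float(elev.max() - elev.min()),
        projection_radius_um=projection_radius_um,
        n_excluded=int((~ok).sum()),
    )
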