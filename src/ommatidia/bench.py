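"""Degradation benchmark: how detection degrades with resolution and contrast.

Resolution is lowered by bin-averaging pixels into larger and larger bins;
contrast by compressing the 8-bit brightness range into narrower and
narrower distributions. Relative count and relative diameter curves against
the undegraded reference quantify the operational range of the detector;
the resolution threshold should sit at or above the Nyquist limit of two
pixels per ommatidial diameter.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import ContrastError, OmmatidiaError
from .oda2d import run_oda

__all__ = [
    "DegradationPoint",
    "rms_contrast",
    "degrade_resolution",
    "degrade_contrast",
    "benchmark_sweep",
    "threshold_resolution",
]


@dataclass
class DegradationPoint:
    """One degradation level and the detection performance at it."""

    bin: int
    px_per_diameter: float      # reference diameter (original px) / bin
    rms_contrast: float         # std of intensities normalized to [0, 1]
    count: int
    rel_count: float            # automated / reference count
    diameter_px: float          # measured, in original-image px
    rel_diameter: float         # automated / reference diameter
    runtime_s: float


def rms_contrast(image: np.ndarray) -> float:
    """RMS contrast: standard deviation of intensities after normalizing
    the 8-bit range to [0, 1]. A full-range binary checkerboard scores 0.5."""
    return float(np.std(np.asarray(image, float) / 255.0))


def degrade_resolution(image: np.ndarray, bin: int) -> np.ndarray:
    """Bin-average ``bin`` x ``bin`` pixel blocks into single pixels.

    Output dimensions are ``floor(dim / bin)``; trailing partial blocks are
    dropped so that every output pixel is an exact block mean.
    """
    if bin < 1 or int(bin) != bin:
        raise OmmatidiaError(f"bin must be a positive integer, got {bin}")
    bin = int(bin)
    img = np.asarray(image, float)
    h, w = img.shape[0] // bin, img.shape[1] // bin
    if h == 0 or w == 0:
        raise OmmatidiaError(f"bin {bin} exceeds image dimensions {img.shape}")
    return img[: h * bin, : w * bin].reshape(h, bin, w, bin).mean(axis=(1, 3))


def degrade_contrast(image: np.ndarray, target_rms: float) -> np.ndarray:
    """Compress the brightness distribution to a target RMS contrast.

    Affine rescaling about the mean on the [0, 1] scale, then requantized
    to 8 bits. Only contrast *reduction* is allowed; a target above the
    current contrast (beyond quantization slack) raises
    :class:`ContrastError`.
    """
    img = np.asarray(image, float) / 255.0
    current = float(img.std())
    if target_rms <= 0:
        raise ContrastError(f"target RMS contrast must be positive, got {target_rms}")
    if target_rms > current + 0.5 / 255:
        raise ContrastError(
            f"target RMS {target_rms:.4f} exceeds current contrast {current:.4f}"
        )
    scaled = img.mean() + (img - img.mean()) * (target_rms / current)
    return np.round(np.clip(scaled, 0, 1) * 255).astype(np.uint8)


def benchmark_sweep(
    image: np.ndarray,
    reference_count: float,
    reference_diameter: float,
    bins: Sequence[int] = (),
    rms_targets: Sequence[float] = (),
    n_fundamentals: int = 3,
    **oda_kwargs,
) -> list:
    """Run the detector at each degradation level.

    ``bins`` drive the resolution sweep (contrast untouched) and
    ``rms_targets`` the contrast sweep (resolution untouched). Measured
    diameters are rescaled by the bin size back to original-image px before
    forming ``rel_diameter``. A detection failure (no lattice found) is
    recorded as ``rel_count = rel_diameter = 0``, matching counts dropping
    to zero at unresolvable degradation levels.
    """
    if reference_count <= 0 or reference_diameter <= 0:
        raise OmmatidiaError("reference count and diameter must be positive")
    image = np.asarray(image, float)
    points = []
    for b in bins:
        degraded = degrade_resolution(image, b)
        points.append(
            _measure_point(
                degraded, b, reference_count, reference_diameter,
                n_fundamentals, oda_kwargs,
            )
        )
    for target in rms_targets:
        degraded = degrade_contrast(image, target)
        points.append(
            _measure_point(
                degraded, 1, reference_count, reference_diameter,
                n_fundamentals, oda_kwargs,
            )
        )
    return points


def _measure_point(degraded, bin, ref_count, ref_diameter, n_fundamentals, oda_kwargs):
    start = time.perf_counter()
    try:
        result = run_oda(degraded, n_fundamentals=n_fundamentals, **oda_kwargs)
        count = result.count
        diameter_px = float(np.mean(result.diameters_px)) * bin if count else 0.0
    except OmmatidiaError:
        count, diameter_px = 0, 0.0
    runtime = time.perf_counter() - start
    return DegradationPoint(
        bin=int(bin),
        px_per_diameter=ref_diameter / bin,
        rms_contrast=rms_contrast(degraded),
        count=count,
        rel_count=count / ref_count,
        diameter_px=diameter_px,
        rel_diameter=diameter_px / ref_diameter,
        runtime_s=runtime,
    )


def threshold_resolution(
    points: Sequence[DegradationPoint], metric: str = "count"
) -> Optional[float]:
    """Lowest resolution (px per diameter) at which detection still works.

    ``metric='count'``: the lowest ``px_per_diameter`` whose relative count
    exceeds half the maximum relative count over the sweep.
    ``metric='diameter'``: the lowest ``px_per_diameter`` whose relative
    diameter deviates from the full-resolution baseline by less than 50%.
    Returns ``None`` when no point qualifies.
    """
    if not points:
        return None
    if metric == "count":
        max_rel = max(p.rel_count for p in points)
        ok = [p.px_per_diameter for p in points if p.rel_count > 0.5 * max_rel]
    elif metric == "diameter":
        baseline = max(points, key=lambda p: p.px_per_diameter).rel_diameter
        if baseline == 0:
            return None
        ok = [
            p.px_per_diameter
            for p in points
            if abs(p.rel_diameter - baseline) < 0.5 * baseline
        ]
    else:
        raise OmmatidiaError(f"unknown threshold metric {metric!r}")
    return min(ok) if ok else None


def points_to_dataframe(points: Sequence[DegradationPoint]):
    import pandas as pd

    return pd.DataFrame([vars(p) for p in points])
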