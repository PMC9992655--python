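"""Static diagnostic plots (the check figures a user inspects after a run)."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .oda2d import OmmatidiaSet2D, compute_reciprocal  # noqa: E402


def plot_detection(image: np.ndarray, result: OmmatidiaSet2D, path) -> None:
    """Two panels: log reciprocal space with the accepted fundamentals, and
    the image with detected centres coloured by lens diameter."""
    image = np.asarray(image, float)
    spectrum = compute_reciprocal(image)
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(11, 5))

    extent = [
        spectrum.freq_cols[0], spectrum.freq_cols[-1],
        spectrum.freq_rows[-1], spectrum.freq_rows[0],
    ]
    ax1.imshow(np.log10(spectrum.power + 1e-12 * spectrum.power.max()),
               extent=extent, cmap="magma")
    if result.fundamentals is not None:
        for peak in result.fundamentals.peaks:
            fr, fc = peak.freq_xy
            for sign in (1, -1):
                ax1.plot(sign * fc, sign * fr, "o", mfc="none", mec="cyan", ms=10)
    lim = 2.5 * max(
        (p.radial_freq for p in result.fundamentals.peaks), default=0.25
    ) if result.fundamentals else 0.25
    ax1.set_xlim(-lim, lim)
    ax1.set_ylim(lim, -lim)
    ax1.set_xlabel("column frequency (cyc/px)")
    ax1.set_ylabel("row frequency (cyc/px)")
    ax1.set_title("reciprocal space")

    ax2.imshow(image, cmap="gray")
    if result.count:
        sc = ax2.scatter(
            result.centers[:, 1], result.centers[:, 0],
            c=result.diameters_um, s=6, cmap="viridis",
        )
        fig.colorbar(sc, ax=ax2, label="diameter (µm)")
    ax2.set_title(f"{result.count} ommatidia")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
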