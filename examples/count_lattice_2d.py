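"""Counting ommatidia in a 2D image.

Builds a synthetic compound-eye image — a hexagonal lattice of bright
spots, one per ommatidium, with additive noise — and runs the full 2D
detector: power spectrum, three fundamental gratings, low-pass
reconstruction, local maxima, neighbour-distance diameters.
"""

from scipy.spatial import cKDTree

from ommatidia import make_hex_lattice_image, run_oda

image, truth = make_hex_lattice_image(
    512, spacing=20, noise_sigma=0.10, seed=42
)
result = run_oda(image, pixel_size=1.0)

dists, _ = cKDTree(truth).query(result.centers)
print(f"true ommatidia    : {len(truth)}")
print(f"detected          : {result.count}")
print(f"diameter          : {result.diameter_mean:.2f} ± {result.diameter_sd:.2f} µm (true 20.00)")
print(f"worst centre error: {dists.max():.2f} px")
print("Count and spacing are recovered from the lattice's three fundamental")
print("frequencies; each centre lands within about one pixel of the truth.")
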