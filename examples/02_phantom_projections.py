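"""Cylinder phantom simulation and Poisson projection data.

Rasterizes the default mathematical cylinder phantom (warm body, one
cold and two hot cylinder stacks), forward-projects it over 120 views,
scales to the three study count levels and adds Poisson noise.
"""

from arspect import (
    DEFAULT_ACQUISITION,
    default_3dmac,
    forward_project,
    rasterize_phantom,
    scale_counts,
    simulate_counts,
)

phantom = default_3dmac()
print(f"phantom: body {phantom.body.diameter:.0f} mm, "
      f"{len(phantom.objects)} embedded cylinders")

volume = rasterize_phantom(phantom, matrix=64, voxel_size=4.0, n_slices=64)
projections = forward_project(volume, DEFAULT_ACQUISITION)
print(f"projections: {projections.data.shape} (angle, row, bin)")

for level in (50_000.0, 100_000.0, 150_000.0):
    scaled = scale_counts(projections, level)
    noisy = simulate_counts(projections, level, seed=1)
    print(
        f"{level:9.0f} counts/projection: mean pixel {scaled.data.mean():5.1f} "
        f"(rounds to {round(scaled.data.mean())}), "
        f"noisy range {noisy.data.min():.0f}-{noisy.data.max():.0f}"
    )

print()
print("Each projection image carries the same expected total, so the mean")
print("pixel count is the level divided by the 64x64 image area; the only")
print("degradation in this ideal system is the Poisson counting noise.")
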