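"""Image-quality metrics on a reconstructed phantom volume.

Reconstructs with OSEM, post-filters with a 3D order-2 Butterworth, and
measures the noise (CoV%), contrast (CR%) and resolution (FWHM) metrics
used throughout the method comparison.
"""

from arspect import (
    DEFAULT_ACQUISITION,
    apply_butterworth,
    contrast_resolution,
    cov_percent,
    cylinder_profile,
    cylinder_roi,
    default_3dmac,
    forward_project,
    fwhm,
    osem_reconstruct,
    rasterize_phantom,
    roi_stats,
    simulate_counts,
    uniform_roi,
)

phantom = default_3dmac()
truth = rasterize_phantom(phantom, 64, 4.0, 64)
noisy = simulate_counts(forward_project(truth, DEFAULT_ACQUISITION), 50_000.0, seed=2)
volume = apply_butterworth(osem_reconstruct(noisy), cutoff=0.84, order=2)

u_roi = uniform_roi(truth, phantom)
M = roi_stats(volume, u_roi)
print(f"uniform 150 mm ROI: mean {M.mean:.3f}, CoV {cov_percent(M):.1f}%")
print()
print("cylinder   activity   CR%     FWHM (mm)")
for act in (0.0, 2.0, 4.0):
    for diam in (10.0, 20.0, 40.0, 60.0):
        roi = cylinder_roi(volume, phantom, act, diam)
        cr = contrast_resolution(roi_stats(volume, roi), M)
        try:
            w = f"{fwhm(cylinder_profile(volume, phantom, act, diam)):7.1f}"
        except Exception:
            w = "    n/a"
        print(f"{diam:5.0f} mm      x{act:g}     {cr:6.1f} {w}")

print()
print("CR% approaches 100 for cold and 300 for the x4 hot cylinders as the")
print("diameter grows (partial volume suppresses small objects); FWHM tracks")
print("the physical diameter once the object is well above the resolution.")
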