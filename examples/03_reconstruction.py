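"""FBP and OSEM reconstruction of noisy phantom projections.

Reconstructs the same noisy dataset with filtered back projection
(signed, analytic) and ordered-subset EM (nonnegative, iterative) and
compares how each recovers the hot cylinder contrast.
"""

from arspect import (
    DEFAULT_ACQUISITION,
    ReconConfig,
    cylinder_roi,
    default_3dmac,
    fbp_reconstruct,
    forward_project,
    osem_reconstruct,
    rasterize_phantom,
    roi_stats,
    simulate_counts,
    uniform_roi,
)

phantom = default_3dmac()
truth = rasterize_phantom(phantom, 64, 4.0, 64)
noisy = simulate_counts(forward_project(truth, DEFAULT_ACQUISITION), 100_000.0, seed=3)

fbp = fbp_reconstruct(noisy, ReconConfig(algorithm="FBP"))
osem = osem_reconstruct(noisy, ReconConfig(osem_subsets=8, osem_iterations=10))

u_roi = uniform_roi(truth, phantom)
hot = cylinder_roi(truth, phantom, 4.0, 60.0)
for name, vol in (("FBP", fbp), ("OSEM 8x10", osem)):
    M = roi_stats(vol, u_roi).mean
    m = roi_stats(vol, hot).mean
    print(
        f"{name:10s} background {M:8.3f}  hot-cylinder {m:8.3f}  "
        f"ratio {m / M:5.2f} (truth 4.00)  min voxel {vol.voxels.min():9.3f}"
    )

print()
print("Both methods recover the 4:1 hot-to-background ratio of the largest")
print("cylinder to within a few percent; FBP retains negative voxels while")
print("the multiplicative OSEM updates keep the volume nonnegative.")
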