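"""The noise-matched three-method comparison, at reduced scale.

Runs the full experiment driver on a coarse grid (32x32, 8 mm voxels,
40 views) so it finishes in well under a minute: AR-OSEM-AR runs first,
its uniform-region CoV% becomes the matching target, and the
Butterworth cutoffs of BW-FBP and OSEM-BW are tuned by bisection before
contrast and resolution are compared.
"""

from arspect import AcquisitionSpec, ExperimentConfig, full_experiment

config = ExperimentConfig(
    acquisition=AcquisitionSpec(n_angles=40, detector_bins=32, bin_size=8.0),
    count_levels=(30_000.0,),
    seeds=(1, 2),
    matrix=32,
    voxel_size=8.0,
    n_slices=32,
    cov_tolerance=0.10,
    metric_diameters=(20.0, 40.0, 60.0),
)
report = full_experiment(config)
summary = report.summary()

print("noise matching (CoV% per method, seed-averaged):")
print(summary["cov"].round(2).to_string(index=False))
print()
print("contrast resolution CR% (seed-averaged):")
print(
    summary["contrast"]
    .pivot(index=["relative_activity", "diameter"], columns="method", values="cr_percent")
    .round(1)
)
print()
print("FWHM (mm, seed-averaged):")
print(
    summary["fwhm"]
    .pivot(index=["relative_activity", "diameter"], columns="method", values="fwhm_mm")
    .round(1)
)
print()
print("All three methods carry the same uniform-region noise, so the CR%")
print("and FWHM differences reflect the filters, not the noise level.")
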