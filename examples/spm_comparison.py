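"""One-dimensional SPM paired comparison and its calibration check.

A paired t statistic is computed at each of the 101 time-normalized nodes;
random field theory (RFT) converts the estimated curve smoothness (FWHM)
into a family-wise critical threshold t*, and supra-threshold clusters
mark where two conditions genuinely differ.  A sign-flip permutation
threshold provides an independent check of the RFT value.
"""

import numpy as np

import kneests as ks
from kneests.spm import SPMConfig, smooth_gaussian_curves

rng = np.random.default_rng(2)
n = 24
baseline = smooth_gaussian_curves(n, 101, 12.0, rng)
effect = 1.2 * np.exp(-0.5 * ((np.arange(101) - 30) / 7.0) ** 2)
condition_a = baseline + effect  # localized difference around node 30
condition_b = smooth_gaussian_curves(n, 101, 12.0, rng)

result = ks.spm_paired_test(condition_a, condition_b)
print(f"df = {result.df}, estimated FWHM = {result.fwhm:.1f} nodes")
print(f"RFT critical threshold t* = {result.critical_threshold:.3f}")
perm = ks.permutation_threshold(condition_a, condition_b,
                                SPMConfig(n_permutations=5000, rng_seed=1))
print(f"permutation threshold     = {perm:.3f} (independent check)")
for c in result.clusters:
    print(f"cluster: nodes [{c.start:.1f}, {c.end:.1f}], "
          f"max |t| = {c.max_abs_t:.2f} "
          f"({'A > B' if c.sign > 0 else 'B > A'})")
print("\nThe cluster should cover node 30, where the difference was "
      "injected; elsewhere |t| stays below t*.")
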