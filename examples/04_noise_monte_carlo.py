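"""Monte-Carlo localization accuracy under electrode noise.

Random gray-matter dipoles are solved once each; Gaussian white noise is
added to the scalp potentials at several SNRs before matching-pursuit
localization.  Mean error grows as SNR falls, and the sparse 10-20
montage is consistently worse than the denser 10-10 montage.
"""

import numpy as np

import spfdloc as sl

labels = sl.make_layered_sphere(spacing_mm=4.0, radii_mm=(44, 38, 32, 28, 18))
sigma = sl.assign_conductivity(labels)
gm = sl.gray_matter_index(labels)

lfms = {}
for system in ("10-10", "10-20"):
    montage = sl.place_montage(labels, system)
    lfms[system] = sl.build_lfm(sigma, montage, gm)

report = sl.run_experiment(
    labels, gm, sigma, lfms,
    n_trials=25, snr_db_list=(np.inf, 20.0, 10.0, 5.0, 0.0), seed=11,
)
print(sl.summarize(report).to_string(index=False))

errs = report.errors(model="10-10", snr_db=5.0)
cdf = sl.cumulative_distribution(errs, bin_mm=0.5)
below = float(np.mean(errs < 10.0))
print(f"\n10-10 at 5 dB: {100 * below:.0f}% of errors below 10 mm "
      f"(cumulative curve over {len(cdf)} half-mm bins)")
r = sl.depth_error_correlation(report, "10-10", 5.0)
print(f"depth-error Pearson correlation at 5 dB: {r:+.3f} "
      "(weak at full scale; noisy at this trial count)")
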