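"""Lead-field mismatch: localizing with the wrong head model.

Scalp potentials are generated in the segmentation-free volume, but each
lead field comes from a different conductivity model.  Even without
noise, a mismatched lead field mislocates sources by several millimeters
— the error produced purely by the conductivity distribution — while the
matched lead field stays near zero.  A pooled two-sample t-test makes
the model contrast quantitative.
"""

import numpy as np

import spfdloc as sl

labels = sl.make_layered_sphere(spacing_mm=4.0, radii_mm=(44, 38, 32, 28, 18))
gm = sl.gray_matter_index(labels)
montage = sl.place_montage(labels, "10-10")

anatomical = sl.assign_conductivity(labels)
segfree = sl.make_segmentation_free(anatomical, 4.0)
models = {
    "segfree (matched)": segfree,
    "anatomical": anatomical,
    "homogeneous": sl.make_homogeneous(labels),
    "csf-insert": sl.make_csf_insert(labels),
}
lfms = {name: sl.build_lfm(vol, montage, gm) for name, vol in models.items()}

report = sl.run_experiment(
    labels, gm, segfree, lfms, n_trials=25, snr_db_list=(np.inf,), seed=3,
)
print("mean localization error, noise-free potentials from segfree volume:")
for name in models:
    print(f"  LFM {name:18s} {report.errors(model=name).mean():6.2f} mm")

p = sl.compare_models(report, report, "segfree (matched)", "homogeneous")
print(f"\nmatched vs homogeneous, pooled t-test: p = {p:.2e}")
# p << 0.05: the conductivity model alone shifts the estimates
# significantly; smooth (matched) conductivity avoids that bias.
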