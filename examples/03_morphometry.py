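"""Cord morphometry: areas, diameters, compression ratio, lesion map.

Measures cross-sectional areas and extents on a healthy and an
atrophied phantom, computes a compression ratio from sagittal
diameters, and averages lesion masks of a patient subgroup into a
lesion-frequency map.
"""

from cordivim import (
    SagittalDiameters,
    compute_compression_ratio,
    compute_csa,
    compute_extents,
    generate_cohort,
    generate_phantom,
    lesion_frequency_map,
    PhantomConfig,
)

cfg = PhantomConfig.smoke(seed=1, snr=None, wm_csa_sd=0.0, gm_csa_sd=0.0)
for group in ("HC", "DCM"):
    s = generate_phantom(cfg, f"{group}01", group)
    vd = cfg.voxel_dims
    slices = range(cfg.grid_shape[2])
    wm = compute_csa(s.seg.wm_mask, vd, slices)
    gm = compute_csa(s.seg.gm_mask, vd, slices)
    ap, lr = compute_extents(s.seg.cord_mask, vd, slices)
    print(f"{group}: WM CSA {wm:5.1f} mm^2, GM CSA {gm:5.1f} mm^2, "
          f"AP {ap:4.1f} mm, LR {lr:4.1f} mm")

d = SagittalDiameters(d_i=6.1, d_a=8.2, d_b=8.2, target="cord")
print(f"\nMSCC for d_i=6.1, references 8.2/8.2: "
      f"{compute_compression_ratio(d):.1f} % diameter reduction")

study = generate_cohort(cfg, n_hc=1, n_dcm=8, seed=5, images=True)
lesions = [s.seg.lesion_mask for s in study.subjects
           if s.record["myelopathy"]]
fmap = lesion_frequency_map(lesions)
print(f"\nlesion-frequency map over {len(lesions)} myelopathic patients: "
      f"max {fmap.max():.0f} % (voxel hit by every lesion), "
      f"{int((fmap > 0).sum())} voxels touched")
print("Voxel values give the percentage of patients with a lesion there.")
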