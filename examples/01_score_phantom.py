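"""Score a digital chest phantom: segment the lungs, then compute the
conventional density-mask emphysema score (origES) and the normalized
score (normES).

The phantom carries exact ground truth, so the printed scores can be read
against the true emphysematous fraction of the lung.
"""

import normes as nm

# A phantom with a known emphysema burden, rendered as if reconstructed
# with a sharp kernel at 1.25 mm slices (the worst case for origES).
spec = nm.PhantomSpec(seed=7, n_clusters=12)
clean, truth_mask, emph = nm.generate_phantom(spec)
true_es = nm.true_emphysema_fraction(truth_mask, emph)

sharp = nm.DEFAULT_KERNELS["sharp"]
scan, scan_mask = nm.render_phantom(clean, truth_mask, sharp, seed=1)

# Lungs segmented from the rendition itself (threshold + morphology).
seg = nm.segment_lungs(scan)

# normES needs a reference-kernel profile; build it from the medium-kernel
# rendition of the same anatomy (in practice: a set of reference scans).
ref_scan, ref_mask = nm.render_phantom(clean, truth_mask,
                                       nm.DEFAULT_KERNELS["medium"], seed=2)
profile = nm.compute_reference_profile([ref_scan], [ref_mask])

orig = nm.compute_orig_es(scan, seg)
norm = nm.compute_norm_es(scan, seg, profile)

print(f"true emphysema extent : {true_es:5.2f} % of lung voxels")
print(f"origES (sharp kernel) : {orig.score:5.2f} %  "
      f"({orig.n_emphysema_voxels} of {orig.n_lung_voxels} voxels)")
print(f"normES                : {norm.score:5.2f} %  "
      f"({norm.n_clusters_removed} noise clusters removed)")
print()
print("origES is inflated far above the truth because sharp-kernel noise")
print("pushes parenchyma below -950 HU; normES harmonizes the scan toward")
print("the reference kernel first and lands near the true extent.")
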