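"""Build the four vector texture images (VTIs) for one synthetic lesion.

A phantom lesion is generated, its gradient and Hessian-eigenvalue vector
fields are converted to spherical coordinates, and each field is quantized
into an angle-only and a full (magnitude + angles) VTI. The printed level
counts and state-space sizes show how the quantization controls the
co-occurrence matrix dimensions downstream.
"""

import numpy as np

from vectex import (DEFAULT_CONFIGS, PhantomSpec, apply_air_threshold,
                    build_vti, deriche_second_derivatives,
                    hessian_eigenvalues, make_phantom, sobel_gradient,
                    to_spherical)

volume, roi = make_phantom(PhantomSpec(class_label=1, seed=1))
roi = apply_air_threshold(volume, roi)  # drop lumen-air voxels (< -450 HU)
print(f"phantom {volume.shape}, ROI {roi.n_voxels} voxels "
      f"(threshold {roi.threshold_hu} HU)")

grad = sobel_gradient(volume)
sph_g = to_spherical(*grad.components())
eig = hessian_eigenvalues(deriche_second_derivatives(volume, alpha=1.0))
sph_h = to_spherical(*eig.components())

for kind, sph in (("GAV", sph_g), ("TGV", sph_g), ("HAV", sph_h),
                  ("THV", sph_h)):
    cfg = DEFAULT_CONFIGS[kind]
    vti = build_vti(kind, sph, cfg, roi)
    inside = [ch[roi.mask] for ch in vti.channels]
    print(f"{kind}: channels {vti.levels} -> {vti.n_states} states; "
          f"occupied {len(set(zip(*[c.tolist() for c in inside])))}")

# Each VTI voxel is a small integer tuple (quantized magnitude/azimuth/polar);
# the state count is the side length of the co-occurrence matrices built next.
print("\ngradient magnitude percentiles inside ROI:",
      np.percentile(sph_g.magnitude[roi.mask], [50, 90, 99]).round(1))
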