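"""TIRF-like image quantification cross-checked against coordinates.

Renders a synthetic ring network into a noisy fluorescence-like image
(Gaussian PSF + Poisson photon noise), runs the image pipeline (mask,
centroid, 50 radial line profiles, intensity-weighted radial median), and
compares against the coordinate-level R_median of the same network.
"""

import numpy as np

from actoring import analysis, imaging
from actoring.state import BoundaryGeometry
from actoring.synthetic import MorphologySpec, RenderSpec, make_snapshot, \
    render_image

bnd = BoundaryGeometry(diameter=4000.0, height=400.0)
snap = make_snapshot(MorphologySpec(kind="ring", boundary=bnd,
                                    total_monomers=30000,
                                    ring_radius_frac=0.85), 7)
truth = analysis.r_median(snap)

img = render_image(snap, RenderSpec(pixel_size_nm=40.0, psf_sigma_nm=120.0,
                                    photons_per_monomer=30.0,
                                    background=2.0), 7)
print(f"rendered {img.data.shape[0]}x{img.data.shape[1]} image, "
      f"pixel 40 nm, PSF sigma 120 nm, Poisson noise")

mask, centroid = imaging.mask_and_centroid(img)
prof = imaging.radial_profiles(img, mask, centroid, n_samples=150)
measured = imaging.intensity_r_median(prof)

print(f"coordinate-level R_median : {truth:.3f}")
print(f"image-pipeline  R_median  : {measured:.3f}")
print(f"difference                : {abs(truth - measured):.3f}  (<= 0.05 "
      "across the fixture suite)")

mean_profile = prof.profiles.mean(axis=0)
slope = imaging.plateau_slope(mean_profile[None, :], prof.r)[0]
print(f"center-to-plateau slope   : {slope:.2f} (normalized intensity per "
      "normalized radius)")
print("\nBoth pipelines agree on where the actin mass sits — this is the")
print("bridge between simulated coordinates and what a microscope reports.")
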