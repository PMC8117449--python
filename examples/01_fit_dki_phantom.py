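"""Fit diffusion/kurtosis metric maps on a noisy simulated patient.

Builds a small DWI phantom (white-matter-like background, spherical lesion
with the tumor-progression group's median MD/MK), adds Rician noise at an
S0-SNR of 25, estimates the noise level from the image background, fits the
22-parameter kurtosis model voxel by voxel, and compares the recovered
lesion medians with the simulated ground truth.
"""

import numpy as np

from fetdki import dki
from fetdki.phantom import PhantomConfig, simulate_dwi_phantom

cfg = PhantomConfig(grid_shape=(24, 24, 16), lesion_center=(8, 12, 8),
                    lesion_radius=7.0, group="TPR", noise_sigma=40.0, seed=1)
dataset, truth = simulate_dwi_phantom(cfg)

sigma = dki.estimate_background_sigma(dataset.signal[..., 0], ~dataset.brain_mask)
print(f"background sigma estimate: {sigma:.2f} (simulated: {cfg.noise_sigma})")

maps = dki.fit_dki_volume(dataset, sigma=sigma)
lesion = np.isclose(truth.md, cfg.lesion_md_target)
print(f"fit report: {maps.report.as_dict()}")
for name, target in (("md", cfg.lesion_md_target), ("mk", cfg.lesion_mk_target)):
    med = np.nanmedian(maps.metric(name)[lesion])
    print(f"lesion median {name.upper()}: {med:.3f} (ground truth {target})")

# The sigma estimate should sit within a few percent of the simulated noise,
# and the lesion MD/MK medians within a few percent of the configured
# targets: that is the accuracy the kurtosis fit delivers at SNR 25 after
# Rician bias correction.
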