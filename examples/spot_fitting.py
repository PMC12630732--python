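"""Localize a single noisy fiducial spot and check the shot-noise limit.

Renders one pixel-integrated Gaussian spot (184 nm wide at 80 nm/px,
5000 expected photons on a 100-count baseline), adds Poisson noise, and
fits it.  Repeating this shows the localization scatter approaching
sigma/sqrt(N) — the reason a handful of bright markers is enough to sense
sub-nanometer drift.
"""

import numpy as np

from stabilock import fit_gaussian_2d
from stabilock.simscope import _add_spot

rng = np.random.default_rng(1)
sigma_px, photons = 184.0 / 80.0, 5000.0

roi = np.zeros((17, 17))
_add_spot(roi, 8.27, 7.83, sigma_px, photons)
fit = fit_gaussian_2d(rng.poisson(roi).astype(float) + 100.0)
print(f"single fit : x = {fit.x:.3f} px (truth 8.270), y = {fit.y:.3f} px (truth 7.830), "
      f"width = {0.5 * (fit.sigma_x + fit.sigma_y) * 80:.1f} nm (truth 184)")

xs = []
for _ in range(500):
    roi = np.zeros((17, 17))
    _add_spot(roi, 8.0, 8.0, sigma_px, photons)
    xs.append(fit_gaussian_2d(rng.poisson(roi).astype(float) + 100.0).x)
print(f"scatter    : {np.std(xs) * 80:.2f} nm over 500 fits "
      f"(shot-noise limit {184.0 / np.sqrt(photons):.2f} nm)")
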