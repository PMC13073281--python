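"""Edge-artifact correction on a propagated two-material step.

Propagation from the sample to the detector adds a term proportional
to the Laplacian of the phase, which overshoots at material borders
and corrupts attenuation values.  Filtering the transmission with
1/(1 + (delta/mu)_rel * Delta * k^2) inverts it exactly when the
relative ratio of the two basis materials is known.
"""

import numpy as np
from scipy.ndimage import gaussian_filter

from stainmap import (
    ScanGeometry,
    edge_overshoot_metric,
    get_material,
    paganin_filter_relative,
    propagate_tie,
    relative_delta_mu,
    soft_tissue,
)

geom = ScanGeometry()  # 25 keV, Delta = 0.16 m, 1.44 µm pixels
ratio = relative_delta_mu(soft_tissue(25.0), get_material("lead", 25.0))

n = 128
tau_exit = np.full((n, n), 0.95)
tau_exit[:, n // 4 : 3 * n // 4] = 0.70  # ethanol -> tissue -> ethanol band
tau_exit = gaussian_filter(tau_exit, 1.0)

tau_detector = propagate_tie(tau_exit, geom, ratio)
tau_corrected = paganin_filter_relative(
    tau_detector, ratio, geom.sample_to_detector_m, geom.effective_pixel_um
)

profile = slice(0, n // 2)  # cross the left edge only
print(f"step height:                  {0.25:.3f}")
print(f"overshoot before correction:  {edge_overshoot_metric(tau_detector[0, profile]):.3f}")
print(f"overshoot after correction:   {edge_overshoot_metric(tau_corrected[0, profile]):.3f}")
err = np.abs(tau_corrected - tau_exit)
away = np.ones(n, dtype=bool)
for edge in (n // 4, 3 * n // 4):
    away[edge - 3 : edge + 3] = False
print(f"max residual off the edges:   {err[:, away].max():.2e}  (fraction of tau)")
print("The filter removes the boundary overshoot and returns the exit-plane")
print("transmission, so attenuation coefficients become quantitative.")
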