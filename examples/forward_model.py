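"""Forward-model g2 curves: point source vs a 5 mm uniform-disk source.

Builds the semi-infinite correlation-diffusion model for a milk-phantom
medium and prints g2 at a few lags for both source geometries at a short
(10 mm) source-detector separation, where the finite spot slows the decay.
"""

import numpy as np

from dcskit import FlowModel, OpticalProperties, model_g2

props = OpticalProperties(mu_a=0.0025, mu_s_prime=1.0, n0=1.33, wavelength_nm=785.0)
flow = FlowModel(DB=2.87e-7)  # cm^2/s, alpha = 1
tau = np.array([1e-7, 1e-6, 1e-5, 1e-4])

point = model_g2(10.0, props, flow, tau, beta=0.5)
disk = model_g2(10.0, props, flow, tau, beta=0.5, source_radius=2.5)

print("tau [s]      g2 point    g2 disk(5 mm)")
for t, gp, gd in zip(tau, point.g2, disk.g2):
    print(f"{t:8.1e}   {gp:9.5f}   {gd:9.5f}")
print()
print("The disk-source curve sits above the point-source curve at every lag:")
print("averaging the Green's function over the spot slows the apparent decay,")
print("which is why a point-model fit of disk data under-reads the flow index.")
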