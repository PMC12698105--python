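"""Flow-index fitting and the finite-source bias.

Fits the point-source semi-infinite model to (a) its own noise-free curve
(exact round trip) and (b) a curve generated by the 5 mm uniform-disk
source at a 10 mm separation, quantifying how the finite illumination spot
biases the recovered Brownian diffusion coefficient low.
"""

import numpy as np

from dcskit import FlowModel, OpticalProperties, disk_point_bias, fit_g2, model_g2

props = OpticalProperties(mu_a=0.0025, mu_s_prime=1.0, n0=1.33, wavelength_nm=785.0)
DB_true = 2.87e-7  # cm^2/s
tau = np.logspace(-9, -2, 140)

point_curve = model_g2(10.0, props, FlowModel(DB=DB_true), tau, 0.5)
self_fit = fit_g2(point_curve, props, 10.0)
print(f"point->point round trip: DB = {self_fit.DB_fit:.6g} cm^2/s "
      f"(truth {DB_true:g}), beta = {self_fit.beta_fit:.4f}")

disk_curve = model_g2(10.0, props, FlowModel(DB=DB_true), tau, 0.5, source_radius=2.5)
cross_fit = fit_g2(disk_curve, props, 10.0, model_kind="point")
print(f"disk->point cross fit:   DB = {cross_fit.DB_fit:.3g} cm^2/s "
      f"({cross_fit.DB_fit / DB_true - 1:+.1%} bias)")

rho_grid = [10.0, 14.0, 20.0]
bias = disk_point_bias(rho_grid, 2.5, props, DB_true)
print("separation sweep (5 mm disk source, point-model fit):")
for rho, b in zip(rho_grid, bias):
    print(f"  rho = {rho:4.0f} mm   fractional DB bias = {b:+.2%}")
print()
print("The bias is a few percent at 10 mm and fades with separation, so")
print("short-separation measurements with broad illumination need the disk model.")
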