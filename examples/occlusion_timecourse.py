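"""Cuff-occlusion flow time course: generate and recover.

Programs a three-phase protocol (baseline, arterial occlusion at 20% flow,
release with hyperemic overshoot), generates per-window g2 curves from the
forward model, fits each window, and compares the recovered relative flow
index with the programmed trace.
"""

import numpy as np

from dcskit import (
    OcclusionProtocolSpec,
    OpticalProperties,
    fit_time_course,
    generate_occlusion_bfi,
)

props = OpticalProperties(mu_a=0.0025, mu_s_prime=1.0, n0=1.33, wavelength_nm=785.0)
spec = OcclusionProtocolSpec(phase_durations=(20.0, 20.0, 20.0),
                             relative_levels=(1.0, 0.2, 1.0), overshoot=1.5)
centers, bfi_true, curves = generate_occlusion_bfi(
    spec, window=2.0, DB_baseline=2.87e-7, props=props, rho=20.0
)
n_base = int(20.0 / 2.0)
tc = fit_time_course(curves, (0, n_base), props, 20.0, window_starts=centers)

true_rel = bfi_true / bfi_true[:n_base].mean()
print("time [s]   programmed rBFi   recovered rBFi")
for t, r_true, r_fit in list(zip(centers, true_rel, tc.relative_BFi))[::3]:
    print(f"{t:7.1f}    {r_true:12.3f}    {r_fit:12.3f}")
err = np.max(np.abs(tc.relative_BFi / true_rel - 1))
print(f"max relative error {err:.2%}: the fitter tracks the drop to 0.2x and")
print("the post-release overshoot, the signature of reactive hyperemia.")
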