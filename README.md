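# dcskit

A toolkit for **diffuse correlation spectroscopy (DCS)** — the near-infrared
optical technique that measures deep-tissue blood flow from the temporal
fluctuations of multiply scattered coherent light. `dcskit` covers the full
computational chain of a DCS experiment comparing illumination geometries
(a narrow multi-mode-fiber spot vs a broad, uniform liquid-light-guide
beam), with a synthetic-data module standing in for the instrument:

- **Forward models** of the intensity autocorrelation `g2(τ)` in a
  semi-infinite homogeneous turbid medium, for point and finite
  uniform-disk sources;
- a **multi-tau correlator** that estimates `g2(τ)` from photon-count
  streams with geometrically widening lag bins;
- an **analytic photon-counting noise model** for the standard deviation of
  `g2` and the measurement SNR;
- **flow-index fitting** (Brownian diffusion coefficient `D_B` and blood
  flow index BFi = α·`D_B`), including time courses and the bias incurred
  by fitting a point-source model to data from a finite illumination spot;
- **limiting-aperture laser-safety analysis**: the maximum total power a
  beam profile may deliver under a skin maximum-permissible-exposure (MPE)
  standard, and beam-uniformity metrics;
- **synthetic data generators** for speckle photon streams, noisy `g2`
  curves, beam images, and cuff-occlusion flow protocols.

## The model

The field autocorrelation obeys the correlation diffusion equation; for a
semi-infinite medium with an extrapolated boundary the Green's function is

    G1(ρ, τ) = (3 μs′/4π) [ exp(−K r1)/r1 − exp(−K r2)/r2 ],
    K²(τ) = 3 μa μs′ + μs′² k0² α ⟨Δr²(τ)⟩,   ⟨Δr²(τ)⟩ = 6 D_B τ,

with `r1, r2` the distances to the true and image sources, and the
extrapolated-boundary terms `z0 = 1/(μa+μs′)`,
`zb = 2(1+Reff)/(3 μs′ (1−Reff))`. The measured intensity autocorrelation
follows from the Siegert relation `g2 = 1 + β|g1|²`. A finite illumination
spot is modelled by averaging the point solution over a uniform disk, which
slows the apparent decay at separations comparable to the spot size.

The per-lag noise of a correlator estimate follows the Koppel-type analytic
model (with its low-count simplification `σ ≈ (1/I)√((1+β e^{−Γτ})/(t T))`),
so SNR = `(g2−1)/σ` scales with the detected count rate — which is what a
uniform, MPE-optimal beam profile buys you.

## Worked example

`examples/fit_flow_index.py` generates a noise-free `g2` curve with the
5 mm disk-source model at a 10 mm source–detector separation
(milk-phantom optics, `D_B = 2.87e-7 cm²/s`) and fits it with the
point-source model:

```
point->point round trip: DB = 2.87e-07 cm^2/s (truth 2.87e-07), beta = 0.5000
disk->point cross fit:   DB = 2.68e-07 cm^2/s (-6.5% bias)
separation sweep (5 mm disk source, point-model fit):
  rho =   10 mm   fractional DB bias = -6.48%
  rho =   14 mm   fractional DB bias = -3.80%
  rho =   20 mm   fractional DB bias = -2.09%
```

The round trip is exact; the cross fit under-reads the flow index by ~6.5%
at 10 mm because the broad spot slows the decay, and the bias fades with
separation. The other scripts in `examples/` each exercise one capability
(forward models, the correlator chain, the noise model, laser safety, the
occlusion time course) and print what the numbers mean; `examples/laser_safety.py`
for instance reports 28.5 mW allowed for a sub-aperture beam, 58.0 mW for a
5 mm flat-top (2.04×), and a 1.76× theoretical SNR gain for uniform delivery.

A thin CLI mirrors the stages for shell use, e.g.:

```bash
dcskit synth beam --kind flattop --diameter 5 --out beam.pgm
dcskit mpe beam.pgm
dcskit synth stream --gamma 5000 --rate 1e5 --out ts.txt
dcskit correlate ts.txt --bin-width 1e-5 --out g2.csv
dcskit fit g2.csv --rho 20
```

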