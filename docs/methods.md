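# Methods

This note documents the models implemented in `dcskit`, the defaults and
units that matter, the synthetic-data generators' fidelity, and the
numerical choices made where the design was open.

## Forward model (`dcskit.core_model`)

The semi-infinite correlation-diffusion Green's function is implemented in
its normalized form `g1(τ) = G1(ρ,τ)/G1(ρ,0)`; the `3 μs′/4π` prefactor
cancels and unnormalized `G1` is internal only, since only normalized `g1`
enters the Siegert relation. Internal length unit is **mm**; `D_B` is
accepted in cm²/s (the unit flow indices are quoted in) and converted
(×100 to mm²/s) before forming `K²`. The effective reflection coefficient
uses the standard polynomial `Reff(n) = −1.44 n⁻² + 0.71 n⁻¹ + 0.668 +
0.064 n` in the relative index `n = n0/n_air`.

Defaults: `n0 = 1.33` (aqueous media such as a diluted-milk phantom;
configurable, and the disk/point bias numbers shift by a few percent with
`n0`), `λ = 785 nm` (typical DCS laser line), moving-scatterer fraction
`α = 1` (homogeneous-phantom convention). Milk-phantom optics used
throughout the tests: `μa = 0.0025 mm⁻¹`, `μs′ = 1.0 mm⁻¹`.

**Disk source.** The finite-spot model averages the point solution over a
uniform disk of radius `a`. Quadrature is polar: Gauss–Legendre in radius
(with the `r` Jacobian) × uniform midpoint in angle (the integrand is
periodic in angle, so the midpoint rule converges spectrally). Orders start
at 16×32 and double until two successive refinements agree to
`quadrature_tol` (default 1e-6 relative) on the normalized curve; failure
to converge raises with diagnostics rather than returning silently. The
integrand is smooth away from a mild peak where the detector is nearest
the disk rim, which the refinement handles. A 400×400 Cartesian Riemann
sum serves as an independent cross-check in the tests (agreement ~3e-5).

## Correlator (`dcskit.correlator`)

The lag layout copies hardware multi-tau taggers: `lags_per_block` lags at
the base bin, then the bin width multiplied by `widening_factor` each
block (defaults 16 and ×3 from a 6.145 ns base, the layout of the tagger
modelled). Each block's first lag is the smallest multiple of its bin
width past the previous block's last lag, so lag times are strictly
increasing and integer shifts on the re-binned series. Re-binning sums
adjacent bins, conserving counts exactly.

**Normalization dialect.** The textbook estimator divides by `⟨I⟩²`; the
default here is the symmetric estimator
`⟨I(t)I(t+τ)⟩ / (⟨I(t)⟩_ov ⟨I(t+τ)⟩_ov)` with all averages over the
overlapping support only (no wrap-around), which removes finite-length
bias and coincides with `⟨I⟩²` for stationary streams. The `⟨I⟩²` variant
is available via `normalization="mean_square"`. Every lag requires at
least `min_overlap` (default 100) product terms; shorter series raise a
coverage error naming the first unsupported lag, or, with `n_blocks=None`,
the correlator simply stops emitting blocks.

One scheme note: with a 6.145 ns base tripling every 16 lags, lag index 70
sits near 7 µs; descriptions quoting "70 delays up to 100 µs" for such a
scheme are not self-consistent, and the implementation follows the stated
base/widening layout.

## Noise model (`dcskit.noise`)

`sigma_full` implements the Koppel-type standard deviation of `g2` for
single-exponential decorrelation in the standard Zhou et al. arrangement
(the β² correlated-fluctuation terms over `1 − e^{−2ΓT}`, the `2β/⟨n⟩`
cross term, and the `(1 + β e^{−Γτ})/⟨n⟩²` shot term, all under
`√(T/t)`); a unit test pins the closed form. Because the name `T` is
overloaded in the field, the bin width is `bin_width_T` and absolute
temperature appears only in the Einstein–Stokes helper.

- `Γ·T = 0` exactly makes the correlated term singular and raises, with
  the low-count simplified form as the suggested branch; small nonzero
  `Γ·T` is evaluated stably via `expm1`.
- For multi-tau grids, each lag may carry its own effective bin width
  (`bin_widths=`), the per-block adaptation of a formula derived for a
  linear correlator; the bin index is `m = round(τ/T_lag)`.
- The simplified model `σ = (1/I)√((1+β e^{−Γτ})/(t T))` is exactly
  ∝ 1/I. The full model reduces to it when the `⟨n⟩⁻²` term dominates;
  quantitatively that requires `2β²/(ΓT) ≪ (1+β)/⟨n⟩²`. At `⟨n⟩ = 1e-4`,
  `ΓT = 1e-6`, `β = 0.5` the two agree to ~0.2% (the tests assert 5%);
  at `⟨n⟩ = 1e-3` the speckle term still contributes ~15%, so the
  "low-count" label must be taken seriously.
- Model-vs-simulation: the analytic σ is compared against the per-lag
  sample SD of 100 simulated 1 s measurements in a shot-noise-dominated
  regime (`Γ = 1e5 s⁻¹`, `5e4 counts/s`, two modes, 0.5 µs bins), where
  agreement is within 25% at `Γτ < 2`. In speckle-noise-dominated regimes
  (`⟨n⟩ ≈ 1`) the model overestimates σ by up to ~27% against the
  symmetric estimator; this is a known limitation of the Gaussian
  factorization behind the formula, not a correlator defect.

## Fitting (`dcskit.fitting`)

`fit_g2` minimizes `Σ w(τ)[g2_model − g2_meas]²` with scipy's bounded
trust-region least squares. `D_B` is parametrized in units of 1e-7 cm²/s
for conditioning, bounded in `[1e-10, 1e-4] cm²/s` (initial 1e-7); β is
free in `(0, 1]` by default (initial `g2(τ₁) − 1`) or can be fixed — both
modes exist because experimental practice varies. Non-convergence is
flagged on the result, never silent. Round-tripping a noise-free
same-model curve recovers the generating parameters to ≥6 significant
digits.

**Fit window.** By default all lags from the first until `g2 − 1` falls
below 5% of its initial amplitude; tail lags carry no flow information and
are noise-dominated in real data. Weighting is uniform by default with
optional `1/σ²`.

**Finite-source bias.** `disk_point_bias` generates noise-free disk-source
curves and fits them with the point model. With the phantom optics, a 5 mm
spot and `D_B = 2.87e-7 cm²/s`, the point fit reads `2.68e-7 cm²/s` at
`ρ = 10 mm` (−6.5%), shrinking monotonically to −2% at 20 mm: broad-beam,
short-separation data need the disk forward model. Which of the pair
(2.87, 2.68) is "truth" is a modelling convention; here the disk
generator carries the truth and the point fit is biased low, matching the
direction "slower decay → smaller fitted D_B".

## Laser safety (`dcskit.mpe_beam`)

Skin MPE standards average irradiance over a fixed limiting aperture
(default 3.5 mm): beams smaller than the aperture have their full power
averaged over the aperture area; larger beams are judged by the worst
3.5 mm sub-aperture. The scan places apertures at every pixel (membership
by pixel-centre inclusion; error <1% for ≥200 pixels across the beam) via
FFT convolution with a disk kernel, and requires a dark margin of at least
one aperture radius around the beam support.

**MPE constant.** The default standard is the IEC skin CW limit
`0.2·10^{0.002(λ−700)} W/cm²` (0.2958 W/cm² at 785 nm), which yields the
quoted 28 mW point-source limit; the flat ANSI 0.28 W/cm² figure is a
named alternative. The familiar 57 mW flat-top figure arises from the
rounded point limit times `(5/3.5)²`; the unrounded chain gives 58.0 mW
and both are reported where relevant. `allowed_power` depends only on
beam shape (invariant under power rescaling), and a flat-top is optimal
among shapes of equal support.

Beam preprocessing follows camera practice: frame averaging, dark-frame
(or border-median, outer 5%) background subtraction, clipping at zero;
uniformity reporting uses the intensity centroid, one-pixel annular radial
averaging, and 50-pixel moving-average cross-sections.

## Synthetic data (`dcskit.synthetic`)

**Speckle streams.** Each detected mode is a complex Gaussian field
simulated as a first-order autoregressive process with autocorrelation
`e^{−Γτ}` — exact for single-rate decay and cheap. Intensity is the mean
of `|E|²` over `M` modes, giving `g2 = 1 + (1/M) e^{−2Γτ}` (`β = 1/M`);
an uncorrelated static intensity fraction `s` yields `β = (1−s)²/M` for
arbitrary contrast. Photon counts are Poisson at a rate proportional to
instantaneous intensity, scaled to the requested mean rate; the simulation
bin must satisfy `sim_bin ≤ 0.05/Γ`. The generator does **not** reproduce
the multi-exponential decay of the semi-infinite kernel, detector
afterpulsing, dead time, or ambient light — fits requiring the exact
kernel use `generate_g2_curves` (analytic model + Gaussian noise with the
analytic σ) instead. Passing tests therefore demonstrate estimator and
pipeline correctness under the stated statistics, not robustness to those
instrument artifacts.

**Occlusion protocol.** Three phases (defaults 40 s each, levels 1 / 0.2 /
1 of baseline) with a hyperemic overshoot (default 1.5× baseline) decaying
exponentially (default time constant 10 s; zero gives a step) — the
canonical cuff-occlusion signature. The in-vivo optical properties are not
independently known here, so the demo uses the phantom values and the
absolute BFi scale is illustrative; relative BFi is the meaningful output.

All generators are pure functions of (spec, seed); replicates use
seed-sequence spawning so they are independent and reproducible.

## Problem sizes and determinism

Default test/acceptance problem sizes were chosen as the smallest that
make the statistical assertions stable: 10 s streams at 1e5 counts/s for
parameter recovery, 100×1 s streams for the σ comparison, 0.02 mm pixel
pitch (~250 pixels across a 5 mm beam) for aperture scans, 140-point log
lag grids for fits. All randomness flows through explicit seeds; reruns
are bit-identical.

## Known limitations

- Homogeneous semi-infinite medium only: no layered or heterogeneous
  media, no transmission geometry, no random-flow (`V²τ²`) dynamics.
- Noise model omits dark counts, afterpulsing and ambient light.
- The limiting-aperture scan quantizes aperture membership at the pixel
  level; sub-pixel aperture placement is not interpolated.
- Ocular and pulsed-exposure MPE rules are out of scope.
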