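# Methods

## The reaction network

Plant phytochromes photoconvert between a red-absorbing ground state (Pr)
and a far-red-absorbing signalling state (Pfr). Because the two absorbance
spectra overlap, red light drives *both* directions of the interconversion,
so constant 658-nm illumination establishes a photostationary mixture —
about 73% Pfr for the phytochrome-B photosensory core module (PCM) — whose
composition is set by the ratio of the photoconversion rates and is
independent of intensity. Intensity sets only how *fast* each molecule
cycles between the two states. The signalling output is the binding of a
phytochrome-interacting factor (PIF), which associates strongly with Pfr
and only negligibly with Pr.

The package models five species — free Pr (`R`), free Pfr (`FR`), the two
complexes (`RP`, `FRP`) and free PIF (`P`) — with mass-action kinetics:

    dR/dt   = -k_p R   - k_aR R P     + k_q FR   + k_dR RP
    dFR/dt  = -k_q FR  - k_aFR FR P   + k_p R    + k_dFR FRP
    dRP/dt  = -k_p RP  - k_dR RP      + k_q FRP  + k_aR R P
    dFRP/dt = -k_q FRP - k_dFR FRP    + k_p RP   + k_aFR FR P
    dP/dt   = -k_aR R P - k_aFR FR P  + k_dR RP  + k_dFR FRP

The key structural assumption — and the one that distinguishes this scheme
from the conventional picture of light-switchable binding — is that the
complex photoconverts at the same rates `k_p`, `k_q` as the free receptor.
A complex that transiently samples the Pr state dissociates quickly
(`k_dR` is of order seconds⁻¹, versus `k_dFR` of order 0.1 s⁻¹), and
because `k_aR = 0` it can only re-form after the free receptor has been
photo-reverted to Pfr and re-associated. At high light intensity this
cycling outruns the bimolecular re-association, depleting the complex even
though the Pr:Pfr ratio itself never changes — the high-light
**attenuation** effect. Dimerisation, Pr:Pfr heterodimers and photostate
substructure are deliberately out of scope; the five-species scheme
reproduces all behaviours the estimators target.

### Units, light and calibration

Concentrations are molar, time in seconds, light intensity in mW cm⁻²,
temperature kelvin internally (Celsius accepted where a table offers a
`T_C` column). Photoconversion rates scale linearly with intensity;
`RateConstants` stores per-intensity coefficients. The default 658-nm
calibration puts `k_p + k_q = 10 s⁻¹` at 69 mW cm⁻² (shutter-controlled
fluorescence measurement) with the split pinned at 0.73:0.27; the
alternative absorbance-derived calibration (5.2 s⁻¹ at 69 mW cm⁻², a
different illumination geometry) is available through
`RateConstants.from_calibration`. The 733-nm channel drives only
Pfr→Pr, 2.4 s⁻¹ at 42 mW cm⁻² by default. Thermal dark reversion
`k_rec` adds to the Pfr→Pr flux independently of light; it defaults to 0
(time constant > 200 h at 15 °C for the PCM) but is first-class because
it controls the low-intensity limb of dose-response curves (see below).
`photon_flux_to_irradiance` converts µE s⁻¹ m⁻² to mW cm⁻² through the
photon molar energy N_A·h·c/λ.

### Integration

Protocols are piecewise-constant light segments; the integrator restarts
at every segment boundary so rate discontinuities never fall inside a
step. Each piece uses LSODA (stiff-capable; the rate constants span six
orders of magnitude) with rtol 1e-8 and atol 1e-16 M — the tight absolute
tolerance matters because the PIF pool (tens of nM) is a thousandfold
smaller than the receptor pool and mass conservation is asserted to 1e-6
relative on both totals at output points.

## Photostationary state

Under constant light the network has a unique steady state. Rather than
transcribing the closed-form cubic for free PIF (whose printed composite
coefficients are easy to corrupt), the solver exploits the network
structure directly: for a *fixed* free-PIF concentration the four receptor
species satisfy a linear balance, so the steady receptor partition is a
4×4 linear solve, and the PIF-conservation residual
f([P]) = [P] + [RP] + [FRP] − P0 is a strictly increasing function on
[0, P0] with a sign change guaranteed at the interval ends. Its root —
the same root the cubic has in the admissible interval — is found by
bracketed Brent iteration to machine precision. The `k_aR = 0` degeneracy
(cubic collapsing to a quadratic) needs no special casing in this form.
Correctness is established the way the estimator itself would be
validated: the analytic state must match the long-time limit of the ODE
integration (chunk-doubled until stationary) to better than 1e-5 relative
across randomized parameter draws; in practice agreement is at rounding
level.

`dose_response` evaluates the bound PIF fraction over a log-spaced
intensity grid and summarises the curve by its low-intensity plateau, peak
and an *attenuation onset*, operationalised as the lowest intensity above
the peak where the bound fraction has fallen 10% below it (the threshold
is a parameter; the source material describes the onset only
qualitatively). `scan_panel` produces curve families over one scanned
dimension: `k_rec` (temperature, via dark reversion), `kinetics_fr`
(k_aFR and k_dFR jointly — affinity-preserving slowdown), `k_dFR`,
`k_dR`, `R0_total` (multipliers each), and `kp_kq_ratio`, whose values
are the ratios themselves with `inf` meaning k_q = 0.

A note on curve shape: with `k_rec = 0` the low-intensity limb is flat
(the photoequilibrium, hence the binding level, is intensity-independent
all the way down), so the full rise–peak–fall shape seen in published
simulations requires `k_rec > 0` competing with `k_p` at low intensity.
The shape tests use `k_rec = 1e-3 s⁻¹` as a representative dark-reversion
rate; the exact values behind the published panels are not printed, so
panel reproductions are qualitative by design.

## Estimators

All fits are nonlinear least squares (`scipy.optimize.curve_fit` /
`least_squares`), unweighted unless the input carries per-point standard
deviations, with asymptotic standard errors from the parameter
covariance. Every estimator is exact on noiseless data generated from its
own model — the round-trip identity the test suite enforces at 1e-10 of
the signal span — and flags, rather than hides, pathological regimes
(constant signal, rate collapse, extrapolated K_d, unresolved slope).

* **Mono-/biexponential** — amplitude(s) and rate(s); the biexponential
  orders `k1 > k2`, flags near-collapse (`k1/k2 < 1.5`) and reports
  whether the slower phase dominates (the dark-recovery signature).
* **Consecutive two-step** (photoreversion then dissociation) — fits the
  downstream rate `k_o` with the photoreversion rate `k_q` held at its
  independently measured value (1.94 s⁻¹ for the PCM, 2.75 s⁻¹ for the
  extended receptor). The removable singularity at `k_o = k_q` is
  evaluated by its analytic limit (1 + k_q t)·exp(−k_q t). An estimate
  within 5% of the fixed `k_q` is flagged: the two steps are then
  kinetically indistinguishable and `k_o` is only a lower bound.
* **Pseudo-first-order** — weighted linear regression of observable rate
  on receptor concentration; slope = k_a, intercept = k_d. Because only
  the Pfr fraction (0.73 under red light for the PCM) can bind, the raw
  slope is divided by that fraction; K_d = k_d / k_a_corrected. A slope
  that is non-positive or within two standard errors of zero marks the
  association unresolved and reports the mean rate as k_d (the Pr-state
  situation). `fit_association_series` wraps the full workflow from raw
  pulse traces and discards the first second after light-off, about 2.5
  lifetimes of the fast transient from Pr-state complexes formed during
  the pulse; without that settle window the transient biases the slope
  by several percent.
* **Binding isotherm** — single-site law against total receptor; with the
  correction enabled, concentrations are first multiplied by the Pfr
  fraction so the fitted K_d refers to the binding-competent population
  (apparent 180 nM → corrected ≈ 131 nM).
* **Arrhenius** — log-space linear fit of ln k against 1/T by default
  (variance-stabilising for rates spanning decades); a direct nonlinear
  fit is selectable.
* **Two-state melt** — Boltzmann-weighted two-state signal with
  ΔG(T) = ΔH·(1 − T/T_m) (ΔCp = 0) and linear folded/unfolded baselines,
  initialised from the curve ends and the half-unfolded crossing.
* **Global multi-intensity fit** — the full ODE model fitted
  simultaneously to reporter-fluorescence traces at several red-light
  intensities, sharing one photoconversion coefficient (k_p scales
  linearly in intensity, k_p:k_q pinned at 0.73:0.27, k_aR pinned at 0),
  the three binding rate constants, and two signal amplitudes. The
  amplitudes enter the signal linearly, so they are profiled out inside
  the residual by bounded linear least squares (variable projection, with
  non-negativity and a data-scale cap that excludes degenerate
  compensating solutions); the four rate parameters are optimised in
  bounded log space by a Nelder–Mead warm start followed by a trust-region
  least-squares polish. `model="conventional"` freezes photoconversion
  inside the complex — the reduced scheme that cannot produce
  fluence-dependent attenuation and serves as the model-comparison foil
  (its residuals are ~100× larger on attenuated data).

  Identifiability caveat: `k_dR` is informed only by the attenuation it
  causes. On data generated without attenuation the estimate is an upper
  bound set by the noise floor (tenths of s⁻¹ at 0.5% noise), not a
  point recovery of zero. A low-intensity trace (1 mW cm⁻²), where the
  kinetics are photoconversion-limited, is what anchors the
  photoconversion coefficient; the four-intensity design recovers all
  four rates within a few percent at 1% noise.

## Hydrodynamics and FCS

Water viscosity uses the Vogel correlation
η = 0.02939·exp(507.88/(T − 149.3)) mPa·s, accurate to well under 1%
across 15–40 °C. Stokes–Einstein conversions are exact algebraic
inversions of D = k_B·T/(6πη·R_h). The Smoluchowski encounter rate
4π·N_A·(R₁+R₂)(D₁+D₂) is reported in two unit conventions because the
source material's printed magnitude (a few 10⁶ for these proteins) omits
the ×1000 m³→L conversion of the standard molar rate constant: the
`as_printed` mode reproduces that magnitude and is the mode in which the
9–12× encounter-to-association comparison is meaningful; `molar` carries
the full SI L mol⁻¹ s⁻¹ value. Both are always computed.

FCS correlograms use the standard single-component 3-D diffusion model
G(τ) = G0·(1 + τ/τ_D)⁻¹·(1 + τ/(γ²τ_D))⁻¹ᐟ², zero long-lag baseline
(one-baseline hardware curves are shifted on input), with the axial ratio
γ and lateral focal radius ω_r taken from instrument calibration
(γ = 9, ω_r = 250 nm for the 510-nm channel; γ = 6, ω_r = 304 nm for the
640-nm channel). D = ω_r²/(4τ_D) — the standard relation between
diffusion time and focal geometry. Detector after-pulsing is removed with
the count-rate-weighted uncorrelated-reference correction
G = G′ − (⟨i_ap⟩/⟨i⟩)(G_ap − 1), the reference interpolated log-linearly
in lag since curves are log-sampled. No triplet term and no photon-stream
(FLCS) processing: only corrected correlograms are modelled.

## Synthetic data

The generator produces every input type the estimators consume, each from
the same forward model the estimator assumes — except association traces,
which come from the full ODE model plus the affine observable map, so the
estimator chain is tested against the mechanism rather than against its
own simplification. Truth parameters travel in a sidecar metadata dict
(file on disk), never in the data table.

Defaults are the study conditions: preset rate constants verbatim from
the measured 15 °C interaction parameters (P6A, PIF6, P3A, PIF3 and the
extended receptor), 20 nM labelled partner, 0.5-s shutter pulses at
69 mW cm⁻² for association kinetics or 20-s continuous light for the
multi-intensity family (1/10/30/69 mW cm⁻²), 0.1-s sampling (the
instrument cadence), far-red dissociation from the consecutive model with
k_q = 2.4 s⁻¹, melting curves over 15–90 °C at 1 °C steps with
ΔH = 300 kJ mol⁻¹, and FCS lags log-spaced over 1 µs–1 s. Noise is
additive i.i.d. Gaussian scaled to the noiseless signal span (replicate
scatter is the only noise statistic the source reports); FCS fixtures
optionally scale σ by lag⁻¹ᐟ² to mimic correlator bin occupancy, and
rate-versus-temperature tables use multiplicative log-normal noise since
rates span decades. Replicate experiments are emulated as three seeds per
condition, matching the triplicate design of the measurements.

What the generator does *not* emulate — instrument drift, photobleaching,
the weak probe-light photoactivation (representable as a constant dim red
segment but off by default), heteroscedastic detector noise, pipetting
error in concentration series — bounds what green tests mean: they
demonstrate correct estimators and a self-consistent model, not
robustness to every artefact of real instruments.

## Numerical choices and limitations

* Steady-state root: Brent bracketing on [0, P0], xtol at machine scale;
  the linear subsystem falls back to least squares if exactly singular.
* ODE: LSODA, rtol 1e-8/atol 1e-16 M for simulation; the global fit uses
  rtol 1e-7 for speed (the difference is far below the noise floor).
* Steady-state-by-integration oracle: chunk-doubled integration stopping
  when the state change per chunk falls below 1e-9 (configurable) of the
  total concentration scale.
* Exponential fits initialise rates from the 1−1/e crossing time;
  melt fits initialise baselines from the outer deciles of the curve.
* Degenerate inputs (constant traces, flat concentration dependence,
  no melting transition, non-decaying correlograms) return flagged
  results rather than raising, since all occur in real campaigns.
* Problem sizes in the test suite (trace lengths of 10²–10³ points,
  100-draw equivalence sweeps, 300-replicate error-calibration runs) were
  chosen to exercise the estimators at realistic data volumes while
  keeping the whole suite around a minute on one core.
* The dose-response engine treats the photostationary state as fully
  reached; transient protocols belong to `simulate`. Inner-filter
  effects, receptor dimerisation and photostate heterogeneity are out of
  scope throughout.
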