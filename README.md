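# phypif

Kinetic modelling and estimation of light-driven phytochrome–PIF
interaction dynamics.

Plant phytochromes such as *Arabidopsis* PhyB interconvert between a
red-absorbing Pr state and a far-red-absorbing Pfr state; only Pfr binds
phytochrome-interacting factors (PIFs), the transcription factors that
relay the light signal. Because the Pr and Pfr spectra overlap, red light
drives *both* directions of the photoconversion, so the Pr:Pfr ratio under
constant red light is fixed (≈0.27:0.73 for the PhyB photosensory core
module) while the cycling speed grows linearly with intensity. A complex
that transiently visits the Pr state dissociates fast, and at high
intensity this light-driven cycling outruns re-association — so stronger
light can *deplete* the PhyB:PIF complex even though the Pfr level never
changes. `phypif` implements the five-species kinetic model of this
mechanism, its closed-form photostationary state, the estimator suite
used on time-resolved fluorescence/absorbance, titration, Arrhenius,
CD-melting and FCS data, and a seeded synthetic-data generator so that
every estimator is verifiable by parameter recovery without any external
data.

The core model couples photoconversion and binding:

    Pr   ⇌(k_p, k_q)  Pfr            photoconversion, ∝ light intensity
    Pfr + P ⇌(k_aFR, k_dFR) Pfr:P    strong binding of the active state
    Pr  + P ⇌(k_aR≈0, k_dR) Pr:P     fast escape out of the ground state
    Pr:P ⇌(k_p, k_q) Pfr:P           the complex photoconverts too

as mass-action ODEs for [R], [FR], [RP], [FRP], [P] with receptor and PIF
mass conservation. The photostationary state is obtained in closed form
(linear reduction of the receptor subsystem plus a bracketed root for
free PIF) and cross-validated against the numerical long-time limit.

Audience: photoreceptor biophysicists and optogenetics tool builders who
need to predict complex formation as a function of light intensity,
temperature and interaction kinetics, or to extract rate constants from
the corresponding measurements.

## Worked example

```python
import numpy as np
from phypif import (RateConstants, SystemComposition,
                    solve_photostationary, dose_response)
from phypif.synthetic import PRESETS

rates = PRESETS["P6A"].rate_constants()   # measured 15 °C parameters
mix = SystemComposition(R0_total=1e-6, P0_total=20e-9)

weak = solve_photostationary(rates, mix, 1.0)    # 1 mW/cm² red light
strong = solve_photostationary(rates, mix, 69.0)
print(f"bound PIF fraction at  1 mW/cm2: {weak.bound_fraction():.3f}")
print(f"bound PIF fraction at 69 mW/cm2: {strong.bound_fraction():.3f}")
print(f"Pfr fraction (both): {weak.pfr_fraction:.3f} / {strong.pfr_fraction:.3f}")

curve = dose_response(rates, mix, np.geomspace(0.01, 100, 40))
print(f"peak bound fraction {curve.peak_height:.3f} at "
      f"{curve.peak_intensity:.2g} mW/cm2; attenuation onset "
      f"{curve.attenuation_onset:.2g} mW/cm2")
```

prints

```
bound PIF fraction at  1 mW/cm2: 0.750
bound PIF fraction at 69 mW/cm2: 0.413
Pfr fraction (both): 0.730 / 0.730
peak bound fraction 0.798 at 0.01 mW/cm2; attenuation onset 2.3 mW/cm2
```

Read: at 1 µM receptor and 20 nM PIF reporter, 75% of the PIF is in
complex under weak red light but only 41% under strong light — even
though the receptor's Pfr fraction is 0.730 in both cases. That is the
attenuation mechanism: the depletion comes from fast cycling through the
dissociation-prone Pr state, not from any change in photoequilibrium.
The dose–response summary says the curve is flat up to ~1 mW/cm² and has
lost 10% of its peak by ≈2.3 mW/cm² under these concentrations.

The same library surface drives the estimators, e.g. recovering the
bimolecular association rate constant from a synthetic shutter-pulse
concentration series:

```python
from phypif import estimators as est
from phypif.synthetic import GeneratorSpec, generate

traces = {}
for i, conc in enumerate((500e-9, 1000e-9, 1500e-9, 2000e-9)):
    ds = generate(GeneratorSpec("association_trace", noise_sd=0.01, seed=i,
                                params={"receptor_M": conc, "pulse_s": 0.5}))
    traces[conc] = ds.data
fit = est.fit_association_series(traces, pfr_fraction=0.73)
print(f"k_aFR = {fit.k_a_corrected:.2e} M-1 s-1, K_d = {fit.K_d*1e9:.0f} nM")
```

A command-line interface mirrors the library
(`phypif simulate|steady-state|dose-response|fit|synth|suite`); all
tabular I/O is plain CSV with units in the column names, and every run
writes a manifest (config digest, seed, version) sufficient to reproduce
it.

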