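# opsinspec

Spectral analysis of **bistable visual pigments** — opsins whose dark
(11-*cis*-retinal) and metarhodopsin (all-*trans*-retinal) states are both
thermally stable and photo-interconvertible, such as the *Drosophila*
circadian photoreceptor Rh7, parapinopsin, or Opn5.

For such pigments the metarhodopsin cannot be isolated: every measured
spectrum is a mixture of the two states at some photosteady fraction.  The
toolkit implements the standard inference chain used to characterize them
from cuvette spectrophotometry, plus the simulators needed to validate
every stage on data with known ground truth:

1. **Template curves** (`opsinspec.templates`) — visual-pigment nomogram
   absorbance curves parameterized by a single λmax, using the
   exponential-sum alpha band

   S(x) = 1 / (e^{A(a−x)} + e^{B(b−x)} + e^{C(c−x)} + D),   x = λmax/λ,

   with a λmax-dependent exponent offset *a* and an optional Gaussian beta
   band.  Families: `a1_pigment`, `metarhodopsin_like`, `retinochrome_like`.
2. **State reconstruction** (`opsinspec.reconstruction`) — fit the
   long-wavelength flank of a photoconversion difference spectrum with
   amplitude·template(λmax) + baseline (the UV-absorbing dark state does not
   absorb there), then recover the dark state by the exact identity
   *original = irradiated + (original − irradiated)*.
3. **Composite decomposition** (`opsinspec.composite`) — nonnegative
   two-template decomposition of unusually broad absorption bands by
   exhaustive λmax grid search, with BIC-based choice between one and two
   components.
4. **Photosteady-state simulator** (`opsinspec.photosim`) — forward
   simulation of a bistable pigment under idealized bench filters
   (UV band, blue band-pass, >500/>550/>575 nm long-pass), with
   f_meta = k_fwd/(k_fwd+k_rev) at steady state, seeded noise and baseline
   drift.  Ships a synthetic Rh7-like fixture (broad composite dark band,
   510 nm metarhodopsin at 8× amplitude).
5. **HPLC isomer quantification** (`opsinspec.hplc`) — Gaussian peak
   detection/integration of retinaloxime chromatograms (A360 vs retention
   time) into 11-*cis* / 13-*cis* / all-*trans* fractions, with a matched
   trace simulator.
6. **G-protein activation rates** (`opsinspec.gprotein`) — initial-rate
   estimation from GDP/GTPγS exchange time courses and per-condition
   summaries (dark / UV / subsequent yellow) with fold changes vs dark.

## Worked example

The `demo` subcommand runs the whole loop on the synthetic Rh7-like
fixture: simulate the dark → UV → yellow → UV → yellow protocol to
photosteady states, compute difference spectra, reconstruct both states,
decompose the reconstructed dark state, quantify matched chromatograms and
G-protein time courses:

```sh
$ opsinspec demo --seed 7 -o demo_out
meta lambda_max = 510.0 nm; composite = 360 nm, 415 nm; gq ordering = uv > yellow > dark
```

`demo_out/report.txt` then reads:

```
[reconstruction]
  meta lambda_max   : 510.03 nm (true 510 nm)
  meta amplitude    : 0.7091 AU
  fit rmse          : 2.854e-03 AU
  regen residual    : 7.123e-03 AU

[composite decomposition of the dark state]
  n components      : 2
  lambda_max        : 360.0 nm, 415.0 nm
  weight shares     : 0.655, 0.345
```

Reading: the fitted metarhodopsin λmax (510.03 nm) recovers the simulated
truth (510 nm) to within the noise; its amplitude (0.709 AU) is the 0.8 AU
state spectrum scaled by the net UV→yellow conversion (~0.886); the
positive photoregeneration residual reflects the 2% all-*trans*
contamination built into the fixture; and the reconstructed dark state
decomposes into the two templates (360/415 nm at 0.65:0.35) it was built
from.  `demo_out/report.json` holds the same numbers machine-readably and
is byte-identical across reruns with the same seed.

Library use mirrors the CLI:

```python
from opsinspec import reconstruct_bistable_pair, read_spectrum

res = reconstruct_bistable_pair(
    read_spectrum("dark.tsv"),
    read_spectrum("after_uv.tsv"),
    read_spectrum("after_yellow.tsv"),
)
print(res.irradiated_fit.params.lambda_max, res.irradiated_fit.amplitude)
```

Other subcommands: `template`, `reconstruct`, `decompose`, `simulate`,
`hplc`, `gq-rates` (`opsinspec COMMAND --help` for options).  Spectra are
two-column delimited text (wavelength nm, absorbance AU); chromatograms are
(minutes, AU); time courses are (time_min, signal, condition[, replicate]).

## Scope notes

Vendor binary instrument formats, scattering/turbidity corrections,
photocascade intermediates, A2 (3,4-dehydroretinal) templates and >2
composite components are out of scope.  See `docs/methods.md` for the
model, parameter defaults, numerical choices and limitations.
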