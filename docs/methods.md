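# Methods

## Model and assumptions

A bistable pigment is modeled as two interconvertible species — a dark
state D (11-*cis* chromophore) and a metarhodopsin M (all-*trans*) — with
absorbance spectra ε_D(λ), ε_M(λ) on a common wavelength grid.  Under
irradiation with spectral intensity I(λ) the metarhodopsin fraction f obeys
the two-state photokinetic rate equation

    df/dt = k_fwd (1 − f) − k_rev f,
    k_fwd = Σ_λ I(λ) ε_D(λ) φ_fwd,    k_rev = Σ_λ I(λ) ε_M(λ) φ_rev,

whose long-time limit is the photosteady state f* = k_fwd/(k_fwd+k_rev).
Assumptions: optically thin sample (absorbed photons ∝ absorbance; no
inner-filter effect — standard for AU ≪ 1 cuvette work), no thermal
reversion between the states on the experimental timescale, and ideal
top-hat filter transmissions.  Every measured spectrum is a convex mixture
(1−f)·ε_D + f·ε_M plus additive Gaussian noise and an optional random
linear baseline per measurement.

All fitting happens on a canonical 1 nm grid from 250 to 700 nm, covering
the usual 300–650 nm observation window with margin.  Absorbances are
relative (arbitrary units); no pathlength or concentration handling.

## Template curves

The alpha band uses the exponential-sum visual-pigment template
(Govardovskii et al. 2000, A1 form): with x = λmax/λ,

    S(x) = 1 / (exp(A(a−x)) + exp(B(b−x)) + exp(C(c−x)) + D),
    a(λmax) = 0.8795 + 0.0459 · exp(−(λmax−300)² / 11940),

normalized so the alpha-band maximum equals 1 (peak found by bounded
scalar optimization to xatol 1e-10).  The beta band is the Gaussian
satellite at 189 + 0.315·λmax nm, width −40.5 + 0.195·λmax nm, amplitude
0.26 of the alpha peak.

Family shape constants (package defaults; all overridable per call via
`shape_overrides`, including pinning `a` to remove its λmax dependence):

| family              | A    | B    | C     | D     | b     | c     |
|---------------------|------|------|-------|-------|-------|-------|
| a1_pigment          | 69.7 | 28.0 | −14.9 | 0.674 | 0.922 | 1.104 |
| metarhodopsin_like  | 64.0 | 26.0 | −14.9 | 0.674 | 0.922 | 1.104 |
| retinochrome_like   | 60.0 | 26.0 | −14.9 | 0.684 | 0.922 | 1.104 |

The photoproduct families keep the published functional form with slightly
smaller flank exponents, giving the broader band expected of meta-I-like
and retinochrome-like photoproducts while remaining a λmax-shiftable,
fixed-shape basis.  The published constants for those specific proteins are
not parameterized in the primary literature this form comes from; the
values above are this package's defaults and are the thing to override when
better constants are available.  3-hydroxyretinal pigments use the same
families (their spectra are nearly indistinguishable from retinal pigments
at this resolution).  The broadened families peak within ~2 nm of the
nominal λmax (the exponential sum's maximum is near, not exactly at, x=1);
curves are normalized to a maximum of 1 regardless.

Beta-band policy: red-flank metarhodopsin fits and the reconstructed
metarhodopsin spectrum use the alpha band only — the fit window lies
hundreds of nm from the beta satellite, so the data cannot constrain it,
and carrying an unconstrained beta band into the reconstruction would
corrupt the reconstructed dark state in the UV.  Dark-state simulation and
composite decomposition (which extend into the UV) include the beta band.

## State reconstruction

Input: a difference spectrum oriented so the metarhodopsin appears as the
positive lobe.  Model: amplitude·template(λmax) + constant baseline, fitted
by unweighted least squares inside a window on the long-wavelength flank,
where the dark state does not absorb.  λmax is found by 1 nm grid search
over 380–650 nm (amplitude and baseline solved in closed form at each
node), followed by parabolic refinement on the three best nodes; ties break
toward lower λmax, making the optimum deterministic.  A constant baseline
is co-fitted by default because real photobleaching series show unsteady
baselines.  The automatic window rule places the lower edge 10 nm red of
the positive-lobe maximum and the upper edge at the last point where
|signal| exceeds 3× a robust noise estimate (1.4826·MAD of successive
differences / √2).

The dark state then follows from original = irradiated + (original −
irradiated), an identity the code preserves to machine precision; negative
reconstructed values are allowed but flagged.  For a full forward/back
cycle (dark → UV → yellow) the back-conversion difference is used, and the
RMS of (after-yellow − dark) is reported as the photoregeneration residual:
zero for a fully reversible cycle, positive when all-*trans* contamination
over-regenerates the dark state.

## Composite decomposition and model selection

One- or two-template nonnegative decomposition over a 330–500 nm λmax grid
at 1 nm, with a 15 nm minimum component separation (closer pairs are not
distinguishable from one template at realistic noise).  At each λmax pair
the two weights are solved by closed-form active-set NNLS (exact for two
variables), so the search is exhaustive and vectorized; the returned node
is globally optimal on the grid, with ties broken toward lower λmax.  The
final RSS is recomputed from the residual vector because the quadratic-form
shortcut cancels catastrophically on near-perfect fits.

Model order is chosen by BIC from Gaussian residuals, k = 2·n_components+1
(λmax and weight per component, plus σ), with RSS floored at n·1e−30 so
noise-free fits do not hit log(0) and ties go to the simpler model.  BIC
rather than an AIC-style 2k penalty: the exhaustive λmax search makes the
effective flexibility of the second component larger than its nominal two
parameters, and the ln(n) penalty absorbs that — with a 2k penalty a
spurious second component is selected on a noticeable fraction of noisy
single-template inputs.

## Synthetic-data generators

The simulators define the study conditions the tests run under.

*Photosimulator.*  Bench filter set encoded as ideal top-hats: UV 330–390
nm, blue 440–460 nm, long-pass >500 / >550 / >575 nm.  Quantum yields
default to equal (never measured for these pigments; exposed as
parameters).  Measurement noise defaults to σ = 0.002 AU additive Gaussian;
baseline drift is a per-measurement random linear ramp with σ given in AU
per 100 nm (default 0).  One seeded generator per run.

The Rh7-like fixture is synthetic, not measured truth: dark state =
0.65·T(360) + 0.35·T(415) with beta bands, scaled to a peak of 0.1 AU;
metarhodopsin = T(510, metarhodopsin_like) at 0.8 AU, i.e. 8× the dark
peak, reproducing the characteristic ~1:8 UV:visible difference-amplitude
ratio of a UV pigment with a strongly absorbing photoproduct.  The fixture
metarhodopsin carries no beta band: a full-strength beta satellite on an
8×-amplitude photoproduct would exceed the weak dark band near 350 nm and
flip the sign of the UV difference lobe, contradicting the sign pattern
such pigments actually show.

*Chromatogram simulator.*  Sum of Gaussians (σ = 0.1 min) at synthetic
retention times on a 3–15 min grid sampled every 0.01 min; syn:anti oxime
split defaults to 70:30 per isomer; equal molar extinction across species
(a corrections hook exists).  Retention times are package fixture values,
not measured data.

*Time-course simulator.*  Linear early-phase signal with a small constant
background and seeded Gaussian noise scaled to 5% of the full-scale signal;
per-condition rates for the demo are dark 0.1, UV 1.0, yellow 0.3
signal/min — the qualitative pattern of a Gq-coupled bistable pigment whose
metarhodopsin is the active state.

What the generators do *not* emulate, hence what passing tests do not show
about real data: wavelength-correlated instrument noise, real (sloped)
filter transmission curves, inner-filter effects at high absorbance,
detergent scattering backgrounds, tailing/asymmetric chromatogram peaks,
and radioactivity counting statistics.

## HPLC quantification

Rolling-minimum baseline subtraction (window 201 samples ≈ 2 min at the
default sampling — several peak widths; a window narrower than a peak
subtracts the peak itself).  Detection by prominence on a Savitzky–Golay
smoothed copy (window 2·min_width+1, order 2) so noise cannot split a peak
top, with a minimum width of 5 samples; integration then jointly fits a
sum of Gaussians plus a constant offset to the *raw* baseline-corrected
trace (the offset absorbs the ~3σ pedestal that rolling-minimum subtraction
leaves on noisy data), each component confined to ±3σ₀ of its detected
position.  Areas are amplitude·σ·√(2π); fractions are extinction-corrected
area shares; peaks more than 0.8 min from any expected retention time that
carry >1% of total area raise an error naming their retention time.

## G-protein rates

Models: line through the origin, line with intercept (default, first 5
points — the near-linear early phase; the intercept absorbs filter
background), and saturating exponential A(1−e^{−kt}) whose initial rate is
A·k with a delta-method standard error.  Condition summaries report the
across-replicate mean ± SE (0 for a single replicate) and fold change
versus the required "dark" reference.  Signals are arbitrary linear units
throughout.

## Numerical choices and tolerances

- Template peak normalization: bounded minimization, xatol 1e-10; template
  banks cached per (λ list, grid, family, beta) for repeated fits.
- Grid-search ties: `argmin` takes the first (lowest λmax) node.
- Parabolic refinement is accepted only if it does not increase the RSS.
- Degenerate inputs raise typed errors (`opsinspec.errors`): all-zero
  spectra, windows with <10 points, rank-deficient windows, sources that
  overlap neither state, missing dark reference, <3 time points.
- Problem sizes in the shipped tests and acceptance script — 200 Monte
  Carlo replicates for λmax recovery, 100 seeds per model-selection case,
  50 chromatogram seeds, 100 G-protein orderings, 10 ODE cross-checks —
  are the sizes at which the binomial success criteria (≥95%) are
  meaningful while the whole suite stays fast.

## Known limitations

- Family shape constants for meta-I-like and retinochrome-like bases are
  package defaults, not protein-specific fits.
- The thin-sample assumption breaks above ~0.3 AU; no inner-filter
  correction is applied.
- Reconstruction assumes exactly two interconverting states; photocascade
  intermediates are out of scope.
- Composite decomposition is limited to two components and assumes the
  input is baseline-free and nonnegative up to noise.
- The BIC selection threshold was characterized at σ ≈ 0.002 AU on
  unit-scale spectra; far noisier data may need the separation guard or the
  search range tightened.
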