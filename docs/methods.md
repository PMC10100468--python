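# Methods

## Quantification model

The assay is absolute internal-standard qNMR: the analyte's integral ratio
against a weighed calibrant is converted to mass through nuclei counts,
molecular weights and purities,

    m_a = (I_a / I_c) · (N_c / N_a) · (m_c / MW_c) · MW_a · (p_c / p_a).

The implementation is exactly linear in the ratio and in the calibrant
mass; negative ratios are rejected as degenerate spectra rather than
clipped, because a negative analyte integral means the integration windows
or the spectrum are wrong, not that the vial holds negative drug.

Defaults describe the CBD/naphthalene assay: N_c/N_a = 4/1 (naphthalene's
four equivalent aromatic protons at 7.48 ppm vs CBD's one olefinic proton
at 5.57 ppm), MW 128.17 vs 314.47 g/mol, both purities 0.99, and a
calibrant mass of 10 mg for whole-patch vials or 1 mg for Franz-disc vials.
Integration windows default to ±0.10 ppm around each centre; only the
centres are physically fixed, the half-width is a package choice sized to
capture ≥ 93% of a 0.01-ppm-wide Lorentzian while staying clear of the
other resonance.

Disc-to-patch scaling multiplies by the area ratio (10-mm disc = 0.785 cm²)
and assumes uniform areal drug loading; real patches can deviate from this,
so reports carry it as a stated assumption rather than a correction.

Label accuracy uses the signed symmetric percent difference,
100·(determined − labeled)/((determined + labeled)/2), judged against a
±10% margin with the boundary inclusive (ties are "correct" — the stricter
reading of an "acceptable margin"). Tabulated differences round to the
nearest integer, half away from zero; the data model keeps full precision.

## Integration

Window integrals are trapezoidal sums over the points inside the window
(≥ 4 required). The `linear_endpoints` baseline subtracts the straight line
through the mean of the three outermost points at each edge, which removes
constant and linear backgrounds exactly and is robust to edge noise;
anything beyond a linear baseline (phasing, polynomial correction, peak
deconvolution) is out of scope. No Lorentzian-tail truncation correction is
applied: when the analyte and calibrant windows have the same
width-to-linewidth ratio the truncated tail fraction is identical and
cancels in the ratio. With unequal linewidths a small ratio bias remains —
a documented approximation, not corrected.

## Synthetic data

The generator emulates what the spectrometer would deliver, not how it
works: frequency-domain spectra as sums of pure Lorentzians
(2A/π)·w/(4(δ−δ₀)² + w²) on an optional linear baseline, with additive
Gaussian noise. Pure Lorentzians keep a closed-form window mass
(A·(2/π)·arctan(2k) within ±k·FWHM) that the integration tests check
against. Defaults: 16,384 points over 0–10 ppm and 0.01-ppm linewidths.
Multiplicity is not simulated — each quantified signal is one lumped
resonance, matching the single integration region used per compound. FID
simulation, apodization, phasing and vendor formats are out of scope.

Franz-cell series mimic the study design in which each time point is an
independent punched disc: the default schedule is 4, 12, 24, 36, 48 h, the
analyte resonance area at each time is proportional to the mass remaining
under a chosen kinetic law (inverting the assay equation, so quantification
of a noiseless spectrum returns the truth exactly up to integration error),
the calibrant area is held fixed, and noise is multiplicative on the
analyte area — integral errors scale with peak size. Released percentages
outside [0, 100] are clipped and flagged in the returned truth. What the
generator does *not* emulate: overlapping matrix resonances, baseline
drift/phase errors, membrane binding, or inter-disc loading variability —
so passing tests validate the analysis chain, not robustness to every real
spectrum.

Simulation sizes used by the test and acceptance suites (2,048–16,384
points per spectrum; 100–200 Monte-Carlo repetitions at 2–5% relative
noise) were chosen to give sampling errors well below the asserted
tolerances.

## Release profiles

Released mass is initial − remaining (the only sign consistent with a
cumulative release curve), release percent is relative to the t = 0 qNMR
determination, and release per area divides by the disc area since each
Franz specimen is a disc (whole-patch reporting is configurable).
Replicates at the same nominal time are averaged with the sample sd kept
for error bars. Negative released values from measurement noise are
retained and flagged, never silently clipped, because dropping them would
bias early-time fits. t = 0 never appears as an observation — it is carried
as m0, which keeps logarithmic transforms downstream well-defined.

## Kinetic fitting

All four models are fitted as straight lines on their transformed
coordinates with an intercept, and r² is the squared Pearson correlation of
the transformed pairs (base-10 logs; the base does not affect r²). Points
with release% ≤ 0 are dropped for logarithmic transforms, and ≥ 100%
additionally for Weibull (log of a non-positive argument); drops are
counted and surfaced. Fewer than 3 usable points or zero variance in x
raise typed errors rather than returning a meaningless fit.

Choices where the design was genuinely open:

* **Higuchi intercept.** The textbook form Q = K_H·√t has no intercept, but
  a free intercept is the default here: release data with a finite first
  sampling time routinely show a nonzero offset, and depletion
  extrapolation from a forced-zero intercept would be inconsistent with the
  fitted line actually drawn through the data. `higuchi_intercept="zero"`
  restores the textbook form.
* **First-order transform.** The literal tabulated linearization regresses
  log(release%) on t, although conventional first-order kinetics would use
  the log of the *remaining* percentage. The literal form is the default
  (it is what the tabulated r² compares), and `convention="remaining"`
  exposes the conventional variant.
* **Weibull form.** Q = 100·(1 − e^(−α·t^β)), fitted by the double-log
  linearization log(−ln(1 − Q/100)) vs log t — the standard
  dissolution-analysis procedure; β is the shape (transport mechanism
  indicator) and α the scale.
* **Selection.** Best model = highest r²; ties within 10⁻⁶ go to the
  simpler/mechanistic model (zero order, then Higuchi, then first order,
  then Weibull). No AIC/BIC — the comparison metric is r² by design, and
  all linearized fits have two parameters anyway.

The rate summary reports K_H as the release rate (%/h^0.5) and
t = ((100 − c)/K_H)² as the extrapolated time of complete release; it
requires a positive slope and an intercept below 100%.

## Numerical notes and limitations

* Trapezoidal integration error is O(Δδ²) in the grid spacing; the default
  grid resolves the default linewidth with ~16 points per FWHM, giving
  window-mass errors ≪ 0.5%.
* Determinism: every stochastic path flows from an integer seed through
  `numpy.random.default_rng`; equal seeds give bitwise-equal spectra.
* Spectrum CSVs round-trip at ≥ 9 significant digits (`%.12g`).
* Linearized (rather than nonlinear least-squares) fitting matches the
  tabulated graphical representations but weights errors on the
  transformed scale; for strongly heteroscedastic data a nonlinear fit
  would differ. This is intentional and documented, not a limitation to be
  fixed silently.
* The package quantifies a single analyte against a single calibrant;
  multi-analyte deconvolution, purity determination, and receptor-medium
  or membrane-transport modeling are out of scope.
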