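# Methods

## The quantification problem

The assay determines 25 ginsenosides in one 25-minute UPLC gradient with
negative-mode Orbitrap detection. Full-scan data quantify each analyte on
its theoretical [M−H]⁻ channel; data-dependent MS/MS spectra identify
compounds through glycosidic neutral-loss ladders. Because authentic
standards for every saponin are rarely available, the package implements —
alongside conventional external-standard calibration — single-marker
quantification (QAMS): one reference standard (Rb2) plus a table of
relative response factors replaces 24 calibration curves.

For analyte *x* and reference *s*,

    Fx = (As/Cs) / (Ax/Cx)          (response-factor definition)
    Cx = Ax / (As/Cs) · Fx          (single-marker quantification)

with Fx averaged over working levels of 10, 20, 50, 100 and 200 ng/mL.
Substituting one equation into the other shows that for strictly
proportional response (area = m·C) QAMS is algebraically identical to ESM;
every deviation between the two on real data comes from non-proportionality
and measurement noise. The package therefore treats *exact equivalence on
proportional noise-free data* as a machine-checkable invariant, and the
standard method difference SMD% = |C_ESM − C_QAMS|/C_ESM·100 as the
statistic of interest under noise.

## Synthetic data model

No raw data from the original study exist publicly, so every stage is
exercised on generated runs whose statistical structure matches what the
analysis assumes:

* **Peak shape.** Gaussian, σ = 0.05 min by default (a plausible UPLC peak
  width; only relative areas matter to either quantification route). Peak
  area is the quantity with physical meaning; apex height is area/(σ√2π).
* **Response.** True area per analyte follows its calibration law. The
  generator refuses nonpositive predicted areas rather than emitting
  unphysical chromatograms. The library's *proportional* variant (all
  intercepts zero) is the default working model — see "Known data issues".
* **Dispersion.** A mean-one lognormal factor with coefficient of variation
  `area_cv` (default 0.02 in noisy studies, matching the reported
  repeatability RSDs of ~1–4%) multiplies each true area; additive Gaussian
  baseline noise with `baseline_sd` counts supports S/N and LOD/LOQ work. A
  constant baseline offset of 6·`baseline_sd` keeps the clipped-at-zero
  trace from truncating the noise distribution.
* **Channels.** Exactly isobaric analytes (eight isomer groups among the 25
  standards) share one [M−H]⁻ channel and are separated only in time, as on
  the instrument.
* **Seeding.** One master seed; per-analyte and per-channel substreams are
  derived from stable name hashes, so adding an analyte to a library never
  perturbs the signals of the others, and repeated generation is
  bit-identical.
* **Replication.** Solutions are injected in sextuplicate and mean areas
  used for calibration and response factors, mirroring the assay's n = 6
  design. Validation metrics use the individual replicates.

What the generator does **not** emulate: isotope envelopes, chimeric MS/MS,
retention-time drift beyond a uniform stretch (`rt_scale`), detector
saturation, or matrix interferences. Passing tests therefore demonstrate
the correctness of the computational method, not robustness to those
instrumental effects.

## Peak measurement

XICs are integrated by trapezoid on the baseline-subtracted trace.
The apex is the window maximum; peak height uses a five-point centred
average (a raw arg-max overstates height at low S/N). Bounds descend from
the apex until the trace falls below baseline + 3·noise, or until it turns
back upward while already below 5% of the peak height (the valley toward a
neighbouring isobar). In pipeline use, each analyte's ±4σ window is clipped
at the midpoint toward any same-channel neighbour, so the closest pairs
(G75/Rg3, 5.2σ apart) cross-contaminate by well under 1% — and because that
truncation is the same linear factor in standards and samples, it cancels
exactly in both quantification routes. Baseline is the median outside the
window; noise is the standard deviation of the median-subtracted baseline
(≥ 20 points). S/N = height/noise; LOD and LOQ are the concentrations whose
predicted height reaches 3 and 10 noise, so LOQ/LOD = 10/3 by construction
(the originally printed pairs deviate from that ratio by rounding and are
not asserted). Relative retention time t_Rk/t_Rs (invariant under uniform
time rescaling) locates peaks across condition variants; ties go to the
nearer ratio, then the larger area.

## Statistics

RSDs use the n−1 sample standard deviation — the estimator that reproduces
the published response-factor table arithmetic (e.g. the 0.32/0.30/0.31/
0.30/0.30 series gives exactly 2.92%). Relative error is reported unsigned.
Calibration is unweighted OLS (a 1/x weighting exists but is off by
default); with a proportional response model the fit is constrained through
the origin — fitting a free intercept to proportional data and then
extrapolating below the lowest level amplifies intercept noise into >100%
concentration error at trace levels, which is a property of the model
mismatch, not of either quantification route. r² is the squared Pearson
correlation of observed and fitted areas. Report tables round half-up to
two decimals; all internal arithmetic is full precision.

## Annotation

Identification reduces to integer decomposition: which multiset of residue
masses (hexose, deoxyhexose, pentose — the three pentoses are isobaric and
collapsed to "Pen" — and glucuronosyl) connects a precursor to an aglycone
[M−H]⁻ within tolerance (5 ppm theoretical-vs-theoretical, 10 ppm against
measured values; ion m/z include the electron mass, without which printed
values are missed by ~2 ppm). Two subtleties:

* **Isobaric backbones.** PPT + Glc + Rha and PPD + 2 Glc have identical
  formulas (likewise PPT + 2Glc + Rha vs PPD + 3Glc, and others), so
  precursor mass cannot decide the backbone. Candidate paths are ranked by
  absolute mass deviation (bucketed at 0.1 mDa so formula-exact ties stay
  tied), then paths whose terminal aglycone ion actually appears in the
  observed MS/MS fragments win; remaining ties prefer fewer residues, then
  fewer residue kinds (ginsenoside sugar chains are predominantly glucose),
  then the alphabetically first backbone. This reproduces the published
  9 PPT / 23 PPD / 3 OA classification compound-for-compound, including the
  three compounds whose printed ladders stop above the aglycone.
* **Isobaric positional isomers.** CK/Rh2, Rg3/G75/F2 and Mc/CY/CMx share
  formula *and* loss ladder; only retention time separates them. Spectrum
  annotation therefore scores ladder coverage first and breaks ties by
  retention-time proximity when the spectrum carries one. Coverage < 0.5
  flags an annotation low-confidence. Dehydrated ginsenosides (Rg6, F4,
  Rh4, Rk3, Rk1, Rg5) match no path by default and classify as "other"; an
  `allow_h2o` switch extends the search by one water loss to recover them
  as modified backbones.

## Known data issues in the published constants

* Several printed calibration lines cannot be literal area laws: Rb2
  (slope 20778.7, intercept −36514.3, range 0.01–1 µg/mL), Rg2, Rd and PPD
  predict negative peak areas across their entire stated ranges, and Rb2 is
  the QAMS internal reference. The package keeps the printed constants in
  its library for the table arithmetic they support, but pipeline runs use
  the proportional (zero-intercept) variant; driving the generator with the
  printed intercepts raises an explicit error, and the corresponding
  noisy-equivalence check fails and is documented as failing.
* Three printed [M+HCOO]⁻/[M−H]⁻ pairs (F1, F2, CMx) differ from the HCOOH
  mass by 4.2–5.8 mDa, outside the 3 mDa band the pair check asserts; the
  check is left failing rather than widened. Two rows (Rk3, Rh4) print
  [M−H]⁻ values ~85 mDa off their formulas and are excluded as typos, and
  the printed Rh2 formula is replaced by the m/z-consistent C36H62O8.
* Some published SMD values cannot be recomputed from the published
  (rounded) concentration pairs; only the self-consistent rows are
  asserted.

## Problem sizes

Default study conditions: 25 analytes, 5 response-factor levels ×6
injections, 9 calibration levels ×6 injections, 6 replicates per validation
metric, 20 seeds for the envelope study, 5 Hz sampling over the ~21.5 min
window. The full suite runs in well under a minute on one core.
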