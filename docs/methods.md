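# Methods

This note records the models implemented in `fpcrevise`, the conventions and
defaults chosen where several were defensible, and what the synthetic tests
do and do not establish about real data.

## Fingerprint PCA and misassignment flagging

The fingerprint is a fixed 12-slot vector: ¹³C shifts at the phloroglucinol
core positions C-1…C-6 and the carbonyl carbons C-7/C-9, plus up to two
aldehydic and two phenolic ¹H shifts, all in CDCl₃. Validation bounds are
0–230 ppm (¹³C) and 0–20 ppm (¹H), with at least 6 of 12 slots required.

*Imputation.* Compounds with a single aldehyde or phenol leave the second
proton slot empty; missing cells are replaced by the column mean over
observed values (zero-fill would plant values far outside chemical ranges
and distort the PCA). The imputation mask is retained for reporting.

*PCA.* Columns are mean-centered and, by default, divided by the population
standard deviation (ddof = 0); without autoscaling the 0–230 ppm carbon
scale would dominate the 0–20 ppm proton scale. Loadings are eigenvectors of
the sample covariance (ddof = 1) of the processed matrix, eigenvalue-ordered,
with each loading's largest-magnitude element made positive so scores and
plots are reproducible across runs and libraries. The implementation is a
direct symmetric eigendecomposition and is cross-checked against
scikit-learn's PCA in the test suite.

*Classification.* Nearest class centroid by Euclidean distance in the first
k = 2 components (matching the PC1/PC2 visual analysis such screens are
based on; k is configurable). Ties break lexicographically on the class
label. Classes with fewer than two members remain usable but carry a warning
in the distance table.

*Flagging.* A compound is flagged when its PCA-nearest class differs from
its reported class, or when some slot lies more than a threshold outside the
reported class's empirical (min, max) range, built per (class, slot) from
slots with ≥3 observations. The default threshold is 1.0 ppm — the smallest
deviation treated as diagnostic for these compound classes, where reported
misassignments show per-position deviations of roughly 1–13 ppm.

## Conformer-ensemble post-processing and DP4+

Inputs are per-conformer relative energies (kcal/mol; kJ/mol accepted at
4.184 kJ/kcal) and isotropic shieldings per nucleus, with element and
hybridization metadata and optional equivalence groups.

* Energy filter: conformers above 3.0 kcal/mol over the minimum are removed;
  the boundary is **inclusive** (a 3.0 kcal/mol conformer is retained). The
  minimum-energy conformer always survives.
* Boltzmann weights: wᵢ = exp(−Eᵢ/RT)/Σ exp(−Eⱼ/RT) with
  R = 1.9872041×10⁻³ kcal mol⁻¹ K⁻¹ and T = 298.15 K by default, computed
  with max-subtraction.
* Averaging: population-weighted mean shielding per nucleus; equivalence
  groups (methyl protons, enantiotopic pairs) are collapsed **after**
  Boltzmann averaging by an unweighted mean over group members, producing
  one value per experimental assignment.
* Shifts: three routes, labelled distinctly in reports —
  `global_scaled` δ = (intercept − σ_iso)/(−slope) with repository-style
  per-element factors (used for the MAE/RMSD headline statistics);
  `regression_scaled`, a per-candidate, per-element least-squares fit of
  calculated on experimental shifts (the DP4+ scaled branch, which removes
  each candidate's own systematic error; ≥3 paired nuclei required);
  and `unscaled` δᵤ = σ_ref(element) − σ_iso with config-supplied reference
  shieldings (the DP4+ unscaled branch).
* DP4+: per nucleus the error e = δ_calc − δ_exp enters a Student-t density
  t_ν((e − μ)/σ)/σ; the scaled branch uses mean-zero parameters per element,
  the unscaled branch parameters keyed by element and, for carbon,
  hybridization (protons are keyed sp3 by convention). Log-densities are
  summed per candidate and normalized across candidates by a max-subtracted
  softmax; component probabilities (scaled-only, unscaled-only, carbon-only,
  proton-only) use the corresponding partial sums. Headline display rounds
  to integer percent; machine-readable output keeps full precision.

The parameter tables ship as editable JSON with provenance strings. The
scaled-branch t parameters follow the widely republished shift-error
statistics (¹³C σ = 2.306, ν = 11.38; ¹H σ = 0.185, ν = 14.18); the
unscaled-branch entries are package defaults calibrated to the magnitude of
raw GIAO errors at mPW1PW91-family levels. Users quoting probabilities for a
specific level of theory should transcribe the published table for that
level into the config; the engine validates key completeness at run time.
Candidate discrimination in the regimes tested here is insensitive to
moderate changes in these parameters because it is driven by several-ppm
localized errors, not by the tails' exact shape.

Open conventions resolved here: MAE/RMSD are reported per element and
pooled, on globally scaled shifts; exchangeable OH protons are not excluded
(callers can restrict via the element/assignment tables); DP4+ runs on ¹H
and ¹³C jointly, with carbon-only and proton-only components also reported.

## ECD synthesis and matching

Each transition (Eᵢ in eV, Rᵢ in 10⁻⁴⁰ cgs) contributes a Gaussian band on
the energy axis,

Δε(E) = Σᵢ Eᵢ Rᵢ / (22.97 σ √π) · exp(−((E − Eᵢ)/σ)²),

with σ = 0.23 eV by default, interpreted as the half-width at Δε_max/e (the
convention of the standard spectral-comparison tools); the prefactor 22.97
is exposed as an argument since it fixes the cgs unit convention. Spectra
are evaluated on a uniform wavelength grid (default 180–400 nm at 1 nm) via
E = 1239.84193/λ, Boltzmann-weighted across conformers, and compared with an
experimental trace by the normalized overlap (cosine)
∫fg dλ / √(∫f² ∫g²) over the common support, trapezoidal rule.

Wavelength (UV) corrections are applied to the calculated spectrum: a scan
over shifts in ±15 nm (default, 1 nm steps) selects the shift maximizing
|similarity|, reporting the signed similarity at that shift. Choosing by
magnitude rather than signed value makes the scan equivariant under
enantiomer flips — negating every rotatory strength flips the sign of the
reported similarity while recovering the same alignment — which is the
behaviour needed when deciding between two enantiomeric candidates. Ties go
to the smallest |shift|; points shifted off the grid become NaN and are
excluded from the overlap integrals.

## Synthetic-data generator

The generators are pure functions of (config, seed); per-purpose substreams
are spawned from the master seed so interleaved calls do not perturb one
another. Defaults encode the study conditions the analysis is meant to
resolve:

* **Fingerprints** — six FPC-like class templates arranged as a 3 × 2
  factorial (ring-fusion skeleton × acylation pattern) so the class means
  span two independent directions of fingerprint space, as real subclasses
  do; diagnostic slots C-2/C-6/C-7 carry the skeleton displacement and
  C-4/C-9 the acylation displacement, every class pair separated by ≥4 ppm
  on some diagnostic slot, within-class sd 1 ppm, proton slots missing with
  probability 0.3–0.4. Base values echo the compound class: oxygenated
  aromatic carbons 90–170 ppm, carbonyls 185–200 ppm, aldehydic ¹H 9.5–10.5,
  phenolic ¹H 11–14.
* **DP4+ scenarios** — ~25 carbons (sp2 ring, carbonyl, sp3 terpene ranges)
  and 15 protons; the correct candidate's Boltzmann-averaged scaled shifts
  deviate from the "experimental" truth by N(0, 1.9 ppm) ¹³C / N(0, 0.13 ppm)
  ¹H (matching revised-structure RMSDs), the incorrect candidate additionally
  carries six carbon positions offset by Uniform(5, 12) ppm with random sign
  (matching the localized deviations of misassigned structures). Shieldings
  are built by inverting the scaling relation and adding per-conformer
  jitter centered over the ≤3.0 kcal/mol subset under renormalized Boltzmann
  weights, so the analysis chain recovers the planted averages exactly.
  Conformer energies are Exponential(mean 1 kcal/mol), re-based to zero.
  Shieldings are statistical stand-ins, not computed observables.
* **ECD scenarios** — random transitions in 200–380 nm with Normal signed
  strengths; the "experimental" trace is the broadened Boltzmann-averaged
  spectrum displaced by a known shift (default planted +7 nm, recovered by
  the scan as the compensating −7 nm correction) plus Normal noise at 5% of
  the peak magnitude.

What passing these tests shows: the post-processing chain is internally
consistent, numerically correct against closed forms and brute-force
oracles, and decisive at the error regimes that separate correct from
misassigned candidates in practice. What it does not show: anything about
the accuracy of the upstream quantum chemistry, about error correlations
between neighbouring nuclei (the generator draws independent errors), or
about fingerprint classes whose real within-class spread departs strongly
from the Normal model.

## Numerical choices and degenerate inputs

Log-space accumulation with max-subtraction wherever softmax-like
normalization occurs; Boltzmann weights are offset-invariant by
construction. PCA eigenvalues are clipped at zero; zero-variance columns
under autoscaling raise an error naming the slot. Regression scaling rejects
slopes of exactly zero and fewer than three pairs per element. Empty
transition sets produce identically zero spectra. DP4+ probability ties
resolve lexicographically on candidate id with a logged warning. Problem
sizes in the test suite and acceptance script (200 replicates, 40 nuclei,
5 conformers, 180-compound fingerprint sets) were chosen as the smallest
sizes at which the planted statistical regimes are stable.

## Known limitations

The toolkit consumes quantum-chemistry outputs; it does not parse engine log
files, generate conformers, or compute shieldings/rotatory strengths. The
similarity metric is a plain cosine overlap — adequate for enantiomer and
shift decisions, but not a replacement for the weighted similarity factors
of dedicated spectral-comparison software. Bundled scaling factors and
unscaled-branch t parameters are defaults of the right magnitude, not
transcriptions for a specific level of theory.
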