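# fpcrevise

Computational post-processing toolkit for revising the structures of
formyl phloroglucinol meroterpenoids (FPCs) — and similar natural
products — from NMR and ECD evidence. Misassigned structures are common in
the natural-products literature; this package implements the desk-side half
of a structure-revision workflow, everything downstream of the quantum
chemistry:

1. **NMR fingerprint screening** — a compound's diagnostic shift vector
   (phloroglucinol core carbons C-1…C-6, carbonyl carbons C-7/C-9, aldehydic
   and phenolic protons) is projected into the PCA space of a curated
   class-labelled table; a compound whose reported substructure class
   disagrees with its nearest class centroid, or whose shifts fall outside
   the class's empirical ranges by more than a threshold (default 1.0 ppm),
   is flagged as a candidate for revision.
2. **DFT-NMR candidate scoring** — per-candidate conformer ensembles
   (relative energies + GIAO isotropic shieldings) are filtered at a
   3.0 kcal/mol window, Boltzmann-weighted at 298.15 K
   (wᵢ ∝ exp(−Eᵢ/RT)), averaged, converted to shifts
   (δ = (intercept − σ_iso)/(−slope), repository-convention linear scaling),
   and scored against experimental assignments by MAE/RMSD and by **DP4+**:
   per-nucleus errors e = δ_calc − δ_exp are modelled as Student-t variables
   in a regression-scaled and an unscaled branch (the latter keyed by
   element and carbon hybridization), and candidate probabilities are the
   softmax of the summed log-densities.
3. **ECD comparison** — TDDFT rotatory strengths are broadened with Gaussian
   bands (σ = 0.23 eV), Boltzmann-weighted, shifted along the wavelength
   axis (UV correction), and matched to an experimental Δε trace by cosine
   similarity over a scanned shift window.

A seeded synthetic-data module generates inputs with the statistical
structure real revision problems exhibit (class-structured fingerprints,
correct-candidate errors at the ~1.5 ppm ¹³C MAE scale vs. incorrect
candidates with localized 5–12 ppm deviations, sparse transition sets), so
the whole pipeline is testable without any quantum-chemistry runs.

## Worked example

Generate a synthetic two-candidate revision scenario and score it:

```sh
$ fpcrevise simulate dp4 --seed 11 --out demo
wrote DP4+ scenario to demo
$ fpcrevise --quiet dp4 --exp demo/experimental.csv \
    --ensemble demo/ensemble_correct.csv --ensemble demo/ensemble_incorrect.csv
correct: MAE 0.82 ppm, RMSD 1.27 ppm
incorrect: MAE 2.28 ppm, RMSD 3.95 ppm
DP4+ correct: 100%
DP4+ incorrect: 0%
verdict: correct
```

The MAE/RMSD lines are computed over all nuclei (¹³C and ¹H pooled) from
the globally scaled, Boltzmann-averaged shifts: the planted "correct"
candidate sits at the small-error regime while the "incorrect" one carries
six large localized carbon deviations, and DP4+ resolves them decisively.

The ECD arm, on a scenario whose "experimental" trace was displaced by a
known +7 nm:

```sh
$ fpcrevise simulate ecd --seed 11 --out demo
wrote ECD scenario to demo (planted shift +7 nm)
$ fpcrevise --quiet ecd --transitions demo/transitions.csv \
    --exp demo/experimental_ecd.txt
similarity: 0.9891
best shift: -7 nm
window:     180-393 nm
```

The scan recovers the compensating −7 nm correction with near-unit cosine
similarity. `fpcrevise fingerprint` and `fpcrevise run` (full pipeline from
a JSON config, emitting JSON + markdown reports) follow the same pattern;
see `fpcrevise --help`.

## Configuration

Scaling factors and DP4+ Student-t parameters ship as editable JSON under
`src/fpcrevise/data/` with provenance strings; replace them with the
published values for your level of theory before quoting probabilities in a
publication. The ECD broadening constant (22.97, cgs convention for R in
10⁻⁴⁰ esu²·cm²), band width, grid and scan window are all exposed as
function arguments.
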