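# Methods

This note documents the models, defaults and numerical choices behind
`n15quant`, and what the simulator does and does not emulate.

## Isotope envelopes at partial ¹⁵N enrichment

A peptide's elemental composition is the sum of its residue monomer
compositions plus one water; carbamidomethylation of cysteine (+C2H3NO per
C) is the default fixed modification, matching standard iodoacetamide
alkylation. Residue formulas and isotope masses/abundances are shipped as
plain-text tables (`n15quant/data/residues.tsv`, `isotopes.tsv`) so results
do not depend on an external source. The isotope table covers H (2 isotopes),
C (2), N (2), O (3) and S (4); ¹⁸O at 0.205% natural abundance contributes
visibly to the M+2 peak of peptides carrying 15–20 oxygens, so oxygen is not
reduced to two isotopes.

The envelope is computed exactly: for each element, the distribution of
extra neutrons over its atoms is an exact multinomial expansion (binary
powering of the single-atom distribution under convolution), and element
distributions are convolved on the unit-mass grid. Nitrogen's two isotope
abundances are replaced by (1 − p, p) at enrichment p; p = 0.00364 is the
natural ¹⁵N fraction (the light channel), p = 0.982 the default labeling
efficiency of the heavy channel. Each grid bin tracks both total probability
and probability-weighted mass, so the reported centroid m/z of every peak is
the abundance-weighted mean of the isotopologues it aggregates. Unit-mass
aggregation (rather than fine structure) reflects reflector MALDI-TOF
resolution, where isotopologue splitting within a nominal mass is not
resolved. Charge is fixed at 1 and m/z = neutral mass + 1.007276 (MALDI,
protonated); ambiguity codes (B, Z, X) and selenocysteine (U) are rejected
rather than approximated.

Envelopes are truncated to the most intense contiguous window of
`max_peaks` bins (default 8, covering >99.9% of intensity for ≤3 kDa
peptides) and renormalized; the retained probability fraction is reported
as `coverage`. The correctness reference in the test suite is a brute-force
isotopologue enumeration, exact on small compositions and with a bounded
pruning tail (<1e-11) on full peptides.

## Digestion and uniqueness

Trypsin cleaves after K or R but not before P (the classic rule; the
suppression is configurable off), with 0–1 missed cleavages by default.
Library peptides are bounded to 5–35 residues, the MALDI-observable range.
Peptide→protein mapping is exact-substring over the digested collection;
uniqueness is parent-set size 1. Because leucine and isoleucine are
isobaric and the quantification run matches by mass only, uniqueness
classification can optionally collapse I/L variants into one entry
(reported with its member sequences); the default bookkeeping keeps
sequences distinct. Protein N-terminal methionine is retained; semi-tryptic
peptides are out of scope.

## Pair extraction and q-values

For each library peptide the theoretical light (natural) and heavy
(enriched) envelopes define slot positions; in every spectrum, each slot
takes the nearest centroided peak within ±30 ppm (ties to the higher
intensity). An envelope counts as detected when at least 3 consecutive
slots are filled in the run containing the theoretically most intense slot.
The pair's q-value is the heavy fraction of the summed matched intensities,
q = ΣI_heavy / (ΣI_light + ΣI_heavy), summing over all matched slots of
each envelope (not just the apex).

Degenerate cases are handled conservatively:

- **Window overlap.** For low-nitrogen peptides the light envelope's tail
  reaches into the heavy window; on a centroiding instrument the colliding
  peaks merge. A peak claimed by both envelopes is assigned to the nearer
  theoretical slot, the spectrum is flagged `overlap`, and it is excluded
  from aggregation.
- **One-sided pairs.** A peptide present in only one sample yields q
  exactly 0 or 1. Such calls are accepted only when the partner window is
  completely empty; partial partner signal (e.g. an envelope that failed
  the consecutive-slot rule because one peak dropped below detection)
  flags the spectrum `partial_partner` and excludes it. Without this rule,
  sporadic peak dropout converts genuine mixed pairs into false
  single-tissue calls that bias the mean q.
- q outside (0.2, 0.8) carries an `uncertain` flag (one side is weak) but
  the flag alone does not reject a measurement.

## Quality and positional filters

Mass-only matching admits false positives, so accepted measurements must
pass three independent checks:

1. **Envelope shape.** For each adjacent pair of filled slots, the bounded
   ratio r_i = I(i+1)/(I(i)+I(i+1)) is compared with the theoretical
   envelope's ratio; the verdict passes iff every |Δr| ≤ threshold
   (default 0.05). The bounded form is symmetric in the two peaks,
   scale-free, and stable where a raw quotient would diverge.
2. **Gel consistency.** The quantification-run gel segment must lie within
   ±1 segment of the identification-run segment, and the molecular-weight
   window of that neighborhood must contain k × (parent protein average
   mass) for some oligomeric state k ∈ {1, 2} — membrane proteins such as
   the PIP aquaporins band both as monomers and dimers. The MW condition
   is evaluated over the neighborhood's window union rather than the
   single quant segment, otherwise the ±1 allowance could never accept a
   neighboring segment. For shared peptides, any parent protein may
   satisfy the mass condition.
3. **Elution consistency.** Mid-fraction retention times of the
   identification (48 spots, 28 min + 0.7 min/fraction) and quantification
   (192 spots, 28 min + 0.15 min/fraction) schedules must agree within
   1.5 min (default). Mid-fraction time is the only elution proxy a
   spotted LC-MALDI run provides; 1.5 min ≈ two identification-run
   fractions, absorbing schedule discretization plus modest drift.

All thresholds live in a YAML-loadable `Settings` object. Filters are
monotone: tightening any tolerance can only shrink the accepted set.

## Aggregation

Peptide-level q is the arithmetic mean of per-spectrum q values (spectra
are the replicate unit; SD is the sample SD over spectra, printed 0.00 for
a single spectrum). Protein-level q averages the means of its *unique*
peptides only; shared peptides never enter a protein aggregate. A protein
with one unique peptide reports that peptide's spectrum SD. No
intensity weighting and no cross-run normalization are applied (samples
are mixed 1:1 by protein mass upstream). In place of a manual inspection
step, every flagged spectrum (overlap, partial partner, uncertain, shape
failure) is exported to `borderline_spectra.tsv`.

## Labeling-efficiency estimation

The ¹⁵N incorporation is estimated by grid search over 90–100% in 0.1%
steps (matching the precision at which such efficiencies are usefully
quoted): for each grid value the theoretical heavy envelope of every
contributing peptide is recomputed and the summed squared adjacent-ratio
differences (the same r statistic as the shape filter) is minimized.
Experiment and theory are aligned on the nominal-mass grid, so the
comparison tolerates the truncation window drifting with enrichment. Fits
at a grid edge, or with no overlapping ratio pairs at all (e.g. unlabeled
input), are flagged as boundary/poor fits. Input envelopes are restricted
to positionally consistent spectra matching exactly one library peptide;
near-isobaric isoform variants otherwise cross-match and their foreign
shapes corrupt the pooled objective.

## Shared-peptide isoform arithmetic

q_shared = Σ w_i q_i under the assumption — flagged in every result — that
the shared peptide ionizes and is detected with equal efficiency from all
parent isoforms. Two-component mixtures invert in closed form; solutions
outside the weight simplex are reported infeasible with the clamped
boundary solution, and |q₁ − q₂| < 0.1 raises an ill-conditioning warning
(the inversion error scales as 1/|q₁ − q₂|). Ratios are reported raw and
rounded to one significant figure. For ≥3 components no point estimate
exists; the package reports feasibility of the observed shared q against
the known component range, the family-level fold q/(1−q), and — when
exactly one component lacks a unique-peptide q — the interval of values
for it compatible with the observation. Least-squares deconvolution of ≥3
unknowns across multiple shared peptides is deliberately out of scope.

## The simulator

`simulate_experiment` emulates the two-run design end to end: a proteome
with a 13-member isoform family (default) mutated from a base sequence at
5% of non-K/R/P positions (so tryptic boundaries align and unmutated
peptides are genuinely shared, at ≥90% identity), digestion into a peptide
library placed on the gel (by parent average mass on a 36-segment
log-spaced 10–260 kDa gel) and the LC gradient (a fixed Kyte–Doolittle
hydropathy-mean proxy mapped monotonically onto 28–56 min — only the
consistency between runs matters, not chromatographic realism), and one
quantification-run spectrum per peptide replicate containing the light and
heavy envelopes scaled to (1 − f) and f.

The noise model is documented and deliberately simple: log-normal
multiplicative intensity error (default CV 5%, a typical MALDI spot-to-spot
reproducibility), uniform m/z jitter (±5 ppm, inside an internally
calibrated instrument's accuracy), Bernoulli peak dropout (1%), and an
optional detection floor. Peaks closer than 0.05 Da merge at the
intensity-weighted centroid, which is what makes overlapping light/heavy
windows of short peptides collide as on a real instrument. Fixed seeds give
byte-identical output directories.

`inject_confounders` adds decoys with truth labels for measuring filter
efficacy: well-shaped envelope pairs in the wrong gel segment and at the
wrong elution time (caught by the positional filters), and impostor
envelopes — a different peptide's natural-abundance shape written at the
target's heavy slot positions, at the correct position (caught only by the
shape test).

What the simulator does not emulate — and hence what passing tests do not
show about real data: chromatographic peak shapes and carry-over, detector
saturation and baseline, correlated (rather than independent) peak noise,
ionization suppression in complex mixtures, real sequence composition
biases, incomplete digestion beyond the missed-cleavage model, and
post-translational modifications other than fixed carbamidomethylation.

## Problem sizes

The shipped tests and the acceptance script run on deliberately small
instances chosen to keep the full suite fast while still exercising every
code path: proteomes of 3–13 isoforms plus background, libraries of 10–25
peptides, 20–60 spectra per condition, nine mixing levels at ≥20 spectra
each, and 40 decoys per class. All sizes scale up through
`SimulationConfig` without code changes.

## Known limitations

- Charge 1 only; no multiply charged species, no variable modifications.
- Uniqueness is exact-substring within the supplied collection; peptides
  shared with proteins *outside* the collection are invisible.
- The enrichment estimator assumes a single global incorporation level;
  per-protein or time-resolved enrichment is not modeled.
- The gel filter uses average (not apparent) molecular mass; anomalously
  migrating proteins need a custom gel model.
- Quantification is relative within one mixed sample; no absolute
  abundances and no FDR machinery.
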