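# Methods

This note records the model, the numerical conventions, and the design
decisions behind `fluxprot`, in the spirit of a methods appendix: what the
package computes, under which assumptions, and what its tests do and do not
demonstrate about real data.

## Isotope envelopes

A peptide's mass isotopomer envelope is the distribution of its aggregate
nominal mass shift. We compute it by exact convolution: each element
contributes the `count`-fold convolution power of its single-atom shift
distribution, and elements are convolved together. Two conventions matter:

- **Integer-shift aggregation.** Shifts are nominal (integer Da); fine
  structure within one isotopomer is summed. This is the right resolution
  for unit-resolution envelope fractions; it is not an exact-mass
  calculator.
- **Window truncation and renormalization.** The extraction workflow we
  model reports only M0–M3, so envelopes are truncated to a window of
  `K = 4` isotopomers and renormalized within it. Truncation is exact (the
  first `K` convolution coefficients are unaffected by higher shifts), and
  every downstream quantity — natural baseline, labeled asymptote, measured
  fractions — lives on the same renormalized window, so the mixture
  identity for `f` stays exactly linear. `K` is configurable because the
  choice of renormalization window is a workflow convention, not physics.

Natural abundances (H, C, N, O, S) ship in a versioned JSON data file
(IUPAC-style values, summing to 1 within 1e-9 per element); every
computation reads that one table, so results are reproducible bit for bit.
Amino-acid residue formulas and the carbamidomethyl fixed modification
(+C2H3NO on Cys, from iodoacetamide alkylation) ship the same way. Only
fixed modifications are supported: variable modifications are rejected
because the kinetic workflow does not use them.

## The labeling model

During synthesis at body-water ²H mole fraction `p`, `n` of the peptide's
C–H positions draw deuterium at probability `p`; all other atoms keep
natural abundance. Two modeling choices:

- **Effective site enrichment is `max(p, a_H)`** where `a_H` is natural ²H
  abundance. Body water never drops below natural abundance, and this
  makes both limits exact: `p = 0` and `p = a_H` each reproduce the
  natural envelope to machine precision.
- **Fractional `n`** (per-residue site counts are literature averages, so
  peptide sums are rarely integers) is handled by linear interpolation
  between the floor- and ceil-site envelopes before renormalization.

The per-residue site-count table is configurable; the shipped defaults are
literature-style values (Ala 4.0 … Trp 0.08). Because the generator and
the estimator share the table, recovery tests are self-consistent and do
not depend on the table's absolute values. `p` is treated as constant per
animal over the labeling window (bolus plus enriched drinking water holds
enrichment stable); no `p(t)` kinetics are modeled.

A polynomial emitter (`em0_polynomial_fit`) reproduces the curve-fit
parameterization of M0 depletion versus `p` used by instrument-side
workflows; the analysis path computes envelopes exactly per `(p, n)`
instead, which removes one approximation.

## From envelopes to rates

`f = (M0_meas − M0_nat) / (M0_labeled − M0_nat)` uses M0 only — the
dominant, best-measured signal. A multi-isotopomer least-squares fit is a
known alternative; it would lower variance slightly at the cost of
correlated-noise assumptions, and is not implemented. Noise can push the
raw ratio outside `[0, 1]`: values are clamped (to `[0, 1]` at the
fraction stage, to 0.99 at the rate stage) and flagged rather than
dropped, so the measurement filters see every peptide.

`k = −ln(1 − f)/t` assumes a single well-mixed pool with first-order
replacement; FSR is reported as `100·k` %/day because the rate constant is
the quantity comparable across stages with different label durations. The
simple `100·f/t` is emitted as a secondary column. The same ratio logic,
applied to deoxyribose ²H enrichment against a fully-turned-over reference
(supplied per study), yields the DNA fraction-new in percent.

Roll-up: animal-level protein FSR is the unweighted mean of peptide FSRs
(abundance weighting is deliberately out of scope); group-level values
need ≥ 2 peptide measurements per sample and ≥ 2 animals per group.
Failures land in a rejects table with the failed rule, and the counts
balance exactly: `proteins_in = compared + excluded_peptide +
excluded_animal`.

## Statistics

- "Student's" t-test means equal-variance by default, Welch by flag.
  Zero-variance degenerate inputs use the `p = 1` (equal means) / `p = 0`
  conventions.
- The cluster direction test is a one-sided exact binomial toward the
  observed majority under a fair-coin null. One-sided is the only reading
  consistent with the published calls this package's regression suite
  checks (e.g. 13/18 significant, 16/23 significant, 9/15 not); a
  two-sided variant is available by flag. Exact ties are excluded from the
  test denominator and reported separately.
- Benjamini–Hochberg is the step-up procedure, applied within each stage's
  protein family (stages are reported separately, so the per-stage family
  is the natural scope). Note BH is not idempotent in general — only
  saturated (constant) p-vectors are fixed points.
- Volcano classification: significant iff `p ≤ 0.05` (the −log₁₀ boundary
  1.301 is inclusive), direction by the sign of log₂FC, missing p counted
  as non-significant and flagged. Percentages are rounded half away from
  zero to one decimal; with this convention 12220/17198 is 71.1%
  (printed sources sometimes show 71.0% — a rounding slip), and
  2397/16940 is 14.1%.
- Per-gene expression p-values come from a two-sided equal-variance t-test
  on per-replicate FPKMs; a count-model (e.g. negative-binomial) test is a
  reasonable alternative the package deliberately does not take, since it
  consumes FPKM tables, not counts. Fold changes use a pseudocount of
  0.1 FPKM (configurable) so zero-expression genes stay finite and 0-vs-0
  maps to exactly 0.
- The flux-vs-expression regression is OLS of gene log₂FC on protein-FSR
  log₂FC. R² is symmetric in the axis choice and the slope p nearly so;
  the reported direction is FPKM-on-FSR.

The injured-limb comparator is configurable: a separate uninjured control
group (default, since systemic responses can contaminate the contralateral
limb) or the contralateral control limb of the same animals.

## The synthetic study

The generator emulates the statistical structure of a four-group
regeneration study: 5 animals/group; labeling windows Proliferation 0–4 d,
Differentiation 4–7 d (3 d label), Maturation 10–14 d, Control 3 d; five
ontology clusters (Cytoplasm, Glycolysis, Mitochondria, Myofibril,
OxPhos) × 20 proteins with 2–5 tryptic-like peptides each (7–25 residues
ending K/R); body water 0.05 ± 0.003; additive Gaussian envelope noise
(SD 0.003 per fraction, then clamp at 0 and renormalize); true FSR regimes
of 2–4 %/day for all control tissue and the proliferation-stage injured
limb (which shows no global flux change), 12–20 %/day injured at
differentiation, and 6–13 %/day at maturation; 17,000 genes with
log-normal baselines, per-stage differential-expression fractions
0.29/0.28/0.09, and directional per-cluster expression shifts for
protein-matched genes; planted DNA division fractions 44/10/3/2 %.

The forward model inverts the estimator exactly (`f = 1 − e^{−kt}`,
mixture on the renormalized window), so noise-free bundles round-trip to
float precision — that is a consistency check, not evidence about real
data. What the synthetic study does *not* emulate: peptide abundance
structure and missingness patterns, correlated (multiplicative) envelope
noise, chromatographic interference, immune-cell contamination, isotope
effects on digestion/ionization, count-level RNA-seq noise, and any
coupling between expression and flux (effects are planted independently,
which is what makes the null R² test meaningful). Passing tests therefore
demonstrate correctness of the computation and power under idealized
noise, not robustness to every artifact of real acquisitions.

Determinism: one `numpy.random.Generator` (PCG64) seeded per bundle; the
algorithm name is recorded in the bundle's `config.yaml`, file hashes in
`manifest.tsv`. Bundle TSVs carry 12 significant digits, which is enough
for the noise-free round trip to survive the file format.

## Problem sizes and tolerances

The default test suite simulates reduced studies (typically 2–8 proteins
per cluster, 100–500 genes) chosen to exercise every code path and
decision boundary; the acceptance script runs the full default design
(100 proteins/group) with a 6,000-gene expression table as its analysis
size. Envelope convolutions are validated against exhaustive
isotope-assignment enumeration for all ≤ 6-atom formulas (tolerance
1e-12); noise-free kinetic round trips are checked at 1e-10 (fraction) and
1e-6 relative (protein FSR); the binomial test is checked against exact
outcome counting for all n ≤ 20. Report tables are written with stable
sort keys and fixed float formatting, so re-running a study is
byte-identical.

## Known limitations

- Single-pool first-order turnover: no precursor delay, no multi-pool or
  degradation-specific modeling.
- M0-only estimation (see above).
- Unweighted peptide→protein aggregation.
- FPKM-level expression testing only; no count-model DE, no GO enrichment.
- No spectral processing: the package consumes extracted M0–M3 tables and
  FPKM tables, not raw spectra or reads.
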