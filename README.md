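# fluxprot

Heavy-water (²H₂O) flux proteomics for tissue regeneration studies: from
peptide mass-isotopomer abundances and body-water deuterium enrichment to
per-protein fractional synthesis rates (FSR), with the statistical layer
needed to compare protein turnover against gene expression across
regeneration stages.

## Who this is for

Labs running continuous ²H₂O metabolic labeling with LC–MS readout of
peptide isotope envelopes (M0–M3), who need a tested, scriptable path from
extracted isotopomer tables to:

- per-peptide fraction-new `f` and first-order replacement rate `k`,
- protein-level FSR roll-ups with the standard measurement filters,
- global, ontology-cluster, and per-protein comparisons between injured and
  control tissue,
- volcano classification of FPKM tables and the transcript-vs-flux
  correlation that tests for post-transcriptional control.

The package ships a synthetic study generator that emulates a four-group
muscle-regeneration design (Proliferation 0–4 dpi, Differentiation 4–7 dpi,
Maturation 10–14 dpi, uninjured 3-day-labeled control; 5 animals/group), so
the entire pipeline is testable end to end with known ground truth.

## The model

During labeling at body-water ²H mole fraction `p`, a newly synthesized
peptide carries deuterium at `n` of its C–H positions (the
per-residue `n` values are a configurable table). Mass isotopomer
distribution analysis (MIDA) gives the envelope of a fully labeled peptide
by exact convolution of per-element isotope multinomials, with the `n`
labeling sites at enrichment `p` instead of natural ²H abundance. A
partially renewed protein pool is a two-component mixture, so the
monoisotopic fraction M0 yields the fraction newly synthesized:

    f = (M0_measured − M0_natural) / (M0_fully_labeled − M0_natural)

and first-order replacement over a labeling window of `t` days gives

    k = −ln(1 − f) / t,      FSR = 100·k   (% of pool per day).

Protein FSR is the unweighted mean over peptides within an animal, then
over animals within a group, after two filters: ≥ 2 peptide isotope
measurements per protein per sample, and ≥ 2 animals per protein per group.
The same `f` ratio applied to deoxyribose enrichment gives the fraction of
newly divided cells from ²H incorporation into DNA.

Statistics follow the field's conventions: Student's unpaired t-tests
(Welch optional), one-way ANOVA, Benjamini–Hochberg step-up FDR within each
stage, one-sided exact binomial tests of direction-of-change within
ontology clusters, and ordinary least squares with R² for the
flux-vs-expression comparison. Expression significance uses the
−log₁₀(p) ≥ 1.301 (p ≤ 0.05) volcano boundary.

## Worked example

Simulate a full study at the default design and run every analysis:

```sh
fluxprot -v all --out demo --seed 42
```

This writes the input bundle under `demo/bundle/` and the report tables
under `demo/report/`. With seed 42, `demo/report/global_tests.tsv` reads:

```
stage            n_proteins  mean_fsr_injured  mean_fsr_comparator  t_statistic  p_value
Differentiation  100         15.716            3.062                54.44        4.4e-121
Maturation       100          9.393            3.062                31.70        1.7e-79
Proliferation    100          3.069            3.062                 0.08        0.94
```

i.e. the injured limb turns its proteome over ~5× faster than uninjured
control tissue during differentiation, ~3× during maturation, and shows no
global change in the proliferation window — while `correlations.tsv` shows
the matched gene-expression fold changes explain almost none of the
protein-flux fold changes (R² ≤ 0.0075 at every stage), and
`dna_summary.tsv` recovers the planted cell-division burst (~42% newly
divided cells at proliferation, falling to ~5% by maturation). Cluster
direction tests (`flux_cluster_summary.tsv`) call every ontology cluster
significantly increased at differentiation (20/20 members, p = 9.5e-7
each). All of these planted effects come from the generator's ground truth,
persisted under `demo/bundle/ground_truth/`.

The same analyses are available piecewise (`fluxprot simulate`, `fsr`,
`stats`, `expression`, `correlate`, `report`) and as library calls
(`fluxprot.run_study`, see the module docstrings).

## Layout

- `src/fluxprot/isotopes.py` — elemental formulas, natural-abundance envelopes
- `src/fluxprot/kinetics.py` — MIDA labeling model, f/k/FSR, roll-up filters, DNA readout
- `src/fluxprot/stats.py` — t/ANOVA/BH/binomial/regression layer
- `src/fluxprot/expression.py` — FPKM fold changes, volcano, cluster direction, gene–protein pairing
- `src/fluxprot/synthetic.py` — the study generator and ground truth
- `src/fluxprot/pipeline.py`, `cli.py` — orchestration, report writing, CLI
- `docs/methods.md` — model assumptions, parameter defaults, and limitations
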