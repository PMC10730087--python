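# markdyn

Statistical toolkit for the downstream analysis of gene-body histone-mark
dynamics across cell-state transitions — the motivating case being H2B
monoubiquitylation (H2Bub1) during cardiomyocyte differentiation, where the
mark is lost from most genes at a specific stage transition, selectively
maintained on a subset of tissue-specific genes, and its loss in mutants
shortens transcripts of long genes.

It is written for computational biologists who have already produced peak
calls (BED/broadPeak), normalized coverage tracks (bedGraph), gene models
(BED12 / minimal GTF) and transcript differential tables (TSV), and need
the analysis layer on top:

- **A/B-compartment enrichment** — peaks join a compartment interval on
  ≥ 20 bp overlap (A: eigenvector score > 0, B: < 0); the expected %B comes
  from 1000 bootstrap resamples of the compartment file at the peak-file
  row count, with per-replicate p-values (empirical tail or
  z = (O − Ē)/SD(E)) and the rule that a stage is significant only if every
  replicate has p < 0.05; stages are compared with
  z = (p₁ − p₂)/√(SE₁² + SE₂²).
- **Mark co-occurrence** — gene-level presence/absence matrices, 2×2 tables
  with fixed-margin expected values e_ij = k_i·m_j/N, Pearson χ² (1 df),
  Welch's t between stages on observed/expected ratios.
- **TSS occupancy clustering** — strand-aware (−2 kb, +10 kb) binned
  matrices and seeded k-means with elbow selection of k.
- **Differential consensus** — q ≤ 0.05 and |log₂FC| ≥ log₂ 1.5, ≥ 2/3
  replicate support, calls required in both independent mutant lines;
  maintained-gene sets; pooled two-proportion z test.
- **Matched nulls** — Poisson-rate length fit, ±10% length matching with
  regulation-class constraints in both conditions, and the 10,000-set
  quantity-matched gene-length enrichment test.
- **Metagene / full-length-transcript analysis** — 100-bin RPM metagenes
  over scaled gene bodies, a central-accumulation score, and 100-window
  log₂(mut/wt) ratios with a permutation test for disproportionate loss of
  the 3′-terminal 20%.

A first-class synthetic-data module generates seeded genomes, coverage,
compartments and differential tables with planted ground truth (bump
amplitude, truncated fraction, compartment bias, regulation classes,
cluster archetypes), so every stage is testable without downloads. See
`docs/methods.md` for the models, assumptions and numerical choices.

## Worked example

Place 300 peaks on a 100-interval compartment track with a known placement
bias toward the B compartment, then test enrichment:

```python
from markdyn.synthetic_data import generate_compartment_scenario
from markdyn.compartment_enrichment import (
    assign_compartments, label_percentages, bootstrap_expected, enrichment_pvalue)

comps, peaks, truth = generate_compartment_scenario(
    n_intervals=100, frac_B=0.5, n_peaks=300, peak_bias=0.6, seed=42)
labels = assign_compartments(peaks, comps, min_overlap=20)
pct = label_percentages(labels)
boot = bootstrap_expected(comps, n_peaks=len(peaks), n_reps=1000, seed=42)
print(f"observed %B      : {pct['B']:.1f}")
print(f"expected %B (E)  : {boot.mean:.2f} +/- {boot.sd:.2f}")
print(f"z                : {(pct['B'] - boot.mean)/boot.sd:.2f}")
print(f"p (normal tail)  : {enrichment_pvalue(pct['B'], boot, method='normal'):.3g}")
print(f"p (empirical)    : {enrichment_pvalue(pct['B'], boot, method='empirical'):.3g}")
```

Output:

```
observed %B      : 78.7
expected %B (E)  : 50.02 +/- 2.98
z                : 9.61
p (normal tail)  : 3.72e-22
p (empirical)    : 0.000999
```

With bias 0.6, 80% of peaks land in B (the 60% biased placements plus half
of the 40% uniform ones): the observed 78.7% sits ~10 bootstrap SDs above
the 50% expectation. The empirical p is floored at 1/(n+1) = 1/1001, which
is why the normal tail is the default for strong enrichments.

## Command line

```bash
markdyn simulate --outdir demo --seed 3        # synthetic bundle + config.yaml
markdyn run --config demo/config.yaml --outdir demo/out
markdyn annotate | tss-matrix | cluster | compartments | cooccur \
       | matched-null | metagene | fulllength   # single-step subcommands
```

`markdyn run` executes the stage-comparison pipeline (TSS matrices,
clusters, compartment and co-occurrence reports, decreased/maintained gene
sets) and the mutant-comparison pipeline (dual-mutant consensus calls,
matched control sets, metagenes, windowed ratios, tail-loss report), with
structured JSONL logs; identical config + seed gives byte-identical output.

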