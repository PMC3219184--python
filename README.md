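# dcismir

Integrated analysis of miRNA and mRNA dysregulation in paired
histologically-normal / preinvasive-lesion (DCIS) breast epithelium designs
— as a tested, reusable Python library with a thin command-line layer.

Early breast neoplasias already carry much of the expression dysregulation
seen in invasive disease. A common study design profiles miRNA by RT-qPCR
arrays (threshold cycles, Ct) and mRNA by expression microarrays in the same
patient-paired normal/lesion samples, plus a pooled healthy-tissue reference
(PRM) run in technical replicate, and then asks which predicted miRNA:mRNA
target pairs move in opposite directions — the signature of miRNA-mediated
mRNA destabilization. `dcismir` implements that full chain:

1. **miRNA differential expression** — nonexpression filtering (undetected
   in > 2/3 pool replicates, or > 6/8 of both patient groups), global-median
   rescaling of each sample to ΔCt = 12, ΔΔCt contrasts with fold change
   2^−ΔΔCt for HN−PRM, DCIS−PRM and DCIS−HN, t-tests with the pooled
   reference's variance inflated by the pool size κ (a pool of κ individuals
   measured in technical replicate understates its biological uncertainty by
   roughly that factor), and nominal (p < 0.005) / Benjamini–Hochberg /
   Bonferroni (0.05/m) significance tiers.
2. **mRNA differential expression** — presence filtering (< 15% of samples),
   a model-averaged Bayesian posterior screen P(fold change > 1.5) with
   cutoffs 0.975/0.025, and a patient-matched linear mixed model with
   lognormal errors; selection at p < 0.05 and fold change > 1.5.
3. **Pair integration** — intersection of ≥ 2 target-prediction programs,
   restriction to dysregulated miRNA and genes, Pearson correlation of
   miRNA −ΔCt vs probe log2 expression across all 16 paired samples, and
   sign-based classification into inverse / coordinate / undefined pairs.
4. **Locus co-expression** — single-linkage chaining of miRNA loci within a
   genomic gap (50 kb default) and within-cluster correlation of expression.
5. **Enrichment** — one-sided Fisher tails with the jackknifed EASE score
   against the measurable background.
6. **Synthetic data** — a first-class generator that emulates the study
   design (9-individual pool in triplicate, 8 patient pairs, logistic
   detection dropout at Ct 40, patient random effects, planted effects and
   negative miRNA→target coupling, prediction tables with decoys) so every
   stage is testable end to end, with planted truth for recovery scoring.

## Worked example

```python
from dcismir import PipelineConfig, run_mirna_de
from dcismir.simulate import planted_design, simulate_ct_dataset

cfg = PipelineConfig()
design = planted_design(seed=11)           # 10 planted |log2 FC| = 2 effects
result = run_mirna_de(simulate_ct_dataset(design), cfg)
print(result.table.sort_values("p_DCIS-HN")
      [["fold_DCIS-HN", "p_DCIS-HN", "tier_DCIS-HN"]].head(6))
```

prints

```
              fold_DCIS-HN  p_DCIS-HN tier_DCIS-HN
miR-sim-0003      4.294496   1.82e-11   bonferroni
miR-sim-0004      0.254507   6.84e-11   bonferroni
miR-sim-0010      0.252104   1.37e-10   bonferroni
miR-sim-0002      0.280287   2.54e-10   bonferroni
miR-sim-0005      4.294275   6.94e-10   bonferroni
miR-sim-0001      4.018140   8.13e-10   bonferroni
```

— the ten planted features carry true 4-fold (or 0.25-fold) lesion effects;
the fold column is 2^−ΔΔCt (> 1 = overexpressed in DCIS), and the tier marks
which survive the Bonferroni cut 0.05/365. The full pipeline with recovery
scoring:

```python
from dcismir import run_all
run = run_all(cfg, design=planted_design(seed=7))
print(run.recovery["pairs"])
# {'precision': 1.0, 'recall': 1.0, 'f1': 1.0, 'n_called': 20, 'n_true': 20}
```

All 20 planted miRNA:mRNA couplings survived the three-program intersection,
both differential-expression gates, and classified inverse.

The `examples/` directory has one short narrative script per capability
(`mirna_differential_expression.py`, `pair_integration.py`,
`locus_clusters_and_enrichment.py`, `run_full_pipeline.py`). A thin CLI
mirrors the stages:

```sh
dcismir simulate --scenario planted --seed 5 --out bundle/
dcismir mirna-de --ct bundle/ct.tsv --annotation bundle/annotation.tsv --out de/
dcismir run-all --simulate planted --seed 5 --out run/
```

Every run writes a provenance record (config snapshot, seed, input digests).

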