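# lnc-immunotype

Discovery of **tumor-specific dysregulated immune lncRNAs** and
**consensus-clustering molecular subtypes** from bulk RNA-seq cohorts.

Long noncoding RNAs regulate immune response and shape the tumor
microenvironment, and lncRNA–immune co-expression has been used to stratify
tumors into prognostically distinct subtypes.  This package implements that
analysis chain as a tested, reusable library for computational biologists:
from a genes × samples TPM matrix to a ranked set of immune lncRNAs, subtype
labels, and their survival and immune characterization.  Because the patient
data behind such studies is access-controlled, the package ships a
synthetic-cohort generator with planted ground truth, so every stage of the
pipeline can be exercised and scored end to end.

## The statistics at the core

For each lncRNA *l* and mRNA *m* within a cohort, Pearson correlation
*R* and its two-sided p-value *P* (from *t = R·√((n−2)/(1−R²))*) define the
correlation score

> Score(l, m) = −log₁₀(P) · sign(R).

Ranking all mRNAs of a lncRNA ascending by Score, the association of an
immune pathway *S* is the GSEA-style running-sum statistic: hits increment by
|w|^α normalized over hits, misses decrement by 1/(N−|S|), and

> lncRES(l, S) = signed maximal deviation of the running sum ∈ [−1, 1],

with a gene-set permutation p-value and BH-FDR across all lncRNA × pathway
tests.  Pairs with FDR < 0.05 and |lncRES| > 0.995 are significant; lncRNAs
significant in tumor but never in normal are *tumor-specific*.  Their
association with each of 24 immune cell types is the upper-tail
hypergeometric probability

> P(X ≥ k) = Σ_{j≥k} C(M, j)·C(N−M, n−j) / C(N, n)

over the lncRNA's *n* significantly correlated mRNAs (universe *N*, marker
set *M*, overlap *k*; overlaps with k < 3 carry no evidence).  lncRNAs
enriched in ≥ 10 cell types form the dysregulated panel.  Tumor samples are
then clustered by resampled consensus clustering on the panel (cluster
number by minimum PAC), and the subtypes are compared by Kaplan–Meier /
log-rank survival analysis, moderated-t differential expression,
over-representation and GSEA screens, and marker-based / single-sample
immune scores.

See `docs/methods.md` for the full description, including the synthetic
cohort's generative model and the design decisions.

## Worked example

The `analysis/` directory is a numbered driver sequence over the library.
Running it end to end on the default synthetic cohort:

```sh
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_coexpression.py
python analysis/03_immune_lncrna.py
python analysis/04_subtype.py
python analysis/05_survival.py
python analysis/06_downstream.py
```

prints (abridged):

```
  planted: 20 tumor-specific + 15 shared immune lncRNAs
tumor: 576,240 lncRNA-mRNA pairs scored; 50,223 significant (|R|>0.5, p<0.05)
tumor: 595 lncRNA-pathway tests, 35 significant pairs (FDR<0.05, |lncRES|>0.995)
normal: 476 lncRNA-pathway tests, 15 significant pairs (FDR<0.05, |lncRES|>0.995)
tumor-specific immune lncRNAs: 20
dysregulated set (enriched in >=10 cell types): 20 lncRNAs
chosen k = 2 (PAC: k=2: 0.000, k=3: 0.001, k=4: 0.112, ...)
subtype sizes: {'C1': 60, 'C2': 60}
OS:  log-rank chi2 = 9.530,  p = 0.002022
DSS: log-rank chi2 = 16.931, p = 3.877e-05
DEGs (FDR<0.05, FC>1.2): 1454 (8 up in C2, 1446 down in C2)
panel lncRNAs differentially expressed: 20/20 = 100.0%
immune pathways over-represented among down-in-C2 genes: 17/17
mean marker score C1 6.172 vs C2 4.095 (rank-sum p=1.15e-15)
concordance with planted subtypes (row %): C1->C1 98.33, C2->C2 98.33
```

Reading this output: the pipeline recovered exactly the 20 planted
tumor-specific lncRNAs (the 15 shared plants were detected in both cohorts
and correctly excluded), chose two subtypes whose labels agree with the
planted ones for 118/120 samples, and reproduced the planted biology —
subtype C1 is immune-high (higher marker scores, immune genes down in C2)
and has better survival (the planted hazard ratio for C2 is 2).  Each step
writes its tables under `results/`.

The same chain is available as one library call:

```python
from lnc_immunotype import (SimulationParams, PipelineConfig,
                            generate_cohort, run_discovery)
b = generate_cohort(SimulationParams(seed=1))
res = run_discovery(b.tumor, b.normal, b.truth.biotype,
                    b.pathways, b.markers, PipelineConfig(rng_seed=1))
res.dysregulated.lnc_ids     # the recovered panel
res.subtype_labels           # C1/C2 per tumor sample
```

Real data enters through the same file formats the generator writes:
expression as genes × samples TSV (TPM), gene sets as GMT, survival and
label tables as headered TSV, configuration as flat YAML mirroring
`PipelineConfig`.

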