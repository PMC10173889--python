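# corelnc

Integrative discovery of **core transcription-factor-effector lncRNAs** —
long non-coding RNAs that a stress-activated transcription factor (the
motivating case is p53) induces directly and recurrently across cell
types, and that in turn mediate part of its downstream program.

Most lncRNAs are cell-type specific, so single-dataset analyses cannot
distinguish a core effector from a context artifact.  `corelnc`
implements the multi-layer evidence chain a systems-biology analyst would
run across public activation transcriptomes, ChIP-seq compendia, tumor
multi-omics cohorts and genome-scale dependency screens — and ships a
synthetic-study generator that plants known ground truth in every layer,
so the whole chain is testable end to end without any external download.

## The method

1. **Rank-aggregation meta-analysis.**  Each activation dataset yields
   ranked up/down gene lists by expression fold-change (CPM
   normalization, Welch t-test on log2(CPM+1)).  Consistency across
   datasets is scored with the robust-rank-aggregation Beta
   order-statistic: for a gene with sorted normalized ranks
   r₍₁₎ ≤ … ≤ r₍ₙ₎ over n lists,
   ρ = min₍ₖ₎ P(Beta(k, n−k+1) ≤ r₍ₖ₎), with a Bonferroni factor n over
   k.  Stability is enforced by leave-one-out repetition: the corrected P
   is averaged over all n leave-one-out reruns and BH-adjusted across
   genes.  A gene passes when FDR ≤ 0.05 **and** it is directionally
   consistent in at least two-thirds of the datasets where it was
   detected.
2. **Direct-binding filter.**  A lncRNA is a direct TF target when a
   ChIP-seq peak lies within 10 kb of its TSS in ≥ 5 peak sets,
   including ≥ 1 Nutlin-class (MDM2-inhibitor) and ≥ 1 non-Nutlin
   (DNA-damage) treated dataset.
3. **Multi-omics association networks.**  Per cancer cohort, every
   retained (lncRNA *l*, mRNA) pair is fit by OLS

   `y = β₀ + β_DM·DM + β_CNV·CNV + β_lnc·lnc_l + ε`

   where DM is the representative promoter-methylation β-value (the
   probe most anti-correlated with expression) and CNV the GISTIC-style
   copy-number score.  Pairs with BH FDR < 10⁻³ form each lncRNA's
   positive / negative association sets (top 200 a side).
4. **Dependency-screen GSEA.**  Each association set is tested by
   pre-ranked GSEA against every cell line's RNAi/CRISPR dependency
   ranking.  A significantly negative NES (set concentrated among the
   strongest dependencies, FDR ≤ 10⁻³) for only the negative set labels
   the lncRNA growth-*suppressive*; only the positive set → *oncogenic*;
   both → excluded.
5. **Cohort statistics.**  Per-cohort Welch tests of lncRNA expression
   in p53 loss-of-function vs wild-type samples, pooled across cancers
   by Fisher's combined probability (−2Σln p, χ² with 2k df, one-tailed);
   and a median-split log-rank survival scan flagging |Z| > 1.96.

## Worked example

```python
from corelnc.config import SimulationConfig, PipelineConfig
from corelnc.pipeline import run_pipeline

sim = SimulationConfig(seed=42, n_genes=400, n_lncrnas=60, n_target_lncrnas=10,
                       n_datasets=6, cohort_n=100, n_cancer_types=1,
                       n_cell_lines=4, assoc_pool_size=60, n_assoc_per_side=12,
                       n_chip_nutlin=4, n_chip_nonnutlin=4, n_chip_control=2)
cfg = PipelineConfig(simulation=sim, seed=42, output_dir="readme_run",
                     chip_min_datasets=4)
report = run_pipeline(cfg)
print(report["counts"])
```

prints the per-stage attrition:

```
{'genes': 400, 'lncrnas': 60, 'meta_selected_up': 110,
 'meta_selected_down': 0, 'meta_selected_up_lncrnas': 10,
 'chip_direct_targets': 10, 'candidates': 10}
```

110 genes are consistently upregulated across the six simulated
activation datasets; 10 of them are lncRNAs, all 10 carry reproducible
promoter binding and survive the direct-target filter — exactly the 10
planted TF-induced lncRNAs.  The final evidence table
(`readme_run/candidates.tsv`) combines all layers per candidate:

```
lncrna_id  meta_fdr  n_chip_bound  n_suppressive_lines      lof_fdr
 LNC00007  0.008846             8                    8 1.487211e-13
 LNC00012  0.008846             7                    8 4.808269e-06
 LNC00016  0.008846             7                    8 9.320853e-10
 LNC00025  0.008991             7                    8 6.321181e-09
 LNC00033  0.008846             8                    8 4.696091e-09
```

Every candidate is bound in 7–8 of the 10 peak sets, classified
growth-suppressive in all 8 (cell line × screen type) combinations, and
significantly downregulated in p53-LOF samples (Fisher-combined BH FDR).

The same run is available from the shell:

```bash
corelnc simulate --config cfg.yaml study/        # write the input bundle
corelnc run-all  --config cfg.yaml --input-dir study/ out/
```

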