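# metamotif

Meta-analysis machinery for multi-study skeletal-muscle transcriptomics:
integrate per-study differential-expression tables into intervention-level
gene lists by robust rank aggregation, then characterize the upstream
regulators of those genes through promoter scanning for transcription
factor binding sites (TFBS), enrichment testing against a reference
promoter set, a motif-overlap statistic that flags candidate heterodimers,
and Markov clustering of TF interaction networks.

The package is aimed at the common situation where dozens of public
expression datasets measure the same biological contrast (e.g. muscle
disuse, aerobic training, acute exercise) on heterogeneous platforms
(RNA-seq, DNA microarray, CAGE) and no single study is trusted on its
own.  Every stage is exercised end-to-end on synthetic data with planted
ground truth, so the whole pipeline is testable without downloading any
public accession.

## Method

**Per-study filter.** A gene enters the meta-analysis for a study if
|FC| > 1.25, P_adj below the platform cutoff (0.05 for RNA-seq/CAGE,
0.1 for microarray), and its biotype is translated (protein-coding or
translated/polymorphic pseudogene).  Passers are split by fold-change
sign and ranked by ascending P_adj.

**Rank aggregation.** For each gene with sorted normalized ranks
r\_(1) ≤ … ≤ r\_(m) across the n studies that measured it (measured but
not retained ⇒ rank 1),

    rho = min_k  P( Binomial(n, r_(k)) >= k )

with the binomial tail evaluated through the regularized incomplete beta
function.  `p_bonf = min(1, n·rho)` is a conservative p-value under the
uniform-rank null; Benjamini–Hochberg across genes gives P_adj, and
genes with P_adj < 0.01 are called DEGs, separately per direction.

**Promoters and scanning.** Promoters are −1500..+500 around the TSS of
the most abundant transcript (0-based half-open, strand-aware).  PWMs
(TRANSFAC- or JASPAR-dialect flat files) are scored as log2-odds with
background pseudocounts; score thresholds are calibrated empirically so
the both-strand hit rate on a background sequence set does not exceed a
stated site frequency (1/2000 bp for enrichment, 1/50 kb for overlap
analysis).

**Enrichment.** Per matrix, promoter-level occurrence (≥1 hit) in DEG
vs reference promoters forms a 2×2 table tested with a one-sided Fisher
exact test; the adjusted fold enrichment FE_adj is the lower bound of
the Woolf 99% confidence interval of the odds ratio (Haldane–Anscombe
corrected when a cell is zero).  A TF with several matrices takes its
maximal FE_adj; significance requires FE_adj > 1.25 and BH FDR < 0.05
(FE_adj > 1.5 flags the most enriched TFs).

**Heterodimer evidence and clustering.** At the sparse 1/50 kb
calibration, the percentage of a TF's motifs overlapped by a motif of a
different TF by more than half the focal motif's length is reported per
TF; TF–TF interaction edge lists are clustered with the Markov cluster
algorithm (expansion/inflation on the column-stochastic walk matrix).

## Worked example

```python
import metamotif as mm
from metamotif.ingest import filter_and_rank
from metamotif.rankagg import aggregate

cfg = mm.MetaSimConfig(n_genes=5000, n_studies=10, n_true_up=100,
                       n_true_down=100, penetrance=0.7, seed=1)
tables, truth = mm.simulate_meta_tables(cfg)
up_lists = [filter_and_rank(t, truth.gene_biotypes)[0] for t in tables]
result = aggregate(up_lists)
degs = set(result.loc[result.is_deg, "gene_id"])
print(f"DEGs called: {len(degs)}")
print(f"sensitivity: {len(degs & truth.true_up_genes)/100:.2f}")
print(f"false positives: {len(degs - truth.true_up_genes)}")
print(result.head(3).to_string(index=False))
```

prints

```
DEGs called: 96
sensitivity: 0.96
false positives: 0
gene_id direction  n_eff          rho       p_bonf         padj  is_deg
G004140        up     10 2.475839e-19 2.475839e-18 1.237919e-14  True
G004018        up      9 3.097109e-18 2.787398e-17 6.968496e-14  True
G002248        up      9 1.514885e-17 1.363396e-16 2.272327e-13  True
```

Ten synthetic studies (mixed RNA-seq/microarray, 10% missingness) carry
100 planted up-regulated genes that respond in each study with
probability 0.7; rank aggregation at P_adj < 0.01 recovers 96 of them
with no false calls.  `rho` is the order-statistic score, `p_bonf` its
Bonferroni bound over list depth, `padj` the BH-adjusted value the DEG
call uses.

The full chain — simulate, ingest, aggregate, build promoters, calibrate
and scan a PWM library, test enrichment, score overlaps, cluster TFs —
runs from one command and writes a hash manifest:

```bash
metamotif run --seed 1 --outdir out/
```

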