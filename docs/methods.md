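# Methods

This note documents the models, statistics and numerical choices behind
`metamotif`, what the synthetic-data generators do and do not emulate,
and where the design was genuinely open.

## Robust rank aggregation

Each study contributes a direction-specific gene list ranked by
ascending adjusted p (ties broken by descending |log2FC|, then gene id,
for determinism; the ranking key itself is a design choice — adjusted p
is the natural ordering when effect sizes are platform-heterogeneous).
For a gene measured in n studies with sorted normalized ranks
r\_(1) ≤ … ≤ r\_(m), the score is

rho = min over k of P(X ≥ k), X ~ Binomial(n, r\_(k)),

computed via the identity P(X ≥ k) = I\_r(k, n−k+1) (regularized
incomplete beta), which is exact and stable for extreme tails; the unit
tests pin it against full 2^n outcome enumeration to 1e-12.
`p_bonf = min(1, n·rho)` bounds the p-value under the null of
independent uniform ranks (Bonferroni over the n choices of k).

**Rank normalization.** Within-study ranked lists store position /
list-length (so the last retained gene has rank exactly 1, a convenient
contract for list serialization), but the aggregation matrix rescales a
retained gene's position against the study's *measured universe* size.
This is the normalization of order-statistic rank aggregation: a gene at
position 5 of a 70-gene retained list drawn from 18,000 measured genes
has normalized rank 5/18,000, not 5/70.  Normalizing by retained-list
length would make the ranks of genuinely co-regulated genes uniform on
(0,1) whenever most of the list is signal — indistinguishable from the
null — and the method would have no power precisely when the signal is
strongest.  Genes measured but not retained take rank 1 (evidence of
absence); genes not measured are excluded from that study's column and
n is decremented (absence of evidence), which matters when platforms
cover different gene universes.  A gene must be measured in ≥2 studies
(configurable) — a meta-analytic claim from one study is degenerate.

After the Bonferroni bound, BH across all genes in the matrix gives the
adjusted p used for the DEG call (P_adj < 0.01).  Whether the original
analysis applied BH on top of the bound or used the bound directly is
not decidable from its description; both are implemented
(`bh_across_genes=False` selects the bound), BH is the default.

## Per-study inclusion filter

|FC| > 1.25 is applied symmetrically on the log2 scale (up: FC > 1.25,
down: FC < 1/1.25).  Platform cutoffs: adjusted p < 0.05 for RNA-seq,
< 0.1 for DNA microarray; CAGE takes the RNA-seq cutoff since both are
count-based sequencing assays.  All inequalities are strict, exactly as
printed; the pipeline config collects every threshold in one place so
these choices are auditable.  Only translated biotypes (protein coding,
polymorphic pseudogene, translated pseudogenes) are eligible.

## Promoters

The promoter is the window −1500..+500 around the TSS of the most
abundant transcript, 0-based half-open: 1500 upstream bases + the TSS
base + 499 downstream bases = 2000 bp.  Whether "+500" includes base
+500 is not decidable from a printed window; the half-open convention
makes the arithmetic exact and testable.  Minus-strand windows are
[pos−499, pos+1501) reverse-complemented so the emitted sequence always
reads 5′→3′ in transcription sense with −1500 first; a marker planted d
bp upstream of the TSS appears at scan offset 1500−d on either strand
(tested).  Ties in abundance break to the 5′-most TSS on the gene's
strand, then transcript id.  Windows clipped at contig edges are
flagged, not dropped.  Condition-specific TSS choice (e.g. promoter
shifts after acute exercise) is supported by running TSS selection on a
condition-specific abundance table; no isoform-switch detection is
implemented.  N bases are retained and scored as background.

## PWM scoring and threshold calibration

Scores are log2-odds in bits with background-distributed pseudocounts
(default 1.0): log_odds[i,b] = log2((c[i,b] + pc·bg_b)/(tot_i + pc)/bg_b).
The proprietary score normalization of commercial scanning platforms is
not public; bit-score log-odds is this package's stand-in, and all
thresholds are stated on that scale.

Thresholds are calibrated *empirically*: the least stringent score whose
observed both-strand hit rate on a background sequence set does not
exceed the target site frequency (1/2000 bp for enrichment scans,
1/50 kb for overlap scans).  The denominator is the number of scannable
windows per strand; hits are counted over both strands.  Empirical
calibration matches "site frequency" as an observed rate and requires no
independence assumptions about the background (the recommended
background is the reference promoter set itself).

A consequence worth knowing: for near-consensus matrices the empirical
score spectrum is coarse (scores cluster by mismatch count), so the
achieved rate can sit well below the target — the next admissible score
level would overshoot it.  The calibration contract is achieved ≤
target; the achieved rate, not the target, is what reproduces on an
independent background draw.  For matrices with a dense score spectrum
the achieved rate lands within a few percent of the target.  Rates are
resolvable only when the background offers ≥ 100/target positions;
shorter backgrounds are rejected.

Overlapping above-threshold windows of the same matrix are all reported
(no greedy merging); the overlap statistic defines its own rule.  The
vectorized scanner accumulates scores position-by-position in matrix
order, so its output is bitwise identical to the naive per-window
scorer used as the test oracle.  A numba kernel accelerates the inner
loop when numba is importable; a pure-numpy path produces identical
results otherwise.

## Enrichment

The counting unit is promoter-level binary occurrence (≥1 hit): at a
site frequency of ≤1 per 2000 bp the expected sites per 2000-bp
promoter are ≤1–2, so occurrence loses little information relative to
site counts and keeps the test exact.  The 2×2 table (DEG/reference ×
occurrence) is tested one-sided (enrichment; depletion is not
interpreted).  The adjusted fold enrichment is operationalized as

FE_adj = exp( ln OR − z\_0.995 · sqrt(1/a + 1/b + 1/c + 1/d) ),

the Woolf 99% lower confidence bound of the odds ratio, with the
Haldane–Anscombe +0.5 correction applied to all cells iff any cell is
zero.  The exact "statistically corrected odds ratio" of the commercial
platform that popularized the FE_adj name is unpublished; the CI-bound
definition is the central surrogate decision of this module.  It is
conservative by construction (FE_adj ≤ OR when OR > 1) and grows with
sample size at fixed proportions.  FDR is BH across the matrices of one
(intervention, direction) analysis.  Per TF, the maximal FE_adj over
its matrices is reported with the minimal FDR; significant means
FE_adj > 1.25 and FDR < 0.05, highly enriched adds FE_adj > 1.5.

## Motif overlap (heterodimer evidence)

A motif of TF X counts as overlapped iff a motif of a *different* TF on
the same promoter covers strictly more than half of X's own length.
"Half the length" is resolved per focal motif because matrices differ
in length; this makes the statistic well-defined and asymmetric (a
12-bp motif inside a 15-bp motif can be overlapped while the longer one
is not).  Same-TF overlaps are excluded by default — a TF's own
redundant matrices do not evidence heterodimers.  Hit intervals are
taken at full matrix length; no separate core/flank annotation is
modelled.  TFs with no motifs at the sparse calibration are reported as
missing (NaN), not 0%.

## Markov clustering

Column-stochastic walk matrix with unit self-loops; iterate expansion
(M→M²) and inflation (elementwise power 2.0, column renormalize),
pruning entries < 1e-10, until the maximum entry change < 1e-6 or 200
iterations.  Clusters are the connected components of the converged
non-zero structure.  Expansion cannot create flow between disconnected
components, so clusters never span components of the input graph — the
planted-partition recovery tests rely on exactly this.  The procedure
is deterministic for a fixed edge list.

## Synthetic-data generators

One global seed fans out through
`numpy.random.SeedSequence(seed, spawn_key=(domain,))` with a fixed
domain index per generator (meta=0, promoters=1, pwms=2, ppi=3,
background=4), so generators are independently reproducible.

**Multi-study DE tables.** Null genes draw adjusted p ~ Uniform(0,1)
and log2FC ~ N(0, 0.15) (≈3% of nulls clear the fold-change filter);
the pipeline consumes post-adjustment tables, so p-values are simulated
directly on the adjusted scale.  A true DEG responds in each measuring
study with probability `penetrance`; a responding gene draws adjusted
p = cutoff·Beta(a,1) with a = 0.1 (guaranteed to pass, and typically
orders of magnitude below chance passers, so true genes occupy the top
of each retained list) and log2FC = sign·(log2 1.25 + |N(0.35, 0.25)|).
Cells are missing completely at random (default 10%); half the studies
are labelled microarray.  Defaults were fixed once as plausible
bulk-transcriptomics magnitudes.  Not emulated: inter-gene correlation,
platform-specific effect-size biases, or gene-level effect sizes
correlated across studies — so passing tests demonstrate the machinery
recovers consistently-ranked planted signal, not that real studies
behave this way.

**Promoter corpus.** I.i.d. background at GC 0.41 (human promoter
neighbourhood); sites sampled column-wise from the PWM probabilities,
planted on a random strand at non-overlapping offsets in a
Bernoulli(prevalence) subset of promoters, every interval recorded.
Real promoters have CpG islands, repeats and composition gradients;
none are modelled — enrichment tests against this corpus validate the
statistics, not genomic realism.  The DEG corpus and the reference
corpus take separate prevalences; a pure-background reference
(background_prevalence = 0) is the planted-recovery study condition,
while the default 0.05 acknowledges that real reference promoters
contain real sites.

**PWM library.** The first matrix is near-consensus (97% consensus base
per column, so sampled sites carry ≤1 mismatch ~94% of the time and
planted-site recall at the 1/2000 threshold exceeds 0.9), the last is
degenerate (Dirichlet(5) columns), the rest draw sparse Dirichlet(0.4)
columns.  Serialized in both TRANSFAC and JASPAR dialects through
Bio.motifs; round-trip parsing preserves counts exactly.

**Interaction graph.** Planted partition: within-cluster edges with
probability p_within (weights U(0.6,1)), between-cluster p_between
(U(0.1,0.4)).

## Problem sizes in the test suite

The acceptance tests run the sizes the analysis is defined at where
that is cheap (5000 genes × 10 studies; 300 DEG vs 5000 reference
promoters; 20 corpus replicates for the enrichment-recovery rate) and
scale the pipeline-determinism runs down (hundreds of genes, 150
reference promoters), since byte-identity does not depend on size.
Backgrounds for calibration checks are 1–4 Mb so the Poisson noise of
the measured rate stays well inside the tolerance being verified.

## Known limitations

- FE_adj is a surrogate for an unpublished commercial statistic; values
  are comparable within this package, not across platforms.
- Empirical calibration quantizes achievable site frequencies for
  sharp matrices (see above).
- The MCL implementation is dense (O(n²) memory) — appropriate for TF
  sets of tens to hundreds of nodes, not genome-scale graphs.
- Raw expression processing (normalization, per-study differential
  testing), GO enrichment, and interaction-database retrieval are out
  of scope: the pipeline consumes their outputs as tables.
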