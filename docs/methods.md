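# Methods

This note records the scientific model implemented by `crhnet`, the
conventions and numerical choices adopted where the methodology leaves
room, what the synthetic-data generator does and does not emulate, and
the package's known limitations.

## Coordinates and formats

All coordinates are 0-based half-open (the BED convention); 1-based
inputs must be converted at the boundary. Overlap requires at least 1 bp
under half-open arithmetic: `[0,10)` and `[10,20)` touch but do not
overlap. A SNP at position *p* lies inside `[s,e)` iff `s ≤ p < e`.
Strand is carried on promoters but never consulted by overlap logic —
peaks and chromatin contacts are unstranded. Interval overlap queries use
interval trees; merging is a sorted sweep and is idempotent.

## Promoters and activity

A promoter is a symmetric window of `width` bp (default 500) centred on
the annotated TSS and clipped at position 0; the method description
specifies only the total width, so symmetry is a package choice and is
configurable. Element activity is the geometric mean of the DNAse and
H3K27ac signal over the element; an element without H3K27ac signal has
activity zero and can never form a functional connection, which is what
separates *candidate* elements from *active* distal elements.

## Contact matrices and balancing

Contacts are intra-chromosomal, binned (10 kb default), and stored as
symmetric sparse matrices; loading applies symmetric closure and sums
duplicate records. The contact between two positions is the entry of
their bin pair; same-bin pairs read the diagonal. Balancing is a
symmetric Sinkhorn scaling `D·M·D` iterated until occupied-row sums agree
to `tol` (default 1e-8): it meets the doubly-stochastic contract of
KR-style matrix balancing without reproducing the Knight–Ruiz algorithm
itself. Zeros are preserved, convergence failure raises with the last
residual, and the operation is idempotent.

ABC scoring consumes **raw** counts by default. The source methodology
applied matrix balancing to every analysis *except* the ABC score, and
the package follows that reading; a balanced matrix can be passed in
where the alternative convention is wanted. The contact pseudocount
defaults to 0 and is exposed for robustness experiments.

## ABC scores, thresholding, calibration

For each gene, every candidate element whose midpoint lies within half
the window (default 5 Mb total, i.e. ±2.5 Mb of the TSS) is scored; the
denominator sums activity×contact over all in-window candidates
(functional or not), and per-gene scores therefore sum to exactly 1
whenever any numerator is positive — a normalization invariant the test
suite asserts to 1e-9. The gene's own promoter term is excluded from the
denominator by default (`include_promoter_activity` restores the original
ABC convention). Scores are invariant to a global rescaling of all
activities.

The functional threshold defaults to 0.012 with an **inclusive** boundary
(`score ≥ t`): ties at the boundary are measure-zero on real-valued
scores and inclusiveness makes thresholding deterministic. Calibration
scans the distinct observed score values and returns the threshold whose
mean number of distal elements per connected gene falls inside the
configured bounds ([2, 5]) and is closest to the target (4.51), breaking
ties toward the larger threshold; the scan is exhaustive, so it trivially
matches a brute-force oracle and is deterministic for fixed input.

## Hubs and roles

CRHs are the connected components of the functional-pair bipartite graph
(networkx); every hub has ≥1 promoter, ≥1 distal element and ≥2 nodes.
*Complexity* is the hub's edge count. Mean pairwise distance uses node
midpoints (the reference point is not fixed by the methodology; midpoints
are symmetric and strand-free). The role taxonomy is the single
internally consistent reading of the hub vocabulary: a node is
*monogamous* iff its hub has exactly two nodes, *1-1-N* iff it has degree
1 inside a hub of ≥3 nodes (its unique partner then necessarily has
degree ≥2), and *polygamous* iff its degree is ≥2. These three classes
partition the nodes of any hub set; published percentage summaries of
role classes depend on unstated denominators, so the package reports
counts per class and per node class and leaves ratios to the caller.

Candidate comparator sets mirror the enrichment design: candidate distal
elements are accessible peaks overlapping no functional distal element
(by ≥1 bp), candidate promoters belong to genes absent from every hub.
Cross-sample pair replication classifies each reference pair as Direct /
SameCRH-NoDirect / NoConnection / NotFound, matching elements across
samples by any coordinate overlap (threshold configurable) and promoters
by gene id.

## Annotation overlap

Compartment category (AA/AB/BB/unassigned) uses the hub's two outermost
elements, each assigned to the A or B block of maximal overlap; ties
break toward A for determinism, and a hub whose extreme element overlaps
no call is unassigned. TAD overlap counts distinct disjoint TADs touching
the hub's genomic span (overlapping TAD calls are rejected — callers
disagree, but any single segmentation must be disjoint). Chromatin-state
"signal" is bp of overlap (state segmentations carry no signal value);
the per-hub state combination is the minimal prefix of
coverage-descending states (name-ordered on ties) reaching 80% of the
hub's total state coverage — the prefix of the top-k states is also a
minimal-size subset achieving the fraction, which the tests verify by
subset enumeration. The 18-state model collapses into Active / Weakly
Active / Inactive-Repressor exactly as the three broad categories are
defined for the neuronal segmentation.

## Statistics

* **Fisher exact 2×2** — two-sided p by the "probability at most that of
  the observed table" rule with 1e-7 relative slack (scipy's and R's
  convention; verified against full hypergeometric enumeration for every
  table with N ≤ 30). The odds ratio is the sample cross-product ratio;
  the Haldane–Anscombe +0.5 correction applies to all cells only when a
  cell is zero, and the 95% CI is the Woolf log-OR normal approximation
  on the (possibly corrected) table. Zero margins are an error — the OR
  is undefined there.
* **BH selection** — Benjamini–Hochberg step-up (statsmodels), selection
  at adjusted p ≤ 0.05.
* **SNP enrichment** — 2×2 of {in annotation A vs comparator} × {p ≤
  threshold vs not}, comparator either a disjoint candidate annotation or
  the rest of the genome. Fold enrichment is (significant fraction inside
  the annotation)/(overall fraction inside), and the relative fold
  divides by the candidate annotation's fold. Both are invariant to
  duplicating every SNP record.
* **Rank tests** — Wilcoxon rank-sum and signed-rank, exact null for
  small tie-free samples (min(n,m) ≤ 8 pairs ≤ 10), normal approximation
  with tie correction otherwise; the rank correlation is Spearman's rho
  (Pearson on average ranks).
* **Logistic regression** — ML fit by Newton scoring (statsmodels Logit,
  tol 1e-8, ≤100 iterations) of gene disease status on expression,
  number of distal connections, an indicator of the proportion of active
  distal elements exceeding the across-gene 90th percentile (the raw
  proportion is available behind a flag; the percentile wording admits
  both readings), and monogamy. Constant covariates, non-convergence and
  (quasi-)separation (|coef| > 15 on the logit scale) raise with advice
  to penalise; on small fixtures the pipeline records the failure rather
  than a spurious estimate.
* **ICC** — one-way random-intercept variance components by ANOVA method
  of moments with the unbalanced-design correction
  `n0 = (N − Σn_i²/N)/(k−1)`; negative between-group variance truncates
  to 0. Hub strata by promoter count: small ≤3, medium >3 and ≤25, large
  >25 (boundaries closed as printed).
* **Heritability annotation** — hub intervals extended ±500 bp, merged,
  and each SNP flagged by membership (thin-annot table). The LD-score
  regression itself needs genome-wide LD reference panels and is out of
  scope.

## SNP-to-DEG linkage

Structures are hubs, single functional promoter–element pairs, and TADs
(genes by TSS containment, distal elements fully inside the TAD; this
nesting-consistent rule is a package choice). A clumped SNP — used
without any p-value threshold — is assigned to every structure owning a
distal element that contains it, never through a promoter. DEG
proportions are per structure (genes counted once each); the per-kind
summary covers structures with ≥1 assigned SNP and kinds are compared by
rank-sum test.

## The synthetic generator

The generator emulates the statistical structure the pipeline assumes,
not real genomes. Each chromosome (2 × 20 Mb default) is divided into
400 kb territories separated by 300 kb gaps; 40 planted hubs with shapes
from (1,1) to (4,20) occupy territories (mean planted distal-per-gene
3.875, inside the [2, 5] calibration band), the remaining genes and
peaks fall elsewhere. Peak signals are lognormal; only planted hub
elements carry H3K27ac (scaled by `frac_active_elements`). Background
contacts are Poisson with a 1/(d+1) distance decay, truncated at 25 bins
(250 kb) — the short-range regime of real contact maps — and planted
promoter–element edges receive a large additive boost (default 2000
counts). Because the gaps exceed the background contact range, active
elements can only contact promoters of their own territory, and the
boost dominates every in-territory background count by orders of
magnitude at the 0.012 threshold; a dry-run ABC computation verifies
after each generation that exactly the planted (active) edges clear the
threshold and raises otherwise. This is what makes exact planted-hub
recovery (adjusted Rand index 1.0) a testable contract rather than a
statistical tendency.

Phenotypes: SNPs are uniform over the genome plus a fixed number per
element (clumped GWAS indices concentrate near signals); p-values are
Uniform(0,1) except inside planted risk elements (half of active
elements), where they follow Beta(a,1) with `a = 1 + log(risk_effect) /
log(0.05)` so the significant fraction at 0.05 is `risk_effect` (default
3) times baseline. Expression is grand mean 6 plus a hub random
intercept sized for ICC 0.25 plus unit noise. DEG labels are Bernoulli
(0.30 inside hubs, 0.074 outside — odds ratio ≈ 5.3). Disease status
follows a logistic model with coefficients (0.5, −0.3, 0.8, 0.4) on the
standard covariates, a hub-membership main effect of 1.6 (raising in-hub
genes from a ~23% to a ~35% association rate while the negative
connection coefficient concentrates association in small hubs), and
association p-values consistent with the planted status so BH selection
approximately recovers it.

Not emulated: linkage disequilibrium between SNPs, long-range and
inter-chromosomal contacts, balancing artifacts, sequence content,
cell-type mixtures. Passing tests therefore demonstrate correctness of
the machinery and calibration of the estimators under the planted model,
not performance on real tissue data.

## Problem sizes and determinism

The default fixture (2 chromosomes × 20 Mb, 300 genes, 1,500 elements,
40 hubs, ~8,500 SNPs) runs through the full pipeline in a few seconds;
the test suite uses this size for recovery checks and a 1 × 10 Mb
variant elsewhere. Estimator-recovery simulations use 200 groups × 10
observations (ICC) and 100–200 replicates of n = 5,000 (logistic
coverage). All randomness flows from a single integer seed through
`numpy.random.default_rng`; identical seeds give byte-identical outputs,
which the pipeline's rerun test asserts file by file.

## Known limitations

* Connected components only — no community detection inside large hubs,
  so one spurious contact can merge two hubs (a known bulk-Hi-C caveat).
* The balancing step is a generic doubly-stochastic scaling, not
  Knight–Ruiz; results agree in the contract (equal occupied-row sums)
  but not necessarily in iteration path or conditioning behaviour.
* Fisher CIs use the Woolf approximation rather than exact conditional
  CIs; for tables with zeros the Haldane correction biases the OR toward
  finite values by construction.
* The ICC is a method-of-moments estimate; REML would be preferable for
  severely unbalanced designs.
* `.hic`/`.cool` parsing, peak calling, TAD/compartment/FIRE calling,
  gene-level association (H-Magma), clumping and the LD-score regression
  are consumed as inputs, never computed.
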