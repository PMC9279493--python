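# Methods

`scimmune` implements the label-conditional analysis stages of a
multi-compartment single-cell immune profiling study: droplet scRNA-seq with
paired single-cell TCR sequencing across tumor (T), nearest non-cancer tissue
(N), draining lymph node (LN), distal normal tissue (D) and peripheral blood
drawn before (P0) and after (P1) neoadjuvant chemoimmunotherapy, with patients
stratified into treatment-naive, non-MPR and MPR response groups (MPR: ≤ 10%
viable tumor cells in the resected specimen). This note records the models,
the defaults and why, the numerical choices, and what the synthetic cohort
does and does not establish.

## Quality control

Per cell we compute the number of detected genes, total UMI, and the
mitochondrial percentage (100 × mitochondrial UMI / total UMI; defined as 0
for an all-zero cell to avoid 0/0 — such cells fail the UMI rule regardless).
A cell is removed when `n_genes < 200`, `n_genes > 6000`, `n_umi < 1000` or
`pct_mito > 10`. All four comparisons are strict, so boundary cells (exactly
200 or 6000 genes, 1000 UMI, 10.0% mito) are retained. Mitochondrial genes are
identified by the `MT-` symbol prefix, overridable with an explicit flag
vector. Filtering precedes every downstream stage, including normalization.

## Normalization

Expression is library-size normalized and log transformed:
`value(g,c) = ln(1 + s · count(g,c) / total(c))` with scale factor
`s = 10⁴` by default. Zeros map to zeros so sparsity is preserved, and a
cell's normalized profile is invariant to rescaling its counts. Marker tests
and signature scoring run on these raw log-normalized values; no batch
correction is applied (integration methods are out of scope, and labels are
consumed as input).

## Marker detection

Markers of a target group versus a reference (or "rest") use the two-sided
Wilcoxon rank-sum test per gene. Genes are pre-filtered to
`max(pct_in, pct_out) > 0.1`, where "expressed" means normalized value > 0.
The log fold change is computed on de-logged means,
`lnFC = ln(mean(expm1(in)) + 1) − ln(mean(expm1(out)) + 1)`, the convention
matching single-cell toolkits that report natural-log fold changes. A gene
passes when `|lnFC| > 0.25` and its p-value is below 0.05; the pass rule uses
the Benjamini–Hochberg adjusted p by default with the raw p also reported (a
config switch selects which one gates, since published thresholds often leave
this ambiguous). The p-value path is exact enumeration over rank assignments
when both groups have ≤ 8 observations (midranks handle ties), and the
tie-corrected normal approximation otherwise (vectorized over genes via
`scipy.stats.mannwhitneyu`).

## Signature enrichment

Three built-in signatures: the Tfh program (CXCL13, CD200, FBLN7, ICOS,
SGPP2, SH2D1A, TIGIT, PDCD1), the 12-chemokine tertiary-lymphoid-structure
signature (CCL2, CCL3, CCL4, CCL5, CCL8, CCL18, CCL19, CCL21, CXCL9, CXCL10,
CXCL11, CXCL13), and CXCL13 alone. Genes are ranked by the difference of
group means of normalized expression (group versus all other cells), with
ties broken by gene name for determinism. The enrichment score is the classic
weighted Kolmogorov–Smirnov running sum with weight exponent 1: hit
increments proportional to |score| normalized over hits (uniform if all hit
scores are zero), miss decrements 1/(N − N_hits); ES is the signed maximum
deviation, always in [−1, 1]. Significance is the proportion of cell-label
permutations whose |ES| meets or exceeds the observed |ES| (the observed
value is not added to the null, so p may be 0). BH adjustment runs over the
whole signature × group table, and the display value is masked to 0 wherever
the adjusted p exceeds 0.05, reproducing the heatmap convention. Ranking
metric and permutation unit are config options; defaults were chosen because
the enrichment procedure in the source workflow names GSEA without a metric.
Signature genes absent from the data are dropped with a warning as long as at
least one remains. NES is not computed (the masked ES heatmap does not use it).

## TCR repertoire

**Clonotypes.** A clonotype is defined by identical productive CDR3
nucleotide sequences. Per cell and chain (TRA/TRB) the highest-UMI productive
contig is kept (ties broken by lexicographically smallest CDR3); the
canonical key is the chain-tagged CDR3 strings, sorted and joined, so
dual-chain cells key on both chains and single-chain cells on one. Cells with
no productive chain are excluded; contigs whose barcode is unknown are logged
and skipped.

**Diversity and clonality.** For clone sizes n_i with N = Σ n_i,
`Shannon = −Σ (n_i/N) · log₁₀(n_i/N)` (the base-10 reading of "lg"; the base
is a config knob) and `Clonality = 1 − [−Σ p_i log₂ p_i] / log₂(N)`. The
clonality normalizer is log₂ of the **total sequence count N**, as printed in
the formula this implements, although the conventional normalizer is the
number of unique clonotypes; `denominator="unique"` selects the conventional
form. With the total-N denominator, an all-singleton repertoire scores
exactly 0 and a monoclonal repertoire (N ≥ 2) exactly 1; clonality is
undefined (NaN) for N < 2. Diversity tables are computed per patient ×
compartment × lineage and pooled per compartment × lineage.

**Sharing and longitudinal matching.** Per-compartment clonotype sets give
all 2^k − 1 exclusive Venn region counts plus pairwise shared counts and
fractions relative to each compartment's clonotype count. P0/P1 matching is a
per-patient inner join on the clonotype key with expansion ratio
size_P1/size_P0; patients missing either blood draw are skipped with a
warning. Intratumoral TCR-bearing cells are partitioned into
`shared_with_P1` versus `tumor_resident_only` by whether their clonotype
occurs in post-therapy blood — labels are clonotype-constant by construction
— and that partition feeds the same marker machinery for the
shared-versus-resident differential expression contrast.

**STARTRAC indices.** expa for cluster k with clone-size distribution q over
U unique clonotypes is `1 − H(q)/log(U)` (base-invariant; U = 1 scores 1 by
convention; clusters with fewer than 2 TCR cells are NA). tran for a cluster
pair (k, l) restricts each clone to k ∪ l and sums `w_c · H₂(f_c)` over
clones, where f_c is the clone's within-pair fraction in k, H₂ is binary
entropy (bits) and w_c the clone's share of cells in the pair; clones
confined to one cluster contribute 0, the matrix is symmetric with an NA
diagonal, and a pair with no TCR cells scores 0. These definitions are pinned
by brute-force per-clone entropy oracles in the test suite. Cross-patient
significance of index differences is the rank-sum test over per-patient
values (`markers.rank_sum_p`).

## Ligand–receptor interactions

CellPhoneDB-style scoring. For ordered cluster pair (a, b) and an L-R pair,
the combination is tested only when the ligand is expressed in more than 10%
of a's cells and the receptor in more than 10% of b's (for a multimeric
complex, every subunit must individually pass). The score is the arithmetic
mean of the ligand-side and receptor-side cluster means, complexes
contributing the minimum of their subunit means. The null permutes cluster
labels globally across all cells (1000 permutations by default) and
recomputes the score; p is the proportion of permuted scores equal to or
above the observed one — observed excluded, so p = 0 is attainable; a config
flag switches to the (k+1)/(n+1) estimator. Both directions of every cluster
pair are scored (ligand and receptor sides are not exchangeable), no
multiple-testing correction is applied across pairs (raw empirical p is
reported, as in the source tool), and a built-in 9-pair table covers the
chemokine/checkpoint axes relevant here; larger databases load from a
delimited table.

## Synthetic cohort generator

The generator emulates the study design so that every stage has checkable
ground truth: 12 patients (4 naive / 4 non-MPR / 4 MPR), naive patients
profiled in T/N/LN/D and treated patients additionally in P0/P1, 75 cells per
sample by default (~4,800 cells). Counts are gamma-Poisson (negative
binomial, global dispersion 0.3) with lognormal gene weights and lognormal
per-cell depth (median 2,500 UMI); six clusters (two CD4, three CD8, one
"other") are drawn from group-specific mixtures. Planted signals, all
recorded in the ground-truth mapping:

- 20 marker genes per cluster at 2× fold;
- the Tfh signature shifted 3× in MPR tumor cells;
- a CCL19→CCR7 axis at 8× between the "other" cluster and a CD4 cluster;
- per-cell mitochondrial fractions drawn from Beta(20, 480) (mean 4%), with
  planted dying cells at Beta(20, 60) (~25%) and planted debris cells at
  ~300 UMI, 2% of cells each;
- TCR coverage of 75.09% of CD4 and 68.64% of CD8 cells, matching the
  reported assay coverage; clone sizes geometric per lineage × compartment
  with CD8 P1 most expanded (parameter 0.35) so post-therapy blood shows the
  highest CD8 clonality; explicit per-patient shared clones across
  compartment pairs (T–P1, T–N, T–LN, T–D, P0–P1) biased toward CD8; and one
  hyper-expanded CD8 clone (12 cells) per treated patient in cluster C3.

CDR3 nucleotide strings (length 30–45 over ACGT) are unique per clonotype,
making clone identity unambiguous; 10% of clonotypes are TRB-only; decoy
contigs (low-UMI duplicate chains, nonproductive contigs) exercise the contig
resolution rules without changing the truth. QC-failing cells carry no TCR so
the clonal ground truth is invariant to filtering. Realized QC violations are
recorded by an independent dense scan at generation time. Everything is
drawn from one seeded generator, so regeneration is bit-identical.

What the generator does **not** emulate: batch effects, doublets, ambient
RNA, realistic gene-gene correlation structure, V/J gene usage, or biological
coupling between expression state and clone size beyond the planted
hyper-expanded clone. Passing tests therefore demonstrate correctness of the
computations and recoverability of planted effects under idealized noise —
not robustness to the full messiness of patient data.

## Pipeline, determinism and problem sizes

Stage order: QC → normalization → labels (input or external hook) →
composition tables → cluster markers → signature GSEA (tumor cells by
response group) → TCR repertoire (sharing, diversity, longitudinal match,
shared-vs-resident partition and DEGs, expa/tran) → L-R interactions. One
master seed feeds fixed named substreams per stage, so toggling one stage
never shifts another's randomness; reruns are byte-identical (floats are
written with `%.10g`). A failure halts with a stage-named error, preserving
the outputs already written and the manifest (package version, seed,
parameters, per-stage cell counts).

Default problem sizes — ~4,800 cells × 500 genes, 1000 permutations for both
GSEA and L-R — run end to end in well under a minute on one CPU; the test
suite's calibration checks use 1000-permutation nulls across hundreds of
replicated small datasets, and a 10,000-cell cohort for the QC oracle check.
Tolerances: entropy/ES oracle agreement is asserted at 1e-12 (identical
floating-point algorithms up to summation order); statistical calibration
bands are ±0.02 around the nominal 0.05 false-positive rate and
Kolmogorov–Smirnov distance < 0.08 against uniform.

## Known limitations

- The clonality denominator (total N) makes values depend on repertoire size
  as printed, not only on shape; cross-compartment comparisons at very
  different cell counts should prefer the `unique` denominator.
- Permutation p-values of 0 are reported as such by default; rank-based
  downstream use should enable the pseudocount estimator.
- The GSEA permutation unit is the cell, so p-values treat cells as
  exchangeable and ignore patient-level correlation.
- The marker test is per-gene rank-sum on cells, which is anticonservative
  for patient-correlated effects (no pseudobulk option in v1).
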