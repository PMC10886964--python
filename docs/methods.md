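# Methods

This note documents the models, conventions and design choices behind
`dismodnet`, in the spirit of a methods appendix: what each stage assumes,
which knobs matter, what the synthetic generator does and does not emulate,
and where genuinely open choices were settled.

## 1. Differential-expression preprocessing

Microarray tables are filtered at adjusted p (FDR) ≤ 0.05 and
|log₂ fold change| ≥ 0.5; proteomics tables at raw p ≤ 0.05 and a
symmetrised linear fold change max(FC, 1/FC) ≥ 1.2. All boundary
comparisons are **inclusive**. The reciprocal symmetrisation is needed
because "absolute fold change" is otherwise undefined on a linear ratio
scale (0.83 ≡ 1.205-fold down).

Probe collapse keeps one row per symbol: highest mean expression, falling
back (when no expression column exists) to highest |log₂FC|, then lowest
adjusted p, then lexicographically smallest probe id. The chain is fixed so
the collapse is deterministic and idempotent; only its first link is
standard practice, the rest is a documented reconstruction for tables that
ship only DE statistics.

Filtered datasets are unioned; genes on the curated disease list become
HDEGs, the rest ODEGs. Rows that are internally discordant within one
dataset carry direction `mixed` and are excluded from cross-dataset
discordance reporting but kept in the union.

## 2. Disease network and overlapping density clustering

The disease network is the subgraph induced by all DE genes present in the
reference interactome plus their direct neighbours ("other genes", OG).
Self-loops are ignored for clustering and path metrics but counted in the
topology report.

Clustering is greedy, seeded and overlapping. Definitions, for a cluster
*c* with |E_c| internal edges: density d(c) = 2|E_c|/(|c|(|c|−1)) (d := 1
for a singleton), and for a neighbouring candidate *n* with |E_nc| edges
into *c*: cluster property cp = |E_nc|/(d(c)·|c|), evaluated **before**
admission. Every node seeds one cluster (seeds in descending degree order,
ties lexicographic). At each step, among neighbours satisfying both
`d(c ∪ {n}) ≥ τ` and `cp ≥ cp_min`, the one with maximal |E_nc| is
admitted; ties break toward the candidate with the most edges into the
cluster's current frontier (this keeps growth cohesive — without it, a
bridge endpoint can absorb its cross-bridge partner and emit a spurious
pair), then toward the smaller name. Growth stops when no neighbour
qualifies. Exact duplicate clusters collapse; clusters below
`min_cluster_size` (default 2) are dropped. Defaults: cp_min = 0.5, nodes
never removed between seeds. Every emitted cluster satisfies d ≥ τ by
construction, and an exhaustive independent simulation of this rule is part
of the test suite (all connected graphs through 7 nodes, plus seeded
8-node samples).

Enrichment: one-sided (greater) Fisher exact test of the 2×2 table
in/out-of-cluster × HDEG/other over all network nodes. SScore = −log₁₀ p,
with p floored at 1e−300; a gene takes the **maximum** SScore over its
clusters ("best evidence"; a sum variant is available via
`sscore_aggregate="sum"`), 0 if unclustered. The ROC universe is all
network genes by default so AUCs are comparable across densities with
different cluster coverage (`roc_universe="clustered"` restricts it). AUC
is the tie-corrected Mann–Whitney pairwise-ordering probability. The run
with the highest AUC wins; ties go to the **lower** density (larger, fewer
clusters). Module calling applies Benjamini–Hochberg across the selected
run's clusters with a **strict** adj-p < 0.05; candidates are significant-
module members that are not HDEGs.

Topology metrics use networkx; path-based metrics are computed on the
largest connected component. Eigenvector centrality is computed by a dense
symmetric eigendecomposition over a sorted node order — iterative solvers
seeded from random vectors are not run-to-run reproducible, and desk-scale
networks make the dense solve cheap. Modularity uses greedy modularity
maximisation. The `fit_power_law` boolean fits the log survival function of
the degree distribution against log degree over degrees ≥ 2 and requires
R² ≥ 0.8 with negative slope; the cumulative form is used because the raw
log-log histogram is dominated by single-count tail noise at these network
sizes. Freeman centralisation is computed from normalised centralities
(degree: divided by n−2; betweenness: by n−1), so a star scores 1.0 on
both.

## 3. Biclustering and miRNA relevance

Each MTI source is folded onto its miRNA side: two miRNAs connect when the
Jaccard similarity of their target sets is ≥ `sim_min` (default 0.33). The
folded graph is clustered with the same density algorithm (threshold 0.5),
and each miRNA cluster attaches every gene targeted by at least
`attach_ratio` (default 0.5) of its miRNAs. Folded-isolated miRNAs still
emit 1×k biclusters of their own targets so low-similarity sources are not
silently dropped. Biclusters with an empty gene side are discarded;
overlaps are allowed. A bicluster whose gene side intersects the disease
list is a sub-MRM.

Relevance scoring, per dataset *n* and miRNA *i*: RS_ni is the product of
the number of sub-MRMs containing *i* and the number of **distinct disease
genes directly targeted by *i*** among genes co-occurring with it in those
sub-MRMs. A miRNA inside a sub-MRM with no direct disease-gene edge
therefore scores exactly 0. The total score is

    TRS_i = ( Σ_n RS_ni / C_n ) / ( Σ_n E_ni )

The normalisation is genuinely ambiguous in the source formula's
typography; this parse — per-dataset normalisation by that dataset's module
count C_n, averaged over the datasets containing the miRNA — keeps TRS
scale-free across sources whose module counts differ by an order of
magnitude, which is what "normalising the score in each dataset" has to
mean for heterogeneous databases. C_n counts all MRMs by default;
`trs_normalize_by="sub_mrm"` switches to sub-MRMs only. TRS is invariant
to dataset relabelling, and miRNAs absent from every dataset are omitted
rather than given an undefined score. Prediction keeps TRS strictly > 0,
ranked TRS descending then name.

The top-k attachment ratio is (A_topk/k)/(A_all/n_pred), with attachments
counted as distinct disease genes directly targeted in the union network.
No intermediate rounding is applied; note that a published figure of this
kind can differ in the second decimal if the per-miRNA mean in the
denominator was rounded before dividing (8.262 exact vs 8.270 with a
two-decimal intermediate).

## 4. Biomarker screening

On the deduplicated union of the MTI edge sets: NSR(m) = number of targets
whose only regulator is m (so ΣNSR equals the number of single-regulator
targets — an identity the tests check by brute force), and TFP is both the
count and the fraction of targets on the transcription-factor list (both
conventions circulate; published tables of "percentages" in this family
are plainly counts). Significance of a single observed scalar cannot be
recovered from a signed-rank recipe, so screening uses the transparent
right-tail empirical probability p_i = #{j : value_j ≥ value_i}/M over all
M network miRNAs — ties count as at-least-as-extreme, giving p ≥ 1/M, a
fully tied statistic p = 1 for everyone, and monotonicity in the statistic.
A candidate needs **both** p_NSR ≤ α and p_TFP ≤ α (α = 0.05, inclusive,
uncorrected).

## 5. Validation arithmetic

`hypergeom_tail(N, K, n, x)` is the exact survival probability P(X ≥ x)
under Hypergeometric(N, K, n), the quantity to report for "at least this
much overlap by chance". The point mass P(X = x) is also exposed
(`hypergeom_point`) because published summary probabilities of this kind
are sometimes point masses rather than tails: on the case-study counts,
the genome-universe value 0.00027 is a right tail, while the two
restricted-universe values 0.031 (N=3850, K=196, n=178, x=14) and 0.0022
(N=430, K=30, n=137, x=17) are reproduced exactly by the point mass — the
corresponding tails are 0.067 and 0.0032. The acceptance suite records
both conventions; new analyses should report the tail. Percentages are
rounded half-up to two decimals.

## 6. The synthetic generator

The generator emulates the *statistical structure* the pipeline assumes,
not the biology: a preferential-attachment background (300 nodes, m = 2)
with six disjoint planted modules of ten nodes wired to ≥ 0.95 internal
density; each module embedded by eight background nodes carrying edges to
about half its members (dense cores with a connected periphery — at
permissive cluster densities the periphery rides along and dilutes the
module, at strict densities it cannot, which is precisely the contrast the
AUC-based density selection exploits). Three of the modules are disease
modules; the curated list samples 70 % of each disease module's members
(stratified, so no module is left unlabelled by sampling accident) plus a
5 % background leak.

DE tables cover every network gene per dataset; disease-module members are
significant with probability 0.9, background genes 0.1, and ~5 % of genes
get duplicate probes. Significant rows draw |log₂FC| from |N(1, 0.25)|+0.5
with adjP ~ U(0, 0.05); non-significant rows fail at least one threshold.
p-values are assigned consistently with the flags rather than via a
simulated test — downstream stages consume thresholded flags only.

MTI data: 60 miRNAs over the PPI gene pool, eight planted 3×6 modules at
0.9 fill with two disease genes each, 300 background edges, served as three
independent 70 % subsamples of the master edge set (partially overlapping
"databases"). Transcription factors are a 15 % sample of the gene pool.

Every generator is a pure function of (parameters, seed). What passing
tests show is that the pipeline recovers planted structure under these
conditions; they say nothing about annotation noise, ascertainment bias in
curated lists, probe-to-gene mapping ambiguity, or the degree correlations
of real interactomes, none of which are modelled.

## 7. Numerical and degenerate-input conventions

- Fisher and hypergeometric probabilities come from scipy's exact routines
  (log-space accumulation); BH from `scipy.stats.false_discovery_control`.
- Degenerate enrichment tables (no HDEGs anywhere, or none in the cluster)
  give p = 1.
- ROC with a single class raises; all-tied scores give AUC = 0.5.
- An edgeless graph clusters to an empty list; an empty MTI source yields
  no biclusters and presence indicator 0.
- Output tables are deterministically sorted (score descending, then
  symbol), and identical config + seed give byte-identical outputs.

## 8. Known limitations

- The clustering and biclustering internals (seed order, cp_min, fold
  side, attachment rule) are reconstructions of the cited algorithm
  family's behaviour, exposed as configuration, not a byte-for-byte port
  of any released tool.
- The biomarker screen's empirical-p replaces an unreproducible per-miRNA
  signed-rank recipe; absolute p-values are not comparable to the original
  tool's, only the ranking intent is preserved.
- Symbol matching is exact string matching after trimming and gene
  uppercasing; alias resolution is out of scope (apply a mapping table
  upstream).
- At desk scale the synthetic scenario has ~100× fewer nodes than a real
  interactome; runtimes and cluster-count tables are not comparable to
  full-scale runs.
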