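# Methods

## Study structure

The pipeline targets a five-arm rat pharmacodynamics design: normal
control (NC), untreated diabetic (DM), and three treatments (SP, FJG,
SP-FJG), with liver expression profiled in four RNA categories (mRNA,
ncRNA, circRNA, miRNA) and per-animal physiology panels. The seven
screened contrasts are DM vs NC and each treatment vs both DM and NC.
Feature ids are namespaced by category (`mRNA:`, `nc:`, `circ:`,
`miR:`) so cross-category stages can never collide.

## Physiology metrics

The tolerance-test AUC is the trapezoid rule over the 0/30/60/120-min
curve with half-widths 0.25/0.25/0.5 h. Two properties matter in
practice: the AUC is linear in the curve, so the AUC of a group-mean
curve equals the mean of per-animal AUCs (this is how the group tables
are reproduced from printed means), and a constant curve c gives 2c.
Reported values are rounded half-up at 2 decimals via decimal
arithmetic on the printed inputs — plain binary-float rounding turns
exact .xx5 values (e.g. 22.055) the wrong way. HOMA-IR is
FBG×FINS/22.5. Group summaries use the sample SD (n−1); comparisons
use the classical one-way ANOVA F with (k−1, N−k) df. The per-group
significance stars of the published tables are reproduced as Welch
t-tests against the DM arm without multiplicity correction, because no
post-hoc procedure is named for them; they are labelled as such in the
outputs. Note that published HOMA-IR cells other than the control
arm's are not reproducible from group means (they reflect per-animal
averaging), so only the control cell is asserted.

## Differential screen

Counts are normalized to counts-per-million and log2(x+1) transformed;
no between-sample scaling beyond library size is attempted. The test
is a two-sample moderated t: per-feature pooled variances are shrunk
toward a scaled inverse-χ² prior fit by the method of moments on
log s² (Newton inversion of the trigamma function), and the statistic
is referred to d₀ + d degrees of freedom. A plain Welch t is available
as a sensitivity switch. Calls need both gates: BH FDR < 0.05 computed
within each RNA category (matching the per-category bookkeeping of the
published table), and fold change > 1.5 or < 0.667. The two published
threshold phrasings (FC gates vs |log2FC| > 0.667, i.e. FC 1.587)
disagree; the FC gates are the default and `logfc_gate=0.667` exposes
the other reading.

## Trend profiles and efficacy

Trend analysis runs on the union of differential features over all
screened contrasts, using *group means* of log-CPM, not per-sample
profiles. The 8 templates are the sign patterns (s₁, s₂) ∈ {−1,0,+1}²
\ {(0,0)} of (DM−NC, Treat−DM), realized as 3-point vectors
(0, s₁, s₁+s₂) and numbered lexicographically; the two restoration
patterns land at ids 2 (down-then-restored) and 5 (up-then-restored).
Assignment is the argmax Pearson correlation with minimum r = 0.85,
ties to the lowest id, flat profiles unassignable (r recorded as 0).
The efficacy rule is sign(DM−NC) = −sign(Treat−DM) ≠ 0 together with a
consistency requirement |Treat−NC| ≤ α·|DM−NC|; "consistent with the
control" has no published threshold, so α = 0.5 is the package default
and is configurable (α → ∞ reduces to sign opposition, α = 0 demands
exact restoration).

## Enrichment, GO tree, pathway network

Over-representation is the one-sided upper-tail hypergeometric test
(one-sided Fisher), with BH FDR across sets reported alongside the raw
p < 0.05 gate. The universe defaults to all features of the relevant
category present in the expression matrix; no external background is
assumed. The GO tree is the sub-DAG induced by significant terms plus
every ancestor connecting them to the roots (non-significant ancestors
are flagged `ancestor_only`); an isolated two-term component in which
one significant term merely subsumes the other is removed from the
display edge set but kept in the records — the published description of
this pruning is garbled, so this interpretation is documented rather
than claimed. Pathway–pathway edges require member-gene Jaccard ≥ 0.2
(edge weight = Jaccard).

## Target prediction and ceRNA assembly

A full hybridization/energy scorer is unnecessary when prediction only
gates pairs, so targets are canonical seed sites: 7mer-m8 (Watson–
Crick match to miRNA positions 2–8), 7mer-A1 (positions 2–7 plus a
target A opposite position 1), and 8mer (both), with fixed scores
3/2/1 and U≡T equivalence. The scanner reports the strongest class per
seed region (the 7mer-A1 pattern nested inside every 8mer is
suppressed). Pairs survive only with opposed non-zero trend signs;
triads additionally require mRNA/sponge trend-sign equality and mRNA
membership in the enriched genes. By default the trends feeding this
stage are the *efficacy* trends (the stricter of the two defensible
readings); any assigned trend can be passed instead. Hub miRNAs are
ranked by degree with the 7-metric topology vector.

## Coexpression

The network is unsigned, a_ij = |cor|^β — the classical default in the
absence of a stated sign convention. β is the smallest power whose
binned log-log connectivity distribution fits a line with R² ≥ 0.8
(argmax R² with a warning otherwise). TOM follows the standard form
TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j)+1−a_ij). Modules are
average-linkage clusters of 1−TOM under a *static* cut — simpler and
deterministic compared with dynamic tree cutting. The default cut
height is 0.95: TOM dissimilarities concentrate near 1 for realistic
soft powers (within-block TOM at |cor| = 0.7 and β = 6 is ≈ 0.12, i.e.
dissimilarity ≈ 0.88, while background pairs sit at ≈ 1.0), so the cut
must sit near the top of the dendrogram to separate planted blocks
from noise; a low cut leaves every feature a singleton. Clusters below
10 members are merged into "grey"; labels are size-ordered color names
(largest = "turquoise"). Module eigengenes are first principal
components of standardized member expression, sign-oriented to
positive mean loading, and module–treatment association is the Pearson
correlation with a one-hot group indicator, p from the exact t
reference with n−2 df. The ncRNA+mRNA and circRNA+mRNA analyses run as
two separate invocations on concatenated matrices.

## Network topology

Metric definitions follow Cytoscape NetworkAnalyzer: per-component
computation (unreachable pairs excluded), closeness = 1/mean shortest
path, betweenness normalized by (n−1)(n−2)/2 within the component,
radiality = (Δ+1−L)/Δ with Δ the component diameter, neighborhood
connectivity = mean neighbor degree, and topological coefficient =
mean over partners sharing ≥ 1 neighbor of (shared neighbors +
adjacency)/degree, defined 0 for degree ≤ 1 and isolated nodes. Edge
lists are de-duplicated simple graphs; STRING-style confidence scores
are kept as attributes and filtered at 0.4 by default (the original
cutoff is unstated). Hub tables sort by degree descending, node id
ascending.

## Synthetic data: what it emulates, and what it does not

Counts are negative binomial (var = μ + φμ²) around gene-wise
lognormal baselines with lognormal per-sample size factors — the
standard parametric picture of bulk RNA-seq; no generative model is
published for the original data, so this is the package's choice.
Desk-scale defaults: 1200/250/250/180 features per category, 5
replicates/group (study scale, 10/group, via config), DE fraction
0.1, planted log2FC 2, dispersion 0.1 (typical for inbred-animal bulk
livers), library-size σ 0.2. Differential features displace the DM
mean; efficacy features (60% of DE) are restored to the control mean
in their responsive arms — half respond to all three arms, the rest to
a random subset — while non-efficacy DE features stay displaced in
every diseased arm. miRNA→target plantings pair an efficacy miRNA with
one mRNA and one sponge of opposite direction and identical responsive
arms, so sign opposition is exact in the planted means. Planted seed
sites are embedded in otherwise random UTRs and re-drawn until an
exhaustive scan finds exactly the planted site set; decoy UTRs are
re-drawn until clean. The PPI generator uses preferential attachment
(heavy-tailed degrees) or Erdős–Rényi. Phenotypes are Gaussian draws
at the published group means/SDs. A separate Gaussian equicorrelated
block generator (√ρ·latent + √(1−ρ)·noise) provides coexpression
benchmarks at a controlled within-block correlation.

Passing tests on these data show the *algorithms* recover what was
planted under the stated noise model; they do not show robustness to
features of real sequencing data the generator omits: batch effects,
GC/length biases, correlated dispersion–mean structure, isoform
ambiguity, or real miRNA binding thermodynamics.

## Numerical choices and degenerate inputs

BH FDR via the standard step-up (statsmodels), verified against the
literal definition; hypergeometric p via the exact survival function,
verified against combinatorial enumeration; graph metrics verified
against a brute-force BFS/path-enumeration oracle on all small graphs;
TOM verified element-wise against its formula. Flat trend profiles,
all-zero samples, empty groups, single-member modules, zero-variance
ANOVA, k ≤ 0 rankings and empty networks all have defined behavior
(documented errors or conventional zeros) rather than NaNs. All
randomness flows through `numpy.random.default_rng(seed)`; every
generator is byte-reproducible for a fixed seed.

## Problem sizes

Tests and the acceptance checks run at desk scale by design — a few
hundred features per category, 5 replicates/group, 50–100 seed
replicates for stochastic claims, graphs of ≤ 8 nodes for exhaustive
oracles and ~500 nodes for hub recovery. These sizes are the package's
validation conditions; study-scale inputs run through the same code
paths unchanged.

## Known limitations

- The published data-dependent results (specific differential counts,
  module colors, named hub genes) require the original sequencing
  data; the package validates schema and algorithmic behavior, not
  those values.
- The moderated t assumes approximate log-normality of CPM; very low
  counts are handled by the +1 offset, not by count-model inference.
- Static tree cutting can split a block whose internal correlation is
  strongly heterogeneous; dynamic cutting is out of scope.
- The seed-match scorer ignores 3' compensatory pairing, site
  accessibility and conservation.
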