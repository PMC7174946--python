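# cernapipe

A tested re-implementation of a liver multi-omic pharmacodynamics
analysis for a five-arm type-2-diabetes rat study: a normal control
(NC), an untreated diabetic arm (DM), and three treatments —
sitagliptin phosphate (SP), Fuzhujiangtang granule (FJG), and their
combination (SP-FJG). The pipeline screens four RNA categories (mRNA,
ncRNA, circRNA, miRNA) for differential expression, classifies
drug-efficacy expression trends, tests functional over-representation,
assembles sign-constrained ceRNA networks, finds weighted coexpression
modules, ranks interaction-network hubs, and computes the closed-form
physiology metrics (glucose-tolerance AUC, HOMA-IR). A synthetic-data
generator with planted ground truth stands in for the study's
sequencing data, so every stage is testable end to end.

## The models and statistics

**Physiology.** For a blood-glucose curve sampled at 0/30/60/120 min
(mmol/L), the tolerance-test summary is the trapezoid area over 2 h:

    AUC = 0.25·(BG₀ + BG₃₀) + 0.25·(BG₃₀ + BG₆₀) + 0.5·(BG₆₀ + BG₁₂₀)

and insulin resistance is HOMA-IR = FBG (mmol/L) × FINS (mIU/L) / 22.5.
Groups are compared by one-way ANOVA on mean ± SD panels.

**Differential screen.** Counts are CPM-normalized and log2(x+1)
transformed; each feature gets a moderated t statistic with
empirical-Bayes variance shrinkage (posterior variance
(d₀s₀² + d·s²)/(d₀ + d) from a scaled inverse-χ² prior fit to all
features). A feature is called when FDR < 0.05 (Benjamini–Hochberg,
within category) *and* its fold change exceeds 1.5 or falls below
0.667 (an |log2FC| > 0.667 gate is available as an alternative).

**Trend profiles.** Each differential RNA's (NC, DM, treatment)
group-mean profile is correlated against the 8 sign-pattern templates
of (DM−NC, Treat−DM); assignment needs Pearson r ≥ 0.85. Profiles 2
and 5 — disease displacement reversed by treatment — are the
drug-efficacy trends, additionally requiring
|Treat − NC| ≤ 0.5·|DM − NC|.

**ceRNA.** miRNA targets are canonical seed matches (8mer, 7mer-m8,
7mer-A1) found by exact scanning; pairs must have opposed trend signs,
and a triad (miRNA, mRNA, sponge) needs the miRNA to target both, the
mRNA and sponge trends to agree, and the mRNA to be functionally
enriched.

**Coexpression.** Unsigned WGCNA-style network a_ij = |cor|^β with β
from the scale-free fit criterion; modules are average-linkage clusters
of 1−TOM; module eigengenes (first principal component) are correlated
with treatment indicators.

**Topology.** NetworkAnalyzer-convention per-node metrics (degree,
mean shortest path, betweenness, closeness, clustering, neighborhood
connectivity, radiality, topological coefficient) with degree-ranked
hub tables.

## Worked example

The numbered drivers under `analysis/` run the whole study on the
synthetic cohort (5 animals/group, desk scale):

```bash
python analysis/01_simulate_study.py
python analysis/02_phenotype_tables.py
...
python analysis/08_ppi_topology.py
```

`01` prints, for seed 0:

```
simulated 25 animals across 5 groups (seed 0)
  mRNA: 1200 features x 25 samples
  ...
  planted DM-vs-NC differential features: 188
  planted efficacy features per arm: SP=89, FJG=89, SP-FJG=89
```

`02` recovers the physiology tables from the per-animal draws — e.g.
HOMA-IR group means `NC=2.12, DM=12.45, SP=7.20, FJG=7.82,
SP-FJG=5.69`, reproducing the published pattern (diabetic insulin
resistance lowered by every treatment, most by the combination), and
`03` reports planted-truth recovery of the differential screen
(DM vs NC recall 0.995 at this seed). `07` shows exact recovery of
three planted coexpression blocks (adjusted Rand index 1.000) and `08`
recovers all 10 planted interaction hubs in the top-10 degree ranking.

The same stages are scriptable through the `cernapipe` CLI
(`simulate`, `de`, `targets`, `topology`, `coexpr`, `enrichcmd`,
`run-all`, ...), e.g. `cernapipe run-all --seed 1 --outdir results/run`.

## Layout

- `src/cernapipe/` — the library: `synthetic`, `phenotypes`,
  `diffexpr`, `trends`, `enrich`, `cerna`, `wgcna`, `topology`,
  `pipeline`, `cli`, `reference` (published group-level values), `io`.
- `analysis/` — numbered narrative drivers writing under `results/`.
- `tests/` — unit, property and acceptance suites (oracle-based:
  enumeration for the hypergeometric test, step-up definition for BH,
  brute-force graph metrics, definitional TOM).
- `docs/methods.md` — modeling assumptions, parameter defaults, and
  known limitations.
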