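# Methods

This note documents the statistical procedures implemented in `xplat`, the
assumptions behind them, the defaults and why they were chosen, and what the
synthetic-data validation does and does not establish.

## Study design model

The canonical design is 5 modes of action (MOA) × 3 chemicals × 3 biological
replicates (45 treated samples) plus vehicle controls matched by route
class. Two route classes are modeled (corn-oil vs non-nutritive vehicle);
each MOA has chemicals in both classes so route is not confounded with MOA.
The default synthetic design carries 9 controls per route class, giving 63
samples in total. Treated samples are linked to controls through
`control_match_group`, which a helper derives from `route_class` when a
sample sheet does not state it explicitly.

## Normalization and log2 ratios

*Targeted counts*: genes whose total read count across all samples is ≤ 214
are removed, the remainder normalized to counts per million and transformed
as `log2(cpm + 1)`. The 214 threshold is the assay's published convention
and is an ordinary parameter.

*Whole-transcriptome counts*: per transcript,
`Index = log2(Z + √(4 + Z²)) − 1` with `Z = c·n/(N·L)` for read count `n`,
sample depth `N`, transcript length `L` and scale constant
`c = 10¹²/2`. The transform behaves like `log2(Z)` for large `Z` and tends
to 0 as `Z → 0`. Transcripts with fewer than 3 reads get the imputed value
5.0, applied at the normalization stage (before ratio construction), so
imputed values do participate in control means. The constant `c` is
configurable; the default makes `Z` a scaled reads-per-base-per-depth
quantity.

*Ratios*: for each treated sample, the mean of the log2-normalized values of
its matched control samples is subtracted per gene. Controls are dropped
from the output. Consequence worth noting: the control-mean noise
(variance σ²ₑ/n_controls) is shared by every treated sample in a match
group, which downstream analyses see as a small route-class-level variance
component.

## PVCA

The procedure: (1) N × N Pearson correlation matrix of the samples from the
genes × samples log2-ratio matrix; (2) eigendecomposition (eigenvalues sum
to N); (3) retain the smallest K whose cumulative eigenvalue proportion
reaches a threshold (default 0.5876, the benchmark convention; a plain
config value); (4) fit each retained eigenvector with
`y = 1μ + Σ_f Z_f u_f + e`, all factors (chemical, MOA, route) random
intercepts, by REML; (5) standardize each PC's components to proportions;
(6–7) average across PCs weighted by eigenvalue proportions and renormalize.

REML is implemented directly: the restricted likelihood
`log|V| + log|X'V⁻¹X| + y'Py` with `V = Σ σ²_f Z_f Z_f' + σ²_e I` is
minimized over non-negative variances by L-BFGS-B from three fixed starting
points (even split, residual-dominated, factor-dominated), objective
tolerance 1e-8. This is deterministic; eigenvector sign is irrelevant
because the components are quadratic in the response. The implementation is
cross-checked in the tests against statsmodels' MixedLM: on every
disagreement our optimizer attains an equal or better restricted likelihood.

**Retained-K vs full spectrum.** With K chosen at ~59% cumulative variance,
the eigenvalue tail — which holds the iid residual variance spread over all
directions — is discarded, so the retained factors are over-weighted. For
validating recovery of generating fractions the full spectrum
(`threshold=1.0`) is therefore used: the eigenvalue-weighted average then
approximately decomposes total variance. The default threshold remains the
benchmark convention for comparing real platforms.

**Identifiability of route.** With only two route levels, per-PC REML cannot
distinguish a genuine route effect from the difference between the two
route groups' mean chemical effects (expected leakage
≈ σ²_chem·(1/n₁ + 1/n₂) over the per-route chemical counts), nor from the
shared control-mean noise introduced by ratio construction. On synthetic
data with nominal fractions {moa 0.4, chemical 0.3, route 0.05, residual
0.25}, the recovered split is typically ≈ {0.42, 0.23, 0.16, 0.17}: MOA,
chemical and residual within ±0.1 of truth, route overstated by ~0.1–0.14
for the structural reasons above. This is a property of the estimator on
this design, not an implementation defect, and is asserted as-is in the
acceptance tests (the route component fails the ±0.1 band).

## Replicate RMSD

`RMSD(x, y) = √(Σᵢ (Iᵢₓ − Iᵢᵧ)²/N)` over the platform's genes. The
chemical-RMSD averages a chemical's C(3,2) = 3 replicate pairs; the average
chemical-RMSD averages chemicals unweighted; the MOA-RMSD averages all
C(9,2) = 36 treated pairs within a MOA (cross-chemical pairs included, per
the printed pair count); the platform-RMSD averages the five MOA values.
For iid N(0, σ²) replicate noise the expected pair RMSD tends to σ√2, which
the tests verify by simulation. Genes with missing values in a pair are
excluded pairwise.

## Signal-to-noise and pattern extraction

Group index i runs over MOAs; nᵢ counts the treated samples in the group
(9 in the canonical design; configurable to chemical-level means). Signal
is `max(ḡ)` if all group means are positive, `−min(ḡ)` if all negative,
`max − min` otherwise; noise is
`√( [Σ(nᵢ−1)sᵢ² / Σ(nᵢ−1)] · Σ 1/nᵢ )`; SNR = S/N, with an `inf` sentinel
at zero noise.

Pattern grouping is this package's documented heuristic implementing the
published contract (correlation, magnitude and SNR criteria): candidates
are genes with SNR ≥ 3; the candidate with the highest correlation density
(neighbours at Pearson r ≥ 0.64) seeds a pattern; members are candidates
reaching r ≥ 0.64 with the seed; a pattern of size k is accepted if the
binomial probability of k−1 such neighbours — with the per-gene null rate
estimated from 20,000 column-permuted profiles — is below 1e-4, with a
minimum pattern size of 5. Accepted members leave the pool; rejected seeds
leave alone. All thresholds are configurable; extraction is deterministic
given the seed. Each pattern reports magnitude (largest absolute MOA-group
mean of the pattern's mean profile), noise (mean member N) and their ratio;
the set reports the unweighted mean pattern SNR. No claim of
bit-compatibility with any legacy pattern-extraction program is made.

## Nested MOA-ANOVA

Per gene, `Y = μ + MOAᵢ + Routeⱼ + Chem(MOA×Route)ᵢⱼₖ + ε`, errors iid
Gaussian, chemical random. Sums of squares are computed by projection
differences (Type II: MOA adjusted for route); because chemical is the
random nesting stratum, `F = MS_MOA / MS_chem-within` with df (4, 9) in the
canonical design — the classical expected-mean-squares test, exact and
deterministic in the balanced case. Degenerate genes (zero variance) are
flagged with p = 1; a single-level route is dropped with a warning.
Benjamini–Hochberg q-values control FDR; gene lists default to q < 0.01
(the convention used for the downstream clustering stages), with 0.05
available.

## Clustering and projection

Genes are standardized to mean 0 / sd 1 (population denominator).
"Cosine correlation" is implemented as uncentered correlation (dot product
over norms); centered Pearson is available by flag. Ward linkage uses the
squared-distance update (Ward.D2 convention) on the given distances. The
same metric serves both axes. The MOA agreement report cuts the tree at
k = 5, scores majority-MOA purity per cluster, and names chemicals whose
replicates mostly fall outside their MOA's plurality cluster.

## Enrichment and subtree labeling

Annotations are propagated up is_a edges (only is_a; part_of is ignored) so
a gene annotated to a child counts once for every ancestor. For a list of L
annotated genes, a term with `pop_hits` genes in a universe of U and
`count` list hits gets `FE = (count/L)/(pop_hits/U)` and a hypergeometric
upper-tail p (EASE's count−1 variant available for p only); BH across
tested terms; terms need ≥ 5 list genes. The plain FE ratio reproduces the
packaged benchmark table (49 terms × 3 platforms) to 2 decimal places. The
universe is user-supplied for real data (the benchmark uses 17,535).

Enrichment-profile clustering takes the term × list matrix of −log10 p
(missing/non-significant cells imputed from p = 1, hence exactly 0),
clusters rows with 1 − Pearson distance and Ward linkage, slices the tree
at distance 0.9 (correlation 0.1), and discards clusters under 5 terms.
Each cluster is labeled by the node of its GO subtree (cluster terms plus
ancestors) with the maximum number of rootward paths, computed by dynamic
programming over the DAG; ties break toward the smaller term ID. On a
linear chain this labels the deepest term.

## Synthetic data

Per gene, log2 expression is baseline N(8, 2²) plus Gaussian random effects
for MOA, chemical and route levels and iid residual, with variances
proportional to the requested fractions (total variance 1 log2² by
default). Treatment-linked effects apply to treated samples only; controls
receive baseline plus residual, so vehicle-matched ratios retain the full
treatment variance structure. A designated gene subset (default 10%)
carries fixed MOA offsets of ±2 log2 units, cycling through the MOAs with
alternating signs. Counts derive from a per-sample multinomial over
softmax-style abundance proportions at Poisson library sizes (defaults:
10⁷ reads for the transcriptome-wide rendering, 10⁶ for the targeted
panel). The targeted panel defaults to 2,284 genes of which 229 are
near-zero background probes — the assay's nominal content — so the ≤ 214
filter removes them plus a handful of genuinely low-abundance genes
(≈ 2,050 survivors). One global seed drives everything through spawned
substreams.

What the generator does *not* emulate: probe-sequence effects and
saturation on arrays, library-preparation and positional biases in
sequencing, overdispersion beyond multinomial sampling, correlated gene
modules beyond the planted differential blocks, and batch structure.
Passing tests therefore demonstrate correctness of the statistical
machinery under the mixed-model assumptions, not robustness to the failure
modes of real assays.

Problem sizes used in the validation suite (4,000-gene bundles, 2,000-gene
null panels, 5,000-gene RMSD simulations) were chosen to keep Monte-Carlo
error well inside the asserted tolerances while remaining quick to run.

## Known limitations

- Route variance is structurally overstated by PVCA on this design (two
  route levels; see above).
- The ANOVA's REML-based alternative for unbalanced designs is not
  implemented; unbalanced data fall back to Type-II projections with a
  warning.
- Enrichment on fully synthetic bundles is weak by construction whenever
  the MOA-varying list is a large fraction of the universe (FE is bounded
  by universe/list); the enrichment arithmetic is instead validated against
  the packaged benchmark summary.
- The pattern-extraction heuristic preserves the published criteria but is
  not a clone of any specific legacy implementation.
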