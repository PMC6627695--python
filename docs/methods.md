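# Methods

## Data model

The unit of analysis is a genes × samples grid of quantification cycles
(Ct). Ct, Cq and Crt dialects are treated as the same currency; the label
is carried as metadata only, since all downstream statistics are invariant
to which threshold convention produced the values. Undetected assays are an
explicit missing marker (NaN); every present value must be finite and
positive. Detection filtering keeps only genes observed in every sample —
the standard prerequisite for ratio-based stability statistics, which have
no principled treatment of informative dropout.

Sample metadata is a sample → (donor, group) map. Group-aware analyses
require ≥ 2 samples per group.

Descriptive statistics use the ordinary sample standard deviation (n−1).
This is deliberately distinct from BestKeeper's dispersion (below): the two
answer different questions (spread of the distribution vs. expected
absolute deviation) and are both reported in practice.

Inter-dataset correlation pairs the two groups' **per-gene mean Ct**
vectors (gene-wise scatter). Donor-level pairing is not assumed — group
sizes may differ — and the qualitative bands are R² > 0.8 "very strong",
R² < 0.6 "fair", otherwise intermediate.

## Transformation

geNorm, comparative ΔCt and NormFinder operate on relative quantities

    q_gs = (1 + E_g) ^ (Ct_min,g − Ct_gs),   0 < E_g ≤ 1,

with `Ct_min,g` the gene's minimum over the analyzed samples, so q ∈ (0, 1]
and max_s q = 1 per gene. E defaults to 1 (ideal doubling per cycle);
per-gene efficiencies are supported but every stability value below is
invariant to the choice of the reference point `Ct_min`, which only fixes
the scale of reported q. BestKeeper uses raw Ct directly.

## The four estimators

**BestKeeper.** Dispersion = mean absolute deviation of Ct around the
gene's arithmetic mean; CV% = 100·dispersion/mean as an auxiliary
diagnostic. The MAD (rather than the n−1 SD) matches the classic applet's
"SD (± Ct)" output and is systematically ≤ the sample SD (asserted in the
tests). Because it works on raw Ct, BestKeeper absorbs shared per-sample
technical offsets into its score — the one estimator that does, which the
offset-invariance property test asserts in both directions. The applet's
index-correlation machinery is intentionally out of scope; only the
dispersion ranking is produced.

**geNorm.** For genes j, k: `A_jk,s = log2(q_js/q_ks)`,
`V_jk = SD_s(A_jk)` (n−1), `M_j = mean_{k≠j} V_jk`. The gene with the
largest M is excluded and M recomputed until two genes remain; they share
the final M. Since `V_jk` never depends on other genes, the pairwise matrix
is computed once (via the covariance identity
`V² = var_j + var_k − 2cov_jk`) and each round only re-averages it; the
brute-force oracle in the tests recomputes every pairwise SD from scratch
each round and must agree exactly. Tie at an exclusion step: the gene later
in input order is excluded. Ranks: final pair takes 1 and 2, ordered by
their M in the last 3-gene round (tie → input order); excluded genes take
3, 4, … by reverse exclusion order. The pairwise-variation V(n/n+1)
criterion for choosing how many RGs to use is not implemented (not part of
this workflow).

**Comparative ΔCt.** Stability of g = `mean_{h≠g} SD_s(y_g − y_h)` on the
transformed values y = log2 q (plain Ct differences at E = 1). With E = 1
this is exactly the mean of geNorm's V row computed on the full gene set —
a cross-method identity the acceptance suite checks to 1e−9 over 100
random matrices.

**NormFinder.** On y = log2 q, per-sample means over genes are subtracted
(sample effects). Within group g (n_g samples, l genes) the naive per-gene
residual variance s²_ig around the gene's group mean is biased because the
subtracted sample means contain a 1/l share of the gene itself; under the
additive model E[s²_i] = σ²_i(1 − 2/l) + Σ_k σ²_k / l². Solving the moment
equations gives the corrected estimator

    σ̂²_ig = l/(l−2) · ( s²_ig − Σ_k s²_kg / (l(l−1)) ),   clipped at 0,

which requires l ≥ 3. The intergroup deviation d̂_ig is the gene's
sample-effect-corrected group mean minus its across-group mean; deviations
sum to zero over genes within each group by construction. Its sampling
variance accounts for the across-group mean re-entering with weight 1/k:

    Var(d̂_ig) = ((k−1)/k)² σ̂²_ig/n_g + (1/k²) Σ_{g'≠g} σ̂²_ig'/n_g'.

The deviation variance across genes is taken as
`γ̂² = Σ d̂² / ((l−1)(k−1))` — the mean square over the free cells left by
the sum constraints, with the sampling-noise share deliberately **not**
subtracted. This keeps the shrinkage conservative and γ̂² strictly positive
whenever any deviation is observed; a fully moment-matched γ̂² (noise share
subtracted) over-shrinks genuine group effects — in simulation it detects a
planted 2-cycle group shift as the worst gene in only ~2/3 of replicates,
versus ≳95% with the conservative form — and collapses to all-tie rankings
when clipped at zero. Then

    d̃_ig = d̂_ig · γ̂² / (γ̂² + Var(d̂_ig)),
    ρ_ig = |d̃_ig| + sqrt(σ̂²_ig / n_g),
    ρ_i  = mean_g ρ_ig.

Single-group mode (used for per-tissue runs, where no sub-grouping exists)
is ρ_i = σ̂_i. Lower ρ = more stable.

## Consensus

The comprehensive score is the geometric mean of the four **integer ranks**
(never of raw stability values, whose scales differ). Final ordering is
ascending geomean; ties break by the better ΔCt rank (ΔCt aggregates all
pairwise information), then input order. Top-k overlap reports the
exclusive Venn region counts of the per-method top-k sets (k = 15 by
default in the CLI).

## Impact of reference choice

Normalization is `ΔCt_s = Ct_target,s − Ct_ref,s`; lower ΔCt = more target
relative to the reference. Group comparisons use the unpaired **pooled-
variance** Student t-test (two-tailed); Welch's correction is intentionally
not applied, matching the conventional analysis this workflow reproduces.
Significance tiers: p ≤ 1e−4 "****", ≤ 1e−3 "***", ≤ 0.01 "**", ≤ 0.05
"*", ≤ 0.1 "#" (trend band), else ns. Outlier screening is a single
two-sided Grubbs pass per group (G = max|x−x̄|/s, critical value
`((N−1)/√N)·√(t²/(N−2+t²))` with t the upper α/(2N) quantile at N−2 df),
removing at most one point per group and **off by default** — flags are
always reported so the analyst can see what screening would have done. A
zero-variance vector has an undefined G; it is reported as degenerate, not
an outlier.

Heatmap clustering follows the common web-tool convention: normalize every
gene by the chosen reference (dropping the reference's identically-zero
row), center each row, then agglomerative clustering with distance
1 − Pearson r and average linkage, on rows and on columns. Rows with zero
variance after centering (constant offset from the reference) have
undefined correlation distance; they are excluded from the dendrogram with
a warning and listed in the result — never imputed. The tested artifact is
the linkage tree (also exported as Newick) plus the centered matrix;
figure rendering is left to the caller.

## Synthetic data

The generator draws `Ct_gs = B_g + δ_{g,group(s)} + u_s + ε_gs` with
baselines B_g ~ U(13, 26) cycles (the realistic abundance span of small-RNA
assays on array-format qPCR panels), shared technical offsets
u_s ~ N(0, τ²), and gene noise ε_gs ~ N(0, σ_g²). Defaults: 47 genes, three
groups of 8/9/9 samples, τ = 0.5 cycles, background σ = 1.0 cycle (typical
inter-donor biological plus assay variability), two planted stable genes
(σ = 0.2), two unstable genes (σ = 2.0), one group-shifted gene (+2 cycles,
i.e. 4-fold, in the last group), no missingness. Normal noise on the Ct
(log-fluorescence) scale is the standard qPCR error model. Missing calls,
when enabled, are injected uniformly at random into background genes only,
so planted genes always survive the detection filter; abundance-dependent
dropout is deliberately not modeled. The emitted truth object stores every
draw (including ε), so the matrix is reconstructible exactly.

What passing recovery tests shows — and does not. The generator emulates
additive group structure, heteroscedastic noise and technical offsets; it
does not emulate plate/position effects, efficiency variation between
replicates, probe cross-hybridization, or abundance-dependent detection.
Recovery results therefore validate the estimators' contracts (ranking by
true stability, offset invariance, shift penalization), not their behavior
under every real-data pathology.

The recovery experiment replays the full pipeline per replicate and
reports: (a) how often a planted stable gene takes consensus rank 1 —
≥ 95% under the strong-separation configuration (stable σ = 0.1 vs
background σ = 1.5 with 2-cycle shifts, 100 replicates); (b) how often the
shifted gene lands in NormFinder's worst decile (reported, typically
~80% when it competes with σ = 2 unstable genes for the bottom slots); and
(c) that raising τ with gene-level draws held fixed changes BestKeeper's
values and only BestKeeper's. Per-replicate seeds derive from a
SeedSequence spawn of the experiment seed.

## Numerical choices and degenerate inputs

- All "sample SD" computations use the n−1 denominator unless a method's
  definition dictates otherwise (BestKeeper's MAD).
- Rank ties anywhere default to input order (stable sort); documented
  method-specific tie-breaks take precedence (geNorm exclusion, consensus
  ΔCt tie-break).
- Variance estimates are clipped at 0 before square roots; shrinkage with a
  zero denominator yields a zero shrunk deviation rather than NaN.
- A t-test on two identical constant groups reports t = 0, p = 1 (no
  evidence of difference) instead of NaN.
- Invariance tolerances asserted in tests are 1e−9 absolute.
- Problem sizes in the default suite (10–47 genes, 8–26 samples, 25–300
  replicates per experiment) were chosen as the smallest that make the
  statistical assertions sharp; the full suite runs in well under a minute.

## Known limitations

- NormFinder's shrinkage weighting follows the conservative formulation
  documented above; alternative moment-matched variants exist and can
  reorder genes with weak group structure.
- BestKeeper's index correlation and significance machinery is not
  implemented (dispersion ranking only).
- No multiple-testing correction is applied across targets in the impact
  analysis; comparisons are reported per pair, as in the conventional
  workflow this package reproduces.
- Efficiencies are assumed known (default E = 1); estimating E from raw
  fluorescence is out of scope.
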