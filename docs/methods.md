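# Methods

`coexnet` implements the integrative lncRNA–mRNA analysis used in two-group
expression-microarray studies (here: osteoarthritis cartilage from Tibetan
vs Han patients, 5 vs 3 samples): normalization, differential expression,
co-expression screening, genomic cis/trans classification of lncRNA targets,
hub ranking of the trans network, and gene-set over-representation. This
note records the models, the parameters that matter, the numerical
conventions, and what the synthetic data do and do not establish.

## Normalization and transformation

Raw intensities are quantile-normalized across samples and then
log2-transformed, in that order. The normalization target is the reference
distribution r = mean across samples of the per-rank sorted intensities;
sample j's value of rank i is replaced by r_i. Ties within a sample receive
the mean of the reference values over the ranks they span (classic
rank-mean handling). For tie-free data the operation leaves every sample
with the same value multiset, preserves within-sample order, and is
idempotent; with ties those properties hold only up to the spanned-rank
means. Ties are measure-zero for continuous intensities.

Quantile normalization assumes the samples' intensity distributions are
exchangeable — i.e. that differential expression does not change the
marginal distribution. It is unbiased in that regime and systematically
distorts *null* features when one group's distribution is genuinely shifted
(see the generator section for how the simulations respect this).

`log2_transform(m, offset)` maps v to log2(v + offset); offset defaults to
0 and exists because raw data may contain exact zeros (any non-positive
v + offset is an error, not a silent −inf).

## Differential expression

Per probe, a two-sided pooled-variance Student's t with
df = n₁ + n₂ − 2 compares case to control on the log2 scale
(Welch's t available behind a flag). Conventions for exactly zero pooled
variance: equal means → (t = 0, p = 1); unequal means → (t = ±inf, p = 0);
both flagged `degenerate_flag`. Fold change is oriented case − control, so
"up" means higher in the case (Tibetan-analog) group.

A probe is called up when log2FC > 1 (fold change strictly > 2) and
p < 0.05, down when log2FC < −1 and p < 0.05, otherwise ns. Both
inequalities are strict: log2FC exactly 1 is not a call. The default
criterion uses the raw p-value; Benjamini–Hochberg adjusted p-values
(statsmodels step-up) are always reported and can replace the criterion
with `use_adjusted`. The volcano table reports −log10 p with exact-zero
p-values capped at 350.

## Co-expression screen

Every DE lncRNA is Pearson-correlated with every DE mRNA. The p-value is
the exact t-transform t = r·sqrt((n−2)/(1−r²)) on n−2 df, two-sided. A pair
is retained when |r| > 0.7 (strict — |r| = 0.7 exactly is rejected) and
p < 0.05; retained pairs are sorted by |r| descending, then lncRNA and mRNA
symbol, so the output order is total and deterministic. The full pre-filter
r grid is emitted for heat-map use. Zero-variance probes are skipped per
pair with a warning, never a pipeline abort.

The screen's sample scope is configurable: `all` (default, both groups
pooled) or `case_only`. Two caveats are inherent to the design and worth
stating. (1) Pooling both groups makes any two same-direction DE probes
correlate strongly through the shared group shift, so the screen retains
most DE×DE pairs — co-expression across groups conflates the group factor
with within-group covariation. (2) With only five case samples, p < 0.05
at df = 3 requires |r| ≳ 0.878, so `case_only` admits only very strong
correlations. Neither mode is hidden or corrected; both are reported as
computed.

## Cis/trans classification

Coordinates are BED-convention throughout: 0-based, half-open. The distance
between a lncRNA and an mRNA is the gap between the whole gene intervals
(0 when they overlap or touch), not TSS-to-TSS. A retained pair is **cis**
when both loci are on the same chromosome and the gap is ≤ 300,000 bp —
the boundary itself is cis, because trans is defined by "distance larger
than 300 kb" — and **trans** when the gap exceeds the window or the
chromosomes differ. Strand is ignored: an up- and downstream window is
symmetric. Pairs with a missing locus are `unclassified` and counted in the
run log; cis + trans + unclassified always equals the retained-pair count.

## Trans network and hub scoring

Trans pairs form an undirected bipartite graph on gene symbols (a symbol
used by both biotypes gets a role suffix), edge weight |r|. Nodes are
scored by the maximum neighborhood component (MNC): the order of the
largest connected component of the subgraph induced on the node's
neighborhood. Open neighborhoods (the cytoHubba definition) are the
default. On a strictly bipartite graph the open-neighborhood MNC is
provably ≤ 1 for every node (a node's neighbors all lie on the opposite
side and are mutually non-adjacent); this degeneracy is asserted as a
structural test. Because of it the package also provides the closed mode
(N(v) ∪ {v}) and an option to densify the network with mRNA–mRNA
co-expression edges above the same |r|/p filter; how the original analysis
obtained a non-degenerate MNC ranking on a bipartite network is not
reconstructable, so no mode is asserted as "the" procedure. The top-k
trans interactions (k default 100, counted as edges) are ranked |r|
descending, then p ascending, then symbols.

## Over-representation analysis

DE mRNA symbols are tested against GMT gene sets with the one-sided
hypergeometric upper tail P(X ≥ k), X ~ Hypergeom(N, K, n), summed exactly
in log space (gammaln + logsumexp). The background universe defaults to all
mRNA symbols on the array annotation, the standard choice for array ORA,
and is configurable. Only intersections with the universe matter: set
members and DE symbols outside it are dropped (with a logged count).
p-values are BH-adjusted across all tested sets; output is sorted by p with
set-name tie-break. DAVID's modified Fisher (EASE) score is deliberately
not emulated; the exact hypergeometric tail is the standard local
equivalent.

## Synthetic data generator

The generator emulates the study design the analysis assumes, with full
ground truth:

- **Design**: 5 case vs 3 control samples (defaults), mRNA and lncRNA
  probes, log2 signal = baseline + group effect + noise, exported on the
  raw scale via 2^x so the normalize-then-log2 path is exercised.
- **Baselines**: uniform on [4, 12] log2 units. Planted-up probes draw
  their baseline from [lo, hi − effect] and planted-down probes from
  [lo + effect, hi], so the shifted state stays inside the global dynamic
  range — the constraint a scanner's dynamic range imposes on real arrays.
  This keeps the two groups' marginal intensity distributions exchangeable,
  the regime in which quantile normalization is valid; without it the
  normalization step visibly biases null probes.
- **Effects**: ±3.0 log2 units on planted probes (default), noise SD 0.5.
  Planted positions are leading blocks of the probe list, so truth
  structure is invariant to the seed.
- **Planted correlations**: a pair shares a latent factor with loading
  sqrt(|rho|) and independent residuals scaled sqrt(1−|rho|), all times
  noise_sd — expected *within-group* Pearson correlation exactly rho with
  unchanged marginal variance. Across both groups the observed correlation
  of two same-direction DE probes is higher, because the group shift adds
  covariance; that is a property of two-group designs, not an artifact.
- **Geometry**: deterministic. Pair classes plant gaps of 100,000 bp
  (cis_near), exactly 300,000 bp (cis_boundary, pinning the inclusive
  boundary end to end), 500,000 bp (trans_far), or different chromosomes
  (trans_diffchrom), in reserved regions of chr1/chr2; all other probes are
  tiled over chr3–chr22 with ≈1 Mb spacing so no background pair can fall
  inside the window.
- **Gene sets**: one set drawn 80% from the planted DE mRNAs plus
  uniform-random sets.
- **Determinism**: identical config and seed reproduce every artifact byte
  for byte; changing only the seed changes values but neither dimensions,
  truth structure, nor annotation.

The **replica fixture** plants the reported scale of the emulated study:
49/68 up/down lncRNAs, 158/139 up/down mRNAs, effect 3.0, noise 0.5, four
cis pairs (within-group rho 0.805, 0.833, 0.833, 0.857; one on the 300 kb
boundary; symbols lnc-SDIM1/SDIM1, lnc-CYB5R2/CYB5R2, lnc-CCDC67/CCDC67,
lnc-OTOA/OTOA — synthetic stand-ins, not real measurements) and six trans
pairs. Fixture probe totals are 500 mRNA / 200 lncRNA: with noise SD 0.5 on
a 5v3 design a null probe passes the joint volcano filter with probability
≈2×10⁻³ per direction, so at a few hundred null probes per biotype the
expected chance calls per class stay well below one and planted-count
recovery can be asserted within ±5%. Distribution-level behavior at array
scale is exercised separately (normalization invariants on a 50,000×8
matrix; null calibration on a 20,000-probe zero-effect design).

What the generator does **not** model: probe-level physics (spot
background, dye effects), probe–probe correlation beyond the planted
structure, heavy-tailed or intensity-dependent noise, and the real
covariance of cartilage transcriptomes. Passing recovery tests therefore
demonstrates correctness of the algorithms under the stated model, not
biological validity on real arrays.

## Numerical choices

- All numeric kernels force C-contiguous float64 input, so results are
  bit-identical whether a matrix arrives from memory or is re-read from a
  written TSV (numpy's pairwise-summation order depends on memory layout).
- Readers parse floats with round-trip precision; writers emit shortest
  round-trip decimals — a written table re-read reproduces values exactly.
- r is clipped to [−1, 1] after the product-moment evaluation; 1 − r² ≤ 0
  maps to p = 0.
- The run manifest contains no timestamps or absolute paths; stage outputs
  are recorded as SHA-256 digests keyed by file name, so two identical runs
  produce byte-identical manifests.

## Known limitations

- The pooled t at n = 5 vs 3 has limited power and its normality assumption
  is unchecked; moderated (limma-style) statistics are deliberately out of
  scope.
- Open-neighborhood MNC is uninformative on purely bipartite networks (see
  above); degree is the de-facto ranking there.
- ORA treats genes as exchangeable; no topology or expression-level
  weighting.
- The cis window (300 kb) is a convention, not an inferred quantity; the
  package is genome-build agnostic and classifies whatever coordinates the
  annotation supplies.
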