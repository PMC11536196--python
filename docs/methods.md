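# Methods

This note documents the statistical model behind `symptomnet`, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical decisions that matter when reproducing results.

## Estimation chain

**Input.** A person × criterion binary matrix with a group label per person.
The canonical criterion set is the nine DSM-5 gambling-disorder indicators
(A1–A9); validation rejects non-binary cells and, for diagnosed cohorts,
rows meeting fewer than 4 criteria can be filtered (`validate_diagnosis`).
Groups are always estimated fully independently.

**Base correlation (`method`, default `phi`).** Two readings of
"correlation between binary criteria" are supported:

- `phi`: Pearson on the 0/1 columns. Most literal, numerically robust at a
  few hundred persons, and the default.
- `tetrachoric`: the correlation of the latent bivariate normal assumed to
  underlie each 2×2 table, with thresholds fixed at the normal quantiles of
  the margins. With margins fixed, maximizing the bivariate-normal
  likelihood over ρ is equivalent to matching the model P(both met) to the
  observed proportion; we solve that equation by bracketing (Brent). Tables
  with a zero cell get the standard +0.5 continuity correction and the pair
  is flagged on the result. The bivariate normal CDF is evaluated through
  Owen's T function (machine-precision agreement with generic multivariate
  integration, and orders of magnitude faster).

**Partial correlations.** The base matrix is inverted to a precision matrix
and standardized: `r_ij·rest = −P_ij/√(P_ii P_jj)`. Near-singular matrices
are ridge-regularized by the smallest diagonal addition that lifts the
minimum eigenvalue to 1e−8; the ridge is recorded on the result and a
matrix needing more than 0.1 is rejected as singular. Precision-inversion
agrees with the residual-regression definition of partial correlation to
1e−8 on random positive-definite fixtures (property-tested).

**Significance gate (`alpha`, default .05).** An edge is retained iff its
two-sided p-value is below α; retained edges carry the signed partial
correlation as weight. Negative weights are possible in principle and are
not suppressed. No multiple-testing correction is applied by default (the
descriptive p < .05 rule standard in this literature); Bonferroni and
Benjamini–Hochberg adjusted p-values are available via `mtc`.

*Phi path.* `t = r √((n−k−2)/(1−r²))` on `n−k−2` df, k = #criteria − 2.
A Fisher-z variant (`test="fisher"`) agrees to ~3 decimals at the sample
sizes of interest.

*Tetrachoric path.* Two facts break the t-transform here. First, a
tetrachoric estimate is intrinsically noisier than a Pearson correlation at
the same n — increasingly so at extreme margins (e.g. a criterion with 94%
prevalence). A delta-method variance accounting for the multinomial
covariance of (p11, margins) quantifies this and is exposed as an
"effective sample size" per pair (`BaseCorrelation.effective_n`). Second,
a matrix assembled from 36 separate pairwise estimates is not a coherent
joint (Wishart) estimate, so partialling adds further variance that no
single-pair formula captures. The pipeline therefore estimates the standard
error of every partial correlation directly by a grouped jackknife:
persons are assigned round-robin to B = 20 blocks (deterministic, no
randomness), the partial-correlation matrix is recomputed with each block
deleted, and `SE² = (B−1)/B · Σ_b (θ_b − θ̄)²`; p-values come from
`t = r/SE` on B−1 df. Monte-Carlo checks in the test suite show this keeps
the per-edge false-positive rate near nominal where the raw t-transform
inflated it to ~0.3, at the cost of ~21× the estimation work (still well
under a second for a 9-criterion group of several thousand persons).
The jackknife needs at least 5 rows per block (n ≥ 100 at B = 20).

**Centralities and topology.** Conventions are fixed so reported values are
directly comparable with common network-visualization software:

- *Eigenvector centrality*: power iteration on the absolute-weighted
  adjacency (tolerance 1e−10; the iteration matrix is shifted by the
  identity, which leaves eigenvectors unchanged but guarantees convergence
  on bipartite graphs such as stars), normalized by the maximum, so the top
  node scores exactly 1. Negative weights enter by absolute value with a
  logged warning.
- *Closeness*: `(n−1)/Σ_u d(v,u)` with hop-count distances on the
  unweighted skeleton, so values lie in (0, 1] and 1 means adjacent to
  every node. The literal reciprocal-sum (un-normalized) convention would
  cap closeness at 1/8 on nine nodes and cannot produce the ~0.7 values
  typical of these networks.
- *Density* `E/(n(n−1)/2)`; *average path length* and *diameter* from
  unweighted all-pairs shortest paths. Hop counts (rather than
  1/|weight| lengths) are the default because observed diameters in this
  literature are small integers and path lengths match hop arithmetic
  exactly; weighted distances are available via `weighted_paths`.
- Disconnected networks raise by default so path metrics cannot silently
  be computed on fragments; `on_disconnected="largest"` computes on the
  largest component and annotates the report, `"flag"` (summaries only)
  returns density with path metrics missing.
- Reports round to 3 decimals; ranks are dense, descending, ties broken by
  criterion code and flagged.

## Synthetic cohort generator

The generator exists so the chain can be validated end-to-end with known
truth; it is a latent-threshold Gaussian copula:

1. A target *partial*-correlation structure (the ground-truth edge set) is
   converted to a correlation matrix by building the precision matrix with
   off-diagonals −r_ij, inverting, and re-standardizing. One pass is exact
   because partial correlations are invariant to diagonal scaling. A
   structure whose precision matrix is not positive-definite is rejected,
   naming the offending eigenvalue.
2. Latent vectors are drawn multivariate normal, and criterion j is coded
   "met" when the latent exceeds `τ_j = Φ⁻¹(1 − π_j)`, so marginals match
   the target prevalences exactly in expectation.
3. Optional truncation keeps only rows meeting ≥ m criteria, by rejection
   sampling with an acceptance-rate guard (error below 1e−4).

This is the model under which tetrachoric correlations are consistent for
the latent structure, which is what makes recovery experiments
interpretable. Randomness is split from a single seed with
`numpy.random.SeedSequence` per group and per replicate, so runs are
bit-for-bit reproducible and subcomponents independently re-runnable.

**Packaged study design** (`default_study_config`): two groups, men
n = 3,836 and women n = 367, truncation at ≥4 criteria. Only four marginal
prevalences are empirical anchors (A1: 0.625 men / 0.632 women, A7: 0.943
men / 0.951 women); the other criteria carry plausible synthetic
placeholder values for a treatment-seeking cohort, with the reported
direction of sex differences (A3, A8 higher in men; A5 in women). The
latent structures are synthetic fixtures: sparse, positive, withdrawal (A2)
as hub in both sexes, tolerance (A1) strongly coupled to it in men and
chasing losses (A6) in women; weights sit near the positive-definiteness
boundary so that the ≥4 truncation still leaves detectable signal.

**What truncation does (and is allowed to do).** Restricting to rows with
≥4 criteria induces negative dependence between criteria, raises marginal
prevalences above their untruncated targets, and attenuates observed
partial correlations by roughly half in these configurations. This mirrors
the clinical situation and is deliberately *not* corrected for in
estimation. Consequences visible in simulated studies: networks are
sparser than their latent structure, occasional small negative edges
appear, and the women-sized group (n = 367) frequently yields a
disconnected network — an honest low-power outcome, handled via the
largest-component flag. Calibration and recovery experiments that need a
clean null or clean truth therefore run without truncation.

**What the generator does not emulate.** Item-level (19-item) responses,
covariates (age, socioeconomic position), measurement error beyond the
binary coding, and any fitting to real cohort data. Passing recovery tests
show the chain is correct under the copula model; they do not certify any
particular empirical dataset's dependence structure.

## Validation surfaces

- `edge_recovery`: confusion-matrix sensitivity/specificity/precision over
  the 36 possible edges against ground truth, plus the Pearson correlation
  of true vs estimated weights on recovered edges (flagged when < 2).
- `calibration_experiment`: replicated generate → estimate → compare; under
  a diagonal structure the per-edge retention frequency estimates the
  type-I rate of the gate (use ≥ 100 replicates); under a planted structure
  it summarizes power. Simulation sizes used in the shipped tests and the
  acceptance script (500 null replicates at n = 4,203; 12–15 recovery
  replicates at n = 3,836 and 367; prevalence checks at n = 10,000) were
  chosen to keep Monte-Carlo error comfortably inside the asserted margins
  while the whole suite runs in well under a minute per experiment.

## Known limitations

- Significance gating is not model selection: with n = 3,836 even tiny
  truncation-induced partials become significant, so large-sample networks
  can contain weak edges a regularized estimator (graphical lasso/EBIC)
  would drop. Regularized estimation is intentionally out of scope.
- The tetrachoric path assumes an underlying bivariate normal per pair;
  grouped-jackknife SEs are calibrated under i.i.d. sampling of persons.
- Cronbach's alpha is exposed as a generic reliability operation; on
  truncated diagnosed cohorts it is strongly attenuated (range restriction
  plus induced negative dependence) and should not be compared with values
  from untruncated samples.
- No formal between-group network comparison test is provided; the sex
  comparison is descriptive (separate networks and rankings), and
  bootstrap edge-stability intervals are a possible extension.
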