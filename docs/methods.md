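# Methods

## Signal quantification

The level of a histone mark on a gene is the weighted sum of peak signal
values over a gene-anchored region, `Σ_p L_p·S_p / L_g`. `L_p` is taken
as the length of the *intersection* between peak and region: the wording
"a peak overlapping with the genomic region" admits both the full peak
length and the overlap length, but only the overlap reading bounds every
term by `S_p` and keeps the statistic a length-weighted average of peak
intensities. The full-length variant remains available via
`gene_signal(..., clip_overlap=False)`. Overlapping peaks within one mark
are summed independently; no merging is performed, since the defining sum
runs over peaks, not over covered base pairs.

Region schemes: `promoter_body` (default; 2 kb upstream of the TSS
through the TTS as one interval), `promoter_only`, `body_only`, and
`promoter_and_body_separate`, which doubles the mark columns
(`mark@promoter`, `mark@body`). Promoters are strand-aware and clipped at
coordinate 0; a gene whose region clips to nothing is dropped with a
warning. Interval overlap is computed by exact vectorized min/max
arithmetic — peak sets at the scale this package targets (processed peak
calls, 10⁴–10⁵ intervals) do not warrant an interval index, and the
arithmetic is exact by construction.

## Preprocessing

Matrices from the two conditions are aligned on the intersection of gene
ids (case-sensitive exact match) and mark names, in the first matrix's
order. A gene is discarded when at least half of the marks (⌈M/2⌉) show
exactly zero signal in both matrices simultaneously; the alternative
reading — at least half zero in each matrix independently — is available
as `filter_rule="independent"`. The log transform is log2(x+1): base 2 is
the fold-change convention of the field, and the +1 pseudocount maps zero
signal to zero while leaving correlation ranks essentially untouched.
Column (mark) scaling and row (gene) scaling use the sample (n−1)
standard deviation. A zero-variance mark column is an error (a degenerate
assay); a zero-variance gene row after mark scaling is removed from both
conditions, recorded in the filter report, and the column scaling is
re-applied so the invariants hold on the final gene set.

## The iterative comparison

The weighted Pearson correlation uses weighted means and weighted
(co)variances; it is invariant to positive rescaling of the weights and
reduces to the ordinary Pearson correlation under equal weights. Context
matrices clip negative correlations to 0 and force a unit diagonal.
Within the inner fixed-point loops the updated weights are the clipped
scores, so weights stay non-negative throughout; the *reported* gene and
mark scores are the final raw correlations and may be negative — a
mildly negative score carries the same message as a score near zero (the
context changed), and clipping the report would mask it.

Two deliberate choices where the procedure is underdetermined:

- **Warm starts.** Each inner loop starts from the weight vector carried
  over from the previous outer iteration (all ones on the first pass, or
  the user-supplied/random initialization). Restarting every inner loop
  from equal weights converges to the same fixed point in our testing
  but wastes iterations; the warm start makes the outer-loop convergence
  criterion (max|Δw| across one outer iteration below `outer_tol`)
  directly meaningful.
- **Self-correlation entries.** The diagonal entries of the two context
  matrices (both exactly 1) are included when correlating equivalent
  rows. Their effect is O(1/G); `include_diagonal=False` excludes them
  (scores correlate > 0.99 either way on structured data).

Tolerances default to 1e-4 for both loops with iteration caps of 100
(inner) and 50 (outer); converged runs on simulated data typically take
2–4 outer iterations. Random initial weights are drawn from
Uniform(0.5, 1.5) and require a seed. Degenerate items (zero weighted
variance anywhere) score 0 and are flagged rather than propagating NaN.
An inner loop whose weights all collapse to 0 raises a "degenerate
comparison" error: the two conditions share no positively correlated
context structure at all, and no reweighting can be estimated from such
data.

The equal-mark-weight mode (`run_icc`) holds mark weights fixed, skips
the mark inner loop and reports mark scores from a single post-hoc
correlation pass; it is exactly the code path of the full algorithm with
mark updates disabled. Leave-marks-out runs drop the requested columns,
re-apply column scaling (idempotent under column removal, applied anyway
for clarity) and recompute the row scaling before re-running.

The optional Fisher-z ("Guan") normalization transforms the raw
gene-context correlations with atanh (inputs clipped to ±(1−10⁻⁶)) and
standardizes the off-diagonal entries to mean 0 / sd 1 per condition,
setting the diagonal to the maximum transformed value. Under this flag
the context matrices are z-scores rather than correlations, so the
[0, 1] clipping is not applied to them (weights are still clipped); the
flag is off by default.

### Windowed conservation tracks

For genome-wide mark-conservation tracks the genome is divided into 1 Mb
windows of 1000 non-overlapping 1 kb bins; bins play the role of genes
(same weighted peak-sum quantification), each window is normalized and
scored independently, and the per-window mark scores are emitted as
bedGraph. Windows that fail preprocessing (all-zero or degenerate
signal) are reported as missing.

## Downstream statistics

- **EDG/ECG**: bottom/top score quartile, ⌈G/4⌉ genes each, ties broken
  by stable input order.
- **Score bins**: 20 near-equal bins by ascending score
  (`numpy.array_split` sizes).
- **Permutation overlap test**: the pooled genes of all categories are
  repartitioned 1000 times into sets of the observed sizes; the
  empirical p-value uses the add-one estimator (1 + #{perm ≥ obs}) /
  (1 + n_perm), which is never 0 and is the standard
  permutation-p convention.
- **Entropy calls**: negative scores are reset to 10⁻⁶; entropy is
  −Σ p ln p over the normalized score profile (natural log; the 20%
  thresholds are rank-based, so the base is immaterial). DDSGs come from
  the bottom 20% of entropies and require the direction's score to be ≥
  2.5-fold lower than every other direction and ≤ the 5% quantile of the
  pooled (genes × directions, reset) scores. DDUGs mirror this: top 20%
  of entropies with minimum score above the pooled 80% quantile —
  "top 20% of genes" is read as top 20% *by entropy*, the symmetric
  counterpart of the DDSG rule. Pooled (rather than per-direction)
  quantiles are the default because the directions share one score scale
  by construction.
- **Enrichment**: upper-tail hypergeometric p, plus Benjamini–Hochberg
  q-values as a utility.
- **Mark dynamics**: per-mark Pearson/Spearman correlation of levels
  across conditions within a gene group; relative changes are
  (a−b)/(a+b) on raw signal, defined as 0 when a+b = 0 (a feature absent
  in both conditions carries no change information).

## Synthetic data

The generator emulates the two properties of real multi-mark matrices
the algorithm relies on: mark-specific signal scales and gene
co-regulation modules. Log2 signal is `mark_mean_m + loading(module(g), m)
+ N(0, 0.5)` with mark means N(2, 1), 5 modules (round-robin gene
assignment) and module loadings N(0, 1.5); signal is 2^log2-signal, so
all values are positive log-normals. Condition 2 adds per-entry N(0,
`perturb_sd`·magnitude) on the log scale to the rows of a `frac_dynamic`
fraction of genes (magnitude ~ U(0.5, 1.5) per gene) and copies conserved
rows unchanged. Defaults — 16 marks, 20% dynamic genes, `perturb_sd` = 1
(≈ 2-fold typical perturbation) — represent a moderately diverged pair of
related cell types with a realistic minority of remodeled genes.

What the generator does *not* emulate: empirical per-mark signal
distributions of specific antibodies, spatial peak structure within
genes, correlated (batch-like) noise between marks, or measurement noise
shared by both conditions. Passing the recovery and robustness tests
therefore shows the algorithm's behavior under planted relative changes
with clean conserved genes, not its performance on any particular
experimental dataset.

The noise model is multiplicative uniform: e → e·(1 + u·s), u ~ U(−1, 1),
which preserves non-negativity and the expectation of every entry.
Row/column permutation fixtures shuffle values while keeping labels, so
the pair's correspondence — not its marginal content — is destroyed.
The toy genome writes ~50 genes on both strands of a 2 Mb chromosome and
per-mark BroadPeak files constructed so that the weighted peak-sum
quantification reproduces a prescribed target matrix exactly: one peak
of length L per (gene, mark) inside the gene's region with signal
T·L_g/L, genes spaced so no peak can reach a neighbour's region.

## Problem sizes and numerical checks

The test suite and the acceptance script use 300×16 and 500×16 simulated
matrices — large enough that gene-context matrices are well-conditioned
and module structure dominates sampling noise, while a full run completes
in well under a second. The vectorized core is verified against a
literal, loop-by-loop reference implementation of the recurrence on
random small instances (≤ 10 genes × ≤ 4 marks) at every outer iteration
to 1e-10, and `weighted_pcc` against the textbook Pearson formula to
1e-12.

## Known limitations

- Pairwise comparisons only; multi-condition designs require running all
  pairs.
- The low-signal filter tests for *exact* zeros; data pipelines that
  emit small positive floors will bypass it.
- Mark scores from very few marks (≲ 5) rest on tiny context vectors and
  are statistically fragile; the windowed-track mode inherits this when
  few marks are supplied.
- Differential-expression calling, GO enrichment and motif scanning are
  out of scope; DEG/essential/TF-target sets are consumed as plain gene
  lists.
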