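# Methods

## Model and procedure

`ictair` treats a regulator's per-sample activity as a latent quantity
that can be read off from the joint expression of its target genes.
The assumptions are minimal but real: (1) within a context, a genuine
target's relative expression is monotonically associated with the
regulator's activity across samples; (2) the starting target list
contains enough genuine targets that the initial activity estimate is
informative; (3) expression values are on a log-like scale where
within-gene relative values (log-ratios or median-centered
intensities) are comparable across samples.

### Activity scoring

For one sample, genes are sorted by descending relative expression
(ties broken by ascending gene index — stable and platform-independent).
Two cumulative curves are built over this ordering: foreground *F*
over the listed targets and background *B* over all other genes.  Each
gene contributes an increment proportional to |e| within its class, so
the curves encapsulate expression *activity* rather than mere rank;
should a class's total |e| be exactly zero (possible after median
centering), that class falls back to uniform increments.  Both curves
are non-decreasing and end at 1.

The preliminary score is the signed maximum deviation D(k\*) of
F − B, with k\* = argmax |F − B| and ties resolved to the smallest k.
It behaves like a Kolmogorov–Smirnov D-statistic between the target
and background expression-mass distributions: +1 when targets hold all
the most-induced expression, −1 when they hold the most-repressed.
We read the foreground-versus-background comparison as this difference
rather than a literal ratio: the difference is the KS analogy made
exact, and a ratio is undefined wherever the background curve is still
zero.  A uniform-increment variant (`weighting="uniform"`) is provided
for sensitivity checks; the |e|-weighted form is the default dialect.

The score is then normalized into the iRAS by dividing by the mean
absolute preliminary score of `n_permutations` random gene sets of the
same effective size, drawn uniformly without replacement from the
matrix's gene universe.  One shared collection of permuted sets is
reused across samples within a call: this keeps scores comparable
between samples and costs 1/S of the alternative, with no statistical
difference.  By construction mean |iRAS| ≈ 1 for uninformative sets —
the calibration checks in the test suite and acceptance script verify
mean iRAS ≈ 0 and mean |iRAS| ≈ 1 on noise-only data.

### Refinement

Each cycle computes the iRAS vector from the current list, then the
Spearman correlation ρ between every listed target's expression row
and that vector.  Ranks use average-rank tie handling; the classical
closed formula 1 − 6Σd²/(s(s²−1)) is the no-ties special case, which
the implementation reproduces exactly on tie-free input.  Targets with
ρ strictly below `min_rho` are dropped (equality keeps the gene); a
target whose row is constant has no defined rank correlation and is
dropped with a logged warning, since a constant gene cannot evidence
co-activity.

Termination: `stable` when a cycle changes nothing; `floor` when the
pruned list would fall below `min_size` — the previous, compliant list
is returned, because the floor exists to guarantee a usable list;
`max_iterations` as the hard cap.  Each iteration redraws its
permutation null from a per-iteration sub-seed of the master seed, so
no single Monte-Carlo error is frozen into every cycle while the whole
run remains exactly reproducible.  Batch refinement gives every set a
sub-seed derived from the master seed and the set name, making each
result independent of batch composition.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `min_rho` | 0.1 | minimum Spearman correlation (unitless, [0,1]) a target must reach; a deliberately relaxed pruning criterion |
| `min_size` | 20 | shortest allowable list; keeps refined lists usable downstream |
| `max_iterations` | 10 | cap on refine cycles; lists typically stabilize well before it |
| `n_permutations` | 1000 | random sets behind the iRAS denominator; 200 suffices for the synthetic studies and is used there to keep runs fast |
| `seed` | — | master seed; every random draw derives from it |

## Synthetic data

`generate_scenario` plants a single regulon: latent activity
a ~ N(0, activity_sd²) per sample; true-target rows
e = β·a + N(0, noise_sd²) with gene-specific β ~ U(effect_low,
effect_high); contaminant and background rows are independent noise.
Scenario S1 (the defaults — 500 background genes, 40 true targets, 40
contaminants, 200 samples, β ∈ [0.5, 1.5], unit SDs) gives an initial
list precision of exactly 0.5 and per-target correlations far enough
above the pruning threshold that a correct implementation should
recover essentially all true targets; 200 samples and ~600 genes keep
every study desk-sized while leaving the permutation null well
resolved.

What the generator does **not** emulate: microarray heteroskedasticity
and probe-level noise, batch effects, correlated background structure
(co-expression modules), multiple overlapping regulons, and repressed
targets (β < 0 is available via `frac_repressed` but off by default —
the one-sided pruning rule removes anti-correlated targets by design).
Passing the synthetic studies therefore demonstrates the algorithm's
correctness and calibration under its own model, not performance on
real tumor expression data.

## Numerical choices

- Descending sort is a stable argsort of −e; all tie-breaks are by
  ascending gene index, making scores bit-reproducible across runs and
  platforms.
- The permutation scorer evaluates F − B only at the 2m candidate
  prefixes where its extrema can occur (at and immediately before each
  target position) — an exact O(P·S·m) reformulation of the O(P·S·n)
  scan, verified against the brute-force per-column path to 1e-12
  including ties and exact-zero expression.
- Score antisymmetry under column negation is exact in real
  arithmetic; floating-point sums over the reversed ordering differ at
  ~1e-16, so tests assert it at 1e-12.
- Degenerate inputs are errors, not silent repairs: missing expression
  values, duplicate gene rows, empty target lists after matrix
  intersection, an all-target gene universe, and a zero permutation
  null all raise with the offending name.
- Sub-seeds come from `numpy` SeedSequence spawn keys (iteration
  number, or CRC32 of the set name) masked to 31 bits.

## Design decisions taken where the procedure was open

- Whether permuted null sets are drawn per sample or shared across
  samples is unspecified in the method's public description; shared is
  the documented choice (comparability, S-fold cheaper).
- Whether floor termination returns the under-floor candidate or the
  previous list is likewise open; returning the previous list honors
  the parameter's purpose.
- Iterations redraw their permutation null rather than reusing one
  draw; reproducibility is preserved through the sub-seed scheme.
- Multi-regulator motif names (e.g. a motif shared by two miRNAs) are
  resolved through the annotation table, one row per regulator symbol,
  each symbol becoming its own network node.

## Limitations

- Refinement sharpens a list around whatever signal dominates the
  initial activity estimate; if contaminants form a coherent
  co-expressed module larger than the genuine regulon, the loop can
  converge on the wrong signal.  Garbage in, refined garbage out.
- The one-sided pruning rule discards genuinely repressed targets.
- iRAS values are comparable across samples within one regulator, not
  calibrated across regulators with very different list sizes beyond
  the |iRAS| ≈ 1 null scale.
- No survival or other outcome analysis is included; refined lists and
  activity matrices are the data products.
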