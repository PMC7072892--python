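# Methods

## Scoring model

Each mature miRNA in an expression table (rows = miRNAs, columns = samples,
post-normalization intensities) receives

    score = w_A·A + w_B·B + w_C·C,

with

- `A = m / m_max`: `m` is the median expression across all samples (even
  counts average the two central order statistics), `m_max` the largest
  median in the analyzed set. Medians are taken on the scale of the input
  table as given — RMA-style log2 intensities and linear RPM both work,
  since only the ratio to the set maximum enters. Negative inputs are
  rejected by default (`A` is meaningless for negative `m`); an opt-in
  min-shift policy translates the whole table instead.
- `B = max(0, 1 − N / N_max)`: `N` is the integer suffix of the miRBase
  MIMAT accession, a chronological deposit number. `N_max` defaults to the
  largest `N` in the loaded annotation set; an override may enlarge it
  (whole-miRBase semantics) but never shrink it, and a configured `N_max`
  smaller than an observed `N` would clip `B` at 0 rather than go negative.
- `C = (c + 1) / 2`: `c` is the Spearman rank correlation (average ranks on
  ties) between the miRNA's expression vector and its precursor's. When a
  mature miRNA derives from several genomic loci, the maximum correlation
  over precursors is used — agreement with any one locus is evidence of
  genuine biogenesis. Monotone transforms of the expression scale do not
  affect `c` (rank-based), so log versus linear input is immaterial here.

All components lie in [0, 1]; weights are non-negative and renormalized to
sum to 1, so the score lies in [0, 1]. Default weights (0.5, 0.3, 0.2) are
the specificity-maximizing choice (see weight optimization below).

Missing correlation: if no precursor row exists, the precursor probe is
absent from the table, or fewer than `min_samples` (default 5) paired
samples are available, `c` is absent. Two policies:

- `neutral` (default): `C = 0.5`, so the miRNA is neither promoted nor
  penalized;
- `drop-weight`: `w_C` is set to 0 and the remaining weights renormalized
  for the whole table — the recommended fallback when the study simply has
  too few samples for rank correlations to mean anything. With `drop-weight`
  the scores are provably independent of the precursor table (a tested
  invariant). This fallback trades away sensitivity: moderately expressed
  but genuinely present miRNAs lose the promotion that a high precursor
  correlation provides (also a tested property).

Output rows are sorted by score descending, ties broken by ascending MIMAT
number (the chronological prior: an earlier accession is more credible).
Expression features absent from the annotation are reported on the result
object, never silently dropped.

## Validation procedures

**Cumulative coverage.** Sorting a reference profile (median RPM per miRNA)
descending and accumulating shows how few miRNAs carry the expression mass;
the curve is non-decreasing and ends at exactly 100%.

**Concordance and the specificity ratio.** Select miRNAs with score strictly
above a threshold (default 0.75); call a selection concordant when its
reference median RPM is strictly above the expressed cutoff (default 10).
miRNAs missing from the reference count as RPM 0 — quantifiers emit every
detected miRNA, so absence is evidence of non-expression. The baseline
selects the same number of miRNAs by raw median expression (ties by
ascending MIMAT); the specificity ratio is baseline-discordant /
score-discordant, undefined (reported as such) when the score selection has
no discordant member.

**Rank separation.** Two-sided Mann–Whitney U between score groups. The
exact null distribution is used when both groups have ≤ 8 observations and
the pooled sample is tie-free; otherwise the normal approximation with tie
correction. Group summaries report means and sample (n−1 denominator)
standard deviations.

**Weight optimization.** Exhaustive evaluation of all weight triples on the
simplex lattice with spacing `grid_step` (default 0.05 → 231 triples). The
component table (m, N, c, A, B, C) is computed once; each candidate only
re-weights it. Objective: the specificity ratio, with zero discordant
treated as +∞ and empty selections as −∞; ties break toward larger
concordant counts, then lexicographically by (w_A, w_B, w_C) descending —
fully deterministic.

## Sequence-level false-positive characterization

A miRNA is called a false positive when its array median is at or above the
empirical top-quantile cutoff (default 0.90; linear-interpolation quantile,
boundary inclusive) *and* its reference RPM is at or below the expressed
cutoff (default exactly 0; configurable).

GC-content is (G + C) / (length excluding N); all-N or empty sequences are
rejected. The genomic occurrence count slides the probe sequence along each
genome record and counts every start position with Hamming distance ≤ k
(default 2, substitutions only — the mismatch model of seed-and-count `-v`
style read mapping; indels are out of scope). Both strands are counted by
also scanning the reverse complement of the pattern against the forward
text; overlapping sites each count, and every position–strand pair counts
once even for palindromic patterns. `N` never matches anything, including
another `N`. Coordinates, where exposed, are 0-based half-open on the
forward strand. The scanner is vectorized per pattern position, so a
22-mer against a megabase costs ~44 vector passes; tests verify it against
an independent oracle that enumerates all ≤ k-substitution neighbors of the
pattern and counts exact window matches.

Group comparison (GC, occurrence counts, or any per-miRNA feature) is a
one-sided Mann–Whitney U testing whether the false-positive group is
stochastically greater, with the same exact/asymptotic switch as above; the
reported direction compares the observed U to its null expectation.

## Synthetic data generator

The generator emulates the paired array/sequencing design the method
targets, with planted ground truth:

- 50 truly expressed + 150 false-positive miRNAs × 30 samples by default;
- array intensities on a log2-like scale: per-miRNA baseline uniform on
  [6, 13] **identically for both groups**, so raw intensity cannot separate
  truth from false positives and any separation must come from the MIMAT and
  correlation components;
- MIMAT numbers sampled without replacement from [1, 5000] for true and
  [5001, 35000] for false miRNAs (disjoint by construction), matching the
  empirical concentration of expressed miRNAs at early accessions;
- mature–precursor correlation through a shared standard-normal latent
  signal: precursor noise is mixed as `ρ·z + √(1−ρ²)·w` with
  `ρ = 2·sin(π·s/6)`, the exact bivariate-normal identity mapping a target
  population Spearman `s` (0.8 for true, 0.0 for false miRNAs) to the
  required Pearson coefficient. At 30 samples the achieved sample Spearman
  lies within ±0.15 of the target for ≥ 90% of true miRNAs (tested);
- reference RPM: log-normal (median 100, σ_log 1.2) for true miRNAs, exactly
  0 for false ones;
- 22-nt mature sequences sampled base-by-base with per-group GC probability
  (0.45 true, 0.60 false);
- a synthetic genome (~60 kb) of GC-0.40 background with every true
  sequence planted once and every false sequence planted in 4 copies, each
  with 0–2 random substitutions — so false positives recur as near-matches,
  mirroring their elevated genomic occurrence counts.

Everything derives from one integer seed through a single `numpy`
`default_rng` stream; identical seeds give bit-identical datasets, which the
determinism tests exploit end to end through the CLI.

What the generator does **not** emulate: probe-level hybridization physics,
sequencing read error, inter-sample normalization artifacts, correlated
expression programs between miRNAs, and — importantly — any coupling between
GC-content and array intensity. The last point means the decile-based
false-positive call selects a random GC-rich subset of the planted false
positives while equally GC-rich uncalled false positives remain in the
comparison group; the decile-call GC comparison on synthetic data is
therefore conservative relative to real arrays, where GC itself drives the
spurious signal. Passing tests demonstrate the statistical machinery and
the planted contrasts, not effect sizes on real hybridization data.

## Numerical and design choices

- Scaling constants `m_max`/`N_max` are taken over the analyzed set (the
  intersection of expression features and annotation records) and logged;
  both are overridable upward.
- Thresholds are strict inequalities (score > 0.75, RPM > 10); the
  false-positive call uses inclusive boundaries (≥ quantile cutoff,
  ≤ expressed cutoff).
- Problem sizes in tests and examples (200 miRNAs, 30 samples, ~60 kb
  genome, ≤ 30-nt patterns against ≤ 200-nt texts for the oracle
  comparison, 100 seeds for the GC-direction check) were chosen as the
  smallest scales at which every tested contrast is comfortably
  identifiable.
- Expression tables must be complete; the loader either rejects missing
  cells (default) or drops affected features on request. Identifier matching
  between tables and annotation is exact and case-sensitive — silent fuzzy
  matching hides data errors.
- The score TSV carries `m_max`, `N_max` and the weights in a `#` header
  line so written tables are self-describing; scores round-trip to 6
  decimals.

## Known limitations

- The MIMAT component encodes a discovery-date prior; genuinely expressed
  but recently deposited miRNAs are penalized by construction. The weights
  cap this penalty at 0.3.
- Only substitution mismatches in genome scanning; no indels, no alignment
  scores.
- The correlation factor requires precursor probes on the platform; arrays
  without them should use `drop-weight`.
- Scores are relative to the analyzed set (via `m_max`, `N_max`): they are
  comparable within one run, not across datasets with different maxima.
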