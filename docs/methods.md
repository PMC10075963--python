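# Methods notes

This note records the models, defaults, and numerical choices behind
`wordpatch`, and what the synthetic data can and cannot establish.

## N-gram statistics

N-gram frequencies are token-weighted by default: each occurrence of an
n-gram in a word contributes the word's corpus frequency (per million),
and overlapping occurrences all count ("AAA" holds two "AA" bigrams). A
type-weighted mode (one count per word type) is available via
`token_weighted=False`; corpora differ in which convention they report,
so both are exposed. Unattested n-grams score `floor = log10(0.01) = -2`
per million — finite, clearly below any attested value, and not so
extreme that one missing window dominates a six-letter string's mean;
it is configurable per table. Strings are uppercased on ingestion and
accented letters are excluded by restricting the alphabet to A-Z.

Candidate enumeration is quadrigram-anchored rather than a filter over
all `26^6` strings: every string containing an attested quadrigram is
constructed directly (identical result, far less work), deduplicated,
and emitted in lexicographic order. Exclusion of embedded words applies
to words of `embed_min_len = 5` letters and up, plus the exact-length
"is itself a word" check.

## Stimulus categories

High/low bands are the outer quartiles of the candidate population per
language and level; the interquartile range is the neutral band
(`q_low = 0.25`, `q_high = 0.75`, configurable). No cutoffs are
canonical for this step, so quartiles were chosen as the weakest
assumption giving four populated cells per level.

Within each nonword category, items are picked greedily: at each step
the candidate minimizing the maximum |Pearson r| between the
manipulated level's statistics and the other levels' statistics (eight
pairs) joins the selection. Running first/second moments make each step
linear in the pool. Achieved correlations are reported in the design
manifest; a warning fires above the 0.3 ceiling. In practice the
selections land near |r| ≈ 0.01 at 180 items per category.

Real-word categories are matched to the corresponding high-quadrigram
cells on all six category-mean statistics (tolerance 0.1 log10 units
per statistic). Matching is co-adaptive: words are selected toward the
Q-cell means by greedy init plus steepest pair swaps; if no selection
fits, the Q cell itself is re-selected with an added mean-tracking
penalty toward the midpoint of the two clouds, and the alternation
repeats (bounded). This mirrors a joint "optimized" selection: neither
side alone is guaranteed to reach the other. The word-frequency band
for the matched categories defaults to 0.5-10000 per million; the
narrower 7-761 band applies to localizer word lists, for which
frequency is a display property rather than a matching constraint.

## Synthetic lexica

The generator emulates two languages over one alphabet:

- **Frequencies**: Zipf, `30000 / rank^1.3` per million over 20000
  words per language (top word ≈ 3% of tokens, tail ≈ 0.08 per million).
- **Composition**: first-order Markov chains whose stationary letter
  preferences diverge between languages by `letter_divergence = 0.7`
  and whose transitions carry language-specific structure
  (`markov_strength = 0.8`).
- **Rank-dependent temperature**: sampling distributions are flattened
  toward the tail of the rank list (`rare_word_temperature = 1.0`), so
  rare words are built from rarer letter combinations — a property of
  real lexica without which high-frequency words cannot be matched to
  nonword categories drawn from quantile bands.
- **Alphabet**: 10 letters by default. Real lexica attest a dense set
  of quadrigrams relative to what six-letter strings can contain
  (about one random string in ten contains one); a compact synthetic
  alphabet reproduces that density at a 20000-word scale, whereas a
  26-letter synthetic alphabet leaves the quadrigram statistics almost
  entirely at the floor and empties the low-frequency cells.
- **Word lengths** 5/6/7 at 25/50/25%, vocabulary `overlap = 0.02`.

A random language pair occasionally admits no word-category match
within tolerance (the word cloud and the Q-cell hull genuinely miss
each other; roughly one draw in ten). `generate_feasible_design`
therefore redraws the languages (derived seeds, bounded at five draws):
the real languages are a single fixed instance for which the design is
known to be constructible, so conditioning on feasibility is part of
emulating them.

Because the strings live on a dense 10-letter alphabet, roughly half of
the within-block orderings that forbid shared letter positions between
consecutive stimuli are infeasible; the scheduler then falls back to the
ordering with fewest violations and counts the event in the run
manifest. With 26-letter stimuli the constraint is almost always
satisfiable and the fallback stays idle.

## Schedules

All durations live on a 50-ms grid and are accumulated as integer grid
units, so events tile each run exactly and volume counts are exact
(`ceil(duration / TR)`, TR = 2 s). The 70-block ITI multiset is 23
balanced {3.8, 5.8, 7.8} triples plus one 5.8-s entry — mean exactly
5.8 s. The seven fixation-only blocks use the composition
{12, 12, 12, 8, 8, 8, 8} (sum 68 s), shuffled; the composition is a
free choice logged in the manifest. Immediate repetition of a condition
is forbidden (standard practice; configurable via `no_repeat`). Catch
targets replace a stimulus at a uniformly drawn position strictly after
the fifth item of a flagged block.

## Synthetic cohorts

Each voxel's main-run beta is

    baseline + c (Y - Y0) * w_condition + patch offset + N(0, sd)

with gradient coefficient `c = 0.0443` slope units per mm TAL Y,
anchor `Y0 = -80` mm (keeps ROI slopes positive over the VOTC span),
TAL Y uniform on [-75, -25] mm, 30 voxels per ROI, and voxel noise sd
0.1 by default (0.05 in the recovery studies). In the
`logographic-split` scenario a fraction of ROIs receives an additive
offset on one language's conditions plus an elevated localizer face
beta, emulating script-specific patches that also respond to faces.
Noise is independent across voxels; spatial correlation, physiological
drifts and motion are not modeled, so passing recovery tests shows the
estimators are unbiased under the stated generative model — not that
they are robust to structured real-world noise. Dominance scores for
exact-correlation fixtures are planted by orthogonalize-and-rescale,
which fixes the *sample* correlation to the target up to floating-point
arithmetic.

Time-course simulation convolves condition boxcars with a two-gamma HRF
(peak 6 s, undershoot 16 s, ratio 1/6 — the canonical parameterization;
the HRF family fixes only the form) at 50-ms resolution, samples at the
TR, and adds AR(1) noise parameterized by its stationary sd. The
simulator and the ROI-GLM share one design-matrix builder; round-trip
recovery at zero noise is therefore exact to solver precision and
validates the GLM assembly, not the HRF choice.

## ROI statistics

- The ROI-GLM percent-transforms raw time courses
  (`100 (x - mean)/mean`); series already in percent units (e.g. the
  simulator's output) skip the transform via
  `apply_percent_transform=False`.
- AR(2) handling is two-pass Cochrane-Orcutt: OLS residuals →
  Yule-Walker (MLE) AR coefficients → prewhitening (first `order` rows
  dropped) → refit. White-noise calibration of contrast p-values is
  verified by KS test in the suite.
- Cluster definition uses 6-connectivity by default (26 available);
  "cluster size > 4" is strict (5+ voxels).
- All t tests are two-tailed. BH-FDR reports monotone q-values; the
  rejection mask and q-values agree by construction.
- Degenerate correlations (zero variance) are reported as NaN with a
  warning, never as r = 0.
- The selectivity index pads all involved betas by |min| when any is
  negative, bounding it in [-1, 1]; a zero padded denominator returns 0
  with a warning.

## Nonparametric ICA

The decomposition restricts the data to its rank-k SVD subspace, then
rotates to maximize the summed negentropy of the voxel-weight columns.
Negentropy is estimated nonparametrically: histogram entropy of
standardized weights with Freedman-Diaconis bins (Scott fallback for
zero IQR); the estimator is a plug-in and its bias cancels in
comparisons across rotations. Optimization is Jacobi-style: bounded
scalar search over each pairwise rotation angle (one period,
[-pi/4, pi/4]), sweeping until the objective stops improving, with the
best of `n_restarts` random initial rotations kept. Components are
ordered by explained variance; profiles have unit norm with the
largest-magnitude element positive. A near-zero gain of the optimum
over random rotations flags a degenerate (rotation-invariant)
landscape, as with Gaussian weights. Back-projection solves
`localizer_data ≈ weights @ profiles` by least squares.

## Problem sizes in the checks

Recovery and calibration checks run at sizes chosen to make their
tolerances meaningful on a single CPU: 20 cohorts of 21 participants ×
10 ROIs for gradient recovery, 200 white-noise runs for GLM
calibration, and 5000 × 14 matrices for ICA recovery. The full
2520-item design is generated at its native 14 x 180 scale.

## Known limitations

- The synthetic languages are Markovian; real orthographies have
  longer-range structure (morphology, syllable constraints) that the
  generator does not produce.
- Logographic stimuli (stroke/radical hierarchies) are represented only
  as condition labels with simulated betas; no visual construction is
  attempted.
- The ROI-GLM operates on ROI-averaged time courses, matching the
  analysis it implements; voxelwise whole-brain inference and cluster
  -level correction are out of scope.
- The nonparametric ICA documents its own estimator and optimizer
  choices; it does not claim numerical equivalence with any external
  implementation of the idea.
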