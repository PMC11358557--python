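# Methods

## The statistic

For a single-channel signal X(1..L), a window of w samples slides in steps of
δ ≤ w; windows start at 0, δ, 2δ, … while they fit entirely inside the signal
(a trailing partial window is discarded — padding would distort the amplitude
distribution). Within each window the amplitude distribution is estimated as
an equal-width histogram over the window's own [min, max] range with
left-closed bins (the last bin closed), Pᵢ = countᵢ / w; a constant window
collapses to a single certain bin. The Tsallis entropy of that distribution,

    E_ts(q) = (1 − Σ Pᵢ^q) / (q − 1),

is computed per window (the Shannon form −Σ Pᵢ ln Pᵢ, in nats, when q = 1),
and the per-window series is summarised by its mean and sample (n−1)
variance. Those two numbers per channel and rhythm are the classifier
features.

Properties relied on throughout: E_ts → Shannon entropy as q → 1;
pseudo-additivity E(X∪Y) = E(X) + E(Y) + (1−q)E(X)E(Y) for independent
subsystems (subextensive for q > 1); bounds 0 ≤ E_ts ≤ (1 − N^{1−q})/(q−1)
with the maximum at the uniform distribution. All are asserted numerically in
the test suite.

Because the histogram is computed over each window's own range, the entropy
features are invariant to per-channel scale and offset; class structure must
therefore live in the *shape* of the amplitude distribution (signal
complexity), not in raw power.

## Parameters

| parameter | default | meaning |
|---|---|---|
| q | 3 (2, 3, 4 in the evaluation campaign) | nonextensivity index; q > 1 emphasises subextensive statistics |
| window w | 200 samples (1 s at 200 Hz) | sliding-window width |
| step δ | 100 samples (50% overlap) | slide step, 1 ≤ δ ≤ w |
| bins | ⌈√w⌉ (= 15 at w = 200) | equal-width histogram bins per window |
| k | 10 | KNN neighbour count |
| metric | euclidean | KNN distance (cityblock, chebyshev, correlation, cosine, hamming, jaccard, mahalanobis, minkowski, seuclidean, spearman also accepted) |
| holdout | 0.2 | test fraction per repetition |
| repetitions | 10 | independent stratified splits averaged |

The window width, step and bin rule are *not* pinned down by the upstream
analysis recipe this package follows; the defaults are common windowed-EEG
practice (1 s windows, 50% overlap, square-root bin rule) and are exposed in
`EntropyConfig` precisely because results depend on them.

## Preprocessing

Order: resample → centre crop → band-pass → per-channel z-score, the filter
and normalisation applied per rhythm. Resampling is polyphase with built-in
anti-aliasing (no upsampling). The crop takes the centred `round(d·rate)`
samples, start index `(n − out) // 2`, 0-based half-open. Rhythms are
extracted with linear-phase Hamming-window FIR band-passes applied forward
and backward (zero net phase — phase distortion would skew window-local
amplitude distributions). The transition width is bandwidth/8 capped at 2 Hz:
constant fractional bandwidth keeps the transition skirts of the narrow
theta band (3 Hz wide) proportionally small, which is what makes ≥ 90% of
filtered broadband power fall inside each nominal band. The two filtering
passes run as FFT convolutions with odd-reflection padding of one filter
length; this is numerically identical (≈1e-16) to `scipy.signal.filtfilt`
with the same padding and far faster for long filters. Z-scoring uses the
sample (n−1) standard deviation and refuses constant channels by name.
Normalisation happens *after* filtering so each rhythm's feature input is
standardised; since the entropy features are scale-invariant anyway, this
choice affects only the stored intermediate trials, not the features.

## Classification and evaluation

KNN stores the training rows and predicts the majority label among the k
nearest under the chosen metric. Tie-breaks are fixed for determinism: a
majority tie falls to the label of the single nearest neighbour; neighbours
at exactly equal distance are taken in training-row order (stable sort).
Holdout splits stratify by (label, subject) by default so every subject
contributes to both sides of each split — the cross-subject regime — keeping
a roughly constant class share per stratum (test share `round(n·fraction)`,
at least 1, per stratum). Repetition r uses sub-seed `seed + r`; the whole
campaign is a pure function of the master seed. Scores: accuracy,
sensitivity, specificity and F1 from the 2×2 confusion matrix with
"positive" as the positive class; a zero-denominator score is reported as
NaN (undefined) rather than coerced to zero, and summaries exclude and count
undefined repetitions.

The evaluation campaign runs three axes per q: per-channel (that channel's
feature pair), per-rhythm (all channels' pairs in that rhythm), per-region
(member channels' pairs concatenated). Channel and region axes are evaluated
within a single rhythm (`unit_band`, default gamma — the band analysed most
closely), so the result table keeps one row per (q, band, unit). Channel
ranking is by mean accuracy, ties by mean F-score then label; the top
quartile of 62 channels is ⌊62/4⌋ = 15; consensus channels are the
intersection of top quartiles across q values.

## Scalp regions

Hemispheres follow the extended 10-20 convention (odd suffix = left, even =
right, `z` = midline, the SEED cerebellar leads CB1/CB2 assigned by their
digit). The anterior/posterior split runs along the central row
(T7 C5 C3 C1 CZ C2 C4 C6 T8), which belongs to neither half; quadrants are
hemisphere ∩ half, so they exclude both midline and central-row electrodes.
Whether the central row "should" count as anterior or posterior is not
derivable from the upstream description; treating it as boundary is this
package's choice and is recorded in the bundled montage file, which users can
replace wholesale.

## Synthetic data

The generator emulates the shape of the SEED recordings: 62 channels at
200 Hz, one-minute trials, 15 subjects, balanced positive/negative classes
(5 trials per class per subject mirrors the five film clips per emotion).
Each channel is

    background noise + gain_ch · [(1−c)·tone + c·band-limited noise],

components unit-variance before mixing, so the class difference is planted in
*complexity* c, not power (deliberate: z-scoring and range-normalised
histograms erase power). The structured component ramps on/off with a 2 s
raised-cosine taper, like a stimulus onset/offset; without it, the abrupt
boundary of a narrowband component makes zero-phase filtering smear a
class-dependent broadband transient into every rhythm — a boundary artifact
the generator excludes by design. Inter-subject variability is a per-subject
lognormal gain jitter (σ = 0.15) and a per-subject spectral tilt of the
background (uniform ±0.4), sub-seeded from the master seed; generation is a
pure function of (profiles, counts, seed).

The canonical fixture plants the difference on FT7/FT8/T7/T8 with gain 3
over a 0.25-amplitude background: the positive class is a pure 40 Hz tone
(c = 0) and the negative class mixes in 32–55 Hz noise at c = gap
(default 0.9). One class is anchored at c = 0 because the measured
entropy-vs-c curve is non-monotone: window-histogram entropy rises steeply
from the pure tone (E ≈ 0.474 at c = 0, q = 3, 15 bins), peaks near c ≈ 0.3
(≈ 0.495), and falls gently toward pure noise (≈ 0.492). A class pair
symmetric around c = 0.5 would shrink together and flip sign as the gap
widens; anchoring at c = 0 keeps the planted separation monotone in the gap.

What passing tests on this generator do and do not show: they demonstrate
that the pipeline detects exactly the planted band-limited complexity
structure (and nothing in bands where none was planted, and nothing when the
class recipes are identical). They do not show that real emotion-laden EEG
carries such structure — real recordings are nonstationary, artifact-laden
and far from a tone/noise mixture — so synthetic accuracies are not
comparable to accuracies on real recordings.

## Problem sizes and numerical choices

The packaged study runs 15 subjects × 10 one-minute trials (150 trials) for
the planted-structure experiment and 10 subjects × 6 trials for the null
control, sizes at which every statistical check has comfortable margins while
the whole suite stays a few minutes on one CPU. Chance intervals for
"accuracy at chance" checks use the 99% binomial band 0.5 ± 2.576·0.5/√n with
n = the number of trials in the dataset, not repetitions × test size:
repeated holdout reuses the same trials, so the dataset size bounds the
effective sample.

Degenerate inputs are handled explicitly: constant windows → single-bin
distribution, entropy 0; constant channels → z-score error naming the
channel; empty regions → flagged result rows rather than silent omission;
zero-denominator scores → NaN with exclusion counts. The histogram bin index
uses one explicit formula (`floor((x−lo)/span·n_bins)`, clipped) in both the
single-window and vectorised paths, so the sliding engine equals a
window-by-window recompute bit-for-bit. Sums over probabilities keep
exact-zero terms so summation order (and hence floating-point results) is
identical across both paths.

## Known limitations

* The amplitude-histogram entropy estimator is biased by bin count and window
  length; comparisons are only meaningful at fixed `EntropyConfig`.
* Per-channel and per-region scores on small test sets can produce undefined
  sensitivity/specificity; they are reported as NaN, not imputed.
* EDF files can be read (via MNE) but not written; the native interchange
  format is delimited matrices plus a JSON manifest.
* No artifact removal is provided — inputs are assumed artifact-cleaned
  upstream.
* q is treated as a user choice; no automatic optimisation of q is attempted.
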