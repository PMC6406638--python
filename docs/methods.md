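# Methods

## Connectivity estimation

Every channel is reduced to a symbol sequence by equiprobable (quantile-
edge) binning computed per analysis segment; values equal to a bin edge
fall in the lower bin, and a constant segment maps to the single symbol 0
(zero entropy). Transfer entropy is the plug-in estimate at embedding
dimension 1 and lag 1: joint counts of (x_{n+1}, x_n, y_n) over the
segment, entropies in bits. Negative values (possible only through float
round-off) are floored at 0.

The estimator's finite-sample bias is removed by subtracting the mean TE
over shuffled-source surrogates; each surrogate is a uniformly random
permutation of the full source sequence, drawn from a seeded generator.
Normalizing by the target's own conditional entropy H(x_{n+1} | x_n)
yields NTE in [0, 1]. Conventions for degenerate input: if H = 0 the
target has no information budget and NTE := 0; values driven below 0 by
surrogate subtraction are clipped to 0 (clip counts are logged). Since
TE ≤ H always (data-processing bound, property-tested), NTE never
exceeds 1.

Matrix estimation computes all 14×13 directed pairs per 2-s epoch and
averages NTE across epochs. Surrogate permutations are shared across
source channels within one epoch: each pair still sees a uniformly random
permutation of its source, and sharing makes the work linear in channels
rather than channel pairs. A numba kernel evaluates all pairs via
n·log₂(n) count tables; a vectorized numpy path mirrors it when numba is
unavailable, and a per-pair reference implementation (the public
`transfer_entropy` / `normalized_te` functions) is cross-checked against
the kernel in the tests.

### Alphabet size

The default alphabet is **B = 4**. A 2-s epoch at 128 Hz yields 255
symbol triples; with B = 4 the triple histogram has 64 cells and remains
well-populated, whereas finer alphabets (e.g. 8 bins → 512 cells) leave
the plug-in estimate dominated by small-sample bias — empirically the
bias floor then swamps any realistic coupling signal at epoch scale.
With B = 4 the uncoupled floor is flat (≈0.009 per pair) and the
coupled-pair response grows monotonically with coupling strength. B is
exposed in the `connectivity:` config block for longer segments.

Entropies are reported in bits (log base 2); the base cancels inside NTE.
The number of surrogates defaults to 20. The conditional-entropy
denominator is computed per epoch, on the same span as the TE it
normalizes.

## Preprocessing

Per-channel mean (baseline) removal, then linear-phase FIR stages of
order 300 (Hamming window): low-pass 45 Hz, high-pass 0.1 Hz, band-stop
notches 50 and 60 Hz (±2 Hz). Each stage is applied forward-backward, so
the chain has exactly zero net phase and preserves signal length; the
effective magnitude response is the square of the single-pass design
(measured: >40 dB notch rejection, <0.1% passband error at 10 Hz). A
notch whose band would reach the Nyquist frequency is skipped with a
warning. Recordings shorter than three filter orders are rejected.

Epochs are 2 s, tiled back-to-back with a 0.5-s gap (starts every 2.5 s)
inside each annotated state span; partial trailing windows are dropped
and no epoch crosses a state boundary. The alternative reading of the
segmentation — 0.5-s *step*, i.e. overlapping epochs — is available via
the `epoch_step_seconds` config key. Artifact handling is an amplitude
criterion: any epoch whose peak absolute amplitude exceeds the limit
(default 100 signal units) is dropped whole; manual component-based
artifact review is out of scope.

## Synthetic cohorts

Real recordings for this paradigm are not publicly deposited, so the
package generates its own study conditions. Channel *i* evolves as

    x_i[t] = a·x_i[t−1] + s(state)·Σ_j g_ij·tanh(x_j[t−1])
             + A·sin(2π·10·t/fs + φ_i) + L·sin(2π·50·t/fs) + ε_i[t]

with ε ~ N(0, noise_sd²), fs = 128 Hz, a 2-s burn-in discarded, and the
network state carried across the rest → drawing → manipulation boundary
(only the engagement multiplier s switches). The tanh coupling provides
the non-linear cross-channel dependence transfer entropy is designed to
detect; the 10 Hz term mimics an alpha rhythm (amplitude 0.5·noise_sd by
default) and the 50 Hz term mains contamination, exercising the notch
stage.

Parameter defaults and why:

| parameter | default | rationale |
|---|---|---|
| AR memory a | 0.6 | the channel must not be fully self-predictable: at long memory (a→0.9+) the integrated drive is readable from the target's own past and measured TE stops growing with coupling; at 0.6 the coupled-pair NTE rises monotonically over the whole scale range used |
| noise_sd | 1.0 | unit innovation scale; everything else is relative to it |
| coupling matrix | 20 directed edges, weights 0.2–0.45 | frontally weighted feed-forward network with feedback and interhemispheric links; row sums ≤0.75 keep the tanh drive out of saturation |
| novice s(state) | 0.35 / 0.7 / 1.3 | engagement rises monotonically into manipulation |
| expert s(state) | 0.35 / 1.0 / 1.0 | experts sustain practiced task engagement from the start and plateau; expert drawing engagement exceeds the novice's |
| subject jitter | ×U(0.9, 1.1) | overall level varies per subject without breaking profile shape |
| durations | rest 120 s; drawing U(38, 137) s; manipulation U(72, 125) s | the observed ranges of the study cohort |
| line noise L | 0.5 | visible 50 Hz peak, fully removed by the notch |

Per-subject seeds derive from the master seed, so cohorts are
reproducible end to end. Every recording is written with a JSON sidecar
holding the generating profile and the ground-truth coupling matrix.

What the generator does **not** emulate: volume conduction / a head
model (channels share no instantaneous mixing), eye-blink and muscle
artifacts, non-stationarity within a state, 1/f spectral shape beyond
the AR(1) roll-off, and the native 2048 Hz acquisition chain. Passing
tests therefore demonstrate that the estimators recover known directed
coupling under realistic noise, filtering, and segment lengths — not
that human EEG would behave identically.

## Graph measures

Binarization keeps edges with weight strictly above the threshold
(default 0.001, removing only negligible connections). Connectivity
density is edges/182. The motif census classifies each of the C(14,3) =
364 node triples into one of the 13 weakly-connected 3-node digraph
classes (canonical class order: by edge count, then by smallest
edge-bitmask over relabelings); triples with a disconnected underlying
graph are uncounted. Clustering uses the Fagiolo directed form, which
reduces to the Watts–Strogatz coefficient on symmetric graphs; σ uses
the pooled (transitivity-style) ratio, and the per-node coefficients are
reported separately. Characteristic path length averages finite directed
shortest-path lengths over ordered pairs, reporting the unreachable
fraction alongside (fully disconnected graphs are flagged undefined
rather than erroring). Random references are degree-preserving directed
edge-swap randomizations (10·|E| attempts, seeded), 100 realizations by
default; graphs with fewer than two edges return their own values with a
warning. Node strength is computed on the unthresholded weighted matrix.

## Information-flow summaries and statistics

Hemisphere membership follows 10-20 parity (odd = left). The four 7×7
sub-matrices are stored source-major, so row sums are per-electrode
outflows. Region nodes: F = {F7, F3, F4, F8}, C = {FC5, T7, T8, FC6},
P = {P7, O1, O2, P8}; AF3/AF4 belong to no region, and within-region
flow is excluded from the six reported directed pairs. Mean information
flow is each electrode's total outgoing NTE. State comparisons use the
Welch two-sample t-test (unequal variances, two-tailed, 95% CI) and
one-way ANOVA with Tukey–Kramer simultaneous intervals for the
multi-comparison step.

## Classification

Twenty-second windows starting every second inside drawing/manipulation
spans each yield one sample; a window is treated as a single segment for
its NTE matrix (2560 symbol pairs populate the histograms far better
than its sixteen 2-s epochs would). The 43-entry feature vector is
density (1), motif counts (2–14), per-electrode clustering (15–28), path
length (29), per-electrode mean information flow (30–43); an undefined
path length is encoded as 0 and flagged. Sequential forward selection
greedily adds the feature maximizing stratified 5-fold CV accuracy with
the wrapped classifier, breaking ties toward the lower feature index and
stopping when no candidate strictly improves; fold assignment is seeded
and fixed across steps so candidates compete on identical folds. The
positive class is *novice* (the larger class); MSE is the mean squared
0/1-label error, identically 1 − accuracy for hard predictions. Rest
windows are excluded — expertise is classified from task activity.

## Problem sizes used by the test suite

Unit tests run on seconds-long recordings. The cohort-level acceptance
check runs the full default conditions: 20 master seeds × (5 novices +
3 experts) with durations drawn from the ranges above, 2-s epochs for
the state-flow contrast and full 1-s-step windowing (~1100–1300 windows
per cohort) for classification; the directionality check uses 100
replicates of a single coupled pair (g = 0.8, noise 0.1, 60 s). The
end-to-end pipeline test uses a duration-scaled cohort (×0.12) purely to
keep the smoke test fast; the scale factor is an ordinary config key.

## Known limitations

- The plug-in TE estimator at dimension 1/lag 1 sees only one-step
  dependencies; longer-memory or multivariate (conditional) transfer is
  out of scope, as are kernel/KSG continuous estimators.
- NTE clipping at 0 makes the noise floor a small positive number
  (≈0.009 per pair at epoch scale with B = 4); comparisons between
  conditions should be paired, as the floor is common-mode.
- The 0.001 binarization threshold rarely prunes edges at window/epoch
  scale (most weights sit above it), so binary-graph contrasts are
  weaker than weighted-flow contrasts on synthetic data.
- EDF support writes EDF+C with int16 quantization and zero-padding to
  whole seconds; CSV is the exact round-trip format.
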