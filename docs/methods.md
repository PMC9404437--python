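# Methods

## Scope and model

vocclust clusters isolated vocalization units (one WAV file or manifest row
per call) without labels. The pipeline is: precondition → transform →
pairwise classification → clustering → cross-method concordance. The package
assumes calls are already segmented, reasonably free of overlapping sounds,
and recorded at a rate whose Nyquist frequency covers the analysis ceiling
(20 kHz by default, hence ≥ 40 kHz sampling).

## Preconditioning

Calls are peak-normalized to 1, high-pass filtered with a 5th-order
Butterworth (600 Hz default; 150 Hz recommended for species with low-pitched
calls), and renormalized. The filter is applied forward-backward
(zero-phase), which preserves contour timing at the cost of squaring the
magnitude response; since the filter only removes low-frequency background,
the steeper rejection is harmless. Filtering is placed after normalization
and followed by renormalization so that energy-based features stay on one
scale regardless of how much low-frequency content was removed. Stereo input
is averaged to mono. RMS normalization was considered and rejected in favor
of peak normalization, which is the field's common convention for segmented
units and keeps synthesis/clipping semantics simple.

## Transformation modes

* **all_in_one** — one value per feature per call; the frequency-domain
  variant is the magnitude FFT of the whole call interpolated onto a fixed
  grid of 2000 bins at 10–20 000 Hz (10 Hz step). The grid is realized by
  linear interpolation of the native-resolution spectrum: a 2048-sample
  window cannot natively resolve 10 Hz, and interpolation keeps the bin
  meaning identical for every call length.
* **win** — 2048-sample windows, 50% overlap, L = ⌊(n − 2048)/1024⌋ + 1
  windows per call; trailing samples shorter than a hop are dropped.
* **win_pct** — the window count L is fixed to the shortest call's `win`
  count; each call's window length is w = ⌊2n/(L + 1)⌋ (so the shortest
  call's windows are 2048 samples up to rounding) and the final window is
  shifted to end exactly at the last sample, guaranteeing full coverage.

Windowed spectra use a Hamming taper and per-window power spectra on the same
2000-bin grid. For vector-based methods the per-call matrices are flattened
window-by-window, zero-padded to the longest call, and z-scored per column;
zero-variance columns (including padding columns) are left at 0 rather than
dividing by zero. For DTW and cross-correlation, which consume per-call
matrices directly, each feature/bin dimension is z-scored with statistics
pooled over all windows of all calls, so distances are comparable across
calls without collapsing the time axis.

## Features

27 features per call or window (26 in `win`, where the window count already
encodes duration; in `win_pct` the whole-call duration is repeated in every
window). Notable implementation choices:

* **F0** — normalized autocorrelation with peak picking in a configurable
  search band (default 100–4000 Hz) and parabolic refinement. Periodic
  signals peak at every multiple of the period, so among peaks within 0.025
  of the maximum the smallest lag is taken, which suppresses octave errors
  toward subharmonics. Peaks below 0.3 are treated as unvoiced (missing).
* **ΔF0** — difference of adjacent per-window F0; the first window has no
  left neighbor and is set to 0; all-in-one reports the median difference.
* **Occupied bandwidth** — the central band containing 99% of spectral power
  (0.5% trimmed per side of the cumulative power); energy quartiles and the
  per-quartile peak frequencies come from the same cumulative distribution.
  "Energy" is spectral power (magnitude squared).
* **LPC bands** — an order-205 linear-predictive envelope (autocorrelation
  method, Toeplitz solve), evaluated on a 1024-point grid to Nyquist; peaks
  with prominence ≥ 1% of the envelope maximum, ascending in frequency, give
  FB1–FB3; bandwidths are peak widths at half prominence. The high literal
  order follows the originating analysis and is configurable (`lpc_order`).
* **Harmonic ratio** — maximum normalized autocorrelation over the pitch
  lags, clipped to [0, 1].
* **Spectral flatness** — geometric over arithmetic mean of spectral power
  with a 1e−12 floor inside the logarithm.
* **MFCC 1–2** — 40 triangular mel filters to Nyquist, log energies, DCT-II
  (orthonormal); coefficients are indexed after the 0th (energy) coefficient.

Unvoiced windows and absent LPC bands yield missing values, which are imputed
with 0 before clustering so no NaN propagates; for real recordings the
extracted contours should be inspected, since weak or masked harmonics make
F0/FB estimates unreliable.

All-in-one summaries take the whole-call spectrum for spectral features and
medians over 2048-sample windows for the intrinsically windowed features
(F0, ΔF0, LPC bands, harmonic ratio, MFCCs).

## Similarity and automatic k

DTW is unconstrained (no warping window), with Euclidean column distance and
the standard step set {repeat column of either signal, advance both}; the
distance is the cumulative cost of the optimal path. Cross-correlation is
unnormalized (Eq.-level definition); vectors are zero-padded at the end to
equal length, matrices are correlated over all 2-D lags (a `time_lag_only`
flag restricts the frequency lag to 0 for speed; default off). Scale control
comes from the upstream z-scoring. kNN uses Euclidean distance on the row
matrix. Ranking ties resolve by ascending call index, which makes every
downstream result deterministic.

The Jaccard matrix uses each call's top-k neighbor set, self excluded (a
self-match carries no pairwise information and would inflate all entries
equally). k is selected by clustering every k in a grid and keeping the k
whose cluster count is most frequent at the highest mean silhouette
(silhouette ties → smallest k). The default grid is {2, …, min(N−1, 30,
max(10, ⌈√N⌉))}: top-k sets carry class information only while k stays below
the typical class size, and counting frequencies over k values far beyond
that floods the selection with washed-out low-K solutions (observed directly
at N = 30, where a perfect K = 4 solution at k = 4–6 was outvoted by k > 12
entries). The grid is per-procedure configurable.

Silhouettes use d = 1 − S on similarity-based paths and Euclidean distance on
row-matrix paths; singleton clusters contribute 0.

## Clustering back-ends

* **Community detection** — in-package greedy agglomerative modularity
  maximization on the weighted graph (diagonal zeroed): starting from
  singleton communities, the merge with the largest ΔQ is applied until one
  community remains, and the partition at maximum Q is returned. The
  single-community endpoint scores Q = 0, so the reported Q is never
  negative. Merge ties resolve to the lexicographically first pair.
* **Adaptive affinity propagation** — sklearn's message passing per
  preference value; the adaptive schedule is in-package. Preferences start at
  the median similarity and are reduced uniformly until at most 3 clusters
  emerge — the scan extends below the similarity range if needed (sparse
  Jaccard graphs may require preferences far below it), with step doubling as
  a safety valve — then swept upward in 50 uniform steps to 1, the Jaccard
  ceiling. Every step records K and silhouette; the non-degenerate step
  (1 < K < N) with the best silhouette is returned, following the adaptive
  scanning strategy of the algorithm this sweep is based on. Non-convergence
  at a step raises the damping factor (0.5 → 0.9 in 0.1 steps) before the
  step is skipped.
* **HDBSCAN** — sklearn's implementation (the standard excess-of-mass
  cluster selection) with minpts = minclustsize = 2; noise points are
  relabeled 0 and excluded from silhouette and NMI computations.
* **Fuzzy c-means with merging** — in-package. The fuzziness sweep is
  warm-started: clustering begins from 15 randomly chosen calls (fixed seed)
  at μ = 1.1, and each subsequent μ continues from the previous centroids;
  centroids within ε = 0.01 (Euclidean, in the clustered space) merge
  permanently, so K(μ) decreases monotonically — increasing fuzziness
  decimates the solution step by step. The K persisting over the most μ
  values wins (ties → smaller K), realized at its best-silhouette μ. Steps
  with K equal to the starting count (no merging yet) are not candidate
  solutions — they reflect the arbitrary cmax, not structure — symmetric to
  excluding affinity propagation's every-point-an-exemplar saturation.
  Convergence: centroid movement < 1e−6 or 300 iterations. The μ = 1 + 2/D
  heuristic for high-dimensional data is available (`mu_from_dimensions`)
  but off by default; it did not help in the originating analysis either.

All methods are deterministic under a fixed seed; the default seed 42 is
recorded in every output.

## Evaluation

NMI normalizes mutual information by the geometric mean of the label
entropies (natural logs; the base cancels). Conventions: exactly one constant
labeling → 0; two constant labelings → 1. Noise-labeled calls (0) are dropped
from both labelings before comparison; Δ-cluster is |K_est − K_ref| computed
on non-noise labels. The pass thresholds are NMI > 0.5 (strict) and Δ ≤ 1.
Chance-adjusted variants (AMI/ARI) are deliberately out of scope.

## Synthetic study conditions

The generator produces additive harmonic synthesis along piecewise-linear F0
contours with an attack/sustain/release envelope, white Gaussian noise at a
target SNR, and per-call jitter (2% on F0 scale, 5% on duration, 2 dB on
SNR) — deterministic per seed.

* **Repertoire condition** (48 kHz, 5 types × 20 calls): tonal types
  separated in register (800–3800 Hz), duration (0.18–0.7 s), contour shape,
  and harmonic count; between-type F0 separation is more than 5 within-type
  SDs ("easy"). A "hard" variant shares register and duration and differs
  only in modulation depth.
* **Signature condition** (96 kHz, 4 individuals × {5, 6, 7, 12} calls): one
  cohesion-call archetype — 2 whole FM cycles, 1350 ± 450 Hz, 0.9 s, 3
  harmonics, 25 dB SNR — with per-individual quarter-cycle phase shifts and
  brief 3% onset/offset ramps. Phase shifting leaves every time-marginal
  statistic identical across individuals (same distribution of instantaneous
  frequencies and slopes), so all-in-one summaries are confusable by
  construction while windowed contours differ maximally. Long onset ramps
  would weight the whole-call spectrum by what the contour does at the call
  edges and leak identity into time-invariant features, which is why the
  ramps are brief.

What passing tests on these fixtures show — and don't: the synthetic calls
are stationary-noise, single-source, perfectly segmented, and harmonically
clean. Real recordings add colored background noise, reverberation, graded
call variants, segmentation errors, and amplitude variation with distance;
results on the fixtures demonstrate the machinery and its qualitative
behavior (windowed extraction recovers FM identity where whole-call summaries
cannot), not field-level performance.

## Problem sizes and numerical choices

The shipped tests and the reproduction script run the two conditions at
N = 100 (repertoire) and N = 30 (signatures), matching the scale the method
targets; a full 48-procedure grid on N = 30 completes in minutes, with 2-D
cross-correlation of spectrogram matrices the dominant cost (the
`time_lag_only` flag trades lag coverage for speed). Degenerate inputs raise
typed errors (`InputError`, `ParameterError`, `DegenerateInputError`) naming
the offending call. Known limitations: no segmentation of continuous
recordings, no SNR screening, no cochleagram/mel filter-bank spectrograms, no
dimensionality reduction, and unconstrained DTW only.
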