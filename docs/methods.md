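# Methods

## Model

Each omics layer enters as a molecule × timed-sample matrix `A` (m ≥ 2
molecules, n ≥ 3 samples) on log scale. The full SVD
`A = Σ_{k=0}^{s−1} λ_k u_k v_kᵀ` is computed exactly
(`numpy.linalg.svd`); singular values below `1e−10 · λ_0` are discarded as
numerical rank noise (they would otherwise corrupt the eigen-entropy).

On normalized data the leading level is a baseline: its sample loadings
are nearly equal, so `v_0 ≅ (1/√n) 1` and `λ_0 u_0 v_0ᵀ ≅ μ 1ᵀ` with `μ`
the row-mean vector. `baseline_diagnostics` checks this with the CV of
`|v_0|` (pass threshold 0.1; the strength of "nearly equal" is a judgment
call and the threshold is configurable) and warns when baseline removal
would not approximate mean-centering. All level-k ≥ 1 analysis operates on
`Ā = A − λ_0 u_0 v_0ᵀ`, for which the identities
`λ_k² = ‖Ā v_k‖²` and `Σ_{k≥1} λ_k² = ‖Ā‖²_F` hold to 1e−8 relative and
are enforced by tests.

Relative contributions are `p_k = λ_k² / Σ_{k'≥1} λ_{k'}²` and the
eigen-entropy is `H = −Σ p_k ln p_k` in nats (the base is a presentation
choice; a normalized variant `H / ln(#levels)` is reported alongside).

### Sign conventions and phase calling

An SVD level is determined only up to a joint sign flip of `(u_k, v_k)`.
`stratify` fixes signs deterministically — skewness of `u_k` ≥ 0, falling
back to making the largest-|loading| molecule positive when the skewness
is numerically zero — and records the applied flip. Because this
convention is data-driven, cross-dataset or truth-referenced analyses
re-orient levels explicitly (`orient_to_reference`, and the lag estimator
scans both orientations).

Phase labels come from loading signs at levels 1 and 2: 1A ⇔ `v_1j > 0`,
1B ⇔ `v_1j < 0`, 2A/2B likewise at level 2 (mapping A to the positive pole
is a configurable presentation choice). Loadings with `|v| < 1e−12` are
flagged "boundary" and excluded from order inference. The cyclic order is
inferred from the circular positions `θ_j = atan2(v_2j, v_1j)`: each
label's midpoint is the circular mean over its samples, the traversal
direction is the sign of the summed wrapped `Δθ` over time-ordered
samples, and the sequence is reported starting at 1B. On quadrature
signals this reproduces the observed cycling 1B → 2A → 1A → 2B. Exactly
equal `λ_1 = λ_2` makes the two levels rotation-ambiguous; phases are
still emitted with a warning.

### Concatenation

Two matrices over the same ordered molecules are combined by removing each
baseline eigen-matrix, scaling to unit Frobenius norm, dividing by √n (so
sample-rich datasets do not dominate), column-concatenating and
stratifying. Levels are indexed from 1 (the baselines were removed) and
each sample-eigenvector is partitioned back into per-dataset segments.

## Preprocessing

The normalization slot is pluggable and provenance-tracked; the built-in
normalizer subtracts from each log-scale column the median of its
difference to a reference column — one robust location shift per sample.
The reference sample maximizes `S_j = Σ_{j'≠j} skew(col_j − col_j')`
(adjusted Fisher–Pearson skewness; a degenerate constant difference
contributes 0 with a warning; ties break to the earliest sample).
Normalization quality is checked by the mode of each pairwise difference
density (Gaussian KDE, Silverman bandwidth, 512-point grid spanning the
data range; pass when |mode| ≤ 0.1). The log transform is
`log2(x + pseudocount)` with pseudocount 1 by default — the source
datasets' own transform details are not recoverable, so both constants are
declared, guarded against double application, and configurable.
Molecules with missing values are dropped rather than imputed: SVD needs
complete matrices, and imputation would inject structure the decomposition
would then "discover".

## Timeline alignment

Dissolved-oxygen curves anchor each dataset's clock. DDTW estimates local
derivatives on the index scale (`d_i = ((x_i − x_{i−1}) + (x_{i+1} −
x_{i−1})/2)/2`, endpoints copying their neighbors) and minimizes the summed
squared derivative difference over monotone paths with steps (1,1), (1,0),
(0,1), full boundary conditions and no window — curves here are short, so
no band constraint is needed. Ties prefer the diagonal, then advancing the
reference. Curves with irregular grids are first linearly resampled to
their median spacing (`resample_uniform`). Sample times are pushed through
the warp by linear interpolation, averaging reference indices where the
path pairs several with one query index.

Known limitation: time warping is locally unidentifiable where the
indicator is flat, and a clock distortion also rescales derivative
amplitudes, which biases DDTW by a fraction of the local warp. With the
default oxygen shape and a smooth monotone distortion of amplitude 0.1 h
(period 3 h), the mapping error stays around 0.05–0.09 h — below the
omics sampling interval (0.19 h at 16 samples/cycle) but not below the
curve grid spacing. Lags smaller than this alignment error should be read
from directly comparable clocks.

Metabolome platforms are merged by linearly interpolating GC-TOFMS rows at
the LC-MS sample times (both on the unified timeline); out-of-span times
clamp to the endpoint with a warning, and a metabolite present on both
platforms keeps its LC-MS row, since the merge targets LC-MS time points.

## Lag estimation

Loading curves (sample loadings vs unified-timeline hours) are resampled
by a natural cubic spline (zero second derivative at the ends) onto a
0.001 h grid over the common span, and Pearson correlation on the
overlapping support is computed at every shift within ±max_lag (default:
half the nominal period, 1.5 h, to resolve the periodic ambiguity toward
the smallest shift). No zero-padding is used — padding biases toward zero
lag. Shifts with under 50% overlap or zero variance are skipped; ties
within 1e−9 resolve to the smallest |lag|, then the negative one.
Positive lag means the first dataset is later. Orientation matching scans
the query level both ways; because near-sinusoidal curves make a flipped
level at lag ± T/2 almost as good as the true orientation at the true lag,
scans whose best |ρ| differ by ≤ 0.05 are treated as tied and the smaller
|lag| wins — the same smallest-shift preference as the in-scan rule. The
scan is computed for all shifts at once via FFT cross-correlation plus
prefix-sum overlap statistics.

The per-pair result reports each requested level and, when both levels 1
and 2 are requested, their unweighted mean as the "averaged" lag.
Confidence intervals come from R = 1000 perturbation replicates (default):
each adds independent Gaussian noise with sd = 10% of the loading series'
sd to both series at the sample points, re-runs spline + scan, and the
2.5/97.5 percentiles of replicate lags form the CI (the percentile
construction and R are this package's choices). Fixed seeds make the CI
deterministic; replicates failing on overlap are dropped, with an error
when more than 20% fail.

## Eigenvector interpretation

**Enrichment.** Gene sets (GMT) with ≥ 5 members present are scored by the
two-sample rank-sum of in-set vs out-of-set loadings — loadings act as a
weighted differential profile, and a rank statistic makes the result
invariant to monotone transforms. Small tie-free problems (set ≤ 10,
total ≤ 25) use the exact distribution; otherwise the
continuity-corrected normal approximation with tie correction. One-sided
p-values are reported per pole with a signed z, and Benjamini–Hochberg
adjustment runs within each pole. A set equal to the whole matrix is
degenerate and reported as z = 0, p = 1.

**Marker randomization.** Using `λ_k u_k = A v_k`, random unit
sample-vectors orthogonal to `v_0..v_k` are pushed through the data,
`u_k^r = A v_k^r / ‖A v_k^r‖`, giving each molecule a null for its
loading. The tail is selected by the observed sign and counted with a +1
correction; since tail selection doubles the null chance of a small
one-sided p, the selected-tail probability is doubled
(`p = min(1, 2(1+count)/(1+R))`) to keep p approximately uniform under an
isotropic null. Exactly zero loadings get p = 1. Markers require
p ≤ 0.01 and |loading| at or above the 95th percentile (both
configurable). Limitation: the null excludes the observed level's own
direction, so on pure noise the test is mildly anti-conservative in the
extreme tail (empirical type-I at 0.05 runs ≈ 0.05–0.08); the KS distance
to uniform stays below 0.06 at R = 1000, m = 500.

**Phase contributions.** A signal matrix (e.g. one histone modification)
is interpolated per gene (linear, a declared choice) to the reference
sampling times; the reference eigenvectors are split as
`u⁺ = max(u, 0)`, `u⁻ = max(−u, 0)`, each normalized to sum 1, and the
contributions are `c(1A) = u₁⁺ᵀ A v₁⁺`, `c(1B) = u₁⁻ᵀ A v₁⁻`, `c(2A) =
u₂⁺ᵀ A v₂⁺`, `c(2B) = u₂⁻ᵀ A v₂⁻`, with CV = sample sd / mean over the
four. A constant matrix yields four equal contributions and CV 0; a
one-signed eigenvector makes one weight vector empty and is an error.

## Synthetic data

The generator emulates the study conditions so every stage has a
parameter-recovery test. Defaults: m = 500 molecules; period T = 3 h;
two full cycles sampled at 16 samples/cycle on a midpoint grid (complete
cycles keep the quadrature pair exactly orthogonal without ever sampling
on a sign boundary); three layers — transcriptome (τ = 0), H3K9ac-like
epigenome (τ = −0.05 h) and metabolome (τ = +0.22 h) — matching the
minute-scale lead/lag ordering of the real system; λ₁ = 2, λ₂ = 1
(λ₁/λ₂ = 2, the primary level dominates). The planted temporal pair is
`v₁(t) = cos(2πt/T + φ)`, `v₂(t) = −sin(2πt/T + φ)`, the quadrature
orientation whose four-phase traversal cycles 1B → 2A → 1A → 2B.

Noise sd is calibrated so the realized top-two contribution is ≈ 0.6 at
the default sampling: beyond the planted signal power
`S = (λ₁² + λ₂²) n/2`, isotropic noise fills ≈ `(n−1) m σ²` of the
baseline-removed variance and inflates the two signal levels by ≈
`(m+n) σ²` each (first-order spiked-matrix behavior), and σ solves
`S + 2(m+n)σ² = 0.6 (S + (n−1) m σ²)` at the reference n = 32.

A marker block (4% of molecules) carries 80% of the u₁ mass in
equal-magnitude weights, half at each pole — two sharply anti-regulated
modules whose sign balance keeps the block nearly orthogonal to the
constant baseline direction. The per-molecule baseline μ ~ N(8, 1) is
orthogonalized against u₁ and u₂ so the planted decomposition coincides
with the SVD under balanced sampling, making noiseless recovery exact.

Oxygen curves share one latent phase through
`o(t) = exp(a cos(θ + b sin θ))` (a = 1.5, b = 0.6, rescaled to 2–60
arbitrary units) — an asymmetric trace with a fast drop and slow recovery.
Per-dataset clock distortions `g(t) = t + d sin(2πt/T + ψ)` default to
identity (d = 0): with shared honest clocks the unified timeline is exact,
which is the regime in which minute-scale lag recovery is meaningful;
distortions are switched on explicitly in alignment tests.

What the generator does **not** emulate: count-level sequencing noise
(noise is Gaussian on the log scale), non-sinusoidal waveform shapes,
drifting periods across cycles, molecule-specific phase offsets beyond two
levels, and real gene-set structure. Passing recovery tests therefore
demonstrates correctness of the machinery under the stated model, not
robustness to every behavior of real data.

## Problem sizes and determinism

Tests and the acceptance script run the default study (500 × 32 per
layer), 20-seed recovery batches, 100 CI-coverage pairs at R = 500, and
R = 1000 randomization nulls — sizes chosen so the whole suite completes
in minutes on one core while keeping Monte-Carlo margins comfortable.
All randomness flows from explicit seeds (`numpy.random.default_rng`);
pipeline reruns with the same config and seed are byte-identical.
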