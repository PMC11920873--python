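# eigenphase

SVD eigen-phase analysis of cyclic multi-omics time courses, built around
the yeast metabolic cycle (YMC): continuous yeast cultures oscillate with a
~3 h period visible at once in dissolved oxygen, transcripts, histone
marks and metabolites. `eigenphase` synthesizes such layered time courses
into one quantitative picture: which molecular program dominates, when each
layer moves, and which molecules drive each phase.

The package is for computational biologists working with periodic bulk
omics (transcriptome, ChIP-seq signal, metabolome) sampled over one or a
few cycles, and for methodologists who want a tested reference
implementation of the underlying matrix machinery.

## The model

Each omics layer is a molecule × timed-sample matrix `A` on log scale. Its
SVD, `A = Σ_k λ_k u_k v_kᵀ`, stratifies the data into ranked eigen-levels:
a singular value `λ_k`, a molecule-eigenvector `u_k` (a differential
profile over molecules) and a sample-eigenvector `v_k` (a temporal
pattern). After normalization, level 0 is a baseline — `v_0 ≅ (1/√n) 1`,
so `λ_0 u_0 v_0ᵀ ≅ μ 1ᵀ` with `μ` the per-molecule mean — and the
remaining levels carry the cyclic variance, with relative contributions
`λ_k² / Σ λ_k²` and eigen-entropy `H = −Σ p_k ln p_k`.

The signs of the sample loadings at levels 1 and 2 define the four
eigen-phases 1A/1B (level 1) and 2A/2B (level 2), which cycle in the order
1B → 2A → 1A → 2B. Writing the per-molecule signal as

    a(i, t) = μ(i) + λ₁ u₁(i) v₁(t − τ) + λ₂ u₂(i) v₂(t − τ) + ε(i, t)

per layer, the shift `τ` captures each layer's timing. Layers are placed
on a unified timeline by derivative dynamic time warping (DDTW) of their
dissolved-oxygen curves; the lag between two layers is the shift maximizing
the cross-correlation of their spline-resampled loading curves, with a
perturbation-based 95% CI. Molecule-eigenvectors are interpreted by
rank-sum gene-set enrichment, by a randomization null over sample-vectors
orthogonal to the leading levels (marker molecules, via `λ_k u_k = A v_k`),
and by phase-contribution bilinear forms `u_k^±ᵀ A v_k^±` with CV across
the four phases.

## Worked example

```bash
python examples/02_align_and_lag.py
```

prints, for a synthetic three-layer study with planted lags −3 min
(histone mark) and +13.2 min (metabolome) relative to the transcriptome:

```
H3K9ac: DDTW cost 0
metabolome: DDTW cost 0
H3K9ac vs transcriptome: lag -2.1 min (95% CI [-3.1, -1.0] min; planted -3.0 min)
metabolome vs transcriptome: lag +13.9 min (95% CI [12.9, 14.9] min; planted +13.2 min)
```

Negative lag = the first layer leads: chromatin acetylation moves a few
minutes before transcription, and metabolite pools respond a quarter hour
after it — the planted values sit inside both confidence intervals. The
other examples cover stratification and phase calling (`01`), markers and
enrichment (`03`), histone phase contributions (`04`) and transcriptome
concatenation (`05`). Each prints the numbers it computes with a note on
what they mean.

A thin CLI wraps the same library calls
(`eigenphase simulate | preprocess | decompose | concat | align | lag |
enrich | markers | contrib | run`); `eigenphase run --config config.yaml`
executes the whole pipeline from a YAML config and writes a deterministic
`summary.json`.

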