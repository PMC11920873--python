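"""Stratify a cyclic omics matrix and call the four eigen-phases.

Builds a synthetic transcriptome time course (two 3 h cycles, 16 samples
per cycle), decomposes it into baseline + ranked eigen-levels, and reads
off contributions, eigen-entropy and the per-sample phase labels.
"""

import numpy as np

import eigenphase as ep

truth = ep.generate_truth(seed=1)
mat = ep.simulate_omics(truth, "transcriptome")
dec = ep.stratify(mat)

contrib = ep.relative_contributions(dec)
print(f"retained levels: {dec.s} (level 0 is the baseline)")
print(f"level-1 contribution: {contrib.ratios[0]:.3f}")
print(f"level-2 contribution: {contrib.ratios[1]:.3f}")
print(f"top-two contribution: {contrib.top_two():.3f}")
print(f"eigen-entropy: {contrib.eigen_entropy:.3f} nats "
      f"(normalized {contrib.normalized_entropy:.3f})")
# The top two levels carry ~60% of the cyclic variance; the eigen-entropy
# measures how spread the remaining variance is across minor levels.

diag = ep.baseline_diagnostics(dec)
print(f"baseline check: CV(|v0|) = {diag['cv_abs_v0']:.2e}, passed = {diag['passed']}")

# orient levels to the planted periodic functions (resolves SVD sign
# ambiguity the way a reference convention would on real data)
t = ep.default_sample_times(truth)
ep.orient_to_reference(dec, 1, truth.v1(t))
ep.orient_to_reference(dec, 2, truth.v2(t))
calls = ep.call_phases(dec)
print(f"cyclic phase order: {' -> '.join(calls.cyclic_order)}")
print(calls.table.head(8).to_string(index=False))
# Each sample carries a level-1 label (1A/1B) and a level-2 label (2A/2B);
# adjacent phases overlap, and the order cycles 1B, 2A, 1A, 2B.
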