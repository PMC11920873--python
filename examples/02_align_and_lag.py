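"""Align three omics layers on one timeline and estimate their time lags.

The epigenome layer is planted 0.05 h (3 min) ahead of the transcriptome
and the metabolome 0.22 h (13 min) behind it. Oxygen indicator curves are
DDTW-aligned to build the unified timeline; lags come from the maximum
cross-correlation of spline-resampled sample-eigenvector loading curves,
with perturbation confidence intervals.
"""

import eigenphase as ep

truth = ep.generate_truth(seed=2)
decs, timelines = {}, {}
ref_curve = ep.simulate_oxygen(truth, "transcriptome", n_points=121)
for label in truth.omics:
    decs[label] = ep.stratify(ep.simulate_omics(truth, label))
    if label != "transcriptome":
        q_curve = ep.simulate_oxygen(truth, label, n_points=121)
        path = ep.ddtw_align(ref_curve, q_curve)
        timelines[label] = ep.map_sample_times(
            path, ref_curve, q_curve, decs[label].sample_times, label
        )
        print(f"{label}: DDTW cost {path.total_cost:.4g}")

for label in ("H3K9ac", "metabolome"):
    planted = truth.omics[label].tau
    ests = ep.lag_ci(decs[label], decs["transcriptome"],
                     timeline=timelines[label], R=500, seed=7)
    avg = [e for e in ests if e.level == "averaged"][0]
    print(f"{label} vs transcriptome: lag {avg.lag * 60:+.1f} min "
          f"(95% CI [{avg.ci_low * 60:.1f}, {avg.ci_high * 60:.1f}] min; "
          f"planted {planted * 60:+.1f} min)")
# Negative lag = the first dataset leads the second. Expect roughly -3 min
# for the epigenome layer and +13 min for the metabolome.
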