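"""Stabilize stochastic clusterers and screen methods against the benchmark.

A stochastic clusterer (k-means here) gives a different partition on every
run; the stabilization step finds how many repeats must be fused by
consensus before the result stops changing.  Method selection then keeps
only candidates that agree with modified k-means (the microstate
benchmark) on most subjects.
"""

import erpconsensus as ec
from erpconsensus.ensemble import select_methods, stabilize_method

study = ec.simulate_study(ec.default_study_spec(n_subjects=8, n_channels=32, seed=0))
ga = study.grand_average_concatenated()

res = stabilize_method("kmeans", ga, k=7, Mr=12, tau=0.90, eps=0.03, seed=0)
print(f"k-means stabilization: r_opt={res.r_opt}, converged={res.converged}")
print("mutual similarity R_r by repeat count:")
for r, value in res.R_series.items():
    print(f"  r={r:2d}: {value:.3f}")
print()

report = select_methods(
    study, k=7,
    candidates=["kmeans", "hierarchical_corr", "fcm", "som",
                "diffusion_spectral", "aahc"],
    sim_threshold=0.8, seed=0, Mr=12,
)
print("subjects agreeing with the benchmark (of", study.n_subjects, "):")
for method, count in report.counts.items():
    marker = "*" if method in report.selected else " "
    print(f" {marker} {method:20s} {count}")
print("selected for the consensus ensemble:", ", ".join(report.selected))
print("(a high count means the method recovers the same microstate")
print(" sequence as modified k-means on that subject's data)")
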