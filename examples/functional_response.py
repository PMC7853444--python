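"""Fit functional responses to one simulated predation study.

Generates the full experimental layout (seven larval densities, four
predator replicates plus one control per density, six species x
temperature combinations), classifies each group's response type, and
estimates attack coefficient b (arena/h) and handling time h (h/prey)
with 95% profile confidence intervals.
"""

from copefr.pipeline import PipelineConfig, run_fr_analysis

result = run_fr_analysis(PipelineConfig(seed=42))

print("group                 type     variant          b [95% CI]            h [95% CI]")
for key, fit in result.fits.items():
    cls = result.classifications[key].classification
    ci_b, ci_h = fit.profile_cis["b"], fit.profile_cis["h"]
    print(
        f"{key[0]:>10s} {key[1]:>3d}C   {cls:8s} {fit.variant:15s} "
        f"{fit.params.b:5.2f} [{ci_b.low:4.2f}, {ci_b.high:5.2f}]   "
        f"{fit.params.h:5.2f} [{ci_h.low:4.2f}, {ci_h.high:4.2f}]"
    )

n_sig = int(result.comparisons.significant.sum())
print(f"\n{n_sig} of {len(result.comparisons)} pairwise CI comparisons are disjoint.")
print(
    "Every group was simulated from the same type II truth (b = 1, h = 0.5),\n"
    "so all groups should classify type II and no pair should differ."
)
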