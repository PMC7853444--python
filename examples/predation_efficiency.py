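"""Abbott-corrected predation efficiency and AIC model ranking.

Generates the predation-efficiency arm (24 dishes of 24 larvae per
temperature: 8 per predator species plus 8 controls), computes each
matched pair's control-corrected efficiency, and ranks six candidate
linear models of efficiency by AIC.
"""

from copefr.pipeline import PipelineConfig, run_efficiency_analysis

result = run_efficiency_analysis(PipelineConfig(seed=42))

d = result.distribution
print(
    f"efficiency over {len(result.records)} pairs: "
    f"min {d['min']:.1f}%, median {d['median']:.1f}%, max {d['max']:.1f}%, "
    f"skewness {d['skewness']:.2f}, kurtosis {d['kurtosis']:.2f}"
)

print("\nmodel ranking (lower AIC is better; a lead >= 2 counts as preferred):")
print(result.selection[["model", "adjusted_r2", "aic", "delta_aic"]].to_string(index=False))

name, est, se, t, p = result.model_fits["mass"].term("mass")
best = result.selection.model.iloc[0]
print(
    f"\nmass-only slope: {est:.1f} +- {se:.1f} % per mg (p = {p:.2g})\n"
    f"best model in this draw: {best}\n"
    "The generator's truth is a pure body-mass effect (34.44 %/mg).  Across\n"
    "many draws the mass-only model wins the ranking most often, but species\n"
    "-- a coarse proxy for mass -- can edge it out in a single study of this\n"
    "size, which is worth remembering when reading any one AIC table."
)
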