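"""Mixed-layer depth and stratification from a synthetic summer cast.

The cast has a density step at 15 m and a surface-to-75 m temperature
gradient of 7.5 degC, so the threshold rule should return 15 m and the
stratification index 0.1 degC/m.
"""

from bactoseries import generate_profile, summarize_cast

cast = generate_profile(mld_true=15.0, surface_T=20.0, deep_T=12.5)
summary = summarize_cast(cast)
print(f"mixed-layer depth: {summary.mld_m:.0f} m (truth 15)")
print(f"stratification index: {summary.stratification_index_C_m:.3f} degC/m (truth 0.100)")
print(f"upper-mixed-layer mean temperature: {summary.uml_means['temperature']:.2f} degC")
# Bacterial and environmental variables are averaged over the depths
# above the mixed-layer depth before any time-series analysis.
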