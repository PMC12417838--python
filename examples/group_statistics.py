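"""Nonparametric group comparison and infiltration correlation.

Computes the 38-feature table on a synthetic cohort, compares key features
across compartments (Kruskal-Wallis omnibus + Dunn post hoc), then draws a
biopsy table whose counts are tied to absolute beta power and recovers the
within-stratum Spearman correlation.
"""

from ecogpipe import (PipelineConfig, compartment_summary,
                      compute_feature_table, generate_infiltration_table,
                      generate_recording, stratify_and_correlate)

config = PipelineConfig(seed=3)  # 30 channels/compartment, 60 s at 500 Hz
recording, truth = generate_recording(config.synth_config())
table, _ = compute_feature_table(recording, config)

summary, pairwise = compartment_summary(
    table, ["rel_delta", "rel_beta", "slope_20_40"])
print("compartment comparison (mean per group, Kruskal-Wallis omnibus):")
cols = [c for c in summary.columns if c.startswith("mean_")] + ["H", "p_omnibus"]
print(summary.set_index("feature")[cols].round(4).to_string())

print("\nDunn post hoc for relative beta (Holm-adjusted p):")
beta = pairwise[pairwise.feature == "rel_beta"]
print(beta[["group_a", "group_b", "z", "p_adj"]].round(4).to_string(index=False))

# biopsy counts drawn so that, below 50 cells/250 um^2, absolute beta power
# falls as infiltration rises (target Spearman rho = -0.5)
biopsies = generate_infiltration_table(table, "abs_beta", -0.5,
                                       n_biopsies=26, seed=4)
corr = stratify_and_correlate(biopsies, table, features=["abs_beta"])
print("\ninfiltration correlation of absolute beta power per stratum:")
print(corr.round(3).to_string(index=False))
print("\nIn the low-infiltration stratum the correlation is negative by")
print("construction; healthy (count 0) and high strata carry no such effect.")
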