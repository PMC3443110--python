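"""Keyword scan of GO Biological Process text on synthetic data.

Counts genes annotated with immune/inflammation terms and asks how many of
them the differential-expression filter called up or down in either age
contrast — the spreadsheet-style functional readout behind statements like
"107 of 368 immune-annotated genes were increased".
"""

from rankde import (
    SimulationConfig,
    compare_groups,
    effect_map,
    keyword_tally,
    samples_for,
    scale_matrix,
    simulate_experiment,
)

exp = simulate_experiment(SimulationConfig(n_genes=3000, immune_fraction=0.1, seed=8))
matrix, _ = scale_matrix(exp.matrix)
sheet = exp.sample_sheet

maps = []
for age in ("PN11", "PN56"):
    out = compare_groups(
        matrix, samples_for(sheet, "WT", age), samples_for(sheet, "KO", age)
    )
    maps.append(effect_map(out))

tally = keyword_tally(exp.annotations, maps, keywords=["immun", "inflamm"])
print(f"keywords: {tally.keywords}")
print(f"genes with matching GO BP text: {tally.n_matching}")
print(f"  increased in either contrast: {tally.n_up} ({tally.pct_up}%)")
print(f"  decreased in either contrast: {tally.n_down}")
# Matching is plain case-insensitive substring ("immun" catches immune,
# immunity, autoimmune...); up/down are aggregated over both age contrasts,
# so one gene can legitimately count in both directions.
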