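"""Dual-luciferase reporter arithmetic.

Normalizes firefly counts by the co-transfected Renilla control per well,
then computes fold-activation of a promoter by a transcription factor over
the empty-vector (pCI) control, with the SEM of the treatment replicates.
"""

from rankde import AssayWell, fold_activation, normalized_activity

control = [
    AssayWell("pCI", 5200.0, 41000.0),
    AssayWell("pCI", 4800.0, 39000.0),
    AssayWell("pCI", 5100.0, 42000.0),
]
klf5 = [
    AssayWell("pCI-Klf5", 51000.0, 43000.0),
    AssayWell("pCI-Klf5", 46000.0, 38000.0),
    AssayWell("pCI-Klf5", 55000.0, 45000.0),
]

for well in control + klf5:
    print(f"{well.condition:9s} firefly/renilla = {normalized_activity(well):.3f}")

fold, sem = fold_activation(klf5, control)
print(f"fold-activation of the promoter by Klf5: {fold:.1f} +/- {sem:.2f} (SEM)")
# Fold is the ratio of mean normalized activities (mean of per-well ratios);
# values near 1 mean the factor leaves the promoter unstimulated.
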