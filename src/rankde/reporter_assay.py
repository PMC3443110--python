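"""Dual-luciferase reporter arithmetic.

Each well yields a firefly count (the promoter under test) and a Renilla
count (a co-transfected constitutive control); their ratio is the
transfection-efficiency-normalized promoter activity. Fold-activation of a
treatment over the empty-vector control is the ratio of the two groups'
mean normalized activities (mean of ratios, not ratio of means).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["AssayWell", "normalized_activity", "fold_activation"]


@dataclass(frozen=True)
class AssayWell:
    condition: str
    firefly: float
    renilla: float


def normalized_activity(well: AssayWell) -> float:
    """firefly / renilla; requires renilla > 0."""
    if not well.renilla > 0:
        raise ValueError(f"renilla must be > 0 (well {well.condition!r})")
    return well.firefly / well.renilla


def fold_activation(
    treatment_wells: Sequence[AssayWell], control_wells: Sequence[AssayWell]
) -> tuple[float, float]:
    """Fold-activation of treatment over control and its SEM.

    fold = mean(normalized treatment) / mean(normalized control). The SEM
    is the standard error of the treatment replicates divided by the
    control mean (nan with a single treatment well).
    """
    if not treatment_wells or not control_wells:
        raise ValueError("both groups must be non-empty")
    tr = np.array([normalized_activity(w) for w in treatment_wells])
    ct = np.array([normalized_activity(w) for w in control_wells])
    control_mean = ct.mean()
    if control_mean == 0:
        raise ValueError("control mean activity is zero")
    fold = float(tr.mean() / control_mean)
    if tr.size > 1:
        sem = float(tr.std(ddof=1) / np.sqrt(tr.size) / control_mean)
    else:
        sem = float("nan")
    return fold, sem
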