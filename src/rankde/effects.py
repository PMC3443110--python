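"""Three-level direction labels shared across the pipeline.

Every per-gene, per-contrast outcome is one of ``Increased``, ``Decreased``
or ``Unchanged`` (a gene is only Increased/Decreased when it passes all
selection criteria of the differential-expression filter). The tuple
:data:`EFFECT_LEVELS` fixes the axis ordering used by the concordance
cross-tabulation.
"""

from __future__ import annotations

INCREASED = "Increased"
DECREASED = "Decreased"
UNCHANGED = "Unchanged"

#: Canonical axis order for cross-tabulations.
EFFECT_LEVELS: tuple[str, str, str] = (INCREASED, DECREASED, UNCHANGED)


def validate_effect(label: str) -> str:
    """Return *label* if it is a valid effect class, else raise ValueError."""
    if label not in EFFECT_LEVELS:
        raise ValueError(
            f"unknown effect class {label!r}; expected one of {EFFECT_LEVELS}"
        )
    return label
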