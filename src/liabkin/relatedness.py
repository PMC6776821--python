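"""Relative classes and their variance-component sharing coefficients.

Each class carries the expected fraction of additive-genetic (A),
dominant-genetic (D) and shared-environment (C) variance that two relatives
of that class share.  Full sisters share half the additive and a quarter of
the dominance variance and, by assumption, all of the shared environment;
maternal half-sisters share a quarter of the additive variance and all of
the shared environment.  For paternal half-siblings and cousins the
environmental sharing is not identified by the designs implemented here, so
their C coefficients default to zero but are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace


@dataclass(frozen=True)
class RelatednessClass:
    """A relative-pair class with component sharing coefficients."""

    label: str
    coeff_a: float
    coeff_d: float
    coeff_c: float

    def __post_init__(self) -> None:
        for name in ("coeff_a", "coeff_d", "coeff_c"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    def with_c(self, coeff_c: float) -> "RelatednessClass":
        return replace(self, coeff_c=coeff_c)


FULL_SIBLING = RelatednessClass("full_sibling", 0.50, 0.25, 1.00)
FULL_SISTER = RelatednessClass("full_sister", 0.50, 0.25, 1.00)
MATERNAL_HALF_SIBLING = RelatednessClass("maternal_half_sibling", 0.25, 0.0, 1.00)
MATERNAL_HALF_SISTER = RelatednessClass("maternal_half_sister", 0.25, 0.0, 1.00)
PATERNAL_HALF_SIBLING = RelatednessClass("paternal_half_sibling", 0.25, 0.0, 0.0)
COUSIN = RelatednessClass("cousin", 0.125, 0.0, 0.0)

CLASSES = {
    c.label: c
    for c in (
        FULL_SIBLING,
        FULL_SISTER,
        MATERNAL_HALF_SIBLING,
        MATERNAL_HALF_SISTER,
        PATERNAL_HALF_SIBLING,
        COUSIN,
    )
}


def get_class(label: str) -> RelatednessClass:
    try:
        return CLASSES[label]
    except KeyError:
        raise ValueError(
            f"unknown relatedness class {label!r}; known: {sorted(CLASSES)}"
        ) from None
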