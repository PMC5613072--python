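"""Critical packing parameter and molecular-shape taxonomy.

The Israelachvili packing parameter s = V/(a·l_c) (chain volume V in Å³,
head-group area a in Å², critical chain length l_c in Å) maps onto mean
molecular shapes used to rationalize how lipids pack in mixed films:

======================  =====================
band                    shape
======================  =====================
s ≤ 1/3                 cone
1/3 < s ≤ 0.95          truncated_cone
0.95 < s ≤ 1.05         cylinder
1.05 < s ≤ 3            inverted_truncated_cone
s > 3                   inverted_cone
======================  =====================

The literature gives the shapes, not numeric boundaries; these bands are
a documented convention (cylinder = 1 ± 0.05, boundary values assigned
to the band nearer the cone end) chosen so the usual qualitative
assignments — phosphatidylcholines conical, sphingomyelin a truncated
cone, cholesterol an inverted cone, 7-ketocholesterol (bulkier polar
part, hence smaller s than cholesterol) an inverted truncated cone —
are all expressible. Users supplying their own V, a, l_c should treat
the word-to-band mapping as a convention, not a measurement.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

from .isotherm import Component

__all__ = [
    "SHAPE_BANDS",
    "ShapeAssessment",
    "packing_parameter",
    "shape_class",
    "assess_shape",
]

#: Upper s bound of each shape band, cone end first.
SHAPE_BANDS: tuple[tuple[float, str], ...] = (
    (1.0 / 3.0, "cone"),
    (0.95, "truncated_cone"),
    (1.05, "cylinder"),
    (3.0, "inverted_truncated_cone"),
    (float("inf"), "inverted_cone"),
)


@dataclass(frozen=True)
class ShapeAssessment:
    """Packing parameter and the shape band it falls in."""

    s: float
    shape: str

    def to_json(self) -> str:
        return json.dumps({"s": self.s, "shape": self.shape}, sort_keys=True)


def packing_parameter(v: float, a: float, l_c: float) -> float:
    """s = V/(a·l_c); all inputs strictly positive."""
    if not (v > 0 and a > 0 and l_c > 0):
        raise ValueError(
            f"V, a, l_c must all be > 0, got V={v}, a={a}, l_c={l_c}"
        )
    return v / (a * l_c)


def shape_class(s: float) -> str:
    """Shape label for a packing parameter; bands documented above."""
    if not s > 0:
        raise ValueError(f"packing parameter must be > 0, got {s}")
    for upper, label in SHAPE_BANDS:
        if s <= upper:
            return label
    raise AssertionError("unreachable")


def assess_shape(component: Component) -> ShapeAssessment:
    """Shape assessment from a component's (V, a, l_c) geometry."""
    if component.geometry is None:
        raise ValueError(
            f"component {component.component_id!r} carries no geometry"
        )
    s = packing_parameter(*component.geometry)
    return ShapeAssessment(s=s, shape=shape_class(s))
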