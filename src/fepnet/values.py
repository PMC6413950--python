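"""Free-energy values with uncertainties and provenance.

A :class:`FreeEnergyValue` is the unit of currency of the whole pipeline:
a value in kcal/mol, a standard error in kcal/mol, and a ``kind`` tag that
records where in the analysis the number came from (a single leg, a single
edge repeat, an aggregated edge mean, or a per-ligand absolute estimate).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum


class ValueKind(str, Enum):
    """Provenance of a free-energy number within the pipeline."""

    LEG = "leg"                  # one environment (free or complex) of one repeat
    EDGE_REPEAT = "edge_repeat"  # ddG of one repeat (complex leg minus free leg)
    EDGE_MEAN = "edge_mean"      # repeat-aggregated ddG of a directed edge
    LIGAND_DG = "ligand_dg"      # absolute dG from network reconstruction


@dataclass(frozen=True)
class FreeEnergyValue:
    """A free energy in kcal/mol with a standard error and provenance tag.

    Parameters
    ----------
    value : float
        Free energy in kcal/mol. Must be finite.
    sigma : float
        One standard error, kcal/mol, non-negative.
    kind : ValueKind
        Stage of the pipeline the number belongs to.
    tag : str
        Free-form provenance label (edge id, ligand id, repeat index ...).
    """

    value: float
    sigma: float = 0.0
    kind: ValueKind = ValueKind.LEG
    tag: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise ValueError(f"free energy value must be finite, got {self.value}")
        if not (self.sigma >= 0.0):
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")

    def __neg__(self) -> "FreeEnergyValue":
        return FreeEnergyValue(-self.value, self.sigma, self.kind, self.tag)

    def with_kind(self, kind: ValueKind) -> "FreeEnergyValue":
        return FreeEnergyValue(self.value, self.sigma, kind, self.tag)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.value:.3f} ± {self.sigma:.3f} kcal/mol"


def quadrature(*sigmas: float) -> float:
    """Combine independent standard errors in quadrature."""
    return math.sqrt(sum(s * s for s in sigmas))
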