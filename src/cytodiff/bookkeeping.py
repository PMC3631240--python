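"""Arithmetic estimates for the xenograft experiments.

Links tumour mass to cell counts (assuming tissue density equal to water),
interpolates tumour burden exponentially between two measured anchors, and
estimates the effective T-cell : tumour-cell ratio achieved by a tail-vein
injection under body-wide mass distribution of the injected cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np

from .errors import DomainError

__all__ = [
    "XenograftScenario",
    "cells_from_mass",
    "exponential_interpolate",
    "tail_vein_ratio",
    "estimate_report",
    "round_to_millions",
]

#: Default cell packing density: 1e9 cells per gram, i.e. 1 ng per cell.
#: Consistent with water-density tissue made of ~1 ng cells; note this is not
#: consistent with a 7 µm cell diameter (a 7 µm sphere of water weighs
#: ~0.18 ng) — the value is exposed as a parameter for exactly that reason.
DEFAULT_CELLS_PER_GRAM = 1e9


@dataclass(frozen=True)
class XenograftScenario:
    """Bookkeeping inputs for one xenograft experiment."""

    injected_tumor_cells: float
    injected_T_cells: float
    tumor_mass_g: float
    body_mass_g: float
    t_injection_weeks: float
    t_assess_weeks: float
    cells_per_gram: float = DEFAULT_CELLS_PER_GRAM

    def __post_init__(self) -> None:
        for name in ("injected_tumor_cells", "injected_T_cells", "tumor_mass_g", "body_mass_g"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be non-negative")
        if self.body_mass_g < self.tumor_mass_g:
            raise DomainError("body mass cannot be smaller than tumour mass")
        if self.cells_per_gram <= 0:
            raise DomainError("cells_per_gram must be > 0")


def cells_from_mass(mass_g: float, cells_per_gram: float = DEFAULT_CELLS_PER_GRAM) -> float:
    """Cell count of a tissue mass: ``mass_g × cells_per_gram``."""
    if mass_g < 0:
        raise DomainError(f"mass must be non-negative, got {mass_g!r}")
    if cells_per_gram <= 0:
        raise DomainError("cells_per_gram must be > 0")
    return mass_g * cells_per_gram


def exponential_interpolate(N0: float, NT: float, T: float, t: float) -> float:
    """Cell count at time ``t`` under exponential growth from ``N0`` (t = 0)
    to ``NT`` (t = T): ``N0 · (NT/N0)^{t/T}``."""
    if N0 <= 0 or NT <= 0:
        raise DomainError("counts must be > 0 for exponential interpolation")
    if T <= 0:
        raise DomainError("total time T must be > 0")
    if not (0 <= t <= T):
        raise DomainError(f"t must lie in [0, T], got t={t}, T={T}")
    return N0 * (NT / N0) ** (t / T)


def tail_vein_ratio(scenario: XenograftScenario, tumor_cells_at_injection: float) -> float:
    """Effective T-cell : tumour-cell ratio after a tail-vein injection.

    Injected T cells are assumed to distribute body-wide in proportion to
    mass, so only the tumour's mass fraction of them reaches the tumour:
    ``injected_T_cells · (tumor_mass/body_mass) / tumor_cells_at_injection``.
    """
    if tumor_cells_at_injection <= 0:
        raise DomainError("tumor_cells_at_injection must be > 0")
    if scenario.body_mass_g <= 0:
        raise DomainError("body mass must be > 0")
    return (
        scenario.injected_T_cells
        * (scenario.tumor_mass_g / scenario.body_mass_g)
        / tumor_cells_at_injection
    )


def round_to_millions(count: float) -> int:
    """Presentation rounding to the nearest million (half up)."""
    return int(math.floor(count / 1e6 + 0.5))


def estimate_report(scenario: XenograftScenario) -> dict:
    """Full bookkeeping chain for one scenario.

    Computes the tumour cell count at assessment from its mass, interpolates
    exponentially back to the T-cell injection time (growth anchored at the
    initially injected tumour cells), and derives the effective tail-vein
    ratio.  Counts are reported both raw and rounded to millions.
    """
    cells_at_assess = cells_from_mass(scenario.tumor_mass_g, scenario.cells_per_gram)
    cells_at_injection = exponential_interpolate(
        scenario.injected_tumor_cells,
        cells_at_assess,
        T=scenario.t_assess_weeks,
        t=scenario.t_injection_weeks,
    )
    ratio = tail_vein_ratio(scenario, cells_at_injection)
    return {
        "scenario": asdict(scenario),
        "tumor_cells_at_assessment": cells_at_assess,
        "tumor_cells_at_assessment_millions": round_to_millions(cells_at_assess),
        "tumor_cells_at_T_injection": cells_at_injection,
        "tumor_cells_at_T_injection_millions": round_to_millions(cells_at_injection),
        "tail_vein_ratio": ratio,
    }
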