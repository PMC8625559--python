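"""Stepwise approximate solubility, intrinsic solubility, sink cap, and
shake-flask partition coefficient (logP)."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Protocol

import numpy as np

__all__ = [
    "SolubilityGrid",
    "DissolutionOracle",
    "ShakeFlaskRun",
    "approximate_solubility",
    "donor_concentration_rule",
    "intrinsic_solubility",
    "sink_cap",
    "shake_flask_logP",
    "mean_logP",
]


class DissolutionOracle(Protocol):
    """Abstract dissolution observer: is the compound fully dissolved at
    concentration ``c`` (mg/mL)? Must be monotone — dissolved at ``c``
    implies dissolved at any lower concentration."""

    def query(self, concentration_mg_ml: float) -> bool: ...


def _default_grid_values() -> tuple[float, ...]:
    # decade categories 1..1000 with quarter subclasses (2.5, 5, 7.5) x decade
    vals: list[float] = []
    for decade in (1.0, 10.0, 100.0):
        vals.extend([decade, 2.5 * decade, 5.0 * decade, 7.5 * decade])
    vals.append(1000.0)
    return tuple(vals)


@dataclass(frozen=True)
class SolubilityGrid:
    """Ascending probe concentrations (mg/mL) for the stepwise method.

    Results outside the grid are reported as sentinels (``">1000"`` /
    ``"<1"`` for the default grid).
    """

    concentrations: tuple[float, ...] = _default_grid_values()

    def __post_init__(self) -> None:
        c = self.concentrations
        if len(c) < 2 or any(b <= a for a, b in zip(c, c[1:])):
            raise ValueError("grid concentrations must be strictly ascending")
        if any(x <= 0 for x in c):
            raise ValueError("grid concentrations must be positive")

    @property
    def top_sentinel(self) -> str:
        return f">{self.concentrations[-1]:g}"

    @property
    def bottom_sentinel(self) -> str:
        return f"<{self.concentrations[0]:g}"


def approximate_solubility(
    oracle: DissolutionOracle,
    grid: SolubilityGrid | None = None,
) -> float | str:
    """Stepwise (category then subclass) approximate solubility.

    Returns the largest grid concentration at which the oracle reports
    full dissolution, the top sentinel when dissolved at the top grid
    value, or the bottom sentinel when undissolved even at the lowest.
    The probing order (coarse categories first, then refinement inside
    the located category) never changes the answer for a monotone
    oracle; it only bounds the number of wet-lab steps.
    """
    grid = grid or SolubilityGrid()
    c = grid.concentrations
    if not oracle.query(c[0]):
        return grid.bottom_sentinel
    if oracle.query(c[-1]):
        return grid.top_sentinel
    # bisect for the largest dissolved index; invariant: dissolved at lo,
    # not dissolved at hi
    lo, hi = 0, len(c) - 1
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if oracle.query(c[mid]):
            lo = mid
        else:
            hi = mid
    return c[lo]


def donor_concentration_rule(
    approx_solubility: float | str,
    cap_mg_ml: float = 500.0,
) -> float:
    """Donor concentration from the approximate solubility: capped at
    half the top solubility category (default 500 mg/mL)."""
    if isinstance(approx_solubility, str):
        if approx_solubility.startswith(">"):
            return cap_mg_ml
        raise ValueError(
            f"compound below measurable solubility ({approx_solubility}); unusable as donor"
        )
    if approx_solubility <= 0:
        raise ValueError("approximate solubility must be > 0")
    return min(approx_solubility, cap_mg_ml)


def intrinsic_solubility(measurements_mg_ml: list[float]) -> tuple[float, float]:
    """Mean +/- sample SD of replicate saturation measurements (SD is
    NaN for a single measurement)."""
    if not measurements_mg_ml:
        raise ValueError("need at least one measurement")
    arr = np.asarray(measurements_mg_ml, dtype=float)
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else math.nan
    return float(np.mean(arr)), sd


def sink_cap(S0_mg_ml: float, fraction: float = 0.1) -> float:
    """Target upper limit of acceptor concentration maintaining sink
    conditions: ``fraction`` of the intrinsic solubility."""
    if S0_mg_ml <= 0:
        raise ValueError("intrinsic solubility must be > 0")
    return fraction * S0_mg_ml


@dataclass(frozen=True)
class ShakeFlaskRun:
    """One shake-flask partition experiment.

    ``A0``/``A1`` are aqueous-phase absorbances before/after partition;
    volumes are of the aqueous and octanol phases.
    """

    A0: float
    A1: float
    Vaq_ml: float
    Voct_ml: float

    def __post_init__(self) -> None:
        if self.Vaq_ml <= 0 or self.Voct_ml <= 0:
            raise ValueError("phase volumes must be > 0")
        if not 0 < self.A1 <= self.A0:
            raise ValueError("require 0 < A1 <= A0")

    @property
    def phase_ratio(self) -> float:
        return self.Vaq_ml / self.Voct_ml


def shake_flask_logP(run: ShakeFlaskRun) -> float:
    """logP = log10( (A0 - A1)/A1 * Vaq/Voct ).

    A1 == A0 (no measurable partition) returns -inf rather than raising:
    the quantity is well-defined as a limit and callers can flag it.
    """
    if run.A1 == run.A0:
        return -math.inf
    return math.log10((run.A0 - run.A1) / run.A1 * run.phase_ratio)


def mean_logP(runs: list[ShakeFlaskRun]) -> tuple[float, float]:
    """Equal-weight mean +/- sample SD of per-run logP across phase
    ratios (SD is NaN for a single run)."""
    if not runs:
        raise ValueError("need at least one run")
    vals = np.array([shake_flask_logP(r) for r in runs], dtype=float)
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else math.nan
    return float(np.mean(vals)), sd
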