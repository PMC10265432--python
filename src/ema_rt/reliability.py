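"""Generalizability computations: ICC, Spearman-Brown projections,
reliability curves, and threshold search.

Both the between-person reliability of an n-occasion mean,
Var(BP)/(Var(BP)+Var(WP)/n), and the within-person reliability of an i-item
occasion mean, Var(WP_occ)/(Var(WP_occ)+Var(WP_trial)/i), are the
Spearman-Brown projection n*rho/(1+(n-1)*rho) of their single-unit variance
ratio rho, so one code path serves both — with an exact algebraic inverse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .varcomp import VarianceComponents

__all__ = [
    "ReliabilityCurve",
    "icc_bp",
    "spearman_brown",
    "bp_reliability_at",
    "wp_reliability_at",
    "invert_reliability",
    "min_units_for",
    "reliability_curve",
]


def icc_bp(vc: VarianceComponents) -> float:
    """Between-person ICC: Var(BP) / (Var(BP) + Var(WP)).

    For 3-level components the within-person variance of a single-item
    occasion is var_occasion + var_item.
    """
    wp = vc.var_occasion + (vc.var_item or 0.0)
    total = vc.var_person + wp
    if total <= 0:
        raise ValueError("all variance components are zero; ICC undefined")
    return vc.var_person / total


def spearman_brown(rho: float, n: float) -> float:
    """Reliability of the mean of n exchangeable units with unit reliability rho."""
    return n * rho / (1.0 + (n - 1.0) * rho)


def bp_reliability_at(icc: float, n: int) -> float:
    """Between-person reliability of the mean of ``n`` occasions."""
    if not 0.0 <= icc <= 1.0:
        raise ValueError(f"icc must be in [0, 1], got {icc}")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    return spearman_brown(icc, n)


def wp_reliability_at(var_occasion: float, var_item: float, i: int) -> float:
    """Within-person reliability of an ``i``-item occasion mean."""
    if var_occasion < 0 or var_item < 0:
        raise ValueError("variances must be nonnegative")
    if var_occasion == 0 and var_item == 0:
        raise ValueError("variances cannot both be zero")
    if i < 1:
        raise ValueError(f"i must be >= 1, got {i}")
    return var_occasion / (var_occasion + var_item / i)


def invert_reliability(rel_at_i: float, i: int) -> float:
    """Single-unit reliability rho whose i-unit projection equals ``rel_at_i``."""
    if i < 1:
        raise ValueError(f"i must be >= 1, got {i}")
    if not 0.0 < rel_at_i <= 1.0:
        raise ValueError(f"reliability must be in (0, 1], got {rel_at_i}")
    if rel_at_i == 1.0:
        return 1.0
    return rel_at_i / (i - (i - 1.0) * rel_at_i)


def min_units_for(rho: float, target: float, n_max: int = 100_000) -> int:
    """Smallest integer n with projected reliability >= target (brute scan)."""
    if not 0.0 <= rho <= 1.0:
        raise ValueError(f"rho must be in [0, 1], got {rho}")
    if not 0.0 < target < 1.0:
        raise ValueError(f"target must be in (0, 1), got {target}")
    if rho == 0.0:
        raise ValueError("rho = 0: target reliability is unattainable")
    for n in range(1, n_max + 1):
        if spearman_brown(rho, n) >= target:
            return n
    raise ValueError(f"target {target} not reached within n_max={n_max}")


@dataclass(frozen=True)
class ReliabilityCurve:
    """Projected reliability as a function of the number of units."""

    unit: str  # "occasions" | "items"
    points: tuple[tuple[int, float], ...]
    rho: float
    item_set: str = ""

    def as_arrays(self):
        n = np.array([p[0] for p in self.points])
        r = np.array([p[1] for p in self.points])
        return n, r


def reliability_curve(
    rho: float | None = None,
    *,
    components: VarianceComponents | None = None,
    unit: str = "occasions",
    n_max: int = 70,
    item_set: str = "",
) -> ReliabilityCurve:
    """Projection curve for n = 1..n_max from a single-unit reliability.

    Supply either ``rho`` directly or 2-/3-level ``components``: for
    ``unit="occasions"`` rho is the BP ICC; for ``unit="items"`` rho is the
    single-item within-person reliability.
    """
    if unit not in ("occasions", "items"):
        raise ValueError(f"unit must be 'occasions' or 'items', got {unit!r}")
    if (rho is None) == (components is None):
        raise ValueError("supply exactly one of rho or components")
    if components is not None:
        if unit == "occasions":
            rho = icc_bp(components)
        else:
            if components.var_item is None:
                raise ValueError("items curve needs 3-level components")
            rho = wp_reliability_at(components.var_occasion, components.var_item, 1)
    if not 0.0 <= rho <= 1.0:
        raise ValueError(f"rho must be in [0, 1], got {rho}")
    pts = tuple((n, spearman_brown(rho, n)) for n in range(1, n_max + 1))
    return ReliabilityCurve(unit=unit, points=pts, rho=float(rho), item_set=item_set)
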