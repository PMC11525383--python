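"""GUM-framework propagation: law of propagation of uncertainty.

First-order combination of independent input uncertainties,
u_c² = Σ (c_i·u_i)², with sensitivity coefficients c_i obtained by central
finite differences with a step of one standard uncertainty per input —
scale-free and in the finite-increment spirit of the framework.  The module
also ranks the per-component contributions into an uncertainty budget and
compares a GUM expanded-uncertainty interval y ± k·u_c against a Monte
Carlo coverage interval endpoint-by-endpoint:

    d_low  = |(y − k·u_c) − y_low|,    d_high = |(y + k·u_c) − y_high|,

with the comparison favorable iff both differences are within the
numerical tolerance δ.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distributions import QuantitySet
from .engine import Model

__all__ = [
    "GumResult",
    "ValidationReport",
    "sensitivity_coefficients",
    "combined_standard_uncertainty",
    "expanded_interval",
    "uncertainty_budget",
    "evaluate_gum",
    "validate_gum",
]

BUDGET_COLUMNS = ("symbol", "estimate", "u", "c", "contribution", "share")


@dataclass(frozen=True)
class GumResult:
    """Law-of-propagation result with its per-component budget."""

    y: float
    u_c: float
    k: float
    budget: pd.DataFrame = field(repr=False)

    @property
    def U(self) -> float:
        return self.k * self.u_c

    @property
    def interval(self) -> tuple[float, float]:
        return (self.y - self.U, self.y + self.U)


@dataclass(frozen=True)
class ValidationReport:
    """Endpoint comparison of a GUM interval against a Monte Carlo interval."""

    d_low: float
    d_high: float
    delta: float
    passed: bool

    @property
    def verdict(self) -> str:
        return "pass" if self.passed else "not pass"


def sensitivity_coefficients(model: Model, quantities: QuantitySet) -> dict[str, float]:
    """Central-difference sensitivities c_i = [f(x+u)−f(x−u)]/(2u).

    Each stochastic input is perturbed by ± one standard uncertainty with
    all other inputs held at their estimates.  Constant quantities are
    excluded.
    """
    base = quantities.model_values()
    coeffs: dict[str, float] = {}
    for q in quantities.stochastic():
        u = q.model_distribution().standard_uncertainty
        hi = dict(base)
        lo = dict(base)
        hi[q.symbol] = base[q.symbol] + u
        lo[q.symbol] = base[q.symbol] - u
        try:
            f_hi = float(model(hi))
            f_lo = float(model(lo))
        except Exception as exc:
            raise RuntimeError(
                f"model evaluation failed while perturbing {q.symbol!r}: {exc}"
            ) from exc
        coeffs[q.symbol] = (f_hi - f_lo) / (2.0 * u)
    return coeffs


def combined_standard_uncertainty(
    coeffs: dict[str, float] | np.ndarray, uncertainties: dict[str, float] | np.ndarray
) -> float:
    """u_c = sqrt(Σ (c_i·u_i)²), inputs taken as independent."""
    if isinstance(coeffs, dict):
        keys = list(coeffs)
        if set(keys) != set(uncertainties):
            raise ValueError("coefficient and uncertainty symbols differ")
        c = np.array([coeffs[k] for k in keys], dtype=float)
        u = np.array([uncertainties[k] for k in keys], dtype=float)
    else:
        c = np.asarray(coeffs, dtype=float)
        u = np.asarray(uncertainties, dtype=float)
        if c.shape != u.shape:
            raise ValueError("coefficient and uncertainty vectors differ in length")
    return float(np.sqrt(np.sum((c * u) ** 2)))


def expanded_interval(y: float, u_c: float, k: float) -> tuple[float, float]:
    """GUM coverage interval y ± k·u_c."""
    if not k > 0:
        raise ValueError(f"coverage factor must be > 0, got {k}")
    return (y - k * u_c, y + k * u_c)


def uncertainty_budget(model: Model, quantities: QuantitySet) -> pd.DataFrame:
    """Per-component budget sorted by descending |c_i·u_i|.

    Columns: symbol, estimate, u, c (sensitivity), contribution (c·u) and
    share of u_c².  Ties in |contribution| keep the quantity-set order.
    """
    coeffs = sensitivity_coefficients(model, quantities)
    rows = []
    for q in quantities.stochastic():
        u = q.model_distribution().standard_uncertainty
        c = coeffs[q.symbol]
        rows.append((q.symbol, q.model_value(), u, c, c * u))
    df = pd.DataFrame(rows, columns=list(BUDGET_COLUMNS[:5]))
    total = float(np.sum(df["contribution"] ** 2))
    df["share"] = df["contribution"] ** 2 / total if total > 0 else 0.0
    df = df.sort_values(
        "contribution", key=lambda s: s.abs(), ascending=False, kind="stable"
    ).reset_index(drop=True)
    return df


def evaluate_gum(model: Model, quantities: QuantitySet, k: float = 1.96) -> GumResult:
    """Full GUM evaluation: estimate, combined uncertainty and budget."""
    if not k > 0:
        raise ValueError(f"coverage factor must be > 0, got {k}")
    y = float(model(quantities.model_values()))
    budget = uncertainty_budget(model, quantities)
    u_c = float(np.sqrt(np.sum(budget["contribution"] ** 2)))
    return GumResult(y=y, u_c=u_c, k=k, budget=budget)


def validate_gum(
    gum_interval: tuple[float, float],
    mcm_low: float,
    mcm_high: float,
    delta: float,
) -> ValidationReport:
    """Endpoint-difference comparison of GUM and Monte Carlo intervals."""
    gum_low, gum_high = gum_interval
    for v in (gum_low, gum_high, mcm_low, mcm_high):
        if not math.isfinite(v):
            raise ValueError("interval endpoints must be finite")
    d_low = abs(gum_low - mcm_low)
    d_high = abs(gum_high - mcm_high)
    return ValidationReport(
        d_low=d_low, d_high=d_high, delta=delta,
        passed=(d_low <= delta and d_high <= delta),
    )
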