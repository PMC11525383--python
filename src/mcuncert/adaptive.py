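"""Adaptive Monte Carlo: run blocks until the results stabilize.

Fixed-size Monte Carlo gives no quality control on its own numerical
results.  The adaptive procedure repeats blocks of M trials and, after the
h-th block, computes for each of the four tracked statistics — the
estimate y, the standard uncertainty u(y), and the two coverage-interval
endpoints — the standard deviation of the mean of its per-block values,

    s = sqrt( (1/(h(h−1))) · Σ_r (v(r) − v̄)² ).

The run terminates at the first h ≥ 2 with 2s ≤ δ for all four statistics,
where δ is the numerical tolerance: half a unit in the last digit regarded
as meaningful in the reported standard uncertainty.  All h·M model values
are then pooled for the final estimate, uncertainty and interval.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distributions import QuantitySet
from .engine import Model, coverage_interval, run_block, summarize

__all__ = [
    "AdaptiveResult",
    "NotConvergedError",
    "numerical_tolerance",
    "stabilization_sd",
    "run_adaptive",
    "convergence_trace",
]

logger = logging.getLogger(__name__)

TRACE_COLUMNS = ("h", "M_cum", "s_y", "s_u", "s_ylow", "s_yhigh",
                 "y", "u", "y_low", "y_high")


class NotConvergedError(RuntimeError):
    """An operation required a converged adaptive result."""


@dataclass(frozen=True)
class AdaptiveResult:
    """Pooled result of an adaptive Monte Carlo run.

    ``trace`` has one row per block with the cumulative trial count, the
    four stabilization standard deviations (NaN at h=1), and the running
    per-block statistics.
    """

    y: float
    u: float
    y_low: float
    y_high: float
    M_total: int
    h: int
    block_size: int
    delta: float
    p: float
    converged: bool
    seed: int
    trace: pd.DataFrame = field(repr=False)
    samples: np.ndarray | None = field(default=None, repr=False)


def numerical_tolerance(u: float, ndig: int = 2) -> float:
    """Numerical tolerance δ from a standard uncertainty.

    Write u as c × 10^l with c an ndig-digit integer; δ is half a unit in
    the last digit, 0.5 × 10^l.  E.g. u ≈ 0.30 with ndig = 2 gives
    c = 30, l = −2, δ = 0.005.
    """
    if not u > 0:
        raise ValueError(f"standard uncertainty must be > 0, got {u}")
    if ndig < 1:
        raise ValueError(f"ndig must be >= 1, got {ndig}")
    l = math.floor(math.log10(u)) - (ndig - 1)
    if round(u / 10.0 ** l) >= 10 ** ndig:  # e.g. u = 0.0999 rounds up a digit
        l += 1
    return 0.5 * 10.0 ** l


def stabilization_sd(per_block_values: np.ndarray) -> float:
    """Standard deviation of the mean of the per-block statistics."""
    v = np.asarray(per_block_values, dtype=float)
    h = v.size
    if h < 2:
        raise ValueError(f"need at least 2 blocks, got {h}")
    vbar = v.mean()
    return float(math.sqrt(np.sum((v - vbar) ** 2) / (h * (h - 1))))


def default_block_size(p: float) -> int:
    """At least 100/(1−p) trials per block, and no fewer than 10^4."""
    return max(math.ceil(100.0 / (1.0 - p)), 10_000)


def run_adaptive(
    model: Model,
    quantities: QuantitySet,
    delta: float,
    p: float = 0.95,
    block_size: int | None = None,
    max_blocks: int = 10_000,
    seed: int = 0,
    keep_samples: bool = False,
) -> AdaptiveResult:
    """Adaptive Monte Carlo propagation to numerical tolerance ``delta``.

    Blocks of ``block_size`` trials are added until twice the
    across-block standard deviations of all four tracked statistics fall
    below ``delta`` (requiring h ≥ 2), or ``max_blocks`` is reached, in
    which case the result is returned with ``converged=False`` rather than
    silently passed off as stable.  The final statistics are computed from
    the pooled h·M model values.
    """
    if not delta > 0:
        raise ValueError(f"numerical tolerance must be > 0, got {delta}")
    if block_size is None:
        block_size = default_block_size(p)
    if block_size < 2:
        raise ValueError(f"block size must be >= 2, got {block_size}")
    if max_blocks < 2:
        raise ValueError(f"max_blocks must be >= 2, got {max_blocks}")

    block_samples: list[np.ndarray] = []
    stats = {"y": [], "u": [], "y_low": [], "y_high": []}
    rows: list[tuple] = []
    converged = False
    h = 0
    while h < max_blocks:
        h += 1
        block = run_block(model, quantities, block_size, p, seed,
                          block_index=h - 1, keep_samples=True)
        block_samples.append(block.samples)
        stats["y"].append(block.y)
        stats["u"].append(block.u)
        stats["y_low"].append(block.y_low)
        stats["y_high"].append(block.y_high)

        if h >= 2:
            sds = tuple(stabilization_sd(stats[k]) for k in ("y", "u", "y_low", "y_high"))
            converged = all(2.0 * s <= delta for s in sds)
        else:
            sds = (math.nan,) * 4
        rows.append((h, h * block_size, *sds, block.y, block.u, block.y_low, block.y_high))
        logger.info(
            "block %d: 2s = (%.3g, %.3g, %.3g, %.3g), delta = %g",
            h, *(2 * s for s in sds), delta,
        )
        if converged:
            break

    pooled = np.concatenate(block_samples)
    y, u = summarize(pooled)
    y_low, y_high = coverage_interval(pooled, p)
    if not converged:
        logger.warning("adaptive run stopped at max_blocks=%d without stabilizing", max_blocks)
    return AdaptiveResult(
        y=y, u=u, y_low=y_low, y_high=y_high,
        M_total=h * block_size, h=h, block_size=block_size,
        delta=delta, p=p, converged=converged, seed=seed,
        trace=pd.DataFrame(rows, columns=list(TRACE_COLUMNS)),
        samples=pooled if keep_samples else None,
    )


def convergence_trace(result: AdaptiveResult) -> pd.DataFrame:
    """Per-block table of cumulative trials and stabilization SDs."""
    return result.trace.copy()
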