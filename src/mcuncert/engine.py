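"""Fixed-size Monte Carlo propagation of distributions.

One block: draw M joint samples of the input quantities (mutually
independent), push them through the measurement model, and summarize the
M model values by their mean (the estimate), their standard deviation (the
standard uncertainty) and a probabilistically symmetric coverage interval
taken from the sorted order statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Union

import numpy as np

from .distributions import QuantitySet

__all__ = [
    "McmBlockResult",
    "InsufficientSampleError",
    "summarize",
    "coverage_interval",
    "run_block",
]

Model = Callable[[Mapping[str, Union[float, np.ndarray]]], np.ndarray]


class InsufficientSampleError(ValueError):
    """Too few model values for the requested summary."""


@dataclass(frozen=True)
class McmBlockResult:
    """Summary of one fixed-size Monte Carlo block."""

    y: float
    u: float
    y_low: float
    y_high: float
    M: int
    samples: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.y_low <= self.y <= self.y_high:
            raise ValueError(
                f"block estimate {self.y} outside its coverage interval "
                f"[{self.y_low}, {self.y_high}]"
            )


def summarize(values: np.ndarray) -> tuple[float, float]:
    """Mean and sample standard deviation (ddof=1) of the model values."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise InsufficientSampleError(f"need at least 2 values, got {values.size}")
    return float(values.mean()), float(values.std(ddof=1))


def coverage_interval(values: np.ndarray, p: float) -> tuple[float, float]:
    """Probabilistically symmetric p-coverage interval by nearest rank.

    The values are sorted into non-decreasing order; with M values and
    q = floor(p·M), the interval is the pair of order statistics at 1-based
    ranks (r, r+q) where r is (M−q)/2 rounded to the nearest integer (at
    least 1) — e.g. for M = 1000 and p = 0.95, ranks 25 and 975.  The
    construction is interpolation-free and guarantees that at least a
    fraction p of the values lie inside the interval.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"coverage probability must be in (0, 1), got {p}")
    values = np.asarray(values, dtype=float)
    M = values.size
    if M * min(p, 1.0 - p) < 1.0:
        raise InsufficientSampleError(
            f"{M} values are too few for a p={p} coverage interval"
        )
    sorted_vals = np.sort(values)
    q = math.floor(p * M)
    r = max(1, math.floor((M - q) / 2 + 0.5))
    return float(sorted_vals[r - 1]), float(sorted_vals[r + q - 1])


def run_block(
    model: Model,
    quantities: QuantitySet,
    M: int,
    p: float,
    seed: int,
    block_index: int = 0,
    keep_samples: bool = True,
) -> McmBlockResult:
    """Sample, evaluate and summarize one Monte Carlo block of size M.

    Sampling uses the per-quantity stream-splitting contract of
    :mod:`mcuncert.distributions`: draws depend on ``(seed, symbol,
    block_index)`` only, so blocks are independent and reproducible.
    """
    if M < 2:
        raise InsufficientSampleError(f"block size must be >= 2, got {M}")
    draws = quantities.sample_all(M, seed, block_index)
    values = np.asarray(model(draws), dtype=float)
    if values.shape != (M,):
        raise ValueError(f"model returned shape {values.shape}, expected ({M},)")
    y, u = summarize(values)
    y_low, y_high = coverage_interval(values, p)
    return McmBlockResult(
        y=y, u=u, y_low=y_low, y_high=y_high, M=M,
        samples=values if keep_samples else None,
    )
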