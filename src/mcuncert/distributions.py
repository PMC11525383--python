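"""Probability density functions assigned to input quantities.

Every input quantity of a measurement model carries a state-of-knowledge
distribution: Gaussian for quantities evaluated from replicate statistics
(type A) or from calibration certificates (type B with a stated coverage
factor), rectangular for quantities known only through symmetric limits.
This module provides the constructors for both evaluation routes, the
sampling primitive used by the Monte Carlo propagation, and the JSON
(de)serialization of whole quantity sets.

Seeding contract
----------------
All sampling goes through per-quantity random streams derived
deterministically from ``(root_seed, symbol, block_index)``.  Adding or
removing a quantity from a set therefore never perturbs the draws of the
others, and successive Monte Carlo blocks use provably distinct streams.
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "DistributionSpec",
    "InputQuantity",
    "QuantitySet",
    "ReplicateSet",
    "InvalidParameterError",
    "InsufficientReplicatesError",
    "DegenerateDispersionError",
    "gaussian_from_estimate",
    "rectangular_from_limits",
    "gaussian_from_expanded",
    "type_a_from_replicates",
    "sample",
    "quantity_rng",
    "load_quantities",
    "save_quantities",
]


class InvalidParameterError(ValueError):
    """A distribution constructor received parameters outside its domain."""


class InsufficientReplicatesError(ValueError):
    """Fewer than two observations were supplied for a type-A evaluation."""


class DegenerateDispersionError(ValueError):
    """Replicates have zero spread, so no positive uncertainty exists."""


@dataclass(frozen=True)
class DistributionSpec:
    """A univariate PDF assigned to one input quantity.

    Parameters
    ----------
    kind
        ``"gaussian"`` or ``"rectangular"``.
    param1
        Gaussian: best estimate *x*.  Rectangular: lower limit *a*.
    param2
        Gaussian: standard uncertainty *u(x)* (> 0).  Rectangular: upper
        limit *b* (> *a*).
    """

    kind: str
    param1: float
    param2: float

    def __post_init__(self) -> None:
        if self.kind == "gaussian":
            if not self.param2 > 0:
                raise InvalidParameterError(
                    f"gaussian standard uncertainty must be > 0, got {self.param2}"
                )
        elif self.kind == "rectangular":
            if not self.param1 < self.param2:
                raise InvalidParameterError(
                    f"rectangular limits require a < b, got a={self.param1}, b={self.param2}"
                )
        else:
            raise InvalidParameterError(f"unknown distribution kind {self.kind!r}")

    @property
    def expectation(self) -> float:
        if self.kind == "gaussian":
            return self.param1
        return 0.5 * (self.param1 + self.param2)

    @property
    def standard_uncertainty(self) -> float:
        if self.kind == "gaussian":
            return self.param2
        return (self.param2 - self.param1) / (2.0 * math.sqrt(3.0))

    def scaled(self, factor: float) -> "DistributionSpec":
        """Return the spec of the quantity multiplied by ``factor`` (> 0)."""
        if factor <= 0:
            raise InvalidParameterError("scale factor must be positive")
        return DistributionSpec(self.kind, self.param1 * factor, self.param2 * factor)


@dataclass(frozen=True)
class ReplicateSet:
    """Independent repeated observations of a single quantity."""

    observations: tuple[float, ...]
    run_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "observations", tuple(float(v) for v in self.observations))
        if len(self.observations) < 2:
            raise InsufficientReplicatesError(
                f"need at least 2 observations, got {len(self.observations)}"
            )
        if self.run_labels is not None:
            object.__setattr__(self, "run_labels", tuple(self.run_labels))
            if len(self.run_labels) != len(self.observations):
                raise InvalidParameterError("run_labels length must match observations")

    def __len__(self) -> int:
        return len(self.observations)


@dataclass(frozen=True)
class InputQuantity:
    """A named model symbol bound to an estimate, unit and PDF.

    ``distribution`` is ``None`` for quantities carried without uncertainty
    (for instance a relative molecular weight taken as exact).  A unit of
    ``"%"`` marks a quantity stated on the percent scale; :meth:`model_value`
    and :meth:`model_distribution` convert it to the fraction the
    measurement equation multiplies by.
    """

    symbol: str
    description: str
    value: float
    unit: str
    distribution: DistributionSpec | None

    def __post_init__(self) -> None:
        if self.distribution is not None:
            expect = self.distribution.expectation
            scale = max(abs(self.value), abs(expect), 1.0)
            if abs(self.value - expect) > 1e-3 * scale:
                raise InvalidParameterError(
                    f"{self.symbol}: stated value {self.value} disagrees with the "
                    f"distribution expectation {expect} beyond 1 part in 10^3"
                )

    @property
    def is_stochastic(self) -> bool:
        return self.distribution is not None

    @property
    def percent_scaled(self) -> bool:
        return self.unit.strip() == "%"

    def model_value(self) -> float:
        return self.value / 100.0 if self.percent_scaled else self.value

    def model_distribution(self) -> DistributionSpec | None:
        if self.distribution is None:
            return None
        if self.percent_scaled:
            return self.distribution.scaled(0.01)
        return self.distribution


class QuantitySet:
    """An ordered, symbol-keyed collection of input quantities."""

    def __init__(self, quantities: Sequence[InputQuantity]):
        self._quantities: list[InputQuantity] = list(quantities)
        symbols = [q.symbol for q in self._quantities]
        if len(set(symbols)) != len(symbols):
            dupes = sorted({s for s in symbols if symbols.count(s) > 1})
            raise InvalidParameterError(f"duplicate symbols in quantity set: {dupes}")
        self._by_symbol = {q.symbol: q for q in self._quantities}

    def __iter__(self) -> Iterator[InputQuantity]:
        return iter(self._quantities)

    def __len__(self) -> int:
        return len(self._quantities)

    def __getitem__(self, symbol: str) -> InputQuantity:
        return self._by_symbol[symbol]

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._by_symbol

    @property
    def symbols(self) -> list[str]:
        return [q.symbol for q in self._quantities]

    def stochastic(self) -> list[InputQuantity]:
        return [q for q in self._quantities if q.is_stochastic]

    def model_values(self) -> dict[str, float]:
        """Best estimates keyed by symbol, on the scale the model uses."""
        return {q.symbol: q.model_value() for q in self._quantities}

    def replace(self, quantity: InputQuantity) -> "QuantitySet":
        """A new set with the quantity of the same symbol swapped out."""
        return QuantitySet(
            [quantity if q.symbol == quantity.symbol else q for q in self._quantities]
        )

    def sample_all(
        self, n: int, root_seed: int, block_index: int = 0
    ) -> dict[str, np.ndarray | float]:
        """Draw ``n`` joint samples; constants pass through as scalars."""
        out: dict[str, np.ndarray | float] = {}
        for q in self._quantities:
            dist = q.model_distribution()
            if dist is None:
                out[q.symbol] = q.model_value()
            else:
                rng = quantity_rng(root_seed, q.symbol, block_index)
                out[q.symbol] = sample(dist, n, rng)
        return out


# ---------------------------------------------------------------------------
# Constructors


def gaussian_from_estimate(x: float, u: float) -> DistributionSpec:
    """N(x, u²) from a best estimate and its standard uncertainty."""
    if not u > 0:
        raise InvalidParameterError(f"standard uncertainty must be > 0, got {u}")
    return DistributionSpec("gaussian", float(x), float(u))


def rectangular_from_limits(a: float, b: float) -> DistributionSpec:
    """R(a, b): expectation (a+b)/2, standard uncertainty (b−a)/(2√3)."""
    if not a < b:
        raise InvalidParameterError(f"rectangular limits require a < b, got {a}, {b}")
    return DistributionSpec("rectangular", float(a), float(b))


def gaussian_from_expanded(x: float, U: float, k: float) -> DistributionSpec:
    """N(x, (U/k)²) from a certificate's expanded uncertainty and coverage factor."""
    if not U > 0:
        raise InvalidParameterError(f"expanded uncertainty must be > 0, got {U}")
    if not k > 0:
        raise InvalidParameterError(f"coverage factor must be > 0, got {k}")
    return DistributionSpec("gaussian", float(x), float(U) / float(k))


def type_a_from_replicates(reps: ReplicateSet) -> DistributionSpec:
    """Type-A evaluation: mean of the replicates, standard deviation of the mean.

    The standard uncertainty is the experimental standard deviation of the
    observations divided by √n — the dispersion of the mean, not of a single
    observation.
    """
    obs = np.asarray(reps.observations, dtype=float)
    n = obs.size
    mean = float(obs.mean())
    sd = float(obs.std(ddof=1))
    if sd == 0.0:
        raise DegenerateDispersionError(
            "replicates have zero spread; a positive standard uncertainty "
            "cannot be evaluated from them"
        )
    return DistributionSpec("gaussian", mean, sd / math.sqrt(n))


# ---------------------------------------------------------------------------
# Sampling


def quantity_rng(root_seed: int, symbol: str, block_index: int = 0) -> np.random.Generator:
    """Deterministic per-(quantity, block) random stream.

    The stream is keyed on a CRC of the symbol so that the draws of one
    quantity are independent of which other quantities exist in the set.
    """
    key = zlib.crc32(symbol.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence((int(root_seed), key, int(block_index))))


def sample(spec: DistributionSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """n independent draws from the spec using the supplied generator."""
    if n < 1:
        raise InvalidParameterError(f"sample size must be >= 1, got {n}")
    if spec.kind == "gaussian":
        return rng.normal(spec.param1, spec.param2, size=n)
    return rng.uniform(spec.param1, spec.param2, size=n)


# ---------------------------------------------------------------------------
# Serialization

_KIND_ALIASES = {"gaussian": "gaussian", "normal": "gaussian", "rectangular": "rectangular",
                 "uniform": "rectangular"}


def _spec_to_json(spec: DistributionSpec | None) -> dict | None:
    if spec is None:
        return None
    return {"type": spec.kind, "parameters": [spec.param1, spec.param2]}


def _spec_from_json(obj: dict | None) -> DistributionSpec | None:
    if obj is None:
        return None
    kind = _KIND_ALIASES.get(str(obj["type"]).lower())
    if kind is None:
        raise InvalidParameterError(f"unknown distribution type {obj['type']!r}")
    p1, p2 = (float(v) for v in obj["parameters"])
    return DistributionSpec(kind, p1, p2)


def load_quantities(path: str | Path) -> QuantitySet:
    """Load a quantity set from a JSON file.

    Format: a list of objects ``{symbol, description, value, unit,
    distribution: {type, parameters} | null}``.
    """
    with open(path) as fh:
        data = json.load(fh)
    return quantities_from_records(data)


def quantities_from_records(records: Sequence[Mapping]) -> QuantitySet:
    quantities = []
    for rec in records:
        quantities.append(
            InputQuantity(
                symbol=str(rec["symbol"]),
                description=str(rec.get("description", "")),
                value=float(rec["value"]),
                unit=str(rec.get("unit", "")),
                distribution=_spec_from_json(rec.get("distribution")),
            )
        )
    return QuantitySet(quantities)


def save_quantities(qset: QuantitySet, path: str | Path) -> None:
    """Write a quantity set back to JSON; inverse of :func:`load_quantities`."""
    records = [
        {
            "symbol": q.symbol,
            "description": q.description,
            "value": q.value,
            "unit": q.unit,
            "distribution": _spec_to_json(q.distribution),
        }
        for q in qset
    ]
    with open(path, "w") as fh:
        json.dump(records, fh, indent=1)
        fh.write("\n")
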