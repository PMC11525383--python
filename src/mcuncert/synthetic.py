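"""Synthetic raw measurement data with the structure the analysis assumes.

The uncertainty budget rests on three evaluation routes: type-A peak
isotope ratios (two runs of five replicate injections per blend), type-B
balance weighings (calibration-derived standard uncertainty), and type-B
certificate data (rectangular density limits, purity with an expanded
uncertainty and coverage factor).  This module generates raw inputs for
all three routes from known ground truth so the whole evaluation chain —
replicate statistics through adaptive propagation — can be tested for
parameter recovery without any instrument data.  It also ships the
published input-quantity budget as a loadable fixture.

The defaults of :class:`SyntheticDesign` reproduce the study conditions:
the three blend ratios with their reported standard uncertainties of the
mean, a 2 × 5 replicate design, the two balance uncertainty tiers
(0.01 mg for blend/sample weighings, 0.005 mg for solution totals),
density limits 1.022–1.026 g/mL, and a certificate purity of
94.9 % ± 1.9 % (k = 2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import idms
from .distributions import (
    DistributionSpec,
    InputQuantity,
    InvalidParameterError,
    QuantitySet,
    ReplicateSet,
    gaussian_from_estimate,
    gaussian_from_expanded,
    load_quantities,
    quantity_rng,
    rectangular_from_limits,
    type_a_from_replicates,
)

__all__ = [
    "SyntheticDesign",
    "generate_ratio_replicates",
    "generate_weighing_records",
    "table1_fixture",
    "quantity_set_from_raw",
    "true_concentration",
    "write_raw_csv",
]

RATIO_SYMBOLS = ("R_L", "R_H", "R_S")

#: Balance tier (mg) per weighed symbol: blend/sample weighings vs totals.
BLEND_BALANCE_U = 0.01
TOTAL_BALANCE_U = 0.005
WEIGHED_SYMBOLS = {
    "S_MH": BLEND_BALANCE_U, "S_ML": BLEND_BALANCE_U,
    "I_MH": BLEND_BALANCE_U, "I_ML": BLEND_BALANCE_U,
    "I_MS": BLEND_BALANCE_U, "W_S": BLEND_BALANCE_U,
    "Q_S1": BLEND_BALANCE_U, "Q_S2": BLEND_BALANCE_U,
    "Q_S3": BLEND_BALANCE_U, "Q_S4": BLEND_BALANCE_U,
    "Q_ST1": TOTAL_BALANCE_U, "Q_ST2": TOTAL_BALANCE_U,
    "Q_ST3": TOTAL_BALANCE_U, "Q_ST4": TOTAL_BALANCE_U,
}


@dataclass(frozen=True)
class SyntheticDesign:
    """Ground truth and acquisition design for synthetic raw data.

    ``ratio_mean_u`` states the target standard uncertainty *of the mean*
    for each ratio; the per-observation SD is back-calculated as
    u · √(runs·reps_per_run), since only the means' uncertainties are
    reported for real acquisitions.
    """

    true_ratios: Mapping[str, float] = field(
        default_factory=lambda: {"R_L": 0.94467, "R_H": 1.1419, "R_S": 1.00815}
    )
    ratio_mean_u: Mapping[str, float] = field(
        default_factory=lambda: {"R_L": 0.00911, "R_H": 0.01759, "R_S": 0.01185}
    )
    runs: int = 2
    reps_per_run: int = 5
    balance_u: Mapping[str, float] = field(default_factory=lambda: dict(WEIGHED_SYMBOLS))
    density_limits: tuple[float, float] = (1.022, 1.026)
    purity_percent: tuple[float, float, float] = (94.9, 1.9, 2.0)  # value, U, k
    seed: int = 0

    def __post_init__(self) -> None:
        if self.runs * self.reps_per_run < 2:
            raise InvalidParameterError("design needs at least 2 replicate observations")
        for sym, u in self.ratio_mean_u.items():
            if not u > 0:
                raise InvalidParameterError(f"ratio uncertainty for {sym} must be > 0")
        for sym, u in self.balance_u.items():
            if not u > 0:
                raise InvalidParameterError(f"balance uncertainty for {sym} must be > 0")

    @property
    def n_obs(self) -> int:
        return self.runs * self.reps_per_run

    def observation_sd(self, symbol: str) -> float:
        return self.ratio_mean_u[symbol] * math.sqrt(self.n_obs)


def generate_ratio_replicates(design: SyntheticDesign) -> dict[str, ReplicateSet]:
    """Gaussian replicate ratio observations for each blend.

    Draws runs × reps observations per ratio around its true mean, with a
    per-observation SD chosen so the SD of the mean matches the design's
    target standard uncertainty.
    """
    out: dict[str, ReplicateSet] = {}
    labels = tuple(
        f"run{r + 1}" for r in range(design.runs) for _ in range(design.reps_per_run)
    )
    for sym in RATIO_SYMBOLS:
        rng = quantity_rng(design.seed, f"raw/{sym}")
        obs = rng.normal(design.true_ratios[sym], design.observation_sd(sym), design.n_obs)
        out[sym] = ReplicateSet(observations=tuple(obs), run_labels=labels)
    return out


def generate_weighing_records(
    design: SyntheticDesign, true_masses: Mapping[str, float]
) -> dict[str, tuple[float, DistributionSpec]]:
    """Balance readings for the given true masses (mg).

    Each reading is the true mass perturbed by N(0, u²) with u the
    calibration-derived balance uncertainty for that weighing, and is
    paired with its assigned PDF N(reading, u²).
    """
    out: dict[str, tuple[float, DistributionSpec]] = {}
    for sym, mass in true_masses.items():
        if not mass > 0:
            raise InvalidParameterError(f"true mass for {sym} must be > 0, got {mass}")
        u = design.balance_u[sym]
        rng = quantity_rng(design.seed, f"raw/{sym}")
        reading = float(rng.normal(mass, u))
        out[sym] = (reading, gaussian_from_estimate(reading, u))
    return out


def table1_fixture() -> QuantitySet:
    """The published 20-symbol input-quantity budget (19 stochastic + M_W).

    The internal-standard mass in blend 1 is fixed at 88.98 mg; see the
    methods note for the fixture's documented discrepancy resolution.
    """
    with resources.as_file(resources.files("mcuncert.data") / "table1.json") as path:
        return load_quantities(path)


def quantity_set_from_raw(
    design: SyntheticDesign,
    true_masses: Mapping[str, float] | None = None,
) -> QuantitySet:
    """Build a complete quantity set from synthetic raw data alone.

    Ratios go through the type-A replicate evaluation, masses through the
    balance type-B evaluation, and density/purity through the certificate
    type-B constructors — the same chain a real acquisition would follow.
    """
    if true_masses is None:
        true_masses = {
            q.symbol: q.value for q in table1_fixture() if q.symbol in WEIGHED_SYMBOLS
        }
    fixture_desc = {q.symbol: q.description for q in table1_fixture()}

    quantities: list[InputQuantity] = []
    weighings = generate_weighing_records(design, true_masses)
    ratios = generate_ratio_replicates(design)
    for sym in idms.MODEL_SYMBOLS:
        desc = fixture_desc.get(sym, sym)
        if sym in weighings:
            reading, spec = weighings[sym]
            quantities.append(InputQuantity(sym, desc, reading, "mg", spec))
        elif sym in ratios:
            spec = type_a_from_replicates(ratios[sym])
            quantities.append(InputQuantity(sym, desc, spec.expectation, "", spec))
        elif sym == "D_S":
            spec = rectangular_from_limits(*design.density_limits)
            quantities.append(InputQuantity(sym, desc, spec.expectation, "g/mL", spec))
        elif sym == "P":
            value, U, k = design.purity_percent
            spec = gaussian_from_expanded(value, U, k)
            quantities.append(InputQuantity(sym, desc, value, "%", spec))
        elif sym == "M_W":
            quantities.append(InputQuantity(sym, desc, 288.4, "g/mol", None))
    return QuantitySet(quantities)


def true_concentration(design: SyntheticDesign, true_masses: Mapping[str, float] | None = None) -> float:
    """Model value at the design's generating parameters (nmol/L)."""
    if true_masses is None:
        true_masses = {
            q.symbol: q.value for q in table1_fixture() if q.symbol in WEIGHED_SYMBOLS
        }
    values: dict[str, float] = dict(true_masses)
    values.update(design.true_ratios)
    values["D_S"] = 0.5 * (design.density_limits[0] + design.density_limits[1])
    values["P"] = design.purity_percent[0] / 100.0
    values["M_W"] = 288.4
    return float(idms.evaluate_idms(values, warn_bracket=False))


def write_raw_csv(design: SyntheticDesign, out_dir: str | Path) -> list[Path]:
    """Export synthetic raw data as CSV: one file per ratio plus weighings."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    ratios = generate_ratio_replicates(design)
    for sym, reps in ratios.items():
        df = pd.DataFrame(
            {
                "run": reps.run_labels,
                "replicate": list(range(1, len(reps) + 1)),
                "value": reps.observations,
            }
        )
        path = out_dir / f"ratios_{sym}.csv"
        df.to_csv(path, index=False)
        written.append(path)
    true_masses = {
        q.symbol: q.value for q in table1_fixture() if q.symbol in WEIGHED_SYMBOLS
    }
    weighings = generate_weighing_records(design, true_masses)
    df = pd.DataFrame(
        [(sym, reading, spec.standard_uncertainty) for sym, (reading, spec) in weighings.items()],
        columns=["symbol", "reading_mg", "u_mg"],
    )
    path = out_dir / "weighings.csv"
    df.to_csv(path, index=False)
    written.append(path)
    return written
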