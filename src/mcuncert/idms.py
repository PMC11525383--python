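"""Triple isotope-dilution bracketing measurement equation.

The measurand is the total analyte concentration in serum, C_S (nmol/L),
obtained by exact-matching double IDMS with bracketing calibration: the
sample blend's analyte/internal-standard peak ratio R_S is interpolated
between two standard blends with ratios R_L < R_H prepared around it,

    C_S = { [(S_MH·S_C/I_MH − S_ML·S_C/I_ML)/(R_H − R_L)]·(R_S − R_L)
            + S_ML·S_C/I_ML } · (I_MS/W_S) · D_S · (1000/M_W) · P

where S_C is the mass fraction of analyte in the standard working solution,
prepared by a four-step gravimetric dilution of the certified reference
material:

    S_C = (Q_S1/Q_ST1)·(Q_S2/Q_ST2)·(Q_S3/Q_ST3)·(Q_S4/Q_ST4).

Unit bookkeeping: with all masses in mg (they cancel pairwise), S_C in g/g,
D_S in g/mL, P a fraction and M_W in g/mol, the bracket expression carries
grams of analyte per gram of sample, so multiplying by D_S·1000/M_W gives
mol/L; the 1e9 factor applied here reports nmol/L.

Every operation is vectorized: passing equal-length arrays of Monte Carlo
draws for the stochastic symbols (scalars for constants) returns the array
of model values.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Union

import numpy as np

__all__ = [
    "MODEL_SYMBOLS",
    "DILUTION_SYMBOLS",
    "InvalidDilutionError",
    "DegenerateBracketError",
    "BracketWarning",
    "working_solution_concentration",
    "evaluate_idms",
]

ArrayLike = Union[float, np.ndarray]

#: Every symbol the measurement equation reads, in budget order.
MODEL_SYMBOLS = (
    "S_MH", "S_ML",
    "Q_S1", "Q_ST1", "Q_S2", "Q_ST2", "Q_S3", "Q_ST3", "Q_S4", "Q_ST4",
    "I_MH", "I_ML", "I_MS", "W_S",
    "R_H", "R_L", "R_S",
    "D_S", "P", "M_W",
)

#: The eight masses of the gravimetric dilution chain.
DILUTION_SYMBOLS = ("Q_S1", "Q_ST1", "Q_S2", "Q_ST2", "Q_S3", "Q_ST3", "Q_S4", "Q_ST4")

NMOL_PER_MOL = 1.0e9


class InvalidDilutionError(ValueError):
    """A dilution-chain mass is non-positive or a transfer exceeds its total."""


class DegenerateBracketError(ValueError):
    """The two calibrant ratios coincide, so interpolation is undefined."""


class BracketWarning(UserWarning):
    """The sample ratio falls outside the calibrant bracket [R_L, R_H]."""


def working_solution_concentration(
    Q_S1: ArrayLike, Q_ST1: ArrayLike,
    Q_S2: ArrayLike, Q_ST2: ArrayLike,
    Q_S3: ArrayLike, Q_ST3: ArrayLike,
    Q_S4: ArrayLike, Q_ST4: ArrayLike,
    *, validate: bool = True,
) -> ArrayLike:
    """Mass fraction of analyte in the working solution (g/g).

    Product of the four transfer/total mass ratios of the gravimetric
    serial dilution.  Validation applies to scalar (best-estimate) inputs;
    Monte Carlo draw vectors are taken as given.
    """
    pairs = ((Q_S1, Q_ST1), (Q_S2, Q_ST2), (Q_S3, Q_ST3), (Q_S4, Q_ST4))
    if validate:
        for i, (qs, qst) in enumerate(pairs, start=1):
            if np.ndim(qs) == 0 and np.ndim(qst) == 0:
                if qs <= 0 or qst <= 0:
                    raise InvalidDilutionError(f"dilution step {i}: masses must be positive")
                if qs > qst:
                    raise InvalidDilutionError(
                        f"dilution step {i}: transferred mass {qs} exceeds total {qst}"
                    )
    out = 1.0
    for qs, qst in pairs:
        out = out * (np.asarray(qs, dtype=float) / np.asarray(qst, dtype=float))
    return out if np.ndim(out) else float(out)


def evaluate_idms(x: Mapping[str, ArrayLike], *, warn_bracket: bool = True) -> ArrayLike:
    """Evaluate the bracketing IDMS equation; returns C_S in nmol/L.

    Parameters
    ----------
    x
        Mapping from model symbol to value.  Scalars give the deterministic
        model value; equal-length arrays give the vector of Monte Carlo
        model values.  ``S_C`` may be supplied directly, otherwise it is
        computed from the eight dilution-chain masses.
    warn_bracket
        Emit :class:`BracketWarning` when a scalar R_S lies outside
        [R_L, R_H].  Monte Carlo draws legitimately cross the bounds, so
        only scalar inputs are checked.
    """
    missing = [s for s in MODEL_SYMBOLS if s not in x and s not in DILUTION_SYMBOLS]
    if "S_C" not in x:
        missing += [s for s in DILUTION_SYMBOLS if s not in x]
    if missing:
        raise KeyError(f"unbound model symbols: {missing}")

    R_H = np.asarray(x["R_H"], dtype=float)
    R_L = np.asarray(x["R_L"], dtype=float)
    R_S = np.asarray(x["R_S"], dtype=float)
    if np.ndim(R_H) == 0 and np.ndim(R_L) == 0 and R_H == R_L:
        raise DegenerateBracketError("R_H equals R_L; bracketing interpolation is undefined")
    if warn_bracket and all(np.ndim(r) == 0 for r in (R_L, R_S, R_H)):
        if not (R_L <= R_S <= R_H):
            warnings.warn(
                f"sample ratio R_S={float(R_S)} outside calibrant bracket "
                f"[{float(R_L)}, {float(R_H)}]",
                BracketWarning,
                stacklevel=2,
            )

    S_C = x.get("S_C")
    if S_C is None:
        S_C = working_solution_concentration(*(x[s] for s in DILUTION_SYMBOLS), validate=False)
    S_C = np.asarray(S_C, dtype=float)

    A_H = np.asarray(x["S_MH"], dtype=float) * S_C / np.asarray(x["I_MH"], dtype=float)
    A_L = np.asarray(x["S_ML"], dtype=float) * S_C / np.asarray(x["I_ML"], dtype=float)
    bracket = (A_H - A_L) / (R_H - R_L) * (R_S - R_L) + A_L

    c_s = (
        bracket
        * np.asarray(x["I_MS"], dtype=float) / np.asarray(x["W_S"], dtype=float)
        * np.asarray(x["D_S"], dtype=float)
        * 1000.0 / np.asarray(x["M_W"], dtype=float)
        * np.asarray(x["P"], dtype=float)
        * NMOL_PER_MOL
    )
    return c_s if np.ndim(c_s) else float(c_s)
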