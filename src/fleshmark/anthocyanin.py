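"""Anthocyanin quantification from 530/620/650 nm absorbances.

Relative anthocyanin content subtracts turbidity/chlorophyll background:

    RAC = (A530 - A620) - 0.1 * (A650 - A620)

Total anthocyanin content is reported on a cyanidin-3-glucoside basis
(MW 449.2 g/mol) with the source formula reproduced verbatim:

    TAC = RAC * MW * DF * 1000 * path_length

Note that this expression *multiplies* by the optical path length and contains
no molar extinction coefficient, so its absolute scale is unconventional; the
standard spectrophotometric convention (dividing by epsilon * path) is available
via :func:`compute_tac_standard` for users who supply an extinction coefficient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AbsorbanceTriple:
    a530: float
    a620: float
    a650: float

    def __post_init__(self) -> None:
        for name in ("a530", "a620", "a650"):
            v = getattr(self, name)
            if not (v == v and abs(v) != float("inf")):
                raise ValueError(f"{name} must be finite")
            if v < 0:
                raise ValueError(f"{name} must be nonnegative, got {v}")


@dataclass(frozen=True)
class QuantParams:
    mw: float = 449.2  # g/mol, cyanidin-3-glucoside
    df: float = 1.0  # dilution factor
    path_length: float = 1.0  # cm

    def __post_init__(self) -> None:
        if self.mw <= 0 or self.df < 1 or self.path_length <= 0:
            raise ValueError("MW and path length must be positive and DF >= 1")


def compute_rac(t: AbsorbanceTriple) -> float:
    """Relative anthocyanin content (absorbance units); may be negative for
    samples whose background exceeds the 530 nm signal (reported with a warning)."""
    rac = (t.a530 - t.a620) - 0.1 * (t.a650 - t.a620)
    if rac < 0:
        logger.warning("negative relative anthocyanin content (%.4f): background "
                       "absorbance exceeds the 530 nm signal", rac)
    return rac


def compute_tac(rac: float, p: QuantParams | None = None) -> float:
    """Total anthocyanin content, formula as printed (multiplicative path length)."""
    p = p or QuantParams()
    return rac * p.mw * p.df * 1000.0 * p.path_length


def compute_tac_standard(rac: float, epsilon: float, p: QuantParams | None = None) -> float:
    """Conventional alternative: TAC = RAC * MW * DF * 1000 / (epsilon * path)."""
    if epsilon <= 0:
        raise ValueError("extinction coefficient must be positive")
    p = p or QuantParams()
    return rac * p.mw * p.df * 1000.0 / (epsilon * p.path_length)


def quantify_table(df: pd.DataFrame, params: QuantParams | None = None) -> pd.DataFrame:
    """Vectorized RAC/TAC over a (sample, A530, A620, A650[, DF]) table."""
    required = {"sample", "A530", "A620", "A650"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    base = params or QuantParams()
    out = []
    for row in df.itertuples(index=False):
        t = AbsorbanceTriple(float(row.A530), float(row.A620), float(row.A650))
        p = QuantParams(base.mw, float(getattr(row, "DF", base.df)), base.path_length)
        rac = compute_rac(t)
        out.append({"sample": row.sample, "RAC": rac, "TAC": compute_tac(rac, p)})
    return pd.DataFrame(out, columns=["sample", "RAC", "TAC"])
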