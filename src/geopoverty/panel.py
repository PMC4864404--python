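"""Cross-country poverty-spell panel construction.

For each country the longest available pair of comparable household
surveys (same welfare indicator, both inside the analysis window) forms
a *spell*; the annualized change in the log headcount poverty rate,
gamma(H) = 100 * (ln H1 - ln H0) / years, and the matching income-growth
rate gamma(mu) are the panel's growth variables. Year-2000 spatial shares
(d1, d2, i1, i2) and country controls are attached for estimation.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SurveyObservation",
    "PovertySpell",
    "select_spell",
    "annualized_log_growth",
    "build_panel",
    "describe_panel",
]

SHARE_COLUMNS = ("d1", "d2", "i1", "i2")


@dataclass
class SurveyObservation:
    """One household survey: headcount poverty rate H (%) and mean income mu ($/month)."""

    country: str
    year: int
    welfare_type: str  # "consumption" or "income"
    H: float
    mu: float
    gini: float = np.nan
    z: float = 2.00  # poverty line, $/person/day

    def __post_init__(self) -> None:
        if not 0.0 <= self.H <= 100.0:
            raise ValueError(f"headcount rate must be in [0, 100], got {self.H}")
        if self.mu <= 0:
            raise ValueError("mean income must be positive")
        if self.z <= 0:
            raise ValueError("poverty line must be positive")
        if self.welfare_type not in ("consumption", "income"):
            raise ValueError(f"unknown welfare indicator {self.welfare_type!r}")


@dataclass
class PovertySpell:
    """A pair of comparable surveys bounding one country's analysis spell."""

    country: str
    t0: int
    t1: int
    welfare_type: str
    H0: float
    H1: float
    mu0: float
    mu1: float

    @property
    def spell_years(self) -> int:
        return self.t1 - self.t0

    def __post_init__(self) -> None:
        if self.t1 <= self.t0:
            raise ValueError("spell must end after it starts")
        if not 2 <= self.spell_years <= 11:
            warnings.warn(
                f"{self.country}: spell length {self.spell_years} outside the usual 2-11 years",
                stacklevel=2,
            )


class SpellSelectionError(ValueError):
    """No compatible survey pair exists for a country."""


def select_spell(
    surveys: list[SurveyObservation], window: tuple[int, int] = (2000, 2012)
) -> PovertySpell:
    """Pick the longest same-indicator survey pair inside the window.

    Ties on spell length are broken by the earlier initial year, then by
    preferring consumption over income surveys.
    """
    lo, hi = window
    cand = [s for s in surveys if lo <= s.year <= hi]
    pairs = [
        (a, b)
        for a in cand
        for b in cand
        if b.year > a.year and a.welfare_type == b.welfare_type
    ]
    if not pairs:
        country = surveys[0].country if surveys else "?"
        logger.info("country %s excluded: no compatible survey pair in %s", country, window)
        raise SpellSelectionError(
            f"fewer than two comparable surveys in window {window}"
        )
    pairs.sort(
        key=lambda p: (
            -(p[1].year - p[0].year),
            p[0].year,
            0 if p[0].welfare_type == "consumption" else 1,
        )
    )
    a, b = pairs[0]
    return PovertySpell(a.country, a.year, b.year, a.welfare_type, a.H, b.H, a.mu, b.mu)


def annualized_log_growth(x0: float, x1: float, years: float) -> float:
    """100 * (ln x1 - ln x0) / years, in percent per year.

    Nonpositive endpoints (e.g. a zero poverty headcount) cannot be
    log-differenced and yield NaN, flagging the country for exclusion
    from that variable.
    """
    if years <= 0:
        raise ValueError("years must be positive")
    if x0 <= 0 or x1 <= 0:
        return float("nan")
    return 100.0 * (math.log(x1) - math.log(x0)) / years


def build_panel(
    spells: list[PovertySpell],
    shares: pd.DataFrame,
    controls: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assemble one panel row per country: growth rates, shares, controls.

    ``shares`` must carry a ``country`` column and the four share columns;
    countries without shares are excluded (logged). Missing controls stay
    NaN and are handled by listwise deletion at fit time.
    """
    share_idx = shares.set_index("country")
    rows = []
    for sp in spells:
        if sp.country not in share_idx.index:
            logger.info("country %s excluded: no spatial shares available", sp.country)
            continue
        rec = {
            "country": sp.country,
            "t0": sp.t0,
            "t1": sp.t1,
            "welfare_type": sp.welfare_type,
            "H0": sp.H0,
            "H1": sp.H1,
            "mu0": sp.mu0,
            "mu1": sp.mu1,
            "gamma_H": annualized_log_growth(sp.H0, sp.H1, sp.spell_years),
            "gamma_mu": annualized_log_growth(sp.mu0, sp.mu1, sp.spell_years),
        }
        for col in SHARE_COLUMNS:
            rec[col] = float(share_idx.loc[sp.country, col]) if col in share_idx else np.nan
        rows.append(rec)
    panel = pd.DataFrame(rows)
    if controls is not None and len(panel):
        panel = panel.merge(controls, on="country", how="left")
    return panel


KEY_VARIABLES = ("H0", "gamma_H", "gamma_mu", "d1", "d2", "i1", "i2")


def describe_panel(panel: pd.DataFrame, variables=KEY_VARIABLES) -> pd.DataFrame:
    """Mean, median and sample SD (n-1 denominator) of the key panel variables."""
    if len(panel) < 2:
        raise ValueError("need at least two records to describe")
    rows = []
    for v in variables:
        if v not in panel.columns:
            continue
        x = panel[v].dropna().to_numpy(dtype=float)
        rows.append(
            {
                "variable": v,
                "n": int(x.size),
                "mean": float(x.mean()) if x.size else np.nan,
                "median": float(np.median(x)) if x.size else np.nan,
                "sd": float(x.std(ddof=1)) if x.size > 1 else 0.0 if x.size == 1 else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("variable")
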