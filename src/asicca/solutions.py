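"""Free-Ca2+ computation and recipe design for chelated recording solutions.

Recording solutions with free [Ca2+] below ~0.1 mM are buffered with EDTA,
EGTA or citrate.  At the working pH a chelator L is partly protonated, which
weakens Ca2+ binding; the standard treatment folds the proton equilibria
into an apparent association constant

    K_app(pH) = K_CaL / (1 + sum_i prod_{j<=i} K_Hj [H+]^i),

after which the 1:1 Ca:L equilibrium gives the free concentration from the
mass balances  Ca_tot = Ca_free (1 + K_app L_free)  and
L_tot = L_free (1 + K_app Ca_free)  (L_free lumps all Ca2+-free protonation
states).  ``free_ca`` solves this numerically; ``design_total_ca`` inverts
it in closed form to choose the total Ca2+ for a desired free concentration
(the workflow usually done with the MaxChelator web calculator).

Shipped constants (EDTA, EGTA, citrate) are 25 C / 0.1 M ionic-strength
class values; ionic-strength and temperature corrections are out of scope
and the recipe only carries tags for provenance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "ChelatorSpec",
    "SolutionRecipe",
    "load_chelator",
    "available_chelators",
    "apparent_kca",
    "free_ca",
    "design_total_ca",
]


@dataclass(frozen=True)
class ChelatorSpec:
    """Binding constants of one chelator (all log10, association form)."""

    name: str
    log_kh: tuple               # stepwise proton association, descending
    log_kca: float
    log_kmg: float | None = None

    def __post_init__(self):
        if not all(np.isfinite(self.log_kh)) or not np.isfinite(self.log_kca):
            raise ValueError("binding constants must be finite")
        if any(a < b for a, b in zip(self.log_kh, self.log_kh[1:])):
            raise ValueError("proton constants must be non-increasing "
                             "(K_H1 >= K_H2 >= ...)")


@dataclass(frozen=True)
class SolutionRecipe:
    """Composition of one recording solution (record-keeping container)."""

    ph: float
    ca_total_m: float
    chelator_total_m: float
    chelator: str = "EGTA"
    salts: dict = field(default_factory=dict)   # e.g. {"NaCl": 0.110}
    temperature: str = "25C"

    def __post_init__(self):
        if self.ca_total_m < 0 or self.chelator_total_m < 0:
            raise ValueError("totals must be >= 0")
        if not 3.0 <= self.ph <= 10.0:
            raise ValueError("pH must lie in [3, 10]")


def _constants_table() -> pd.DataFrame:
    with resources.files("asicca.data").joinpath(
            "chelator_constants.csv").open() as fh:
        return pd.read_csv(fh, comment="#")


def available_chelators() -> list:
    return _constants_table()["name"].tolist()


def load_chelator(name: str) -> ChelatorSpec:
    """Load a shipped chelator by name (EGTA, EDTA, citrate)."""
    table = _constants_table()
    row = table[table["name"].str.lower() == name.lower()]
    if row.empty:
        raise KeyError(f"unknown chelator {name!r}; "
                       f"available: {available_chelators()}")
    row = row.iloc[0]
    kh = tuple(float(row[c]) for c in ("log_kh1", "log_kh2", "log_kh3",
                                       "log_kh4") if pd.notna(row.get(c)))
    kmg = float(row["log_kmg"]) if pd.notna(row.get("log_kmg")) else None
    return ChelatorSpec(name=row["name"], log_kh=kh,
                        log_kca=float(row["log_kca"]), log_kmg=kmg)


def apparent_kca(chel: ChelatorSpec, ph: float) -> float:
    """Apparent Ca2+ association constant (1/M) of a chelator at a given pH.

    Decreases monotonically as the pH drops (protons outcompete Ca2+ for the
    ligand).  A pH outside [3, 10] triggers a validity warning: the shipped
    constants are not meant for extreme pH.
    """
    if not 3.0 <= ph <= 10.0:
        warnings.warn(f"pH {ph} outside the validity range [3, 10] of the "
                      "shipped constants", stacklevel=2)
    h = 10.0 ** (-ph)
    denom, cum = 1.0, 0.0
    for i, logk in enumerate(chel.log_kh, start=1):
        cum += logk
        denom += 10.0 ** cum * h ** i
    return 10.0 ** chel.log_kca / denom


def free_ca(recipe: SolutionRecipe, chel: ChelatorSpec | None = None) -> float:
    """Free [Ca2+] (M) of a chelated solution, from 1:1 binding mass balance.

    Solves ``Ca_tot = x + K_app x L_tot / (1 + K_app x)`` for the free
    concentration x by bracketed root finding; conserves both total Ca2+ and
    total chelator to better than 1e-10 relative.
    """
    if chel is None:
        chel = load_chelator(recipe.chelator)
    ca_tot, l_tot = recipe.ca_total_m, recipe.chelator_total_m
    if ca_tot == 0:
        return 0.0
    if l_tot == 0:
        return ca_tot
    k = apparent_kca(chel, recipe.ph)

    def balance(x):
        return x + k * x * l_tot / (1.0 + k * x) - ca_tot

    # balance is strictly increasing in x; root is bracketed by [0, Ca_tot]
    lo, hi = 0.0, ca_tot
    if balance(hi) < 0:
        raise ArithmeticError(
            f"no positive root: balance({hi})={balance(hi)} < 0 "
            f"(K_app={k:.3g}, Ca_tot={ca_tot}, L_tot={l_tot})")
    x = brentq(balance, lo, hi, xtol=1e-30, rtol=1e-15, maxiter=300)
    resid = abs(balance(x)) / ca_tot
    if resid > 1e-10:
        raise ArithmeticError(f"mass balance violated: relative residual {resid}")
    return float(x)


def design_total_ca(target_free_m: float, chelator_total_m: float, ph: float,
                    chel: ChelatorSpec) -> float:
    """Total Ca2+ (M) needed to reach a target free concentration.

    The total is an explicit function of the free concentration,
    ``Ca_tot = x (1 + K_app L_tot / (1 + K_app x))``, so the inverse of
    :func:`free_ca` is exact; the round-trip agrees to 1e-8 relative.
    """
    if target_free_m <= 0:
        raise ValueError("target free Ca2+ must be positive")
    if chelator_total_m < 0:
        raise ValueError("chelator total must be >= 0")
    if chelator_total_m == 0:
        return target_free_m
    k = apparent_kca(chel, ph)
    x = target_free_m
    return float(x * (1.0 + k * chelator_total_m / (1.0 + k * x)))
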