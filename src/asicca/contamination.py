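"""In-silico endogenous-current contamination of pH activation curves.

Xenopus oocytes carry an endogenous low-Ca2+-activated (connexin
hemichannel) current that is *inhibited* by acid (pH50 ~5.41), i.e. has the
opposite pH dependence of an ASIC.  A small endogenous admixture therefore
raises the alkaline foot of an apparent activation curve and distorts the
fitted parameters.  This module builds mixture curves

    total(pH) = (1 - f) * Hill_activation(pH) + f * Hill_acid_inhibition(pH),

normalized to the grid maximum, re-fits them with the plain Hill activation
equation, and reports the apparent pH50 shift and Hill coefficient, plus the
ASIC amplitude at which a given endogenous amplitude reaches a contamination
fraction (93 nA at 10% -> 0.93 uA).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .doseresponse import fit_hill, hill_activation

__all__ = [
    "ContaminationScenario",
    "mixed_curve",
    "contamination_effect",
    "contamination_table",
    "amplitude_threshold",
]


def _default_grid():
    # spans the WT 80 nM activation curve; alkaline to acidic
    return tuple(np.round(np.arange(8.0, 6.6 - 1e-9, -0.2), 10))


@dataclass(frozen=True)
class ContaminationScenario:
    """One mixture scenario.  Defaults are the WT 80 nM parameters
    (pH50 7.48, nH 2.08) and the endogenous acid-inhibition midpoint 5.41
    with an assumed Hill coefficient of 1."""

    f_endo: float = 0.10
    asic_ph50: float = 7.48
    asic_nh: float = 2.08
    endo_ph50: float = 5.41
    endo_nh: float = 1.0
    ph_grid: tuple = field(default_factory=_default_grid)

    def __post_init__(self):
        if not 0.0 <= self.f_endo <= 1.0:
            raise ValueError("f_endo must lie in [0, 1]")
        g = np.asarray(self.ph_grid, dtype=float)
        if len(g) < 4 or not (np.all(np.diff(g) > 0) or np.all(np.diff(g) < 0)):
            raise ValueError("pH grid must be strictly ordered, >= 4 points")


def mixed_curve(sc: ContaminationScenario):
    """(pH, total response) points of the contaminated activation curve,
    normalized to the maximum over the grid."""
    ph = np.asarray(sc.ph_grid, dtype=float)
    asic = hill_activation(ph, sc.asic_ph50, sc.asic_nh)
    endo = 1.0 - hill_activation(ph, sc.endo_ph50, sc.endo_nh)  # acid-inhibited
    total = (1.0 - sc.f_endo) * asic + sc.f_endo * endo
    return ph, total / total.max()


def contamination_effect(sc: ContaminationScenario) -> dict:
    """Apparent Hill parameters of the contaminated curve.

    Fits :func:`mixed_curve` output with the plain Hill activation equation
    (free amplitude, no baseline term) and reports the fitted pH50 minus the
    true ASIC pH50 (positive = alkaline shift) and the fitted nH.
    """
    if sc.f_endo >= 1.0:
        raise ValueError("a pure endogenous curve has no ASIC component to "
                         "characterize; f_endo must be < 1")
    ph, total = mixed_curve(sc)
    fit = fit_hill(ph, total, kind="activation")
    return {
        "f_endo": sc.f_endo,
        "apparent_ph50": fit.midpoint,
        "shift": fit.midpoint - sc.asic_ph50,
        "apparent_nh": fit.n_h,
    }


def contamination_table(fractions=(0.05, 0.10, 0.15, 0.20),
                        **scenario_kwargs) -> pd.DataFrame:
    """Apparent shift and nH for a series of endogenous fractions."""
    rows = [contamination_effect(
        ContaminationScenario(f_endo=f, **scenario_kwargs))
        for f in fractions]
    return pd.DataFrame(rows)


def amplitude_threshold(endo_amplitude_na: float, f_endo: float) -> float:
    """ASIC peak amplitude (uA) at which an endogenous current of the given
    amplitude makes up the fraction ``f_endo`` of the total maximal peak.

    E.g. a 93 nA endogenous current reaches 10% contamination for ASIC peaks
    of 0.93 uA; larger ASIC currents are contaminated less.
    """
    if not 0.0 < f_endo < 1.0:
        raise ValueError("f_endo must lie in (0, 1)")
    if endo_amplitude_na < 0:
        raise ValueError("amplitude must be >= 0")
    return endo_amplitude_na / f_endo / 1000.0
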