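"""Shift statistics for Ca2+/H+ competition and permutation inference.

The competition readout is the shift of the fitted midpoint between a low-
and a high-Ca2+ condition, Delta-pH50 = mean(pH50 at low Ca2+) - mean(pH50
at 2 mM), reported with the conservative combined uncertainty
s.d.(low) + s.d.(high) ("mean +/- sum of s.d.") because the two condition
groups come from different cells.

Whether a mutant's shift differs from the wild type's is tested with a
permutation null: construct labels are shuffled within each Ca2+-condition
stratum (cells are unpaired across conditions and the stratification keeps
the condition structure intact), the statistic being the difference of
shifts.  Small instances are enumerated exhaustively; otherwise Monte-Carlo
permutations (default 10 000) with the +1-corrected two-sided p-value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = [
    "DeltaShift",
    "PermutationResult",
    "delta_shift",
    "permutation_test",
    "significance_stars",
    "summarize_constructs",
]

_TIE_EPS = 1e-12


@dataclass
class DeltaShift:
    """A construct's midpoint shift between two Ca2+ conditions."""

    construct: str
    pair: tuple                # (low label, high label)
    delta: float               # mean(low) - mean(high)
    uncertainty: float         # s.d.(low) + s.d.(high)
    sd_low: float
    sd_high: float
    n_low: int
    n_high: int

    @classmethod
    def from_summary(cls, mean_low, sd_low, mean_high, sd_high,
                     construct="", pair=("80nM", "2mM"),
                     n_low=0, n_high=0) -> "DeltaShift":
        """Build a shift from printed group summaries (mean +/- s.d.)."""
        return cls(construct=construct, pair=pair,
                   delta=mean_low - mean_high,
                   uncertainty=sd_low + sd_high,
                   sd_low=sd_low, sd_high=sd_high,
                   n_low=n_low, n_high=n_high)


def delta_shift(midpoints_low, midpoints_high, construct="",
                pair=("80nM", "2mM")) -> DeltaShift:
    """Delta-pH50 (or Delta-pHD50) from per-cell fitted midpoints.

    Sample s.d. uses ddof=1; at least two cells per condition are required.
    """
    low = np.asarray(midpoints_low, dtype=float)
    high = np.asarray(midpoints_high, dtype=float)
    if len(low) < 2 or len(high) < 2:
        raise ValueError("need >= 2 cells per condition")
    sd_low, sd_high = float(low.std(ddof=1)), float(high.std(ddof=1))
    return DeltaShift(construct=construct, pair=tuple(pair),
                      delta=float(low.mean() - high.mean()),
                      uncertainty=sd_low + sd_high,
                      sd_low=sd_low, sd_high=sd_high,
                      n_low=len(low), n_high=len(high))


@dataclass
class PermutationResult:
    observed: float            # Delta(mutant) - Delta(WT)
    p_value: float
    n_perm: int
    seed: int | None
    exhaustive: bool


def _stat_from_wt_sums(sum_wt_low, sum_wt_high, tot_low, tot_high,
                       k_wt_low, k_mut_low, k_wt_high, k_mut_high):
    mean_wt_low = sum_wt_low / k_wt_low
    mean_wt_high = sum_wt_high / k_wt_high
    mean_mut_low = (tot_low - sum_wt_low) / k_mut_low
    mean_mut_high = (tot_high - sum_wt_high) / k_mut_high
    return (mean_mut_low - mean_mut_high) - (mean_wt_low - mean_wt_high)


def permutation_test(wt_low, wt_high, mut_low, mut_high,
                     n_perm: int = 10_000, seed=None) -> PermutationResult:
    """Permutation test of Delta(mutant) - Delta(WT).

    ``*_low`` / ``*_high`` are per-cell fitted midpoints at the low- and
    high-Ca2+ condition for each construct.  Construct labels are permuted
    within each condition stratum.  When the total number of distinct label
    assignments is at most ``n_perm`` the null is enumerated exhaustively
    (exact p = fraction of arrangements at least as extreme, the identity
    included); otherwise ``n_perm`` Monte-Carlo draws are taken and
    p = (#{|stat*| >= |obs|} + 1) / (n_perm + 1).  Two-sided throughout.
    """
    groups = [np.asarray(g, dtype=float)
              for g in (wt_low, wt_high, mut_low, mut_high)]
    if any(len(g) == 0 for g in groups):
        raise ValueError("every construct needs cells in both Ca2+ strata")
    wl, wh, ml, mh = groups
    low = np.concatenate([wl, ml])
    high = np.concatenate([wh, mh])
    kwl, kwh, kml, kmh = len(wl), len(wh), len(ml), len(mh)
    tot_low, tot_high = low.sum(), high.sum()
    obs = _stat_from_wt_sums(wl.sum(), wh.sum(), tot_low, tot_high,
                             kwl, kml, kwh, kmh)
    thresh = abs(obs) - _TIE_EPS

    n_arrangements = math.comb(len(low), kwl) * math.comb(len(high), kwh)
    if n_arrangements <= n_perm:
        count = 0
        low_sums = [low[list(c)].sum()
                    for c in combinations(range(len(low)), kwl)]
        high_sums = [high[list(c)].sum()
                     for c in combinations(range(len(high)), kwh)]
        low_sums = np.asarray(low_sums)
        high_sums = np.asarray(high_sums)
        stats = _stat_from_wt_sums(low_sums[:, None], high_sums[None, :],
                                   tot_low, tot_high, kwl, kml, kwh, kmh)
        count = int(np.count_nonzero(np.abs(stats) >= thresh))
        return PermutationResult(observed=float(obs),
                                 p_value=count / n_arrangements,
                                 n_perm=n_arrangements, seed=seed,
                                 exhaustive=True)

    rng = np.random.default_rng(seed)
    count = 0
    batch = 2048
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        ord_low = np.argsort(rng.random((b, len(low))), axis=1)[:, :kwl]
        ord_high = np.argsort(rng.random((b, len(high))), axis=1)[:, :kwh]
        s_low = low[ord_low].sum(axis=1)
        s_high = high[ord_high].sum(axis=1)
        stats = _stat_from_wt_sums(s_low, s_high, tot_low, tot_high,
                                   kwl, kml, kwh, kmh)
        count += int(np.count_nonzero(np.abs(stats) >= thresh))
        done += b
    return PermutationResult(observed=float(obs),
                             p_value=(count + 1) / (n_perm + 1),
                             n_perm=n_perm, seed=seed, exhaustive=False)


def significance_stars(p: float) -> str:
    """Figure-legend star convention: * <0.05, ** <0.01, *** <0.001, # <1e-4."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if p < 1e-4:
        return "#"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def summarize_constructs(shifts, permutations=None) -> pd.DataFrame:
    """Tidy results table of shifts and (optionally) permutation p-values.

    ``shifts`` maps construct name -> DeltaShift; ``permutations`` maps
    construct name -> PermutationResult (typically vs the WT reference).
    """
    pairs = {s.pair for s in shifts.values()}
    if len(pairs) > 1:
        raise ValueError(f"inconsistent condition pairs across constructs: {pairs}")
    rows = []
    for name, s in shifts.items():
        row = {"construct": name, "condition_low": s.pair[0],
               "condition_high": s.pair[1], "delta": s.delta,
               "uncertainty": s.uncertainty, "n_low": s.n_low,
               "n_high": s.n_high, "p_value": np.nan, "stars": ""}
        if permutations and name in permutations:
            p = permutations[name].p_value
            row["p_value"] = p
            row["stars"] = significance_stars(p)
        rows.append(row)
    return pd.DataFrame(rows)
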