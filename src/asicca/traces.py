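"""TEVC sweep containers, feature extraction, QC and current-ratio metrics.

A :class:`Trace` is one sweep of whole-cell current versus time, uniformly
sampled (default 20 ms interval), with t = 0 at the solution change; samples
at t < 0 are the pre-switch baseline.  Inward currents are negative.

The endogenous-current QC rule screens out cells whose slowly activating
low-Ca2+ current (connexin hemichannels in Xenopus oocytes) could contaminate
ASIC measurements: a cell passes only if, for every sweep at stimulation
pH >= 7.3, the slow-component amplitude is strictly below 5% of the cell's
maximal acid-induced peak.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ProtocolStep",
    "Trace",
    "TraceFeatures",
    "QCReport",
    "extract_features",
    "qc_endogenous",
    "current_ratio",
    "percent_inhibition",
]


@dataclass(frozen=True)
class ProtocolStep:
    """One stimulation epoch of the perfusion protocol.

    Solutions are described by their pH and free Ca2+ (M); the oocyte is held
    at ``holding_mv`` (default -60 mV) and exposed to the stimulation solution
    for ``duration_s`` seconds, once per ``interval_s``.
    """

    conditioning_ph: float = 7.4
    conditioning_ca_m: float = 2e-3
    stimulation_ph: float = 5.0
    stimulation_ca_m: float = 2e-3
    duration_s: float = 10.0
    interval_s: float = 60.0
    holding_mv: float = -60.0

    def __post_init__(self):
        if self.stimulation_ca_m <= 0 or self.conditioning_ca_m <= 0:
            raise ValueError("free Ca2+ must be positive")
        if self.duration_s <= 0:
            raise ValueError("stimulation duration must be positive")


@dataclass
class Trace:
    """One sweep: current (nA) vs time (s), with protocol metadata."""

    time_s: np.ndarray
    current_na: np.ndarray
    protocol: ProtocolStep
    cell_id: str = ""
    construct: str = ""

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.current_na = np.asarray(self.current_na, dtype=float)
        if self.time_s.shape != self.current_na.shape:
            raise ValueError("time and current must have the same length")
        dt = np.diff(self.time_s)
        if len(dt) and not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError("sampling must be uniform")

    @property
    def dt(self) -> float:
        return float(self.time_s[1] - self.time_s[0])

    def to_csv(self, path, meta_path=None):
        pd.DataFrame({"time_s": self.time_s, "current_nA": self.current_na}
                     ).to_csv(path, index=False)
        if meta_path is not None:
            meta = {"cell_id": self.cell_id, "construct": self.construct,
                    "protocol": vars(self.protocol) | {}}
            Path(meta_path).write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_csv(cls, path, meta_path=None):
        df = pd.read_csv(path)
        proto, cell_id, construct = ProtocolStep(), "", ""
        if meta_path is not None:
            meta = json.loads(Path(meta_path).read_text())
            proto = ProtocolStep(**meta.get("protocol", {}))
            cell_id = meta.get("cell_id", "")
            construct = meta.get("construct", "")
        return cls(df["time_s"].to_numpy(), df["current_nA"].to_numpy(),
                   proto, cell_id, construct)


@dataclass
class TraceFeatures:
    """Derived per-sweep metrics (all currents baseline-subtracted, signed)."""

    cell_id: str
    stimulation_ph: float
    stimulation_ca_m: float
    baseline_na: float
    peak_na: float
    time_to_peak_s: float
    current_at_3p5s_na: float
    sustained_na: float
    slow_component_na: float
    flags: list = field(default_factory=list)


@dataclass
class QCReport:
    cell_id: str
    passed: bool
    ratios: pd.DataFrame          # per high-pH sweep: stimulation_ph, ratio
    offending: list
    max_acid_peak_na: float


def extract_features(trace: Trace, peak_window_s=(0.0, 2.0),
                     slow_at_s=3.5) -> TraceFeatures:
    """Extract baseline, peak and slow-component metrics from one sweep.

    The baseline is the mean of all pre-switch (t < 0) samples; the peak is
    the baseline-subtracted extremum (largest magnitude, signed) within
    ``peak_window_s`` after the switch.  The slow-component amplitude is the
    baseline-subtracted current at ``slow_at_s`` (3.5 s by default, after the
    ASIC peak), the standard operational measure of the endogenous current.
    """
    t, i = trace.time_s, trace.current_na
    pre = t < 0
    post = t >= 0
    if pre.sum() < 10 or post.sum() < 10:
        raise ValueError("need >= 10 samples on each side of the switch")
    baseline = float(i[pre].mean())
    sub = i - baseline

    w0, w1 = peak_window_s
    win = (t >= w0) & (t <= w1)
    flags = []
    if not win.any():
        raise ValueError("peak window contains no samples")
    sub_w = sub[win]
    k = int(np.argmax(np.abs(sub_w)))
    peak = float(sub_w[k])
    ttp = float(t[win][k])
    if np.ptp(i) < 1e-12:
        peak, ttp = 0.0, 0.0
        flags.append("flat_trace")

    def at(ts):
        if ts > t[-1]:
            return float("nan")
        return float(sub[np.argmin(np.abs(t - ts))])

    i35 = at(slow_at_s)
    end = sub[post][-max(1, int(0.05 * post.sum())):]
    sustained = float(end.mean())
    # simple operational rule: the slow (endogenous) component is the current
    # remaining at 3.5 s, after the transient ASIC peak has decayed
    slow = 0.0 if np.isnan(i35) else i35

    return TraceFeatures(
        cell_id=trace.cell_id,
        stimulation_ph=trace.protocol.stimulation_ph,
        stimulation_ca_m=trace.protocol.stimulation_ca_m,
        baseline_na=baseline, peak_na=peak, time_to_peak_s=ttp,
        current_at_3p5s_na=i35, sustained_na=sustained,
        slow_component_na=slow, flags=flags,
    )


def qc_endogenous(features, ph_threshold=7.3, max_fraction=0.05) -> QCReport:
    """Apply the endogenous-current acceptance rule to one cell's sweeps.

    ``features`` is an iterable of :class:`TraceFeatures` from a single cell.
    The cell passes iff every sweep with stimulation pH >= ``ph_threshold``
    has ``|slow_component| < max_fraction * max acid peak`` (strict ``<``);
    vacuously true when no such sweep exists.  Sweeps below the pH threshold
    define the maximal acid-induced peak; at least one is required.
    """
    feats = list(features)
    if not feats:
        raise ValueError("no sweeps supplied")
    cell_ids = {f.cell_id for f in feats}
    if len(cell_ids) > 1:
        raise ValueError(f"sweeps from multiple cells: {sorted(cell_ids)}")
    acid = [f for f in feats if f.stimulation_ph < ph_threshold]
    if not acid:
        raise ValueError("no acid stimulation sweep to define the maximal peak")
    max_peak = max(abs(f.peak_na) for f in acid)
    if max_peak == 0:
        raise ValueError("maximal acid-induced peak is zero")
    rows, offending = [], []
    for idx, f in enumerate(feats):
        if f.stimulation_ph >= ph_threshold:
            ratio = abs(f.slow_component_na) / max_peak
            rows.append({"sweep": idx, "stimulation_ph": f.stimulation_ph,
                         "slow_over_max": ratio})
            if not ratio < max_fraction:
                offending.append(idx)
    ratios = pd.DataFrame(rows, columns=["sweep", "stimulation_ph",
                                         "slow_over_max"])
    return QCReport(cell_id=feats[0].cell_id, passed=not offending,
                    ratios=ratios, offending=offending,
                    max_acid_peak_na=max_peak)


def current_ratio(numerator: TraceFeatures, denominator: TraceFeatures) -> float:
    """Ratio of peak amplitudes (absolute values) from the same cell.

    E.g. I_pH7.4(80 nM Ca2+) / I_pH5(2 mM Ca2+), the low-Ca2+-induced current
    normalized to the acid-induced current of the same oocyte.
    """
    if numerator.cell_id != denominator.cell_id:
        raise ValueError("current ratios must be computed within one cell")
    if denominator.peak_na == 0:
        raise ZeroDivisionError("denominator peak is zero; ratio undefined")
    return abs(numerator.peak_na) / abs(denominator.peak_na)


def percent_inhibition(ratio: float) -> float:
    """Percent inhibition implied by a current ratio: ``100 * (1 - ratio)``."""
    if ratio < 0:
        raise ValueError("ratio must be non-negative")
    return 100.0 * (1.0 - ratio)
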