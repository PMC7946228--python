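"""Growth-kinetics calls from live-cell confluence time series.

Two concentrations summarize a compound's kinetic effect on one cell
line.  The growth-reducing concentration is the lowest dose whose
confluence gain over the 40-72 h window is significantly below the
vehicle's (least-square-means dose-vs-vehicle contrasts, one-sided for
decrease, Holm-adjusted).  The growth-arresting concentration is the
lowest dose whose median 96-120 h confluence gain is below 3
percentage points — a late window, chosen so arrest is a stable state
rather than a transient dip.  After drug withdrawal a condition is
called reversible when the cells regain at least the same 3-point gain
within 72 h.  The module also classifies externally supplied
apoptosis / cell-cycle summary fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


class GrowthError(ValueError):
    """Raised for series that cannot support the requested window or call."""


@dataclass
class ConfluenceSeries:
    """Percent confluence vs hours for one cell line x compound x dose x replicate."""

    cell_line: str
    compound: str
    concentration: float  # nM; 0 = vehicle
    replicate: int
    times: np.ndarray  # hours, strictly increasing
    confluence: np.ndarray  # percent, within [0, 100]
    withdrawal_at: float | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.confluence = np.asarray(self.confluence, dtype=float)
        if self.times.ndim != 1 or self.times.size != self.confluence.size:
            raise GrowthError("times and confluence must be 1-D and aligned")
        if np.any(np.diff(self.times) < 0):
            raise GrowthError("times must be non-decreasing")
        if np.any((self.confluence < 0) | (self.confluence > 100)):
            raise GrowthError("confluence must lie in [0, 100]")


@dataclass
class MechanismSummary:
    """Pre-summarized apoptosis / cell-cycle shifts vs matched control."""

    cell_line: str
    compound: str
    apoptotic_increase_pct: float
    phase_shifts: dict = field(default_factory=dict)  # {"G1": pp, "S": pp, "G2": pp}


@dataclass
class KineticCall:
    cell_line: str
    compound: str
    growth_reducing_conc: float | None
    growth_arresting_conc: float | None
    reversible: bool | None
    evidence: pd.DataFrame  # per-concentration window statistics


def window_delta(series: ConfluenceSeries, t0: float, t1: float) -> float:
    """Confluence at t1 minus confluence at t0, linearly interpolated.

    Duplicated sample rows are harmless; endpoints must fall inside the
    sampled span.
    """
    t = series.times
    if t0 < t[0] or t1 > t[-1]:
        raise GrowthError(
            f"window [{t0}, {t1}] h outside sampled span [{t[0]}, {t[-1]}] h")
    c0, c1 = np.interp([t0, t1], t, series.confluence)
    return float(c1 - c0)


def _group_deltas(series_set, window) -> pd.DataFrame:
    rows = [(s.concentration, s.replicate, window_delta(s, *window))
            for s in series_set]
    return pd.DataFrame(rows, columns=["concentration", "replicate", "delta"])


def growth_reducing_concentration(series_set, alpha: float = 0.05,
                                  window: tuple[float, float] = (40.0, 72.0),
                                  ) -> float | None:
    """Lowest dose with a significant 40-72 h growth decrease vs vehicle.

    One-way layout on the window deltas; dose-vs-vehicle contrasts are
    the least-square means of the groups with a pooled residual
    variance, tested one-sided for decrease and Holm-adjusted across
    doses.  With zero residual variance (noise-free input) a contrast is
    significant iff the group mean is strictly below the vehicle mean.

    The call respects dose-response coherence: a significant dose
    separated from the contiguous significant run that contains the
    highest significant dose is treated as noise (the effect is assumed
    monotone in concentration), so the returned value is the lowest
    dose of that top run.  Returns None when no dose qualifies.
    """
    df = _group_deltas(series_set, window)
    if not (df["concentration"] == 0).any():
        raise GrowthError("vehicle (concentration 0) group is required")
    counts = df.groupby("concentration")["delta"].count()
    if (counts < 2).any():
        raise GrowthError("need >=2 replicates per concentration group")
    means = df.groupby("concentration")["delta"].mean()
    n = counts.astype(float)
    sse = float(((df["delta"] - df["concentration"].map(means)) ** 2).sum())
    dof = int(len(df) - len(means))
    s2 = sse / dof if dof > 0 else 0.0

    doses = sorted(c for c in means.index if c > 0)
    mu0, n0 = means[0.0], n[0.0]
    pvals = []
    for c in doses:
        diff = means[c] - mu0
        se = np.sqrt(s2 * (1.0 / n[c] + 1.0 / n0))
        if se < 1e-12:
            p = 0.0 if diff < -1e-12 else 1.0
        else:
            p = float(stats.t.cdf(diff / se, dof))  # one-sided: decrease
        pvals.append(p)
    reject, _, _, _ = multipletests(pvals, alpha=alpha, method="holm")
    if not reject.any():
        return None
    # lowest dose of the contiguous significant run ending at the
    # highest significant dose
    top = max(i for i, rej in enumerate(reject) if rej)
    lo = top
    while lo > 0 and reject[lo - 1]:
        lo -= 1
    return float(doses[lo])


def growth_arresting_concentration(series_set, max_gain: float = 3.0,
                                   window: tuple[float, float] = (96.0, 120.0),
                                   ) -> float | None:
    """Lowest dose whose median 96-120 h confluence gain is below ``max_gain`` points."""
    df = _group_deltas(series_set, window)
    med = df[df["concentration"] > 0].groupby("concentration")["delta"].median()
    for c in sorted(med.index):
        if med[c] < max_gain:
            return float(c)
    return None


def classify_reversibility(series: ConfluenceSeries, min_regrowth: float = 3.0,
                           horizon: float = 72.0) -> bool:
    """Reversible iff confluence gain over (withdrawal, withdrawal + horizon] >= min_regrowth."""
    if series.withdrawal_at is None:
        raise GrowthError("series has no withdrawal time")
    t_w = series.withdrawal_at
    if series.times[-1] < t_w + horizon:
        raise GrowthError(
            f"series ends before {horizon} h past withdrawal at {t_w} h")
    return window_delta(series, t_w, t_w + horizon) >= min_regrowth


def classify_apoptosis(apoptotic_increase_pct: float) -> str:
    """'strong' above 15 points, 'moderate' above 5, else 'none' (strict boundaries)."""
    if apoptotic_increase_pct > 15.0:
        return "strong"
    if apoptotic_increase_pct > 5.0:
        return "moderate"
    return "none"


def cell_cycle_shift_filter(summaries, min_shift: float = 5.0):
    """Keep summaries where any cell-cycle phase increased by more than ``min_shift`` points."""
    return [s for s in summaries
            if s.phase_shifts and max(s.phase_shifts.values()) > min_shift]


def call_kinetics(series_set, alpha: float = 0.05, arrest_delta: float = 3.0,
                  regrowth_delta: float = 3.0) -> KineticCall:
    """Full kinetic call for one cell line x compound series set (vehicle included)."""
    first = series_set[0]
    reducing = growth_reducing_concentration(series_set, alpha=alpha)
    arresting = growth_arresting_concentration(series_set, max_gain=arrest_delta)

    ev_rows = []
    for s in series_set:
        row = {"concentration": s.concentration, "replicate": s.replicate,
               "delta_40_72": window_delta(s, 40.0, 72.0),
               "delta_96_120": window_delta(s, 96.0, 120.0)}
        if s.withdrawal_at is not None and s.times[-1] >= s.withdrawal_at + 72.0:
            row["delta_post_withdrawal"] = window_delta(
                s, s.withdrawal_at, s.withdrawal_at + 72.0)
        ev_rows.append(row)
    evidence = pd.DataFrame(ev_rows)

    reversible = None
    if arresting is not None:
        arrested = [s for s in series_set
                    if s.concentration == arresting and s.withdrawal_at is not None
                    and s.times[-1] >= s.withdrawal_at + 72.0]
        if arrested:
            flags = [classify_reversibility(s, min_regrowth=regrowth_delta)
                     for s in arrested]
            reversible = bool(np.median(flags) >= 0.5)

    return KineticCall(cell_line=first.cell_line, compound=first.compound,
                       growth_reducing_conc=reducing,
                       growth_arresting_conc=arresting,
                       reversible=reversible, evidence=evidence)


def call_kinetics_table(series_list, alpha: float = 0.05,
                        arrest_delta: float = 3.0,
                        regrowth_delta: float = 3.0) -> pd.DataFrame:
    """Kinetic calls for every (cell_line, compound) group in a series list."""
    groups: dict[tuple[str, str], list[ConfluenceSeries]] = {}
    for s in series_list:
        groups.setdefault((s.cell_line, s.compound), []).append(s)
    rows = []
    for (line, compound) in sorted(groups):
        call = call_kinetics(groups[(line, compound)], alpha=alpha,
                             arrest_delta=arrest_delta,
                             regrowth_delta=regrowth_delta)
        rows.append({
            "cell_line": line, "compound": compound,
            "growth_reducing_conc_nM": call.growth_reducing_conc,
            "growth_arresting_conc_nM": call.growth_arresting_conc,
            "reversible": call.reversible,
        })
    return pd.DataFrame(rows)
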