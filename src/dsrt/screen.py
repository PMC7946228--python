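"""Primary drug-screen analysis: control normalization, plate QC, viability scoring.

A 384-well screening plate carries drug wells (one compound at one
concentration each), benzethonium-chloride (BzCl) full-kill positive
controls, and DMSO vehicle negative controls.  Raw luminescence is
normalized per plate as

    viability = (signal - median(BzCl)) / (median(DMSO) - median(BzCl))

so 1 means untreated-like viability and 0 means full kill.  Each
compound x cell-line five-point profile is then constrained to be
non-increasing in concentration and bounded in [0, 1] (least absolute
deviation antitonic regression), and summarized by the trapezoidal
area under the viability curve over log10 concentration.  With five
10-fold spaced concentrations the score lives in [0, 4]: 0 = kill at
every dose, 4 = no effect at any dose.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ROLE_DRUG = "drug"
ROLE_POS = "pos_ctrl"
ROLE_NEG = "neg_ctrl"


class ScreenError(ValueError):
    """Raised for degenerate plates or malformed profiles."""


@dataclass(frozen=True)
class PlateQC:
    """Per-plate control summaries and quality statistics."""

    plate_id: str
    mu_neg: float
    sd_neg: float
    mu_pos: float
    sd_pos: float
    z_prime: float
    ssmd: float
    pass_zprime: bool
    pass_ssmd: bool


@dataclass
class ViabilityProfile:
    """One compound x cell line: raw and smoothed viabilities plus the AUC score."""

    cell_line: str
    compound: str
    concentrations: np.ndarray
    viability_raw: np.ndarray
    viability_smoothed: np.ndarray = field(default=None)
    auc: float = field(default=None)


# ---------------------------------------------------------------------------
# QC statistics
# ---------------------------------------------------------------------------

def zprime(pos_signals, neg_signals) -> float:
    """Z'-factor of the control separation window.

    z' = 1 - 3 (sd_pos + sd_neg) / |mu_neg - mu_pos|, with sample SDs.
    Equals 1 only in the zero-variance limit; > 0.5 is the conventional
    acceptance bar for a screening plate.
    """
    pos = np.asarray(pos_signals, dtype=float)
    neg = np.asarray(neg_signals, dtype=float)
    if pos.size < 2 or neg.size < 2:
        raise ScreenError("z'-factor needs at least 2 wells per control group")
    mu_p, mu_n = pos.mean(), neg.mean()
    if mu_p == mu_n:
        raise ScreenError("z'-factor undefined: control means are equal")
    sd_p = pos.std(ddof=1)
    sd_n = neg.std(ddof=1)
    return 1.0 - 3.0 * (sd_p + sd_n) / abs(mu_n - mu_p)


def ssmd(pos_signals, neg_signals) -> float:
    """Strictly standardized mean difference of the control groups.

    beta = (mu_pos - mu_neg) / sqrt(sd_pos^2 + sd_neg^2).  A strong kill
    control sitting below the vehicle control gives a large negative
    beta; |beta| >= 3 indicates good separation.
    """
    pos = np.asarray(pos_signals, dtype=float)
    neg = np.asarray(neg_signals, dtype=float)
    if pos.size < 2 or neg.size < 2:
        raise ScreenError("SSMD needs at least 2 wells per control group")
    sd_p = pos.std(ddof=1)
    sd_n = neg.std(ddof=1)
    denom = np.sqrt(sd_p**2 + sd_n**2)
    if denom == 0:
        raise ScreenError("SSMD undefined: both control SDs are zero")
    return (pos.mean() - neg.mean()) / denom


def plate_qc(wells: pd.DataFrame, zprime_min: float = 0.5,
             ssmd_min: float = 3.0) -> pd.DataFrame:
    """Compute PlateQC rows for every plate in a well table."""
    rows = []
    for plate_id, grp in wells.groupby("plate_id", sort=True):
        pos = grp.loc[grp["role"] == ROLE_POS, "signal"].to_numpy(float)
        neg = grp.loc[grp["role"] == ROLE_NEG, "signal"].to_numpy(float)
        zp = zprime(pos, neg)
        b = ssmd(pos, neg)
        rows.append(PlateQC(
            plate_id=str(plate_id),
            mu_neg=neg.mean(), sd_neg=neg.std(ddof=1),
            mu_pos=pos.mean(), sd_pos=pos.std(ddof=1),
            z_prime=zp, ssmd=b,
            pass_zprime=bool(zp > zprime_min),
            pass_ssmd=bool(abs(b) >= ssmd_min),
        ))
    return pd.DataFrame([r.__dict__ for r in rows])


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def normalize_plate(wells: pd.DataFrame) -> pd.DataFrame:
    """Per-well control-normalized viability, control medians taken per plate.

    Returns a copy of the well table with a ``viability`` column.  Values
    are deliberately NOT clipped here: over-unity or negative wells stay
    visible for QC and are only constrained by the smoothing step.
    """
    wells = wells.copy()
    out = []
    for plate_id, grp in wells.groupby("plate_id", sort=False):
        pos = grp.loc[grp["role"] == ROLE_POS, "signal"]
        neg = grp.loc[grp["role"] == ROLE_NEG, "signal"]
        if len(pos) < 2 or len(neg) < 2:
            raise ScreenError(
                f"plate {plate_id!r}: need >=2 wells of each control role")
        med_pos = float(pos.median())
        med_neg = float(neg.median())
        if med_pos == med_neg:
            raise ScreenError(
                f"plate {plate_id!r}: degenerate controls (equal medians)")
        grp = grp.copy()
        grp["viability"] = (grp["signal"] - med_pos) / (med_neg - med_pos)
        out.append(grp)
    return pd.concat(out, axis=0)


# ---------------------------------------------------------------------------
# Monotone smoothing and AUC scoring
# ---------------------------------------------------------------------------

def _isotonic_l1(y: np.ndarray) -> np.ndarray:
    # Pool-adjacent-violators with block medians: an L1-optimal
    # non-decreasing fit (optimum may be non-unique; any block-median
    # solution attains the minimum).
    blocks: list[list[float]] = []
    meds: list[float] = []
    for v in y:
        blocks.append([float(v)])
        meds.append(float(v))
        while len(blocks) > 1 and meds[-2] > meds[-1]:
            merged = blocks[-2] + blocks[-1]
            blocks[-2:] = [merged]
            meds[-2:] = [float(np.median(merged))]
    out = np.empty(len(y), dtype=float)
    i = 0
    for blk, m in zip(blocks, meds):
        out[i:i + len(blk)] = m
        i += len(blk)
    return out


def smooth_profile(viability_raw, concentrations=None) -> np.ndarray:
    """L1-optimal non-increasing fit of a viability profile, bounded in [0, 1].

    The qualitative constraints are monotone decay in concentration and
    viability within [0, 1]; among all curves satisfying them this
    returns one minimizing the sum of absolute deviations from the raw
    values (antitonic pool-adjacent-violators on the reversed sequence,
    then clipping — clipping a monotone L1 fit to a box keeps it
    L1-optimal among box-constrained monotone curves).  Already-feasible
    input passes through unchanged; the operation is idempotent.
    """
    y = np.asarray(viability_raw, dtype=float)
    if y.ndim != 1 or y.size < 3:
        raise ScreenError("smoothing needs at least 3 concentrations")
    if concentrations is not None:
        c = np.asarray(concentrations, dtype=float)
        if c.size != y.size or np.any(np.diff(c) <= 0):
            raise ScreenError("concentrations must be strictly ascending")
    fit = _isotonic_l1(y[::-1])[::-1]
    return np.clip(fit, 0.0, 1.0)


def auc_score(viability, concentrations) -> float:
    """Trapezoidal area under viability over log10 concentration.

    10-fold dose spacing gives each panel unit width, so a five-point
    profile spanning 1 nM - 10 uM scores in [0, 4]: the flat profile of
    ones scores 4, all-kill scores 0, and the half-effect worked example
    [1, 1, 0.5, 0, 0] scores 2.
    """
    v = np.asarray(viability, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    if v.size != c.size or v.size < 2:
        raise ScreenError("profile and concentrations must align (>=2 points)")
    if np.any(c <= 0) or np.any(np.diff(c) <= 0):
        raise ScreenError("concentrations must be positive and strictly ascending")
    return float(np.trapezoid(v, np.log10(c)))


def build_profiles(norm_wells: pd.DataFrame) -> list[ViabilityProfile]:
    """Assemble smoothed, scored profiles from a normalized well table."""
    profiles = []
    drug = norm_wells[norm_wells["role"] == ROLE_DRUG]
    for (line, compound), grp in drug.groupby(["cell_line", "compound"], sort=True):
        grp = grp.sort_values("concentration_nM")
        # replicate wells at one concentration enter as their mean viability
        agg = grp.groupby("concentration_nM", sort=True)["viability"].mean()
        conc = agg.index.to_numpy(float)
        raw = agg.to_numpy(float)
        smoothed = smooth_profile(raw, conc)
        profiles.append(ViabilityProfile(
            cell_line=str(line), compound=str(compound),
            concentrations=conc, viability_raw=raw,
            viability_smoothed=smoothed,
            auc=auc_score(smoothed, conc),
        ))
    return profiles


def auc_table(profiles: list[ViabilityProfile]) -> pd.DataFrame:
    """Pivot profiles into a compound x cell-line AUC matrix (NaN = not tested)."""
    rows = [(p.compound, p.cell_line, p.auc) for p in profiles]
    df = pd.DataFrame(rows, columns=["compound", "cell_line", "auc"])
    return df.pivot(index="compound", columns="cell_line", values="auc").sort_index()


def select_hits(auc: pd.DataFrame, threshold: float = 2.0,
                min_lines: int = 1) -> pd.DataFrame:
    """Compounds with AUC <= threshold (inclusive) in >= min_lines cell lines.

    Ranked by minimum AUC ascending, ties broken by the number of
    qualifying lines (more lines first).  Missing entries (not tested)
    are ignored.  An empty table yields an empty hit list.
    """
    if auc.empty:
        return pd.DataFrame(columns=["compound", "min_auc", "n_lines_qualifying"])
    qualifying = (auc <= threshold).sum(axis=1)
    hits = auc.index[qualifying >= min_lines]
    out = pd.DataFrame({
        "compound": hits,
        "min_auc": auc.loc[hits].min(axis=1).to_numpy(),
        "n_lines_qualifying": qualifying.loc[hits].to_numpy(),
    })
    return (out.sort_values(["min_auc", "n_lines_qualifying"],
                            ascending=[True, False])
               .reset_index(drop=True))
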