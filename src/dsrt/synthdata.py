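"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the assays the analysis consumes:

* 384-well screening plates — latent four-parameter log-logistic (4PL)
  concentration-response truths drive well luminescence between a BzCl
  kill floor and a DMSO vehicle level, with multiplicative lognormal
  noise (plate reads are positive and right-skewed);
* confluence time series — logistic growth whose rate is suppressed by
  a per-concentration multiplier, optional drug withdrawal with
  reversion to the baseline rate, additive Gaussian noise truncated to
  [0, 100];
* GR-assay endpoint counts — exponential growth tuned so the GR
  transform of the generated counts equals a 4PL GR truth exactly;
* an FPKM-like expression matrix with planted gene-drug rank
  correlations (lognormal background) plus a configurable fraction of
  genes held below the expression filter floor in every line;
* random gene sets in GMT structure, optionally one set concentrated
  in planted biomarker genes.

A single global seed fans out to fixed per-stream child seeds, so
adding one generator never shifts another's draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .screen import ROLE_DRUG, ROLE_NEG, ROLE_POS, auc_score
from .growth import ConfluenceSeries
from .grfit import gr_curve, gr50_from_params

DEFAULT_CONCENTRATIONS_NM = (1.0, 10.0, 100.0, 1000.0, 10000.0)
#: seven 10-fold dilutions starting from 100 uM, in nM
GR_CONCENTRATIONS_NM = (0.1, 1.0, 10.0, 100.0, 1000.0, 10000.0, 100000.0)

_STREAMS = {"plate": 0, "growth": 1, "gr": 2, "expression": 3,
            "gene_sets": 4, "scenario": 5}


def stream_rng(seed: int, stream: str, subkey: int = 0) -> np.random.Generator:
    """Child generator for a named stream (and optional sub-stream) of the global seed."""
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream], subkey)))


# ---------------------------------------------------------------------------
# Truth records
# ---------------------------------------------------------------------------

@dataclass
class ScreenTruth:
    """Latent 4PL viability truth for one compound x cell line."""

    cell_line: str
    compound: str
    e_inf: float  # viability floor in [0, e_max]
    ec50: float  # nM
    hill: float
    e_max: float = 1.0

    def __post_init__(self):
        if not (0.0 <= self.e_inf <= self.e_max <= 1.0):
            raise ValueError("require 0 <= e_inf <= e_max <= 1")
        if self.ec50 <= 0 or self.hill <= 0:
            raise ValueError("ec50 and hill must be positive")

    def viability(self, conc) -> np.ndarray:
        conc = np.asarray(conc, dtype=float)
        return self.e_inf + (self.e_max - self.e_inf) / (
            1.0 + (conc / self.ec50) ** self.hill)

    def true_auc(self, concentrations=DEFAULT_CONCENTRATIONS_NM) -> float:
        return auc_score(self.viability(concentrations), concentrations)


@dataclass
class GRCurveTruth:
    """Latent GR dose-response truth (lower asymptote may be negative)."""

    cell_line: str
    compound: str
    gr_inf: float  # in [-1, 1]
    gec50: float  # nM
    hill: float

    def __post_init__(self):
        if not (-1.0 <= self.gr_inf <= 1.0):
            raise ValueError("gr_inf must lie in [-1, 1]")
        if self.gec50 <= 0 or self.hill <= 0:
            raise ValueError("gec50 and hill must be positive")

    def gr(self, conc):
        return gr_curve(conc, self.gr_inf, self.gec50, self.hill)

    def true_gr50(self) -> float:
        return gr50_from_params(self.gr_inf, self.gec50, self.hill)


@dataclass
class GrowthTruth:
    """Logistic-growth truth with dose-suppressed rate.

    ``drug_effect`` maps concentration (nM) to a rate multiplier in
    [0, 1], non-increasing in concentration.  ``reversible`` marks
    whether arrested conditions resume baseline growth after drug
    withdrawal.
    """

    cell_line: str
    baseline_rate: float  # doublings per hour
    carrying_capacity: float = 95.0  # percent confluence
    initial_confluence: float = 5.0
    drug_effect: dict = field(default_factory=dict)
    reversible: bool = False

    def __post_init__(self):
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be positive")
        if not (0 < self.carrying_capacity <= 100):
            raise ValueError("carrying capacity must lie in (0, 100]")
        concs = sorted(self.drug_effect)
        mults = [self.drug_effect[c] for c in concs]
        if any(not (0.0 <= m <= 1.0) for m in mults):
            raise ValueError("rate multipliers must lie in [0, 1]")
        if any(b > a for a, b in zip(mults, mults[1:])):
            raise ValueError("rate multiplier must be non-increasing in concentration")

    def multiplier(self, conc: float) -> float:
        if conc == 0:
            return 1.0
        if conc not in self.drug_effect:
            raise KeyError(f"no rate multiplier defined for {conc} nM")
        return self.drug_effect[conc]


@dataclass
class ExpressionTruth:
    """Planted gene-drug correlations on top of a lognormal FPKM background."""

    planted_biomarkers: list  # (gene, compound, direction, effect_size)
    n_genes: int = 1000
    n_lines: int = 13
    frac_below_floor: float = 0.1

    def __post_init__(self):
        if len(self.planted_biomarkers) > self.n_genes:
            raise ValueError("cannot plant more biomarkers than genes")
        for gene, compound, direction, effect in self.planted_biomarkers:
            if direction not in ("sensitizing", "resistance"):
                raise ValueError(f"unknown direction {direction!r}")
            if not (0.0 < effect <= 1.0):
                raise ValueError("effect_size must lie in (0, 1]")


@dataclass
class PlateLayout:
    """384-well geometry with control well counts and control signal levels."""

    n_rows: int = 16
    n_cols: int = 24
    n_neg: int = 16
    n_pos: int = 16
    neg_level: float = 10000.0  # DMSO luminescence, arbitrary units
    pos_level: float = 200.0  # BzCl kill floor, near the plate floor

    @property
    def capacity(self) -> int:
        return self.n_rows * self.n_cols

    def well_names(self):
        rows = [chr(ord("A") + i) for i in range(self.n_rows)]
        return [f"{r}{c:02d}" for r in rows for c in range(1, self.n_cols + 1)]


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def _lognormal_factors(rng, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise with the given CV."""
    if cv < 0:
        raise ValueError("noise_cv must be >= 0")
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma, size=size)


def gen_plate(truths, layout: PlateLayout | None = None,
              noise_cv: float = 0.05, n_reps: int = 1,
              concentrations=DEFAULT_CONCENTRATIONS_NM,
              seed: int = 0, plate_id: str | None = None,
              plate_index: int = 0) -> pd.DataFrame:
    """One screening plate of well records for truths sharing a cell line.

    Raw signal for a drug well is pos_level + (neg_level - pos_level) *
    v(c) with v the 4PL truth viability, perturbed multiplicatively by
    lognormal noise of CV ``noise_cv``; control wells sit at their
    levels with the same noise.  Deterministic given the seed.
    """
    layout = layout or PlateLayout()
    lines = {t.cell_line for t in truths}
    if len(lines) > 1:
        raise ValueError("one plate carries a single cell line")
    cell_line = lines.pop() if lines else "NA"
    conc = list(concentrations)
    need = layout.n_neg + layout.n_pos + len(truths) * len(conc) * n_reps
    if need > layout.capacity:
        raise ValueError(
            f"layout overflow: {need} wells needed but plate holds {layout.capacity}")
    rng = stream_rng(seed, "plate", subkey=plate_index)
    wells = layout.well_names()
    plate_id = plate_id or f"P-{cell_line}"

    rows = []
    i = 0
    for _ in range(layout.n_neg):
        rows.append((plate_id, wells[i], ROLE_NEG, None, np.nan, cell_line,
                     layout.neg_level))
        i += 1
    for _ in range(layout.n_pos):
        rows.append((plate_id, wells[i], ROLE_POS, None, np.nan, cell_line,
                     layout.pos_level))
        i += 1
    for t in truths:
        v = t.viability(conc)
        for j, c in enumerate(conc):
            expected = layout.pos_level + (layout.neg_level - layout.pos_level) * v[j]
            for _ in range(n_reps):
                rows.append((plate_id, wells[i], ROLE_DRUG, t.compound, c,
                             cell_line, expected))
                i += 1
    df = pd.DataFrame(rows, columns=["plate_id", "well", "role", "compound",
                                     "concentration_nM", "cell_line", "signal"])
    df["signal"] = df["signal"].to_numpy() * _lognormal_factors(rng, noise_cv, len(df))
    df["row"] = df["well"].str[0]
    df["col"] = df["well"].str[1:].astype(int)
    return df[["plate_id", "well", "row", "col", "role", "compound",
               "concentration_nM", "cell_line", "signal"]]


def gen_screen(truths, seed: int = 0, **kwargs) -> pd.DataFrame:
    """One plate per cell line; truths grouped automatically."""
    by_line: dict[str, list] = {}
    for t in truths:
        by_line.setdefault(t.cell_line, []).append(t)
    frames = []
    for k, line in enumerate(sorted(by_line)):
        frames.append(gen_plate(by_line[line], seed=seed, plate_index=k, **kwargs))
    return pd.concat(frames, ignore_index=True)


def _logistic_step(c: float, rate: float, capacity: float, dt: float) -> float:
    # exact logistic solution over one interval at a constant rate
    if c <= 0:
        return 0.0
    if rate == 0:
        return c
    return capacity / (1.0 + (capacity / c - 1.0) * np.exp(-rate * dt))


def gen_growth_curves(truth: GrowthTruth, concentrations,
                      t_grid=None, n_reps: int = 3,
                      withdrawal_at: float | None = None,
                      noise_sd: float = 1.0, seed: int = 0,
                      compound: str = "drug",
                      subkey: int = 0) -> list[ConfluenceSeries]:
    """Replicated confluence series per concentration (0 = vehicle).

    Logistic growth at rate ln2 * baseline_rate * multiplier(c) per
    hour; when ``withdrawal_at`` is set and the truth is reversible, the
    rate reverts to baseline past that time.  Observation noise is
    additive Gaussian, truncated to [0, 100].  Deterministic per seed.
    """
    if t_grid is None:
        t_end = 120.0 if withdrawal_at is None else withdrawal_at + 72.0
        t_grid = np.arange(0.0, t_end + 1e-9, 3.0)
    t_grid = np.asarray(t_grid, dtype=float)
    if np.any(np.diff(t_grid) <= 0):
        raise ValueError("time grid must be strictly increasing")
    rng = stream_rng(seed, "growth", subkey=subkey)
    k = truth.carrying_capacity
    base = np.log(2.0) * truth.baseline_rate

    out = []
    for conc in concentrations:
        mult = truth.multiplier(conc)
        traj = np.empty_like(t_grid)
        c = truth.initial_confluence
        traj[0] = c
        for i in range(1, t_grid.size):
            t0, t1 = t_grid[i - 1], t_grid[i]
            m = mult
            if (withdrawal_at is not None and truth.reversible
                    and t0 >= withdrawal_at):
                m = 1.0
            c = _logistic_step(c, base * m, k, t1 - t0)
            traj[i] = c
        for rep in range(n_reps):
            obs = traj + rng.normal(0.0, noise_sd, size=t_grid.size) \
                if noise_sd > 0 else traj.copy()
            out.append(ConfluenceSeries(
                cell_line=truth.cell_line, compound=compound,
                concentration=float(conc), replicate=rep,
                times=t_grid.copy(), confluence=np.clip(obs, 0.0, 100.0),
                withdrawal_at=withdrawal_at))
    return out


def gen_gr_assay(truths, concentrations=GR_CONCENTRATIONS_NM,
                 division_time: float = 24.0, t_end: float = 72.0,
                 x0: float = 1000.0, noise_cv: float = 0.0,
                 seed: int = 0) -> pd.DataFrame:
    """Endpoint counts whose GR transform equals each truth's GR curve.

    Controls grow exponentially: x_ctrl = x0 * 2^(t_end/division_time).
    For a target GR value g, the treated endpoint is x_c = x0 *
    2^((t_end/division_time) * log2(1 + g)), which inverts the GR
    transform exactly.  Optional multiplicative lognormal noise on the
    treated counts.
    """
    if t_end <= 0 or division_time <= 0:
        raise ValueError("t_end and division_time must be positive")
    rng = stream_rng(seed, "gr")
    doublings = t_end / division_time
    x_ctrl = x0 * 2.0 ** doublings
    rows = []
    for t in truths:
        g = np.asarray(t.gr(list(concentrations)), dtype=float)
        x_c = x0 * 2.0 ** (doublings * np.log2(1.0 + g))
        if noise_cv > 0:
            x_c = x_c * _lognormal_factors(rng, noise_cv, x_c.size)
        for c, xc in zip(concentrations, x_c):
            rows.append((t.cell_line, t.compound, float(c), x0, x_ctrl, float(xc)))
    return pd.DataFrame(rows, columns=["cell_line", "compound",
                                       "concentration_nM", "x0", "x_ctrl", "x_c"])


def gen_expression(truth: ExpressionTruth, gr50_table: pd.DataFrame,
                   seed: int = 0, bg_mu: float = 1.3, bg_mu_sd: float = 0.4,
                   within_sd: float = 0.3, planted_scale: float = 0.35,
                   planted_loc: float = 1.5):
    """FPKM matrix (genes x lines) with planted responders; returns (df, info).

    Background genes draw log10 FPKM independently of response.  A
    planted (gene, compound, direction, effect) gets log expression
    effect * s * z + sqrt(1 - effect^2) * noise, where z standardizes
    the rank of that compound's GR50 across lines and s is +1 for
    resistance markers, -1 for sensitizing ones — so at effect 1 the
    full-panel Spearman rho is exactly +/-1.  The last
    ``frac_below_floor`` of background genes sit below FPKM 10 in every
    line.
    """
    lines = list(gr50_table.columns)
    if len(lines) < 3:
        raise ValueError("gr50_table must cover >=3 cell lines")
    if truth.n_lines != len(lines):
        raise ValueError("truth.n_lines must match gr50_table columns")
    rng = stream_rng(seed, "expression")
    n_g, n_s = truth.n_genes, len(lines)
    genes = [f"G{i:05d}" for i in range(n_g)]

    mu = rng.normal(bg_mu, bg_mu_sd, size=n_g)
    logf = mu[:, None] + rng.normal(0.0, within_sd, size=(n_g, n_s))

    planted_rows = {}
    for k, (gene, compound, direction, effect) in enumerate(truth.planted_biomarkers):
        if compound not in gr50_table.index:
            raise ValueError(f"compound {compound!r} absent from gr50_table")
        genes[k] = gene
        ranks = pd.Series(gr50_table.loc[compound, lines]).rank().to_numpy(float)
        z = (ranks - ranks.mean()) / ranks.std()
        s = 1.0 if direction == "resistance" else -1.0
        noise = rng.normal(0.0, 1.0, size=n_s)
        latent = effect * s * z + np.sqrt(1.0 - effect**2) * noise
        logf[k] = planted_loc + planted_scale * latent
        planted_rows[gene] = (compound, direction, effect)

    n_floor = int(round(truth.frac_below_floor * n_g))
    floor_genes = []
    if n_floor > 0:
        lo = n_g - n_floor
        logf[lo:] = np.log10(rng.uniform(0.1, 5.0, size=(n_floor, n_s)))
        floor_genes = genes[lo:]

    df = pd.DataFrame(10.0 ** logf, index=pd.Index(genes, name="gene"),
                      columns=lines)
    info = {"planted": planted_rows, "below_floor": list(floor_genes)}
    return df, info


def gen_gene_sets(gene_universe, n_sets: int = 30,
                  set_size_range=(15, 50), planted_set=None,
                  seed: int = 0) -> dict:
    """Random gene sets plus an optional set concentrated in planted genes."""
    universe = list(gene_universe)
    if not universe:
        raise ValueError("gene universe is empty")
    lo, hi = set_size_range
    if hi > len(universe):
        raise ValueError("set sizes cannot exceed the universe size")
    rng = stream_rng(seed, "gene_sets")
    sets = {}
    if planted_set is not None:
        deduped = list(dict.fromkeys(planted_set))
        if len(deduped) < len(planted_set):
            warnings.warn("duplicate gene symbols in planted set; deduplicated")
        sets["PLANTED_SET"] = deduped
    for k in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(universe), size=size, replace=False)
        sets[f"RANDOM_SET_{k:03d}"] = [universe[i] for i in sorted(members)]
    return sets


# ---------------------------------------------------------------------------
# Default end-to-end scenario
# ---------------------------------------------------------------------------

@dataclass
class Scenario:
    """All truths and generated inputs for one full synthetic study."""

    cell_lines: list
    compounds: list
    hit_compounds: list
    screen_truths: list
    gr_truths: list
    growth_truths: dict  # (cell_line, compound) -> GrowthTruth
    expression_truth: ExpressionTruth
    true_auc: pd.DataFrame
    true_gr50: pd.DataFrame


def default_scenario(seed: int = 0, n_lines: int = 13, n_compounds: int = 10,
                     n_hits: int = 6, n_genes: int = 400,
                     planted_effect: float = 1.0,
                     n_growth_compounds: int = 2) -> Scenario:
    """The default study shape: 13 lines, 10 compounds of which 6 are hits.

    Hit compounds get potent truths (EC50 3-50 nM, viability floor near
    0) whose true AUC sits well below the half-scale threshold in every
    line; the rest are inactive in the tested range (EC50 >= 300 uM).
    GR truths share each line's EC50 so screen AUC and GR50 order cell
    lines identically.  Two planted expression biomarkers (one
    sensitizing, one resistance) per hit compound.
    """
    rng = stream_rng(seed, "scenario")
    lines = [f"LS{i + 1:02d}" for i in range(n_lines)]
    compounds = [f"DRUG-{i + 1:02d}" for i in range(n_compounds)]
    hits = compounds[:n_hits]

    screen_truths, gr_truths = [], []
    for ci, compound in enumerate(compounds):
        is_hit = ci < n_hits
        hill = float(rng.uniform(0.8, 1.6))
        base_ec50 = float(10 ** rng.uniform(np.log10(3), np.log10(50))) if is_hit \
            else float(10 ** rng.uniform(np.log10(3e5), np.log10(3e6)))
        e_inf = float(rng.uniform(0.0, 0.08)) if is_hit else float(rng.uniform(0.1, 0.3))
        gr_inf = -0.5 if is_hit else -0.2
        for line in lines:
            ec50 = base_ec50 * float(np.exp(rng.normal(0.0, 0.3)))
            screen_truths.append(ScreenTruth(cell_line=line, compound=compound,
                                             e_inf=e_inf, ec50=ec50, hill=hill))
            gr_truths.append(GRCurveTruth(cell_line=line, compound=compound,
                                          gr_inf=gr_inf, gec50=ec50, hill=hill))

    auc_rows = {}
    for t in screen_truths:
        auc_rows.setdefault(t.compound, {})[t.cell_line] = t.true_auc()
    true_auc = pd.DataFrame(auc_rows).T.loc[compounds, lines]
    gr50_rows = {}
    for t in gr_truths:
        gr50_rows.setdefault(t.compound, {})[t.cell_line] = t.true_gr50()
    true_gr50 = pd.DataFrame(gr50_rows).T.loc[compounds, lines]

    growth_truths = {}
    ec50_of = {(t.cell_line, t.compound): t.ec50 for t in screen_truths}
    for compound in compounds[:n_growth_compounds]:
        for line in lines:
            ec50 = ec50_of[(line, compound)]
            effect = {c: float(1.0 / (1.0 + (c / ec50) ** 2))
                      for c in DEFAULT_CONCENTRATIONS_NM}
            growth_truths[(line, compound)] = GrowthTruth(
                cell_line=line, baseline_rate=1.0 / 24.0, drug_effect=effect)

    planted = []
    for k, compound in enumerate(hits):
        planted.append((f"BM_SENS_{compound}", compound, "sensitizing",
                        planted_effect))
        planted.append((f"BM_RES_{compound}", compound, "resistance",
                        planted_effect))
    expr_truth = ExpressionTruth(planted_biomarkers=planted, n_genes=n_genes,
                                 n_lines=n_lines)

    return Scenario(cell_lines=lines, compounds=compounds, hit_compounds=hits,
                    screen_truths=screen_truths, gr_truths=gr_truths,
                    growth_truths=growth_truths, expression_truth=expr_truth,
                    true_auc=true_auc, true_gr50=true_gr50)
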