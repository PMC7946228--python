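"""End-to-end orchestration: synthesize -> screen -> kinetics -> GR fits -> biomarkers.

``run_pipeline`` executes the enabled stages in dependency order on a
synthetic study, writes every intermediate artifact under the output
directory, and records a manifest (paths, parameters, seed, SHA-256
content hashes).  Reruns with an identical config reproduce identical
hashes.  ``concordance`` compares the three per-line response summaries
(screen AUC, GR50, growth-arresting concentration) compound by compound
with Spearman rank correlation on untransformed values.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import biomarker as bm
from . import grfit, growth, io, screen, synthdata


@dataclass
class RunConfig:
    """Pipeline configuration; thresholds default to the published analysis values."""

    outdir: str = "dsrt_run"
    seed: int = 0
    # synthesis scale
    n_lines: int = 13
    n_compounds: int = 10
    n_hits: int = 6
    n_genes: int = 400
    n_sets: int = 20
    noise_cv: float = 0.05
    growth_noise_sd: float = 1.0
    # stage toggles
    stage_screen: bool = True
    stage_growth: bool = True
    stage_grfit: bool = True
    stage_biomarker: bool = True
    # thresholds
    auc_threshold: float = 2.0
    min_lines: int = 1
    alpha: float = 0.05
    arrest_delta: float = 3.0
    regrowth_delta: float = 3.0
    rho_min: float = 0.65
    rho_fold: float = 0.8
    n_perm: int = 1000
    fdr_max: float = 0.001
    es_min: float = 0.5
    gsea_min_size: int = 15
    gsea_max_size: int = 500

    def __post_init__(self):
        for name, lo, hi in [("auc_threshold", 0, 4), ("alpha", 0, 1),
                             ("rho_min", 0, 1), ("rho_fold", 0, 1),
                             ("fdr_max", 0, 1), ("es_min", 0, 1)]:
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with Path(path).open() as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def concordance(auc_table: pd.DataFrame, gr50_table: pd.DataFrame,
                arrest_table: pd.DataFrame | None = None,
                min_n: int = 4, alpha: float = 0.05) -> pd.DataFrame:
    """Per-compound Spearman rho between response summaries across cell lines.

    Pairs with fewer than ``min_n`` shared cell lines are omitted with a
    reason; only p < alpha entries are flagged significant.
    """
    tables = {"auc": auc_table, "gr50": gr50_table}
    if arrest_table is not None:
        tables["arrest"] = arrest_table
    names = list(tables)
    rows = []
    compounds = sorted(set().union(*[set(t.index) for t in tables.values()]))
    for compound in compounds:
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                ta, tb = tables[a], tables[b]
                if compound not in ta.index or compound not in tb.index:
                    continue
                sa, sb = ta.loc[compound].dropna(), tb.loc[compound].dropna()
                sa, sb = sa[np.isfinite(sa)], sb[np.isfinite(sb)]
                shared = sa.index.intersection(sb.index)
                if len(shared) < min_n:
                    rows.append({"compound": compound, "pair": f"{a}_vs_{b}",
                                 "n": len(shared), "rho": np.nan, "p_value": np.nan,
                                 "significant": False,
                                 "skip_reason": f"only {len(shared)} shared lines"})
                    continue
                if sa.loc[shared].nunique() < 2 or sb.loc[shared].nunique() < 2:
                    rows.append({"compound": compound, "pair": f"{a}_vs_{b}",
                                 "n": len(shared), "rho": np.nan, "p_value": np.nan,
                                 "significant": False,
                                 "skip_reason": "constant values"})
                    continue
                rho, p = stats.spearmanr(sa.loc[shared], sb.loc[shared])
                rows.append({"compound": compound, "pair": f"{a}_vs_{b}",
                             "n": len(shared), "rho": float(rho),
                             "p_value": float(p),
                             "significant": bool(p < alpha),
                             "skip_reason": None})
    return pd.DataFrame(rows)


def _stage_synth(cfg: RunConfig, outdir: Path, manifest: dict):
    scen = synthdata.default_scenario(
        seed=cfg.seed, n_lines=cfg.n_lines, n_compounds=cfg.n_compounds,
        n_hits=cfg.n_hits, n_genes=cfg.n_genes)
    wells = synthdata.gen_screen(scen.screen_truths, seed=cfg.seed,
                                 noise_cv=cfg.noise_cv)
    io.write_plate_csv(wells, outdir / "plates.csv")

    series = []
    for k, (line, compound) in enumerate(sorted(scen.growth_truths)):
        series.extend(synthdata.gen_growth_curves(
            scen.growth_truths[(line, compound)],
            concentrations=(0.0,) + synthdata.DEFAULT_CONCENTRATIONS_NM,
            noise_sd=cfg.growth_noise_sd, seed=cfg.seed, subkey=k,
            compound=compound))
    io.write_confluence_csv(series, outdir / "confluence.csv")

    gr = synthdata.gen_gr_assay(scen.gr_truths, seed=cfg.seed)
    gr.to_csv(outdir / "gr_assay.csv", index=False)

    expr, info = synthdata.gen_expression(scen.expression_truth, scen.true_gr50,
                                          seed=cfg.seed)
    io.write_gct(expr, outdir / "expression.gct")
    planted_genes = sorted(info["planted"])
    sets = synthdata.gen_gene_sets(list(expr.index), n_sets=cfg.n_sets,
                                   set_size_range=(15, 40),
                                   planted_set=planted_genes, seed=cfg.seed)
    io.write_gmt(sets, outdir / "gene_sets.gmt")
    io.write_truths_yaml({
        "hit_compounds": scen.hit_compounds,
        "true_auc": scen.true_auc, "true_gr50": scen.true_gr50,
        "planted_biomarkers": {g: list(v) for g, v in info["planted"].items()},
        "below_floor_genes": info["below_floor"],
    }, outdir / "truths.yaml")
    manifest["stages"]["synth"] = {"outputs": [
        "plates.csv", "confluence.csv", "gr_assay.csv", "expression.gct",
        "gene_sets.gmt", "truths.yaml"]}
    return scen


def _stage_screen(cfg: RunConfig, outdir: Path, manifest: dict):
    wells = io.read_plate_csv(outdir / "plates.csv")
    qc = screen.plate_qc(wells)
    qc.to_csv(outdir / "plate_qc.csv", index=False)
    norm = screen.normalize_plate(wells)
    profiles = screen.build_profiles(norm)
    auc = screen.auc_table(profiles)
    auc.to_csv(outdir / "auc_matrix.csv")
    hits = screen.select_hits(auc, threshold=cfg.auc_threshold,
                              min_lines=cfg.min_lines)
    hits.to_csv(outdir / "hits.tsv", sep="\t", index=False)
    manifest["stages"]["screen"] = {
        "outputs": ["plate_qc.csv", "auc_matrix.csv", "hits.tsv"],
        "params": {"auc_threshold": cfg.auc_threshold, "min_lines": cfg.min_lines}}
    return auc, hits


def _stage_growth(cfg: RunConfig, outdir: Path, manifest: dict):
    series = io.read_confluence_csv(outdir / "confluence.csv")
    calls = growth.call_kinetics_table(series, alpha=cfg.alpha,
                                       arrest_delta=cfg.arrest_delta,
                                       regrowth_delta=cfg.regrowth_delta)
    calls.to_csv(outdir / "kinetic_calls.csv", index=False)
    manifest["stages"]["growth"] = {
        "outputs": ["kinetic_calls.csv"],
        "params": {"alpha": cfg.alpha, "arrest_delta": cfg.arrest_delta}}
    return calls


def _stage_grfit(cfg: RunConfig, outdir: Path, manifest: dict):
    gr_df = io.read_gr_csv(outdir / "gr_assay.csv")
    if "gr" not in gr_df.columns:
        gr_df["gr"] = grfit.gr_transform(gr_df["x0"], gr_df["x_ctrl"], gr_df["x_c"])
    rows = []
    for (line, compound), grp in gr_df.groupby(["cell_line", "compound"], sort=True):
        fit = grfit.fit_gr_curve(grp["concentration_nM"], grp["gr"])
        rows.append({"cell_line": line, "compound": compound,
                     "gr_inf": fit.gr_inf, "gec50_nM": fit.gec50,
                     "hill": fit.hill, "gr50_nM": fit.gr50,
                     "converged": fit.converged, "residual": fit.residual})
    fits = pd.DataFrame(rows)
    fits.to_csv(outdir / "gr_fits.csv", index=False)
    gr50 = fits.pivot(index="compound", columns="cell_line", values="gr50_nM")
    gr50.to_csv(outdir / "gr50_matrix.csv")
    manifest["stages"]["grfit"] = {"outputs": ["gr_fits.csv", "gr50_matrix.csv"]}
    return gr50


def _stage_biomarker(cfg: RunConfig, outdir: Path, manifest: dict,
                     gr50: pd.DataFrame):
    raw = bm.ExpressionMatrix(io.read_gct(outdir / "expression.gct"))
    expressed = bm.filter_expressed(raw)
    processed = bm.preprocess_expression(expressed)
    sets = io.read_gmt(outdir / "gene_sets.gmt")

    assoc_frames, loo_frames, enr_frames = [], [], []
    for k, compound in enumerate(sorted(gr50.index)):
        response = gr50.loc[compound].dropna()
        assoc = bm.correlate_gene_drug(processed, response,
                                       rho_min=cfg.rho_min, alpha=cfg.alpha)
        assoc.insert(0, "compound", compound)
        assoc_frames.append(assoc)
        loo = bm.loo_robust_biomarkers(processed, response, rho_fold=cfg.rho_fold)
        loo.insert(0, "compound", compound)
        loo_frames.append(loo)
        ranking = assoc.dropna(subset=["rho"]).set_index("gene")["rho"]
        enr = bm.gsea_preranked(ranking, sets, n_perm=cfg.n_perm,
                                seed=cfg.seed + k, min_size=cfg.gsea_min_size,
                                max_size=cfg.gsea_max_size,
                                fdr_max=cfg.fdr_max, es_min=cfg.es_min)
        enr.insert(0, "compound", compound)
        enr_frames.append(enr)
    pd.concat(assoc_frames, ignore_index=True).to_csv(
        outdir / "associations.csv", index=False)
    pd.concat(loo_frames, ignore_index=True).to_csv(
        outdir / "loo_biomarkers.csv", index=False)
    enrich = pd.concat(enr_frames, ignore_index=True)
    if "leading_edge" in enrich:
        enrich["leading_edge_size"] = enrich["leading_edge"].map(
            lambda x: len(x) if isinstance(x, list) else np.nan)
        enrich = enrich.drop(columns=["leading_edge"])
    enrich.to_csv(outdir / "enrichment.csv", index=False)
    manifest["stages"]["biomarker"] = {
        "outputs": ["associations.csv", "loo_biomarkers.csv", "enrichment.csv"],
        "params": {"rho_min": cfg.rho_min, "rho_fold": cfg.rho_fold,
                   "n_perm": cfg.n_perm, "fdr_max": cfg.fdr_max,
                   "es_min": cfg.es_min}}


def run_pipeline(config: RunConfig) -> dict:
    """Execute enabled stages in dependency order; returns the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"config": asdict(config), "seed": config.seed, "stages": {}}
    try:
        _stage_synth(config, outdir, manifest)
        auc = hits = gr50 = calls = None
        if config.stage_screen:
            auc, hits = _stage_screen(config, outdir, manifest)
        if config.stage_growth:
            calls = _stage_growth(config, outdir, manifest)
        if config.stage_grfit:
            gr50 = _stage_grfit(config, outdir, manifest)
        if config.stage_biomarker:
            if gr50 is None:
                raise RuntimeError("biomarker stage requires the grfit stage")
            _stage_biomarker(config, outdir, manifest, gr50)
        if config.stage_screen and config.stage_grfit:
            arrest = None
            if calls is not None and len(calls):
                arrest = calls.pivot(index="compound", columns="cell_line",
                                     values="growth_arresting_conc_nM")
            conc = concordance(auc, gr50, arrest, alpha=config.alpha)
            conc.to_csv(outdir / "concordance.csv", index=False)
            manifest["stages"]["concordance"] = {"outputs": ["concordance.csv"]}
    except Exception as exc:  # record the cause, then re-raise
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                         default=str))
        raise
    for stage in manifest["stages"].values():
        stage["hashes"] = {name: _sha256(outdir / name)
                           for name in stage["outputs"]}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     default=str))
    return manifest
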