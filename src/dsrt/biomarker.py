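"""Expression-biomarker discovery for drug response.

Starting from an FPKM matrix (genes x cell lines), the workflow is:

1. preprocessing — duplicate gene rows resolved by highest standard
   deviation, quantile normalization across samples, then log10 after
   adding a 1e-5 pseudocount;
2. expression filtering — genes below an FPKM floor (default 10) in
   every cell line are dropped;
3. single-gene association — Spearman rank correlation of each gene
   with the per-line GR50 of a compound; since a high GR50 means low
   sensitivity, rho < 0 marks a sensitizing gene (high expression,
   better response) and rho > 0 a resistance gene.  A gene "passes" at
   |rho| >= 0.65 with two-sided p < 0.05;
4. robustness — leave-one-out cross-validation over cell lines; a gene
   is a robust biomarker only when |rho| > 0.8 with a consistent sign
   in every fold;
5. pathway level — pre-ranked GSEA on the per-gene rho values with a
   gene-label permutation null, normalized enrichment scores and a
   signed-pool FDR; a set is significant at FDR < 0.001 and |ES| > 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class BiomarkerError(ValueError):
    """Raised for stage mismatches or degenerate inputs."""


STAGE_RAW = "raw_fpkm"
STAGE_LOG = "normalized_log"


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix with an explicit processing stage tag."""

    values: pd.DataFrame  # index = genes, columns = samples
    stage: str = STAGE_RAW

    def __post_init__(self):
        if self.stage not in (STAGE_RAW, STAGE_LOG):
            raise BiomarkerError(f"unknown stage {self.stage!r}")
        if not np.isfinite(self.values.to_numpy(float)).all():
            raise BiomarkerError("expression values must be finite")
        if self.stage == STAGE_LOG and self.values.index.duplicated().any():
            raise BiomarkerError("duplicate gene ids at stage normalized_log")


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def dedup_genes(df: pd.DataFrame) -> pd.DataFrame:
    """Resolve duplicated gene rows by keeping the row with the highest SD."""
    if not df.index.duplicated().any():
        return df
    sd = df.std(axis=1, ddof=1).to_numpy()
    order = pd.DataFrame({"gene": df.index, "sd": sd, "pos": np.arange(len(df))})
    keep = (order.sort_values(["sd", "pos"], ascending=[False, True])
                 .drop_duplicates("gene")["pos"].sort_values())
    return df.iloc[keep.to_numpy()]


def quantile_normalize(df: pd.DataFrame) -> pd.DataFrame:
    """Force every sample onto the common distribution of per-rank means.

    The reference distribution is the across-sample mean of the sorted
    columns; each value is replaced by the reference value at its rank.
    Ties within a sample receive the mean of the reference quantiles
    they span.
    """
    x = df.to_numpy(float)
    n, m = x.shape
    ref = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(m):
        col = x[:, j]
        order = np.argsort(col, kind="mergesort")
        sorted_col = col[order]
        assigned = ref.copy()
        # average the reference over runs of tied values
        starts = np.flatnonzero(np.r_[True, np.diff(sorted_col) != 0])
        ends = np.r_[starts[1:], n]
        for s, e in zip(starts, ends):
            if e - s > 1:
                assigned[s:e] = ref[s:e].mean()
        out[order, j] = assigned
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def preprocess_expression(matrix: ExpressionMatrix,
                          pseudocount: float = 1e-5) -> ExpressionMatrix:
    """Dedup -> quantile normalize -> add pseudocount -> log10."""
    if matrix.stage != STAGE_RAW:
        raise BiomarkerError("preprocess_expression expects a raw FPKM matrix")
    if (matrix.values.to_numpy(float) < 0).any():
        raise BiomarkerError("negative FPKM values")
    df = dedup_genes(matrix.values)
    df = quantile_normalize(df)
    df = np.log10(df + pseudocount)
    return ExpressionMatrix(values=df, stage=STAGE_LOG)


def filter_expressed(matrix: ExpressionMatrix, floor: float = 10.0,
                     ) -> ExpressionMatrix:
    """Drop genes whose FPKM is below ``floor`` in every sample (decided on FPKM scale)."""
    if matrix.stage != STAGE_RAW:
        raise BiomarkerError("filter_expressed expects a raw FPKM matrix")
    keep = (matrix.values >= floor).any(axis=1)
    return ExpressionMatrix(values=matrix.values.loc[keep], stage=STAGE_RAW)


# ---------------------------------------------------------------------------
# Spearman association
# ---------------------------------------------------------------------------

def _spearman_rows(X: np.ndarray, y: np.ndarray):
    """Spearman rho of each row of X against y, with the t-approximation p.

    Average ranks for ties; rows (or a response) with zero rank variance
    get rho = NaN.  Returns (rho, p) arrays.
    """
    n = y.size
    rx = stats.rankdata(X, axis=1)
    ry = stats.rankdata(y)
    rx = rx - rx.mean(axis=1, keepdims=True)
    ry = ry - ry.mean()
    sx = np.sqrt((rx**2).sum(axis=1))
    sy = np.sqrt((ry**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rx @ ry) / (sx * sy)
    rho = np.where((sx == 0) | (sy == 0), np.nan, rho)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p = np.where(np.abs(rho) >= 1.0, 0.0, p)
    p = np.where(np.isnan(rho), np.nan, p)
    return rho, p


def correlate_gene_drug(matrix: ExpressionMatrix, response: pd.Series,
                        rho_min: float = 0.65, alpha: float = 0.05,
                        ) -> pd.DataFrame:
    """Per-gene Spearman association with one compound's response values.

    ``response`` maps cell line -> GR50 (any monotone transform gives the
    same rho).  Genes with undefined rho (constant expression) are kept
    in the table with a ``skip_reason`` so the omission is auditable.
    """
    if matrix.stage != STAGE_LOG:
        raise BiomarkerError("correlate_gene_drug expects a normalized_log matrix")
    shared = [s for s in matrix.values.columns if s in response.index]
    if len(shared) < 4:
        raise BiomarkerError("need >=4 shared samples between matrix and response")
    y = response.loc[shared].to_numpy(float)
    X = matrix.values[shared].to_numpy(float)
    rho, p = _spearman_rows(X, y)
    out = pd.DataFrame({
        "gene": matrix.values.index,
        "rho": rho,
        "p_value": p,
        "n": len(shared),
    })
    out["direction"] = np.where(out["rho"] < 0, "sensitizing", "resistance")
    out.loc[out["rho"].isna(), "direction"] = None
    out["passes_single"] = (out["rho"].abs() >= rho_min) & (out["p_value"] < alpha)
    out["passes_single"] = out["passes_single"].fillna(False)
    out["skip_reason"] = np.where(out["rho"].isna(), "constant expression or response", None)
    return out


def loo_robust_biomarkers(matrix: ExpressionMatrix, response: pd.Series,
                          rho_fold: float = 0.8) -> pd.DataFrame:
    """Genes robustly associated with response across leave-one-out folds.

    One fold per cell line: drop it, recompute Spearman rho on the rest.
    A gene is selected when |rho| > rho_fold (strict) with a consistent
    sign in every fold; any fold with undefined rho disqualifies the
    gene.  Returns a per-gene table with fold rho extremes and the
    selection flag.
    """
    if matrix.stage != STAGE_LOG:
        raise BiomarkerError("loo_robust_biomarkers expects a normalized_log matrix")
    shared = [s for s in matrix.values.columns if s in response.index]
    if len(shared) < 5:
        raise BiomarkerError("need >=5 shared samples for leave-one-out folds")
    X = matrix.values[shared].to_numpy(float)
    y = response.loc[shared].to_numpy(float)
    n = len(shared)
    fold_rhos = np.empty((X.shape[0], n))
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        fold_rhos[:, i], _ = _spearman_rows(X[:, mask], y[mask])
    defined = np.isfinite(fold_rhos).all(axis=1)
    passes_mag = np.where(defined, (np.abs(fold_rhos) > rho_fold).all(axis=1), False)
    sign_consistent = np.where(
        defined,
        (np.sign(fold_rhos) == np.sign(fold_rhos[:, [0]])).all(axis=1), False)
    selected = passes_mag & sign_consistent
    with np.errstate(invalid="ignore"):
        return pd.DataFrame({
            "gene": matrix.values.index,
            "rho_fold_min": np.nanmin(fold_rhos, axis=1),
            "rho_fold_max": np.nanmax(fold_rhos, axis=1),
            "min_abs_rho": np.abs(fold_rhos).min(axis=1),
            "sign_consistent": sign_consistent,
            "passes_loo": selected,
        })


# ---------------------------------------------------------------------------
# Pre-ranked GSEA
# ---------------------------------------------------------------------------

def enrichment_score(scores: np.ndarray, hit_mask: np.ndarray,
                     weight: float = 1.0):
    """Weighted Kolmogorov-Smirnov running-sum ES for one gene set.

    ``scores`` must be sorted descending; ``hit_mask`` marks set members
    at each rank.  Hits advance the sum by |score|^weight (normalized),
    misses retreat by 1/(N - n_hits); ES is the extremum of larger
    magnitude.  Returns (es, peak_index, running_sum).
    """
    n = scores.size
    n_hit = int(hit_mask.sum())
    if n_hit == 0 or n_hit == n:
        raise BiomarkerError("gene set must hit a strict subset of the ranking")
    w = np.abs(scores) ** weight
    nr = w[hit_mask].sum()
    if nr == 0:
        raise BiomarkerError("all member scores are zero; ES undefined")
    steps = np.where(hit_mask, w / nr, -1.0 / (n - n_hit))
    running = np.cumsum(steps)
    i_max = int(np.argmax(running))
    i_min = int(np.argmin(running))
    if running[i_max] >= -running[i_min]:
        return float(running[i_max]), i_max, running
    return float(running[i_min]), i_min, running


def _null_es_matrix(scores: np.ndarray, n_hit: int, n_perm: int,
                    rng: np.random.Generator, weight: float = 1.0) -> np.ndarray:
    """ES null by gene-label permutation: random same-size hit sets."""
    n = scores.size
    w = np.abs(scores) ** weight
    es = np.empty(n_perm)
    miss_step = -1.0 / (n - n_hit)
    for k in range(n_perm):
        pos = rng.choice(n, size=n_hit, replace=False)
        steps = np.full(n, miss_step)
        steps[pos] = w[pos] / w[pos].sum()
        running = np.cumsum(steps)
        hi, lo = running.max(), running.min()
        es[k] = hi if hi >= -lo else lo
    return es


def gsea_preranked(ranking: pd.Series, gene_sets: dict, n_perm: int = 1000,
                   seed: int = 0, min_size: int = 15, max_size: int = 500,
                   weight: float = 1.0, fdr_max: float = 0.001,
                   es_min: float = 0.5) -> pd.DataFrame:
    """Pre-ranked GSEA over a gene -> score ranking.

    Sets are restricted to genes present in the ranking and dropped
    outside the [min_size, max_size] window (after restriction) or when
    the intersection is empty; dropped sets appear in the output with a
    ``skip_reason``.  NES = ES / mean(|null ES| of matching sign), and
    FDR follows the standard signed-pool procedure on NES.
    Deterministic given ``seed``.
    """
    if ranking.index.duplicated().any():
        raise BiomarkerError("ranking has duplicate gene ids")
    if np.unique(ranking.to_numpy(float)).size < 2:
        raise BiomarkerError("ranking needs >=2 distinct scores")
    # descending by score; gene id breaks ties deterministically
    ordered = ranking.sort_index().sort_values(ascending=False, kind="mergesort")
    genes = ordered.index.to_numpy()
    scores = ordered.to_numpy(float)
    pos_of = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(seed)

    rows, null_by_size = [], {}
    for name in sorted(gene_sets):
        members = [g for g in dict.fromkeys(gene_sets[name]) if g in pos_of]
        if len(members) == 0:
            rows.append({"gene_set": name, "skip_reason": "no genes in ranking"})
            continue
        if not (min_size <= len(members) <= max_size):
            rows.append({"gene_set": name,
                         "skip_reason": f"size {len(members)} outside window"})
            continue
        mask = np.zeros(genes.size, dtype=bool)
        mask[[pos_of[g] for g in members]] = True
        es, peak, _ = enrichment_score(scores, mask, weight)
        if len(members) not in null_by_size:
            null_by_size[len(members)] = _null_es_matrix(
                scores, len(members), n_perm, rng, weight)
        null = null_by_size[len(members)]
        pos_null = null[null > 0]
        neg_null = null[null < 0]
        if es >= 0:
            nes = es / pos_null.mean() if pos_null.size else np.nan
        else:
            nes = -es / neg_null.mean() if neg_null.size else np.nan
        if es >= 0:
            lead = genes[:peak + 1][mask[:peak + 1]]
        else:
            lead = genes[peak:][mask[peak:]]
        rows.append({"gene_set": name, "es": es, "nes": nes,
                     "n_genes": len(members), "leading_edge": list(lead),
                     "skip_reason": None, "_null": null})

    scored = [r for r in rows if r.get("skip_reason") is None]
    if scored:
        # signed-pool FDR on NES: pool every set's normalized null
        pooled = []
        for r in scored:
            null = r.pop("_null")
            pos_null = null[null > 0]
            neg_null = null[null < 0]
            nn = np.where(null >= 0,
                          null / pos_null.mean() if pos_null.size else np.nan,
                          -null / neg_null.mean() if neg_null.size else np.nan)
            pooled.append(nn[np.isfinite(nn)])
        pooled = np.concatenate(pooled)
        obs = np.array([r["nes"] for r in scored])
        for r in scored:
            nes = r["nes"]
            if not np.isfinite(nes):
                r["fdr"] = np.nan
                continue
            # fractions are taken within the matching-sign subsets of the
            # pooled null and of the observed NES, per the standard procedure
            if r["es"] >= 0:
                null_side = pooled[pooled >= 0]
                obs_side = obs[obs >= 0]
                num = np.mean(null_side >= nes) if null_side.size else 0.0
                den = np.mean(obs_side >= nes) if obs_side.size else 1.0
            else:
                null_side = pooled[pooled < 0]
                obs_side = obs[obs < 0]
                num = np.mean(null_side <= nes) if null_side.size else 0.0
                den = np.mean(obs_side <= nes) if obs_side.size else 1.0
            r["fdr"] = float(min(1.0, num / max(den, 1.0 / max(len(obs), 1))))
            r["significant"] = bool(r["fdr"] < fdr_max and abs(r["es"]) > es_min)
    out = pd.DataFrame(rows)
    out.drop(columns=[c for c in ("_null",) if c in out], inplace=True)
    return out
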