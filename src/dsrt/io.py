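"""File formats: plate CSV, confluence CSV, GCT v1.2, GMT, GR tables, YAML truths."""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .growth import ConfluenceSeries

PLATE_COLUMNS = ["plate_id", "well", "row", "col", "role", "compound",
                 "concentration_nM", "cell_line", "signal"]
CONFLUENCE_COLUMNS = ["cell_line", "compound", "concentration_nM", "replicate",
                      "time_h", "confluence_pct", "withdrawal_at_h"]


def write_plate_csv(wells: pd.DataFrame, path):
    wells.to_csv(path, index=False, columns=PLATE_COLUMNS)


def read_plate_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"plate CSV missing columns: {missing}")
    return df


def write_confluence_csv(series_list, path):
    frames = []
    for s in series_list:
        frames.append(pd.DataFrame({
            "cell_line": s.cell_line, "compound": s.compound,
            "concentration_nM": s.concentration, "replicate": s.replicate,
            "time_h": s.times, "confluence_pct": s.confluence,
            "withdrawal_at_h": np.nan if s.withdrawal_at is None else s.withdrawal_at,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_confluence_csv(path) -> list[ConfluenceSeries]:
    df = pd.read_csv(path)
    out = []
    keys = ["cell_line", "compound", "concentration_nM", "replicate"]
    for (line, compound, conc, rep), grp in df.groupby(keys, sort=True):
        grp = grp.sort_values("time_h")
        w = grp["withdrawal_at_h"].iloc[0] if "withdrawal_at_h" in grp else np.nan
        out.append(ConfluenceSeries(
            cell_line=str(line), compound=str(compound),
            concentration=float(conc), replicate=int(rep),
            times=grp["time_h"].to_numpy(float),
            confluence=grp["confluence_pct"].to_numpy(float),
            withdrawal_at=None if pd.isna(w) else float(w)))
    return out


def write_gct(df: pd.DataFrame, path, descriptions=None):
    """Expression matrix to GCT v1.2 (Name, Description, then samples)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{df.shape[0]}\t{df.shape[1]}\n")
        fh.write("Name\tDescription\t" + "\t".join(map(str, df.columns)) + "\n")
        desc = descriptions or {}
        for gene, row in df.iterrows():
            fh.write(str(gene) + "\t" + str(desc.get(gene, "na")) + "\t"
                     + "\t".join(repr(float(v)) for v in row) + "\n")


def read_gct(path) -> pd.DataFrame:
    path = Path(path)
    with path.open() as fh:
        version = fh.readline().strip()
        if not version.startswith("#1.2"):
            raise ValueError(f"unsupported GCT version line: {version!r}")
        n_genes, n_samples = map(int, fh.readline().split()[:2])
        df = pd.read_csv(fh, sep="\t", index_col=0)
    df = df.drop(columns=["Description"])
    if df.shape != (n_genes, n_samples):
        raise ValueError("GCT dimension line disagrees with the table")
    df.index.name = "gene"
    return df


def write_expression_csv(df: pd.DataFrame, path):
    df.to_csv(path, index_label="gene")


def read_expression_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def write_gmt(gene_sets: dict, path, descriptions=None):
    desc = descriptions or {}
    with Path(path).open("w") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([str(name), str(desc.get(name, "na"))]
                               + [str(g) for g in genes]) + "\n")


def read_gmt(path) -> dict:
    """GMT gene sets; duplicate symbols within one set are deduplicated with a warning."""
    sets = {}
    with Path(path).open() as fh:
        for ln in fh:
            parts = ln.rstrip("\n").split("\t")
            if len(parts) < 3:
                if len(parts) <= 1 and not parts[0].strip():
                    continue
                raise ValueError(f"GMT line needs >=3 tab-separated fields: {ln!r}")
            name, genes = parts[0], parts[2:]
            deduped = list(dict.fromkeys(genes))
            if len(deduped) < len(genes):
                warnings.warn(f"gene set {name!r}: duplicate symbols deduplicated")
            sets[name] = deduped
    return sets


def read_gr_csv(path) -> pd.DataFrame:
    """GR-assay table: raw counts (x0, x_ctrl, x_c) or pre-transformed (gr)."""
    df = pd.read_csv(path)
    counts = {"x0", "x_ctrl", "x_c"}.issubset(df.columns)
    if not counts and "gr" not in df.columns:
        raise ValueError("GR CSV needs either x0/x_ctrl/x_c or a gr column")
    return df


def write_truths_yaml(obj, path):
    """Ground-truth sidecar (dataclasses flattened to plain mappings)."""
    def clean(x):
        if hasattr(x, "__dataclass_fields__"):
            return {k: clean(v) for k, v in x.__dict__.items()}
        if isinstance(x, dict):
            return {str(k): clean(v) for k, v in x.items()}
        if isinstance(x, (list, tuple)):
            return [clean(v) for v in x]
        if isinstance(x, (np.floating, np.integer)):
            return x.item()
        if isinstance(x, np.ndarray):
            return x.tolist()
        if isinstance(x, pd.DataFrame):
            return {str(i): {str(c): float(v) for c, v in row.items()}
                    for i, row in x.iterrows()}
        return x
    with Path(path).open("w") as fh:
        yaml.safe_dump(clean(obj), fh, sort_keys=False)


def read_yaml(path):
    with Path(path).open() as fh:
        return yaml.safe_load(fh)
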