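"""Regional normalisation of per-site signals and gene-body deltas.

Per-site estimates are summarised in non-overlapping 1000-bp bins and over
gene bodies. For 5mC and 5hmC the regional signal is the depth-weighted
mean of site levels — the deconvolved analogue of TNC / (TNC + TNT) on raw
counts, to which it reduces exactly for a single-library signal. For
5fC/caC, whose genomic density is far lower, the regional signal is the
unweighted arithmetic mean of corrected levels over *retained* sites only.

Gene-body deltas compare the case and control regional levels per gene;
the sign of ``delta = level_case - level_control`` defines the gain/loss
direction used by the integration stage.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synthetic import GeneModel, assign_genes

DEFAULT_BIN_SIZE = 1000
DEFAULT_MIN_SITES = 3

MODIFICATIONS = ("5mC", "5hmC", "5fC/caC")


def _site_table(df: pd.DataFrame, modification: str) -> pd.DataFrame:
    """Normalise an estimate/call table to (chrom, pos, level, weight).

    5mC/5hmC rows come from the joint-estimate table and are weighted by
    the library depth backing the level (oxBS depth for 5mC, BS depth for
    5hmC). 5fC/caC rows come from the caller output restricted to retained
    sites, weight 1 (unweighted mean downstream).
    """
    if modification == "5mC":
        out = df[["chrom", "pos"]].copy()
        out["level"] = df["p_m"].to_numpy()
        out["weight"] = df["depth_ox"].to_numpy(dtype=float)
    elif modification == "5hmC":
        out = df[["chrom", "pos"]].copy()
        out["level"] = df["p_h"].to_numpy()
        out["weight"] = df["depth_bs"].to_numpy(dtype=float)
    elif modification == "5fC/caC":
        kept = df[df["retained"]] if "retained" in df.columns else df
        out = kept[["chrom", "pos"]].copy()
        out["level"] = kept["level"].to_numpy()
        out["weight"] = 1.0
    else:
        raise ValueError(f"unknown modification {modification!r}")
    return out


def bin_signals(
    df: pd.DataFrame,
    modification: str,
    bin_size: int = DEFAULT_BIN_SIZE,
) -> pd.DataFrame:
    """Aggregate per-site levels into non-overlapping genomic bins.

    Bins are half-open ``[k*bin_size, (k+1)*bin_size)`` anchored at 0; a
    bin appears in the output only when at least one passing site falls in
    it (its signal is otherwise undefined). Signal is the weighted mean of
    site levels with the modification's weighting convention (depth for
    5mC/5hmC, uniform for 5fC/caC over retained sites).

    Returns columns: chrom, start, end, signal, n_sites, depth.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    st = _site_table(df, modification)
    if st.empty:
        return pd.DataFrame(columns=["chrom", "start", "end", "signal", "n_sites", "depth"])
    st = st.copy()
    st["start"] = (st["pos"] // bin_size) * bin_size
    st["wl"] = st["weight"] * st["level"]
    g = st.groupby(["chrom", "start"], as_index=False).agg(
        wl=("wl", "sum"), w=("weight", "sum"), n_sites=("level", "size")
    )
    g["end"] = g["start"] + bin_size
    g["signal"] = g["wl"] / g["w"]
    g["depth"] = g["w"]
    return g[["chrom", "start", "end", "signal", "n_sites", "depth"]]


def _gene_levels(
    df: pd.DataFrame,
    genes: list[GeneModel],
    modification: str,
) -> pd.DataFrame:
    st = _site_table(df, modification)
    if st.empty:
        return pd.DataFrame(columns=["gene_id", "level", "n_sites"])
    st = st.copy()
    st["gene_id"] = assign_genes(st, genes)
    st = st[st["gene_id"] != ""]
    st["wl"] = st["weight"] * st["level"]
    g = st.groupby("gene_id", as_index=False).agg(
        wl=("wl", "sum"), w=("weight", "sum"), n_sites=("level", "size")
    )
    g["level"] = g["wl"] / g["w"]
    return g[["gene_id", "level", "n_sites"]]


def gene_body_delta(
    case_df: pd.DataFrame,
    control_df: pd.DataFrame,
    genes: list[GeneModel],
    modification: str,
    min_sites: int = DEFAULT_MIN_SITES,
    pseudo: float = 0.01,
) -> pd.DataFrame:
    """Per-gene signed methylation change between case and control.

    Gene bodies are the full ``[start, end)`` interval. ``delta`` is the
    arithmetic difference of the gene-body levels and drives ``direction``
    (gain/loss/no-change); a fold ``ratio`` on pseudo-counted levels is
    reported alongside. Genes with fewer than ``min_sites`` passing sites
    in either group are emitted with ``defined = False`` and NaN delta, to
    be excluded downstream.

    Returns columns: gene_id, modification, level_case, level_control,
    delta, ratio, direction, n_sites_case, n_sites_control, defined.
    """
    known = set(case_df.get("chrom", pd.Series(dtype=str))) | set(
        control_df.get("chrom", pd.Series(dtype=str))
    )
    if known:
        for g in genes:
            if g.chrom not in known:
                raise ValueError(f"gene {g.gene_id} on unknown chromosome {g.chrom}")

    case = _gene_levels(case_df, genes, modification).set_index("gene_id")
    ctrl = _gene_levels(control_df, genes, modification).set_index("gene_id")
    rows = []
    for g in genes:
        lc = case["level"].get(g.gene_id, np.nan)
        l0 = ctrl["level"].get(g.gene_id, np.nan)
        nc = int(case["n_sites"].get(g.gene_id, 0))
        n0 = int(ctrl["n_sites"].get(g.gene_id, 0))
        defined = nc >= min_sites and n0 >= min_sites
        if defined:
            delta = lc - l0
            ratio = (lc + pseudo) / (l0 + pseudo)
            direction = "gain" if delta > 0 else ("loss" if delta < 0 else "no-change")
        else:
            delta, ratio, direction = np.nan, np.nan, "undefined"
        rows.append(
            dict(
                gene_id=g.gene_id, modification=modification,
                level_case=lc, level_control=l0, delta=delta, ratio=ratio,
                direction=direction, n_sites_case=nc, n_sites_control=n0,
                defined=defined,
            )
        )
    return pd.DataFrame(rows)


def write_bedgraph(bins: pd.DataFrame, path) -> None:
    bins[["chrom", "start", "end", "signal"]].to_csv(
        path, sep="\t", index=False, header=False, float_format="%.6g"
    )


def write_deltas(deltas: pd.DataFrame, path) -> None:
    deltas.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_deltas(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
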