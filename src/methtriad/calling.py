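"""Per-site methylome calling from paired BS/oxBS and MAB-seq counts.

Two estimators:

1. **Joint 5mC/5hmC maximum likelihood** from a BS/oxBS count pair. With
   ideal conversion the BS library reads C with probability ``p_m + p_h``
   and the oxBS library with probability ``p_m``, so the joint likelihood is

       Binom(k_bs; n_bs, p_m + p_h) * Binom(k_ox; n_ox, p_m)

   maximised over the simplex ``{p_m >= 0, p_h >= 0, p_m + p_h <= 1}``.
   The interior solution is the method-of-moments closed form
   ``p_m = k_ox/n_ox``, ``p_h = k_bs/n_bs - k_ox/n_ox``; the only
   reachable constraint violation is ``p_h < 0`` (the interior p_m is a
   proportion, and p_m + p_h = k_bs/n_bs <= 1), in which case the MLE sits
   on the ``p_h = 0`` edge where both libraries measure the same
   proportion and the pooled estimate ``(k_bs + k_ox)/(n_bs + n_ox)``
   maximises the product likelihood.

2. **5fC/5caC binomial calling** from MAB-seq T-counts against the
   bisulfite non-conversion null. Under the null (no 5fC/caC) every read is
   protected by M.SssI and reads T only through non-conversion, so
   ``T ~ Binomial(n, e)`` with ``e = 0.0164`` by default. The exact upper
   tail ``P(X >= t)`` is the site p-value; the corrected level is
   ``max(0, (t/n - e) / (1 - e))``. Sites are retained when depth >= 10,
   p < 0.01 and Benjamini-Hochberg q < 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEFAULT_MIN_DEPTH = 10
DEFAULT_E = 0.0164
DEFAULT_ALPHA = 0.01
DEFAULT_FDR = 0.01


@dataclass(frozen=True)
class ModificationEstimate:
    chrom: str
    pos: int
    p_m_hat: float
    p_h_hat: float
    depth_bs: int
    depth_ox: int
    boundary_flag: bool


def _mask_trees(mask) -> dict:
    trees: dict[str, IntervalTree] = {}
    for iv in mask or ():
        chrom, start, end = iv[0], int(iv[1]), int(iv[2])
        if end <= start:
            raise ValueError(f"malformed mask interval {chrom}:{start}-{end}")
        trees.setdefault(chrom, IntervalTree()).addi(start, end)
    return trees


def filter_and_mask(
    records: pd.DataFrame,
    min_depth: int = DEFAULT_MIN_DEPTH,
    mask=None,
) -> pd.DataFrame:
    """Depth-filter count records and drop sites in masked intervals.

    Records with ``n_C + n_T < min_depth`` are removed. Positions falling in
    any 0-based half-open mask interval (a variant blacklist) are removed
    across all libraries. For the BS/oxBS pair, a site is kept only when it
    passes the depth filter in *both* libraries of the same group and
    replicate, so the downstream joint estimator always sees a
    coordinate-matched pair.
    """
    df = records.copy()
    depth = df["n_C"] + df["n_T"]
    df = df[depth >= min_depth]

    trees = _mask_trees(mask)
    if trees:
        keep = np.ones(len(df), dtype=bool)
        pos = df["pos"].to_numpy()
        chroms = df["chrom"].to_numpy()
        for chrom, tree in trees.items():
            sel = chroms == chrom
            if sel.any():
                hit = np.fromiter(
                    (bool(tree.overlaps_point(int(p))) for p in pos[sel]),
                    dtype=bool,
                    count=int(sel.sum()),
                )
                keep[np.flatnonzero(sel)[hit]] = False
        df = df[keep]

    # coordinate-match the BS/oxBS pair within (chrom, pos, group, replicate)
    pair = df[df["library"].isin(["BS", "oxBS"])]
    if not pair.empty:
        key = ["chrom", "pos", "group", "replicate"]
        nlib = pair.groupby(key)["library"].nunique()
        complete = nlib[nlib == 2].index
        keep_pair = pd.MultiIndex.from_frame(pair[key]).isin(complete)
        df = pd.concat([pair[keep_pair], df[df["library"] == "MAB"]])
        df = df.sort_index()
    return df.reset_index(drop=True)


def estimate_mh(bs: tuple[int, int], oxbs: tuple[int, int]) -> tuple[float, float, bool]:
    """Constrained joint MLE of (p_m, p_h) from one BS/oxBS count pair.

    Returns ``(p_m_hat, p_h_hat, boundary_flag)``; the flag is set when the
    interior closed form violates ``p_h >= 0`` and the pooled boundary
    solution is returned instead.
    """
    k_bs, n_bs = bs
    k_ox, n_ox = oxbs
    if n_bs <= 0 or n_ox <= 0:
        raise ValueError("estimate undefined: zero depth in BS or oxBS library")
    if not (0 <= k_bs <= n_bs and 0 <= k_ox <= n_ox):
        raise ValueError("C-counts must lie in [0, depth]")
    p_m = k_ox / n_ox
    p_h = k_bs / n_bs - p_m
    if p_h < 0:
        p_m = (k_bs + k_ox) / (n_bs + n_ox)
        return p_m, 0.0, True
    return p_m, p_h, False


def estimate_mh_cohort(records: pd.DataFrame) -> pd.DataFrame:
    """Vectorised joint 5mC/5hmC estimation over a filtered count table.

    Counts are pooled across replicates per (chrom, pos, group, library)
    before estimation. Only sites with both libraries present (guaranteed
    after :func:`filter_and_mask`) are emitted.

    Returns columns: chrom, pos, group, p_m, p_h, depth_bs, depth_ox,
    boundary_flag.
    """
    pair = records[records["library"].isin(["BS", "oxBS"])]
    if pair.empty:
        return pd.DataFrame(
            columns=["chrom", "pos", "group", "p_m", "p_h",
                     "depth_bs", "depth_ox", "boundary_flag"]
        )
    agg = (
        pair.groupby(["chrom", "pos", "group", "library"], as_index=False)[["n_C", "n_T"]]
        .sum()
    )
    wide = agg.pivot_table(
        index=["chrom", "pos", "group"], columns="library",
        values=["n_C", "n_T"], aggfunc="first",
    )
    wide = wide.dropna()
    k_bs = wide[("n_C", "BS")].to_numpy(dtype=float)
    n_bs = k_bs + wide[("n_T", "BS")].to_numpy(dtype=float)
    k_ox = wide[("n_C", "oxBS")].to_numpy(dtype=float)
    n_ox = k_ox + wide[("n_T", "oxBS")].to_numpy(dtype=float)

    p_m = k_ox / n_ox
    p_h = k_bs / n_bs - p_m
    boundary = p_h < 0
    pooled = (k_bs + k_ox) / (n_bs + n_ox)
    p_m = np.where(boundary, pooled, p_m)
    p_h = np.where(boundary, 0.0, p_h)

    out = wide.index.to_frame(index=False)
    out["p_m"] = p_m
    out["p_h"] = p_h
    out["depth_bs"] = n_bs.astype(np.int64)
    out["depth_ox"] = n_ox.astype(np.int64)
    out["boundary_flag"] = boundary
    return out


def mh_loglik(k_bs, n_bs, k_ox, n_ox, p_m, p_h) -> float:
    """Joint BS/oxBS binomial log-likelihood at (p_m, p_h); test oracle hook."""
    return float(
        stats.binom.logpmf(k_bs, n_bs, min(p_m + p_h, 1.0))
        + stats.binom.logpmf(k_ox, n_ox, p_m)
    )


def call_fcac(t: int, n: int, e: float = DEFAULT_E) -> tuple[float, float]:
    """Exact binomial upper-tail p-value and corrected 5fC/caC level.

    ``p = P(X >= t)`` for ``X ~ Binomial(n, e)`` (tail includes the
    observed count); ``level = max(0, (t/n - e)/(1 - e))`` clipped to 1.
    """
    if n < 1:
        raise ValueError("depth must be >= 1")
    if not (0 <= t <= n):
        raise ValueError("t_count must lie in [0, depth]")
    if not (0.0 <= e < 1.0):
        raise ValueError("non-conversion rate must lie in [0, 1)")
    p = float(stats.binom.sf(t - 1, n, e))
    level = min(max(0.0, (t / n - e) / (1.0 - e)), 1.0)
    return min(p, 1.0), level


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving with input."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_fcac_cohort(
    records: pd.DataFrame,
    e: float = DEFAULT_E,
    min_depth: int = DEFAULT_MIN_DEPTH,
    alpha: float = DEFAULT_ALPHA,
    fdr: float = DEFAULT_FDR,
) -> pd.DataFrame:
    """5fC/caC calls over a MAB count table, with BH across passing sites.

    Counts are pooled across replicates per (chrom, pos, group); sites
    below ``min_depth`` after pooling are dropped before testing, so BH is
    computed over depth-passing sites only. ``retained`` requires depth >=
    min_depth, p < alpha and q < fdr (strict).

    Returns columns: chrom, pos, group, depth, t, p, q, level, retained.
    """
    mab = records[records["library"] == "MAB"]
    cols = ["chrom", "pos", "group", "depth", "t", "p", "q", "level", "retained"]
    if mab.empty:
        return pd.DataFrame(columns=cols)
    agg = mab.groupby(["chrom", "pos", "group"], as_index=False)[["n_C", "n_T"]].sum()
    agg["depth"] = agg["n_C"] + agg["n_T"]
    agg = agg[agg["depth"] >= min_depth].reset_index(drop=True)
    if agg.empty:
        return pd.DataFrame(columns=cols)

    t = agg["n_T"].to_numpy()
    n = agg["depth"].to_numpy()
    p = np.minimum(stats.binom.sf(t - 1, n, e), 1.0)
    level = np.clip((t / n - e) / (1.0 - e), 0.0, 1.0)
    q = bh_fdr(p)

    out = agg[["chrom", "pos", "group"]].copy()
    out["depth"] = n
    out["t"] = t
    out["p"] = p
    out["q"] = q
    out["level"] = level
    out["retained"] = (p < alpha) & (q < fdr)
    return out
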