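"""RPKM normalisation, differential expression, correlation and set tests.

The DE caller applies the fold-change > 1.5 and p < 0.05 thresholds on
RPKM. The builtin test is a two-sided Welch t-test on log2(RPKM + 0.5) —
an explicit, documented stand-in for an exact-test DE engine; an
``external`` path ingests any precomputed per-gene (log2FC, p) table and
applies only the thresholds, so a dedicated DE package's output can be
slotted in unchanged.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_FC_THRESHOLD = 1.5
DEFAULT_P_THRESHOLD = 0.05
DEFAULT_EXPRESSION_MIN = 1.0
PSEUDO = 0.5


def compute_rpkm(
    counts: pd.DataFrame,
    gene_lengths: pd.Series,
    library_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """Reads per kilobase of gene per million mapped reads.

    ``RPKM = count / ((length/1e3) * (lib_size/1e6))``. Library sizes
    default to per-sample column sums of the count matrix.
    """
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = counts.index[lengths.isna()][:5].tolist()
        raise ValueError(f"missing gene lengths, e.g. {missing}")
    if (lengths < 1).any():
        raise ValueError("gene lengths must be >= 1 bp")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    library_sizes = library_sizes.reindex(counts.columns)
    if (library_sizes < 1).any() or library_sizes.isna().any():
        raise ValueError("library sizes must be >= 1 read per sample")
    denom = np.outer(lengths.to_numpy() / 1e3, library_sizes.to_numpy() / 1e6)
    return pd.DataFrame(
        counts.to_numpy() / denom, index=counts.index, columns=counts.columns
    )


def de_genes(
    rpkm: pd.DataFrame,
    groups: pd.Series,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    method: str = "builtin",
    external_table: pd.DataFrame | None = None,
    case: str = "case",
    control: str = "control",
) -> pd.DataFrame:
    """Differential expression with strict FC and p cutoffs.

    A gene is ``significant`` iff ``fold_change > fc_threshold`` or
    ``fold_change < 1/fc_threshold`` (strict), and ``p < p_threshold``
    (strict). Fold change is the ratio of group-mean RPKM with pseudo-count
    0.5. ``method='external'`` takes ``external_table`` (columns gene_id,
    log2fc, p) and applies only the thresholds.

    Returns columns: gene_id, mean_case, mean_control, fc, log2fc, p,
    significant.
    """
    if method == "external":
        if external_table is None:
            raise ValueError("external method requires external_table")
        t = external_table.copy()
        t["fc"] = np.exp2(t["log2fc"])
        t["significant"] = (
            ((t["fc"] > fc_threshold) | (t["fc"] < 1.0 / fc_threshold))
            & (t["p"] < p_threshold)
        )
        return t
    if method != "builtin":
        raise ValueError(f"unknown DE method {method!r}")

    case_cols = groups.index[groups == case]
    ctrl_cols = groups.index[groups == control]
    if len(case_cols) < 2 or len(ctrl_cols) < 2:
        raise ValueError("builtin DE test needs >= 2 samples per group")

    a = rpkm[case_cols].to_numpy()
    b = rpkm[ctrl_cols].to_numpy()
    la, lb = np.log2(a + PSEUDO), np.log2(b + PSEUDO)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(la, lb, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)  # zero-variance-in-both degenerate case

    mean_case = a.mean(axis=1)
    mean_control = b.mean(axis=1)
    fc = (mean_case + PSEUDO) / (mean_control + PSEUDO)
    out = pd.DataFrame(
        {
            "gene_id": rpkm.index,
            "mean_case": mean_case,
            "mean_control": mean_control,
            "fc": fc,
            "log2fc": np.log2(fc),
            "p": p,
        }
    )
    out["significant"] = (
        ((out["fc"] > fc_threshold) | (out["fc"] < 1.0 / fc_threshold))
        & (out["p"] < p_threshold)
    )
    return out


def profile_correlation(
    matrix_a: pd.DataFrame,
    matrix_b: pd.DataFrame,
    expression_min: float = DEFAULT_EXPRESSION_MIN,
) -> pd.DataFrame:
    """Pearson r between every sample pair of two normalised matrices.

    For each (sample_a, sample_b) pair, genes shared between the matrices
    and expressed above ``expression_min`` (strict) in at least one of the
    two profiles enter the correlation, computed on log2(value + 0.5).
    Raises when a pair has fewer than 3 qualifying genes.
    """
    shared = matrix_a.index.intersection(matrix_b.index)
    a, b = matrix_a.loc[shared], matrix_b.loc[shared]
    out = pd.DataFrame(index=a.columns, columns=b.columns, dtype=float)
    for sa in a.columns:
        for sb in b.columns:
            x, y = a[sa].to_numpy(dtype=float), b[sb].to_numpy(dtype=float)
            use = (x > expression_min) | (y > expression_min)
            if use.sum() < 3:
                raise ValueError(
                    f"fewer than 3 shared expressed genes for ({sa}, {sb})"
                )
            r, _ = stats.pearsonr(np.log2(x[use] + PSEUDO), np.log2(y[use] + PSEUDO))
            out.loc[sa, sb] = r
    return out


def overlap_sets(named_sets: dict) -> dict:
    """Exact counts for every Venn region of 2-4 named sets.

    Region keys are frozensets of member names; the count is of elements
    belonging to exactly those sets. Regions partition the union.
    """
    if not (2 <= len(named_sets) <= 4):
        raise ValueError("overlap_sets supports 2 to 4 sets")
    names = list(named_sets)
    sets = {k: set(v) for k, v in named_sets.items()}
    regions: dict[frozenset, int] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(sets[c] for c in combo))
            outside = set.union(set(), *(sets[c] for c in names if c not in combo))
            regions[frozenset(combo)] = len(inside - outside)
    return regions


def hypergeometric_enrichment(query_set, reference_set, universe) -> float:
    """Upper-tail hypergeometric p for the query/reference overlap.

    ``P(overlap >= observed)`` when ``|query|`` genes are drawn without
    replacement from a universe of which ``|reference|`` are marked.
    """
    universe = set(universe)
    query = set(query_set)
    reference = set(reference_set)
    if not query <= universe or not reference <= universe:
        raise ValueError("query and reference must be subsets of the universe")
    k = len(query & reference)
    return float(stats.hypergeom.sf(k - 1, len(universe), len(reference), len(query)))
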