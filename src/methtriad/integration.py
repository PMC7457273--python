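"""Methylation-expression integration and independent-cohort validation.

Genes are partitioned by the sign of their gene-body methylation change
(gain vs loss; no-change genes belong to neither stratum) and the two
strata's expression log2 fold-changes are compared with a two-sided
Wilcoxon rank-sum test — exact for small samples, tie-corrected normal
approximation otherwise. Direction-matched signature genes are the
intersection of two cohorts' significant DE sets split by agreement of
fold-change sign. Trend concordance against an independent cohort is the
fraction of genes whose signed methylation delta agrees in sign.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

EXACT_MAX_N = 20


def significance_stars(p: float) -> str:
    """Star convention: p<0.001 ***, p<0.01 **, p<0.05 *, else ns."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class StratificationResult:
    modification: str
    n_gain: int
    n_loss: int
    gain_log2fc: np.ndarray
    loss_log2fc: np.ndarray
    statistic: float
    p_value: float
    stars: str = field(init=False)
    method: str = "asymptotic"

    def __post_init__(self):
        self.stars = significance_stars(self.p_value)

    def to_dict(self) -> dict:
        return {
            "modification": self.modification,
            "n_gain": self.n_gain,
            "n_loss": self.n_loss,
            "median_log2fc_gain": float(np.median(self.gain_log2fc)),
            "median_log2fc_loss": float(np.median(self.loss_log2fc)),
            "statistic": self.statistic,
            "p_value": self.p_value,
            "stars": self.stars,
            "method": self.method,
        }


@dataclass
class ConcordanceReport:
    n_tested: int
    n_consistent: int
    fraction: float
    flags: pd.DataFrame  # gene_id, delta_discovery, delta_validation, consistent

    def to_dict(self) -> dict:
        return {
            "n_tested": self.n_tested,
            "n_consistent": self.n_consistent,
            "fraction": self.fraction,
        }


def rank_sum_test(x, y) -> tuple[float, float, str]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) with method selection.

    Exact enumeration when both samples have <= 20 observations and no
    ties; exact permutation of the U statistic when ties are present at
    that size; tie-corrected normal approximation with continuity
    correction for larger samples. Returns (U, p, method).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("rank-sum test undefined for an empty stratum")
    small = x.size <= EXACT_MAX_N and y.size <= EXACT_MAX_N
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    if small and not has_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return float(res.statistic), float(res.pvalue), "exact"
    if small:
        def stat(a, b):
            return stats.mannwhitneyu(a, b, alternative="two-sided",
                                      method="asymptotic").statistic
        perm = stats.permutation_test(
            (x, y), stat, permutation_type="independent",
            alternative="two-sided", n_resamples=np.inf,
        )
        return float(perm.statistic), float(min(perm.pvalue, 1.0)), "exact-permutation"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue), "asymptotic"


def stratify_by_methylation(
    de_results: pd.DataFrame,
    deltas: pd.DataFrame,
    modification: str = "5mC",
) -> StratificationResult:
    """Compare expression log2FC between methylation-gain and -loss genes.

    Genes are joined by id; only genes with a defined delta enter, and
    no-change (delta == 0) genes belong to neither stratum. The two
    log2FC samples are compared with the two-sided rank-sum test.
    """
    d = deltas[deltas["modification"] == modification] if "modification" in deltas else deltas
    d = d[d["direction"].isin(["gain", "loss"])]
    merged = d.merge(de_results[["gene_id", "log2fc"]], on="gene_id")
    gain = merged.loc[merged["direction"] == "gain", "log2fc"].to_numpy()
    loss = merged.loc[merged["direction"] == "loss", "log2fc"].to_numpy()
    if gain.size == 0 or loss.size == 0:
        raise ValueError("empty gain or loss stratum: test undefined")
    u, p, method = rank_sum_test(gain, loss)
    return StratificationResult(
        modification=modification, n_gain=gain.size, n_loss=loss.size,
        gain_log2fc=gain, loss_log2fc=loss, statistic=u, p_value=p,
        method=method,
    )


def select_signature(
    de_tissue: pd.DataFrame,
    de_model: pd.DataFrame,
    direction_match: bool = True,
) -> dict:
    """Shared significant DE genes between two cohorts, split by direction.

    Returns ``up_up`` and ``down_down`` gene lists (significant in both
    with agreeing fold-change sign), the ``discordant`` count, and the
    ``raw_overlap`` (significance-only intersection, returned whole when
    ``direction_match`` is False).
    """
    sig_t = de_tissue[de_tissue["significant"]].drop_duplicates("gene_id")
    sig_m = de_model[de_model["significant"]].drop_duplicates("gene_id")
    merged = sig_t.merge(sig_m, on="gene_id", suffixes=("_tissue", "_model"))
    raw = sorted(merged["gene_id"])
    up_up = sorted(
        merged.loc[(merged["log2fc_tissue"] > 0) & (merged["log2fc_model"] > 0), "gene_id"]
    )
    down_down = sorted(
        merged.loc[(merged["log2fc_tissue"] < 0) & (merged["log2fc_model"] < 0), "gene_id"]
    )
    result = {
        "raw_overlap": raw,
        "up_up": up_up,
        "down_down": down_down,
        "discordant": len(raw) - len(up_up) - len(down_down),
    }
    if not direction_match:
        result["signature"] = raw
    else:
        result["signature"] = sorted(up_up + down_down)
    return result


def trend_concordance(
    discovery: pd.DataFrame,
    validation: pd.DataFrame,
) -> ConcordanceReport:
    """Sign agreement of per-gene methylation deltas across two cohorts.

    A gene is testable when its delta is defined and nonzero in both
    cohorts, and consistent when the two signs agree.
    """
    d = discovery[["gene_id", "delta"]].rename(columns={"delta": "delta_discovery"})
    v = validation[["gene_id", "delta"]].rename(columns={"delta": "delta_validation"})
    m = d.merge(v, on="gene_id")
    m = m.dropna()
    m = m[(m["delta_discovery"] != 0) & (m["delta_validation"] != 0)]
    if m.empty:
        raise ValueError("no testable genes: concordance report undefined")
    m["consistent"] = np.sign(m["delta_discovery"]) == np.sign(m["delta_validation"])
    n_tested = len(m)
    n_consistent = int(m["consistent"].sum())
    return ConcordanceReport(
        n_tested=n_tested,
        n_consistent=n_consistent,
        fraction=n_consistent / n_tested,
        flags=m.reset_index(drop=True),
    )
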