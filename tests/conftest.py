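import numpy as np
import pytest

from methtriad import (
    simulate_counts,
    simulate_expression,
    simulate_genome,
    simulate_truth,
)


@pytest.fixture(scope="session")
def small_genome():
    """30 genes, ~3 kb sites over ~100 kb: shared by unit tests."""
    genes, sites = simulate_genome(
        n_genes=30, gene_length_range=(1500, 3000), cpg_density=0.02,
        intergenic_gap=1000, seed=11,
    )
    return genes, sites


@pytest.fixture(scope="session")
def planted_truth(small_genome):
    genes, sites = small_genome
    gids = [g.gene_id for g in genes]
    return simulate_truth(
        sites, genes,
        planted={"gain_genes": gids[:5], "loss_genes": gids[5:10], "delta": 0.2},
        log2fc_mag=1.0,
        seed=12,
    )


@pytest.fixture(scope="session")
def counts(planted_truth):
    return simulate_counts(planted_truth, depth_model=(30, 5), seed=13)


@pytest.fixture(scope="session")
def expression(small_genome, planted_truth):
    genes, _ = small_genome
    return simulate_expression(
        genes, planted_truth, n_per_group=5, nb_dispersion=0.05, seed=14
    )


def grid_loglik_max(k_bs, n_bs, k_ox, n_ox, step=1e-3):
    """Independent grid-search oracle for the joint BS/oxBS likelihood.

    The joint log-likelihood separates as f(p_m) + g(s) with s = p_m + p_h,
    maximised over the simplex (s >= p_m); the grid maximum over both axes
    at the given step is found via a suffix-max over g.
    """
    p = np.arange(0.0, 1.0 + step / 2, step)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = k_ox * np.log(p) + (n_ox - k_ox) * np.log1p(-p)
        g = k_bs * np.log(p) + (n_bs - k_bs) * np.log1p(-p)
    f = np.where(np.isnan(f), -np.inf, f)
    g = np.where(np.isnan(g), -np.inf, g)
    # 0*log(0) = 0 convention at the boundary
    if k_ox == 0:
        f[0] = (n_ox - k_ox) * np.log1p(-p[0])
    if k_ox == n_ox:
        f[-1] = k_ox * np.log(p[-1])
    if k_bs == 0:
        g[0] = (n_bs - k_bs) * np.log1p(-p[0])
    if k_bs == n_bs:
        g[-1] = k_bs * np.log(p[-1])
    g_suffix = np.maximum.accumulate(g[::-1])[::-1]
    return float(np.max(f + g_suffix))


def loglik_kernel(k_bs, n_bs, k_ox, n_ox, p_m, p_h):
    """Joint log-likelihood without binomial coefficients (same kernel as
    the grid oracle, so values are directly comparable)."""
    def term(k, n, p):
        out = 0.0
        if k > 0:
            out += k * np.log(p)
        if n - k > 0:
            out += (n - k) * np.log1p(-p)
        return out
    s = min(p_m + p_h, 1.0)
    return term(k_ox, n_ox, p_m) + term(k_bs, n_bs, s)
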