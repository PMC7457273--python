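"""Tests for the synthetic genome/truth/counts/expression generators."""

import numpy as np
import pandas as pd
import pytest

from methtriad import (
    GeneModel,
    simulate_counts,
    simulate_expression,
    simulate_genome,
    simulate_truth,
    simulate_validation_deltas,
    trend_concordance,
)


class TestSimulateGenome:
    def test_empty_case(self):
        genes, sites = simulate_genome(0, seed=1)
        assert genes == [] and sites.empty

    def test_no_overlap_and_length_range(self):
        genes, _ = simulate_genome(50, gene_length_range=(1000, 2000), seed=7)
        for a, b in zip(genes, genes[1:]):
            assert a.end <= b.start
        assert all(1000 <= g.length <= 2000 for g in genes)

    def test_site_density_mean(self):
        """Bernoulli(0.02) per bp: mean site count over seeds ~ 0.02 * span."""
        density, counts, spans = 0.02, [], []
        for seed in range(100):
            genes, sites = simulate_genome(
                20, gene_length_range=(4000, 4000), cpg_density=density,
                intergenic_gap=1000, seed=seed,
            )
            spans.append(genes[-1].end + 1000)
            counts.append(len(sites))
        span = spans[0]
        expect = density * span
        se = np.sqrt(span * density * (1 - density) / 100)
        assert abs(np.mean(counts) - expect) < 3 * se

    @pytest.mark.parametrize("kwargs", [
        dict(n_genes=-1), dict(cpg_density=0.0), dict(cpg_density=0.3),
        dict(gene_length_range=(0, 10)), dict(gene_length_range=(10, 5)),
    ])
    def test_parameter_errors(self, kwargs):
        with pytest.raises(ValueError):
            simulate_genome(**{"n_genes": 5, **kwargs})

    def test_gene_model_invariants(self):
        with pytest.raises(ValueError):
            GeneModel("g", "c", 10, 10)
        with pytest.raises(ValueError):
            GeneModel("g", "c", -1, 10)


class TestSimulateTruth:
    def test_null_delta_identical_groups(self, small_genome):
        genes, sites = small_genome
        truth = simulate_truth(sites, genes, planted={"delta": 0.0}, seed=3)
        pd.testing.assert_frame_equal(truth.levels["case"], truth.levels["control"])

    def test_planted_shift_pre_clipping(self, small_genome):
        genes, sites = small_genome
        gid = genes[0].gene_id
        truth = simulate_truth(
            sites, genes, planted={"gain_genes": [gid], "delta": 0.2}, seed=3
        )
        in_gene = truth.sites["gene_id"] == gid
        ctrl = truth.levels["control"].loc[in_gene.to_numpy(), "p_m"]
        case = truth.levels["case"].loc[in_gene.to_numpy(), "p_m"]
        shifted = np.minimum(ctrl + 0.2, 1.0)
        assert case.to_numpy() == pytest.approx(shifted.to_numpy())

    def test_simplex_everywhere(self, planted_truth):
        for lv in planted_truth.levels.values():
            arr = lv[["p_m", "p_h", "p_f"]].to_numpy()
            assert (arr >= 0).all() and (arr <= 1).all()
            assert (arr.sum(axis=1) <= 1 + 1e-12).all()

    def test_symmetric_beta_mean(self, small_genome):
        genes, sites = small_genome
        truth = simulate_truth(
            sites, genes, baseline_beta={"m": (3, 3), "h": (1, 1e9), "f": (1, 1e9)},
            seed=5,
        )
        assert truth.levels["control"]["p_m"].mean() == pytest.approx(0.5, abs=0.02)

    def test_overlapping_gain_loss_rejected(self, small_genome):
        genes, sites = small_genome
        gid = genes[0].gene_id
        with pytest.raises(ValueError):
            simulate_truth(
                sites, genes,
                planted={"gain_genes": [gid], "loss_genes": [gid], "delta": 0.1},
            )


class TestSimulateCounts:
    def test_determinism(self, planted_truth):
        a = simulate_counts(planted_truth, seed=9)
        b = simulate_counts(planted_truth, seed=9)
        pd.testing.assert_frame_equal(a, b)
        c = simulate_counts(planted_truth, seed=10)
        assert not a.equals(c)

    def test_mab_null_t_fraction_matches_inefficiency(self, small_genome):
        """With p_f = 0, the aggregate MAB T-fraction is the 1.64%
        non-conversion inefficiency."""
        genes, sites = small_genome
        truth = simulate_truth(
            sites, genes, baseline_beta={"f": (1, 1e12)}, seed=21
        )
        counts = simulate_counts(truth, depth_model=(40, 50), seed=22)
        mab = counts[counts["library"] == "MAB"]
        total = (mab["n_C"] + mab["n_T"]).sum()
        frac = mab["n_T"].sum() / total
        se = np.sqrt(0.0164 * (1 - 0.0164) / total)
        assert abs(frac - 0.0164) < 4 * se

    def test_oxbs_all_c_when_pm_one(self, small_genome):
        genes, sites = small_genome
        truth = simulate_truth(
            sites, genes,
            baseline_beta={"m": (1e9, 1e-9 + 1), "h": (1, 1e12), "f": (1, 1e12)},
            seed=2,
        )
        # force the exact boundary
        truth.levels["control"][:] = 0.0
        truth.levels["control"]["p_m"] = 1.0
        truth.levels["case"][:] = 0.0
        truth.levels["case"]["p_m"] = 1.0
        counts = simulate_counts(truth, errors={"eps_ox": 0.0}, seed=4)
        ox = counts[counts["library"] == "oxBS"]
        assert (ox["n_T"] == 0).all()

    def test_law_of_large_numbers_bs_ox(self, small_genome):
        """At depth 10,000 with zero errors, empirical C-fractions converge
        to pi_BS = p_m + p_h and pi_oxBS = p_m (3 SE per site)."""
        genes, sites = small_genome
        truth = simulate_truth(sites, genes, seed=31)
        counts = simulate_counts(
            truth, depth_model=(10_000, 1e9),
            errors={"eps_bs": 0, "eps_ox": 0, "e_mab": 0}, seed=32,
        )
        lv = truth.levels["control"]
        for lib, pi in [("BS", lv["p_m"] + lv["p_h"]), ("oxBS", lv["p_m"])]:
            sub = counts[(counts["library"] == lib) & (counts["group"] == "control")]
            depth = (sub["n_C"] + sub["n_T"]).to_numpy()
            frac = sub["n_C"].to_numpy() / depth
            se = np.sqrt(pi * (1 - pi) / depth).to_numpy()
            ok = np.abs(frac - pi.to_numpy()) <= 3 * np.maximum(se, 1e-4)
            assert ok.mean() > 0.98  # ~3-sigma coverage

    def test_invalid_error_rates(self, planted_truth):
        with pytest.raises(ValueError):
            simulate_counts(planted_truth, errors={"e_mab": 1.0})


class TestSimulateExpression:
    def test_zero_dispersion_limit(self, small_genome):
        genes, sites = small_genome
        gids = [g.gene_id for g in genes]
        truth = simulate_truth(
            sites, genes,
            planted={"gain_genes": gids[:3], "delta": 0.1},
            log2fc_mag=1.0, seed=41,
        )
        mat, design = simulate_expression(
            genes, truth, n_per_group=3, nb_dispersion=0.0, seed=42
        )
        case = mat.loc[:, design == "case"].mean(axis=1)
        ctrl = mat.loc[:, design == "control"].mean(axis=1)
        ratio = (case / ctrl)[gids[:3]]
        assert ratio.to_numpy() == pytest.approx(2.0, rel=0.01)
        assert (case / ctrl)[gids[10]] == pytest.approx(1.0, rel=0.01)

    def test_determinism_and_errors(self, small_genome, planted_truth):
        genes, _ = small_genome
        a, _ = simulate_expression(genes, planted_truth, seed=5)
        b, _ = simulate_expression(genes, planted_truth, seed=5)
        pd.testing.assert_frame_equal(a, b)
        with pytest.raises(ValueError):
            simulate_expression(genes, planted_truth, n_per_group=1)
        with pytest.raises(ValueError):
            simulate_expression(genes, planted_truth, lib_size=0)


class TestSimulateValidationDeltas:
    def _discovery(self, n, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {"gene_id": [f"G{i}" for i in range(n)],
             "delta": rng.uniform(0.05, 0.3, n) * rng.choice([-1, 1], n)}
        )

    @pytest.mark.parametrize("rho, expected", [(1.0, 1.0), (0.0, 0.0)])
    def test_extreme_rho(self, rho, expected):
        disc = self._discovery(200)
        val = simulate_validation_deltas(disc, rho, seed=1)
        rep = trend_concordance(disc, val)
        assert rep.fraction == expected

    def test_rho_half_binomial_se(self):
        disc = self._discovery(1000)
        val = simulate_validation_deltas(disc, 0.5, seed=2)
        rep = trend_concordance(disc, val)
        assert abs(rep.fraction - 0.5) < 3 * np.sqrt(0.25 / 1000)

    def test_zero_deltas_stay_zero(self):
        disc = pd.DataFrame({"gene_id": ["a", "b"], "delta": [0.0, 0.1]})
        val = simulate_validation_deltas(disc, 0.5, seed=3)
        assert val.loc[val["gene_id"] == "a", "delta"].iloc[0] == 0.0

    def test_invalid_rho(self):
        with pytest.raises(ValueError):
            simulate_validation_deltas(self._discovery(5), 1.5)
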