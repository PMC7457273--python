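"""Pipeline orchestration: config, stages, run report.

Each stage is a pure function from a validated :class:`RunConfig` plus the
files already in the output directory to new files in that directory, so
running stages one by one reproduces a single ``all`` run byte for byte.
Every stochastic stage derives its seed from the global seed by a fixed
offset; changing one stage's draw count therefore never perturbs another
stage. The run report (``report.json``) accumulates per-stage row counts,
parameter echoes and key statistics; it carries no timestamps, so repeated
runs with one seed are byte-identical.
"""

from __future__ import annotations

import copy
import json
import logging
import os
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import aggregation, calling, expression, integration, synthetic

log = logging.getLogger("methtriad")

# fixed per-stage seed offsets (added to the global seed)
SEED_OFFSETS = {
    "genome": 11,
    "truth": 23,
    "counts": 37,
    "expression_tissue": 41,
    "expression_model": 43,
    "validation": 53,
}

DEFAULTS: dict = {
    "seed": 1,
    "outdir": "results",
    "simulate": {
        "n_genes": 150,
        "gene_length_range": [2000, 6000],
        "cpg_density": 0.02,
        "intergenic_gap": 1000,
        "n_gain": 20,
        "n_loss": 20,
        "delta": 0.2,
        "log2fc_mag": 1.0,
        "depth_mean": 30.0,
        "depth_dispersion": 5.0,
        "eps_bs": 0.0,
        "eps_ox": 0.0,
        "e_mab": 0.0164,
        "n_replicates": 1,
        "n_per_group": 5,
        "nb_dispersion": 0.1,
        "lib_size": 1.0e6,
        "coupling": {"gain": "up", "loss": "down"},
    },
    "call": {
        "min_depth": 10,
        "e": 0.0164,
        "alpha": 0.01,
        "fdr": 0.01,
        "mask_bed": None,
    },
    "aggregate": {
        "bin_size": 1000,
        "min_sites": 3,
    },
    "express": {
        "fc_threshold": 1.5,
        "p_threshold": 0.05,
        "expression_min": 1.0,
        "method": "builtin",
        "external_table": None,
    },
    "integrate": {
        "modification": "5mC",
    },
    "validate": {
        "concordance_rho": 0.57,
        "magnitude_noise": 0.25,
        "validation_deltas": None,
    },
}


class ConfigError(ValueError):
    """A user-facing configuration problem (unknown key, bad value)."""


def _merge(defaults: dict, user: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, value in (user or {}).items():
        here = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ConfigError(f"unknown config key: {here}")
        if isinstance(defaults[key], dict) and key != "coupling":
            if not isinstance(value, dict):
                raise ConfigError(f"{here} must be a mapping")
            out[key] = _merge(defaults[key], value, here)
        else:
            out[key] = value
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Build the effective config: defaults <- YAML file <- CLI overrides."""
    user = {}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
    cfg = _merge(DEFAULTS, user)
    for key, value in (overrides or {}).items():
        if value is not None:
            cfg[key] = value
    return cfg


def _atomic_write_df(df: pd.DataFrame, path: Path, **kwargs) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    df.to_csv(tmp, sep="\t", **kwargs)
    os.replace(tmp, path)


def _atomic_write_text(text: str, path: Path) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(text)
    os.replace(tmp, path)


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage '{stage}' needs input file {path}; run the producing stage first"
        )
    return path


def _load_report(outdir: Path) -> dict:
    p = outdir / "report.json"
    if p.exists():
        return json.loads(p.read_text())
    return {"version": __version__, "stages": {}}


def _save_report(report: dict, cfg: dict, outdir: Path) -> None:
    report["version"] = __version__
    report["seed"] = cfg["seed"]
    _atomic_write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n", outdir / "report.json"
    )


# ---------------------------------------------------------------------------
# stages

def stage_simulate(cfg: dict, outdir: Path) -> dict:
    p = cfg["simulate"]
    seed = cfg["seed"]
    genes, sites = synthetic.simulate_genome(
        n_genes=p["n_genes"],
        gene_length_range=tuple(p["gene_length_range"]),
        cpg_density=p["cpg_density"],
        intergenic_gap=p["intergenic_gap"],
        seed=seed + SEED_OFFSETS["genome"],
    )
    gene_ids = [g.gene_id for g in genes]
    gain = gene_ids[: p["n_gain"]]
    loss = gene_ids[p["n_gain"]: p["n_gain"] + p["n_loss"]]
    truth = synthetic.simulate_truth(
        sites, genes,
        planted={"gain_genes": gain, "loss_genes": loss, "delta": p["delta"]},
        log2fc_mag=p["log2fc_mag"],
        seed=seed + SEED_OFFSETS["truth"],
    )
    counts = synthetic.simulate_counts(
        truth,
        depth_model=(p["depth_mean"], p["depth_dispersion"]),
        errors={"eps_bs": p["eps_bs"], "eps_ox": p["eps_ox"], "e_mab": p["e_mab"]},
        n_replicates=p["n_replicates"],
        seed=seed + SEED_OFFSETS["counts"],
    )
    # two expression cohorts (e.g. tissue and cell model) sharing the truth
    expr_t, design = synthetic.simulate_expression(
        genes, truth, n_per_group=p["n_per_group"],
        nb_dispersion=p["nb_dispersion"], lib_size=p["lib_size"],
        coupling=p["coupling"], seed=seed + SEED_OFFSETS["expression_tissue"],
    )
    expr_m, _ = synthetic.simulate_expression(
        genes, truth, n_per_group=p["n_per_group"],
        nb_dispersion=p["nb_dispersion"], lib_size=p["lib_size"],
        coupling=p["coupling"], seed=seed + SEED_OFFSETS["expression_model"],
    )

    synthetic.write_genes_bed(genes, outdir / "genes.bed")
    _atomic_write_df(counts, outdir / "counts.tsv", index=False)
    synthetic.write_truth(truth, outdir / "truth.tsv")
    _atomic_write_df(expr_t, outdir / "expression_tissue.tsv")
    _atomic_write_df(expr_m, outdir / "expression_model.tsv")
    _atomic_write_df(
        design.rename_axis("sample").to_frame(), outdir / "design.tsv"
    )
    return {
        "n_genes": len(genes),
        "n_sites": len(sites),
        "n_count_records": len(counts),
        "n_gain_planted": len(gain),
        "n_loss_planted": len(loss),
        "params": p,
    }


def stage_call(cfg: dict, outdir: Path) -> dict:
    p = cfg["call"]
    counts = synthetic.read_counts(_require(outdir / "counts.tsv", "call"))
    mask = None
    if p["mask_bed"]:
        mask = [
            (g.chrom, g.start, g.end)
            for g in synthetic.read_genes_bed(_require(Path(p["mask_bed"]), "call"))
        ]
    filtered = calling.filter_and_mask(counts, min_depth=p["min_depth"], mask=mask)
    estimates = calling.estimate_mh_cohort(filtered)
    calls = calling.call_fcac_cohort(
        filtered, e=p["e"], min_depth=p["min_depth"],
        alpha=p["alpha"], fdr=p["fdr"],
    )
    _atomic_write_df(estimates, outdir / "estimates.tsv", index=False)
    _atomic_write_df(calls, outdir / "fcac_calls.tsv", index=False)
    return {
        "n_input_records": len(counts),
        "n_filtered_records": len(filtered),
        "n_estimates": len(estimates),
        "n_fcac_sites_tested": len(calls),
        "n_fcac_retained": int(calls["retained"].sum()) if len(calls) else 0,
        "params": p,
    }


def stage_aggregate(cfg: dict, outdir: Path) -> dict:
    p = cfg["aggregate"]
    estimates = pd.read_csv(_require(outdir / "estimates.tsv", "aggregate"), sep="\t")
    calls = pd.read_csv(_require(outdir / "fcac_calls.tsv", "aggregate"), sep="\t")
    genes = synthetic.read_genes_bed(_require(outdir / "genes.bed", "aggregate"))

    n_bins = {}
    for mod, source in [("5mC", estimates), ("5hmC", estimates), ("5fC_caC", calls)]:
        mod_name = mod.replace("_", "/")
        for group, sub in source.groupby("group"):
            bins = aggregation.bin_signals(sub, mod_name, bin_size=p["bin_size"])
            path = outdir / f"bins_{mod}_{group}.bedgraph"
            _atomic_write_text(
                bins[["chrom", "start", "end", "signal"]].to_csv(
                    sep="\t", index=False, header=False, float_format="%.6g"
                ),
                path,
            )
            n_bins[f"{mod_name}:{group}"] = len(bins)

    deltas = []
    for mod_name, source in [
        ("5mC", estimates), ("5hmC", estimates), ("5fC/caC", calls)
    ]:
        deltas.append(
            aggregation.gene_body_delta(
                source[source["group"] == "case"],
                source[source["group"] == "control"],
                genes, mod_name, min_sites=p["min_sites"],
            )
        )
    delta_df = pd.concat(deltas, ignore_index=True)
    _atomic_write_df(delta_df, outdir / "gene_deltas.tsv", index=False,
                     float_format="%.10g")
    defined = delta_df[delta_df["defined"]]
    return {
        "n_bins": n_bins,
        "n_gene_deltas": len(delta_df),
        "n_defined": int(delta_df["defined"].sum()),
        "n_gain_5mC": int(
            ((defined["modification"] == "5mC") & (defined["direction"] == "gain")).sum()
        ),
        "n_loss_5mC": int(
            ((defined["modification"] == "5mC") & (defined["direction"] == "loss")).sum()
        ),
        "params": p,
    }


def _de_for(cfg: dict, outdir: Path, cohort: str) -> pd.DataFrame:
    p = cfg["express"]
    mat = synthetic.read_expression(
        _require(outdir / f"expression_{cohort}.tsv", "express")
    )
    design = synthetic.read_design(_require(outdir / "design.tsv", "express"))
    genes = synthetic.read_genes_bed(_require(outdir / "genes.bed", "express"))
    lengths = pd.Series({g.gene_id: g.length for g in genes})
    rpkm = expression.compute_rpkm(mat, lengths)
    _atomic_write_df(rpkm, outdir / f"rpkm_{cohort}.tsv", float_format="%.10g")
    if p["method"] == "external":
        ext = pd.read_csv(_require(Path(p["external_table"]), "express"), sep="\t")
        de = expression.de_genes(
            rpkm, design, fc_threshold=p["fc_threshold"],
            p_threshold=p["p_threshold"], method="external", external_table=ext,
        )
    else:
        de = expression.de_genes(
            rpkm, design, fc_threshold=p["fc_threshold"],
            p_threshold=p["p_threshold"],
        )
    _atomic_write_df(de, outdir / f"de_{cohort}.tsv", index=False,
                     float_format="%.10g")
    return de


def stage_express(cfg: dict, outdir: Path) -> dict:
    de_t = _de_for(cfg, outdir, "tissue")
    de_m = _de_for(cfg, outdir, "model")
    return {
        "n_genes": len(de_t),
        "n_significant_tissue": int(de_t["significant"].sum()),
        "n_significant_model": int(de_m["significant"].sum()),
        "params": cfg["express"],
    }


def stage_integrate(cfg: dict, outdir: Path) -> dict:
    mod = cfg["integrate"]["modification"]
    de_t = pd.read_csv(_require(outdir / "de_tissue.tsv", "integrate"), sep="\t")
    de_m = pd.read_csv(_require(outdir / "de_model.tsv", "integrate"), sep="\t")
    deltas = aggregation.read_deltas(_require(outdir / "gene_deltas.tsv", "integrate"))

    strat = integration.stratify_by_methylation(de_t, deltas, modification=mod)
    sig = integration.select_signature(de_t, de_m, direction_match=True)

    _atomic_write_text(
        json.dumps(strat.to_dict(), indent=2, sort_keys=True) + "\n",
        outdir / "stratification.json",
    )
    _atomic_write_text("\n".join(sig["up_up"]) + "\n", outdir / "signature_up.txt")
    _atomic_write_text("\n".join(sig["down_down"]) + "\n", outdir / "signature_down.txt")
    return {
        "stratification": strat.to_dict(),
        "n_signature_up": len(sig["up_up"]),
        "n_signature_down": len(sig["down_down"]),
        "n_discordant": sig["discordant"],
        "params": cfg["integrate"],
    }


def stage_validate(cfg: dict, outdir: Path) -> dict:
    p = cfg["validate"]
    deltas = aggregation.read_deltas(_require(outdir / "gene_deltas.tsv", "validate"))
    mod = cfg["integrate"]["modification"]
    disc = deltas[(deltas["modification"] == mod) & deltas["defined"]]
    if p["validation_deltas"]:
        val = aggregation.read_deltas(_require(Path(p["validation_deltas"]), "validate"))
    else:
        val = synthetic.simulate_validation_deltas(
            disc, concordance_rho=p["concordance_rho"],
            magnitude_noise=p["magnitude_noise"],
            seed=cfg["seed"] + SEED_OFFSETS["validation"],
        )
        _atomic_write_df(val, outdir / "validation_deltas.tsv", index=False,
                         float_format="%.10g")
    report = integration.trend_concordance(disc, val)
    _atomic_write_text(
        json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n",
        outdir / "concordance.json",
    )
    return {"concordance": report.to_dict(), "params": p}


STAGES = {
    "simulate": stage_simulate,
    "call": stage_call,
    "aggregate": stage_aggregate,
    "express": stage_express,
    "integrate": stage_integrate,
    "validate": stage_validate,
}
STAGE_ORDER = ["simulate", "call", "aggregate", "express", "integrate", "validate"]


def run_pipeline(cfg: dict, subcommand: str = "all") -> dict:
    """Run one stage or the whole pipeline; returns the updated run report."""
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    report = _load_report(outdir)
    names = STAGE_ORDER if subcommand == "all" else [subcommand]
    if subcommand != "all" and subcommand not in STAGES:
        raise ConfigError(f"unknown subcommand {subcommand!r}")
    for name in names:
        log.info("running stage %s", name)
        report["stages"][name] = STAGES[name](cfg, outdir)
    # echo effective parameters; the output location is not a parameter
    report["config"] = {k: cfg[k] for k in cfg if k != "outdir"}
    _save_report(report, cfg, outdir)
    return report
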