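"""Synthetic triple-library bisulfite data with known ground truth.

Emulates the measurement chain of a BS/oxBS/MAB-seq experiment on a toy
genome so that every downstream stage (site calling, binning, gene-body
deltas, expression integration, cohort validation) can be tested against a
planted truth without any external data.

Chemistry encoded here (per-read C/T readout probabilities):

* BS-seq:   C is read with probability ``p_m + p_h`` (5mC and 5hmC are
  protected; unmodified C, 5fC and 5caC convert to T), plus an optional
  non-conversion error ``eps_bs`` on the convertible fraction.
* oxBS-seq: 5hmC is oxidised to 5fC before conversion, so only 5mC is
  protected: C-probability ``p_m + eps_ox * (1 - p_m)``.
* MAB-seq:  M.SssI methylates every unmodified CpG first, so only 5fC/5caC
  read as T; the T-probability is ``p_f + e_mab * (1 - p_f)`` where
  ``e_mab`` is the bisulfite non-conversion inefficiency (default 1.64%,
  the measured null rate used for the binomial caller).

5fC and 5caC are simulated and estimated as a single pooled species
``p_f``. CpG sites are represented at the plus-strand cytosine only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# Default study conditions. Depth: negative binomial, WGBS-typical mean 30
# with dispersion 5. MAB non-conversion inefficiency 1.64%. Beta baselines
# give a broad 5mC landscape, moderate 5hmC, and a low (mean ~1.6%) 5fC/caC
# floor.
DEFAULT_DEPTH_MODEL = (30.0, 5.0)
DEFAULT_E_MAB = 0.0164
DEFAULT_BASELINE_BETA = {"m": (2.0, 2.0), "h": (2.0, 5.0), "f": (1.0, 60.0)}

GROUPS = ("control", "case")
LIBRARIES = ("BS", "oxBS", "MAB")

COUNT_COLUMNS = [
    "chrom", "pos", "strand", "library", "group", "replicate", "n_C", "n_T",
]


@dataclass(frozen=True)
class GeneModel:
    """A gene body interval, 0-based half-open, non-overlapping per chrom."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(
                f"gene {self.gene_id}: end ({self.end}) must exceed start ({self.start})"
            )
        if self.start < 0:
            raise ValueError(f"gene {self.gene_id}: negative start")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SimulationTruth:
    """Planted per-site modification levels and per-gene expression effects.

    ``levels[group]`` is a DataFrame indexed like ``sites`` with columns
    ``p_m, p_h, p_f`` satisfying ``p_m + p_h + p_f <= 1`` at every site.
    ``gene_effects`` carries the true |log2 fold-change| and the planted
    methylation direction flag per gene ('gain', 'loss' or '').
    """

    sites: pd.DataFrame           # chrom, pos, gene_id ('' if intergenic)
    levels: dict                  # group -> DataFrame(p_m, p_h, p_f)
    gene_effects: pd.DataFrame    # gene_id, log2fc_mag, meth_direction
    delta: float = 0.0
    seed: int = field(default=0)

    def validate(self) -> None:
        for group, df in self.levels.items():
            arr = df[["p_m", "p_h", "p_f"]].to_numpy()
            if (arr < 0).any() or (arr > 1).any():
                raise ValueError(f"{group}: modification fractions outside [0,1]")
            if (arr.sum(axis=1) > 1 + 1e-12).any():
                raise ValueError(f"{group}: p_m + p_h + p_f exceeds 1 at some site")


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def simulate_genome(
    n_genes: int,
    gene_length_range: tuple[int, int] = (2_000, 10_000),
    cpg_density: float = 0.02,
    intergenic_gap: int = 2_000,
    seed: int = 0,
    chrom: str = "chrS",
) -> tuple[list[GeneModel], pd.DataFrame]:
    """Lay out non-overlapping genes left-to-right and scatter CpG sites.

    CpG positions are i.i.d. Bernoulli(``cpg_density``) per base pair over
    the whole span (genic and intergenic alike), so the expected site count
    over a span of L bp is ``cpg_density * L``.

    Returns the gene list and a site table (chrom, pos, gene_id) where
    ``gene_id`` is the containing gene or '' for intergenic sites.
    """
    lo, hi = int(gene_length_range[0]), int(gene_length_range[1])
    if n_genes < 0:
        raise ValueError("n_genes must be >= 0")
    if not (0.0 < cpg_density <= 0.2):
        raise ValueError("cpg_density must lie in (0, 0.2]")
    if lo <= 0 or hi < lo:
        raise ValueError("gene lengths must be positive with min <= max")
    if intergenic_gap < 0:
        raise ValueError("intergenic_gap must be >= 0")

    rng = _rng(seed)
    genes: list[GeneModel] = []
    cursor = intergenic_gap
    for i in range(n_genes):
        length = int(rng.integers(lo, hi + 1))
        genes.append(GeneModel(f"G{i:04d}", chrom, cursor, cursor + length))
        cursor += length + intergenic_gap

    span = cursor if n_genes else 0
    if span == 0:
        sites = pd.DataFrame({"chrom": [], "pos": [], "gene_id": []}).astype(
            {"chrom": str, "pos": np.int64, "gene_id": str}
        )
        return genes, sites

    pos = np.flatnonzero(rng.random(span) < cpg_density).astype(np.int64)
    sites = pd.DataFrame({"chrom": chrom, "pos": pos, "gene_id": ""})
    sites["gene_id"] = assign_genes(sites, genes)
    return genes, sites


def assign_genes(sites: pd.DataFrame, genes: list[GeneModel]) -> pd.Series:
    """Map each site to the gene body containing it ('' if none).

    Genes per chromosome must be non-overlapping; containment is resolved
    with a sorted-interval search, O((S+G) log G).
    """
    out = pd.Series("", index=sites.index, dtype=object)
    for chrom, sub in sites.groupby("chrom"):
        gsub = sorted((g for g in genes if g.chrom == chrom), key=lambda g: g.start)
        if not gsub:
            continue
        starts = np.array([g.start for g in gsub])
        ends = np.array([g.end for g in gsub])
        idx = np.searchsorted(starts, sub["pos"].to_numpy(), side="right") - 1
        ok = (idx >= 0) & (sub["pos"].to_numpy() < ends[np.clip(idx, 0, None)])
        names = np.array([g.gene_id for g in gsub], dtype=object)
        vals = np.where(ok, names[np.clip(idx, 0, None)], "")
        out.loc[sub.index] = vals
    return out


def simulate_truth(
    sites: pd.DataFrame,
    genes: list[GeneModel],
    baseline_beta: dict | None = None,
    planted: dict | None = None,
    log2fc_mag: float = 1.0,
    seed: int = 0,
) -> SimulationTruth:
    """Draw control-group modification levels and plant case-group shifts.

    Control levels per site: ``p_m ~ Beta(a_m, b_m)``, ``p_h ~ Beta(a_h,
    b_h)``, ``p_f ~ Beta(a_f, b_f)``, sequentially clipped so that
    ``p_m + p_h + p_f <= 1``. Case levels equal control levels except on
    sites inside ``planted['gain_genes']`` / ``planted['loss_genes']``,
    whose 5mC is shifted by ±``planted['delta']`` and re-clipped to the
    simplex. Planted genes also receive a true expression effect of
    magnitude ``log2fc_mag`` (direction applied later by
    :func:`simulate_expression` through its coupling map).
    """
    bb = dict(DEFAULT_BASELINE_BETA, **(baseline_beta or {}))
    planted = planted or {}
    gain = set(planted.get("gain_genes", ()))
    loss = set(planted.get("loss_genes", ()))
    delta = float(planted.get("delta", 0.0))
    if gain & loss:
        raise ValueError(f"gain/loss gene sets overlap: {sorted(gain & loss)[:5]}")

    rng = _rng(seed)
    n = len(sites)
    p_m = rng.beta(*bb["m"], size=n)
    p_h = rng.beta(*bb["h"], size=n)
    p_f = rng.beta(*bb["f"], size=n)
    # sequential projection onto the simplex: 5mC keeps its draw, 5hmC and
    # 5fC/caC yield in turn
    p_h = np.minimum(p_h, 1.0 - p_m)
    p_f = np.minimum(p_f, 1.0 - p_m - p_h)

    control = pd.DataFrame({"p_m": p_m, "p_h": p_h, "p_f": p_f}, index=sites.index)

    shift = np.zeros(n)
    gid = sites["gene_id"].to_numpy()
    shift[np.isin(gid, list(gain))] = +delta
    shift[np.isin(gid, list(loss))] = -delta
    case = control.copy()
    case["p_m"] = np.clip(control["p_m"] + shift, 0.0, 1.0)
    # re-project so the shifted site still sits on the simplex
    case["p_h"] = np.minimum(case["p_h"], 1.0 - case["p_m"])
    case["p_f"] = np.minimum(case["p_f"], 1.0 - case["p_m"] - case["p_h"])

    effects = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "log2fc_mag": [
                log2fc_mag if (g.gene_id in gain or g.gene_id in loss) else 0.0
                for g in genes
            ],
            "meth_direction": [
                "gain" if g.gene_id in gain else ("loss" if g.gene_id in loss else "")
                for g in genes
            ],
        }
    )
    truth = SimulationTruth(
        sites=sites,
        levels={"control": control, "case": case},
        gene_effects=effects,
        delta=delta,
        seed=seed,
    )
    truth.validate()
    return truth


def _nb_depths(rng, mean: float, dispersion: float, size: int) -> np.ndarray:
    """Negative-binomial depths with var = mean + mean^2 / dispersion."""
    if mean <= 0 or dispersion <= 0:
        raise ValueError("depth model mean and dispersion must be positive")
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def simulate_counts(
    truth: SimulationTruth,
    depth_model: tuple[float, float] = DEFAULT_DEPTH_MODEL,
    errors: dict | None = None,
    n_replicates: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw per-site BS/oxBS/MAB count records for every group/replicate.

    Per site, group, replicate and library: depth ~ NB(mean, dispersion),
    then ``n_C ~ Binomial(depth, pi)`` with the library's C-readout
    probability composed from the true levels and the error rates
    (``eps_bs``, ``eps_ox`` default 0; ``e_mab`` defaults to 0.0164).
    """
    err = {"eps_bs": 0.0, "eps_ox": 0.0, "e_mab": DEFAULT_E_MAB}
    err.update(errors or {})
    for k, v in err.items():
        if not (0.0 <= v < 1.0):
            raise ValueError(f"{k} must lie in [0, 1)")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")

    rng = _rng(seed)
    sites = truth.sites
    n = len(sites)
    frames = []
    for group in truth.levels:
        lv = truth.levels[group]
        p_m = lv["p_m"].to_numpy()
        p_h = lv["p_h"].to_numpy()
        p_f = lv["p_f"].to_numpy()
        pi = {
            "BS": p_m + p_h + err["eps_bs"] * (1.0 - p_m - p_h),
            "oxBS": p_m + err["eps_ox"] * (1.0 - p_m),
            "MAB": 1.0 - (p_f + err["e_mab"] * (1.0 - p_f)),
        }
        for name, prob in pi.items():
            if (prob < -1e-12).any() or (prob > 1 + 1e-12).any():
                raise RuntimeError(f"{name}: composed C-probability outside [0,1]")
        for rep in range(1, n_replicates + 1):
            for lib in LIBRARIES:
                depth = _nb_depths(rng, depth_model[0], depth_model[1], n)
                n_c = rng.binomial(depth, np.clip(pi[lib], 0.0, 1.0))
                frames.append(
                    pd.DataFrame(
                        {
                            "chrom": sites["chrom"].to_numpy(),
                            "pos": sites["pos"].to_numpy(),
                            "strand": "+",
                            "library": lib,
                            "group": group,
                            "replicate": rep,
                            "n_C": n_c,
                            "n_T": depth - n_c,
                        }
                    )
                )
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=COUNT_COLUMNS
    )
    return out[COUNT_COLUMNS]


def simulate_expression(
    genes: list[GeneModel],
    truth: SimulationTruth,
    n_per_group: int = 5,
    nb_dispersion: float = 0.1,
    lib_size: float = 1e6,
    coupling: dict | None = None,
    baseline_mean_range: tuple[float, float] = (20.0, 2_000.0),
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Negative-binomial expression counts coupled to methylation direction.

    ``coupling`` maps a planted methylation direction to an expression
    direction; the default ``{'gain': 'up', 'loss': 'down'}`` encodes the
    observation the integration stage is meant to recover (5mC loss on the
    gene body accompanies lower expression). A gene with planted direction
    d gets case-group mean ``base * 2**(±log2fc_mag)`` with the sign from
    ``coupling[d]``; uncoupled genes keep their baseline mean. Counts are
    NB with variance ``mu + nb_dispersion * mu^2``; ``nb_dispersion = 0``
    is the deterministic limit (counts = rounded mean).

    Returns (counts DataFrame genes x samples, sample->group Series).
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if nb_dispersion < 0:
        raise ValueError("nb_dispersion must be >= 0")
    if lib_size <= 0:
        raise ValueError("lib_size must be positive")
    coupling = coupling or {"gain": "up", "loss": "down"}
    sign = {"up": +1.0, "down": -1.0}

    rng = _rng(seed)
    eff = truth.gene_effects.set_index("gene_id")
    gene_ids = [g.gene_id for g in genes]
    base = rng.uniform(*baseline_mean_range, size=len(gene_ids))
    # relative means scaled to the target library size
    base = base / base.sum() * lib_size if len(gene_ids) else base

    log2fc = np.zeros(len(gene_ids))
    for i, gid in enumerate(gene_ids):
        d = eff.loc[gid, "meth_direction"]
        if d in coupling:
            log2fc[i] = sign[coupling[d]] * eff.loc[gid, "log2fc_mag"]

    samples, groups, cols = [], [], []
    for group in GROUPS:
        mu = base * np.exp2(log2fc) if group == "case" else base
        for r in range(1, n_per_group + 1):
            name = f"{group}_{r}"
            if nb_dispersion == 0:
                counts = np.rint(mu).astype(np.int64)
            else:
                size = 1.0 / nb_dispersion
                p = size / (size + np.where(mu > 0, mu, 1.0))
                counts = np.where(
                    mu > 0, rng.negative_binomial(size, p, size=len(mu)), 0
                ).astype(np.int64)
            cols.append(counts)
            samples.append(name)
            groups.append(group)

    mat = pd.DataFrame(
        np.column_stack(cols) if cols else np.empty((len(gene_ids), 0), dtype=np.int64),
        index=pd.Index(gene_ids, name="gene_id"),
        columns=samples,
    )
    return mat, pd.Series(groups, index=samples, name="group")


def simulate_validation_deltas(
    discovery_deltas: pd.DataFrame,
    concordance_rho: float,
    magnitude_noise: float = 0.25,
    seed: int = 0,
) -> pd.DataFrame:
    """An independent cohort's per-gene deltas with controlled sign agreement.

    Each validation delta keeps the discovery sign with probability
    ``concordance_rho`` and flips it otherwise; the magnitude is perturbed
    by a lognormal factor ``exp(magnitude_noise * N(0,1))`` (always
    positive, so the sign is exactly the Bernoulli draw). Zero-delta
    discovery genes stay zero.
    """
    if not (0.0 <= concordance_rho <= 1.0):
        raise ValueError("concordance_rho must lie in [0, 1]")
    rng = _rng(seed)
    d = discovery_deltas["delta"].to_numpy(dtype=float)
    keep = rng.random(len(d)) < concordance_rho
    factor = np.exp(magnitude_noise * rng.standard_normal(len(d)))
    out_delta = np.where(keep, np.sign(d), -np.sign(d)) * np.abs(d) * factor
    out = discovery_deltas.copy()
    out["delta"] = out_delta
    out["direction"] = np.where(
        out_delta > 0, "gain", np.where(out_delta < 0, "loss", "no-change")
    )
    return out


# ---------------------------------------------------------------------------
# plain-text writers (TSV/BED) used by the pipeline and test harnesses

def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index=False)


def read_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"count table missing columns: {sorted(missing)}")
    return df[COUNT_COLUMNS]


def write_genes_bed(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


def read_genes_bed(path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            genes.append(
                GeneModel(
                    gene_id=f[3] if len(f) > 3 else f"{f[0]}:{f[1]}-{f[2]}",
                    chrom=f[0],
                    start=int(f[1]),
                    end=int(f[2]),
                    strand=f[5] if len(f) > 5 else "+",
                )
            )
    return genes


def write_truth(truth: SimulationTruth, path) -> None:
    rows = []
    for group, lv in truth.levels.items():
        df = truth.sites[["chrom", "pos", "gene_id"]].copy()
        df["group"] = group
        rows.append(pd.concat([df, lv.reset_index(drop=True)], axis=1))
    pd.concat(rows, ignore_index=True).to_csv(path, sep="\t", index=False)


def write_expression(mat: pd.DataFrame, path) -> None:
    mat.to_csv(path, sep="\t")


def read_expression(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_design(groups: pd.Series, path) -> None:
    groups.rename_axis("sample").to_frame().to_csv(path, sep="\t")


def read_design(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0]
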