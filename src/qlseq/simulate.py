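"""Synthetic count experiments with the study's structure and known truth.

The generator emulates a clustered two-species experiment: 2 species x 5
individuals x 6 brain parts (optionally dropping one low-depth sample),
library sizes spanning roughly 3e5 to 3e6 reads, and NB counts with
gene-wise dispersion. Effects enter on the log2 scale: a per-individual
random effect shared by all of an individual's samples (what makes the
design clustered), sparse brain-part effects shared by both species, and
sparse species-by-part interaction effects that break between-species
equivalence for every part pair involving the affected part.

Each gene draws from its own counter-derived RNG stream, so enlarging the
gene count extends, rather than reshuffles, an existing simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import DEFAULT_PARTS, CountMatrix, SampleTable

LN2 = np.log(2.0)


@dataclass
class SimConfig:
    """Generator parameters; defaults are the emulated study conditions."""

    genes: int = 10000
    individuals_per_species: int = 5
    species: tuple = ("Na", "Ve")
    parts: tuple = DEFAULT_PARTS
    seed: int = None  # type: ignore[assignment]  # mandatory

    # library sizes: log-normal, median ~1e6, range ~3e5-3e6 over 60 draws
    lib_size_meanlog: float = np.log(1.0e6)
    lib_size_sdlog: float = 0.4

    # baseline expression: log2-cpm ~ Normal(mean, sd)
    baseline_log2cpm_mean: float = 5.0
    baseline_log2cpm_sd: float = 2.0

    # NB dispersion ~ Gamma(shape, scale); mean 0.1, bulk in 0.05-0.2
    dispersion_shape: float = 4.0
    dispersion_scale: float = 0.025

    # sparse effects (log2 scale)
    frac_part_de: float = 0.10
    part_lfc_low: float = 1.0
    part_lfc_high: float = 3.0
    frac_interaction: float = 0.05
    interaction_lfc_low: float = 2.5
    interaction_lfc_high: float = 4.0

    individual_sd: float = 0.10   # log2 units
    drop_one_sample: bool = False
    equivalence_delta: float = 2.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if self.genes < 1 or len(self.parts) < 2:
            raise ValueError("degenerate configuration: need >=1 gene and >=2 parts")
        for frac in (self.frac_part_de, self.frac_interaction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("effect fractions must lie in [0, 1]")
        for val in (
            self.lib_size_sdlog, self.dispersion_shape, self.dispersion_scale,
        ):
            if val <= 0:
                raise ValueError("scale parameters must be positive")


@dataclass
class SimTruth:
    """Ground truth of one simulated experiment."""

    baseline_log2cpm: np.ndarray
    dispersion: np.ndarray
    part_effects: dict            # species -> (G, n_parts) log2 effects
    interaction: np.ndarray       # (G, n_parts) species2-minus-species1 offsets
    within_lfc: pd.DataFrame      # gene x within-species contrast, true log2FC
    interaction_lfc: pd.DataFrame # gene x interaction contrast, true log2FC
    equivalence_delta: float

    def global_null(self, family: str) -> pd.Series:
        """True global-null flag per gene for a hypothesis family."""
        table = self.within_lfc if family == "within_species" else self.interaction_lfc
        return (table.abs() < 1e-12).all(axis=1)

    def equivalent_truth(self) -> pd.DataFrame:
        """Per gene x interaction contrast: |true difference| < Delta."""
        return self.interaction_lfc.abs() < self.equivalence_delta


def _contrast_names(cfg: SimConfig) -> tuple[list[str], list[str]]:
    within = [f"{p}-avg_{s}" for s in cfg.species for p in cfg.parts]
    inter = []
    parts = list(cfg.parts)
    s1, s2 = cfg.species[:2] if len(cfg.species) > 1 else (cfg.species[0], cfg.species[0])
    for i, pi in enumerate(parts):
        for pj in parts[i + 1:]:
            inter.append(f"{pi}v{pj}_{s1}-{pi}v{pj}_{s2}")
    return within, inter


def simulate_experiment(config: SimConfig) -> tuple[CountMatrix, SampleTable, SimTruth]:
    """Draw one experiment; deterministic given ``config.seed``."""
    cfg = config
    parts = list(cfg.parts)
    n_parts = len(parts)
    species = list(cfg.species)
    root = np.random.SeedSequence(cfg.seed)
    meta_rng = np.random.default_rng(root.spawn(1)[0])
    gene_seeds = np.random.SeedSequence(cfg.seed, spawn_key=(1,)).spawn(cfg.genes)

    individuals = [
        f"{s}{i + 1}" for s in species for i in range(cfg.individuals_per_species)
    ]
    ind_species = {
        ind: s for s in species for ind in individuals if ind.startswith(s)
    }
    rows = [
        {"sample_id": f"{ind}_{p}", "individual": ind, "species": ind_species[ind], "brain_part": p}
        for ind in individuals
        for p in parts
    ]
    n = len(rows)
    lib = np.exp(meta_rng.normal(cfg.lib_size_meanlog, cfg.lib_size_sdlog, size=n))
    lib = np.maximum(np.round(lib), 1.0)
    if cfg.drop_one_sample:
        drop = int(meta_rng.integers(n))
        rows = [r for k, r in enumerate(rows) if k != drop]
        lib = np.delete(lib, drop)
        n = len(rows)
    samples = SampleTable(pd.DataFrame(rows), tuple(parts))
    sample_ind = np.array([r["individual"] for r in rows])
    sample_part = np.array([r["brain_part"] for r in rows])
    sample_spec = np.array([r["species"] for r in rows])

    G = cfg.genes
    gene_ids = [f"g{g + 1:05d}" for g in range(G)]
    counts = np.empty((G, n), dtype=np.int64)
    baseline = np.empty(G)
    disp = np.empty(G)
    part_eff = {s: np.zeros((G, n_parts)) for s in species}
    inter = np.zeros((G, n_parts))
    part_index = {p: j for j, p in enumerate(parts)}

    for g in range(G):
        rng = np.random.default_rng(gene_seeds[g])
        baseline[g] = rng.normal(cfg.baseline_log2cpm_mean, cfg.baseline_log2cpm_sd)
        disp[g] = rng.gamma(cfg.dispersion_shape, cfg.dispersion_scale)
        ind_eff = {
            ind: rng.normal(0.0, cfg.individual_sd) for ind in individuals
        }
        if rng.random() < cfg.frac_part_de:
            p_hit = parts[rng.integers(n_parts)]
            lfc = rng.uniform(cfg.part_lfc_low, cfg.part_lfc_high) * rng.choice([-1.0, 1.0])
            for s in species:
                part_eff[s][g, part_index[p_hit]] += lfc
        if len(species) > 1 and rng.random() < cfg.frac_interaction:
            p_hit = parts[rng.integers(n_parts)]
            lfc = rng.uniform(cfg.interaction_lfc_low, cfg.interaction_lfc_high) * rng.choice([-1.0, 1.0])
            part_eff[species[1]][g, part_index[p_hit]] += lfc
            inter[g, part_index[p_hit]] = lfc

        log2mu = (
            baseline[g]
            + np.array([ind_eff[i] for i in sample_ind])
            + np.array([part_eff[s][g, part_index[p]] for s, p in zip(sample_spec, sample_part)])
        )
        mu = lib / 1e6 * 2.0 ** log2mu
        if disp[g] > 0:
            r = 1.0 / disp[g]
            counts[g] = rng.negative_binomial(r, r / (r + mu))
        else:
            counts[g] = rng.poisson(mu)

    sample_ids = [r["sample_id"] for r in rows]
    # library sizes are the drawn sequencing depths (the generated genes are
    # a subset of the transcriptome, so column sums understate depth)
    cm = CountMatrix(
        pd.DataFrame(counts, index=gene_ids, columns=sample_ids),
        lib_sizes=pd.Series(lib.astype(np.int64), index=sample_ids),
    )

    within_names, inter_names = _contrast_names(cfg)
    within = np.empty((G, len(within_names)))
    col = 0
    for s in species:
        E = part_eff[s]
        for j in range(n_parts):
            others = [k for k in range(n_parts) if k != j]
            within[:, col] = E[:, j] - E[:, others].mean(axis=1)
            col += 1
    inter_lfc = np.empty((G, len(inter_names)))
    col = 0
    if len(species) > 1:
        d = part_eff[species[0]] - part_eff[species[1]]  # = -inter per part
        for i in range(n_parts):
            for j in range(i + 1, n_parts):
                inter_lfc[:, col] = d[:, i] - d[:, j]
                col += 1

    truth = SimTruth(
        baseline_log2cpm=baseline,
        dispersion=disp,
        part_effects=part_eff,
        interaction=inter,
        within_lfc=pd.DataFrame(within, index=gene_ids, columns=within_names),
        interaction_lfc=pd.DataFrame(inter_lfc, index=gene_ids, columns=inter_names),
        equivalence_delta=cfg.equivalence_delta,
    )
    return cm, samples, truth


# ---------------------------------------------------------------------------
# Scoring


def evaluate_fdr(flags, truth: SimTruth, family: str = "within_species") -> dict:
    """Gene-level FDR, per-hypothesis FDR and power against the truth.

    ``flags`` is either a per-gene boolean Series (gene flagged by the
    procedure) or a StagewiseResult, from which per-gene flags are the
    screened-and-confirmed genes.
    """
    if hasattr(flags, "flagged_genes"):
        per_hyp = flags.significant_matrix()
        flags = flags.flagged_genes()
    else:
        per_hyp = None
        flags = pd.Series(flags)
    null = truth.global_null(family)
    if not set(flags.index) <= set(null.index):
        raise ValueError("gene ids of result and truth do not match")
    # genes absent from the result (e.g. filtered out) count as unflagged
    flags = flags.reindex(null.index, fill_value=False).astype(bool)
    n_flagged = int(flags.sum())
    false = int((flags & null).sum())
    fdr = false / max(1, n_flagged)
    non_null = ~null
    power = float((flags & non_null).sum() / max(1, int(non_null.sum())))
    out = {"gene_fdr": fdr, "n_flagged": n_flagged, "power": power}
    if per_hyp is not None:
        table = truth.within_lfc if family == "within_species" else truth.interaction_lfc
        common = [c for c in per_hyp.columns if c in table.columns]
        if common:
            hyp_flags = per_hyp[common].fillna(False).astype(bool).to_numpy()
            hyp_null = (table[common].abs() < 1e-12).reindex(per_hyp.index).to_numpy()
            n_rej = int(hyp_flags.sum())
            out["hypothesis_fdr"] = float((hyp_flags & hyp_null).sum() / max(1, n_rej))
    return out


def evaluate_recovery(
    estimates: pd.DataFrame, truth: SimTruth, family: str = "within_species"
) -> pd.DataFrame:
    """Bias and RMSE of estimated log2FC by stratum of the true effect.

    Strata are the integer-rounded absolute true log2 fold changes; the
    zero stratum collects truly null gene-contrast pairs.
    """
    table = truth.within_lfc if family == "within_species" else truth.interaction_lfc
    common = [c for c in estimates.columns if c in table.columns]
    if not common:
        raise ValueError("no common contrasts between estimates and truth")
    est = estimates[common]
    if est.shape[0] != table.shape[0] or set(est.index) != set(table.index):
        raise ValueError("estimates and truth are not aligned")
    tru = table[common].reindex(est.index)
    err = (est - tru).to_numpy().ravel()
    t = tru.to_numpy().ravel()
    stratum = np.round(np.abs(t)).astype(int)
    rows = []
    for s in np.unique(stratum):
        sel = stratum == s
        rows.append(
            {
                "stratum_abs_lfc": int(s),
                "n": int(sel.sum()),
                "bias": float(err[sel].mean()),
                "rmse": float(np.sqrt(np.mean(err[sel] ** 2))),
            }
        )
    return pd.DataFrame(rows)


def truth_to_frame(truth: SimTruth) -> pd.DataFrame:
    """Flat per-gene truth table for the run outputs."""
    df = pd.DataFrame(
        {
            "gene_id": truth.within_lfc.index,
            "baseline_log2cpm": truth.baseline_log2cpm,
            "dispersion": truth.dispersion,
            "global_null_within": truth.global_null("within_species").to_numpy(),
            "global_null_interaction": truth.global_null("interaction").to_numpy(),
        }
    )
    for c in truth.within_lfc.columns:
        df[f"true_lfc_{c}"] = truth.within_lfc[c].to_numpy()
    for c in truth.interaction_lfc.columns:
        df[f"true_lfc_{c}"] = truth.interaction_lfc[c].to_numpy()
    return df
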