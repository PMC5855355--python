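"""End-to-end orchestration: filter -> TMM -> MDS -> fit -> stage-wise
testing per hypothesis family -> threshold test -> equivalence -> optional
enrichment -> candidate-gene report, with every intermediate written as a
TSV and a JSON run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from . import effects, geneset, io, model, normalize, stagewise
from .simulate import SimConfig, simulate_experiment, truth_to_frame

log = logging.getLogger("qlseq")


@dataclass
class RunConfig:
    """All knobs of one pipeline run; defaults are the study's constants."""

    counts_path: str | None = None
    samples_path: str | None = None
    gene_sets_path: str | None = None
    gene_sets_format: str = "gmt"
    out_dir: str = "qlseq_out"

    min_cpm: float = 15.0
    min_samples: int = 4
    alpha: float = 0.05
    tau_log2: float = 2.0
    delta_log2: float = 2.0
    mds_top: int = 500
    heatmap_top: int = 200
    reference_part: str | None = None

    pool_families: bool = False           # screen both families jointly
    equivalence_universe: str = "filtered"  # or "screened"
    mds_selection: str = "pairwise"
    candidate_genes: list = field(default_factory=list)

    seed: int = 0
    simulate: dict | None = None  # SimConfig fields; replaces counts/samples

    def validate(self) -> None:
        for name in ("min_cpm", "alpha", "tau_log2", "delta_log2", "mds_top", "heatmap_top"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.simulate is None and (self.counts_path is None or self.samples_path is None):
            raise ValueError("either input paths or a simulation section is required")


def config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _file_sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage; returns the result bundle and writes TSVs plus
    ``manifest.json`` into ``cfg.out_dir``."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    produced: dict[str, str] = {}
    bundle: dict = {}

    def emit(name: str, frame: pd.DataFrame, stage: str) -> None:
        path = out / name
        io.write_results_table(frame, path)
        produced[name] = stage

    # --- inputs ------------------------------------------------------------
    truth = None
    if cfg.simulate is not None:
        sim_cfg = SimConfig(**{"seed": cfg.seed, **cfg.simulate})
        counts, samples, truth = simulate_experiment(sim_cfg)
        io.write_count_matrix(counts, out / "counts.tsv")
        io.write_sample_table(samples, out / "samples.tsv")
        emit("truth.tsv", truth_to_frame(truth), "simulate")
        produced["counts.tsv"] = produced["samples.tsv"] = "simulate"
    else:
        counts = io.read_count_matrix(cfg.counts_path)
        samples = io.read_sample_table(cfg.samples_path)
    samples = samples.aligned_to(counts.sample_ids)
    log.info("stage=input genes=%d samples=%d", *counts.shape)

    # --- filter ------------------------------------------------------------
    mask = normalize.filter_low_counts(counts, cfg.min_cpm, cfg.min_samples)
    counts_f = io.CountMatrix(counts.counts.loc[mask.to_numpy()], counts.lib_sizes)
    log.info("stage=filter genes_in=%d genes_out=%d", len(mask), counts_f.shape[0])

    # --- normalization & MDS ----------------------------------------------
    factors = normalize.tmm_factors(counts_f)
    logcpm = normalize.cpm(counts_f, factors, log=True)
    mds = normalize.mds_coordinates(logcpm, top=cfg.mds_top, selection=cfg.mds_selection)
    emit("tmm_factors.tsv", factors.factors.rename_axis("sample_id").reset_index(), "normalize")
    emit("mds_coordinates.tsv", mds.coordinates.rename_axis("sample_id").reset_index(), "normalize")
    bundle["factors"], bundle["mds"], bundle["logcpm"] = factors, mds, logcpm

    # --- model -------------------------------------------------------------
    design = model.build_design(samples, cfg.reference_part)
    offsets = np.log(factors.effective_lib_sizes(counts_f.lib_sizes).to_numpy(float))
    disp = model.estimate_dispersion(counts_f, design, offsets)
    fits = model.fit_genes(counts_f, design, offsets, disp.phi_trend)
    emit(
        "dispersions.tsv",
        pd.DataFrame(
            {
                "gene_id": fits.gene_ids,
                "abundance_log2cpm": disp.abundance,
                "phi_gene": disp.phi_gene,
                "phi_trend": disp.phi_trend,
                "ql_s2_raw": disp.s2_raw,
                "ql_s2_shrunk": disp.s2_shrunk,
            }
        ),
        "fit",
    )
    coef = pd.DataFrame(fits.beta / model.LN2, index=fits.gene_ids, columns=design.columns)
    emit("coefficients_log2.tsv", coef.rename_axis("gene_id").reset_index(), "fit")
    log.info("stage=fit genes=%d prior_df=%.3g", len(fits.gene_ids), disp.prior_df)
    bundle.update(design=design, dispersions=disp, fits=fits)

    # --- stage-wise testing ------------------------------------------------
    within = model.within_species_contrasts(design)
    inter = model.interaction_contrasts(design)
    if cfg.pool_families and len(inter):
        pooled = model.ContrastSet({**within.vectors, **inter.vectors}, "pooled")
        sw_pooled = stagewise.stagewise_analysis(fits, disp, pooled, cfg.alpha)
        sw_within = sw_inter = sw_pooled
    else:
        sw_within = stagewise.stagewise_analysis(fits, disp, within, cfg.alpha)
        sw_inter = (
            stagewise.stagewise_analysis(fits, disp, inter, cfg.alpha)
            if len(inter)
            else None
        )
    emit("stagewise_within_screening.tsv", sw_within.screening, "stagewise")
    emit("stagewise_within_confirmation.tsv", sw_within.confirmation, "stagewise")
    if sw_inter is not None:
        emit("stagewise_interaction_screening.tsv", sw_inter.screening, "stagewise")
        emit("stagewise_interaction_confirmation.tsv", sw_inter.confirmation, "stagewise")
    bundle.update(stagewise_within=sw_within, stagewise_interaction=sw_inter)
    log.info(
        "stage=stagewise screened_within=%d screened_interaction=%s",
        sw_within.n_screened,
        sw_inter.n_screened if sw_inter else "NA",
    )

    # --- threshold (TREAT) test on screened genes ---------------------------
    screened = pd.Series(
        sw_within.screening.screened.to_numpy(), index=sw_within.screening.gene_id
    )
    if screened.any():
        treat = effects.threshold_test_screened(
            fits, disp, within, screened, cfg.tau_log2, cfg.alpha
        )
        emit("threshold_test.tsv", treat, "treat")
        bundle["treat"] = treat

    # --- equivalence --------------------------------------------------------
    if len(inter):
        if cfg.equivalence_universe == "screened":
            uni_mask = sw_inter.screening.screened.to_numpy() if sw_inter else None
        else:
            uni_mask = None
        tost_p = effects.tost_matrix(fits, disp, inter, cfg.delta_log2)
        if uni_mask is not None:
            tost_p = tost_p.loc[uni_mask]
        per_contrast = effects.equivalence_per_contrast(tost_p, cfg.alpha)
        global_eq = effects.equivalence_global(tost_p, cfg.alpha)
        emit("equivalence_per_contrast.tsv", per_contrast.summary, "equivalence")
        emit(
            "equivalence_flags.tsv",
            per_contrast.flags.rename_axis("gene_id").reset_index(),
            "equivalence",
        )
        emit("equivalence_global.tsv", global_eq.reset_index(), "equivalence")
        bundle.update(tost_p=tost_p, equivalence=per_contrast, equivalence_global=global_eq)
        log.info(
            "stage=equivalence avg_prop=%.3f", per_contrast.average_prop_equivalent
        )

    # --- enrichment ---------------------------------------------------------
    if cfg.gene_sets_path:
        gsc = io.read_gene_sets(cfg.gene_sets_path, cfg.gene_sets_format)
        enr = _run_enrichment(cfg, design, fits, disp, sw_within, gsc, logcpm)
        for (spec, part), tab in enr["tables"].items():
            emit(f"enrichment_{spec}_{part}.tsv", tab, "enrich")
        emit(
            "enrichment_shared.tsv",
            pd.DataFrame(
                [
                    {"brain_part": p, "shared_significant_sets": ";".join(s)}
                    for p, s in enr["shared_significant"].items()
                ]
            ),
            "enrich",
        )
        bundle["enrichment"] = enr

    # --- candidate gene report ----------------------------------------------
    if cfg.candidate_genes:
        report = candidate_gene_report(sw_within, mask, cfg.candidate_genes)
        emit("candidate_genes.tsv", report, "report")
        bundle["candidate_report"] = report

    # --- heatmap data -------------------------------------------------------
    heat = top_gene_heatmap_data(sw_within, logcpm, cfg.heatmap_top)
    emit("heatmap_matrix.tsv", heat["matrix"].rename_axis("gene_id").reset_index(), "heatmap")
    emit(
        "heatmap_orders.tsv",
        pd.DataFrame(
            {
                "axis": ["row"] * len(heat["row_order"]) + ["col"] * len(heat["col_order"]),
                "label": heat["row_order"] + heat["col_order"],
            }
        ),
        "heatmap",
    )
    bundle["heatmap"] = heat

    # --- manifest ------------------------------------------------------------
    manifest = {
        "config": asdict(cfg),
        "config_hash": config_hash(cfg),
        "seed": cfg.seed,
        "n_genes_input": int(len(mask)),
        "n_genes_filtered": int(counts_f.shape[0]),
        "n_samples": int(counts_f.shape[1]),
        "outputs": {
            name: {"stage": stage, "sha256": _file_sha(out / name)}
            for name, stage in sorted(produced.items())
        },
        "elapsed_s": round(time.time() - t0, 2),
    }
    # the manifest hash covers outputs only, so a rerun can be compared
    outputs_blob = json.dumps(manifest["outputs"], sort_keys=True).encode()
    manifest["outputs_hash"] = hashlib.sha256(outputs_blob).hexdigest()[:16]
    io.write_manifest(manifest, out / "manifest.json")
    bundle["manifest"] = manifest
    bundle["truth"] = truth
    bundle["counts_filtered"] = counts_f
    return bundle


def _run_enrichment(cfg, design, fits, disp, sw_within, gsc, logcpm):
    """Assemble the per-species stage-wise views and ranking stats that the
    competitive enrichment needs."""
    species = design.species
    within = model.within_species_contrasts(design)
    by_species: dict = {}
    stats_map: dict = {}
    conf = sw_within.confirmation.set_index("gene_id")
    for spec in species:
        names = [n for n in within.names() if n.endswith(f"_{spec}")]
        sig = conf[[f"significant_{n}" for n in names]]
        sig.columns = names

        class _View:
            def __init__(self, sig):
                self._sig = sig

            def significant_matrix(self):
                return self._sig

        by_species[spec] = _View(sig)
        for name in names:
            part = name.split("-", 1)[0]
            pvals = conf[f"p_{name}"].fillna(1.0).to_numpy()
            lfc = conf[f"log2FC_{name}"].to_numpy()
            stats_map[(spec, part)] = pd.Series(
                geneset.gene_stats_from_tests(pvals, lfc, disp.df_total),
                index=conf.index,
            )
    resid = logcpm - pd.DataFrame(
        fits.design.X @ np.linalg.lstsq(fits.design.X, logcpm.T.to_numpy(), rcond=None)[0],
        index=logcpm.columns, columns=logcpm.index,
    ).T
    return geneset.enrichment_workflow(
        by_species, gsc, stats_map,
        residuals=resid, design=design.X, alpha=cfg.alpha,
    )


def candidate_gene_report(
    sw_within, filter_mask: pd.Series, gene_list: list | dict
) -> pd.DataFrame:
    """Per requested gene: detection status, per-contrast log2FC, adjusted
    p and over-expression flag from the within-species analysis."""
    symbol_map = gene_list if isinstance(gene_list, dict) else {g: g for g in gene_list}
    conf = sw_within.confirmation.set_index("gene_id")
    names = [c.removeprefix("significant_") for c in conf.columns if c.startswith("significant_")]
    rows = []
    for symbol, gid in symbol_map.items():
        row: dict = {"symbol": symbol, "gene_id": gid}
        if gid not in conf.index:
            known = gid in filter_mask.index
            row["status"] = "not detected" if known else "unknown id"
            if not known:
                warnings.warn(f"candidate gene id {gid!r} not in the count matrix")
            rows.append(row)
            continue
        row["status"] = "detected"
        for name in names:
            row[f"log2FC_{name}"] = conf.loc[gid, f"log2FC_{name}"]
            row[f"holm_p_{name}"] = conf.loc[gid, f"holm_p_{name}"]
            sig = conf.loc[gid, f"significant_{name}"]
            if pd.isna(sig):
                row[f"overexpressed_{name}"] = pd.NA
            else:
                row[f"overexpressed_{name}"] = bool(sig) and conf.loc[gid, f"log2FC_{name}"] > 0
        rows.append(row)
    return pd.DataFrame(rows)


def top_gene_heatmap_data(sw_within, logcpm: pd.DataFrame, top: int = 200) -> dict:
    """Row-standardised log-cpm of the genes with the lowest screening
    adjusted p-values, with hierarchical-clustering leaf orders
    (Euclidean distance, complete linkage). Ties break by raw p then id."""
    scr = sw_within.screening.sort_values(
        ["padj_screen", "p_screen", "gene_id"], kind="stable"
    )
    if top > len(scr):
        warnings.warn(f"only {len(scr)} genes available; using all")
        top = len(scr)
    genes = list(scr.gene_id.iloc[:top])
    sub = logcpm.loc[genes]
    z = sub.sub(sub.mean(axis=1), axis=0)
    sd = sub.std(axis=1).replace(0.0, 1.0)
    z = z.div(sd, axis=0)
    row_link = hierarchy.linkage(pdist(z.to_numpy()), method="complete")
    col_link = hierarchy.linkage(pdist(z.to_numpy().T), method="complete")
    row_order = [z.index[i] for i in hierarchy.leaves_list(row_link)]
    col_order = [z.columns[i] for i in hierarchy.leaves_list(col_link)]
    return {"matrix": z, "row_order": row_order, "col_order": col_order}
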