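"""Competitive gene-set testing with inter-gene correlation correction.

A competitive test asks whether the genes of a set rank higher (or lower)
in differential expression than the genes outside it. Because co-regulated
genes are correlated, the naive two-sample comparison of mean gene
statistics is anti-conservative; the in-set variance is therefore inflated
by VIF = 1 + (m - 1) * rho, where rho is the mean pairwise correlation of
the set genes' independence-transformed residuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .io import GeneSetCollection
from .stagewise import bh_adjust

DEFAULT_VIF_FLOOR = 1.0
MIN_SET_SIZE = 2


def residual_space(X: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the residual space of a design (n x (n-p))."""
    return linalg.null_space(np.asarray(X, float).T)


def estimate_vif(
    residuals: np.ndarray,
    design: np.ndarray | None = None,
    vif_floor: float = DEFAULT_VIF_FLOOR,
) -> tuple[float, float]:
    """Mean inter-gene correlation and variance inflation factor of a set.

    ``residuals`` is genes x samples. If a design is given, rows are first
    projected onto its residual space so the transformed coordinates are
    exchangeable under the null. Returns ``(rho_bar, VIF)`` with
    ``VIF = 1 + (m-1) rho_bar`` bounded below by ``vif_floor``.
    """
    R = np.atleast_2d(np.asarray(residuals, float))
    m = R.shape[0]
    if m == 1:
        return 0.0, 1.0
    if m < 2:
        raise ValueError("set must contain at least 2 genes")
    if design is not None:
        Q = residual_space(design)
        if Q.shape[1] < 1:
            raise ValueError("residual df is 0; correlation not estimable")
        U = R @ Q
    else:
        U = R - R.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(U, axis=1)
    norms = np.where(norms > 0, norms, 1.0)
    U = U / norms[:, None]
    total = U.sum(axis=0)
    rho = (float(total @ total) - m) / (m * (m - 1))
    vif = max(1.0 + (m - 1) * rho, vif_floor)
    return rho, vif


@dataclass
class GeneSetTestResult:
    set_id: str
    size: int
    rho: float
    vif: float
    statistic: float
    direction: str
    p: float
    padj: float | None = None


def camera_test(
    gene_stats: np.ndarray,
    membership: np.ndarray,
    vif: float = 1.0,
    set_id: str = "",
) -> GeneSetTestResult:
    """Correlation-adjusted competitive test of one set.

    Two-sample comparison of the mean gene-level statistic in the set
    against the rest of the universe, with the in-set contribution of the
    pooled standard error inflated by ``vif``. With ``vif=1`` this is the
    ordinary two-sample t-test. Two-tailed p on ``G - 2`` df.
    """
    z = np.asarray(gene_stats, float)
    sel = np.asarray(membership, bool)
    G = len(z)
    m = int(sel.sum())
    if m < MIN_SET_SIZE:
        raise ValueError(f"set size {m} below minimum {MIN_SET_SIZE}")
    if m >= G:
        raise ValueError("set must be a strict subset of the universe")
    z_in, z_out = z[sel], z[~sel]
    delta = z_in.mean() - z_out.mean()
    s2p = ((m - 1) * z_in.var(ddof=1) + (G - m - 1) * z_out.var(ddof=1)) / (G - 2)
    if abs(delta) < 1e-12:
        # ties to machine precision: no evidence of a shift either way
        t, p, direction = 0.0, 1.0, "none"
    else:
        se = np.sqrt(max(s2p, 1e-300) * (vif / m + 1.0 / (G - m)))
        t = delta / se
        p = float(2.0 * stats.t.sf(abs(t), G - 2))
        direction = "up" if delta > 0 else "down"
    return GeneSetTestResult(
        set_id=set_id, size=m, rho=np.nan, vif=vif, statistic=float(t),
        direction=direction, p=p,
    )


def gene_stats_from_tests(p: np.ndarray, log2fc: np.ndarray, df: float) -> np.ndarray:
    """Signed normal-equivalent score from two-sided p-values and the sign
    of the estimated fold change."""
    p = np.clip(np.asarray(p, float), 1e-300, 1.0)
    z = stats.norm.isf(p / 2.0)
    return np.sign(np.asarray(log2fc, float)) * z


def camera_collection(
    gene_stats: pd.Series,
    gene_sets: GeneSetCollection,
    residuals: pd.DataFrame | None = None,
    design: np.ndarray | None = None,
    alpha: float = 0.05,
    vif_floor: float = DEFAULT_VIF_FLOOR,
    use_vif: bool = True,
) -> pd.DataFrame:
    """Run the competitive test over every set of a collection.

    ``gene_stats`` is indexed by gene id and defines the universe. Sets
    are intersected with the universe; singletons are reported
    descriptively with NA statistics, not tested.
    """
    universe = list(gene_stats.index)
    restricted = gene_sets.restricted_to(universe, min_size=1)
    z = gene_stats.to_numpy(dtype=float)
    pos = {g: i for i, g in enumerate(universe)}
    rows = []
    for sid, genes in restricted.sets.items():
        idx = np.array(sorted(pos[g] for g in genes))
        m = len(idx)
        if m < MIN_SET_SIZE or m >= len(universe):
            rows.append(
                {
                    "set_id": sid, "size": m, "rho": np.nan, "vif": np.nan,
                    "statistic": np.nan, "direction": "NA", "p": np.nan,
                }
            )
            continue
        mask = np.zeros(len(universe), dtype=bool)
        mask[idx] = True
        if use_vif and residuals is not None:
            rho, vif = estimate_vif(
                residuals.loc[[universe[i] for i in idx]].to_numpy(), design, vif_floor
            )
        else:
            rho, vif = 0.0, 1.0
        res = camera_test(z, mask, vif=vif, set_id=sid)
        rows.append(
            {
                "set_id": sid, "size": m, "rho": rho, "vif": vif,
                "statistic": res.statistic, "direction": res.direction, "p": res.p,
            }
        )
    out = pd.DataFrame(rows)
    tested = out.p.notna()
    out["padj"] = np.nan
    if tested.any():
        out.loc[tested, "padj"] = bh_adjust(out.loc[tested, "p"].to_numpy())
    out["significant"] = out.padj <= alpha
    out = out.sort_values(["p", "set_id"], na_position="last").reset_index(drop=True)
    return out


def uniquely_de_genes(sig_matrix: pd.DataFrame) -> pd.Series:
    """Per gene: the single part it is confirmed in, or NA.

    ``sig_matrix`` is a gene x contrast boolean frame for the six
    part-vs-average contrasts of one species.
    """
    filled = sig_matrix.fillna(False).astype(bool)
    counts = filled.sum(axis=1)
    out = pd.Series(pd.NA, index=sig_matrix.index, dtype="object")
    one = counts == 1
    out[one] = filled.loc[one].idxmax(axis=1)
    return out


def enrichment_workflow(
    stagewise_by_species: dict,
    gene_sets: GeneSetCollection,
    fits_stats: dict,
    residuals: pd.DataFrame | None = None,
    design: np.ndarray | None = None,
    alpha: float = 0.05,
    top_k: int = 5,
    universe: str = "all_de",
) -> dict:
    """Competitive enrichment per species x brain part.

    The universe is the union of genes confirmed in any part-vs-average
    contrast ("all DE genes"); per species and part the ranking statistic
    is the signed normal-equivalent score of that part's contrast.
    Reports per-table BH flags, the sets significant in both species per
    part, and the top-k upregulated sets shared by both species.

    ``stagewise_by_species`` maps species -> StagewiseResult of the
    within-species family restricted to that species' six contrasts;
    ``fits_stats`` maps (species, part) -> pd.Series of signed scores
    indexed by gene id.
    """
    de_union: set = set()
    unique_part: dict = {}
    for spec, sw in stagewise_by_species.items():
        sig = sw.significant_matrix()
        filled = sig.fillna(False).astype(bool)
        de_union |= set(sig.index[filled.any(axis=1)])
        unique_part[spec] = uniquely_de_genes(sig)
    if not de_union:
        raise ValueError("empty universe: no DE genes")

    tables: dict = {}
    for (spec, part), stats_series in fits_stats.items():
        z = stats_series[stats_series.index.isin(de_union)]
        if universe == "whole":
            z = stats_series
        tab = camera_collection(
            z, gene_sets, residuals=residuals, design=design, alpha=alpha
        )
        uniq = unique_part[spec]
        target = f"{part}-avg_{spec}"
        uniq_genes = set(uniq.index[(uniq == target).fillna(False)])
        tab["n_unique_de"] = tab.set_id.map(
            lambda sid: len(gene_sets.sets.get(sid, frozenset()) & uniq_genes)
        )
        tables[(spec, part)] = tab

    species = list(stagewise_by_species)
    shared: dict = {}
    top_up: dict = {}
    parts = sorted({part for (_, part) in fits_stats})
    for part in parts:
        sig_sets = None
        for spec in species:
            tab = tables.get((spec, part))
            if tab is None:
                continue
            s = set(tab.set_id[tab.significant.fillna(False)])
            sig_sets = s if sig_sets is None else (sig_sets & s)
        shared[part] = sorted(sig_sets or set())
        ups = []
        for spec in species:
            tab = tables.get((spec, part))
            if tab is None:
                continue
            up = tab[(tab.direction == "up") & tab.significant.fillna(False)]
            ups.append(set(up.set_id))
        both_up = set.intersection(*ups) if ups else set()
        first = tables[(species[0], part)]
        ranked = first[first.set_id.isin(both_up)].nsmallest(top_k, "p")
        top_up[part] = list(ranked.set_id)
    return {"tables": tables, "shared_significant": shared, "top_upregulated": top_up}
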