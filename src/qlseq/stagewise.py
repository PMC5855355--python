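"""Stage-wise testing with gene-level false discovery rate control.

Stage I screens each gene's global null hypothesis (no effect in any
contrast of the family) with a quasi-likelihood omnibus F test and
Benjamini-Hochberg correction at level alpha. Stage II tests the
individual contrasts only within screened genes, controlling the
within-gene family-wise error rate by Holm at the screening-adjusted
level alpha * R / G (R screened of G tested genes). The two stages
together control the overall, gene-level FDR at alpha.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import ContrastSet, DispersionModel, GeneFitSet, ql_f_test


def _check_p(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return p


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = _check_p(p)
    n = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def holm_adjust(p) -> np.ndarray:
    """Holm step-down adjusted p-values."""
    p = _check_p(p)
    n = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * (n - np.arange(n))
    adj = np.maximum.accumulate(ranked)
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def screen(omnibus_p, alpha: float = 0.05) -> tuple[np.ndarray, float, np.ndarray]:
    """Stage-I screen: BH on the per-gene omnibus p-values.

    Returns (screened boolean mask, adjusted confirmation level
    alpha * R / G, BH-adjusted p-values).
    """
    p = _check_p(omnibus_p)
    padj = bh_adjust(p)
    screened = padj <= alpha
    G = len(p)
    R = int(screened.sum())
    alpha_adj = alpha * R / G
    return screened, alpha_adj, padj


def confirm(per_hypothesis_p: np.ndarray, alpha_adj: float) -> tuple[np.ndarray, np.ndarray]:
    """Stage-II confirmation: Holm within each screened gene's row, flag
    hypotheses whose Holm-adjusted p is at most ``alpha_adj``.

    ``per_hypothesis_p`` has one row per screened gene only.
    """
    P = np.atleast_2d(np.asarray(per_hypothesis_p, float))
    if np.any(~np.isfinite(P)):
        raise ValueError("rows must belong to screened genes (no NA p-values)")
    holm = np.vstack([holm_adjust(row) for row in P]) if P.size else P
    return holm <= alpha_adj, holm


@dataclass
class StagewiseResult:
    family: str
    alpha: float
    alpha_adj: float
    n_genes: int
    n_screened: int
    screening: pd.DataFrame     # gene_id, p_screen, padj_screen, screened
    confirmation: pd.DataFrame  # gene_id x contrast: log2FC, p, holm_p, significant

    def flagged_genes(self) -> pd.Series:
        """Per-gene flag: screened and at least one confirmed contrast."""
        sig_cols = [c for c in self.confirmation.columns if c.startswith("significant_")]
        any_sig = self.confirmation[sig_cols].fillna(False).any(axis=1)
        return pd.Series(
            any_sig.to_numpy(), index=self.confirmation.gene_id, name="flagged"
        )

    def significant_matrix(self) -> pd.DataFrame:
        sig_cols = [c for c in self.confirmation.columns if c.startswith("significant_")]
        m = self.confirmation.set_index("gene_id")[sig_cols]
        m.columns = [c.removeprefix("significant_") for c in m.columns]
        return m


def stagewise_analysis(
    fits: GeneFitSet,
    dispersions: DispersionModel,
    contrast_family: ContrastSet,
    alpha: float = 0.05,
) -> StagewiseResult:
    """Run both stages for one hypothesis family.

    The screening statistic is the omnibus QL F test of the family's
    stacked contrast matrix; confirmation tests each contrast separately
    on the screened genes.
    """
    if len(contrast_family) == 0:
        raise ValueError("empty contrast family")
    omni = ql_f_test(fits, dispersions, contrast_family)
    screened, alpha_adj, padj = screen(omni.p.to_numpy(), alpha)
    screening = pd.DataFrame(
        {
            "gene_id": fits.gene_ids,
            "p_screen": omni.p.to_numpy(),
            "padj_screen": padj,
            "screened": screened,
        }
    )

    names = contrast_family.names()
    G = len(fits.gene_ids)
    conf = pd.DataFrame({"gene_id": fits.gene_ids})
    for name, vec in contrast_family.vectors.items():
        conf[f"log2FC_{name}"] = fits.log2fc(vec)
        conf[f"p_{name}"] = np.nan
        conf[f"holm_p_{name}"] = np.nan
        conf[f"significant_{name}"] = pd.array([pd.NA] * G, dtype="boolean")

    idx = np.where(screened)[0]
    if idx.size:
        pmat = np.empty((idx.size, len(names)))
        for j, (name, vec) in enumerate(contrast_family.vectors.items()):
            res = ql_f_test(fits, dispersions, vec[None, :], genes=idx)
            pmat[:, j] = res.p.to_numpy()
        flags, holm = confirm(pmat, alpha_adj)
        for j, name in enumerate(names):
            conf.loc[idx, f"p_{name}"] = pmat[:, j]
            conf.loc[idx, f"holm_p_{name}"] = holm[:, j]
            conf.loc[idx, f"significant_{name}"] = flags[:, j]

    return StagewiseResult(
        family=contrast_family.family,
        alpha=alpha,
        alpha_adj=alpha_adj,
        n_genes=G,
        n_screened=int(screened.sum()),
        screening=screening,
        confirmation=conf,
    )
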