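"""Effect-size-aware tests: fold-change-threshold testing and TOST
equivalence testing.

The threshold test asks whether |log2FC| significantly exceeds a
biologically meaningful threshold tau (default 2, i.e. a fourfold
change): under the composite null |log2FC| <= tau, the p-value sums the
tail probabilities of the test statistic shifted to the nearer and the
farther boundary.

The TOST equivalence test inverts the question: both one-sided tests
against the equivalence bounds -Delta and +Delta (default Delta = 2 on
the log2 scale) must reject for a gene to be declared equivalent; its
p-value is the maximum of the two one-sided p-values. One-sided p-values
are obtained from signed square roots of quasi-likelihood F statistics
computed by refitting with boundary-shifted offsets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .glm import irls_nb
from .model import (
    LN2,
    DispersionModel,
    GeneFitSet,
    contrast_se,
)
from .stagewise import bh_adjust


def _tdist(df: float):
    return stats.norm if np.isinf(df) else stats.t(df)


def treat_test(
    fits: GeneFitSet,
    dispersions: DispersionModel,
    contrast: np.ndarray,
    tau_log2: float = 2.0,
    genes=None,
) -> pd.DataFrame:
    """Test H0: |log2FC| <= tau against |log2FC| > tau for one contrast.

    Uses the QL standard error; p = P(T > (|est|-tau)/SE) + P(T > (|est|+tau)/SE)
    with T on prior+residual df. tau=0 reduces to the ordinary two-sided test.
    """
    if tau_log2 < 0:
        raise ValueError("tau must be non-negative")
    c = np.asarray(contrast, float)
    idx = np.arange(len(fits.gene_ids)) if genes is None else np.arange(len(fits.gene_ids))[genes]
    est_ln = fits.beta[idx] @ c
    se = contrast_se(fits, dispersions, c)[idx]
    tau_ln = tau_log2 * LN2
    td = _tdist(dispersions.df_total)
    t_near = (np.abs(est_ln) - tau_ln) / se
    t_far = (np.abs(est_ln) + tau_ln) / se
    p = np.clip(td.sf(t_near) + td.sf(t_far), 0.0, 1.0)
    return pd.DataFrame(
        {
            "gene_id": [fits.gene_ids[i] for i in idx],
            "log2FC": est_ln / LN2,
            "p": p,
        }
    )


def threshold_test_screened(
    fits: GeneFitSet,
    dispersions: DispersionModel,
    contrasts,
    screened_genes: pd.Series,
    tau_log2: float = 2.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Threshold test over the screened genes of every contrast, with BH
    across screened genes within each contrast."""
    mask = screened_genes.reindex(fits.gene_ids).fillna(False).to_numpy(dtype=bool)
    if not mask.any():
        raise ValueError("no screened genes to test")
    frames = []
    for name, vec in contrasts.vectors.items():
        res = treat_test(fits, dispersions, vec, tau_log2, genes=mask)
        res.insert(1, "contrast", name)
        res["padj"] = bh_adjust(res.p.to_numpy())
        res["significant"] = res.padj <= alpha
        frames.append(res)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# TOST equivalence


def _reparam(X: np.ndarray, c: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Basis change making ``c . beta`` a single coefficient.

    Returns (z1, X_null): the design column carrying the contrast
    coefficient and the null design spanning {X b : c.b = 0}.
    """
    c = np.asarray(c, float)
    B = linalg.null_space(c[None, :])
    A = np.vstack([c, B.T])
    Ainv = np.linalg.inv(A)
    return X @ Ainv[:, 0], X @ Ainv[:, 1:]


def tost_equivalence(
    fits: GeneFitSet,
    dispersions: DispersionModel,
    contrast: np.ndarray,
    delta_log2: float = 2.0,
    genes=None,
) -> pd.DataFrame:
    """TOST p-value for one contrast by boundary-shifted refits.

    The design is reparametrised so the contrast is one coefficient; the
    sample-wise offset is shifted by -Delta*ln2 and +Delta*ln2 times that
    coefficient's column, each shifted null is tested one-sidedly with a
    signed sqrt-F statistic, and the equivalence p-value is the maximum of
    the two one-sided p-values.
    """
    c = np.asarray(contrast, float)
    X = fits.design.X
    XtX_pinv = np.linalg.pinv(X.T @ X)
    if not np.allclose(c @ (XtX_pinv @ (X.T @ X)), c, atol=1e-8):
        raise ValueError("contrast not in the design row space")
    idx = np.arange(len(fits.gene_ids)) if genes is None else np.arange(len(fits.gene_ids))[genes]
    Y = fits.Y[idx]
    phi = dispersions.phi_trend[idx]
    s2 = np.maximum(dispersions.s2_shrunk[idx], 1e-10)
    df2 = dispersions.df_total
    td = _tdist(df2)

    z1, X0 = _reparam(X, c)
    delta_ln = delta_log2 * LN2
    full = irls_nb(Y, X, fits.offsets, phi, beta0=fits.beta[idx])
    gamma = full.beta @ c  # natural-log contrast estimate

    p_sides = []
    for bound in (-delta_ln, +delta_ln):
        red = irls_nb(Y, X0, fits.offsets + bound * z1, phi)
        F = np.maximum(red.deviance - full.deviance, 0.0) / s2
        t = np.sign(gamma - bound) * np.sqrt(F)
        if bound < 0:
            p_sides.append(td.sf(t))   # H1: gamma > -Delta
        else:
            p_sides.append(td.cdf(t))  # H1: gamma < +Delta
    p_low, p_high = p_sides
    p = np.maximum(p_low, p_high)
    return pd.DataFrame(
        {
            "gene_id": [fits.gene_ids[i] for i in idx],
            "log2FC": gamma / LN2,
            "p_lower": p_low,
            "p_upper": p_high,
            "p": p,
        }
    )


def tost_matrix(
    fits: GeneFitSet,
    dispersions: DispersionModel,
    contrasts,
    delta_log2: float = 2.0,
) -> pd.DataFrame:
    """TOST p-values for every contrast in a set (genes x contrasts)."""
    cols = {}
    for name, vec in contrasts.vectors.items():
        cols[name] = tost_equivalence(fits, dispersions, vec, delta_log2).p.to_numpy()
    return pd.DataFrame(cols, index=fits.gene_ids)


def equivalence_per_contrast(tost_p: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """BH within each contrast column; per-contrast equivalent proportion."""
    if tost_p.shape[0] == 0:
        raise ValueError("empty TOST matrix")
    rows = []
    flags = {}
    for name in tost_p.columns:
        col = tost_p[name].to_numpy()
        if np.any(~np.isfinite(col)):
            raise ValueError(f"contrast {name} has missing p-values")
        padj = bh_adjust(col)
        flag = padj <= alpha
        flags[name] = flag
        rows.append(
            {
                "contrast": name,
                "n_genes": len(col),
                "n_equivalent": int(flag.sum()),
                "prop_equivalent": float(flag.mean()),
            }
        )
    summary = pd.DataFrame(rows)
    flags_df = pd.DataFrame(flags, index=tost_p.index)
    return _EquivalenceTables(summary, flags_df)


class _EquivalenceTables:
    """Per-contrast equivalence summary plus per-gene flags."""

    def __init__(self, summary: pd.DataFrame, flags: pd.DataFrame):
        self.summary = summary
        self.flags = flags
        self.average_prop_equivalent = float(summary.prop_equivalent.mean())


def equivalence_global(tost_p: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Across-contrast equivalence: BH over per-gene maximum p-values.

    A gene is globally equivalent only when its worst contrast is
    convincingly equivalent.
    """
    if tost_p.isna().to_numpy().any():
        raise ValueError("every gene must be tested in every contrast")
    max_p = tost_p.max(axis=1)
    padj = bh_adjust(max_p.to_numpy())
    return pd.DataFrame(
        {
            "gene_id": tost_p.index,
            "max_p": max_p.to_numpy(),
            "padj": padj,
            "equivalent": padj <= alpha,
        }
    ).set_index("gene_id")
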