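"""Library-size normalization, low-count filtering and MDS coordinates.

Counts-per-million (CPM) scale expression by effective library size; the
trimmed mean of M-values (TMM) estimates between-sample scaling factors
from doubly trimmed, precision-weighted log expression ratios, correcting
for differences in RNA population composition on top of sequencing depth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CountMatrix


@dataclass
class NormalizationFactors:
    """Per-sample TMM scaling factors, geometric-mean centred to 1."""

    factors: pd.Series
    reference: str

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise ValueError("normalization factors must be positive")

    def effective_lib_sizes(self, lib_sizes: pd.Series) -> pd.Series:
        return lib_sizes * self.factors.reindex(lib_sizes.index)


@dataclass
class MdsResult:
    distances: pd.DataFrame      # samples x samples
    coordinates: pd.DataFrame    # samples x k
    variance_explained: np.ndarray


# ---------------------------------------------------------------------------


def cpm(
    counts: CountMatrix,
    factors: NormalizationFactors | None = None,
    log: bool = False,
    prior_count: float = 2.0,
) -> pd.DataFrame:
    """Counts per million over effective library sizes.

    With ``log``, returns log2(cpm) computed with a prior count scaled per
    sample in proportion to its effective library size (the standard
    effective-library prior convention), so that zeros map to a finite
    floor shared across samples.
    """
    lib = counts.lib_sizes.astype(float)
    if factors is not None:
        lib = lib * factors.factors.reindex(lib.index)
    if (lib <= 0).any():
        raise ValueError("zero effective library size")
    y = counts.counts.to_numpy(dtype=float)
    L = lib.to_numpy()
    if not log:
        return pd.DataFrame(
            y / L[None, :] * 1e6, index=counts.counts.index, columns=counts.counts.columns
        )
    # sample-specific prior proportional to library size
    pc = prior_count * L / L.mean()
    adj_lib = L + 2.0 * pc
    out = np.log2((y + pc[None, :]) / adj_lib[None, :] * 1e6)
    return pd.DataFrame(out, index=counts.counts.index, columns=counts.counts.columns)


def filter_low_counts(
    counts: CountMatrix, min_cpm: float = 15.0, min_samples: int = 4
) -> pd.Series:
    """Boolean mask of genes with cpm >= ``min_cpm`` in >= ``min_samples``
    samples (unit normalization factors at this stage)."""
    if min_samples > counts.shape[1]:
        raise ValueError(
            f"min_samples={min_samples} exceeds sample count {counts.shape[1]}"
        )
    c = cpm(counts)
    mask = (c >= min_cpm).sum(axis=1) >= min_samples
    mask.name = "keep"
    return mask


# ---------------------------------------------------------------------------
# TMM


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """Log2 TMM factor of one sample against the reference."""
    pos = (obs > 0) & (ref > 0)
    if not pos.any():
        raise ValueError("sample shares no positive genes with the reference")
    o, r = obs[pos], ref[pos]
    m = np.log2((o / n_obs) / (r / n_ref))
    a = 0.5 * np.log2((o / n_obs) * (r / n_ref))
    # asymptotic binomial precision weights
    w = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
    finite = np.isfinite(m) & np.isfinite(a)
    m, a, w = m[finite], a[finite], w[finite]
    if abs(np.max(m) - np.min(m)) < 1e-6:
        return 0.0
    n = len(m)
    lo_m = int(np.floor(n * trim_m)) + 1
    hi_m = n + 1 - lo_m
    lo_a = int(np.floor(n * trim_a)) + 1
    hi_a = n + 1 - lo_a
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 0.0
    f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    return 0.0 if not np.isfinite(f) else f


def tmm_factors(
    counts: CountMatrix,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    ref: str | None = None,
) -> NormalizationFactors:
    """Trimmed-mean-of-M-values scaling factors.

    The reference is the sample whose upper-quartile count proportion is
    closest to the mean upper quartile; its own factor is computed like
    any other sample's (it is 1 by construction before centring). Factors
    are centred to geometric mean 1.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    Y = counts.counts.to_numpy(dtype=float)
    if (Y.sum(axis=0) == 0).any():
        raise ValueError("every sample needs at least one positive count")
    lib = counts.lib_sizes.to_numpy(dtype=float)
    samples = counts.sample_ids
    if ref is None:
        q75 = np.array([np.quantile(Y[:, k] / lib[k], 0.75) for k in range(len(samples))])
        ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))
    else:
        ref_idx = samples.index(ref)
    logf = np.array(
        [
            _tmm_pair(Y[:, k], Y[:, ref_idx], lib[k], lib[ref_idx], trim_m, trim_a)
            for k in range(len(samples))
        ]
    )
    f = 2.0 ** logf
    f = f / np.exp(np.mean(np.log(f)))
    return NormalizationFactors(
        pd.Series(f, index=counts.counts.columns, name="tmm"), samples[ref_idx]
    )


# ---------------------------------------------------------------------------
# MDS


def mds_coordinates(
    logcpm: pd.DataFrame,
    top: int = 500,
    k: int = 2,
    selection: str = "pairwise",
) -> MdsResult:
    """Classical MDS of between-sample distances on log expression.

    ``selection="pairwise"`` uses, for each sample pair, the root mean
    square of the ``top`` largest absolute log-expression differences
    (leading log-fold-change distance). ``selection="common"`` uses the
    RMS difference over one common set of the ``top`` most variable genes.
    """
    G, n = logcpm.shape
    if n < 3:
        raise ValueError("MDS needs at least 3 samples")
    top = min(top, G)
    Xm = logcpm.to_numpy()
    D = np.zeros((n, n))
    if selection == "pairwise":
        for i in range(n):
            for j in range(i + 1, n):
                d2 = (Xm[:, i] - Xm[:, j]) ** 2
                if top < G:
                    d2 = np.partition(d2, G - top)[G - top:]
                D[i, j] = D[j, i] = np.sqrt(d2.mean())
    elif selection == "common":
        v = Xm.var(axis=1)
        idx = np.argsort(-v, kind="stable")[:top]
        sub = Xm[idx]
        for i in range(n):
            for j in range(i + 1, n):
                D[i, j] = D[j, i] = np.sqrt(np.mean((sub[:, i] - sub[:, j]) ** 2))
    else:
        raise ValueError(f"unknown selection {selection!r}")

    coords, var_exp = classical_mds(D, k)
    samples = list(logcpm.columns)
    return MdsResult(
        distances=pd.DataFrame(D, index=samples, columns=samples),
        coordinates=pd.DataFrame(
            coords, index=samples, columns=[f"dim{d + 1}" for d in range(k)]
        ),
        variance_explained=var_exp,
    )


def classical_mds(D: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Torgerson double-centring + eigendecomposition of a distance matrix."""
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(-evals)
    evals, evecs = evals[order], evecs[:, order]
    npos = int(np.sum(evals > 1e-10))
    if k > npos:
        raise ValueError(f"k={k} exceeds the {npos} positive eigenvalues")
    coords = evecs[:, :k] * np.sqrt(evals[:k])[None, :]
    pos_sum = evals[:npos].sum()
    var_exp = evals[:k] / pos_sum
    return coords, var_exp


def top_variance_genes(logcpm: pd.DataFrame, top: int) -> list[str]:
    v = logcpm.var(axis=1)
    return list(v.sort_values(ascending=False, kind="stable").index[:top])
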