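"""Gene-wise NB quasi-likelihood modelling of the clustered two-species,
six-brain-part design.

The design has one indicator per individual (fixed effects absorbing both
the species main effect and the between-individual correlation of the six
samples from one fish), shared brain-part effect columns, and
species-by-part interaction columns holding the part-effect differences of
the second species. Species main effects are deliberately not estimable:
they are confounded with housing (one aquarium per species), so only
within-species part contrasts and between-species interaction differences
are testable.

Inference follows the quasi-likelihood route: gene-wise NB dispersions by
Cox-Reid adjusted profile likelihood, an abundance-dispersion trend,
per-gene quasi-likelihood dispersions from the residual deviance, and
empirical-Bayes squeezing toward the trend; hypotheses are tested with
quasi-likelihood F-statistics whose denominator df adds the prior df.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .glm import BatchFit, adjusted_profile_loglik, irls_nb, nb_deviance
from .io import CountMatrix, SampleTable

LN2 = np.log(2.0)


# ---------------------------------------------------------------------------
# Design


@dataclass
class DesignMatrix:
    matrix: pd.DataFrame              # samples x coefficients
    individuals: list[str]
    species: list[str]
    parts: list[str]
    reference_part: str
    rank: int

    @property
    def X(self) -> np.ndarray:
        return self.matrix.to_numpy(dtype=float)

    @property
    def columns(self) -> list[str]:
        return list(self.matrix.columns)

    @property
    def n_coef(self) -> int:
        return self.matrix.shape[1]

    def part_effect_vector(self, part: str, spec: str) -> np.ndarray:
        """Coefficient weights whose dot with beta gives the expression
        effect of ``part`` (relative to the reference part) in species
        ``spec``."""
        v = np.zeros(self.n_coef)
        cols = self.columns
        if part not in self.parts:
            raise ValueError(f"unknown part {part!r}")
        if spec not in self.species:
            raise ValueError(f"unknown species {spec!r}")
        if part != self.reference_part:
            v[cols.index(f"part_{part}")] = 1.0
            if len(self.species) > 1 and spec == self.species[1]:
                v[cols.index(f"int_{part}")] = 1.0
        return v


def build_design(samples: SampleTable, reference_part: str | None = None) -> DesignMatrix:
    """Design matrix for the clustered species x brain-part layout.

    Columns: one indicator per individual, part effects for every
    non-reference part (shared across species), and, with two species,
    interaction columns carrying the second species' part-effect offsets.
    """
    t = samples.table
    parts = samples.brain_parts
    if len(parts) < 2:
        raise ValueError("need at least 2 brain parts")
    if reference_part is None:
        reference_part = parts[0]
    if reference_part not in parts:
        raise ValueError(f"reference part {reference_part!r} not observed")
    individuals = samples.individuals
    species = samples.species
    if len(species) > 2:
        raise ValueError("at most 2 species supported")
    per_ind = t.groupby("individual")["brain_part"].nunique()
    if (per_ind < 2).any():
        raise ValueError(
            f"individuals with fewer than 2 parts: {per_ind.index[per_ind < 2].tolist()}"
        )

    cols: dict[str, np.ndarray] = {}
    for ind in individuals:
        cols[f"ind_{ind}"] = (t.individual == ind).to_numpy(float)
    nonref = [p for p in parts if p != reference_part]
    for p in nonref:
        cols[f"part_{p}"] = (t.brain_part == p).to_numpy(float)
    if len(species) == 2:
        sp2 = species[1]
        is_sp2 = (t.species == sp2).to_numpy(float)
        for p in nonref:
            cols[f"int_{p}"] = cols[f"part_{p}"] * is_sp2

    M = pd.DataFrame(cols, index=t.sample_id)
    X = M.to_numpy(dtype=float)
    rank = int(np.linalg.matrix_rank(X))
    if rank < M.shape[1]:
        # name the offending coefficients via the pivoted QR
        _, _, piv = linalg.qr(X, pivoting=True)
        bad = [M.columns[i] for i in piv[rank:]]
        raise ValueError(f"design rank-deficient; non-estimable coefficients: {bad}")
    return DesignMatrix(
        matrix=M,
        individuals=individuals,
        species=species,
        parts=parts,
        reference_part=reference_part,
        rank=rank,
    )


# ---------------------------------------------------------------------------
# Contrasts


@dataclass
class ContrastSet:
    """Named linear combinations of design coefficients."""

    vectors: dict[str, np.ndarray]
    family: str  # "within_species" | "interaction"

    def __len__(self) -> int:
        return len(self.vectors)

    def names(self) -> list[str]:
        return list(self.vectors)

    def matrix(self) -> np.ndarray:
        return np.stack(list(self.vectors.values()))


def within_species_contrasts(design: DesignMatrix) -> ContrastSet:
    """One contrast per (part, species): that part's effect minus the mean
    effect of the remaining parts, within the species. 12 contrasts for
    the 6-part, 2-species design."""
    parts = design.parts
    if len(parts) < 2:
        raise ValueError("need at least 2 parts")
    vectors: dict[str, np.ndarray] = {}
    for spec in design.species:
        suffix = spec
        effs = {p: design.part_effect_vector(p, spec) for p in parts}
        for p in parts:
            others = [q for q in parts if q != p]
            v = effs[p] - np.mean([effs[q] for q in others], axis=0)
            vectors[f"{p}-avg_{suffix}"] = v
    return ContrastSet(vectors, "within_species")


def interaction_contrasts(design: DesignMatrix) -> ContrastSet:
    """One contrast per unordered part pair: the part-difference in species
    1 minus the same difference in species 2. C(6,2)=15 contrasts."""
    if len(design.species) < 2:
        warnings.warn("single species: no interaction contrasts")
        return ContrastSet({}, "interaction")
    sp1, sp2 = design.species[:2]
    parts = design.parts
    vectors: dict[str, np.ndarray] = {}
    for i, pi in enumerate(parts):
        for pj in parts[i + 1:]:
            d1 = design.part_effect_vector(pi, sp1) - design.part_effect_vector(pj, sp1)
            d2 = design.part_effect_vector(pi, sp2) - design.part_effect_vector(pj, sp2)
            name = f"{pi}v{pj}_{sp1}-{pi}v{pj}_{sp2}"
            vectors[name] = d1 - d2
    return ContrastSet(vectors, "interaction")


# ---------------------------------------------------------------------------
# Fitting


@dataclass
class GeneFitSet:
    """Full-design NB fits for a block of genes, plus what is needed to
    refit under constraints."""

    Y: np.ndarray                # (G, n)
    design: DesignMatrix
    offsets: np.ndarray          # (n,) natural log effective lib sizes
    dispersion: np.ndarray       # (G,) NB dispersion used in the fit
    beta: np.ndarray             # (G, p), natural-log scale
    mu: np.ndarray               # (G, n)
    deviance: np.ndarray         # (G,)
    converged: np.ndarray
    degenerate: np.ndarray
    gene_ids: list[str]

    @property
    def df_residual(self) -> int:
        return self.Y.shape[1] - self.design.n_coef

    def log2fc(self, contrast: np.ndarray) -> np.ndarray:
        return (self.beta @ contrast) / LN2


@dataclass
class GeneFit:
    """Single-gene view of a fit (convenience wrapper)."""

    beta: np.ndarray
    mu: np.ndarray
    deviance: float
    converged: bool
    degenerate: bool


def fit_genes(
    counts: CountMatrix | np.ndarray,
    design: DesignMatrix,
    offsets: np.ndarray,
    dispersion,
    gene_ids: list[str] | None = None,
) -> GeneFitSet:
    """Fit the full NB GLM to every gene at fixed dispersion."""
    if isinstance(counts, CountMatrix):
        Y = counts.counts.to_numpy(dtype=float)
        gene_ids = counts.gene_ids
    else:
        Y = np.asarray(counts, dtype=float)
        if Y.ndim == 1:
            Y = Y[None, :]
        if gene_ids is None:
            gene_ids = [f"g{i}" for i in range(Y.shape[0])]
    phi = np.broadcast_to(np.asarray(dispersion, float), (Y.shape[0],)).copy()
    fit = irls_nb(Y, design.X, offsets, phi)
    return GeneFitSet(
        Y=Y,
        design=design,
        offsets=np.asarray(offsets, float),
        dispersion=phi,
        beta=fit.beta,
        mu=fit.mu,
        deviance=fit.deviance,
        converged=fit.converged,
        degenerate=fit.degenerate,
        gene_ids=list(gene_ids),
    )


def fit_gene(counts_row, design: DesignMatrix, offsets, dispersion: float) -> GeneFit:
    """Fit a single gene; degenerate all-zero rows are flagged, not raised."""
    fs = fit_genes(np.asarray(counts_row, float)[None, :], design, offsets, dispersion)
    return GeneFit(
        beta=fs.beta[0],
        mu=fs.mu[0],
        deviance=float(fs.deviance[0]),
        converged=bool(fs.converged[0]),
        degenerate=bool(fs.degenerate[0]),
    )


# ---------------------------------------------------------------------------
# Dispersion estimation


@dataclass
class DispersionModel:
    phi_gene: np.ndarray      # gene-wise APL estimates
    phi_trend: np.ndarray     # trended values used by the QL fit
    abundance: np.ndarray     # average log2-cpm per gene
    s2_raw: np.ndarray        # residual deviance / residual df
    s2_shrunk: np.ndarray     # EB-squeezed QL dispersions
    prior_df: float           # d0 (may be inf)
    df_residual: int
    prior_s2: float = np.nan  # s0^2, the squeeze target

    @property
    def df_total(self) -> float:
        return self.prior_df + self.df_residual


def _trigamma_inverse(x: np.ndarray) -> np.ndarray:
    """Solve trigamma(y) = x by Newton iteration (vectorised)."""
    x = np.asarray(x, dtype=float)
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if np.all(np.abs(dif) < 1e-8 * y):
            break
    return y


def fit_f_dist(s2: np.ndarray, df1: float) -> tuple[float, float]:
    """Moment-match a scaled F prior to observed variances.

    Models ``s2 ~ s0^2 F(df1, d0)`` by matching the mean and variance of
    ``log s2``; returns ``(s0^2, d0)`` with ``d0 = inf`` when the observed
    spread is no larger than the sampling spread.
    """
    s2 = np.maximum(np.asarray(s2, float), 1e-10)
    z = np.log(s2)
    if s2.size < 2:
        return float(np.exp(z.mean())), np.inf
    e = z - special.digamma(df1 / 2.0) + np.log(df1 / 2.0)
    emean = e.mean()
    evar = np.var(e, ddof=1) - special.polygamma(1, df1 / 2.0)
    if evar <= 0:
        # no excess spread over the sampling distribution: infinite prior
        # df; keep the observed (geometric-mean) scale so identical inputs
        # are returned unchanged
        return float(np.exp(z.mean())), np.inf
    d0 = 2.0 * float(_trigamma_inverse(np.array([evar]))[0])
    s0 = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    return float(s0), float(d0)


def squeeze_var(s2: np.ndarray, df: float) -> tuple[np.ndarray, float, float]:
    """Empirical-Bayes squeeze of per-gene variances toward a common value."""
    s0, d0 = fit_f_dist(s2, df)
    if np.isinf(d0):
        return np.full_like(s2, s0), d0, s0
    shrunk = (d0 * s0 + df * s2) / (d0 + df)
    return shrunk, d0, s0


DEFAULT_PHI_GRID = np.logspace(-4, 0.7, 18)


def estimate_dispersion(
    counts: CountMatrix | np.ndarray,
    design: DesignMatrix,
    offsets: np.ndarray,
    *,
    phi_grid: np.ndarray = DEFAULT_PHI_GRID,
    trend_frac: float = 0.4,
    common_only: bool = False,
) -> DispersionModel:
    """Gene-wise, trended and squeezed quasi-likelihood dispersions.

    Gene-wise NB dispersions maximise the Cox-Reid adjusted profile
    likelihood over a log-spaced grid with quadratic interpolation; a
    robust lowess of log-dispersion on average log2-cpm gives the trend;
    per-gene QL dispersions are residual deviance over residual df at the
    trended dispersion, then squeezed by moment-matched scaled-F
    empirical Bayes. ``common_only`` replaces the trend with one common
    value (testing aid).
    """
    Y = counts.counts.to_numpy(dtype=float) if isinstance(counts, CountMatrix) else np.asarray(counts, float)
    G, n = Y.shape
    p = design.n_coef
    df_resid = n - p
    if df_resid < 1:
        raise ValueError("saturated design: residual df is 0")
    offsets = np.asarray(offsets, float)

    abundance = np.log2(np.maximum(Y / np.exp(offsets)[None, :] * 1e6, 0.5).mean(axis=1))

    apls = np.empty((len(phi_grid), G))
    beta_ws = None
    for i, phi in enumerate(phi_grid):
        apl, fit = adjusted_profile_loglik(Y, design.X, offsets, phi, beta0=beta_ws)
        beta_ws = fit.beta
        apls[i] = apl

    lg = np.log(phi_grid)
    best = np.argmax(apls, axis=0)
    phi_gene = np.empty(G)
    for g in range(G):
        j = best[g]
        if 0 < j < len(phi_grid) - 1:
            y0, y1, y2 = apls[j - 1, g], apls[j, g], apls[j + 1, g]
            denom = y0 - 2 * y1 + y2
            shift = 0.0 if denom >= 0 else 0.5 * (y0 - y2) / denom
            shift = np.clip(shift, -1.0, 1.0)
            phi_gene[g] = np.exp(lg[j] + shift * (lg[1] - lg[0]))
        else:
            phi_gene[g] = phi_grid[j]

    if common_only or G < 10:
        phi_trend = np.full(G, float(np.median(phi_gene)))
    else:
        sm = lowess(
            np.log(phi_gene), abundance, frac=trend_frac, it=3,
            xvals=abundance, return_sorted=False,
        )
        phi_trend = np.exp(sm)

    fit = irls_nb(Y, design.X, offsets, phi_trend, beta0=beta_ws)
    s2_raw = np.maximum(fit.deviance, 0.0) / df_resid
    s2_shrunk, d0, s0 = squeeze_var(s2_raw, df_resid)
    return DispersionModel(
        phi_gene=phi_gene,
        phi_trend=phi_trend,
        abundance=abundance,
        s2_raw=s2_raw,
        s2_shrunk=s2_shrunk,
        prior_df=d0,
        df_residual=df_resid,
        prior_s2=s0,
    )


# ---------------------------------------------------------------------------
# Quasi-likelihood F tests


def contrast_null_design(X: np.ndarray, C: np.ndarray) -> tuple[np.ndarray, int]:
    """Design of the null model where every row of ``C`` annihilates beta.

    Projects the coefficient space onto the orthogonal complement of the
    contrast rows; returns the reduced design and the number of
    independent constraints.
    """
    C = np.atleast_2d(np.asarray(C, float))
    if np.allclose(C, 0):
        raise ValueError("zero contrast vector")
    ns = linalg.null_space(C)
    df1 = C.shape[1] - ns.shape[1]
    return X @ ns, df1


def ql_f_test(
    fits: GeneFitSet,
    dispersions: DispersionModel,
    contrasts: ContrastSet | np.ndarray,
    *,
    genes: np.ndarray | None = None,
) -> pd.DataFrame:
    """Quasi-likelihood F test of one or several contrasts jointly.

    F = (deviance of the constrained refit - full deviance) / (df1 * s2~),
    with denominator df = prior df + residual df. Per-contrast log2 fold
    changes come from the full fit. ``genes`` restricts to a boolean mask
    or index array of genes.
    """
    if isinstance(contrasts, ContrastSet):
        C = contrasts.matrix()
        names = contrasts.names()
    else:
        C = np.atleast_2d(np.asarray(contrasts, float))
        names = [f"c{i}" for i in range(C.shape[0])]
    if C.size == 0:
        raise ValueError("empty contrast set")
    X = fits.design.X
    # estimability: every contrast row must lie in the row space of X
    XtX_pinv = np.linalg.pinv(X.T @ X)
    proj = C @ (XtX_pinv @ (X.T @ X))
    if not np.allclose(proj, C, atol=1e-8):
        raise ValueError("contrast not estimable on this design")

    idx = np.arange(fits.Y.shape[0]) if genes is None else np.arange(fits.Y.shape[0])[genes]
    Y = fits.Y[idx]
    phi = dispersions.phi_trend[idx]
    full = irls_nb(Y, X, fits.offsets, phi, beta0=fits.beta[idx])
    X0, df1 = contrast_null_design(X, C)
    red = irls_nb(Y, X0, fits.offsets, phi)
    num = np.maximum(red.deviance - full.deviance, 0.0)
    s2 = dispersions.s2_shrunk[idx]
    F = num / (df1 * np.maximum(s2, 1e-10))
    df2 = dispersions.df_total
    if np.isinf(df2):
        p = stats.chi2.sf(F * df1, df1)
    else:
        p = stats.f.sf(F, df1, df2)
    out = pd.DataFrame(
        {
            "gene_id": [fits.gene_ids[i] for i in idx],
            "F": F,
            "df1": df1,
            "df2": df2,
            "p": p,
        }
    )
    for name, vec in zip(names, C):
        out[f"log2FC_{name}"] = (full.beta @ vec) / LN2
    return out


def coef_covariance(fits: GeneFitSet, dispersions: DispersionModel) -> np.ndarray:
    """Per-gene coefficient covariance ``s2~ (X'WX)^-1`` on the natural-log
    scale (quasi-likelihood scaled)."""
    X = fits.design.X
    w = fits.mu / (1.0 + fits.dispersion[:, None] * fits.mu)
    Xw = w[:, :, None] * X[None, :, :]
    A = np.matmul(np.swapaxes(Xw, 1, 2), X[None, :, :])
    cov = np.linalg.inv(A + 1e-10 * np.eye(X.shape[1])[None])
    return cov * dispersions.s2_shrunk[:, None, None]


def contrast_se(fits: GeneFitSet, dispersions: DispersionModel, contrast: np.ndarray) -> np.ndarray:
    """QL standard error of ``contrast . beta`` (natural-log scale)."""
    cov = coef_covariance(fits, dispersions)
    c = np.asarray(contrast, float)
    var = np.einsum("i,gij,j->g", c, cov, c)
    return np.sqrt(np.maximum(var, 1e-300))
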