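"""Variance-component (SKAT) burden tests and Fisher-method combination.

The sequence kernel association test aggregates weighted per-variant
score statistics against a covariate-adjusted least-squares null and is
robust to bidirectional effects. The statistic Q = ||W G' r||^2 / s^2
follows a mixture sum(lambda_i chi2_1) under the null, with lambda the
eigenvalues of W G' P G W (P the projection off the covariate space).
Group p-values from independent callsets are combined with Fisher's
method: -2 sum(ln p_i) ~ chi-square with 2k degrees of freedom.

P-values use Liu moment matching by default, with an exact Imhof
numerical-inversion evaluator for small groups and as a cross-check.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, stats

from lipidwgs.assoc import _design, mean_impute
from lipidwgs.containers import GenotypeMatrix, VariantGroup

log = logging.getLogger(__name__)

DEFAULT_MAX_MAF = 0.01
BETA_WEIGHT_A, BETA_WEIGHT_B = 1.0, 25.0


@dataclass
class NullModel:
    """Least-squares null fit: residuals plus the covariate projector."""

    qx: np.ndarray  # orthonormal basis of the covariate column space
    residuals: np.ndarray
    sigma2: float  # residual variance, RSS / (n - p)
    df: int

    def project(self, a: np.ndarray) -> np.ndarray:
        """Project columns of ``a`` off the covariate space."""
        return a - self.qx @ (self.qx.T @ a)


def fit_null(trait: np.ndarray | pd.Series, covariates: pd.DataFrame) -> NullModel:
    """Fit the covariate-only model (intercept always included).

    Raises on rank-deficient covariates, naming the collinear columns.
    """
    y = np.asarray(trait, dtype=float)
    X = _design(covariates)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns by incremental rank
        bad = []
        kept = np.empty((X.shape[0], 0))
        names = ["intercept"] + list(covariates.columns)
        for j in range(X.shape[1]):
            cand = np.hstack([kept, X[:, [j]]])
            if np.linalg.matrix_rank(cand) > kept.shape[1]:
                kept = cand
            else:
                bad.append(names[j] if j < len(names) else f"column_{j}")
        raise ValueError(f"rank-deficient covariates; collinear columns: {bad}")
    q, _ = np.linalg.qr(X)
    r = y - q @ (q.T @ y)
    df = len(y) - X.shape[1]
    sigma2 = float(r @ r) / df
    return NullModel(qx=q, residuals=r, sigma2=sigma2, df=df)


def beta_maf_weights(maf: np.ndarray, a: float = BETA_WEIGHT_A, b: float = BETA_WEIGHT_B) -> np.ndarray:
    """SKAT's default Beta(1,25)-density weights on MAF."""
    return stats.beta.pdf(np.asarray(maf, dtype=float), a, b)


def liu_pvalue(q: float, lambdas: np.ndarray) -> float:
    """Moment-matching tail probability for Q ~ sum(lambda_i chi2_1).

    Matches mean, variance and skewness to a (non)central chi-square
    (Liu-Tang-Zhang). Exact when a single eigenvalue remains.
    """
    lam = np.asarray(lambdas, dtype=float)
    lam = lam[lam > 1e-12 * max(lam.max(), 1.0)] if lam.size else lam
    if lam.size == 0:
        return 1.0
    if lam.size == 1:
        return float(stats.chi2.sf(q / lam[0], df=1))
    c1, c2, c3, c4 = (float((lam ** k).sum()) for k in (1, 2, 3, 4))
    s1 = c3 / c2 ** 1.5
    s2 = c4 / c2 ** 2
    if s1 ** 2 > s2:
        a = 1.0 / (s1 - math.sqrt(s1 ** 2 - s2))
        ncp = s1 * a ** 3 - a ** 2
        dof = a ** 2 - 2 * ncp
    else:
        ncp = 0.0
        dof = 1.0 / s2
    mu_q, sigma_q = c1, math.sqrt(2 * c2)
    mu_x, sigma_x = dof + ncp, math.sqrt(2 * (dof + 2 * ncp))
    t = (q - mu_q) / sigma_q * sigma_x + mu_x
    return float(stats.ncx2.sf(t, dof, ncp)) if ncp > 0 else float(stats.chi2.sf(t, dof))


def imhof_pvalue(q: float, lambdas: np.ndarray) -> float:
    """Exact tail probability by numerical inversion (Imhof's formula)."""
    lam = np.asarray(lambdas, dtype=float)
    lam = lam[lam > 1e-12 * max(lam.max(), 1.0)] if lam.size else lam
    if lam.size == 0:
        return 1.0

    def integrand(u: float) -> float:
        theta = 0.5 * np.sum(np.arctan(lam * u)) - 0.5 * q * u
        rho = np.exp(0.25 * np.sum(np.log1p((lam * u) ** 2)))
        return math.sin(theta) / (u * rho)

    import warnings

    with warnings.catch_warnings():
        # slowly decaying oscillatory tail; accuracy is ample for p-values
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        val, _ = integrate.quad(integrand, 0.0, np.inf, limit=400)
    return float(min(max(0.5 + val / math.pi, 0.0), 1.0))


@dataclass
class SkatResult:
    group_id: str
    q: float
    p: float
    n_carriers: int
    n_variants: int

    def __post_init__(self) -> None:
        if self.q < 0:
            raise ValueError("Q statistic must be nonnegative")


def skat_test(
    group_genotypes: np.ndarray | GenotypeMatrix,
    null: NullModel,
    weights: np.ndarray | None = None,
    max_maf: float = DEFAULT_MAX_MAF,
    method: str = "liu",
    group_id: str = "",
) -> SkatResult | None:
    """SKAT for one variant group against a fitted null.

    ``group_genotypes`` is the samples x group-variants dosage block
    (missing mean-imputed). Variants at MAF above ``max_maf`` (or
    monomorphic) are dropped; an emptied group returns None with a log
    entry. Default weights are the Beta(1,25) density at each MAF;
    ``method`` selects 'liu' moment matching or exact 'imhof'.
    """
    G = group_genotypes.dosages if isinstance(group_genotypes, GenotypeMatrix) else group_genotypes
    G = np.asarray(G, dtype=float)
    if G.ndim == 1:
        G = G[:, None]
    with np.errstate(invalid="ignore"):
        af = np.nanmean(G, axis=0) / 2.0
    maf = np.minimum(af, 1.0 - af)
    keep = (maf > 0) & (maf <= max_maf)
    if not keep.any():
        log.info("group %s: no variants at MAF <= %g; skipped", group_id or "<anon>", max_maf)
        return None
    G = mean_impute(G[:, keep])
    maf = maf[keep]
    w = beta_maf_weights(maf) if weights is None else np.asarray(weights, dtype=float)[keep]

    A = G * w  # weighted genotype block
    score = A.T @ null.residuals
    q = float(score @ score) / null.sigma2
    PA = null.project(A)
    lam = np.linalg.eigvalsh(PA.T @ PA)
    pfun = imhof_pvalue if method == "imhof" else liu_pvalue
    p = pfun(q, lam)
    carriers = int(((np.nan_to_num(G) > 0.5).any(axis=1)).sum())
    return SkatResult(group_id=group_id, q=q, p=min(max(p, np.finfo(float).tiny), 1.0),
                      n_carriers=carriers, n_variants=int(keep.sum()))


def fisher_combine(pvalues: list[float] | np.ndarray) -> float:
    """Fisher's method: -2 sum(ln p) ~ chi-square(2k); upper-tail p.

    Zero inputs are clamped to the smallest positive float with a log
    entry. A single p-value is returned unchanged (the formula is the
    identity at k=1).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if (p <= 0).any():
        log.warning("clamping %d non-positive p-values", int((p <= 0).sum()))
        p = np.maximum(p, np.finfo(float).tiny)
    if (p > 1).any():
        raise ValueError("p-values above 1")
    x2 = -2.0 * np.log(p).sum()
    return float(stats.chi2.sf(x2, df=2 * p.size))


def burden_scan(
    groups: list[VariantGroup],
    callsets: list[tuple[GenotypeMatrix, NullModel]],
    max_maf: float = DEFAULT_MAX_MAF,
    family_alpha: float = 0.05,
    n_tests: int | None = None,
) -> pd.DataFrame:
    """Per-group SKAT in each callset, Fisher-combined, with Bonferroni flag.

    The significance threshold is ``family_alpha`` divided by the number
    of groups tested (override with ``n_tests``). Callsets carry
    disjoint samples, so Fisher's independence assumption holds.
    """
    indexes = [gm.variant_index() for gm, _ in callsets]
    rows = []
    for g in groups:
        per_callset = []
        n_var = 0
        for (gm, null), idx in zip(callsets, indexes):
            cols = idx.get_indexer(list(g.variant_ids))
            cols = cols[cols >= 0]
            if cols.size == 0:
                per_callset.append(np.nan)
                continue
            res = skat_test(gm.dosages[:, cols], null, max_maf=max_maf, group_id=g.group_id)
            per_callset.append(res.p if res is not None else np.nan)
            if res is not None:
                n_var = max(n_var, res.n_variants)
        usable = [p for p in per_callset if not np.isnan(p)]
        combined = fisher_combine(usable) if usable else np.nan
        rows.append([g.group_id, g.method, *per_callset, combined, n_var])
    cols = (["group_id", "method"]
            + [f"p_callset{k + 1}" for k in range(len(callsets))]
            + ["combined_p", "n_variants"])
    out = pd.DataFrame(rows, columns=cols)
    threshold = family_alpha / (n_tests if n_tests is not None else max(len(groups), 1))
    out["alpha"] = threshold
    out["significant"] = out["combined_p"] < threshold
    return out
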