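"""Common/low-frequency single-variant association and meta-analysis.

Per-variant effects come from fixed-effect least squares (equivalent,
by Frisch-Waugh, to regressing covariate-residualized trait on
covariate-residualized dosage), with Wald p-values. Callset results
are combined by inverse-variance-weighted fixed-effect meta-analysis
with Cochran's Q heterogeneity, test-statistic inflation is summarized
by the genomic-control lambda, and iterative conditional scans peel
independent signals at a locus until the top conditional p exceeds
1e-4.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from lipidwgs.containers import GenotypeMatrix

log = logging.getLogger(__name__)

CHI2_MEDIAN_1DF = 0.45493642311957285  # chi-square(1) median

DEFAULT_MAF_MIN = 0.001
DEFAULT_ALPHA_GW = 5e-8
DEFAULT_COND_STOP_P = 1e-4


def _design(covariates: pd.DataFrame) -> np.ndarray:
    """Covariate design matrix with intercept; categoricals dummy-coded."""
    num = covariates.select_dtypes(include=[np.number])
    cat = covariates.select_dtypes(exclude=[np.number])
    parts = [np.ones((len(covariates), 1))]
    if num.shape[1]:
        parts.append(num.to_numpy(dtype=float))
    if cat.shape[1]:
        parts.append(pd.get_dummies(cat, drop_first=True).to_numpy(dtype=float))
    return np.hstack(parts)


def _residualize(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ coef


def mean_impute(dosages: np.ndarray) -> np.ndarray:
    """Replace missing dosages with the per-variant mean (regression only)."""
    out = dosages.copy()
    mu = np.nanmean(out, axis=0)
    idx = np.where(np.isnan(out))
    out[idx] = np.take(mu, idx[1])
    return out


def assoc_scan(
    genotypes: GenotypeMatrix,
    trait: np.ndarray | pd.Series,
    covariates: pd.DataFrame,
    maf_min: float = DEFAULT_MAF_MIN,
) -> pd.DataFrame:
    """Per-variant least-squares association of a quantitative trait.

    Covariates should include age, age^2, sex and cohort (ancestry where
    multi-ethnic). Variants with MAF below ``maf_min`` or constant after
    imputation are excluded. Returns a frame with vid, beta, se, p, n,
    maf (per ALT-allele coding; effect allele is ALT).
    """
    y = np.asarray(trait, dtype=float)
    keep_s = ~np.isnan(y)
    y = y[keep_s]
    X = _design(covariates)[keep_s]
    G = genotypes.dosages[keep_s]

    with np.errstate(invalid="ignore"):
        af = np.nanmean(G, axis=0) / 2.0
    maf = np.minimum(af, 1.0 - af)
    n_obs = (~np.isnan(G)).sum(axis=0)
    G = mean_impute(G)

    y_res = _residualize(y, X)
    # residualize all dosage columns against covariates at once
    coef, *_ = np.linalg.lstsq(X, G, rcond=None)
    G_res = G - X @ coef

    gtg = (G_res ** 2).sum(axis=0)
    usable = (maf >= maf_min) & (gtg > 1e-10)
    if (~usable & (gtg <= 1e-10) & (maf >= maf_min)).any():
        log.info("skipping %d variants constant after covariate adjustment",
                 int((~usable & (gtg <= 1e-10) & (maf >= maf_min)).sum()))

    n, p_cov = X.shape
    df = n - p_cov - 1
    beta = np.full(genotypes.n_variants, np.nan)
    se = np.full(genotypes.n_variants, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        b = (G_res * y_res[:, None]).sum(axis=0) / gtg
        rss = (y_res ** 2).sum() - b ** 2 * gtg
        s2 = np.maximum(rss, 0.0) / df
        se_all = np.sqrt(s2 / gtg)
    beta[usable] = b[usable]
    se[usable] = se_all[usable]
    tstat = beta / se
    pval = 2.0 * stats.t.sf(np.abs(tstat), df)

    out = pd.DataFrame({
        "vid": genotypes.variants["vid"],
        "chrom": genotypes.variants["chrom"],
        "pos": genotypes.variants["pos"],
        "ref": genotypes.variants["ref"],
        "alt": genotypes.variants["alt"],
        "effect_allele": genotypes.variants["alt"],
        "beta": beta,
        "se": se,
        "p": pval,
        "n": n_obs,
        "maf": maf,
    })
    return out[usable].reset_index(drop=True)


def ivw_meta(results: list[pd.DataFrame]) -> pd.DataFrame:
    """Inverse-variance-weighted fixed-effect meta-analysis across callsets.

    beta = sum(b_i/se_i^2) / sum(1/se_i^2), se = sum(1/se_i^2)^-1/2;
    Cochran's Q heterogeneity p (``het_p``) is attached (NaN for
    single-callset variants). Variants absent from every callset are
    absent from the output.
    """
    if not results:
        raise ValueError("no callset results to meta-analyze")
    tagged = []
    for k, r in enumerate(results):
        r = r.dropna(subset=["beta", "se"]).copy()
        r["_callset"] = k
        tagged.append(r)
    allr = pd.concat(tagged, ignore_index=True)

    rows = []
    for vid, grp in allr.groupby("vid", sort=False):
        w = 1.0 / grp["se"].to_numpy() ** 2
        b = grp["beta"].to_numpy()
        beta = float((w * b).sum() / w.sum())
        se = float(w.sum() ** -0.5)
        z = beta / se
        p = 2.0 * stats.norm.sf(abs(z))
        k = len(grp)
        if k > 1:
            q = float((w * (b - beta) ** 2).sum())
            het_p = float(stats.chi2.sf(q, k - 1))
        else:
            q, het_p = np.nan, np.nan
        first = grp.iloc[0]
        rows.append((vid, first["chrom"], first["pos"], first["ref"], first["alt"],
                     first["effect_allele"], beta, se, p, int(grp["n"].sum()),
                     float((grp["maf"] * grp["n"]).sum() / grp["n"].sum()), k, q, het_p))
    return pd.DataFrame(rows, columns=["vid", "chrom", "pos", "ref", "alt",
                                       "effect_allele", "beta", "se", "p", "n",
                                       "maf", "n_callsets", "het_q", "het_p"])


def genomic_lambda(pvals: np.ndarray | pd.Series, min_n: int = 100) -> float:
    """Genomic-control inflation factor.

    lambda = median of the chi-square(1) quantiles implied by the
    p-values, divided by the null median 0.4549.
    """
    p = np.asarray(pvals, dtype=float)
    p = p[~np.isnan(p)]
    if p.size == 0:
        raise ValueError("no p-values supplied")
    if p.size < min_n:
        log.warning("genomic lambda on only %d p-values", p.size)
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / CHI2_MEDIAN_1DF)


def conditional_scan(
    genotypes: GenotypeMatrix,
    trait: np.ndarray | pd.Series,
    covariates: pd.DataFrame,
    stop_p: float = DEFAULT_COND_STOP_P,
    maf_min: float = DEFAULT_MAF_MIN,
    max_signals: int | None = None,
) -> pd.DataFrame:
    """Iteratively peel independent signals at a locus.

    Repeatedly runs the association scan with previously selected
    variants added as covariates; stops when the minimum conditional p
    exceeds ``stop_p``. Leads collinear with existing covariates are
    skipped with a log entry. Returns selected signals in discovery
    order with their conditional statistics.
    """
    max_signals = max_signals if max_signals is not None else genotypes.n_variants
    covs = covariates.copy()
    selected: list[dict] = []
    taken: set[str] = set()
    imputed = mean_impute(genotypes.dosages)
    vid_pos = {v: j for j, v in enumerate(genotypes.variants["vid"])}

    for _ in range(max_signals):
        res = assoc_scan(genotypes, trait, covs, maf_min=maf_min)
        res = res[~res["vid"].isin(taken)]
        res = res.dropna(subset=["p"])
        if res.empty:
            break
        top = res.loc[res["p"].idxmin()]
        if top["p"] > stop_p:
            break
        j = vid_pos[top["vid"]]
        g = imputed[:, j]
        X = _design(covs)
        resid = _residualize(g, X)
        if resid.var() < 1e-10 * max(g.var(), 1e-30):
            log.info("lead %s collinear with current covariates; skipped", top["vid"])
            taken.add(top["vid"])
            continue
        selected.append({"vid": top["vid"], "beta": top["beta"], "se": top["se"],
                         "p": top["p"], "order": len(selected) + 1})
        taken.add(top["vid"])
        covs[f"cond_{top['vid']}"] = g
    return pd.DataFrame(selected, columns=["vid", "beta", "se", "p", "order"])
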