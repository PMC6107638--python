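"""Joint monogenic/polygenic analysis of extreme LDL-C.

Extremes are the top/bottom 5th ancestry-specific percentiles of
LDL-C. Monogenic carriers hold a qualifying variant (pathogenic or
likely-pathogenic with no benign assertion, or loss-of-function, below
the gene's allele-frequency bound) under the gene's inheritance model:
one allele suffices for dominant genes; recessive genes need a
homozygote or two distinct heterozygous qualifying variants (unphased
putative compound het). Polygenic scores are weighted effect-allele
dosage sums built three ways from GWAS summary statistics — lead
variants only, clumping + p-thresholding, and a closed-form LD
shrinkage family over a causal-fraction grid — with the best model
chosen by training R^2. Carrier status and high/low score flags enter
logistic (odds of extreme) and linear (mg/dl) models jointly with age,
age^2 and sex, per ancestry, and case-based population attributable
fractions PAF = (exposed fraction among cases) x (OR-1)/OR are
reported in percent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from lipidwgs.containers import GenotypeMatrix

log = logging.getLogger(__name__)

AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
DEFAULT_EXTREME_Q = 0.05
DOMINANT_AF_MAX = 0.01
RECESSIVE_AF_MAX = 0.10


@dataclass
class MendelianGeneConfig:
    """One Mendelian dyslipidemia gene and its qualifying-variant rules."""

    gene: str
    inheritance: str = "dominant"
    max_af: float | None = None  # default 1% dominant, 10% recessive
    direction: str = "raising"

    def __post_init__(self) -> None:
        if self.inheritance not in {"dominant", "recessive"}:
            raise ValueError(f"unknown inheritance {self.inheritance!r}")
        if self.max_af is None:
            self.max_af = DOMINANT_AF_MAX if self.inheritance == "dominant" else RECESSIVE_AF_MAX
        if not 0 < self.max_af < 1:
            raise ValueError("max_af must lie in (0, 1)")


#: the six genes screened for LDL-raising / LDL-lowering mutations
LDL_GENE_CONFIGS = [
    MendelianGeneConfig("LDLR", "dominant", direction="raising"),
    MendelianGeneConfig("APOB", "dominant", direction="raising"),
    MendelianGeneConfig("PCSK9", "dominant", direction="raising"),
    MendelianGeneConfig("ABCG5", "recessive", direction="raising"),
    MendelianGeneConfig("ABCG8", "recessive", direction="raising"),
    MendelianGeneConfig("LDLRAP1", "recessive", direction="raising"),
]


def define_extremes(
    ldl: np.ndarray | pd.Series,
    ancestry: np.ndarray | pd.Series,
    q: float = DEFAULT_EXTREME_Q,
    min_n: int = 20,
) -> tuple[pd.Series, pd.DataFrame]:
    """Label samples in the top/bottom q-th ancestry-specific percentile.

    Cutoffs use the linear-interpolation quantile convention; 'extreme
    high' is strictly above the upper cutoff and 'extreme low' strictly
    below the lower one, so exact ties stay 'neither'. Returns (labels,
    per-ancestry cutoff table). Raises for ancestries below ``min_n``.
    """
    ldl = pd.Series(np.asarray(ldl, dtype=float))
    anc = pd.Series(np.asarray(ancestry, dtype=object))
    labels = pd.Series("neither", index=ldl.index, dtype=object)
    rows = []
    for a, idx in anc.groupby(anc).groups.items():
        vals = ldl.loc[idx].dropna()
        if len(vals) < min_n:
            raise ValueError(f"ancestry {a!r} has only {len(vals)} samples (< {min_n})")
        lo = float(np.quantile(vals, q))
        hi = float(np.quantile(vals, 1.0 - q))
        labels.loc[idx] = np.where(ldl.loc[idx] > hi, "extreme_high",
                                   np.where(ldl.loc[idx] < lo, "extreme_low", "neither"))
        rows.append((a, lo, hi))
    cutoffs = pd.DataFrame(rows, columns=["ancestry", "low_cutoff", "high_cutoff"])
    return labels, cutoffs


def _qualifying_variants(variants: pd.DataFrame, af: np.ndarray,
                         cfg: MendelianGeneConfig) -> np.ndarray:
    """Boolean mask of variants qualifying under a gene's rules."""
    in_gene = (variants["gene"] == cfg.gene).to_numpy()
    clin = variants.get("clinvar", pd.Series("", index=variants.index)).fillna("").str.lower()
    pathogenic = (clin.str.contains("pathogenic") & ~clin.str.contains("benign")).to_numpy()
    cons = variants.get("consequence", pd.Series("", index=variants.index)).fillna("").str.lower()
    from lipidwgs.groups import LOF_CONSEQUENCES
    lof = cons.isin({c.lower() for c in LOF_CONSEQUENCES}).to_numpy()
    return in_gene & (pathogenic | lof) & (af < cfg.max_af)


def classify_monogenic(
    genotypes: GenotypeMatrix,
    gene_configs: list[MendelianGeneConfig] | None = None,
) -> pd.DataFrame:
    """Carrier flags per configured Mendelian gene.

    Dominant: >= 1 qualifying allele. Recessive: a qualifying homozygote
    or two distinct heterozygous qualifying variants in the gene
    (unphased putative compound het). Variants in genes absent from the
    configuration are ignored with a log entry. Adds ``carrier_raising``
    / ``carrier_lowering`` any-gene columns.
    """
    configs = gene_configs if gene_configs is not None else LDL_GENE_CONFIGS
    v = genotypes.variants
    known = {c.gene for c in configs}
    labeled = set(v.loc[v["gene"].fillna("") != "", "gene"]) if "gene" in v.columns else set()
    for g in sorted(labeled - known):
        log.info("gene %s absent from Mendelian configuration; variants ignored", g)

    af = genotypes.alt_frequency()
    out = pd.DataFrame(index=genotypes.samples.index)
    raising = np.zeros(genotypes.n_samples, dtype=bool)
    lowering = np.zeros(genotypes.n_samples, dtype=bool)
    for cfg in configs:
        mask = _qualifying_variants(v, af, cfg)
        dos = np.nan_to_num(genotypes.dosages[:, mask])
        if cfg.inheritance == "dominant":
            carrier = (dos >= 1).any(axis=1)
        else:
            hom = (dos >= 2).any(axis=1)
            compound = (dos == 1).sum(axis=1) >= 2
            carrier = hom | compound
        out[f"carrier_{cfg.gene}"] = carrier.astype(int)
        if cfg.direction == "raising":
            raising |= carrier
        else:
            lowering |= carrier
    out["carrier_raising"] = raising.astype(int)
    out["carrier_lowering"] = lowering.astype(int)
    return out


# ---------------------------------------------------------------------------
# polygenic score construction


@dataclass
class ScoreModel:
    """Variant weights for an additive effect-allele dosage score."""

    method: str  # lead_variants | p_r2_threshold | shrinkage
    table: pd.DataFrame  # vid, chrom, pos, effect_allele, other_allele, weight
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ambiguous = [
            vid for vid, ea, oa in zip(self.table.get("vid", []),
                                       self.table.get("effect_allele", []),
                                       self.table.get("other_allele", []))
            if (str(ea).upper(), str(oa).upper()) in AMBIGUOUS_PAIRS
        ]
        if ambiguous:
            raise ValueError(f"strand-ambiguous variants in score model: {ambiguous[:5]}")

    @property
    def n_variants(self) -> int:
        return len(self.table)


_SCORE_COLS = ["vid", "chrom", "pos", "effect_allele", "other_allele", "weight"]


def _drop_ambiguous(stats_df: pd.DataFrame) -> pd.DataFrame:
    ea = stats_df["effect_allele"].str.upper()
    oa = stats_df["other_allele"].str.upper()
    amb = [(a, b) in AMBIGUOUS_PAIRS for a, b in zip(ea, oa)]
    n = int(np.sum(amb))
    if n:
        log.info("excluding %d strand-ambiguous (A/T, C/G) variants", n)
    return stats_df[~np.asarray(amb)].reset_index(drop=True)


def _ld_lookup(ld: pd.DataFrame | np.ndarray, stats_df: pd.DataFrame) -> np.ndarray:
    """Pairwise r^2 matrix aligned to stats rows."""
    if isinstance(ld, pd.DataFrame):
        idx = ld.index.get_indexer(stats_df["vid"])
        if (idx < 0).any():
            raise KeyError("summary-stat variants missing from the LD matrix")
        r2 = ld.to_numpy()[np.ix_(idx, idx)]
    else:
        r2 = np.asarray(ld, dtype=float)
        if r2.shape[0] != len(stats_df):
            raise ValueError("LD matrix shape does not match summary stats")
    return r2 ** 2 if (r2 < 0).any() else r2  # accept r or r^2 input


def _as_score_table(stats_df: pd.DataFrame, weights: np.ndarray) -> pd.DataFrame:
    t = stats_df[["vid", "chrom", "pos", "effect_allele", "other_allele"]].copy()
    t["weight"] = weights
    return t.reset_index(drop=True)


def build_score_lead(
    summary_stats: pd.DataFrame,
    ld: pd.DataFrame | np.ndarray,
    alpha: float = 5e-8,
    r2_independent: float = 0.1,
) -> ScoreModel:
    """Restricted score: most significant variant per locus, r^2-pruned.

    Variants with p < ``alpha`` are walked in order of significance;
    a variant joins the model when its r^2 with every kept variant is
    below ``r2_independent``. Weights are the discovery betas. Raises
    when nothing passes ``alpha``.
    """
    stats_df = _drop_ambiguous(summary_stats)
    r2 = _ld_lookup(ld, stats_df)
    sig = stats_df.index[stats_df["p"] < alpha]
    if len(sig) == 0:
        raise ValueError(f"no variant passes the genome-wide threshold {alpha:g}")
    order = sig[np.argsort(stats_df.loc[sig, "p"].to_numpy(), kind="stable")]
    kept: list[int] = []
    for j in order:
        if all(r2[j, k] < r2_independent for k in kept):
            kept.append(j)
    sub = stats_df.loc[kept]
    return ScoreModel(method="lead_variants",
                      table=_as_score_table(sub, sub["beta"].to_numpy()),
                      provenance={"alpha": alpha, "r2_independent": r2_independent})


def _clump(stats_df: pd.DataFrame, r2: np.ndarray, r2_max: float) -> list[int]:
    """Greedy p-ordered clumping: keep index variants, drop r^2 > r2_max."""
    order = np.argsort(stats_df["p"].to_numpy(), kind="stable")
    kept: list[int] = []
    removed = np.zeros(len(stats_df), dtype=bool)
    for j in order:
        if removed[j]:
            continue
        kept.append(j)
        removed |= r2[j] > r2_max
        removed[j] = True
    return sorted(kept)


def build_score_pt(
    summary_stats: pd.DataFrame,
    ld: pd.DataFrame | np.ndarray,
    p_grid: list[float],
    r2_grid: list[float],
) -> list[ScoreModel]:
    """Clump-then-threshold models over a (p, r^2) grid, weights unrescaled.

    One model per grid cell; cells where no variant survives carry an
    empty table with ``provenance['empty'] = True``.
    """
    if not p_grid or not r2_grid:
        raise ValueError("p_grid and r2_grid must be nonempty")
    stats_df = _drop_ambiguous(summary_stats)
    r2 = _ld_lookup(ld, stats_df)
    models = []
    for r2_t in r2_grid:
        clumped = _clump(stats_df, r2, r2_t)
        for p_t in p_grid:
            keep = [j for j in clumped if stats_df["p"].iloc[j] <= p_t]
            sub = stats_df.iloc[keep]
            models.append(ScoreModel(
                method="p_r2_threshold",
                table=_as_score_table(sub, sub["beta"].to_numpy()),
                provenance={"p_threshold": p_t, "r2_threshold": r2_t,
                            "empty": len(keep) == 0},
            ))
    return models


def build_score_shrunk(
    summary_stats: pd.DataFrame,
    ld: pd.DataFrame | np.ndarray,
    causal_fractions: list[float],
    n_gwas: int,
    h2: float = 0.25,
    window: int = 200,
    ridge_eps: float = 1e-6,
) -> list[ScoreModel]:
    """Closed-form LD-shrinkage score family over a causal-fraction grid.

    For causal fraction rho = 1 the weights are the infinitesimal-model
    posterior means beta~ = (D + (M/(N h^2)) I)^-1 beta^ computed within
    LD windows of ``window`` variants (D the LD correlation matrix). For
    rho < 1 a point-normal thresholding step first restricts to the top
    rho fraction of variants by |z| and uses M_eff = rho * M in the
    shrinkage constant. Non-positive-definite windows are
    ridge-stabilized with a log entry.
    """
    stats_df = _drop_ambiguous(summary_stats)
    r2 = _ld_lookup(ld, stats_df)
    D_full = np.sqrt(np.clip(r2, 0.0, 1.0))  # |r| as correlation magnitude
    np.fill_diagonal(D_full, 1.0)
    m = len(stats_df)
    beta_hat = stats_df["beta"].to_numpy(dtype=float)
    z = np.abs(beta_hat / stats_df["se"].to_numpy(dtype=float)) if "se" in stats_df \
        else np.abs(beta_hat)

    models = []
    for rho in causal_fractions:
        if not 0 < rho <= 1:
            raise ValueError("causal fractions must lie in (0, 1]")
        active = np.ones(m, dtype=bool)
        if rho < 1:
            k = max(1, int(round(rho * m)))
            active = np.zeros(m, dtype=bool)
            active[np.argsort(-z, kind="stable")[:k]] = True
        shrink = (rho * m) / (n_gwas * h2)
        weights = np.zeros(m)
        idx_active = np.nonzero(active)[0]
        for s in range(0, len(idx_active), window):
            blk = idx_active[s: s + window]
            D = D_full[np.ix_(blk, blk)] + shrink * np.eye(len(blk))
            try:
                w = np.linalg.solve(D, beta_hat[blk])
            except np.linalg.LinAlgError:
                log.warning("ridge-stabilizing non-positive-definite LD window")
                w = np.linalg.solve(D + ridge_eps * np.eye(len(blk)), beta_hat[blk])
            weights[blk] = w
        sub = stats_df
        models.append(ScoreModel(
            method="shrinkage",
            table=_as_score_table(sub, weights),
            provenance={"rho": rho, "h2": h2, "n_gwas": n_gwas},
        ))
    return models


def apply_score(model: ScoreModel, genotypes: GenotypeMatrix) -> np.ndarray:
    """Per-sample score = sum of weight x effect-allele dosage.

    Variants are matched by (chrom, pos): when the model's effect allele
    is the matrix ALT the dosage is used as-is; when alleles are swapped
    the dosage is flipped (2 - d); ambiguous or unmatched entries are
    dropped with a log entry. Missing dosages take the per-variant mean.
    Raises if no model variant matches.
    """
    if model.n_variants == 0:
        raise ValueError("empty score model")
    key = {(str(c), int(p)): j for j, (c, p) in
           enumerate(zip(genotypes.variants["chrom"], genotypes.variants["pos"]))}
    score = np.zeros(genotypes.n_samples)
    matched = 0
    for _, row in model.table.iterrows():
        j = key.get((str(row["chrom"]), int(row["pos"])))
        if j is None:
            continue
        ea, oa = str(row["effect_allele"]), str(row["other_allele"])
        if (ea.upper(), oa.upper()) in AMBIGUOUS_PAIRS:
            log.info("dropping strand-ambiguous variant %s from scoring", row["vid"])
            continue
        ref = str(genotypes.variants["ref"].iloc[j])
        alt = str(genotypes.variants["alt"].iloc[j])
        d = genotypes.dosages[:, j]
        d = np.where(np.isnan(d), np.nanmean(d), d)
        if ea == alt and oa == ref:
            score += row["weight"] * d
        elif ea == ref and oa == alt:
            score += row["weight"] * (2.0 - d)
        else:
            log.info("allele mismatch for %s; variant dropped", row["vid"])
            continue
        matched += 1
    if matched == 0:
        raise ValueError("no score-model variant matched the genotype matrix")
    return score


def select_best_score(
    models: list[ScoreModel],
    genotypes: GenotypeMatrix,
    trait: np.ndarray | pd.Series,
) -> tuple[ScoreModel, pd.DataFrame]:
    """Pick the model with the best linear-regression R^2 on training data.

    The training cohort must be disjoint from the evaluation cohort.
    Returns (best model, full R^2 table with the relative gain of each
    model over the first, computed as (R2 - R2_first) / R2_first).
    """
    if not models:
        raise ValueError("empty model list")
    y = np.asarray(trait, dtype=float)
    rows = []
    r2s = []
    for k, mdl in enumerate(models):
        if mdl.n_variants == 0:
            r2s.append(np.nan)
            rows.append((k, mdl.method, 0, np.nan))
            continue
        s = apply_score(mdl, genotypes)
        ok = ~np.isnan(y)
        X = sm.add_constant(s[ok])
        r2 = float(sm.OLS(y[ok], X).fit().rsquared)
        r2s.append(r2)
        rows.append((k, mdl.method, mdl.n_variants, r2))
    table = pd.DataFrame(rows, columns=["model", "method", "n_variants", "r2"])
    base = table["r2"].iloc[0]
    table["relative_gain_pct"] = 100.0 * (table["r2"] - base) / base if base and not np.isnan(base) else np.nan
    best = int(np.nanargmax(np.asarray(r2s)))
    return models[best], table


def relative_r2_gain(r2_restricted: float, r2_expanded: float) -> float:
    """Relative variance-explained increase, in percent."""
    if r2_restricted <= 0:
        raise ValueError("restricted R^2 must be positive")
    return 100.0 * (r2_expanded - r2_restricted) / r2_restricted


def classify_polygenic(
    scores: np.ndarray | pd.Series,
    ancestry: np.ndarray | pd.Series,
    q: float = DEFAULT_EXTREME_Q,
    min_n: int = 20,
) -> pd.DataFrame:
    """High/low score flags at ancestry-specific percentiles.

    High = strictly above the (1-q) quantile within ancestry; low =
    strictly below the q quantile (linear-interpolation quantiles, so
    with distinct scores exactly floor(qn) samples flag on each side).
    """
    s = pd.Series(np.asarray(scores, dtype=float))
    anc = pd.Series(np.asarray(ancestry, dtype=object))
    high = pd.Series(0, index=s.index, dtype=int)
    low = pd.Series(0, index=s.index, dtype=int)
    for a, idx in anc.groupby(anc).groups.items():
        vals = s.loc[idx]
        if len(vals) < min_n:
            raise ValueError(f"ancestry {a!r} has fewer than {min_n} samples")
        hi = float(np.quantile(vals, 1.0 - q))
        lo = float(np.quantile(vals, q))
        high.loc[idx] = (vals > hi).astype(int)
        low.loc[idx] = (vals < lo).astype(int)
    return pd.DataFrame({"high_score": high, "low_score": low})


# ---------------------------------------------------------------------------
# association and attributable fraction


@dataclass
class ExtremeResult:
    """Per-ancestry contingency counts and adjusted effects."""

    ancestry: str
    n_total: int
    n_extreme: int
    carriers_in_extreme: int
    high_score_in_extreme: int
    or_carrier: float = np.nan
    or_carrier_ci: tuple[float, float] = (np.nan, np.nan)
    p_carrier: float = np.nan
    or_score: float = np.nan
    or_score_ci: tuple[float, float] = (np.nan, np.nan)
    p_score: float = np.nan
    beta_carrier: float = np.nan
    se_carrier: float = np.nan
    beta_score: float = np.nan
    se_score: float = np.nan
    beta_per_sd: float = np.nan
    paf_carrier: float = np.nan
    paf_score: float = np.nan

    def __post_init__(self) -> None:
        if not (self.carriers_in_extreme <= self.n_extreme <= self.n_total):
            raise ValueError("inconsistent contingency counts")


def attributable_fraction(carriers_in_cases: int, n_cases: int, odds_ratio: float) -> float:
    """Case-based population attributable fraction, in percent.

    PAF = 100 x (carriers_in_cases / n_cases) x (OR - 1) / OR. Valid
    for adjusted odds ratios because only the exposure fraction among
    cases enters (Miettinen's case-based form).
    """
    if odds_ratio <= 0:
        raise ValueError("odds ratio must be positive")
    if n_cases <= 0 or not 0 <= carriers_in_cases <= n_cases:
        raise ValueError("invalid counts")
    return 100.0 * (carriers_in_cases / n_cases) * (odds_ratio - 1.0) / odds_ratio


def _fit_logistic(y: np.ndarray, X: np.ndarray):
    try:
        with np.errstate(divide="ignore", over="ignore"):
            return sm.Logit(y, X).fit(disp=0, maxiter=200)
    except Exception as exc:  # perfect separation and friends
        log.warning("logistic fit failed: %s", exc)
        return None


def extreme_association(
    extreme: np.ndarray | pd.Series,
    carrier: np.ndarray | pd.Series,
    score_flag: np.ndarray | pd.Series,
    covariates: pd.DataFrame,
    ldl: np.ndarray | pd.Series,
    ancestry: np.ndarray | pd.Series,
    scores: np.ndarray | pd.Series | None = None,
) -> list[ExtremeResult]:
    """Adjusted OR and mg/dl effects of carrier status and score flag.

    Per ancestry, fits (1) a logistic model of extreme membership on
    carrier + score flag + covariates (age, age^2, sex) and (2) a
    linear model of continuous LDL-C on the same terms. When continuous
    ``scores`` are given, the per-SD linear score effect is attached.
    Ancestries with zero carriers report counts with missing ORs.
    """
    ex = np.asarray(extreme).astype(bool)
    car = np.asarray(carrier).astype(int)
    flag = np.asarray(score_flag).astype(int)
    anc = pd.Series(np.asarray(ancestry, dtype=object))
    y_ldl = np.asarray(ldl, dtype=float)

    results = []
    for a, idx in anc.groupby(anc).groups.items():
        i = np.asarray(idx)
        Xcov = covariates.iloc[i].to_numpy(dtype=float)
        X = np.column_stack([np.ones(len(i)), car[i], flag[i], Xcov])
        res = ExtremeResult(
            ancestry=str(a),
            n_total=len(i),
            n_extreme=int(ex[i].sum()),
            carriers_in_extreme=int((ex[i] & (car[i] == 1)).sum()),
            high_score_in_extreme=int((ex[i] & (flag[i] == 1)).sum()),
        )
        if car[i].sum() > 0 and flag[i].sum() > 0 and 0 < ex[i].sum() < len(i):
            fit = _fit_logistic(ex[i].astype(float), X)
            if fit is not None:
                ci = fit.conf_int()
                with np.errstate(over="ignore"):  # near-separation CIs can overflow
                    res.or_carrier = float(np.exp(fit.params[1]))
                    res.or_carrier_ci = tuple(np.exp(ci[1]).tolist())
                    res.p_carrier = float(fit.pvalues[1])
                    res.or_score = float(np.exp(fit.params[2]))
                    res.or_score_ci = tuple(np.exp(ci[2]).tolist())
                    res.p_score = float(fit.pvalues[2])
                if res.n_extreme > 0 and res.or_carrier > 1:
                    res.paf_carrier = attributable_fraction(
                        res.carriers_in_extreme, res.n_extreme, res.or_carrier)
                if res.n_extreme > 0 and res.or_score > 1:
                    res.paf_score = attributable_fraction(
                        res.high_score_in_extreme, res.n_extreme, res.or_score)
        else:
            log.info("ancestry %s: degenerate exposure or outcome; ORs reported missing", a)

        lin = sm.OLS(y_ldl[i], X, missing="drop").fit()
        res.beta_carrier = float(lin.params[1])
        res.se_carrier = float(lin.bse[1])
        res.beta_score = float(lin.params[2])
        res.se_score = float(lin.bse[2])

        if scores is not None:
            s = np.asarray(scores, dtype=float)[i]
            s_sd = (s - s.mean()) / s.std()
            Xs = np.column_stack([np.ones(len(i)), s_sd, Xcov])
            res.beta_per_sd = float(sm.OLS(y_ldl[i], Xs, missing="drop").fit().params[1])
        results.append(res)
    return results


def results_to_frame(results: list[ExtremeResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append({
            "ancestry": r.ancestry, "n_total": r.n_total, "n_extreme": r.n_extreme,
            "carriers_in_extreme": r.carriers_in_extreme,
            "high_score_in_extreme": r.high_score_in_extreme,
            "or_carrier": r.or_carrier, "or_carrier_lo": r.or_carrier_ci[0],
            "or_carrier_hi": r.or_carrier_ci[1], "p_carrier": r.p_carrier,
            "paf_carrier": r.paf_carrier,
            "or_score": r.or_score, "or_score_lo": r.or_score_ci[0],
            "or_score_hi": r.or_score_ci[1], "p_score": r.p_score,
            "paf_score": r.paf_score,
            "beta_carrier": r.beta_carrier, "se_carrier": r.se_carrier,
            "beta_score": r.beta_score, "se_score": r.se_score,
            "beta_per_sd": r.beta_per_sd,
        })
    return pd.DataFrame(rows)
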