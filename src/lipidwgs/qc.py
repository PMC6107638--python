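"""Genotype- and variant-level hard-filter quality control.

Genotype filters (applied first): GQ < 20, DP < 10 or > 200, and poor
allele balance — homozygous calls with < 0.90 of reads supporting the
called allele, heterozygous calls with < 0.20 of reads supporting the
minor of the two called alleles — are set to missing. Variant filters
(applied after): > 5% missing calls, or exact-test Hardy-Weinberg
p < 1e-9 within any cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from lipidwgs.containers import GenotypeMatrix


@dataclass
class QcThresholds:
    min_gq: float = 20.0
    min_dp: float = 10.0
    max_dp: float = 200.0
    hom_ab_min: float = 0.90
    het_ab_min: float = 0.20
    max_missing: float = 0.05
    min_phwe: float = 1e-9

    def __post_init__(self) -> None:
        for name in ("hom_ab_min", "het_ab_min", "max_missing"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a fraction in [0, 1], got {v}")
        if self.min_dp >= self.max_dp:
            raise ValueError(f"min_dp {self.min_dp} must be below max_dp {self.max_dp}")
        if not 0.0 <= self.min_phwe <= 1.0:
            raise ValueError(f"min_phwe must be a probability, got {self.min_phwe}")

    @classmethod
    def disabled(cls) -> "QcThresholds":
        """Thresholds that pass every genotype and variant (identity filter)."""
        return cls(min_gq=-math.inf, min_dp=-math.inf, max_dp=math.inf,
                   hom_ab_min=0.0, het_ab_min=0.0, max_missing=1.0, min_phwe=0.0)


def filter_genotypes(matrix: GenotypeMatrix, thresholds: QcThresholds | None = None) -> GenotypeMatrix:
    """Set individual genotype calls failing hard filters to missing.

    Requires GQ, DP and AD arrays on the matrix; raises a configuration
    error naming the first absent field. Returns a new matrix.
    """
    t = thresholds or QcThresholds()
    for name in ("gq", "dp", "ad_ref", "ad_alt"):
        if getattr(matrix, name) is None:
            raise ValueError(f"genotype filtering requires FORMAT field arrays; {name!r} is absent")

    out = matrix.copy()
    dos = out.dosages
    called = ~np.isnan(dos)

    fail = np.zeros_like(dos, dtype=bool)
    fail |= out.gq < t.min_gq
    fail |= (out.dp < t.min_dp) | (out.dp > t.max_dp)

    total = out.ad_ref + out.ad_alt
    with np.errstate(divide="ignore", invalid="ignore"):
        ref_frac = np.where(total > 0, out.ad_ref / total, np.nan)
        alt_frac = np.where(total > 0, out.ad_alt / total, np.nan)
    # homozygous: fraction supporting the called allele; het: minor read fraction
    hom_ref_bad = (dos == 0) & (ref_frac < t.hom_ab_min)
    hom_alt_bad = (dos == 2) & (alt_frac < t.hom_ab_min)
    het_bad = (dos == 1) & (np.minimum(ref_frac, alt_frac) < t.het_ab_min)
    fail |= hom_ref_bad | hom_alt_bad | het_bad

    out.dosages = np.where(called & fail, np.nan, dos)
    return out


def hwe_exact_pvalue(n_het: int, n_hom_minor: int, n_hom_major: int) -> float:
    """Exact two-sided Hardy-Weinberg test p-value (mid-p off).

    Conditions on observed allele counts and sums the probabilities of
    all heterozygote counts no more likely than the observed one, using
    the standard log-space recurrence over het configurations.
    """
    if min(n_het, n_hom_minor, n_hom_major) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_het + n_hom_minor + n_hom_major
    if n == 0:
        return 1.0
    minor = 2 * n_hom_minor + n_het
    if minor > n:  # ensure 'minor' really is the rarer allele
        n_hom_minor, n_hom_major = n_hom_major, n_hom_minor
        minor = 2 * n_hom_minor + n_het

    # P(het = k | allele counts) up to a constant, via the recurrence
    #   P(k+2)/P(k) = 4 * hom_minor(k) * hom_major(k) / ((k+2)(k+1))
    parity = minor % 2
    ks = list(range(parity, minor + 1, 2))
    logp = {}
    k0 = ks[0]
    logp[k0] = 0.0
    for k in ks[:-1]:
        hm = (minor - k) // 2
        hM = n - k - hm
        ratio = 4.0 * hm * hM / ((k + 2.0) * (k + 1.0))
        logp[k + 2] = logp[k] + math.log(ratio)
    m = max(logp.values())
    probs = {k: math.exp(v - m) for k, v in logp.items()}
    total = sum(probs.values())
    obs = probs[n_het] / total
    p = sum(v / total for v in probs.values() if v / total <= obs * (1.0 + 1e-12))
    return min(p, 1.0)


def _hwe_pvals(dosages: np.ndarray) -> np.ndarray:
    """Per-variant exact HWE p over hard calls in a dosage block."""
    out = np.ones(dosages.shape[1])
    for j in range(dosages.shape[1]):
        col = dosages[:, j]
        col = col[~np.isnan(col)]
        n_het = int((col == 1).sum())
        n_alt = int((col == 2).sum())
        n_ref = int((col == 0).sum())
        out[j] = hwe_exact_pvalue(n_het, n_alt, n_ref)
    return out


def filter_variants(
    matrix: GenotypeMatrix,
    thresholds: QcThresholds | None = None,
    cohort_column: str = "cohort",
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop variants with excess missingness or HWE failure in any cohort.

    Runs after :func:`filter_genotypes`. Returns the retained matrix and
    a per-variant report frame with ``filter`` reason codes (``PASS``,
    ``MISSINGNESS``, ``HWE``; semicolon-joined when both fail).
    """
    t = thresholds or QcThresholds()
    if cohort_column not in matrix.samples.columns:
        raise ValueError(f"sample table lacks cohort column {cohort_column!r}")

    miss = matrix.missingness()
    reasons = [[] for _ in range(matrix.n_variants)]
    for j in np.nonzero(miss > t.max_missing)[0]:
        reasons[j].append("MISSINGNESS")

    if t.min_phwe > 0:
        for _, idx in matrix.samples.groupby(cohort_column, sort=False).indices.items():
            p = _hwe_pvals(matrix.dosages[idx])
            for j in np.nonzero(p < t.min_phwe)[0]:
                if "HWE" not in reasons[j]:
                    reasons[j].append("HWE")

    report = matrix.variants[["vid"]].copy()
    report["missingness"] = miss
    report["filter"] = [";".join(r) if r else "PASS" for r in reasons]
    keep = np.array([not r for r in reasons])
    return matrix.take_variants(np.nonzero(keep)[0]), report
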