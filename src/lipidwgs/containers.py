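"""Core in-memory containers shared across analysis stages."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: columns required in the variant metadata frame
VARIANT_COLUMNS = ["vid", "chrom", "pos", "ref", "alt"]


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix with per-genotype quality fields.

    ``dosages`` holds ALT-allele counts 0/1/2 as floats with ``nan`` for
    missing calls. ``variants`` is a DataFrame with at least ``vid``,
    ``chrom``, ``pos`` (0-based), ``ref``, ``alt``; annotation columns
    (gene, consequence, clinical labels) ride along. ``samples`` is a
    DataFrame keyed by ``sample_id`` carrying ancestry/cohort/callset
    labels. GQ/DP/AD arrays, when present, are aligned with ``dosages``.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    samples: pd.DataFrame
    gq: np.ndarray | None = None
    dp: np.ndarray | None = None
    ad_ref: np.ndarray | None = None
    ad_alt: np.ndarray | None = None

    def __post_init__(self) -> None:
        n_s, n_v = self.dosages.shape
        if len(self.variants) != n_v:
            raise ValueError(
                f"variant table has {len(self.variants)} rows for {n_v} dosage columns"
            )
        if len(self.samples) != n_s:
            raise ValueError(
                f"sample table has {len(self.samples)} rows for {n_s} dosage rows"
            )
        missing = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing:
            raise ValueError(f"variant table lacks columns {missing}")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def alt_frequency(self) -> np.ndarray:
        """ALT allele frequency per variant over non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        """Minor allele frequency per variant (folded ALT frequency)."""
        af = self.alt_frequency()
        return np.minimum(af, 1.0 - af)

    def missingness(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)

    def take_variants(self, index: np.ndarray) -> "GenotypeMatrix":
        """Subset to the given variant (column) indices, preserving order."""
        index = np.asarray(index)
        sel = lambda a: None if a is None else a[:, index]
        return GenotypeMatrix(
            dosages=self.dosages[:, index],
            variants=self.variants.iloc[index].reset_index(drop=True),
            samples=self.samples,
            gq=sel(self.gq),
            dp=sel(self.dp),
            ad_ref=sel(self.ad_ref),
            ad_alt=sel(self.ad_alt),
        )

    def take_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        """Subset to the given sample (row) indices, preserving order."""
        index = np.asarray(index)
        sel = lambda a: None if a is None else a[index]
        return GenotypeMatrix(
            dosages=self.dosages[index],
            variants=self.variants,
            samples=self.samples.iloc[index].reset_index(drop=True),
            gq=sel(self.gq),
            dp=sel(self.dp),
            ad_ref=sel(self.ad_ref),
            ad_alt=sel(self.ad_alt),
        )

    def copy(self) -> "GenotypeMatrix":
        cp = lambda a: None if a is None else a.copy()
        return GenotypeMatrix(
            dosages=self.dosages.copy(),
            variants=self.variants.copy(),
            samples=self.samples.copy(),
            gq=cp(self.gq),
            dp=cp(self.dp),
            ad_ref=cp(self.ad_ref),
            ad_alt=cp(self.ad_alt),
        )

    def variant_index(self) -> pd.Index:
        return pd.Index(self.variants["vid"])


@dataclass(frozen=True)
class VariantGroup:
    """Named set of rare variants tested jointly.

    ``method`` records grouping provenance: ``coding`` (per-gene LoF +
    disruptive missense), ``window`` (3 kb sliding windows), ``proximity``
    (promoter/enhancer near TSS), ``link`` (chromatin-correlation links)
    or ``abc`` (Activity-by-Contact links).
    """

    group_id: str
    variant_ids: tuple[str, ...]
    method: str
    combined_maf: float | None = None

    def __post_init__(self) -> None:
        if len(set(self.variant_ids)) != len(self.variant_ids):
            raise ValueError(f"group {self.group_id} contains duplicate variants")
        if self.method not in {"coding", "window", "proximity", "link", "abc"}:
            raise ValueError(f"unknown grouping method {self.method!r}")


@dataclass(frozen=True)
class GeneLink:
    """A regulatory element linked to a gene by one of the two engines."""

    chrom: str
    start: int
    end: int
    gene: str
    cell_type: str
    method: str  # "correlation" | "abc"
    score: float  # posterior odds p/(1-p) or ABC score


def groups_to_frame(groups: list[VariantGroup]) -> pd.DataFrame:
    """Long-format (group_id, vid, method) table, one row per membership."""
    rows = [
        (g.group_id, vid, g.method, g.combined_maf)
        for g in groups
        for vid in g.variant_ids
    ]
    return pd.DataFrame(rows, columns=["group_id", "vid", "method", "combined_maf"])


def links_to_frame(links: list[GeneLink]) -> pd.DataFrame:
    return pd.DataFrame(
        [(l.chrom, l.start, l.end, l.gene, l.cell_type, l.method, l.score) for l in links],
        columns=["chrom", "start", "end", "gene", "cell_type", "method", "score"],
    )
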