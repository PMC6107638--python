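"""Rare-variant aggregation: one coding and four non-coding schemes.

Coding groups collect loss-of-function and disruptive-missense rare
variants per gene. Non-coding groups come from (1) 3 kb sliding windows
stepping 1.5 kb, restricted to variants overlapping enhancer/promoter/
DHS annotation outside exons, (2) promoter intervals within +/-5 kb and
enhancer intervals within +/-20 kb of a gene's TSS at DHS sites, and
(3)/(4) the element sets produced by the two linking engines. Rarity
means MAF < 1% throughout; the per-group combined MAF is the sum of
member MAFs (an upper bound on the carrier fraction).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from lipidwgs.containers import GenotypeMatrix, GeneLink, VariantGroup

log = logging.getLogger(__name__)

LOF_CONSEQUENCES = {"lof", "nonsense", "stop_gained", "frameshift", "splice",
                    "canonical_splice_site", "frameshift_variant", "splice_donor",
                    "splice_acceptor"}
DISRUPTIVE_MISSENSE = {"disruptive_missense"}


@dataclass
class GroupingConfig:
    rare_maf_max: float = 0.01
    window_size: int = 3000
    window_step: int = 1500
    promoter_flank: int = 5000
    enhancer_flank: int = 20000

    def __post_init__(self) -> None:
        if self.window_step > self.window_size:
            raise ValueError("window_step must not exceed window_size")
        if self.promoter_flank <= 0 or self.enhancer_flank <= 0:
            raise ValueError("flanks must be positive")
        if not 0 < self.rare_maf_max < 1:
            raise ValueError("rare_maf_max must lie in (0, 1)")


def _interval_tree(intervals: pd.DataFrame, kinds: set[str] | None = None) -> dict[str, IntervalTree]:
    """Per-chromosome interval trees, optionally restricted to kinds."""
    trees: dict[str, IntervalTree] = {}
    df = intervals
    kind_col = "kind" if "kind" in df.columns else "name"
    if kinds is not None:
        df = df[df[kind_col].isin(kinds)]
    for chrom, sub in df.groupby("chrom"):
        trees[str(chrom)] = IntervalTree.from_tuples(
            (int(s), int(e)) for s, e in zip(sub["start"], sub["end"]) if e > s
        )
    return trees


def _overlaps(trees: dict[str, IntervalTree], chrom: str, pos: int) -> bool:
    t = trees.get(str(chrom))
    return bool(t is not None and t.overlaps(pos))


def _rare_mask(genotypes: GenotypeMatrix, rare_maf_max: float) -> np.ndarray:
    maf = genotypes.maf()
    return (maf > 0) & (maf < rare_maf_max)


def coding_groups(
    genotypes: GenotypeMatrix,
    config: GroupingConfig | None = None,
) -> list[VariantGroup]:
    """Per-gene groups of rare LoF / disruptive-missense variants.

    Requires ``gene`` and ``consequence`` columns on the variant table
    (canonical-transcript annotation consumed as labels). Genes with no
    qualifying variant are omitted.
    """
    cfg = config or GroupingConfig()
    v = genotypes.variants
    for col in ("gene", "consequence"):
        if col not in v.columns:
            raise ValueError(f"coding grouping requires variant annotation column {col!r}")
    rare = _rare_mask(genotypes, cfg.rare_maf_max)
    damaging = v["consequence"].isin(LOF_CONSEQUENCES | DISRUPTIVE_MISSENSE).to_numpy()
    qual = rare & damaging & (v["gene"].fillna("") != "").to_numpy()

    maf = genotypes.maf()
    groups = []
    for gene, idx in v[qual].groupby("gene", sort=True).groups.items():
        vids = tuple(v.loc[idx, "vid"])
        groups.append(VariantGroup(group_id=str(gene), variant_ids=vids, method="coding",
                                   combined_maf=float(maf[np.asarray(idx)].sum())))
    return groups


def sliding_windows(
    genotypes: GenotypeMatrix,
    annotations: pd.DataFrame,
    config: GroupingConfig | None = None,
    exons: pd.DataFrame | None = None,
) -> list[VariantGroup]:
    """3 kb windows stepping 1.5 kb over regulatory rare variants.

    Windows are anchored at position 0 of each chromosome so keys are
    reproducible from (chrom, start). A window's group holds the rare
    variants inside it that overlap enhancer/promoter/DHS annotation and
    no exon (1 bp of exon overlap excludes). Empty windows are omitted;
    with step = size/2 every variant lands in at most two windows.
    """
    cfg = config or GroupingConfig()
    reg_trees = _interval_tree(annotations, kinds={"enhancer", "promoter", "dhs"})
    exon_trees = _interval_tree(exons) if exons is not None and len(exons) else {}

    maf = genotypes.maf()
    rare = _rare_mask(genotypes, cfg.rare_maf_max)
    v = genotypes.variants

    window_members: dict[tuple[str, int], list[int]] = {}
    for j in np.nonzero(rare)[0]:
        chrom, pos = str(v["chrom"].iloc[j]), int(v["pos"].iloc[j])
        if not _overlaps(reg_trees, chrom, pos):
            continue
        if _overlaps(exon_trees, chrom, pos):
            continue
        # windows anchored at 0 with the configured step that cover pos
        first = max(0, (pos - cfg.window_size) // cfg.window_step + 1)
        start = first * cfg.window_step
        while start <= pos:
            if pos < start + cfg.window_size:
                window_members.setdefault((chrom, start), []).append(j)
            start += cfg.window_step

    groups = []
    for (chrom, start), idx in sorted(window_members.items()):
        vids = tuple(v["vid"].iloc[idx])
        groups.append(VariantGroup(
            group_id=f"{chrom}:{start}-{start + cfg.window_size}",
            variant_ids=vids, method="window",
            combined_maf=float(maf[idx].sum()),
        ))
    return groups


def proximity_groups(
    genotypes: GenotypeMatrix,
    tss_table: pd.DataFrame,
    annotations: pd.DataFrame,
    config: GroupingConfig | None = None,
) -> list[VariantGroup]:
    """Per-gene groups from promoter/enhancer elements near the TSS.

    A rare variant joins a gene's group when it overlaps DHS annotation
    and lies in a promoter interval within +/-5 kb, or an enhancer
    interval within +/-20 kb, of the gene's TSS (outermost TSS for
    multi-TSS genes; flanks unsigned, so the rule is strand-symmetric).
    ``tss_table`` needs columns gene, tss and (optionally) chrom.
    """
    cfg = config or GroupingConfig()
    if "gene" not in tss_table.columns or "tss" not in tss_table.columns:
        raise ValueError("tss_table requires 'gene' and 'tss' columns")
    tss = tss_table.copy()
    # outermost TSS convention: keep min and max per gene, test both
    agg = tss.groupby("gene")["tss"].agg(["min", "max"]).reset_index()

    prom_trees = _interval_tree(annotations, kinds={"promoter"})
    enh_trees = _interval_tree(annotations, kinds={"enhancer"})
    dhs_trees = _interval_tree(annotations, kinds={"dhs"})

    maf = genotypes.maf()
    rare = _rare_mask(genotypes, cfg.rare_maf_max)
    v = genotypes.variants
    rare_idx = np.nonzero(rare)[0]

    groups = []
    for _, row in agg.iterrows():
        members = []
        for j in rare_idx:
            chrom, pos = str(v["chrom"].iloc[j]), int(v["pos"].iloc[j])
            if not _overlaps(dhs_trees, chrom, pos):
                continue
            d = min(abs(pos - int(row["min"])), abs(pos - int(row["max"])))
            in_prom = d <= cfg.promoter_flank and _overlaps(prom_trees, chrom, pos)
            in_enh = d <= cfg.enhancer_flank and _overlaps(enh_trees, chrom, pos)
            if in_prom or in_enh:
                members.append(j)
        if members:
            groups.append(VariantGroup(
                group_id=str(row["gene"]),
                variant_ids=tuple(v["vid"].iloc[members]),
                method="proximity",
                combined_maf=float(maf[members].sum()),
            ))
    return groups


def groups_from_links(
    genotypes: GenotypeMatrix,
    links: list[GeneLink],
    config: GroupingConfig | None = None,
    method: str = "link",
) -> list[VariantGroup]:
    """Per-gene groups of rare variants inside any linked element.

    An element linked to two genes contributes its variants to both
    groups. ``method`` tags provenance ('link' for correlation links,
    'abc' for Activity-by-Contact links).
    """
    cfg = config or GroupingConfig()
    maf = genotypes.maf()
    rare = _rare_mask(genotypes, cfg.rare_maf_max)
    v = genotypes.variants
    rare_idx = np.nonzero(rare)[0]

    by_gene: dict[str, dict[str, IntervalTree]] = {}
    for l in links:
        tree = by_gene.setdefault(l.gene, {}).setdefault(str(l.chrom), IntervalTree())
        if l.end > l.start:
            tree.addi(int(l.start), int(l.end))

    groups = []
    for gene in sorted(by_gene):
        trees = by_gene[gene]
        members = [j for j in rare_idx
                   if _overlaps(trees, str(v["chrom"].iloc[j]), int(v["pos"].iloc[j]))]
        if members:
            groups.append(VariantGroup(
                group_id=gene, variant_ids=tuple(v["vid"].iloc[members]),
                method=method, combined_maf=float(maf[members].sum()),
            ))
    return groups


def tile_windows(start: int, end: int, config: GroupingConfig | None = None) -> list[int]:
    """Window start positions (anchored at 0) whose window intersects [start, end).

    The final window may overhang the region end.
    """
    cfg = config or GroupingConfig()
    first = max(0, (start - cfg.window_size) // cfg.window_step + 1) * cfg.window_step
    return list(range(first, end, cfg.window_step))


def combined_maf(group: VariantGroup, genotypes: GenotypeMatrix) -> float:
    """Sum of member MAFs: an upper bound on the group carrier frequency."""
    if not group.variant_ids:
        raise ValueError(f"group {group.group_id} is empty")
    idx = genotypes.variant_index().get_indexer(list(group.variant_ids))
    if (idx < 0).any():
        missing = [v for v, i in zip(group.variant_ids, idx) if i < 0]
        raise KeyError(f"variants absent from matrix: {missing[:5]}")
    return float(genotypes.maf()[idx].sum())


def bonferroni_alpha(n_groups: int, family_alpha: float = 0.05) -> float:
    """Significance threshold 0.05 / number-of-groups."""
    if n_groups <= 0:
        raise ValueError("n_groups must be positive")
    return family_alpha / n_groups


def write_group_file(groups: list[VariantGroup], path) -> None:
    """EPACTS-style group text: one line per group, members space-separated."""
    with open(path, "w") as fh:
        for g in groups:
            fh.write(f"{g.group_id}\t" + "\t".join(g.variant_ids) + "\n")
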