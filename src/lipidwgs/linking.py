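"""Enhancer-gene linking engines.

Two independent engines connect regulatory elements to genes:

1. A chromatin-correlation classifier. For each candidate 200-bp bin /
   gene pair within 1 Mb of the TSS, the Pearson correlation of five
   chromatin-mark signals (H3K27ac, H3K9ac, H3K4me1, H3K4me2, DNase)
   with the gene's expression across cell types forms a 5-feature
   vector. Per stratum (cell type, chromatin state, TSS offset) a
   ridge-regularized logistic model is trained to separate observed
   correlations (positives) from correlations computed after permuting
   the gene-to-expression assignment (negatives). Links with posterior
   odds p/(1-p) >= 2.5 are retained; by default only the primary
   enhancer state 7_Enh is exported.

2. The Activity-by-Contact (ABC) score. Candidate elements are DNase
   peaks expanded by 500 bp and merged; Activity is the geometric mean
   of pseudocounted DNase and H3K27ac read counts; Contact decays as a
   power law in distance (or comes from a dense matrix). The score of
   an element for a gene is its Activity x Contact normalized by the
   sum over all candidate elements within 5 Mb of the gene, so per-gene
   scores sum to one and are invariant to rescaling either input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from lipidwgs._rng import substream
from lipidwgs.containers import GeneLink
from lipidwgs.cohort import BIN_SIZE, MARKS, RegulatoryLandscape

log = logging.getLogger(__name__)

LINK_STATES = ("6_EnhG", "7_Enh", "12_EnhBiv")
ODDS_THRESHOLD = 2.5  # retain links with p/(1-p) >= 2.5, i.e. p >= 5/7


@dataclass
class LinkingConfig:
    odds_threshold: float = ODDS_THRESHOLD
    max_distance: int = 1_000_000  # bp from TSS
    smoothing_bp: int = 5000  # training instances pooled within this offset window
    offset_step: int = 200  # stratum offset resolution (one model per 200-bp offset)
    min_examples: int = 10  # per class; sparser strata fall back to nearest offset
    states: tuple[str, ...] = LINK_STATES
    export_states: tuple[str, ...] = ("7_Enh",)
    seed: int = 0


def mark_expression_correlations(
    signal: np.ndarray,
    expression: np.ndarray,
    bin_index: int,
    gene_index: int,
    min_pairs: int = 3,
) -> np.ndarray:
    """Pearson correlation of each mark's signal with a gene's expression.

    ``signal`` is (bins, cell types, marks); ``expression`` is (genes,
    cell types). Cell types with missing signal or expression are
    omitted pairwise; fewer than ``min_pairs`` complete pairs, or zero
    variance on either side, yields NaN for that mark.
    """
    feats = np.full(signal.shape[2], np.nan)
    e = expression[gene_index]
    for m in range(signal.shape[2]):
        s = signal[bin_index, :, m]
        ok = ~(np.isnan(s) | np.isnan(e))
        if ok.sum() < min_pairs:
            continue
        ss, ee = s[ok], e[ok]
        if ss.std() == 0 or ee.std() == 0:
            continue
        feats[m] = float(np.corrcoef(ss, ee)[0, 1])
    return feats


class CorrelationLinker:
    """Chromatin-correlation linking engine over a regulatory landscape."""

    def __init__(self, landscape: RegulatoryLandscape, config: LinkingConfig | None = None):
        self.landscape = landscape
        self.config = config or LinkingConfig()
        self._features = self._feature_tensor()
        self._perm = self._gene_permutation()
        self._models: dict[tuple[int, str, int], LogisticRegression | None] = {}
        self._pairs_cache: dict[tuple[int, tuple[str, ...]], pd.DataFrame] = {}

    # -- features ---------------------------------------------------------

    def _feature_tensor(self) -> np.ndarray:
        """Correlations for every (bin, gene, mark), across cell types."""
        sig = self.landscape.signal  # (B, C, M)
        expr = self.landscape.expression  # (G, C)
        s = sig - sig.mean(axis=1, keepdims=True)
        e = expr - expr.mean(axis=1, keepdims=True)
        s_norm = np.sqrt((s ** 2).sum(axis=1))  # (B, M)
        e_norm = np.sqrt((e ** 2).sum(axis=1))  # (G,)
        dot = np.einsum("bcm,gc->bgm", s, e)
        with np.errstate(divide="ignore", invalid="ignore"):
            corr = dot / (s_norm[:, None, :] * e_norm[None, :, None])
        return corr  # (B, G, M); NaN where variance vanished

    def features(self, bin_index: int, gene_index: int) -> np.ndarray:
        return self._features[bin_index, gene_index]

    def _gene_permutation(self) -> np.ndarray:
        """Fixed-seed permutation of gene->expression used for negatives."""
        rng = substream(self.config.seed, "link-negatives")
        n = self.landscape.expression.shape[0]
        if n == 1:
            return np.array([0])
        for _ in range(50):
            perm = rng.permutation(n)
            if not np.any(perm == np.arange(n)):
                return perm
        return np.roll(np.arange(n), 1)

    # -- strata -----------------------------------------------------------

    def candidate_pairs(self, cell_type_index: int, states: tuple[str, ...] | None = None) -> pd.DataFrame:
        """(bin, gene, offset, state) pairs within the distance limit."""
        ls, cfg = self.landscape, self.config
        states = tuple(states) if states is not None else tuple(cfg.states)
        key = (cell_type_index, states)
        if key in self._pairs_cache:
            return self._pairs_cache[key]
        col = ls.states[:, cell_type_index]
        rows = []
        for b in np.nonzero(np.isin(col, states))[0]:
            start = int(ls.bin_starts[b])
            for g, tssv in enumerate(ls.genes["tss"]):
                offset = start - int(tssv)
                if abs(offset) <= cfg.max_distance:
                    rows.append((b, g, offset, col[b]))
        pairs = pd.DataFrame(rows, columns=["bin", "gene", "offset", "state"])
        self._pairs_cache[key] = pairs
        return pairs

    def _bucket(self, offset: int) -> int:
        return int(np.floor(offset / self.config.offset_step))

    def build_training_set(self, cell_type_index: int, state: str, offset: int
                           ) -> tuple[np.ndarray, np.ndarray]:
        """Positive and matched negative feature matrices for a stratum.

        One positive (observed correlations) and one negative (gene
        expression permuted) per state instance at the stratum offset or
        within the 5 kb smoothing window of it.
        """
        pairs = self.candidate_pairs(cell_type_index, states=(state,))
        near = pairs[np.abs(pairs["offset"] - offset) <= self.config.smoothing_bp]
        pos = np.array([self.features(b, g) for b, g in zip(near["bin"], near["gene"])])
        neg = np.array([self.features(b, self._perm[g]) for b, g in zip(near["bin"], near["gene"])])
        if len(pos) == 0:
            return np.empty((0, len(MARKS))), np.empty((0, len(MARKS)))
        return np.nan_to_num(pos), np.nan_to_num(neg)

    def _fit(self, X_pos: np.ndarray, X_neg: np.ndarray) -> LogisticRegression:
        X = np.vstack([X_pos, X_neg])
        y = np.r_[np.ones(len(X_pos)), np.zeros(len(X_neg))]
        model = LogisticRegression(C=1.0, solver="lbfgs", max_iter=1000)
        model.fit(X, y)
        return model

    def _model(self, cell_type_index: int, state: str, bucket: int) -> LogisticRegression | None:
        key = (cell_type_index, state, bucket)
        if key in self._models:
            return self._models[key]
        offset = bucket * self.config.offset_step + self.config.offset_step // 2
        X_pos, X_neg = self.build_training_set(cell_type_index, state, offset)
        model = None
        if len(X_pos) >= self.config.min_examples:
            model = self._fit(X_pos, X_neg)
        else:
            # fall back to the nearest offset bucket with enough examples
            max_b = self.config.max_distance // self.config.offset_step + 1
            for delta in range(1, 2 * max_b):
                for cand in (bucket - delta, bucket + delta):
                    if abs(cand) > max_b:
                        continue
                    off = cand * self.config.offset_step + self.config.offset_step // 2
                    Xp, Xn = self.build_training_set(cell_type_index, state, off)
                    if len(Xp) >= self.config.min_examples:
                        model = self._fit(Xp, Xn)
                        break
                if model is not None:
                    break
        self._models[key] = model
        return model

    # -- scoring ----------------------------------------------------------

    def score_links(self, cell_type_index: int = 0) -> list[GeneLink]:
        """Score export-state candidates; retain posterior odds >= threshold."""
        ls, cfg = self.landscape, self.config
        pairs = self.candidate_pairs(cell_type_index, states=cfg.export_states)
        links = []
        for _, row in pairs.iterrows():
            model = self._model(cell_type_index, row["state"], self._bucket(row["offset"]))
            if model is None:
                continue
            x = np.nan_to_num(self.features(row["bin"], row["gene"]))[None, :]
            p = float(model.predict_proba(x)[0, list(model.classes_).index(1.0)])
            if p >= 1.0 or p / (1.0 - p) >= cfg.odds_threshold:
                start = int(ls.bin_starts[row["bin"]])
                links.append(GeneLink(
                    chrom=ls.chrom, start=start, end=start + BIN_SIZE,
                    gene=str(ls.genes["gene"].iloc[row["gene"]]),
                    cell_type=ls.cell_types[cell_type_index],
                    method="correlation",
                    score=p / (1.0 - p) if p < 1.0 else np.inf,
                ))
        return links


def train_link_classifier(positives: np.ndarray, negatives: np.ndarray) -> LogisticRegression:
    """Ridge-regularized (C=1) logistic model over the 5 correlation features."""
    if len(positives) == 0 or len(negatives) == 0:
        raise ValueError("both classes must be non-empty")
    X = np.vstack([np.nan_to_num(positives), np.nan_to_num(negatives)])
    y = np.r_[np.ones(len(positives)), np.zeros(len(negatives))]
    model = LogisticRegression(C=1.0, solver="lbfgs", max_iter=1000)
    model.fit(X, y)
    return model


def score_links(landscape: RegulatoryLandscape, config: LinkingConfig | None = None,
                cell_type_index: int = 0) -> list[GeneLink]:
    """Run the correlation engine end to end for one cell type."""
    return CorrelationLinker(landscape, config).score_links(cell_type_index)


# ---------------------------------------------------------------------------
# Activity-by-Contact


ABC_RADIUS = 5_000_000  # bp
ABC_DEFAULT_CUTOFF = 0.02


def abc_candidate_elements(peaks: pd.DataFrame, flank: int = 500) -> pd.DataFrame:
    """Expand DNase peaks by ``flank`` bp on either side and merge overlaps.

    Abutting or overlapping expanded intervals collapse into one. Starts
    are clipped at zero. Input needs chrom/start/end; output is sorted.
    """
    rows = []
    for chrom, sub in peaks.groupby("chrom"):
        iv = sub.sort_values("start")
        cur_s = cur_e = None
        for s, e in zip(iv["start"], iv["end"]):
            s, e = max(0, int(s) - flank), int(e) + flank
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            rows.append((chrom, cur_s, cur_e))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"]).sort_values(
        ["chrom", "start"]).reset_index(drop=True)


def abc_activity(dnase: np.ndarray, h3k27ac: np.ndarray,
                 pseudocount_dnase: float = 1.0, pseudocount_h3k27ac: float = 1.0) -> np.ndarray:
    """Geometric mean of pseudocounted DNase and H3K27ac read counts."""
    d = np.asarray(dnase, dtype=float)
    k = np.asarray(h3k27ac, dtype=float)
    if (d < 0).any() or (k < 0).any():
        raise ValueError("read counts must be nonnegative")
    return np.sqrt((d + pseudocount_dnase) * (k + pseudocount_h3k27ac))


def abc_score(
    elements: pd.DataFrame,
    tss: int,
    contact,
    radius: int = ABC_RADIUS,
) -> np.ndarray:
    """Per-element ABC scores for one gene.

    ``elements`` needs chrom/start/end plus either an ``activity``
    column or ``dnase``+``h3k27ac`` read counts. ``contact`` is a
    callable distance(bp) -> nonnegative real, or a vector of per-
    element contact values. Scores for elements outside ``radius`` are
    zero; within-radius scores are normalized to sum to one. A gene
    whose denominator is zero yields all-NaN scores (caller skips it).
    """
    if "activity" in elements.columns:
        activity = elements["activity"].to_numpy(dtype=float)
    else:
        activity = abc_activity(elements["dnase"].to_numpy(), elements["h3k27ac"].to_numpy())
    mid = (elements["start"].to_numpy() + elements["end"].to_numpy()) / 2.0
    dist = np.abs(mid - tss)
    if callable(contact):
        c = np.asarray(contact(dist), dtype=float)
    else:
        c = np.asarray(contact, dtype=float)
        if c.shape[0] != len(elements):
            raise ValueError("contact vector length must match elements")
    if (c < 0).any():
        raise ValueError("contact values must be nonnegative")
    ac = activity * c
    ac = np.where(dist <= radius, ac, 0.0)
    denom = ac.sum()
    if denom <= 0:
        log.info("all-zero Activity x Contact within %d bp of TSS %d; gene skipped", radius, tss)
        return np.full(len(elements), np.nan)
    return ac / denom


def abc_links(
    elements: pd.DataFrame,
    genes: pd.DataFrame,
    contact,
    cutoff: float = ABC_DEFAULT_CUTOFF,
    radius: int = ABC_RADIUS,
    cell_type: str = "HepG2",
) -> list[GeneLink]:
    """Element-gene pairs with ABC score >= cutoff.

    ``genes`` needs gene and tss columns; ``contact`` as in
    :func:`abc_score` (callable, shared across genes).
    """
    links = []
    for _, g in genes.iterrows():
        scores = abc_score(elements, int(g["tss"]), contact, radius=radius)
        if np.isnan(scores).all():
            continue
        for i in np.nonzero(scores >= cutoff)[0]:
            row = elements.iloc[i]
            links.append(GeneLink(
                chrom=str(row["chrom"]), start=int(row["start"]), end=int(row["end"]),
                gene=str(g["gene"]), cell_type=cell_type, method="abc",
                score=float(scores[i]),
            ))
    return links
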