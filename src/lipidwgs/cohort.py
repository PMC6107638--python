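"""Synthetic multi-ancestry cohort generation with known ground truth.

Emulates the structure of a deep-coverage WGS lipid study at desk
scale: unrelated samples of several ancestries partitioned into three
disjoint "callsets" (mirroring three jointly-called VCFs), genotypes in
Hardy-Weinberg equilibrium, lipid phenotypes built from additive
polygenic, large-effect monogenic, covariate and noise components, a
regulatory landscape (enhancer/promoter/DHS intervals, chromatin-state
labels per 200-bp bin, per-cell-type mark signal correlated with gene
expression for planted links) and a power-law chromatin contact model.

All randomness derives from a single seed via named substreams, so a
fixed seed fixes every output bit-for-bit. Truth labels (carrier flags,
causal variants, planted links) are emitted for downstream recovery
tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from lipidwgs._rng import substream
from lipidwgs.containers import GenotypeMatrix

MARKS = ("H3K27ac", "H3K9ac", "H3K4me1", "H3K4me2", "DNase")
BIN_SIZE = 200  # bp, chromatin-state / signal resolution

# ancestry -> (cohort label, callset id) choices with sampling weights,
# mirroring a three-callset design (1: FHS/JHS-like, 2: MESA-like,
# 3: FIN/EST-like)
_COHORT_MAP = {
    "EA": [("FHS", 1, 0.5), ("MESA", 2, 0.3), ("ESTFIN", 3, 0.2)],
    "AA": [("JHS", 1, 0.6), ("MESA", 2, 0.4)],
    "EAS": [("MESA", 2, 1.0)],
    "HIS": [("MESA", 2, 1.0)],
}


@dataclass
class MonogenicGene:
    """One Mendelian dyslipidemia gene planted in the cohort."""

    gene: str
    inheritance: str = "dominant"  # or "recessive"
    carrier_effect: float = 30.0  # mg/dl added to carriers
    carrier_frequency: float = 0.003
    direction: str = "raising"  # or "lowering"

    def __post_init__(self) -> None:
        if self.inheritance not in {"dominant", "recessive"}:
            raise ValueError(f"unknown inheritance {self.inheritance!r}")
        if not 0.0 < self.carrier_frequency < 1.0:
            raise ValueError("carrier_frequency must lie in (0, 1)")
        if not np.isfinite(self.carrier_effect):
            raise ValueError("carrier_effect must be finite")

    @property
    def signed_effect(self) -> float:
        return self.carrier_effect if self.direction == "raising" else -self.carrier_effect


@dataclass
class CohortConfig:
    """Generative model for the synthetic cohort.

    Defaults follow the study conditions the package is tested under:
    two main ancestries, residual noise SD 15 mg/dl, one dominant
    LDL-raising gene at 30 mg/dl carrier effect with ~0.3% carriers,
    and a sparse additive polygenic background.
    """

    n_samples: dict[str, int] = field(default_factory=lambda: {"EA": 4000, "AA": 2000})
    n_variants: int = 300
    # fractions of variants drawn with rare (<1%), low-frequency
    # (0.1-1%) and common (>1%) minor allele frequencies
    maf_spectrum: tuple[float, float, float] = (0.4, 0.2, 0.4)
    polygenic_weights: np.ndarray | None = None  # mg/dl per ALT allele
    causal_fraction: float = 0.1  # used when weights are not given
    causal_effect_sd: float = 2.0  # mg/dl, SD of nonzero weights
    monogenic: list[MonogenicGene] = field(default_factory=lambda: [MonogenicGene("LDLR")])
    intercept: float = 130.0  # mg/dl baseline LDL-C
    beta_age: float = 0.5  # mg/dl per year
    beta_age2: float = -0.003
    beta_sex: float = -4.0  # male vs female
    noise_sd: float = 15.0  # mg/dl residual SD
    statin_fraction: float = 0.09
    chrom: str = "1"
    chrom_length: int = 10_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.n_samples or any(n <= 0 for n in self.n_samples.values()):
            raise ValueError("n_samples must map each ancestry to a positive count")
        if self.n_variants <= 0:
            raise ValueError("n_variants must be positive")
        if abs(sum(self.maf_spectrum) - 1.0) > 1e-9:
            raise ValueError("maf_spectrum fractions must sum to 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def _spectrum_frequencies(rng: np.random.Generator, n: int,
                          spectrum: tuple[float, float, float]) -> np.ndarray:
    """Draw minor allele frequencies from the configured mixture."""
    kind = rng.choice(3, size=n, p=np.asarray(spectrum))
    f = np.empty(n)
    f[kind == 0] = rng.uniform(2e-4, 0.01, size=(kind == 0).sum())  # rare
    f[kind == 1] = rng.uniform(1e-3, 0.01, size=(kind == 1).sum())  # low-frequency
    f[kind == 2] = rng.uniform(0.01, 0.5, size=(kind == 2).sum())  # common
    return f


def simulate_genotypes(config: CohortConfig) -> GenotypeMatrix:
    """Draw HWE genotypes for unrelated samples of each ancestry.

    Per-ancestry allele frequencies are jittered around a shared base
    frequency on the logit scale; genotypes are Binomial(2, f) per
    sample. One pathogenic variant per configured Mendelian gene is
    appended with allele frequency set so the expected carrier fraction
    matches the configured one (f = c/2 dominant, sqrt(c) recessive).
    Simulated GQ/DP/AD fields are clean by construction (deep coverage,
    allele-consistent read support) so QC defaults pass them.
    """
    rng = substream(config.seed, "genotypes")
    n_poly = config.n_variants
    base_f = _spectrum_frequencies(rng, n_poly, config.maf_spectrum)

    ancestries = sorted(config.n_samples)
    freq = {}
    for anc in ancestries:
        logit = np.log(base_f / (1 - base_f)) + rng.normal(0.0, 0.3, size=n_poly)
        freq[anc] = 1.0 / (1.0 + np.exp(-logit))

    # pathogenic variants for Mendelian genes, shared frequency across ancestries
    patho_f = []
    for gene in config.monogenic:
        c = gene.carrier_frequency
        patho_f.append(c / 2.0 if gene.inheritance == "dominant" else float(np.sqrt(c)))
    n_total = n_poly + len(patho_f)

    sample_rows = []
    blocks = []
    for anc in ancestries:
        n = config.n_samples[anc]
        f_anc = np.concatenate([freq[anc], np.asarray(patho_f)]) if patho_f else freq[anc]
        blocks.append(rng.binomial(2, np.broadcast_to(f_anc, (n, n_total))).astype(float))
        choices = _COHORT_MAP.get(anc, [(f"{anc}_COHORT", 2, 1.0)])
        labels = rng.choice(len(choices), size=n, p=[w for _, _, w in choices])
        for i in range(n):
            cohort, callset, _ = choices[labels[i]]
            sample_rows.append((f"{anc}_{i:05d}", anc, cohort, callset))

    dosages = np.vstack(blocks)
    samples = pd.DataFrame(sample_rows, columns=["sample_id", "ancestry", "cohort", "callset"])

    pos = np.sort(rng.choice(config.chrom_length, size=n_total, replace=False))
    refs = rng.choice(list("ACGT"), size=n_total)
    alts = np.array([rng.choice([b for b in "ACGT" if b != r]) for r in refs])
    variants = pd.DataFrame({
        "vid": [f"{config.chrom}:{p + 1}:{r}:{a}" for p, r, a in zip(pos, refs, alts)],
        "chrom": config.chrom,
        "pos": pos,  # 0-based internally
        "ref": refs,
        "alt": alts,
        "gene": "",
        "consequence": "",
        "clinvar": "",
        "causal_weight": 0.0,
    })
    for k, gene in enumerate(config.monogenic):
        j = n_poly + k
        variants.loc[j, ["gene", "consequence", "clinvar"]] = [gene.gene, "lof", "pathogenic"]

    # clean per-genotype quality fields at deep coverage
    n_s = dosages.shape[0]
    dp = rng.poisson(38, size=(n_s, n_total)).clip(min=4)
    err = 0.002
    alt_p = np.where(dosages == 0, err, np.where(dosages == 1, 0.5, 1 - err))
    ad_alt = rng.binomial(dp, alt_p)
    ad_ref = dp - ad_alt
    gq = np.full((n_s, n_total), 99.0)

    return GenotypeMatrix(dosages=dosages, variants=variants, samples=samples,
                          gq=gq.astype(float), dp=dp.astype(float),
                          ad_ref=ad_ref.astype(float), ad_alt=ad_alt.astype(float))


def carrier_flags(genotypes: GenotypeMatrix, config: CohortConfig) -> pd.DataFrame:
    """Truth carrier flags per Mendelian gene from planted genotypes."""
    flags = {}
    for gene in config.monogenic:
        mask = (genotypes.variants["gene"] == gene.gene).to_numpy()
        dos = np.nan_to_num(genotypes.dosages[:, mask])
        if gene.inheritance == "dominant":
            flags[gene.gene] = (dos.sum(axis=1) >= 1).astype(int)
        else:
            flags[gene.gene] = (dos >= 2).any(axis=1).astype(int)
    return pd.DataFrame(flags, index=genotypes.samples.index)


def simulate_phenotypes(genotypes: GenotypeMatrix, config: CohortConfig) -> pd.DataFrame:
    """Generate lipid phenotypes on top of simulated genotypes.

    True LDL-C = intercept + b_age*age + b_age2*age^2 + b_sex*male
    + sum_j w_j g_j + gamma*carrier + N(0, sd^2). HDL and TG are drawn
    independently and TC is assembled as LDL + HDL + TG/5 so the
    Friedewald derivation is exact on untreated samples. Statin users
    have observed TC scaled by 0.8 and LDL by 0.7, which the statin
    adjustment inverts. Truth columns (``ldl_true``, ``carrier_<gene>``,
    ``polygenic_true``) are carried for recovery tests.
    """
    rng = substream(config.seed, "phenotypes")
    n = genotypes.n_samples
    n_poly = config.n_variants

    if config.polygenic_weights is not None:
        w = np.asarray(config.polygenic_weights, dtype=float)
        if w.shape[0] != n_poly:
            raise ValueError(
                f"polygenic_weights has {w.shape[0]} entries for {n_poly} polygenic variants"
            )
    else:
        w = np.zeros(n_poly)
        causal = rng.random(n_poly) < config.causal_fraction
        w[causal] = rng.normal(0.0, config.causal_effect_sd, size=causal.sum())
    genotypes.variants.loc[: n_poly - 1, "causal_weight"] = w

    age = np.clip(rng.normal(51.0, 15.0, size=n), 20.0, 90.0)
    male = rng.binomial(1, 0.47, size=n).astype(float)

    poly = np.nan_to_num(genotypes.dosages[:, :n_poly]) @ w
    flags = carrier_flags(genotypes, config)
    mono = np.zeros(n)
    for gene in config.monogenic:
        mono += gene.signed_effect * flags[gene.gene].to_numpy()

    ldl_true = (config.intercept + config.beta_age * age + config.beta_age2 * age ** 2
                + config.beta_sex * male + poly + mono
                + rng.normal(0.0, config.noise_sd, size=n))

    hdl = np.clip(rng.normal(52.0, 14.0, size=n), 15.0, None)
    tg = np.clip(rng.lognormal(np.log(100.0), 0.45, size=n), 20.0, None)
    tc_true = ldl_true + hdl + tg / 5.0

    on_statin = rng.binomial(1, config.statin_fraction, size=n).astype(bool)
    tc_obs = np.where(on_statin, tc_true * 0.8, tc_true)
    ldl_obs = np.where(on_statin, ldl_true * 0.7, ldl_true)
    # observed TG/HDL kept equal to the generated values; observed TC for
    # statin users no longer satisfies Friedewald exactly, mirroring the
    # approximation made when adjusting measured data
    tg_obs = np.where(on_statin, 5.0 * (tc_obs - hdl - ldl_obs), tg)

    out = genotypes.samples.copy()
    out["age"] = age
    out["sex"] = male  # 1 = male
    out["on_statin"] = on_statin.astype(int)
    out["tc"] = tc_obs
    out["hdl"] = hdl
    out["tg"] = tg_obs
    out["ldl_true"] = ldl_true
    out["polygenic_true"] = poly
    for gene in config.monogenic:
        out[f"carrier_{gene.gene}"] = flags[gene.gene].to_numpy()
    return out


# ---------------------------------------------------------------------------
# regulatory landscape


@dataclass
class LandscapeConfig:
    """Generative model for the synthetic regulatory landscape.

    Cell-type count defaults to 56, matching the reference-epigenome
    panel size over which mark/expression correlations are computed.
    """

    n_cell_types: int = 56
    n_genes: int = 12
    n_bins: int = 600  # 200-bp bins on one synthetic chromosome
    enhancer_fraction: float = 0.15  # of bins carrying an enhancer state
    true_link_fraction: float = 0.5  # of enhancer bins planted as real links
    rho_true: float = 0.9  # mark/expression correlation at planted links
    contact_gamma: float = 1.0  # power-law decay exponent
    chrom: str = "1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cell_types < 3:
            raise ValueError("need at least 3 cell types to compute correlations")
        if self.n_genes < 1 or len(MARKS) < 5:
            raise ValueError("need at least 1 gene and 5 marks")
        if not -1.0 <= self.rho_true <= 1.0:
            raise ValueError("rho_true must lie in [-1, 1]")


@dataclass
class RegulatoryLandscape:
    """Annotations, signals and contact model for the linking engines."""

    genes: pd.DataFrame  # gene, tss (bp), strand
    bin_starts: np.ndarray  # (n_bins,) bp, 200-bp tiling
    states: np.ndarray  # (n_bins, n_cell_types) chromatin-state labels
    cell_types: list[str]
    signal: np.ndarray  # (n_bins, n_cell_types, n_marks), nonnegative
    expression: np.ndarray  # (n_genes, n_cell_types), nonnegative
    intervals: pd.DataFrame  # chrom, start, end, kind in {enhancer, promoter, dhs}, cell_type
    true_links: pd.DataFrame  # bin_index, gene (planted ground truth)
    contact_gamma: float = 1.0
    chrom: str = "1"

    def contact(self, distance_bp: np.ndarray | float) -> np.ndarray | float:
        """Power-law contact frequency C(d) = (|d| + 1) ** -gamma."""
        return (np.abs(distance_bp) + 1.0) ** (-self.contact_gamma)


def simulate_regulatory_landscape(config: LandscapeConfig) -> RegulatoryLandscape:
    """Build a landscape with planted enhancer-gene links.

    Planted links get mark signal whose across-cell-type profile equals
    rho_true * standardized expression of the target gene plus Gaussian
    noise of variance 1 - rho_true^2 (so the population Pearson
    correlation is rho_true); decoy enhancer bins get independent noise.
    Signals are shifted to be nonnegative. Chromatin states are assigned
    per cell type; planted and decoy enhancer bins carry 7_Enh in the
    first cell type and in a random half of the others.
    """
    rng = substream(config.seed, "landscape")
    n_ct, n_g, n_b = config.n_cell_types, config.n_genes, config.n_bins
    cell_types = [f"CT{t:02d}" for t in range(n_ct)]
    chrom_len = n_b * BIN_SIZE
    bin_starts = np.arange(n_b) * BIN_SIZE

    # TSSs on a jittered regular grid: every enhancer bin then lies within
    # half a gene spacing of its nearest TSS, so planted links occupy
    # offset strata that carry enough true examples to train on
    spacing = n_b / n_g
    tss_bins = ((np.arange(n_g) + 0.5) * spacing
                + rng.uniform(-0.1 * spacing, 0.1 * spacing, size=n_g)).astype(int)
    tss_bins = np.clip(tss_bins, 0, n_b - 1)
    tss = np.sort(tss_bins) * BIN_SIZE
    genes = pd.DataFrame({
        "gene": [f"GENE{g:03d}" for g in range(n_g)],
        "tss": tss,
        "strand": rng.choice(["+", "-"], size=n_g),
    })

    if n_ct <= n_g + 1:
        raise ValueError("need more cell types than genes for decorrelated expression")
    # expression profiles with exactly zero pairwise sample correlation, so
    # every non-target (bin, gene) pair is a genuine null: chance
    # co-expression would otherwise make planted truth unidentifiable
    z = rng.normal(0.0, 1.0, size=(n_g, n_ct))
    z -= z.mean(axis=1, keepdims=True)
    for g in range(n_g):  # Gram-Schmidt among centered rows
        for h in range(g):
            z[g] -= (z[g] @ z[h]) / (z[h] @ z[h]) * z[h]
        z[g] /= z[g].std()
    expr_std = z
    expr = np.maximum(10.0 + 3.0 * z, 0.0)

    tss_bins = set((tss // BIN_SIZE).tolist())
    candidates = np.array([b for b in range(n_b) if b not in tss_bins])
    n_enh = max(2, int(round(config.enhancer_fraction * n_b)))
    enh_bins = np.sort(rng.choice(candidates, size=n_enh, replace=False))
    n_true = int(round(config.true_link_fraction * n_enh))
    true_idx = rng.choice(n_enh, size=n_true, replace=False)
    is_true = np.zeros(n_enh, dtype=bool)
    is_true[true_idx] = True

    # each planted bin links to its nearest gene by TSS distance
    target = np.empty(n_enh, dtype=int)
    for i, b in enumerate(enh_bins):
        target[i] = int(np.argmin(np.abs(tss - b * BIN_SIZE)))

    rho = config.rho_true
    signal = rng.normal(0.0, 1.0, size=(n_b, n_ct, len(MARKS)))
    for i, b in enumerate(enh_bins):
        if is_true[i]:
            e = expr_std[target[i]]
            noise = rng.normal(0.0, 1.0, size=(n_ct, len(MARKS)))
            signal[b] = rho * e[:, None] + np.sqrt(max(0.0, 1 - rho ** 2)) * noise
    signal = signal + 6.0  # shift to a nonnegative read-count-like scale
    np.maximum(signal, 0.0, out=signal)

    # chromatin states per cell type: 7_Enh at enhancer bins in the first
    # cell type and a random half of the rest; TssA at promoter bins
    states = np.full((n_b, n_ct), "quiescent", dtype=object)
    for i, b in enumerate(enh_bins):
        on = np.zeros(n_ct, dtype=bool)
        on[0] = True
        on[1 + rng.choice(n_ct - 1, size=(n_ct - 1) // 2, replace=False)] = True
        states[b, on] = "7_Enh"
    for t in tss_bins:
        states[t, :] = "1_TssA"

    rows = []
    for i, b in enumerate(enh_bins):
        s, e = b * BIN_SIZE, (b + 1) * BIN_SIZE
        rows.append((config.chrom, s, e, "enhancer", "shared"))
        rows.append((config.chrom, s, e, "dhs", "shared"))
    for t in sorted(tss_bins):
        s, e = t * BIN_SIZE, (t + 1) * BIN_SIZE
        rows.append((config.chrom, s, e, "promoter", "shared"))
        rows.append((config.chrom, s, e, "dhs", "shared"))
    intervals = pd.DataFrame(rows, columns=["chrom", "start", "end", "kind", "cell_type"])
    intervals = intervals.sort_values(["kind", "start"]).reset_index(drop=True)

    true_links = pd.DataFrame({
        "bin_index": enh_bins[is_true],
        "gene": [genes["gene"].iloc[t] for t in target[is_true]],
    })

    return RegulatoryLandscape(
        genes=genes, bin_starts=bin_starts, states=states, cell_types=cell_types,
        signal=signal, expression=expr, intervals=intervals, true_links=true_links,
        contact_gamma=config.contact_gamma, chrom=config.chrom,
    )


# ---------------------------------------------------------------------------
# assembled cohort and on-disk round trip


@dataclass
class Cohort:
    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame
    landscape: RegulatoryLandscape
    config: CohortConfig
    landscape_config: LandscapeConfig


def simulate_cohort(config: CohortConfig | None = None,
                    landscape_config: LandscapeConfig | None = None) -> Cohort:
    """Generate genotypes, phenotypes and a regulatory landscape together."""
    config = config or CohortConfig()
    landscape_config = landscape_config or LandscapeConfig(seed=config.seed)
    gm = simulate_genotypes(config)
    ph = simulate_phenotypes(gm, config)
    ls = simulate_regulatory_landscape(landscape_config)
    return Cohort(genotypes=gm, phenotypes=ph, landscape=ls,
                  config=config, landscape_config=landscape_config)


def write_cohort(cohort: Cohort, directory: str | Path) -> dict[str, Path]:
    """Write the cohort as VCF + BED + TSV files; round-trip safe.

    Produces ``genotypes.vcf`` (GT:GQ:DP:AD, 1-based positions),
    ``annotations.bed`` (0-based half-open, name = kind), ``states.bed``,
    ``phenotypes.tsv``, ``expression.tsv``, ``signal.tsv``, ``genes.tsv``
    and ``truth_links.tsv``.
    """
    from lipidwgs import io as lio  # local import: io depends on containers only

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}

    paths["vcf"] = directory / "genotypes.vcf"
    lio.write_vcf(cohort.genotypes, paths["vcf"])

    paths["annotations"] = directory / "annotations.bed"
    lio.write_bed(cohort.landscape.intervals.rename(columns={"kind": "name"}),
                  paths["annotations"])

    ls = cohort.landscape
    state_rows = [
        (ls.chrom, int(s), int(s) + BIN_SIZE, f"{ct}:{ls.states[b, t]}")
        for b, s in enumerate(ls.bin_starts)
        for t, ct in enumerate(ls.cell_types)
        if ls.states[b, t] != "quiescent"
    ]
    paths["states"] = directory / "states.bed"
    lio.write_bed(pd.DataFrame(state_rows, columns=["chrom", "start", "end", "name"]),
                  paths["states"])

    paths["phenotypes"] = directory / "phenotypes.tsv"
    cohort.phenotypes.to_csv(paths["phenotypes"], sep="\t", index=False)

    expr = pd.DataFrame(ls.expression, index=ls.genes["gene"], columns=ls.cell_types)
    paths["expression"] = directory / "expression.tsv"
    expr.to_csv(paths["expression"], sep="\t", index_label="gene")

    sig = pd.DataFrame(
        ls.signal.reshape(ls.signal.shape[0], -1),
        columns=[f"{ct}|{m}" for ct in ls.cell_types for m in MARKS],
    )
    sig.insert(0, "bin_start", ls.bin_starts)
    paths["signal"] = directory / "signal.tsv"
    sig.to_csv(paths["signal"], sep="\t", index=False)

    paths["genes"] = directory / "genes.tsv"
    ls.genes.to_csv(paths["genes"], sep="\t", index=False)

    paths["truth_links"] = directory / "truth_links.tsv"
    ls.true_links.to_csv(paths["truth_links"], sep="\t", index=False)

    meta = {"seed": cohort.config.seed, "n_samples": cohort.config.n_samples,
            "n_variants": cohort.config.n_variants}
    paths["meta"] = directory / "cohort.json"
    paths["meta"].write_text(json.dumps(meta, indent=2, sort_keys=True))
    return paths
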