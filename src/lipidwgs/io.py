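"""Readers and writers for VCF, BED and annotated TSV files.

Internal coordinates are 0-based half-open; VCF positions are 1-based
on disk. VCF reading goes through cyvcf2 and splits multi-allelic sites
into biallelic records with allele-specific dosages.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from lipidwgs.containers import GenotypeMatrix


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> Path:
    """Write a biallelic VCF 4.2 with FORMAT GT:GQ:DP:AD.

    Annotation columns on the variant table (gene, consequence, clinvar)
    are emitted as INFO keys so a round trip preserves them.
    """
    path = Path(path)
    v = matrix.variants
    info_cols = [c for c in ("gene", "consequence", "clinvar") if c in v.columns]
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={v['chrom'].iloc[0] if len(v) else '1'}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
    ]
    for c in info_cols:
        lines.append(f'##INFO=<ID={c.upper()},Number=1,Type=String,Description="{c}">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.samples["sample_id"]))

    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    has_fmt = matrix.gq is not None and matrix.dp is not None and matrix.ad_ref is not None
    for j in range(matrix.n_variants):
        row = v.iloc[j]
        info = ";".join(f"{c.upper()}={row[c]}" for c in info_cols if str(row[c])) or "."
        fields = [str(row["chrom"]), str(int(row["pos"]) + 1), str(row["vid"]),
                  str(row["ref"]), str(row["alt"]), ".", "PASS", info,
                  "GT:GQ:DP:AD" if has_fmt else "GT"]
        for i in range(matrix.n_samples):
            d = matrix.dosages[i, j]
            gt = "./." if np.isnan(d) else gt_map[float(d)]
            if has_fmt:
                gt += (f":{int(matrix.gq[i, j])}:{int(matrix.dp[i, j])}"
                       f":{int(matrix.ad_ref[i, j])},{int(matrix.ad_alt[i, j])}")
            fields.append(gt)
        lines.append("\t".join(fields))
    path.write_text("\n".join(lines) + "\n")
    return path


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a VCF into a GenotypeMatrix (multi-allelics split per ALT)."""
    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    n_s = len(sample_ids)

    dosage_cols, gq_cols, dp_cols, adr_cols, ada_cols, meta = [], [], [], [], [], []
    has_fmt = True
    for var in vcf:
        genos = var.genotypes  # [[a1, a2, phased], ...]
        try:
            gq = var.gt_quals
            dp = var.format("DP")
            ad = var.format("AD")
        except KeyError:  # FORMAT field absent from header
            gq = dp = ad = None
        if gq is None or dp is None or ad is None:
            has_fmt = False
        alts = var.ALT if var.ALT else []
        for k, alt in enumerate(alts, start=1):
            dos = np.full(n_s, np.nan)
            for i, g in enumerate(genos):
                alleles = [a for a in g[:-1]]
                if any(a < 0 for a in alleles):
                    continue
                dos[i] = float(sum(1 for a in alleles if a == k))
            dosage_cols.append(dos)
            info_gene = var.INFO.get("GENE") or ""
            meta.append((var.ID or f"{var.CHROM}:{var.POS}:{var.REF}:{alt}",
                         var.CHROM, var.POS - 1, var.REF, alt,
                         info_gene, var.INFO.get("CONSEQUENCE") or "",
                         var.INFO.get("CLINVAR") or ""))
            if has_fmt:
                gq_cols.append(np.asarray(gq, dtype=float))
                dp_cols.append(np.asarray(dp, dtype=float).reshape(n_s))
                ad_arr = np.asarray(ad, dtype=float).reshape(n_s, -1)
                adr_cols.append(ad_arr[:, 0])
                ada_cols.append(ad_arr[:, min(k, ad_arr.shape[1] - 1)])

    variants = pd.DataFrame(meta, columns=["vid", "chrom", "pos", "ref", "alt",
                                           "gene", "consequence", "clinvar"])
    samples = pd.DataFrame({"sample_id": sample_ids})
    stack = lambda cols: np.column_stack(cols) if cols else None
    dosages = (np.column_stack(dosage_cols) if dosage_cols
               else np.empty((n_s, 0)))
    return GenotypeMatrix(dosages=dosages, variants=variants, samples=samples,
                          gq=stack(gq_cols) if has_fmt else None,
                          dp=stack(dp_cols) if has_fmt else None,
                          ad_ref=stack(adr_cols) if has_fmt else None,
                          ad_alt=stack(ada_cols) if has_fmt else None)


def write_bed(intervals: pd.DataFrame, path: str | Path) -> Path:
    """Write BED3+ (0-based half-open) with optional extra columns."""
    path = Path(path)
    cols = ["chrom", "start", "end"] + [c for c in intervals.columns
                                        if c not in ("chrom", "start", "end")]
    intervals[cols].to_csv(path, sep="\t", header=False, index=False)
    return path


def read_bed(path: str | Path, extra_names: list[str] | None = None) -> pd.DataFrame:
    """Read BED3+ into a sorted frame of 0-based half-open intervals.

    Column 4 onward are named ``name``, then ``extra_names`` if given.
    Raises on negative starts or start >= end.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    names = ["chrom", "start", "end", "name"] + (extra_names or [])
    df.columns = names[: df.shape[1]] + [f"col{i}" for i in range(len(names), df.shape[1])]
    if (df["start"] < 0).any():
        raise ValueError("BED interval with negative start")
    if (df["start"] >= df["end"]).any():
        raise ValueError("BED interval with start >= end")
    return df.sort_values(["chrom", "start", "end"]).reset_index(drop=True)


def write_tsv(df: pd.DataFrame, path: str | Path, meta: dict | None = None) -> Path:
    """Write a TSV with '#key=value' header comments (config hash, seed...)."""
    path = Path(path)
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"#{k}={v}\n")
        df.to_csv(fh, sep="\t", index=False)
    return path


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def config_hash(obj) -> str:
    """Short stable hash of a configuration's repr, for output headers."""
    return hashlib.sha256(repr(obj).encode()).hexdigest()[:12]
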