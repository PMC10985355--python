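"""Readers and writers for the pipeline's plain-text interchange formats.

Genotypes travel as a dosage TSV (samples × SNPs, header of "chrom_pos"
SNP ids) or as minimal VCF v4.2 (GT only, 1-based positions); phenotypes as
a long TSV (variety, trait, year, regime, rep, value); counts as a
gene × sample TSV with a length column; LD pairs / QC reports / blocks as
TSV.  Haplotype blocks export BED-style half-open 0-based coordinates for
interoperability with genome-arithmetic tools.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synthetic_data import MISSING, ExpressionMatrix, GenotypeMatrix


def write_genotypes_tsv(geno: GenotypeMatrix, path: str) -> None:
    df = pd.DataFrame(
        geno.dosage, index=pd.Index(geno.samples, name="sample"), columns=geno.snps["id"]
    ).replace(MISSING, "NA")
    df.to_csv(path, sep="\t")


def read_genotypes_tsv(path: str) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values="NA")
    chrom_pos = [c.rsplit("_", 1) for c in df.columns]
    snps = pd.DataFrame(
        {
            "id": df.columns,
            "chrom": [c for c, _ in chrom_pos],
            "pos": [int(p) for _, p in chrom_pos],
            "ref": "A",
            "alt": "G",
        }
    )
    dosage = df.to_numpy(dtype=float)
    out = np.where(np.isnan(dosage), MISSING, dosage).astype(np.int8)
    return GenotypeMatrix(samples=list(df.index), snps=snps, dosage=out)


_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(geno: GenotypeMatrix, path: str) -> None:
    """Minimal VCF v4.2 with GT only."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(geno.snps["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.samples)
            + "\n"
        )
        for j, snp in geno.snps.iterrows():
            gts = "\t".join(_GT_CODE[int(g)] for g in geno.dosage[:, j])
            fh.write(
                f"{snp['chrom']}\t{snp['pos']}\t{snp['id']}\t{snp['ref']}\t"
                f"{snp['alt']}\t.\t.\t.\tGT\t{gts}\n"
            )


def read_vcf(path: str) -> GenotypeMatrix:
    """Read a VCF (GT field) into a dosage matrix; needs cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    rows, dosages = [], []
    for var in vcf:
        alt = var.ALT[0] if var.ALT else "."
        rows.append(
            (
                var.ID or f"{var.CHROM}_{var.POS}",
                var.CHROM,
                var.POS,
                var.REF,
                alt,
            )
        )
        gt = var.gt_types  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        dos = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=MISSING)
        dosages.append(dos.astype(np.int8))
    snps = pd.DataFrame(rows, columns=["id", "chrom", "pos", "ref", "alt"])
    return GenotypeMatrix(
        samples=samples, snps=snps, dosage=np.column_stack(dosages)
    )


def write_pheno_tsv(pheno: pd.DataFrame, path: str) -> None:
    pheno.to_csv(path, sep="\t", index=False)


def read_pheno_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_counts_tsv(expr: ExpressionMatrix, path: str) -> None:
    df = expr.counts.copy()
    df.insert(0, "length", expr.lengths.reindex(df.index))
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def read_counts_tsv(path: str, samples: pd.DataFrame) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    lengths = df.pop("length")
    return ExpressionMatrix(counts=df, lengths=lengths, samples=samples)


def blocks_to_bed(blocks: list[dict]) -> pd.DataFrame:
    """Haplotype blocks as BED-like rows (0-based half-open start/end)."""
    return pd.DataFrame(
        [
            {
                "chrom": b["chrom"],
                "start": b["start"] - 1,
                "end": b["end"],
                "n_snps": len(b["snps"]),
                "snps": ",".join(b["snps"]),
            }
            for b in blocks
        ]
    )
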