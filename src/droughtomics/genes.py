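"""Candidate-gene extraction around significant SNPs.

Genes are 1-based inclusive intervals read from GFF3 (via gffutils).  A gene
is a candidate for a SNP when the distance from the SNP position to the
nearest gene edge is at most the window (inclusive), the window defaulting
to the genome-wide LD-decay estimate.  Relations are strand-aware: "within"
when the SNP falls inside the gene, otherwise "upstream" (5′ of the TSS) or
"downstream" (3′ of the gene end).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: the two window presets used for candidate extraction (bp)
WINDOW_200KB = 200_000
WINDOW_LD_DECAY = 288_000


def load_gff(path: str) -> pd.DataFrame:
    """Parse gene features from a GFF3 file into a sorted gene-model table.

    Returns columns gene_id, chrom, start, end (1-based inclusive), strand,
    annotation.  Malformed lines are collected in ``df.attrs['bad_lines']``.
    """
    import gffutils
    from gffutils.exceptions import EmptyInputError

    try:
        db = gffutils.create_db(
            path,
            ":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except EmptyInputError as exc:
        raise ValueError(f"no gene features in {path}") from exc
    rows = []
    for feat in db.features_of_type("gene"):
        gid = feat.attributes.get("ID", [feat.id])[0]
        note = ";".join(feat.attributes.get("Note", []))
        rows.append((gid, feat.seqid, feat.start, feat.end, feat.strand or ".", note))
    if not rows:
        raise ValueError(f"no gene features in {path}")
    genes = pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "strand", "annotation"]
    )
    genes = genes.sort_values(["chrom", "start"]).reset_index(drop=True)
    return genes


def write_gff(genes: pd.DataFrame, path: str) -> None:
    """Write gene models back out as minimal GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, g in genes.iterrows():
            attrs = f"ID={g['gene_id']}"
            if g.get("annotation"):
                attrs += f";Note={g['annotation']}"
            fh.write(
                f"{g['chrom']}\tsim\tgene\t{g['start']}\t{g['end']}\t.\t"
                f"{g.get('strand', '.')}\t.\t{attrs}\n"
            )


def genes_near_snp(
    snp: tuple[str, int], genes: pd.DataFrame, window: int
) -> pd.DataFrame:
    """Genes within ``window`` bp (inclusive) of a SNP position.

    Returns columns gene_id, relation ∈ {within, upstream, downstream},
    distance (bp to the nearest gene edge, 0 if within) and window.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    chrom, pos = snp
    sub = genes[genes["chrom"] == chrom]
    rows = []
    for _, g in sub.iterrows():
        start, end, strand = int(g["start"]), int(g["end"]), g.get("strand", ".")
        if start <= pos <= end:
            relation, dist = "within", 0
        elif pos < start:
            dist = start - pos
            relation = "downstream" if strand == "-" else "upstream"
        else:
            dist = pos - end
            relation = "upstream" if strand == "-" else "downstream"
        if dist <= window:
            rows.append((g["gene_id"], chrom, start, end, strand, relation, dist, window))
    out = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "chrom", "start", "end", "strand", "relation", "distance", "window",
        ],
    )
    return out.sort_values(["distance", "gene_id"]).reset_index(drop=True)


def candidate_gene_table(
    sig_snps: pd.DataFrame, genes: pd.DataFrame, window: int = WINDOW_LD_DECAY
) -> pd.DataFrame:
    """One row per (lead SNP, nearby gene), grouped by trait.

    ``sig_snps`` is a significant-association table (columns id, chrom, pos,
    trait, environment, p, r2); lead SNPs per trait × environment follow the
    smallest-p-then-smallest-position rule.
    """
    from .gwas import lead_snps

    if sig_snps.empty:
        return pd.DataFrame(
            columns=[
                "trait", "environment", "id", "chrom", "pos", "p", "r2",
                "gene_id", "relation", "distance", "window",
            ]
        )
    leads = lead_snps(sig_snps)
    rows = []
    for _, s in leads.iterrows():
        near = genes_near_snp((s["chrom"], int(s["pos"])), genes, window)
        for _, g in near.iterrows():
            rows.append(
                {
                    "trait": s["trait"],
                    "environment": s["environment"],
                    "id": s["id"],
                    "chrom": s["chrom"],
                    "pos": int(s["pos"]),
                    "p": s["p"],
                    "r2": s.get("r2", np.nan),
                    "gene_id": g["gene_id"],
                    "relation": g["relation"],
                    "distance": int(g["distance"]),
                    "window": window,
                }
            )
    out = pd.DataFrame(rows)
    if not out.empty:
        out = out.sort_values(["trait", "environment", "distance", "gene_id"]).reset_index(
            drop=True
        )
    return out
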