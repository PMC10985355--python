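"""GWAS × transcriptome integration.

Significant SNPs define candidate intervals (default width: the genome-wide
LD-decay estimate of 288 kbp, centred on each SNP; overlapping intervals
are merged before gene assignment).  The up/down DEG ratios inside those
intervals are compared with the genome-wide ratios by Fisher's exact test,
and GWAS candidate genes that are also DEGs form the validated candidate
list.
"""

from __future__ import annotations

import json
import os

import numpy as np
import pandas as pd
from scipy import stats

from .genes import WINDOW_LD_DECAY


def deg_ratios(deg_table: pd.DataFrame, genes: set[str] | None = None) -> dict:
    """Up/down-regulated fractions over tested genes (optionally a subset)."""
    if deg_table.empty:
        raise ValueError("empty DEG table")
    sub = deg_table[deg_table["tested"]]
    if genes is not None:
        sub = sub[sub["gene_id"].isin(genes)]
    n = len(sub["gene_id"].unique())
    if n == 0:
        return {"up": np.nan, "down": np.nan, "n": 0, "undefined": True}
    per_gene = sub.groupby("gene_id")["direction"].agg(
        lambda s: "up" if (s == "up").any() else ("down" if (s == "down").any() else "ns")
    )
    return {
        "up": float((per_gene == "up").mean()),
        "down": float((per_gene == "down").mean()),
        "n": n,
        "undefined": False,
    }


def merge_intervals(intervals: list[tuple[str, int, int]]) -> list[tuple[str, int, int]]:
    """Merge overlapping/touching (chrom, start, end) intervals (1-based incl.)."""
    merged: list[list] = []
    for chrom, start, end in sorted(intervals):
        if merged and merged[-1][0] == chrom and start <= merged[-1][2] + 1:
            merged[-1][2] = max(merged[-1][2], end)
        else:
            merged.append([chrom, start, end])
    return [tuple(m) for m in merged]


def snp_intervals(
    sig_snps: pd.DataFrame, window: int = WINDOW_LD_DECAY
) -> list[tuple[str, int, int]]:
    """±window/2 intervals around significant SNPs, merged when overlapping."""
    half = window // 2
    ivals = [
        (row["chrom"], max(1, int(row["pos"]) - half), int(row["pos"]) + half)
        for _, row in sig_snps.drop_duplicates(subset=["id"]).iterrows()
    ]
    return merge_intervals(ivals)


def genes_in_intervals(
    genes: pd.DataFrame, intervals: list[tuple[str, int, int]]
) -> set[str]:
    """Genes overlapping any interval (edge-inclusive)."""
    hits: set[str] = set()
    for chrom, lo, hi in intervals:
        sub = genes[
            (genes["chrom"] == chrom) & (genes["end"] >= lo) & (genes["start"] <= hi)
        ]
        hits.update(sub["gene_id"])
    return hits


def interval_deg_comparison(
    sig_snps: pd.DataFrame,
    genes: pd.DataFrame,
    deg_table: pd.DataFrame,
    window: int = WINDOW_LD_DECAY,
) -> dict:
    """Compare DEG enrichment inside SNP intervals against the rest of the genome.

    Builds merged ±window/2 intervals around the significant SNPs, splits
    tested genes into in-interval vs out, and applies Fisher's exact test to
    the DEG vs non-DEG × in vs out 2×2 table (one-sided, enrichment).
    """
    intervals = snp_intervals(sig_snps, window)
    inside = genes_in_intervals(genes, intervals)
    tested = deg_table[deg_table["tested"]]
    per_gene = tested.groupby("gene_id")["direction"].agg(lambda s: (s != "ns").any())
    in_mask = per_gene.index.isin(inside)
    a = int(per_gene[in_mask].sum())  # DEG, in interval
    b = int(in_mask.sum() - a)  # non-DEG, in interval
    c = int(per_gene[~in_mask].sum())  # DEG, outside
    d = int((~in_mask).sum() - c)
    if a + b == 0:
        return {
            "intervals": intervals,
            "warning": "no tested genes in any interval",
            "p": np.nan,
        }
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    ratios_in = deg_ratios(deg_table, inside)
    ratios_genome = deg_ratios(deg_table)
    return {
        "intervals": intervals,
        "n_in": a + b,
        "n_out": c + d,
        "deg_in": a,
        "deg_out": c,
        "odds_ratio": float(odds),
        "p": float(p),
        "interval_ratios": ratios_in,
        "genome_ratios": ratios_genome,
    }


def overlap_gwas_degs(
    candidates: pd.DataFrame, deg_table: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Candidate genes that are DEGs in at least one contrast, plus Venn counts.

    Returns the validated candidate list annotated with DEG direction and
    log2fc (deduplicated by gene × SNP × contrast) and the Venn counts
    {candidates_only, degs_only, overlap}.
    """
    cand_genes = set(candidates["gene_id"]) if not candidates.empty else set()
    deg_hits = deg_table[(deg_table["tested"]) & (deg_table["direction"] != "ns")]
    deg_genes = set(deg_hits["gene_id"])
    if cand_genes and deg_table["gene_id"].nunique() > 0:
        overlap_space = cand_genes & set(deg_table["gene_id"])
        if len(overlap_space) / len(cand_genes) < 0.5:
            raise ValueError(
                "more than half of candidate genes are absent from the DEG table; "
                "check that gene identifier namespaces match"
            )
    venn = {
        "candidates_only": len(cand_genes - deg_genes),
        "degs_only": len(deg_genes - cand_genes),
        "overlap": len(cand_genes & deg_genes),
    }
    if candidates.empty:
        return candidates.copy(), venn
    merged = candidates.merge(deg_hits, on="gene_id", how="inner")
    keys = ["gene_id", "id"]
    for col in ("variety", "tissue"):
        if col in merged.columns:
            keys.append(col)
    merged = merged.drop_duplicates(subset=keys).reset_index(drop=True)
    return merged, venn


def final_report(outputs: dict, out_dir: str) -> dict:
    """Write all stage outputs as a TSV bundle plus a JSON run log.

    ``outputs`` maps stage name → DataFrame (written as <name>.tsv) or
    JSON-serialisable object (collected into run_log.json).  Raises when a
    required stage is missing.
    """
    required = ["genetic_params", "significant_snps", "candidate_genes", "deg_table"]
    missing = [k for k in required if k not in outputs]
    if missing:
        raise ValueError(f"missing stage outputs: {', '.join(missing)}")
    os.makedirs(out_dir, exist_ok=True)
    log = {}
    written = {}
    for name, obj in outputs.items():
        if isinstance(obj, pd.DataFrame):
            path = os.path.join(out_dir, f"{name}.tsv")
            obj.to_csv(path, sep="\t", index=False)
            written[name] = path
        else:
            log[name] = obj
    with open(os.path.join(out_dir, "run_log.json"), "w") as fh:
        json.dump(log, fh, indent=2, default=str)
    written["run_log"] = os.path.join(out_dir, "run_log.json")
    return written
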