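"""Join SNPs to gene intervals and tally per-gene outlier counts.

Coordinates: SNP positions are 1-based, gene intervals are BED (0-based,
half-open).  A SNP at 1-based position P overlaps [start, end) iff
start < P <= end, i.e. P - 1 lies inside the half-open interval.  This is
the only place where the two conventions meet.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd
from intervaltree import IntervalTree

from .core_io import GeneIntervalSet
from .highland_scan import ScanResult

OUTLIER_FLAGS = ("global_outlier", "di_outlier", "chi2_outlier", "common")


def map_snps_to_genes(
    snps: pd.DataFrame,
    genes: GeneIntervalSet,
    exclude_genes: Sequence[str] = (),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Annotate SNPs with overlapping gene ids.

    ``snps`` needs ``chrom`` and ``pos`` (1-based) columns.  Returns the
    annotated per-SNP frame (``gene_ids`` as a sorted comma-joined string,
    ``region`` in {genic, intergenic}) and a per-gene frame with the number
    of overlapping SNPs.  ``exclude_genes`` drops the named gene ids (e.g.
    uninformative placeholder symbols) before the join.
    """
    exclude = set(exclude_genes)
    trees: dict[str, IntervalTree] = {}
    for rec in genes.frame.itertuples(index=False):
        if rec.gene_id in exclude:
            continue
        trees.setdefault(str(rec.chrom), IntervalTree()).addi(
            int(rec.start), int(rec.end), rec.gene_id
        )
    gene_ids = []
    for chrom, pos in zip(snps["chrom"].astype(str), snps["pos"].astype(int)):
        tree = trees.get(chrom)
        hits = sorted({iv.data for iv in tree[pos - 1]}) if tree is not None else []
        gene_ids.append(hits)
    annotated = snps[["chrom", "pos"]].copy().reset_index(drop=True)
    annotated["gene_ids"] = [",".join(h) for h in gene_ids]
    annotated["region"] = ["genic" if h else "intergenic" for h in gene_ids]

    counts: dict[str, int] = {}
    for hits in gene_ids:
        for g in hits:
            counts[g] = counts.get(g, 0) + 1
    per_gene = pd.DataFrame(
        sorted(counts.items()), columns=["gene_id", "n_snps"]
    )
    return annotated, per_gene


def gene_summary(annotated: pd.DataFrame, scan: ScanResult) -> pd.DataFrame:
    """Per-gene counts of outlier SNPs by flag.

    A SNP overlapping several genes increments each of them.  Genes with no
    outlier SNP of any kind are omitted.
    """
    frame = scan.frame
    if not annotated[["chrom", "pos"]].reset_index(drop=True).equals(
        frame[["chrom", "pos"]].reset_index(drop=True)
    ):
        raise ValueError("annotated SNPs and scan result are not aligned")
    rows: dict[str, dict[str, int]] = {}
    flags = frame[list(OUTLIER_FLAGS)].to_numpy()
    for genestr, flagrow in zip(annotated["gene_ids"], flags):
        if not genestr or not flagrow.any():
            continue
        for g in genestr.split(","):
            cell = rows.setdefault(g, {f: 0 for f in OUTLIER_FLAGS})
            for f, v in zip(OUTLIER_FLAGS, flagrow):
                cell[f] += int(v)
    out = pd.DataFrame(
        [{"gene_id": g, **c} for g, c in sorted(rows.items())],
        columns=["gene_id", *OUTLIER_FLAGS],
    )
    return out
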