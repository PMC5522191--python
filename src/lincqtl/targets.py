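"""Cis target-gene prediction for differentially expressed lncRNAs.

The conventional cis rule is applied: a protein-coding gene is a putative
target of a lncRNA when the gap between their genomic bodies is at most
``window`` bp (default 100 kb) on the same chromosome.  The relation is
reported in genome coordinates (strand-agnostic): a gene entirely before
the lncRNA is *upstream*, entirely after it *downstream*, otherwise
*overlapping* with distance 0.  A strand-aware mode orients
upstream/downstream by the lncRNA's strand instead.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Dict, Iterable, List, Sequence, Union

import pandas as pd

from .models import (
    GeneModel,
    LncRNARecord,
    TargetPair,
    TranscriptModel,
    ValidationError,
)


def _as_transcript(item) -> TranscriptModel:
    return item.transcript if isinstance(item, LncRNARecord) else item


def assign_cis_targets(
    lncrnas: Sequence[Union[LncRNARecord, TranscriptModel]],
    genes: Sequence[GeneModel],
    window: int = 100_000,
    strand_aware: bool = False,
) -> List[TargetPair]:
    """Emit every lncRNA-gene pair whose body-to-body gap is <= window."""
    if window < 0:
        raise ValidationError("window must be non-negative")
    genes_by_chrom: Dict[str, List[GeneModel]] = defaultdict(list)
    for g in genes:
        genes_by_chrom[g.chrom].append(g)
    for gl in genes_by_chrom.values():
        gl.sort(key=lambda g: g.start)

    pairs: List[TargetPair] = []
    for item in lncrnas:
        tx = _as_transcript(item)
        for g in genes_by_chrom.get(tx.chrom, ()):
            if g.start >= tx.end:  # gene after lncRNA
                gap = g.start - tx.end
                relation = "downstream"
            elif g.end <= tx.start:  # gene before lncRNA
                gap = tx.start - g.end
                relation = "upstream"
            else:
                gap = 0
                relation = "overlapping"
            if gap > window:
                continue
            if strand_aware and relation != "overlapping" and tx.strand == "-":
                relation = "upstream" if relation == "downstream" else "downstream"
            pairs.append(
                TargetPair(
                    lncrna_id=tx.transcript_id,
                    gene_id=g.gene_id,
                    distance=gap,
                    relation=relation,
                )
            )
    return pairs


def pair_de_tables(
    pairs: Iterable[TargetPair],
    lnc_de: pd.DataFrame,
    gene_de: pd.DataFrame,
    de_genes_only: bool = False,
) -> pd.DataFrame:
    """Join cis pairs with both DE tables into a report of DE lncRNAs and
    their target genes.

    Rows are restricted to lncRNAs whose status is not *ns*; with
    ``de_genes_only`` the target gene must be DE as well.  The DE tables
    are indexed by feature id and carry ``fold_change`` and ``status``.
    """
    rows = []
    for p in pairs:
        if p.lncrna_id not in lnc_de.index or p.gene_id not in gene_de.index:
            continue
        lnc = lnc_de.loc[p.lncrna_id]
        gene = gene_de.loc[p.gene_id]
        if lnc["status"] == "ns":
            continue
        if de_genes_only and gene["status"] == "ns":
            continue
        rows.append(
            {
                "lncRNA_ID": p.lncrna_id,
                "lnc_fold_change": lnc["fold_change"],
                "lnc_regulated": lnc["status"],
                "gene_ID": p.gene_id,
                "gene_fold_change": gene["fold_change"],
                "gene_regulated": gene["status"],
                "distance": p.distance,
                "relation": p.relation,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "lncRNA_ID", "lnc_fold_change", "lnc_regulated",
            "gene_ID", "gene_fold_change", "gene_regulated",
            "distance", "relation",
        ],
    )
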