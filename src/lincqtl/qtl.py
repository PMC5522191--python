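"""Colocalization of DE features with trait-linked QTL intervals.

Features are mapped onto QTL regions by any-overlap of the feature body
(>= 1 bp, half-open internal coordinates); a feature may belong to many
QTLs.  Each QTL is scored as the number of DE lncRNAs it contains divided
by its span (end - start on the printed 1-based coordinates), a per-bp
density that ranks short, lncRNA-dense intervals first.  Trait tallies
count *distinct* DE features across all of a trait's QTLs, so a feature
overlapping several QTLs of one trait counts once for that trait while
still contributing to each QTL's own score.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from intervaltree import IntervalTree

from .models import (
    ColocatedPair,
    FeatureInterval,
    QtlRegion,
    QtlScoreRow,
    TraitTally,
    ValidationError,
)


def map_to_qtl(
    features: Sequence[FeatureInterval],
    qtls: Sequence[QtlRegion],
    containment: bool = False,
) -> Dict[int, Set[str]]:
    """Membership map qtl_id -> ids of features overlapping the interval.

    ``containment`` switches from any-overlap to whole-body containment.
    """
    trees: Dict[str, IntervalTree] = defaultdict(IntervalTree)
    for f in features:
        trees[f.chrom][f.start:f.end] = f
    membership: Dict[int, Set[str]] = {}
    for q in qtls:
        hits = trees.get(q.chrom, IntervalTree()).overlap(q.start0, q.end0)
        if containment:
            ids = {
                iv.data.feature_id
                for iv in hits
                if q.start0 <= iv.begin and iv.end <= q.end0
            }
        else:
            ids = {iv.data.feature_id for iv in hits}
        membership[q.qtl_id] = ids
    return membership


def tally_by_trait(
    membership_lnc: Mapping[int, Set[str]],
    membership_mrna: Mapping[int, Set[str]],
    qtls: Sequence[QtlRegion],
    lnc_status: Mapping[str, str],
    mrna_status: Mapping[str, str],
) -> List[TraitTally]:
    """Per-trait tallies of distinct DE lncRNAs and mRNAs.

    ``n_qtl_id`` counts the trait's QTLs containing at least one DE
    lncRNA; traits with none are omitted.  Statuses map feature id to
    up/down.
    """
    by_trait: Dict[str, List[QtlRegion]] = defaultdict(list)
    for q in qtls:
        by_trait[q.trait].append(q)
    tallies = []
    for trait in sorted(by_trait):
        regions = by_trait[trait]
        lnc_ids: Set[str] = set()
        mrna_ids: Set[str] = set()
        n_qtl = 0
        for q in regions:
            members = membership_lnc.get(q.qtl_id, set())
            if members:
                n_qtl += 1
            lnc_ids |= members
            mrna_ids |= membership_mrna.get(q.qtl_id, set())
        if not lnc_ids and not mrna_ids:
            continue
        lnc_up = sum(1 for f in lnc_ids if lnc_status.get(f) == "up")
        mrna_up = sum(1 for f in mrna_ids if mrna_status.get(f) == "up")
        tallies.append(
            TraitTally(
                trait=trait,
                n_qtl_id=n_qtl,
                de_lncrna_total=len(lnc_ids),
                de_lncrna_up=lnc_up,
                de_lncrna_down=len(lnc_ids) - lnc_up,
                de_mrna_total=len(mrna_ids),
                de_mrna_up=mrna_up,
                de_mrna_down=len(mrna_ids) - mrna_up,
            )
        )
    return tallies


def score_qtl(qtl: QtlRegion, de_lncrna_count: int) -> QtlScoreRow:
    """Score one QTL as DE-lncRNA count / span (lncRNAs per bp)."""
    span = qtl.span
    if span <= 0:
        raise ValidationError(f"QTL {qtl.qtl_id}: span must be positive")
    return QtlScoreRow(
        qtl_id=qtl.qtl_id,
        chrom=qtl.chrom,
        trait=qtl.trait,
        symbol=qtl.symbol,
        start=qtl.start,
        end=qtl.end,
        de_lncrna_count=int(de_lncrna_count),
        span=span,
        score=de_lncrna_count / span,
    )


def score_all(
    qtls: Sequence[QtlRegion], membership_lnc: Mapping[int, Set[str]]
) -> List[QtlScoreRow]:
    return [score_qtl(q, len(membership_lnc.get(q.qtl_id, set()))) for q in qtls]


def rank_qtl(
    rows: Iterable[QtlScoreRow], top_n: Optional[int] = None
) -> List[QtlScoreRow]:
    """Descending by score, ties broken by ascending qtl_id; truncated."""
    ranked = sorted(rows, key=lambda r: (-r.score, r.qtl_id))
    return ranked[:top_n] if top_n is not None else ranked


def colocated_pairs(
    membership_lnc: Mapping[int, Set[str]],
    membership_mrna: Mapping[int, Set[str]],
) -> List[ColocatedPair]:
    """QTLs containing at least one DE lncRNA *and* one DE gene."""
    pairs = []
    for qtl_id in sorted(set(membership_lnc) & set(membership_mrna)):
        lncs = membership_lnc[qtl_id]
        genes = membership_mrna[qtl_id]
        if lncs and genes:
            pairs.append(
                ColocatedPair(
                    qtl_id=qtl_id,
                    lncrna_ids=tuple(sorted(lncs)),
                    gene_ids=tuple(sorted(genes)),
                )
            )
    return pairs
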