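"""lncRNA identification: candidate filtering, four-tool coding-potential
intersection, and positional classification against the annotation.

The filter cascade retains transcripts that are longer than ``min_length``
(strictly), have at least ``min_exons`` exons, at least ``min_coverage``
mean per-base fragment coverage, and reach ``min_fpkm`` in at least one
sample.  A transcript is a lncRNA candidate only when all four
coding-potential classifiers call it noncoding.

Positional categories are assigned by precedence:

1. *antisense* — exonic overlap with a gene's exons on the opposite strand;
2. *sense* — exonic overlap with a gene's exons on the same strand;
3. *intronic* — wholly contained in a single intron of a gene (either
   strand), with no exonic overlap;
4. *lincRNA* — no overlap with any gene body.

When several genes match the winning category, the nearest gene by
midpoint distance is reported (ties broken by gene_id).  A transcript that
overlaps a gene body without matching 1-3 (possible only when an explicit
gene envelope extends past its outermost exons) falls through to lincRNA.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple, Union

from intervaltree import IntervalTree

from .models import (
    CATEGORIES,
    CategorySummary,
    CodingCallSet,
    ExpressionTable,
    GeneModel,
    LncRNARecord,
    TranscriptModel,
    ValidationError,
)

logger = logging.getLogger("lincqtl")


@dataclass(frozen=True)
class FilterParams:
    """Thresholds of the candidate filter cascade.

    Defaults follow the conventional lncRNA-calling filter: spliced length
    strictly greater than 200 bp, at least two exons, mean per-base
    fragment coverage of at least 3 reads, and FPKM of at least 0.1 in at
    least one sample.
    """

    min_length: int = 200
    min_exons: int = 2
    min_coverage: float = 3.0
    min_fpkm: float = 0.1
    fpkm_per_sample: bool = False  # require min_fpkm in every sample instead

    def __post_init__(self) -> None:
        if min(self.min_length, self.min_exons) <= 0 or min(
            self.min_coverage, self.min_fpkm
        ) <= 0:
            raise ValidationError("all filter thresholds must be > 0")


#: Cascade order in which the first failing rule is tallied.
FILTER_RULES = ("length", "exons", "coverage", "fpkm")


def filter_candidates(
    transcripts: Sequence[TranscriptModel],
    expression: ExpressionTable,
    params: FilterParams = FilterParams(),
) -> Tuple[List[TranscriptModel], Dict[str, int]]:
    """Apply the filter cascade; return retained transcripts and a tally of
    how many transcripts failed each rule (first failing rule only)."""
    missing = [t.transcript_id for t in transcripts if t.transcript_id not in expression.fpkm.index]
    if missing:
        raise ValidationError(
            f"{len(missing)} transcripts lack expression rows: "
            + ", ".join(missing[:10])
            + ("..." if len(missing) > 10 else "")
        )
    tally = {rule: 0 for rule in FILTER_RULES}
    retained: List[TranscriptModel] = []
    fpkm = expression.fpkm
    for tx in transcripts:
        row = fpkm.loc[tx.transcript_id]
        fpkm_stat = row.min() if params.fpkm_per_sample else row.max()
        if not tx.spliced_length > params.min_length:
            tally["length"] += 1
        elif not tx.n_exons >= params.min_exons:
            tally["exons"] += 1
        elif not tx.fragment_coverage >= params.min_coverage:
            tally["coverage"] += 1
        elif not fpkm_stat >= params.min_fpkm:
            tally["fpkm"] += 1
        else:
            retained.append(tx)
    return retained, tally


def intersect_coding_calls(
    calls: Sequence[CodingCallSet],
) -> Tuple[List[str], Dict[Tuple[str, ...], int]]:
    """Intersect the four tools' verdicts.

    Returns the transcript ids called noncoding by *all* tools (the lncRNA
    candidates, sorted) and the Venn cell counts keyed by the sorted tuple
    of tools voting noncoding (the empty tuple collects transcripts every
    tool called coding).
    """
    venn: Counter = Counter()
    candidates: List[str] = []
    for cs in calls:
        cell = cs.noncoding_tools
        venn[cell] += 1
        if cs.is_candidate and len(cs.verdicts) > 0:
            candidates.append(cs.transcript_id)
    return sorted(candidates), dict(venn)


class GeneIndex:
    """Per-chromosome interval trees over gene bodies and gene exons."""

    def __init__(self, genes: Iterable[GeneModel]):
        self.body_trees: Dict[str, IntervalTree] = defaultdict(IntervalTree)
        self.exon_trees: Dict[str, IntervalTree] = defaultdict(IntervalTree)
        self.by_chrom: Dict[str, List[GeneModel]] = defaultdict(list)
        for g in genes:
            self.body_trees[g.chrom][g.start:g.end] = g
            for s, e in g.exons:
                self.exon_trees[g.chrom][s:e] = g
            self.by_chrom[g.chrom].append(g)

    def body_overlaps(self, tx: TranscriptModel) -> List[GeneModel]:
        hits = self.body_trees.get(tx.chrom, IntervalTree()).overlap(tx.start, tx.end)
        return [iv.data for iv in hits]

    def exon_overlaps(self, tx: TranscriptModel) -> Set[GeneModel]:
        tree = self.exon_trees.get(tx.chrom)
        if tree is None:
            return set()
        out: Set[GeneModel] = set()
        for s, e in tx.exons:
            out.update(iv.data for iv in tree.overlap(s, e))
        return out

    def nearest(self, tx: TranscriptModel) -> Union[GeneModel, None]:
        genes = self.by_chrom.get(tx.chrom)
        if not genes:
            return None
        return min(genes, key=lambda g: (abs(g.midpoint - tx.midpoint), g.gene_id))


def _pick(genes: Iterable[GeneModel], tx: TranscriptModel) -> GeneModel:
    return min(genes, key=lambda g: (abs(g.midpoint - tx.midpoint), g.gene_id))


def classify_lncrna(
    candidate: TranscriptModel,
    genes: Union[Sequence[GeneModel], GeneIndex],
) -> LncRNARecord:
    """Assign the positional category of one candidate (see module docs)."""
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    if candidate.chrom not in index.by_chrom:
        logger.warning(
            "transcript %s: chromosome %s absent from annotation; "
            "classified as lincRNA", candidate.transcript_id, candidate.chrom
        )
        return LncRNARecord(candidate, "lincRNA", None)

    exonic = index.exon_overlaps(candidate)
    anti = [g for g in exonic if g.strand != candidate.strand]
    if anti:
        return LncRNARecord(candidate, "antisense", _pick(anti, candidate).gene_id)
    if exonic:
        return LncRNARecord(candidate, "sense", _pick(exonic, candidate).gene_id)

    intronic_hosts = []
    for g in index.body_overlaps(candidate):
        for istart, iend in g.introns():
            if istart <= candidate.start and candidate.end <= iend:
                intronic_hosts.append(g)
                break
    if intronic_hosts:
        return LncRNARecord(
            candidate, "intronic", _pick(intronic_hosts, candidate).gene_id
        )

    nearest = index.nearest(candidate)
    return LncRNARecord(candidate, "lincRNA", nearest.gene_id if nearest else None)


def classify_all(
    candidates: Sequence[TranscriptModel], genes: Sequence[GeneModel]
) -> List[LncRNARecord]:
    index = GeneIndex(genes)
    return [classify_lncrna(tx, index) for tx in candidates]


def summarize_categories(
    records: Union[Sequence[LncRNARecord], Mapping[str, int]],
) -> CategorySummary:
    """Counts and percentages (2 decimals) per positional category."""
    if isinstance(records, Mapping):
        counts = {c: int(records.get(c, 0)) for c in CATEGORIES}
    else:
        if len(records) == 0:
            raise ValidationError("cannot summarize zero lncRNA records")
        census = Counter(r.category for r in records)
        counts = {c: census.get(c, 0) for c in CATEGORIES}
    return CategorySummary.from_counts(counts)
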