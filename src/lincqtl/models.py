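"""Core value types shared by all pipeline stages.

Coordinate convention: every type in this module stores 0-based half-open
intervals.  External tables (GTF, QTL databases) are 1-based inclusive and
are converted exactly once, at the I/O boundary (:mod:`lincqtl.io`).  The
single exception is :class:`QtlRegion`, which keeps the coordinates as
printed in the source table (1-based inclusive) because the downstream
count/span score is defined on the printed numbers; half-open views are
exposed as ``start0`` / ``end0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Tuple

import pandas as pd


class LincqtlError(Exception):
    """Base class for all errors raised by lincqtl."""


class ParseError(LincqtlError):
    """A malformed input file (message names the offending line)."""


class ValidationError(LincqtlError):
    """Structurally valid input that violates a documented invariant."""


Interval = Tuple[int, int]

#: The four positional lncRNA categories, in classification precedence order
#: (antisense and sense by exonic overlap, intronic by containment,
#: lincRNA by absence of any gene-body overlap).
CATEGORIES = ("lincRNA", "antisense", "intronic", "sense")

#: Default names of the four coding-potential classifiers whose verdicts
#: are intersected.
DEFAULT_TOOLS = ("CPC", "CNCI", "CPAT", "Pfam")


def _check_exons(exons: Sequence[Interval], what: str) -> Tuple[Interval, ...]:
    exons = tuple((int(s), int(e)) for s, e in exons)
    if not exons:
        raise ValidationError(f"{what}: at least one exon required")
    for s, e in exons:
        if s >= e:
            raise ValidationError(f"{what}: empty or inverted exon ({s}, {e})")
    for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
        if s2 < e1:
            raise ValidationError(
                f"{what}: exons not sorted/non-overlapping at ({s1},{e1}) vs ({s2},{e2})"
            )
    return exons


@dataclass(frozen=True)
class GeneModel:
    """A reference gene: the annotation unit lncRNAs are classified against."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: Tuple[Interval, ...]
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: strand must be + or -")
        if self.start >= self.end:
            raise ValidationError(f"gene {self.gene_id}: start >= end")
        exons = _check_exons(self.exons, f"gene {self.gene_id}")
        object.__setattr__(self, "exons", exons)
        if exons[0][0] < self.start or exons[-1][1] > self.end:
            raise ValidationError(f"gene {self.gene_id}: exon outside gene body")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    def introns(self) -> Tuple[Interval, ...]:
        """Gaps between consecutive exons, half-open."""
        return tuple(
            (e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]) if s2 > e1
        )


@dataclass(frozen=True)
class TranscriptModel:
    """An assembled transcript flowing through filtering and classification.

    ``fragment_coverage`` is the assembler-reported mean read depth per
    spliced base (the ``cov`` GTF attribute in Cufflinks-style output).
    """

    transcript_id: str
    gene_id: Optional[str]
    chrom: str
    strand: str
    exons: Tuple[Interval, ...]
    fragment_coverage: float = 0.0

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"transcript {self.transcript_id}: strand must be + or -"
            )
        exons = _check_exons(self.exons, f"transcript {self.transcript_id}")
        object.__setattr__(self, "exons", exons)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)


@dataclass
class ExpressionTable:
    """Feature x sample FPKM and fragment-count matrices.

    ``lengths`` are spliced lengths in bp; ``library_sizes`` are the
    per-sample totals of mapped fragments used as FPKM denominators.
    ``gene_ids`` optionally maps each feature to its gene for gene-level
    aggregation.
    """

    fpkm: pd.DataFrame
    fragments: pd.DataFrame
    lengths: pd.Series
    library_sizes: pd.Series
    gene_ids: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if not self.fpkm.index.equals(self.fragments.index):
            raise ValidationError("fpkm and fragments feature indices differ")
        if list(self.fpkm.columns) != list(self.fragments.columns):
            raise ValidationError("fpkm and fragments sample columns differ")
        if not self.fpkm.index.equals(self.lengths.index):
            raise ValidationError("lengths index does not match features")
        if list(self.library_sizes.index) != list(self.fpkm.columns):
            raise ValidationError("library_sizes index does not match samples")
        if (self.fpkm.values < 0).any() or (self.fragments.values < 0).any():
            raise ValidationError("expression values must be non-negative")
        if (self.lengths <= 0).any():
            raise ValidationError("feature lengths must be positive")
        if (self.library_sizes <= 0).any():
            raise ValidationError("library sizes must be positive")

    @property
    def features(self) -> list:
        return list(self.fpkm.index)

    @property
    def samples(self) -> list:
        return list(self.fpkm.columns)


@dataclass(frozen=True)
class CodingCallSet:
    """Per-transcript verdicts of the four coding-potential classifiers."""

    transcript_id: str
    verdicts: Mapping[str, str]

    def __post_init__(self) -> None:
        for tool, verdict in self.verdicts.items():
            if verdict not in ("coding", "noncoding"):
                raise ValidationError(
                    f"{self.transcript_id}/{tool}: verdict {verdict!r} "
                    "not in {coding, noncoding}"
                )

    @property
    def noncoding_tools(self) -> Tuple[str, ...]:
        return tuple(sorted(t for t, v in self.verdicts.items() if v == "noncoding"))

    @property
    def is_candidate(self) -> bool:
        """True when every tool calls the transcript noncoding."""
        return all(v == "noncoding" for v in self.verdicts.values())


@dataclass(frozen=True)
class QtlRegion:
    """A trait-linked genomic interval, coordinates as printed (1-based)."""

    qtl_id: int
    chrom: str
    trait: str
    symbol: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(f"QTL {self.qtl_id}: start >= end")

    @property
    def start0(self) -> int:
        """0-based half-open start."""
        return self.start - 1

    @property
    def end0(self) -> int:
        """0-based half-open end."""
        return self.end

    @property
    def span(self) -> int:
        """Interval span on the printed coordinates (end - start)."""
        return self.end - self.start


@dataclass(frozen=True)
class LibraryMetrics:
    """Per-sample sequencing-library QC metrics (Table-1 style)."""

    sample_id: str
    metrics: Mapping[str, float]


@dataclass(frozen=True)
class LncRNARecord:
    """A transcript that survived filtering plus the four-way intersection,
    labelled with its positional category relative to the annotation."""

    transcript: TranscriptModel
    category: str
    nearest_gene_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValidationError(f"unknown category {self.category!r}")


@dataclass(frozen=True)
class CategorySummary:
    """Counts and percentages of the four positional categories."""

    counts: Mapping[str, int]
    percentages: Mapping[str, float]
    total: int

    @classmethod
    def from_counts(cls, counts: Mapping[str, int]) -> "CategorySummary":
        total = sum(counts.values())
        if total == 0:
            raise ValidationError("cannot summarize an empty category census")
        pct = {c: round(100.0 * n / total, 2) for c, n in counts.items()}
        return cls(counts=dict(counts), percentages=pct, total=total)


@dataclass(frozen=True)
class TargetPair:
    """A lncRNA / protein-coding gene pair within the cis window."""

    lncrna_id: str
    gene_id: str
    distance: int
    relation: str  # upstream | downstream | overlapping (genome coordinates)
    lnc_status: Optional[str] = None
    gene_status: Optional[str] = None


@dataclass(frozen=True)
class QtlScoreRow:
    """A QTL with its DE-lncRNA count and per-bp density score."""

    qtl_id: int
    chrom: str
    trait: str
    symbol: str
    start: int
    end: int
    de_lncrna_count: int
    span: int
    score: float

    @property
    def score_str(self) -> str:
        """Score in scientific notation with 3 significant digits."""
        return f"{self.score:.2E}"


@dataclass(frozen=True)
class TraitTally:
    """Distinct DE features falling in any QTL of one trait."""

    trait: str
    n_qtl_id: int
    de_lncrna_total: int
    de_lncrna_up: int
    de_lncrna_down: int
    de_mrna_total: int
    de_mrna_up: int
    de_mrna_down: int


@dataclass(frozen=True)
class ColocatedPair:
    """DE lncRNAs and DE genes sharing one QTL interval."""

    qtl_id: int
    lncrna_ids: Tuple[str, ...]
    gene_ids: Tuple[str, ...]


@dataclass(frozen=True)
class FeatureInterval:
    """A minimal genomic feature for overlap queries (0-based half-open)."""

    feature_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(f"feature {self.feature_id}: start >= end")
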