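"""Readers and writers for every external table the pipeline touches.

All external genomic tables are 1-based inclusive (GTF, QTL tables); this
module is the single place where they are converted to the internal
0-based half-open convention.  Tabular formats are TSV with documented
headers; GTF lines are parsed with gffutils so attribute quoting and
dialect quirks are handled by an established parser.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
from gffutils.feature import feature_from_line

from .models import (
    CodingCallSet,
    DEFAULT_TOOLS,
    ExpressionTable,
    GeneModel,
    LibraryMetrics,
    ParseError,
    QtlRegion,
    TranscriptModel,
    ValidationError,
)

logger = logging.getLogger("lincqtl")


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def _merge_intervals(intervals: Iterable[Tuple[int, int]]) -> Tuple[Tuple[int, int], ...]:
    merged: List[Tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return tuple(merged)


def read_gtf(path) -> Tuple[List[TranscriptModel], List[GeneModel]]:
    """Read a GTF file into transcript and gene models.

    Exon records are grouped per ``transcript_id`` and sorted; 1-based
    inclusive GTF coordinates become 0-based half-open.  Gene models are
    reconstructed as exon-union envelopes over each ``gene_id`` (explicit
    gene records are not required).  A ``cov`` attribute, when present,
    populates ``fragment_coverage``.

    Raises
    ------
    ParseError
        on a malformed line, naming its line number.
    ValidationError
        when an exon lies outside its declared transcript envelope.
    """
    path = Path(path)
    tx_exons: Dict[str, List[Tuple[int, int]]] = defaultdict(list)
    tx_meta: Dict[str, Tuple[Optional[str], str, str, float]] = {}
    declared: Dict[str, Tuple[int, int]] = {}
    order: List[str] = []

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if len(line.split("\t")) != 9:
                raise ParseError(
                    f"{path}: malformed GTF line {lineno}: expected 9 tab-separated fields"
                )
            try:
                feat = feature_from_line(line)
            except Exception as exc:  # gffutils raises assorted error types
                raise ParseError(f"{path}: malformed GTF line {lineno}: {exc}") from exc
            if feat.featuretype not in ("exon", "transcript"):
                continue
            attrs = feat.attributes
            tids = attrs.get("transcript_id", [])
            if not tids:
                raise ParseError(
                    f"{path}: line {lineno}: {feat.featuretype} record lacks transcript_id"
                )
            tid = tids[0]
            gid = attrs.get("gene_id", [None])[0]
            cov = float(attrs.get("cov", ["0"])[0] or 0.0)
            start0, end0 = feat.start - 1, feat.end
            if feat.featuretype == "transcript":
                declared[tid] = (start0, end0)
            else:
                tx_exons[tid].append((start0, end0))
            if tid not in tx_meta:
                tx_meta[tid] = (gid, feat.seqid, feat.strand, cov)
                order.append(tid)
            elif cov and not tx_meta[tid][3]:
                g, c, s, _ = tx_meta[tid]
                tx_meta[tid] = (g, c, s, cov)

    transcripts: List[TranscriptModel] = []
    for tid in order:
        gid, chrom, strand, cov = tx_meta[tid]
        exons = sorted(tx_exons.get(tid, []))
        if not exons:
            if tid in declared:  # transcript line without exon children
                exons = [declared[tid]]
            else:
                continue
        if tid in declared:
            ds, de = declared[tid]
            if exons[0][0] < ds or exons[-1][1] > de:
                raise ValidationError(
                    f"{path}: transcript {tid}: exon outside declared envelope "
                    f"[{ds},{de})"
                )
        transcripts.append(
            TranscriptModel(tid, gid, chrom, strand, tuple(exons), cov)
        )

    genes = genes_from_transcripts(transcripts)
    return transcripts, genes


def genes_from_transcripts(transcripts: Sequence[TranscriptModel]) -> List[GeneModel]:
    """Reconstruct genes as exon-union envelopes over shared gene_ids."""
    by_gene: Dict[str, List[TranscriptModel]] = defaultdict(list)
    order: List[str] = []
    for tx in transcripts:
        gid = tx.gene_id or tx.transcript_id
        if gid not in by_gene:
            order.append(gid)
        by_gene[gid].append(tx)
    genes = []
    for gid in order:
        members = by_gene[gid]
        strands = {t.strand for t in members}
        if len(strands) > 1:
            logger.warning("gene %s has transcripts on both strands; using first", gid)
        exons = _merge_intervals(
            (s, e) for t in members for s, e in t.exons
        )
        genes.append(
            GeneModel(
                gene_id=gid,
                chrom=members[0].chrom,
                strand=members[0].strand,
                start=exons[0][0],
                end=exons[-1][1],
                exons=exons,
            )
        )
    return genes


def write_gtf(path, transcripts: Sequence[TranscriptModel], source: str = "lincqtl") -> None:
    """Write transcript + exon records, converting back to 1-based inclusive."""
    with open(path, "w") as fh:
        for tx in transcripts:
            attrs = f'gene_id "{tx.gene_id or tx.transcript_id}"; transcript_id "{tx.transcript_id}";'
            if tx.fragment_coverage:
                attrs += f' cov "{tx.fragment_coverage:.6g}";'
            fh.write(
                "\t".join(
                    [tx.chrom, source, "transcript", str(tx.start + 1), str(tx.end),
                     ".", tx.strand, ".", attrs]
                )
                + "\n"
            )
            for s, e in tx.exons:
                fh.write(
                    "\t".join(
                        [tx.chrom, source, "exon", str(s + 1), str(e),
                         ".", tx.strand, ".", attrs]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# Expression tables
# ---------------------------------------------------------------------------

def read_expression(expr_path, samples_path) -> Tuple[ExpressionTable, pd.DataFrame]:
    """Read the wide expression TSV plus the sample sheet.

    The expression TSV has columns ``feature_id``, ``gene_id`` (optional),
    ``length``, then ``<sample>_fpkm`` and ``<sample>_frags`` per sample.
    The sample sheet has columns ``sample_id``, ``group``, ``library_size``.

    Returns the :class:`ExpressionTable` and the sample sheet DataFrame.
    """
    samples = pd.read_csv(samples_path, sep="\t", dtype={"sample_id": str})
    for col in ("sample_id", "group", "library_size"):
        if col not in samples.columns:
            raise ValidationError(f"{samples_path}: missing column {col!r}")
    expr = pd.read_csv(expr_path, sep="\t", index_col="feature_id")
    sample_ids = list(samples["sample_id"])
    fpkm = pd.DataFrame(
        {s: expr[f"{s}_fpkm"] for s in sample_ids}, index=expr.index
    )
    frags = pd.DataFrame(
        {s: expr[f"{s}_frags"] for s in sample_ids}, index=expr.index
    )
    table = ExpressionTable(
        fpkm=fpkm,
        fragments=frags,
        lengths=expr["length"],
        library_sizes=pd.Series(
            samples["library_size"].values, index=sample_ids, dtype=float
        ),
        gene_ids=expr["gene_id"] if "gene_id" in expr.columns else None,
    )
    return table, samples


def write_expression(expr: ExpressionTable, expr_path) -> None:
    out = pd.DataFrame(index=expr.fpkm.index)
    out.index.name = "feature_id"
    if expr.gene_ids is not None:
        out["gene_id"] = expr.gene_ids
    out["length"] = expr.lengths
    for s in expr.samples:
        out[f"{s}_fpkm"] = expr.fpkm[s].round(4)
        out[f"{s}_frags"] = expr.fragments[s].astype(int)
    out.to_csv(expr_path, sep="\t")


def write_samples(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# QTL tables
# ---------------------------------------------------------------------------

_QTL_SYNONYMS = {
    "qtlid": "qtl_id",
    "chrome": "chrom",
    "chromosome": "chrom",
    "chrom": "chrom",
    "chr": "chrom",
    "trait": "trait",
    "traitname": "trait",
    "name": "symbol",
    "symbol": "symbol",
    "start": "start",
    "end": "end",
}


def read_qtl_table(path) -> List[QtlRegion]:
    """Read an Animal-QTLdb-style TSV of trait-linked intervals.

    Columns are matched by name (synonyms allowed: Chrome/Chromosome/Chr,
    Trait/Trait Name, Name/Symbol), in any order; unknown extra columns are
    ignored with a warning.  Coordinates are kept as printed (1-based
    inclusive); half-open views live on :class:`QtlRegion`.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    rename = {}
    for col in df.columns:
        key = str(col).strip().lower().replace(" ", "").replace("_", "")
        if key in _QTL_SYNONYMS:
            rename[col] = _QTL_SYNONYMS[key]
        else:
            logger.warning("%s: ignoring unknown column %r", path, col)
    df = df.rename(columns=rename)
    for col in ("qtl_id", "chrom", "trait", "start", "end"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing required column {col!r}")
    regions: List[QtlRegion] = []
    seen = set()
    for _, row in df.iterrows():
        qtl_id = int(row["qtl_id"])
        start, end = int(row["start"]), int(row["end"])
        if start >= end:
            raise ValidationError(f"{path}: QTL {qtl_id}: Start >= End")
        if qtl_id in seen:
            raise ValidationError(f"{path}: duplicate QTL_ID {qtl_id}")
        seen.add(qtl_id)
        regions.append(
            QtlRegion(
                qtl_id=qtl_id,
                chrom=str(row["chrom"]),
                trait=str(row["trait"]),
                symbol=str(row.get("symbol", "")),
                start=start,
                end=end,
            )
        )
    return regions


def write_qtl_table(regions: Sequence[QtlRegion], path) -> None:
    pd.DataFrame(
        {
            "QTL_ID": [q.qtl_id for q in regions],
            "Chrome": [q.chrom for q in regions],
            "Trait": [q.trait for q in regions],
            "Name": [q.symbol for q in regions],
            "Start": [q.start for q in regions],
            "End": [q.end for q in regions],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Coding-potential verdict tables
# ---------------------------------------------------------------------------

def read_coding_calls(
    paths: Mapping[str, object],
) -> Tuple[List[CodingCallSet], Dict[str, List[str]]]:
    """Read one verdict TSV per tool and assemble complete call sets.

    Each file has columns ``transcript_id`` and ``verdict`` with verdicts in
    {coding, noncoding}.  Only transcripts present in *all* files yield a
    :class:`CodingCallSet`; the second return value maps each incomplete
    transcript to the tools it is missing from (these are unclassifiable
    and excluded from candidacy).
    """
    per_tool: Dict[str, Dict[str, str]] = {}
    for tool, path in paths.items():
        df = pd.read_csv(path, sep="\t", dtype=str)
        if "transcript_id" not in df.columns or "verdict" not in df.columns:
            raise ValidationError(f"{path}: expected columns transcript_id, verdict")
        calls = {}
        for _, row in df.iterrows():
            verdict = str(row["verdict"]).strip().lower()
            if verdict not in ("coding", "noncoding"):
                raise ValidationError(
                    f"{path}: transcript {row['transcript_id']}: "
                    f"verdict {row['verdict']!r} not in {{coding, noncoding}}"
                )
            calls[str(row["transcript_id"])] = verdict
        per_tool[tool] = calls

    all_ids = sorted(set().union(*(set(c) for c in per_tool.values())))
    callsets: List[CodingCallSet] = []
    missing: Dict[str, List[str]] = {}
    for tid in all_ids:
        absent = [tool for tool, calls in per_tool.items() if tid not in calls]
        if absent:
            missing[tid] = absent
        else:
            callsets.append(
                CodingCallSet(tid, {t: per_tool[t][tid] for t in per_tool})
            )
    if missing:
        logger.warning(
            "%d transcripts missing from at least one coding-call file; "
            "treated as unclassifiable", len(missing)
        )
    return callsets, missing


def write_coding_calls(calls: Mapping[str, str], path) -> None:
    """Write one tool's verdict table (transcript_id -> verdict)."""
    pd.DataFrame(
        {"transcript_id": list(calls), "verdict": list(calls.values())}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Term annotation maps
# ---------------------------------------------------------------------------

def read_term_map(path) -> Dict[str, Tuple[str, frozenset]]:
    """Read a TSV of (term_id, term_name, gene_id) rows into term -> gene sets."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("term_id", "term_name", "gene_id"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    names: Dict[str, str] = {}
    genes: Dict[str, set] = defaultdict(set)
    for _, row in df.iterrows():
        names[row["term_id"]] = row["term_name"]
        genes[row["term_id"]].add(row["gene_id"])
    return {t: (names[t], frozenset(genes[t])) for t in sorted(genes)}


def write_term_map(term_map: Mapping[str, Tuple[str, Iterable[str]]], path) -> None:
    rows = []
    for term_id, (name, gene_set) in term_map.items():
        for gid in sorted(gene_set):
            rows.append((term_id, name, gid))
    pd.DataFrame(rows, columns=["term_id", "term_name", "gene_id"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Library QC summaries
# ---------------------------------------------------------------------------

def read_library_metrics(path) -> List[LibraryMetrics]:
    """Read a Table-1-style TSV: first column ``metric``, one column per sample."""
    df = pd.read_csv(path, sep="\t", index_col="metric")
    return [
        LibraryMetrics(sample_id=str(col), metrics=df[col].to_dict())
        for col in df.columns
    ]


def summarize_libraries(metrics: Sequence[LibraryMetrics]) -> Dict[str, float]:
    """Arithmetic mean of each QC metric across samples.

    Metrics whose values are all integral are rounded to the nearest
    integer (read and base counts); the rest (percentages) are rounded to
    two decimals.
    """
    if not metrics:
        raise ValidationError("at least one sample required")
    keys = list(metrics[0].metrics)
    for m in metrics[1:]:
        if set(m.metrics) != set(keys):
            raise ValidationError(
                f"sample {m.sample_id}: metric keys differ from {metrics[0].sample_id}"
            )
    out: Dict[str, float] = {}
    for key in keys:
        values = [float(m.metrics[key]) for m in metrics]
        mean = sum(values) / len(values)
        if all(v.is_integer() for v in values):
            out[key] = int(round(mean))
        else:
            out[key] = round(mean, 2)
    return out
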