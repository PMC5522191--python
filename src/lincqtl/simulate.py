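"""Seed-driven generator of every input the pipeline consumes, with
planted ground truth.

The generator emulates the data shapes of a two-breed, no-replicate pig
RNA-seq contrast: an annotation of protein-coding genes, assembled
transcripts containing both mRNAs and lncRNAs planted in the four
positional categories, a two-sample expression table with planted
log2-fold-change effects on the Luchuan column, four noisy
coding-potential verdict tables, trait-linked QTL intervals, and a flat
term-annotation map.

Layout guarantees: genes never overlap each other; each planted lncRNA is
placed so that the classification definitions recover its category
exactly (antisense/sense overlap the host gene's exons on the
opposite/same strand, intronic transcripts sit wholly inside intron 1,
lincRNAs sit in intergenic gaps).  Expression is drawn log-normally and
rescaled so that expected fragment totals equal the library size (the
FPKM normalization identity for a closed transcriptome); fragment counts
are Poisson (optionally negative-binomial to stress the calibration of
the replicate-free test).  All randomness flows from one
``numpy.random.Generator`` seeded from ``SimConfig.seed``, so equal seeds
give byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import io as lio
from .models import (
    DEFAULT_TOOLS,
    ExpressionTable,
    GeneModel,
    QtlRegion,
    TranscriptModel,
    ValidationError,
)

_READ_BASES = 300  # paired-end 2 x 150 bp per fragment, for coverage

_DEFAULT_TRAITS = (
    "Average backfat thickness",
    "Abdominal fat weight",
    "Adipocyte diameter",
    "Arachidonic acid content",
    "Abdominal fat percentage",
    "Loin fat percentage",
)

_TERM_NAMES = (
    "lipid metabolic process", "fatty acid biosynthesis", "adipocytokine signaling",
    "calcium signaling", "PI3K-Akt signaling", "insulin signaling",
    "electron carrier activity", "antioxidant activity", "MAPK cascade",
    "FOXO signaling", "triglyceride storage", "fatty acid elongation",
    "glucose homeostasis", "adipocyte differentiation", "cholesterol transport",
    "oxidative phosphorylation", "AMPK signaling", "lipolysis regulation",
    "membrane lipid remodeling", "peroxisomal beta-oxidation",
)


@dataclass(frozen=True)
class SimConfig:
    """Study-shaped simulation conditions.

    ``lncrna_per_category`` defaults to the observed category mix scaled
    to 100 transcripts; ``coding_tool_error_rates`` maps each tool to
    (false-coding, false-noncoding) flip probabilities.
    """

    seed: int = 0
    n_chromosomes: int = 3
    chrom_length: int = 30_000_000
    n_genes: int = 120
    lncrna_per_category: Mapping[str, int] = field(
        default_factory=lambda: {
            "lincRNA": 49, "antisense": 5, "intronic": 5, "sense": 41
        }
    )
    de_fraction: float = 0.1
    planted_log2fc: float = 2.0
    fpkm_lognormal: Tuple[float, float] = (2.0, 1.2)
    library_size: int = 20_000_000
    coding_tool_error_rates: Mapping[str, Tuple[float, float]] = field(
        default_factory=lambda: {t: (0.05, 0.05) for t in DEFAULT_TOOLS}
    )
    n_qtl: int = 24
    qtl_span: Tuple[int, int] = (50_000, 5_000_000)
    traits: Tuple[str, ...] = _DEFAULT_TRAITS
    samples: Tuple[Tuple[str, str], ...] = (
        ("L-fat", "Luchuan"), ("D-fat", "Duroc")
    )
    fragment_dist: str = "poisson"
    nb_dispersion: float = 10.0

    def __post_init__(self) -> None:
        if not 0 <= self.de_fraction <= 1:
            raise ValidationError("de_fraction must be in [0,1]")
        for tool, (fc, fn) in self.coding_tool_error_rates.items():
            if not (0 <= fc <= 1 and 0 <= fn <= 1):
                raise ValidationError(f"tool {tool}: error rates must be in [0,1]")
        if self.qtl_span[0] <= 0 or self.qtl_span[0] > self.qtl_span[1]:
            raise ValidationError("qtl_span must be a positive (lo, hi) range")
        if self.fragment_dist not in ("poisson", "negative_binomial"):
            raise ValidationError("fragment_dist must be poisson or negative_binomial")


@dataclass
class SimTruth:
    """Planted labels backing recovery tests."""

    categories: Dict[str, str]          # lncRNA transcript -> category
    coding: Dict[str, str]              # transcript -> coding/noncoding
    de_status: Dict[str, str]           # feature (lnc tx or gene) -> up/down/ns
    true_log2fc: Dict[str, float]       # feature -> planted effect
    qtl_members: Dict[int, Tuple[str, ...]]  # qtl_id -> DE feature ids inside


@dataclass
class SimDataset:
    """Paths and in-memory objects of one generated dataset."""

    out_dir: Path
    paths: Dict[str, object]
    truth: SimTruth
    transcripts: List[TranscriptModel]
    genes: List[GeneModel]
    expression: ExpressionTable
    qtls: List[QtlRegion]


def sample_lengths(n: int, rng: np.random.Generator) -> np.ndarray:
    """Spliced lengths mimicking the observed mix: mostly 600-1200 bp,
    a middle band, and a >= 3000 bp tail."""
    bands = rng.choice(3, size=n, p=[0.55, 0.30, 0.15])
    lo = np.array([600, 1200, 3000])[bands]
    hi = np.array([1200, 3000, 4500])[bands]
    return rng.integers(lo, hi + 1)


def simulate_expression(
    feature_ids: Sequence[str],
    lengths: np.ndarray,
    rng: np.random.Generator,
    de_fraction: float = 0.1,
    planted_log2fc: float = 2.0,
    library_size: int = 20_000_000,
    fpkm_lognormal: Tuple[float, float] = (2.0, 1.2),
    samples: Sequence[Tuple[str, str]] = (("L-fat", "Luchuan"), ("D-fat", "Duroc")),
    fragment_dist: str = "poisson",
    nb_dispersion: float = 10.0,
) -> Tuple[ExpressionTable, pd.DataFrame]:
    """Draw a two-group expression table with planted fold changes.

    Baseline FPKMs are log-normal, rescaled so that sum(fpkm * length)
    equals 1e9 — i.e. expected fragments total the library size.  A
    ``de_fraction`` of features receives log2 fold change
    ``+-planted_log2fc`` applied to the Luchuan (numerator) group.

    Returns the :class:`ExpressionTable` (FPKM recomputed from the
    sampled counts) and a truth frame with columns ``true_log2fc`` and
    ``status``.
    """
    n = len(feature_ids)
    lengths = np.asarray(lengths, dtype=float)
    mu, sigma = fpkm_lognormal
    rel = rng.lognormal(mu, sigma, size=n)
    base_fpkm = rel * 1e9 / float(np.sum(rel * lengths))

    lfc = np.zeros(n)
    n_de = int(round(de_fraction * n))
    if n_de:
        de_idx = rng.choice(n, size=n_de, replace=False)
        signs = rng.choice([1.0, -1.0], size=n_de)
        lfc[de_idx] = signs * planted_log2fc

    frag_cols: Dict[str, np.ndarray] = {}
    fpkm_cols: Dict[str, np.ndarray] = {}
    for sample_id, group in samples:
        fpkm_true = base_fpkm * np.where(group == "Luchuan", 2.0 ** lfc, 1.0)
        lam = fpkm_true * lengths * library_size / 1e9
        if fragment_dist == "poisson":
            counts = rng.poisson(lam)
        else:
            size = nb_dispersion
            counts = rng.negative_binomial(size, size / (size + lam))
        frag_cols[sample_id] = counts
        fpkm_cols[sample_id] = counts * 1e9 / (lengths * library_size)

    index = pd.Index(feature_ids, name="feature_id")
    lib = pd.Series(
        {s: float(library_size) for s, _ in samples},
        index=[s for s, _ in samples],
    )
    table = ExpressionTable(
        fpkm=pd.DataFrame(fpkm_cols, index=index),
        fragments=pd.DataFrame(frag_cols, index=index),
        lengths=pd.Series(lengths, index=index),
        library_sizes=lib,
    )
    status = np.where(lfc > 0, "up", np.where(lfc < 0, "down", "ns"))
    truth = pd.DataFrame({"true_log2fc": lfc, "status": status}, index=index)
    return table, truth


# ---------------------------------------------------------------------------
# Genome layout
# ---------------------------------------------------------------------------

_EXON_TEMPLATE = ((0, 1500), (3500, 5000), (7500, 9000))
_GENE_SPAN = 9000
_LINC_SLOT_OFFSET = 5000   # lincRNA slot begins this far past the host gene
_LINC_SLOT_WIDTH = 13000   # random offset range inside the slot
_MIN_GAP = 30_000          # minimum intergenic gap (> slot + lincRNA length)


def _place_genes(config: SimConfig, rng: np.random.Generator) -> List[GeneModel]:
    chroms = [str(i + 1) for i in range(config.n_chromosomes)]
    cursors = {c: 100_000 for c in chroms}
    genes = []
    for i in range(config.n_genes):
        chrom = chroms[i % len(chroms)]
        start = cursors[chrom]
        if start + _GENE_SPAN + _MIN_GAP > config.chrom_length:
            raise ValidationError(
                f"infeasible placement: chromosome {chrom} of length "
                f"{config.chrom_length} cannot hold gene {i}"
            )
        exons = tuple((start + s, start + e) for s, e in _EXON_TEMPLATE)
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneModel(
                gene_id=f"ENSSSCG{i:011d}",
                chrom=chrom,
                strand=strand,
                start=exons[0][0],
                end=exons[-1][1],
                exons=exons,
            )
        )
        cursors[chrom] = start + _GENE_SPAN + int(rng.integers(_MIN_GAP, 80_001))
    return genes


def _place_lncrnas(
    config: SimConfig, genes: List[GeneModel], rng: np.random.Generator
) -> Tuple[List[TranscriptModel], Dict[str, str]]:
    lncs: List[TranscriptModel] = []
    categories: Dict[str, str] = {}
    counter = 0

    def _add(exons, chrom, strand, category):
        nonlocal counter
        tid = f"TCONS_{counter:08d}"
        counter += 1
        lncs.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=f"XLOC_{counter:06d}",
                chrom=chrom,
                strand=strand,
                exons=tuple(exons),
            )
        )
        categories[tid] = category

    order = ("lincRNA", "antisense", "intronic", "sense")
    for category in order:
        for _ in range(int(config.lncrna_per_category.get(category, 0))):
            host = genes[int(rng.integers(len(genes)))]
            g0 = host.start
            j = int(rng.integers(0, 200))  # jitter; placements stay in-category
            if category == "lincRNA":
                s = host.end + _LINC_SLOT_OFFSET + int(
                    rng.integers(_LINC_SLOT_WIDTH - 2000)
                )
                exons = [(s, s + 500), (s + 900, s + 1400)]
                strand = "+" if rng.random() < 0.5 else "-"
            elif category == "antisense":
                exons = [(g0 + 300 + j, g0 + 900 + j), (g0 + 3800 + j, g0 + 4300 + j)]
                strand = "-" if host.strand == "+" else "+"
            elif category == "intronic":
                i0 = g0 + 1500  # intron 1 spans [g0+1500, g0+3500)
                exons = [(i0 + 200 + j, i0 + 600 + j), (i0 + 1000 + j, i0 + 1500 + j)]
                strand = "+" if rng.random() < 0.5 else "-"
            else:  # sense
                exons = [(g0 + 3900 + j, g0 + 4500 + j), (g0 + 7700 + j, g0 + 8200 + j)]
                strand = host.strand
            _add(exons, host.chrom, strand, category)
    return lncs, categories


def _draw_qtls(config: SimConfig, rng: np.random.Generator) -> List[QtlRegion]:
    chroms = [str(i + 1) for i in range(config.n_chromosomes)]
    qtl_ids = sorted(
        int(q) for q in rng.choice(np.arange(100, 99_999), config.n_qtl, replace=False)
    )
    qtls = []
    for i, qtl_id in enumerate(qtl_ids):
        span = int(rng.integers(config.qtl_span[0], config.qtl_span[1] + 1))
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(1, config.chrom_length - span))
        trait = config.traits[i % len(config.traits)]
        symbol = "".join(w[0] for w in trait.split()).upper()
        qtls.append(
            QtlRegion(
                qtl_id=qtl_id, chrom=chrom, trait=trait, symbol=symbol,
                start=start, end=start + span,
            )
        )
    return qtls


def generate_dataset(config: SimConfig, out_dir) -> SimDataset:
    """Generate all pipeline input files plus the planted truth.

    Writes ``annotation.gtf``, ``transcripts.gtf``, ``expression.tsv``,
    ``samples.tsv``, ``coding_calls/<tool>.tsv``, ``qtl.tsv``,
    ``term_map.tsv`` and two truth tables under ``out_dir``.
    """
    rng = np.random.default_rng(config.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "coding_calls").mkdir(exist_ok=True)

    genes = _place_genes(config, rng)
    mrnas = [
        TranscriptModel(
            transcript_id=f"ENSSSCT{i:011d}",
            gene_id=g.gene_id,
            chrom=g.chrom,
            strand=g.strand,
            exons=g.exons,
        )
        for i, g in enumerate(genes)
    ]
    lncs, categories = _place_lncrnas(config, genes, rng)
    transcripts = mrnas + lncs

    feature_ids = [t.transcript_id for t in transcripts]
    lengths = np.array([t.spliced_length for t in transcripts], dtype=float)
    expr, expr_truth = simulate_expression(
        feature_ids,
        lengths,
        rng,
        de_fraction=config.de_fraction,
        planted_log2fc=config.planted_log2fc,
        library_size=config.library_size,
        fpkm_lognormal=config.fpkm_lognormal,
        samples=config.samples,
        fragment_dist=config.fragment_dist,
        nb_dispersion=config.nb_dispersion,
    )
    expr.gene_ids = pd.Series(
        {t.transcript_id: (t.gene_id or t.transcript_id) for t in transcripts},
        index=expr.fpkm.index,
    )

    # assembler-style coverage: read bases of the deepest sample per base
    max_frags = expr.fragments.max(axis=1).to_numpy(dtype=float)
    coverage = np.round(max_frags * _READ_BASES / lengths, 2)
    transcripts = [
        TranscriptModel(
            t.transcript_id, t.gene_id, t.chrom, t.strand, t.exons,
            float(cov),
        )
        for t, cov in zip(transcripts, coverage)
    ]

    # planted DE labels: transcript-level for lncRNAs, gene-level for mRNAs
    # (each gene carries a single transcript, so the labels coincide)
    de_status: Dict[str, str] = {}
    true_lfc: Dict[str, float] = {}
    for tx in transcripts:
        fid = tx.transcript_id
        status = str(expr_truth.loc[fid, "status"])
        lfc = float(expr_truth.loc[fid, "true_log2fc"])
        if fid.startswith("TCONS_"):
            de_status[fid] = status
            true_lfc[fid] = lfc
        else:
            de_status[tx.gene_id] = status
            true_lfc[tx.gene_id] = lfc

    # coding-potential verdicts with per-tool flip noise
    coding_truth = {
        t.transcript_id: (
            "noncoding" if t.transcript_id.startswith("TCONS_") else "coding"
        )
        for t in transcripts
    }
    call_paths: Dict[str, Path] = {}
    for tool, (false_coding, false_noncoding) in config.coding_tool_error_rates.items():
        calls = {}
        for tid, truth_label in coding_truth.items():
            u = rng.random()
            if truth_label == "noncoding":
                calls[tid] = "coding" if u < false_coding else "noncoding"
            else:
                calls[tid] = "noncoding" if u < false_noncoding else "coding"
        path = out_dir / "coding_calls" / f"{tool}.tsv"
        lio.write_coding_calls(calls, path)
        call_paths[tool] = path

    qtls = _draw_qtls(config, rng)
    # planted QTL membership: DE features whose body overlaps the interval
    feature_spans: Dict[str, Tuple[str, int, int]] = {}
    for tx, g in zip(mrnas, genes):
        feature_spans[g.gene_id] = (g.chrom, g.start, g.end)
    for tx in lncs:
        feature_spans[tx.transcript_id] = (tx.chrom, tx.start, tx.end)
    qtl_members: Dict[int, Tuple[str, ...]] = {}
    for q in qtls:
        members = [
            fid
            for fid, (chrom, s, e) in feature_spans.items()
            if chrom == q.chrom and s < q.end0 and e > q.start0
            and de_status.get(fid) != "ns"
        ]
        qtl_members[q.qtl_id] = tuple(sorted(members))

    # flat term annotations over the gene universe
    n_terms = len(_TERM_NAMES)
    term_map: Dict[str, Tuple[str, set]] = {
        f"T{i:03d}": (_TERM_NAMES[i], set()) for i in range(n_terms)
    }
    for g in genes:
        k = int(rng.integers(1, 4))
        for ti in rng.choice(n_terms, size=k, replace=False):
            term_map[f"T{int(ti):03d}"][1].add(g.gene_id)

    # --- write files -------------------------------------------------------
    paths: Dict[str, object] = {"coding_calls": call_paths}
    paths["annotation_gtf"] = out_dir / "annotation.gtf"
    lio.write_gtf(paths["annotation_gtf"], mrnas)
    paths["transcripts_gtf"] = out_dir / "transcripts.gtf"
    lio.write_gtf(paths["transcripts_gtf"], transcripts)
    paths["expression"] = out_dir / "expression.tsv"
    lio.write_expression(expr, paths["expression"])
    paths["samples"] = out_dir / "samples.tsv"
    lio.write_samples(
        pd.DataFrame(
            {
                "sample_id": [s for s, _ in config.samples],
                "group": [g for _, g in config.samples],
                "library_size": [config.library_size] * len(config.samples),
            }
        ),
        paths["samples"],
    )
    paths["qtl_table"] = out_dir / "qtl.tsv"
    lio.write_qtl_table(qtls, paths["qtl_table"])
    paths["term_map"] = out_dir / "term_map.tsv"
    lio.write_term_map(
        {t: (name, genes_) for t, (name, genes_) in term_map.items() if genes_},
        paths["term_map"],
    )

    truth = SimTruth(
        categories=categories,
        coding=coding_truth,
        de_status=de_status,
        true_log2fc=true_lfc,
        qtl_members=qtl_members,
    )
    paths["truth_features"] = out_dir / "truth_features.tsv"
    rows = []
    for fid in sorted(set(de_status)):
        rows.append(
            {
                "feature_id": fid,
                "kind": "lncRNA" if fid.startswith("TCONS_") else "gene",
                "category": categories.get(fid, ""),
                "status": de_status[fid],
                "true_log2fc": true_lfc[fid],
            }
        )
    pd.DataFrame(rows).to_csv(paths["truth_features"], sep="\t", index=False)
    paths["truth_qtl"] = out_dir / "truth_qtl.tsv"
    pd.DataFrame(
        {
            "qtl_id": list(qtl_members),
            "members": [",".join(m) for m in qtl_members.values()],
        }
    ).to_csv(paths["truth_qtl"], sep="\t", index=False)

    return SimDataset(
        out_dir=out_dir,
        paths=paths,
        truth=truth,
        transcripts=transcripts,
        genes=genes,
        expression=expr,
        qtls=qtls,
    )
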