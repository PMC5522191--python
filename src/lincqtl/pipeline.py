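"""End-to-end orchestration: identify -> de -> targets -> qtl -> enrich.

Every stage reads and writes plain TSV with documented headers so that
reruns on identical inputs are byte-identical and diffable.  A parameter
manifest (YAML) records every threshold actually used.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Mapping, Optional

import pandas as pd
import yaml

from . import io as lio
from .diffexpr import DEParams, differential_expression
from .enrich import hypergeom_enrich
from .identify import (
    FilterParams,
    classify_all,
    filter_candidates,
    intersect_coding_calls,
    summarize_categories,
)
from .models import FeatureInterval, LincqtlError, ValidationError
from .qtl import colocated_pairs, map_to_qtl, rank_qtl, score_all, tally_by_trait
from .targets import assign_cis_targets, pair_de_tables

logger = logging.getLogger("lincqtl")


@dataclass
class PipelineConfig:
    """Paths and parameters for a full run."""

    transcripts_gtf: Path
    annotation_gtf: Path
    expression: Path
    samples: Path
    coding_calls: Dict[str, Path]
    qtl_table: Path
    term_map: Path
    output_dir: Path
    filter_params: FilterParams = field(default_factory=FilterParams)
    de_params: DEParams = field(default_factory=DEParams)
    window: int = 100_000
    containment: bool = False
    top_n: int = 20
    numerator: str = "Luchuan"
    denominator: str = "Duroc"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        inputs = raw.get("inputs", {})
        params = raw.get("params", {})
        de_raw = dict(params.get("de", {}))
        preset = de_raw.pop("preset", None)
        de_params = DEParams.from_preset(preset) if preset else DEParams()
        if de_raw:
            from dataclasses import replace

            de_params = replace(de_params, **de_raw)
        return cls(
            transcripts_gtf=Path(inputs["transcripts_gtf"]),
            annotation_gtf=Path(inputs["annotation_gtf"]),
            expression=Path(inputs["expression"]),
            samples=Path(inputs["samples"]),
            coding_calls={k: Path(v) for k, v in inputs["coding_calls"].items()},
            qtl_table=Path(inputs["qtl_table"]),
            term_map=Path(inputs["term_map"]),
            output_dir=Path(raw["output_dir"]),
            filter_params=FilterParams(**params.get("filter", {})),
            de_params=de_params,
            window=int(params.get("window", 100_000)),
            containment=bool(params.get("containment", False)),
            top_n=int(params.get("top_n", 20)),
            numerator=params.get("numerator", "Luchuan"),
            denominator=params.get("denominator", "Duroc"),
        )

    def check_inputs(self) -> None:
        paths = [
            self.transcripts_gtf, self.annotation_gtf, self.expression,
            self.samples, self.qtl_table, self.term_map,
            *self.coding_calls.values(),
        ]
        for p in paths:
            if not Path(p).exists():
                raise LincqtlError(f"input file does not exist: {p}")


def run_all(config: PipelineConfig) -> Dict[str, object]:
    """Run every stage; returns the main result tables keyed by name."""
    config.check_inputs()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- load --------------------------------------------------------------
    transcripts, _ = lio.read_gtf(config.transcripts_gtf)
    _, genes = lio.read_gtf(config.annotation_gtf)
    expr, sample_sheet = lio.read_expression(config.expression, config.samples)
    groups = dict(zip(sample_sheet["sample_id"], sample_sheet["group"]))
    callsets, missing = lio.read_coding_calls(config.coding_calls)
    qtls = lio.read_qtl_table(config.qtl_table)
    term_map = lio.read_term_map(config.term_map)

    # --- identify ----------------------------------------------------------
    retained, tally = filter_candidates(transcripts, expr, config.filter_params)
    logger.info("filter cascade retained %d/%d transcripts (%s)",
                len(retained), len(transcripts), tally)
    candidate_ids, venn = intersect_coding_calls(callsets)
    candidate_set = set(candidate_ids)
    candidates = [t for t in retained if t.transcript_id in candidate_set]
    records = classify_all(candidates, genes)
    summary = summarize_categories(records) if records else None

    rec_df = pd.DataFrame(
        {
            "transcript_id": [r.transcript.transcript_id for r in records],
            "chrom": [r.transcript.chrom for r in records],
            "strand": [r.transcript.strand for r in records],
            "start": [r.transcript.start for r in records],
            "end": [r.transcript.end for r in records],
            "spliced_length": [r.transcript.spliced_length for r in records],
            "category": [r.category for r in records],
            "nearest_gene_id": [r.nearest_gene_id or "" for r in records],
        }
    )
    rec_df.to_csv(out / "lncrna_records.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "noncoding_tools": ["+".join(cell) if cell else "(none)" for cell in sorted(venn)],
            "count": [venn[cell] for cell in sorted(venn)],
        }
    ).to_csv(out / "venn_counts.tsv", sep="\t", index=False)
    if summary is not None:
        pd.DataFrame(
            {
                "category": list(summary.counts),
                "count": list(summary.counts.values()),
                "percent": [summary.percentages[c] for c in summary.counts],
            }
        ).to_csv(out / "category_summary.tsv", sep="\t", index=False)

    # --- differential expression ------------------------------------------
    lnc_ids = [r.transcript.transcript_id for r in records]
    lnc_expr_ids = [f for f in expr.features if f in set(lnc_ids)]
    mrna_ids = [f for f in expr.features if f not in set(lnc_ids)]

    def _subset(ids):
        from .models import ExpressionTable

        return ExpressionTable(
            fpkm=expr.fpkm.loc[ids],
            fragments=expr.fragments.loc[ids],
            lengths=expr.lengths.loc[ids],
            library_sizes=expr.library_sizes,
            gene_ids=expr.gene_ids.loc[ids] if expr.gene_ids is not None else None,
        )

    lnc_de = differential_expression(
        _subset(lnc_expr_ids), groups, config.numerator, config.denominator,
        config.de_params,
    )
    gene_annot = {g.gene_id for g in genes}
    tx2gene = {
        f: expr.gene_ids[f]
        for f in mrna_ids
        if expr.gene_ids is not None and expr.gene_ids[f] in gene_annot
    }
    gene_de = differential_expression(
        _subset(sorted(tx2gene)), groups, config.numerator, config.denominator,
        config.de_params, tx2gene=tx2gene,
    )
    lnc_de.to_csv(out / "lnc_de.tsv", sep="\t")
    gene_de.to_csv(out / "gene_de.tsv", sep="\t")

    # --- cis targets -------------------------------------------------------
    pairs = assign_cis_targets(records, genes, window=config.window)
    pair_table = pair_de_tables(pairs, lnc_de, gene_de)
    pair_table.to_csv(out / "target_pairs.tsv", sep="\t", index=False)

    # --- QTL colocalization -------------------------------------------------
    by_id = {r.transcript.transcript_id: r.transcript for r in records}
    de_lnc = [
        FeatureInterval(f, by_id[f].chrom, by_id[f].start, by_id[f].end)
        for f in lnc_de.index[lnc_de["status"] != "ns"]
        if f in by_id
    ]
    gene_by_id = {g.gene_id: g for g in genes}
    de_genes = [
        FeatureInterval(g, gene_by_id[g].chrom, gene_by_id[g].start, gene_by_id[g].end)
        for g in gene_de.index[gene_de["status"] != "ns"]
        if g in gene_by_id
    ]
    mem_lnc = map_to_qtl(de_lnc, qtls, containment=config.containment)
    mem_gene = map_to_qtl(de_genes, qtls, containment=config.containment)
    tallies = tally_by_trait(
        mem_lnc, mem_gene, qtls,
        lnc_de["status"].to_dict(), gene_de["status"].to_dict(),
    )
    pd.DataFrame([asdict(t) for t in tallies]).to_csv(
        out / "trait_tally.tsv", sep="\t", index=False
    )
    ranked = rank_qtl(score_all(qtls, mem_lnc), config.top_n)
    score_df = pd.DataFrame([asdict(r) for r in ranked])
    if not score_df.empty:
        score_df["score"] = [r.score_str for r in ranked]
    score_df.to_csv(out / "qtl_scores.tsv", sep="\t", index=False)
    pairs_qtl = colocated_pairs(mem_lnc, mem_gene)
    pd.DataFrame(
        {
            "qtl_id": [p.qtl_id for p in pairs_qtl],
            "lncrna_ids": [",".join(p.lncrna_ids) for p in pairs_qtl],
            "gene_ids": [",".join(p.gene_ids) for p in pairs_qtl],
        }
    ).to_csv(out / "colocated_pairs.tsv", sep="\t", index=False)

    # --- enrichment ---------------------------------------------------------
    annotated = set()
    for _, gene_set in term_map.values():
        annotated |= gene_set
    target_genes = sorted(
        {p.gene_id for p in pairs if p.lncrna_id in set(lnc_de.index[lnc_de["status"] != "ns"])}
        & annotated
    )
    enrichment = hypergeom_enrich(target_genes, term_map)
    pd.DataFrame([asdict(r) for r in enrichment]).to_csv(
        out / "enrichment.tsv", sep="\t", index=False
    )

    # --- manifest -----------------------------------------------------------
    manifest = {
        "filter": asdict(config.filter_params),
        "de": asdict(config.de_params),
        "window": config.window,
        "containment": config.containment,
        "top_n": config.top_n,
        "numerator": config.numerator,
        "denominator": config.denominator,
        "n_transcripts": len(transcripts),
        "n_retained": len(retained),
        "n_candidates": len(candidates),
        "n_missing_coding_calls": len(missing),
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)

    return {
        "records": records,
        "summary": summary,
        "venn": venn,
        "lnc_de": lnc_de,
        "gene_de": gene_de,
        "target_pairs": pair_table,
        "tallies": tallies,
        "qtl_scores": ranked,
        "colocated": pairs_qtl,
        "enrichment": enrichment,
        "missing_coding_calls": missing,
        "filter_tally": tally,
    }
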