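"""Filter cascade, four-way intersection, and positional classification."""

import itertools

import numpy as np
import pandas as pd
import pytest

from lincqtl.identify import (
    FilterParams,
    classify_all,
    classify_lncrna,
    filter_candidates,
    intersect_coding_calls,
    summarize_categories,
)
from lincqtl.models import (
    CodingCallSet,
    ExpressionTable,
    GeneModel,
    TranscriptModel,
    ValidationError,
)

TOOLS = ("CPC", "CNCI", "CPAT", "Pfam")


def make_tx(tid, exons, chrom="1", strand="+", cov=10.0, gene_id=None):
    return TranscriptModel(tid, gene_id, chrom, strand, tuple(exons), cov)


def make_expr(fpkm_by_id):
    ids = list(fpkm_by_id)
    fpkm = pd.DataFrame({"L": list(fpkm_by_id.values()),
                         "D": list(fpkm_by_id.values())}, index=ids)
    frags = (fpkm * 10).astype(int)
    return ExpressionTable(
        fpkm=fpkm,
        fragments=frags,
        lengths=pd.Series(1000, index=ids),
        library_sizes=pd.Series({"L": 1e6, "D": 1e6}),
    )


class TestFilterCandidates:
    def test_each_rule_fails_once_two_pass(self):
        # cascade order: length, exons, coverage, fpkm
        txs = [
            make_tx("short", [(0, 100), (200, 250)]),              # 150 bp
            make_tx("monoexonic", [(0, 500)]),
            make_tx("shallow", [(0, 300), (400, 700)], cov=1.0),
            make_tx("silent", [(0, 300), (400, 700)]),
            make_tx("ok1", [(0, 300), (400, 700)]),
            make_tx("ok2", [(0, 600), (800, 1400)]),
        ]
        fpkm = {t.transcript_id: 5.0 for t in txs}
        fpkm["silent"] = 0.05
        retained, tally = filter_candidates(txs, make_expr(fpkm), FilterParams())
        assert [t.transcript_id for t in retained] == ["ok1", "ok2"]
        assert tally == {"length": 1, "exons": 1, "coverage": 1, "fpkm": 1}

    def test_length_filter_is_strict(self):
        tx = make_tx("edge", [(0, 100), (150, 250)])  # exactly 200 bp
        retained, tally = filter_candidates([tx], make_expr({"edge": 1.0}))
        assert retained == [] and tally["length"] == 1

    def test_missing_expression_rows_listed(self):
        tx = make_tx("t1", [(0, 300), (400, 700)])
        with pytest.raises(ValidationError, match="t1"):
            filter_candidates([tx], make_expr({"other": 1.0}))

    def test_relaxing_thresholds_never_shrinks_retained_set(self, rng):
        txs = []
        fpkm = {}
        for i in range(200):
            n_ex = int(rng.integers(1, 4))
            exons, pos = [], 0
            for _ in range(n_ex):
                length = int(rng.integers(50, 400))
                exons.append((pos, pos + length))
                pos += length + int(rng.integers(50, 200))
            txs.append(make_tx(f"t{i}", exons, cov=float(rng.uniform(0, 6))))
            fpkm[f"t{i}"] = float(rng.uniform(0, 0.3))
        expr = make_expr(fpkm)
        strict, _ = filter_candidates(txs, expr, FilterParams())
        for relaxed in (
            FilterParams(min_length=100),
            FilterParams(min_exons=1),
            FilterParams(min_coverage=1.0),
            FilterParams(min_fpkm=0.01),
        ):
            loose, _ = filter_candidates(txs, expr, relaxed)
            assert {t.transcript_id for t in strict} <= {t.transcript_id for t in loose}


class TestIntersectCodingCalls:
    def _cs(self, tid, noncoding_tools):
        return CodingCallSet(
            tid, {t: ("noncoding" if t in noncoding_tools else "coding") for t in TOOLS}
        )

    def test_unanimous_noncoding_is_candidate(self):
        ids, _ = intersect_coding_calls([self._cs("t1", TOOLS)])
        assert ids == ["t1"]

    def test_three_of_four_dropped_into_three_way_cell(self):
        ids, venn = intersect_coding_calls([self._cs("t2", ("CPC", "CNCI", "CPAT"))])
        assert ids == []
        assert venn[("CNCI", "CPAT", "CPC")] == 1

    def test_venn_cells_match_set_arithmetic(self, rng):
        calls = []
        per_tool = {t: set() for t in TOOLS}
        for i in range(500):
            noncoding = tuple(t for t in TOOLS if rng.random() < 0.8)
            calls.append(self._cs(f"t{i}", noncoding))
            for t in noncoding:
                per_tool[t].add(f"t{i}")
        ids, venn = intersect_coding_calls(calls)
        universe = {c.transcript_id for c in calls}
        assert set(ids) == set.intersection(*per_tool.values())
        for cell in (c for n in range(5) for c in itertools.combinations(sorted(TOOLS), n)):
            inside = set(universe)
            for t in TOOLS:
                inside &= per_tool[t] if t in cell else (universe - per_tool[t])
            assert venn.get(cell, 0) == len(inside)


def make_gene(gid, exons, strand="+", chrom="1"):
    exons = tuple(exons)
    return GeneModel(gid, chrom, strand, exons[0][0], exons[-1][1], exons)


GENE = make_gene("g1", [(1000, 1500), (2500, 3000), (4000, 4500)], strand="+")


class TestClassifyLncrna:
    def test_opposite_strand_exonic_overlap_is_antisense(self):
        tx = make_tx("a", [(1200, 1400), (2600, 2800)], strand="-")
        rec = classify_lncrna(tx, [GENE])
        assert (rec.category, rec.nearest_gene_id) == ("antisense", "g1")

    def test_same_strand_exonic_overlap_is_sense(self):
        tx = make_tx("s", [(1200, 1400), (2600, 2800)], strand="+")
        assert classify_lncrna(tx, [GENE]).category == "sense"

    def test_contained_in_single_intron_is_intronic(self):
        # intron 2 of the gene spans [3000, 4000)
        tx = make_tx("i", [(3100, 3300), (3500, 3800)], strand="+")
        assert classify_lncrna(tx, [GENE]).category == "intronic"

    def test_spanning_two_introns_touches_an_exon(self):
        tx = make_tx("x", [(1600, 3200)], strand="+")
        assert classify_lncrna(tx, [GENE]).category == "sense"

    def test_no_gene_overlap_is_lincRNA_with_nearest_gene(self):
        tx = make_tx("l", [(8000, 8400), (8800, 9200)])
        rec = classify_lncrna(tx, [GENE])
        assert (rec.category, rec.nearest_gene_id) == ("lincRNA", "g1")

    def test_empty_chromosome_is_lincRNA_without_nearest(self):
        tx = make_tx("l", [(10, 300), (400, 600)], chrom="99")
        rec = classify_lncrna(tx, [GENE])
        assert (rec.category, rec.nearest_gene_id) == ("lincRNA", None)

    def test_categories_partition_candidates(self, rng):
        genes, txs = _random_layout(rng, n_genes=30, n_tx=200)
        records = classify_all(txs, genes)
        assert len(records) == len(txs)
        assert all(r.category in ("lincRNA", "antisense", "intronic", "sense")
                   for r in records)

    def test_matches_quadratic_oracle(self, rng):
        genes, txs = _random_layout(rng, n_genes=40, n_tx=1000)
        records = classify_all(txs, genes)
        for rec in records:
            assert rec.category == oracle_category(rec.transcript, genes), (
                rec.transcript.transcript_id
            )


def _random_layout(rng, n_genes, n_tx, chroms=("1", "2")):
    genes = []
    for i in range(n_genes):
        start = int(rng.integers(0, 80_000))
        exons, pos = [], start
        for _ in range(int(rng.integers(2, 4))):
            length = int(rng.integers(200, 800))
            exons.append((pos, pos + length))
            pos += length + int(rng.integers(300, 1500))
        genes.append(
            make_gene(
                f"g{i}", exons,
                strand="+" if rng.random() < 0.5 else "-",
                chrom=str(rng.choice(chroms)),
            )
        )
    txs = []
    for i in range(n_tx):
        start = int(rng.integers(0, 90_000))
        exons, pos = [], start
        for _ in range(int(rng.integers(1, 3))):
            length = int(rng.integers(100, 600))
            exons.append((pos, pos + length))
            pos += length + int(rng.integers(100, 800))
        txs.append(
            make_tx(
                f"t{i}", exons,
                strand="+" if rng.random() < 0.5 else "-",
                chrom=str(rng.choice(chroms)),
            )
        )
    return genes, txs


def oracle_category(tx, genes):
    """All-pairs re-derivation of the precedence rules, no interval tree."""

    def exonic(g):
        return any(
            ts < ge and te > gs
            for ts, te in tx.exons
            for gs, ge in g.exons
        )

    same_chrom = [g for g in genes if g.chrom == tx.chrom]
    if any(exonic(g) and g.strand != tx.strand for g in same_chrom):
        return "antisense"
    if any(exonic(g) and g.strand == tx.strand for g in same_chrom):
        return "sense"
    for g in same_chrom:
        for istart, iend in g.introns():
            if istart <= tx.start and tx.end <= iend:
                return "intronic"
    return "lincRNA"


class TestSummarizeCategories:
    def test_reported_category_mix(self):
        counts = {"lincRNA": 2403, "antisense": 252, "intronic": 216, "sense": 1997}
        s = summarize_categories(counts)
        assert s.total == 4868
        assert s.percentages == {
            "lincRNA": 49.36, "antisense": 5.18, "intronic": 4.44, "sense": 41.02
        }

    def test_single_category_is_100_percent(self):
        recs = classify_all([make_tx("l", [(10, 300), (400, 600)], chrom="9")], [GENE])
        s = summarize_categories(recs)
        assert s.percentages["lincRNA"] == 100.0

    def test_random_counts_match_independent_arithmetic(self, rng):
        for _ in range(20):
            counts = {c: int(rng.integers(0, 5000)) for c in
                      ("lincRNA", "antisense", "intronic", "sense")}
            if sum(counts.values()) == 0:
                continue
            s = summarize_categories(counts)
            total = counts["lincRNA"] + counts["antisense"] + counts["intronic"] + counts["sense"]
            for c, n in counts.items():
                assert s.percentages[c] == round(n * 100 / total, 2)

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            summarize_categories([])


def test_planted_categories_recovered_exactly(sim_zero_noise):
    """With clean coding calls every planted lncRNA survives the cascade
    and classification recovers 100% of planted category labels."""
    from lincqtl import io as lio

    transcripts, _ = lio.read_gtf(sim_zero_noise.paths["transcripts_gtf"])
    _, genes = lio.read_gtf(sim_zero_noise.paths["annotation_gtf"])
    expr, _ = lio.read_expression(
        sim_zero_noise.paths["expression"], sim_zero_noise.paths["samples"]
    )
    retained, _ = filter_candidates(transcripts, expr)
    callsets, missing = lio.read_coding_calls(sim_zero_noise.paths["coding_calls"])
    assert missing == {}
    candidate_ids, _ = intersect_coding_calls(callsets)
    candidates = [t for t in retained if t.transcript_id in set(candidate_ids)]
    truth = sim_zero_noise.truth.categories
    assert {t.transcript_id for t in candidates} == set(truth)
    for rec in classify_all(candidates, genes):
        assert rec.category == truth[rec.transcript.transcript_id]
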