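"""QTL membership, trait tallies, count/span scoring and ranking."""

import math

import pytest

from lincqtl.models import FeatureInterval, QtlRegion, ValidationError
from lincqtl.qtl import (
    colocated_pairs,
    map_to_qtl,
    rank_qtl,
    score_all,
    score_qtl,
    tally_by_trait,
)


def qtl(qtl_id, start, end, chrom="1", trait="backfat"):
    return QtlRegion(qtl_id, chrom, trait, "BFT", start, end)


def feat(fid, start, end, chrom="1"):
    return FeatureInterval(fid, chrom, start, end)


class TestMapToQtl:
    def test_overlap_of_one_bp_is_membership(self):
        mem = map_to_qtl([feat("f", 150, 200)], [qtl(1, 101, 300)])
        assert mem == {1: {"f"}}

    def test_feature_ending_at_interval_start_is_not_member(self):
        # printed start 101 -> half-open [100, 300); feature [50, 100) abuts
        mem = map_to_qtl([feat("f", 50, 100)], [qtl(1, 101, 300)])
        assert mem == {1: set()}

    def test_containment_mode_requires_whole_body(self):
        features = [feat("in", 120, 200), feat("straddle", 50, 200)]
        regions = [qtl(1, 101, 300)]
        assert map_to_qtl(features, regions)[1] == {"in", "straddle"}
        assert map_to_qtl(features, regions, containment=True)[1] == {"in"}

    def test_matches_all_pairs_overlap_oracle(self, rng):
        features = [
            feat(f"f{i}", s := int(rng.integers(0, 1_000_000)),
                 s + int(rng.integers(100, 5000)),
                 chrom=str(rng.choice(["1", "2"])))
            for i in range(200)
        ]
        regions = [
            qtl(i, s := int(rng.integers(1, 900_000)),
                s + int(rng.integers(1000, 200_000)),
                chrom=str(rng.choice(["1", "2"])))
            for i in range(30)
        ]
        mem = map_to_qtl(features, regions)
        for q in regions:
            expected = {
                f.feature_id
                for f in features
                if f.chrom == q.chrom and f.start < q.end0 and f.end > q.start0
            }
            assert mem[q.qtl_id] == expected


class TestTallyByTrait:
    def test_up_down_split_inside_one_qtl(self):
        regions = [qtl(1, 101, 10_000, trait="backfat")]
        mem_lnc = {1: {"l1", "l2", "l3", "l4", "l5"}}
        status = {"l1": "up", "l2": "up", "l3": "up", "l4": "down", "l5": "down"}
        (t,) = tally_by_trait(mem_lnc, {1: set()}, regions, status, {})
        assert (t.de_lncrna_total, t.de_lncrna_up, t.de_lncrna_down) == (5, 3, 2)

    def test_feature_in_two_qtls_of_one_trait_counted_once(self):
        regions = [qtl(1, 101, 5000, trait="backfat"), qtl(2, 4000, 9000, trait="backfat")]
        mem = {1: {"l1", "l2"}, 2: {"l1", "l3"}}
        status = {"l1": "up", "l2": "down", "l3": "up"}
        (t,) = tally_by_trait(mem, {1: set(), 2: set()}, regions, status, {})
        assert (t.n_qtl_id, t.de_lncrna_total, t.de_lncrna_up) == (2, 3, 2)

    def test_matches_brute_force_recount(self, rng):
        regions = [
            qtl(i, s := int(rng.integers(1, 500_000)), s + 50_000,
                trait=f"trait{int(rng.integers(3))}")
            for i in range(20)
        ]
        features = [
            feat(f"l{i}", s := int(rng.integers(0, 600_000)), s + 2000)
            for i in range(100)
        ]
        status = {f.feature_id: ("up" if rng.random() < 0.5 else "down")
                  for f in features}
        mem = map_to_qtl(features, regions)
        tallies = {t.trait: t for t in tally_by_trait(mem, {}, regions, status, {})}
        for trait in {q.trait for q in regions}:
            ids = set()
            for q in regions:
                if q.trait == trait:
                    ids |= mem[q.qtl_id]
            if not ids:
                assert trait not in tallies
                continue
            t = tallies[trait]
            assert t.de_lncrna_total == len(ids)
            assert t.de_lncrna_up == sum(1 for f in ids if status[f] == "up")
            assert t.de_lncrna_total <= len(features)


class TestScoreQtl:
    def test_printed_score_dense_interval(self):
        row = score_qtl(qtl(31542, 138365048, 138414114), 3)
        assert row.span == 49066
        assert row.score_str == "6.11E-05"

    def test_printed_score_single_lncrna(self):
        assert score_qtl(qtl(658, 11227321, 11306620), 1).score_str == "1.26E-05"

    def test_zero_count_scores_zero(self):
        assert score_qtl(qtl(1, 101, 200), 0).score == 0.0

    def test_score_times_span_recovers_count(self, rng):
        for _ in range(50):
            s = int(rng.integers(1, 10**8))
            row = score_qtl(qtl(1, s, s + int(rng.integers(1, 10**7))),
                            int(rng.integers(0, 20)))
            assert math.isclose(row.score * row.span, row.de_lncrna_count,
                                rel_tol=1e-12, abs_tol=1e-12)


class TestRankQtl:
    def test_printed_table_ordering_reproduced(self, qtl_top20):
        rows = [
            score_qtl(
                QtlRegion(int(r.QTL_ID), str(r.Chrome), r.Trait, r.Name,
                          int(r.Start), int(r.End)),
                int(r.DE_lncRNAs),
            )
            for r in qtl_top20.itertuples()
        ]
        ranked = rank_qtl(rows, top_n=20)
        assert [r.qtl_id for r in ranked] == list(qtl_top20["QTL_ID"])
        assert [r.score_str for r in ranked] == list(qtl_top20["Score"])

    def test_all_equal_scores_order_by_ascending_id(self):
        rows = [score_qtl(qtl(i, 101, 1101), 1) for i in (5, 2, 9, 1)]
        assert [r.qtl_id for r in rank_qtl(rows)] == [1, 2, 5, 9]

    def test_random_rows_match_sort_oracle(self, rng):
        rows = [
            score_qtl(qtl(i, 101, 101 + int(rng.integers(1000, 10**6))),
                      int(rng.integers(0, 5)))
            for i in range(40)
        ]
        ranked = rank_qtl(rows, top_n=10)
        oracle = sorted(rows, key=lambda r: (-r.score, r.qtl_id))[:10]
        assert ranked == oracle


class TestColocatedPairs:
    def test_qtl_with_both_feature_classes(self):
        out = colocated_pairs({21252: {"l1", "l2"}}, {21252: {"ELOVL6"}})
        (p,) = out
        assert (p.qtl_id, p.lncrna_ids, p.gene_ids) == (
            21252, ("l1", "l2"), ("ELOVL6",)
        )

    def test_qtl_without_mrna_is_skipped(self):
        assert colocated_pairs({1: {"l1"}}, {1: set()}) == []

    def test_matches_brute_force_cross_check(self, rng):
        regions = [qtl(i, s := int(rng.integers(1, 500_000)), s + 80_000)
                   for i in range(15)]
        lncs = [feat(f"l{i}", s := int(rng.integers(0, 600_000)), s + 1500)
                for i in range(40)]
        genes = [feat(f"g{i}", s := int(rng.integers(0, 600_000)), s + 8000)
                 for i in range(40)]
        mem_l, mem_g = map_to_qtl(lncs, regions), map_to_qtl(genes, regions)
        pairs = {p.qtl_id: p for p in colocated_pairs(mem_l, mem_g)}
        for q in regions:
            if mem_l[q.qtl_id] and mem_g[q.qtl_id]:
                p = pairs[q.qtl_id]
                assert set(p.lncrna_ids) == mem_l[q.qtl_id]
                assert set(p.gene_ids) == mem_g[q.qtl_id]
            else:
                assert q.qtl_id not in pairs


def test_planted_qtl_membership_equals_truth(sim_planted_de):
    """The generator's planted DE-feature memberships coincide with the
    pipeline's own overlap mapping."""
    ds = sim_planted_de
    de_feats = []
    for t in ds.transcripts:
        fid = t.transcript_id if t.transcript_id.startswith("TCONS_") else t.gene_id
        if ds.truth.de_status.get(fid) != "ns":
            de_feats.append(FeatureInterval(fid, t.chrom, t.start, t.end))
    # gene bodies, not transcript bodies, for the mRNA side
    gene_span = {g.gene_id: g for g in ds.genes}
    de_feats = [
        f if f.feature_id.startswith("TCONS_") else FeatureInterval(
            f.feature_id, gene_span[f.feature_id].chrom,
            gene_span[f.feature_id].start, gene_span[f.feature_id].end)
        for f in de_feats
    ]
    mem = map_to_qtl(de_feats, ds.qtls)
    for q in ds.qtls:
        assert mem[q.qtl_id] == set(ds.truth.qtl_members[q.qtl_id])
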