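"""Homology features: mincov, template search, propensities, SPW."""

import math

import networkx as nx
import numpy as np
import pytest

from hoppi.features import (
    FeatureContext,
    SeqFeature,
    build_network,
    build_propensity_table,
    compute_mincov,
    fdom_score,
    featurize_pair,
    fnet_score,
    fseq_feature,
    has_zero_evalue_template,
    spw,
)
from hoppi.io_model import POSITIVE, NEGATIVE, InteractionPair, SimilarityHit

from _oracles import fseq_oracle, spw_enumeration_oracle


def hit(q, s, ev, pos=50, ql=100, sl=100):
    return SimilarityHit(q, s, ev, pos, ql, sl)


class TestMincov:
    def test_longer_sequence_divides(self):
        assert compute_mincov(hit("q", "s", 1e-5, pos=50, ql=100, sl=80)) == 0.5

    def test_zero_positives(self):
        assert compute_mincov(hit("q", "s", 1e-5, pos=0)) == 0.0

    def test_full_length_identity(self):
        assert compute_mincov(hit("q", "s", 0.0, pos=100, ql=100, sl=100)) == 1.0

    def test_gapped_alignment_clipped_to_one(self):
        assert compute_mincov(hit("q", "s", 1e-5, pos=130, ql=100, sl=90)) == 1.0


class TestFseq:
    def test_single_candidate(self):
        hitsA = [hit("q1", "t1", 1e-30, pos=90)]
        hitsB = [hit("q2", "t2", 1e-20, pos=80)]
        fs = fseq_feature(hitsA, hitsB, {("t1", "t2")})
        assert fs == SeqFeature(1e-30, 0.9, 1e-20, 0.8)

    def test_no_template_default(self):
        fs = fseq_feature([hit("q1", "t1", 1e-30)], [hit("q2", "t2", 1e-20)], set())
        assert fs == SeqFeature(100.0, 0.0, 100.0, 0.0)

    def test_cutoff_excludes_weak_hits(self):
        hitsA = [hit("q1", "t1", 5e2)]
        hitsB = [hit("q2", "t2", 1e-20)]
        assert fseq_feature(hitsA, hitsB, {("t1", "t2")}) == SeqFeature()

    def test_smaller_euclidean_norm_wins(self):
        hitsA = [hit("q1", "t1", 1.0), hit("q1", "u1", 0.5)]
        hitsB = [hit("q2", "t2", 1.0), hit("q2", "u2", 2.0)]
        fs = fseq_feature(hitsA, hitsB, {("t1", "t2"), ("u1", "u2")})
        # sqrt(1+1) < sqrt(0.25+4)
        assert (fs.evalueA, fs.evalueB) == (1.0, 1.0)

    def test_unordered_template_membership(self):
        # the stored canonical pair covers both slot assignments
        hitsA = [hit("q1", "z", 1e-10)]
        hitsB = [hit("q2", "a", 1e-12)]
        fs = fseq_feature(hitsA, hitsB, {("a", "z")})
        assert fs.evalueA == 1e-10 and fs.evalueB == 1e-12

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(30):
            nA, nB = rng.integers(1, 8, size=2)
            subjects = [f"s{i}" for i in range(6)]
            def rand_hits(q, n):
                return [
                    (
                        subjects[rng.integers(6)],
                        float(10.0 ** rng.uniform(-30, 2.5)),
                        int(rng.integers(0, 120)),
                        int(rng.integers(50, 200)),
                        int(rng.integers(50, 200)),
                    )
                    for _ in range(n)
                ]
            rawA, rawB = rand_hits("qa", nA), rand_hits("qb", nB)
            pos = set()
            for _ in range(4):
                a, b = subjects[rng.integers(6)], subjects[rng.integers(6)]
                pos.add(tuple(sorted((a, b))))
            hitsA = [SimilarityHit("qa", *t) for t in rawA]
            hitsB = [SimilarityHit("qb", *t) for t in rawB]
            got = fseq_feature(hitsA, hitsB, pos)
            want = fseq_oracle(rawA, rawB, pos)
            assert (got.evalueA, got.mincovA, got.evalueB, got.mincovB) == pytest.approx(want)


class TestPropensity:
    def test_hand_computed_ln2(self):
        pairs = [
            InteractionPair("a", "b", POSITIVE),
            InteractionPair("c", "d", NEGATIVE),
        ]
        domains = {
            "a": frozenset({"d1"}), "b": frozenset({"d2"}),
            "c": frozenset({"d3"}), "d": frozenset({"d4"}),
        }
        table = build_propensity_table(pairs, domains)
        assert table.propensity("d1", "d2") == pytest.approx(math.log(2))
        assert table.propensity("d2", "d1") == pytest.approx(math.log(2))

    def test_balanced_pair_has_zero_propensity(self):
        pairs = [
            InteractionPair("a", "b", POSITIVE),
            InteractionPair("c", "d", NEGATIVE),
        ]
        domains = {k: frozenset({"dx"}) for k in "abcd"}
        table = build_propensity_table(pairs, domains)
        assert table.propensity("dx", "dx") == pytest.approx(0.0)

    def test_counts_match_explicit_counting(self, rng):
        # 5-pair toy set against a brute-force counting oracle
        prots = list("abcdef")
        doms = {p: frozenset(f"D{i}" for i in rng.integers(0, 4, rng.integers(0, 3)))
                for p in prots}
        pairs = []
        for _ in range(5):
            a, b = rng.choice(prots, 2, replace=False)
            pairs.append(InteractionPair(a, b, int(rng.integers(0, 2))))
        table = build_propensity_table(pairs, doms)
        # oracle: explicit loops
        expect: dict = {}
        for p in pairs:
            seen = set()
            for dx in doms.get(p.idA, ()):
                for dy in doms.get(p.idB, ()):
                    seen.add(tuple(sorted((dx, dy))))
            for key in seen:
                cell = expect.setdefault(key, [0, 0])
                cell[p.label] += 1
        assert set(table.counts) == set(expect)
        for key, (fneg_fpos) in expect.items():
            assert table.counts[key] == (expect[key][1], expect[key][0])
        # conservation: totals equal summed incidences per class
        assert table.pos_total == sum(v[1] for v in expect.values())
        assert table.neg_total == sum(v[0] for v in expect.values())


class TestFdom:
    def test_empty_domains_give_zero(self):
        table = build_propensity_table([], {})
        assert fdom_score(frozenset(), frozenset({"d1"}), table) == 0.0

    def test_single_pair_mean(self):
        table = build_propensity_table([], {})
        table.counts[("d1", "d2")] = (1, 0)
        table.pos_total, table.neg_total = 1, 0
        val = table.propensity("d1", "d2")
        assert fdom_score({"d1"}, {"d2"}, table) == pytest.approx(val)

    def test_unseen_pairs_count_in_denominator(self):
        # table with (d1,d3) at a known propensity; (d2,d3) absent -> 0
        pairs = [InteractionPair("a", "b", POSITIVE),
                 InteractionPair("c", "d", NEGATIVE)]
        domains = {"a": frozenset({"d1"}), "b": frozenset({"d3"}),
                   "c": frozenset({"x"}), "d": frozenset({"y"})}
        table = build_propensity_table(pairs, domains)
        p13 = table.propensity("d1", "d3")
        got = fdom_score({"d1", "d2"}, {"d3"}, table)
        assert got == pytest.approx((p13 + 0.0) / 2)


class TestNetwork:
    def test_build_dedup_and_selfloop(self):
        g = build_network([("a", "b"), ("b", "a"), ("c", "c")])
        assert g.number_of_edges() == 2  # one a-b edge plus self-loop
        assert g.has_edge("c", "c")
        assert g["a"]["b"]["weight"] == 1.0

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ValueError):
            build_network([("a", "b")], default_weight=0.0)

    def test_chain(self):
        g = build_network([("a", "b"), ("b", "c")])
        assert spw(g, "a", "c") == 2.0

    def test_self_distance_zero_without_selfloop(self):
        g = build_network([("a", "b")])
        assert spw(g, "a", "a") == 0.0

    def test_no_path_and_absent_nodes(self):
        g = build_network([("a", "b"), ("c", "d")])
        assert spw(g, "a", "c") is None
        assert spw(g, "a", "zz") is None

    def test_agrees_with_path_enumeration_on_random_graphs(self, rng):
        for _ in range(60):
            n = int(rng.integers(2, 9))
            nodes = [f"n{i}" for i in range(n)]
            edges = []
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.5:
                        edges.append((nodes[i], nodes[j], float(rng.uniform(0.1, 5))))
            if not edges:
                continue
            g = nx.Graph()
            for u, v, w in edges:
                g.add_edge(u, v, weight=w)
            src, dst = rng.choice(nodes, 2)
            got = spw(g, src, dst)
            want = spw_enumeration_oracle(edges, src, dst)
            if want is None:
                assert got is None
            else:
                assert got == pytest.approx(want)


class TestFnet:
    def test_no_hits_gives_sentinel(self):
        g = build_network([("a", "b")])
        assert fnet_score([], [hit("q", "a", 1e-5)], g) == -1.0

    def test_chain_through_hits(self):
        g = build_network([("a", "b"), ("b", "c")])
        assert fnet_score([hit("q1", "a", 1e-5)], [hit("q2", "c", 1e-5)], g) == 2.0

    def test_min_over_hit_combinations(self):
        g = build_network([("a", "b"), ("b", "c"), ("x", "c")])
        hitsA = [hit("q1", "a", 1e-5), hit("q1", "x", 1e-5)]
        hitsB = [hit("q2", "c", 1e-5)]
        assert fnet_score(hitsA, hitsB, g) == 1.0

    def test_evalue_cutoff_applies(self):
        g = build_network([("a", "b")])
        assert fnet_score([hit("q1", "a", 1.0)], [hit("q2", "b", 1e-9)], g) == -1.0

    def test_shared_hit_gives_zero(self):
        g = build_network([("a", "b")])
        assert fnet_score([hit("q1", "a", 1e-9)], [hit("q2", "a", 1e-9)], g) == 0.0

    def test_adding_edge_never_increases(self, rng):
        g = build_network([("a", "b"), ("b", "c"), ("c", "d")])
        hitsA = [hit("q1", "a", 1e-6)]
        hitsB = [hit("q2", "d", 1e-6)]
        before = fnet_score(hitsA, hitsB, g)
        g.add_edge("a", "d", weight=1.0)
        after = fnet_score(hitsA, hitsB, g)
        assert after <= before


class TestFeaturizePair:
    def _ctx(self):
        pairs = [InteractionPair("a", "b", POSITIVE),
                 InteractionPair("c", "d", NEGATIVE)]
        hits_map = {
            "a": [hit("a", "a", 0.0, pos=100)],
            "b": [hit("b", "b", 0.0, pos=100)],
        }
        domains = {"a": frozenset({"d1"}), "b": frozenset({"d2"})}
        return FeatureContext.build(pairs, hits_map, domains)

    def test_no_hits_anywhere_gives_all_defaults(self):
        ctx = self._ctx()
        fv = featurize_pair("zz", "yy", ctx)
        assert fv.fseq == SeqFeature(100.0, 0.0, 100.0, 0.0)
        assert fv.fdom == 0.0
        assert fv.fnet == -1.0

    def test_training_pair_scores_perfectly(self):
        ctx = self._ctx()
        fv = featurize_pair("a", "b", ctx)
        assert fv.fseq == SeqFeature(0.0, 1.0, 0.0, 1.0)
        assert fv.fnet == 1.0  # direct edge between the self-hits

    def test_swap_symmetry(self):
        ctx = self._ctx()
        fv = featurize_pair("a", "b", ctx)
        sw = featurize_pair("b", "a", ctx)
        assert sw.fseq == fv.fseq.swapped()
        assert sw.fdom == fv.fdom and sw.fnet == fv.fnet

    def test_zero_evalue_template_detection(self):
        ctx = self._ctx()
        assert has_zero_evalue_template("a", "b", ctx)
        assert not has_zero_evalue_template("a", "zz", ctx)
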