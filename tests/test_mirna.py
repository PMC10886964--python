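import itertools

import numpy as np
import pytest

from dismodnet.mirna import (BipartiteMTI, Bicluster, attachment_ratio,
                             bicluso_bicluster, build_mti, mark_sub_mrms,
                             predict_mirnas, relevance_scores)


def mti(name, *edges):
    return BipartiteMTI(source_name=name, edges=set(edges))


class TestBuildMTI:
    def test_restricts_to_query_genes(self):
        out = build_mti({("m1", "g1"), ("m1", "g9")}, {"g1"})
        assert out.edges == {("m1", "g1")}

    def test_disjoint_query_warns_and_empties(self):
        with pytest.warns(UserWarning):
            out = build_mti({("m1", "g1")}, {"zz"})
        assert out.edges == set()

    def test_matches_linear_scan(self):
        rng = np.random.default_rng(0)
        edges = {(f"m{rng.integers(20)}", f"g{rng.integers(50)}") for _ in range(300)}
        query = {f"g{i}" for i in range(0, 50, 3)}
        out = build_mti(edges, query)
        assert out.edges == {e for e in edges if e[1] in query}


class TestBiclustering:
    def test_complete_bipartite_single_bicluster(self):
        edges = [(f"m{i}", f"g{j}") for i in range(2) for j in range(3)]
        bcs = bicluso_bicluster(mti("s", *edges))
        assert len(bcs) == 1
        assert bcs[0].mirnas == frozenset(("m0", "m1"))
        assert bcs[0].genes == frozenset(("g0", "g1", "g2"))
        assert bcs[0].fill == 1.0

    def test_two_disjoint_blocks_found_separately(self):
        edges = [(f"m{i}", f"g{j}") for i in range(2) for j in range(2)]
        edges += [(f"m{i}", f"g{j}") for i in range(2, 4) for j in range(2, 4)]
        bcs = bicluso_bicluster(mti("s", *edges))
        assert {b.mirnas for b in bcs} == {frozenset(("m0", "m1")),
                                           frozenset(("m2", "m3"))}

    def test_singleton_mirna_emits_its_targets(self):
        edges = [("m1", "g1"), ("m1", "g2"), ("m2", "g9")]
        bcs = bicluso_bicluster(mti("s", *edges), sim_min=0.5)
        assert {(b.mirnas, b.genes) for b in bcs} == {
            (frozenset(("m1",)), frozenset(("g1", "g2"))),
            (frozenset(("m2",)), frozenset(("g9",)))}

    def test_attached_genes_meet_attach_ratio(self):
        rng = np.random.default_rng(4)
        edges = {(f"m{rng.integers(12)}", f"g{rng.integers(30)}") for _ in range(150)}
        source = mti("s", *edges)
        for b in bicluso_bicluster(source, attach_ratio=0.5):
            for g in b.genes:
                n_hit = sum(1 for m in b.mirnas if (m, g) in source.edges)
                assert n_hit >= 0.5 * len(b.mirnas)

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            bicluso_bicluster(mti("s", ("m", "g")), sim_min=0.0)


class TestSubMRMs:
    def test_flag_iff_gene_side_hits_disease_set(self):
        bcs = [Bicluster(frozenset(("m1",)), frozenset(("g1",)), 1.0)]
        assert mark_sub_mrms(bcs, {"g1"})[0].is_sub_mrm
        assert not mark_sub_mrms(bcs, set())[0].is_sub_mrm

    def test_agrees_with_direct_intersection_on_random_mrms(self):
        rng = np.random.default_rng(8)
        disease = {f"g{i}" for i in range(0, 40, 4)}
        bcs = [Bicluster(frozenset((f"m{i}",)),
                         frozenset(rng.choice([f"g{j}" for j in range(40)], size=5,
                                              replace=False)), 1.0)
               for i in range(100)]
        mark_sub_mrms(bcs, disease)
        for b in bcs:
            assert b.is_sub_mrm == bool(set(b.genes) & disease)


def hand_fixture():
    """One dataset: 10 MRMs, of which two sub-MRMs share miRNA mx."""
    disease = {"d1", "d2", "d3"}
    edges = {("mx", "d1"), ("mx", "d2"), ("mx", "d3"), ("mx", "g1"),
             ("my", "g2"), ("mz", "d1")}
    source = mti("s1", *edges)
    sub1 = Bicluster(frozenset(("mx", "mz")), frozenset(("d1", "d2", "g1")), 0.8,
                     is_sub_mrm=True)
    sub2 = Bicluster(frozenset(("mx",)), frozenset(("d3",)), 1.0, is_sub_mrm=True)
    plain = [Bicluster(frozenset(("my",)), frozenset(("g2",)), 1.0) for _ in range(8)]
    return {"s1": [sub1, sub2] + plain}, {"s1": source}, disease


class TestRelevanceScores:
    def test_rs_is_attachments_times_clusters(self):
        mrms, mtis, disease = hand_fixture()
        scores = {s.mirna: s for s in relevance_scores(mrms, mtis, disease)}
        # mx: 3 disease genes attached across 2 sub-MRMs, C=10 -> RS=6, TRS=0.6
        assert scores["mx"].rs["s1"] == 6.0
        assert scores["mx"].trs == pytest.approx(0.6)

    def test_no_direct_disease_edge_scores_zero(self):
        # mz sits in a sub-MRM; d2 is in the module but mz only targets d1
        mrms, mtis, disease = hand_fixture()
        mtis["s1"].edges.discard(("mz", "d1"))
        mtis["s1"].edges.add(("mz", "g1"))
        scores = {s.mirna: s for s in relevance_scores(mrms, mtis, disease)}
        assert scores["mz"].rs["s1"] == 0.0
        assert scores["mz"].trs == 0.0

    def test_trs_multi_dataset_normalisation(self):
        # RS=(4,0,6), C=(2,5,3), E=(1,0,1) -> TRS=(4/2+6/3)/2=2.0
        disease = {"d"}
        sources = {
            "n1": mti("n1", ("m", "d"), ("m", "a")),
            "n2": mti("n2", ("q", "x")),
            "n3": mti("n3", ("m", "d"), ("m", "b")),
        }
        mrms = {
            "n1": [Bicluster(frozenset("m"), frozenset(("d", "a")), 1.0, True),
                   Bicluster(frozenset("m"), frozenset(("d", "b")), 1.0, True),
                   Bicluster(frozenset("m"), frozenset(("d", "c")), 1.0, True),
                   Bicluster(frozenset("m"), frozenset(("d", "e")), 1.0, True)]
                  [:2],
            "n2": [Bicluster(frozenset("q"), frozenset("x"), 1.0, False)] * 5,
            "n3": [Bicluster(frozenset("m"), frozenset(("d", "b")), 1.0, True)] * 3,
        }
        # n1: mx in 2 sub-MRMs, 1 disease gene with direct edge -> wait, RS there
        scores = {s.mirna: s for s in relevance_scores(mrms, sources, disease)}
        s = scores["m"]
        assert s.rs["n1"] == 2.0 and s.rs["n3"] == 3.0
        assert s.e == {"n1": 1, "n2": 0, "n3": 1}
        assert s.trs == pytest.approx((2.0 / 2 + 3.0 / 3) / 2)

    def test_trs_invariant_to_dataset_relabelling(self):
        mrms, mtis, disease = hand_fixture()
        base = {s.mirna: s.trs for s in relevance_scores(mrms, mtis, disease)}
        for perm in itertools.permutations(["a", "b", "c"]):
            renamed_mrms = {perm[0]: mrms["s1"], perm[1]: [], perm[2]: []}
            renamed_mtis = {perm[0]: mtis["s1"],
                            perm[1]: BipartiteMTI(perm[1], set()),
                            perm[2]: BipartiteMTI(perm[2], set())}
            got = {s.mirna: s.trs for s in relevance_scores(renamed_mrms, renamed_mtis,
                                                            disease)}
            assert got == pytest.approx(base)

    def test_sub_mrm_normalisation_variant(self):
        mrms, mtis, disease = hand_fixture()
        scores = {s.mirna: s for s in
                  relevance_scores(mrms, mtis, disease, normalize_by="sub_mrm")}
        assert scores["mx"].trs == pytest.approx(6.0 / 2)


class TestPrediction:
    def test_positive_trs_called(self):
        mrms, mtis, disease = hand_fixture()
        pred = predict_mirnas(relevance_scores(mrms, mtis, disease))
        assert [s.mirna for s in pred] == ["mx", "mz"]

    def test_all_zero_yields_empty(self):
        source = {"s": mti("s", ("m1", "g1"))}
        mrms = {"s": mark_sub_mrms(bicluso_bicluster(source["s"]), set())}
        assert predict_mirnas(relevance_scores(mrms, source, set())) == []

    def test_planted_mrm_mirnas_outrank_background(self, synthetic_scenario):
        """miRNAs of planted disease-wired modules should dominate the ranking."""
        from dismodnet.synthetic import generate_mti
        disease = synthetic_scenario["truth"].disease_genes
        sources, mti_truth = generate_mti(seed=21, disease_genes=disease)
        mrms = {n: mark_sub_mrms(bicluso_bicluster(s), disease)
                for n, s in sources.items()}
        pred = predict_mirnas(relevance_scores(mrms, sources, disease))
        planted = set().union(*(m for m, _ in mti_truth.planted_mrms))
        ranks = {s.mirna: i for i, s in enumerate(pred)}
        planted_ranks = [ranks[m] for m in planted if m in ranks]
        other_ranks = [i for m, i in ranks.items() if m not in planted]
        assert planted_ranks, "no planted miRNA predicted"
        if other_ranks:
            assert np.median(planted_ranks) < np.median(other_ranks)


class TestAttachmentRatio:
    @staticmethod
    def _scores(names):
        from dismodnet.mirna import MiRNAScore
        return [MiRNAScore(m, {}, {}, {}, {}, {}, trs=1.0) for m in names]

    def test_top_equals_all_is_unity(self):
        preds = self._scores(["m1", "m2"])
        edges = {("m1", "d1"), ("m2", "d2")}
        assert attachment_ratio(preds, 2, edges, {"d1", "d2"}) == pytest.approx(1.0)

    def test_small_arithmetic_example(self):
        # top-1 has 5 of the 10 total attachments over 5 miRNAs -> (5/1)/(10/5)=2.5
        preds = self._scores([f"m{i}" for i in range(5)])
        edges = {("m0", f"d{j}") for j in range(5)}
        edges |= {(f"m{i}", f"d{i + 10}") for i in range(1, 5)}
        edges.add(("m1", "d20"))
        disease = {e[1] for e in edges}
        assert attachment_ratio(preds, 1, edges, disease) == pytest.approx(2.5)

    def test_k_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            attachment_ratio(self._scores(["m1"]), 2, {("m1", "d")}, {"d"})
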