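"""Hamming-distance clonal networks: construction, extraction, consensus."""

import numpy as np
import pytest

from ighrep import (
    Cohort,
    build_network,
    consensus_matrix,
    extract_relevant,
    hamming,
)
from conftest import make_sample


class TestHamming:
    def test_identical_zero(self):
        assert hamming("CARDW", "CARDW") == 0

    def test_single_substitution(self):
        assert hamming("CARDW", "CARDY") == 1

    def test_unequal_length_undefined(self):
        assert hamming("CARW", "CARDW") is None

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            hamming("", "A")


def one_seq_cohort(seq_by_sample, group_by_sample=None):
    samples = []
    meta = {}
    for sid, seqs in seq_by_sample.items():
        group = (group_by_sample or {}).get(sid, "nontreated")
        rows = [(s, "IGHV3-30", "IGHJ4", 1) for s in seqs]
        samples.append(make_sample(sid, group, "IGHG", rows))
        meta[sid] = group
    return Cohort(samples, meta)


class TestBuildNetwork:
    def test_shared_identical_sequence_distance_zero_edge(self):
        cohort = one_seq_cohort({"P1": ["CARDW"], "P2": ["CARDW"]})
        net = build_network(cohort, "IGHG", max_distance=2)
        comps = net.components()
        assert len(comps) == 1
        edge = net.edge_table().iloc[0]
        assert edge["distance"] == 0

    def test_chain_connects_beyond_direct_distance(self):
        cohort = one_seq_cohort(
            {"P1": ["AAAA"], "P2": ["AAAC"], "P3": ["AACC"], "P4": ["ACCC"]}
        )
        net = build_network(cohort, "IGHG", max_distance=2)
        comps = net.components()
        assert len(comps) == 1
        assert comps[0].sample_set == {"P1", "P2", "P3", "P4"}
        # AAAA-ACCC is distance 3: no direct edge, connected via the chain
        edges = {
            frozenset((r["cdr3_a"], r["cdr3_b"]))
            for _, r in net.edge_table().iterrows()
        }
        assert frozenset(("AAAA", "ACCC")) not in edges
        assert frozenset(("AAAA", "AACC")) in edges

    def test_matches_brute_force_all_pairs(self, small_synthetic):
        net = build_network(
            small_synthetic, "IGHG", 2, sample_ids=small_synthetic.endemic_sample_ids
        )
        nodes = sorted(net.graph.nodes)
        expected = set()
        for i, (sa, qa) in enumerate(nodes):
            for sb, qb in nodes[i + 1:]:
                d = hamming(qa, qb)
                if d is not None and d <= 2:
                    expected.add(frozenset(((sa, qa), (sb, qb))))
        got = {frozenset((u, v)) for u, v in net.graph.edges}
        assert got == expected

    def test_invariant_to_row_order(self, small_synthetic):
        import pandas as pd
        from ighrep.records import RepertoireSample

        shuffled = Cohort(
            [
                RepertoireSample(
                    s.sample_id, s.group, s.isotype,
                    s.df.sample(frac=1.0, random_state=1).reset_index(drop=True),
                )
                for s in small_synthetic.samples
            ],
            small_synthetic.metadata,
        )
        n1 = build_network(small_synthetic, "IGHG", 2)
        n2 = build_network(shuffled, "IGHG", 2)
        assert set(n1.graph.nodes) == set(n2.graph.nodes)
        assert {frozenset(e) for e in n1.graph.edges} == {frozenset(e) for e in n2.graph.edges}

    def test_distance_zero_groups_identical_sequences(self):
        cohort = one_seq_cohort(
            {"P1": ["CARDW", "CAAAW"], "P2": ["CARDW"], "P3": ["CARDY"]}
        )
        net = build_network(cohort, "IGHG", max_distance=0)
        comps = net.components()
        seq_groups = sorted(tuple(sorted({q for _, q in c.nodes})) for c in comps)
        assert seq_groups == [("CAAAW",), ("CARDW",), ("CARDY",)]

    def test_components_length_homogeneous(self, small_synthetic):
        net = build_network(small_synthetic, "IGHG", 2)
        for comp in net.components():
            assert len({len(q) for _, q in comp.nodes}) == 1


class TestExtractRelevant:
    def _network(self, sample_groups):
        cohort = one_seq_cohort(
            {sid: ["CARDW"] for sid in sample_groups},
            group_by_sample=sample_groups,
        )
        return build_network(cohort, "IGHG", max_distance=2)

    def test_below_threshold_excluded(self):
        net = self._network({"P1": "nontreated", "P2": "treated", "P3": "remission"})
        assert extract_relevant(net, min_samples=4) == []

    def test_patient_exclusive_component(self):
        net = self._network(
            {"P1": "nontreated", "P2": "treated", "P3": "remission", "P4": "nontreated"}
        )
        comps = extract_relevant(net, min_samples=4)
        assert len(comps) == 1
        assert comps[0].exclusivity == "patient_exclusive"

    def test_mixed_component_retained(self):
        groups = {"P1": "nontreated", "P2": "treated", "P3": "remission",
                  "P4": "nontreated", "C1": "endemic_control"}
        net = self._network(groups)
        comps = extract_relevant(net, min_samples=4)
        assert len(comps) == 1
        assert comps[0].exclusivity == "mixed"

    def test_restrict_to_counts_only_listed_samples(self):
        groups = {"P1": "nontreated", "P2": "treated", "P3": "remission",
                  "C1": "endemic_control", "C2": "endemic_control"}
        net = self._network(groups)
        # 5 samples total but only 3 patients
        assert extract_relevant(net, 4, restrict_to={"P1", "P2", "P3"}) == []
        assert len(extract_relevant(net, 4)) == 1


class TestConsensus:
    def test_majority_and_matrix(self):
        cons, pfm = consensus_matrix(["CAR", "CAR", "CAK"])
        assert cons == "CAR"
        assert pfm.loc[2, "R"] == pytest.approx(2 / 3)
        assert pfm.loc[2, "K"] == pytest.approx(1 / 3)
        assert np.allclose(pfm.sum(axis=1), 1.0)

    def test_single_member_degenerate(self):
        cons, pfm = consensus_matrix(["CARW"])
        assert cons == "CARW"
        assert np.allclose(pfm.max(axis=1), 1.0)

    def test_alphabetical_tie_break(self):
        cons, _ = consensus_matrix(["A", "A", "C", "C"])
        assert cons == "A"

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="length"):
            consensus_matrix(["CAR", "CARW"])
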