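"""Array-fragment reconstruction from spacer adjacency."""

import numpy as np
import pytest

from spacerscope.assembly import (
    AdjacencyGraph,
    ArrayFragment,
    assemble_fragments,
    build_adjacency,
    compare_fragments,
)
from spacerscope.cluster import cluster_all
from spacerscope.extract import SpacerObservation, extract_from_read
from spacerscope.repeats import revcomp
from spacerscope.simulate import random_dna

from .conftest import make_clean_spacer, make_read


def reads_over_array(cluster_ids, window=2, depth=3):
    """Observations covering every junction of an ordered array."""
    obs = []
    ident = {c: c for c in cluster_ids}
    rid = 0
    for _ in range(depth):
        for start in range(len(cluster_ids) - window + 1):
            for k in range(window):
                obs.append(
                    SpacerObservation(
                        cluster_ids[start + k], "s1", "site", "I-E",
                        f"r{rid}", k,
                    )
                )
            rid += 1
    return obs, ident


def test_path_graph_from_covered_array():
    cids = [f"S{i}" for i in range(5)]
    obs, ident = reads_over_array(cids, depth=3)
    g = build_adjacency(obs, ident, min_support=2)
    assert set(g.edges) == {(f"S{i}", f"S{i+1}") for i in range(4)}
    assert all(v >= 3 for v in g.edges.values())


def test_low_support_chimeric_edge_pruned():
    cids = [f"S{i}" for i in range(5)]
    obs, ident = reads_over_array(cids, depth=3)
    obs += [
        SpacerObservation("S0", "s1", "site", "I-E", "chim", 0),
        SpacerObservation("S3", "s1", "site", "I-E", "chim", 1),
    ]
    g = build_adjacency(obs, ident, min_support=2)
    assert ("S0", "S3") not in g.edges


def test_shared_spacer_creates_branch_no_through_path():
    g = AdjacencyGraph(
        edges={("S1", "X"): 5, ("T1", "X"): 5, ("X", "S2"): 5, ("X", "T2"): 5},
        triples={},
    )
    frags = assemble_fragments(g)
    # without triples, the branch node X terminates all four chains;
    # no fragment asserts a through-path
    for f in frags:
        assert not (
            ("S1" in f.spacers and "T2" in f.spacers)
            or ("T1" in f.spacers and "S2" in f.spacers)
        )


def test_triples_phase_x_shaped_graph():
    g = AdjacencyGraph(
        edges={("S1", "X"): 5, ("T1", "X"): 5, ("X", "S2"): 5, ("X", "T2"): 5},
        triples={("S1", "X", "S2"): 3, ("T1", "X", "T2"): 3},
    )
    frags = assemble_fragments(g)
    paths = sorted(f.spacers for f in frags)
    assert ("S1", "X", "S2") in paths
    assert ("T1", "X", "T2") in paths


def test_clean_path_gives_single_fragment():
    cids = [f"S{i:02d}" for i in range(12)]
    obs, ident = reads_over_array(cids, depth=4)
    g = build_adjacency(obs, ident, min_support=2)
    frags = assemble_fragments(g, type_label="I-E")
    assert len(frags) == 1
    assert frags[0].spacers == tuple(cids)
    assert all(s >= 2 for s in frags[0].junction_support)


def test_fragment_set_invariant_under_read_order_and_orientation(rng, cons_by_type, consensi):
    """End-to-end: reads of one planted array, shuffled and some
    reverse-complemented, reconstruct the same fragment."""
    ie = cons_by_type["I-E"]
    spacers = [make_clean_spacer(rng, ie) for _ in range(8)]
    reads = []
    for start in range(len(spacers) - 1):
        for _ in range(3):
            r, _ = make_read(rng, ie, spacers[start : start + 2])
            reads.append(r)

    def run(read_list):
        obs = []
        for i, r in enumerate(read_list):
            obs += extract_from_read(r, None, consensi, 3, sample_id="s1",
                                     source_id=f"r{i}")
        clusters = cluster_all(obs)
        ident = {seq: c.cluster_id for c in clusters for seq in c.members}
        centre = {c.cluster_id: c.centre_sequence for c in clusters}
        g = build_adjacency(obs, ident, min_support=2)
        frags = assemble_fragments(g, "I-E")
        return sorted(tuple(centre[c] for c in f.spacers) for f in frags)

    base = run(reads)
    perm = list(reads)
    np.random.default_rng(3).shuffle(perm)
    flipped = [revcomp(r) if i % 2 else r for i, r in enumerate(perm)]
    assert base == run(flipped)
    assert base == [tuple(spacers)]


def test_cycle_broken_at_lowest_support_edge():
    g = AdjacencyGraph(
        edges={("A", "B"): 9, ("B", "C"): 9, ("C", "A"): 2},
        triples={},
    )
    frags = assemble_fragments(g)
    assert len(frags) == 1
    assert frags[0].spacers == ("A", "B", "C")


def test_planted_array_recovered_through_full_pipeline(rng, cons_by_type, consensi):
    """A 15-spacer array sequenced to >= 10x junction coverage with 0.5%
    error reconstructs in exactly the planted order."""
    ib = cons_by_type["I-B"]
    spacers = [make_clean_spacer(rng, ib) for _ in range(15)]

    def add_errors(s, rate=0.005):
        out = list(s)
        for i in np.flatnonzero(rng.random(len(s)) < rate):
            out[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[i]]
        return "".join(out)

    obs = []
    rid = 0
    for _ in range(10):
        for start in range(len(spacers) - 1):
            read, _ = make_read(rng, ib, spacers[start : start + 2])
            obs += extract_from_read(add_errors(read), None, consensi, 3,
                                     sample_id="s1", source_id=f"r{rid}")
            rid += 1
    clusters = cluster_all(obs)
    ident = {seq: c.cluster_id for c in clusters for seq in c.members}
    centre = {c.cluster_id: c.centre_sequence for c in clusters}
    g = build_adjacency(obs, ident, min_support=2)
    frags = assemble_fragments(g, "I-B")
    best = max(frags, key=len)
    assert [centre[c] for c in best.spacers] == spacers


class TestCompareFragments:
    def frag(self, ids, fid="f"):
        return ArrayFragment(fid, "I-E", tuple(ids), (5,) * (len(ids) - 1))

    def test_identical(self):
        a = self.frag([f"S{i}" for i in range(10)])
        cmp = compare_fragments(a, self.frag(list(a.spacers), "g"))
        assert cmp.classification == "identical"
        assert len(cmp.shared_block) == 10

    def test_lost_three_from_one_end(self):
        ids = [f"S{i}" for i in range(10)]
        a = self.frag(ids)
        b = self.frag(ids[:-3], "g")
        cmp = compare_fragments(a, b)
        assert cmp.classification == "end-trimmed"
        assert cmp.n_trimmed == 3
        assert cmp.trimmed_end == "right"

    def test_partially_renewed_two_spacer_block(self):
        a = self.frag(["A1", "A2", "A3", "K1", "K2"])
        b = self.frag(["B1", "B2", "B3", "K1", "K2"], "g")
        cmp = compare_fragments(a, b)
        assert cmp.classification == "partially-renewed"
        assert cmp.shared_block == ("K1", "K2")

    def test_leader_proximal_end_labelled(self):
        # both fragments carry private additions at the left end only
        a = self.frag(["A1", "A2", "K1", "K2", "K3"])
        b = self.frag(["B1", "K1", "K2", "K3"], "g")
        cmp = compare_fragments(a, b)
        assert cmp.classification == "partially-renewed"
        assert cmp.leader_proximal_end == "left"

    def test_unrelated(self):
        cmp = compare_fragments(
            self.frag(["A1", "A2"]), self.frag(["B1", "B2"], "g")
        )
        assert cmp.classification == "unrelated"

    def test_orientation_flip_detected(self):
        ids = [f"S{i}" for i in range(6)]
        cmp = compare_fragments(self.frag(ids), self.frag(ids[::-1], "g"))
        assert cmp.classification == "identical"
        assert cmp.reversed_b

    def test_sequence_level_equivalence(self, rng):
        seqs = {f"S{i}": random_dna(rng, 32) for i in range(4)}
        seqs["T0"] = seqs["S0"][:-1] + ("A" if seqs["S0"][-1] != "A" else "C")
        a = self.frag(["S0", "S1", "S2", "S3"])
        b = ArrayFragment("g", "I-E", ("T0", "S1", "S2", "S3"), (5, 5, 5))
        cmp = compare_fragments(a, b, sequences=seqs)
        assert cmp.classification == "identical"


def test_fragment_invariants():
    with pytest.raises(ValueError):
        ArrayFragment("f", "I-E", ("A",), ())
    with pytest.raises(ValueError):
        ArrayFragment("f", "I-E", ("A", "B"), (1, 2))
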