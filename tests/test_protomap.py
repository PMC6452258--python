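"""Protospacer search, flank extraction, PAM models and bias statistics."""

import numpy as np
import pytest

from spacerscope.protomap import (
    Gene,
    build_pam,
    extract_flanks,
    hits_by_type_table,
    locality_table,
    search_protospacers,
    strand_bias,
)
from spacerscope.repeats import revcomp
from spacerscope.simulate import random_dna


def mutate(rng, seq, k):
    out = list(seq)
    for i in rng.choice(len(seq), size=k, replace=False):
        out[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[i]]
    return "".join(out)


def plant(rng, target_len, spacer, pos, strand="+"):
    genome = list(random_dna(rng, target_len))
    ins = spacer if strand == "+" else revcomp(spacer)
    genome[pos : pos + len(spacer)] = list(ins)
    return "".join(genome)


class TestSearch:
    def test_planted_verbatim_hit(self, rng):
        sp = random_dna(rng, 32)
        tgt = plant(rng, 5000, sp, 1000)
        hits = search_protospacers({"s1": sp}, {"t": tgt})
        assert len(hits) == 1
        h = hits[0]
        assert (h.start, h.end, h.strand, h.identity) == (1000, 1032, "+", 1.0)

    def test_minus_strand_hit(self, rng):
        sp = random_dna(rng, 32)
        tgt = plant(rng, 5000, sp, 2000, strand="-")
        hits = search_protospacers({"s1": sp}, {"t": tgt})
        assert len(hits) == 1
        assert hits[0].strand == "-"
        assert hits[0].start == 2000

    def test_identity_threshold_boundary(self, rng):
        """28/32 = 0.875 > 0.85 is kept; 27/32 = 0.84375 is rejected."""
        sp = random_dna(rng, 32)
        t4 = plant(rng, 3000, mutate(rng, sp, 4), 500)
        t5 = plant(rng, 3000, mutate(rng, sp, 5), 500)
        assert len(search_protospacers({"s": sp}, {"t": t4})) == 1
        assert search_protospacers({"s": sp}, {"t": t5}) == []

    def test_gapped_match_is_no_hit(self, rng):
        """A spacer matching only with an internal deletion is rejected."""
        sp = random_dna(rng, 32)
        gapped = sp[:16] + sp[18:]  # 2-nt deletion
        tgt = plant(rng, 3000, gapped, 700)
        # ensure the ungapped alignment is well below threshold
        hits = search_protospacers({"s": sp}, {"t": tgt})
        assert all(h.identity > 0.85 and (h.end - h.start) == 32 for h in hits)
        assert hits == []

    def test_equivalence_with_bruteforce_scan(self):
        """Seed-and-extend equals an exhaustive every-offset scan."""
        rng = np.random.default_rng(17)
        spacers = {}
        tgt = list(random_dna(rng, 20000))
        for i in range(12):
            sp = random_dna(rng, 30 + int(rng.integers(0, 6)))
            spacers[f"s{i:02d}"] = sp
            if i % 2 == 0:  # plant half of them, with 0-4 mutations
                pos = 100 + i * 1500
                ins = mutate(rng, sp, int(rng.integers(0, 5)))
                if rng.random() < 0.5:
                    ins = revcomp(ins)
                tgt[pos : pos + len(sp)] = list(ins)
        target = "".join(tgt)
        got = {
            (h.spacer_id, h.start, h.strand, h.mismatches)
            for h in search_protospacers(spacers, {"t": target})
        }
        brute = set()
        for sid, sp in spacers.items():
            for strand in ("+", "-"):
                q = sp if strand == "+" else revcomp(sp)
                for i in range(len(target) - len(q) + 1):
                    mm = sum(a != b for a, b in zip(q, target[i : i + len(q)]))
                    if (len(q) - mm) / len(q) > 0.85:
                        brute.add((sid, i, strand, mm))
        assert got == brute

    def test_target_revcomp_invariance(self, rng):
        sp = random_dna(rng, 32)
        tgt = plant(rng, 4000, sp, 1500)
        fwd = search_protospacers({"s": sp}, {"t": tgt})
        rev = search_protospacers({"s": sp}, {"t": revcomp(tgt)})
        L = len(tgt)
        assert len(fwd) == len(rev) == 1
        assert rev[0].start == L - fwd[0].end
        assert {fwd[0].strand, rev[0].strand} == {"+", "-"}
        assert fwd[0].up_flank == rev[0].up_flank
        assert fwd[0].down_flank == rev[0].down_flank


class TestFlanks:
    def test_plus_strand_coordinates(self):
        tgt = "".join("ACGT"[i % 4] for i in range(300))
        up, down = extract_flanks(tgt, 100, 132, "+")
        assert up == tgt[92:100]
        assert down == tgt[132:140]

    def test_minus_strand_is_revcomp_of_opposite_sides(self, rng):
        tgt = random_dna(rng, 300)
        up, down = extract_flanks(tgt, 100, 132, "-")
        assert up == revcomp(tgt[132:140])
        assert down == revcomp(tgt[92:100])

    def test_contig_edge_truncation(self, rng):
        tgt = random_dna(rng, 100)
        up, down = extract_flanks(tgt, 0, 32, "+")
        assert up is None and down is not None
        up, down = extract_flanks(tgt, 65, 97, "+")  # 3 nt from the end
        assert down is None and up is not None


class TestPam:
    def make_hits(self, rng, flanks_up, tlab="I-E"):
        from spacerscope.protomap import ProtospacerHit

        return [
            ProtospacerHit(f"s{i}", tlab, "", "t", "+", 0, 32, 1.0, 0,
                           up, random_dna(rng, 8))
            for i, up in enumerate(flanks_up)
        ]

    def test_planted_aag_recovered(self, rng):
        ups = [random_dna(rng, 5) + "AAG" for _ in range(20)]
        model = build_pam(self.make_hits(rng, ups))
        assert model.up_consensus[-3:] == "AAG"

    def test_uniform_flanks_all_n_low_information(self, rng):
        ups = [random_dna(rng, 8) for _ in range(400)]
        model = build_pam(self.make_hits(rng, ups))
        assert set(model.up_consensus) == {"N"}
        assert model.up_information.max() < 0.1

    def test_single_sequence_full_information(self, rng):
        ups = ["ACGTACGT"] * 10
        model = build_pam(self.make_hits(rng, ups))
        assert np.allclose(model.up_information, 2.0)
        assert model.up_consensus == "ACGTACGT"

    def test_too_few_hits_warns(self, rng):
        with pytest.warns(UserWarning):
            model = build_pam(self.make_hits(rng, ["AAAAAAAA"] * 3))
        assert model.n_hits == 3
        assert model.up_consensus == "n" * 8

    def test_column_sums_equal_contributing_hits(self, rng):
        ups = [random_dna(rng, 8) for _ in range(30)]
        model = build_pam(self.make_hits(rng, ups))
        assert (model.up_counts.sum(axis=1) == 30).all()
        assert (model.down_counts.sum(axis=1) == 30).all()


class TestLocality:
    def test_planted_local_enrichment(self):
        from spacerscope.protomap import ProtospacerHit

        sites = {f"L{i}": "here" for i in range(40)}
        sites.update({f"F{i}": "there" for i in range(400)})
        hits = [
            ProtospacerHit(f"L{i}", "I-E", "here", "phage", "+", 0, 32, 1.0, 0, None, None)
            for i in range(30)
        ] + [
            ProtospacerHit(f"F{i}", "I-E", "there", "phage", "+", 0, 32, 1.0, 0, None, None)
            for i in range(2)
        ]
        table, p = locality_table(hits, sites, "here", "phage")
        assert table == [[30, 10], [2, 398]]
        assert p < 1e-6

    def test_proportional_hits_near_null(self):
        from spacerscope.protomap import ProtospacerHit

        sites = {f"L{i}": "here" for i in range(100)}
        sites.update({f"F{i}": "there" for i in range(100)})
        hits = [
            ProtospacerHit(sid, "I-E", sites[sid], "phage", "+", 0, 32, 1.0, 0, None, None)
            for sid in list(sites)[:10] + list(sites)[100:110]
        ]
        _, p = locality_table(hits, sites, "here", "phage")
        assert p == 1.0


class TestStrandBias:
    def hit(self, strand, start=100, tlab="IIIAB"):
        from spacerscope.protomap import ProtospacerHit

        return ProtospacerHit("s", tlab, "", "t", strand, start, start + 32,
                              1.0, 0, None, None)

    def test_all_transcribed_fraction_one(self):
        genes = [Gene("t", 0, 1000, "+")]
        hits = [self.hit("-", 100 + 40 * i) for i in range(8)]
        res = strand_bias(hits, genes)
        assert res["fraction_transcribed"] == 1.0
        assert res["p_value"] == pytest.approx(2 * 0.5 ** 8)

    def test_balanced_fraction_half(self):
        genes = [Gene("t", 0, 2000, "+")]
        hits = [self.hit("+" if i % 2 else "-", 100 + 40 * i) for i in range(40)]
        res = strand_bias(hits, genes)
        assert res["fraction_transcribed"] == 0.5
        assert res["p_value"] > 0.05

    def test_no_gene_overlap_is_nan(self):
        genes = [Gene("t", 5000, 6000, "+")]
        res = strand_bias([self.hit("+")], genes)
        assert res["n_hits"] == 0
        assert np.isnan(res["fraction_transcribed"])

    def test_partial_overlap_threshold(self):
        genes = [Gene("t", 0, 116, "+")]  # covers 16/32 of a hit at 100
        res = strand_bias([self.hit("-", 100)], genes, min_overlap_frac=0.5)
        assert res["n_hits"] == 1
        res = strand_bias([self.hit("-", 101)], genes, min_overlap_frac=0.5)
        assert res["n_hits"] == 0


def test_hits_by_type_table_with_pam_column(rng):
    from spacerscope.protomap import ProtospacerHit

    hits = [
        ProtospacerHit("a", "I-E", "s", "p1", "+", 0, 32, 1.0, 0, None, None),
        ProtospacerHit("b", "I-E", "s", "p2", "+", 0, 32, 1.0, 0, None, None),
        ProtospacerHit("c", "I-B", "s", "p1", "+", 0, 36, 1.0, 0, None, None),
    ]
    tab = hits_by_type_table(hits, {"I-E": "NNNNNAAG", "I-B": "NNNNGGTN"})
    assert tab.loc["I-E", "p1"] == 1
    assert tab.loc["I-B", "p1"] == 1
    assert tab.loc["I-E", "PAM"] == "NNNNNAAG"
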