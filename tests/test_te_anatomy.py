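"""Structural detectors for TE anatomy, each checked against the printed
worked cases and an exhaustive brute-force oracle."""

import numpy as np
import pytest

from conftest import random_dna
from oracles import (
    best_orf_chain_total,
    brute_orfs,
    brute_pbs,
    brute_ppt,
    brute_tir,
    brute_tsd,
    rc,
)
from tetrace.genomeio import FeatureRecord, GenomeAssembly, revcomp
from tetrace.te_anatomy import (
    annotate_orf_layout,
    census_elements,
    classify_rnap3_association,
    cluster_solo_ltrs,
    detect_dimeric_rnap3,
    detect_tsd,
    find_ltr_pair,
    find_pbs,
    find_ppt,
    find_terminal_inverted_repeat,
)


class TestTerminalInvertedRepeat:
    def test_printed_hexamer_pair(self, py_random):
        inner = random_dna(py_random, 100)
        seq = "TGTAAG" + inner + "CTTACA"
        # block accidental extension past the printed hexamer
        if seq[6] == rc(seq[-7])[-1]:
            seq = seq[:6] + ("A" if seq[6] != "A" else "C") + seq[7:]
        res = find_terminal_inverted_repeat(seq)
        assert (res.length, res.mismatches, res.conforming) == (6, 0, True)
        assert (res.left_seq, res.right_seq) == ("TGTAAG", "CTTACA")

    def test_minimal_tg_ca(self):
        seq = "TGA" + "C" * 30 + "TCA"
        res = find_terminal_inverted_repeat(seq)
        assert (res.length, res.conforming) == (3, True)

    @pytest.mark.parametrize("max_mm", [0, 1])
    def test_matches_exhaustive_oracle(self, py_random, max_mm):
        for _ in range(200):
            seq = random_dna(py_random, py_random.randrange(20, 400))
            res = find_terminal_inverted_repeat(seq, max_mismatch=max_mm)
            oracle = brute_tir(seq, max_mm)
            if oracle is None:
                assert res is None
            else:
                assert (res.length, res.mismatches) == oracle


class TestTargetSiteDuplication:
    def test_printed_offset_case(self, py_random):
        up = "GCGCGC" + random_dna(py_random, 20) + "CGATTTTT"
        down = "ATTTTG" + random_dna(py_random, 20)
        res = detect_tsd(up, down, min_len=4, offset_tol=1, max_mismatch=0)
        assert (res.length, res.offset) == (5, 1)
        assert (res.upstream_copy, res.downstream_copy) == ("ATTTT", "ATTTT")

    def test_identical_nine_mer(self):
        word = "GATTACAAG"
        up = "C" * 20 + word
        down = word + "C" * 20
        res = detect_tsd(up, down)
        assert (res.length, res.offset) == (9, 0)

    def test_matches_exhaustive_oracle_and_low_false_positive_rate(
        self, py_random
    ):
        nones = 0
        n_draws = 1000
        for _ in range(n_draws):
            up = random_dna(py_random, 20)
            down = random_dna(py_random, 20)
            res = detect_tsd(up, down, min_len=4, offset_tol=1)
            oracle = brute_tsd(up, down)
            if oracle is None:
                assert res is None
                nones += 1
            else:
                assert (res.length, res.offset) == oracle
        assert nones / n_draws >= 0.95


class TestLtrPair:
    def test_exact_repeat_recovered(self, py_random):
        ltr = random_dna(py_random, 244)
        seq = ltr + random_dna(py_random, 2000) + ltr
        res = find_ltr_pair(seq, min_ltr=100, max_ltr=400)
        assert res is not None
        assert res.ltr_length == 244
        assert res.identity == 1.0
        assert res.ltr5 == (0, 244)
        assert res.ltr3 == (len(seq) - 244, len(seq))

    def test_unrepeated_termini_give_none(self, py_random):
        assert find_ltr_pair(random_dna(py_random, 1500)) is None

    def test_diverged_repeat_within_tolerance(self, py_random):
        r = np.random.default_rng(7)
        ltr = random_dna(py_random, 244)
        mutated = list(ltr)
        for i in r.choice(len(ltr), size=7, replace=False):  # ~3%
            mutated[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mutated[i]]
        seq = ltr + random_dna(py_random, 1500) + "".join(mutated)
        res = find_ltr_pair(seq, min_ltr=100, max_ltr=400)
        assert res is not None
        assert abs(res.ltr_length - 244) <= 2
        assert abs(res.identity - (1 - 7 / 244)) <= 0.01


class TestPrimerBindingSite:
    def test_printed_geometry(self, py_random):
        trna = random_dna(py_random, 40)
        internal = (
            trna[-1] * 2 + revcomp(trna[-14:]) + random_dna(py_random, 100)
        )
        res = find_pbs(internal, {"tRNA-iMet": trna}, min_match=8)
        assert (res.start_offset, res.match_length, res.trna_id) == (
            2, 14, "tRNA-iMet",
        )

    def test_no_trnas_none(self, py_random):
        assert find_pbs(random_dna(py_random, 100), {}) is None

    def test_matches_exhaustive_oracle(self, py_random):
        hits = 0
        n_draws = 1000
        for _ in range(n_draws):
            internal = random_dna(py_random, 60)
            ends = {f"t{j}": random_dna(py_random, 20) for j in range(10)}
            res = find_pbs(internal, ends, min_match=10, search_window=20)
            oracle = brute_pbs(internal, ends, min_match=10, window=20)
            if oracle is None:
                assert res is None
            else:
                hits += 1
                assert (res.start_offset, res.match_length) == oracle[:2]
        assert hits / n_draws <= 0.01


class TestPolypurineTract:
    def test_thirteen_purine_run(self):
        tail = "CTCTCTCT" + "AGGAGAAAGGGAG"
        res = find_ppt(tail, min_run=8)
        assert (res.run_length, res.end_offset) == (13, 0)

    def test_all_pyrimidine_none(self):
        assert find_ppt("CTCTTTCCCTTTCT" * 4) is None

    def test_matches_brute_force_scan(self, py_random):
        for _ in range(500):
            tail = random_dna(py_random, py_random.randrange(20, 120))
            res = find_ppt(tail, min_run=6, search_window=20)
            oracle = brute_ppt(tail, min_run=6, window=20)
            if oracle is None:
                assert res is None
            else:
                assert (res.run_length, res.end_offset) == oracle


class TestOrfLayout:
    def test_stop_free_frame_is_single_orf(self, py_random):
        codons = [c for c in
                  (random_dna(py_random, 3) for _ in range(400))
                  if c not in ("TAA", "TAG", "TGA")][:300]
        seq = "".join(codons)
        res = annotate_orf_layout(seq, min_orf_aa=100)
        assert len(res.orfs) == 1
        assert res.orfs[0][2] == 300

    def test_two_orf_spacer_with_four_stops(self):
        from tetrace.synthdata import ElementTemplate, build_element

        rng = np.random.default_rng(3)
        seq, _ = build_element(
            ElementTemplate(family="x", total_length=3000,
                            orf1_aa=300, orf2_aa=350),
            rng,
        )
        res = annotate_orf_layout(seq, min_orf_aa=100)
        assert res.spacer_lengths == [324]
        assert res.spacer_stop_counts == [4]

    def test_candidates_and_chain_match_oracle(self, py_random):
        for _ in range(100):
            seq = random_dna(py_random, py_random.randrange(300, 600))
            res = annotate_orf_layout(seq, min_orf_aa=10)
            cands = brute_orfs(seq, 10)
            # every reported ORF is a true maximal ORF
            assert all(o in cands for o in res.orfs)
            # non-overlapping and ordered
            for (s1, e1, _), (s2, _, _) in zip(res.orfs, res.orfs[1:]):
                assert e1 <= s2
            # chain is total-length optimal
            assert sum(o[2] for o in res.orfs) == best_orf_chain_total(cands)


def _tdna(chrom, start, end, strand, fid="t1"):
    return FeatureRecord(chrom, start, end, strand, "tDNA", fid)


class TestRnap3Association:
    def test_sixteen_bp_upstream_is_targeted(self):
        g = _tdna("c", 1000, 1075, "+")
        assert classify_rnap3_association(984, [g]) == "rnap3-start-targeted"

    def test_five_bp_inside_is_internal(self):
        g = _tdna("c", 1000, 1075, "+")
        assert classify_rnap3_association(1005, [g]) == "rnap3-internal"

    def test_far_away_unassociated(self):
        g = _tdna("c", 1000, 1075, "+")
        assert classify_rnap3_association(11_000, [g]) == "unassociated"

    def test_strand_symmetry(self, py_random):
        n = 5000
        for _ in range(100):
            s = py_random.randrange(100, n - 200)
            e = s + 75
            strand = py_random.choice("+-")
            p = py_random.randrange(0, n)
            fwd = classify_rnap3_association(p, [_tdna("c", s, e, strand)])
            mirrored = classify_rnap3_association(
                n - 1 - p,
                [_tdna("c", n - e, n - s, "-" if strand == "+" else "+")],
            )
            assert fwd == mirrored


class TestDimericRnap3:
    def test_gap_in_band_pairs(self):
        a = _tdna("c", 100, 175, "+", "a")
        b = _tdna("c", 187, 262, "+", "b")  # 12-nt gap
        assert detect_dimeric_rnap3([a, b]) == [(a, b)]

    @pytest.mark.parametrize("gap", [4, 27])
    def test_boundary_gaps_excluded(self, gap):
        a = _tdna("c", 100, 175, "+", "a")
        b = _tdna("c", 175 + gap, 250 + gap, "+", "b")
        assert detect_dimeric_rnap3([a, b]) == []

    def test_matches_brute_force_adjacent_scan(self, py_random):
        for _ in range(50):
            feats = []
            pos = 0
            for i in range(10):
                pos += py_random.randrange(1, 60)
                feats.append(
                    _tdna("c", pos, pos + 75, py_random.choice("+-"), f"f{i}")
                )
                pos += 75
            got = detect_dimeric_rnap3(feats)
            expected = [
                (a, b)
                for a, b in zip(feats, feats[1:])
                if a.strand == b.strand and 5 <= b.start - a.end <= 26
            ]
            assert got == expected


class TestSoloLtrClustering:
    @staticmethod
    def _mutate(seq, rate, r):
        out = list(seq)
        for i in range(len(out)):
            if r.random() < rate:
                out[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[i]]
        return "".join(out)

    def test_two_families_resolved(self, py_random):
        base1 = random_dna(py_random, 280)
        base2 = random_dna(py_random, 340)
        cands = {}
        for i in range(10):
            cands[f"a{i}"] = self._mutate(base1, 0.04, py_random)
        for i in range(5):
            cands[f"b{i}"] = self._mutate(base2, 0.04, py_random)
        fams = cluster_solo_ltrs(cands, identity_threshold=0.80)
        assert len(fams) == 2
        memberships = sorted(
            frozenset(m[0] for m in f.members) for f in fams
        )
        assert memberships == [frozenset("a"), frozenset("b")]

    def test_singleton_family_is_its_own_consensus(self, py_random):
        seq = random_dna(py_random, 300)
        fams = cluster_solo_ltrs({"only": seq})
        assert len(fams) == 1
        assert fams[0].consensus == seq
        assert fams[0].mean_length == 300

    def test_planted_length_bands_recovered(self, py_random):
        cands = {}
        for label, length in (("w", 278), ("x", 337), ("y", 302), ("z", 444)):
            base = random_dna(py_random, length)
            for i in range(5):
                cands[f"{label}{i}"] = self._mutate(base, 0.03, py_random)
        fams = cluster_solo_ltrs(cands)
        assert len(fams) == 4
        lengths = sorted(f.mean_length for f in fams)
        assert lengths == [278, 302, 337, 444]


class TestCensus:
    def test_planted_copies_and_fragments(self, py_random):
        ref = random_dna(py_random, 2000)
        chrom = random_dna(py_random, 3000)
        for piece in (ref, ref, ref, ref[200:700], ref[900:1400]):
            at = py_random.randrange(0, len(chrom))
            chrom = chrom[:at] + piece + chrom[at:]
        genome = GenomeAssembly("g", {"c1": chrom})
        counts, hits = census_elements(genome, {"fam1": ref})
        assert counts["fam1"] == {"full": 3, "partial": 0, "fragment": 2}

    def test_no_homology_all_zero(self, py_random):
        genome = GenomeAssembly("g", {"c1": "AT" * 3000})
        counts, hits = census_elements(genome, {"fam1": "GC" * 500})
        assert counts["fam1"] == {"full": 0, "partial": 0, "fragment": 0}
        assert hits == []

    def test_long_truncated_copy_is_partial(self, py_random):
        ref = random_dna(py_random, 6494)
        copy = ref[:3800]
        chrom = random_dna(py_random, 2000) + copy + random_dna(py_random, 2000)
        genome = GenomeAssembly("g", {"c1": chrom})
        counts, hits = census_elements(genome, {"ylli": ref})
        assert counts["ylli"] == {"full": 0, "partial": 1, "fragment": 0}
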