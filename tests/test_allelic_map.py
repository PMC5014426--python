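"""Pairwise alignment, variant counting/densities and reciprocal iLocus
mapping."""

import numpy as np
import pytest

from conftest import random_dna
from oracles import gotoh_score
from tetrace.genomeio import FeatureRecord, GenomeAssembly
from tetrace.iloci import build_iloci
from tetrace.allelic_map import (
    AlignParams,
    VariantCounts,
    align_pair,
    count_variants,
    pair_densities,
    reciprocal_map,
    variant_density,
)


class TestAlignPair:
    def test_identical_sequences(self, py_random):
        s = random_dna(py_random, 1000)
        aln = align_pair(s, s)
        assert aln.identity == 1.0
        assert aln.ops == "=" * 1000
        assert count_variants(aln) == VariantCounts(0, 0, 0)

    def test_three_interior_substitutions(self, py_random):
        a = random_dna(py_random, 1000)
        b = list(a)
        for i in (200, 500, 800):
            b[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[i]]
        aln = align_pair(a, "".join(b))
        counts = count_variants(aln)
        assert counts.mismatches == 3
        assert counts.inserted_bases == counts.deleted_bases == 0
        assert aln.identity == pytest.approx(0.997)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_pair("", "ACGT")

    def test_score_matches_quadratic_dp_oracle(self, py_random):
        for trial in range(50):
            n = py_random.randrange(20, 300)
            a = random_dna(py_random, n)
            if trial % 2:
                b = list(a)
                for _ in range(py_random.randrange(0, 8)):
                    i = py_random.randrange(len(b))
                    b[i] = py_random.choice("ACGT")
                if py_random.random() < 0.5 and len(b) > 30:
                    i = py_random.randrange(5, len(b) - 6)
                    del b[i : i + py_random.randrange(1, 6)]
                b = "".join(b)
            else:
                b = random_dna(py_random, py_random.randrange(20, 300))
            aln = align_pair(a, b)
            assert aln.score == pytest.approx(gotoh_score(a, b))

    def test_mirror_symmetry_swaps_insertions_and_deletions(self, py_random):
        a = random_dna(py_random, 400)
        b = a[:150] + a[160:]  # 10-bp deletion from A's perspective
        ab = align_pair(a, b)
        ba = align_pair(b, a)
        ca, cb = count_variants(ab), count_variants(ba)
        assert ca.inserted_bases == cb.deleted_bases
        assert ca.deleted_bases == cb.inserted_bases
        assert ca.mismatches == cb.mismatches

    def test_embedded_locus_aligns_without_overhang_penalty(self, py_random):
        inner = random_dna(py_random, 300)
        outer = random_dna(py_random, 200) + inner + random_dna(py_random, 250)
        aln = align_pair(inner, outer)
        assert aln.identity == 1.0
        assert aln.coverage_a == 1.0
        assert aln.coverage_b == pytest.approx(300 / 750)


class TestVariantCounting:
    def test_constructed_insertion(self, py_random):
        a = random_dna(py_random, 1500)
        b = a[:700] + a[710:]  # b lacks 10 bases present in a
        mutated = list(b)
        for i in (100, 400, 1200):
            mutated[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[i]]
        aln = align_pair(a, "".join(mutated))
        counts = count_variants(aln)
        assert counts == VariantCounts(3, 10, 0)

    def test_n_columns_excluded(self):
        a = "ACGTACGTNN" + "ACGT" * 20
        b = "ACGTACGTCC" + "ACGT" * 20
        counts = count_variants(align_pair(a, b))
        assert counts.mismatches == 0

    def test_counts_match_column_recount(self, py_random):
        for _ in range(30):
            a = random_dna(py_random, 500)
            b = list(a)
            for _ in range(py_random.randrange(0, 10)):
                i = py_random.randrange(len(b))
                b[i] = py_random.choice("ACGT")
            if py_random.random() < 0.7:
                i = py_random.randrange(20, 480)
                del b[i : i + py_random.randrange(1, 8)]
            aln = align_pair(a, "".join(b))
            counts = count_variants(aln)
            mm = ins = dele = 0
            for ca, cb in zip(aln.aligned_a, aln.aligned_b):
                if "N" in (ca, cb):
                    continue
                if cb == "-":
                    ins += 1
                elif ca == "-":
                    dele += 1
                elif ca != cb:
                    mm += 1
            assert (counts.mismatches, counts.inserted_bases,
                    counts.deleted_bases) == (mm, ins, dele)


class TestVariantDensity:
    def test_arithmetic(self):
        d = variant_density(VariantCounts(3, 10, 0), 1500)
        assert d.M == pytest.approx(2.0)
        assert d.I == pytest.approx(10 / 1.5)
        assert d.D == 0.0

    def test_zero_counts(self):
        d = variant_density(VariantCounts(0, 0, 0), 800)
        assert (d.M, d.I, d.D) == (0.0, 0.0, 0.0)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            variant_density(VariantCounts(1, 0, 0), 0)

    def test_recovers_planted_substitution_rate(self, py_random):
        rate, n_loci, locus_len = 0.005, 200, 1000
        rng = np.random.default_rng(5)
        total_m = 0
        for _ in range(n_loci):
            a = random_dna(py_random, locus_len)
            b = list(a)
            for i in np.nonzero(rng.random(locus_len) < rate)[0]:
                b[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[i]]
            counts = count_variants(align_pair(a, "".join(b)))
            total_m += variant_density(counts, locus_len).M
        mean_m = total_m / n_loci
        se = np.sqrt(rate * locus_len) / (locus_len / 1000) / np.sqrt(n_loci)
        assert abs(mean_m - 5.0) <= 3 * se


def _annotated_genome(py_random, n_genes=8, chrom_len=20_000, name="g"):
    chrom = random_dna(py_random, chrom_len)
    feats = [
        FeatureRecord("c1", s, s + 600, "+", "gene", f"g{i}")
        for i, s in enumerate(range(1000, 1000 + n_genes * 2000, 2000))
    ]
    return GenomeAssembly(name, {"c1": chrom}), feats


class TestReciprocalMap:
    def test_identical_genomes_pair_completely(self, py_random):
        genome, feats = _annotated_genome(py_random)
        iloci_a = build_iloci(feats, genome)
        iloci_b = build_iloci(feats, genome)
        res = reciprocal_map(iloci_a, iloci_b, genome, genome)
        reciprocal = [p for p in res.pairs if p.reciprocal]
        assert len(reciprocal) == len(iloci_a)
        assert res.orphans_a == res.orphans_b == []
        assert all(p.identity == 1.0 for p in reciprocal)

    def test_duplicated_segment_copy_is_orphan(self, py_random):
        genome_a, feats = _annotated_genome(py_random)
        chrom = genome_a.chromosomes["c1"]
        # strain A carries a tandem duplication of one gene locus
        seg = chrom[3000:3600]
        dup_chrom = chrom[:8200] + seg + chrom[8200:]
        feats_a = []
        for f in feats:
            if f.start >= 8200:
                feats_a.append(FeatureRecord(
                    f.chrom, f.start + 600, f.end + 600, f.strand, f.kind, f.id
                ))
            else:
                feats_a.append(f)
        feats_a.append(FeatureRecord("c1", 8200, 8800, "+", "gene", "gdup"))
        dup_genome = GenomeAssembly("a", {"c1": dup_chrom})
        genome_b = GenomeAssembly("b", {"c1": chrom})
        iloci_a = build_iloci(feats_a, dup_genome)
        iloci_b = build_iloci(feats, genome_b)
        res = reciprocal_map(iloci_a, iloci_b, dup_genome, genome_b)
        dup_locus = next(
            l for l in iloci_a if "gdup" in l.member_feature_ids
        )
        orig_locus = next(
            l for l in iloci_a if (l.start, l.end) == (3000, 3600)
        )
        recip_a = {p.ilocus_a_id for p in res.pairs if p.reciprocal}
        assert orig_locus.id in recip_a
        assert dup_locus.id not in recip_a
        assert dup_locus.id in res.orphans_a

    def test_role_swap_symmetry(self, py_random):
        genome_a, feats_a = _annotated_genome(py_random, name="a")
        chrom_b = list(genome_a.chromosomes["c1"])
        rng = np.random.default_rng(11)
        for i in np.nonzero(rng.random(len(chrom_b)) < 0.003)[0]:
            chrom_b[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[chrom_b[i]]
        genome_b = GenomeAssembly("b", {"c1": "".join(chrom_b)})
        iloci_a = build_iloci(feats_a, genome_a)
        iloci_b = build_iloci(feats_a, genome_b)
        fwd = reciprocal_map(iloci_a, iloci_b, genome_a, genome_b)
        rev = reciprocal_map(iloci_b, iloci_a, genome_b, genome_a)
        fwd_set = {(p.ilocus_a_id, p.ilocus_b_id) for p in fwd.pairs
                   if p.reciprocal}
        rev_set = {(p.ilocus_b_id, p.ilocus_a_id) for p in rev.pairs
                   if p.reciprocal}
        assert fwd_set == rev_set
        # per-column operations swap I and D exactly
        for (aid, bid) in fwd_set:
            f = fwd.alignments[(aid, bid)]
            r = rev.alignments[(bid, aid)]
            assert f.ops.count("I") == r.ops.count("D")
            assert f.ops.count("D") == r.ops.count("I")
            assert f.ops.count("X") == r.ops.count("X")

    def test_locus_order_invariance(self, py_random):
        genome_a, feats = _annotated_genome(py_random)
        rng = np.random.default_rng(3)
        chrom_b = list(genome_a.chromosomes["c1"])
        for i in np.nonzero(rng.random(len(chrom_b)) < 0.002)[0]:
            chrom_b[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[chrom_b[i]]
        genome_b = GenomeAssembly("b", {"c1": "".join(chrom_b)})
        iloci_a = build_iloci(feats, genome_a)
        iloci_b = build_iloci(feats, genome_b)
        baseline = {
            (p.ilocus_a_id, p.ilocus_b_id)
            for p in reciprocal_map(iloci_a, iloci_b, genome_a, genome_b).pairs
        }
        shuffled = build_iloci(list(reversed(feats)), genome_a)
        again = {
            (p.ilocus_a_id, p.ilocus_b_id)
            for p in reciprocal_map(shuffled, iloci_b, genome_a, genome_b).pairs
        }
        assert baseline == again
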