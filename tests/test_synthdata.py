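"""The synthetic two-strain generator: determinism, realized rates, planted
anatomy round trips and truth consistency."""

import json

import numpy as np
import pytest

from tetrace.genomeio import write_fasta, write_gff3
from tetrace.te_anatomy import (
    census_elements,
    classify_rnap3_association,
    detect_tsd,
)
from tetrace.synthdata import (
    ElementTemplate,
    SimulationConfig,
    TEPlanEntry,
    build_element,
    config_from_dict,
    config_to_dict,
    default_config,
    generate_ancestor,
    plant_element,
    simulate_hybrid_strains,
    tyl3_like_template,
)


def _small_config(seed=0, **overrides):
    base = dict(
        seed=seed,
        chromosome_lengths=(60_000,),
        te_plan=[
            TEPlanEntry(
                "L", ElementTemplate(family="L", solo=True, ltr_length=244),
                3, "ancestral",
            ),
            TEPlanEntry(
                "L", ElementTemplate(family="L", solo=True, ltr_length=244),
                2, "lineage-B", "parent2-blocks",
            ),
        ],
    )
    base.update(overrides)
    return SimulationConfig(**base)


class TestGenerateAncestor:
    def test_feature_placement_non_overlapping(self):
        cfg = SimulationConfig(
            seed=1, chromosome_lengths=(200_000,), gene_density=0.0005,
            gene_length_mean=1000.0, gene_length_sd=1.0,
        )
        genome, feats = generate_ancestor(cfg)
        genes = sorted(
            (f.start, f.end) for f in feats if f.kind == "gene"
        )
        assert len(genes) == 100
        for (s1, e1), (s2, e2) in zip(genes, genes[1:]):
            assert e1 <= s2

    def test_same_seed_byte_identical(self, tmp_path):
        paths = []
        for run in (1, 2):
            cfg = SimulationConfig(seed=7, chromosome_lengths=(50_000,))
            genome, feats = generate_ancestor(cfg)
            fa = tmp_path / f"run{run}.fa"
            gff = tmp_path / f"run{run}.gff3"
            write_fasta(genome, fa)
            write_gff3(feats, gff)
            paths.append((fa.read_bytes(), gff.read_bytes()))
        assert paths[0] == paths[1]

    def test_gc_content_within_bound(self):
        cfg = SimulationConfig(seed=3, chromosome_lengths=(200_000,),
                               gc_content=0.49)
        genome, _ = generate_ancestor(cfg)
        seq = genome.chromosomes["chrA"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.49) <= 0.01

    def test_infeasible_density_rejected(self):
        cfg = SimulationConfig(
            seed=1, chromosome_lengths=(20_000,), gene_density=0.002,
            gene_length_mean=1500.0,
        )
        with pytest.raises(ValueError, match="infeasible"):
            generate_ancestor(cfg)


class TestBuildElement:
    def test_tyl3_preset_dimensions(self, rng):
        seq, truth = build_element(tyl3_like_template(), rng)
        assert len(seq) == 5973
        assert truth["ltr_length"] == 244
        assert seq[:244] == seq[-244:]

    def test_solo_element_is_one_ltr(self, rng):
        seq, truth = build_element(
            ElementTemplate(family="s", solo=True, ltr_length=278), rng
        )
        assert len(seq) == 278
        assert truth["classification"] == "solo-LTR"


class TestPlantElement:
    def test_tsd_round_trip(self, rng):
        genome, feats = generate_ancestor(
            SimulationConfig(seed=5, chromosome_lengths=(30_000,))
        )
        element, _ = build_element(
            ElementTemplate(family="s", solo=True, ltr_length=244), rng
        )
        seq, new_feats, truth = plant_element(
            genome.chromosomes["chrA"], feats, "chrA", element, 12_000,
            tsd_length=5, tsd_offset=1, te_id="te1", family="s",
        )
        up = seq[truth["start"] - 15 : truth["start"]]
        down = seq[truth["end"] : truth["end"] + 15]
        res = detect_tsd(up, down)
        # the detector may extend by chance at an arbitrary site, but the
        # planted word is always recoverable
        assert res is not None
        assert res.length >= 5

    def test_downstream_features_shifted(self, rng):
        element, _ = build_element(
            ElementTemplate(family="s", solo=True, ltr_length=244), rng
        )
        from tetrace.genomeio import FeatureRecord

        feats = [FeatureRecord("c", 5000, 6000, "+", "gene", "g1")]
        seq0 = "ACGT" * 2500
        seq, new_feats, truth = plant_element(
            seq0, feats, "c", element, 1000, 5, 1, te_id="te", family="s"
        )
        g1 = next(f for f in new_feats if f.id == "g1")
        shift = len(seq) - len(seq0)
        assert (g1.start, g1.end) == (5000 + shift, 6000 + shift)

    def test_rnap3_targeted_plant_classifies_as_targeted(self):
        cfg = SimulationConfig(
            seed=11,
            chromosome_lengths=(60_000,),
            tdna_density=0.0002,
            te_plan=[
                TEPlanEntry(
                    "s",
                    ElementTemplate(family="s", solo=True, ltr_length=244),
                    2, "lineage-A", "rnap3-targeted",
                )
            ],
        )
        a, b, fa, fb, truth = simulate_hybrid_strains(cfg)
        tdnas = [f for f in fa if f.kind == "tDNA"]
        for te in truth.tes:
            chrom, s, e = te.interval_a
            calls = {
                classify_rnap3_association(s, tdnas, chrom=chrom),
                classify_rnap3_association(e, tdnas, chrom=chrom),
            }
            assert "rnap3-start-targeted" in calls

    def test_position_out_of_range(self, rng):
        with pytest.raises(ValueError):
            plant_element("ACGT" * 100, [], "c", "AAAA", 2000, 5)


class TestSimulateHybridStrains:
    def test_zero_rates_make_identical_strains(self):
        cfg = _small_config(
            seed=2,
            sub_rate_genic=0.0, sub_rate_intergenic=0.0,
            indel_rate_genic=0.0, indel_rate_intergenic=0.0,
            te_plan=[
                TEPlanEntry(
                    "L",
                    ElementTemplate(family="L", solo=True, ltr_length=244),
                    3, "ancestral",
                )
            ],
        )
        a, b, fa, fb, truth = simulate_hybrid_strains(cfg)
        assert a.chromosomes == b.chromosomes
        for te in truth.tes:
            assert te.interval_a == te.interval_b

    def test_byte_determinism_across_runs(self, tmp_path):
        blobs = []
        for run in (1, 2):
            cfg = _small_config(seed=9)
            a, b, fa, fb, truth = simulate_hybrid_strains(cfg)
            fa_p = tmp_path / f"a{run}.fa"
            write_fasta(a, fa_p)
            tr_p = tmp_path / f"t{run}.json"
            truth.to_json(tr_p)
            blobs.append((fa_p.read_bytes(), tr_p.read_bytes()))
        assert blobs[0] == blobs[1]

    def test_substitution_counts_within_three_se(self):
        cfg = _small_config(
            seed=4, chromosome_lengths=(150_000,),
            parent2_block_fraction=0.0,
            te_plan=[],
        )
        a, b, fa, fb, truth = simulate_hybrid_strains(cfg)
        for cls, rate in (
            ("genic", cfg.sub_rate_genic),
            ("intergenic", cfg.sub_rate_intergenic),
        ):
            n = truth.class_lengths[cls]
            expected = rate * n
            se = np.sqrt(rate * (1 - rate) * n)
            assert abs(truth.sub_counts_by_class[cls] - expected) <= 3 * se

    def test_census_recall_at_zero_mutation(self):
        cfg = _small_config(
            seed=6,
            sub_rate_genic=0.0, sub_rate_intergenic=0.0,
            indel_rate_genic=0.0, indel_rate_intergenic=0.0,
        )
        a, b, fa, fb, truth = simulate_hybrid_strains(cfg)
        ref_te = next(t for t in truth.tes if t.interval_b is not None)
        chrom, s, e = te_iv = ref_te.interval_b
        ref_seq = b.chromosomes[chrom][s:e]
        counts, hits = census_elements(b, {"L": ref_seq})
        found = {(h.chrom, h.start, h.end) for h in hits}
        for te in truth.tes:
            if te.interval_b is None:
                continue
            assert tuple(te.interval_b) in found

    def test_lineage_b_elements_confined_to_parent2_blocks(self):
        cfg = _small_config(seed=8)
        a, b, fa, fb, truth = simulate_hybrid_strains(cfg)
        for te in truth.tes:
            if te.inheritance != "lineage-B":
                continue
            chrom, s, e = te.interval_b
            assert any(
                bs <= s and e <= be
                for bs, be in truth.parent2_blocks[chrom]
            )

    def test_blockless_config_with_block_placement_rejected(self):
        cfg = _small_config(seed=1, parent2_block_fraction=0.0)
        with pytest.raises(ValueError, match="block"):
            simulate_hybrid_strains(cfg)


class TestConfigSerialisation:
    def test_round_trip(self):
        cfg = default_config(seed=13)
        again = config_from_dict(json.loads(json.dumps(config_to_dict(cfg))))
        assert config_to_dict(again) == config_to_dict(cfg)

    def test_unknown_key_named_in_error(self):
        with pytest.raises(ValueError, match="not_a_key"):
            config_from_dict({"not_a_key": 1})
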