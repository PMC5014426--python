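"""End-to-end comparison workflow shared by the CLI and analysis scripts.

Given two assemblies with feature and TE annotations, this builds the
iLocus partitions, maps allelic loci reciprocally, derives per-locus
variant densities, resolves the flanking loci of every TE, classifies each
element as allelic or non-allelic, profiles flanking densities for both
strains' elements, searches for empty sites of non-allelic elements, and
assembles the three-hypothesis report.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

from .genomeio import FeatureRecord, GenomeAssembly
from .iloci import FlankSet, ILocusSet, build_iloci, flanking_iloci
from .allelic_map import (
    AlignParams,
    ReciprocalMapResult,
    VariantDensity,
    classify_te_allelism,
    pair_densities,
    reciprocal_map,
)
from .inheritance import (
    EmptySiteResult,
    FlankDensityRecord,
    flank_density_profile,
    hypothesis_report,
    locate_empty_site,
    reconstruct_naive_site,
)
from .te_anatomy import ElementAnatomy, detect_tsd


@dataclass
class CompareResult:
    iloci_a: ILocusSet
    iloci_b: ILocusSet
    mapping: ReciprocalMapResult
    densities_a: dict[str, VariantDensity]
    densities_b: dict[str, VariantDensity]
    allelism: dict[str, str]
    flanksets: dict[str, FlankSet]
    flank_records: list[FlankDensityRecord]
    empty_sites: dict[str, EmptySiteResult]
    report: dict
    warnings: list[str] = field(default_factory=list)


def anatomies_from_features(
    genome: GenomeAssembly, features: Sequence[FeatureRecord]
) -> list[ElementAnatomy]:
    """Lightweight anatomy records (interval + family + detected TSD) for TE
    features, enough for allelism calls and naive-site reconstruction."""
    out: list[ElementAnatomy] = []
    for f in features:
        if f.kind != "TE":
            continue
        chrom_seq = genome.chromosomes[f.chrom]
        up = chrom_seq[max(0, f.start - 20) : f.start]
        down = chrom_seq[f.end : f.end + 20]
        tsd = None
        if len(up) >= 13 and len(down) >= 12:
            tsd = detect_tsd(up, down)
        cls = "solo-LTR" if f.length <= 1000 else "partial"
        out.append(
            ElementAnatomy(
                family=f.family or "TE",
                chrom=f.chrom,
                start=f.start,
                end=f.end,
                classification=cls,
                id=f.id,
                tsd=tsd,
            )
        )
    return out


def run_compare(
    genome_a: GenomeAssembly,
    genome_b: GenomeAssembly,
    features_a: Sequence[FeatureRecord],
    features_b: Sequence[FeatureRecord],
    te_a: Sequence[ElementAnatomy] | None = None,
    te_b: Sequence[ElementAnatomy] | None = None,
    min_identity: float = 0.80,
    min_coverage: float = 0.80,
    params: AlignParams | None = None,
    naive_window: int = 300,
    n_perm: int = 10_000,
    seed: int = 0,
    search_empty_sites: bool = True,
) -> CompareResult:
    """Run the full comparison; TE sets default to the TE features present
    in each strain's annotation.  Density denominators are anchored on the
    query strain of each locus (strain A for A-side loci and vice versa);
    flanking records for both strains' elements are pooled into one report.
    """
    shared = set(genome_a.chromosomes) & set(genome_b.chromosomes)
    if not shared:
        raise ValueError("assemblies share no chromosome names")
    params = params or AlignParams()
    te_a = list(te_a) if te_a is not None else anatomies_from_features(
        genome_a, features_a
    )
    te_b = list(te_b) if te_b is not None else anatomies_from_features(
        genome_b, features_b
    )
    iloci_a = build_iloci(features_a, genome_a)
    iloci_b = build_iloci(features_b, genome_b)
    mapping = reciprocal_map(
        iloci_a, iloci_b, genome_a, genome_b,
        min_identity=min_identity, min_coverage=min_coverage, params=params,
    )
    densities_a, densities_b = pair_densities(mapping, iloci_a, iloci_b)
    te_feature_ids_a = frozenset(t.id for t in te_a)
    te_feature_ids_b = frozenset(t.id for t in te_b)
    swapped_pairs = [
        type(p)(
            ilocus_a_id=p.ilocus_b_id,
            ilocus_b_id=p.ilocus_a_id,
            identity=p.identity,
            coverage_a=p.coverage_b,
            coverage_b=p.coverage_a,
            aligned_length=p.aligned_length,
            reciprocal=p.reciprocal,
        )
        for p in mapping.pairs
    ]
    # flank records and allelism are computed per strain side; keys are
    # prefixed "A:"/"B:" because an allelic element carries the same id in
    # both annotations.  Allelic elements enter the pooled density records
    # once (from the A side); non-allelic elements are strain-specific and
    # enter from whichever side carries them.
    allelism: dict[str, str] = {}
    flanksets: dict[str, FlankSet] = {}
    warnings: list[str] = []
    records_by_side: dict[str, list[tuple[ElementAnatomy, str]]] = {
        "A": [], "B": []
    }
    for side, te_set, iloci_q, iloci_t, pairs_q, te_other, te_ids in (
        ("A", te_a, iloci_a, iloci_b, mapping.pairs, te_b, te_feature_ids_a),
        ("B", te_b, iloci_b, iloci_a, swapped_pairs, te_a, te_feature_ids_b),
    ):
        for te in te_set:
            key = f"{side}:{te.id}"
            fs = flanking_iloci(
                iloci_q, (te.chrom, te.start, te.end), k=2,
                te_id=key, te_feature_ids=te_ids,
            )
            flanksets[key] = fs
            label, warn = classify_te_allelism(
                te, fs, pairs_q, te_other, iloci_q, iloci_t
            )
            allelism[key] = label
            if warn:
                warnings.append(f"{key}: flanks have no reciprocal partners")
            if label == "allelic" and side == "B":
                continue
            records_by_side[side].append((replace(te, id=key), label))
    # iLocus ids are per-assembly, so each side's records are profiled
    # against that side's density table
    flank_records = flank_density_profile(
        records_by_side["A"], flanksets, densities_a
    ) + flank_density_profile(records_by_side["B"], flanksets, densities_b)
    empty_sites: dict[str, EmptySiteResult] = {}
    if search_empty_sites:
        for side, te_set, genome_q, genome_t in (
            ("A", te_a, genome_a, genome_b),
            ("B", te_b, genome_b, genome_a),
        ):
            for te in te_set:
                key = f"{side}:{te.id}"
                if allelism.get(key) != "non-allelic":
                    continue
                naive = reconstruct_naive_site(genome_q, te, window=naive_window)
                if len(naive.sequence) < 60:
                    continue
                empty_sites[key] = locate_empty_site(naive, genome_t)
    baselines: dict[str, float] = {}
    for cls in ("feature", "intergenic"):
        vals = [
            densities_a[lid].M
            for lid in densities_a
            if iloci_a.get(lid).locus_class == cls
        ]
        if vals:
            baselines[f"{cls}_M"] = sum(vals) / len(vals)
            for metric in ("I", "D"):
                mv = [
                    getattr(densities_a[lid], metric)
                    for lid in densities_a
                    if iloci_a.get(lid).locus_class == cls
                ]
                baselines[f"{cls}_{metric}"] = sum(mv) / len(mv)
    report = hypothesis_report(
        flank_records,
        empty_site_results=empty_sites,
        genome_wide_baselines=baselines,
        n_perm=n_perm,
        seed=seed,
    )
    return CompareResult(
        iloci_a=iloci_a,
        iloci_b=iloci_b,
        mapping=mapping,
        densities_a=densities_a,
        densities_b=densities_b,
        allelism=allelism,
        flanksets=flanksets,
        flank_records=flank_records,
        empty_sites=empty_sites,
        report=report,
        warnings=warnings,
    )
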