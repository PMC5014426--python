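"""Distinguishing chromosomal inheritance from post-cross transposition.

Two closely related strains can differ in TE content for three reasons:

* H1 — an apparent strain-specific element is really an ancient relic that
  decayed beyond recognition in the other strain.  Tested by reconstructing
  the pre-insertion ("naive") sequence — element excised, one TSD copy
  retained — and searching the other genome: finding the intact empty site
  excludes a decayed relic.
* H2 — strain-specific elements were inherited with flanking chromosome from
  the other, more divergent parent of a cross.  Predicts that non-allelic
  elements sit in flanking sequence enriched in variants relative to the
  partner genome.
* H3 — elements transposed after the cross into random positions.  Predicts
  flanking variant density near the genome-wide average for both groups.

The discriminating statistic contrasts the mean per-kb variant densities
(M/I/D) of the iLoci flanking allelic versus non-allelic elements, with a
label-permutation test on the difference of group means.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
from scipy import stats

from .genomeio import GenomeAssembly
from .iloci import FlankSet
from .allelic_map import VariantDensity
from .te_anatomy import ElementAnatomy


@dataclass
class NaiveSite:
    """Reconstructed pre-insertion sequence: flank window + single TSD copy
    + flank window."""

    source_te_id: str
    sequence: str
    window: int
    tsd_length: int
    no_tsd: bool = False
    truncated: bool = False


@dataclass
class FlankDensityRecord:
    te_id: str
    family: str
    allelism: str  # "allelic" | "non-allelic"
    mean_M: float
    mean_I: float
    mean_D: float
    n_flanks: int


@dataclass
class GroupComparison:
    metric: str
    statistic: float  # mean(non-allelic) - mean(allelic)
    p_value: float
    rank_sum_p: float
    n_permutations: int
    seed: int
    n_allelic: int
    n_non_allelic: int


def reconstruct_naive_site(
    genome: GenomeAssembly, te: ElementAnatomy, window: int = 300
) -> NaiveSite:
    """Excise an element plus one TSD copy, keeping ``window`` bp of each
    flank around the single remaining copy.

    The element interval spans the element body (LTR start to LTR end); the
    upstream TSD copy plus any offset bases sit immediately before it and the
    downstream copy immediately after.  Removing the element, the offset
    bases and the downstream copy restores the pre-insertion locus exactly.
    Without a detected TSD the flanks are simply abutted and flagged.
    """
    chrom_seq = genome.chromosomes[te.chrom]
    tsd_len = te.tsd.length if te.tsd else 0
    offset = te.tsd.offset if te.tsd else 0
    left_end = te.start - offset
    right_start = te.end + tsd_len
    left_start = max(0, left_end - window - tsd_len)
    right_end = min(len(chrom_seq), right_start + window)
    truncated = (left_end - left_start < window + tsd_len) or (
        right_end - right_start < window
    )
    seq = chrom_seq[left_start:left_end] + chrom_seq[right_start:right_end]
    return NaiveSite(
        source_te_id=te.id,
        sequence=seq,
        window=window,
        tsd_length=tsd_len,
        no_tsd=te.tsd is None,
        truncated=truncated,
    )


@dataclass
class EmptySiteResult:
    found: bool
    chrom: str | None = None
    start: int | None = None
    end: int | None = None
    identity: float = 0.0


def locate_empty_site(
    naive: NaiveSite, other_genome: GenomeAssembly, min_identity: float = 0.90
) -> EmptySiteResult:
    """Search the partner genome for the intact empty site of a naive
    sequence.

    The naive junction sequence is aligned as an infix of each chromosome
    (edit-distance semigobal alignment); the site counts as found when the
    whole naive sequence aligns contiguously at identity >=
    ``min_identity``.  An allele still carrying the element cannot satisfy
    this: the element interrupts the junction, so at most one flank aligns
    and identity stays far below threshold.
    """
    if len(naive.sequence) < 60:
        raise ValueError("naive sequence shorter than 60 bp")
    best = EmptySiteResult(found=False)
    q = naive.sequence
    max_dist = int(len(q) * (1.0 - min_identity) / 0.9) + 1
    for chrom, seq in other_genome.chromosomes.items():
        res = edlib.align(q, seq, mode="HW", task="locations", k=max_dist)
        if res["editDistance"] < 0:
            continue
        identity = 1.0 - res["editDistance"] / len(q)
        if identity > best.identity:
            loc = res["locations"][0]
            best = EmptySiteResult(
                found=identity >= min_identity,
                chrom=chrom,
                start=int(loc[0]),
                end=int(loc[1]) + 1,
                identity=identity,
            )
    return best


def flank_density_profile(
    te_records: Sequence[tuple[ElementAnatomy, str]],
    flanksets: Mapping[str, FlankSet],
    densities: Mapping[str, VariantDensity],
) -> list[FlankDensityRecord]:
    """Per-TE unweighted mean M/I/D over the flank iLoci that have allelic
    partners (and hence densities).

    ``te_records`` pairs each element with its allelism label.  Flanks
    without partners contribute nothing and reduce ``n_flanks``; elements
    with no usable flank are dropped.
    """
    out: list[FlankDensityRecord] = []
    for te, allelism in te_records:
        fs = flanksets.get(te.id)
        if fs is None:
            continue
        flank_ids = [i for i in fs.upstream + fs.downstream if i in densities]
        if not flank_ids:
            continue
        ms = [densities[i].M for i in flank_ids]
        is_ = [densities[i].I for i in flank_ids]
        ds = [densities[i].D for i in flank_ids]
        out.append(
            FlankDensityRecord(
                te_id=te.id,
                family=te.family,
                allelism=allelism,
                mean_M=sum(ms) / len(ms),
                mean_I=sum(is_) / len(is_),
                mean_D=sum(ds) / len(ds),
                n_flanks=len(flank_ids),
            )
        )
    return out


def compare_groups(
    records_allelic: Sequence[FlankDensityRecord],
    records_non_allelic: Sequence[FlankDensityRecord],
    metric: str = "M",
    n_perm: int = 10_000,
    seed: int = 0,
) -> GroupComparison:
    """Two-sided label-permutation test on the difference of group mean
    flanking densities, with a rank-sum p-value reported alongside.

    Uses the (count + 1) / (n_perm + 1) convention, so p is in (0, 1] and
    never exactly zero; reproducible for a fixed seed.
    """
    if len(records_allelic) < 2 or len(records_non_allelic) < 2:
        raise ValueError("each group needs at least 2 records")
    attr = {"M": "mean_M", "I": "mean_I", "D": "mean_D"}[metric]
    x = np.array([getattr(r, attr) for r in records_non_allelic], dtype=float)
    y = np.array([getattr(r, attr) for r in records_allelic], dtype=float)
    observed = float(x.mean() - y.mean())
    pooled = np.concatenate([x, y])
    rng = np.random.default_rng(seed)
    n_x = len(x)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        stat = perm[:n_x].mean() - perm[n_x:].mean()
        if abs(stat) >= abs(observed) - 1e-12:
            count += 1
    p = (count + 1) / (n_perm + 1)
    if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
        rank_p = 1.0
    else:
        rank_p = float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
    return GroupComparison(
        metric=metric,
        statistic=observed,
        p_value=p,
        rank_sum_p=rank_p,
        n_permutations=n_perm,
        seed=seed,
        n_allelic=len(y),
        n_non_allelic=len(x),
    )


def hypothesis_report(
    records: Sequence[FlankDensityRecord],
    empty_site_results: Mapping[str, EmptySiteResult] | None = None,
    genome_wide_baselines: Mapping[str, float] | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
    per_family: bool = False,
) -> dict:
    """Summarise the three-hypothesis analysis.

    Pools all families for the headline comparison (per-family mode
    optional): group sizes, group mean densities, permutation p-values per
    metric, the fraction of naive sites found empty in the partner genome,
    and verdict fields — H1 is excluded when empty sites are found; H2 is
    supported when non-allelic densities exceed allelic ones at p < alpha;
    otherwise the data are consistent with H3.
    """
    empty_site_results = empty_site_results or {}

    def summarise(recs: Sequence[FlankDensityRecord]) -> dict | None:
        allelic = [r for r in recs if r.allelism == "allelic"]
        non_allelic = [r for r in recs if r.allelism == "non-allelic"]
        entry: dict = {
            "n_allelic": len(allelic),
            "n_non_allelic": len(non_allelic),
            "group_means": {},
            "p_values": {},
        }
        for metric, attr in (("M", "mean_M"), ("I", "mean_I"), ("D", "mean_D")):
            entry["group_means"][metric] = {
                "allelic": (
                    sum(getattr(r, attr) for r in allelic) / len(allelic)
                    if allelic
                    else None
                ),
                "non_allelic": (
                    sum(getattr(r, attr) for r in non_allelic) / len(non_allelic)
                    if non_allelic
                    else None
                ),
            }
        if len(allelic) >= 2 and len(non_allelic) >= 2:
            for metric in ("M", "I", "D"):
                cmp = compare_groups(
                    allelic, non_allelic, metric=metric, n_perm=n_perm, seed=seed
                )
                entry["p_values"][metric] = cmp.p_value
        return entry

    report: dict = {"pooled": summarise(records), "families": {}, "warnings": []}
    families = sorted({r.family for r in records})
    for fam in families:
        fam_recs = [r for r in records if r.family == fam]
        if not fam_recs:
            report["warnings"].append(f"family {fam} has no usable records")
            continue
        entry = summarise(fam_recs) if per_family else {
            "n_allelic": sum(r.allelism == "allelic" for r in fam_recs),
            "n_non_allelic": sum(r.allelism == "non-allelic" for r in fam_recs),
        }
        report["families"][fam] = entry
    n_searched = len(empty_site_results)
    n_empty = sum(1 for r in empty_site_results.values() if r.found)
    report["empty_sites"] = {
        "n_searched": n_searched,
        "n_found_empty": n_empty,
        "fraction_empty": (n_empty / n_searched) if n_searched else None,
    }
    pooled = report["pooled"]
    h1 = "excluded" if n_empty > 0 else "not-assessed" if not n_searched else "open"
    verdict = "undetermined"
    p_m = pooled["p_values"].get("M") if pooled else None
    means = pooled["group_means"]["M"] if pooled else {}
    if p_m is not None and means.get("allelic") is not None:
        higher = means["non_allelic"] > means["allelic"]
        if higher and p_m < alpha:
            verdict = "H2-supported"
        else:
            verdict = "H3-consistent"
    report["verdicts"] = {"H1": h1, "H2_vs_H3": verdict}
    if genome_wide_baselines:
        report["genome_wide_baselines"] = dict(genome_wide_baselines)
    return report


def write_flank_records_tsv(
    records: Iterable[FlankDensityRecord], path: str | Path
) -> None:
    with Path(path).open("w") as fh:
        fh.write("te_id\tfamily\tallelism\tmean_M\tmean_I\tmean_D\tn_flanks\n")
        for r in records:
            fh.write(
                f"{r.te_id}\t{r.family}\t{r.allelism}\t{r.mean_M:.4f}\t"
                f"{r.mean_I:.4f}\t{r.mean_D:.4f}\t{r.n_flanks}\n"
            )


def write_report_json(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def write_density_bed(
    densities: Mapping[str, VariantDensity],
    iloci,
    path: str | Path,
    metric: str = "M",
) -> None:
    """BED track of per-iLocus densities for genome-browser display."""
    with Path(path).open("w") as fh:
        for lid in sorted(densities):
            loc = iloci.get(lid)
            val = getattr(densities[lid], metric)
            fh.write(f"{loc.chrom}\t{loc.start}\t{loc.end}\t{lid}\t{val:.4f}\t.\n")
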