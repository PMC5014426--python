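"""Synthetic hybrid-strain generator with planted transposable elements.

Emulates the data structure behind a parent/progeny strain comparison: an
ancestor genome with annotated genes and tDNAs; strain A inheriting the
ancestor directly; strain B a haploid mosaic in which a fraction of the
chromosome derives from a second, more divergent parent ("parent-2 blocks"
carrying extra substitution and indel divergence).  TE insertions are
planted with full structural anatomy (LTR pair with TG...CA terminal
inverted repeats, target-site duplication with optional one-base offset,
primer-binding site, polypurine tract, two-ORF layout) and a known
inheritance label: ``ancestral`` elements are inserted before the strains
split and are therefore allelic; ``lineage-A``/``lineage-B`` elements are
strain-specific, and lineage-B elements may be confined to parent-2 blocks
(the chromosomal-inheritance scenario) or scattered uniformly (the
post-cross transposition scenario).  Every planted fact is recorded in a
truth object so downstream detectors can be scored exactly.

All randomness flows from one :func:`numpy.random.default_rng` seed;
identical config + seed gives byte-identical FASTA/GFF3/JSON output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .genomeio import FeatureRecord, GenomeAssembly, revcomp, write_fasta, write_gff3
from .te_anatomy import detect_tsd

BASES = np.array(list("ACGT"))
STOPS = ("TAA", "TAG", "TGA")
_SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOPS
)
# 9-mer whose frame-0 codons are sense (CTA ACT GAC) while the two shifted
# frames read a stop (TAA, TGA) every 9 bp: used for inter-ORF padding so no
# accidental open reading frame can span a pad.
_PAD_UNIT = "CTAACTGAC"
# stop codons in all three phases within 11 bp; breaks accidental ORFs
# inside non-coding element regions such as LTR interiors
_STOP_BLOCK = "TAAATAAATAA"

#: synthetic initiator-tRNA 3' terminus (ends in the universal CCA)
DEFAULT_TRNA_END = "GGGTCGTGGTTCGAATCCACCA"

#: spec string for the spec'd 13-purine polypurine tract
DEFAULT_PPT = "AGGAGAAAGGGAG"


@dataclass
class ElementTemplate:
    """Anatomy recipe for one TE family."""

    family: str
    total_length: int = 5973  # LTR start to LTR end
    ltr_length: int = 244
    tsd_length: int = 5
    tsd_offset: int = 1
    pbs_offset: int = 2
    pbs_length: int = 14
    ppt: str = DEFAULT_PPT
    orf1_aa: int = 500
    orf2_aa: int = 600
    spacer_length: int = 324
    spacer_stops: int = 4
    solo: bool = False  # a solo LTR: single LTR only, no internal domain
    trna_end: str = DEFAULT_TRNA_END

    @property
    def element_length(self) -> int:
        return self.ltr_length if self.solo else self.total_length


@dataclass
class TEPlanEntry:
    family: str
    template: ElementTemplate
    count: int
    inheritance: str  # ancestral | lineage-A | lineage-B
    placement: str = "uniform-intergenic"  # | parent2-blocks | rnap3-targeted


@dataclass
class SimulationConfig:
    """Study conditions for the two-strain simulation.

    Substitution and indel rates are expressed as the expected strain-A vs
    strain-B divergence per bp (applied to strain B relative to the common
    ancestor); parent-2 blocks multiply them by ``parent2_extra_divergence``.
    """

    seed: int = 0
    chromosome_lengths: tuple[int, ...] = (150_000, 150_000)
    gc_content: float = 0.49
    gene_density: float = 0.00025  # genes per bp
    gene_length_mean: float = 1300.0
    gene_length_sd: float = 300.0
    tdna_density: float = 0.000025
    tdna_length: int = 75
    sub_rate_genic: float = 0.0012
    sub_rate_intergenic: float = 0.0024
    indel_rate_genic: float = 0.0002
    indel_rate_intergenic: float = 0.0005
    indel_mean_length: float = 2.0
    indel_max_length: int = 50
    parent2_block_fraction: float = 0.30
    parent2_block_mean_length: float = 20_000.0
    parent2_extra_divergence: float = 3.0
    te_plan: list[TEPlanEntry] = field(default_factory=list)
    placement_margin: int = 50

    def __post_init__(self) -> None:
        rates = (
            self.sub_rate_genic,
            self.sub_rate_intergenic,
            self.indel_rate_genic,
            self.indel_rate_intergenic,
        )
        if any(not (0.0 <= r <= 0.2) for r in rates):
            raise ValueError("rates must lie in [0, 0.2]")
        if not (0.0 <= self.parent2_block_fraction <= 1.0):
            raise ValueError("parent2_block_fraction must lie in [0, 1]")
        if any(e.count < 0 for e in self.te_plan):
            raise ValueError("TE counts must be >= 0")


def tyl3_like_template(family: str = "TyS1") -> ElementTemplate:
    """A full-length Ty3/Gypsy anatomy preset: 5,973 bp LTR-start to
    LTR-end, 244-bp LTRs with TGTAAG/CTTACA terminal hexamers, 5-bp TSD
    offset by one base, 14-nt PBS two bases downstream of the 5' LTR, a
    13-purine PPT, and a 324-bp GAG-POL spacer carrying four stops."""
    return ElementTemplate(family=family)


def default_te_plan() -> list[TEPlanEntry]:
    """The default study conditions: a full-length Ty3/Gypsy-like family and
    a solo-LTR family, with ancestral (allelic) copies plus lineage-B copies
    confined to parent-2 blocks — the chromosomal-inheritance scenario.

    The full-length template is scaled to 3 kb to suit the 150-kb study
    chromosomes (intergenic gaps must accommodate whole elements)."""
    full = ElementTemplate(family="TyS1", total_length=3000,
                           orf1_aa=300, orf2_aa=350)
    solo = ElementTemplate(family="LTRs1", solo=True, ltr_length=244)
    return [
        TEPlanEntry("TyS1", full, 2, "ancestral"),
        TEPlanEntry("LTRs1", solo, 6, "ancestral"),
        TEPlanEntry("TyS1", full, 2, "lineage-B", "parent2-blocks"),
        TEPlanEntry("LTRs1", solo, 8, "lineage-B", "parent2-blocks"),
        TEPlanEntry("LTRs1", solo, 2, "lineage-A"),
    ]


def default_config(seed: int = 0) -> SimulationConfig:
    return SimulationConfig(seed=seed, te_plan=default_te_plan())


# ---------------------------------------------------------------------------
# truth records


@dataclass
class PlantedTE:
    te_id: str
    family: str
    inheritance: str
    placement: str
    ltr_length: int | None
    tsd: str
    tsd_offset: int
    pbs_offset: int | None
    pbs_length: int | None
    ppt_length: int | None
    orf_spacer: int | None
    spacer_stops: int | None
    classification: str  # full-length | solo-LTR
    # intervals per strain (None when absent), 0-based half-open
    interval_a: tuple[str, int, int] | None = None
    interval_b: tuple[str, int, int] | None = None


@dataclass
class SyntheticTruth:
    config_seed: int
    tes: list[PlantedTE] = field(default_factory=list)
    parent2_blocks: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    substitutions_b: dict[str, list[int]] = field(default_factory=dict)
    sub_counts_by_class: dict[str, int] = field(default_factory=dict)
    class_lengths: dict[str, int] = field(default_factory=dict)
    trna_end: str = DEFAULT_TRNA_END

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(asdict(self), indent=1, sort_keys=True) + "\n"
        )


# ---------------------------------------------------------------------------
# sequence construction


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(BASES[rng.choice(4, size=n, p=p)])


def _pad(start_pos: int, length: int, sense_frame: int) -> str:
    """Padding whose codons in ``sense_frame`` are sense while both other
    frames hit a stop every 9 bp."""
    return "".join(
        _PAD_UNIT[(start_pos + i - sense_frame) % 9] for i in range(length)
    )


def _pad_with_stops(start_pos: int, length: int, sense_frame: int) -> str:
    """Like :func:`_pad` but with a stop every 10th ``sense_frame`` codon,
    so a pad can never host an open reading frame in any frame."""
    s = list(_pad(start_pos, length, sense_frame))
    first = (sense_frame - start_pos) % 3
    ci = 0
    for off in range(first, length - 2, 3):
        if ci % 10 == 0:
            s[off : off + 3] = "TAA"
        ci += 1
    return "".join(s)


def _build_ltr(template: ElementTemplate, rng: np.random.Generator) -> str:
    """One LTR: canonical TG...CA termini with a TGTAAG/CTTACA hexamer pair,
    a stop block at the interior midpoint, random interior elsewhere."""
    n = template.ltr_length
    interior_len = n - 12
    interior = list(_random_dna(rng, interior_len, 0.5))
    mid = interior_len // 2
    for i, ch in enumerate(_STOP_BLOCK):
        if mid + i < interior_len:
            interior[mid + i] = ch
    ltr = list("TGTAAG" + "".join(interior) + "CTTACA")
    # keep the terminal inverted repeat at exactly 6 bp: position 6 must not
    # pair with the 7th-from-last base (setting them equal guarantees this)
    ltr[6] = ltr[n - 7]
    return "".join(ltr)


def build_element(
    template: ElementTemplate, rng: np.random.Generator
) -> tuple[str, dict]:
    """Construct one element sequence from its anatomy template.

    Returns the sequence (LTR start to LTR end; the TSD is added at planting
    time) and a dict of the planted anatomy facts.
    """
    ltr = _build_ltr(template, rng)
    if template.solo:
        return ltr, {
            "ltr_length": template.ltr_length,
            "pbs_offset": None,
            "pbs_length": None,
            "ppt_length": None,
            "orf_spacer": None,
            "spacer_stops": None,
            "classification": "solo-LTR",
        }
    t = template
    pbs = revcomp(t.trna_end[-t.pbs_length :])
    orf1_len = 3 * t.orf1_aa + 3  # includes terminating stop
    orf2_len = 3 * t.orf2_aa + 3
    internal_len = t.total_length - 2 * t.ltr_length
    fixed = t.pbs_offset + t.pbs_length + orf1_len + t.spacer_length + orf2_len + len(t.ppt)
    pad_total = internal_len - fixed - 3  # 3 bp for the stop before ORF1
    if pad_total < 60:
        raise ValueError("template too short for its ORF layout")
    pad_a = pad_total // 2
    pad_b = pad_total - pad_a
    # the two offset bases before the PBS are set to the tRNA terminal base,
    # which can never pair with itself, so the PBS match cannot shift closer
    off = t.trna_end[-1] * t.pbs_offset

    def sense(n_codons: int) -> str:
        idx = rng.integers(0, len(_SENSE_CODONS), size=n_codons)
        return "".join(_SENSE_CODONS[i] for i in idx)

    pos = t.ltr_length + t.pbs_offset + t.pbs_length  # element coord of pad A
    orf1_start = pos + pad_a + 3
    f1 = orf1_start % 3
    pad_a_seq = _pad_with_stops(pos, pad_a, f1) + "TAA"  # stop just before ORF1
    orf1 = sense(t.orf1_aa) + "TAA"
    # spacer: frame-f1 codons; 4 stop codons, the last one immediately
    # before ORF2 so the downstream maximal ORF starts exactly at the
    # spacer end
    n_cod = t.spacer_length // 3
    stop_slots = set(
        np.linspace(2, n_cod - 1, num=t.spacer_stops, dtype=int).tolist()
    )
    spacer_start = orf1_start + orf1_len
    spacer_codons = []
    for ci in range(n_cod):
        if ci in stop_slots:
            spacer_codons.append("TAA")
        else:
            p0 = spacer_start + 3 * ci
            spacer_codons.append(_pad(p0, 3, f1))
    spacer = "".join(spacer_codons)
    orf2 = sense(t.orf2_aa) + "TAA"
    pos_b = spacer_start + t.spacer_length + orf2_len
    pad_b_seq = list(_pad_with_stops(pos_b, pad_b, f1))
    if pad_b_seq and pad_b_seq[-1] in "AG":
        pad_b_seq[-1] = "C"  # keep the polypurine run from extending left
    internal = (
        off + pbs + pad_a_seq + orf1 + spacer + orf2 + "".join(pad_b_seq) + t.ppt
    )
    assert len(internal) == internal_len, (len(internal), internal_len)
    seq = ltr + internal + ltr
    return seq, {
        "ltr_length": t.ltr_length,
        "pbs_offset": t.pbs_offset,
        "pbs_length": t.pbs_length,
        "ppt_length": len(t.ppt),
        "orf_spacer": t.spacer_length,
        "spacer_stops": t.spacer_stops,
        "classification": "full-length",
    }


# ---------------------------------------------------------------------------
# ancestor generation


def generate_ancestor(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[GenomeAssembly, list[FeatureRecord]]:
    """Random ancestor genome with non-overlapping gene and tDNA features."""
    rng = rng or np.random.default_rng(config.seed)
    chroms: dict[str, str] = {}
    features: list[FeatureRecord] = []
    for ci, length in enumerate(config.chromosome_lengths):
        chrom = f"chr{chr(ord('A') + ci)}"
        chroms[chrom] = _random_dna(rng, length, config.gc_content)
        n_genes = int(round(config.gene_density * length))
        n_tdna = int(round(config.tdna_density * length))
        lengths = [
            int(np.clip(rng.normal(config.gene_length_mean, config.gene_length_sd),
                        400, 3000))
            for _ in range(n_genes)
        ] + [config.tdna_length] * n_tdna
        kinds = ["gene"] * n_genes + ["tDNA"] * n_tdna
        if sum(lengths) + 200 * len(lengths) > 0.95 * length:
            raise ValueError(
                f"feature density infeasible for chromosome length {length}"
            )
        placed: list[tuple[int, int]] = []
        for j, (flen, kind) in enumerate(zip(lengths, kinds)):
            ok = False
            for _ in range(200):
                start = int(rng.integers(100, length - flen - 100))
                if not any(
                    start < e + 100 and start + flen > s - 100 for s, e in placed
                ):
                    placed.append((start, start + flen))
                    strand = "+" if rng.random() < 0.5 else "-"
                    features.append(
                        FeatureRecord(
                            chrom=chrom,
                            start=start,
                            end=start + flen,
                            strand=strand,
                            kind=kind,
                            id=f"{chrom}_{kind}_{j:04d}",
                        )
                    )
                    ok = True
                    break
            if not ok:
                raise ValueError(
                    f"feature density infeasible for chromosome length {length}"
                )
    features.sort(key=lambda f: (f.chrom, f.start, f.id))
    return GenomeAssembly(name="ancestor", chromosomes=chroms), features


# ---------------------------------------------------------------------------
# planting


def _intergenic_intervals(
    features: Sequence[FeatureRecord], chrom: str, chrom_len: int, margin: int
) -> list[tuple[int, int]]:
    ivals = sorted(
        (f.start, f.end) for f in features if f.chrom == chrom
    )
    out: list[tuple[int, int]] = []
    cursor = margin
    for s, e in ivals:
        if s - margin > cursor:
            out.append((cursor, s - margin))
        cursor = max(cursor, e + margin)
    if chrom_len - margin > cursor:
        out.append((cursor, chrom_len - margin))
    return out


def _complement_intervals(
    ivals: Sequence[tuple[int, int]], length: int
) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    cursor = 0
    for s, e in sorted(ivals):
        if s > cursor:
            out.append((cursor, s))
        cursor = max(cursor, e)
    if cursor < length:
        out.append((cursor, length))
    return out


def plant_element(
    seq: str,
    features: list[FeatureRecord],
    chrom: str,
    element_seq: str,
    position: int,
    tsd_length: int,
    tsd_offset: int = 0,
    te_id: str = "te",
    family: str = "TE",
) -> tuple[str, list[FeatureRecord], dict]:
    """Insert an element at ``position``, duplicating ``tsd_length`` target
    bases on both sides of the insertion.

    The target word ``S = seq[position : position + tsd_length]`` ends up
    once upstream of the element (followed by ``tsd_offset`` copies of its
    last base, the offset filler) and once downstream, so excising the
    element, the filler and one copy restores the original sequence exactly.
    Downstream feature coordinates are shifted; features spanning the
    insertion point are extended.  Returns (new sequence, shifted features +
    the new TE feature, truth dict).
    """
    if not (0 <= position <= len(seq) - tsd_length):
        raise ValueError("position out of range")
    tsd = seq[position : position + tsd_length]
    filler = (tsd[-1] * tsd_offset) if tsd_length else ""
    new_seq = (
        seq[:position] + tsd + filler + element_seq + seq[position:]
    )
    shift = tsd_length + len(filler) + len(element_seq)
    el_start = position + tsd_length + len(filler)
    el_end = el_start + len(element_seq)
    out_features: list[FeatureRecord] = []
    for f in features:
        if f.chrom != chrom or f.end <= position:
            out_features.append(f)
        elif f.start >= position:
            out_features.append(
                FeatureRecord(f.chrom, f.start + shift, f.end + shift, f.strand,
                              f.kind, f.id, f.family)
            )
        else:  # spans the insertion point
            out_features.append(
                FeatureRecord(f.chrom, f.start, f.end + shift, f.strand,
                              f.kind, f.id, f.family)
            )
    out_features.append(
        FeatureRecord(chrom, el_start, el_end, "+", "TE", te_id, family)
    )
    out_features.sort(key=lambda f: (f.chrom, f.start, f.id))
    truth = {
        "te_id": te_id,
        "family": family,
        "chrom": chrom,
        "start": el_start,
        "end": el_end,
        "tsd": tsd,
        "tsd_offset": tsd_offset,
    }
    return new_seq, out_features, truth


def _tsd_roundtrips(
    seq: str, el_start: int, el_end: int, tsd_length: int, tsd_offset: int
) -> bool:
    """True when the TSD detector recovers exactly the planted length and
    offset at this site (the surrounding sequence can otherwise extend the
    duplication by chance)."""
    up = seq[max(0, el_start - 20) : el_start]
    down = seq[el_end : el_end + 20]
    if len(up) < 13 or len(down) < 12:
        return False
    res = detect_tsd(up, down)
    return (
        res is not None
        and res.length == tsd_length
        and res.offset == tsd_offset
    )


# ---------------------------------------------------------------------------
# mutation with coordinate tracking


class CoordMap:
    """Maps pre-indel coordinates to post-indel coordinates."""

    def __init__(self, edits: list[tuple[int, int]]):
        # edits: (old position, signed length); insertions shift everything
        # at or beyond the position, deletions remove [pos, pos - length)
        self.edits = sorted(edits)

    def map(self, pos: int) -> int:
        delta = 0
        for p, d in self.edits:
            if p >= pos:
                break
            if d > 0:
                delta += d
            else:
                dele = min(-d, pos - p)
                delta -= dele
        return pos + delta

    def map_interval(self, start: int, end: int) -> tuple[int, int]:
        return self.map(start), self.map(end)


def mutate_sequence(
    seq: str,
    rng: np.random.Generator,
    sub_rate: np.ndarray,
    indel_rate: np.ndarray,
    indel_mean: float,
    indel_max: int,
    gc: float,
) -> tuple[str, CoordMap, list[int]]:
    """Apply substitutions and indels with per-position rates.

    ``sub_rate``/``indel_rate`` are per-bp arrays over the input sequence.
    Substitutions are applied first (in place), then indel events; returns
    the mutated sequence, the coordinate map and the substitution positions.
    """
    n = len(seq)
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    sub_pos = np.nonzero(rng.random(n) < sub_rate)[0]
    for p in sub_pos:
        cur = arr[p].decode()
        if cur == "N":
            continue
        alts = [b for b in "ACGT" if b != cur]
        arr[p] = alts[rng.integers(0, 3)].encode()
    mutated = arr.tobytes().decode()
    ind_pos = np.nonzero(rng.random(n) < indel_rate)[0]
    edits: list[tuple[int, int]] = []
    pieces: list[str] = []
    cursor = 0
    geo_p = 1.0 / max(indel_mean, 1.0)
    for p in ind_pos:
        p = int(p)
        if p < cursor:
            continue
        length = int(min(rng.geometric(geo_p), indel_max))
        if rng.random() < 0.5:  # insertion
            pieces.append(mutated[cursor:p])
            pieces.append(_random_dna(rng, length, gc))
            cursor = p
            edits.append((p, length))
        else:  # deletion
            length = min(length, n - p)
            pieces.append(mutated[cursor:p])
            cursor = p + length
            edits.append((p, -length))
    pieces.append(mutated[cursor:])
    return "".join(pieces), CoordMap(edits), [int(p) for p in sub_pos]


def _rate_arrays(
    n: int,
    features: Sequence[FeatureRecord],
    chrom: str,
    config: SimulationConfig,
    blocks: Sequence[tuple[int, int]],
    protected: Sequence[tuple[int, int]],
) -> tuple[np.ndarray, np.ndarray]:
    sub = np.full(n, config.sub_rate_intergenic)
    ind = np.full(n, config.indel_rate_intergenic)
    for f in features:
        if f.chrom == chrom and f.kind in ("gene", "tDNA"):
            sub[f.start : f.end] = config.sub_rate_genic
            ind[f.start : f.end] = config.indel_rate_genic
    for s, e in blocks:
        sub[s:e] *= config.parent2_extra_divergence
        ind[s:e] *= config.parent2_extra_divergence
    for s, e in protected:
        sub[s:e] = 0.0
        ind[s:e] = 0.0
    return sub, ind


def _draw_blocks(
    chrom_len: int, config: SimulationConfig, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Alternating-renewal mosaic: parent-2 blocks with exponential lengths
    at the configured mean, separated by gaps sized to hit the target
    genome fraction."""
    f = config.parent2_block_fraction
    if f <= 0:
        return []
    if f >= 1:
        return [(0, chrom_len)]
    mean_block = config.parent2_block_mean_length
    mean_gap = mean_block * (1 - f) / f
    blocks: list[tuple[int, int]] = []
    # stationary alternating renewal: start inside a block with probability f
    in_block = bool(rng.random() < f)
    pos = 0.0
    while pos < chrom_len:
        if in_block:
            end = min(float(chrom_len), pos + rng.exponential(mean_block))
            if end - pos >= 1:
                blocks.append((int(pos), int(end)))
            pos = end
        else:
            pos += rng.exponential(mean_gap)
        in_block = not in_block
    return blocks


# ---------------------------------------------------------------------------
# the two-strain simulation


def _plant_plan_entries(
    genome: dict[str, str],
    features: list[FeatureRecord],
    entries: Sequence[tuple[TEPlanEntry, int]],
    config: SimulationConfig,
    rng: np.random.Generator,
    allowed: dict[str, list[tuple[int, int]]] | None = None,
    shift_tracks: list[dict[str, list[tuple[int, int]]]] | None = None,
    family_cache: dict | None = None,
) -> tuple[dict[str, str], list[FeatureRecord], list[dict]]:
    """Plant a batch of plan entries into a strain's chromosomes.

    ``allowed`` optionally restricts candidate positions per chromosome
    (e.g. to parent-2 blocks); positions are re-drawn until the planted TSD
    round-trips through the detector, so the truth labels are exact.
    Interval dicts in ``shift_tracks`` (including ``allowed`` itself when
    listed) are kept in genomic register as insertions accumulate.
    """
    truths: list[dict] = []
    chrom_names = list(genome)
    # one master sequence per family (copies of a family are identical at
    # planting time, like recent insertions of one element lineage)
    if family_cache is None:
        family_cache = {}
    for entry, index in entries:
        te_id = f"{entry.family}_{entry.inheritance}_{index:03d}"
        cache_key = (entry.family, entry.template.solo)
        if cache_key not in family_cache:
            family_cache[cache_key] = build_element(entry.template, rng)
        element_seq, anatomy = family_cache[cache_key]
        placed = False
        for _attempt in range(300):
            chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
            chrom_len = len(genome[chrom])
            if entry.placement == "rnap3-targeted":
                tdnas = [
                    f for f in features if f.chrom == chrom and f.kind == "tDNA"
                ]
                if not tdnas:
                    continue
                g = tdnas[int(rng.integers(0, len(tdnas)))]
                gap = int(rng.integers(15, 18))
                if g.strand == "-":
                    position = (
                        g.end + gap - entry.template.tsd_length
                        - entry.template.tsd_offset - 1
                    )
                else:
                    position = g.start - gap
                if not (
                    config.placement_margin
                    <= position
                    < chrom_len - config.placement_margin
                ):
                    continue
            else:
                ivals = _intergenic_intervals(
                    features, chrom, chrom_len, config.placement_margin
                )
                if entry.placement == "parent2-blocks" and (
                    allowed is None or not any(allowed.values())
                ):
                    raise ValueError(
                        "parent2-blocks placement requires parent-2 blocks"
                    )
                if allowed is not None:
                    regions = allowed.get(chrom, [])
                    if not regions:
                        continue
                    ivals = [
                        (max(s, bs), min(e, be))
                        for s, e in ivals
                        for bs, be in regions
                        if min(e, be) - max(s, bs) > 0
                    ]
                room = len(element_seq) + 2 * entry.template.tsd_length + 10
                ivals = [(s, e) for s, e in ivals if e - s > room]
                if not ivals:
                    continue
                widths = np.array([e - s for s, e in ivals], dtype=float)
                ci = int(rng.choice(len(ivals), p=widths / widths.sum()))
                s, e = ivals[ci]
                position = int(rng.integers(s, e - room))
            new_seq, new_features, truth = plant_element(
                genome[chrom],
                features,
                chrom,
                element_seq,
                position,
                entry.template.tsd_length,
                entry.template.tsd_offset,
                te_id=te_id,
                family=entry.family,
            )
            if entry.template.tsd_length and not _tsd_roundtrips(
                new_seq,
                truth["start"],
                truth["end"],
                entry.template.tsd_length,
                entry.template.tsd_offset,
            ):
                continue
            genome = dict(genome)
            genome[chrom] = new_seq
            features = new_features
            ins_len = truth["end"] - position
            for track in shift_tracks or ():
                track[chrom] = [
                    (
                        s + ins_len if s >= position else s,
                        e + ins_len if e > position else e,
                    )
                    for s, e in track.get(chrom, [])
                ]
            truth.update(anatomy)
            truth.update(
                inheritance=entry.inheritance, placement=entry.placement
            )
            truths.append(truth)
            placed = True
            break
        if not placed:
            raise ValueError(
                f"could not place element {te_id} under placement rule "
                f"{entry.placement!r}"
            )
    return genome, features, truths


def _shift_intervals(
    ivals: Sequence[tuple[int, int]], cmap: CoordMap
) -> list[tuple[int, int]]:
    return [cmap.map_interval(s, e) for s, e in ivals]


def simulate_hybrid_strains(
    config: SimulationConfig,
) -> tuple[
    GenomeAssembly,
    GenomeAssembly,
    list[FeatureRecord],
    list[FeatureRecord],
    SyntheticTruth,
]:
    """Generate strain A and strain B from a common ancestor.

    Strain A is the ancestor plus lineage-A elements.  Strain B carries the
    configured substitution/indel divergence (amplified inside parent-2
    blocks), plus lineage-B elements placed per their placement rule.
    Ancestral elements are planted before the split and appear in both
    strains at allelic positions.  The returned truth records every planted
    fact in final per-strain coordinates.
    """
    rng = np.random.default_rng(config.seed)
    ancestor, anc_features = generate_ancestor(config, rng)
    genome = dict(ancestor.chromosomes)
    features = list(anc_features)

    plan_by_label: dict[str, list[tuple[TEPlanEntry, int]]] = {
        "ancestral": [],
        "lineage-A": [],
        "lineage-B": [],
    }
    counter = 0
    for entry in config.te_plan:
        for _ in range(entry.count):
            plan_by_label[entry.inheritance].append((entry, counter))
            counter += 1
    for entry, _ in plan_by_label["lineage-B"]:
        if entry.placement == "parent2-blocks" and config.parent2_block_fraction <= 0:
            raise ValueError(
                "parent2-blocks placement requested with block fraction 0"
            )

    # parent-2 blocks are drawn on ancestor coordinates before any planting;
    # ancestral (allelic) elements are confined to parent-1-derived sequence
    # — under the chromosomal-inheritance scenario, elements shared by both
    # strains ride the less divergent parental background
    blocks = {c: _draw_blocks(len(genome[c]), config, rng) for c in genome}
    if config.parent2_block_fraction > 0 and not any(blocks.values()):
        # a hybrid with a positive parent-2 fraction carries at least one
        # block; guard against a degenerate renewal draw on small genomes
        chrom = max(genome, key=lambda c: len(genome[c]))
        length = int(
            min(config.parent2_block_mean_length, 0.5 * len(genome[chrom]))
        )
        start = int(rng.integers(0, len(genome[chrom]) - length))
        blocks[chrom] = [(start, start + length)]
    non_block = {
        c: _complement_intervals(blocks[c], len(genome[c])) for c in genome
    }
    family_cache: dict = {}
    genome, features, anc_truths = _plant_plan_entries(
        genome,
        features,
        plan_by_label["ancestral"],
        config,
        rng,
        allowed=non_block if any(blocks.values()) else None,
        shift_tracks=[blocks, non_block],
        family_cache=family_cache,
    )

    # ---- strain A: ancestor (+ planted ancestral TEs) + lineage-A TEs
    genome_a, features_a, a_truths = _plant_plan_entries(
        dict(genome), list(features), plan_by_label["lineage-A"], config, rng,
        family_cache=family_cache,
    )

    # ---- strain B: parent-2 mosaic divergence, then lineage-B TEs
    te_bodies = {
        c: [
            (t["start"], t["end"])
            for t in anc_truths
            if t["chrom"] == c
        ]
        for c in genome
    }
    genome_b: dict[str, str] = {}
    features_b: list[FeatureRecord] = []
    cmaps: dict[str, CoordMap] = {}
    subs_b: dict[str, list[int]] = {}
    sub_counts = {"genic": 0, "intergenic": 0}
    class_lengths = {"genic": 0, "intergenic": 0}
    for chrom, seq in genome.items():
        sub, ind = _rate_arrays(
            len(seq), features, chrom, config, blocks[chrom], te_bodies[chrom]
        )
        mutated, cmap, sub_pos = mutate_sequence(
            seq, rng, sub, ind, config.indel_mean_length,
            config.indel_max_length, config.gc_content,
        )
        genome_b[chrom] = mutated
        cmaps[chrom] = cmap
        subs_b[chrom] = sub_pos
        genic_mask = np.zeros(len(seq), dtype=bool)
        for f in features:
            if f.chrom == chrom and f.kind in ("gene", "tDNA"):
                genic_mask[f.start : f.end] = True
        sub_arr = np.array(sub_pos, dtype=int)
        if len(sub_arr):
            sub_counts["genic"] += int(genic_mask[sub_arr].sum())
            sub_counts["intergenic"] += int((~genic_mask[sub_arr]).sum())
        class_lengths["genic"] += int(genic_mask.sum())
        class_lengths["intergenic"] += int((~genic_mask).sum())
    for f in features:
        s, e = cmaps[f.chrom].map_interval(f.start, f.end)
        if e > s:
            features_b.append(
                FeatureRecord(f.chrom, s, e, f.strand, f.kind, f.id, f.family)
            )
    blocks_b = {
        c: _shift_intervals(blocks[c], cmaps[c]) for c in genome
    }
    genome_b, features_b, b_truths = _plant_plan_entries(
        genome_b,
        features_b,
        plan_by_label["lineage-B"],
        config,
        rng,
        allowed=blocks_b,
        shift_tracks=[blocks_b],
        family_cache=family_cache,
    )

    # ---- assemble the truth
    feat_a = {f.id: f for f in features_a}
    feat_b = {f.id: f for f in features_b}
    tes: list[PlantedTE] = []
    for t in anc_truths + a_truths + b_truths:
        fa = feat_a.get(t["te_id"])
        fb = feat_b.get(t["te_id"])
        tes.append(
            PlantedTE(
                te_id=t["te_id"],
                family=t["family"],
                inheritance=t["inheritance"],
                placement=t["placement"],
                ltr_length=t["ltr_length"],
                tsd=t["tsd"],
                tsd_offset=t["tsd_offset"],
                pbs_offset=t["pbs_offset"],
                pbs_length=t["pbs_length"],
                ppt_length=t["ppt_length"],
                orf_spacer=t["orf_spacer"],
                spacer_stops=t["spacer_stops"],
                classification=t["classification"],
                interval_a=(fa.chrom, fa.start, fa.end) if fa else None,
                interval_b=(fb.chrom, fb.start, fb.end) if fb else None,
            )
        )
    truth = SyntheticTruth(
        config_seed=config.seed,
        tes=tes,
        parent2_blocks=blocks_b,
        substitutions_b=subs_b,
        sub_counts_by_class=sub_counts,
        class_lengths=class_lengths,
    )
    strain_a = GenomeAssembly(name="strainA", chromosomes=genome_a)
    strain_b = GenomeAssembly(name="strainB", chromosomes=genome_b)
    return strain_a, strain_b, features_a, features_b, truth


# ---------------------------------------------------------------------------
# config (de)serialisation and output


def config_to_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["chromosome_lengths"] = list(config.chromosome_lengths)
    d["te_plan"] = [
        {
            "family": e.family,
            "count": e.count,
            "inheritance": e.inheritance,
            "placement": e.placement,
            "template": asdict(e.template),
        }
        for e in config.te_plan
    ]
    return d


def config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    valid = set(SimulationConfig.__dataclass_fields__)
    for key in d:
        if key not in valid:
            raise ValueError(f"unknown config key: {key!r}")
    plan = []
    for e in d.pop("te_plan", []):
        tmpl = ElementTemplate(**e["template"])
        plan.append(
            TEPlanEntry(
                family=e["family"],
                template=tmpl,
                count=e["count"],
                inheritance=e["inheritance"],
                placement=e.get("placement", "uniform-intergenic"),
            )
        )
    if "chromosome_lengths" in d:
        d["chromosome_lengths"] = tuple(d["chromosome_lengths"])
    return SimulationConfig(te_plan=plan, **d)


def load_config(path: str | Path) -> SimulationConfig:
    with Path(path).open() as fh:
        return config_from_dict(yaml.safe_load(fh))


def save_config(config: SimulationConfig, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=True)


def write_outputs(
    out_dir: str | Path,
    strain_a: GenomeAssembly,
    strain_b: GenomeAssembly,
    features_a: Sequence[FeatureRecord],
    features_b: Sequence[FeatureRecord],
    truth: SyntheticTruth,
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(strain_a, out / "strainA.fasta")
    write_fasta(strain_b, out / "strainB.fasta")
    write_gff3(features_a, out / "strainA.gff3")
    write_gff3(features_b, out / "strainB.gff3")
    truth.to_json(out / "truth.json")
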