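"""Genome and annotation I/O, plus in-silico nicking-enzyme digest utilities.

All internal coordinates are 0-based half-open; GFF3 (1-based inclusive) is
converted at the boundary.  Sequences are uppercase DNA over ``{A,C,G,T,N}``;
``U`` is mapped to ``T`` on input.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from gffutils.feature import feature_from_line

VALID_BASES = frozenset("ACGTN")

#: Recognition sequence of the Nt.BspQI nicking endonuclease.
NT_BSPQI_MOTIF = "GCTCTTC"

#: Mapping from GFF3 ``type`` column values to the internal feature kinds.
GFF3_KIND_MAP = {
    "gene": "gene",
    "mRNA": "gene",
    "CDS": "gene",
    "pseudogene": "gene",
    "tRNA": "tDNA",
    "tRNA_gene": "tDNA",
    "tDNA": "tDNA",
    "rRNA_5S": "rDNA5S",
    "5S_rRNA": "rDNA5S",
    "ncRNA": "ncRNA",
    "snRNA": "ncRNA",
    "snoRNA": "ncRNA",
    "RNase_P_RNA": "ncRNA",
    "SRP_RNA": "ncRNA",
    "transposable_element": "TE",
    "mobile_genetic_element": "TE",
    "mobile_element": "TE",
    "repeat_region": "TE",
    "LTR_retrotransposon": "TE",
    "long_terminal_repeat": "TE",
    "solo_LTR": "TE",
    "region": "other",
}

_KIND_TO_GFF3 = {
    "gene": "gene",
    "tDNA": "tRNA",
    "rDNA5S": "rRNA_5S",
    "ncRNA": "ncRNA",
    "TE": "transposable_element",
    "other": "region",
}

FEATURE_KINDS = frozenset(_KIND_TO_GFF3)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string (N self-complementary)."""
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeIOError(ValueError):
    """Raised for malformed FASTA/GFF3 input."""


@dataclass
class GenomeAssembly:
    """A named set of chromosome sequences.

    ``chromosomes`` is an ordered mapping chromosome-id -> uppercase DNA
    string over ``{A,C,G,T,N}``.
    """

    name: str
    chromosomes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cid, seq in self.chromosomes.items():
            if not seq:
                raise GenomeIOError(f"chromosome {cid!r} is empty")
            bad = set(seq) - VALID_BASES
            if bad:
                raise GenomeIOError(
                    f"chromosome {cid!r} contains invalid characters {sorted(bad)}"
                )

    def __len__(self) -> int:
        return len(self.chromosomes)

    def length_of(self, chrom: str) -> int:
        return len(self.chromosomes[chrom])

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.chromosomes.values())


@dataclass(frozen=True)
class FeatureRecord:
    """One annotated genomic feature in 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    strand: str
    kind: str
    id: str
    family: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise GenomeIOError(
                f"feature {self.id!r}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in {"+", "-", "."}:
            raise GenomeIOError(f"feature {self.id!r}: invalid strand {self.strand!r}")
        if self.kind not in FEATURE_KINDS:
            raise GenomeIOError(f"feature {self.id!r}: unknown kind {self.kind!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class NickSiteMap:
    """Positions of a nicking-enzyme recognition motif on one chromosome.

    ``sites`` are ascending 0-based start positions of motif occurrences on
    either strand; ``strands`` gives the strand per site.  Nicking enzymes cut
    a single strand, so occurrences on the two strands are kept separate.
    """

    chrom: str
    motif: str
    sites: list[int] = field(default_factory=list)
    strands: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sites)

    def merged_positions(self, min_distance: int = 0) -> list[int]:
        """Strand-merged site list, optionally collapsing sites closer than
        ``min_distance`` bp (near-adjacent opposite-strand nicks appear as one
        label on an optical map)."""
        if min_distance <= 0:
            return list(self.sites)
        merged: list[int] = []
        for p in self.sites:
            if merged and p - merged[-1] < min_distance:
                continue
            merged.append(p)
        return merged


def _normalise_sequence(raw: str, header: str) -> str:
    seq = raw.upper().replace("U", "T")
    for pos, ch in enumerate(seq):
        if ch not in VALID_BASES:
            raise GenomeIOError(
                f"record {header!r}: invalid character {ch!r} at position {pos}"
            )
    return seq


def read_fasta(path: str | Path, name: str | None = None) -> GenomeAssembly:
    """Read a multi-FASTA file into a :class:`GenomeAssembly`.

    Sequences are uppercased, ``U`` is mapped to ``T``; characters outside
    ``{A,C,G,T,N}`` and duplicate or empty records are rejected.
    """
    path = Path(path)
    chroms: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in chroms:
            raise GenomeIOError(f"duplicate FASTA header {rec.id!r} in {path}")
        seq = _normalise_sequence(str(rec.seq), rec.id)
        if not seq:
            raise GenomeIOError(f"empty FASTA record {rec.id!r} in {path}")
        chroms[rec.id] = seq
    if not chroms:
        raise GenomeIOError(f"no FASTA records found in {path}")
    return GenomeAssembly(name=name or path.stem, chromosomes=chroms)


def write_fasta(genome: GenomeAssembly, path: str | Path, width: int = 70) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for cid, seq in genome.chromosomes.items():
            fh.write(f">{cid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_gff3(path: str | Path, genome: GenomeAssembly) -> list[FeatureRecord]:
    """Read GFF3 features, converting to 0-based half-open coordinates.

    The GFF3 ``type`` column is mapped to the internal kind vocabulary via
    :data:`GFF3_KIND_MAP` (unknown types become ``other``).  Features on
    chromosomes absent from ``genome`` or with ``end < start`` are rejected.
    """
    path = Path(path)
    records: list[FeatureRecord] = []
    seen_ids: set[str] = set()
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            feat = feature_from_line(line)
            if feat.seqid not in genome.chromosomes:
                raise GenomeIOError(
                    f"{path}:{lineno}: unknown chromosome {feat.seqid!r}"
                )
            if feat.end < feat.start:
                raise GenomeIOError(f"{path}:{lineno}: end < start")
            start0, end0 = feat.start - 1, feat.end
            if end0 > genome.length_of(feat.seqid):
                raise GenomeIOError(
                    f"{path}:{lineno}: feature extends past chromosome end"
                )
            fid = feat.attributes.get("ID", [None])[0]
            if fid is None:
                fid = f"{path.stem}_{lineno}"
            if fid in seen_ids:
                fid = f"{fid}_{lineno}"
            seen_ids.add(fid)
            family = feat.attributes.get("family", [None])[0]
            kind = GFF3_KIND_MAP.get(feat.featuretype, "other")
            records.append(
                FeatureRecord(
                    chrom=feat.seqid,
                    start=start0,
                    end=end0,
                    strand=feat.strand if feat.strand in "+-" else ".",
                    kind=kind,
                    id=fid,
                    family=family,
                )
            )
    return records


def write_gff3(
    features: Iterable[FeatureRecord], path: str | Path, source: str = "tetrace"
) -> None:
    """Write features as GFF3 (1-based inclusive); round-trips coordinates."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = f"ID={f.id}"
            if f.family:
                attrs += f";family={f.family}"
            gtype = _KIND_TO_GFF3[f.kind]
            fh.write(
                f"{f.chrom}\t{source}\t{gtype}\t{f.start + 1}\t{f.end}\t.\t"
                f"{f.strand}\t.\t{attrs}\n"
            )


def virtual_nick_digest(
    sequence: str, motif: str = NT_BSPQI_MOTIF, chrom: str = "seq"
) -> NickSiteMap:
    """In-silico single-strand nickase digest: every occurrence of ``motif``
    and of its reverse complement, with strand, overlapping matches included.

    N bases never match the motif (exact matching only), so assembly gaps
    produce no spurious sites.
    """
    if len(motif) < 4:
        raise ValueError("motif length must be >= 4")
    motif = motif.upper()
    hits: list[tuple[int, str]] = []
    for strand, m in (("+", motif), ("-", revcomp(motif))):
        pat = re.compile(f"(?={re.escape(m)})")
        hits.extend((mo.start(), strand) for mo in pat.finditer(sequence))
    hits.sort()
    return NickSiteMap(
        chrom=chrom,
        motif=motif,
        sites=[p for p, _ in hits],
        strands=[s for _, s in hits],
    )


def write_bed(sitemap: NickSiteMap, path: str | Path) -> None:
    """Export a nick-site map as 6-column BED (one row per site)."""
    with Path(path).open("w") as fh:
        for i, (pos, strand) in enumerate(zip(sitemap.sites, sitemap.strands)):
            fh.write(
                f"{sitemap.chrom}\t{pos}\t{pos + len(sitemap.motif)}\t"
                f"nick_{i}\t0\t{strand}\n"
            )


def detect_tandem_period(
    sitemap: NickSiteMap,
    window: tuple[int, int] | None = None,
    min_repeats: int = 3,
    rel_tol: float = 0.05,
    min_inter_site_distance: int = 0,
) -> float | None:
    """Estimate the dominant spacing period of a nick-site pattern, in bp.

    Optical-map labels of a tandem array (e.g. an rDNA cluster of ~10-kb
    units) recur with the unit period.  The strand-merged position list is
    folded at every candidate period (each sum of ``k`` consecutive
    inter-site intervals); a period is accepted when it explains at least
    ``min_repeats`` consecutive repeats, i.e. intervals match their k-shifted
    counterparts within ``rel_tol`` relative tolerance.  Returns the mean
    unit length of the best candidate, or ``None``.
    """
    positions = sitemap.merged_positions(min_inter_site_distance)
    if window is not None:
        lo, hi = window
        positions = [p for p in positions if lo <= p < hi]
    if len(positions) < 6:
        return None
    intervals = [b - a for a, b in zip(positions, positions[1:])]
    n = len(intervals)
    best: tuple[int, float] | None = None  # (repeats_explained, period)
    for k in range(1, n // 2 + 1):
        period = sum(intervals[:k])
        if period <= 0:
            continue
        tol = max(2.0, rel_tol * period)
        # count consecutive unit repeats from the start of the array
        ok = all(
            abs(sum(intervals[i : i + k]) - period) <= tol
            and abs(intervals[i + j] - intervals[j]) <= max(2.0, rel_tol * period)
            for i in range(k, n - k + 1, k)
            for j in range(k)
        )
        if not ok:
            continue
        n_units = n // k
        if n_units + 1 < min_repeats:
            continue
        unit_sums = [sum(intervals[i : i + k]) for i in range(0, (n // k) * k, k)]
        mean_period = sum(unit_sums) / len(unit_sums)
        if best is None or n_units > best[0]:
            best = (n_units, mean_period)
        # the smallest valid k is the fundamental period; stop there
        break
    return best[1] if best else None
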