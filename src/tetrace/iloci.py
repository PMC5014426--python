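"""Interval loci: an ordered, exhaustive partition of each chromosome into
feature loci (merged overlapping or abutting annotated features) and the
intergenic gaps between them.

The partition gives every annotated feature and every intergenic region a
stable address, so two assemblies can be compared locus-by-locus and a TE
insertion can be related to its nearest surrounding loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .genomeio import FeatureRecord, GenomeAssembly


@dataclass(frozen=True)
class ILocus:
    id: str
    chrom: str
    start: int
    end: int
    locus_class: str  # "feature" | "intergenic"
    member_feature_ids: tuple[str, ...] = ()

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ILocusSet:
    """Per-chromosome ordered iLocus lists plus an id index."""

    by_chrom: dict[str, list[ILocus]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._index = {
            loc.id: loc for loci in self.by_chrom.values() for loc in loci
        }

    def __iter__(self):
        for loci in self.by_chrom.values():
            yield from loci

    def __len__(self) -> int:
        return sum(len(v) for v in self.by_chrom.values())

    def get(self, locus_id: str) -> ILocus:
        return self._index[locus_id]

    def __contains__(self, locus_id: str) -> bool:
        return locus_id in self._index


@dataclass(frozen=True)
class FlankSet:
    """The nearest iLoci on each side of a TE insertion (nearest first)."""

    te_id: str
    upstream: tuple[str, ...]
    downstream: tuple[str, ...]
    shortfall: bool = False  # fewer than k flanks available on some side
    te_flank: bool = False  # some flank is itself a TE feature iLocus


def build_iloci(
    features: Sequence[FeatureRecord], genome: GenomeAssembly
) -> ILocusSet:
    """Partition every chromosome into feature and intergenic iLoci.

    Overlapping or abutting features merge into one feature iLocus whose
    member list preserves the constituent feature ids; gaps become
    intergenic iLoci; the union of intervals is exactly the chromosome.
    Input feature order never affects the output.
    """
    for f in features:
        if f.chrom not in genome.chromosomes:
            raise ValueError(f"feature {f.id!r} on unknown chromosome {f.chrom!r}")
        if f.end > genome.length_of(f.chrom):
            raise ValueError(f"feature {f.id!r} extends past chromosome end")
    by_chrom: dict[str, list[ILocus]] = {}
    feats_by_chrom: dict[str, list[FeatureRecord]] = {
        c: [] for c in genome.chromosomes
    }
    for f in features:
        feats_by_chrom[f.chrom].append(f)
    for chrom, chrom_len in ((c, genome.length_of(c)) for c in genome.chromosomes):
        feats = sorted(feats_by_chrom[chrom], key=lambda f: (f.start, f.end, f.id))
        merged: list[tuple[int, int, list[str]]] = []
        for f in feats:
            if merged and f.start <= merged[-1][1]:
                s, e, ids = merged[-1]
                merged[-1] = (s, max(e, f.end), ids + [f.id])
            else:
                merged.append((f.start, f.end, [f.id]))
        loci: list[ILocus] = []
        cursor = 0
        counter = 0

        def add(start: int, end: int, cls: str, members: tuple[str, ...]) -> None:
            nonlocal counter
            counter += 1
            loci.append(
                ILocus(
                    id=f"iL_{chrom}_{counter:05d}",
                    chrom=chrom,
                    start=start,
                    end=end,
                    locus_class=cls,
                    member_feature_ids=members,
                )
            )

        for s, e, ids in merged:
            if s > cursor:
                add(cursor, s, "intergenic", ())
            add(s, e, "feature", tuple(ids))
            cursor = e
        if cursor < chrom_len:
            add(cursor, chrom_len, "intergenic", ())
        by_chrom[chrom] = loci
    return ILocusSet(by_chrom=by_chrom)


def flanking_iloci(
    ilocus_set: ILocusSet,
    te_interval: tuple[str, int, int],
    k: int = 2,
    te_id: str = "",
    te_feature_ids: frozenset[str] | None = None,
) -> FlankSet:
    """The nearest ``k`` iLoci on each side of a TE interval.

    iLoci overlapping the TE interval (including any locus fully inside the
    span) are skipped.  Near a chromosome end fewer than ``k`` loci may exist
    on a side; the shortfall is flagged.  Neighbouring TE feature iLoci may
    serve as flanks; when one does, ``te_flank`` is flagged.
    """
    chrom, ts, te = te_interval
    if k < 1:
        raise ValueError("k must be >= 1")
    if chrom not in ilocus_set.by_chrom:
        raise ValueError(f"unknown chromosome {chrom!r}")
    loci = ilocus_set.by_chrom[chrom]
    if not loci or ts < 0 or te > loci[-1].end:
        raise ValueError("TE interval outside the genome")
    upstream = [loc for loc in loci if loc.end <= ts]
    downstream = [loc for loc in loci if loc.start >= te]
    up = tuple(loc.id for loc in reversed(upstream[-k:]))
    down = tuple(loc.id for loc in downstream[:k])
    te_ids = te_feature_ids or frozenset()
    flank_loci = [ilocus_set.get(i) for i in up + down]
    te_flank = any(
        loc.locus_class == "feature"
        and any(fid in te_ids for fid in loc.member_feature_ids)
        for loc in flank_loci
    )
    return FlankSet(
        te_id=te_id,
        upstream=up,
        downstream=down,
        shortfall=len(up) < k or len(down) < k,
        te_flank=te_flank,
    )


def write_iloci_gff3(
    ilocus_set: ILocusSet, path: str | Path, source: str = "tetrace"
) -> None:
    with Path(path).open("w") as fh:
        fh.write("##gff-version 3\n")
        for loc in ilocus_set:
            attrs = f"ID={loc.id};ilocus_class={loc.locus_class}"
            if loc.member_feature_ids:
                attrs += ";members=" + ",".join(loc.member_feature_ids)
            fh.write(
                f"{loc.chrom}\t{source}\tregion\t{loc.start + 1}\t{loc.end}\t.\t"
                f".\t.\t{attrs}\n"
            )


def write_flanksets_tsv(flanksets: Iterable[FlankSet], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("te_id\tupstream\tdownstream\tshortfall\tte_flank\n")
        for fs in flanksets:
            fh.write(
                f"{fs.te_id}\t{','.join(fs.upstream)}\t{','.join(fs.downstream)}\t"
                f"{int(fs.shortfall)}\t{int(fs.te_flank)}\n"
            )
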