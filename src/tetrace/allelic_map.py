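"""Allelic mapping between two assemblies at iLocus resolution.

Loci of strain A and strain B are paired by a two-layered reciprocal
best-hit search over global affine-gap alignments (A loci as queries against
B loci and vice versa, with a shared-k-mer prescreen restricting candidate
partners).  For each allelic pair the mismatch, inserted-base and
deleted-base counts of the alignment are converted to per-kb variant
densities (M, I, D); TE insertions are then classified as allelic (a
same-family element sits in the partner region of strain B) or non-allelic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from Bio import Align

from .genomeio import GenomeAssembly
from .iloci import FlankSet, ILocusSet
from .te_anatomy import ElementAnatomy


@dataclass
class AlignParams:
    """Affine-gap scoring (glocal-aligner-style defaults) and the length cap
    above which alignment switches to anchor chaining."""

    match: int = 1
    mismatch: int = -2
    gap_open: int = -6
    gap_extend: int = -1
    length_cap: int = 50_000
    anchor_k: int = 21

    def aligner(self) -> Align.PairwiseAligner:
        """Glocal-style aligner: both sequences fully consumed, internal
        gaps affine, terminal gaps free on both sides (so a locus embedded
        in a longer partner aligns without penalising the overhang)."""
        aligner = Align.PairwiseAligner(
            mode="global",
            match_score=self.match,
            mismatch_score=self.mismatch,
            # Biopython charges open_gap_score for the first gap base:
            # a length-L gap costs open + L*extend under the usual
            # (gapopen, gapextend) convention.
            open_gap_score=self.gap_open + self.gap_extend,
            extend_gap_score=self.gap_extend,
        )
        try:
            aligner.end_insertion_score = 0.0
            aligner.end_deletion_score = 0.0
        except AttributeError:  # older Biopython attribute names
            aligner.target_end_gap_score = 0.0
            aligner.query_end_gap_score = 0.0
        return aligner

    def strict_aligner(self) -> Align.PairwiseAligner:
        """Fully global aligner (end gaps penalised); used between anchors
        where both segment ends are pinned."""
        return Align.PairwiseAligner(
            mode="global",
            match_score=self.match,
            mismatch_score=self.mismatch,
            open_gap_score=self.gap_open + self.gap_extend,
            extend_gap_score=self.gap_extend,
        )


DEFAULT_PARAMS = AlignParams()


@dataclass
class PairwiseAlignment:
    """A global alignment of two sequences with per-column operations.

    ``ops`` is a string over ``=`` (match), ``X`` (mismatch), ``I`` (base in
    A absent from B) and ``D`` (base in B absent from A); ``aligned_a`` and
    ``aligned_b`` are the gapped sequences, kept so variant counting can
    exclude columns involving N.
    """

    query_id: str
    target_id: str
    ops: str
    aligned_a: str
    aligned_b: str
    score: float
    identity: float
    coverage_a: float
    coverage_b: float


@dataclass(frozen=True)
class VariantCounts:
    mismatches: int
    inserted_bases: int  # present in A, absent in B
    deleted_bases: int  # absent in A, present in B


@dataclass(frozen=True)
class VariantDensity:
    """Mismatch/insertion/deletion densities per kb of strain-A locus."""

    M: float
    I: float
    D: float
    denominator_kb: float


@dataclass(frozen=True)
class AllelicPair:
    ilocus_a_id: str
    ilocus_b_id: str
    identity: float
    coverage_a: float
    coverage_b: float
    aligned_length: int
    reciprocal: bool = True


def _ops_from_biopython(
    aln, seq_a: str, seq_b: str, trim_ends: bool = True
) -> tuple[str, str, str]:
    """Expand a Biopython alignment into per-column ops + gapped strings.

    With ``trim_ends`` (the glocal semantics), terminal overhangs —
    sequence outside the first/last aligned block, which the scoring
    leaves unpenalised — are excluded: they are unaligned sequence, not
    insertions or deletions.
    """
    blocks_a, blocks_b = aln.aligned
    if len(blocks_a) == 0:
        if trim_ends:
            return "", "", ""
        ops = "I" * len(seq_a) + "D" * len(seq_b)
        return ops, seq_a + "-" * len(seq_b), "-" * len(seq_a) + seq_b
    ops: list[str] = []
    ga: list[str] = []
    gb: list[str] = []
    pa = int(blocks_a[0][0]) if trim_ends else 0
    pb = int(blocks_b[0][0]) if trim_ends else 0
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        a0, a1, b0, b1 = int(a0), int(a1), int(b0), int(b1)
        if a0 > pa:
            ops.append("I" * (a0 - pa))
            ga.append(seq_a[pa:a0])
            gb.append("-" * (a0 - pa))
        if b0 > pb:
            ops.append("D" * (b0 - pb))
            ga.append("-" * (b0 - pb))
            gb.append(seq_b[pb:b0])
        for ca, cb in zip(seq_a[a0:a1], seq_b[b0:b1]):
            ops.append("=" if ca == cb else "X")
        ga.append(seq_a[a0:a1])
        gb.append(seq_b[b0:b1])
        pa, pb = a1, b1
    if not trim_ends:
        if pa < len(seq_a):
            ops.append("I" * (len(seq_a) - pa))
            ga.append(seq_a[pa:])
            gb.append("-" * (len(seq_a) - pa))
        if pb < len(seq_b):
            ops.append("D" * (len(seq_b) - pb))
            ga.append("-" * (len(seq_b) - pb))
            gb.append(seq_b[pb:])
    return "".join(ops), "".join(ga), "".join(gb)


def _summarise(
    ops: str, ga: str, gb: str, score: float, na: int, nb: int,
    query_id: str, target_id: str,
) -> PairwiseAlignment:
    matches = ops.count("=")
    mismatches = ops.count("X")
    aligned = matches + mismatches
    identity = matches / aligned if aligned else 0.0
    return PairwiseAlignment(
        query_id=query_id,
        target_id=target_id,
        ops=ops,
        aligned_a=ga,
        aligned_b=gb,
        score=score,
        identity=identity,
        coverage_a=aligned / na if na else 0.0,
        coverage_b=aligned / nb if nb else 0.0,
    )


def align_pair(
    seq_a: str,
    seq_b: str,
    params: AlignParams = DEFAULT_PARAMS,
    query_id: str = "A",
    target_id: str = "B",
) -> PairwiseAlignment:
    """Global affine-gap alignment of two sequences.

    Below ``params.length_cap`` the exact dynamic program is used; longer
    pairs are aligned by chaining unique shared k-mer anchors and aligning
    the gaps between anchors exactly.  Deterministic for fixed inputs.
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    # canonical orientation (shorter/lexically-smaller sequence first) so
    # that align_pair(a, b) and align_pair(b, a) are exact mirrors
    if (len(seq_b), seq_b) < (len(seq_a), seq_a):
        mirrored = align_pair(seq_b, seq_a, params, target_id, query_id)
        swap = str.maketrans("ID", "DI")
        return PairwiseAlignment(
            query_id=query_id,
            target_id=target_id,
            ops=mirrored.ops.translate(swap),
            aligned_a=mirrored.aligned_b,
            aligned_b=mirrored.aligned_a,
            score=mirrored.score,
            identity=mirrored.identity,
            coverage_a=mirrored.coverage_b,
            coverage_b=mirrored.coverage_a,
        )
    if max(len(seq_a), len(seq_b)) <= params.length_cap:
        aln = params.aligner().align(seq_a, seq_b)[0]
        ops, ga, gb = _ops_from_biopython(aln, seq_a, seq_b)
        return _summarise(ops, ga, gb, float(aln.score), len(seq_a), len(seq_b),
                          query_id, target_id)
    return _anchored_align(seq_a, seq_b, params, query_id, target_id)


def _anchored_align(
    seq_a: str, seq_b: str, params: AlignParams, query_id: str, target_id: str
) -> PairwiseAlignment:
    """Chain unique shared k-mers (longest increasing chain), align between
    anchors exactly; used above the exact-DP length cap."""
    k = params.anchor_k

    def unique_kmers(s: str) -> dict[str, int]:
        seen: dict[str, int] = {}
        dup: set[str] = set()
        for i in range(len(s) - k + 1):
            km = s[i : i + k]
            if km in seen:
                dup.add(km)
            else:
                seen[km] = i
        return {km: p for km, p in seen.items() if km not in dup and "N" not in km}

    ka, kb = unique_kmers(seq_a), unique_kmers(seq_b)
    shared = sorted(
        ((ka[km], kb[km]) for km in ka.keys() & kb.keys()), key=lambda t: t[0]
    )
    # longest chain strictly increasing in both coordinates
    import bisect

    tails: list[int] = []
    tails_idx: list[int] = []
    prev = [-1] * len(shared)
    for i, (_, b) in enumerate(shared):
        j = bisect.bisect_left(tails, b)
        if j == len(tails):
            tails.append(b)
            tails_idx.append(i)
        else:
            tails[j] = b
            tails_idx[j] = i
        prev[i] = tails_idx[j - 1] if j > 0 else -1
    chain: list[tuple[int, int]] = []
    i = tails_idx[-1] if tails_idx else -1
    while i >= 0:
        chain.append(shared[i])
        i = prev[i]
    chain.reverse()
    # drop overlapping anchors
    anchors: list[tuple[int, int]] = []
    for a, b in chain:
        if not anchors or (a >= anchors[-1][0] + k and b >= anchors[-1][1] + k):
            anchors.append((a, b))
    ops_parts: list[str] = []
    ga_parts: list[str] = []
    gb_parts: list[str] = []
    score = 0.0
    pa = pb = 0
    segments = [(a, b) for a, b in anchors] + [(len(seq_a), len(seq_b))]
    aligner = params.strict_aligner()
    for a, b in segments:
        sub_a, sub_b = seq_a[pa:a], seq_b[pb:b]
        if sub_a and sub_b:
            aln = aligner.align(sub_a, sub_b)[0]
            ops, ga, gb = _ops_from_biopython(aln, sub_a, sub_b, trim_ends=False)
            score += float(aln.score)
        else:
            ops = "I" * len(sub_a) + "D" * len(sub_b)
            ga = sub_a + "-" * len(sub_b)
            gb = "-" * len(sub_a) + sub_b
            gap = len(sub_a) + len(sub_b)
            if gap:
                score += params.gap_open + params.gap_extend * gap
        ops_parts.append(ops)
        ga_parts.append(ga)
        gb_parts.append(gb)
        if (a, b) != (len(seq_a), len(seq_b)):
            anchor_a = seq_a[a : a + k]
            ops_parts.append("=" * k)
            ga_parts.append(anchor_a)
            gb_parts.append(anchor_a)
            score += params.match * k
            pa, pb = a + k, b + k
    return _summarise(
        "".join(ops_parts), "".join(ga_parts), "".join(gb_parts),
        score, len(seq_a), len(seq_b), query_id, target_id,
    )


def count_variants(alignment: PairwiseAlignment) -> VariantCounts:
    """Count mismatch columns, bases of A unaligned to B (insertions) and
    bases of B unaligned to A (deletions); columns involving N are excluded
    from all three so assembly gaps never inflate variant counts."""
    mm = ins = dele = 0
    for op, ca, cb in zip(alignment.ops, alignment.aligned_a, alignment.aligned_b):
        if ca == "N" or cb == "N":
            continue
        if op == "X":
            mm += 1
        elif op == "I":
            ins += 1
        elif op == "D":
            dele += 1
    return VariantCounts(mismatches=mm, inserted_bases=ins, deleted_bases=dele)


def variant_density(counts: VariantCounts, ilocus_a_length: int) -> VariantDensity:
    """Per-kb densities anchored on the strain-A locus length."""
    if ilocus_a_length <= 0:
        raise ValueError("iLocus length must be positive")
    kb = ilocus_a_length / 1000.0
    return VariantDensity(
        M=counts.mismatches / kb,
        I=counts.inserted_bases / kb,
        D=counts.deleted_bases / kb,
        denominator_kb=kb,
    )


# ---------------------------------------------------------------------------
# reciprocal mapping


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(0, len(seq) - k + 1)}


@dataclass
class ReciprocalMapResult:
    pairs: list[AllelicPair]
    orphans_a: list[str]
    orphans_b: list[str]
    alignments: dict[tuple[str, str], PairwiseAlignment] = field(
        default_factory=dict
    )


def reciprocal_map(
    iloci_a: ILocusSet,
    iloci_b: ILocusSet,
    genome_a: GenomeAssembly,
    genome_b: GenomeAssembly,
    min_identity: float = 0.80,
    min_coverage: float = 0.80,
    params: AlignParams = DEFAULT_PARAMS,
    prescreen_k: int = 15,
    max_candidates: int = 3,
) -> ReciprocalMapResult:
    """Two-layered reciprocal best-hit mapping of iLoci between assemblies.

    Candidate partners are restricted by a shared-k-mer prescreen; each
    candidate pair is aligned once (glocal affine).  A hit is valid when
    identity >= ``min_identity`` and the better-covered side reaches
    ``min_coverage`` (a short locus embedded in a longer partner — e.g. an
    intergenic fragment created by a strain-specific TE insertion — still
    counts).  A reciprocal pair is emitted when each locus is the other's
    best valid hit; remaining loci with a valid best hit are additionally
    paired non-reciprocally (``reciprocal=False``) so their variant
    densities stay available, but they are still listed as orphans.  Best
    hit = highest identity x max-coverage product, ties broken by longer
    alignment, then lexicographic target id.
    """
    seqs_a = {
        loc.id: genome_a.chromosomes[loc.chrom][loc.start : loc.end]
        for loc in iloci_a
    }
    seqs_b = {
        loc.id: genome_b.chromosomes[loc.chrom][loc.start : loc.end]
        for loc in iloci_b
    }
    kmers_b = {lid: _kmer_set(s, prescreen_k) for lid, s in seqs_b.items()}
    # invert: kmer -> B loci
    kmer_index: dict[str, list[str]] = {}
    for lid, ks in kmers_b.items():
        for km in ks:
            kmer_index.setdefault(km, []).append(lid)

    alignments: dict[tuple[str, str], PairwiseAlignment] = {}

    def get_alignment(aid: str, bid: str) -> PairwiseAlignment:
        key = (aid, bid)
        if key not in alignments:
            alignments[key] = align_pair(
                seqs_a[aid], seqs_b[bid], params, query_id=aid, target_id=bid
            )
        return alignments[key]

    def candidates_for(aid: str) -> list[str]:
        ks = _kmer_set(seqs_a[aid], prescreen_k)
        counts: dict[str, int] = {}
        for km in ks:
            for bid in kmer_index.get(km, ()):
                counts[bid] = counts.get(bid, 0) + 1
        if not counts:
            return []
        threshold = max(3, int(0.05 * len(ks)))
        ranked = sorted(
            (bid for bid, c in counts.items() if c >= threshold),
            key=lambda bid: (-counts[bid], bid),
        )
        return ranked[:max_candidates]

    def valid(aln: PairwiseAlignment) -> bool:
        return (
            aln.identity >= min_identity
            and max(aln.coverage_a, aln.coverage_b) >= min_coverage
        )

    def hit_key(aln: PairwiseAlignment):
        return (
            aln.identity * max(aln.coverage_a, aln.coverage_b),
            len(aln.ops),
        )

    best_a: dict[str, str] = {}
    for aid in sorted(seqs_a):
        best: tuple | None = None
        best_bid: str | None = None
        for bid in candidates_for(aid):
            aln = get_alignment(aid, bid)
            if not valid(aln):
                continue
            key = hit_key(aln)
            if best is None or key > best or (key == best and bid < best_bid):
                best, best_bid = key, bid
        if best_bid is not None:
            best_a[aid] = best_bid
    # reverse layer: for each B locus, best valid hit among candidate A loci
    kmers_a_index: dict[str, list[str]] = {}
    for lid, s in seqs_a.items():
        for km in _kmer_set(s, prescreen_k):
            kmers_a_index.setdefault(km, []).append(lid)
    best_b: dict[str, str] = {}
    for bid in sorted(seqs_b):
        ks = kmers_b[bid]
        counts: dict[str, int] = {}
        for km in ks:
            for aid in kmers_a_index.get(km, ()):
                counts[aid] = counts.get(aid, 0) + 1
        threshold = max(3, int(0.05 * len(ks)))
        ranked = sorted(
            (aid for aid, c in counts.items() if c >= threshold),
            key=lambda aid: (-counts[aid], aid),
        )[:max_candidates]
        best: tuple | None = None
        best_aid: str | None = None
        for aid in ranked:
            aln = get_alignment(aid, bid)
            if not valid(aln):
                continue
            key = hit_key(aln)
            if best is None or key > best or (key == best and aid < best_aid):
                best, best_aid = key, aid
        if best_aid is not None:
            best_b[bid] = best_aid

    def make_pair(aid: str, bid: str, reciprocal: bool) -> AllelicPair:
        aln = alignments[(aid, bid)]
        return AllelicPair(
            ilocus_a_id=aid,
            ilocus_b_id=bid,
            identity=aln.identity,
            coverage_a=aln.coverage_a,
            coverage_b=aln.coverage_b,
            aligned_length=len(aln.ops),
            reciprocal=reciprocal,
        )

    pairs: list[AllelicPair] = []
    paired_a: set[str] = set()
    paired_b: set[str] = set()
    for aid, bid in sorted(best_a.items()):
        if best_b.get(bid) == aid:
            pairs.append(make_pair(aid, bid, True))
            paired_a.add(aid)
            paired_b.add(bid)
    # rescue layer: loci without a reciprocal partner keep their best valid
    # hit as a non-reciprocal pair (density transfer only)
    for aid, bid in sorted(best_a.items()):
        if aid not in paired_a:
            pairs.append(make_pair(aid, bid, False))
    for bid, aid in sorted(best_b.items()):
        if bid not in paired_b and best_a.get(aid) != bid:
            pairs.append(make_pair(aid, bid, False))
    return ReciprocalMapResult(
        pairs=pairs,
        orphans_a=sorted(set(seqs_a) - paired_a),
        orphans_b=sorted(set(seqs_b) - paired_b),
        alignments=alignments,
    )


def pair_densities(
    result: ReciprocalMapResult, iloci_a: ILocusSet, iloci_b: ILocusSet
) -> tuple[dict[str, VariantDensity], dict[str, VariantDensity]]:
    """M/I/D densities per paired iLocus, keyed by strain-A and strain-B
    locus ids respectively; each side's density is anchored on that side's
    locus length.  Reciprocal pairs take precedence over rescue pairs."""
    dens_a: dict[str, VariantDensity] = {}
    dens_b: dict[str, VariantDensity] = {}
    for reciprocal_only in (True, False):
        for pair in result.pairs:
            if pair.reciprocal != reciprocal_only:
                continue
            aln = result.alignments[(pair.ilocus_a_id, pair.ilocus_b_id)]
            counts = count_variants(aln)
            if pair.ilocus_a_id not in dens_a:
                dens_a[pair.ilocus_a_id] = variant_density(
                    counts, iloci_a.get(pair.ilocus_a_id).length
                )
            if pair.ilocus_b_id not in dens_b:
                dens_b[pair.ilocus_b_id] = variant_density(
                    counts, iloci_b.get(pair.ilocus_b_id).length
                )
    return dens_a, dens_b


def classify_te_allelism(
    te: ElementAnatomy,
    flankset: FlankSet,
    pairs: Sequence[AllelicPair],
    te_set_b: Sequence[ElementAnatomy],
    iloci_a: ILocusSet,
    iloci_b: ILocusSet,
) -> tuple[str, bool]:
    """Classify a strain-A TE as allelic or non-allelic.

    The strain-B region delimited by the B-partners of the TE's nearest
    flanking iLoci is searched for a same-family TE of any class (a solo LTR
    in B at a full-length element's A position still counts as allelic).
    Only reciprocal pairs anchor the partner region; TEs whose flanks have
    no reciprocal partners are non-allelic, and when both sides are
    unresolved a warning flag is returned alongside.
    """
    partner_of = {p.ilocus_a_id: p.ilocus_b_id for p in pairs if p.reciprocal}
    up_partner = next(
        (partner_of[i] for i in flankset.upstream if i in partner_of), None
    )
    down_partner = next(
        (partner_of[i] for i in flankset.downstream if i in partner_of), None
    )
    if up_partner is None and down_partner is None:
        return "non-allelic", True
    partner_loci = [
        iloci_b.get(i) for i in (up_partner, down_partner) if i is not None
    ]
    chroms = {loc.chrom for loc in partner_loci}
    if len(chroms) != 1:
        return "non-allelic", False
    chrom_b = chroms.pop()
    lo = min(loc.start for loc in partner_loci)
    hi = max(loc.end for loc in partner_loci)
    for other in te_set_b:
        if other.family != te.family or other.chrom != chrom_b:
            continue
        if other.start < hi and other.end > lo:
            return "allelic", False
    return "non-allelic", False


def write_pairs_tsv(
    result: ReciprocalMapResult,
    densities: Mapping[str, VariantDensity],
    path: str | Path,
) -> None:
    with Path(path).open("w") as fh:
        fh.write(
            "ilocus_a\tilocus_b\tidentity\tcoverage_a\tcoverage_b\tM\tI\tD\n"
        )
        for p in result.pairs:
            d = densities.get(p.ilocus_a_id)
            m, i, dd = (f"{d.M:.4f}", f"{d.I:.4f}", f"{d.D:.4f}") if d else ("", "", "")
            fh.write(
                f"{p.ilocus_a_id}\t{p.ilocus_b_id}\t{p.identity:.4f}\t"
                f"{p.coverage_a:.4f}\t{p.coverage_b:.4f}\t{m}\t{i}\t{dd}\n"
            )
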