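"""Structural anatomy of transposable elements from sequence alone.

LTR retrotransposons leave characteristic sequence signatures even after the
coding capacity decays: a pair of near-identical long terminal repeats (LTRs)
in direct orientation, terminal inverted repeats (TIRs, minimally TG...CA),
a short target-site duplication (TSD) of host sequence flanking the element,
a primer-binding site (PBS) complementary to a tRNA 3' end just downstream of
the 5' LTR, a polypurine tract (PPT) just upstream of the 3' LTR, and a
GAG-POL two-ORF layout.  Solo LTRs — the product of inter-LTR recombination —
retain only a single LTR with its TSD.  This module detects each signature
independently and assembles them into a per-element anatomy record, plus the
genome-level censuses built on them: solo-LTR family clustering, a homology
census by length class (full-length / partial / fragment), association of
insertion points with RNA-polymerase-III-transcribed genes, and dimeric
RNAP3 gene detection.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import Align

from .genomeio import FeatureRecord, GenomeAssembly, revcomp

PURINES = frozenset("AG")
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


class MissingToolError(RuntimeError):
    """Raised when a required external command-line tool is absent."""


# ---------------------------------------------------------------------------
# result types


@dataclass(frozen=True)
class TIRResult:
    """A terminal inverted repeat: element prefix vs reverse-complemented
    element suffix."""

    length: int
    left_seq: str
    right_seq: str
    mismatches: int
    conforming: bool  # termini match the canonical TG...CA


@dataclass(frozen=True)
class TSDResult:
    """A target-site duplication found across the two element flanks.

    ``offset`` is the shift of the upstream copy away from the element
    junction (the upstream copy may carry extra bases between it and the
    element, as in the ATTTTT/ATTTT case with offset 1).
    """

    length: int
    upstream_copy: str
    downstream_copy: str
    offset: int
    mismatches: int


@dataclass(frozen=True)
class LTRPair:
    """A pair of near-identical direct terminal repeats (element-relative
    intervals, 0-based half-open)."""

    ltr5: tuple[int, int]
    ltr3: tuple[int, int]
    identity: float
    ltr_length: int


@dataclass(frozen=True)
class PBSResult:
    """Primer-binding site: reverse-complement match to a tRNA 3' end."""

    start_offset: int  # bp downstream of the upstream LTR end
    match_length: int
    trna_id: str


@dataclass(frozen=True)
class PPTResult:
    """Polypurine tract just upstream of the downstream LTR."""

    run_length: int
    end_offset: int  # bp upstream of the downstream LTR start


@dataclass(frozen=True)
class ORFLayout:
    """Forward-strand open reading frames of an element and their spacers.

    ORFs are maximal stop-free codon runs (stop-to-stop, terminating stop
    included in the interval) selected into a non-overlapping chain of
    maximal total coding length.  ``spacer_stop_counts[i]`` counts in-frame
    stop codons inside spacer ``i`` read in the upstream ORF's frame.
    """

    orfs: list[tuple[int, int, int]]  # (start, end, length_aa)
    spacer_lengths: list[int]
    spacer_stop_counts: list[int]


@dataclass
class ElementAnatomy:
    """Assembled structural record of one TE insertion."""

    family: str
    chrom: str
    start: int
    end: int
    classification: str  # full-length | solo-LTR | partial | fragment
    id: str = ""
    tir: TIRResult | None = None
    tsd: TSDResult | None = None
    ltr_pair: LTRPair | None = None
    pbs: PBSResult | None = None
    ppt: PPTResult | None = None
    orf_layout: ORFLayout | None = None

    def __post_init__(self) -> None:
        if self.classification == "full-length" and self.ltr_pair is None:
            raise ValueError("full-length element requires an LTR pair")
        if self.classification == "solo-LTR" and self.ltr_pair is not None:
            raise ValueError("solo LTR cannot carry an LTR pair")

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class SoloLTRFamily:
    family_id: str
    consensus: str
    members: list[str]  # candidate ids
    mean_length: float


# ---------------------------------------------------------------------------
# detectors


def find_terminal_inverted_repeat(
    element_seq: str, max_mismatch: int = 0
) -> TIRResult | None:
    """Longest terminal inverted repeat with at most ``max_mismatch``
    mismatches; flags whether the termini conform to the canonical TG...CA.
    """
    n = len(element_seq)
    if n < 20:
        return None
    best: TIRResult | None = None
    for length in range(2, n // 2 + 1):
        left = element_seq[:length]
        right = element_seq[-length:]
        rc = revcomp(right)
        mm = sum(1 for a, b in zip(left, rc) if a != b)
        if mm <= max_mismatch:
            conforming = left.startswith("TG") and right.endswith("CA")
            best = TIRResult(length, left, right, mm, conforming)
    return best


def detect_tsd(
    upstream_flank: str,
    downstream_flank: str,
    min_len: int = 4,
    max_len: int = 12,
    offset_tol: int = 1,
    max_mismatch: int = 0,
) -> TSDResult | None:
    """Longest duplicated word bridging an insertion: a suffix of the
    upstream flank (shifted up to ``offset_tol`` bases away from the
    junction) equal to a prefix of the downstream flank.

    Ties are broken by longer length, then smaller offset.  Returns ``None``
    below ``min_len``.
    """
    if len(upstream_flank) < max_len + offset_tol or len(downstream_flank) < max_len:
        raise ValueError("flanks shorter than max_len + offset_tol")
    nu = len(upstream_flank)
    for length in range(max_len, min_len - 1, -1):
        down = downstream_flank[:length]
        for off in range(0, offset_tol + 1):
            up = upstream_flank[nu - length - off : nu - off]
            mm = sum(
                1 for a, b in zip(up, down) if a != b or a == "N" or b == "N"
            )
            if mm <= max_mismatch:
                return TSDResult(length, up, down, off, mm)
    return None


_LTR_ALIGNER = Align.PairwiseAligner(
    mode="local",
    match_score=2,
    mismatch_score=-3,
    open_gap_score=-6,
    extend_gap_score=-2,
)


def find_ltr_pair(
    element_seq: str,
    min_ltr: int = 100,
    max_ltr: int = 1000,
    min_identity: float = 0.90,
) -> LTRPair | None:
    """Best pair of near-identical terminal repeats in direct orientation.

    The first and last ``max_ltr`` bp are locally aligned; the aligned spans
    are reported as the LTR intervals when the alignment covers at least
    ``min_ltr`` bp at identity >= ``min_identity``, the two spans have equal
    length within 2 bp, and the 5' span precedes the 3' span without overlap.
    """
    n = len(element_seq)
    if n < 2 * min_ltr:
        return None
    head_len = min(max_ltr, n // 2)
    head = element_seq[:head_len]
    tail_start = n - min(max_ltr, n // 2)
    tail = element_seq[tail_start:]
    alns = _LTR_ALIGNER.align(head, tail)
    if len(alns) == 0:
        return None
    aln = alns[0]
    blocks_q, blocks_t = aln.aligned
    if len(blocks_q) == 0:
        return None
    q0, q1 = int(blocks_q[0][0]), int(blocks_q[-1][1])
    t0, t1 = int(blocks_t[0][0]), int(blocks_t[-1][1])
    matches = mismatches = 0
    for (qa, qb), (ta, tb) in zip(blocks_q, blocks_t):
        for a, b in zip(head[qa:qb], tail[ta:tb]):
            if a == b and a != "N":
                matches += 1
            elif a != "N" and b != "N":
                mismatches += 1
    if matches + mismatches == 0:
        return None
    identity = matches / (matches + mismatches)
    ltr5 = (q0, q1)
    ltr3 = (tail_start + t0, tail_start + t1)
    len5 = ltr5[1] - ltr5[0]
    len3 = ltr3[1] - ltr3[0]
    if min(len5, len3) < min_ltr or identity < min_identity:
        return None
    if abs(len5 - len3) > 2 or ltr5[1] > ltr3[0]:
        return None
    return LTRPair(ltr5=ltr5, ltr3=ltr3, identity=identity, ltr_length=len5)


def find_pbs(
    internal_seq: str,
    trna_three_prime_ends: Mapping[str, str],
    min_match: int = 8,
    search_window: int = 20,
    allow_gu: bool = False,
) -> PBSResult | None:
    """Primer-binding site: best reverse-complement match between a window
    starting within ``search_window`` bp of the upstream LTR and the 3'
    terminus of any provided tRNA.

    Minus-strand reverse transcription is primed by a tRNA annealed to the
    PBS, so the PBS is the reverse complement of the tRNA 3' end.  Best match
    is the longest, then the closest to the LTR.  With ``allow_gu``, G:U
    wobble-equivalent pairs (PBS T against tRNA G, PBS G against tRNA U/T)
    also count as paired.
    """
    if not trna_three_prime_ends:
        return None

    def paired(pbs_base: str, trna_base: str) -> bool:
        if pbs_base == revcomp(trna_base) and pbs_base != "N":
            return True
        if allow_gu:
            return (pbs_base == "T" and trna_base == "G") or (
                pbs_base == "G" and trna_base == "T"
            )
        return False

    best: PBSResult | None = None
    for trna_id, trna in sorted(trna_three_prime_ends.items()):
        max_l = min(len(trna), len(internal_seq))
        for length in range(max_l, min_match - 1, -1):
            target = trna[-length:]
            for start in range(0, search_window + 1):
                window = internal_seq[start : start + length]
                if len(window) < length:
                    break
                # PBS read 5'->3' pairs antiparallel with the tRNA 3' end
                ok = all(
                    paired(window[i], target[length - 1 - i]) for i in range(length)
                )
                if ok:
                    cand = PBSResult(start, length, trna_id)
                    if best is None or (cand.match_length, -cand.start_offset) > (
                        best.match_length,
                        -best.start_offset,
                    ):
                        best = cand
                    break
            if best is not None and best.match_length >= length:
                break
    return best


def find_ppt(
    internal_tail_seq: str, min_run: int = 8, search_window: int = 20
) -> PPTResult | None:
    """Longest run of purines (A/G) ending within ``search_window`` bp of the
    downstream LTR (the end of ``internal_tail_seq``); ties broken by
    proximity to the LTR."""
    n = len(internal_tail_seq)
    runs: list[tuple[int, int]] = []  # (run_length, end_offset)
    i = 0
    while i < n:
        if internal_tail_seq[i] in PURINES:
            j = i
            while j < n and internal_tail_seq[j] in PURINES:
                j += 1
            end_offset = n - j
            if end_offset <= search_window and j - i >= min_run:
                runs.append((j - i, end_offset))
            i = j
        else:
            i += 1
    if not runs:
        return None
    length, off = max(runs, key=lambda r: (r[0], -r[1]))
    return PPTResult(run_length=length, end_offset=off)


def _maximal_orfs(seq: str, min_orf_aa: int) -> list[tuple[int, int, int]]:
    """Maximal stop-to-stop ORFs in the three forward frames.

    An ORF is a maximal run of non-stop codons; its interval includes the
    terminating stop codon when present.  Length in aa counts sense codons.
    """
    orfs: list[tuple[int, int, int]] = []
    n = len(seq)
    for frame in range(3):
        run_start = frame
        pos = frame
        while pos + 3 <= n:
            codon = seq[pos : pos + 3]
            if codon in STOP_CODONS:
                aa = (pos - run_start) // 3
                if aa >= min_orf_aa:
                    orfs.append((run_start, pos + 3, aa))
                run_start = pos + 3
            pos += 3
        aa = (pos - run_start) // 3
        if aa >= min_orf_aa:
            orfs.append((run_start, pos, aa))
    orfs.sort()
    return orfs


def annotate_orf_layout(element_seq: str, min_orf_aa: int = 100) -> ORFLayout:
    """Forward-strand ORF layout: maximal ORFs >= ``min_orf_aa`` selected into
    a non-overlapping chain of maximal total coding length, with spacer
    lengths and in-frame stop counts between consecutive ORFs."""
    if len(element_seq) < 300:
        raise ValueError("element shorter than 300 bp")
    cands = _maximal_orfs(element_seq, min_orf_aa)
    # weighted interval scheduling on aa length
    chosen: list[tuple[int, int, int]] = []
    if cands:
        import bisect

        cands_by_end = sorted(cands, key=lambda o: o[1])
        ends = [o[1] for o in cands_by_end]
        best_aa = [0] * (len(cands_by_end) + 1)
        take: list[bool] = [False] * len(cands_by_end)
        prev_idx = [0] * len(cands_by_end)
        for i, (s, e, aa) in enumerate(cands_by_end):
            j = bisect.bisect_right(ends, s)
            prev_idx[i] = j
            with_i = best_aa[j] + aa
            if with_i > best_aa[i]:
                best_aa[i + 1] = with_i
                take[i] = True
            else:
                best_aa[i + 1] = best_aa[i]
        i = len(cands_by_end)
        while i > 0:
            if take[i - 1]:
                chosen.append(cands_by_end[i - 1])
                i = prev_idx[i - 1]
            else:
                i -= 1
        chosen.reverse()
    spacers: list[int] = []
    stops: list[int] = []
    for (s1, e1, _), (s2, _, _) in zip(chosen, chosen[1:]):
        spacers.append(s2 - e1)
        count = 0
        pos = e1
        while pos + 3 <= s2:
            if element_seq[pos : pos + 3] in STOP_CODONS:
                count += 1
            pos += 3
        stops.append(count)
    return ORFLayout(orfs=chosen, spacer_lengths=spacers, spacer_stop_counts=stops)


# ---------------------------------------------------------------------------
# genomic-context classifiers


def classify_rnap3_association(
    insertion_point: int,
    tdna_features: Sequence[FeatureRecord],
    five_s_features: Sequence[FeatureRecord] = (),
    targeted_window: tuple[int, int] = (15, 17),
    adjacent_window: int = 100,
    chrom: str | None = None,
) -> str:
    """Relate a TE insertion boundary to RNAP3-transcribed genes.

    Ty3/Gypsy-class integrases target RNAP3 transcription start sites; with a
    ~10-nt pre-tRNA leader and a 5-bp TSD, element sequence lands 15-17 bp
    upstream of the mature tRNA coding start.  ``insertion_point`` is the
    element's outer boundary nearest the candidate gene.  Returns one of
    ``rnap3-start-targeted``, ``rnap3-internal``, ``rnap3-adjacent``,
    ``unassociated``; start-targeting takes precedence over internal, which
    takes precedence over adjacency.
    """
    lo, hi = targeted_window
    genes = [
        g
        for g in list(tdna_features) + list(five_s_features)
        if chrom is None or g.chrom == chrom
    ]
    p = insertion_point
    targeted = internal = adjacent = False
    for g in genes:
        if g.strand == "-":
            d = p - (g.end - 1)
        else:
            d = g.start - p
        if lo <= d <= hi:
            targeted = True
        if g.start <= p < g.end:
            internal = True
        elif max(g.start - p, p - (g.end - 1)) <= adjacent_window:
            adjacent = True
    if targeted:
        return "rnap3-start-targeted"
    if internal:
        return "rnap3-internal"
    if adjacent:
        return "rnap3-adjacent"
    return "unassociated"


def detect_dimeric_rnap3(
    rnap3_features: Sequence[FeatureRecord], min_gap: int = 5, max_gap: int = 26
) -> list[tuple[FeatureRecord, FeatureRecord]]:
    """Dimeric RNAP3 genes: adjacent same-strand genes separated by a gap in
    ``[min_gap, max_gap]`` nt, returned as (upstream, downstream) pairs in
    genomic order per chromosome."""
    pairs: list[tuple[FeatureRecord, FeatureRecord]] = []
    by_chrom: dict[str, list[FeatureRecord]] = {}
    for f in rnap3_features:
        by_chrom.setdefault(f.chrom, []).append(f)
    for feats in by_chrom.values():
        feats.sort(key=lambda f: (f.start, f.end))
        for a, b in zip(feats, feats[1:]):
            gap = b.start - a.end
            if a.strand == b.strand and min_gap <= gap <= max_gap:
                pairs.append((a, b))
    return pairs


# ---------------------------------------------------------------------------
# family clustering and census

_GLOBAL_ALIGNER = Align.PairwiseAligner(
    mode="global",
    match_score=1,
    mismatch_score=-2,
    open_gap_score=-7,
    extend_gap_score=-1,
)


def _edlib_identity(a: str, b: str) -> float:
    import edlib

    if not a or not b:
        return 0.0
    res = edlib.align(a, b, task="distance")
    return 1.0 - res["editDistance"] / max(len(a), len(b))


def cluster_solo_ltrs(
    candidate_seqs: Mapping[str, str], identity_threshold: float = 0.80
) -> list[SoloLTRFamily]:
    """Group solo-LTR candidates into families by primary sequence.

    Single-linkage clustering at pairwise identity >= ``identity_threshold``
    (edit-distance identity over the longer sequence), then a per-family
    majority-rule consensus built by star alignment of every member onto the
    family medoid (the member with highest mean within-family identity).
    """
    ids = sorted(candidate_seqs)
    for cid in ids:
        if not (100 <= len(candidate_seqs[cid]) <= 1000):
            raise ValueError(f"candidate {cid!r} outside the 100-1000 bp band")
    parent = {cid: cid for cid in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    ident: dict[tuple[str, str], float] = {}
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            idn = _edlib_identity(candidate_seqs[a], candidate_seqs[b])
            ident[(a, b)] = idn
            if idn >= identity_threshold:
                parent[find(a)] = find(b)
    clusters: dict[str, list[str]] = {}
    for cid in ids:
        clusters.setdefault(find(cid), []).append(cid)

    families: list[SoloLTRFamily] = []
    for k, members in enumerate(sorted(clusters.values(), key=lambda m: m[0])):
        if len(members) == 1:
            cons = candidate_seqs[members[0]]
        else:
            def mean_id(m: str) -> float:
                vals = [
                    ident.get((min(m, o), max(m, o)), 0.0) for o in members if o != m
                ]
                return sum(vals) / len(vals)

            medoid = max(members, key=lambda m: (mean_id(m), m))
            cons = _star_consensus(candidate_seqs[medoid],
                                   [candidate_seqs[m] for m in members])
        mean_len = sum(len(candidate_seqs[m]) for m in members) / len(members)
        families.append(
            SoloLTRFamily(
                family_id=f"family_{k + 1}",
                consensus=cons,
                members=list(members),
                mean_length=mean_len,
            )
        )
    return families


def _star_consensus(medoid: str, members: list[str]) -> str:
    """Majority-rule consensus over medoid columns from pairwise global
    alignments of each member onto the medoid (insertions relative to the
    medoid are ignored; a gap majority deletes the column)."""
    votes: list[dict[str, int]] = [dict() for _ in medoid]
    for mem in members:
        aln = _GLOBAL_ALIGNER.align(medoid, mem)[0]
        blocks_q, blocks_t = aln.aligned
        covered = [False] * len(medoid)
        for (qa, qb), (ta, tb) in zip(blocks_q, blocks_t):
            for off in range(qb - qa):
                votes[qa + off][mem[ta + off]] = votes[qa + off].get(mem[ta + off], 0) + 1
                covered[qa + off] = True
        for i, c in enumerate(covered):
            if not c:
                votes[i]["-"] = votes[i].get("-", 0) + 1
    out = []
    for col in votes:
        base = max(sorted(col), key=lambda b: col[b])
        if base != "-":
            out.append(base)
    return "".join(out)


@dataclass
class CensusHit:
    family: str
    chrom: str
    start: int
    end: int
    classification: str  # full-length | partial | fragment


def _require_blastn() -> str:
    exe = shutil.which("blastn")
    if exe is None:
        raise MissingToolError("blastn not found on PATH")
    return exe


def census_elements(
    genome: GenomeAssembly,
    family_reference_seqs: Mapping[str, str],
    full_length_fraction: float = 0.92,
    min_identity: float = 0.80,
    min_hit_len: int = 30,
    partial_min_len: int = 1000,
) -> tuple[dict[str, dict[str, int]], list[CensusHit]]:
    """Per-family census of homology hits, classified by length class.

    Each family reference is searched against the genome with ``blastn``;
    overlapping hits to one family are merged, then classified: full-length
    when the merged span covers >= ``full_length_fraction`` of the reference
    length, partial above ``partial_min_len`` bp, fragment between
    ``min_hit_len`` and ``partial_min_len``; shorter spans are discarded.
    Returns (counts per family, merged hits).
    """
    counts = {
        fam: {"full": 0, "partial": 0, "fragment": 0} for fam in family_reference_seqs
    }
    if not family_reference_seqs:
        return counts, []
    exe = _require_blastn()
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        subj = tmp / "genome.fa"
        with subj.open("w") as fh:
            for cid, seq in genome.chromosomes.items():
                fh.write(f">{cid}\n{seq}\n")
        qry = tmp / "refs.fa"
        with qry.open("w") as fh:
            for fam, seq in family_reference_seqs.items():
                fh.write(f">{fam}\n{seq}\n")
        out = subprocess.run(
            [
                exe,
                "-query", str(qry),
                "-subject", str(subj),
                "-outfmt", "6 qseqid sseqid pident length sstart send",
                "-evalue", "1e-5",
                "-dust", "no",
                "-soft_masking", "false",
                "-perc_identity", str(min_identity * 100),
            ],
            capture_output=True,
            text=True,
            check=True,
        ).stdout
    raw: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for line in out.splitlines():
        fam, chrom, _pident, _length, sstart, send = line.split("\t")
        s, e = int(sstart), int(send)
        lo, hi = (s - 1, e) if s <= e else (e - 1, s)
        raw.setdefault((fam, chrom), []).append((lo, hi))
    hits: list[CensusHit] = []
    for (fam, chrom), ivals in sorted(raw.items()):
        ref_len = len(family_reference_seqs[fam])
        ivals.sort()
        merged: list[list[int]] = []
        for lo, hi in ivals:
            if merged and lo < merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], hi)
            else:
                merged.append([lo, hi])
        for lo, hi in merged:
            span = hi - lo
            if span < min_hit_len:
                continue
            if span >= full_length_fraction * ref_len:
                cls = "full"
            elif span > partial_min_len:
                cls = "partial"
            else:
                cls = "fragment"
            counts[fam][cls] += 1
            label = {"full": "full-length", "partial": "partial", "fragment": "fragment"}
            hits.append(CensusHit(fam, chrom, lo, hi, label[cls]))
    return counts, hits


# ---------------------------------------------------------------------------
# anatomy assembly


def assemble_anatomy(
    genome: GenomeAssembly,
    chrom: str,
    start: int,
    end: int,
    family: str,
    element_id: str = "",
    classification: str | None = None,
    trna_three_prime_ends: Mapping[str, str] | None = None,
    flank: int = 30,
    min_ltr: int = 100,
    max_ltr: int = 1000,
    min_orf_aa: int = 100,
) -> ElementAnatomy:
    """Run every detector on one genomic TE interval and assemble the record.

    Classification, when not supplied, follows the sub-results: an LTR pair
    means full-length; otherwise a 100-1000 bp span is called a solo LTR,
    longer spans partial, shorter ones fragment.
    """
    seq = genome.chromosomes[chrom][start:end]
    chrom_len = genome.length_of(chrom)
    up = genome.chromosomes[chrom][max(0, start - max(flank, 13)) : start]
    down = genome.chromosomes[chrom][end : min(chrom_len, end + max(flank, 13))]
    tir = find_terminal_inverted_repeat(seq) if len(seq) >= 20 else None
    tsd = None
    if len(up) >= 13 and len(down) >= 12:
        tsd = detect_tsd(up, down)
    ltr_pair = find_ltr_pair(seq, min_ltr=min_ltr, max_ltr=max_ltr)
    pbs = ppt = orf_layout = None
    if ltr_pair is not None:
        internal = seq[ltr_pair.ltr5[1] : ltr_pair.ltr3[0]]
        if trna_three_prime_ends:
            pbs = find_pbs(internal, trna_three_prime_ends)
        ppt = find_ppt(internal)
        if len(seq) >= 300:
            orf_layout = annotate_orf_layout(seq, min_orf_aa=min_orf_aa)
    if classification is None or (
        classification == "full-length" and ltr_pair is None
    ):
        # a census "full-length" call is relative to the family reference;
        # without a detected LTR pair the structural class falls back to
        # the length-based one
        if ltr_pair is not None:
            classification = "full-length"
        elif 100 <= len(seq) <= 1000:
            classification = "solo-LTR"
        elif len(seq) > 1000:
            classification = "partial"
        else:
            classification = "fragment"
    if classification == "solo-LTR":
        ltr_pair = None
    return ElementAnatomy(
        family=family,
        chrom=chrom,
        start=start,
        end=end,
        classification=classification,
        id=element_id or f"{family}_{chrom}_{start}",
        tir=tir,
        tsd=tsd,
        ltr_pair=ltr_pair,
        pbs=pbs,
        ppt=ppt,
        orf_layout=orf_layout,
    )


def write_anatomy_gff3(
    anatomies: Iterable[ElementAnatomy], path: str | Path, source: str = "tetrace"
) -> None:
    """GFF3 export: one parent TE feature per element with SO-style child
    features for LTRs, PBS, PPT, ORFs and TSD."""
    with Path(path).open("w") as fh:
        fh.write("##gff-version 3\n")
        for a in anatomies:
            attrs = f"ID={a.id};family={a.family};class={a.classification}"
            fh.write(
                f"{a.chrom}\t{source}\ttransposable_element\t{a.start + 1}\t"
                f"{a.end}\t.\t+\t.\t{attrs}\n"
            )

            def child(gtype: str, s: int, e: int, suffix: str) -> None:
                fh.write(
                    f"{a.chrom}\t{source}\t{gtype}\t{s + 1}\t{e}\t.\t+\t.\t"
                    f"ID={a.id}_{suffix};Parent={a.id}\n"
                )

            if a.ltr_pair:
                child("long_terminal_repeat", a.start + a.ltr_pair.ltr5[0],
                      a.start + a.ltr_pair.ltr5[1], "ltr5")
                child("long_terminal_repeat", a.start + a.ltr_pair.ltr3[0],
                      a.start + a.ltr_pair.ltr3[1], "ltr3")
                if a.pbs:
                    pbs_s = a.start + a.ltr_pair.ltr5[1] + a.pbs.start_offset
                    child("primer_binding_site", pbs_s,
                          pbs_s + a.pbs.match_length, "pbs")
                if a.ppt:
                    ppt_e = a.start + a.ltr_pair.ltr3[0] - a.ppt.end_offset
                    child("RR_tract", ppt_e - a.ppt.run_length, ppt_e, "ppt")
            if a.orf_layout:
                for i, (s, e, _aa) in enumerate(a.orf_layout.orfs):
                    child("ORF", a.start + s, a.start + e, f"orf{i + 1}")
            if a.tsd:
                child("target_site_duplication",
                      a.start - a.tsd.offset - a.tsd.length,
                      a.start - a.tsd.offset, "tsd_up")
                child("target_site_duplication", a.end, a.end + a.tsd.length,
                      "tsd_down")
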