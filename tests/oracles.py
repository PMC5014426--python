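"""Independent brute-force oracles used to cross-check the detectors.

Each function here is a deliberately naive reimplementation (exhaustive
enumeration or quadratic dynamic programming) that shares no code with the
package implementation it checks.
"""

from __future__ import annotations

import re

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def brute_tir(seq: str, max_mm: int = 0):
    """Longest terminal inverted repeat (length, mismatches) or None."""
    best = None
    for length in range(2, len(seq) // 2 + 1):
        mm = sum(
            1
            for a, b in zip(seq[:length], rc(seq[-length:]))
            if a != b
        )
        if mm <= max_mm:
            best = (length, mm)
    return best


def brute_tsd(up, down, min_len=4, max_len=12, offset_tol=1, max_mm=0):
    """First acceptable (length desc, offset asc) duplication or None."""
    for length in range(max_len, min_len - 1, -1):
        for off in range(offset_tol + 1):
            u = up[len(up) - length - off : len(up) - off]
            d = down[:length]
            mm = sum(1 for a, b in zip(u, d) if a != b or "N" in (a, b))
            if mm <= max_mm:
                return (length, off)
    return None


def brute_ppt(seq: str, min_run: int = 8, window: int = 20):
    """(run_length, end_offset) of the best purine run or None."""
    runs = []
    for m in re.finditer(r"[AG]+", seq):
        end_off = len(seq) - m.end()
        if end_off <= window and m.end() - m.start() >= min_run:
            runs.append((m.end() - m.start(), end_off))
    if not runs:
        return None
    return max(runs, key=lambda r: (r[0], -r[1]))


def brute_pbs(internal, trna_ends, min_match=8, window=20):
    """(start, length, trna_id) of the best reverse-complement match."""
    best = None
    for tid in sorted(trna_ends):
        trna = trna_ends[tid]
        for length in range(min(len(trna), len(internal)), min_match - 1, -1):
            for start in range(window + 1):
                w = internal[start : start + length]
                if len(w) < length:
                    break
                if w == rc(trna[-length:]) and "N" not in w:
                    cand = (length, -start, tid)
                    if best is None or cand[:2] > best[:2]:
                        best = cand
                    break
    if best is None:
        return None
    return (-best[1], best[0], best[2])


def brute_orfs(seq: str, min_aa: int):
    """All maximal stop-to-stop ORFs >= min_aa in the 3 forward frames."""
    stops = {"TAA", "TAG", "TGA"}
    out = []
    for frame in range(3):
        run = frame
        pos = frame
        while pos + 3 <= len(seq):
            if seq[pos : pos + 3] in stops:
                if (pos - run) // 3 >= min_aa:
                    out.append((run, pos + 3, (pos - run) // 3))
                run = pos + 3
            pos += 3
        if (pos - run) // 3 >= min_aa:
            out.append((run, pos, (pos - run) // 3))
    return sorted(out)


def best_orf_chain_total(cands) -> int:
    """Max total aa over non-overlapping subsets, by exhaustive search."""
    best = 0
    n = len(cands)

    def rec(i, end, total):
        nonlocal best
        best = max(best, total)
        for j in range(i, n):
            s, e, aa = cands[j]
            if s >= end:
                rec(j + 1, e, total + aa)

    rec(0, -1, 0)
    return best


def brute_digest(seq: str, motif: str):
    """Both-strand O(n*m) motif scan -> sorted (pos, strand) list."""
    hits = []
    for strand, m in (("+", motif), ("-", rc(motif))):
        for i in range(len(seq) - len(m) + 1):
            if seq[i : i + len(m)] == m:
                hits.append((i, strand))
    return sorted(hits)


def gotoh_score(a, b, match=1, mismatch=-2, gap_open=-6, gap_extend=-1):
    """Affine-gap alignment score with free terminal gaps on both
    sequences (glocal), by explicit quadratic dynamic programming.

    A length-L gap costs ``gap_open + L * gap_extend``, matching the
    package scoring convention.
    """
    NEG = float("-inf")
    n, m = len(a), len(b)
    open_cost = gap_open + gap_extend
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consumes a)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consumes b)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            start = 0.0 if (i == 1 or j == 1) else NEG
            M[i][j] = s + max(
                M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1], start
            )
            X[i][j] = max(M[i - 1][j] + open_cost, X[i - 1][j] + gap_extend)
            Y[i][j] = max(M[i][j - 1] + open_cost, Y[i][j - 1] + gap_extend)
    best = 0.0
    for i in range(1, n + 1):
        best = max(best, M[i][m], X[i][m], Y[i][m])
    for j in range(1, m + 1):
        best = max(best, M[n][j], X[n][j], Y[n][j])
    return best


def brute_flanks(loci, ts, te, k):
    """Nearest-k non-overlapping intervals on each side of [ts, te)."""
    up = sorted((loc for loc in loci if loc.end <= ts), key=lambda l: -l.end)
    down = sorted((loc for loc in loci if loc.start >= te), key=lambda l: l.start)
    return [l.id for l in up[:k]], [l.id for l in down[:k]]
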