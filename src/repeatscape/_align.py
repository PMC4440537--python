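"""Shared sequence/alignment primitives.

Gap-free seeded diagonal alignment is the workhorse for homology masking and
copy-number scans: library copies in the simulated genomes diverge by point
substitutions only, so every true hit lies on a single diagonal and the
maximal-scoring segment on that diagonal (match +1 / mismatch -1) is the
exact local alignment.  Indel-tolerant comparisons (clustering, family
rules, LTR-pair dating) go through edlib instead.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import edlib
import numpy as np

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_BASE_TO_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_TO_CODE[ord(_b)] = _i
    _BASE_TO_CODE[ord(_b.lower())] = _i

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def revcomp(seq: str) -> str:
    """Reverse complement (ACGTN, case preserved)."""
    return seq.translate(_COMP)[::-1]


def encode(seq: str) -> np.ndarray:
    """Map a nucleotide string to uint8 codes A=0 C=1 G=2 T=3, anything else 4."""
    return _BASE_TO_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Rolling k-mer integer codes; windows containing non-ACGT get -1."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    valid = codes < 4
    c = np.where(valid, codes, 0).astype(np.int64)
    out = np.zeros(n, dtype=np.int64)
    ok = np.ones(n, dtype=bool)
    for j in range(k):
        out = out * 4 + c[j : j + n]
        ok &= valid[j : j + n]
    out[~ok] = -1
    return out


def max_segment_score(vals: np.ndarray) -> int:
    """Best max-subarray score (Kadane, vectorized); 0 if all negative."""
    if len(vals) == 0:
        return 0
    cs = np.cumsum(vals)
    prev = np.concatenate(([0], cs[:-1]))
    return max(0, int(np.max(cs - np.minimum.accumulate(prev))))


def extract_segments(vals: np.ndarray, min_score: int) -> list[tuple[int, int, int]]:
    """All disjoint maximal-scoring segments with score >= min_score.

    Iterated best-segment extraction: repeatedly take the highest-scoring
    subarray (ties: smallest end, then longest), record it, then mask it out.
    Deterministic; used identically by the seeded scan and the exhaustive
    oracle so the two agree segment-for-segment.
    """
    vals = vals.astype(np.int64, copy=True)
    out: list[tuple[int, int, int]] = []
    while True:
        cs = np.cumsum(vals)
        prev = np.concatenate(([0], cs[:-1]))
        minprev = np.minimum.accumulate(prev)
        scores = cs - minprev
        best = int(scores.max(initial=0))
        if best < min_score:
            break
        end = int(np.argmax(scores))  # smallest end index with the best score
        # segment start: smallest index attaining the running prefix minimum
        start = int(np.argmax(prev[: end + 1] == minprev[end]))
        out.append((start, end + 1, best))
        vals[start : end + 1] = -(10**9)
    out.sort()
    return out


@dataclass(frozen=True)
class AlnStats:
    matches: int
    mismatches: int
    gap_columns: int

    @property
    def columns(self) -> int:
        return self.matches + self.mismatches + self.gap_columns

    @property
    def identity(self) -> float:
        return self.matches / self.columns if self.columns else 0.0


def _stats_from_cigar(cigar: str) -> AlnStats:
    m = x = g = 0
    for num, op in _CIGAR_RE.findall(cigar):
        n = int(num)
        if op == "=":
            m += n
        elif op in "XM":
            x += n
        else:
            g += n
    return AlnStats(m, x, g)


def align_stats(query: str, target: str, mode: str = "NW") -> AlnStats:
    """edlib alignment column statistics.

    mode "NW": global.  mode "HW": glocal — the whole query aligned inside
    the target (coverage of the query is 1.0 by construction).
    """
    if not query or not target:
        raise ValueError("empty sequence")
    res = edlib.align(query.upper(), target.upper(), mode=mode, task="path")
    return _stats_from_cigar(res["cigar"])


def glocal_identity(a: str, b: str) -> float:
    """Identity (matches / alignment columns) of the shorter sequence aligned
    glocally inside the longer one."""
    q, t = (a, b) if len(a) <= len(b) else (b, a)
    return align_stats(q, t, mode="HW").identity


def seeded_diagonal_hits(
    target: np.ndarray,
    query: np.ndarray,
    k: int,
    min_score: int,
    max_rep_positions: int = 4,
    skip_covered: float | None = 0.98,
) -> list[tuple[int, int, int, int]]:
    """Gap-free local alignments of `query` against `target`.

    Returns (t_start, t_end, score, matches) tuples on the forward
    orientation of both arrays.  Seeds are exact k-mers shared by query and
    target; each seeded diagonal band (clipped to the query extent) is scored
    +1/-1 and maximal segments >= min_score are extracted.

    Per k-mer at most `max_rep_positions` query offsets are indexed — inside
    a tandem query every offset of a repeated k-mer lands on an equivalent
    diagonal, so a few representatives suffice.  `skip_covered`: a diagonal
    whose band is already covered by accepted segments at that fraction is
    skipped (only triggers on internally periodic sequence).
    """
    nq, nt = len(query), len(target)
    if nt < k or nq < k:
        return []
    qcodes = kmer_codes(query, k)
    index: dict[int, list[int]] = {}
    for pos, code in enumerate(qcodes):
        if code < 0:
            continue
        lst = index.get(code)
        if lst is None:
            index[code] = [pos]
        elif len(lst) < max_rep_positions:
            lst.append(pos)
    tcodes = kmer_codes(target, k)
    lib = np.fromiter(index.keys(), dtype=np.int64, count=len(index))
    hits = np.nonzero(np.isin(tcodes, lib))[0]
    diags: set[int] = set()
    for tpos in hits:
        for qpos in index[tcodes[tpos]]:
            diags.add(int(tpos) - qpos)
    covered = np.zeros(nt, dtype=bool) if skip_covered is not None else None
    out: list[tuple[int, int, int, int]] = []
    tv = target
    for d in sorted(diags):
        ts = max(0, d)
        te = min(nt, d + nq)
        if te - ts < k:
            continue
        if covered is not None and covered[ts:te].mean() >= skip_covered:
            continue
        q = query[ts - d : te - d]
        eq = (tv[ts:te] == q) & (tv[ts:te] < 4) & (q < 4)  # N never matches
        vals = np.where(eq, 1, -1).astype(np.int64)
        if max_segment_score(vals) < min_score:
            continue
        for s, e, score in extract_segments(vals, min_score):
            matches = (score + (e - s)) // 2
            out.append((ts + s, ts + e, score, matches))
            if covered is not None:
                covered[ts + s : ts + e] = True
    out.sort()
    return out
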