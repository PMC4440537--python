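"""Homology-based repeat identification, classification and masking.

A classified consensus library (headers ``id#Class/Subclass/Superfamily/Family``)
is aligned against the target genome with a k-mer-seeded, gap-free local
alignment (match +1 / mismatch -1); overlapping hits are resolved
deterministically and rolled up into per-category coverage summaries
(element count, masked length, percent of sequence).

The aligner is gap-free by design: the divergence model used throughout this
package is point substitution, under which every true homology segment lies
on a single alignment diagonal.  This makes the seeded scan exactly
equivalent to an exhaustive all-diagonals scan with the same thresholds,
which is how it is validated.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from ._align import encode, extract_segments, revcomp, seeded_diagonal_hits

KNOWN_CLASSES = (
    "Retroelement",
    "DNA transposon",
    "Unclassified",
    "Small RNA",
    "Satellite",
    "Simple repeat",
    "Low complexity",
)

_EPS = 1e-9


@dataclass(frozen=True)
class RepeatLibraryEntry:
    """One classified repeat consensus."""

    entry_id: str
    classification: tuple[str | None, str | None, str | None, str | None]
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"empty sequence for library entry {self.entry_id!r}")
        if set(self.sequence.upper()) - set("ACGTN"):
            raise ValueError(f"non-ACGTN characters in library entry {self.entry_id!r}")

    @property
    def repeat_class(self) -> str:
        return self.classification[0] or "Unclassified"

    @property
    def superfamily(self) -> str | None:
        return self.classification[2]


@dataclass(frozen=True)
class MaskedSegment:
    """One (overlap-resolved) homology hit on the genome."""

    seq_id: str
    start: int
    end: int
    strand: str
    entry_id: str
    identity: float
    score: int
    category: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class RepeatSummary:
    """Per-category count / masked length / percent roll-up plus totals."""

    total_length: int
    rows: pd.DataFrame = field(default=None)

    def to_tsv(self, path: str | Path) -> None:
        self.rows.to_csv(path, sep="\t", index=False)


def parse_classification(header: str) -> tuple[str, tuple[str | None, ...]]:
    """Split ``id#Class/Subclass/Superfamily/Family`` (trailing levels optional).

    FASTA ids cannot contain spaces, so multi-word class tokens are written
    with underscores (``DNA_transposon``) and normalized here.
    """
    if "#" in header:
        entry_id, path = header.split("#", 1)
        levels = [x.replace("_", " ") or None for x in path.split("/")]
    else:
        entry_id, levels = header, []
    levels = (levels + [None] * 4)[:4]
    if levels[0] is None or levels[0] not in KNOWN_CLASSES:
        levels[0] = "Unclassified"
    return entry_id, tuple(levels)


def load_repeat_library(path: str | Path) -> list[RepeatLibraryEntry]:
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"empty repeat library: {path}")
    entries = []
    seen = set()
    for rec in records:
        header, seq = rec.id, str(rec.seq).upper()
        entry_id, classification = parse_classification(header)
        if entry_id in seen:
            raise ValueError(f"duplicate library entry id: {entry_id!r}")
        seen.add(entry_id)
        entries.append(RepeatLibraryEntry(entry_id, classification, seq))
    return entries


def deduplicate_library(
    entries: list[RepeatLibraryEntry],
    identity_min: float = 0.95,
    coverage_min: float = 0.95,
) -> list[RepeatLibraryEntry]:
    """Greedy longest-first redundancy removal (>=95% identity over >=95% of
    the shorter entry's length joins a cluster; longest member is kept)."""
    from ._align import align_stats

    if not (0 < identity_min <= 1 and 0 < coverage_min <= 1):
        raise ValueError("thresholds must be in (0, 1]")
    ordered = sorted(entries, key=lambda e: (-len(e.sequence), e.entry_id))
    reps: list[RepeatLibraryEntry] = []
    for e in ordered:
        redundant = False
        for rep in reps:
            # glocal: entire shorter entry aligned inside the representative,
            # i.e. coverage of the shorter is 1.0 >= coverage_min
            if align_stats(e.sequence, rep.sequence, mode="HW").identity >= identity_min - _EPS:
                redundant = True
                break
        if not redundant:
            reps.append(e)
    return reps


def mask_sequence(
    seq: str,
    entries: list[RepeatLibraryEntry],
    min_score: int = 225,
    min_identity: float = 0.7,
    seq_id: str = "seq",
    k: int = 11,
    skip_covered: float | None = 0.98,
) -> list[MaskedSegment]:
    """Raw homology segments of every library entry (both strands) on `seq`.

    Returned segments are filtered by score and identity but NOT yet
    overlap-resolved; feed them to :func:`resolve_overlaps` before
    summarization.
    """
    if not entries:
        raise ValueError("empty repeat library")
    target = encode(seq)
    segments: list[MaskedSegment] = []
    for entry in entries:
        for strand, qseq in (("+", entry.sequence), ("-", revcomp(entry.sequence))):
            query = encode(qseq)
            for s, e, score, matches in seeded_diagonal_hits(
                target, query, k=k, min_score=min_score, skip_covered=skip_covered
            ):
                identity = matches / (e - s)
                if identity >= min_identity - _EPS:
                    segments.append(
                        MaskedSegment(
                            seq_id, s, e, strand, entry.entry_id, identity, score,
                            entry.repeat_class,
                        )
                    )
    segments.sort(key=lambda g: (g.seq_id, g.start, g.end, g.entry_id, g.strand))
    return segments


def mask_sequence_oracle(
    seq: str,
    entries: list[RepeatLibraryEntry],
    min_score: int = 225,
    min_identity: float = 0.7,
    seq_id: str = "seq",
) -> list[MaskedSegment]:
    """Exhaustive all-diagonals scan (quadratic); same thresholds and segment
    extraction as :func:`mask_sequence` but with no seeding heuristic.
    Intended for validation on small inputs."""
    if not entries:
        raise ValueError("empty repeat library")
    target = encode(seq)
    nt = len(target)
    segments: list[MaskedSegment] = []
    for entry in entries:
        for strand, qseq in (("+", entry.sequence), ("-", revcomp(entry.sequence))):
            query = encode(qseq)
            nq = len(query)
            for d in range(-nq + 1, nt):
                ts, te = max(0, d), min(nt, d + nq)
                if te <= ts:
                    continue
                q = query[ts - d : te - d]
                t = target[ts:te]
                eq = (t == q) & (t < 4) & (q < 4)
                vals = np.where(eq, 1, -1).astype(np.int64)
                for s, e, score in extract_segments(vals, min_score):
                    matches = (score + (e - s)) // 2
                    identity = matches / (e - s)
                    if identity >= min_identity - _EPS:
                        segments.append(
                            MaskedSegment(
                                seq_id, ts + s, ts + e, strand, entry.entry_id,
                                identity, score, entry.repeat_class,
                            )
                        )
    segments.sort(key=lambda g: (g.seq_id, g.start, g.end, g.entry_id, g.strand))
    return segments


def detect_low_complexity(
    seq: str, window: int = 64, entropy_max: float = 1.0, seq_id: str = "seq"
) -> list[MaskedSegment]:
    """Merged windows whose mononucleotide Shannon entropy <= entropy_max (bits)."""
    if window < 8:
        raise ValueError("window must be >= 8")
    codes = encode(seq)
    n = len(codes)
    if n == 0:
        return []
    w = min(window, n)
    onehot = np.zeros((n + 1, 4), dtype=np.int32)
    for b in range(4):
        onehot[1:, b] = np.cumsum(codes == b)
    counts = onehot[w:] - onehot[:-w]  # counts per window start
    p = counts / w
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = -np.nansum(np.where(p > 0, p * np.log2(p), 0.0), axis=1)
    flagged = np.nonzero(ent <= entropy_max + _EPS)[0]
    segments: list[MaskedSegment] = []
    for i in flagged:
        s, e = int(i), int(i) + w
        if segments and s <= segments[-1].end:
            last = segments[-1]
            segments[-1] = replace(last, end=max(last.end, e), score=max(last.end, e) - last.start)
        else:
            segments.append(
                MaskedSegment(seq_id, s, e, "+", "low_complexity", 1.0, e - s, "Low complexity")
            )
    return segments


def _priority(seg: MaskedSegment):
    # higher score wins overlapping bases; ties: identity, then length, then id
    return (-seg.score, -seg.identity, -(seg.end - seg.start), seg.entry_id, seg.seq_id, seg.start)


def resolve_overlaps(segments: list[MaskedSegment]) -> list[MaskedSegment]:
    """Deterministic overlap resolution.

    Segments are admitted in priority order (score desc, identity desc,
    length desc, entry_id, coordinates).  A loser keeps only its longest
    remaining unoccupied stretch (leftmost on ties); slivers disappear rather
    than inflating element counts.  The result is non-overlapping.
    """
    occupied: dict[str, list[tuple[int, int]]] = {}
    out: list[MaskedSegment] = []
    for seg in sorted(segments, key=_priority):
        iv = occupied.setdefault(seg.seq_id, [])
        free = _subtract(seg.start, seg.end, iv)
        if not free:
            continue
        s, e = max(free, key=lambda x: (x[1] - x[0], -x[0]))
        iv.append((s, e))
        iv.sort()
        if (s, e) != (seg.start, seg.end):
            seg = replace(seg, start=s, end=e, score=min(seg.score, e - s))
        out.append(seg)
    out.sort(key=lambda g: (g.seq_id, g.start))
    return out


def _subtract(start: int, end: int, occupied: list[tuple[int, int]]) -> list[tuple[int, int]]:
    free = []
    cur = start
    for s, e in occupied:
        if e <= cur or s >= end:
            continue
        if s > cur:
            free.append((cur, s))
        cur = max(cur, e)
        if cur >= end:
            break
    if cur < end:
        free.append((cur, end))
    return free


def summarize_repeats(segments: list[MaskedSegment], total_length: int) -> RepeatSummary:
    """Per-category element counts, masked lengths and percentages (2 dp)."""
    if total_length <= 0:
        raise ValueError("total_length must be positive")
    counts: Counter = Counter()
    lengths: Counter = Counter()
    for seg in segments:
        counts[seg.category] += 1
        lengths[seg.category] += seg.length
    rows = []
    for cat in KNOWN_CLASSES:
        rows.append(
            {
                "category": cat,
                "element_count": counts.get(cat, 0),
                "masked_length": lengths.get(cat, 0),
                "percent": round(100.0 * lengths.get(cat, 0) / total_length, 2),
            }
        )
    total_masked = sum(lengths.values())
    rows.append(
        {
            "category": "Total",
            "element_count": sum(counts.values()),
            "masked_length": total_masked,
            "percent": round(100.0 * total_masked / total_length, 2),
        }
    )
    summary = RepeatSummary(total_length=total_length)
    summary.rows = pd.DataFrame(rows)
    return summary


def apply_mask(seq: str, segments: list[MaskedSegment], hard: bool = False) -> str:
    """Soft-mask (lower-case) or hard-mask (N) resolved segments."""
    chars = list(seq)
    for seg in segments:
        for i in range(seg.start, seg.end):
            chars[i] = "N" if hard else chars[i].lower()
    return "".join(chars)


def segments_to_frame(segments: list[MaskedSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "score": g.score,
                "identity": round(g.identity, 4),
                "seq_id": g.seq_id,
                "start": g.start,
                "end": g.end,
                "strand": g.strand,
                "entry_id": g.entry_id,
                "class": g.category,
            }
            for g in segments
        ],
        columns=["score", "identity", "seq_id", "start", "end", "strand", "entry_id", "class"],
    )
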