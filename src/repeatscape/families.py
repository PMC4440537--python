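"""Family-level analysis of LTR-retrotransposon candidates.

Implements the candidate funnel: redundancy removal (95/95 greedy
clustering), novelty filtering against a classified repeat library, family
assignment by the 80-80 rule (two elements are one family when they are at
least 80% identical over at least 80% of their internal/coding regions, or of
their LTRs, or both), genome copy-number estimation (hits at >= 80% identity
and >= 80% coverage), and the membership margin rule replacing the original
manual curation (a hit is a member when it matches the probed family
exclusively, or with identity higher than any other family by a configurable
margin, 10 percentage points by default).

``same_family`` decisions are reflexive and symmetric but not assumed
transitive; family graphs are built by single linkage over pairwise
decisions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from ._align import align_stats, encode, revcomp, seeded_diagonal_hits

logger = logging.getLogger("repeatscape.families")

_EPS = 1e-9


@dataclass
class ElementRecord:
    """An element with optional region annotations for the 80-80 rule."""

    element_id: str
    sequence: str
    ltr5: str | None = None
    ltr3: str | None = None
    internal: str | None = None

    @classmethod
    def from_candidate(cls, cand) -> "ElementRecord":
        return cls(
            element_id=f"{cand.seq_id}:{cand.start}-{cand.end}",
            sequence=cand.sequence,
            ltr5=cand.ltr5_seq,
            ltr3=cand.ltr3_seq,
            internal=cand.internal_seq,
        )


@dataclass(frozen=True)
class FamilyDecision:
    query_id: str
    subject_id: str
    identity: float
    coverage: float
    compared_region: str  # LTRs | internal | whole
    same_family: bool
    rule: str


@dataclass
class CopyNumberEstimate:
    element_id: str
    hits: list[tuple[str, int, int, float, float]]  # (target, start, end, identity, coverage)
    count: int = field(init=False)

    def __post_init__(self):
        self.count = len(self.hits)


def _region_identity(a: str, b: str) -> tuple[float, float]:
    """(identity, coverage) of the shorter sequence aligned glocally inside
    the longer; coverage of the shorter is 1.0 by construction."""
    q, t = (a, b) if len(a) <= len(b) else (b, a)
    return align_stats(q, t, mode="HW").identity, 1.0


def same_family(
    a: ElementRecord,
    b: ElementRecord,
    regions: tuple[str, ...] = ("LTRs", "internal", "whole"),
    identity_min: float = 0.80,
    coverage_min: float = 0.80,
) -> FamilyDecision:
    """80-80 family rule: true when any compared region passes both
    thresholds.  Falls back to whole-element comparison when region
    annotations are missing."""
    tried: list[tuple[str, float, float]] = []
    for region in regions:
        if region == "LTRs":
            if a.ltr5 is None or b.ltr5 is None:
                continue
            ident, cov = _region_identity(a.ltr5, b.ltr5)
        elif region == "internal":
            if a.internal is None or b.internal is None:
                continue
            ident, cov = _region_identity(a.internal, b.internal)
        elif region == "whole":
            ident, cov = _region_identity(a.sequence, b.sequence)
        else:
            raise ValueError(f"unknown region {region!r}")
        tried.append((region, ident, cov))
        if ident >= identity_min - _EPS and cov >= coverage_min - _EPS:
            return FamilyDecision(
                a.element_id, b.element_id, ident, cov, region, True,
                f"{region} {ident:.3f}/{cov:.3f} >= {identity_min}/{coverage_min}",
            )
    if not tried:
        logger.warning(
            "no region annotations for %s vs %s; falling back to whole-element",
            a.element_id, b.element_id,
        )
        ident, cov = _region_identity(a.sequence, b.sequence)
        tried.append(("whole", ident, cov))
        if ident >= identity_min - _EPS and cov >= coverage_min - _EPS:
            return FamilyDecision(
                a.element_id, b.element_id, ident, cov, "whole", True, "whole fallback",
            )
    region, ident, cov = max(tried, key=lambda t: t[1])
    return FamilyDecision(
        a.element_id, b.element_id, ident, cov, region, False,
        f"best {region} {ident:.3f}/{cov:.3f} < {identity_min}/{coverage_min}",
    )


def dedup_candidates(
    items: list[ElementRecord], identity: float = 0.95, coverage: float = 0.95
) -> list[ElementRecord]:
    """Greedy longest-first clustering; one representative per cluster."""
    if not items:
        raise ValueError("need at least one candidate")
    ordered = sorted(items, key=lambda x: (-len(x.sequence), x.element_id))
    reps: list[ElementRecord] = []
    for item in ordered:
        joined = False
        for rep in reps:
            ident, cov = _region_identity(item.sequence, rep.sequence)
            if ident >= identity - _EPS and cov >= coverage - _EPS:
                joined = True
                break
        if not joined:
            reps.append(item)
    return reps


def filter_known(
    candidates: list[ElementRecord],
    repeat_library,
    identity_min: float = 0.80,
    coverage_min: float = 0.80,
) -> tuple[list[ElementRecord], list[FamilyDecision]]:
    """Exclude candidates that fall into a known family of the library by the
    80-80 rule; returns (novel, exclusion decisions)."""
    novel: list[ElementRecord] = []
    decisions: list[FamilyDecision] = []
    for cand in candidates:
        hit = None
        for entry in repeat_library:
            rec = ElementRecord(entry.entry_id, entry.sequence)
            dec = same_family(
                cand, rec, regions=("whole",), identity_min=identity_min, coverage_min=coverage_min
            )
            if dec.same_family:
                hit = dec
                break
        if hit is None:
            novel.append(cand)
        else:
            decisions.append(hit)
            logger.info("excluded %s as known (%s)", cand.element_id, hit.rule)
    return novel, decisions


def estimate_copy_number(
    element: ElementRecord,
    genome_sequences: dict[str, str],
    identity_min: float = 0.80,
    coverage_min: float = 0.80,
    k: int = 11,
) -> CopyNumberEstimate:
    """Count non-overlapping genomic hits at >= identity_min over
    >= coverage_min of the element length (both strands)."""
    if not genome_sequences:
        raise ValueError("genome_sequences must be non-empty")
    elen = len(element.sequence)
    min_score = max(20, int(elen * coverage_min * (2 * identity_min - 1) * 0.5))
    hits: list[tuple[str, int, int, float, float, int]] = []
    for target_id in sorted(genome_sequences):
        target = encode(genome_sequences[target_id])
        for qseq in (element.sequence, revcomp(element.sequence)):
            query = encode(qseq)
            for s, e, score, matches in seeded_diagonal_hits(
                target, query, k=k, min_score=min_score
            ):
                ident = matches / (e - s)
                cov = (e - s) / elen
                if ident >= identity_min - _EPS and cov >= coverage_min - _EPS:
                    hits.append((target_id, s, e, ident, cov, score))
    # greedy non-overlapping by score
    hits.sort(key=lambda h: (-h[5], h[0], h[1]))
    chosen: list[tuple[str, int, int, float, float]] = []
    for tid, s, e, ident, cov, _score in hits:
        if any(t == tid and s < ce and cs < e for t, cs, ce, _, _ in chosen):
            continue
        chosen.append((tid, s, e, ident, cov))
    chosen.sort()
    return CopyNumberEstimate(element.element_id, chosen)


def assign_membership(
    target_identity: float,
    other_identities: list[float],
    margin: float = 0.10,
) -> bool:
    """Membership rule: member when no other family aligns at all, or the
    best other-family identity is lower than the target identity by at least
    the margin."""
    if not other_identities:
        logger.info("membership: exclusive hit at identity %.3f -> member", target_identity)
        return True
    gap = target_identity - max(other_identities)
    member = gap >= margin - _EPS
    logger.info(
        "membership: target %.3f vs best other %.3f (gap %.3f, margin %.2f) -> %s",
        target_identity, max(other_identities), gap, margin, "member" if member else "not member",
    )
    return member


def single_linkage_families(
    elements: list[ElementRecord],
    regions: tuple[str, ...] = ("LTRs", "internal", "whole"),
    identity_min: float = 0.80,
    coverage_min: float = 0.80,
) -> list[list[ElementRecord]]:
    """Partition elements into families by single linkage over pairwise
    same_family decisions."""
    n = len(elements)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            dec = same_family(elements[i], elements[j], regions, identity_min, coverage_min)
            if dec.same_family:
                parent[find(i)] = find(j)
    groups: dict[int, list[ElementRecord]] = {}
    for i, el in enumerate(elements):
        groups.setdefault(find(i), []).append(el)
    fams = sorted(groups.values(), key=lambda g: min(e.element_id for e in g))
    return fams


def make_designation(superfamily: str | None, family_name: str, accession: str) -> str:
    """Family designation: RLC (Copia) / RLG (Gypsy) / RLX (unknown) prefix
    plus family name and accession."""
    prefix = {"Copia": "RLC", "Gypsy": "RLG"}.get(superfamily or "", "RLX")
    return f"{prefix}_{family_name}_{accession}"
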