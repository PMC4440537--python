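"""Microsatellite (SSR) detection, canonicalization, classification and summaries.

SSRs are perfect tandem repeats with unit length 1-6 nt.  A motif is reported
in canonical form: the lexicographically smallest string among all rotations
of the motif and all rotations of its reverse complement, so that e.g. (GA)n
and (TC)n — the same locus read from either strand — collapse to one class.
Motifs are classified compositionally: AT-rich (>50% A/T), GC-rich (>50%
G/C), or AT/GC-balanced (exactly 50%, only possible for even unit sizes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from ._align import encode, revcomp

SSR_CLASSES = ("AT-rich", "GC-rich", "AT/GC-balanced")

#: default minimum copy numbers per unit size (mono..hexa)
DEFAULT_MIN_COPIES = {1: 10, 2: 6, 3: 5, 4: 5, 5: 5, 6: 5}


@dataclass(frozen=True)
class SSRLocus:
    seq_id: str
    start: int
    end: int
    motif: str  # canonical unit
    unit_length: int
    copy_number: float
    ssr_class: str

    @property
    def length(self) -> int:
        return self.end - self.start


def _is_reducible(motif: str) -> bool:
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return True
    return False


def _validate_motif(motif: str) -> None:
    if not motif or len(motif) > 6:
        raise ValueError(f"motif length must be 1-6: {motif!r}")
    if set(motif) - set("ACGT"):
        raise ValueError(f"motif must be over ACGT: {motif!r}")
    if _is_reducible(motif):
        raise ValueError(f"motif is a tandem of a shorter unit: {motif!r}")


def canonical_motif(motif: str) -> str:
    """Lexicographically smallest rotation of the motif or of its reverse
    complement.  Idempotent; strand- and phase-invariant."""
    motif = motif.upper()
    _validate_motif(motif)
    rc = revcomp(motif)
    candidates = {motif[i:] + motif[:i] for i in range(len(motif))}
    candidates |= {rc[i:] + rc[:i] for i in range(len(rc))}
    return min(candidates)


def classify_ssr(motif: str, strict_balanced: bool = False) -> str:
    """Compositional class of a canonical motif.

    With ``strict_balanced`` the balanced class is restricted to di- and
    tetranucleotide motifs; a hexamer at exactly 50% AT is then binned as
    GC-rich (an arbitrary but documented tie resolution).
    """
    at = sum(1 for b in motif if b in "AT") / len(motif)
    if at > 0.5:
        return "AT-rich"
    if at < 0.5:
        return "GC-rich"
    if strict_balanced and len(motif) not in (2, 4):
        return "GC-rich"
    return "AT/GC-balanced"


def find_ssrs(
    seq: str,
    min_copies_by_unit: Mapping[int, int] | None = None,
    min_tract_length: int = 0,
    seq_id: str = "seq",
    strict_balanced: bool = False,
) -> list[SSRLocus]:
    """Maximal perfect tandem tracts, each reported under its smallest unit.

    A tract of unit u at [s, e) satisfies seq[i] == seq[i+u] for all
    i in [s, e-u); maximality means it extends neither left nor right.  A
    tract whose motif is itself a tandem of a shorter unit belongs to that
    unit and is skipped; tracts contained in an already-reported smaller-unit
    tract are suppressed.
    """
    mins = dict(DEFAULT_MIN_COPIES)
    if min_copies_by_unit:
        mins.update(min_copies_by_unit)
    if any(v <= 0 for v in mins.values()) or min_tract_length < 0:
        raise ValueError("thresholds must be positive")
    codes = encode(seq)
    n = len(codes)
    loci: list[SSRLocus] = []
    reported: list[tuple[int, int]] = []  # intervals of accepted tracts (any unit)
    for u in range(1, 7):
        if n < 2 * u:
            continue
        eq = (codes[:-u] == codes[u:]) & (codes[:-u] < 4) & (codes[u:] < 4)
        if not eq.any():
            continue
        padded = np.concatenate(([False], eq, [False]))
        diff = np.diff(padded.astype(np.int8))
        run_starts = np.nonzero(diff == 1)[0]
        run_ends = np.nonzero(diff == -1)[0]
        for rs, re_ in zip(run_starts, run_ends):
            s, e = int(rs), int(re_) + u  # tract interval
            length = e - s
            if length < u * mins[u] or length < min_tract_length:
                continue
            motif = seq[s : s + u].upper()
            if _is_reducible(motif):
                continue  # belongs to a smaller unit
            if any(cs <= s and e <= ce for cs, ce in reported):
                continue
            canon = canonical_motif(motif)
            loci.append(
                SSRLocus(
                    seq_id, s, e, canon, u, length / u, classify_ssr(canon, strict_balanced)
                )
            )
            reported.append((s, e))
    loci.sort(key=lambda x: (x.start, x.unit_length))
    return loci


def find_ssrs_oracle(
    seq: str,
    min_copies_by_unit: Mapping[int, int] | None = None,
    min_tract_length: int = 0,
    seq_id: str = "seq",
) -> list[SSRLocus]:
    """Brute-force per-position extension scan; validation oracle for
    :func:`find_ssrs` on small inputs."""
    mins = dict(DEFAULT_MIN_COPIES)
    if min_copies_by_unit:
        mins.update(min_copies_by_unit)
    s_up = seq.upper()
    n = len(s_up)
    loci: list[SSRLocus] = []
    reported: list[tuple[int, int]] = []
    for u in range(1, 7):
        i = 0
        while i + 2 * u <= n:
            if any(c not in "ACGT" for c in s_up[i : i + u]):
                i += 1
                continue
            # extend the perfect tandem starting at i as far as possible
            j = i + u
            while j < n and s_up[j] in "ACGT" and s_up[j] == s_up[j - u]:
                j += 1
            if j - i >= 2 * u:
                # maximal to the left?
                if i == 0 or s_up[i - 1] not in "ACGT" or s_up[i - 1] != s_up[i - 1 + u]:
                    length = j - i
                    motif = s_up[i : i + u]
                    if (
                        length >= u * mins[u]
                        and length >= min_tract_length
                        and not _is_reducible(motif)
                        and not any(cs <= i and j <= ce for cs, ce in reported)
                    ):
                        canon = canonical_motif(motif)
                        loci.append(
                            SSRLocus(seq_id, i, j, canon, u, length / u, classify_ssr(canon))
                        )
                        reported.append((i, j))
                i = j - u + 1
            else:
                i += 1
    loci.sort(key=lambda x: (x.start, x.unit_length))
    return loci


def ssr_frequency(loci: list[SSRLocus], sequence_total_length: int) -> float:
    """kb of sequence per SSR ("one SSR per N kb"); +inf when no SSRs."""
    if sequence_total_length <= 0:
        raise ValueError("sequence_total_length must be positive")
    if not loci:
        return math.inf
    return sequence_total_length / len(loci) / 1000.0


def motif_specificity(catalogs: Mapping[str, Iterable[str]]) -> dict[str, str]:
    """Motifs present in exactly one named catalog -> owning catalog name."""
    if len(catalogs) < 2:
        raise ValueError("need at least two named catalogs")
    membership: dict[str, set[str]] = {}
    for name, motifs in catalogs.items():
        for m in motifs:
            membership.setdefault(m, set()).add(name)
    return {m: next(iter(names)) for m, names in sorted(membership.items()) if len(names) == 1}


def summarize_catalog(loci: list[SSRLocus], sequence_total_length: int) -> pd.DataFrame:
    """Unit-size counts and class fractions (percent), plus frequency."""
    unit_names = {1: "mono", 2: "di", 3: "tri", 4: "tetra", 5: "penta", 6: "hexa"}
    rows = []
    for u in range(1, 7):
        sub = [x for x in loci if x.unit_length == u]
        row = {"unit": unit_names[u], "count": len(sub)}
        for cls in SSR_CLASSES:
            row[cls] = sum(1 for x in sub if x.ssr_class == cls)
        rows.append(row)
    total = {"unit": "total", "count": len(loci)}
    for cls in SSR_CLASSES:
        total[cls] = sum(1 for x in loci if x.ssr_class == cls)
    rows.append(total)
    df = pd.DataFrame(rows)
    df["class_percent_of_total"] = [
        round(100.0 * r["count"] / len(loci), 2) if loci else 0.0 for r in rows
    ]
    df.attrs["kb_per_ssr"] = ssr_frequency(loci, sequence_total_length)
    return df


def loci_to_frame(loci: list[SSRLocus]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "seq_id": x.seq_id,
                "start": x.start,
                "end": x.end,
                "motif": x.motif,
                "unit_length": x.unit_length,
                "copies": round(x.copy_number, 3),
                "class": x.ssr_class,
            }
            for x in loci
        ],
        columns=["seq_id", "start", "end", "motif", "unit_length", "copies", "class"],
    )
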