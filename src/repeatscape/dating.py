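"""Insertion-time estimation from LTR-LTR divergence.

At integration the two LTRs of a retrotransposon are identical; they then
accumulate point substitutions independently, so the divergence K between
them clocks the insertion: T = K / (2 r), with r the substitution rate per
site per year (default 1.36e-8).  K is the p-distance of the aligned LTR
pair (gap columns excluded) either raw or with the Jukes-Cantor correction
K = -(3/4) ln(1 - (4/3) p).

The raw p-distance is the default model: at the divergences where LTR dating
is informative (p well below 0.2) the JC correction is a second-order
adjustment, and the simpler model keeps the estimate directly interpretable;
the model used is always recorded in the output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from ._align import AlnStats, align_stats

DEFAULT_RATE_R = 1.36e-8

MODELS = ("raw_p", "jukes_cantor")


@dataclass(frozen=True)
class AgeEstimate:
    element_id: str
    aligned_columns: int  # gap-free columns
    mismatches: int
    p_distance: float
    model: str
    K: float
    r: float
    T: float  # years

    @property
    def T_myr(self) -> float:
        return self.T / 1e6


def align_ltr_pair(ltr5: str, ltr3: str) -> AlnStats:
    """Global alignment of the two LTRs; gap columns are excluded from the
    distance downstream ("per aligned site").

    Equal-length pairs are compared positionally: under a substitution-only
    divergence process the gapless alignment is the correct global alignment,
    and an edit-distance aligner may otherwise explain adjacent mismatches as
    an equal-cost indel pair, deflating the mismatch count.  Unequal lengths
    fall back to an edit-distance global alignment.
    """
    if not ltr5 or not ltr3:
        raise ValueError("empty LTR sequence")
    a, b = ltr5.upper(), ltr3.upper()
    if len(a) == len(b):
        mism = sum(x != y for x, y in zip(a, b))
        return AlnStats(len(a) - mism, mism, 0)
    return align_stats(a, b, mode="NW")


def p_distance(stats: AlnStats) -> float:
    cols = stats.matches + stats.mismatches
    if cols == 0:
        raise ValueError("no gap-free aligned columns")
    return stats.mismatches / cols


def estimate_K(p: float, model: str = "raw_p") -> float:
    """Substitutions per site from the p-distance."""
    if model == "raw_p":
        return p
    if model == "jukes_cantor":
        if p >= 0.75:
            raise ValueError(f"Jukes-Cantor distance undefined for p = {p} >= 0.75")
        return -0.75 * math.log(1.0 - (4.0 / 3.0) * p)
    raise ValueError(f"unknown model {model!r}")


def insertion_time(K: float, r: float = DEFAULT_RATE_R) -> float:
    """T = K / (2 r), in years."""
    if K < 0:
        raise ValueError("K must be >= 0")
    if r <= 0:
        raise ValueError("r must be positive")
    return K / (2.0 * r)


def date_ltr_pair(
    element_id: str,
    ltr5: str,
    ltr3: str,
    model: str = "raw_p",
    r: float = DEFAULT_RATE_R,
) -> AgeEstimate:
    stats = align_ltr_pair(ltr5, ltr3)
    p = p_distance(stats)
    K = estimate_K(p, model)
    return AgeEstimate(
        element_id=element_id,
        aligned_columns=stats.matches + stats.mismatches,
        mismatches=stats.mismatches,
        p_distance=p,
        model=model,
        K=K,
        r=r,
        T=insertion_time(K, r),
    )


def ages_to_frame(estimates: list[AgeEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "element_id": a.element_id,
                "aligned_columns": a.aligned_columns,
                "mismatches": a.mismatches,
                "p": round(a.p_distance, 6),
                "model": a.model,
                "K": round(a.K, 6),
                "T_years": round(a.T, 1),
                "T_Myr": round(a.T_myr, 4),
            }
            for a in estimates
        ],
        columns=["element_id", "aligned_columns", "mismatches", "p", "model", "K", "T_years", "T_Myr"],
    )
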