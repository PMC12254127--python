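"""Position-wise nucleotide enrichment between high- and low-activity guides.

Guides are split at the median activity (strictly above goes high, ties
fall low — robust to the skewed activity distributions typical of editing
assays).  For each position and nucleotide, the high-activity group is the
foreground and the low-activity group supplies the background frequency;
the score is the signed log10 binomial tail probability of the foreground
count, positive for enrichment and negative for depletion, with a
Bonferroni significance line over all positions x 4 tests.  This is the
same statistic family as sequence-logo enrichment tools (pLogo-style),
implemented in-package so the analysis is self-contained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sgrna_encoder import SgRnaRecord

NUCLEOTIDES = "ACGT"

#: Default analysis window: the 23-nt protospacer+PAM region, which is the
#: primary determinant of activity; the constant scaffold carries no signal.
DEFAULT_RANGE = range(0, 23)

_P_FLOOR = 1e-300


@dataclass
class ActivityGroups:
    """Median-threshold split of records into high and low activity."""

    high: list[SgRnaRecord]
    low: list[SgRnaRecord]
    threshold: float
    degenerate: bool = False


def median_split(records: Sequence[SgRnaRecord]) -> ActivityGroups:
    """Split at the median activity: strictly above goes high, ties go low.

    For even n the median is the average of the two middle values.  If all
    activities are identical the high group is empty; a warning is issued
    and the result is flagged degenerate.
    """
    if len(records) < 2:
        raise ValueError("median split requires at least 2 records")
    activities = np.array([r.activity for r in records])
    threshold = float(np.median(activities))
    high = [r for r in records if r.activity > threshold]
    low = [r for r in records if r.activity <= threshold]
    degenerate = not high
    if degenerate:
        warnings.warn("all activities tie at the median; high group is empty")
    return ActivityGroups(high=high, low=low, threshold=threshold,
                          degenerate=degenerate)


@dataclass
class EnrichmentMatrix:
    """Signed -log10 binomial tail scores per (position, nucleotide)."""

    scores: np.ndarray            # (n_positions, 4)
    fg_counts: np.ndarray         # (n_positions, 4) foreground occurrences
    bg_counts: np.ndarray         # (n_positions, 4) background occurrences
    positions: list[int]          # 0-based positions analysed
    significance_threshold: float  # Bonferroni line on the |score| scale
    alpha: float = 0.05

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: position (1-based), nucleotide, score, counts."""
        rows = []
        for i, pos in enumerate(self.positions):
            for j, nt in enumerate(NUCLEOTIDES):
                rows.append({
                    "position": pos + 1,
                    "nucleotide": nt,
                    "score": self.scores[i, j],
                    "fg_count": int(self.fg_counts[i, j]),
                    "bg_count": int(self.bg_counts[i, j]),
                    "significant": abs(self.scores[i, j])
                    >= self.significance_threshold,
                })
        return pd.DataFrame(rows)

    def top_cells(self, k: int) -> list[tuple[int, str]]:
        """The k (0-based position, nucleotide) cells of largest |score|."""
        flat = np.argsort(np.abs(self.scores), axis=None)[::-1][:k]
        return [(self.positions[i // 4], NUCLEOTIDES[i % 4]) for i in flat]


def enrichment(groups: ActivityGroups,
               positions: Sequence[int] | range = DEFAULT_RANGE,
               alpha: float = 0.05) -> EnrichmentMatrix:
    """Position-wise nucleotide enrichment of high- vs low-activity guides.

    For each position and nucleotide the low group's frequency is the
    background probability p; with k foreground occurrences out of n, the
    score is ``-log10 P(X >= k)`` when the foreground frequency exceeds p
    (enrichment) and ``log10 P(X <= k)`` otherwise (depletion, negative).
    A background frequency of zero for an observed foreground nucleotide
    falls back to a +1 pseudocount (logged as a warning).  Probabilities
    are floored at 1e-300 so scores stay finite.
    """
    if not groups.high or not groups.low:
        raise ValueError("both activity groups must be non-empty")
    positions = list(positions)
    length = len(groups.high[0].sequence)
    for r in list(groups.high) + list(groups.low):
        if len(r.sequence) != length:
            raise ValueError("all records must have equal sequence length")
    if positions and (min(positions) < 0 or max(positions) >= length):
        raise ValueError("analysis positions outside the sequence")

    fg = _count_matrix(groups.high, positions)
    bg = _count_matrix(groups.low, positions)
    n_fg = len(groups.high)
    n_bg = len(groups.low)
    scores = np.zeros_like(fg, dtype=float)
    for i in range(fg.shape[0]):
        for j in range(4):
            k = int(fg[i, j])
            p = bg[i, j] / n_bg
            if p == 0.0 and k > 0:
                warnings.warn(
                    f"zero background frequency for {NUCLEOTIDES[j]} at "
                    f"position {positions[i] + 1}; using +1 pseudocount"
                )
                p = 1.0 / (n_bg + 4)
            if p == 0.0:
                # absent in both groups: no evidence either way
                scores[i, j] = 0.0
                continue
            if k / n_fg > p:
                tail = max(float(stats.binom.sf(k - 1, n_fg, p)), _P_FLOOR)
                scores[i, j] = -np.log10(tail)
            else:
                tail = max(float(stats.binom.cdf(k, n_fg, p)), _P_FLOOR)
                scores[i, j] = np.log10(tail)

    n_tests = len(positions) * 4
    threshold = -np.log10(alpha / n_tests) if n_tests else np.inf
    return EnrichmentMatrix(scores=scores, fg_counts=fg, bg_counts=bg,
                            positions=positions,
                            significance_threshold=threshold, alpha=alpha)


def _count_matrix(records: Sequence[SgRnaRecord],
                  positions: Sequence[int]) -> np.ndarray:
    counts = np.zeros((len(positions), 4), dtype=int)
    index = {nt: j for j, nt in enumerate(NUCLEOTIDES)}
    for r in records:
        for i, pos in enumerate(positions):
            j = index.get(r.sequence[pos])
            if j is not None:  # 'N' positions are not counted
                counts[i, j] += 1
    return counts
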