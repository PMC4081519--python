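"""Per-column conservation analysis of protein alignments.

Conservation is scored as information content, ``log2(20) − H``, where
``H`` is the Shannon entropy of a column's residue frequencies computed
over non-gap residues.  This is a transparent, alignment-only statistic;
it deliberately does not attempt phylogeny-aware rate estimation, so
scores are comparable within an alignment but are not evolutionary
rates.  The module also provides:

* 5-residue moving-average smoothing (edge-truncated, masked columns
  skipped) for histogram-style conservation tracks;
* a reference-sequence column map so two family alignments (e.g. RGK
  vs. Ras) can be compared residue-by-residue in a shared numbering;
* differential conservation (family A minus family B) through that map;
* sequence-logo letter heights (``h_a = f_a · R``);
* pairwise percent identity over co-aligned columns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import UndefinedResultError, UsageError
from .seqio import AMINO_ACIDS, AlignmentBlock

MAX_SCORE = math.log2(20)  # a fully conserved column
DEFAULT_WINDOW = 5
DEFAULT_GAP_CUTOFF = 0.5


@dataclass(frozen=True)
class ConservationProfile:
    """Per-column information content of an alignment (bits)."""

    scores: tuple[float, ...]
    smoothed: tuple[float, ...]
    mask: tuple[bool, ...]  # True where the gap fraction exceeded the cutoff
    window: int
    gap_cutoff: float
    method: str = "information-content"

    @property
    def n_columns(self) -> int:
        return len(self.scores)


def _column_entropy(column: str) -> tuple[float, int]:
    """Shannon entropy (bits) over the non-gap, non-'X' residues and
    their count."""
    counts: dict[str, int] = {}
    for ch in column:
        if ch in AMINO_ACIDS:
            counts[ch] = counts.get(ch, 0) + 1
    n = sum(counts.values())
    if n == 0:
        return 0.0, 0
    h = 0.0
    for aa in sorted(counts):  # fixed order: row-permutation invariant to the bit
        f = counts[aa] / n
        h -= f * math.log2(f)
    return h, n


def conservation_profile(
    alignment: AlignmentBlock,
    window: int = DEFAULT_WINDOW,
    gap_cutoff: float = DEFAULT_GAP_CUTOFF,
) -> ConservationProfile:
    """Column-wise information content with moving-average smoothing.

    A column's score is ``log2 20 − H`` over its non-gap residues
    (an all-gap column scores 0).  Columns whose gap fraction exceeds
    ``gap_cutoff`` keep their score but are masked, and smoothing — a
    centred moving average of width ``window`` (odd), truncated at the
    profile edges — averages over unmasked columns only.  A masked
    column's smoothed value is the average of its unmasked neighbours.
    """
    if window < 1 or window % 2 == 0:
        raise UsageError(f"window must be odd and ≥ 1, got {window}")
    if not 0 <= gap_cutoff <= 1:
        raise UsageError(f"gap_cutoff must be in [0, 1], got {gap_cutoff}")
    n_rows = alignment.n_rows
    scores, mask = [], []
    for j in range(alignment.n_columns):
        col = alignment.column(j)
        h, n_obs = _column_entropy(col)
        scores.append(MAX_SCORE - h if n_obs > 0 else 0.0)
        gap_fraction = col.count("-") / n_rows
        mask.append(gap_fraction > gap_cutoff)

    half = window // 2
    smoothed = []
    for j in range(len(scores)):
        vals = [
            scores[k]
            for k in range(max(0, j - half), min(len(scores), j + half + 1))
            if not mask[k]
        ]
        smoothed.append(sum(vals) / len(vals) if vals else float("nan"))

    return ConservationProfile(
        scores=tuple(scores),
        smoothed=tuple(smoothed),
        mask=tuple(mask),
        window=window,
        gap_cutoff=gap_cutoff,
    )


def map_columns(alignment: AlignmentBlock, reference_id: str) -> dict[int, int]:
    """Map reference residue numbers (1-based) to alignment column indices.

    Only non-gap reference positions are mapped; the map is a bijection
    onto the reference's non-gap columns.  An all-gap reference row
    yields an empty map.
    """
    row = alignment.row(reference_id)  # raises UsageError when absent
    col_map: dict[int, int] = {}
    residue = 0
    for j, ch in enumerate(row):
        if ch != "-":
            residue += 1
            col_map[residue] = j
    return col_map


@dataclass(frozen=True)
class DifferentialProfile:
    """Family A minus family B conservation at shared reference residues."""

    reference_id: str
    differences: dict[int, float]       # reference residue number -> A − B
    omitted_residues: tuple[int, ...]   # present in one alignment only


def differential_conservation(
    profile_a: ConservationProfile,
    alignment_a: AlignmentBlock,
    profile_b: ConservationProfile,
    alignment_b: AlignmentBlock,
    reference_id: str,
) -> DifferentialProfile:
    """Per-residue conservation difference (A − B) through a shared
    reference sequence.

    The reference must be a row of both alignments; each of its residues
    present (non-gap) in both is assigned
    ``profile_a[col_a] − profile_b[col_b]``.  Residues gapped in either
    alignment are omitted and listed.  No smoothing is applied.
    """
    map_a = map_columns(alignment_a, reference_id)
    map_b = map_columns(alignment_b, reference_id)
    shared = sorted(set(map_a) & set(map_b))
    omitted = tuple(sorted(set(map_a) ^ set(map_b)))
    diffs = {
        r: profile_a.scores[map_a[r]] - profile_b.scores[map_b[r]] for r in shared
    }
    return DifferentialProfile(
        reference_id=reference_id, differences=diffs, omitted_residues=omitted
    )


@dataclass(frozen=True)
class LogoMatrix:
    """Sequence-logo information content and letter heights per column."""

    span: tuple[int, int]                       # half-open column interval
    information: tuple[float, ...]              # R per column, bits
    heights: tuple[dict[str, float], ...]       # residue -> f_a * R

    @property
    def n_columns(self) -> int:
        return len(self.information)


def logo_matrix(
    alignment: AlignmentBlock,
    span: tuple[int, int] | None = None,
    small_sample_correction: bool = False,
) -> LogoMatrix:
    """Logo letter heights for a column span (default: terminal 20 columns).

    Per column, ``R = log2 20 − H`` (gaps excluded) and each observed
    residue gets height ``f_a · R``; heights therefore sum to R.  An
    all-gap column has R = 0 and no letters.  With
    ``small_sample_correction`` the standard approximation
    ``e_n = 19 / (2·ln 2·n)`` is subtracted from R (floored at 0).
    """
    n_cols = alignment.n_columns
    if span is None:
        span = (max(0, n_cols - 20), n_cols)
    lo, hi = span
    if not (0 <= lo < hi <= n_cols):
        raise UsageError(f"invalid column span {span} for {n_cols} columns")
    information, heights = [], []
    for j in range(lo, hi):
        col = alignment.column(j)
        h, n_obs = _column_entropy(col)
        if n_obs == 0:
            information.append(0.0)
            heights.append({})
            continue
        r = MAX_SCORE - h
        if small_sample_correction:
            r = max(0.0, r - 19.0 / (2.0 * math.log(2) * n_obs))
        freqs: dict[str, int] = {}
        for ch in col:
            if ch in AMINO_ACIDS:
                freqs[ch] = freqs.get(ch, 0) + 1
        information.append(r)
        heights.append({aa: (c / n_obs) * r for aa, c in sorted(freqs.items())})
    return LogoMatrix(
        span=(lo, hi), information=tuple(information), heights=tuple(heights)
    )


def percent_identity(row_a: str, row_b: str) -> float:
    """Percent identity over columns where both rows are non-gap."""
    if len(row_a) != len(row_b):
        raise UsageError("rows must come from the same alignment (equal length)")
    co_aligned = identical = 0
    for a, b in zip(row_a, row_b):
        if a != "-" and b != "-":
            co_aligned += 1
            if a == b:
                identical += 1
    if co_aligned == 0:
        raise UndefinedResultError("no co-aligned columns between the two rows")
    return 100.0 * identical / co_aligned
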