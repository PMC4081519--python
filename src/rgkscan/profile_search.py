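"""Pattern-hit-initiated iterative profile (PSSM) search.

A two-iteration search over a protein database, modelled on pattern-hit
initiated search followed by one round of position-specific iteration:

1. **Iteration 1** — candidates are records whose C-terminus carries an
   anchored signature hit; each is scored with a profile built from a
   seed alignment of the C-terminal region and included when its
   z-score against an empirical null clears the threshold.
2. **Iteration 2** — the profile is rebuilt from the seed rows plus the
   iteration-1 inclusions and *every* database record is rescored (the
   pattern requirement is dropped), so profile-similar homologs whose
   signature has drifted can still be recovered.

Profiles are per-column log-odds matrices in bits with pseudocounts:
``score(a) = log2(p_a / q_a)`` where ``p_a = (c_a + α·q_a) / (N + α)``,
``c_a`` the residue count in the column, ``N`` the non-gap observation
count, ``q`` the background distribution and ``α > 0`` the pseudocount
weight.  Statistical significance uses a seeded empirical null (best
window score on sequences drawn i.i.d. from the background) rather than
analytic extreme-value statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DegenerateNullError, UsageError
from .motif_engine import MotifHit, MotifPattern, scan_c_terminus
from .seqio import AMINO_ACIDS, AlignmentBlock, ProteinRecord

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
N_RESIDUES = len(AMINO_ACIDS)

DEFAULT_ALPHA = 0.5
DEFAULT_N_SHUFFLES = 500
DEFAULT_Z_THRESHOLD = 5.0
#: span of the C-terminal region the seed alignment covers
C_TERMINAL_WINDOW = 40


def uniform_background() -> np.ndarray:
    return np.full(N_RESIDUES, 1.0 / N_RESIDUES)


@dataclass(frozen=True)
class ProfileModel:
    """Position-specific log-odds matrix (bits) over the 20 residues."""

    columns: np.ndarray          # shape (length, 20), bits
    alpha: float
    background: np.ndarray      # shape (20,), sums to 1
    source: tuple[str, ...]      # ids of the sequences the profile was built from

    @property
    def length(self) -> int:
        return int(self.columns.shape[0])


def build_profile(
    alignment: AlignmentBlock,
    alpha: float = DEFAULT_ALPHA,
    background: np.ndarray | Sequence[float] | None = None,
) -> ProfileModel:
    """Build a log-odds profile from an alignment.

    Gaps are excluded from the counts; a column with no non-gap
    observations scores 0 for every residue.  'X' residues are ignored
    (treated as missing observations).
    """
    if alpha <= 0:
        raise UsageError(f"pseudocount weight must be > 0, got {alpha}")
    q = uniform_background() if background is None else np.asarray(background, dtype=float)
    if q.shape != (N_RESIDUES,) or np.any(q <= 0):
        raise UsageError("background must be 20 strictly positive frequencies")
    q = q / q.sum()

    n_cols = alignment.n_columns
    scores = np.zeros((n_cols, N_RESIDUES))
    for j in range(n_cols):
        counts = np.zeros(N_RESIDUES)
        for _, seq in alignment.rows:
            ch = seq[j]
            idx = _AA_INDEX.get(ch)
            if idx is not None:
                counts[idx] += 1
        n_obs = counts.sum()
        if n_obs == 0:
            continue  # all-gap column scores 0 everywhere
        p = (counts + alpha * q) / (n_obs + alpha)
        scores[j] = np.log2(p / q)
    return ProfileModel(
        columns=scores, alpha=alpha, background=q, source=alignment.ids
    )


def score_window(seq: str, profile: ProfileModel, offset: int) -> float:
    """Sum of column scores for the window at ``offset``; 'X' scores 0."""
    if offset < 0 or offset > len(seq) - profile.length:
        raise UsageError(
            f"offset {offset} out of range for sequence length {len(seq)} "
            f"and profile length {profile.length}"
        )
    total = 0.0
    for i in range(profile.length):
        idx = _AA_INDEX.get(seq[offset + i])
        if idx is not None:
            total += profile.columns[i, idx]
    return float(total)


def best_window_score(seq: str, profile: ProfileModel) -> tuple[float, int]:
    """Best window score over all offsets and its (leftmost) offset."""
    if len(seq) < profile.length:
        raise UsageError("sequence shorter than profile")
    idx = np.array([_AA_INDEX.get(ch, -1) for ch in seq])
    pos = np.arange(profile.length)
    best, best_off = -np.inf, 0
    for off in range(len(seq) - profile.length + 1):
        window = idx[off : off + profile.length]
        mask = window >= 0  # 'X' contributes 0
        s = float(profile.columns[pos[mask], window[mask]].sum())
        if s > best:
            best, best_off = s, off
    return best, best_off


def empirical_null(
    profile: ProfileModel,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    seed: int = 0,
    length_model: int | None = None,
) -> tuple[float, float]:
    """Mean and SD of best-window scores on background sequences.

    ``n_shuffles`` sequences of length ``length_model`` (default: the
    profile length, i.e. a single window) are drawn i.i.d. from the
    profile background and each one's best window score recorded.
    Deterministic for a fixed seed.
    """
    if n_shuffles < 100:
        raise UsageError(f"n_shuffles must be ≥ 100, got {n_shuffles}")
    length = profile.length if length_model is None else int(length_model)
    if length < profile.length:
        raise UsageError("null sequence length shorter than profile")
    rng = np.random.default_rng(seed)
    draws = rng.choice(N_RESIDUES, size=(n_shuffles, length), p=profile.background)
    scores = np.empty(n_shuffles)
    cols = profile.columns
    n_win = length - profile.length + 1
    pos = np.arange(profile.length)
    for i in range(n_shuffles):
        row = draws[i]
        best = -np.inf
        for off in range(n_win):
            s = cols[pos, row[off : off + profile.length]].sum()
            if s > best:
                best = s
        scores[i] = best
    mean = float(scores.mean())
    sd = float(scores.std(ddof=1))
    if sd == 0:
        raise DegenerateNullError("empirical null has zero standard deviation")
    return mean, sd


@dataclass(frozen=True)
class SearchResult:
    record_id: str
    signature_hit: MotifHit | None
    window_score: float
    z_score: float
    iteration_found: int | None  # 1, 2 or None when never included
    included: bool


def _c_terminal_rows(records: Sequence[ProteinRecord], width: int) -> list[tuple[str, str]]:
    rows = []
    for rec in records:
        if rec.length >= width:
            rows.append((rec.id, rec.sequence[-width:]))
    return rows


def pattern_initiated_search(
    db: Sequence[ProteinRecord],
    signature: MotifPattern,
    seed_alignment: AlignmentBlock,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
    seed: int = 0,
    alpha: float = DEFAULT_ALPHA,
    background: np.ndarray | None = None,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    max_iter: int = 2,
) -> list[SearchResult]:
    """Two-iteration pattern-initiated profile search over ``db``.

    The seed alignment is reduced to its terminal ``C_TERMINAL_WINDOW``
    columns (it may be wider); records are scored on their C-terminal
    window.  See the module docstring for the iteration semantics.
    Results are returned in database order, fully determined by
    (db order, seed, alpha, background, z_threshold).
    """
    if not db:
        return []
    if seed_alignment.n_columns < C_TERMINAL_WINDOW:
        raise UsageError(
            f"seed alignment must cover ≥ {C_TERMINAL_WINDOW} C-terminal columns"
        )
    window = C_TERMINAL_WINDOW
    seed_rows = tuple(
        (rid, seq[-window:]) for rid, seq in seed_alignment.rows
    )
    profile = build_profile(AlignmentBlock(rows=seed_rows), alpha, background)
    mean, sd = empirical_null(profile, n_shuffles=n_shuffles, seed=seed)

    sig_hits: dict[str, MotifHit | None] = {}
    scores: dict[str, float] = {}
    for rec in db:
        sig_hits[rec.id] = scan_c_terminus(rec, signature)
        if rec.length >= window:
            scores[rec.id] = score_window(rec.sequence, profile, rec.length - window)

    # Iteration 1: anchored pattern hit required
    iteration_found: dict[str, int] = {}
    included: set[str] = set()
    for rec in db:
        if sig_hits[rec.id] is None or rec.id not in scores:
            continue
        z = (scores[rec.id] - mean) / sd
        if z >= z_threshold:
            included.add(rec.id)
            iteration_found[rec.id] = 1
    z_scores = {rid: (s - mean) / sd for rid, s in scores.items()}

    # Subsequent iterations: refit profile, drop the pattern requirement
    for iteration in range(2, max_iter + 1):
        inclusion_rows = _c_terminal_rows(
            [rec for rec in db if rec.id in included], window
        )
        profile = build_profile(
            AlignmentBlock(rows=seed_rows + tuple(inclusion_rows)),
            alpha,
            background,
        )
        mean, sd = empirical_null(profile, n_shuffles=n_shuffles, seed=seed)
        included = set()
        for rec in db:
            if rec.id not in scores:
                continue
            score = score_window(rec.sequence, profile, rec.length - window)
            scores[rec.id] = score
            z = (score - mean) / sd
            z_scores[rec.id] = z
            if z >= z_threshold:
                included.add(rec.id)
                iteration_found.setdefault(rec.id, iteration)

    return [
        SearchResult(
            record_id=rec.id,
            signature_hit=sig_hits[rec.id],
            window_score=scores.get(rec.id, float("-inf")),
            z_score=z_scores.get(rec.id, float("-inf")),
            iteration_found=iteration_found.get(rec.id)
            if rec.id in included
            else None,
            included=rec.id in included,
        )
        for rec in db
    ]
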