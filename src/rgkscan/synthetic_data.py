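"""Seeded synthetic proteomes for exercising every pipeline stage.

The generator emulates the sequence architecture of RGK-family
proteins: a variable-length N-terminal extension, a Ras-type G-domain
whose boundaries are set by planted G1 (``GDSGVGKS``) and G5 (``ETSA``)
motifs separated so that the motif-anchored domain parses to 175
residues, and a 40-residue C-terminal tail whose last eleven residues
are drawn from the residue classes of the RGK signature.  Alongside the
positives it produces two negative classes:

* **decoys** — Ras/Rit-like sequences sharing the G-motifs (and hence a
  parseable G-domain) but whose tails are rejection-sampled to miss the
  signature; a configurable fraction are "near misses" whose tail
  conforms to the signature everywhere except the invariant cysteine,
  for testing profile-search recovery beyond the pattern stage;
* **background** — i.i.d. sequences with no planted structure.

Every generator is a pure function of (spec, seed): one global random
stream drives a run and identical inputs yield byte-identical output.
A :class:`TruthTable` records each record's class and planted
coordinates for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .errors import UsageError
from .motif_engine import rgk_signature
from .seqio import AMINO_ACIDS, AlignmentBlock, ProteinRecord, write_fasta

PLANTED_G1 = "GDSGVGKS"
PLANTED_G5 = "ETSA"
TAIL_LENGTH = 40
SIGNATURE_LENGTH = 11

#: Family consensus for the 29 tail residues preceding the signature
#: (offsets −40…−12).  The −35…−15 stretch is lysine/arginine-rich,
#: emulating the polybasic / calmodulin-binding region of RGK C-termini;
#: positives diverge from this consensus per-position (``tail_divergence``)
#: the way family members diverge in a real alignment.
FAMILY_TAIL_CONSENSUS = "NTQSP" + "RKSKSKLRRSKSPLKKRGSRA" + "LRS"
assert len(FAMILY_TAIL_CONSENSUS) == TAIL_LENGTH - SIGNATURE_LENGTH

#: distance from G1 start to G5 start such that the extracted domain
#: (−6 from G1, +30 from G5 start) is exactly 175 residues long
DEFAULT_G1_G5_SEPARATION = 175 - 36
#: residues between the end of G5 and the domain end (+30 from G5 start)
_POST_G5_LINKER = 30 - len(PLANTED_G5)


@dataclass(frozen=True)
class BenchmarkSpec:
    """Study conditions for one synthetic benchmark.

    ``tail_noise`` is a per-position substitution probability applied to
    the C-terminal tail.  ``noise_protects`` controls which planted
    positions noise may not touch: ``"fixed"`` (default) protects every
    non-wildcard signature position so truth labels stay consistent at
    any noise level; ``"c_anchor"`` protects only the invariant
    cysteine, letting noise escape the other signature classes (used for
    retention-rate calibration).  ``corrupt_anchors=True`` lifts all
    protection (negative controls).
    """

    n_rgk: int = 200
    n_decoy: int = 200
    n_background: int = 600
    seed: int = 42
    tail_noise: float = 0.05
    #: per-position probability that a tail-prefix residue departs from
    #: the family consensus (family divergence, independent of tail_noise)
    tail_divergence: float = 0.2
    n_term_length_range: tuple[int, int] = (60, 150)
    g1_g5_separation: int = DEFAULT_G1_G5_SEPARATION
    background_frequencies: tuple[float, ...] | None = None  # None = uniform
    background_length_range: tuple[int, int] = (200, 400)
    near_miss_fraction: float = 0.1
    noise_protects: Literal["fixed", "c_anchor"] = "fixed"
    corrupt_anchors: bool = False

    def __post_init__(self):
        if min(self.n_rgk, self.n_decoy, self.n_background) < 0:
            raise UsageError("counts must be ≥ 0")
        if not 0 <= self.tail_noise <= 1:
            raise UsageError("tail_noise must be in [0, 1]")
        if not 0 <= self.near_miss_fraction <= 1:
            raise UsageError("near_miss_fraction must be in [0, 1]")
        if self.g1_g5_separation < len(PLANTED_G1):
            raise UsageError("g1_g5_separation must exceed the G1 motif length")

    def frequencies(self) -> np.ndarray:
        if self.background_frequencies is None:
            return np.full(len(AMINO_ACIDS), 1.0 / len(AMINO_ACIDS))
        q = np.asarray(self.background_frequencies, dtype=float)
        if q.shape != (len(AMINO_ACIDS),) or np.any(q < 0):
            raise UsageError("background_frequencies must be 20 non-negative values")
        return q / q.sum()


@dataclass(frozen=True)
class TruthRow:
    record_id: str
    true_class: Literal["RGK", "decoy", "background"]
    g1_start: int | None = None
    g5_start: int | None = None
    signature_start: int | None = None
    near_miss: bool = False


def _random_residues(rng: np.random.Generator, n: int, freqs: np.ndarray) -> str:
    idx = rng.choice(len(AMINO_ACIDS), size=n, p=freqs)
    return "".join(AMINO_ACIDS[i] for i in idx)


def _signature_class_tail(rng: np.random.Generator) -> str:
    """Draw 11 residues uniformly from the signature's position classes."""
    sig = rgk_signature()
    return "".join(
        sorted(cls)[rng.integers(len(cls))] for cls in sig.positions
    )


def _family_tail_prefix(
    rng: np.random.Generator, spec: BenchmarkSpec, freqs: np.ndarray
) -> str:
    """The 29 consensus-derived residues preceding the signature."""
    out = []
    for ch in FAMILY_TAIL_CONSENSUS:
        if rng.random() < spec.tail_divergence:
            out.append(AMINO_ACIDS[rng.choice(len(AMINO_ACIDS), p=freqs)])
        else:
            out.append(ch)
    return "".join(out)


def _protected_tail_offsets(spec: BenchmarkSpec) -> set[int]:
    """Tail positions (0-based within the 40-residue tail) noise must skip."""
    if spec.corrupt_anchors:
        return set()
    sig = rgk_signature()
    base = TAIL_LENGTH - SIGNATURE_LENGTH
    if spec.noise_protects == "c_anchor":
        protected_sig = sig.singleton_positions("C")
    else:
        protected_sig = sig.fixed_positions
    return {base + i for i in protected_sig}


def _apply_tail_noise(
    tail: str, spec: BenchmarkSpec, rng: np.random.Generator, freqs: np.ndarray
) -> str:
    if spec.tail_noise == 0:
        return tail
    protected = _protected_tail_offsets(spec)
    out = list(tail)
    for i in range(len(out)):
        if i in protected:
            continue
        if rng.random() < spec.tail_noise:
            out[i] = AMINO_ACIDS[rng.choice(len(AMINO_ACIDS), p=freqs)]
    return "".join(out)


def _g_domain_scaffold(
    rng: np.random.Generator, spec: BenchmarkSpec, freqs: np.ndarray
) -> tuple[str, int, int]:
    """N-terminus + planted G1 … G5 + post-G5 linker; returns the
    scaffold and the G1/G5 start coordinates."""
    lo, hi = spec.n_term_length_range
    n_term_len = int(rng.integers(lo, hi + 1))
    n_term = _random_residues(rng, n_term_len, freqs)
    mid_len = spec.g1_g5_separation - len(PLANTED_G1)
    mid = _random_residues(rng, mid_len, freqs)
    linker = _random_residues(rng, _POST_G5_LINKER, freqs)
    scaffold = n_term + PLANTED_G1 + mid + PLANTED_G5 + linker
    g1_start = n_term_len
    g5_start = n_term_len + spec.g1_g5_separation
    return scaffold, g1_start, g5_start


def generate_rgk_like(
    n: int, spec: BenchmarkSpec, rng: np.random.Generator | None = None
) -> tuple[list[ProteinRecord], list[TruthRow]]:
    """Generate ``n`` RGK-like positives with planted motif coordinates."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    freqs = spec.frequencies()
    records, truth = [], []
    for k in range(n):
        scaffold, g1_start, g5_start = _g_domain_scaffold(rng, spec, freqs)
        tail = _family_tail_prefix(rng, spec, freqs) + _signature_class_tail(rng)
        tail = _apply_tail_noise(tail, spec, rng, freqs)
        seq = scaffold + tail
        rid = f"rgk_{k + 1:04d}"
        records.append(
            ProteinRecord(id=rid, sequence=seq, description="synthetic RGK-like")
        )
        truth.append(
            TruthRow(
                record_id=rid,
                true_class="RGK",
                g1_start=g1_start,
                g5_start=g5_start,
                signature_start=len(seq) - SIGNATURE_LENGTH,
            )
        )
    return records, truth


def generate_decoys(
    n: int, spec: BenchmarkSpec, rng: np.random.Generator | None = None
) -> tuple[list[ProteinRecord], list[TruthRow]]:
    """Ras-like decoys: planted G-motifs, tails that miss the signature.

    The first ``round(n · near_miss_fraction)`` decoys get a
    signature-conforming tail mutated at exactly the invariant-cysteine
    position; the rest get background tails rejection-sampled until the
    anchored signature does not match.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    freqs = spec.frequencies()
    sig = rgk_signature()
    n_near = int(round(n * spec.near_miss_fraction))
    c_index = sig.singleton_positions("C")[0]
    records, truth = [], []
    for k in range(n):
        scaffold, g1_start, g5_start = _g_domain_scaffold(rng, spec, freqs)
        near_miss = k < n_near
        if near_miss:
            # profile-similar family tail, broken only at the {C} anchor
            tail_prefix = _family_tail_prefix(rng, spec, freqs)
            last11 = list(_signature_class_tail(rng))
            non_cys = [aa for aa in AMINO_ACIDS if aa != "C"]
            last11[c_index] = non_cys[rng.integers(len(non_cys))]
            last11 = "".join(last11)
        else:
            tail_prefix = _random_residues(rng, TAIL_LENGTH - SIGNATURE_LENGTH, freqs)
            while True:
                last11 = _random_residues(rng, SIGNATURE_LENGTH, freqs)
                mismatch = any(
                    last11[i] not in cls
                    for i, cls in enumerate(sig.positions)
                    if cls != frozenset(AMINO_ACIDS)
                )
                if mismatch:
                    break
        seq = scaffold + tail_prefix + last11
        rid = f"decoy_{k + 1:04d}"
        records.append(
            ProteinRecord(id=rid, sequence=seq, description="synthetic Ras-like decoy")
        )
        truth.append(
            TruthRow(
                record_id=rid,
                true_class="decoy",
                g1_start=g1_start,
                g5_start=g5_start,
                near_miss=near_miss,
            )
        )
    return records, truth


def generate_background(
    n: int,
    length_range: tuple[int, int] = (200, 400),
    frequencies: Sequence[float] | None = None,
    seed: int | np.random.Generator = 0,
) -> list[ProteinRecord]:
    """``n`` i.i.d. background sequences, lengths uniform in range."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if frequencies is None:
        freqs = np.full(len(AMINO_ACIDS), 1.0 / len(AMINO_ACIDS))
    else:
        freqs = np.asarray(frequencies, dtype=float)
        if not np.isclose(freqs.sum(), 1.0):
            raise UsageError("frequencies must sum to 1")
    lo, hi = length_range
    records = []
    for k in range(n):
        length = int(rng.integers(lo, hi + 1))
        records.append(
            ProteinRecord(
                id=f"bg_{k + 1:04d}",
                sequence=_random_residues(rng, length, freqs),
                description="synthetic background",
            )
        )
    return records


def generate_benchmark(
    spec: BenchmarkSpec,
) -> tuple[list[ProteinRecord], list[TruthRow]]:
    """The full benchmark: RGK positives, decoys, background — one stream."""
    rng = np.random.default_rng(spec.seed)
    records, truth = [], []
    rgk, t = generate_rgk_like(spec.n_rgk, spec, rng)
    records += rgk
    truth += t
    dec, t = generate_decoys(spec.n_decoy, spec, rng)
    records += dec
    truth += t
    bg = generate_background(
        spec.n_background, spec.background_length_range, None, rng
    )
    records += bg
    truth += [TruthRow(record_id=r.id, true_class="background") for r in bg]
    return records, truth


def generate_seed_alignment(
    n_rows: int = 32, seed: int = 7, tail_noise: float = 0.0
) -> AlignmentBlock:
    """A gap-free alignment of synthetic RGK C-terminal 40-mers, for use
    as the seed of the iterative profile search."""
    spec = BenchmarkSpec(
        n_rgk=n_rows, n_decoy=0, n_background=0, seed=seed, tail_noise=tail_noise
    )
    records, _ = generate_rgk_like(n_rows, spec)
    rows = tuple(
        (f"seed_{rec.id}", rec.sequence[-TAIL_LENGTH:]) for rec in records
    )
    return AlignmentBlock(rows=rows)


_REGIME_TOKENS = ("fixed", "mix", "uniform")


def generate_alignment(
    n_rows: int, conservation_layout: Sequence[str], seed: int = 0
) -> AlignmentBlock:
    """Generate an alignment realizing a per-column conservation layout.

    Each layout token is ``"fixed"`` (one residue everywhere; optionally
    ``"fixed:L"``), ``"mix"`` (a 50/50 two-residue column, optionally
    ``"mix:AB"``), or ``"uniform"`` (i.i.d. over the 20 residues).
    Expected information content per regime is analytically known:
    log2 20, log2 20 − 1, and ≈0 respectively.
    """
    if n_rows < 1:
        raise UsageError("n_rows must be ≥ 1")
    rng = np.random.default_rng(seed)
    columns = []
    for token in conservation_layout:
        kind, _, residues = token.partition(":")
        if kind not in _REGIME_TOKENS:
            raise UsageError(f"unknown column regime {token!r}")
        if kind == "fixed":
            aa = residues or AMINO_ACIDS[rng.integers(20)]
            columns.append(aa * n_rows)
        elif kind == "mix":
            pair = residues or "".join(
                AMINO_ACIDS[i] for i in rng.choice(20, size=2, replace=False)
            )
            half = n_rows // 2
            col = pair[0] * half + pair[1] * (n_rows - half)
            columns.append(col)
        else:
            columns.append(_random_residues(rng, n_rows, np.full(20, 0.05)))
    rows = tuple(
        (f"row_{i + 1:03d}", "".join(col[i] for col in columns))
        for i in range(n_rows)
    )
    return AlignmentBlock(rows=rows)


def write_truth_table(truth: Sequence[TruthRow], path: str | Path) -> None:
    """Write the truth table as TSV (1-based coordinates, '.' for absent)."""
    def fmt(v):
        return "." if v is None else str(v + 1)

    with open(path, "w") as fh:
        fh.write(
            "record_id\ttrue_class\tg1_start_1based\tg5_start_1based"
            "\tsignature_start_1based\tnear_miss\n"
        )
        for row in truth:
            fh.write(
                f"{row.record_id}\t{row.true_class}\t{fmt(row.g1_start)}"
                f"\t{fmt(row.g5_start)}\t{fmt(row.signature_start)}"
                f"\t{int(row.near_miss)}\n"
            )
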