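"""Position-class pattern compilation and motif scanning.

This module implements the signature-based annotation machinery for RGK
family GTPases:

* a compiler for a minimal PROSITE-like grammar (residue letters,
  bracketed classes ``[...]`` and the ``x`` wildcard — no repetition or
  exclusion syntax);
* anchored scanning of the C-terminal RGK signature, an eleven-residue
  motif whose fifth position is an invariant cysteine sitting seven
  residues from the protein end (the "C-7" cysteine);
* G-motif finding (G1/G3/G4/G5 of the Ras-type G-domain) with an
  optional one-mismatch tolerance for divergent lineages;
* G-domain extraction by motif-anchored boundary rules: the domain
  starts 6 residues upstream of G1 and ends 30 residues downstream of
  the G5 anchor (two conventions for the G5 anchor are provided, see
  :data:`G5_CONVENTIONS`);
* C-terminal feature annotation (polybasic/CaM window, −8 serine,
  C-7 cysteine, class I PDZ ligand).

All coordinates are 0-based half-open; C-terminal offsets count the
final residue as −1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import NoDomainError, PatternSyntaxError, UsageError
from .seqio import AMINO_ACIDS, ProteinRecord

ALL_RESIDUES = frozenset(AMINO_ACIDS)

#: The C-terminal RGK signature: the last eleven residues, with the
#: invariant cysteine (singleton class) at pattern position 5 (1-based),
#: i.e. offset −7 from the C-terminus.
RGK_SIGNATURE_TEXT = "[KR][SAF][KR][SH][C][HNED][DNEV][LM]x[VSA][L]"


@dataclass(frozen=True)
class MotifPattern:
    """A compiled position-class pattern."""

    source_text: str
    positions: tuple[frozenset, ...]

    @property
    def length(self) -> int:
        return len(self.positions)

    @property
    def fixed_positions(self) -> tuple[int, ...]:
        """Indices whose class is narrower than the full alphabet."""
        return tuple(
            i for i, cls in enumerate(self.positions) if cls != ALL_RESIDUES
        )

    @property
    def wildcard_positions(self) -> tuple[int, ...]:
        return tuple(
            i for i, cls in enumerate(self.positions) if cls == ALL_RESIDUES
        )

    def singleton_positions(self, residue: str | None = None) -> tuple[int, ...]:
        """Indices with a one-residue class (optionally a given residue)."""
        out = []
        for i, cls in enumerate(self.positions):
            if len(cls) == 1 and (residue is None or residue in cls):
                out.append(i)
        return tuple(out)

    def render(self) -> str:
        """Re-render the pattern; compiling the result is equivalent."""
        toks = []
        for cls in self.positions:
            if cls == ALL_RESIDUES:
                toks.append("x")
            elif len(cls) == 1:
                toks.append(next(iter(cls)))
            else:
                toks.append("[" + "".join(sorted(cls)) + "]")
        return "".join(toks)


@dataclass(frozen=True)
class MotifHit:
    motif_name: str
    start: int
    end: int
    n_mismatches: int
    matched_text: str

    @property
    def length(self) -> int:
        return self.end - self.start


def compile_pattern(text: str, name: str = "") -> MotifPattern:
    """Compile PROSITE-like pattern text into a :class:`MotifPattern`.

    Grammar: single residue letters (fixed positions), bracketed classes
    ``[KR]``, and ``x``/``X`` as the 20-residue wildcard.  Anything else —
    including unbalanced or empty brackets — raises
    :class:`~rgkscan.errors.PatternSyntaxError` with the failing offset.
    """
    positions: list[frozenset] = []
    i = 0
    n = len(text)
    while i < n:
        ch = text[i]
        if ch in ("x", "X"):
            positions.append(ALL_RESIDUES)
            i += 1
        elif ch == "[":
            j = text.find("]", i + 1)
            if j == -1:
                raise PatternSyntaxError("unbalanced '['", i)
            body = text[i + 1 : j]
            if not body:
                raise PatternSyntaxError("empty residue class", i)
            bad = set(body) - set(AMINO_ACIDS)
            if bad:
                raise PatternSyntaxError(
                    f"illegal residue(s) {sorted(bad)} in class", i
                )
            positions.append(frozenset(body))
            i = j + 1
        elif ch == "]":
            raise PatternSyntaxError("unmatched ']'", i)
        elif ch in AMINO_ACIDS:
            positions.append(frozenset(ch))
            i += 1
        elif ch in " -\t":  # cosmetic separators are tolerated
            i += 1
        else:
            raise PatternSyntaxError(f"illegal character {ch!r}", i)
    if not positions:
        raise PatternSyntaxError("empty pattern", 0)
    return MotifPattern(source_text=name or text, positions=tuple(positions))


def read_pattern_file(path: str | Path) -> list[MotifPattern]:
    """Read patterns, one per line; '#' starts a comment."""
    patterns = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                patterns.append(compile_pattern(line))
    return patterns


def rgk_signature() -> MotifPattern:
    """The compiled eleven-residue C-terminal RGK signature."""
    return compile_pattern(RGK_SIGNATURE_TEXT, name="RGK-signature")


def match_at(
    seq: str,
    pattern: MotifPattern,
    offset: int,
    max_mismatches: int = 0,
    motif_name: str | None = None,
) -> MotifHit | None:
    """Test ``pattern`` against ``seq`` at ``offset``.

    A hit is returned when at most ``max_mismatches`` non-wildcard
    positions are violated; ``n_mismatches`` records the violation count.
    'X' in the sequence never satisfies a non-wildcard class.
    """
    if offset < 0 or offset > len(seq) - pattern.length:
        raise UsageError(
            f"offset {offset} out of range for sequence of length {len(seq)} "
            f"and pattern of length {pattern.length}"
        )
    mismatches = 0
    for i, cls in enumerate(pattern.positions):
        if cls == ALL_RESIDUES:
            continue
        if seq[offset + i] not in cls:
            mismatches += 1
            if mismatches > max_mismatches:
                return None
    return MotifHit(
        motif_name=motif_name if motif_name is not None else pattern.source_text,
        start=offset,
        end=offset + pattern.length,
        n_mismatches=mismatches,
        matched_text=seq[offset : offset + pattern.length],
    )


def scan_all(
    seq: str,
    pattern: MotifPattern,
    max_mismatches: int = 0,
    motif_name: str | None = None,
) -> list[MotifHit]:
    """All hits at any offset, ascending by start."""
    hits = []
    for off in range(len(seq) - pattern.length + 1):
        hit = match_at(seq, pattern, off, max_mismatches, motif_name)
        if hit is not None:
            hits.append(hit)
    return hits


def scan_c_terminus(
    record: ProteinRecord,
    pattern: MotifPattern,
    max_mismatches: int = 0,
    anchored: bool = True,
) -> MotifHit | None | list[MotifHit]:
    """Scan a record's C-terminus for the signature.

    In anchored mode (the default) only the final ``pattern.length``
    residues are tested, returning a hit or ``None``; sequences shorter
    than the pattern yield ``None``.  In ``anchored=False`` ("anywhere")
    mode all offsets are scanned and a list of hits is returned.
    """
    seq = record.sequence
    if not anchored:
        return scan_all(seq, pattern, max_mismatches)
    if len(seq) < pattern.length:
        return None
    return match_at(seq, pattern, len(seq) - pattern.length, max_mismatches)


# --- G-motifs -------------------------------------------------------------

@dataclass(frozen=True)
class GMotifDefinition:
    """One canonical G-motif of the Ras-type G-domain."""

    name: str
    pattern: MotifPattern
    #: motifs used to delimit the G-domain (G1, G5); G3/G4 are annotation-only
    boundary: bool = True

    @property
    def fixed_positions(self) -> tuple[int, ...]:
        return self.pattern.fixed_positions


def default_g_motif_catalog() -> dict[str, GMotifDefinition]:
    """The RGK G-motif catalog.

    G1 ``G-x-x-G-x-G-K-S`` (P-loop) and G5 ``E-x-S-A`` delimit the
    domain; G3 ``D-x-W-E`` (the RGK variant of the canonical DXXG) and
    the G4 ``N-K`` core are annotation-only.
    """
    return {
        "G1": GMotifDefinition("G1", compile_pattern("GxxGxGKS", name="G1")),
        "G3": GMotifDefinition("G3", compile_pattern("DxWE", name="G3"), boundary=False),
        "G4": GMotifDefinition("G4", compile_pattern("NK", name="G4"), boundary=False),
        "G5": GMotifDefinition("G5", compile_pattern("ExSA", name="G5")),
    }


TOLERANT_MAX_MISMATCHES = 1


def find_g_motifs(
    seq: str,
    catalog: Mapping[str, GMotifDefinition] | None = None,
    tolerant: bool = False,
) -> list[MotifHit]:
    """All G-motif hits in ``seq``, ascending by start then motif name.

    In tolerant mode one fixed-position mismatch is allowed per hit
    (``n_mismatches`` flags such hits), accommodating the weaker G1/G5
    conservation seen outside vertebrates.  Tolerance applies to the
    boundary motifs only; the short annotation-only motifs (G3, G4)
    would be meaninglessly promiscuous with a free mismatch.
    """
    if catalog is None:
        catalog = default_g_motif_catalog()
    if not catalog:
        raise UsageError("G-motif catalog must be non-empty")
    hits: list[MotifHit] = []
    for name in catalog:
        gdef = catalog[name]
        max_mm = TOLERANT_MAX_MISMATCHES if (tolerant and gdef.boundary) else 0
        hits.extend(scan_all(seq, gdef.pattern, max_mm, motif_name=name))
    hits.sort(key=lambda h: (h.start, h.motif_name))
    return hits


# --- G-domain extraction --------------------------------------------------

G5_CONVENTIONS = ("g5-start+30", "g5-end+30")
G_DOMAIN_UPSTREAM = 6     # residues before the start of G1 (β1 strand)
G_DOMAIN_DOWNSTREAM = 30  # residues after the G5 anchor (α5 helix + ~10)
#: G-domains parsed this way are typically 170–180 residues; 175 is the
#: midpoint used to resolve ambiguous G1/G5 pairings.
TARGET_G_DOMAIN_LENGTH = 175


@dataclass(frozen=True)
class GDomainAnnotation:
    """A parsed G-domain interval with its motif evidence."""

    record_id: str
    g1_hit: MotifHit
    g5_hit: MotifHit
    start: int
    end: int
    convention: str
    truncated_flag: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


def extract_g_domain(
    record: ProteinRecord,
    convention: str = "g5-start+30",
    catalog: Mapping[str, GMotifDefinition] | None = None,
    tolerant: bool = False,
) -> GDomainAnnotation:
    """Delimit the G-domain of ``record`` from its G1 and G5 motifs.

    The domain starts ``G1.start − 6`` (clamped at 0, setting
    ``truncated_flag``) and ends 30 residues after the G5 anchor — the
    start of G5 under ``"g5-start+30"`` (default) or its end under
    ``"g5-end+30"`` — clipped to the sequence length.  When several
    G1/G5 pairings exist the one whose length is closest to 175 residues
    wins; ties go to the leftmost G1 (then leftmost G5).

    Raises :class:`~rgkscan.errors.NoDomainError` naming the missing
    motif(s) when no valid pairing exists.
    """
    if convention not in G5_CONVENTIONS:
        raise UsageError(
            f"unknown convention {convention!r}; expected one of {G5_CONVENTIONS}"
        )
    if catalog is None:
        catalog = default_g_motif_catalog()
    max_mm = TOLERANT_MAX_MISMATCHES if tolerant else 0
    g1_hits = scan_all(record.sequence, catalog["G1"].pattern, max_mm, "G1")
    g5_hits = scan_all(record.sequence, catalog["G5"].pattern, max_mm, "G5")
    missing = [name for name, found in (("G1", g1_hits), ("G5", g5_hits)) if not found]
    if missing:
        raise NoDomainError(record.id, missing)

    candidates = []
    for g1 in g1_hits:
        for g5 in g5_hits:
            if g5.start < g1.end:  # G5 must lie downstream of G1
                continue
            start = max(0, g1.start - G_DOMAIN_UPSTREAM)
            anchor = g5.start if convention == "g5-start+30" else g5.end
            end = min(record.length, anchor + G_DOMAIN_DOWNSTREAM)
            if end <= start:
                continue
            candidates.append((g1, g5, start, end))
    if not candidates:
        raise NoDomainError(record.id, ["G1/G5 pairing (G5 downstream of G1)"])

    def rank(cand):
        g1, g5, start, end = cand
        return (abs((end - start) - TARGET_G_DOMAIN_LENGTH), g1.start, g5.start)

    g1, g5, start, end = min(candidates, key=rank)
    return GDomainAnnotation(
        record_id=record.id,
        g1_hit=g1,
        g5_hit=g5,
        start=start,
        end=end,
        convention=convention,
        truncated_flag=(g1.start - G_DOMAIN_UPSTREAM < 0),
    )


# --- C-terminal features --------------------------------------------------

POLYBASIC_WINDOW = (-35, -15)  # polybasic / calmodulin-binding region
SER_14_3_3_OFFSET = -8         # phosphoserine 14-3-3 site
C7_OFFSET = -7                 # invariant cysteine of the C-7 motif
PDZ_WINDOW = (-4, -1)          # class I PDZ ligand X-[ST]-X-[VL]


@dataclass(frozen=True)
class CTerminalFeatureMap:
    """Positional C-terminal features, offsets counted with the last
    residue at −1."""

    record_id: str
    signature_hit: MotifHit | None
    c7_cysteine: bool
    ser_minus8: bool
    pdz_class1: bool
    polybasic_fraction: float | None  # None when the window is not evaluable


def annotate_c_terminus(
    record: ProteinRecord,
    signature: MotifPattern | None = None,
    max_mismatches: int = 0,
) -> CTerminalFeatureMap:
    """Annotate the C-terminal landmarks of an RGK-like protein.

    ``polybasic_fraction`` is the K/R fraction of the window −35…−15
    (inclusive, 21 residues); it is ``None`` for records shorter than 35
    residues.  Signature and positional features need at least 11
    residues.
    """
    if signature is None:
        signature = rgk_signature()
    seq = record.sequence
    n = len(seq)
    sig_hit = scan_c_terminus(record, signature, max_mismatches) if n >= signature.length else None

    c7 = n >= 7 and seq[C7_OFFSET] == "C"
    ser8 = n >= 8 and seq[SER_14_3_3_OFFSET] == "S"
    pdz = n >= 4 and seq[-3] in "ST" and seq[-1] in "VL"

    if n >= abs(POLYBASIC_WINDOW[0]):
        lo = n + POLYBASIC_WINDOW[0]
        hi = n + POLYBASIC_WINDOW[1] + 1  # inclusive window end
        window = seq[lo:hi]
        polybasic = sum(ch in "KR" for ch in window) / len(window)
    else:
        polybasic = None

    return CTerminalFeatureMap(
        record_id=record.id,
        signature_hit=sig_hit,
        c7_cysteine=c7,
        ser_minus8=ser8,
        pdz_class1=pdz,
        polybasic_fraction=polybasic,
    )
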