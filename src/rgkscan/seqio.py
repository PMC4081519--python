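"""Sequence and alignment I/O plus small sequence utilities.

Protein sequences travel through the pipeline as :class:`ProteinRecord`
objects over the 20-letter amino-acid alphabet plus ``X`` for unknown
residues.  Alignments (aligned FASTA or Clustal) are consumed, never
computed, and are held as :class:`AlignmentBlock`.  The DNA side is a
single utility, :func:`find_dna_sites`, used to verify restriction sites
engineered into cloning primers.

Coordinates are 0-based half-open internally; report writers render
1-based inclusive positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import AlignIO, SeqIO

from .errors import AlignmentFormatError, FastaParseError, UsageError

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: residues outside the 20-letter alphabet that are collapsed to 'X' on input
_AMBIGUOUS = {"B": "X", "Z": "X", "U": "X", "O": "X", "J": "X"}

FASTA_LINE_WIDTH = 60


@dataclass(frozen=True)
class ProteinRecord:
    """One identified, annotated amino-acid sequence."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self):
        if not self.id:
            raise UsageError("record id must be non-empty")
        if "-" in self.sequence:
            raise UsageError(f"record {self.id!r}: sequence contains gap characters")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DnaOligo:
    """A named DNA oligonucleotide (e.g. a cloning primer)."""

    name: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise UsageError(f"oligo {self.name!r}: empty sequence")
        bad = set(self.sequence) - set("ACGT")
        if bad:
            raise UsageError(
                f"oligo {self.name!r}: alphabet restricted to A/C/G/T, found {sorted(bad)}"
            )


@dataclass(frozen=True)
class AlignmentBlock:
    """A multiple sequence alignment: ordered (id, gapped sequence) rows."""

    rows: tuple[tuple[str, str], ...]

    def __post_init__(self):
        if not self.rows:
            raise UsageError("alignment must have at least one row")
        lengths = {len(seq) for _, seq in self.rows}
        if len(lengths) != 1:
            raise AlignmentFormatError(
                f"ragged alignment rows: lengths {sorted(lengths)}"
            )

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0][1])

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(rid for rid, _ in self.rows)

    def row(self, rid: str) -> str:
        for row_id, seq in self.rows:
            if row_id == rid:
                return seq
        raise UsageError(f"row {rid!r} not present in alignment")

    def column(self, j: int) -> str:
        return "".join(seq[j] for _, seq in self.rows)

    def ungapped(self) -> list[ProteinRecord]:
        return [
            ProteinRecord(id=rid, sequence=seq.replace("-", ""))
            for rid, seq in self.rows
        ]


def _normalize_protein(seq: str, rid: str) -> str:
    seq = seq.upper().rstrip("*")
    out = []
    for ch in seq:
        if ch in _AMBIGUOUS:
            logger.warning(
                "record %s: non-standard residue %r mapped to 'X'", rid, ch
            )
            ch = _AMBIGUOUS[ch]
        out.append(ch)
    seq = "".join(out)
    bad = set(seq) - set(AMINO_ACIDS + "X")
    if bad:
        raise FastaParseError(
            f"record {rid!r}: illegal characters {sorted(bad)} in sequence"
        )
    return seq


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA file into a list of :class:`ProteinRecord`.

    Sequences are uppercased, terminal ``*`` stop characters stripped and
    non-standard letters (B, Z, U, O, J) mapped to ``X`` with a logged
    warning.  Duplicate ids, empty sequences and empty headers raise
    :class:`~rgkscan.errors.FastaParseError` naming the offending record.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FastaParseError(f"{path}: record with empty header")
        if rec.id in seen:
            raise FastaParseError(f"{path}: duplicate id {rec.id!r}")
        seen.add(rec.id)
        seq = _normalize_protein(str(rec.seq), rec.id)
        if not seq:
            raise FastaParseError(f"{path}: record {rec.id!r} has an empty sequence")
        desc = rec.description[len(rec.id) :].strip() if rec.description else ""
        records.append(ProteinRecord(id=rec.id, sequence=seq, description=desc))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records as FASTA with a fixed 60-column line width."""
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}"
            if rec.description:
                header += f" {rec.description}"
            fh.write(header + "\n")
            for i in range(0, rec.length, FASTA_LINE_WIDTH):
                fh.write(rec.sequence[i : i + FASTA_LINE_WIDTH] + "\n")


_ALIGNMENT_FORMATS = {"fasta": "fasta", "afa": "fasta", "clustal": "clustal"}


def read_alignment(path: str | Path, format: str = "fasta") -> AlignmentBlock:
    """Read an aligned-FASTA or Clustal alignment into an AlignmentBlock.

    Interleaved Clustal blocks are concatenated.  Ragged rows raise
    :class:`~rgkscan.errors.AlignmentFormatError`.
    """
    fmt = _ALIGNMENT_FORMATS.get(format.lower())
    if fmt is None:
        raise UsageError(
            f"unknown alignment format {format!r}; use 'fasta' or 'clustal'"
        )
    try:
        aln = AlignIO.read(str(path), fmt)
    except ValueError as exc:
        raise AlignmentFormatError(f"{path}: {exc}") from exc
    rows = tuple(
        (rec.id, _normalize_gapped(str(rec.seq), rec.id)) for rec in aln
    )
    return AlignmentBlock(rows=rows)


def _normalize_gapped(seq: str, rid: str) -> str:
    seq = seq.upper().replace(".", "-")
    ungapped = seq.replace("-", "")
    _normalize_protein(ungapped, rid)  # validate the residue alphabet
    return "".join(_AMBIGUOUS.get(ch, ch) for ch in seq)


def write_alignment(block: AlignmentBlock, path: str | Path) -> None:
    """Write an alignment as aligned FASTA (60-column lines)."""
    with open(path, "w") as fh:
        for rid, seq in block.rows:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), FASTA_LINE_WIDTH):
                fh.write(seq[i : i + FASTA_LINE_WIDTH] + "\n")


def find_dna_sites(oligo: DnaOligo, site: str) -> list[int]:
    """All (possibly overlapping) 0-based start offsets of ``site`` in the oligo.

    Used to confirm that cloning primers carry the restriction sites they
    were designed to incorporate (e.g. MluI ``ACGCGT`` in forward and NotI
    ``GCGGCCGC`` in reverse primers).
    """
    if not site:
        raise UsageError("restriction site must be non-empty")
    bad = set(site) - set("ACGT")
    if bad:
        raise UsageError(f"site alphabet restricted to A/C/G/T, found {sorted(bad)}")
    hits = []
    start = oligo.sequence.find(site)
    while start != -1:
        hits.append(start)
        start = oligo.sequence.find(site, start + 1)
    return hits


def records_to_alignment(records: Sequence[ProteinRecord]) -> AlignmentBlock:
    """Stack equal-length ungapped records as trivial alignment rows."""
    return AlignmentBlock(rows=tuple((r.id, r.sequence) for r in records))


def read_oligo_table(path: str | Path) -> list[DnaOligo]:
    """Read a TSV oligo table (columns ``name`` and ``sequence``; extra
    columns ignored; '#' comment lines allowed)."""
    oligos = []
    with open(path) as fh:
        header: list[str] | None = None
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                continue
            row = dict(zip(header, fields))
            oligos.append(DnaOligo(name=row["name"], sequence=row["sequence"].upper()))
    return oligos


def load_cloning_primers() -> dict[str, dict[str, DnaOligo]]:
    """The RGK cloning primer sets shipped with the package.

    Returns ``{gene: {"forward": oligo, "reverse": oligo}}`` for the four
    zebrafish (dr_Gem/dr_Rad/dr_Rem1/dr_Rem2) and three fruit-fly
    (dm_RGK1/dm_RGK2/dm_RGK3) primer sets, plus the truncated dm_RGK2t
    forward primer.  Forward primers were designed to carry an MluI site
    (ACGCGT) and reverse primers a NotI site (GCGGCCGC).
    """
    from importlib import resources

    sets: dict[str, dict[str, DnaOligo]] = {}
    path = resources.files("rgkscan.data").joinpath("primers.tsv")
    with resources.as_file(path) as p, open(p) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            if not line.strip():
                continue
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            sets.setdefault(row["gene"], {})[row["direction"]] = DnaOligo(
                name=row["name"], sequence=row["sequence"]
            )
    return sets


MLUI_SITE = "ACGCGT"
NOTI_SITE = "GCGGCCGC"
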