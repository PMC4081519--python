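"""RGK-likeness classification and pipeline orchestration.

A record is judged by an explicit decision ladder built from the
annotation stages:

* no G1/G5 pair                     → ``no-G-domain``
* G-domain present, no signature    → ``Ras-like-non-RGK``
* G-domain present and an anchored
  C-terminal signature hit          → ``RGK-like``
* anything else (degenerate input)  → ``unclassified``

The G-domain length window (170–180 residues by default) is advisory:
it is reported (``g_domain_length_ok``) but never gates the verdict,
because real lineages with G-domain insertions exist.  Checks of the
Cavβ-interaction residues (mouse Gem numbering R196, V223, H225)
require a caller-supplied alignment containing a reference Gem row;
without one the field is reported as not evaluated — the package never
builds alignments itself.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

from . import conservation as cons
from . import motif_engine as me
from . import profile_search as ps
from .errors import NoDomainError, RgkScanError, UsageError
from .seqio import (
    AlignmentBlock,
    ProteinRecord,
    read_alignment,
    read_fasta,
    write_fasta,
)

logger = logging.getLogger(__name__)

VERDICTS = ("RGK-like", "Ras-like-non-RGK", "no-G-domain", "unclassified")
DEFAULT_LENGTH_WINDOW = (170, 180)


@dataclass(frozen=True)
class ReferenceResidueMap:
    """Named key residues with reference numbering and allowed residues.

    ``interaction`` holds the Cavβ-interaction residues (mouse Gem
    numbering; V223 tolerates the hydrophobic substitutions V/L/I seen
    in functional homologs).  ``annotation_only`` residues (human Gem
    numbering) are reported but carry no classification weight.
    ``partner_residues`` documents the interacting rat Cavβ3 aspartates;
    they are never evaluated here.
    """

    interaction: Mapping[str, frozenset] = field(
        default_factory=lambda: {
            "R196": frozenset("R"),
            "V223": frozenset("VLI"),
            "H225": frozenset("H"),
        }
    )
    annotation_only: Mapping[str, frozenset] = field(
        default_factory=lambda: {
            "W141": frozenset("W"),
            "C146": frozenset("C"),
            "N191": frozenset("N"),
            "K192": frozenset("K"),
            "E219": frozenset("E"),
            "S221": frozenset("S"),
        }
    )
    partner_residues: tuple[str, ...] = ("D194", "D270", "D272")  # rat Cavβ3

    def __post_init__(self):
        for name, allowed in {**self.interaction, **self.annotation_only}.items():
            if not allowed:
                raise UsageError(f"allowed set for {name} must be non-empty")

    @staticmethod
    def residue_number(name: str) -> int:
        return int(name[1:])


@dataclass
class ClassifyConfig:
    """Everything :func:`classify_record` needs; built from defaults or a
    YAML config file (see :func:`load_config`)."""

    signature: me.MotifPattern = field(default_factory=me.rgk_signature)
    signature_max_mismatches: int = 0
    catalog: Mapping[str, me.GMotifDefinition] = field(
        default_factory=me.default_g_motif_catalog
    )
    tolerant_g_motifs: bool = False
    g5_convention: str = "g5-start+30"
    length_window: tuple[int, int] = DEFAULT_LENGTH_WINDOW
    refmap: ReferenceResidueMap = field(default_factory=ReferenceResidueMap)


@dataclass(frozen=True)
class ClassificationReport:
    record_id: str
    signature_present: bool
    g_domain: me.GDomainAnnotation | None
    g_domain_length_ok: bool | None
    interaction_residues: Mapping[str, str] | None  # residue -> "pass"/"fail"/"gap"
    c_terminal: me.CTerminalFeatureMap
    verdict: str
    evidence: tuple[str, ...]


def check_interaction_residues(
    alignment: AlignmentBlock,
    reference_id: str,
    refmap: ReferenceResidueMap | None = None,
    include_annotation_residues: bool = False,
) -> dict[str, dict[str, str]]:
    """Per-row, per-residue pass/fail of the key-residue checks.

    For each aligned row, the residue in the column mapped from each
    reference residue is tested against its allowed set; a gap fails
    with reason ``"gap"``.  Returns ``{row_id: {residue_name: verdict}}``
    with verdict in {"pass", "fail", "gap"}.
    """
    if refmap is None:
        refmap = ReferenceResidueMap()
    col_map = cons.map_columns(alignment, reference_id)
    checks = dict(refmap.interaction)
    if include_annotation_residues:
        checks.update(refmap.annotation_only)
    ref_len = len(col_map)
    table: dict[str, dict[str, str]] = {}
    for name in checks:
        if ReferenceResidueMap.residue_number(name) > ref_len:
            raise UsageError(
                f"reference residue {name} beyond reference length {ref_len}"
            )
    for row_id, seq in alignment.rows:
        row_result = {}
        for name, allowed in checks.items():
            col = col_map[ReferenceResidueMap.residue_number(name)]
            ch = seq[col]
            if ch == "-":
                row_result[name] = "gap"
            else:
                row_result[name] = "pass" if ch in allowed else "fail"
        table[row_id] = row_result
    return table


def classify_record(
    record: ProteinRecord,
    config: ClassifyConfig | None = None,
    interaction_result: Mapping[str, str] | None = None,
) -> ClassificationReport:
    """Apply the decision ladder to one record.

    ``interaction_result`` is the record's row from
    :func:`check_interaction_residues` when a reference alignment is
    available; otherwise the field is reported as not evaluated.
    Degenerate inputs never raise — they yield ``unclassified`` with
    reasons in ``evidence``.
    """
    if config is None:
        config = ClassifyConfig()
    evidence: list[str] = []

    sig_hit = None
    if record.length >= config.signature.length:
        sig_hit = me.scan_c_terminus(
            record, config.signature, config.signature_max_mismatches
        )
        if sig_hit is not None:
            evidence.append(
                f"anchored signature hit at {sig_hit.start + 1}-{sig_hit.end} "
                f"({sig_hit.n_mismatches} mismatches)"
            )
        else:
            evidence.append("no anchored C-terminal signature")
    else:
        evidence.append("sequence shorter than the signature")
    signature_present = sig_hit is not None

    g_domain = None
    length_ok: bool | None = None
    try:
        g_domain = me.extract_g_domain(
            record,
            convention=config.g5_convention,
            catalog=config.catalog,
            tolerant=config.tolerant_g_motifs,
        )
        lo, hi = config.length_window
        length_ok = lo <= g_domain.length <= hi
        evidence.append(
            f"G-domain {g_domain.start + 1}-{g_domain.end} "
            f"(length {g_domain.length}, within [{lo},{hi}]: {length_ok})"
        )
    except NoDomainError as exc:
        evidence.append(f"no G-domain: missing {', '.join(exc.missing)}")

    c_term = me.annotate_c_terminus(record, config.signature)

    if g_domain is None:
        verdict = "no-G-domain"
    elif signature_present:
        verdict = "RGK-like"
    else:
        verdict = "Ras-like-non-RGK"
    evidence.append(f"verdict: {verdict}")

    return ClassificationReport(
        record_id=record.id,
        signature_present=signature_present,
        g_domain=g_domain,
        g_domain_length_ok=length_ok,
        interaction_residues=dict(interaction_result) if interaction_result else None,
        c_terminal=c_term,
        verdict=verdict,
        evidence=tuple(evidence),
    )


def classify_records(
    records: Sequence[ProteinRecord],
    config: ClassifyConfig | None = None,
    interaction_table: Mapping[str, Mapping[str, str]] | None = None,
) -> list[ClassificationReport]:
    interaction_table = interaction_table or {}
    return [
        classify_record(rec, config, interaction_table.get(rec.id))
        for rec in records
    ]


# --- configuration + pipeline --------------------------------------------

def load_config(path: str | Path) -> tuple[ClassifyConfig, dict]:
    """Load a YAML pipeline config; returns the ClassifyConfig plus the
    raw mapping (for optional stages such as profile search)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise UsageError(f"config {path} must be a mapping")
    cfg = ClassifyConfig()
    if "signature" in raw:
        cfg.signature = me.compile_pattern(raw["signature"], name="RGK-signature")
    cfg.signature_max_mismatches = int(raw.get("signature_max_mismatches", 0))
    cfg.tolerant_g_motifs = bool(raw.get("tolerant_g_motifs", False))
    cfg.g5_convention = raw.get("g5_convention", "g5-start+30")
    if cfg.g5_convention not in me.G5_CONVENTIONS:
        raise UsageError(f"unknown g5_convention {cfg.g5_convention!r}")
    if "g_domain_length_window" in raw:
        lo, hi = raw["g_domain_length_window"]
        cfg.length_window = (int(lo), int(hi))
    return cfg, raw


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def reports_to_tsv(reports: Sequence[ClassificationReport], path: str | Path) -> None:
    """Write classification reports as a deterministic TSV (1-based
    inclusive coordinates; '.' for absent values)."""
    cols = [
        "record_id", "verdict", "signature_present", "g_domain_start_1based",
        "g_domain_end_1based", "g_domain_length", "g_domain_length_ok",
        "c7_cysteine", "ser_minus8", "pdz_class1", "polybasic_fraction",
        "interaction_residues", "evidence",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for rep in reports:
            gd = rep.g_domain
            inter = (
                ";".join(f"{k}={v}" for k, v in sorted(rep.interaction_residues.items()))
                if rep.interaction_residues
                else "not-evaluated"
            )
            poly = rep.c_terminal.polybasic_fraction
            fh.write(
                "\t".join(
                    [
                        rep.record_id,
                        rep.verdict,
                        str(int(rep.signature_present)),
                        str(gd.start + 1) if gd else ".",
                        str(gd.end) if gd else ".",
                        str(gd.length) if gd else ".",
                        "." if rep.g_domain_length_ok is None
                        else str(int(rep.g_domain_length_ok)),
                        str(int(rep.c_terminal.c7_cysteine)),
                        str(int(rep.c_terminal.ser_minus8)),
                        str(int(rep.c_terminal.pdz_class1)),
                        "." if poly is None else f"{poly:.4f}",
                        inter,
                        "; ".join(rep.evidence),
                    ]
                )
                + "\n"
            )


def run_pipeline(
    db_path: str | Path,
    config_path: str | Path | None,
    out_dir: str | Path,
    seed: int = 0,
) -> dict[str, Any]:
    """Run scan → G-domain extraction → (optional) profile search →
    (optional) conservation → classification, writing TSV/JSON reports
    and a run manifest.

    Optional stages are driven by config sections ``profile_search``
    (keys ``seed_alignment``, ``format``, ``z_threshold``) and
    ``conservation`` (keys ``alignment``, ``format``, ``reference_id``);
    interaction-residue checks by ``interaction_alignment`` (keys
    ``path``, ``format``, ``reference_id``).  Returns the manifest.
    Stage failures raise, after writing a ``FAILED`` marker naming the
    stage; partial outputs are preserved.
    """
    db_path = Path(db_path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        if config_path is not None:
            cfg, raw = load_config(config_path)
        else:
            cfg, raw = ClassifyConfig(), {}

        stage = "read-db"
        records = read_fasta(db_path)

        stage = "interaction-residues"
        interaction_table: dict[str, Mapping[str, str]] = {}
        ia = raw.get("interaction_alignment")
        if ia:
            aln = read_alignment(ia["path"], ia.get("format", "fasta"))
            interaction_table = check_interaction_residues(
                aln, ia["reference_id"], cfg.refmap
            )

        stage = "classify"
        reports = classify_records(records, cfg, interaction_table)
        reports_to_tsv(reports, out / "classification.tsv")

        stage = "g-domains"
        domains = [
            ProteinRecord(
                id=rep.record_id,
                sequence=next(
                    r.sequence for r in records if r.id == rep.record_id
                )[rep.g_domain.start : rep.g_domain.end],
                description=f"G-domain {rep.g_domain.start + 1}-{rep.g_domain.end}",
            )
            for rep in reports
            if rep.g_domain is not None
        ]
        write_fasta(domains, out / "g_domains.fasta")

        stage = "profile-search"
        search_summary = None
        pscfg = raw.get("profile_search")
        if pscfg:
            seed_aln = read_alignment(
                pscfg["seed_alignment"], pscfg.get("format", "fasta")
            )
            results = ps.pattern_initiated_search(
                records,
                cfg.signature,
                seed_aln,
                z_threshold=float(pscfg.get("z_threshold", ps.DEFAULT_Z_THRESHOLD)),
                seed=seed,
            )
            with open(out / "profile_search.tsv", "w") as fh:
                fh.write("record_id\tscore_bits\tz\titeration\tincluded\n")
                for res in results:
                    fh.write(
                        f"{res.record_id}\t{res.window_score:.4f}\t"
                        f"{res.z_score:.4f}\t"
                        f"{res.iteration_found if res.iteration_found else '.'}\t"
                        f"{int(res.included)}\n"
                    )
            search_summary = {
                "n_included": sum(r.included for r in results),
                "n_iteration_1": sum(r.iteration_found == 1 for r in results),
                "n_iteration_2": sum(r.iteration_found == 2 for r in results),
            }

        stage = "conservation"
        conservation_summary = None
        ccfg = raw.get("conservation")
        if ccfg:
            aln = read_alignment(ccfg["alignment"], ccfg.get("format", "fasta"))
            prof = cons.conservation_profile(aln)
            ref = ccfg.get("reference_id")
            col_map = cons.map_columns(aln, ref) if ref else {}
            inv_map = {v: k for k, v in col_map.items()}
            with open(out / "conservation.tsv", "w") as fh:
                fh.write("column\tref_residue_number\tscore\tsmoothed\tmask\n")
                for j, (s, sm, m) in enumerate(
                    zip(prof.scores, prof.smoothed, prof.mask)
                ):
                    fh.write(
                        f"{j}\t{inv_map.get(j, '.')}\t{s:.4f}\t{sm:.4f}\t{int(m)}\n"
                    )
            conservation_summary = {"n_columns": prof.n_columns}

        stage = "manifest"
        counts: dict[str, int] = {v: 0 for v in VERDICTS}
        for rep in reports:
            counts[rep.verdict] += 1
        manifest = {
            "db": str(db_path),
            "db_sha256": _sha256(db_path),
            "config": str(config_path) if config_path else None,
            "seed": seed,
            "signature": cfg.signature.render(),
            "g5_convention": cfg.g5_convention,
            "length_window": list(cfg.length_window),
            "n_records": len(records),
            "verdict_counts": counts,
            "profile_search": search_summary,
            "conservation": conservation_summary,
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return manifest
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        logger.error("pipeline failed at stage %s: %s", stage, exc)
        raise


# --- optional external validation ----------------------------------------

def validate_accessions(
    fasta_path: str | Path,
    expected_lengths: Mapping[str, int] | None = None,
    max_g_domain_length: int = 180,
) -> dict[str, dict[str, Any]]:
    """Check fetched reference accessions against the G-domain rules.

    For each record in ``fasta_path`` (fetched with
    ``scripts/fetch_accessions.py``; never bundled), extract the
    G-domain with default conventions and report its length and whether
    it is ≤ ``max_g_domain_length``; optionally check full-sequence
    lengths against ``expected_lengths``.
    """
    records = read_fasta(fasta_path)
    out: dict[str, dict[str, Any]] = {}
    for rec in records:
        entry: dict[str, Any] = {"length": rec.length}
        if expected_lengths and rec.id in expected_lengths:
            entry["length_ok"] = rec.length == expected_lengths[rec.id]
        try:
            gd = me.extract_g_domain(rec, tolerant=True)
            entry["g_domain_length"] = gd.length
            entry["g_domain_ok"] = gd.length <= max_g_domain_length
        except NoDomainError as exc:
            entry["g_domain_length"] = None
            entry["g_domain_ok"] = False
            entry["error"] = str(exc)
        out[rec.id] = entry
    return out
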