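# rgkscan

Signature-based discovery and annotation of RGK-family proteins.

RGK proteins (Gem, Rad, Rem1, Rem2 and their relatives across
deuterostomes and protostomes) are atypical Ras-superfamily GTPases
that bind the β subunits of voltage-gated Ca²⁺ channels.  They are
recognisable from sequence alone by two features: a Ras-type G-domain
delimited by the canonical nucleotide-binding motifs, and a unique
eleven-residue C-terminal signature

```
[KR]-[SAF]-[KR]-[SH]-C-[HNED]-[DNEV]-[LM]-x-[VSA]-L
```

whose fifth position — an invariant cysteine seven residues from the
protein end — is conserved in every known family member.  `rgkscan`
implements that recognition procedure as a tested pipeline for people
doing comparative sequence analysis of small GTPases:

* **seqio** — FASTA/Clustal I/O (`ProteinRecord`, `AlignmentBlock`),
  plus a DNA restriction-site scan for cloning-primer checks;
* **motif_engine** — a PROSITE-like pattern compiler, anchored
  C-terminal signature scanning, G-motif finding (G1 `GxxGxGKS`,
  G3 `DxWE`, G4 `NK`, G5 `ExSA`), G-domain extraction by the
  −6-from-G1 / +30-from-G5 anchor rules, and C-terminal feature
  annotation (polybasic −35…−15 window, −8 Ser, C-7 Cys, class I PDZ
  ligand);
* **profile_search** — a two-iteration, pattern-hit-initiated PSSM
  search (log-odds in bits with pseudocounts, seeded empirical-null
  z-scores) that recovers homologs whose signature has drifted;
* **conservation** — per-column information content (`log2 20 − H`),
  5-column moving-average smoothing, reference-mapped differential
  conservation between two families, sequence-logo letter heights,
  percent identity;
* **classify** — an explicit decision ladder (`RGK-like`,
  `Ras-like-non-RGK`, `no-G-domain`, `unclassified`), Cavβ-interaction
  residue checks (Gem R196/V223/H225), and a full-pipeline runner with
  reproducible manifests;
* **synthetic_data** — a seeded generator of RGK-like positives,
  Ras-like decoys and background sequences with truth tables, so the
  whole pipeline is testable without downloads.

See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

Generate a small labelled proteome and classify it:

```sh
$ rgkscan simulate --out demo --seed 7 --n-rgk 3 --n-decoy 2 --n-background 2
wrote 7 records to demo
$ rgkscan classify demo/benchmark.fasta --out demo/cls.tsv
{"RGK-like": 3, "Ras-like-non-RGK": 2, "no-G-domain": 2}
```

The three planted RGK-like records are called `RGK-like` (signature +
G-domain), the two decoys — which share the G-motifs but not the
signature — are `Ras-like-non-RGK`, and the background sequences have
no G-domain at all.  The extracted domains show the motif-anchored
parsing at work:

```sh
$ rgkscan gdomain demo/benchmark.fasta
record_id	start_1based	end_1based	length	truncated
rgk_0001	140	314	175	0
rgk_0002	77	251	175	0
rgk_0003	89	263	175	0
decoy_0001	86	260	175	0
decoy_0002	66	240	175	0
```

Each interval runs from 6 residues before the G1 match to 30 residues
past the G5 start — 175 residues here, inside the 170–180 range
expected for domains parsed this way.  C-terminal annotation reports
the positional landmarks (1 = present; polybasic fraction is the K/R
share of the −35…−15 window):

```sh
$ rgkscan cterm demo/benchmark.fasta
record_id	signature	c7_cysteine	ser_minus8	pdz_class1	polybasic_fraction
rgk_0001	1	1	0	0	0.4286
rgk_0002	1	1	0	0	0.4286
rgk_0003	1	1	1	0	0.3810
decoy_0001	0	0	0	0	0.1905
...
```

Other subcommands: `scan`, `profile-build`, `profile-search`,
`conserve`, `logo`, `run` (full pipeline with manifest).  All of them
are thin wrappers over the library — `rgkscan.motif_engine`,
`rgkscan.profile_search`, etc. — which is the intended programmatic
interface.

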