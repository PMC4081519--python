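# Methods

## Background and scope

RGK proteins (Gem, Rad, Rem1, Rem2 and their invertebrate relatives) are
atypical Ras-superfamily GTPases that bind voltage-gated Ca²⁺-channel β
subunits.  Two sequence features identify them: a Ras-type G-domain with
the canonical nucleotide-binding loops, and an eleven-residue C-terminal
signature — residue classes `[KR][SAF][KR][SH][C][HNED][DNEV][LM]x[VSA][L]`
— whose fifth position, an invariant cysteine, sits seven residues from
the protein end (the "C-7" cysteine).  `rgkscan` turns that recognition
procedure into a reusable, fully tested pipeline: pattern scanning,
motif-anchored G-domain parsing, an iterative profile search for
divergent homologs, alignment conservation analysis, and a rule-based
classification.  It consumes sequences and precomputed alignments; it
never builds alignments, trees, or structures.

## Pattern grammar and scanning

Patterns use the minimal PROSITE-like subset the signature needs:
residue letters, bracketed classes `[KR]`, and the `x` wildcard.  No
repetition counts or exclusion classes — a smaller grammar that can be
tested exhaustively.  Matching is mismatch-count based: a hit at
tolerance *t* may violate at most *t* non-wildcard positions, and every
tolerant hit carries its mismatch count.  C-terminal scanning is
**anchored** by default (only the final eleven residues are tested)
because the signature is defined as the last eleven amino acids; an
"anywhere" mode exists for generality.

Under i.i.d. uniform residues the probability that a random 11-mer
matches the signature is the product of class sizes over 20¹¹,
2.25 × 10⁻¹⁰ — small enough that anchored scanning is effectively
specific at proteome scale; tests confirm 0–2 hits per 10⁶ random
11-mers.

## G-domain parsing

G-motifs are searched with G1 `G-x-x-G-x-G-K-S` (P-loop), G3 `D-x-W-E`
(the family's variant of DXXG), G4 `N-K` and G5 `E-x-S-A`.  The domain
interval is anchored on G1 and G5: start = G1 start − 6 (clamped at 0
with a truncation flag), end = G5 anchor + 30, clipped to the sequence.
Two G5 anchor conventions are provided because the source material for
this parsing rule is self-contradictory — "+30 from the *beginning* of
G5" in one place and "+30 from the *end* of G5" in another.  The
default is `g5-start+30`; `g5-end+30` yields intervals exactly four
residues (the G5 length) longer.  Neither convention is endorsed; both
are flags.

When several G1/G5 pairings exist, the pairing whose interval length is
closest to 175 residues wins (the midpoint of the 170–180 range typical
of domains parsed this way), with ties broken toward the leftmost G1.
A "tolerant" mode allows one fixed-position mismatch in G1/G5 for
divergent lineages; the short annotation-only motifs (G3, G4) always
match exactly, since a free mismatch would make a 2–4 position motif
meaninglessly promiscuous.  The 170–180 length window is **advisory**
in classification — reported, never a verdict gate — because real
homologs with G-domain insertions exist.

## C-terminal features

Offsets count the final residue as −1.  Annotated features: the K/R
fraction of the polybasic/calmodulin window −35…−15 (21 residues; not
evaluable on shorter sequences), the −8 serine (a candidate 14-3-3
site; positional check only, no phosphosite scoring), the −7 cysteine,
and the class I PDZ ligand X-[ST]-X-[VL] over −4…−1.

## Iterative profile search

The search emulates a pattern-hit-initiated search followed by one
position-specific iteration, with transparent statistics instead of
database-search E-values:

* **Profile**: per-column log-odds in bits,
  `score(a) = log2(p_a / q_a)` with
  `p_a = (c_a + α q_a)/(N + α)`; gaps are excluded from counts,
  all-gap columns score zero, `X` in a query scores zero.  Defaults:
  α = 0.5, uniform background.  The profile covers the terminal 40
  alignment columns — the span over which RGK C-termini are commonly
  aligned.
* **Null**: best-window scores of sequences drawn i.i.d. from the
  background (default length = profile length), n = 500, seeded;
  z = (score − mean)/sd.  Default inclusion threshold z ≥ 5.
* **Iteration 1** admits only records with an anchored signature hit;
  **iteration 2** rebuilds the profile from the seed rows plus the
  iteration-1 inclusions and rescores every record with the pattern
  requirement dropped, so signature-broken but profile-similar
  homologs can be recovered.  Two iterations by default (`max_iter`
  raises it).

The z-threshold of 5 is deliberately conservative: on the synthetic
benchmark true positives score z ≈ 11–16 while unrelated sequences stay
below z ≈ 3.5, so the operating point is not delicate.  Adding a
record's own window to the profile can only raise that record's score
(pseudocounted log-odds are monotone in the observation count), which
the suite checks as an invariant.

## Conservation analysis

Per-column conservation is information content, `log2 20 − H`, with
`H` the Shannon entropy of the column's non-gap residue frequencies —
a transparent, alignment-only statistic chosen over phylogeny-aware
rate estimation (no tree, no substitution model; scores are not
evolutionary rates, and columns dominated by a large clade will look
more conserved than a rate-based method would report).  Columns with a
gap fraction above 0.5 are flagged, never dropped, keeping column
indices stable for the reference map.  Smoothing is a centred
5-column moving average, truncated at the edges and skipping masked
columns.  Differential conservation maps two family alignments onto a
shared reference row (residue number → column per alignment) and
reports family A − family B at residues present in both; no smoothing.
Logo heights are `f_a · R` per column (heights sum to R); the standard
small-sample correction `19/(2 ln 2 · n)` is available behind a flag
and off by default.  Percent identity counts only columns where both
rows are non-gap; "similarity" in the substitution-matrix sense is
deliberately not implemented.

## Classification

The decision ladder: no G1/G5 pairing → `no-G-domain`; G-domain
without an anchored signature → `Ras-like-non-RGK`; G-domain plus
signature → `RGK-like`; degenerate inputs → `unclassified` with
reasons.  This is a made-explicit rule — the recognition practice it
formalises was never stated as a formal inclusion criterion — so every
rule firing is logged into the report's evidence list.
Cavβ-interaction residues (R196 {R}, V223 {V, L, I}, H225 {H}, mouse
Gem numbering) are checked per alignment row when the caller supplies
an alignment containing the reference row; absent that, the field is
"not evaluated" rather than silently skipped.

## Synthetic benchmark

The generator emulates the family's architecture: N-terminal extension
of 60–150 residues (the union of the vertebrate ranges reported for
these proteins; protostome N-termini run much longer but add nothing
to the tests), planted G1 `GDSGVGKS` and G5 `ETSA` separated by 139
residues so the parsed domain is exactly 175 long, and a 40-residue
tail.  The tail's last eleven residues are drawn uniformly from the
signature classes; the preceding 29 residues are drawn from a fixed
family consensus (K/R-rich over the polybasic window) with
per-position divergence 0.2 — family-like conservation that gives the
profile search something real to learn and the polybasic annotation
something to measure.  Decoys share the G-motif scaffold but their
tails are rejection-sampled to miss the signature; a near-miss
fraction (default 0.1) instead gets a fully conforming family tail
broken at exactly the cysteine anchor, the designed test case for
iteration-2 recovery.  Background sequences are i.i.d., 200–400
residues.

Tail noise (default 0.05/position) never touches the non-wildcard
signature positions or G-motif fixed positions (`noise_protects =
"fixed"`), so a record labelled RGK still is one at any noise level
and truth labels stay meaningful.  Two alternative settings exist for
calibration and negative controls: `"c_anchor"` protects only the
invariant cysteine, making the signature-retention rate follow the
closed form Π[(1 − p) + p·|class|/20] (≈ 0.669 at p = 0.05), which a
test verifies against a binomial 99% CI; `corrupt_anchors=True` lifts
all protection.  Every generator is a pure function of (spec, seed):
reruns are byte-identical.

What the benchmark does **not** emulate: indels, phylogenetic
correlation between sequences, composition bias, G2/switch-I
variability, and the long disordered N-termini of insect homologs.
Passing tests therefore demonstrate the machinery's correctness and
its operating characteristics under the stated generative model, not
performance on real proteomes; the optional accession-validation
checks (`scripts/fetch_accessions.py`) exist for that purpose.

## Problem sizes and numerics

Default study conditions: 200 RGK-like, 200 decoys, 600 background,
seed 42; profile-search demonstrations use a 32-row seed alignment of
synthetic tails and 500-draw nulls; the false-positive-rate check uses
10⁶ vectorised 11-mers.  Scores are float64 throughout; column
entropies sum in sorted-residue order so profiles are bit-identical
under row permutation; all coordinates are 0-based half-open
internally and rendered 1-based inclusive in reports.

## Known limitations

* Conservation scores are entropy-based, not rate-based; differential
  profiles are sign-fixed to (family A − family B) by argument order.
* The exact historical G1/G5 deviation lists for divergent lineages
  are not machine-readable; tolerant matching (≤ 1 mismatch, flagged)
  stands in for them.
* The profile search has no gapped alignment and no E-values; its
  z-scores are calibrated only against the i.i.d. background null.
* The −8 serine and PDZ checks are purely positional.
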