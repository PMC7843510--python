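# Methods

## The measurement problem

An ichnovirus delivers tens of circular dsDNA segments into its
caterpillar host. Within infected cells each circle can persist as an
episome or integrate into a host chromosome, and integration follows one
of two modes: *conserved* breakage at a fixed junction pair bounded by a
host integration motif (HIM), which excises the intervening segment, or
*random* linearisation anywhere on the circle. The observable is
short-read resequencing of infected tissue: integration leaves virus–host
chimeric reads whose internal boundary pinpoints both the circle
linearisation junction and the host insertion site. This package turns a
circle set, a host assembly and a read set into per-circle integration
profiles, HIM models, and breakpoint-microhomology tables.

## Read mapping

The aligner is a standard seed-and-extend local search with the scoring
match +1, mismatch −2, gap open −5, gap extend −2 — a scheme close in
effect to BLASTN defaults at the ≥ 95 % identities of resequencing reads.
Exact 15-mers seed candidate loci (150 bp reads at ≤ 1 % substitution
error essentially always contain an exact 15-mer in any 20 nt window);
diagonal-clustered seeds define a target window, and the optimal local
alignment of read × window is computed with the Smith–Waterman/Gotoh
implementation in scikit-bio (`pair_align`). Both strands are searched by
also querying the reverse complement. Circles are indexed on their
doubled sequence so seeds and alignments spanning the origin are found;
reported coordinates are reduced modulo circle size into `1..size`.

Retention requires matched length ≥ 20 nt, identity ≥ 0.95, and
Karlin–Altschul E ≤ 10⁻⁵, with `E = K·m·n·exp(−λ·score)`. λ is root-found
(Brent) from `Σ pᵢpⱼ exp(λ sᵢⱼ) = 1` at uniform base composition
(λ ≈ 1.333 for +1/−2). K is taken as the standard tabulated 0.621 for
this scoring rather than recomputed: E-values here act only as a
retention gate spanning many orders of magnitude, so the full lattice
K computation would add complexity without affecting any decision.

Reads with two equal-best hits at different loci are ambiguous and are
excluded from chimera calling — repeats must not manufacture integration
sites. The search is two-pass, circles before host, and only
circle-related reads are mapped to the host, mirroring how such screens
are run in practice.

## Chimeric reads and junction inference

A qualified chimeric read has its best circle hit and best host hit on
opposite read ends (each end-anchored within 5 nt, neither interval
containing the other), each ≥ 20 nt, with matched lengths summing to
> 140 bp, implemented strictly as ≥ 141 (`--min-sum`). Rejections are
enumerated (`no_host_hit`, `ambiguous`, `too_short_side`,
`sum_below_threshold`, `same_side`, `nested`) so accepted + rejected
always equals the circle-hit-bearing read count.

Each junction is read from its own hit's inner (junction-facing)
boundary, strand-aware. The worked convention: a read whose bases 1–51
align to a circle at 2048–1988 (minus strand) and bases 50–150 to a
scaffold at 80256–80156 yields circle junction 1987–1988 and host
insertion 80256–80257. When the two hit intervals overlap — breakpoint
microhomology — both hits legitimately cover the shared bases, each
junction stays at its own hit's boundary, and the overlap is reported as
the interval intersection with its sequence. Calls also record which end
of the integrated arc the read anchors (`right_end`: the arc ends just
before the junction; `left_end`: it begins just after), inferred from
strand and hit order.

## Per-circle statistics

With `N` related reads (any retained circle hit; counted toward the
read's best circle), `c` chimeric reads, circle size `s` and read length
150: depth `x = N·150/s`; percent integrated `% = (c/2)/x·100` (two
junctions per integrated copy); a circle is `integrated` when `% ≥ 1.0`
(boundary inclusive; `--percent-threshold`).

The conserved ratio needs care. A conserved junction *pair* surfaces as
two junction coordinates — the upstream junction from arc-right-end reads
and the downstream junction from arc-left-end reads — so a naive modal
fraction over single junctions would cap near 0.5 for a perfect CBC.
A single random linearisation, by contrast, yields the *same* coordinate
from both arc ends. The ratio therefore takes the modal junction of each
arc end separately and pools their supports:
`ratio = (modal right_end support + modal left_end support) / total`.
For scattered random breaks both modal supports stay small, so the
classification threshold keeps its published meaning: CBC iff
ratio > 0.5 strictly, RBC otherwise. Circles with fewer than 4 chimeric
reads are left `undetermined` (`--min-mode-reads`; a one-read "ratio" is
meaningless, though the guard can be lowered to 1). `--junction-tol`
optionally merges junctions within ±tol nt of the modal one into its
support, absorbing residual microhomology ambiguity; the default is 0
(exact matching).

## HIM models

For a CBC, the junction pair is the modal junction per arc end
(single-ended evidence is an error, not a guess). The deletion length is
`downstream.left − upstream.left` modulo circle size — the exclusive
convention, which reproduces the published DsIV CBC lengths (54, 32,
311, 76); the published cross-virus predictions count one more base, and
`inclusive=True` reproduces those (33 … 1781). The two conventions differ
by exactly one base and the discrepancy is documented rather than
silently patched.

The HIM region is the excised segment plus 25 nt flanks (wrap-aware).
Repeat discovery enumerates all *maximal* substring pairs `(s, t)` with
`t = reverse_complement(s)`, `|s| ≥ 5`, `s` within 25 nt of the upstream
junction and `t` within 25 nt of the downstream junction, via a dynamic
programming pass over window × reverse-complemented window, reported
longest first. Maximality is judged within the search windows. Chance
5–6-mers do appear in ~50 nt windows (expected ≈ 2 per region); the
planted/real pairs are distinguished by length and exact junction
adjacency.

Cross-virus prediction aligns each HIM region against every subject
segment with the same engine but seed k = 8 — at the 80 % identity
retention floor an exact 15-mer survives in only ~3 % of windows, an
8-mer in ~17 % per position — and keeps hits with identity > 0.80,
aligned length ≥ 16 ("length > 15" read strictly) and E < 10. Subject
junctions are the alignment images of the query's junction offsets
(projected through the alignment columns; minus-strand hits swap the
pair); hits whose alignment does not cover both query junctions are not
reported as predictions.

## The synthetic-data generator

The generator emulates the full experiment with exact truth records.

**Host genome** — i.i.d. uniform A/C/G/T scaffolds (default 5 × 50 kb).
Real host genomes have repeats, GC structure and gaps; uniform sequence
makes ambiguous mappings rare, so passing tests demonstrate coordinate
correctness, not robustness to repeat-rich genomes (see Limitations).

**Circles** — default 8 circles of 3–6 kb, the first 3 HIM-bearing. The
planted HIM, reading across the future excised segment `u+1..d`
(deletion drawn uniformly from 32–311 nt as observed for DsIV):

```
... [inner 6] |u| [outer 11] ... core ... [rc(outer) 11] [spacer 3] |d| [rc(inner) 6] ...
```

The outer 11 nt reverse-complementary pair sits just inside the excised
ends, the inner 6 nt pair just outside on the retained arc. Two 11+6
pairs cannot both fit strictly inside a 32 nt deletion, so the inner pair
straddling the junctions is the layout that supports the full observed
deletion range. A 3 nt spacer plus resampled neighbour bases guarantee
each planted pair is exactly maximal (discovery recovers them verbatim,
never extended by a lucky flanking base).

**Integrations** — default: 2 conserved circles and 3 random circles, 5
events each, inserted at length-weighted uniform host positions kept
≥ 600 nt apart (≥ 300 nt from scaffold edges). Conserved events
linearise at the HIM pair and delete the excised segment; random events
insert the full circle linearised at a uniform position, without
deletion — whether random breakage also deletes sequence is unobserved,
and no deletion is the explicit assumption here.

**Microhomology** — per event, a length k is drawn from a weight table
over 0–10 nt (default mean ≈ 2.3 nt) and one junction side is chosen;
the k host-reference bases at that flank are rewritten to equal the
arc's terminal k bases, and the mosaic joins the arc to the host with
the shared bases appearing once. The rewritten scaffolds are the emitted
host reference, so truth coordinates stay valid and mapping recovers the
overlap as a k-base hit-interval intersection.

Two refinements keep the truth *exact* rather than a lower bound:

* The side is preferred whose rewrite cannot coincide with the opposite
  arc terminus (which would plant an unintended 1-base overlap at the
  other junction). When the arc's termini force a coincidence, a ±1
  ambiguity in the *host insertion* on the non-microhomology side
  remains — inherent to microhomology, and the reason recovery is scored
  per event via either junction.
* Host flank bases near each junction are resampled so that any
  junction-crossing alignment extension scores ≤ −1 in every prefix
  (horizon 18 nt) under the +1/−2 scoring. Without this, coincidental
  flank identities extend hits past the junction with geometric
  probability and the "true" junction is ill-defined at single-base
  resolution. The resampling touches ~4 bases per event in a 250 kb
  genome and leaves composition statistics intact.

**Reads** — 150 bp pairs, insert ~ N(400, 40²), uniform fragment starts
(circles sampled with wraparound), per-base substitutions at 0.1 %
(default), constant placeholder qualities. Pair counts follow
`round(L·coverage/(2·150))` per template: default 15× over the mosaic
genome and 30× per episomal circle. Everything derives from one seed via
independent substreams; identical seeds give byte-identical outputs.

## Problem sizes

The standard scene (5 × 50 kb host, 8 circles, 25 events, ≈ 45 k reads)
profiles in ~20 s on one CPU and anchors the end-to-end checks; the
repeated break-mode study uses a reduced scene (2 × 15 kb host, one
conserved + one random circle, 5 events each, ≈ 4 k reads) across twenty
seeds. These sizes were chosen so the whole validation suite runs in
minutes while every per-junction support count stays ≥ ~10 reads, the
regime the classification thresholds presume.

## Numerical and convention choices

* Internal coordinates 0-based half-open; all reported coordinates
  1-based inclusive; junctions are between-base pairs `a–a+1`, with
  `(size, 1)` legal on circles.
* "More than 140 bp" → ≥ 141; "ratio > 50 %" → strictly greater (0.5 is
  RBC); "% threshold 1 %" → integrated iff ≥ 1.0; "length > 15" → ≥ 16.
* Modal-junction ties break toward the smallest circle coordinate.
* Equal-best-score hits at different loci ⇒ read excluded as ambiguous.
* Lowercase input is uppercased; N is allowed in host scaffolds and
  reads, never in circles, and matches nothing in alignment identity.
* Mates are treated independently; there is no pair-spanning evidence.

## Limitations

* The aligner targets high-identity short reads; it is not a general
  aligner (no spliced alignment, no affine E-values for gapped scores,
  no mate rescue) and does not reproduce BLASTN hit counts bit-exactly.
* The uniform-sequence host genome understates the ambiguous-mapping
  problem of real repeat-rich genomes; results on real data depend on
  the ambiguity filter more than these tests exercise.
* Sequencing errors within ~2 nt of a junction can shift an individual
  read's inferred junction by a base; per-event modal voting absorbs
  this, but single-read junctions carry that noise.
* PCR duplicates are not simulated; every read is counted by default.
  Whether duplicate chimeric reads should be collapsed on real data is
  unknowable without UMIs, so `--dedup` (drop identical-sequence reads)
  is off by default. Indel sequencing errors and quality-score structure
  are not modelled.
* The microhomology enrichment permutation test is an optional extra
  beyond the core profiling statistics, and its null (uniform re-drawn
  insertion points) ignores host composition structure.
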