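# ivprofiler

Genome-wide profiling of ichnovirus circle integration into a lepidopteran
host genome from short-read resequencing data.

Polydnaviruses (PDVs) are symbiotic dsDNA viruses of parasitoid wasps whose
encapsidated genome is a set of circular segments ("circles"). Injected into
a caterpillar host at oviposition, the circles cannot replicate — yet some
persist by integrating into host chromosomes. `ivprofiler` is for
virologists and genome scientists who want to measure that process from
150 bp paired-end resequencing of infected tissue: which circles integrate,
how often, whether each circle linearises at one conserved junction pair or
at random positions, what the *host integration motif* (HIM) of a conserved
breaker looks like, and how much microhomology the breakpoints carry.

Because the real datasets are terabyte-scale SRA accessions, the package
ships a first-class synthetic-data generator that emulates the whole
experiment — episomal circle copies, HIM-mediated and random integrations,
breakpoint microhomology, sequencing errors — with a machine-readable truth
set, so every stage is testable end to end on one CPU in minutes.

## Method

1. **Two-pass search.** Every read is screened against the circle set with
   a k-mer seeded Smith–Waterman local aligner (match +1, mismatch −2, gap
   open −5, extend −2; ungapped Karlin–Altschul E-values, E < 10⁻⁵; circles
   indexed on their doubled sequence so origin-spanning hits wrap
   correctly). Only circle-related reads are then mapped against the host
   scaffolds.
2. **Chimeric reads.** A qualified chimeric read carries a circle hit and a
   host hit on opposite read ends, each ≥ 20 nt, with matched lengths
   summing to > 140 bp. From the hit boundaries facing the middle of the
   read, the circle's linearisation junction and the host insertion site
   are inferred as between-base positions `a–a+1`; the intersection of the
   two hit intervals is the breakpoint overlap (microhomology).
3. **Per-circle statistics.** With `N` related reads, `c` chimeric reads
   and circle size `s`:

   depth `x = N × 150 / s` — percent integrated `% = (c/2) / x × 100`
   (each integrated copy produces two junctions) — a circle is *integrated*
   if `% ≥ 1`. The conserved ratio is the fraction of chimeric reads at the
   circle's modal junction pair; > 50 % makes it a conserved-broken circle
   (CBC), otherwise random-broken (RBC).
4. **HIM discovery.** For each CBC the junction pair, the excised-segment
   length (`downstream.left − upstream.left`, wrap-aware), and all maximal
   reverse-complementary repeat pairs flanking the two junctions are
   reported; HIM regions can be scanned against other virus segment sets
   (identity > 80 %, aligned length > 15, E < 10) to predict candidate
   HIMs, as done for the DsIV → HfIV/TrIV predictions.

## Worked example

The analysis is organised as numbered drivers over the library:

```bash
python analysis/01_simulate.py --seed 1   # scene + truth under results/scene/
python analysis/02_profile.py             # mapping, chimeras, circle profiles
python analysis/03_him_discovery.py       # HIM models + cross-virus scan
python analysis/04_microhomology.py       # overlap classes + permutation test
```

Step 2 prints, for the seed-1 scene (8 circles, 25 planted events, 45,028
reads):

```
45028 reads in, 20374 circle-related, 587 chimeric (rejected: {'no_host_hit': 19787})
  circle_01: 124 chimeric reads, depth 107.1x, 57.9% integrated -> integrated, break mode CBC
  circle_02: 118 chimeric reads, depth 101.6x, 58.1% integrated -> integrated, break mode CBC
  circle_03: 0 chimeric reads, depth 30.0x, 0.0% integrated -> non_integrated, break mode undetermined
  circle_04: 89 chimeric reads, depth 103.8x, 42.9% integrated -> integrated, break mode RBC
  ...
```

The two circles simulated with conserved (HIM-mediated) integration come
back as CBCs, the three random integrators as RBCs, and circles with no
events (depth 30× — their episomal coverage — and zero chimeric reads) as
non-integrated. Step 3 then recovers each planted HIM exactly:

```
circle_01: junctions 3170-3171 / 3309-3310, deletion 139 nt, boundary repeats:
           AGCATGTGGGG/CCCCACATGCT (11 nt), GTTCGA/TCGAAC (6 nt)
```

i.e. the excised segment is bounded by an 11 nt and a 6 nt
reverse-complementary repeat pair — the structure reported for DsIV HIMs
(`CCGTACGCTCT`/`AGAGCGTACGG` and `ACTGTA`/`TACAGT`). Step 4 reports the
breakpoint-overlap classes and a one-sided permutation test of
microhomology enrichment (seed-1 scene: observed mean overlap 1.62 nt vs
0.33 nt at permuted insertion points, p ≈ 5 × 10⁻⁴).

A `simulate / profile / himscan` command-line interface (`ivprofiler
--help`) wraps the same library for use on arbitrary FASTA/FASTQ inputs.

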