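# Methods

## Read filtering

Filtering removes whole reads, never trims. A read is rejected for the
first matching rule, in a fixed order:

1. **low quality** — arithmetic mean of its Phred scores strictly below
   `min_mean_phred` (default 28; a mean of exactly 28 passes);
2. **adapter** — any configured adapter occurs verbatim anywhere in the
   read, or an adapter *prefix* of ≥ 12 nt sits at the 3′ end with at
   most one mismatch (full-insert read-through, the dominant real-world
   adapter artifact);
3. **low complexity** — the most frequent single base accounts for
   ≥ 90% of non-N positions, or a single homopolymer run covers ≥ 80% of
   the read, or more than 10% of positions are N. The thresholds are
   exposed on `FilterParams`; the defaults are chosen to catch polyT-tract
   artifacts without flagging merely AT-rich biological sequence.

Pairs are filtered jointly: good/good pairs survive intact, bad/bad pairs
are dropped, and mixed pairs either salvage the good mate as an unpaired
read (`salvage_singletons=True`, appropriate when assembling the largest
possible read set) or drop it, counting it as `removed_broken_pair`. The
`FilterReport` counts obey `kept + Σ removed_* = total_reads` for any
input.

## Depth ladder

The unit of subsampling is the pair (mates travel together; salvaged
singletons are single-read units). The unit order is randomized once with
a seeded Fisher–Yates shuffle; subsets are then *prefixes* of that one
permutation, so subsets are nested by construction and depth is the only
variable along the ladder. Depths count reads; a subset is the shortest
unit prefix reaching its depth (units are never split). The pipeline
randomizes the raw pool, filters, then cuts subsets from the filtered
reads; filtering and subsampling commute in expectation because the
permutation is uniform.

## Toy assembler

K-mers (default k = 25, odd, canonical strand-collapsed, N-free) are
counted over the read set; k-mers seen fewer than `coverage_cutoff` times
(default 3; 10 reproduces the stricter-cutoff contrast) are deleted
before graph construction. Contigs are the maximal non-branching paths of
the surviving k-mer graph, emitted in the lexicographically smaller of
the two orientations for determinism, and discarded below
`min_contig_length` (default 100, one read length). Loci are connected
components of the graph linking contigs that share ≥ 1 canonical k-mer.

Known limitations, by design: single k only, no paired-end scaffolding,
no bubble/repeat resolution. "Transcripts per locus" therefore reflects
unitig fragmentation, not isoform structure, and the tool is a pipeline
stand-in, not an assembler benchmark. Real assemblies can be substituted
as FASTA (+ optional locus TSV) at every stage that consumes contigs.

## Translated search and E-values

Member proteins are aligned to all six frames of each contig with local
affine-gap Smith–Waterman (BLOSUM62; a gap of length L costs 11 + L),
via Biopython's `PairwiseAligner`. Stop codons translate to `*`, which
BLOSUM62 scores at −4 against everything, so alignments can bridge a stop
at a price — exactly the behaviour that produces the
"shorter-than-alignment" class. The E-value uses the Karlin–Altschul form
E = K·m·n·e^(−λS) with the published gapped BLOSUM62 constants λ = 0.267
and K = 0.041, m the query length and n the summed residue count of all
translated frames, with no length corrections. The cutoff (default 1e-6)
is a detection gate, not a statistic we interpret finely; exact parity
with any particular BLAST release is neither needed nor claimed.

For speed, a BLAST-like seeding prefilter skips query/frame pairs sharing
fewer than 2 exact 4-mer words; at the divergence levels the simulator
produces (≥ ~70% identity) homologous pairs share dozens of words, so the
prefilter only ever discards pairs that could not reach the E-value gate.
`word_size=0` disables it for exhaustive search.

## CDS extraction, best hit, classification

From a hit's nucleotide span (on the aligned strand, in the aligned
frame), the scanner walks 5′ codon-by-codon to the nearest in-frame ATG,
failing if it meets an in-frame stop or the contig edge first; from that
ATG it translates to the **first** in-frame stop, failing at the contig
edge. Both termini are required — a truncated ORF yields nothing, which
is what makes full-length recovery depth-sensitive. Because the first
stop may fall inside the aligned span, the extracted protein can be
shorter than the alignment (class 5).

Among passing alignments the winner is the first with an extractable CDS
in the order (score desc, percent identity desc, aligned query residues
desc, contig id asc) — the tie-break order is a documented choice, as
"best alignment" is underdetermined. The protein length (stop excluded)
is classified against the cluster's ratio-extended bounds; the 90%
alignment-coverage rule is measured in query (reference protein)
residues; non-integer bounds are floored (lower) and ceiled (upper),
permissive in both directions. `n_full_length` counts class 1 only;
`n_within_length` counts classes 1–2; `detected` needs any passing hit.

## Synthetic data model

The generator produces what the analysis assumes, no more:

* **Transcripts** — i.i.d. bases with an exact per-transcript GC base
  count (realized GC equals the target to within half a base); lengths
  uniform in a range.
* **Expression** — log-uniform over the requested orders of magnitude,
  endpoints pinned so the realized dynamic range is exact; the true
  expression law of real libraries is unknown and this is a stand-in,
  not a fidelity claim. A log-normal behind the same interface would be
  an equally defensible choice.
* **Ortholog clusters** — a random ancestral protein (N-terminal Met);
  each lineage gets i.i.d. substitutions (default rate 0.10) and a
  C-terminal truncation/extension by a uniform factor in ±5.9%, giving a
  mean longest-to-shortest length spread near the ~11.8% observed in
  six-species reference sets. No internal indels. The *sampled organism*
  is one extra lineage excluded from the reference cluster — as a
  non-model species would be — so its protein length can fall outside
  the cluster bounds; genes where it does are recorded as non-plantable
  and can never score full-length, which the recovery analysis accounts
  for.
* **Reads** — 2×100 bp from inserts Normal(180, 20) clamped to
  [read_len, transcript length], fragment positions uniform, transcript
  choice ∝ weight × length, mate 2 on the opposite strand, strand
  assignment fair-coin. Per-base substitution errors at 0.001,
  consistent with the Phred ≈ 38 baseline quality model (Normal(38, 2)
  clamped to [2, 41]). Artifacts are drawn per read, mutually exclusive,
  and ledgered in the truth object: adapter read-through (TruSeq read-1
  sequence inserted verbatim; default rate 0.004), polyT reads (≥ 95% T;
  0.002), and low-quality reads (qualities Normal(20, 3); 0.11). The
  default rates reproduce a realistic filtration profile in which ~11–12%
  of reads are removed, ~95% of them for quality. Errors are never
  applied inside planted artifact signal, so artifact recall is a
  property of the filters, not of collision luck.

What the simulator does **not** model — splice variants, strand-specific
protocols, PCR duplicates, quality-by-cycle decay, coverage bias,
paralogy — bounds what passing tests show: they validate the pipeline's
logic and its depth-response on clean transcriptional structure, not
performance on any real library.

## Default study conditions

The default `RunConfig` simulates 60 genes, 50 carrying ortholog CDSs
(clusters of 6 species, ancestral proteins 150–250 aa, UTRs 150–300 nt so
the CDS sits on the interior coverage plateau), expression spanning one
order of magnitude, and 22,000 read pairs; the ladder is 4,000 / 14,000 /
36,000 reads, the top rung sized to fit inside the ~88% of reads that
survive filtration. With k = 25 and cutoff 3, the lowest-expressed genes
cross the k-mer coverage cutoff between the bottom and top rungs, which
is what makes the full-length curve rise across the ladder. These sizes
are the package's desk-scale defaults; every one of them is a constructor
argument.

## Numerical and degenerate-input conventions

N50 by descending cumulative sum, first length reaching ≥ half the total;
median of an even count is the mean of the central pair; the scalar GC is
pooled over bases while histograms are per-sequence (both are emitted, as
the two conventions differ on skewed length distributions); empty
assemblies summarize to zero counts with NaN means rather than errors;
an empty filtered pool or a depth exceeding it is a hard error naming the
shortfall. All randomness flows from one integer seed per entry point;
reruns are byte-identical and the run manifest records SHA-256 checksums
of every artifact.
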