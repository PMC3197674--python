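# Methods

## Model

A-to-I editing converts adenosine to inosine on the sense strand of
double-stranded RNA; sequencing reads inosine as guanosine.  An ultra-edited
molecule therefore differs from its genomic source by a dense cluster of
A→G substitutions and (ideally) nothing else.  The detection model treats
editing as the only systematic difference between read and genome: masking
the A/G distinction in both sequences makes the cluster invisible to the
aligner, and the evidence for editing is then re-read from the original
sequences along the alignment path.

Strand bookkeeping follows from two independent unknowns: the strand of the
genomic locus that was transcribed, and the strand of the cDNA that was
sequenced.  Internally every combination is reduced to a +-genome frame: a
combination that nominally aligns against the − DNA strand is executed as
the reverse-complemented read against the + genome reduced with the
*complementary* substitution (A→G on − equals T→C on +), which is an exact
algebraic identity, not an approximation.  Consequently a dominant T-to-C
cluster in the + frame is an A-to-G call on the − strand.  The two
complement-symmetric control substitutions (G→C, A→T) coincide with their
own mirror images, which is why 4 + 4 + 2 + 2 = 12 combinations suffice.

### Calling criteria

With `n` dominant-type mismatches, `m` total mismatches and `a` adenosines
of the edited strand in the inclusive genomic span from the first to the
last dominant-type site:

* ultra: `n ≥ 12` and `n/m > 0.9` (strict) and `n/a ≥ 0.2` (non-strict);
* hyper: `5 ≤ n ≤ 11` with the same purity and rate conditions.

The 12-site cutoff is the mismatch load at which a 300 bp Alu-length read
falls below a 96% identity screen (4% × 300 = 12), and 12 sites is ≈20% of
the ~60 adenosines of the repeat consensus — the two derived cutoffs are
recomputed in the acceptance script.  The adenosine denominator is counted
on the **edited strand** (T on the + genome for −-strand calls), inclusive
of both endpoint sites; editing chemistry acts on the sense strand, and the
endpoints are themselves edited adenosines.  Purity counts mismatch columns
only; gap columns are policed separately by the gap filter.  A tie for the
dominant type is unclassifiable rather than arbitrarily resolved — a genuine
cluster dominates by construction.

## Aligner

Seeding is exact word matching (default word size 12 on the reduced
alphabet); seeded diagonals are clustered (±96) into windows, and each
window is solved *exactly* by affine-gap Smith–Waterman (numba kernel) with
full traceback.  On targets up to 4 kb a single whole-target window is used,
so the result provably equals a full Smith–Waterman whenever any seed
exists; on genome-scale targets the windows are a heuristic and are ranked
by seed support when they must be capped (24 per contig).  Scoring defaults
are MEGABLAST-like: match +1, mismatch −2, gap open −4 plus −2 per gapped
column.  Acceptance requires E ≤ 10⁻⁵⁰, identity ≥ 95% and ≥ 100 columns
(gap columns included, matching how BLAST reports alignment length); ties
break by lower E-value, more columns, then leftmost genome start, which
makes the pipeline fully deterministic.

E-values use ungapped Karlin–Altschul statistics computed from the scoring
scheme and the background composition of the reduced target: λ solves
Σ p(s)e^{λs} = 1 (Brent's method) and K comes from the classical renewal
series for integer-lattice walks.  Gaps open rarely enough under the default
penalties that the ungapped null describes random alignments well; the test
suite checks agreement with an empirical shuffle null within an order of
magnitude, which is ample for a 10⁻⁵⁰ threshold.

The independent oracle used in tests (`sw_oracle`) is Biopython's
`PairwiseAligner` in local mode — a separate C implementation sharing no
code with the seed-and-extend path.

## Filters

All five filters are pure functions of one read's calls and the genome, so
the verdict is independent of application order.  Two interpretation choices
were genuinely open:

* **Paralog filter.** "A better alignment in another locus" compares the
  *untransformed* search against itself: the best untransformed hit at a
  non-overlapping locus must beat the best untransformed hit overlapping
  the called locus (and cover ≥ 90% of the original alignment's columns).
  Comparing the competitor against the transformed score would make the
  filter vacuous, because masking inflates that score.  "Another locus"
  means zero genomic-interval overlap.
* **Homogeneity filter.** Run length and base frequencies are computed on
  the original, untransformed aligned subsequences; the reduced alphabet
  necessarily violates any composition band.

The strand-support filter is the operational stand-in for ruling out T-to-C
editing: it fires only when at least two annotated transcripts support
exclusively the opposite strand.

## Prefilter

Candidates must be > 250 bp, have every base frequency within (10%, 60%)
(computed over ACGT positions, so N-rich reads are not double-penalized),
≤ 10% ambiguity codes (all non-ACGT IUPAC codes count), and ≤ 50%
simple-repeat content.  The simple-repeat scanner is a windowed tandem scan
over periods 1–6 (24 bp windows; a window counts as repetitive when ≥ 90% of
its (i, i+p) position pairs agree) — a declared stand-in for the dedicated
maskers used on real data, adequate for the pure cases the filter targets.
Finally, reads aligning untransformed at ≥ 98% identity over ≥ 90% of their
length (either strand) are dropped: they are ordinary genomic reads with no
masked signal to recover.

## Synthetic data

The generator emulates the data regime the screen was designed for:

* a background i.i.d. genome (60 kb default) carrying 20 repeat copies of a
  300 bp consensus, mutually ~4% diverged, each copy on the − strand with
  probability 0.5 so inverted pairs exist;
* the consensus is drawn A-rich with A > T (33% A, 19% T), mimicking the
  sense-strand composition bias of Alu;
* transcripts copy a repeat locus on its sense strand with 10 bp unedited
  flanks; each adenosine inside the repeat is edited independently with
  probability min(1, p·w_up·w_down), the default base rate p = 0.25 with
  neighbor weights w_up(G) = 0.2 and w_down(G) = 2.0 reproducing the ADAR
  preference (G depleted 5′, enriched 3′); uniform substitution errors at
  0.1% hit unedited positions; the read is reverse-complemented with
  probability 0.5;
* artifact classes: uniform 5% mismatch clusters (purity control),
  +-strand-only G→A clusters of 18 sites (the sequencing-error signature,
  dense enough to satisfy the rate criterion within a G-span), repeat copies
  with an embedded 40 bp A-run (homogeneity-filter target), and paralog
  pairs where a shadow copy carries the source's adenosines partially
  replaced by G; shadow transcripts receive exactly eight genuine edits so
  they evade the untransformed identity screen while the masked alignment
  ties between the two copies and resolves deterministically to the source —
  the paralog-filter target.

Everything is driven by `numpy.random.default_rng` seeded from a single
mandatory seed; outputs are byte-identical across runs.

What the simulator does **not** emulate: quality scores, indel sequencing
errors (the gap filter is exercised with constructed alignments instead),
spliced transcripts, polyA tails, nested or truncated repeats, and real Alu
subfamily structure.  Passing tests therefore demonstrate the pipeline's
internal correctness and its selectivity against the modeled artifact
classes, not performance on real EST libraries.

### Truth-based metrics

A simulated read counts as *truly* ultra-edited when its planted sites
satisfy the calling definition (≥ 12 sites at ≥ 20% of the span's
adenosines).  Sensitivity is measured over those reads; a read whose
stochastic editing draw fell below the definition is not a detection target.
Site precision is the fraction of cataloged unique sites that were planted.

## Numerical and interface choices

* Coordinates are 0-based half-open everywhere, BED-compatible; site
  neighbors are read 5′→3′ on the edited strand.
* The dsRNA proxy aligns a region to its own reverse complement
  (untransformed scoring, word size 8) and reports total matching bases of
  the best alignment; alignments under 20 columns count as zero, which
  suppresses chance self-pairing of random sequence.
* Inverted-repeat statistics use a 5 kb flank clipped at contig ends; the
  edited repeat is the one with maximal overlap with the region and the
  distance to the nearest opposite-strand repeat is the inter-interval gap
  (0 when overlapping).
* Enrichment per category is observed/expected with
  expected = (category total / grand total) × total edited; zero-total
  categories yield NaN rather than a silent drop.
* Problem sizes in tests and the acceptance script (50-read cohorts on a
  60 kb genome, 200 oracle pairs ≤ 500 bp) were chosen as the smallest
  cohorts at which the binomial confidence bands and recovery bounds are
  meaningfully tight.

## Known limitations

* The windowed aligner is exact per window but can in principle miss a
  lower-scoring co-optimal locus outside all seeded windows; with 12-mer
  seeding this requires ≥ 8% divergence in reduced space, above the 5%
  identity cutoff anyway.
* Ungapped E-value statistics slightly misstate the gapped null; the
  threshold regime (10⁻⁵⁰) is insensitive to this.
* Reads edited lightly enough to align untransformed at ≥ 95% identity pass
  several transformation combinations simultaneously and are removed by the
  multi-combination filter; this is the method's intrinsic behavior at the
  detection boundary, inherited from its reliance on a pool of
  previously *unalignable* reads.
* Spliced reads are out of scope: the aligner performs no intron-aware
  chaining, so an ultra-edited read spanning a splice junction would at best
  be recovered over its longest exonic segment.
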