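# Methods

## Problem and model

Alu elements are ~300 nt SINE retrotransposons; a sense and an antisense
copy transcribed in one RNA base-pair into a long hairpin whose stems DICER
cleaves into 21–24 nt endogenous siRNAs. This package quantifies such Alu
endo-siRNAs in small-RNA sequencing libraries and screens for their
candidate RNAi targets. Three analyses are modeled:

1. **Hierarchical annotation.** Each preprocessed read is assigned to the
   first reference category it aligns to, in the fixed order
   rRNA → tRNA → miRNA → repeat → snoRNA → transcript → genome. The
   ordering resolves the dominant ambiguity in small-RNA data: abundant
   rRNA/tRNA fragments and miRNAs are removed from consideration before the
   repeat step, so "repeat" reads are those explainable by nothing earlier.
   Alu siRNAs are repeat-assigned reads whose subfamily name begins with
   "Alu", restricted to 19–24 nt when counted as siRNAs.
2. **Exclusion-normalized differential.** Library-size normalization by
   total reads would be distorted by the two classes under study, so the
   Alu siRNA count is divided by the read total *excluding* miRNA and Alu
   siRNA reads, × 10⁶. The knockdown differential is the per-length
   difference of these normalized numbers (treated − control); depletion is
   negative by construction. The per-length numerator shares one global,
   library-level denominator — the normalization is defined per library,
   not per length.
3. **Target screen.** Genes are censused for Alu copies overlapping their
   3′UTR; orientation is defined relative to the mRNA (repeat strand equals
   gene strand ⇒ sense). Candidates have exactly one copy in the requested
   orientation and zero in the other — a sense+antisense pair is an
   inverted repeat, a different biological object, and is excluded from
   both screens — and log₁₀ expression strictly above the cut (default
   4.5). Seed sites are exact reverse-complement matches of guide
   nucleotides 2–8 (the standard 7-mer seed window) in the mRNA-sense
   3′UTR; an optional mode admits one seed mismatch. No supplementary
   pairing, G:U wobbles or context scoring: the screen models plain seed
   complementarity.

## Alignment semantics

Alignment is ungapped and end-to-end on both strands with at most `max_mm`
Hamming mismatches (default 2, applied uniformly at every cascade step);
N never matches any base, including another N. Candidate placements are
enumerated by pigeonhole seeding — a placement with ≤ m mismatches must
contain at least one of m+1 disjoint exact 6-mers — and each candidate is
verified, so the result provably equals a full scan over every offset
(queries shorter than 6·(m+1) nt fall back to scanning all offsets
directly). Hits are ordered deterministically (fewest mismatches, lowest
start, + before −, then reference input order) and the cascade reports one
representative hit per read; the category, the quantity the analyses
consume, is independent of which within-set hit is chosen. Reads aligning
equally well to several sets are claimed by the earliest set — by design,
adding sequences to a later set can never change an earlier assignment.

The dicing mode maps in vitro DICER products with zero mismatches after
removing the 5′ cloning adaptor as an exact prefix and the 3′ adaptor by
prefix-overlap trimming, and accumulates full per-position coverage per
strand. Reads without a detectable 3′ adaptor are mapped as-is (they may be
pre-trimmed); reads that place nowhere at zero mismatches are counted as
unmapped. Note that the two stems of a near-palindromic hairpin can
cross-map: with sibling-subfamily arms a fragment may be placed on the
homologous position of the other stem. Coverage then still falls entirely
within the stems; only the per-arm attribution blurs.

## Preprocessing choices

Adaptor trimming is exact-match (no error tolerance): the insert ends at
the leftmost position where the rest of the read equals a prefix of the
adaptor (the full adaptor when the read runs past it) with overlap ≥ 6.
Exact matching is deterministic and oracle-checkable, and the simulator
emits error-free adaptors. Reads with no detectable adaptor are discarded
by default — their 3′ end is unknown — with `keep_untrimmed` to retain
them. Exogenous (transfected) siRNA reads are removed by substring
containment in both directions, catching partially trimmed forms. All
downstream counts are multiplicity-weighted, so collapsed and uncollapsed
libraries give identical numbers (a tested property).

The CPM denominator for length distributions is selectable (all
preprocessed reads by default, or aligned-only, or a caller-supplied raw
total), since different library QC conventions exist; the choice is
explicit rather than hidden.

## Synthetic data: what it emulates, what it does not

The generator builds, from one integer seed: Alu subfamily consensi (a
shared ~300 nt ancestor with 8% per-subfamily divergence), a miniature
genome with annotated embedded copies (1% copy divergence by default),
gene models whose 3′UTRs carry 0 / 1 sense / 1 antisense / an inverted pair
of copies, disjoint rRNA/tRNA/miRNA/snoRNA/transcript sets, and mixed raw
libraries with the full 3′ adaptor appended and per-read ground truth.
Default class mix: miRNA 0.55, rRNA 0.22, tRNA 0.12, Alu sense+antisense
0.00165 (so Alu siRNA : miRNA = 0.003, the observed in vivo order of
magnitude), background 0.10835. Non-dicer insert lengths span 19–35 nt
with a 21–24 nt mode and a small 30–32 shoulder; Alu inserts are 21–24 nt
dicer fragments with independent (non-phased) cleavage positions sampled
uniformly within hairpin stems.

Two deliberate cleanliness constraints make ground truth exact: the small
reference sets share no 19-mer with any Alu consensus (either orientation),
so class labels cannot collide except when `cross_contaminate` plants a
shared 21-mer on purpose for precedence tests; and all reference sequences
exclude the 6 nt 3′-adaptor seed prefixes in both orientations, so
simulated inserts never trigger spurious trimming. Real libraries satisfy
neither constraint perfectly — passing tests show the machinery is correct
under known truth, not that real rRNA never shares k-mers with Alu.

Knockdown pairs are generated by *matched thinning*: the treated library is
the control with each Alu-class read kept with probability `alu_scale` and
every other read carried over unchanged. This realizes "all non-Alu classes
identical" exactly, which is what makes the per-length differential sign
strict wherever the control observes reads. `SimConfig.alu_scale`
alternatively rescales the class probabilities (renormalized) for
independent libraries. Other known simplifications: no ligation bias, no
PCR duplicates, no quality scores, no A-to-I editing; an optional uniform
substitution rate exercises the ≤2-mismatch path. Per-class RNG substreams
are derived deterministically from the seed, so altering one class's
parameters leaves the other classes' draws untouched.

## Numerical and degenerate-input conventions

Coordinates are 0-based half-open internally; display strings are 1-based
inclusive. RNA input is folded to the DNA alphabet at the boundary.
Zero or negative normalization denominators raise rather than returning
infinities. An empty library yields an all-zero summary; a query longer
than its reference yields no hits, not an error. Table outputs are
byte-deterministic for identical inputs.

## Problem sizes used by the test suite and acceptance script

Simulated libraries of 10⁵ reads (annotation, ratio recovery, knockdown
differential), 10⁴ dicer fragments on a 300 nt / 533 nt / 300 nt hairpin
(matching a known intronic inverted-Alu configuration), 10 genes in the
screen world, and 5,000–10,000 random 1 kb UTRs for the seed-site null
calibration, whose expectation is (L−6)·4⁻⁷ sites per UTR. These sizes
put all stochastic checks within 3-standard-error resolution of their
targets (e.g. the 0.003 Alu/miRNA ratio is estimated with SE ≈ 2.3·10⁻⁴
at 10⁵ reads).

## Known limitations

Single-interval 3′UTRs only (no spliced UTRs, no GFF parsing); ungapped
alignment only (indel-containing reads go unassigned or mis-tally
mismatches); the screen does not rank candidates by predicted efficacy or
thermodynamics; the dicing mode reports coverage, not cleavage-register
statistics; desk-scale references (the full-scan guarantee is practical for
kilobase-to-megabase references, not whole mammalian genomes).
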