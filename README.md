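# alusirna

Analysis toolkit for **Alu-derived endogenous siRNAs** in human small-RNA
sequencing data. Alu elements are ~300 nt primate SINE retrotransposons;
when a sense and an antisense copy sit in one transcript they fold into a
long hairpin whose stems DICER can cleave into 21–24 nt endo-siRNAs. These
siRNAs are rare (on the order of 0.3% of miRNA reads), map to both strands
of Alu consensus sequences, load onto AGO2, and can silence genes that carry
a complementary Alu copy in their 3′UTR. Detecting them therefore takes a
careful annotation cascade (so rRNA/tRNA/miRNA fragments don't masquerade as
repeat reads), strand-resolved profiling, and a normalization that is not
distorted by the very classes being compared.

The package provides, as an importable library:

- **Preprocessing** — exact 3′-adaptor trimming (leftmost adaptor-prefix
  match, minimum overlap 6), removal of transfected exogenous siRNA reads by
  bidirectional substring containment, and the 19–35 nt length gate.
- **Annotation cascade** — ungapped end-to-end alignment of each read on
  both strands with at most 2 Hamming mismatches (N matches nothing),
  assigning each read to the first category it hits in the fixed order
  rRNA → tRNA → miRNA → repeat → snoRNA → transcript → genome.
  The aligner enumerates candidates by pigeonhole seeding and verifies every
  one, so its hit set equals an exhaustive scan.
- **Alu siRNA profiling** — 19–24 nt Alu-mapped reads counted per length and
  strand in CPM; 5′-start profiles along a consensus; the exclusion-normalized
  differential

      norm = n_Alu / (n_total − n_miRNA − n_Alu) × 10⁶,
      Δ(len) = norm_treated(len) − norm_control(len)

  (negative Δ = depletion after knockdown); and a zero-mismatch dicing mode
  that maps in vitro DICER products onto an inverted-Alu hairpin per strand.
- **Target screen** — per-gene census of 3′UTR Alu copies by orientation
  relative to the mRNA, selection of genes with *exactly one* sense or
  antisense copy (inverted pairs excluded) above a log₁₀ 4.5 expression cut,
  and seed-site prediction: every occurrence of the reverse-complemented
  siRNA seed (guide nucleotides 2–8) in the mRNA-sense 3′UTR.
- **Synthetic data** — a deterministic generator of Alu consensi, an
  annotated genome with embedded copies and gene models, inverted-repeat
  hairpins, dicer fragments, and full mixed libraries with per-read ground
  truth, so the whole pipeline is testable without downloads.

## Worked example

```python
from alusirna import (SimConfig, make_synthetic_references, preprocess_reads,
                      run_cascade, alu_sirna_count, normalized_alu_count,
                      simulate_library)

refs = make_synthetic_references(seed=1)
config = SimConfig(seed=1, n_reads=100_000)
reads, truth = simulate_library(config, refs)
passed, report = preprocess_reads(reads, config.adaptor)
summary = run_cascade(passed, refs.ref_sets)
print(summary.counts)
print(round(100 * alu_sirna_count(summary) / summary.counts["miRNA"], 3), "%")
print(round(normalized_alu_count(summary), 1))
```

prints

```
{'rRNA': 21857, 'tRNA': 12046, 'miRNA': 55019, 'repeat': 158, 'snoRNA': 0,
 'transcript': 0, 'genome': 0, 'unaligned': 10920}
0.287 %
3525.0
```

i.e. the cascade partitions all 100,000 preprocessed reads exactly, Alu
siRNAs come out at 0.287% of miRNA reads — recovering the simulated 0.3%
condition within counting noise — and their exclusion-normalized abundance
is 3,525 per million non-miRNA/non-Alu reads.
The scripts in `examples/` walk through each capability (annotation,
profiling, knockdown differential, dicing coverage, target screen) with
printed output and a line on what it means.

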