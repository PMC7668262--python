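"""Synthetic genomes, annotations, hairpins and small-RNA libraries.

Every pipeline stage is testable without downloads: this module builds a
miniature genome with embedded, annotated Alu copies and gene models, small
reference sets for each cascade category, inverted-repeat hairpins, and raw
small-RNA libraries (3' adaptor appended) with full per-read ground truth.

The generator's defaults encode the study conditions: a mixed library
dominated by miRNAs with rRNA/tRNA fragments and unannotated background, and
Alu endo-siRNAs at 0.3% of the miRNA count; Alu siRNAs are 21-24 nt dicer
cleavage products sampled independently from hairpin stems (no processive
phasing).  All randomness flows from one integer seed; each read class draws
from its own deterministic substream so changing one class's parameters does
not perturb the others' draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .align import revcomp
from .io import (
    CATEGORIES,
    GeneModel,
    HairpinLocus,
    NamedSequence,
    ReferenceSet,
    RepeatAnnotation,
)
from .preprocess import (
    ADAPTOR_3P_AGO2,
    ADAPTOR_3P_TOTAL,
    SmallRead,
)
from .profiling import DICING_ADAPTOR_3P

__all__ = [
    "SIM_CLASSES",
    "SimConfig",
    "SimRefParams",
    "SyntheticReferences",
    "GroundTruth",
    "make_synthetic_references",
    "make_hairpin",
    "simulate_dicer_products",
    "simulate_library",
    "apply_alu_knockdown",
    "simulate_paired_libraries",
]

SIM_CLASSES = (
    "miRNA",
    "rRNA_frag",
    "tRNA_frag",
    "alu_sirna_sense",
    "alu_sirna_antisense",
    "random_background",
)

# Alu siRNA : miRNA read ratio 0.003, matching the observed 0.3% in vivo.
DEFAULT_CLASS_MIX = {
    "miRNA": 0.55,
    "rRNA_frag": 0.22,
    "tRNA_frag": 0.12,
    "alu_sirna_sense": 0.000825,
    "alu_sirna_antisense": 0.000825,
    "random_background": 0.10835,
}

# Insert lengths 19-35 nt with the observed 21-24 major mode and a small
# 30-32 shoulder (applies to non-dicer classes; dicer products are 21-24).
_LEN_VALUES = tuple(range(19, 36))
_LEN_WEIGHTS = (2, 3, 10, 14, 10, 6, 3, 2, 1.5, 1, 1, 1.5, 2, 2, 1, 0.5, 0.5)

DICER_LENGTHS = (21, 22, 23, 24)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# Inserts must never contain a spurious 3'-adaptor seed, or trimming would
# shorten them; references are rejection-sampled against these k-mers in
# both orientations.
_ADAPTOR_SEED_LEN = 6
_FORBIDDEN_KMERS = frozenset(
    k
    for a in (ADAPTOR_3P_TOTAL, ADAPTOR_3P_AGO2, DICING_ADAPTOR_3P)
    for k in (a[:_ADAPTOR_SEED_LEN], revcomp(a[:_ADAPTOR_SEED_LEN]))
)


def _rand_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _clean_rand_seq(
    rng: np.random.Generator,
    length: int,
    avoid_19mers: set[str] | None = None,
    max_tries: int = 1000,
) -> str:
    """Random sequence free of adaptor seeds and, optionally, Alu 19-mers."""
    for _ in range(max_tries):
        seq = _rand_seq(rng, length)
        if any(k in seq for k in _FORBIDDEN_KMERS):
            continue
        if avoid_19mers and length >= 19 and not _kmers(seq, 19).isdisjoint(avoid_19mers):
            continue
        return seq
    raise RuntimeError("could not sample a clean sequence")


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Per-base substitutions at the given rate (to a different base)."""
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hit:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


# ---------------------------------------------------------------------------
# Reference generation


@dataclass
class SimRefParams:
    """Sizes and composition of the synthetic reference world.

    Alu consensi are ~300 nt (the canonical element length); gene 3'UTRs
    carry 0, 1 sense, 1 antisense, or an inverted pair of Alu copies in the
    stated numbers.  Expression scores are drawn above the screen's default
    4.5 log10 cut so constructed single-Alu genes are recoverable.
    """

    n_alu_subfamilies: int = 3
    alu_len: int = 300
    subfamily_divergence: float = 0.08
    copies_per_subfamily: int = 2
    n_rrna: int = 2
    rrna_len: int = 1500
    n_trna: int = 10
    trna_len: int = 75
    n_mirna: int = 20
    n_snorna: int = 8
    snorna_len: int = 100
    n_transcript: int = 5
    transcript_len: int = 800
    n_genes_single_antisense: int = 4
    n_genes_single_sense: int = 3
    n_genes_inverted: int = 2
    n_genes_no_alu: int = 1
    utr_flank: int = 150
    expression_range: tuple[float, float] = (4.6, 6.2)
    genome_mutation_rate: float = 0.01
    spacer_len: int = 150
    cross_contaminate: bool = False


@dataclass
class SyntheticReferences:
    """Reference sets (cascade order), annotations, gene models and genome."""

    ref_sets: list[ReferenceSet]
    repeats: list[RepeatAnnotation]
    genes: list[GeneModel]
    genome: NamedSequence
    alu_consensi: list[NamedSequence]
    gene_truth: dict[str, str]

    def reference_set(self, category: str) -> ReferenceSet:
        for rs in self.ref_sets:
            if rs.category == category:
                return rs
        raise KeyError(category)


def make_synthetic_references(
    seed: int, params: SimRefParams | None = None
) -> SyntheticReferences:
    """Build the full synthetic reference world deterministically from a seed.

    The genome carries mutated, annotated Alu copies (standalone and inside
    designated gene 3'UTRs); the rRNA/tRNA/miRNA/snoRNA/transcript sets share
    no 19-mer with any Alu consensus (rejection-sampled) unless
    ``cross_contaminate`` plants a deliberate shared 21-mer in the first rRNA
    for cascade-precedence tests.
    """
    p = params or SimRefParams()
    rng = np.random.default_rng([seed, 101])

    # Alu subfamily consensi: a shared ancestor with per-subfamily divergence.
    base = _clean_rand_seq(rng, p.alu_len)
    consensi: list[NamedSequence] = []
    for i in range(p.n_alu_subfamilies):
        for _ in range(1000):
            seq = _mutate(base, p.subfamily_divergence, rng)
            if not any(k in seq for k in _FORBIDDEN_KMERS) and not any(
                k in revcomp(seq) for k in _FORBIDDEN_KMERS
            ):
                break
        else:  # pragma: no cover
            raise RuntimeError("could not sample a clean consensus")
        consensi.append(NamedSequence(f"AluSim{i + 1}", seq))
    if len({c.seq for c in consensi}) != len(consensi):  # pragma: no cover
        raise RuntimeError("degenerate consensus set; use a different seed")

    alu19 = set()
    for c in consensi:
        alu19 |= _kmers(c.seq, 19) | _kmers(revcomp(c.seq), 19)

    def small_set(n: int, length) -> list[str]:
        lengths = length if isinstance(length, (list, tuple)) else [length] * n
        return [_clean_rand_seq(rng, lengths[i % len(lengths)], alu19) for i in range(n)]

    rrna = small_set(p.n_rrna, p.rrna_len)
    trna = small_set(p.n_trna, p.trna_len)
    mirna = small_set(p.n_mirna, [21, 22])
    snorna = small_set(p.n_snorna, p.snorna_len)
    transcripts = small_set(p.n_transcript, p.transcript_len)

    if p.cross_contaminate:
        # Plant a 21-mer of the first consensus inside the first rRNA, so a
        # read from it multi-matches rRNA and repeat; the cascade must pick rRNA.
        shared = consensi[0].seq[100:121]
        pos = p.rrna_len // 2
        rrna[0] = rrna[0][:pos] + shared + rrna[0][pos + 21 :]

    # --- genome assembly ------------------------------------------------
    chrom = "chrS1"
    parts: list[str] = []
    cursor = 0
    repeats: list[RepeatAnnotation] = []
    genes: list[GeneModel] = []
    gene_truth: dict[str, str] = {}

    def add(seq: str) -> int:
        nonlocal cursor
        start = cursor
        parts.append(seq)
        cursor += len(seq)
        return start

    def embed_alu(sub_idx: int, strand: str) -> None:
        cons = consensi[sub_idx % len(consensi)]
        seq = _mutate(cons.seq, p.genome_mutation_rate, rng)
        if strand == "-":
            seq = revcomp(seq)
        start = add(seq)
        repeats.append(
            RepeatAnnotation(chrom, start, start + len(seq), strand, cons.id, "Alu")
        )

    gene_plan = (
        [("single_antisense", i) for i in range(p.n_genes_single_antisense)]
        + [("single_sense", i) for i in range(p.n_genes_single_sense)]
        + [("inverted", i) for i in range(p.n_genes_inverted)]
        + [("no_alu", i) for i in range(p.n_genes_no_alu)]
    )
    for g, (kind, _) in enumerate(gene_plan):
        gene_id = f"GSIM{g:03d}"
        gene_strand = "+" if g % 2 == 0 else "-"
        add(_rand_seq(rng, p.spacer_len))
        utr_start = cursor
        add(_rand_seq(rng, p.utr_flank))
        if kind == "single_antisense":
            embed_alu(g, "-" if gene_strand == "+" else "+")
        elif kind == "single_sense":
            embed_alu(g, gene_strand)
        elif kind == "inverted":
            embed_alu(g, gene_strand)
            add(_rand_seq(rng, 60))
            embed_alu(g + 1, "-" if gene_strand == "+" else "+")
        elif kind == "no_alu":
            add(_rand_seq(rng, p.alu_len))
        add(_rand_seq(rng, p.utr_flank))
        utr_end = cursor
        utr_seq = "".join(parts)[utr_start:utr_end]
        if gene_strand == "-":
            utr_seq = revcomp(utr_seq)
        genes.append(
            GeneModel(
                gene_id=gene_id,
                chrom=chrom,
                strand=gene_strand,
                utr3_start=utr_start,
                utr3_end=utr_end,
                expression=float(rng.uniform(*p.expression_range)),
                utr3_seq=utr_seq,
            )
        )
        gene_truth[gene_id] = kind

    # Standalone intergenic copies.
    for i in range(p.n_alu_subfamilies):
        for c in range(p.copies_per_subfamily):
            add(_rand_seq(rng, p.spacer_len))
            embed_alu(i, "+" if c % 2 == 0 else "-")
    add(_rand_seq(rng, p.spacer_len))

    genome = NamedSequence(chrom, "".join(parts))

    def named(prefix: str, seqs: list[str]) -> list[NamedSequence]:
        return [NamedSequence(f"{prefix}{i + 1}", s) for i, s in enumerate(seqs)]

    ref_sets = [
        ReferenceSet("rRNA", named("rRNA_", rrna)),
        ReferenceSet("tRNA", named("tRNA_", trna)),
        ReferenceSet("miRNA", named("miR_sim_", mirna)),
        ReferenceSet("repeat", list(consensi), {c.id: c.id for c in consensi}),
        ReferenceSet("snoRNA", named("snoRNA_", snorna)),
        ReferenceSet("transcript", named("tx_", transcripts)),
        ReferenceSet("genome", [genome]),
    ]
    return SyntheticReferences(ref_sets, repeats, genes, genome, consensi, gene_truth)


# ---------------------------------------------------------------------------
# Hairpins and dicer products


def make_hairpin(
    name: str,
    sense_arm: NamedSequence,
    antisense_source: NamedSequence,
    loop_len: int = 533,
    seed: int = 0,
) -> HairpinLocus:
    """Inverted-repeat hairpin: sense Alu, connecting loop, antisense Alu.

    The right arm is the reverse complement of ``antisense_source`` so the
    two arms base-pair; the default 533 nt loop matches the intronic
    inverted-Alu configuration used for in vitro dicing.
    """
    rng = np.random.default_rng([seed, 733])
    loop = _rand_seq(rng, loop_len)
    full = sense_arm.seq + loop + revcomp(antisense_source.seq)
    la = len(sense_arm.seq)
    return HairpinLocus(
        name=name,
        left_arm=(0, la),
        loop=(la, la + loop_len),
        right_arm=(la + loop_len, len(full)),
        full_seq=full,
    )


def simulate_dicer_products(
    hairpin: HairpinLocus,
    n: int,
    seed: int,
    lengths: tuple[int, ...] = DICER_LENGTHS,
    minus_fraction: float = 0.5,
) -> list[tuple[str, str, int]]:
    """Sample dicer cleavage fragments from hairpin stems.

    Fragments are 21-24 nt by default, with 5' starts uniform within either
    arm such that the fragment stays inside the arm; - strand fragments are
    reverse-complemented arm substrings.  Cleavage positions are independent
    (no processive phasing).  Returns (sequence, strand, start-on-hairpin).
    """
    max_len = max(lengths)
    for a0, a1 in hairpin.arms:
        if a1 - a0 < max_len:
            raise ValueError(f"hairpin {hairpin.name}: arm shorter than {max_len} nt")
    rng = np.random.default_rng([seed, 577])
    out: list[tuple[str, str, int]] = []
    arms = hairpin.arms
    for _ in range(n):
        length = int(rng.choice(lengths))
        # Arm chosen in proportion to its number of valid placements.
        weights = np.array([a1 - a0 - length + 1 for a0, a1 in arms], dtype=float)
        arm = arms[int(rng.choice(2, p=weights / weights.sum()))]
        start = int(arm[0] + rng.integers(0, arm[1] - arm[0] - length + 1))
        frag = hairpin.full_seq[start : start + length]
        strand = "-" if rng.random() < minus_fraction else "+"
        out.append((revcomp(frag) if strand == "-" else frag, strand, start))
    return out


# ---------------------------------------------------------------------------
# Library simulation


@dataclass
class SimConfig:
    """Conditions for one simulated small-RNA library."""

    seed: int
    n_reads: int = 100_000
    class_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MIX)
    )
    alu_scale: float = 1.0
    read_len_dist: dict[int, float] | None = None
    adaptor: str = ADAPTOR_3P_TOTAL
    mutation_rate: float = 0.0
    machine_read_len: int = 50
    partial_adaptor_frac: float = 0.0

    def __post_init__(self) -> None:
        if set(self.class_mix) != set(SIM_CLASSES):
            raise ValueError(f"class_mix must have keys {SIM_CLASSES}")
        if any(v < 0 for v in self.class_mix.values()):
            raise ValueError("class proportions must be >= 0")
        if abs(sum(self.class_mix.values()) - 1.0) > 1e-9:
            raise ValueError("class_mix must sum to 1")
        if not 0 <= self.alu_scale:
            raise ValueError("alu_scale must be >= 0")

    def probabilities(self) -> np.ndarray:
        """Class probabilities with alu_scale applied and renormalized."""
        p = np.array([self.class_mix[c] for c in SIM_CLASSES], dtype=float)
        for i, c in enumerate(SIM_CLASSES):
            if c.startswith("alu_sirna"):
                p[i] *= self.alu_scale
        return p / p.sum()


@dataclass
class GroundTruth:
    """Per-read truth (class, source, strand, insert length) for a library."""

    per_read: pd.DataFrame
    class_counts: dict[str, int]

    def check(self, reads: list[SmallRead]) -> None:
        if list(self.per_read["read_id"]) != [r.id for r in reads]:
            raise AssertionError("ground truth does not cover the reads exactly")


def _len_probs(dist: dict[int, float] | None) -> tuple[np.ndarray, np.ndarray]:
    if dist is None:
        values = np.array(_LEN_VALUES)
        probs = np.array(_LEN_WEIGHTS, dtype=float)
    else:
        values = np.array(sorted(dist))
        probs = np.array([dist[v] for v in values], dtype=float)
    return values, probs / probs.sum()


def simulate_library(
    config: SimConfig, refs: SyntheticReferences
) -> tuple[list[SmallRead], GroundTruth]:
    """Simulate a raw small-RNA library with the full 3' adaptor appended.

    Each read draws its class from the (alu-scaled) mix, then its insert:
    miRNAs are exact mature sequences; rRNA/tRNA fragments are random
    substrings with the configured length distribution; Alu siRNAs are 21-24
    nt dicer-style fragments of an Alu consensus, sense as-is and antisense
    reverse-complemented; background is i.i.d. uniform sequence.  The insert
    plus adaptor is truncated to the machine read length.  Ground truth
    covers every emitted read.
    """
    for cat, attr in (("miRNA", "miRNA"), ("rRNA", "rRNA_frag"), ("tRNA", "tRNA_frag")):
        if not refs.reference_set(cat).sequences:
            raise ValueError(f"empty reference set for requested class {attr}")
    if not refs.alu_consensi:
        raise ValueError("no Alu consensi available for the Alu siRNA classes")

    master = np.random.default_rng([config.seed, 0])
    class_idx = master.choice(len(SIM_CLASSES), size=config.n_reads, p=config.probabilities())
    rngs = {i: np.random.default_rng([config.seed, i + 1]) for i in range(len(SIM_CLASSES))}
    len_values, len_probs = _len_probs(config.read_len_dist)

    mirna = refs.reference_set("miRNA").sequences
    rrna = refs.reference_set("rRNA").sequences
    trna = refs.reference_set("tRNA").sequences
    consensi = refs.alu_consensi

    reads: list[SmallRead] = []
    rows: list[tuple[str, str, str, str, int]] = []
    for i, ci in enumerate(class_idx):
        cls = SIM_CLASSES[ci]
        rng = rngs[int(ci)]
        if cls == "miRNA":
            src = mirna[int(rng.integers(len(mirna)))]
            insert, source, strand = src.seq, src.id, "+"
        elif cls in ("rRNA_frag", "tRNA_frag"):
            pool = rrna if cls == "rRNA_frag" else trna
            src = pool[int(rng.integers(len(pool)))]
            length = int(min(rng.choice(len_values, p=len_probs), len(src.seq)))
            start = int(rng.integers(0, len(src.seq) - length + 1))
            insert, source, strand = src.seq[start : start + length], src.id, "+"
        elif cls in ("alu_sirna_sense", "alu_sirna_antisense"):
            cons = consensi[int(rng.integers(len(consensi)))]
            length = int(rng.choice(DICER_LENGTHS))
            start = int(rng.integers(0, len(cons.seq) - length + 1))
            frag = cons.seq[start : start + length]
            if cls == "alu_sirna_antisense":
                insert, strand = revcomp(frag), "-"
            else:
                insert, strand = frag, "+"
            source = cons.id
        else:  # random_background
            length = int(rng.choice(len_values, p=len_probs))
            insert, source, strand = _rand_seq(rng, length), "background", "+"
        if config.mutation_rate > 0:
            insert = _mutate(insert, config.mutation_rate, rng)
        adaptor = config.adaptor
        if config.partial_adaptor_frac > 0 and rng.random() < config.partial_adaptor_frac:
            adaptor = adaptor[: int(rng.integers(1, len(adaptor) + 1))]
        raw = (insert + adaptor)[: config.machine_read_len]
        read_id = f"read{i:07d}"
        reads.append(SmallRead(read_id, raw))
        rows.append((read_id, cls, source, strand, len(insert)))

    per_read = pd.DataFrame(
        rows, columns=["read_id", "true_class", "source", "strand", "insert_len"]
    )
    counts = {c: 0 for c in SIM_CLASSES}
    for c, n in per_read["true_class"].value_counts().items():
        counts[c] = int(n)
    truth = GroundTruth(per_read, counts)
    truth.check(reads)
    return reads, truth


def apply_alu_knockdown(
    reads: list[SmallRead],
    truth: GroundTruth,
    alu_scale: float,
    seed: int,
) -> tuple[list[SmallRead], GroundTruth]:
    """Derive a matched knockdown library by thinning the Alu siRNA classes.

    Each Alu-class read is kept with probability ``alu_scale``; every other
    read is carried over unchanged.  This models a knockdown that depletes
    Alu siRNA production while leaving the rest of the library identical,
    giving an exactly matched treated/control pair.
    """
    if not 0 <= alu_scale <= 1:
        raise ValueError("alu_scale must be in [0, 1] for thinning")
    rng = np.random.default_rng([seed, 9973])
    is_alu = truth.per_read["true_class"].str.startswith("alu_sirna").to_numpy()
    keep = np.ones(len(reads), dtype=bool)
    keep[is_alu] = rng.random(int(is_alu.sum())) < alu_scale
    kept_reads = [r for r, k in zip(reads, keep) if k]
    per_read = truth.per_read[keep].reset_index(drop=True)
    counts = {c: 0 for c in SIM_CLASSES}
    for c, n in per_read["true_class"].value_counts().items():
        counts[c] = int(n)
    out = GroundTruth(per_read, counts)
    out.check(kept_reads)
    return kept_reads, out


def simulate_paired_libraries(
    config: SimConfig,
    refs: SyntheticReferences,
    alu_scale: float = 0.5,
) -> tuple[list[SmallRead], GroundTruth, list[SmallRead], GroundTruth]:
    """Matched control/treated pair sharing all non-Alu reads.

    Returns (control_reads, control_truth, treated_reads, treated_truth);
    the treated library is the control with its Alu siRNA classes thinned to
    ``alu_scale``.
    """
    control_reads, control_truth = simulate_library(config, refs)
    treated_reads, treated_truth = apply_alu_knockdown(
        control_reads, control_truth, alu_scale, config.seed
    )
    return control_reads, control_truth, treated_reads, treated_truth
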