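"""Alu endo-siRNA quantification.

Covers: per-length sense/antisense abundance in counts per million (CPM);
strand-resolved 5'-start profiles on repeat consensus sequences; the
exclusion-normalized knockdown-minus-control differential, in which the Alu
siRNA read count is divided by the library total excluding miRNA and Alu
siRNA reads and scaled to one million; and zero-mismatch strand coverage of
in vitro dicing products on an inverted-repeat hairpin.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .align import AnnotationSummary, CategoryAssignment, SequenceIndex
from .io import HairpinLocus, NamedSequence
from .preprocess import SmallRead, trim_adaptor

__all__ = [
    "DICING_ADAPTOR_5P",
    "DICING_ADAPTOR_3P",
    "LengthDistribution",
    "ConsensusProfile",
    "DifferentialProfile",
    "StrandCoverage",
    "select_alu_sirnas",
    "alu_sirna_count",
    "length_distribution",
    "consensus_profile",
    "normalized_alu_count",
    "differential_profile",
    "map_dicing_products",
]

# Cloning adaptors of the in vitro dicing-product libraries.
DICING_ADAPTOR_5P = "TGGAATTCTCGGGCACCAAGGT"
DICING_ADAPTOR_3P = "ACGCTGGAATTCGCGGTTAAA"

#: siRNA length window used when counting Alu siRNAs.
SIRNA_LO, SIRNA_HI = 19, 24
#: Full small-RNA length window retained by preprocessing.
WINDOW_LO, WINDOW_HI = 19, 35


def _is_alu(a: CategoryAssignment) -> bool:
    return (
        a.category == "repeat"
        and a.subfamily is not None
        and a.subfamily.startswith("Alu")
    )


def _read_len(a: CategoryAssignment) -> int:
    assert a.hit is not None
    return a.hit.end - a.hit.start


def select_alu_sirnas(
    summary: AnnotationSummary, lo: int = SIRNA_LO, hi: int = SIRNA_HI
) -> list[CategoryAssignment]:
    """Alu-subfamily repeat-mapped reads within the siRNA length window.

    Strand (sense = matches the consensus, antisense = its reverse
    complement) is carried by each assignment's hit.
    """
    return [
        a
        for a in summary.assignments
        if _is_alu(a) and lo <= _read_len(a) <= hi
    ]


def alu_sirna_count(
    summary: AnnotationSummary, lo: int = SIRNA_LO, hi: int = SIRNA_HI
) -> int:
    """Multiplicity-weighted Alu siRNA read count in the length window."""
    return sum(a.mult for a in select_alu_sirnas(summary, lo, hi))


@dataclass
class LengthDistribution:
    """Per-length CPM of Alu-mapped reads, split by consensus strand."""

    lengths: np.ndarray
    sense_cpm: np.ndarray
    antisense_cpm: np.ndarray
    library_total: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "length": self.lengths,
                "sense_cpm": self.sense_cpm,
                "antisense_cpm": self.antisense_cpm,
            }
        )


def length_distribution(
    summary: AnnotationSummary,
    denominator_mode: str = "preprocessed",
    total_raw: int | None = None,
    lo: int = WINDOW_LO,
    hi: int = WINDOW_HI,
) -> LengthDistribution:
    """CPM per length and strand for Alu-mapped reads.

    The CPM denominator is selectable: "preprocessed" (all reads entering the
    cascade, the default), "aligned" (reads assigned to any category), or
    "total_raw" (caller-supplied raw library size).
    """
    if denominator_mode == "preprocessed":
        denom = summary.total_input
    elif denominator_mode == "aligned":
        denom = summary.total_input - summary.counts.get("unaligned", 0)
    elif denominator_mode == "total_raw":
        if total_raw is None:
            raise ValueError("denominator_mode='total_raw' requires total_raw")
        denom = total_raw
    else:
        raise ValueError(f"unknown denominator_mode {denominator_mode!r}")
    if denom <= 0:
        raise ValueError("CPM denominator is zero")
    lengths = np.arange(lo, hi + 1)
    sense = np.zeros(len(lengths))
    anti = np.zeros(len(lengths))
    for a in summary.assignments:
        if not _is_alu(a):
            continue
        n = _read_len(a)
        if not lo <= n <= hi:
            continue
        tgt = sense if a.hit.strand == "+" else anti
        tgt[n - lo] += a.mult
    scale = 1e6 / denom
    return LengthDistribution(lengths, sense * scale, anti * scale, denom)


@dataclass
class ConsensusProfile:
    """5'-start histograms of reads on one consensus, per strand.

    For - strand hits the recorded position is the hit's leftmost reference
    coordinate, so sense and antisense profiles share one axis.
    """

    consensus_id: str
    sense: np.ndarray
    antisense: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        pos = np.arange(len(self.sense))
        return pd.DataFrame(
            {
                "consensus": self.consensus_id,
                "pos": np.concatenate([pos, pos]),
                "strand": ["+"] * len(pos) + ["-"] * len(pos),
                "count": np.concatenate([self.sense, self.antisense]),
            }
        )


def consensus_profile(
    alu_reads_with_hits: Iterable[CategoryAssignment],
    consensus: NamedSequence,
) -> ConsensusProfile:
    """Accumulate multiplicity-weighted 5'-start counts on one consensus."""
    n = len(consensus.seq)
    sense = np.zeros(n)
    anti = np.zeros(n)
    for a in alu_reads_with_hits:
        if a.hit is None or a.hit.ref_id != consensus.id:
            continue
        if a.hit.end > n or a.hit.start < 0:
            raise ValueError(
                f"hit {a.hit.start}-{a.hit.end} outside consensus {consensus.id}"
            )
        (sense if a.hit.strand == "+" else anti)[a.hit.start] += a.mult
    return ConsensusProfile(consensus.id, sense, anti)


def normalized_alu_count(
    summary: AnnotationSummary,
    length: int | None = None,
    lo: int = SIRNA_LO,
    hi: int = SIRNA_HI,
) -> float:
    """Exclusion-normalized Alu siRNA abundance.

    Divides the Alu siRNA count by the library total excluding miRNA and Alu
    siRNA reads, times one million.  The per-length variant (``length``)
    restricts the numerator to Alu-mapped reads of that exact length while
    keeping the same global denominator.
    """
    alu_total = alu_sirna_count(summary, lo, hi)
    denom = summary.total_input - summary.counts.get("miRNA", 0) - alu_total
    if denom <= 0:
        raise ValueError("non-positive normalization denominator")
    if length is None:
        num = alu_total
    else:
        num = sum(
            a.mult
            for a in summary.assignments
            if _is_alu(a) and _read_len(a) == length
        )
    return num / denom * 1e6


@dataclass
class DifferentialProfile:
    """Per-length knockdown-minus-control normalized Alu siRNA difference.

    delta(len) < 0 means the treated (knockdown/knockout) library has fewer
    normalized Alu siRNA reads of that length than the control.
    """

    lengths: np.ndarray
    norm_treated: np.ndarray
    norm_control: np.ndarray
    delta: np.ndarray
    treated_alu: int
    treated_denominator: int
    control_alu: int
    control_denominator: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "length": self.lengths,
                "norm_treated": self.norm_treated,
                "norm_control": self.norm_control,
                "delta": self.delta,
            }
        )


def differential_profile(
    treated: AnnotationSummary,
    control: AnnotationSummary,
    lo: int = SIRNA_LO,
    hi: int = SIRNA_HI,
) -> DifferentialProfile:
    """Per-length normalized(treated) - normalized(control).

    A depletion of Alu siRNAs in the treated library gives negative deltas.
    """
    lengths = np.arange(lo, hi + 1)
    nt = np.array([normalized_alu_count(treated, int(n), lo, hi) for n in lengths])
    nc = np.array([normalized_alu_count(control, int(n), lo, hi) for n in lengths])
    t_alu = alu_sirna_count(treated, lo, hi)
    c_alu = alu_sirna_count(control, lo, hi)
    return DifferentialProfile(
        lengths=lengths,
        norm_treated=nt,
        norm_control=nc,
        delta=nt - nc,
        treated_alu=t_alu,
        treated_denominator=treated.total_input
        - treated.counts.get("miRNA", 0)
        - t_alu,
        control_alu=c_alu,
        control_denominator=control.total_input
        - control.counts.get("miRNA", 0)
        - c_alu,
    )


@dataclass
class StrandCoverage:
    """Per-position read coverage of a hairpin sequence, per strand."""

    name: str
    plus: np.ndarray
    minus: np.ndarray
    n_mapped: int
    n_unmapped: int

    def loop_coverage(self, hairpin: HairpinLocus) -> float:
        lo, hi = hairpin.loop
        return float(self.plus[lo:hi].sum() + self.minus[lo:hi].sum())

    def to_frame(self) -> pd.DataFrame:
        pos = np.arange(len(self.plus))
        return pd.DataFrame(
            {
                "hairpin": self.name,
                "pos": np.concatenate([pos, pos]),
                "strand": ["+"] * len(pos) + ["-"] * len(pos),
                "coverage": np.concatenate([self.plus, self.minus]),
            }
        )


def map_dicing_products(
    raw_reads: Iterable[SmallRead],
    hairpin: HairpinLocus,
    adaptor5: str = DICING_ADAPTOR_5P,
    adaptor3: str = DICING_ADAPTOR_3P,
    min_overlap: int = 6,
) -> StrandCoverage:
    """Map in vitro dicing-product reads onto their source hairpin.

    The 5' adaptor is removed as an exact prefix and the 3' adaptor by exact
    prefix-overlap trimming; inserts are then placed on both strands of the
    hairpin with zero mismatches and full coverage is accumulated over the
    hit interval.  Reads whose 3' adaptor is absent are mapped as-is (they
    may be pre-trimmed or full-length inserts without read-through); reads
    that do not place anywhere at zero mismatches are counted as unmapped.
    """
    idx = SequenceIndex(hairpin.full_seq)
    n = len(hairpin.full_seq)
    plus = np.zeros(n)
    minus = np.zeros(n)
    mapped = unmapped = 0
    a5 = adaptor5.upper().replace("U", "T")
    for read in raw_reads:
        seq = read.seq
        if seq.startswith(a5):
            seq = seq[len(a5):]
        if not seq:
            unmapped += read.mult
            continue
        trimmed = trim_adaptor(SmallRead(read.id, seq, read.mult), adaptor3, min_overlap)
        insert = trimmed.seq if trimmed is not None else seq
        hits = idx.hits(insert, max_mm=0)
        if not hits:
            unmapped += read.mult
            continue
        strand, start, _ = hits[0]
        (plus if strand == "+" else minus)[start : start + len(insert)] += read.mult
        mapped += read.mult
    return StrandCoverage(hairpin.name, plus, minus, mapped, unmapped)
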