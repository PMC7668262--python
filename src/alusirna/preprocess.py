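"""Read preprocessing: 3'-adaptor removal, exogenous-siRNA removal, length gate.

Small-RNA libraries are sequenced through the insert into the 3' sequencing
adaptor.  The insert is recovered by locating the leftmost exact match of an
adaptor prefix; trimmed inserts are then screened against the transfected
(exogenous) siRNA sequences and gated to 19-35 nt before annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

__all__ = [
    "SmallRead",
    "PreprocessReport",
    "ADAPTOR_3P_TOTAL",
    "ADAPTOR_3P_AGO2",
    "EXOGENOUS_SIRNAS",
    "trim_adaptor",
    "remove_exogenous",
    "length_filter",
    "preprocess_reads",
]

# 3' sequencing adaptors used for total and AGO2-immunoprecipitated libraries.
ADAPTOR_3P_TOTAL = "TGGAATTCTCGGGTGCCAAGGAACTCCAGTCAC"
ADAPTOR_3P_AGO2 = "TCTCGTATCGTATGCCGTCTTCTGCTTG"

# Transfected control / ADAR1 siRNA strands removed from knockdown libraries.
EXOGENOUS_SIRNAS = (
    "CGTACGCGGAATACTTCGAAG",
    "TCGAAGTATTCCGCGTACGAT",
    "CCGCCATCATTATGAAAAAAG",
    "TTTTTCATAATGATGGCGGAT",
)

_ALPHABET = frozenset("ACGTN")


def _clean(seq: str, what: str = "sequence") -> str:
    """Upper-fold, map U->T, and validate the ACGTN alphabet."""
    s = seq.upper().replace("U", "T")
    if not s:
        raise ValueError(f"empty {what}")
    bad = set(s) - _ALPHABET
    if bad:
        raise ValueError(f"invalid characters {sorted(bad)} in {what}")
    return s


@dataclass(frozen=True)
class SmallRead:
    """One small-RNA read: identifier, sequence, collapsed multiplicity."""

    id: str
    seq: str
    mult: int = 1

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"read {self.id!r}: empty sequence")
        if self.mult < 1:
            raise ValueError(f"read {self.id!r}: multiplicity must be >= 1")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class PreprocessReport:
    """Multiplicity-weighted partition of the input library.

    n_input == n_no_adaptor + n_exogenous_removed + n_length_fail + n_pass.
    """

    n_input: int = 0
    n_no_adaptor: int = 0
    n_exogenous_removed: int = 0
    n_length_fail: int = 0
    n_pass: int = 0

    def check(self) -> None:
        total = (
            self.n_no_adaptor
            + self.n_exogenous_removed
            + self.n_length_fail
            + self.n_pass
        )
        if total != self.n_input:
            raise AssertionError(
                f"preprocess report does not partition input: {self}"
            )


def trim_adaptor(
    read: SmallRead, adaptor: str, min_overlap: int = 6
) -> SmallRead | None:
    """Remove the 3' adaptor from a read by exact prefix matching.

    Finds the leftmost position ``p >= 1`` at which the remainder of the read
    matches a prefix of the adaptor exactly (the full adaptor when the read
    runs past it), with overlap >= ``min_overlap``, and returns the insert
    ``read.seq[:p]``.  Returns None when no such position exists; an empty
    insert (adaptor at position 0) also yields None.
    """
    adaptor = _clean(adaptor, "adaptor")
    if not (1 <= min_overlap <= len(adaptor)):
        raise ValueError("require adaptor length >= min_overlap >= 1")
    seq = read.seq
    n = len(seq)
    for p in range(1, n):
        overlap = min(len(adaptor), n - p)
        if overlap < min_overlap:
            break
        if seq[p : p + overlap] == adaptor[:overlap]:
            return replace(read, seq=seq[:p])
    return None


def remove_exogenous(
    reads: Iterable[SmallRead], blacklist: Sequence[str]
) -> tuple[list[SmallRead], int]:
    """Drop reads matching transfected siRNA sequences.

    A read is removed iff its sequence contains a blacklist entry as a
    substring or is itself contained within one (catching partially trimmed
    siRNA reads).  Returns the kept reads in input order and the
    multiplicity-weighted removed count.
    """
    black = [_clean(b, "blacklist entry") for b in blacklist]
    kept: list[SmallRead] = []
    removed = 0
    for read in reads:
        if any(b in read.seq or read.seq in b for b in black):
            removed += read.mult
        else:
            kept.append(read)
    return kept, removed


def length_filter(
    reads: Iterable[SmallRead], lo: int = 19, hi: int = 35
) -> tuple[list[SmallRead], PreprocessReport]:
    """Keep reads with lo <= length <= hi (both ends inclusive)."""
    if lo > hi:
        raise ValueError("require lo <= hi")
    report = PreprocessReport()
    kept: list[SmallRead] = []
    for read in reads:
        report.n_input += read.mult
        if lo <= len(read) <= hi:
            kept.append(read)
            report.n_pass += read.mult
        else:
            report.n_length_fail += read.mult
    report.check()
    return kept, report


def preprocess_reads(
    reads: Iterable[SmallRead],
    adaptor: str = ADAPTOR_3P_TOTAL,
    blacklist: Sequence[str] = (),
    lo: int = 19,
    hi: int = 35,
    min_overlap: int = 6,
    keep_untrimmed: bool = False,
) -> tuple[list[SmallRead], PreprocessReport]:
    """Full preprocessing stage: trim, remove exogenous siRNAs, length-gate.

    Reads with no detectable adaptor are discarded by default (their 3' end is
    unknown); ``keep_untrimmed`` retains them unmodified.  The returned report
    partitions the multiplicity-weighted input exactly, and read order is
    preserved through every stage.
    """
    report = PreprocessReport()
    trimmed: list[SmallRead] = []
    for read in reads:
        report.n_input += read.mult
        t = trim_adaptor(read, adaptor, min_overlap)
        if t is None:
            if keep_untrimmed:
                trimmed.append(read)
            else:
                report.n_no_adaptor += read.mult
        else:
            trimmed.append(t)
    kept, report.n_exogenous_removed = remove_exogenous(trimmed, blacklist)
    passed: list[SmallRead] = []
    for read in kept:
        if lo <= len(read) <= hi:
            passed.append(read)
            report.n_pass += read.mult
        else:
            report.n_length_fail += read.mult
    report.check()
    return passed, report
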