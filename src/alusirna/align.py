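"""Ungapped both-strand alignment and the ordered annotation cascade.

Reads are placed end-to-end on each reference (forward query for + hits,
reverse complement for - hits) allowing a bounded number of Hamming
mismatches; N never matches anything, including another N.  Each read is then
assigned to the first reference category, in the fixed order
rRNA > tRNA > miRNA > repeat > snoRNA > transcript > genome, in which it
aligns at all — the first-hit-wins cascade.

The aligner is exact: candidate placements are enumerated by a pigeonhole
seed lookup (for a hit with <= m mismatches, at least one of m+1 disjoint
6-mers of the query must match exactly) and every candidate is verified, so
the hit set equals a full scan over every offset and strand.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .io import CATEGORIES, NamedSequence, ReferenceSet
from .preprocess import SmallRead

__all__ = [
    "revcomp",
    "AlignmentHit",
    "CategoryAssignment",
    "AnnotationSummary",
    "SequenceIndex",
    "CascadeIndex",
    "align_ungapped",
    "assign_read",
    "run_cascade",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement on the DNA alphabet; N maps to N."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AlignmentHit:
    """Ungapped placement of a read on a reference.

    ``strand`` "-" means the read matches the reverse complement of the
    reference interval; ``start``/``end`` are always reference coordinates,
    0-based half-open, with end - start equal to the read length.
    """

    category: str | None
    ref_id: str
    start: int
    end: int
    strand: str
    mismatches: int


@dataclass
class CategoryAssignment:
    """The cascade's verdict for one read: its category and representative hit."""

    read_id: str
    category: str  # one of CATEGORIES or "unaligned"
    hit: AlignmentHit | None
    subfamily: str | None = None
    mult: int = 1

    def __post_init__(self) -> None:
        if (self.category == "unaligned") == (self.hit is not None):
            raise ValueError("hit must be present iff category != unaligned")


@dataclass
class AnnotationSummary:
    """Partition of a library over the seven categories plus 'unaligned'."""

    counts: dict[str, int]
    assignments: list[CategoryAssignment]
    total_input: int

    def check(self) -> None:
        if sum(self.counts.values()) != self.total_input:
            raise AssertionError("category counts do not partition the input")


_STRAND_RANK = {"+": 0, "-": 1}


class SequenceIndex:
    """Exact seed index over one reference sequence for bounded-Hamming search."""

    SEED = 6

    def __init__(self, seq: str):
        self.seq = seq
        self._arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        self._n_code = np.uint8(ord("N"))
        index: dict[str, list[int]] = defaultdict(list)
        for pos in range(len(seq) - self.SEED + 1):
            kmer = seq[pos : pos + self.SEED]
            if "N" not in kmer:
                index[kmer].append(pos)
        self._index = dict(index)

    def _mismatches(self, qarr: np.ndarray, start: int) -> int:
        win = self._arr[start : start + len(qarr)]
        bad = (win != qarr) | (win == self._n_code) | (qarr == self._n_code)
        return int(bad.sum())

    def hits(self, query: str, max_mm: int) -> list[tuple[str, int, int]]:
        """All placements with <= max_mm mismatches as (strand, start, mm),
        sorted by (mm, start, + before -)."""
        if max_mm < 0:
            raise ValueError("max_mm must be >= 0")
        qlen, rlen = len(query), len(self.seq)
        if qlen == 0 or qlen > rlen:
            return []
        out: list[tuple[str, int, int]] = []
        for strand, q in (("+", query), ("-", revcomp(query))):
            qarr = np.frombuffer(q.encode(), dtype=np.uint8)
            if qlen >= self.SEED * (max_mm + 1):
                starts: set[int] = set()
                for i in range(max_mm + 1):
                    off = i * self.SEED
                    for pos in self._index.get(q[off : off + self.SEED], ()):
                        s = pos - off
                        if 0 <= s <= rlen - qlen:
                            starts.add(s)
                candidates: Iterable[int] = sorted(starts)
            else:
                # Query too short for seeding: check every offset directly.
                candidates = range(rlen - qlen + 1)
            for s in candidates:
                mm = self._mismatches(qarr, s)
                if mm <= max_mm:
                    out.append((strand, s, mm))
        out.sort(key=lambda h: (h[2], h[1], _STRAND_RANK[h[0]]))
        return out


def align_ungapped(
    query: str, ref: NamedSequence, max_mm: int, category: str | None = None
) -> list[AlignmentHit]:
    """All end-to-end placements of ``query`` on both strands of ``ref``.

    Hits are sorted by (mismatches, start, + before -).  A query longer than
    the reference yields an empty list.
    """
    idx = SequenceIndex(ref.seq)
    return [
        AlignmentHit(category, ref.id, s, s + len(query), strand, mm)
        for strand, s, mm in idx.hits(query, max_mm)
    ]


class CascadeIndex:
    """Prebuilt seed indexes for an ordered list of reference sets.

    Building once and reusing across libraries keeps repeated cascade runs
    (e.g. paired knockdown/control) cheap.
    """

    def __init__(self, refs: Sequence[ReferenceSet]):
        self.refs = list(refs)
        self._indexes = [
            [SequenceIndex(seq.seq) for seq in rs.sequences] for rs in refs
        ]

    def best_hit(self, query: str, max_mm: int, step: int) -> AlignmentHit | None:
        """Deterministic representative hit of ``query`` in reference set
        ``step``: fewest mismatches, then lowest start, then + before -, then
        reference input order."""
        refset = self.refs[step]
        best: tuple[int, int, int, int] | None = None
        best_hit: AlignmentHit | None = None
        for ref_order, (seq, idx) in enumerate(
            zip(refset.sequences, self._indexes[step])
        ):
            hits = idx.hits(query, max_mm)
            if not hits:
                continue
            strand, s, mm = hits[0]
            key = (mm, s, _STRAND_RANK[strand], ref_order)
            if best is None or key < best:
                best = key
                best_hit = AlignmentHit(
                    refset.category, seq.id, s, s + len(query), strand, mm
                )
        return best_hit

    def assign(self, query: str, max_mm: int) -> tuple[str, AlignmentHit | None, str | None]:
        """First-hit-wins category for a query sequence."""
        for step, refset in enumerate(self.refs):
            hit = self.best_hit(query, max_mm, step)
            if hit is not None:
                subfamily = None
                if refset.subfamily_of is not None:
                    subfamily = refset.subfamily_of.get(hit.ref_id)
                return refset.category, hit, subfamily
        return "unaligned", None, None


def _check_order(refs: Sequence[ReferenceSet]) -> None:
    cats = tuple(rs.category for rs in refs)
    if len(set(cats)) != len(cats):
        raise ValueError("duplicate categories in reference list")


def assign_read(
    read: SmallRead,
    refs: Sequence[ReferenceSet],
    max_mm: int = 2,
    index: CascadeIndex | None = None,
) -> CategoryAssignment:
    """Assign one read to the first reference set, in order, that it aligns to.

    The default ordering is the seven-step cascade of ``CATEGORIES``; any
    ordered subset is accepted.
    """
    _check_order(refs)
    if index is None:
        index = CascadeIndex(refs)
    category, hit, subfamily = index.assign(read.seq, max_mm)
    return CategoryAssignment(read.id, category, hit, subfamily, read.mult)


def run_cascade(
    reads: Iterable[SmallRead],
    refs: Sequence[ReferenceSet],
    max_mm: int = 2,
    index: CascadeIndex | None = None,
) -> AnnotationSummary:
    """Annotate a whole library; counts are multiplicity-weighted.

    Identical sequences share one alignment (results are independent of
    whether the library was collapsed).  The returned summary partitions the
    input exactly: category counts plus 'unaligned' sum to the total.
    """
    _check_order(refs)
    if index is None:
        index = CascadeIndex(refs)
    counts = {c: 0 for c in [rs.category for rs in refs]}
    counts["unaligned"] = 0
    cache: dict[str, tuple[str, AlignmentHit | None, str | None]] = {}
    assignments: list[CategoryAssignment] = []
    total = 0
    for read in reads:
        total += read.mult
        res = cache.get(read.seq)
        if res is None:
            res = index.assign(read.seq, max_mm)
            cache[read.seq] = res
        category, hit, subfamily = res
        counts[category] = counts.get(category, 0) + read.mult
        assignments.append(
            CategoryAssignment(read.id, category, hit, subfamily, read.mult)
        )
    summary = AnnotationSummary(counts=counts, assignments=assignments, total_input=total)
    summary.check()
    return summary
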