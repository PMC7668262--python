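"""In-silico RNAi target screen on 3'UTR Alu elements.

Genes are classified by the number and orientation of Alu repeats inside
their 3'UTR (sense/antisense relative to the mRNA, not the genome), reduced
to single-copy candidates above an expression cut, and scanned for
seed-complementary siRNA binding sites.  A site is the exact reverse
complement of the siRNA seed (nucleotides 2-8 from the 5' end) in the
mRNA-sense 3'UTR; one seed mismatch can optionally be tolerated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .align import revcomp
from .io import GeneModel, RepeatAnnotation
from .preprocess import _clean

__all__ = [
    "UtrAluStatus",
    "SiRNA",
    "TargetSite",
    "classify_utr_alus",
    "screen_single_alu_genes",
    "predict_target_sites",
]

SEED_START, SEED_END = 1, 8  # 0-based half-open: positions 2-8, 5'->3'


@dataclass
class UtrAluStatus:
    """Per-gene 3'UTR Alu census: sense and antisense copy counts."""

    gene_id: str
    n_sense: int
    n_antisense: int
    expression: float


@dataclass(frozen=True)
class SiRNA:
    """A 19-24 nt siRNA guide strand (5'->3'); seed = nucleotides 2-8."""

    name: str
    seq: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", _clean(self.seq, f"siRNA {self.name}"))
        if not 19 <= len(self.seq) <= 24:
            raise ValueError(f"siRNA {self.name}: length must be 19-24 nt")

    @property
    def seed(self) -> str:
        return self.seq[SEED_START:SEED_END]


@dataclass(frozen=True)
class TargetSite:
    """A seed-complementary site in a 3'UTR (mRNA-sense coordinates)."""

    gene_id: str
    start: int
    end: int
    match_class: str  # perfect_seed | seed_with_mismatch
    matched_sirna: str


def classify_utr_alus(
    genes: Sequence[GeneModel],
    repeats: Sequence[RepeatAnnotation],
    min_overlap_frac: float = 1.0,
) -> list[UtrAluStatus]:
    """Count 3'UTR Alu copies per gene, split by orientation.

    A repeat is counted iff its family is Alu and its overlap with the 3'UTR
    interval is at least ``min_overlap_frac`` of the repeat length (default:
    fully contained) and nonzero.  A repeat on the same genomic strand as the
    gene is sense to the mRNA; opposite strand is antisense.
    """
    if not 0.0 <= min_overlap_frac <= 1.0:
        raise ValueError("min_overlap_frac must be in [0, 1]")
    out: list[UtrAluStatus] = []
    alus = [r for r in repeats if r.family == "Alu"]
    for gene in genes:
        n_sense = n_anti = 0
        for rep in alus:
            if rep.chrom != gene.chrom:
                continue
            overlap = min(rep.end, gene.utr3_end) - max(rep.start, gene.utr3_start)
            if overlap <= 0 or overlap < min_overlap_frac * (rep.end - rep.start):
                continue
            if rep.strand == gene.strand:
                n_sense += 1
            else:
                n_anti += 1
        out.append(UtrAluStatus(gene.gene_id, n_sense, n_anti, gene.expression))
    return out


def screen_single_alu_genes(
    statuses: Iterable[UtrAluStatus],
    orientation: str,
    expr_threshold: float = 4.5,
) -> list[str]:
    """Genes with exactly one 3'UTR Alu in the requested orientation.

    The other orientation's count must be zero (a sense+antisense pair forms
    a potential inverted repeat and is excluded from both screens), and the
    log10 expression must exceed the threshold strictly.  Returns gene ids
    sorted lexicographically.
    """
    if orientation not in {"sense", "antisense"}:
        raise ValueError(f"orientation must be sense/antisense, got {orientation!r}")
    picked = []
    for st in statuses:
        if orientation == "antisense":
            single = st.n_antisense == 1 and st.n_sense == 0
        else:
            single = st.n_sense == 1 and st.n_antisense == 0
        if single and st.expression > expr_threshold:
            picked.append(st.gene_id)
    return sorted(picked)


def _hamming(a: str, b: str) -> int:
    # N matches nothing, including another N.
    return sum(1 for x, y in zip(a, b) if x != y or x == "N" or y == "N")


def predict_target_sites(
    sirna: SiRNA,
    utr3_seq: str,
    gene_id: str = "",
    allow_seed_mm: int = 0,
) -> list[TargetSite]:
    """All seed-complementary sites of an siRNA in an mRNA-sense 3'UTR.

    Every exact occurrence of the reverse-complemented seed is a
    ``perfect_seed`` site; with ``allow_seed_mm=1``, windows at Hamming
    distance 1 are reported as ``seed_with_mismatch``.  Overlapping sites are
    all reported, sorted by start.  A UTR shorter than the 7 nt seed yields
    an empty list.
    """
    if allow_seed_mm not in (0, 1):
        raise ValueError("allow_seed_mm must be 0 or 1")
    utr = _clean(utr3_seq, "3'UTR") if utr3_seq else ""
    target = revcomp(sirna.seed)
    k = len(target)
    if len(utr) < k:
        return []
    sites: list[TargetSite] = []
    if allow_seed_mm == 0:
        pos = utr.find(target)
        while pos != -1:
            sites.append(TargetSite(gene_id, pos, pos + k, "perfect_seed", sirna.name))
            pos = utr.find(target, pos + 1)
    else:
        for s in range(len(utr) - k + 1):
            mm = _hamming(utr[s : s + k], target)
            if mm == 0:
                sites.append(TargetSite(gene_id, s, s + k, "perfect_seed", sirna.name))
            elif mm == 1:
                sites.append(
                    TargetSite(gene_id, s, s + k, "seed_with_mismatch", sirna.name)
                )
    return sites
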