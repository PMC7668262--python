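"""Readers and writers for the external formats the pipeline touches.

All nucleotide input is folded to the DNA alphabet (U->T, upper case) at the
boundary so one alphabet is used internally.  All genomic intervals are
0-based half-open; human-readable region strings are 1-based inclusive
(genome-browser style).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

from .preprocess import SmallRead, _clean

__all__ = [
    "CATEGORIES",
    "NamedSequence",
    "ReferenceSet",
    "RepeatAnnotation",
    "GeneModel",
    "HairpinLocus",
    "read_fasta",
    "read_small_reads",
    "write_fasta",
    "write_fastq",
    "read_repeat_annotations",
    "read_gene_models",
    "write_tables",
    "format_region",
    "parse_region",
]

#: Annotation cascade categories, in assignment order.
CATEGORIES = ("rRNA", "tRNA", "miRNA", "repeat", "snoRNA", "transcript", "genome")

_STRANDS = {"+", "-"}


def _fold_strand(s: str) -> str:
    # Unicode minus signs occur in copy-pasted annotation tables.
    return {"−": "-", "–": "-"}.get(s, s)


@dataclass(frozen=True)
class NamedSequence:
    """A named nucleotide sequence over {A,C,G,T,N}."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        object.__setattr__(self, "seq", _clean(self.seq, f"sequence {self.id!r}"))

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class ReferenceSet:
    """One cascade step's reference collection.

    ``subfamily_of`` maps reference ids to repeat subfamily names (e.g.
    "AluJb") and is meaningful for the ``repeat`` category only.
    """

    category: str
    sequences: list[NamedSequence]
    subfamily_of: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        ids = [s.id for s in self.sequences]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate sequence ids in {self.category} set")
        if self.subfamily_of is not None:
            unknown = set(self.subfamily_of) - set(ids)
            if unknown:
                raise ValueError(f"subfamily_of keys not in set: {sorted(unknown)}")


@dataclass(frozen=True)
class RepeatAnnotation:
    """A repeat instance (rmsk-style): subfamily, genomic interval, strand."""

    chrom: str
    start: int
    end: int
    strand: str
    subfamily: str
    family: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"bad repeat interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"unknown strand {self.strand!r}")


@dataclass(frozen=True)
class GeneModel:
    """Gene with a single-interval 3'UTR and a log10 expression score.

    ``utr3_seq``, when present, is the 3'UTR in mRNA-sense orientation and
    must match the interval length.
    """

    gene_id: str
    chrom: str
    strand: str
    utr3_start: int
    utr3_end: int
    expression: float
    utr3_seq: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in _STRANDS:
            raise ValueError(f"gene {self.gene_id}: unknown strand {self.strand!r}")
        if not self.utr3_start < self.utr3_end:
            raise ValueError(f"gene {self.gene_id}: bad 3'UTR interval")
        if self.utr3_seq is not None:
            object.__setattr__(
                self, "utr3_seq", _clean(self.utr3_seq, f"3'UTR of {self.gene_id}")
            )
            if len(self.utr3_seq) != self.utr3_end - self.utr3_start:
                raise ValueError(
                    f"gene {self.gene_id}: 3'UTR sequence length does not "
                    "match interval"
                )


@dataclass(frozen=True)
class HairpinLocus:
    """An inverted-repeat hairpin: left arm, loop, right arm on one sequence.

    The three intervals are contiguous, non-overlapping and cover
    ``full_seq``; arms are the base-pairing stems, the loop connects them.
    """

    name: str
    left_arm: tuple[int, int]
    loop: tuple[int, int]
    right_arm: tuple[int, int]
    full_seq: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "full_seq", _clean(self.full_seq, self.name))
        la, lo, ra = self.left_arm, self.loop, self.right_arm
        ok = (
            la[0] == 0
            and la[0] < la[1] == lo[0] < lo[1] == ra[0] < ra[1] == len(self.full_seq)
        )
        if not ok:
            raise ValueError(
                f"hairpin {self.name}: arms/loop must be contiguous, ordered, "
                "and cover the full sequence"
            )

    @property
    def arms(self) -> tuple[tuple[int, int], tuple[int, int]]:
        return (self.left_arm, self.right_arm)


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_fasta(path: str | Path) -> list[NamedSequence]:
    """Read a FASTA file into NamedSequences (order preserved, U->T, upper).

    Rejects duplicate ids and empty records, naming the offending record.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out: list[NamedSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        if len(rec.seq) == 0:
            raise ValueError(f"{path}: empty record {rec.id!r}")
        out.append(NamedSequence(rec.id, str(rec.seq)))
    return out


def read_small_reads(path: str | Path, fmt: str | None = None) -> list[SmallRead]:
    """Read sequencing reads (FASTA or FASTQ; qualities ignored) as SmallReads.

    ``fmt`` is inferred from the extension when not given.  Read ids of the
    form ``name_xN`` set the multiplicity to N (collapsed-read convention).
    """
    path = Path(path)
    if fmt is None:
        fmt = "fastq" if path.suffix.lower() in {".fastq", ".fq"} else "fasta"
    reads: list[SmallRead] = []
    for rec in SeqIO.parse(str(path), fmt):
        m = re.search(r"_x(\d+)$", rec.id)
        mult = int(m.group(1)) if m else 1
        reads.append(SmallRead(rec.id, _clean(str(rec.seq), rec.id), mult))
    return reads


def write_fasta(sequences: Iterable[NamedSequence | SmallRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sequences:
            fh.write(f">{s.id}\n{s.seq}\n")


def write_fastq(reads: Iterable[SmallRead], path: str | Path) -> None:
    """Write reads as FASTQ with uniform placeholder qualities."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.seq}\n+\n{'I' * len(r.seq)}\n")


# ---------------------------------------------------------------------------
# Annotation tables

_KNOWN_FAMILY_PREFIXES = ("Alu", "MIR", "L1", "L2", "SVA", "FLAM", "FRAM")


def _derive_family(subfamily: str) -> str:
    for prefix in _KNOWN_FAMILY_PREFIXES:
        if subfamily.startswith(prefix):
            return prefix
    return subfamily


def read_repeat_annotations(
    path: str | Path, dialect: str = "bed6"
) -> list[RepeatAnnotation]:
    """Read repeat instances from a BED6 or rmsk-style TSV file.

    Both dialects are 0-based half-open.  BED6 columns: chrom, start, end,
    name (subfamily), score, strand.  The rmsk dialect requires a header and
    consumes only genoName, genoStart, genoEnd, strand, repName and, when
    present, repFamily; the family is otherwise derived from the subfamily
    prefix (AluJb -> Alu).
    """
    path = Path(path)
    if dialect == "bed6":
        df = pd.read_csv(
            path,
            sep=r"\s+",
            header=None,
            names=["chrom", "start", "end", "name", "score", "strand"],
            dtype={"chrom": str, "name": str, "strand": str},
        )
        rows = [
            (r.chrom, int(r.start), int(r.end), r.strand, r.name, None)
            for r in df.itertuples()
        ]
    elif dialect == "rmsk_tsv":
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"genoName", "genoStart", "genoEnd", "strand", "repName"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"{path}: rmsk table missing columns {sorted(missing)}")
        has_family = "repFamily" in df.columns
        rows = [
            (
                r.genoName,
                int(r.genoStart),
                int(r.genoEnd),
                r.strand,
                r.repName,
                r.repFamily if has_family else None,
            )
            for r in df.itertuples()
        ]
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    out = []
    for chrom, start, end, strand, sub, fam in rows:
        out.append(
            RepeatAnnotation(
                chrom=chrom,
                start=start,
                end=end,
                strand=_fold_strand(strand),
                subfamily=sub,
                family=fam if fam else _derive_family(sub),
            )
        )
    return out


_GENE_COLUMNS = ("gene_id", "chrom", "strand", "utr3_start", "utr3_end", "expression")


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models from a TSV with header
    gene_id, chrom, strand, utr3_start, utr3_end, expression[, utr3_seq].
    """
    df = pd.read_csv(Path(path), sep="\t", dtype=str)
    missing = set(_GENE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: gene table missing columns {sorted(missing)}")
    has_seq = "utr3_seq" in df.columns
    out: list[GeneModel] = []
    seen: set[str] = set()
    for r in df.itertuples():
        if r.gene_id in seen:
            raise ValueError(f"{path}: duplicate gene_id {r.gene_id!r}")
        seen.add(r.gene_id)
        try:
            start, end = int(r.utr3_start), int(r.utr3_end)
            expr = float(r.expression)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: malformed numeric field for {r.gene_id}") from exc
        seq = getattr(r, "utr3_seq", None) if has_seq else None
        if isinstance(seq, float) or seq == "":  # pandas NaN for absent cells
            seq = None
        out.append(
            GeneModel(
                gene_id=r.gene_id,
                chrom=r.chrom,
                strand=_fold_strand(r.strand),
                utr3_start=start,
                utr3_end=end,
                expression=expr,
                utr3_seq=seq,
            )
        )
    return out


def write_tables(results: Mapping[str, pd.DataFrame], out_dir: str | Path) -> list[Path]:
    """Write each result DataFrame as ``<name>.tsv`` under ``out_dir``.

    Output is deterministic: byte-identical across runs on identical inputs.
    Returns the written paths in name order.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name in sorted(results):
        p = out_dir / f"{name}.tsv"
        results[name].to_csv(p, sep="\t", index=False, lineterminator="\n")
        paths.append(p)
    return paths


# ---------------------------------------------------------------------------
# Coordinate display

_REGION_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)[-–‐](?P<end>\d+)$")


def format_region(chrom: str, start: int, end: int) -> str:
    """0-based half-open interval -> 1-based inclusive browser string."""
    if not 0 <= start < end:
        raise ValueError(f"bad interval {chrom}:{start}-{end}")
    return f"{chrom}:{start + 1}-{end}"


def parse_region(text: str) -> tuple[str, int, int]:
    """1-based inclusive browser string -> (chrom, start, end) half-open."""
    m = _REGION_RE.match(text.strip())
    if not m:
        raise ValueError(f"cannot parse region {text!r}")
    start1, end1 = int(m.group("start")), int(m.group("end"))
    if not 1 <= start1 <= end1:
        raise ValueError(f"bad region coordinates in {text!r}")
    return m.group("chrom"), start1 - 1, end1
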