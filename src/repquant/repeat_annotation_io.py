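"""Domain types for genomes and repeat annotations, plus format I/O.

Internal coordinates are 0-based half-open everywhere; conversion to and
from the 1-based inclusive RepeatMasker convention happens only at the
format boundary.  Strand is stored but ignored by the counting layer (the
library preparation is assumed non-strand-specific).

Supported formats: RepeatMasker ``.out`` (read), BED6 (read/write),
FASTA (read/write) and FASTQ Phred+33 (read/write).
"""

from __future__ import annotations

import io
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

__all__ = [
    "GenomeSequence",
    "RepeatInstance",
    "RepeatCatalog",
    "SequenceRead",
    "read_repeatmasker_out",
    "read_bed",
    "write_bed",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
]

_DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeSequence:
    """A named contig with an upper-case DNA sequence over {A,C,G,T,N}."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"contig {self.name!r}: empty sequence")
        bad = set(self.sequence) - _DNA_ALPHABET
        if bad:
            raise ValueError(
                f"contig {self.name!r}: non-ACGTN symbols {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class RepeatInstance:
    """One annotated genomic copy of a repeat subfamily.

    ``start``/``end`` are 0-based half-open on ``contig``.  ``subfamily``
    is the unit of quantification; each subfamily belongs to exactly one
    (family, class) pair.
    """

    contig: str
    start: int
    end: int
    strand: str
    subfamily: str
    family: str
    repeat_class: str
    instance_id: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"instance {self.instance_id}: bad interval "
                f"[{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"instance {self.instance_id}: strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, contig: str, start: int, end: int) -> int:
        """Overlap in bp with the half-open interval [start, end)."""
        if contig != self.contig:
            return 0
        return max(0, min(self.end, end) - max(self.start, start))


class RepeatCatalog:
    """Ordered collection of :class:`RepeatInstance` with two indexes.

    Instances are indexed by subfamily (lists sorted by contig, start) and
    by interval per contig for overlap queries.  Instance ids must be
    unique; the subfamily → (family, class) mapping must be consistent.
    """

    def __init__(self, instances: Iterable[RepeatInstance]):
        self.instances: list[RepeatInstance] = list(instances)
        ids = [inst.instance_id for inst in self.instances]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate instance ids in catalog")
        self._by_subfamily: dict[str, list[RepeatInstance]] = {}
        lineage: dict[str, tuple[str, str]] = {}
        for inst in self.instances:
            key = (inst.family, inst.repeat_class)
            prev = lineage.setdefault(inst.subfamily, key)
            if prev != key:
                raise ValueError(
                    f"subfamily {inst.subfamily!r} maps to both {prev} and {key}"
                )
            self._by_subfamily.setdefault(inst.subfamily, []).append(inst)
        for insts in self._by_subfamily.values():
            insts.sort(key=lambda i: (i.contig, i.start))
        # Interval index: per contig, instances sorted by start with a
        # running maximum of end positions so queries can stop early.
        self._by_contig: dict[str, list[RepeatInstance]] = {}
        for inst in self.instances:
            self._by_contig.setdefault(inst.contig, []).append(inst)
        self._starts: dict[str, list[int]] = {}
        self._max_end: dict[str, list[int]] = {}
        for contig, insts in self._by_contig.items():
            insts.sort(key=lambda i: i.start)
            self._starts[contig] = [i.start for i in insts]
            running = []
            top = 0
            for i in insts:
                top = max(top, i.end)
                running.append(top)
            self._max_end[contig] = running

    def __len__(self) -> int:
        return len(self.instances)

    def __iter__(self) -> Iterator[RepeatInstance]:
        return iter(self.instances)

    @property
    def subfamilies(self) -> list[str]:
        return sorted(self._by_subfamily)

    def instances_of(self, subfamily: str) -> list[RepeatInstance]:
        return list(self._by_subfamily[subfamily])

    def lineage(self, subfamily: str) -> tuple[str, str]:
        """Return (family, class) for a subfamily."""
        inst = self._by_subfamily[subfamily][0]
        return inst.family, inst.repeat_class

    def overlapping(self, contig: str, start: int, end: int) -> list[RepeatInstance]:
        """All instances overlapping [start, end) on contig by ≥1 bp."""
        insts = self._by_contig.get(contig)
        if not insts:
            return []
        starts = self._starts[contig]
        hi = bisect_right(starts, end - 1)  # instances starting before `end`
        out = []
        max_end = self._max_end[contig]
        for i in range(hi - 1, -1, -1):
            if max_end[i] <= start:
                break
            if insts[i].end > start:
                out.append(insts[i])
        out.reverse()
        return out


@dataclass(frozen=True)
class SequenceRead:
    """A FASTQ record: id, sequence, Phred+33 quality string."""

    name: str
    sequence: str
    quality: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise ValueError(
                f"read {self.name!r}: sequence length {len(self.sequence)} "
                f"!= quality length {len(self.quality)}"
            )


# ---------------------------------------------------------------------------
# RepeatMasker .out
# ---------------------------------------------------------------------------

def read_repeatmasker_out(path: str | Path) -> RepeatCatalog:
    """Parse a RepeatMasker ``.out`` file into a :class:`RepeatCatalog`.

    The dialect: three header lines, whitespace-delimited columns, query
    coordinates 1-based inclusive (columns 6-7), strand column "+" or "C"
    (column 9), repeat name (column 10) and "class/family" (column 11).
    Coordinates are converted to 0-based half-open and "C" becomes "-".
    """
    instances: list[RepeatInstance] = []
    next_id = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if lineno <= 3 or not line.strip():
                continue
            fields = line.split()
            if len(fields) < 11:
                raise ValueError(
                    f"{path}: line {lineno}: expected ≥11 columns, got {len(fields)}"
                )
            try:
                contig = fields[4]
                start1 = int(fields[5])
                end1 = int(fields[6])
                strand_raw = fields[8]
                name = fields[9]
                cls_fam = fields[10]
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
            start, end = start1 - 1, end1
            if end <= start:
                raise ValueError(
                    f"{path}: line {lineno}: empty interval after conversion "
                    f"({start1}..{end1})"
                )
            if strand_raw == "+":
                strand = "+"
            elif strand_raw == "C":
                strand = "-"
            else:
                raise ValueError(
                    f"{path}: line {lineno}: strand column {strand_raw!r}"
                )
            if "/" in cls_fam:
                repeat_class, family = cls_fam.split("/", 1)
            else:
                repeat_class = family = cls_fam
            instances.append(
                RepeatInstance(
                    contig=contig,
                    start=start,
                    end=end,
                    strand=strand,
                    subfamily=name,
                    family=family,
                    repeat_class=repeat_class,
                    instance_id=next_id,
                )
            )
            next_id += 1
    return RepeatCatalog(instances)


def write_repeatmasker_out(catalog: RepeatCatalog, path: str | Path) -> None:
    """Write a minimal RepeatMasker-dialect ``.out`` file (inverse of read)."""
    with open(path, "w") as fh:
        fh.write(
            "   SW  perc perc perc  query     position in query    matching"
            "  repeat       position in repeat\n"
        )
        fh.write(
            "score  div. del. ins.  sequence  begin  end   (left)   repeat"
            "  class/family begin end (left)\n"
        )
        fh.write("\n")
        for inst in catalog:
            strand = "+" if inst.strand == "+" else "C"
            if inst.family == inst.repeat_class:
                cls_fam = inst.repeat_class
            else:
                cls_fam = f"{inst.repeat_class}/{inst.family}"
            fh.write(
                f"  225  10.0  0.0  0.0  {inst.contig}  {inst.start + 1}  "
                f"{inst.end}  (0)  {strand}  {inst.subfamily}  {cls_fam}  "
                f"1  {len(inst)}  (0)  {inst.instance_id}\n"
            )


# ---------------------------------------------------------------------------
# BED6
# ---------------------------------------------------------------------------

def _bed_name(inst: RepeatInstance) -> str:
    return f"{inst.subfamily}#{inst.repeat_class}/{inst.family}"


def write_bed(catalog: RepeatCatalog, path: str | Path) -> None:
    """Write BED6 with names encoded as ``subfamily#class/family``."""
    with open(path, "w") as fh:
        for inst in catalog:
            fh.write(
                f"{inst.contig}\t{inst.start}\t{inst.end}\t{_bed_name(inst)}\t"
                f"{inst.instance_id}\t{inst.strand}\n"
            )


def read_bed(path: str | Path) -> RepeatCatalog:
    """Read BED6 (already 0-based half-open) into a catalog.

    The name column is either ``subfamily`` or ``subfamily#class/family``;
    the score column carries the instance id when integral.
    """
    instances: list[RepeatInstance] = []
    fallback_id = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                raise ValueError(
                    f"{path}: line {lineno}: BED6 requires ≥6 columns, "
                    f"got {len(fields)}"
                )
            contig, start_s, end_s, name, score, strand = fields[:6]
            if "#" in name:
                subfamily, cls_fam = name.split("#", 1)
                if "/" in cls_fam:
                    repeat_class, family = cls_fam.split("/", 1)
                else:
                    repeat_class = family = cls_fam
            else:
                subfamily = name
                repeat_class = family = name
            try:
                instance_id = int(score)
            except ValueError:
                instance_id = fallback_id
            instances.append(
                RepeatInstance(
                    contig=contig,
                    start=int(start_s),
                    end=int(end_s),
                    strand=strand,
                    subfamily=subfamily,
                    family=family,
                    repeat_class=repeat_class,
                    instance_id=instance_id,
                )
            )
            fallback_id += 1
    return RepeatCatalog(instances)


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read a FASTA file; sequences are upper-cased."""
    records: list[GenomeSequence] = []
    name: str | None = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    records.append(GenomeSequence(name, "".join(chunks).upper()))
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        records.append(GenomeSequence(name, "".join(chunks).upper()))
    return records


def write_fasta(
    records: Iterable[GenomeSequence], path: str | Path, width: int = 70
) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.name}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_fastq(path: str | Path) -> list[SequenceRead]:
    """Read FASTQ (Phred+33); sequences are upper-cased."""
    reads: list[SequenceRead] = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            if not header.startswith("@"):
                raise ValueError(f"{path}: malformed FASTQ header {header!r}")
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not plus.startswith("+"):
                raise ValueError(f"{path}: malformed FASTQ separator for {header!r}")
            reads.append(
                SequenceRead(header[1:].rstrip("\n").split()[0], seq.upper(), qual)
            )
    return reads


def write_fastq(reads: Iterable[SequenceRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.name}\n{r.sequence}\n+\n{r.quality}\n")
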