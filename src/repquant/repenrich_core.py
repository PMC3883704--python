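"""Two-pass repeat-subfamily counting.

Pass 1: uniquely mapping reads are counted against the repeat catalog by
interval overlap (≥1 bp; ties resolved by larger overlap, then
lexicographic subfamily name).  Pass 2: multi-mapping reads are aligned
against per-subfamily pseudo-genomes (all genomic instances of the
subfamily concatenated with N spacers) and assigned 1/k to each of the k
distinct subfamilies hit.  The two passes are summed per subfamily;
rounding to integers (half-up) happens once, at the matrix stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .alignment import (
    DEFAULT_MAX_MISMATCHES,
    ReadAssignmentClass,
    ReferenceIndex,
    align_all,
)
from .repeat_annotation_io import GenomeSequence, RepeatCatalog

__all__ = [
    "PseudoGenome",
    "FractionalAssignment",
    "SubfamilyCountMatrix",
    "SampleAccounting",
    "build_pseudogenomes",
    "count_unique_overlaps",
    "assign_multimap",
    "aggregate_counts",
    "quantify_sample",
]


@dataclass
class PseudoGenome:
    """Concatenation of all genomic instances of one subfamily.

    ``offsets`` maps instance id → (start offset in the concatenated
    sequence, instance length), so every instance is recoverable.
    """

    subfamily: str
    sequence: str
    offsets: dict[int, tuple[int, int]]


@dataclass
class FractionalAssignment:
    """A multi-mapping read spread over the distinct subfamilies it hit."""

    read_id: str
    subfamilies: frozenset[str]

    @property
    def weight(self) -> float:
        return 1.0 / len(self.subfamilies)


@dataclass
class SampleAccounting:
    """Per-sample read ledger; the conservation identity must hold:
    unique_overlap + unique_non_overlap + multi_assigned + multi_unassigned
    + unmapped = total_reads."""

    sample: str
    total_reads: int
    unique_overlap: int
    unique_non_overlap: int
    multi_assigned: int
    multi_unassigned: int
    unmapped: int
    library_size: int

    def check(self) -> None:
        total = (
            self.unique_overlap
            + self.unique_non_overlap
            + self.multi_assigned
            + self.multi_unassigned
            + self.unmapped
        )
        if total != self.total_reads:
            raise ValueError(
                f"sample {self.sample}: read-accounting ledger violated "
                f"({total} != {self.total_reads})"
            )

    def to_dict(self) -> dict:
        return dict(self.__dict__)


class SubfamilyCountMatrix:
    """Subfamily × sample count table with per-sample library sizes.

    ``stage`` is "fractional" (exact, pre-rounding) or "rounded"
    (half-up integers).  Rows cover the catalog's full subfamily set,
    zero-filled.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        library_sizes: Mapping[str, int],
        stage: str,
        lineage: Mapping[str, tuple[str, str]] | None = None,
    ):
        if stage not in ("fractional", "rounded"):
            raise ValueError(f"unknown stage {stage!r}")
        if (counts.values < 0).any():
            raise ValueError("negative counts")
        missing = set(counts.columns) - set(library_sizes)
        if missing:
            raise ValueError(f"samples without library size: {sorted(missing)}")
        self.counts = counts
        self.library_sizes = {s: int(library_sizes[s]) for s in counts.columns}
        self.stage = stage
        self.lineage = dict(lineage or {})

    @property
    def subfamilies(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def rounded(self) -> "SubfamilyCountMatrix":
        """Round half-up to integers (the single rounding step)."""
        if self.stage == "rounded":
            return self
        rounded = np.floor(self.counts.values + 0.5).astype(np.int64)
        return SubfamilyCountMatrix(
            pd.DataFrame(rounded, index=self.counts.index, columns=self.counts.columns),
            self.library_sizes,
            "rounded",
            self.lineage,
        )

    def to_tsv(self, path: str | Path, header_lines: Sequence[str] = ()) -> None:
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            for sample in self.samples:
                fh.write(f"# library_size\t{sample}\t{self.library_sizes[sample]}\n")
            cols = "\t".join(self.samples)
            fh.write(f"subfamily\tfamily\tclass\t{cols}\n")
            for subfam in self.subfamilies:
                family, cls = self.lineage.get(subfam, (subfam, subfam))
                vals = "\t".join(
                    repr(v) if self.stage == "fractional" else str(int(v))
                    for v in self.counts.loc[subfam]
                )
                fh.write(f"{subfam}\t{family}\t{cls}\t{vals}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SubfamilyCountMatrix":
        library_sizes: dict[str, int] = {}
        rows = []
        header: list[str] | None = None
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("# library_size\t"):
                    _, sample, size = line[2:].split("\t")
                    library_sizes[sample] = int(size)
                    continue
                if line.startswith("#") or not line:
                    continue
                fields = line.split("\t")
                if header is None:
                    header = fields
                    continue
                rows.append(fields)
        if header is None:
            raise ValueError(f"{path}: no count table found")
        samples = header[3:]
        index, lineage, data = [], {}, []
        for fields in rows:
            index.append(fields[0])
            lineage[fields[0]] = (fields[1], fields[2])
            data.append([float(v) for v in fields[3:]])
        df = pd.DataFrame(data, index=index, columns=samples)
        integral = bool(np.all(df.values == np.floor(df.values)))
        stage = "rounded" if integral else "fractional"
        if stage == "rounded":
            df = df.astype(np.int64)
        return cls(df, library_sizes, stage, lineage)


# ---------------------------------------------------------------------------
# Pseudo-genome construction
# ---------------------------------------------------------------------------

def build_pseudogenomes(
    genome: Sequence[GenomeSequence] | Mapping[str, str],
    catalog: RepeatCatalog,
    spacer_length: int,
    reverse_complement_minus: bool = False,
    flank: int = 0,
) -> dict[str, PseudoGenome]:
    """One pseudo-genome per subfamily: instances joined by N-spacers.

    Instances are extracted from the plus strand in annotation order
    (catalog order within subfamily: contig, start); by default
    minus-strand instances are NOT reverse complemented — downstream
    alignment is strand-agnostic — and no flanking genomic bases are
    included, but both behaviors are toggleable.  ``spacer_length``
    should be ≥ read length so no read can span two instances.
    """
    if isinstance(genome, Mapping):
        contigs = dict(genome)
    else:
        contigs = {g.name: g.sequence for g in genome}
    spacer = "N" * spacer_length
    out: dict[str, PseudoGenome] = {}
    for subfam in catalog.subfamilies:
        parts: list[str] = []
        offsets: dict[int, tuple[int, int]] = {}
        pos = 0
        for inst in catalog.instances_of(subfam):
            try:
                contig_seq = contigs[inst.contig]
            except KeyError:
                raise ValueError(
                    f"instance {inst.instance_id}: contig {inst.contig!r} "
                    "not in genome"
                ) from None
            if inst.end > len(contig_seq):
                raise ValueError(
                    f"instance {inst.instance_id}: interval [{inst.start}, "
                    f"{inst.end}) outside contig {inst.contig!r} "
                    f"(length {len(contig_seq)})"
                )
            if parts:
                parts.append(spacer)
                pos += spacer_length
            lo = max(0, inst.start - flank)
            hi = min(len(contig_seq), inst.end + flank)
            seq = contig_seq[lo:hi]
            if reverse_complement_minus and inst.strand == "-":
                from .repeat_annotation_io import reverse_complement

                seq = reverse_complement(seq)
            offsets[inst.instance_id] = (pos, len(seq))
            parts.append(seq)
            pos += len(seq)
        out[subfam] = PseudoGenome(subfam, "".join(parts), offsets)
    return out


# ---------------------------------------------------------------------------
# Pass 1: unique reads vs catalog intervals
# ---------------------------------------------------------------------------

def count_unique_overlaps(
    unique_reads: Iterable[ReadAssignmentClass],
    catalog: RepeatCatalog,
    read_length: int | None = None,
) -> tuple[dict[str, int], dict[str, tuple[str, int]]]:
    """Count uniquely mapping reads into subfamilies by interval overlap.

    A read overlapping ≥1 bp of an instance counts once for that
    instance's subfamily.  If it overlaps instances of several
    subfamilies it goes to the one with the larger overlap; ties break
    lexicographically on subfamily name.  Returns (per-subfamily counts,
    per-read attribution of (subfamily, instance id)); reads overlapping
    nothing are absent from the attribution.
    """
    counts: dict[str, int] = {}
    attribution: dict[str, tuple[str, int]] = {}
    for cls in unique_reads:
        if cls.read_class != "unique" or len(cls.hits) != 1:
            raise ValueError(
                f"read {cls.read_id!r} is not uniquely mapped"
            )
        hit = cls.hits[0]
        length = read_length if read_length is not None else len(cls.sequence)
        if length <= 0:
            raise ValueError(f"read {cls.read_id!r}: unknown read length")
        start, end = hit.position, hit.position + length
        candidates = catalog.overlapping(hit.target, start, end)
        if not candidates:
            continue
        best = min(
            candidates,
            key=lambda inst: (
                -inst.overlap(hit.target, start, end),
                inst.subfamily,
                inst.instance_id,
            ),
        )
        counts[best.subfamily] = counts.get(best.subfamily, 0) + 1
        attribution[cls.read_id] = (best.subfamily, best.instance_id)
    return counts, attribution


# ---------------------------------------------------------------------------
# Pass 2: multi reads vs pseudo-genomes
# ---------------------------------------------------------------------------

def assign_multimap(
    multi_reads: Iterable[ReadAssignmentClass],
    pseudogenomes: Mapping[str, PseudoGenome] | Sequence[ReferenceIndex],
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
) -> tuple[list[FractionalAssignment], list[str]]:
    """Assign each multi-mapping read 1/k to the k distinct subfamilies
    whose pseudo-genome it aligns to (multiple hits within one
    pseudo-genome count once).  Returns (assignments, unassigned read
    ids); unassigned reads stay in the library size.
    """
    if isinstance(pseudogenomes, Mapping):
        indexes = [
            ReferenceIndex(pg.subfamily, pg.sequence)
            for pg in pseudogenomes.values()
        ]
    else:
        indexes = list(pseudogenomes)
    assignments: list[FractionalAssignment] = []
    unassigned: list[str] = []
    for cls in multi_reads:
        if cls.read_class != "multi":
            raise ValueError(f"read {cls.read_id!r} is not multi-mapping")
        if not cls.sequence:
            raise ValueError(f"read {cls.read_id!r}: sequence unavailable")
        hit_subfams = {
            h.target for h in align_all(cls.sequence, indexes, max_mismatches)
        }
        if hit_subfams:
            assignments.append(
                FractionalAssignment(cls.read_id, frozenset(hit_subfams))
            )
        else:
            unassigned.append(cls.read_id)
    return assignments, unassigned


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

def aggregate_counts(
    unique_counts: Mapping[str, Mapping[str, int]],
    fractional_assignments: Mapping[str, Sequence[FractionalAssignment]],
    catalog: RepeatCatalog,
    library_sizes: Mapping[str, int],
) -> SubfamilyCountMatrix:
    """Sum the two passes into the fractional-stage subfamily × sample
    matrix (zero-filled over the catalog's subfamily set)."""
    if set(unique_counts) != set(fractional_assignments):
        raise ValueError(
            "sample sets differ between unique and multi passes: "
            f"{sorted(set(unique_counts) ^ set(fractional_assignments))}"
        )
    samples = list(unique_counts)
    subfams = catalog.subfamilies
    data = np.zeros((len(subfams), len(samples)))
    row = {s: i for i, s in enumerate(subfams)}
    for j, sample in enumerate(samples):
        for subfam, n in unique_counts[sample].items():
            data[row[subfam], j] += n
        for assign in fractional_assignments[sample]:
            w = assign.weight
            for subfam in assign.subfamilies:
                data[row[subfam], j] += w
    lineage = {s: catalog.lineage(s) for s in subfams}
    df = pd.DataFrame(data, index=subfams, columns=samples)
    return SubfamilyCountMatrix(df, library_sizes, "fractional", lineage)


# ---------------------------------------------------------------------------
# Whole-sample convenience
# ---------------------------------------------------------------------------

def quantify_sample(
    sample: str,
    classes: Sequence[ReadAssignmentClass],
    catalog: RepeatCatalog,
    pseudo_indexes: Sequence[ReferenceIndex],
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
) -> tuple[dict[str, int], list[FractionalAssignment], SampleAccounting]:
    """Run both counting passes for one sample's classified reads."""
    unique = [c for c in classes if c.read_class == "unique"]
    multi = [c for c in classes if c.read_class == "multi"]
    unmapped = [c for c in classes if c.read_class == "unmapped"]
    ucounts, attribution = count_unique_overlaps(unique, catalog)
    assignments, unassigned = assign_multimap(multi, pseudo_indexes, max_mismatches)
    ledger = SampleAccounting(
        sample=sample,
        total_reads=len(classes),
        unique_overlap=len(attribution),
        unique_non_overlap=len(unique) - len(attribution),
        multi_assigned=len(assignments),
        multi_unassigned=len(unassigned),
        unmapped=len(unmapped),
        library_size=len(unique) + len(multi),
    )
    ledger.check()
    return ucounts, assignments, ledger
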