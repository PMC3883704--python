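"""Exhaustive short-read Hamming alignment and read classification.

The contract of :func:`align_all` is complete enumeration: every
(reference, position, strand) at Hamming distance ≤ v from the read is
reported, for the forward read and its reverse complement.  ``N`` counts
as a mismatch against anything, including another ``N``.

The implementation seeds with (v+1) disjoint k-mers (pigeonhole: a hit
with ≤ v mismatches must contain at least one exact seed segment) and
verifies candidates with vectorized comparison, but tests hold it to
equivalence with a naive full scan.

Classification follows a two-stratum rule: with ``best_stratum=True``
(default) hits are first restricted to the minimum-mismatch stratum, then
one hit → unique, two or more → multi, none → unmapped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .repeat_annotation_io import SequenceRead, reverse_complement

__all__ = [
    "AlignmentHit",
    "ReadAssignmentClass",
    "ReferenceIndex",
    "align_all",
    "classify_reads",
    "align_and_classify",
    "read_sam",
    "write_sam",
    "library_size",
]

DEFAULT_MAX_MISMATCHES = 2

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGTN"):
    _ENCODE[_b] = _i
_N_CODE = 4
# complement in code space: A<->T, C<->G, N->N
_COMP_CODE = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


def encode_sequence(seq: str) -> np.ndarray:
    """Encode ACGTN to uint8 codes 0..4; reject other symbols."""
    arr = _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if arr.size and arr.max() == 255:
        bad = sorted(set(seq) - set("ACGTN"))
        raise ValueError(f"non-ACGTN symbols in sequence: {bad}")
    return arr


@dataclass(frozen=True, order=True)
class AlignmentHit:
    """One alignment location: target reference, 0-based start, strand."""

    target: str
    position: int
    strand: str
    mismatches: int


@dataclass
class ReadAssignmentClass:
    """Per-read classification with the genomic hits that produced it."""

    read_id: str
    read_class: str  # "unique" | "multi" | "unmapped"
    hits: list[AlignmentHit]
    sequence: str = ""


class ReferenceIndex:
    """Seeded index over one reference sequence for Hamming queries."""

    def __init__(self, name: str, sequence: str):
        self.name = name
        self.sequence = sequence
        self.codes = encode_sequence(sequence)
        self._kmer_index: dict[int, dict[int, np.ndarray]] = {}

    def __len__(self) -> int:
        return len(self.sequence)

    def _index_for(self, k: int) -> dict[int, np.ndarray]:
        """Map k-mer code (base-5 integer) → sorted start positions."""
        cached = self._kmer_index.get(k)
        if cached is not None:
            return cached
        n = len(self.codes)
        if n < k:
            self._kmer_index[k] = {}
            return self._kmer_index[k]
        windows = np.lib.stride_tricks.sliding_window_view(self.codes, k)
        powers = 5 ** np.arange(k - 1, -1, -1, dtype=np.int64)
        vals = windows.astype(np.int64) @ powers
        order = np.argsort(vals, kind="stable")
        sorted_vals = vals[order]
        boundaries = np.flatnonzero(np.diff(sorted_vals)) + 1
        groups = np.split(order, boundaries)
        index = {int(vals[g[0]]): np.sort(g) for g in groups}
        self._kmer_index[k] = index
        return index

    def hits_for(self, read_codes: np.ndarray, v: int) -> tuple[np.ndarray, np.ndarray]:
        """Positions and mismatch counts of all hits for one oriented read."""
        L = read_codes.size
        n = len(self.codes)
        if L > n:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        k = L // (v + 1)
        if k < 4:  # short reads: fall back to a full scan
            windows = np.lib.stride_tricks.sliding_window_view(self.codes, L)
            mism = (
                (windows != read_codes)
                | (windows == _N_CODE)
                | (read_codes == _N_CODE)
            ).sum(axis=1)
            pos = np.flatnonzero(mism <= v)
            return pos.astype(np.int64), mism[pos].astype(np.int64)
        index = self._index_for(k)
        powers = 5 ** np.arange(k - 1, -1, -1, dtype=np.int64)
        cands: list[np.ndarray] = []
        for seg in range(v + 1):
            off = seg * k
            code = int(read_codes[off : off + k].astype(np.int64) @ powers)
            positions = index.get(code)
            if positions is not None:
                c = positions - off
                cands.append(c[(c >= 0) & (c <= n - L)])
        if not cands:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        cand = np.unique(np.concatenate(cands))
        windows = self.codes[cand[:, None] + np.arange(L)]
        mism = (
            (windows != read_codes)
            | (windows == _N_CODE)
            | (read_codes == _N_CODE)
        ).sum(axis=1)
        ok = mism <= v
        return cand[ok], mism[ok].astype(np.int64)


def build_indexes(references: Mapping[str, str]) -> list[ReferenceIndex]:
    return [ReferenceIndex(name, seq) for name, seq in references.items()]


def align_all(
    read: str,
    references: Mapping[str, str] | Sequence[ReferenceIndex],
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
) -> list[AlignmentHit]:
    """Every (target, position, strand) within ``max_mismatches`` of the read.

    Both the forward read and its reverse complement are matched against
    the forward reference strand.  A location matching equally well in
    both orientations yields two hits.
    """
    if isinstance(references, Mapping):
        references = build_indexes(references)
    fwd = encode_sequence(read)
    rev = _COMP_CODE[fwd[::-1]]
    hits: list[AlignmentHit] = []
    for ref in references:
        for strand, codes in (("+", fwd), ("-", rev)):
            pos, mism = ref.hits_for(codes, max_mismatches)
            hits.extend(
                AlignmentHit(ref.name, int(p), strand, int(m))
                for p, m in zip(pos, mism)
            )
    hits.sort()
    return hits


def classify_reads(
    hits_per_read: Mapping[str, list[AlignmentHit]],
    best_stratum: bool = True,
    sequences: Mapping[str, str] | None = None,
) -> list[ReadAssignmentClass]:
    """Partition reads into unique / multi / unmapped.

    With ``best_stratum`` on, hits are restricted to the minimum-mismatch
    stratum before counting; off, all hits within the mismatch budget
    count.
    """
    out: list[ReadAssignmentClass] = []
    for read_id, hits in hits_per_read.items():
        kept = list(hits)
        if best_stratum and kept:
            best = min(h.mismatches for h in kept)
            kept = [h for h in kept if h.mismatches == best]
        if not kept:
            cls = "unmapped"
        elif len(kept) == 1:
            cls = "unique"
        else:
            cls = "multi"
        seq = sequences.get(read_id, "") if sequences else ""
        out.append(ReadAssignmentClass(read_id, cls, kept, seq))
    return out


def align_and_classify(
    reads: Iterable[SequenceRead],
    references: Mapping[str, str] | Sequence[ReferenceIndex],
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
    best_stratum: bool = True,
) -> list[ReadAssignmentClass]:
    """Convenience: align every read and classify, preserving read order."""
    if isinstance(references, Mapping):
        references = build_indexes(references)
    out: list[ReadAssignmentClass] = []
    for read in reads:
        hits = align_all(read.sequence, references, max_mismatches)
        kept = hits
        if best_stratum and kept:
            best = min(h.mismatches for h in kept)
            kept = [h for h in kept if h.mismatches == best]
        if not kept:
            cls = "unmapped"
        elif len(kept) == 1:
            cls = "unique"
        else:
            cls = "multi"
        out.append(ReadAssignmentClass(read.name, cls, kept, read.sequence))
    return out


# ---------------------------------------------------------------------------
# SAM ingestion / export
# ---------------------------------------------------------------------------

def read_sam(
    path: str | Path,
    best_stratum: bool = True,
    references: Mapping[str, str] | None = None,
) -> list[ReadAssignmentClass]:
    """Ingest a SAM file (secondary alignments included) and classify reads.

    Mismatch counts are taken from the ``NM`` tag; when absent they are
    recomputed against ``references`` (error if neither is available).
    Order of first appearance in the file is preserved.
    """
    import pysam

    hits: dict[str, list[AlignmentHit]] = {}
    seqs: dict[str, str] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            name = rec.query_name
            hits.setdefault(name, [])
            if rec.is_unmapped:
                if rec.query_sequence and name not in seqs:
                    seqs[name] = rec.query_sequence.upper()
                continue
            strand = "-" if rec.is_reverse else "+"
            if rec.query_sequence and name not in seqs:
                seq = rec.query_sequence.upper()
                seqs[name] = reverse_complement(seq) if rec.is_reverse else seq
            if rec.has_tag("NM"):
                nm = int(rec.get_tag("NM"))
            elif references is not None and rec.query_sequence:
                ref_seq = references[rec.reference_name]
                window = ref_seq[
                    rec.reference_start : rec.reference_start
                    + len(rec.query_sequence)
                ]
                q = rec.query_sequence.upper()
                nm = sum(
                    1
                    for a, b in zip(q, window)
                    if a != b or a == "N" or b == "N"
                )
            else:
                raise ValueError(
                    f"{path}: read {name!r} lacks an NM tag and no reference "
                    "was provided to recompute mismatches"
                )
            hits[name].append(
                AlignmentHit(rec.reference_name, rec.reference_start, strand, nm)
            )
    return classify_reads(hits, best_stratum=best_stratum, sequences=seqs)


def write_sam(
    classes: Iterable[ReadAssignmentClass],
    references: Mapping[str, str],
    path: str | Path,
) -> None:
    """Write classified reads as SAM with every hit reported.

    The first hit of a read is primary; the rest carry the secondary flag.
    Unmapped reads get a flag-4 record so read_sam can reproduce the
    classification exactly.
    """
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name, seq in references.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{len(seq)}\n")
        for cls in classes:
            seq = cls.sequence or "*"
            qual = "I" * len(cls.sequence) if cls.sequence else "*"
            if not cls.hits:
                fh.write(f"{cls.read_id}\t4\t*\t0\t0\t*\t*\t0\t0\t{seq}\t{qual}\n")
                continue
            for i, hit in enumerate(cls.hits):
                flag = 0
                if hit.strand == "-":
                    flag |= 16
                if i > 0:
                    flag |= 256
                out_seq, out_qual = seq, qual
                if hit.strand == "-" and cls.sequence:
                    out_seq = reverse_complement(cls.sequence)
                    out_qual = qual[::-1]
                cigar = f"{len(cls.sequence)}M" if cls.sequence else "*"
                fh.write(
                    f"{cls.read_id}\t{flag}\t{hit.target}\t{hit.position + 1}"
                    f"\t255\t{cigar}\t*\t0\t0\t{out_seq}\t{out_qual}"
                    f"\tNM:i:{hit.mismatches}\n"
                )


def library_size(classes: Iterable[ReadAssignmentClass]) -> int:
    """Total genome-mapping reads: unique + multi (unmapped excluded)."""
    return sum(1 for c in classes if c.read_class in ("unique", "multi"))
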