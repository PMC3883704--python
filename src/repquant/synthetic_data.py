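"""Synthetic genomes, repeat annotations and replicate read sets.

Generates a toy genome with planted repeat subfamilies (random consensus
per subfamily; each instance is the consensus with i.i.d. substitutions,
planted non-overlapping on a random strand), plus FASTQ read sets for a
groups × replicates design.  Replicate-to-replicate count variation is
negative-binomial via a gamma-Poisson construction; sequencing errors are
substitutions only.  All randomness flows from a single master seed
through named substreams, so outputs are byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .repeat_annotation_io import (
    GenomeSequence,
    RepeatCatalog,
    RepeatInstance,
    SequenceRead,
    reverse_complement,
    write_bed,
    write_fasta,
    write_fastq,
)

__all__ = [
    "SubfamilySpec",
    "DesignMatrixSpec",
    "SimulationTruth",
    "build_genome",
    "simulate_sample",
    "simulate_study",
    "load_simulation_spec",
    "default_simulation_spec",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_DEFAULT_QUALITY_CHAR = "I"  # Phred 40

BACKGROUND = "background"


@dataclass(frozen=True)
class SubfamilySpec:
    """Blueprint for one planted repeat subfamily.

    ``group_weights`` gives the relative expression per design group (one
    nonnegative value per group, in design group order); divergence is
    the per-base substitution probability applied to each instance copy.
    """

    name: str
    family: str
    repeat_class: str
    consensus_length: int
    n_instances: int
    divergence: float
    group_weights: tuple[float, ...]
    parent: str | None = None  # derive consensus from this subfamily's
    parent_divergence: float = 0.02  # ... with substitutions at this rate

    def __post_init__(self) -> None:
        if not 0.0 <= self.divergence <= 0.3:
            raise ValueError(f"{self.name}: divergence {self.divergence} ∉ [0, 0.3]")
        if self.n_instances < 1:
            raise ValueError(f"{self.name}: need ≥1 instance")
        if self.consensus_length < 1:
            raise ValueError(f"{self.name}: consensus length must be positive")
        if any(w < 0 for w in self.group_weights):
            raise ValueError(f"{self.name}: negative group weight")


@dataclass(frozen=True)
class DesignMatrixSpec:
    """The study layout and noise model for read simulation."""

    group_labels: tuple[str, ...]
    replicates: int
    dispersion: float
    background_fraction: float
    reads_per_sample: int
    read_length: int
    error_rate: float
    seed: int

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise ValueError("need ≥2 replicates per group for any tested contrast")
        if not 0.0 <= self.background_fraction <= 1.0:
            raise ValueError("background fraction must be in [0, 1]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be ≥ 0")
        if len(set(self.group_labels)) != len(self.group_labels):
            raise ValueError("duplicate group labels")

    @property
    def samples(self) -> list[tuple[str, int]]:
        return [
            (g, r)
            for g in self.group_labels
            for r in range(1, self.replicates + 1)
        ]


@dataclass
class SimulationTruth:
    """Ground truth: expected per-group read proportions and consensi.

    ``group_proportions`` has one row per subfamily plus a
    ``background`` row; each group column sums to 1.
    """

    group_proportions: pd.DataFrame
    consensus: dict[str, str]

    def log2_fold_change(self, subfamily: str, group_a: str, group_b: str) -> float:
        pa = self.group_proportions.loc[subfamily, group_a]
        pb = self.group_proportions.loc[subfamily, group_b]
        return float(np.log2(pa / pb))

    def contrast_table(self, group_a: str, group_b: str) -> pd.Series:
        subfams = [i for i in self.group_proportions.index if i != BACKGROUND]
        return pd.Series(
            {s: self.log2_fold_change(s, group_a, group_b) for s in subfams},
            name=f"{group_a}_vs_{group_b}",
        )


def _substream(seed: int, *key: int) -> np.random.Generator:
    """Named substream of the master seed."""
    return np.random.default_rng(np.random.SeedSequence([seed, *key]))


def _random_dna(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: float) -> np.ndarray:
    """I.i.d. substitutions at `rate`, always to a different base."""
    if rate <= 0:
        return seq.copy()
    out = seq.copy()
    hit = np.flatnonzero(rng.random(seq.size) < rate)
    if hit.size:
        shift = rng.integers(1, 4, size=hit.size)
        idx = (np.searchsorted(_BASES, out[hit]) + shift) % 4
        out[hit] = _BASES[idx]
    return out


def _expected_proportions(
    specs: Sequence[SubfamilySpec], design: DesignMatrixSpec
) -> pd.DataFrame:
    weights = np.array([s.group_weights for s in specs], dtype=float)
    if weights.shape[1] != len(design.group_labels):
        raise ValueError(
            "each subfamily needs one weight per design group "
            f"({len(design.group_labels)} groups)"
        )
    totals = weights.sum(axis=0)
    if np.any(totals <= 0):
        raise ValueError("every group needs positive total subfamily weight")
    props = (1.0 - design.background_fraction) * weights / totals
    df = pd.DataFrame(
        props, index=[s.name for s in specs], columns=list(design.group_labels)
    )
    df.loc[BACKGROUND] = design.background_fraction
    return df


def build_genome(
    specs: Sequence[SubfamilySpec],
    background_length: int,
    seed: int,
    design: DesignMatrixSpec | None = None,
    contig_name: str = "chrT",
) -> tuple[GenomeSequence, RepeatCatalog, SimulationTruth]:
    """Build a single-contig genome with planted repeat instances.

    Background is i.i.d. random DNA; instances are placed non-overlapping
    at positions drawn uniformly (stars-and-bars over the free space, so
    placement never fails when the background is long enough), each on a
    random strand (minus-strand instances are reverse complemented into
    the genome).  The catalog records the exact planted intervals.
    """
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate subfamily names")
    rng = _substream(seed, 0)
    total_planted = sum(s.consensus_length * s.n_instances for s in specs)
    n_total = sum(s.n_instances for s in specs)
    free = background_length - total_planted
    if free < 2 * n_total + 1:
        raise ValueError(
            f"background length {background_length} too short for "
            f"{total_planted} bp of planted repeats plus margins"
        )

    consensus: dict[str, np.ndarray] = {}
    for s in specs:
        if s.parent is None:
            consensus[s.name] = _random_dna(rng, s.consensus_length)
    for s in specs:
        if s.parent is not None:
            if s.parent not in consensus:
                raise ValueError(
                    f"{s.name}: parent {s.parent!r} unknown or itself derived"
                )
            base = consensus[s.parent]
            if base.size != s.consensus_length:
                raise ValueError(
                    f"{s.name}: consensus length differs from parent's"
                )
            consensus[s.name] = _mutate(rng, base, s.parent_divergence)
    # every planted copy: (spec, mutated sequence, strand)
    copies: list[tuple[SubfamilySpec, np.ndarray, str]] = []
    for s in specs:
        for _ in range(s.n_instances):
            mutated = _mutate(rng, consensus[s.name], s.divergence)
            strand = "+" if rng.random() < 0.5 else "-"
            copies.append((s, mutated, strand))
    order = rng.permutation(len(copies))
    copies = [copies[i] for i in order]

    # stars-and-bars placement: n+1 nonnegative gaps summing to `free`,
    # at least 1 bp between consecutive instances
    n = len(copies)
    cuts = np.sort(rng.choice(free - n, size=n, replace=False)) + np.arange(1, n + 1)
    lengths = np.array([c[1].size for c in copies])
    starts = cuts + np.concatenate(([0], np.cumsum(lengths[:-1])))

    genome = _random_dna(rng, background_length)
    instances: list[RepeatInstance] = []
    for inst_id, ((s, mutated, strand), start) in enumerate(zip(copies, starts)):
        planted = mutated
        if strand == "-":
            rc = reverse_complement(mutated.tobytes().decode("ascii"))
            planted = np.frombuffer(rc.encode("ascii"), dtype=np.uint8)
        genome[start : start + planted.size] = planted
        instances.append(
            RepeatInstance(
                contig=contig_name,
                start=int(start),
                end=int(start + planted.size),
                strand=strand,
                subfamily=s.name,
                family=s.family,
                repeat_class=s.repeat_class,
                instance_id=inst_id,
            )
        )
    catalog = RepeatCatalog(instances)
    if design is not None:
        props = _expected_proportions(specs, design)
    else:
        uniform = DesignMatrixSpec(
            group_labels=("g",),
            replicates=2,
            dispersion=0.0,
            background_fraction=0.0,
            reads_per_sample=1,
            read_length=1,
            error_rate=0.0,
            seed=seed,
        )
        one_weight = [
            SubfamilySpec(
                s.name, s.family, s.repeat_class, s.consensus_length,
                s.n_instances, s.divergence, (s.group_weights[0],),
            )
            for s in specs
        ]
        props = _expected_proportions(one_weight, uniform)
    truth = SimulationTruth(
        group_proportions=props,
        consensus={
            name: arr.tobytes().decode("ascii") for name, arr in consensus.items()
        },
    )
    return (
        GenomeSequence(contig_name, genome.tobytes().decode("ascii")),
        catalog,
        truth,
    )


def _background_starts(
    genome: GenomeSequence, catalog: RepeatCatalog, read_length: int
) -> np.ndarray:
    """Start positions whose read window overlaps no repeat instance."""
    ok = np.ones(len(genome) - read_length + 1, dtype=bool)
    for inst in catalog:
        lo = max(0, inst.start - read_length + 1)
        hi = min(ok.size, inst.end)
        ok[lo:hi] = False
    return np.flatnonzero(ok)


def simulate_sample(
    genome: GenomeSequence,
    catalog: RepeatCatalog,
    truth: SimulationTruth,
    design: DesignMatrixSpec,
    group: str,
    replicate: int,
    seed: int | None = None,
) -> tuple[list[SequenceRead], pd.DataFrame]:
    """Simulate one sample's FASTQ reads plus a per-read truth table.

    Per-subfamily expected counts are the group proportions perturbed by
    a gamma multiplier (shape 1/dispersion, mean 1), renormalized, then a
    multinomial draw fixes the total at ``reads_per_sample`` exactly.
    Reads take a uniform instance, uniform start, fair-coin strand, and
    i.i.d. substitution errors; background reads come from repeat-free
    windows.
    """
    if group not in design.group_labels:
        raise ValueError(f"unknown group {group!r}")
    L = design.read_length
    shortest = min(len(inst) for inst in catalog)
    if L > shortest:
        raise ValueError(
            f"read length {L} exceeds shortest planted instance ({shortest} bp)"
        )
    if seed is None:
        seed = design.seed
    g_idx = design.group_labels.index(group)
    rng = _substream(seed, 1, g_idx, replicate)

    props = truth.group_proportions[group].copy()
    subfams = [i for i in props.index if i != BACKGROUND]
    p = props.loc[subfams].to_numpy(dtype=float)
    if design.dispersion > 0:
        shape = 1.0 / design.dispersion
        p = p * rng.gamma(shape, scale=1.0 / shape, size=p.size)
    weights = np.concatenate([p, [props.loc[BACKGROUND]]])
    total = weights.sum()
    if total <= 0:
        raise ValueError(f"group {group!r}: all expected proportions are zero")
    counts = rng.multinomial(design.reads_per_sample, weights / total)

    sample_id = f"{group}_rep{replicate}"
    bg_starts = None
    names: list[str] = []
    seqs: list[str] = []
    origins: list[str] = []
    origin_ids: list[int] = []
    for subfam, n_reads in zip(subfams + [BACKGROUND], counts):
        if n_reads == 0:
            continue
        if subfam == BACKGROUND:
            if bg_starts is None:
                bg_starts = _background_starts(genome, catalog, L)
            if bg_starts.size == 0:
                raise ValueError("no repeat-free windows for background reads")
            starts = bg_starts[rng.integers(0, bg_starts.size, size=n_reads)]
            for s in starts:
                seqs.append(genome.sequence[s : s + L])
                origins.append(BACKGROUND)
                origin_ids.append(-1)
        else:
            insts = catalog.instances_of(subfam)
            picks = rng.integers(0, len(insts), size=n_reads)
            for k in picks:
                inst = insts[k]
                s = int(rng.integers(inst.start, inst.end - L + 1))
                seqs.append(genome.sequence[s : s + L])
                origins.append(subfam)
                origin_ids.append(inst.instance_id)
    # orientation, errors, shuffle
    order = rng.permutation(len(seqs))
    reads: list[SequenceRead] = []
    rows = []
    qual = _DEFAULT_QUALITY_CHAR * L
    for out_i, src_i in enumerate(order):
        seq = seqs[src_i]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            seq = reverse_complement(seq)
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
        arr = _mutate(rng, arr, design.error_rate)
        name = f"{sample_id}:r{out_i:07d}"
        reads.append(SequenceRead(name, arr.tobytes().decode("ascii"), qual))
        rows.append((name, origins[src_i], origin_ids[src_i], strand))
    read_truth = pd.DataFrame(
        rows, columns=["read_id", "origin_subfamily", "origin_instance", "strand"]
    )
    return reads, read_truth


def simulate_study(
    specs: Sequence[SubfamilySpec],
    design: DesignMatrixSpec,
    out_dir: str | Path,
    background_length: int = 100_000,
) -> pd.DataFrame:
    """Simulate the full study into ``out_dir``; returns the manifest.

    Writes genome.fasta, repeats.bed, one FASTQ per sample, per-read and
    per-subfamily truth TSVs, and manifest.tsv (sample id, group,
    replicate, fastq path).  Deterministic given ``design.seed``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome, catalog, truth = build_genome(
        specs, background_length, design.seed, design=design
    )
    write_fasta([genome], out / "genome.fasta")
    write_bed(catalog, out / "repeats.bed")
    truth.group_proportions.rename_axis("subfamily").to_csv(
        out / "truth_subfamily.tsv", sep="\t"
    )
    rows = []
    seen_paths: set[Path] = set()
    read_truths = []
    for group, replicate in design.samples:
        sample_id = f"{group}_rep{replicate}"
        fastq = out / f"{sample_id}.fastq"
        if fastq in seen_paths:
            raise ValueError(f"output path collision: {fastq}")
        seen_paths.add(fastq)
        reads, read_truth = simulate_sample(
            genome, catalog, truth, design, group, replicate
        )
        write_fastq(reads, fastq)
        read_truth.insert(0, "sample", sample_id)
        read_truths.append(read_truth)
        rows.append((sample_id, group, replicate, fastq.name))
    pd.concat(read_truths, ignore_index=True).to_csv(
        out / "truth_reads.tsv", sep="\t", index=False
    )
    manifest = pd.DataFrame(
        rows, columns=["sample", "group", "replicate", "fastq"]
    )
    manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    return manifest


# ---------------------------------------------------------------------------
# Spec files
# ---------------------------------------------------------------------------

def load_simulation_spec(
    path: str | Path,
) -> tuple[list[SubfamilySpec], DesignMatrixSpec]:
    """Load subfamily and design specs from a YAML/JSON file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    design = DesignMatrixSpec(
        group_labels=tuple(doc["design"]["groups"]),
        replicates=int(doc["design"]["replicates"]),
        dispersion=float(doc["design"].get("dispersion", 0.1)),
        background_fraction=float(doc["design"].get("background_fraction", 0.3)),
        reads_per_sample=int(doc["design"].get("reads_per_sample", 20_000)),
        read_length=int(doc["design"].get("read_length", 50)),
        error_rate=float(doc["design"].get("error_rate", 0.005)),
        seed=int(doc["design"].get("seed", 0)),
    )
    specs = [
        SubfamilySpec(
            name=s["name"],
            family=s.get("family", s["name"]),
            repeat_class=s.get("class", s.get("family", s["name"])),
            consensus_length=int(s["consensus_length"]),
            n_instances=int(s["n_instances"]),
            divergence=float(s.get("divergence", 0.05)),
            group_weights=tuple(float(w) for w in s["group_weights"]),
            parent=s.get("parent"),
            parent_divergence=float(s.get("parent_divergence", 0.02)),
        )
        for s in doc["subfamilies"]
    ]
    return specs, design


def default_simulation_spec(
    seed: int = 0,
    n_subfamilies: int = 12,
    reads_per_sample: int = 20_000,
    derepressed: Sequence[str] = ("L1Toy_2", "SatToy_1"),
    derepression_log2fc: float = 2.0,
) -> tuple[list[SubfamilySpec], DesignMatrixSpec]:
    """A bundled toy study: 3 age-like groups × 3 replicates, a mixed
    repeat landscape, and derepression planted in the oldest group only.

    Subfamily base weights are log-uniform; ``derepressed`` subfamilies
    get a ``2**derepression_log2fc`` boost in the last group.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 99]))
    groups = ("young", "mid", "old")
    families = [
        ("L1Toy", "L1", "LINE", 600, 6, 0.06),
        ("SINEToy", "B1", "SINE", 150, 8, 0.08),
        ("LTRToy", "ERVK", "LTR", 400, 4, 0.07),
        ("SatToy", "Satellite", "Satellite", 300, 5, 0.03),
    ]
    specs: list[SubfamilySpec] = []
    for i in range(n_subfamilies):
        base, fam, cls, length, n_inst, div = families[i % len(families)]
        variant = i // len(families)
        name = f"{base}_{variant}"
        w = float(10 ** rng.uniform(-1, 1))
        weights = [w, w, w]
        if name in derepressed:
            weights[-1] = w * 2**derepression_log2fc
        # later variants are siblings of variant 0, so windows of their
        # instances can multi-map across subfamilies (the 1/k pathway)
        parent = f"{base}_0" if variant > 0 else None
        specs.append(
            SubfamilySpec(
                name=name,
                family=fam,
                repeat_class=cls,
                consensus_length=length,
                n_instances=n_inst,
                divergence=div if variant == 0 else div / 3,
                group_weights=tuple(weights),
                parent=parent,
                parent_divergence=0.015,
            )
        )
    design = DesignMatrixSpec(
        group_labels=groups,
        replicates=3,
        dispersion=0.05,
        background_fraction=0.3,
        reads_per_sample=reads_per_sample,
        read_length=50,
        error_rate=0.002,
        seed=seed,
    )
    return specs, design
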