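"""Synthetic metagenomic communities with full ground truth.

The generator emulates the statistical structure of coastal sequence-discrete
archaeal populations: a handful of populations with specified relative
abundances, near-clonal intra-population divergence (per-base substitution
probability delta, so recruited reads sit around 100*(1 - delta - epsilon) %
identity), optional co-occurring sister clades at a chosen ANI, and one
embedded universal single-copy marker locus per genome standing in for rpoB.

Everything is seed-deterministic; mutation and sequencing-error models are
substitution-only (no indels), which keeps the truth aligner exact: every
read has one gapless alignment at its known origin, and percent identity is
a direct Hamming comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import SequenceRecord, TabularAlignment

__all__ = [
    "PopulationSpec",
    "SimulationConfig",
    "Community",
    "ReadSet",
    "CommunityTruth",
    "generate_genome",
    "derive_relative",
    "build_community",
    "generate_reads",
    "truth_align",
    "emit_marker_hits",
    "marker_references",
    "write_fastq",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def _encode(seq: str) -> np.ndarray:
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if np.any(codes == 255):
        raise ValueError("sequence contains characters outside ACGT")
    return codes


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


@dataclass(frozen=True)
class PopulationSpec:
    """One population of the synthetic community.

    ``abundance`` is the population's fraction of community genome-equivalent
    depth; ``divergence`` is the per-base substitution probability separating
    individual cells from the population's reference (clonal regime:
    0.002-0.008). ``marker_length`` is the embedded single-copy marker locus.
    """

    id: str
    genome_length: int
    abundance: float
    gc: float = 0.5
    divergence: float = 0.004
    marker_length: int = 4000

    def __post_init__(self) -> None:
        if not (0.0 < self.gc < 1.0):
            raise ValueError(f"GC content must be in (0, 1): {self.gc}")
        if not (0.0 <= self.divergence <= 0.02):
            raise ValueError(f"intra-population divergence outside [0, 0.02]: {self.divergence}")
        if self.abundance < 0:
            raise ValueError("abundance must be >= 0")
        if self.marker_length >= self.genome_length:
            raise ValueError("marker locus longer than genome")


@dataclass(frozen=True)
class SimulationConfig:
    """Read-simulation settings; a fixed seed makes all outputs byte-identical."""

    seed: int
    total_reads: int = 100_000
    read_length: int = 150
    error_rate: float = 0.001
    sister_ani_targets: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.read_length < 1 or self.total_reads < 1:
            raise ValueError("read_length and total_reads must be >= 1")
        if not (0.0 <= self.error_rate < 1.0):
            raise ValueError("error_rate must be in [0, 1)")


def generate_genome(
    length: int, gc: float, seed: int | np.random.Generator, genome_id: str = "genome"
) -> SequenceRecord:
    """Random i.i.d. genome with P(G) + P(C) = gc, single contig."""
    if length < 10_000:
        raise ValueError(f"genome length must be >= 10000 bp, got {length}")
    if not (0.0 < gc < 1.0):
        raise ValueError(f"GC content must be in (0, 1): {gc}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    codes = rng.choice(np.array([0, 1, 2, 3], dtype=np.uint8), size=length, p=p)
    return SequenceRecord(id=genome_id, sequence=_decode(codes))


def derive_relative(
    genome: SequenceRecord,
    divergence: float,
    seed: int | np.random.Generator,
    genome_id: str | None = None,
) -> SequenceRecord:
    """Derive a sister genome by i.i.d. substitution at the given rate.

    Each base is replaced with probability ``divergence``, uniformly over the
    three alternatives (Jukes-Cantor-like, no indels), so the two sequences
    stay colinear and their expected ANI is 100*(1 - divergence).
    """
    if not (0.0 <= divergence < 0.3):
        raise ValueError(f"divergence outside [0, 0.3): {divergence}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    codes = _encode(genome.sequence).copy()
    mask = rng.random(codes.size) < divergence
    shift = rng.integers(1, 4, size=int(mask.sum()), dtype=np.uint8)
    codes[mask] = (codes[mask] + shift) % 4
    gid = genome_id or f"{genome.id}_d{divergence:g}"
    return SequenceRecord(id=gid, sequence=_decode(codes))


@dataclass
class Community:
    """Reference genomes plus marker-locus coordinates for each population."""

    populations: list[PopulationSpec]
    genomes: dict[str, SequenceRecord]
    marker_loci: dict[str, tuple[int, int]]  # 0-based half-open on the genome

    def spec(self, pop_id: str) -> PopulationSpec:
        for p in self.populations:
            if p.id == pop_id:
                return p
        raise KeyError(pop_id)


def build_community(
    specs: Sequence[PopulationSpec], seed: int, normalize: bool = False
) -> Community:
    """Generate reference genomes and place one marker locus per population.

    Population abundances must sum to 1 (pass ``normalize=True`` to rescale).
    """
    total = sum(p.abundance for p in specs)
    if normalize:
        specs = [replace(p, abundance=p.abundance / total) for p in specs]
    elif abs(total - 1.0) > 1e-9:
        raise ValueError(f"population abundances sum to {total}, not 1")
    rng = np.random.default_rng(seed)
    genomes: dict[str, SequenceRecord] = {}
    loci: dict[str, tuple[int, int]] = {}
    for p in specs:
        genomes[p.id] = generate_genome(p.genome_length, p.gc, rng, genome_id=p.id)
        start = int(rng.integers(0, p.genome_length - p.marker_length + 1))
        loci[p.id] = (start, start + p.marker_length)
    return Community(list(specs), genomes, loci)


def marker_references(community: Community) -> list[SequenceRecord]:
    """Per-population marker gene sequences (the genome slice at the locus)."""
    out = []
    for p in community.populations:
        s, e = community.marker_loci[p.id]
        out.append(
            SequenceRecord(
                id=f"{p.id}|rpoB", sequence=community.genomes[p.id].sequence[s:e]
            )
        )
    return out


@dataclass
class ReadSet:
    """Simulated reads in packed 2-bit form, one row per read."""

    ids: list[str]
    population: list[str]
    start: np.ndarray  # origin position on the population's genome
    codes: np.ndarray  # shape (n_reads, read_length), uint8 in {0..3}
    mismatches: np.ndarray  # Hamming distance to the population's own reference

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def read_length(self) -> int:
        return int(self.codes.shape[1])

    def sequence(self, i: int) -> str:
        return _decode(self.codes[i])


@dataclass
class CommunityTruth:
    """Ground-truth ledger: provenance of every emitted read plus expectations."""

    community: Community
    provenance: pd.DataFrame  # read_id, population, start, end, mismatches
    true_proportions: dict[str, float]
    expected_read_identity: dict[str, float]  # 100 * (1 - delta - epsilon)
    config: SimulationConfig


def generate_reads(
    community: Community, config: SimulationConfig
) -> tuple[ReadSet, CommunityTruth]:
    """Draw reads population-by-population with full provenance.

    Read counts follow Multinomial(total_reads, weights), with weights
    proportional to abundance x genome length (so equal-length genomes give
    depth proportional to abundance). Each read first receives lineage
    substitutions at the population's divergence rate, then sequencing errors
    at ``error_rate``; both substitutions always change the base.
    """
    rng = np.random.default_rng(config.seed)
    specs = community.populations
    weights = np.array([p.abundance * p.genome_length for p in specs], dtype=float)
    weights /= weights.sum()
    counts = rng.multinomial(config.total_reads, weights)
    L = config.read_length

    ids: list[str] = []
    pops: list[str] = []
    starts_all: list[np.ndarray] = []
    codes_all: list[np.ndarray] = []
    mism_all: list[np.ndarray] = []
    for p, n in zip(specs, counts):
        if n == 0:
            continue
        ref = _encode(community.genomes[p.id].sequence)
        if ref.size < L:
            raise ValueError(f"genome {p.id} shorter than read length {L}")
        starts = rng.integers(0, ref.size - L + 1, size=n)
        windows = ref[starts[:, None] + np.arange(L)[None, :]]
        reads = windows.copy()
        for rate in (p.divergence, config.error_rate):
            if rate > 0:
                mask = rng.random(reads.shape) < rate
                shift = rng.integers(1, 4, size=int(mask.sum()), dtype=np.uint8)
                reads[mask] = (reads[mask] + shift) % 4
        mism = (reads != windows).sum(axis=1)
        ids.extend(f"{p.id}_r{i}" for i in range(n))
        pops.extend([p.id] * n)
        starts_all.append(starts)
        codes_all.append(reads)
        mism_all.append(mism)

    starts = np.concatenate(starts_all) if starts_all else np.empty(0, dtype=int)
    codes = np.concatenate(codes_all) if codes_all else np.empty((0, L), dtype=np.uint8)
    mism = np.concatenate(mism_all) if mism_all else np.empty(0, dtype=int)
    readset = ReadSet(ids, pops, starts, codes, mism)

    prov = pd.DataFrame(
        {
            "read_id": ids,
            "population": pops,
            "start": starts,
            "end": starts + L,
            "mismatches": mism,
        }
    )
    truth = CommunityTruth(
        community=community,
        provenance=prov,
        true_proportions={p.id: p.abundance for p in specs},
        expected_read_identity={
            p.id: 100.0 * (1.0 - p.divergence - config.error_rate) for p in specs
        },
        config=config,
    )
    return readset, truth


def truth_align(
    reads: ReadSet,
    truth: CommunityTruth,
    references: Mapping[str, SequenceRecord] | None = None,
    target: Mapping[str, str] | None = None,
) -> list[TabularAlignment]:
    """One gapless alignment per read at its true origin coordinates.

    ``references`` maps population id to the reference record to align
    against (default: each population's own genome); ``target`` redirects
    populations to another reference id for cross-recruitment experiments
    (references must be colinear, as produced by :func:`derive_relative`).
    Percent identity is computed by direct base comparison.
    """
    if references is None:
        references = truth.community.genomes
    target = target or {}
    L = reads.read_length
    ref_codes = {rid: _encode(rec.sequence) for rid, rec in references.items()}

    order = np.arange(len(reads))
    out: list[TabularAlignment | None] = [None] * len(reads)
    pops = np.array(reads.population)
    for pop in pd.unique(pops):
        idx = order[pops == pop]
        rid = target.get(pop, pop)
        if rid not in ref_codes:
            raise ValueError(f"no reference available for population {pop!r} (wanted {rid!r})")
        ref = ref_codes[rid]
        sseqid = references[rid].id
        starts = reads.start[idx]
        if starts.size and int(starts.max()) + L > ref.size:
            raise ValueError(f"reference {rid!r} lacks the origin interval of some reads")
        windows = ref[starts[:, None] + np.arange(L)[None, :]]
        mism = (reads.codes[idx] != windows).sum(axis=1)
        for i, m in zip(idx, mism):
            matches = L - int(m)
            s = int(reads.start[i])
            out[i] = TabularAlignment(
                qseqid=reads.ids[i],
                sseqid=sseqid,
                pident=round(100.0 * matches / L, 4),
                length=L,
                mismatch=int(m),
                gapopen=0,
                qstart=1,
                qend=L,
                sstart=s + 1,
                send=s + L,
                evalue=0.0,
                bitscore=float(2 * matches),
            )
    return [a for a in out if a is not None]


def emit_marker_hits(reads: ReadSet, truth: CommunityTruth) -> list[TabularAlignment]:
    """Alignments of marker-derived reads against the pooled marker references.

    Exactly the reads whose origin interval overlaps their population's
    marker locus are emitted, clipped to the overlap, so expected aligned
    bases equal depth x marker length. This stands in for an upstream
    model-filtered marker (rpoB) search.
    """
    L = reads.read_length
    community = truth.community
    out: list[TabularAlignment] = []
    genome_codes = {pid: _encode(rec.sequence) for pid, rec in community.genomes.items()}
    for i in range(len(reads)):
        pop = reads.population[i]
        locus_s, locus_e = community.marker_loci[pop]
        r_s = int(reads.start[i])
        r_e = r_s + L
        ov_s, ov_e = max(r_s, locus_s), min(r_e, locus_e)
        if ov_s >= ov_e:
            continue
        ref_seg = genome_codes[pop][ov_s:ov_e]
        read_seg = reads.codes[i][ov_s - r_s : ov_e - r_s]
        m = int((read_seg != ref_seg).sum())
        n = ov_e - ov_s
        matches = n - m
        out.append(
            TabularAlignment(
                qseqid=reads.ids[i],
                sseqid=f"{pop}|rpoB",
                pident=round(100.0 * matches / n, 4),
                length=n,
                mismatch=m,
                gapopen=0,
                qstart=ov_s - r_s + 1,
                qend=ov_e - r_s,
                sstart=ov_s - locus_s + 1,
                send=ov_e - locus_s,
                evalue=0.0,
                bitscore=float(2 * matches),
            )
        )
    return out


def write_fastq(reads: ReadSet, path: str | Path, quality_char: str = "I") -> None:
    qual = quality_char * reads.read_length
    with open(path, "w") as fh:
        for i in range(len(reads)):
            fh.write(f"@{reads.ids[i]}\n{reads.sequence(i)}\n+\n{qual}\n")
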