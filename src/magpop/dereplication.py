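"""Quality scoring, MinHash ANI estimation, and greedy genome dereplication.

Time-series assemblies recover the same population many times over; before
any abundance bookkeeping the near-identical genome bins are collapsed to one
representative per population. The quality score is

    score = completeness - 4 * contamination        (percent units)

and bins with score >= 50 are conventionally retained. Pairwise ANI is
estimated from bottom-s MinHash sketches of canonical k-mers (Mash-style);
clustering is a single greedy pass in descending quality order, so every
cluster representative maximizes the quality score within its cluster by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

from .io_formats import SequenceRecord

__all__ = [
    "GenomeQuality",
    "Sketch",
    "ClusterSet",
    "quality_score",
    "quality_filter",
    "sketch",
    "ani_estimate",
    "greedy_cluster",
]

HASH_NAME = "splitmix64"

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def quality_score(completeness: float, contamination: float) -> float:
    """completeness − 4 × contamination, both in percent."""
    if not (0.0 <= completeness <= 100.0):
        raise ValueError(f"completeness outside [0, 100]: {completeness}")
    if contamination < 0.0:
        raise ValueError(f"negative contamination: {contamination}")
    return completeness - 4.0 * contamination


@dataclass(frozen=True)
class GenomeQuality:
    """Completeness/contamination metadata for one genome bin."""

    genome_id: str
    completeness: float
    contamination: float

    @property
    def score(self) -> float:
        return quality_score(self.completeness, self.contamination)


def quality_filter(
    genomes: Iterable[GenomeQuality], min_score: float = 50.0
) -> list[GenomeQuality]:
    """Keep genomes with score >= min_score (inclusive boundary), order preserved."""
    return [g for g in genomes if g.score >= min_score]


def _splitmix64(x: np.ndarray) -> np.ndarray:
    """Deterministic 64-bit finalizer (splitmix64), vectorized with wraparound."""
    z = (x + np.uint64(0x9E3779B97F4A7C15)).astype(np.uint64)
    z ^= z >> np.uint64(30)
    z *= np.uint64(0xBF58476D1CE4E5B9)
    z ^= z >> np.uint64(27)
    z *= np.uint64(0x94D049BB133111EB)
    z ^= z >> np.uint64(31)
    return z


def _canonical_kmers(seq: str, k: int) -> np.ndarray:
    """2-bit packed canonical k-mers of one contig; windows containing N dropped."""
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    valid = codes != 255
    ok = np.ones(n, dtype=bool)
    for j in range(k):
        ok &= valid[j : j + n]
    codes64 = codes.astype(np.uint64)
    fwd = np.zeros(n, dtype=np.uint64)
    rev = np.zeros(n, dtype=np.uint64)
    comp = (np.uint64(3) - codes64) & np.uint64(3)  # only read where valid
    for j in range(k):
        fwd = (fwd << np.uint64(2)) | codes64[j : j + n]
        rev |= comp[j : j + n] << np.uint64(2 * j)
    return np.minimum(fwd[ok], rev[ok])


@dataclass(frozen=True)
class Sketch:
    """Bottom-s MinHash sketch: the s smallest hash values of canonical k-mers."""

    genome_id: str
    k: int
    s: int
    hashes: np.ndarray  # sorted ascending, distinct, uint64
    total_length: int = 0
    hash_name: str = HASH_NAME


def sketch(
    genome: Sequence[SequenceRecord], k: int = 21, s: int = 5000, genome_id: str = ""
) -> Sketch:
    """Sketch a genome (list of contigs). Canonical k-mer = min(kmer, revcomp)."""
    if k < 1 or 2 * k > 63:
        raise ValueError(f"k must be in [1, 31], got {k}")
    if s < 1:
        raise ValueError("sketch size s must be >= 1")
    total = sum(len(rec) for rec in genome)
    if total < k:
        raise ValueError(f"genome shorter ({total} bp) than k ({k})")
    parts = [_canonical_kmers(rec.sequence, k) for rec in genome]
    kmers = np.unique(np.concatenate(parts)) if parts else np.empty(0, dtype=np.uint64)
    if kmers.size == 0:
        raise ValueError("no valid (N-free) k-mers in genome")
    hashes = np.unique(_splitmix64(kmers))
    if hashes.size > s:
        hashes = np.sort(np.partition(hashes, s)[:s])
    gid = genome_id or genome[0].id
    return Sketch(gid, k, s, hashes, total_length=total)


def ani_estimate(
    a: Sketch, b: Sketch, transform: Literal["binomial", "mash"] = "binomial"
) -> float | None:
    """MinHash ANI estimate in percent, or None when below sketch resolution.

    The Jaccard index j is estimated on the bottom-s values of the merged
    sketches; with w = 2j/(1+j) the shared k-mer fraction,

    * ``binomial`` (default): ANI = 100 * w**(1/k), the exact inversion of
      w = (1 - d)**k for per-base divergence d;
    * ``mash``: ANI = 100 * (1 - D) with Mash distance D = -ln(w)/k.

    j = 0 (no shared hashes) is reported as None rather than a number.
    """
    if a.k != b.k or a.s != b.s:
        raise ValueError(
            f"sketch parameters differ: k={a.k}/{b.k}, s={a.s}/{b.s}"
        )
    union = np.union1d(a.hashes, b.hashes)
    bottom = union[: min(a.s, union.size)]
    inter = np.intersect1d(a.hashes, b.hashes, assume_unique=True)
    shared = int(np.searchsorted(inter, bottom[-1], side="right")) if inter.size else 0
    j = shared / bottom.size
    if j == 0.0:
        return None
    w = 2.0 * j / (1.0 + j)
    if transform == "mash":
        d = -np.log(w) / a.k
    elif transform == "binomial":
        d = 1.0 - w ** (1.0 / a.k)
    else:
        raise ValueError(f"unknown transform {transform!r}")
    return float(100.0 * (1.0 - d))


@dataclass
class ClusterSet:
    """A partition of genome ids into ANI clusters with quality-best representatives."""

    ani_threshold: float
    clusters: dict[str, list[str]] = field(default_factory=dict)  # representative -> members
    ani_to_representative: dict[str, float | None] = field(default_factory=dict)
    hash_name: str = HASH_NAME

    @property
    def representatives(self) -> list[str]:
        return list(self.clusters)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def cluster_of(self, genome_id: str) -> str:
        for rep, members in self.clusters.items():
            if genome_id in members:
                return rep
        raise KeyError(genome_id)

    def as_partition(self) -> list[frozenset[str]]:
        return [frozenset(m) for m in self.clusters.values()]


def greedy_cluster(
    genomes: Mapping[str, Sequence[SequenceRecord]],
    qualities: Mapping[str, GenomeQuality] | Iterable[GenomeQuality],
    ani_threshold: float = 95.0,
    inclusive: bool = True,
    k: int = 21,
    s: int = 5000,
    transform: Literal["binomial", "mash"] = "binomial",
    sketches: Mapping[str, Sketch] | None = None,
) -> ClusterSet:
    """Greedy dereplication at an ANI threshold.

    Genomes are visited in descending quality score (ties: longer total
    length, then lexicographic id). Each genome joins the existing
    representative with the highest estimated ANI meeting the threshold
    (``>=`` when inclusive, else ``>``), otherwise it founds a new cluster.
    Representatives therefore maximize quality within their cluster.
    """
    if not isinstance(qualities, Mapping):
        qualities = {q.genome_id: q for q in qualities}
    missing = set(genomes) - set(qualities)
    if missing:
        raise ValueError(f"qualities missing for genomes: {sorted(missing)}")
    if sketches is None:
        sketches = {gid: sketch(recs, k=k, s=s, genome_id=gid) for gid, recs in genomes.items()}
    order = sorted(
        genomes,
        key=lambda g: (-qualities[g].score, -sketches[g].total_length, g),
    )
    result = ClusterSet(ani_threshold=ani_threshold)
    for gid in order:
        best_rep: str | None = None
        best_ani = -np.inf
        for rep in result.clusters:
            ani = ani_estimate(sketches[gid], sketches[rep], transform=transform)
            if ani is None:
                continue
            meets = ani >= ani_threshold if inclusive else ani > ani_threshold
            if meets and ani > best_ani:
                best_rep, best_ani = rep, ani
        if best_rep is None:
            result.clusters[gid] = [gid]
            result.ani_to_representative[gid] = 100.0
        else:
            result.clusters[best_rep].append(gid)
            result.ani_to_representative[gid] = float(best_ani)
    return result
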