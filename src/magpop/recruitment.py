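"""Read-recruitment statistics for sequence-discrete populations.

Given gapless read alignments against a genome bin this module computes

* per-base :class:`DepthProfile` objects (bedtools-genomecov style),
* the truncated average depth :func:`tad` (TAD80 by default) — the mean
  per-base depth after discarding the top and bottom 10% of sorted positions,
  which is robust against conserved-region pile-ups and contig-edge dropoffs,
* depth-by-identity histograms and 2-D recruitment matrices,
* the sequence-discrete population cutoff (:func:`detect_cutoff`), an
  automated form of the visual rule "the identity at which coverage drops by
  3–4 orders of magnitude below the in-population peak",
* read-based average nucleotide identity :func:`anir`, the standard proxy for
  intra-population sequence diversity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .io_formats import DepthTrack, SequenceRecord, TabularAlignment

__all__ = [
    "DepthProfile",
    "IdentityHistogram",
    "PopulationCutoff",
    "RecruitmentMatrix",
    "NoRecruitedReads",
    "compute_depth",
    "tad",
    "identity_histogram",
    "detect_cutoff",
    "anir",
    "recruitment_matrix",
]


class NoRecruitedReads(ValueError):
    """No alignment passed the identity cutoff; ANIr is undefined (not zero)."""


@dataclass
class DepthProfile:
    """Per-base sequencing depth for every contig of one genome bin."""

    genome_id: str
    depths: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for contig, vec in self.depths.items():
            vec = np.asarray(vec, dtype=float)
            if vec.ndim != 1:
                raise ValueError(f"depth vector for {contig} is not 1-D")
            if np.any(vec < 0):
                raise ValueError(f"negative depth on contig {contig}")
            self.depths[contig] = vec

    @property
    def total_length(self) -> int:
        return int(sum(v.size for v in self.depths.values()))

    def concatenated(self) -> np.ndarray:
        """All per-base depths, contigs concatenated in insertion order."""
        if not self.depths:
            return np.empty(0, dtype=float)
        return np.concatenate(list(self.depths.values()))

    def mean(self) -> float:
        return float(self.concatenated().mean())

    def to_bedgraph_tracks(self) -> list[DepthTrack]:
        """Run-length encode the profile (genomecov ``-bga`` style, zeros included)."""
        tracks: list[DepthTrack] = []
        for contig, vec in self.depths.items():
            if vec.size == 0:
                continue
            change = np.flatnonzero(np.diff(vec)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [vec.size]))
            for s, e in zip(starts, ends):
                tracks.append(DepthTrack(contig, int(s), int(e), float(vec[s])))
        return tracks

    @classmethod
    def from_bedgraph_tracks(
        cls, genome_id: str, tracks: Iterable[DepthTrack], lengths: dict[str, int] | None = None
    ) -> "DepthProfile":
        """Rebuild a profile from BedGraph tracks; gaps are zero-depth."""
        tracks = list(tracks)
        if lengths is None:
            lengths = {}
            for t in tracks:
                lengths[t.contig] = max(lengths.get(t.contig, 0), t.end)
        depths = {c: np.zeros(n, dtype=float) for c, n in lengths.items()}
        for t in tracks:
            if t.contig not in depths:
                raise ValueError(f"track on unknown contig {t.contig!r}")
            if t.end > depths[t.contig].size:
                raise ValueError(f"track [{t.start}, {t.end}) exceeds contig {t.contig!r}")
            depths[t.contig][t.start : t.end] = t.depth
        return cls(genome_id, depths)


def compute_depth(
    alignments: Iterable[TabularAlignment], genome: Sequence[SequenceRecord], genome_id: str = ""
) -> DepthProfile:
    """Per-base depth: depth at base p = number of alignments covering p.

    Every alignment must map to a known contig and lie within its bounds.
    Implemented with difference arrays (one +1/-1 pair per alignment followed
    by a cumulative sum), equivalent to the brute-force per-base count.
    """
    lengths = {rec.id: len(rec) for rec in genome}
    diffs = {c: np.zeros(n + 1, dtype=float) for c, n in lengths.items()}
    for a in alignments:
        if a.sseqid not in diffs:
            raise ValueError(f"alignment of {a.qseqid!r} to unknown contig {a.sseqid!r}")
        if a.subject_end > lengths[a.sseqid]:
            raise ValueError(
                f"alignment of {a.qseqid!r} exceeds contig {a.sseqid!r}: "
                f"[{a.subject_start}, {a.subject_end}) on {lengths[a.sseqid]} bp"
            )
        diffs[a.sseqid][a.subject_start] += 1.0
        diffs[a.sseqid][a.subject_end] -= 1.0
    gid = genome_id or (genome[0].id.split("|")[0] if genome else "")
    return DepthProfile(gid, {c: np.cumsum(d[:-1]) for c, d in diffs.items()})


def tad(profile: DepthProfile, central_fraction: float = 0.8) -> float:
    """Truncated average depth over all bases of the genome.

    Per-base depths of all contigs are concatenated (zero-coverage positions
    included), sorted ascending, and ``floor(((1 - central_fraction)/2) * L)``
    positions are dropped from each end before taking the arithmetic mean.
    ``central_fraction=0.8`` is the conventional TAD80.
    """
    if not (0.0 < central_fraction <= 1.0):
        raise ValueError(f"central_fraction must be in (0, 1], got {central_fraction}")
    vec = profile.concatenated()
    if vec.size == 0:
        raise ValueError("cannot compute TAD of an empty depth profile")
    # epsilon guards float noise: (1-0.8)/2*10 is 0.999... in binary
    k = math.floor((1.0 - central_fraction) / 2.0 * vec.size + 1e-9)
    if 2 * k >= vec.size:
        raise ValueError(
            f"truncation removes all {vec.size} positions (central_fraction={central_fraction})"
        )
    vec = np.sort(vec)
    return float(vec[k : vec.size - k].mean())


@dataclass
class IdentityHistogram:
    """Recruited aligned bases binned by percent identity, as depth per bin.

    ``edges`` are the ascending lower bin edges covering [lo, hi]; a pident
    exactly on an edge belongs to the upper bin, and pident == hi falls in the
    top bin.  ``bases[i]`` is the aligned-base total of bin i; ``depth`` is
    bases divided by genome length.
    """

    edges: np.ndarray
    bases: np.ndarray
    bin_width: float
    genome_length: int

    @property
    def depth(self) -> np.ndarray:
        return self.bases / float(self.genome_length)

    @property
    def total_bases(self) -> float:
        return float(self.bases.sum())


def _bin_index(pident: float, lo: float, width: float, n_bins: int) -> int | None:
    if pident < lo:
        return None
    idx = int(math.floor((pident - lo) / width + 1e-9))
    return min(idx, n_bins - 1)


def identity_histogram(
    alignments: Iterable[TabularAlignment],
    genome_length: int,
    bin_width: float = 0.5,
    lo: float = 70.0,
    hi: float = 100.0,
) -> IdentityHistogram:
    """Histogram of aligned bases by percent identity, normalized to depth.

    Each alignment contributes its aligned length to the bin containing its
    pident; alignments below ``lo`` are out of range and ignored.
    """
    if genome_length < 1:
        raise ValueError("genome_length must be >= 1")
    span = hi - lo
    n_bins = round(span / bin_width)
    if abs(n_bins * bin_width - span) > 1e-9 or n_bins < 1:
        raise ValueError(f"bin_width {bin_width} does not divide the [{lo}, {hi}] span")
    bases = np.zeros(n_bins, dtype=float)
    for a in alignments:
        if not (0.0 <= a.pident <= 100.0):
            raise ValueError(f"pident outside [0, 100]: {a.pident}")
        idx = _bin_index(a.pident, lo, bin_width, n_bins)
        if idx is not None:
            bases[idx] += a.length
    edges = lo + bin_width * np.arange(n_bins)
    return IdentityHistogram(edges, bases, bin_width, genome_length)


@dataclass
class PopulationCutoff:
    """Detected identity cutoff separating a sequence-discrete population."""

    cutoff: float
    discontinuity_found: bool
    peak_depth: float
    drop_ratio: float


def detect_cutoff(
    hist: IdentityHistogram,
    drop_orders: float = 3.0,
    floor: float = 95.0,
    require_resumption: bool = True,
) -> PopulationCutoff:
    """Locate the identity below which recruitment collapses by ``drop_orders``.

    Scanning from the peak bin toward lower identity, the cutoff is the lower
    edge of the last bin whose depth stays >= peak * 10**(-drop_orders) before
    the first bin that falls below that threshold.

    With ``require_resumption=True`` (default) the drop only counts as a
    population boundary if recruitment climbs back above the threshold at
    lower identity — i.e. there is a discrete second cluster (sister
    population or background) on the far side of the gap.  A clean
    single-population histogram, whose tail simply dies out, then reports
    ``discontinuity_found=False`` and the configured ``floor`` as cutoff.
    ``require_resumption=False`` treats any sub-threshold bin as the boundary.
    """
    depth = hist.depth
    if depth.size == 0 or depth.sum() <= 0:
        raise ValueError("cannot detect a cutoff on an all-zero histogram")
    # highest-identity peak bin wins ties
    peak_idx = depth.size - 1 - int(np.argmax(depth[::-1]))
    peak = float(depth[peak_idx])
    thr = peak * 10.0 ** (-drop_orders)

    gap_idx: int | None = None
    for i in range(peak_idx - 1, -1, -1):
        if depth[i] < thr:
            gap_idx = i
            break

    if gap_idx is None:
        scanned = depth[:peak_idx] if peak_idx > 0 else depth[: peak_idx + 1]
        ratio = peak / max(float(scanned.min()), 1e-300)
        return PopulationCutoff(floor, False, peak, ratio)

    ratio = peak / max(float(depth[gap_idx]), 1e-300)
    if require_resumption and not np.any(depth[:gap_idx] >= thr):
        return PopulationCutoff(floor, False, peak, ratio)
    return PopulationCutoff(float(hist.edges[gap_idx + 1]), True, peak, ratio)


def anir(
    alignments: Iterable[TabularAlignment],
    cutoff: float,
    weighting: Literal["aligned_bases", "per_read"] = "aligned_bases",
) -> float:
    """Read-based average nucleotide identity over reads recruited above ``cutoff``.

    ``aligned_bases`` weights each alignment's identity by its aligned length
    (a base-level average); ``per_read`` is the unweighted mean over reads.
    Raises :class:`NoRecruitedReads` when nothing passes the cutoff.
    """
    if weighting not in ("aligned_bases", "per_read"):
        raise ValueError(f"unknown weighting {weighting!r}")
    pid_sum = 0.0
    weight_sum = 0.0
    for a in alignments:
        if a.pident >= cutoff:
            w = float(a.length) if weighting == "aligned_bases" else 1.0
            pid_sum += a.pident * w
            weight_sum += w
    if weight_sum == 0.0:
        raise NoRecruitedReads(f"no reads recruited at >= {cutoff}% identity")
    return pid_sum / weight_sum


@dataclass
class RecruitmentMatrix:
    """Aligned bases binned by (genome position, percent identity).

    Positions are on the concatenated-genome axis (contigs laid end to end in
    FASTA order); alignments are assigned to position bins by their midpoint.
    The identity marginal equals the :class:`IdentityHistogram` of the same
    alignments times genome length.
    """

    genome_id: str
    position_edges: np.ndarray
    identity_edges: np.ndarray
    matrix: np.ndarray  # shape (n_position_bins, n_identity_bins), aligned bases
    contig_offsets: dict[str, int]

    @property
    def identity_marginal(self) -> np.ndarray:
        return self.matrix.sum(axis=0)

    @property
    def position_marginal(self) -> np.ndarray:
        return self.matrix.sum(axis=1)


def recruitment_matrix(
    alignments: Iterable[TabularAlignment],
    genome: Sequence[SequenceRecord],
    position_bin: int = 1000,
    identity_bin: float = 0.5,
    lo: float = 70.0,
    hi: float = 100.0,
    genome_id: str = "",
) -> RecruitmentMatrix:
    """2-D recruitment plot substrate: aligned bases per (position, identity) cell."""
    if position_bin < 1:
        raise ValueError("position_bin must be >= 1")
    span = hi - lo
    n_ident = round(span / identity_bin)
    if abs(n_ident * identity_bin - span) > 1e-9 or n_ident < 1:
        raise ValueError(f"identity_bin {identity_bin} does not divide the [{lo}, {hi}] span")
    offsets: dict[str, int] = {}
    total = 0
    lengths: dict[str, int] = {}
    for rec in genome:
        offsets[rec.id] = total
        lengths[rec.id] = len(rec)
        total += len(rec)
    n_pos = max(1, math.ceil(total / position_bin))
    mat = np.zeros((n_pos, n_ident), dtype=float)
    for a in alignments:
        if a.sseqid not in offsets:
            raise ValueError(f"alignment of {a.qseqid!r} to unknown contig {a.sseqid!r}")
        if a.subject_end > lengths[a.sseqid]:
            raise ValueError(f"alignment of {a.qseqid!r} exceeds contig {a.sseqid!r}")
        iid = _bin_index(a.pident, lo, identity_bin, n_ident)
        if iid is None:
            continue
        mid = offsets[a.sseqid] + (a.subject_start + a.subject_end - 1) // 2
        mat[min(mid // position_bin, n_pos - 1), iid] += a.length
    pos_edges = position_bin * np.arange(n_pos + 1)
    pos_edges[-1] = total
    ident_edges = lo + identity_bin * np.arange(n_ident)
    return RecruitmentMatrix(genome_id, pos_edges, ident_edges, mat, offsets)
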