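"""End-to-end recovery experiments on synthetic communities.

Each experiment builds a community with :mod:`magpop.synthetic`, runs the
production code path (truth alignments -> depth -> TAD -> marker depth ->
abundance -> cutoff -> ANIr, or sketch -> ANI -> clustering), and returns the
measured quantities next to their ground truth. The same functions back the
test suite and ``scripts/acceptance.py``; problem sizes are desk-scale
(100-300 kb genomes, tens of thousands of reads) as documented in
``docs/methods.md``.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from . import abundance as ab
from . import dereplication as derep
from . import recruitment as rec
from . import synthetic as syn

__all__ = [
    "reference_mags",
    "group_mean_lengths",
    "prevalence_reference_values",
    "anir_recovery",
    "cutoff_detection",
    "abundance_recovery",
    "dereplication_recovery",
    "minhash_accuracy",
]


def _subseeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(x) for x in rng.integers(0, 2**31 - 1, size=n)]


# ---------------------------------------------------------------------------
# printed-table arithmetic


def reference_mags() -> pd.DataFrame:
    """The eleven representative Helgoland archaeal MAGs (published statistics)."""
    with resources.files("magpop.data").joinpath("helgoland_archaeal_mags.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def group_mean_lengths() -> dict[str, float]:
    """Mean genome length (Mbp, one decimal) per MAG group."""
    df = reference_mags()
    means = df.groupby("group")["length_mbp"].mean()
    return {g: round(float(v), 1) for g, v in means.items()}


def prevalence_reference_values() -> tuple[float, float]:
    """Prevalence of a genome detected in 25/38 samples and in a 9/10 subset."""
    det = pd.DataFrame(
        [[i < 25 for i in range(38)]],
        index=["MGIIa_c6"],
        columns=[f"s{i}" for i in range(38)],
    )
    overall = ab.prevalence(det)["MGIIa_c6"]
    post_bloom = [f"s{i}" for i in range(10)]
    det_post = pd.DataFrame(
        [[i < 9 for i in range(10)]], index=["MGIIa_c6"], columns=post_bloom
    )
    post = ab.prevalence(det_post, subset=post_bloom)["MGIIa_c6"]
    return float(overall), float(post)


# ---------------------------------------------------------------------------
# simulation experiments


def _single_population(
    pop_id: str,
    genome_length: int,
    divergence: float,
    seed: int,
    gc: float = 0.5,
    abundance: float = 1.0,
) -> syn.Community:
    spec = syn.PopulationSpec(
        id=pop_id, genome_length=genome_length, abundance=abundance,
        gc=gc, divergence=divergence,
    )
    genome = syn.generate_genome(genome_length, gc, seed, genome_id=pop_id)
    return syn.Community([spec], {pop_id: genome}, {pop_id: (0, spec.marker_length)})


@dataclass
class AnirRecovery:
    anir: float
    expected: float
    n_reads: int
    cutoff: float


def anir_recovery(
    seed: int,
    depth: float = 50.0,
    genome_length: int = 100_000,
    read_length: int = 500,
    delta: float = 0.004,
    epsilon: float = 0.001,
    cutoff: float = 98.0,
) -> AnirRecovery:
    """Simulate a clonal population and recover ANIr above the cutoff.

    Expected ANIr is 100*(1 - delta - epsilon); at >= 50x depth the
    base-weighted estimate should sit within 0.1 points of it.
    """
    s1, s2 = _subseeds(seed, 2)
    community = _single_population("pop1", genome_length, delta, s1)
    n_reads = int(round(depth * genome_length / read_length))
    config = syn.SimulationConfig(
        seed=s2, total_reads=n_reads, read_length=read_length, error_rate=epsilon
    )
    reads, truth = syn.generate_reads(community, config)
    alignments = syn.truth_align(reads, truth)
    value = rec.anir(alignments, cutoff=cutoff)
    return AnirRecovery(value, 100.0 * (1.0 - delta - epsilon), n_reads, cutoff)


@dataclass
class CutoffDetection:
    cutoff: rec.PopulationCutoff
    histogram: rec.IdentityHistogram
    sister_present: bool


def cutoff_detection(
    seed: int,
    with_sister: bool = True,
    sister_ani: float = 92.0,
    depth: float = 50.0,
    genome_length: int = 200_000,
    read_length: int = 500,
    delta: float = 0.004,
    epsilon: float = 0.001,
    drop_orders: float = 3.0,
    floor: float = 95.0,
) -> CutoffDetection:
    """Two-population recruitment to one reference; find the identity gap.

    The focal population recruits at ~100*(1-delta-epsilon)% identity; a
    sister clade at ``sister_ani`` co-recruits at equal depth. With the
    sister present the histogram is bimodal and a >= 10**drop_orders coverage
    gap separates the clusters; without it the in-population tail simply dies
    out and no discontinuity is reported.
    """
    s1, s2, s3, s4 = _subseeds(seed, 4)
    focal = _single_population("focal", genome_length, delta, s1)
    n_reads = int(round(depth * genome_length / read_length))
    config = syn.SimulationConfig(
        seed=s2, total_reads=n_reads, read_length=read_length, error_rate=epsilon
    )
    reads_f, truth_f = syn.generate_reads(focal, config)
    alignments = syn.truth_align(reads_f, truth_f)

    if with_sister:
        sister_genome = syn.derive_relative(
            focal.genomes["focal"], 1.0 - sister_ani / 100.0, s3, genome_id="sister"
        )
        sister = syn.Community(
            [syn.PopulationSpec(id="sister", genome_length=genome_length,
                                abundance=1.0, divergence=delta)],
            {"sister": sister_genome},
            {"sister": (0, 4000)},
        )
        reads_s, truth_s = syn.generate_reads(
            sister,
            syn.SimulationConfig(seed=s4, total_reads=n_reads,
                                 read_length=read_length, error_rate=epsilon),
        )
        # sister reads recruited onto the focal reference (colinear genomes)
        alignments += syn.truth_align(
            reads_s, truth_s, references={"sister": focal.genomes["focal"]}
        )

    hist = rec.identity_histogram(alignments, genome_length)
    cut = rec.detect_cutoff(hist, drop_orders=drop_orders, floor=floor)
    return CutoffDetection(cut, hist, with_sister)


def abundance_recovery(
    seed: int,
    abundances: tuple[float, ...] = (0.40, 0.30, 0.15, 0.10, 0.05),
    genome_length: int = 100_000,
    read_length: int = 150,
    total_reads: int = 80_000,
    delta: float = 0.004,
    epsilon: float = 0.001,
) -> pd.DataFrame:
    """Full pipeline on a multi-population community with known proportions.

    Returns one row per population with the true proportion, the TAD80 /
    marker-depth estimate, and the relative error. Default settings give
    ~120x pooled marker depth, comfortably above the 100x regime where
    proportions should be recovered within 20% relative error.
    """
    s1, s2 = _subseeds(seed, 2)
    gcs = np.linspace(0.375, 0.505, len(abundances))
    specs = [
        syn.PopulationSpec(
            id=f"pop{i+1}", genome_length=genome_length, abundance=a,
            gc=float(g), divergence=delta,
        )
        for i, (a, g) in enumerate(zip(abundances, gcs))
    ]
    community = syn.build_community(specs, s1)
    config = syn.SimulationConfig(
        seed=s2, total_reads=total_reads, read_length=read_length, error_rate=epsilon
    )
    reads, truth = syn.generate_reads(community, config)
    alignments = syn.truth_align(reads, truth)
    marker_hits = syn.emit_marker_hits(reads, truth)
    marker = ab.marker_depth(
        ab.simple_marker_filter(marker_hits),
        [p.marker_length for p in specs],
        sample_id="sim",
    )

    by_contig: dict[str, list] = {p.id: [] for p in specs}
    for a in alignments:
        by_contig[a.sseqid].append(a)
    rows = []
    for p in specs:
        profile = rec.compute_depth(by_contig[p.id], [community.genomes[p.id]], genome_id=p.id)
        tad80 = rec.tad(profile, central_fraction=0.8)
        est = ab.relative_abundance(tad80, marker)
        rows.append(
            {
                "population": p.id,
                "true_proportion": p.abundance,
                "tad80": tad80,
                "estimated_proportion": est,
                "relative_error": abs(est - p.abundance) / p.abundance,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["marker_depth"] = marker.depth
    return df


@dataclass
class DereplicationRecovery:
    clusters_95: derep.ClusterSet
    clusters_99: derep.ClusterSet
    truth_partition: list[frozenset[str]]
    qualities: dict[str, derep.GenomeQuality]


def dereplication_recovery(
    seed: int, genome_length: int = 200_000, n_groups: int = 3
) -> DereplicationRecovery:
    """Ten genomes in three known groups, clustered at 95% and 99% ANI.

    Within-group pairwise ANI is >= 99.5% (derived at divergences <= 0.0025);
    between-group genomes are independent random sequences (ANI far below
    90%, beneath MinHash resolution).
    """
    rng = np.random.default_rng(seed)
    group_sizes = [4, 3, 3][:n_groups]
    divergences = [0.0, 0.001, 0.0015, 0.0025]
    genomes: dict[str, list] = {}
    qualities: dict[str, derep.GenomeQuality] = {}
    truth: list[frozenset[str]] = []
    for g, size in enumerate(group_sizes):
        base = syn.generate_genome(
            genome_length, 0.40 + 0.08 * g, int(rng.integers(2**31 - 1)),
            genome_id=f"g{g}_m0",
        )
        members = []
        for m in range(size):
            gid = f"g{g}_m{m}"
            if m == 0:
                rec_ = base
            else:
                rec_ = syn.derive_relative(
                    base, divergences[m], int(rng.integers(2**31 - 1)), genome_id=gid
                )
            genomes[gid] = [rec_]
            qualities[gid] = derep.GenomeQuality(
                gid,
                completeness=float(95.0 - 5.0 * m - g),
                contamination=float(0.5 * m),
            )
            members.append(gid)
        truth.append(frozenset(members))
    c95 = derep.greedy_cluster(genomes, qualities, ani_threshold=95.0)
    c99 = derep.greedy_cluster(genomes, qualities, ani_threshold=99.0)
    return DereplicationRecovery(c95, c99, truth, qualities)


def minhash_accuracy(
    seed: int,
    divergences: tuple[float, ...] = (0.01, 0.03, 0.05, 0.08, 0.10),
    genome_length: int = 300_000,
    k: int = 21,
    s: int = 20_000,
) -> pd.DataFrame:
    """MinHash ANI versus the realized ANI of genome pairs at known divergence.

    The sketch size (20k) keeps the Jaccard sampling error of the estimate
    well under the +/-0.5 point band even at 10% divergence.
    """
    rng = np.random.default_rng(seed)
    base = syn.generate_genome(genome_length, 0.5, int(rng.integers(2**31 - 1)), "base")
    sk_base = derep.sketch([base], k=k, s=s)
    rows = []
    for d in divergences:
        other = syn.derive_relative(base, d, int(rng.integers(2**31 - 1)), f"d{d:g}")
        mismatches = sum(x != y for x, y in zip(base.sequence, other.sequence))
        realized_ani = 100.0 * (1.0 - mismatches / genome_length)
        est = derep.ani_estimate(sk_base, derep.sketch([other], k=k, s=s))
        rows.append(
            {
                "divergence": d,
                "realized_ani": realized_ani,
                "estimated_ani": est,
                "abs_error": abs(est - realized_ani),
            }
        )
    return pd.DataFrame(rows)
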