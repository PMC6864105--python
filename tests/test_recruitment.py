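"""Depth profiles, TAD, identity histograms, cutoff detection, ANIr."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from magpop.io_formats import SequenceRecord
from magpop.recruitment import (
    DepthProfile,
    IdentityHistogram,
    NoRecruitedReads,
    anir,
    compute_depth,
    detect_cutoff,
    identity_histogram,
    recruitment_matrix,
    tad,
)
from magpop import synthetic as syn


def profile_of(*vectors):
    return DepthProfile("g", {f"c{i}": np.asarray(v, float) for i, v in enumerate(vectors)})


class TestComputeDepth:
    def test_overlapping_intervals(self, make_aln):
        genome = [SequenceRecord("c1", "A" * 20)]
        alns = [make_aln(99.0, length=10, sstart=1), make_aln(99.0, length=10, sstart=6)]
        prof = compute_depth(alns, genome)
        expected = [1] * 5 + [2] * 5 + [1] * 5 + [0] * 5
        assert prof.depths["c1"].tolist() == expected

    def test_no_alignments_all_zero(self):
        prof = compute_depth([], [SequenceRecord("c1", "ACGT" * 5)])
        assert prof.depths["c1"].sum() == 0
        assert prof.total_length == 20

    def test_unknown_contig_and_out_of_bounds(self, make_aln):
        genome = [SequenceRecord("c1", "A" * 50)]
        with pytest.raises(ValueError, match="unknown contig"):
            compute_depth([make_aln(99.0, length=10, contig="nope")], genome)
        with pytest.raises(ValueError, match="exceeds contig"):
            compute_depth([make_aln(99.0, length=10, sstart=45)], genome)

    def test_matches_brute_force_count(self, make_aln, rng):
        """1000 random 100 bp reads on a 10 kb contig: diff-array == per-base loop."""
        L, n, rl = 10_000, 1000, 100
        genome = [SequenceRecord("c1", "A" * L)]
        starts = rng.integers(1, L - rl + 2, size=n)
        alns = [make_aln(99.0, length=rl, sstart=int(s)) for s in starts]
        prof = compute_depth(alns, genome)
        brute = np.zeros(L)
        for s in starts:
            brute[s - 1 : s - 1 + rl] += 1
        assert np.array_equal(prof.depths["c1"], brute)
        assert prof.mean() == pytest.approx(n * rl / L, rel=0.1)

    def test_bedgraph_round_trip(self):
        prof = profile_of([0, 0, 1, 2, 2, 0], [3, 3, 3])
        back = DepthProfile.from_bedgraph_tracks(
            "g", prof.to_bedgraph_tracks(), {"c0": 6, "c1": 3}
        )
        for c in prof.depths:
            assert np.array_equal(back.depths[c], prof.depths[c])


class TestTad:
    @pytest.mark.parametrize(
        "vectors, cf, expected",
        [
            ([[7.0] * 10], 0.8, 7.0),
            ([[0, 0, 1, 1, 1, 1, 1, 1, 100, 100]], 0.8, 13.25),
            ([[2, 4, 6]], 1.0, 4.0),
            ([[0, 1], [1, 1, 1, 1, 100, 100, 0, 1]], 0.8, 13.25),  # contigs concatenated
        ],
    )
    def test_examples(self, vectors, cf, expected):
        assert tad(profile_of(*vectors), cf) == pytest.approx(expected)

    def test_empty_profile_errors(self):
        with pytest.raises(ValueError):
            tad(profile_of([]))
        with pytest.raises(ValueError, match="central_fraction"):
            tad(profile_of([1, 2, 3]), central_fraction=1.5)

    @given(
        st.lists(st.floats(min_value=0, max_value=1e4), min_size=5, max_size=60),
        st.floats(min_value=0.3, max_value=1.0),
    )
    def test_permutation_invariant_and_bounded(self, depths, cf):
        p1 = profile_of(depths)
        p2 = profile_of(list(reversed(depths)))
        v = tad(p1, cf)
        assert v == tad(p2, cf)
        assert min(depths) - 1e-9 <= v <= max(depths) + 1e-9

    @given(
        st.lists(st.floats(min_value=0, max_value=100), min_size=5, max_size=40),
        st.floats(min_value=0, max_value=5),
    )
    def test_scales_linearly(self, depths, c):
        base = tad(profile_of(depths))
        scaled = tad(profile_of([c * d for d in depths]))
        assert scaled == pytest.approx(c * base, abs=1e-6)


class TestIdentityHistogram:
    def test_single_read_top_bin(self, make_aln):
        hist = identity_histogram([make_aln(100.0, length=100)], genome_length=1000)
        assert hist.depth[-1] == pytest.approx(0.1)
        assert hist.depth[:-1].sum() == 0

    def test_edge_goes_to_upper_bin(self, make_aln):
        hist = identity_histogram([make_aln(98.0, length=50)], genome_length=100)
        idx = int(np.flatnonzero(hist.bases)[0])
        assert hist.edges[idx] == 98.0  # bin [98.0, 98.5)

    def test_conserves_in_range_bases(self, make_aln, rng):
        pidents = rng.uniform(71, 100, size=200).round(2)
        lengths = rng.integers(50, 150, size=200)
        alns = [make_aln(float(p), length=int(l)) for p, l in zip(pidents, lengths)]
        hist = identity_histogram(alns, genome_length=10_000)
        assert hist.total_bases == pytest.approx(lengths.sum())
        # brute-force tally of one arbitrary bin
        lo = hist.edges[10]
        expected = sum(int(l) for p, l in zip(pidents, lengths) if lo <= p < lo + 0.5)
        assert hist.bases[10] == pytest.approx(expected)

    def test_below_range_ignored_but_invalid_rejected(self, make_aln):
        hist = identity_histogram([make_aln(60.0, length=10)], genome_length=100)
        assert hist.total_bases == 0
        from types import SimpleNamespace

        with pytest.raises(ValueError, match="pident"):
            identity_histogram([SimpleNamespace(pident=150.0, length=10)], 100)

    def test_bimodal_from_generator(self, rng):
        """In-population (~99.5%) and sister (~92%) reads produce two separated modes."""
        spec = syn.PopulationSpec(id="p", genome_length=20_000, abundance=1.0, divergence=0.004)
        genome = syn.generate_genome(20_000, 0.5, 7, genome_id="p")
        comm = syn.Community([spec], {"p": genome}, {"p": (0, 4000)})
        cfg = syn.SimulationConfig(seed=8, total_reads=2000, read_length=500, error_rate=0.001)
        reads, truth = syn.generate_reads(comm, cfg)
        sister = syn.derive_relative(genome, 0.08, 9, genome_id="s")
        alns = syn.truth_align(reads, truth) + syn.truth_align(
            reads, truth, references={"p": sister}
        )
        hist = identity_histogram(alns, 20_000)
        peaks = hist.edges[hist.depth > 0.2 * hist.depth.max()]
        assert peaks.min() < 94 and peaks.max() > 98.5


def hist_from_depth(depth_by_edge: dict[float, float]) -> IdentityHistogram:
    edges = 70.0 + 0.5 * np.arange(60)
    bases = np.zeros(60)
    for edge, d in depth_by_edge.items():
        bases[int(round((edge - 70.0) / 0.5))] = d
    return IdentityHistogram(edges, bases, 0.5, genome_length=1)


class TestDetectCutoff:
    BIMODAL = {99.5: 800.0, 99.0: 300.0, 98.5: 40.0, 98.0: 6.0, 97.5: 0.0005, 92.0: 500.0}

    def test_gap_with_resumption_is_a_population_boundary(self):
        cut = detect_cutoff(hist_from_depth(self.BIMODAL))
        assert cut.cutoff == 98.0
        assert cut.discontinuity_found
        assert cut.drop_ratio >= 1e3

    def test_trailing_void_not_a_boundary_by_default(self):
        tail_only = {k: v for k, v in self.BIMODAL.items() if k != 92.0}
        cut = detect_cutoff(hist_from_depth(tail_only))
        assert not cut.discontinuity_found
        assert cut.cutoff == 95.0  # configured floor

    def test_trailing_void_counts_under_literal_rule(self):
        tail_only = {k: v for k, v in self.BIMODAL.items() if k != 92.0}
        cut = detect_cutoff(hist_from_depth(tail_only), require_resumption=False)
        assert cut.cutoff == 98.0
        assert cut.discontinuity_found

    def test_single_spike_literal_rule(self):
        cut = detect_cutoff(hist_from_depth({99.5: 10.0}), require_resumption=False)
        assert cut.cutoff == 99.5
        assert cut.discontinuity_found

    def test_uniform_histogram_returns_floor(self):
        edges = 70.0 + 0.5 * np.arange(60)
        hist = IdentityHistogram(edges, np.full(60, 5.0), 0.5, 1)
        cut = detect_cutoff(hist)
        assert cut.cutoff == 95.0
        assert not cut.discontinuity_found

    def test_all_zero_errors(self):
        edges = 70.0 + 0.5 * np.arange(60)
        with pytest.raises(ValueError):
            detect_cutoff(IdentityHistogram(edges, np.zeros(60), 0.5, 1))


class TestAnir:
    def test_all_perfect_reads(self, make_aln):
        assert anir([make_aln(100.0) for _ in range(5)], cutoff=98.0) == 100.0

    def test_weighting_modes(self, make_aln):
        alns = [make_aln(99.0, length=100), make_aln(100.0, length=300)]
        assert anir(alns, 98.0, "aligned_bases") == pytest.approx(99.75)
        assert anir(alns, 98.0, "per_read") == pytest.approx(99.5)

    def test_cutoff_filters(self, make_aln):
        alns = [make_aln(97.0), make_aln(99.5)]
        assert anir(alns, 98.0) == pytest.approx(99.5)

    def test_no_recruited_reads_is_an_error(self, make_aln):
        with pytest.raises(NoRecruitedReads):
            anir([make_aln(90.0)], cutoff=98.0)
        with pytest.raises(ValueError, match="weighting"):
            anir([make_aln(99.0)], 98.0, "bogus")

    @given(st.lists(st.floats(min_value=70, max_value=100), min_size=1, max_size=50))
    def test_monotone_in_cutoff_and_bounded(self, pidents):
        from magpop.io_formats import TabularAlignment

        alns = [
            TabularAlignment("q", "s", round(p, 3), 100, 0, 0, 1, 100, 1, 100, 0.0, 1.0)
            for p in pidents
        ]
        cutoffs = [70.0, 80.0, 90.0, 95.0]
        values = []
        for c in cutoffs:
            try:
                v = anir(alns, c)
            except NoRecruitedReads:
                break
            assert c <= v <= 100.0
            values.append(v)
        assert values == sorted(values)


class TestRecruitmentMatrix:
    def test_single_read_single_cell(self, make_aln):
        genome = [SequenceRecord("c1", "A" * 5000)]
        mat = recruitment_matrix([make_aln(99.2, length=100, sstart=1500)], genome)
        assert (mat.matrix > 0).sum() == 1
        assert mat.matrix.sum() == 100

    def test_empty_alignments(self):
        mat = recruitment_matrix([], [SequenceRecord("c1", "A" * 12000)])
        assert mat.matrix.sum() == 0

    def test_identity_marginal_matches_histogram(self, make_aln, rng):
        genome = [SequenceRecord("c1", "A" * 9000), SequenceRecord("c2", "A" * 6000)]
        alns = []
        for _ in range(300):
            contig, clen = ("c1", 9000) if rng.random() < 0.6 else ("c2", 6000)
            alns.append(
                make_aln(
                    float(rng.uniform(75, 100)),
                    length=100,
                    sstart=int(rng.integers(1, clen - 100)),
                    contig=contig,
                )
            )
        mat = recruitment_matrix(alns, genome)
        hist = identity_histogram(alns, genome_length=15_000)
        assert np.allclose(mat.identity_marginal, hist.depth * 15_000)
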