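from collections import Counter

import numpy as np
import pytest

from readmimic import (
    GenomicInterval,
    ProfileError,
    ReferenceGenome,
    SimulationConfig,
    SimulationError,
    ValidationError,
    compute_profile,
    filter_ambiguous,
    profile_distance,
    reverse_complement,
    sample_candidate,
    sample_candidate_from_reads,
    score_read,
    select_candidate,
    simulate,
)
from readmimic.core import PSEUDOCOUNT, _GenomeSampler, generate_biased_reads
from tests.conftest import reads_from_strings, single_position_profile


class TestFilterAmbiguous:
    def test_discards_reads_with_n(self):
        retained, discarded = filter_ambiguous(
            reads_from_strings(["ACGT", "ACNT", "TTTT"])
        )
        assert [r.sequence for r in retained] == ["ACGT", "TTTT"]
        assert discarded == 1

    def test_clean_input_untouched(self):
        reads = reads_from_strings(["ACGT", "TTTT"])
        retained, discarded = filter_ambiguous(reads)
        assert retained == list(reads)
        assert discarded == 0

    def test_nothing_left_is_an_error(self):
        with pytest.raises(SimulationError):
            filter_ambiguous(reads_from_strings(["NNNN"]))


class TestSampleCandidate:
    def test_single_valid_position(self, rng):
        genome = ReferenceGenome({"chr1": "AAAA"})
        seq, iv = sample_candidate(genome, None, 4, rng)
        assert seq in ("AAAA", "TTTT")
        assert (iv.chrom, iv.start, iv.end) == ("chr1", 0, 4)

    def test_minus_strand_is_reverse_complement(self, rng):
        genome = ReferenceGenome({"chr1": "ACGTTTGCA"})
        for _ in range(30):
            seq, iv = sample_candidate(genome, None, 5, rng)
            ref = genome.fetch(iv.chrom, iv.start, iv.end)
            assert seq == (reverse_complement(ref) if iv.strand == "-" else ref)

    def test_region_restriction_contract(self, rng):
        genome = ReferenceGenome({"chr1": "ACGT" * 25})
        regions = [GenomicInterval("chr1", 10, 20)]
        for _ in range(50):
            _, iv = sample_candidate(genome, regions, 5, rng)
            assert 10 <= iv.start and iv.end <= 20

    def test_draws_proportional_to_valid_positions(self, rng):
        # valid starts: chr1 120-21+1=100, chr2 60-21+1=40
        genome = ReferenceGenome(
            {"chr1": "ACGT" * 30, "chr2": "TGCA" * 15}
        )
        sampler = _GenomeSampler(genome)
        _, intervals = sampler.draw(21, 100_000, rng)
        counts = Counter(iv.chrom for iv in intervals)
        p = 100 / 140
        sd = np.sqrt(p * (1 - p) * 100_000)
        assert abs(counts["chr1"] - p * 100_000) < 4 * sd

    def test_candidates_never_contain_n(self, rng):
        genome = ReferenceGenome({"chr1": "ACGTN" * 40})
        for _ in range(100):
            seq, _ = sample_candidate(genome, None, 3, rng)
            assert "N" not in seq

    def test_all_n_reference_aborts(self, rng):
        genome = ReferenceGenome({"chr1": "N" * 50})
        with pytest.raises(SimulationError, match="consecutive"):
            sample_candidate(genome, None, 5, rng)

    def test_no_valid_position_is_an_error(self, rng):
        genome = ReferenceGenome({"chr1": "ACGT"})
        with pytest.raises(SimulationError, match="length 10"):
            sample_candidate(genome, None, 10, rng)


class TestSampleCandidateFromReads:
    def test_single_choice(self, rng):
        src = reads_from_strings(["ACGTACGT"])
        assert sample_candidate_from_reads(src, 8, rng) == "ACGTACGT"

    def test_too_short_sources_skipped(self, rng):
        src = reads_from_strings(["AAAA", "CC"])
        assert sample_candidate_from_reads(src, 4, rng) == "AAAA"

    def test_weighted_by_valid_start_positions(self, rng):
        # "AAAA" has 1 valid start, "CCCCC" has 2 -> AAAA with prob 1/3
        src = reads_from_strings(["AAAA", "CCCCC"])
        n = 30_000
        hits = sum(
            sample_candidate_from_reads(src, 4, rng)[0] == "A" for _ in range(n)
        )
        sd = np.sqrt((1 / 3) * (2 / 3) * n)
        assert abs(hits - n / 3) < 4 * sd

    def test_no_source_long_enough(self, rng):
        with pytest.raises(SimulationError):
            sample_candidate_from_reads(reads_from_strings(["ACG"]), 10, rng)


class TestScoreRead:
    def test_uniform_profile_scores_all_sequences_equally(self):
        prof = compute_profile(reads_from_strings(["ACGT", "CAGT", "GTCA", "TGAC"]))
        # not uniform; build an exactly uniform one instead
        prof.freqs[4][:] = 0.25
        expected = 4 * np.log(0.25 + PSEUDOCOUNT)
        for seq in ("ACGT", "TTTT", "GGCC"):
            assert score_read(seq, prof) == pytest.approx(expected)

    def test_point_mass_monotonicity(self):
        prof = compute_profile(reads_from_strings(["ACGT"] * 10))
        assert score_read("ACGT", prof) > score_read("ACGA", prof)

    def test_closed_form_difference(self):
        prof = compute_profile(reads_from_strings(["AA", "AA", "AA", "CA"]))
        diff = score_read("AA", prof) - score_read("CA", prof)
        expected = np.log((0.75 + PSEUDOCOUNT) / (0.25 + PSEUDOCOUNT))
        assert diff == pytest.approx(expected)

    def test_length_absent_from_profile(self):
        prof = compute_profile(reads_from_strings(["ACGT"]))
        with pytest.raises(ProfileError, match="length 3"):
            score_read("ACG", prof)


class TestSelectCandidate:
    def test_single_candidate(self, rng):
        assert select_candidate([-1.0], rng) == 0

    def test_identical_scores_uniform(self, rng):
        n, trials = 4, 10_000
        counts = Counter(select_candidate([-2.0] * n, rng) for _ in range(trials))
        sd = np.sqrt((1 / n) * (1 - 1 / n) * trials)
        for i in range(n):
            assert abs(counts[i] - trials / n) < 4 * sd

    def test_frequency_proportional_in_one_position_case(self, rng):
        prof = single_position_profile([0.75, 0.25, 0.0, 0.0])
        scores = [score_read("A", prof), score_read("C", prof)]
        trials = 10_000
        hits = sum(select_candidate(scores, rng) == 0 for _ in range(trials))
        sd = np.sqrt(0.75 * 0.25 * trials)
        assert abs(hits - 0.75 * trials) < 4 * sd

    def test_empty_list_rejected(self, rng):
        with pytest.raises(ValidationError):
            select_candidate([], rng)


class TestSimulate:
    def test_count_and_length_conservation(self, small_genome):
        reads = reads_from_strings(
            ["ACGTACGTAC", "ACNTT", "TTTTTTTT", "GGGGGNNN", "ACACACAC"]
        )
        sims, summary = simulate(
            reads, small_genome, SimulationConfig(seed=1, candidate_count=5)
        )
        assert summary.reads_in == 5
        assert summary.reads_discarded == 2
        assert summary.reads_simulated == 3 == len(sims)
        retained, _ = filter_ambiguous(reads)
        assert [len(s) for s in sims] == [len(r) for r in retained]

    def test_determinism_same_seed(self, small_genome, biased_reads):
        cfg = SimulationConfig(seed=99, candidate_count=10)
        reads = biased_reads[:300]
        a, _ = simulate(reads, small_genome, cfg)
        b, _ = simulate(reads, small_genome, cfg)
        assert a == b

    def test_different_seeds_differ(self, small_genome, biased_reads):
        reads = biased_reads[:100]
        a, _ = simulate(reads, small_genome, SimulationConfig(seed=1))
        b, _ = simulate(reads, small_genome, SimulationConfig(seed=2))
        assert a != b

    def test_quality_copied_verbatim(self, small_genome):
        reads = reads_from_strings(["ACGTACGT"] * 5, quality_char="F")
        sims, _ = simulate(
            reads, small_genome, SimulationConfig(seed=3, candidate_count=2)
        )
        assert all(s.quality == "FFFFFFFF" for s in sims)

    def test_constant_quality_mode(self, small_genome):
        reads = reads_from_strings(["ACGTACGT"] * 5)
        sims, _ = simulate(
            reads,
            small_genome,
            SimulationConfig(
                seed=3, candidate_count=2, quality_mode="constant", quality_char="I"
            ),
        )
        assert all(s.quality == "IIIIIIII" for s in sims)

    def test_fasta_input_copy_mode_has_no_quality(self, small_genome):
        reads = reads_from_strings(["ACGTACGT"] * 3)
        sims, _ = simulate(
            reads, small_genome, SimulationConfig(seed=3, candidate_count=2)
        )
        assert all(s.quality is None for s in sims)

    def test_bed_faithfulness(self, small_genome, biased_reads):
        sims, _ = simulate(
            biased_reads[:200],
            small_genome,
            SimulationConfig(seed=5, candidate_count=5),
        )
        for s in sims:
            ref = small_genome.fetch(s.interval.chrom, s.interval.start, s.interval.end)
            if s.interval.strand == "-":
                ref = reverse_complement(ref)
            assert ref == s.sequence

    def test_no_selection_pressure_gives_genome_composition(self, small_genome):
        # candidate_count=1, adjust off: pure uniform sampling; the biased
        # input profile (T=0.9 at pos 18) must NOT be reproduced
        rng = np.random.default_rng(7)
        reads = generate_biased_reads(
            small_genome, 5000, (20, 20), {18: {"T": 0.9}}, rng
        )
        sims, _ = simulate(
            reads,
            small_genome,
            SimulationConfig(seed=8, candidate_count=1, adjust=False),
        )
        prof = compute_profile(reads_from_strings([s.sequence for s in sims]))
        t_freq = prof.freqs[20][18, 3]
        assert abs(t_freq - 0.25) < 0.05

    def test_input_sequencing_mode_yields_substrings(self, rng):
        src = reads_from_strings(
            ["".join("ACGT"[c] for c in rng.integers(0, 4, 40)) for _ in range(50)]
        )
        reads = reads_from_strings(
            ["".join("ACGT"[c] for c in rng.integers(0, 4, 12)) for _ in range(100)]
        )
        sims, _ = simulate(
            reads,
            src,
            SimulationConfig(
                seed=2, candidate_count=5, source_mode="input_sequencing"
            ),
        )
        assert all(s.interval is None for s in sims)
        assert all(
            any(s.sequence in r.sequence for r in src) for s in sims
        )

    def test_source_mode_mismatch_rejected(self, small_genome, biased_reads):
        with pytest.raises(ValidationError):
            simulate(
                biased_reads[:10],
                small_genome,
                SimulationConfig(source_mode="input_sequencing"),
            )

    def test_region_restricted_simulation(self, small_genome, biased_reads):
        regions = [
            GenomicInterval("chr1", s, s + 500) for s in range(0, 10_000, 1000)
        ]
        sims, _ = simulate(
            biased_reads[:200],
            small_genome,
            SimulationConfig(seed=4, candidate_count=5, regions=regions),
        )
        for s in sims:
            assert any(
                r.start <= s.interval.start and s.interval.end <= r.end
                for r in regions
            )


class TestConvergence:
    def _distance(self, reads, genome, seed, **kw):
        cfg = SimulationConfig(seed=seed, **kw)
        _, summary = simulate(reads, genome, cfg)
        return summary.final_distance

    def test_order_robust_convergence(self, small_genome):
        """Input order shifts the final profile distance by less than twice
        its across-seed spread."""
        rng = np.random.default_rng(41)
        reads = generate_biased_reads(
            small_genome, 5000, (20, 20), {18: {"T": 0.9}, 19: {"T": 0.9}}, rng
        )
        dists = [
            self._distance(reads, small_genome, seed, candidate_count=20)
            for seed in range(5)
        ]
        shuffled = list(reads)
        np.random.default_rng(4242).shuffle(shuffled)
        d_shuffled = self._distance(shuffled, small_genome, 0, candidate_count=20)
        assert abs(d_shuffled - dists[0]) < 2 * np.std(dists, ddof=1)

    def test_monotone_fidelity_in_candidate_count(self, small_genome):
        """More candidates per read gives a closer profile (median over seeds)."""
        rng = np.random.default_rng(43)
        reads = generate_biased_reads(
            small_genome, 3000, (20, 20), {18: {"T": 0.9}, 19: {"T": 0.9}}, rng
        )
        medians = {
            cc: np.median(
                [
                    self._distance(reads, small_genome, seed, candidate_count=cc)
                    for seed in range(3)
                ]
            )
            for cc in (1, 5, 50)
        }
        assert medians[50] <= medians[5] <= medians[1]

    def test_adjustment_improves_convergence(self, small_genome):
        rng = np.random.default_rng(44)
        reads = generate_biased_reads(
            small_genome, 4000, (20, 20), {18: {"T": 0.9}, 19: {"T": 0.9}}, rng
        )
        d_on = self._distance(reads, small_genome, 5, candidate_count=20)
        d_off = self._distance(
            reads, small_genome, 5, candidate_count=20, adjust=False
        )
        assert d_on < d_off
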