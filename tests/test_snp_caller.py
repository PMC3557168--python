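
import numpy as np
import pytest
from helpers import (
    _random_observations,
    brute_force_adjacent,
    brute_force_discover,
    brute_force_homopolymer,
    make_site,
)
from hypothesis import given, settings
from hypothesis import strategies as st

from rrlsnp import (
    CallerConfig,
    DepthStats,
    ReferenceGenome,
    SimConfig,
    apply_site_filters,
    call_candidate,
    discover_snps,
    estimate_false_positive_rate,
    filter_adjacent,
    filter_homopolymer,
    simulate_experiment,
)
from rrlsnp.snp_caller import homopolymer_context


class TestCallCandidate:
    def test_ratio_boundary_point_nine(self):
        cand = call_candidate(make_site("G" * 9 + "A", ref="A"))
        assert cand.alt_allele == "G"
        assert cand.consensus_ratio == pytest.approx(0.9)

    def test_no_variant_when_consensus_is_reference(self):
        assert call_candidate(make_site("A" * 10, ref="A")) is None

    def test_majority_rule_with_minority_third_allele(self):
        cand = call_candidate(make_site("G" * 8 + "T" * 2, ref="A"))
        assert cand.alt_allele == "G"
        assert cand.consensus_ratio == pytest.approx(0.8)

    def test_tied_consensus_yields_no_call(self):
        assert call_candidate(make_site("GGGTTT", ref="A")) is None

    def test_reference_N_site_skipped(self):
        assert call_candidate(make_site("GGG", ref="N")) is None

    def test_quality_is_mean_of_consensus_supporting_calls(self):
        cand = call_candidate(make_site("GGA", quals=[30, 40, 10], ref="A"))
        assert cand.quality == pytest.approx(35.0)

    def test_rms_mapping_quality_caps_site_quality(self):
        site = make_site("GGG", quals=[40, 40, 40], ref="A", map_quals=[10, 10, 10])
        assert call_candidate(site).quality == pytest.approx(10.0)


class TestSiteFilters:
    stats = DepthStats("GT1", mean_depth=10.0, sd_depth=5.0, n_covered_positions=100)

    def flags(self, calls, **kw):
        cand = call_candidate(make_site(calls, **kw))
        return apply_site_filters(cand, self.stats, CallerConfig()).filter_flags

    def test_depth_at_minimum_passes(self):
        assert self.flags("GGG", ref="A") == set()

    def test_below_minimum_depth_flagged(self):
        assert "low_depth" in self.flags("GG", ref="A")

    def test_above_cutoff_flagged(self):
        assert "high_depth" in self.flags("G" * 21, ref="A")  # cutoff = 20

    def test_low_ratio_flagged(self):
        assert "low_ratio" in self.flags("G" * 8 + "T" * 2, ref="A")

    def test_low_quality_flagged(self):
        assert "low_quality" in self.flags("GGG", quals=[15, 15, 15], ref="A")

    def test_mismatched_stats_rejected(self):
        cand = call_candidate(make_site("GGG", ref="A"))
        with pytest.raises(ValueError):
            apply_site_filters(cand, DepthStats("GT2", 10, 1, 5), CallerConfig())



class TestHomopolymerFilter:
    def test_snp_inside_run_flagged(self):
        #  C A A A T : middle A sits in a run of 3
        assert homopolymer_context("CAAAT", 2, 3)

    def test_no_run_not_flagged(self):
        assert not homopolymer_context("ACGT", 1, 3)

    def test_base_abutting_run_flagged(self):
        # G immediately after TTT
        assert homopolymer_context("ATTTGC", 4, 3)

    def test_matches_brute_force_oracle_on_random_sequence(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=600))
        for pos in range(len(seq)):
            assert homopolymer_context(seq, pos, 3) == brute_force_homopolymer(
                seq, pos, 3
            ), f"disagreement at {pos}"

    def test_position_outside_contig_rejected(self, small_reference):
        cand = call_candidate(make_site("GGG", ref="A", pos=99, contig="c1"))
        with pytest.raises(IndexError):
            filter_homopolymer(cand, small_reference)


def cands_at(positions, contig="c1"):
    return [
        call_candidate(make_site("GGG", ref="A", pos=p, contig=contig))
        for p in positions
    ]



class TestAdjacentFilter:
    @pytest.mark.parametrize(
        "positions, flagged",
        [
            ([100, 101], {100, 101}),  # gap 0: both removed
            ([100, 103], set()),  # gap 2: boundary, kept
            ([100, 102, 104], {100, 102, 104}),  # chain: all removed
        ],
    )
    def test_pairs_and_chains(self, positions, flagged):
        out = filter_adjacent(cands_at(positions), min_gap=2)
        assert {c.position for c in out if "adjacent" in c.filter_flags} == flagged

    def test_different_contigs_never_adjacent(self):
        out = filter_adjacent(
            sorted(
                cands_at([100], "c1") + cands_at([101], "c2"),
                key=lambda c: (c.contig_id, c.position),
            ),
            min_gap=2,
        )
        assert all("adjacent" not in c.filter_flags for c in out)

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError):
            filter_adjacent(cands_at([200, 100]))

    @settings(max_examples=60, deadline=None)
    @given(
        st.sets(st.integers(min_value=1, max_value=300), min_size=1, max_size=25),
        st.integers(min_value=0, max_value=4),
    )
    def test_matches_all_pairs_oracle(self, positions, min_gap):
        positions = sorted(positions)
        out = filter_adjacent(cands_at(positions), min_gap=min_gap)
        got = {c.position for c in out if "adjacent" in c.filter_flags}
        assert got == brute_force_adjacent(positions, min_gap)


# ---------------------------------------------------------------------------
# Whole-pipeline properties
# ---------------------------------------------------------------------------




class TestDiscoverPipeline:
    def test_single_clean_variant(self, rng):
        ref = ReferenceGenome([("c1", "".join(rng.choice(list("ACGT"), size=100)))])
        pos = 50
        alt = next(b for b in "ACGT" if b != ref.base_at("c1", pos - 1))
        if homopolymer_context(ref.sequence("c1"), pos - 1, 3):
            pos = 20
            alt = next(b for b in "ACGT" if b != ref.base_at("c1", pos - 1))
        site = make_site(alt * 10, ref=ref.base_at("c1", pos - 1), pos=pos)
        filler = [
            make_site(ref.base_at("c1", p - 1) * 10, ref=ref.base_at("c1", p - 1), pos=p)
            for p in range(1, 15)
        ]
        snps, _, _ = discover_snps({"GT1": filler + [site]}, ref)
        expected = 0 if homopolymer_context(ref.sequence("c1"), pos - 1, 3) else 1
        assert len(snps) == expected

    def test_shared_variant_merged_across_genotypes(self):
        ref = ReferenceGenome([("c1", "ACGTACGTACGTACGTACGT")])
        mk = lambda gt: [
            make_site("C" * 10, ref="G", pos=7, contig="c1", genotype=gt)
        ] + [
            make_site(ref.base_at("c1", p) * 10, ref=ref.base_at("c1", p), pos=p + 1, genotype=gt)
            for p in range(12, 18)
        ]
        snps, _, _ = discover_snps({"GT1": mk("GT1"), "GT2": mk("GT2")}, ref)
        assert len(snps) == 1
        assert snps[0].presence_set == {"GT1", "GT2"}

    def test_truth_recovery_under_clean_conditions(self, recoverable_experiment):
        exp = recoverable_experiment
        pileups = {g: exp.pileup(g) for g in exp.genotype_sequences}
        snps, _, _ = discover_snps(pileups, exp.reference)
        called = {
            (s.contig_id, s.position, g, s.alt_alleles[g])
            for s in snps
            for g in s.presence_set
        }
        truth = {
            (c, p, g, alt)
            for g, variants in exp.truth.variants.items()
            for (c, p), (_, alt) in variants.items()
        }
        assert called == truth

    def test_order_independence(self, rng):
        exp = simulate_experiment(
            SimConfig(genome_length=60_000, n_contigs=2, snp_density=1e-3,
                      depth_dispersion=0.2, base_error_rate=0.01, seed=3)
        )
        pileups = {g: list(exp.pileup(g)) for g in exp.genotype_sequences}
        snps_a, _, _ = discover_snps({k: v for k, v in pileups.items()}, exp.reference)
        shuffled = {
            k: list(rng.permutation(np.array(v, dtype=object)))
            for k, v in reversed(list(pileups.items()))
        }
        snps_b, _, _ = discover_snps(shuffled, exp.reference)
        assert snps_a == snps_b

    def test_matches_brute_force_evaluator(self, rng):
        ref = ReferenceGenome(
            [
                ("c1", "".join(rng.choice(list("ACGT"), size=6000))),
                ("c2", "".join(rng.choice(list("ACGT"), size=4000))),
            ]
        )
        for trial in range(3):
            config = CallerConfig(
                min_depth=int(rng.integers(2, 5)),
                min_consensus_ratio=float(rng.choice([0.8, 0.9, 0.95])),
                min_quality=float(rng.choice([15, 20, 25])),
                min_gap_between_snps=int(rng.integers(1, 4)),
            )
            obs = {
                gt: _random_observations(rng, ref, gt)
                for gt in ("GT1", "GT2")
            }
            snps, _, _ = discover_snps({k: list(v) for k, v in obs.items()}, ref, config)
            got = {
                (s.contig_id, s.position): dict(s.alt_alleles) for s in snps
            }
            expected = brute_force_discover(obs, ref, config)
            assert got == expected, f"trial {trial}"

    def test_monotone_in_thresholds(self):
        exp = simulate_experiment(
            SimConfig(genome_length=80_000, snp_density=1e-3, depth_dispersion=0.3,
                      base_error_rate=0.02, seed=5)
        )
        def passing(config):
            pileups = {g: exp.pileup(g) for g in exp.genotype_sequences}
            snps, _, _ = discover_snps(pileups, exp.reference, config)
            return {(s.contig_id, s.position, g) for s in snps for g in s.presence_set}

        base = passing(CallerConfig())
        for stricter in (
            CallerConfig(min_depth=5),
            CallerConfig(min_consensus_ratio=0.95),
            CallerConfig(min_quality=30),
        ):
            assert passing(stricter) <= base

    def test_reference_self_call_is_empty(self, recoverable_experiment):
        exp = recoverable_experiment
        ref_pileup = simulate_self_pileup(exp)
        snps, _, _ = discover_snps({"REF": ref_pileup}, exp.reference)
        assert snps == []

    def test_empty_genotype_excluded_with_warning(self, caplog):
        ref = ReferenceGenome([("c1", "ACGTACGT")])
        obs = [make_site("G" * 5, ref="A", pos=1, genotype="GT1")]
        snps, stats, _ = discover_snps({"GT1": obs, "GT2": []}, ref)
        assert "GT2" not in stats


def simulate_self_pileup(exp):
    """Error-free reads of the reference itself (the self-mapping control)."""
    from rrlsnp import simulate_pileup

    ref_seqs = {cid: seq for cid, seq in exp.reference.contigs}
    return simulate_pileup(
        ref_seqs, exp.fragments, exp.config, "REF",
        np.random.default_rng(99), reference=exp.reference,
    )


class TestFalsePositiveRate:
    def test_printed_self_mapping_rate(self):
        rate = estimate_false_positive_rate(6_072, 318_000_000)
        assert rate == pytest.approx(1.9e-5, rel=0.01)

    def test_zero_sites_zero_rate(self):
        assert estimate_false_positive_rate(0, 100) == 0.0

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            estimate_false_positive_rate(5, 0)
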