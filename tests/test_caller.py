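"""Statistical engine: Fisher, binomial, noise rates, batch calling."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import fisher_exact

from clonesift.caller import (
    BatchPileupSet,
    CallerThresholds,
    CandidateCall,
    between_sample_test,
    bonferroni,
    call_batch,
    enumerate_candidates,
    fisher_two_sided,
    fisher_two_sided_many,
    log_noise_ratio,
    passing_calls,
    substitution_class,
    within_sample_noise_rate,
    within_sample_test,
)
from clonesift.pileup import LibraryPileup
from clonesift.simulate import (
    BatchArtefact,
    NoiseProfile,
    SpikedClone,
    simulate_batch_counts,
)

# ---------------------------------------------------------------------------
# independent oracles


def fisher_oracle_exact(a, b, c, d):
    """Two-sided Fisher by exact rational hypergeometric enumeration."""
    n = a + b + c + d
    k_tot = a + c
    r = a + b
    if k_tot in (0, n) or r in (0, n):
        return 1.0
    denom = math.comb(n, r)

    def pmf(k):
        return Fraction(math.comb(k_tot, k) * math.comb(n - k_tot, r - k), denom)

    lo = max(0, r - (n - k_tot))
    hi = min(r, k_tot)
    p_obs = pmf(a)
    tot = sum((p for k in range(lo, hi + 1) if (p := pmf(k)) <= p_obs), Fraction(0))
    return float(min(Fraction(1), tot))


def binom_upper_oracle(n_alt, d, eps):
    """Upper-tail binomial by direct pmf summation from n_alt upward."""
    if n_alt == 0:
        return 1.0
    tot = 0.0
    for k in range(n_alt, d + 1):
        term = math.comb(d, k) * eps**k * (1 - eps) ** (d - k)
        tot += term
        if k > n_alt + 20 and term < tot * 1e-16:
            break
    return min(1.0, tot)


# ---------------------------------------------------------------------------
# Fisher exact


class TestFisherTwoSided:
    def test_carrier_table_reproduces_printed_value(self):
        assert round(fisher_two_sided(26, 68, 24, 75), 2) == 0.62

    def test_no_alternate_observations_is_uninformative(self):
        assert fisher_two_sided(0, 100, 0, 1000) == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_two_sided(-1, 5, 5, 5)

    def test_deep_table_golden_value(self):
        # frozen from the exact rational enumeration oracle
        p = fisher_two_sided(10, 9990, 3, 299997)
        assert p == pytest.approx(3.177795305149683e-13, rel=1e-9)

    def test_exclusive_deep_signal_golden_value(self):
        p = fisher_two_sided(20, 39980, 0, 400000)
        assert p == pytest.approx(1.4800302835215442e-21, rel=1e-9)

    def test_matches_scipy_on_random_tables(self, rng):
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(0, 40, 4))
            mine = fisher_two_sided(a, b, c, d)
            ref = fisher_exact([[a, b], [c, d]]).pvalue
            assert mine == pytest.approx(float(ref), rel=1e-9)

    def test_vectorised_matches_scalar(self, rng):
        tables = [tuple(int(x) for x in rng.integers(0, 60, 4)) for _ in range(150)]
        many = fisher_two_sided_many(tables)
        for tab, p in zip(tables, many):
            assert p == pytest.approx(fisher_two_sided(*tab), rel=1e-12)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(0, 50)] * 4))
    def test_symmetry_under_row_swap_and_transpose(self, table):
        a, b, c, d = table
        p = fisher_two_sided(a, b, c, d)
        assert fisher_two_sided(c, d, a, b) == pytest.approx(p, rel=1e-9)
        assert fisher_two_sided(a, c, b, d) == pytest.approx(p, rel=1e-9)


# ---------------------------------------------------------------------------
# within-sample binomial test, LNR, Bonferroni


class TestWithinSample:
    def test_zero_alternate_is_one(self):
        assert within_sample_test(0, 50_000, 1e-4) == 1.0

    def test_golden_value_deep_site(self):
        # frozen from the direct pmf summation oracle
        p = within_sample_test(15, 50_000, 1e-4)
        assert p == pytest.approx(0.00022604146060315567, rel=1e-9)

    def test_zero_rate_uses_floor(self):
        p_floor = within_sample_test(3, 10_000, 0.0, eps_floor=1e-5)
        assert p_floor == pytest.approx(binom_upper_oracle(3, 10_000, 1e-5), rel=1e-9)
        with pytest.raises(ValueError):
            within_sample_test(3, 10_000, 0.0)

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            within_sample_test(3, 100, 1.5)

    def test_matches_oracle_on_random_instances(self, rng):
        for _ in range(100):
            d = int(rng.integers(50, 2000))
            n_alt = int(rng.integers(1, 12))
            eps = float(rng.uniform(1e-5, 5e-3))
            assert within_sample_test(n_alt, d, eps) == pytest.approx(
                binom_upper_oracle(n_alt, d, eps), rel=1e-9
            )


def test_log_noise_ratio_boundaries():
    assert log_noise_ratio(1e-3, 1e-4, 1e-6) == pytest.approx(1.0)
    assert log_noise_ratio(2e-4, 2e-4, 1e-6) == pytest.approx(0.0)
    # zero rate floored to a finite positive value
    assert math.isfinite(log_noise_ratio(1e-3, 0.0, 1e-5))
    assert log_noise_ratio(1e-3, 0.0, 1e-5) == pytest.approx(2.0)


def test_bonferroni_correction():
    assert bonferroni(0.03, 4) == pytest.approx(0.12)
    assert bonferroni(0.5, 10) == 1.0
    assert bonferroni(1e-9, 1000) == pytest.approx(1e-6)
    with pytest.raises(ValueError):
        bonferroni(0.5, 0)


# ---------------------------------------------------------------------------
# noise-rate estimation


def _hand_pileup(target, spec, library_id="libA"):
    """spec: {pos: {allele: count}}"""
    p = LibraryPileup(library_id=library_id, target=target)
    for pos, site in spec.items():
        for allele, n in site.items():
            p.add(pos, allele, n)
    return p


def test_noise_rate_pools_matching_reference_base(toy_target):
    """C->T rate from other C sites only; candidate site always excluded."""
    ref = toy_target.ref_seq
    c_positions = [toy_target.start + i for i, b in enumerate(ref) if b == "C"]
    assert len(c_positions) >= 3
    cand_pos, other = c_positions[0], c_positions[1:]
    spec = {cand_pos: {"C": 900, "T": 100}}  # own site is noisy but excluded
    for pos in other:
        spec[pos] = {"C": 990, "T": 10}
    pile = _hand_pileup(toy_target, spec)
    eps, den = within_sample_noise_rate(
        [pile], ("C", "T"), ("toy", cand_pos)
    )
    assert den == 1000 * len(other)
    assert eps == pytest.approx(10 * len(other) / (1000 * len(other)))


def test_noise_rate_simple_arithmetic(toy_target):
    """30 class-matching errors over 300,000 eligible bases -> 1e-4."""
    ref = toy_target.ref_seq
    a_positions = [toy_target.start + i for i, b in enumerate(ref) if b == "A"][:3]
    cand = toy_target.start + ref.index("C")
    spec = {cand: {"C": 100, "G": 1}}
    per = 300_000 // len(a_positions)
    per_err = 30 // len(a_positions)
    for pos in a_positions:
        spec[pos] = {"A": per - per_err, "G": per_err}
    pile = _hand_pileup(toy_target, spec)
    eps, den = within_sample_noise_rate([pile], ("A", "G"), ("toy", cand))
    assert den == 300_000
    assert eps == pytest.approx(1e-4)

    # no eligible positions: rate undefined
    eps2, den2 = within_sample_noise_rate([pile], ("T", "G"), ("toy", cand))
    assert eps2 is None and den2 == 0


def test_excluded_sites_do_not_contribute(toy_target):
    ref = toy_target.ref_seq
    a_positions = [toy_target.start + i for i, b in enumerate(ref) if b == "A"][:3]
    cand = a_positions[0]
    spec = {
        cand: {"A": 100, "C": 5},
        a_positions[1]: {"A": 50, "C": 50},  # a putative clone: excluded
        a_positions[2]: {"A": 1000, "C": 1},
    }
    pile = _hand_pileup(toy_target, spec)
    eps, den = within_sample_noise_rate(
        [pile], ("A", "C"), ("toy", cand), frozenset({("toy", a_positions[1])})
    )
    assert den == 1001
    assert eps == pytest.approx(1 / 1001)


# ---------------------------------------------------------------------------
# between-sample test and batch calling


def _two_lib_batch(toy_target):
    pos = toy_target.start + 2
    ref = toy_target.ref_base(pos)
    alt = "T" if ref != "T" else "A"
    p1 = _hand_pileup(toy_target, {pos: {ref: 990, alt: 10}}, "lib1")
    p2 = _hand_pileup(toy_target, {pos: {ref: 1000}}, "lib2")
    return BatchPileupSet(batch_id="b", libraries=[p1, p2]), pos, ref, alt


def test_between_sample_two_library_batch_equals_direct_test(toy_target):
    batch, pos, ref, alt = _two_lib_batch(toy_target)
    cand = CandidateCall(
        library_id="lib1",
        batch_id="b",
        run_id="",
        target_name="toy",
        chrom=toy_target.chrom,
        position=pos,
        ref=ref,
        alt=alt,
        n_alt=10,
        n_ref=990,
        depth=1000,
    )
    assert between_sample_test(cand, batch) == pytest.approx(
        fisher_two_sided(10, 990, 0, 1000), rel=1e-12
    )


def test_between_sample_homogeneous_alt_is_not_significant(toy_target):
    pos = toy_target.start + 2
    ref = toy_target.ref_base(pos)
    alt = "T" if ref != "T" else "A"
    libs = [
        _hand_pileup(toy_target, {pos: {ref: 10_000, alt: 30}}, f"lib{i}")
        for i in range(6)
    ]
    batch = BatchPileupSet(batch_id="b", libraries=libs)
    cand = CandidateCall(
        library_id="lib0",
        batch_id="b",
        run_id="",
        target_name="toy",
        chrom=toy_target.chrom,
        position=pos,
        ref=ref,
        alt=alt,
        n_alt=30,
        n_ref=10_000,
        depth=10_030,
    )
    assert between_sample_test(cand, batch) > 0.5


def test_between_sample_unknown_library_is_error(toy_target):
    batch, pos, ref, alt = _two_lib_batch(toy_target)
    cand = CandidateCall(
        library_id="ghost",
        batch_id="b",
        run_id="",
        target_name="toy",
        chrom=toy_target.chrom,
        position=pos,
        ref=ref,
        alt=alt,
        n_alt=5,
        n_ref=100,
        depth=105,
    )
    with pytest.raises(ValueError):
        between_sample_test(cand, batch)


def test_enumerate_candidates(toy_target):
    pos = toy_target.start + 4
    ref = toy_target.ref_base(pos)
    alt = "G" if ref != "G" else "C"
    p1 = _hand_pileup(toy_target, {pos: {ref: 98, alt: 2}}, "lib1")
    p2 = _hand_pileup(toy_target, {pos: {ref: 100}}, "lib2")
    batch = BatchPileupSet(batch_id="b", libraries=[p1, p2])
    cands = enumerate_candidates(batch)
    assert len(cands) == 1
    assert cands[0].n_alt == 2 and cands[0].alt == alt
    # all-reference batch: no candidates
    p3 = _hand_pileup(toy_target, {pos: {ref: 100}}, "lib1")
    p4 = _hand_pileup(toy_target, {pos: {ref: 100}}, "lib2")
    assert enumerate_candidates(BatchPileupSet(batch_id="b", libraries=[p3, p4])) == []
    # min_alt_count filters
    assert enumerate_candidates(batch, min_alt_count=3) == []


def test_candidate_set_matches_truth_ledger_enumeration(stat3_targets):
    """Candidates equal a brute-force recount over the simulated pileups."""
    batch, _ = simulate_batch_counts(stat3_targets, 4, 2000, seed=5)
    cands = enumerate_candidates(batch, min_alt_count=2)
    expected = set()
    for p in batch.libraries:
        for pos in p.positions():
            ref = p.target.ref_base(pos)
            for allele, n in p.site_counts(pos).items():
                if allele != ref and n >= 2:
                    expected.add((p.library_id, p.target.name, pos, allele, n))
    got = {(c.library_id, c.target_name, c.position, c.alt, c.n_alt) for c in cands}
    assert got == expected
    assert len(cands) == len(got)


def test_call_batch_noise_rate_equals_reference_estimator(stat3_targets):
    """The incremental per-class rate in call_batch matches the direct op."""
    batch, _ = simulate_batch_counts(stat3_targets, 3, 3000, seed=9)
    calls = call_batch(batch)
    assert calls and not any(v.passed for v in calls)
    lib_pileups = {lid: batch.pileups_for_library(lid) for lid in batch.library_ids}
    for v in calls[::25]:
        c = v.candidate
        eps, den = within_sample_noise_rate(
            lib_pileups[c.library_id],
            substitution_class(c.ref, c.alt),
            (c.target_name, c.position),
        )
        assert v.stats.noise_rate == pytest.approx(eps if eps is not None else 0.0)
        assert v.stats.noise_floor == pytest.approx(1.0 / den)


class TestCallBatch:
    def test_pure_noise_yields_zero_calls(self, stat3_targets):
        batch, _ = simulate_batch_counts(stat3_targets, 8, 25_000, seed=101)
        calls = call_batch(batch)
        assert calls, "deep noise should produce candidates"
        assert passing_calls(calls) == []
        assert all(v.stats.m_tests == len(calls) for v in calls[:5])

    def test_spiked_clone_is_the_only_call(self, stat3_targets):
        t = stat3_targets[0]
        pos = t.start + 31
        ref = t.ref_base(pos)
        alt = "A" if ref != "A" else "G"
        spike = SpikedClone("donor2", t.name, pos, ref, alt, 0.005)
        batch, _ = simulate_batch_counts(
            stat3_targets, 8, 25_000, spikes=[spike], seed=77
        )
        hits = passing_calls(call_batch(batch))
        assert len(hits) == 1
        c = hits[0].candidate
        assert (c.library_id, c.position, c.alt) == ("lib2", pos, alt)

    def test_batch_recurrent_artefact_is_rejected(self, stat3_targets):
        t = stat3_targets[1]
        pos = t.start + 60
        ref = t.ref_base(pos)
        alt = "T" if ref != "T" else "C"
        art = BatchArtefact(t.name, pos, alt, 0.003)
        batch, _ = simulate_batch_counts(
            stat3_targets, 8, 25_000, artefacts=[art], seed=13
        )
        calls = call_batch(batch)
        site = [v for v in calls if v.candidate.position == pos and v.candidate.alt == alt]
        assert site, "the artefact produces candidates in every library"
        assert not any(v.passed for v in site)
        # the artefact fails specifically on the between-sample criterion
        assert all(v.filter == "between" for v in site)

    def test_threshold_monotonicity(self, stat3_targets):
        t = stat3_targets[0]
        pos = t.start + 40
        ref = t.ref_base(pos)
        alt = "C" if ref != "C" else "T"
        spike = SpikedClone("donor1", t.name, pos, ref, alt, 0.004)
        batch, _ = simulate_batch_counts(
            stat3_targets, 6, 20_000, spikes=[spike], seed=55
        )

        def pass_keys(th):
            return {
                (v.candidate.library_id, v.candidate.position, v.candidate.alt)
                for v in passing_calls(call_batch(batch, th))
            }

        default = pass_keys(CallerThresholds())
        looser = pass_keys(
            CallerThresholds(alpha_between=0.01, alpha_within=0.01, lnr_min=0.5)
        )
        tighter = pass_keys(
            CallerThresholds(alpha_between=1e-4, alpha_within=1e-4, lnr_min=1.5)
        )
        assert default <= looser
        assert tighter <= default

    def test_deterministic_for_fixed_input(self, stat3_targets):
        batch, _ = simulate_batch_counts(stat3_targets, 3, 2000, seed=4)
        c1 = call_batch(batch)
        c2 = call_batch(batch)
        assert c1 == c2


def test_batch_requires_two_libraries(toy_target):
    p1 = _hand_pileup(toy_target, {toy_target.start: {"A": 10}}, "only")
    with pytest.raises(ValueError):
        BatchPileupSet(batch_id="b", libraries=[p1])
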