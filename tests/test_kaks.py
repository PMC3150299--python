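"""Ka/Ks chain: site counting against exhaustive mutation enumeration,
pathway-averaged substitutions, the pseudocounted Jukes-Cantor
estimator, selection classification and the pooled-percentile
bootstrap."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from estpoly import kaks
from estpoly.kaks import (
    BootstrapInterval, CodonAlignment, SaturationError, StopCodonError,
    analyze_pair, bootstrap_interval, classify_selection,
    codon_alignment_from_consensus, count_sites, count_substitutions,
    kaks_modified_jc, summarize_kaks,
)
from estpoly.simulate import Orf
import oracles

SENSE_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
                if a + b + c not in ("TAA", "TAG", "TGA")]


def test_phe_codon_site_fractions():
    # of TTT's nine single-base mutations only TTT->TTC is synonymous
    s, n = count_sites("TTT")
    assert s == pytest.approx(1 / 3)
    assert n == pytest.approx(8 / 3)


def test_sites_sum_to_sequence_length(rng):
    for _ in range(20):
        seq = "".join(rng.choice(SENSE_CODONS, size=50))
        s, n = count_sites(seq)
        assert s + n == pytest.approx(len(seq))


def test_site_counts_match_enumeration_oracle(rng):
    for _ in range(20):
        seq = "".join(rng.choice(SENSE_CODONS, size=30))
        s, n = count_sites(seq)
        es = sum(oracles.enumerate_codon_sites(seq[i:i + 3])[0]
                 for i in range(0, len(seq), 3))
        assert s == pytest.approx(es, abs=1e-9)


def test_stop_codon_error_names_codon_index():
    with pytest.raises(StopCodonError, match="index 2"):
        count_sites("AAACCCTAAGGG")


def test_single_synonymous_substitution():
    sd, nd = count_substitutions(CodonAlignment("x", "GAA", "GAG"))
    assert (sd, nd) == (1.0, 0.0)


def test_identical_sequences_have_zero_substitutions():
    seq = "GAAGCTTTT"
    assert count_substitutions(CodonAlignment("x", seq, seq)) == (0.0, 0.0)


def test_multi_hit_codons_match_pathway_oracle(rng):
    for _ in range(300):
        c1 = str(rng.choice(SENSE_CODONS))
        c2 = str(rng.choice(SENSE_CODONS))
        got = count_substitutions(CodonAlignment("x", c1, c2))
        want = oracles.enumerate_pair_substitutions(c1, c2)
        assert got == pytest.approx(want, abs=1e-9)


def test_two_difference_pair_averages_both_orderings():
    # TTT -> GTA: via GTT (F->V->V? no: F(TTT)->V(GTT) non-syn, V->V(GTA) syn)
    # or via TTA (F->L non-syn, L->V non-syn); average (1+0)/2 syn, (1+2)/2 non
    sd, nd = count_substitutions(CodonAlignment("x", "TTT", "GTA"))
    assert sd == pytest.approx(0.5)
    assert nd == pytest.approx(1.5)


def test_order_symmetry(rng):
    for _ in range(20):
        a = "".join(rng.choice(SENSE_CODONS, size=40))
        b = "".join(rng.choice(SENSE_CODONS, size=40))
        try:
            r1 = analyze_pair(CodonAlignment("x", a, b))
            r2 = analyze_pair(CodonAlignment("x", b, a))
        except SaturationError:
            continue
        assert r1.ratio == pytest.approx(r2.ratio, rel=1e-12)
        assert (r1.syn_subs, r1.nonsyn_subs) == (r2.syn_subs, r2.nonsyn_subs)


def test_identical_pair_has_finite_positive_ratio():
    seq = "".join(SENSE_CODONS[:40])
    r = analyze_pair(CodonAlignment("x", seq, seq))
    assert (r.syn_subs, r.nonsyn_subs) == (0.0, 0.0)
    assert 0 < r.ratio < math.inf   # the pseudocount's purpose


def test_symmetric_counts_give_ratio_one():
    r = kaks_modified_jc(syn_subs=5, nonsyn_subs=5, syn_sites=100,
                         nonsyn_sites=100)
    assert r.ratio == pytest.approx(1.0)


def test_estimator_matches_hand_computed_chain():
    """A 300-codon pair with exactly 10 synonymous and 2 non-synonymous
    planted changes must reproduce the pS/pN -> Jukes-Cantor -> ratio
    arithmetic to 1e-12."""
    a = ["GAA"] * 300
    b = list(a)
    for i in range(10):
        b[i] = "GAG"            # E->E synonymous
    for i in range(10, 12):
        b[i] = "CAA"            # E->Q non-synonymous
    aln = CodonAlignment("x", "".join(a), "".join(b))
    result = analyze_pair(aln)
    assert (result.syn_subs, result.nonsyn_subs) == (10.0, 2.0)
    s = sum(oracles.enumerate_codon_sites(c)[0] for c in a) / 2 \
        + sum(oracles.enumerate_codon_sites(c)[0] for c in b) / 2
    n = 900 - s
    ps, pn = (10 + 1) / s, (2 + 1) / n
    ks = -0.75 * math.log(1 - 4 * ps / 3)
    ka = -0.75 * math.log(1 - 4 * pn / 3)
    assert result.ks == pytest.approx(ks, abs=1e-12)
    assert result.ka == pytest.approx(ka, abs=1e-12)
    assert result.ratio == pytest.approx(ka / ks, abs=1e-12)


def test_saturation_is_an_error():
    with pytest.raises(SaturationError):
        kaks_modified_jc(80, 1, 100, 200)


def test_pseudocount_washes_out_at_high_counts():
    base = kaks_modified_jc(20, 6, 1000, 3000, pseudocount=0.0).ratio
    diffs = []
    for scale in (1, 10, 100):
        with_pc = kaks_modified_jc(20 * scale, 6 * scale, 1000 * scale,
                                   3000 * scale, pseudocount=1.0).ratio
        diffs.append(abs(with_pc - base) / base)
    assert diffs[0] > diffs[1] > diffs[2]
    assert diffs[2] < 0.01


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.integers(0, 40), st.integers(0, 40))
def test_ratio_strictly_increases_in_nonsynonymous_count(nd, nd2):
    if nd == nd2:
        nd2 += 1
    lo, hi = sorted((nd, nd2))
    r_lo = kaks_modified_jc(5, lo, 300, 600).ratio
    r_hi = kaks_modified_jc(5, hi, 300, 600).ratio
    assert r_lo < r_hi


def test_selection_class_boundaries():
    assert classify_selection(0.106) == "stabilizing"
    assert classify_selection(0.149999) == "stabilizing"
    assert classify_selection(0.15) == "intermediate"
    assert classify_selection(0.499) == "intermediate"
    assert classify_selection(0.50) == "diversifying"
    assert classify_selection(1.0) == "diversifying"
    assert classify_selection(2.50) == "diversifying"
    assert classify_selection(2.51) == "discarded"
    assert classify_selection(6.4) == "discarded"


def test_alignment_from_consensus_drops_ambiguous_codons():
    orf = Orf("c", 3, 18)
    cons_a = "AAA" + "GAAGCTTTTNTTAAA" + "CCC"
    cons_b = "AAA" + "GAGGCTTTTATTAAA" + "CCC"
    aln = codon_alignment_from_consensus(cons_a, cons_b, orf)
    assert aln.n_codons == 4                  # the N-codon is dropped
    assert aln.seq_a == "GAAGCTTTTAAA"
    # unequal lengths (repeat-length polymorphism) are not analysable
    assert codon_alignment_from_consensus(cons_a, cons_b + "T", orf) is None


def test_bootstrap_degenerate_and_bounds(rng):
    b = bootstrap_interval([0.4] * 10, n_draws=1000, seed=1)
    assert (b.lower, b.upper) == (0.4, 0.4)
    ratios = rng.uniform(0.05, 2.0, size=200)
    b = bootstrap_interval(ratios, n_draws=5000, seed=2)
    assert ratios.min() <= b.lower <= b.upper <= ratios.max()
    with pytest.raises(ValueError):
        bootstrap_interval([], n_draws=10, seed=3)


def test_bootstrap_is_seed_reproducible(rng):
    ratios = list(rng.uniform(0.05, 2.0, size=100))
    b1 = bootstrap_interval(ratios, n_draws=20_000, seed=42)
    b2 = bootstrap_interval(ratios, n_draws=20_000, seed=42)
    assert (b1.lower, b1.upper) == (b2.lower, b2.upper)


def test_bootstrap_converges_to_empirical_quantiles(rng):
    ratios = rng.gamma(2.0, 0.2, size=500)
    b = bootstrap_interval(ratios, n_draws=1_000_000, alpha=0.025, seed=5)
    assert float(np.mean(ratios <= b.lower)) == pytest.approx(0.025, abs=0.005)
    assert float(np.mean(ratios <= b.upper)) == pytest.approx(0.975, abs=0.005)


def test_distribution_summary():
    from estpoly.kaks import KaKsResult

    def res(ratio):
        return KaKsResult("c", 100, 200, 1, 1, 0.1, 0.1, ratio,
                          ratio > 2.5, classify_selection(ratio))

    results = [res(0.1), res(0.3), res(0.5), res(6.0)]
    summary = summarize_kaks(results)
    assert summary.median == pytest.approx(0.3)
    assert summary.n_discarded == 1
    assert summary.class_counts == {"stabilizing": 1, "intermediate": 1,
                                    "diversifying": 1}
    assert sum(summary.class_counts.values()) == summary.n_pairs


def test_simulation_recovers_target_ratio():
    """Planted ORF divergence at a 0.3 non-synonymous:synonymous rate
    ratio is recovered by the estimator's median within +-0.1."""
    from estpoly.simulate import SimulationConfig, generate_reference_set

    cfg = SimulationConfig(n_contigs=500, contig_length=(900.0, 0.0),
                           orf_fraction=1.0, fixed_divergence=0.04,
                           het_rate=0.0, ka_ks_target=0.3, seed=77)
    refset = generate_reference_set(cfg)
    results = []
    for orf in refset.orfs:
        aln = codon_alignment_from_consensus(
            refset.consensus["A"][orf.contig],
            refset.consensus["B"][orf.contig], orf)
        results.append(analyze_pair(aln))
    summary = summarize_kaks(results)
    assert summary.n_pairs >= 450
    assert abs(summary.median - 0.3) <= 0.1
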