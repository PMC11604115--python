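"""Diversity partitions, rarefaction (against the enumeration oracle) and
leave-one-out contributions."""

import numpy as np
import pytest

from metapopdiv.diversity import (
    allelic_richness_partition,
    choose_rarefaction_size,
    gene_diversity_partition,
    gene_diversity_within,
    group_level_partition,
    marginal_contributions,
    nei_minimum_distance_matrix,
    private_allele_richness,
    rarefacted_absent_count,
    rarefacted_allele_count,
    unseen_probability,
)

from conftest import make_counts, random_counts
from oracles import oracle_absent_count, oracle_allele_count, oracle_private


# --------------------------------------------- gene-diversity partition ------


def test_gene_diversity_hand_example():
    # p = 0.75 -> He = 2 * 0.75 * 0.25 = 0.375; p = 0.5 -> He = 0.5.
    counts = make_counts([[6, 4]], [[8, 8]])
    hs = gene_diversity_within(counts)
    assert hs["pop0"] == pytest.approx((0.375 + 0.5) / 2)


def test_nei_distance_hand_example():
    # Biallelic Nei minimum distance reduces to (p_i - p_j)^2 per locus.
    counts = make_counts([[8, 2], [2, 2]], [[8, 8], [8, 8]])
    D = nei_minimum_distance_matrix(counts)
    assert D[0, 1] == pytest.approx(((1.0 - 0.25) ** 2 + 0.0) / 2)
    assert D[0, 0] == 0.0


def test_partition_opposite_fixation():
    # Two subpopulations fixed for opposite alleles: HS = 0, DG = 0.5, HT = 0.5
    # (DG averages D over all n^2 ordered pairs including zero self-pairs).
    counts = make_counts([[10], [0]], [[10], [10]])
    part = gene_diversity_partition(counts)
    assert part.HS == pytest.approx(0.0)
    assert part.DG == pytest.approx(0.5)
    assert part.HT == pytest.approx(0.5)


def test_pooled_frequency_identity(rng):
    # Equal subpopulation weights make HT the gene diversity of the pooled
    # (equal-weight mean) frequency vector, to machine precision.
    for _ in range(50):
        counts = random_counts(rng)
        part = gene_diversity_partition(counts)
        p_bar = counts.freq.mean(axis=0)
        ht_pooled = float(np.mean(1.0 - (p_bar**2 + (1 - p_bar) ** 2)))
        assert abs(part.HT - ht_pooled) < 1e-12


def test_partition_additivity_and_permutation_invariance(rng):
    counts = random_counts(rng, n_subpops=5)
    part = gene_diversity_partition(counts)
    assert part.HT == pytest.approx(part.HS + part.DG, abs=1e-14)
    perm = ["pop3", "pop0", "pop4", "pop2", "pop1"]
    part2 = gene_diversity_partition(counts, included=perm)
    assert part2.HT == pytest.approx(part.HT, abs=1e-14)
    assert part2.HS == pytest.approx(part.HS, abs=1e-14)


# ----------------------------------------------------- rarefaction -----------


def test_unseen_probability_edge_cases():
    # All copies carry the allele -> certainly seen; zero copies -> never seen.
    assert unseen_probability(np.array([10]), np.array([10]), 4)[0] == 0.0
    assert unseen_probability(np.array([10]), np.array([0]), 4)[0] == 1.0
    # One copy among N: Q = (N - g)/N.
    assert unseen_probability(np.array([10]), np.array([1]), 4)[0] == pytest.approx(0.6)


def test_rarefaction_matches_enumeration_oracle_small():
    # Exhaustive-subset oracle over all biallelic configurations with N <= 8.
    for N in range(2, 9):
        for ref in range(N + 1):
            for g in range(2, N + 1):
                got = rarefacted_allele_count(np.array([ref, N - ref]), N, g)
                want = float(oracle_allele_count((ref, N - ref), g))
                assert abs(got - want) < 1e-12


def test_absent_count_matches_enumeration_oracle_small():
    for N_i, N_j in ((4, 6), (6, 6), (8, 4)):
        for ri in range(N_i + 1):
            for rj in range(N_j + 1):
                for g in range(2, min(N_i, N_j) + 1):
                    got = rarefacted_absent_count(
                        np.array([ri, N_i - ri]), N_i, np.array([rj, N_j - rj]), N_j, g
                    )
                    want = float(
                        oracle_absent_count((ri, N_i - ri), N_i, (rj, N_j - rj), N_j, g)
                    )
                    assert abs(got - want) < 1e-12


def test_private_richness_matches_enumeration_oracle():
    cfgs = [
        ([4, 0, 1], [6, 6, 6]),
        ([3, 2, 0], [6, 4, 6]),
        ([6, 6, 5], [6, 6, 6]),
    ]
    for refs, tots in cfgs:
        counts = make_counts(
            np.array(refs)[:, None], np.array(tots)[:, None]
        )
        g = min(tots)
        got = private_allele_richness(counts, g=g)
        want = oracle_private(
            [(r, t - r) for r, t in zip(refs, tots)], tots, g
        )
        for i in range(3):
            assert abs(got.iloc[i] - float(want[i])) < 1e-12


def test_rarefied_count_monotone_in_g():
    copies = np.array([7, 5])
    vals = [rarefacted_allele_count(copies, 12, g) for g in range(2, 13)]
    assert all(b >= a - 1e-15 for a, b in zip(vals, vals[1:]))
    assert vals[-1] == pytest.approx(2.0)  # full sample sees both alleles


def test_choose_rarefaction_size():
    counts = make_counts([[3, 2], [5, 0]], [[6, 8], [10, 12]])
    assert choose_rarefaction_size(counts) == 6
    assert choose_rarefaction_size(counts, override=4) == 4
    with pytest.raises(ValueError):
        choose_rarefaction_size(counts, override=1)


def test_private_allele_detected():
    # Reference allele only segregates in pop0; pop1/pop2 are fixed alternate.
    counts = make_counts([[4], [0], [0]], [[8], [8], [8]])
    P = private_allele_richness(counts, g=8)
    assert P["pop0"] > 0.9
    assert P["pop1"] == pytest.approx(0.0, abs=1e-12)
    assert P["pop2"] == pytest.approx(0.0, abs=1e-12)


def test_allelic_partition_additivity(rng):
    counts = random_counts(rng, n_subpops=5, n_loci=20)
    part = allelic_richness_partition(counts)
    assert part.AT == pytest.approx(part.AS + part.DA, abs=1e-14)
    assert np.allclose(part.d, part.d.T)
    assert np.all(np.diag(part.d) == 0)


# ------------------------------------------------ contributions --------------


def test_worked_contribution_example():
    # Three subpopulations, one locus, frequencies (1, 0, 1).  The divergent
    # subpopulation contributes +100% of HT; each of the two identical fixed
    # subpopulations contributes -12.5%.
    counts = make_counts([[20], [0], [20]], [[20], [20], [20]])
    tab = marginal_contributions(counts)
    assert tab.loc["pop1", "cHT"] == pytest.approx(100.0, abs=1e-9)
    assert tab.loc["pop0", "cHT"] == pytest.approx(-12.5, abs=1e-9)
    assert tab.loc["pop2", "cHT"] == pytest.approx(-12.5, abs=1e-9)


def test_contribution_additivity(rng):
    for _ in range(20):
        counts = random_counts(rng, n_subpops=5, n_loci=15)
        tab = marginal_contributions(counts)
        assert np.allclose(tab["cHS"] + tab["cDG"], tab["cHT"], atol=1e-10)
        assert np.allclose(tab["cAS"] + tab["cDA"], tab["cAT"], atol=1e-10)


def test_homogeneous_metapopulation_contributes_zero():
    row_ref = np.array([5, 3, 7, 2])
    row_tot = np.array([10, 10, 10, 10])
    counts = make_counts(np.tile(row_ref, (4, 1)), np.tile(row_tot, (4, 1)))
    tab = marginal_contributions(counts)
    for col in ("cHS", "cDG", "cHT", "cAS", "cDA", "cAT"):
        assert np.allclose(tab[col], 0.0, atol=1e-12), col


def test_outgroup_retained_not_targeted(rng):
    counts = random_counts(rng, n_subpops=4)
    tab = marginal_contributions(counts, outgroup="pop3")
    assert "pop3" not in tab.index
    assert set(tab.index) == {"pop0", "pop1", "pop2"}
    # Retaining the outgroup changes the removal baseline: removing pop0 from
    # {pop0..pop3} is not the same as from {pop0, pop1, pop2}.
    tab_no_og = marginal_contributions(counts.restricted_to(["pop0", "pop1", "pop2"]))
    assert not np.allclose(tab["cHT"], tab_no_og["cHT"])


def test_g_frozen_across_removals(rng):
    counts = random_counts(rng, n_subpops=4)
    tab = marginal_contributions(counts)
    assert tab["g"].nunique() == 1
    assert tab["g"].iloc[0] == choose_rarefaction_size(counts)


def test_group_level_singleton_groups_match_subpop_level(rng):
    counts = random_counts(rng, n_subpops=4)
    tab = marginal_contributions(counts)
    grp = group_level_partition(counts, {s: s.upper() for s in counts.subpop_labels})
    for s in counts.subpop_labels:
        assert grp.loc[s.upper(), "cHT"] == pytest.approx(tab.loc[s, "cHT"], abs=1e-10)
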