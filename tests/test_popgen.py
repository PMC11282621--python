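"""Diversity statistics: Ho, He, Fis, Weir-Cockerham theta."""

import itertools

import numpy as np
import pytest

from capricline import (
    MISSING,
    expected_heterozygosity,
    fis_from_het,
    observed_heterozygosity,
    pairwise_fst,
    population_stats,
    summarize_diversity,
)

from conftest import make_matrix


class TestObservedHeterozygosity:
    def test_all_hets(self):
        assert observed_heterozygosity(np.ones((4, 3))) == 1.0

    def test_no_hets(self):
        calls = np.array([[0, 2], [2, 0], [0, 0]])
        assert observed_heterozygosity(calls) == 0.0

    def test_hand_counted_with_missing(self):
        # locus 1: 2 hets of 4 called; locus 2: 1 het of 2 called
        calls = np.array(
            [[1, 1], [1, MISSING], [0, 0], [2, MISSING]], dtype=np.int8
        )
        assert observed_heterozygosity(calls) == pytest.approx((0.5 + 0.5) / 2)

    def test_no_usable_locus_errors(self):
        with pytest.raises(ValueError):
            observed_heterozygosity(np.full((3, 2), MISSING, dtype=np.int8))


def he_pair_enumeration_oracle(calls_one_locus):
    """Unbiased gene diversity as the probability that two allele copies
    drawn without replacement from the sample differ (direct enumeration)."""
    alleles = []
    for c in calls_one_locus:
        if c != MISSING:
            alleles += [1] * c + [0] * (2 - c)
    pairs = list(itertools.combinations(range(len(alleles)), 2))
    diff = sum(alleles[i] != alleles[j] for i, j in pairs)
    return diff / len(pairs)


class TestExpectedHeterozygosity:
    def test_monomorphic_is_zero(self):
        assert expected_heterozygosity(np.zeros((5, 2))) == 0.0
        assert expected_heterozygosity(np.full((5, 2), 2)) == 0.0

    def test_balanced_locus_formula(self):
        """p = 0.5 with 10 genotypes: (20/19) * 0.5."""
        calls = np.array([[1]] * 10)
        assert expected_heterozygosity(calls) == pytest.approx(20 / 19 * 0.5)

    @pytest.mark.parametrize(
        "locus",
        [(0, 1, 2, 1, 0), (2, 2, 1, 0, 1), (0, 0, 0, 1, 2), (1, 1, 1, 1, 1)],
    )
    def test_matches_allele_pair_enumeration(self, locus):
        calls = np.array(locus).reshape(-1, 1)
        assert expected_heterozygosity(calls) == pytest.approx(
            he_pair_enumeration_oracle(locus), rel=1e-12
        )

    def test_missing_handled_locus_wise(self):
        locus = (1, MISSING, 0, 2, MISSING)
        calls = np.array(locus).reshape(-1, 1)
        usable = [c for c in locus if c != MISSING]
        assert expected_heterozygosity(calls) == pytest.approx(
            he_pair_enumeration_oracle(usable)
        )


class TestFis:
    def test_equal_het_is_zero(self):
        assert fis_from_het(0.4, 0.4) == 0.0

    def test_printed_style_values(self):
        assert fis_from_het(0.376, 0.391) == pytest.approx(1 - 0.376 / 0.391)

    def test_homozygote_deficit_is_negative(self):
        assert fis_from_het(0.45, 0.40) < 0

    def test_zero_he_errors(self):
        with pytest.raises(ValueError, match="undefined"):
            fis_from_het(0.0, 0.0)


def wc_longhand_oracle(pop_counts_a, pop_counts_b):
    """Weir-Cockerham theta evaluated long-hand from genotype counts.

    ``pop_counts_*`` are per-locus (n_aa, n_ab, n_bb) tuples.  The a, b, c
    variance components are written out term by term, scalar arithmetic
    only, following the published two-allele, r=2 recipe.
    """
    num = den = 0.0
    for (aa1, ab1, bb1), (aa2, ab2, bb2) in zip(pop_counts_a, pop_counts_b):
        n1, n2 = aa1 + ab1 + bb1, aa2 + ab2 + bb2
        p1 = (2 * bb1 + ab1) / (2 * n1)
        p2 = (2 * bb2 + ab2) / (2 * n2)
        h1, h2 = ab1 / n1, ab2 / n2
        r = 2
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        if pbar in (0.0, 1.0):
            continue
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        num += a
        den += a + b + c
    return num / den


def counts_to_calls(counts):
    """Expand per-locus (n_aa, n_ab, n_bb) into a calls matrix."""
    n = sum(counts[0])
    calls = np.zeros((n, len(counts)), dtype=np.int8)
    for j, (aa, ab, bb) in enumerate(counts):
        calls[:, j] = [0] * aa + [1] * ab + [2] * bb
    return calls


class TestPairwiseFst:
    def test_identical_populations_near_zero(self, rng):
        p = rng.uniform(0.1, 0.9, size=400)
        calls = rng.binomial(2, p, size=(50, 400)).astype(np.int8)
        res = pairwise_fst(calls, calls.copy())
        assert abs(res.theta) < 0.02

    def test_fixed_opposite_alleles_is_one(self):
        a = np.zeros((5, 10), dtype=np.int8)
        b = np.full((5, 10), 2, dtype=np.int8)
        assert pairwise_fst(a, b).theta == pytest.approx(1.0)

    def test_matches_longhand_variance_components(self):
        """3-locus toy with written-out genotype counts."""
        counts_a = [(6, 3, 1), (2, 5, 3), (8, 2, 0)]
        counts_b = [(1, 4, 5), (5, 4, 1), (3, 5, 2)]
        res = pairwise_fst(counts_to_calls(counts_a), counts_to_calls(counts_b))
        assert res.theta == pytest.approx(wc_longhand_oracle(counts_a, counts_b), rel=1e-12)
        assert res.n_loci_used == 3

    def test_monomorphic_loci_excluded(self):
        counts_a = [(10, 0, 0), (2, 5, 3), (1, 5, 4)]
        counts_b = [(10, 0, 0), (5, 4, 1), (2, 6, 2)]
        res = pairwise_fst(counts_to_calls(counts_a), counts_to_calls(counts_b))
        assert res.n_loci_used == 2

    def test_single_individual_pop_rejected(self):
        with pytest.raises(ValueError):
            pairwise_fst(np.array([[1, 1]]), np.array([[0, 2], [2, 0]]))

    def test_self_split_theta_small_on_average(self, rng):
        """Random halves of one population: mean theta over 50 splits ~ 0."""
        p = rng.uniform(0.1, 0.9, size=300)
        calls = rng.binomial(2, p, size=(60, 300)).astype(np.int8)
        thetas = []
        for _ in range(50):
            perm = rng.permutation(60)
            thetas.append(pairwise_fst(calls[perm[:30]], calls[perm[30:]]).theta)
        assert abs(np.mean(thetas)) < 0.01


class TestAlleleSwapInvariance:
    def test_ho_he_invariant_to_counted_allele(self, rng):
        calls = rng.integers(-1, 3, size=(15, 40)).astype(np.int8)
        # ensure at least one called genotype per locus
        calls[0] = np.abs(calls[0])
        swapped = np.where(calls == MISSING, MISSING, 2 - calls).astype(np.int8)
        assert observed_heterozygosity(calls) == pytest.approx(
            observed_heterozygosity(swapped)
        )
        assert expected_heterozygosity(calls) == pytest.approx(
            expected_heterozygosity(swapped)
        )

    def test_theta_invariant_to_counted_allele(self, rng):
        p = rng.uniform(0.2, 0.8, 50)
        a = rng.binomial(2, p, size=(10, 50)).astype(np.int8)
        b = rng.binomial(2, np.clip(p + 0.2, 0, 1), size=(12, 50)).astype(np.int8)
        t1 = pairwise_fst(a, b).theta
        t2 = pairwise_fst(2 - a, 2 - b).theta
        assert t1 == pytest.approx(t2)


class TestSummaries:
    def test_continental_means_match_published(self, fixture_tables):
        means = {
            c: summarize_diversity(t.diversity) for c, t in fixture_tables.items()
        }
        # published means come from unrounded per-breed values; the table
        # entries are rounded to 3 decimals, so agreement is to ~0.002
        assert means["asia"]["ho"] == pytest.approx(0.381, abs=0.002)
        assert means["asia"]["he"] == pytest.approx(0.381, abs=0.002)
        assert means["africa"]["fis"] == pytest.approx(0.0033, abs=0.0001)
        assert means["europe"]["fis"] == pytest.approx(-0.0025, abs=0.0001)
        assert means["asia"]["fis"] == pytest.approx(-0.0012, abs=0.0001)

    def test_single_breed_subset_is_its_row(self, fixture_tables):
        div = fixture_tables["europe"].diversity
        out = summarize_diversity(div, ["CRP"])
        row = div.set_index("breed_id").loc["CRP"]
        assert out["ho"] == row["ho"] and out["he"] == row["he"]

    def test_empty_subset_errors(self, fixture_tables):
        with pytest.raises(ValueError):
            summarize_diversity(fixture_tables["asia"].diversity, [])


class TestPopulationStats:
    def test_consistency_of_components(self, rng):
        p = rng.uniform(0.1, 0.9, 100)
        calls = rng.binomial(2, p, size=(20, 100)).astype(np.int8)
        gm = make_matrix(calls)
        s = population_stats(gm, "B1")
        assert s.fis == pytest.approx(1 - s.ho / s.he)
        assert s.n_loci_used == 100
        assert s.n_individuals == 20
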