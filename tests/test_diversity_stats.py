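"""Diversity statistics: polymorphic sites, typing efficiency, Hunter–Gaston D,
and Nei–Gojobori dN/dS (cross-checked against independent oracles)."""

import math
from itertools import combinations, permutations, product

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from Bio.Data import CodonTable
from Bio.Seq import Seq

from mlstkit.diversity_stats import (
    count_polymorphic_sites,
    discriminatory_power,
    gene_dnds,
    locus_stats,
    nei_gojobori_pair,
    scheme_summary,
    typing_efficiency,
)
from mlstkit.synthetic_data import SimulationConfig, generate_allele_pool

_CT = CodonTable.unambiguous_dna_by_id[1]
STOPS = set(_CT.stop_codons)
SENSE = sorted(_CT.forward_table)


class TestPolymorphicSites:
    def test_examples(self):
        assert count_polymorphic_sites(["AAA", "AAT", "ATT"]) == 2
        assert count_polymorphic_sites(["ACGT", "ACGT"]) == 0
        assert count_polymorphic_sites(["ACGT"]) == 0

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            count_polymorphic_sites(["AAA", "AA"])


class TestTypingEfficiency:
    def test_values(self):
        assert typing_efficiency(5, 4) == pytest.approx(1.25)
        assert typing_efficiency(10, 10) == pytest.approx(1.0)

    def test_monomorphic_locus_undefined(self):
        assert typing_efficiency(3, 0) is None


def _pair_counting_oracle(counts):
    """Probability of a discordant unordered pair, by exhaustive enumeration."""
    labels = [i for i, c in enumerate(counts) for _ in range(c)]
    pairs = list(combinations(labels, 2))
    discordant = sum(1 for a, b in pairs if a != b)
    return discordant / len(pairs)


class TestDiscriminatoryPower:
    def test_closed_form_example(self):
        assert discriminatory_power([3, 2, 1]) == pytest.approx(1 - 8 / 30)
        assert discriminatory_power([3, 2, 1]) == pytest.approx(0.73333, abs=1e-5)

    def test_extremes(self):
        assert discriminatory_power([7]) == 0.0
        assert discriminatory_power([1] * 9) == 1.0

    def test_single_strain_rejected(self):
        with pytest.raises(ValueError):
            discriminatory_power([1])

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            n_groups = int(rng.integers(1, 12))
            counts = rng.integers(1, 15, size=n_groups).tolist()
            if sum(counts) < 2:
                continue
            assert discriminatory_power(counts) == pytest.approx(
                _pair_counting_oracle(counts)
            )

    @given(st.lists(st.integers(min_value=1, max_value=20), min_size=2, max_size=10))
    @settings(max_examples=50, derandomize=True)
    def test_relabeling_invariance(self, counts):
        assert discriminatory_power(counts) == pytest.approx(
            discriminatory_power(list(reversed(counts)))
        )

    @given(st.lists(st.integers(min_value=1, max_value=20), min_size=1, max_size=10))
    @settings(max_examples=50, derandomize=True)
    def test_splitting_a_strain_off_never_decreases_d(self, counts):
        largest = max(counts)
        if largest < 2 or sum(counts) < 3:
            return
        moved = sorted(counts)
        moved[-1] -= 1
        moved.append(1)
        assert discriminatory_power(moved) >= discriminatory_power(counts) - 1e-12


def _oracle_codon_diffs(c1, c2):
    """Independent minimal-pathway enumeration using Biopython translation."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    results = []
    for order in permutations(diff):
        cur, syn, non = c1, 0, 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOPS:
                blocked = True
                break
            if Seq(cur).translate() == Seq(nxt).translate():
                syn += 1
            else:
                non += 1
            cur = nxt
        if not blocked:
            results.append((syn, non))
    if not results:  # every path passes a stop; count all paths, stops nonsyn
        for order in permutations(diff):
            cur, syn, non = c1, 0, 0
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
                if nxt in STOPS or cur in STOPS:
                    non += 1
                elif Seq(cur).translate() == Seq(nxt).translate():
                    syn += 1
                else:
                    non += 1
                cur = nxt
            results.append((syn, non))
    sd = sum(r[0] for r in results) / len(results)
    nd = sum(r[1] for r in results) / len(results)
    return sd, nd


class TestNeiGojobori:
    def test_identical_sequences(self):
        r = nei_gojobori_pair("TTTAAA", "TTTAAA")
        assert (r.Sd, r.Nd, r.dS, r.dN) == (0.0, 0.0, 0.0, 0.0)

    def test_synonymous_single_change(self):
        r = nei_gojobori_pair("TTT", "TTC")  # Phe -> Phe
        assert (r.Sd, r.Nd) == (1.0, 0.0)

    def test_nonsynonymous_single_change(self):
        r = nei_gojobori_pair("TTT", "TTA")  # Phe -> Leu
        assert (r.Sd, r.Nd) == (0.0, 1.0)

    def test_symmetry(self):
        a, b = "TTTGCAAGA", "TTCGGAAGG"
        r1, r2 = nei_gojobori_pair(a, b), nei_gojobori_pair(b, a)
        assert (r1.Sd, r1.Nd, r1.S, r1.N) == (r2.Sd, r2.Nd, r2.S, r2.N)

    def test_differences_sum_to_nucleotide_distance(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            c1, c2 = (SENSE[i] for i in rng.integers(0, len(SENSE), 2))
            r = nei_gojobori_pair(c1, c2)
            assert r.Sd + r.Nd == pytest.approx(
                sum(1 for a, b in zip(c1, c2) if a != b)
            )

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            nei_gojobori_pair("TAATTT", "TAATTC")

    def test_jukes_cantor_undefined_at_saturation(self):
        # force pN near 1: every position differs non-synonymously is hard,
        # so call the correction directly through a crafted extreme pair
        from mlstkit.diversity_stats import _jukes_cantor

        assert _jukes_cantor(0.8) is None
        assert _jukes_cantor(0.1) == pytest.approx(-0.75 * math.log(1 - 0.4 / 3))

    def test_matches_biopython_ng86_on_random_orfs(self):
        from Bio.Align import Alignment, analysis
        from mlstkit.synthetic_data import _mutate_orf, _random_orf

        rng = np.random.default_rng(17)
        for _ in range(5):
            a = _random_orf(rng, 240)
            b = _mutate_orf(a, 10, 0.5, rng)
            mine = nei_gojobori_pair(a, b)
            dn, ds = analysis.calculate_dn_ds(Alignment([a, b]), method="NG86")
            assert mine.dN == pytest.approx(dn, abs=1e-9)
            assert mine.dS == pytest.approx(ds, abs=1e-9)


class TestGeneDnDs:
    def test_identical_sequences_ratio_undefined(self):
        dn, ds, ratio = gene_dnds(["TTTAAA", "TTTAAA", "TTTAAA"])
        assert dn == 0.0 and ds == 0.0
        assert ratio is None

    def test_pure_synonymous_pool_has_zero_dn(self):
        cfg = SimulationConfig(seed=23, n_loci=1, locus_length=300,
                               n_alleles_per_locus=5, n_strains=5, n_STs=2,
                               mutation_rate=0.02, syn_bias=1.0)
        pools, _, _ = generate_allele_pool(cfg)
        seqs = list(next(iter(pools.values())).alleles.values())
        dn, ds, ratio = gene_dnds(seqs)
        assert dn == 0.0
        assert ds > 0.0
        assert ratio == 0.0

    def test_three_sequences_equal_mean_of_pairs(self):
        seqs = ["TTTGCAAGA", "TTCGCAAGA", "TTTGGAAGA"]
        dn, ds, _ = gene_dnds(seqs, jukes_cantor=False)
        pairs = [
            nei_gojobori_pair(a, b, jukes_cantor=False)
            for a, b in combinations(seqs, 2)
        ]
        assert dn == pytest.approx(sum(p.dN for p in pairs) / 3)
        assert ds == pytest.approx(sum(p.dS for p in pairs) / 3)

    def test_distinct_only_mode_uses_allele_representatives(self):
        seqs = ["TTTGCA"] * 5 + ["TTCGCA"]
        dn_all, ds_all, _ = gene_dnds(seqs, jukes_cantor=False)
        dn_distinct, ds_distinct, _ = gene_dnds(seqs, jukes_cantor=False,
                                                distinct_only=True)
        # with duplicates most pairs are identical, diluting the mean
        assert ds_distinct > ds_all

    def test_syn_bias_half_gives_moderate_ratio(self):
        """Sanity band: a 50/50 substitution mix should not look like strong
        purifying or positive selection at the counting level."""
        cfg = SimulationConfig(seed=31, n_loci=1, locus_length=600,
                               n_alleles_per_locus=8, n_strains=8, n_STs=4,
                               mutation_rate=0.02, syn_bias=0.5)
        pools, _, _ = generate_allele_pool(cfg)
        seqs = list(next(iter(pools.values())).alleles.values())
        dn, ds, ratio = gene_dnds(seqs)
        # equal substitution counts, but ~3x fewer synonymous sites
        assert 0.1 < ratio < 1.0


class TestSchemeSummary:
    def test_mean_over_loci(self, study_sim):
        stats = [
            locus_stats(locus, list(pool.alleles.values()))
            for locus, pool in list(study_sim.db.alleles.items())[:2]
        ]
        manual = (stats[0].discriminatory_power + stats[1].discriminatory_power) / 2
        summary = scheme_summary("SYN", [1, 1, 2], stats)
        assert summary.mean_D == pytest.approx(manual)
        assert summary.n_STs == 2

    def test_single_locus_scheme(self):
        s = locus_stats("x", ["TTTGCA", "TTCGCA", "TTTGCA"])
        summary = scheme_summary("MINI", [1, 2, 1], [s])
        assert summary.mean_D == pytest.approx(s.discriminatory_power)

    def test_st_count_matches_planted(self, study_sim):
        summary = scheme_summary(
            "SYN", [s.st for s in study_sim.truth.strains], []
        )
        assert summary.n_STs == 31
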