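import itertools
import math

import numpy as np
import pytest
from Bio.Data import CodonTable
from hypothesis import given, settings
from hypothesis import strategies as st

from mitolocus.alignment_io import make_alignment
from mitolocus.distances import (
    bootstrap_se,
    codon_mask_from_columns,
    complete_deletion,
    complete_deletion_codons,
    k2p_distance,
    k2p_from_pq,
    ng_differences,
    ng_distance,
    ng_site_counts,
    p_distance,
    pairwise_matrix,
    transition_transversion_proportions,
)
from mitolocus.errors import (
    AlignmentError,
    InputError,
    SaturationError,
    UndefinedDistanceError,
)

MITO = CodonTable.unambiguous_dna_by_id[2]
SENSE_CODONS = sorted(MITO.forward_table)

dna_pairs = st.integers(0, 2**31 - 1).map(
    lambda seed: _random_pair(np.random.default_rng(seed))
)


def _random_pair(rng, length=60):
    bases = np.array(list("ACGT"))
    s1 = "".join(rng.choice(bases, size=length))
    s2 = "".join(
        b if rng.random() > 0.3 else rng.choice(bases) for b in s1
    )
    return s1, s2


def brute_force_k2p(s1, s2):
    """Independent oracle: explicit site loop for P and Q, then the
    closed-form correction."""
    purines, pyrimidines = set("AG"), set("CT")
    ts = tv = 0
    for a, b in zip(s1, s2):
        if a == b:
            continue
        if {a, b} <= purines or {a, b} <= pyrimidines:
            ts += 1
        else:
            tv += 1
    p, q = ts / len(s1), tv / len(s1)
    return -0.5 * math.log(1 - 2 * p - q) - 0.25 * math.log(1 - 2 * q)


class TestCompleteDeletion:
    def test_gapless_unchanged(self, tiny_alignment):
        clean, kept = complete_deletion(tiny_alignment)
        assert clean.records == tiny_alignment.records
        assert kept == list(range(1, 13))

    def test_column_with_single_gap_removed_for_all(self):
        aln = make_alignment([("a", "A-GT"), ("b", "ACGT"), ("c", "ACGT")])
        clean, kept = complete_deletion(aln)
        assert clean.length == 3
        assert kept == [1, 3, 4]

    def test_ambiguity_column_removed(self):
        aln = make_alignment([("a", "ARGT"), ("b", "ACGT")])
        clean, _ = complete_deletion(aln)
        assert clean.length == 3

    def test_all_columns_removed_is_error(self):
        aln = make_alignment([("a", "R-N"), ("b", "ACG")])
        with pytest.raises(AlignmentError):
            complete_deletion(aln)

    def test_codon_wise_deletion_preserves_frame(self):
        # a gap in codon 2 removes that whole codon for all sequences
        aln = make_alignment([("a", "ATGA-GTTC"), ("b", "ATGACGTTC")])
        clean, kept_codons = complete_deletion_codons(aln)
        assert clean.length == 6
        assert kept_codons == [1, 3]
        assert clean.sequences[0] == "ATGTTC"

    def test_position_mask_rederived_after_deletion(self):
        # original columns 1..9, column 5 (a 2nd position) removed
        mask = codon_mask_from_columns([1, 2, 3, 4, 6, 7, 8, 9])
        assert mask.positions(1) == frozenset({1, 4, 6})  # orig 1, 4, 7
        assert mask.positions(2) == frozenset({2, 7})  # orig 2, 8
        assert mask.positions(3) == frozenset({3, 5, 8})  # orig 3, 6, 9


class TestPDistance:
    def test_identical(self):
        assert p_distance("ACGT", "ACGT") == 0.0

    def test_one_in_four(self):
        assert p_distance("ACGT", "ACGA") == pytest.approx(0.25)

    def test_three_in_twenty(self):
        s1 = "A" * 20
        s2 = "G" * 2 + "T" * 1 + "A" * 17  # 2 transitions + 1 transversion
        assert p_distance(s1, s2) == pytest.approx(0.15)

    def test_empty_subset_rejected(self):
        with pytest.raises(UndefinedDistanceError):
            p_distance("ACGT", "ACGT", np.array([], dtype=int))


class TestK2P:
    def test_identical(self):
        assert k2p_distance("ACGT", "ACGT") == 0.0

    def test_worked_example(self):
        # 20 sites, 2 transitions + 1 transversion: P=0.1, Q=0.05
        s1 = "A" * 20
        s2 = "G" * 2 + "T" + "A" * 17
        p, q = transition_transversion_proportions(s1, s2)
        assert (p, q) == (0.1, 0.05)
        assert k2p_distance(s1, s2) == pytest.approx(0.170181, abs=1e-6)

    def test_saturation_error(self):
        with pytest.raises(SaturationError):
            k2p_from_pq(0.5, 0.0)

    @given(dna_pairs)
    @settings(derandomize=True, max_examples=100)
    def test_agrees_with_brute_force_oracle(self, pair):
        s1, s2 = pair
        try:
            expected = brute_force_k2p(s1, s2)
        except ValueError:
            with pytest.raises(SaturationError):
                k2p_distance(s1, s2)
            return
        assert k2p_distance(s1, s2) == pytest.approx(expected, abs=1e-12)

    @given(dna_pairs)
    @settings(derandomize=True, max_examples=100)
    def test_k2p_at_least_p_distance(self, pair):
        s1, s2 = pair
        try:
            k2p = k2p_distance(s1, s2)
        except SaturationError:
            return
        p = p_distance(s1, s2)
        assert k2p >= p - 1e-12
        if p == 0.0:
            assert k2p == 0.0


def brute_force_pathways(c1, c2):
    """Independent pathway enumeration using translated amino acids only."""
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    results = []
    for order in itertools.permutations(diffs):
        cur, sd, nd, ok = c1, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in MITO.stop_codons:
                ok = False
                break
            sd += MITO.forward_table[cur] == MITO.forward_table[nxt]
            nd += MITO.forward_table[cur] != MITO.forward_table[nxt]
            cur = nxt
        if ok:
            results.append((sd, nd))
    return results


class TestNeiGojobori:
    def test_phe_codon_one_third_synonymous(self):
        # TTT: only TTT->TTC of the nine single-base changes is synonymous
        prof = ng_site_counts("TTT")
        assert prof.s_sites == pytest.approx(1 / 3)
        assert prof.n_sites == pytest.approx(3 - 1 / 3)

    def test_val_codon_fully_degenerate_third_position(self):
        prof = ng_site_counts("GTT")
        assert prof.s_sites == pytest.approx(1.0)

    def test_sites_conservation_identity(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            codons = rng.choice(SENSE_CODONS, size=20)
            seq = "".join(codons)
            prof = ng_site_counts(seq)
            assert prof.s_sites + prof.n_sites == pytest.approx(3 * 20)

    def test_internal_stop_rejected(self):
        with pytest.raises(InputError):
            ng_site_counts("TTTAGATTT")

    def test_simple_differences(self):
        assert ng_differences("TTT", "TTT") == (0.0, 0.0)
        assert ng_differences("TTT", "TTC") == (1.0, 0.0)  # Phe->Phe
        assert ng_differences("TTT", "GTT") == (0.0, 1.0)  # Phe->Val

    def test_exhaustive_pathway_enumeration_all_sense_pairs(self):
        """sd+nd equals the number of differing positions for every
        ordered pair of sense codons with a valid pathway, and the
        averaged counts match an independent enumerator."""
        checked = 0
        for c1 in SENSE_CODONS:
            for c2 in SENSE_CODONS:
                k = sum(a != b for a, b in zip(c1, c2))
                paths = brute_force_pathways(c1, c2)
                if not paths:
                    with pytest.raises(UndefinedDistanceError):
                        ng_differences(c1, c2)
                    continue
                sd, nd = ng_differences(c1, c2)
                assert sd + nd == pytest.approx(k)
                assert sd == pytest.approx(np.mean([p[0] for p in paths]))
                assert nd == pytest.approx(np.mean([p[1] for p in paths]))
                checked += 1
        assert checked > 3000  # nearly all of the 3600 ordered sense pairs

    def test_distance_examples(self):
        assert ng_distance("TTTGTT", "TTTGTT") == (0.0, 0.0)
        ds, dn = ng_distance("TTTGTT", "TTCGTT")
        mean_s = 0.5 * (
            ng_site_counts("TTTGTT").s_sites + ng_site_counts("TTCGTT").s_sites
        )
        assert ds == pytest.approx(1.0 / mean_s)
        assert dn == 0.0


class TestPairwiseMatrix:
    def test_symmetric_zero_diagonal(self, tiny_alignment):
        mat = pairwise_matrix(tiny_alignment, "p")
        assert np.allclose(mat.values, mat.values.T)
        assert np.allclose(np.diag(mat.values), 0.0)

    @pytest.mark.parametrize("n,expected", [(3, 3), (5, 10), (1343, 901153)])
    def test_unordered_pair_count(self, n, expected):
        assert n * (n - 1) // 2 == expected

    def test_condensed_matches_pair_count(self, tiny_alignment):
        mat = pairwise_matrix(tiny_alignment, "p")
        assert mat.condensed().size == 3

    def test_position_subsets_partition_signal(self):
        # differences only at third positions show up only in pos3
        aln = make_alignment([("a", "ATGATGATG"), ("b", "ATAATAATC")])
        assert pairwise_matrix(aln, "p", "pos1").values[0, 1] == 0.0
        assert pairwise_matrix(aln, "p", "pos2").values[0, 1] == 0.0
        assert pairwise_matrix(aln, "p", "pos3").values[0, 1] == pytest.approx(1.0)


class TestBootstrap:
    def test_invariant_alignment_zero_se(self):
        aln = make_alignment([("a", "ACGT" * 30), ("b", "ACGT" * 30)])
        result = bootstrap_se(aln, "p", replicates=50, seed=1)
        assert result.se == 0.0

    def test_deterministic_given_seed(self, tiny_alignment):
        r1 = bootstrap_se(tiny_alignment, "p", replicates=100, seed=7)
        r2 = bootstrap_se(tiny_alignment, "p", replicates=100, seed=7)
        assert r1.se == r2.se

    def test_matches_analytic_binomial_se(self):
        # two sequences, p = 0.1 over 1,000 sites: SE ~ sqrt(p(1-p)/L)
        rng = np.random.default_rng(12)
        length = 1000
        s1 = "".join(rng.choice(list("ACGT"), size=length))
        diff_sites = rng.choice(length, size=100, replace=False)
        s2 = list(s1)
        for i in diff_sites:
            choices = [b for b in "ACGT" if b != s2[i]]
            s2[i] = choices[rng.integers(0, 3)]
        aln = make_alignment([("a", s1), ("b", "".join(s2))])
        result = bootstrap_se(aln, "p", replicates=1000, seed=3)
        analytic = math.sqrt(0.1 * 0.9 / length)
        assert result.se == pytest.approx(analytic, rel=0.2)
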