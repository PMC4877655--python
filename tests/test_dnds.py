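"""NG86 site/difference counting against a brute-force oracle, and omega recovery."""

import math

import numpy as np
import pytest

from ladderlens.dnds import (SENSE_CODONS, STOP_CODONS, DndsEstimate,
                             codon_site_counts, locus_mean_dnds,
                             pairwise_dnds, pathway_difference_counts,
                             translate)
from ladderlens.io import CodonRecord
from ladderlens.simulate import simulate_codon_family, simulate_codon_pair

# ---------------------------------------------------------------------------
# Independent oracle: recursive pathway enumeration over the codon graph
# ---------------------------------------------------------------------------

def oracle_site_counts(codon):
    aa = translate(codon)
    s = 0.0
    for pos in range(3):
        changes = [codon[:pos] + nt + codon[pos + 1 :]
                   for nt in "ACGT" if nt != codon[pos]]
        sense = [c for c in changes if c not in STOP_CODONS]
        if sense:
            s += sum(translate(c) == aa for c in sense) / len(sense)
    return 3.0 - s, s


def oracle_pathway_counts(a, b):
    """Depth-first enumeration of codon-graph paths changing one differing
    position at a time; stop-containing paths excluded, survivors averaged."""
    results = []

    def walk(current, remaining, nd, sd, blocked):
        if not remaining:
            results.append((nd, sd, blocked))
            return
        for pos in remaining:
            nxt = current[:pos] + b[pos] + current[pos + 1 :]
            rest = [p for p in remaining if p != pos]
            if nxt in STOP_CODONS:
                walk(nxt, rest, nd + 1, sd, True)
            elif current in STOP_CODONS:
                walk(nxt, rest, nd + 1, sd, True)
            elif translate(current) == translate(nxt):
                walk(nxt, rest, nd, sd + 1, blocked)
            else:
                walk(nxt, rest, nd + 1, sd, blocked)

    diff = [i for i in range(3) if a[i] != b[i]]
    if not diff:
        return 0.0, 0.0
    walk(a, diff, 0, 0, False)
    valid = [(nd, sd) for nd, sd, blocked in results if not blocked]
    pool = valid if valid else [(nd, sd) for nd, sd, _ in results]
    return (sum(p[0] for p in pool) / len(pool),
            sum(p[1] for p in pool) / len(pool))


class TestSiteCounts:
    def test_phenylalanine_codon(self):
        n, s = codon_site_counts("TTT")
        assert s == pytest.approx(1 / 3)
        assert n == pytest.approx(8 / 3)

    def test_methionine_codon(self):
        n, s = codon_site_counts("ATG")
        assert (n, s) == (3.0, 0.0)

    def test_sites_conserve_three_per_codon(self):
        for codon in SENSE_CODONS:
            n, s = codon_site_counts(codon)
            assert n + s == pytest.approx(3.0)

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            codon_site_counts("TAA")

    def test_all_codons_match_oracle(self):
        for codon in SENSE_CODONS:
            assert codon_site_counts(codon) == pytest.approx(oracle_site_counts(codon))


class TestPathwayCounts:
    def test_all_codon_pairs_match_oracle(self):
        """Implementation (permutation averaging) equals independent
        recursive path enumeration for every sense-codon pair."""
        for a in SENSE_CODONS:
            for b in SENSE_CODONS:
                got = pathway_difference_counts(a, b)
                exp = oracle_pathway_counts(a, b)
                assert got == pytest.approx(exp), (a, b)

    def test_total_differences_conserved(self):
        for a in SENSE_CODONS[::7]:
            for b in SENSE_CODONS[::5]:
                nd, sd = pathway_difference_counts(a, b)
                k = sum(x != y for x, y in zip(a, b))
                assert nd + sd == pytest.approx(k)


class TestPairwise:
    def test_identical_sequences(self):
        a = CodonRecord(id="a", sequence="ATGTTTAAA")
        est = pairwise_dnds(a, CodonRecord(id="b", sequence="ATGTTTAAA"))
        assert est.nd == est.sd == 0.0
        assert est.dn == est.ds == 0.0
        assert est.omega is None

    def test_single_synonymous_difference(self):
        a = CodonRecord(id="a", sequence="TTT")
        b = CodonRecord(id="b", sequence="TTC")
        est = pairwise_dnds(a, b)
        assert est.sd == 1.0 and est.nd == 0.0
        assert est.s_sites == pytest.approx(1 / 3)
        assert est.ps == pytest.approx(3.0)  # saturated on one codon
        assert est.ds is None and est.omega is None

    def test_sites_averaged_over_both_sequences(self):
        a = CodonRecord(id="a", sequence="TTTATG")
        b = CodonRecord(id="b", sequence="CTTATG")  # Phe -> Leu
        est = pairwise_dnds(a, b)
        na, sa = codon_site_counts("TTT")
        nb, sb = codon_site_counts("CTT")
        nm, sm = codon_site_counts("ATG")
        assert est.n_sites == pytest.approx((na + nb) / 2 + nm)
        assert est.s_sites == pytest.approx((sa + sb) / 2 + sm)
        assert est.n_sites + est.s_sites == pytest.approx(3 * est.n_codons)

    def test_ambiguous_codons_skipped(self):
        a = CodonRecord(id="a", sequence="ATGNNNTTT")
        b = CodonRecord(id="b", sequence="ATGAAATTC")
        est = pairwise_dnds(a, b)
        assert est.n_codons == 2

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            pairwise_dnds(CodonRecord(id="a", sequence="ATG"),
                          CodonRecord(id="b", sequence="ATGATG"))

    def test_sites_conservation_on_simulated_pairs(self):
        for seed in range(5):
            a, b, _ = simulate_codon_pair(100, 0.5, 0.4, seed=seed)
            est = pairwise_dnds(a, b)
            assert est.n_sites + est.s_sites == pytest.approx(3 * est.n_codons)
            assert est.nd <= est.n_sites and est.sd <= est.s_sites


class TestLocusSummary:
    def test_identical_sequences_error(self):
        recs = [CodonRecord(id=f"s{i}", sequence="ATGTTTAAA" * 10) for i in range(5)]
        with pytest.raises(ValueError, match="no sequence pair"):
            locus_mean_dnds(recs, n_boot=10, seed=1)

    def test_below_five_sequences_warns(self):
        recs, _ = simulate_codon_family(3, 120, 0.5, 0.4, seed=1)
        with pytest.warns(UserWarning, match="fewer than 5"):
            locus_mean_dnds(recs, n_boot=10, seed=1)

    def test_deterministic_under_seed(self):
        recs, _ = simulate_codon_family(6, 150, 0.3, 0.3, seed=2)
        s1 = locus_mean_dnds(recs, n_boot=50, seed=9)
        s2 = locus_mean_dnds(recs, n_boot=50, seed=9)
        assert (s1.mean_omega, s1.ci_low, s1.ci_high) == \
            (s2.mean_omega, s2.ci_low, s2.ci_high)

    def test_purifying_selection_recovered(self):
        means = []
        for seed in range(10):
            recs, _ = simulate_codon_family(10, 300, 0.2, 0.3, seed=seed)
            s = locus_mean_dnds(recs, n_boot=50, seed=seed)
            means.append(s.mean_omega)
        assert 0.1 <= float(np.mean(means)) <= 0.35

    def test_neutral_evolution_recovered(self):
        means = []
        for seed in range(10):
            recs, _ = simulate_codon_family(10, 300, 1.0, 0.3, seed=seed)
            s = locus_mean_dnds(recs, n_boot=50, seed=seed)
            means.append(s.mean_omega)
        assert 0.8 <= float(np.mean(means)) <= 1.25

    def test_ci_brackets_mean(self):
        recs, _ = simulate_codon_family(8, 200, 0.4, 0.3, seed=5)
        s = locus_mean_dnds(recs, n_boot=100, seed=5)
        assert s.ci_low <= s.mean_omega <= s.ci_high


class TestEstimateInvariants:
    def test_saturation_flagged_and_distance_undefined(self):
        est = pairwise_dnds(CodonRecord(id="a", sequence="TTT"),
                            CodonRecord(id="b", sequence="TTC"))
        assert est.saturated and est.ds is None

    def test_realistic_pairs_keep_counts_within_sites(self):
        for seed in range(5):
            a, b, _ = simulate_codon_pair(200, 0.5, 0.3, seed=seed)
            est = pairwise_dnds(a, b)
            assert est.nd <= est.n_sites and est.sd <= est.s_sites
            assert not est.saturated
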