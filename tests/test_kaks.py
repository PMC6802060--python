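"""Codon-statistics tests, anchored by an independent brute-force oracle
for the Nei–Gojobori counting method."""

import itertools
import math

import numpy as np
import pytest
from Bio.Seq import Seq

from retroforge.kaks import (
    CodonAlignment,
    DatingParams,
    classify_selection,
    codon_align,
    codon_pairs_from_cds,
    estimate_age,
    ks_histogram,
    ng86,
)
from retroforge.simulate import _mutate, _random_cds

STOPS = {"TAA", "TAG", "TGA"}


# --------------------------------------------------------------------------
# independent oracle: plain-string enumeration of neighbours and pathways


def oracle_syn_sites(codon):
    aa = str(Seq(codon).translate())
    syn = 0
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            neighbour = codon[:pos] + base + codon[pos + 1 :]
            if neighbour in STOPS:
                continue  # change to a stop counts as nonsynonymous
            if str(Seq(neighbour).translate()) == aa:
                syn += 1
    return syn / 3.0


def oracle_pathways(c1, c2):
    positions = [i for i in range(3) if c1[i] != c2[i]]
    results, blocked_results = [], []
    for order in itertools.permutations(positions):
        cur, sd, nd, blocked = c1, 0, 0, False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOPS:
                blocked = True
                break
            if str(Seq(cur).translate()) == str(Seq(nxt).translate()):
                sd += 1
            else:
                nd += 1
            cur = nxt
        if not blocked:
            results.append((sd, nd))
    if results:
        return results
    for order in itertools.permutations(positions):
        cur, sd, nd = c1, 0, 0
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            same = str(Seq(cur).translate()) == str(Seq(nxt).translate())
            if same and cur not in STOPS and nxt not in STOPS:
                sd += 1
            else:
                nd += 1
            cur = nxt
        blocked_results.append((sd, nd))
    return blocked_results


def oracle_ng86(pairs):
    s_sites = sd = nd = 0.0
    for a, b in pairs:
        s_sites += (oracle_syn_sites(a) + oracle_syn_sites(b)) / 2
        paths = oracle_pathways(a, b)
        sd += sum(p[0] for p in paths) / len(paths)
        nd += sum(p[1] for p in paths) / len(paths)
    n_sites = 3 * len(pairs) - s_sites
    return n_sites, s_sites, nd, sd


# --------------------------------------------------------------------------


def _random_pairs(rng, n_codons, rate):
    cds = _random_cds(rng, n_codons)
    mut, _ = _mutate(rng, cds, rate, 1.0, False)
    return codon_pairs_from_cds(cds, mut).pairs


class TestNg86:
    def test_counts_match_bruteforce_oracle_exactly(self):
        rng = np.random.default_rng(17)
        for trial in range(20):
            rate = [0.01, 0.05, 0.15, 0.4][trial % 4]
            pairs = _random_pairs(rng, 100, rate)
            res = ng86(pairs)
            n, s, nd, sd = oracle_ng86(pairs)
            assert res.n_sites == pytest.approx(n, abs=1e-9)
            assert res.s_sites == pytest.approx(s, abs=1e-9)
            assert res.nd == pytest.approx(nd, abs=1e-9)
            assert res.sd == pytest.approx(sd, abs=1e-9)

    def test_identical_sequences_have_zero_rates_and_no_omega(self):
        pairs = _random_pairs(np.random.default_rng(0), 50, 0.0)
        res = ng86(pairs)
        assert res.ka == 0.0 and res.ks == 0.0 and res.omega is None

    def test_pure_synonymous_divergence_gives_zero_ka_positive_ks(self):
        pairs = [("TTT", "TTC")] * 5 + [("AAA", "AAA")] * 55
        res = ng86(pairs)
        assert res.nd == 0.0 and res.ka == 0.0
        assert res.ks is not None and res.ks > 0.0

    def test_symmetric_in_sequence_order(self):
        rng = np.random.default_rng(5)
        pairs = _random_pairs(rng, 80, 0.1)
        fwd = ng86(pairs)
        rev = ng86([(b, a) for a, b in pairs])
        assert (fwd.n_sites, fwd.s_sites, fwd.nd, fwd.sd) == (
            rev.n_sites,
            rev.s_sites,
            rev.nd,
            rev.sd,
        )

    def test_sites_sum_to_three_per_codon(self):
        pairs = _random_pairs(np.random.default_rng(2), 60, 0.2)
        res = ng86(pairs)
        assert res.n_sites + res.s_sites == pytest.approx(3 * len(pairs))

    def test_saturation_is_flagged_not_negative(self):
        # every codon differs synonymously: ps = Sd/S = 3 saturates JC
        res = ng86([("TTT", "TTC")] * 30)
        assert res.ks is None and res.saturated_ks and res.omega is None

    def test_short_alignment_rejected(self):
        with pytest.raises(ValueError):
            ng86([("AAA", "AAA")], min_codons=10)


class TestCodonAlign:
    def test_identical_cds_aligns_every_codon(self):
        cds = _random_cds(np.random.default_rng(1), 100)
        aln = codon_align(cds, cds)
        assert len(aln) == 100 and aln.identity == 1.0

    def test_single_codon_deletion_drops_one_column(self):
        cds = _random_cds(np.random.default_rng(2), 100)
        deleted = cds[:150] + cds[153:]
        aln = codon_align(cds, deleted)
        assert len(aln) == 99

    def test_backthreaded_identity_matches_nucleotide_divergence(self):
        rng = np.random.default_rng(3)
        cds = _random_cds(rng, 50)
        mut, _ = _mutate(rng, cds, 0.02, 1.0, False)
        aln = codon_align(cds, mut)
        direct = codon_pairs_from_cds(cds, mut)
        assert aln.pairs == direct.pairs

    def test_rejects_stop_codons_in_pairs(self):
        with pytest.raises(ValueError):
            CodonAlignment([("TAA", "AAA")])


class TestDating:
    def test_zero_ks_is_zero_age(self):
        assert estimate_age(0.0) == 0.0

    def test_canid_calibration_maps_ks_002_to_7p5_mya(self):
        assert estimate_age(0.02) == pytest.approx(7.5, abs=0.05)

    def test_printed_rounded_rate_maps_ks_00266_to_10_mya(self):
        rounded = DatingParams(per_generation_rate=1.33e-9 * 3, generation_time_years=3.0)
        assert estimate_age(0.0266, rounded) == pytest.approx(10.0, abs=0.05)

    def test_lambda_derives_from_generation_rate_and_time(self):
        p = DatingParams()
        assert p.lambda_per_year == pytest.approx(p.per_generation_rate / p.generation_time_years)

    def test_age_is_linear_in_ks(self):
        assert estimate_age(0.08) == pytest.approx(2 * estimate_age(0.04))

    def test_saturated_ks_has_no_age(self):
        assert estimate_age(None) is None


class TestSelectionClasses:
    @pytest.mark.parametrize(
        "ka,ks,expected",
        [
            (0.015, 0.05, "constrained"),  # omega 0.3
            (0.05, 0.05, "intermediate"),  # omega 1.0
            (0.06, 0.05, "intermediate"),  # omega 1.2: inclusive upper edge
            (0.065, 0.05, "elevated"),  # omega 1.3
        ],
    )
    def test_omega_bins(self, ka, ks, expected):
        from retroforge.kaks import KaKsResult

        res = KaKsResult(100, 225.0, 75.0, 1, 1, 0.0, 0.0, ka, ks)
        assert classify_selection(res) == expected

    def test_ks_zero_is_undefined(self):
        from retroforge.kaks import KaKsResult

        res = KaKsResult(100, 225.0, 75.0, 0, 0, 0.0, 0.0, 0.0, 0.0)
        assert classify_selection(res) == "undefined"


class TestKsHistogram:
    def test_single_value_fills_one_bin(self):
        h = ks_histogram([0.03] * 10)
        assert h.modal_bin == (0.02, 0.04)
        assert h.fractions[1] == 1.0

    def test_pooled_tail_bins(self):
        h = ks_histogram([0.5, 1.5, 2.5])
        counts = dict(zip(h.edges, h.counts))
        assert counts[(0.5, 0.52)] == 1
        assert counts[(1.0, 2.0)] == 1
        assert counts[(2.0, math.inf)] == 1

    def test_counts_sum_to_input_size(self):
        vals = list(np.random.default_rng(0).uniform(0, 3, size=200))
        h = ks_histogram(vals)
        assert sum(h.counts) == 200
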