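"""NG86 counting estimator against an independently coded brute-force
pathway-enumeration oracle, plus the exclusion and classification rules."""

import random

import numpy as np
import pytest

import oracles
from tickdup._codons import SENSE_CODONS, STOP_CODONS
from tickdup.kaks import (
    CodonAlignment,
    KaKsResult,
    build_codon_alignment,
    classify_selection,
    compute_kaks,
    count_differences,
    count_sites,
    jukes_cantor,
)
from tickdup.synthetic_data import evolve_pair, simulate_ancestral_cds


class TestCountSites:
    def test_sites_sum_to_three_for_every_sense_codon(self):
        for codon in SENSE_CODONS:
            s, n = count_sites(codon)
            assert s + n == pytest.approx(3.0, abs=1e-12)
            assert (s, n) == pytest.approx(oracles.site_counts(codon), abs=1e-12)

    def test_fourfold_degenerate_third_position(self):
        # glycine: any third-position change is synonymous
        s, _ = count_sites("GGA")
        assert s == pytest.approx(1.0)

    def test_met_has_no_synonymous_sites(self):
        assert count_sites("ATG")[0] == 0.0

    @pytest.mark.parametrize("stop", sorted(STOP_CODONS))
    def test_stop_codons_rejected(self, stop):
        with pytest.raises(ValueError):
            count_sites(stop)


class TestCountDifferences:
    def test_identical_codons(self):
        assert count_differences("AAA", "AAA") == (0.0, 0.0)

    def test_single_synonymous_third_position_change(self):
        assert count_differences("TTT", "TTC") == (1.0, 0.0)

    def test_matches_enumeration_oracle_on_random_pairs(self, rng):
        from conftest import random_codon_pair

        for _ in range(500):
            a, b = random_codon_pair(rng)
            try:
                expected = oracles.diff_counts(a, b)
            except ValueError:
                with pytest.raises(ValueError):
                    count_differences(a, b)
                continue
            got = count_differences(a, b)
            assert got == pytest.approx(expected, abs=1e-12)
            d = sum(x != y for x, y in zip(a, b))
            assert sum(got) == pytest.approx(d, abs=1e-12)


def _alignment(cols_a, cols_b, pair_id="t"):
    return CodonAlignment(pair_id, tuple(cols_a), tuple(cols_b))


class TestComputeKaks:
    def test_identical_pair_excluded(self):
        aln = _alignment(["ATG", "GGA"] * 50, ["ATG", "GGA"] * 50)
        r = compute_kaks(aln)
        assert r.excluded and r.exclusion_reason == "identical"
        assert r.Ka == 0.0 and r.Ks == 0.0

    def test_pure_synonymous_divergence_is_negative_selection(self):
        # 10 third-position synonymous changes among 100 glycine codons
        a = ["GGA"] * 100
        b = ["GGT"] * 10 + ["GGA"] * 90
        r = compute_kaks(_alignment(a, b))
        S, N, Sd, Nd, Ks, Ka = oracles.ng86(a, b)
        assert r.Ka == 0.0
        assert r.Ks == pytest.approx(Ks, abs=1e-12)
        assert r.Ks > 0
        assert r.label == "negative"

    def test_saturation_exclusion(self):
        # every codon synonymously different: pS = Sd/S = 1 >= 3/4
        r = compute_kaks(_alignment(["GGA"] * 20, ["GGT"] * 20))
        assert r.excluded and r.exclusion_reason == "saturated"

    def test_column_permutation_invariance(self, rng):
        from conftest import random_codon_pair

        cols = [random_codon_pair(rng, 0.3) for _ in range(80)]
        a, b = zip(*cols)
        base = compute_kaks(_alignment(a, b))
        perm = rng.permutation(80)
        shuffled = compute_kaks(_alignment([a[i] for i in perm], [b[i] for i in perm]))
        for field in ("S", "N", "Sd", "Nd", "Ka", "Ks"):
            assert getattr(base, field) == pytest.approx(getattr(shuffled, field),
                                                         abs=1e-12)

    def test_matches_oracle_on_random_alignments(self, rng):
        from conftest import random_codon_pair

        for _ in range(50):
            n = int(rng.integers(10, 120))
            cols = [random_codon_pair(rng, 0.2) for _ in range(n)]
            a, b = zip(*cols)
            r = compute_kaks(_alignment(a, b))
            S, N, Sd, Nd, Ks, Ka = oracles.ng86(list(a), list(b))
            assert r.S == pytest.approx(S, abs=1e-12)
            assert r.N == pytest.approx(N, abs=1e-12)
            assert r.Sd == pytest.approx(Sd, abs=1e-12)
            assert r.Nd == pytest.approx(Nd, abs=1e-12)
            if Ks is not None and not r.excluded:
                assert r.Ks == pytest.approx(Ks, abs=1e-12)
                assert r.Ka == pytest.approx(Ka, abs=1e-12)


class TestClassifySelection:
    def _result(self, ratio):
        return KaKsResult("p", 100, 200, 5, 5, 0.05, 0.025, 0.05, 0.03,
                          ratio, "unclassified", "none")

    def test_thresholds(self):
        assert classify_selection(self._result(1.5)) == "positive"
        assert classify_selection(self._result(0.3)) == "negative"
        assert classify_selection(self._result(1.0)) == "neutral"

    def test_excluded_input_rejected(self):
        bad = KaKsResult("p", 100, 200, 0, 0, 0, 0, 0, 0, None,
                         "excluded", "identical")
        with pytest.raises(ValueError):
            classify_selection(bad)


class TestOnSimulatedPairs:
    def test_mean_ks_nondecreasing_in_target(self):
        means = []
        for i, target in enumerate((0.05, 0.1, 0.2, 0.4)):
            vals = []
            for rep in range(6):
                anc = simulate_ancestral_cds(300, 900 + 10 * i + rep)
                a, b, _ = evolve_pair(anc, target, 0.1, 500 + 10 * i + rep)
                r = compute_kaks(build_codon_alignment("p", a.seq[:-3], b.seq[:-3]))
                vals.append(r.Ks)
            means.append(np.mean(vals))
        assert all(m2 >= m1 for m1, m2 in zip(means, means[1:]))

    def test_positive_selection_pairs_labelled_positive(self):
        hits = 0
        for rep in range(50):
            anc = simulate_ancestral_cds(300, 3000 + rep)
            a, b, _ = evolve_pair(anc, 0.2, 3.0, 4000 + rep)
            r = compute_kaks(build_codon_alignment("p", a.seq[:-3], b.seq[:-3]))
            hits += (not r.excluded) and r.label == "positive"
        assert hits >= 40  # >= 80 % of replicates

    def test_purifying_pairs_labelled_negative(self):
        hits = 0
        for rep in range(40):
            anc = simulate_ancestral_cds(300, 5000 + rep)
            a, b, _ = evolve_pair(anc, 0.2, 0.1, 6000 + rep)
            r = compute_kaks(build_codon_alignment("p", a.seq[:-3], b.seq[:-3]))
            hits += (not r.excluded) and r.label == "negative"
        assert hits >= 38  # >= 95 %


def test_jukes_cantor_domain():
    assert jukes_cantor(0.0) == 0.0
    with pytest.raises(ValueError):
        jukes_cantor(0.75)
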