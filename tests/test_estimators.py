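"""Frequency counts and the five richness estimators, checked against
independent brute-force recomputation and worked hand examples."""

import subprocess
import textwrap

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from richsim import (
    EstimatorDomainError,
    FormatError,
    chao2,
    chiu_chao,
    compute_estimates,
    ice,
    jackknife1,
    jackknife2,
    tabulate_frequencies,
)
from richsim.estimators import estimate_true_singletons

from _oracle import (
    oracle_chao2,
    oracle_chiu_chao,
    oracle_counts,
    oracle_ice,
    oracle_jackknife1,
    oracle_jackknife2,
)
from conftest import make_counts, make_matrix


def random_matrix(rng, max_s=12, max_t=8, min_t=1):
    s = rng.integers(1, max_s + 1)
    t = rng.integers(min_t, max_t + 1)
    p = rng.uniform(0.05, 0.9, size=s)
    return (rng.random((s, t)) < p[:, None]).astype(int)


small_matrices = st.lists(
    st.lists(st.integers(0, 1), min_size=2, max_size=6),
    min_size=1,
    max_size=6,
).filter(lambda rows: len({len(r) for r in rows}) == 1)


class TestTabulateFrequencies:
    def test_direct_count(self):
        counts = tabulate_frequencies(make_matrix([[1, 0], [1, 1], [0, 0]]))
        assert (counts.S_obs, counts.q(1), counts.q(2)) == (2, 1, 1)
        assert counts.T == 2 and counts.total_incidences == 3

    def test_all_zero_matrix(self):
        counts = tabulate_frequencies(make_matrix(np.zeros((4, 3), dtype=int)))
        assert counts.S_obs == 0 and counts.Q == {}

    def test_non_binary_rejected(self):
        with pytest.raises(Exception):
            make_matrix([[0, 2]])

    @given(small_matrices)
    def test_identities_hold(self, rows):
        counts = tabulate_frequencies(make_matrix(rows))
        assert sum(counts.Q.values()) == counts.S_obs
        assert counts.total_incidences == sum(sum(r) for r in rows)

    def test_matches_brute_force_on_random_matrices(self, rng):
        for _ in range(100):
            rows = random_matrix(rng).tolist()
            counts = tabulate_frequencies(make_matrix(rows))
            T, s_obs, q = oracle_counts(rows)
            assert (counts.T, counts.S_obs, counts.Q) == (T, s_obs, q)


class TestChao2:
    def test_classic_branch_hand_example(self):
        res = chao2(make_counts(T=10, s_obs=20, q1=4, q2=2))
        assert res.estimate == pytest.approx(23.6)
        assert not res.fallback_used

    def test_corrected_branch_hand_example(self):
        res = chao2(make_counts(T=10, s_obs=20, q1=4, q2=0))
        assert res.estimate == pytest.approx(25.4)
        assert res.fallback_used

    def test_no_uniques_returns_observed(self):
        res = chao2(make_counts(T=7, s_obs=15))
        assert res.estimate == 15.0

    @pytest.mark.parametrize("q1", [0, 1])
    def test_corrected_branch_degenerates_to_observed(self, q1):
        res = chao2(make_counts(T=9, s_obs=10, q1=q1, q2=0))
        assert res.estimate == 10.0


class TestJackknives:
    def test_first_order_hand_examples(self):
        assert jackknife1(make_counts(T=10, s_obs=20, q1=4)).estimate == pytest.approx(23.6)
        assert jackknife1(make_counts(T=10, s_obs=20)).estimate == 20.0
        assert jackknife1(make_counts(T=2, s_obs=5, q1=5)).estimate == pytest.approx(7.5)

    def test_second_order_hand_examples(self):
        res = jackknife2(make_counts(T=10, s_obs=20, q1=4, q2=2))
        assert res.estimate == pytest.approx(20 + 6.8 - 128 / 90)
        assert res.estimate == pytest.approx(25.3778, abs=5e-5)
        assert jackknife2(make_counts(T=10, s_obs=20)).estimate == 20.0
        assert jackknife2(make_counts(T=5, s_obs=10, q1=2, q2=0)).estimate == pytest.approx(12.8)

    def test_domain_errors_below_minimum_units(self):
        with pytest.raises(EstimatorDomainError):
            jackknife1(make_counts(T=1, s_obs=3, q1=3))
        with pytest.raises(EstimatorDomainError):
            jackknife2(make_counts(T=2, s_obs=3, q1=3))


class TestICE:
    def test_worked_example(self):
        # frequencies {12, 11, 1, 1, 2} over T=12; singletons in units 0 and 1,
        # the doubleton in units 2-3: C=0.5, gamma^2=0, S_hat = 2 + 6 + 0 = 8
        values = np.zeros((5, 12), dtype=int)
        values[0, :] = 1
        values[1, :11] = 1
        values[2, 0] = 1
        values[3, 1] = 1
        values[4, 2:4] = 1
        res = ice(make_matrix(values))
        assert res.estimate == pytest.approx(8.0)
        assert res.components["C"] == pytest.approx(0.5)
        assert res.components["gamma2"] == 0.0

    def test_no_infrequent_species_returns_observed(self):
        values = np.ones((6, 15), dtype=int)
        assert ice(make_matrix(values)).estimate == 6.0

    def test_empty_matrix_returns_zero(self):
        assert ice(make_matrix(np.zeros((3, 4), dtype=int))).estimate == 0.0

    def test_all_uniques_falls_back_to_chao2(self):
        values = np.eye(4, dtype=int)
        res = ice(make_matrix(values))
        expected = chao2(tabulate_frequencies(make_matrix(values))).estimate
        assert res.fallback_used
        assert res.estimate == pytest.approx(expected)

    def test_matches_hand_evaluation_on_random_matrices(self, rng):
        for _ in range(100):
            rows = random_matrix(rng, max_s=15, max_t=8).tolist()
            res = ice(make_matrix(rows), infrequent_threshold=3)
            assert res.estimate == pytest.approx(oracle_ice(rows, 3), rel=1e-9)


class TestChiuChao:
    def test_fallback_equals_classic_chao2(self):
        counts = make_counts(T=10, s_obs=20, q1=4, q2=2)
        res = chiu_chao(counts)
        assert res.fallback_used
        assert res.estimate == pytest.approx(23.6)
        assert res.estimate == chao2(counts).estimate

    def test_no_rare_species_returns_observed(self):
        res = chiu_chao(make_counts(T=8, s_obs=12))
        assert res.estimate == 12.0

    def test_corrected_singletons_match_independent_transcription(self):
        counts = make_counts(T=20, s_obs=30, q1=6, q2=4, q3=3, q4=2)
        res = chiu_chao(counts)
        q1_hat = 2 * 4 * (4 + 3) / (3 * 3 + 4 * 2)
        assert res.components["q1_hat"] == pytest.approx(q1_hat)
        expected = 30 - 6 + q1_hat + (19 / 20) * q1_hat**2 / (2 * 4)
        assert res.estimate == pytest.approx(expected, rel=1e-12)

    def test_singleton_estimate_undefined_without_q3_q4(self):
        with pytest.raises(EstimatorDomainError):
            estimate_true_singletons(make_counts(T=10, s_obs=8, q1=5, q2=3))

    def test_singleton_estimate_exact_under_equal_rates(self):
        # Poisson(lambda) expected class sizes: Q_k proportional to lambda^k / k!
        import math

        lam, scale = 1.6, 5000.0
        q = {
            k: scale * lam**k / math.factorial(k) * np.exp(-lam) for k in (1, 2, 3, 4)
        }
        q1_hat = 2 * q[2] * (q[2] + q[3]) / (3 * q[3] + 4 * q[4])
        assert q1_hat == pytest.approx(q[1], rel=1e-12)

    @given(
        st.integers(0, 6),
        st.integers(0, 6),
        st.integers(5, 20),
        st.integers(0, 10),
    )
    def test_identical_to_chao2_whenever_q3_q4_zero(self, q1, q2, t, bulk):
        counts = make_counts(T=t, s_obs=q1 + q2 + bulk, q1=q1, q2=q2)
        assert chiu_chao(counts).estimate == chao2(counts).estimate


class TestCrossCuttingProperties:
    def test_estimators_never_below_observed_richness(self, rng):
        # holds for chao2, ice, jackknife1 (jackknife2 and chiu_chao are exempt)
        for _ in range(150):
            rows = random_matrix(rng, min_t=2)
            m = make_matrix(rows)
            counts = tabulate_frequencies(m)
            assert chao2(counts).estimate >= counts.S_obs
            assert ice(m).estimate >= counts.S_obs
            assert jackknife1(counts).estimate >= counts.S_obs

    def test_oracle_equivalence_on_200_random_matrices(self, rng):
        oracles = {
            "chao2": oracle_chao2,
            "jackknife1": oracle_jackknife1,
            "jackknife2": oracle_jackknife2,
            "chiu_chao": oracle_chiu_chao,
        }
        for _ in range(200):
            rows = random_matrix(rng, max_s=12, max_t=8, min_t=3).tolist()
            m = make_matrix(rows)
            T, s_obs, q = oracle_counts(rows)
            results = {r.estimator: r for r in compute_estimates(m)}
            for name, fn in oracles.items():
                assert results[name].estimate == pytest.approx(
                    fn(T, s_obs, q), rel=1e-9
                ), name
            assert results["ice"].estimate == pytest.approx(oracle_ice(rows), rel=1e-9)

    def test_invariance_under_row_and_column_permutation(self, rng):
        for _ in range(25):
            rows = random_matrix(rng, min_t=3)
            perm = rows[rng.permutation(rows.shape[0])][:, rng.permutation(rows.shape[1])]
            a = {r.estimator: r.estimate for r in compute_estimates(make_matrix(rows))}
            b = {r.estimator: r.estimate for r in compute_estimates(make_matrix(perm))}
            assert a == pytest.approx(b)

    def test_counts_validate_consistency(self):
        from richsim import FrequencyCounts

        with pytest.raises(FormatError):
            FrequencyCounts(T=5, S_obs=2, Q={1: 1, 2: 2})


class TestAgainstVegan:
    def test_specpool_reproduces_chao2_and_jackknives(self, worked_matrix, tmp_path):
        """vegan::specpool (R) as an independent third-party implementation."""
        csv = tmp_path / "m.csv"
        np.savetxt(csv, worked_matrix.values.T, fmt="%d", delimiter=",")
        script = textwrap.dedent(
            f"""
            suppressMessages(library(vegan))
            m <- as.matrix(read.csv("{csv}", header=FALSE))
            p <- specpool(m)
            cat(p$chao, p$jack1, p$jack2, sep="\\n")
            """
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        r_chao, r_jack1, r_jack2 = map(float, out.stdout.split())
        counts = tabulate_frequencies(worked_matrix)
        assert chao2(counts).estimate == pytest.approx(r_chao, rel=1e-6)
        assert jackknife1(counts).estimate == pytest.approx(r_jack1, rel=1e-6)
        assert jackknife2(counts).estimate == pytest.approx(r_jack2, rel=1e-6)
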