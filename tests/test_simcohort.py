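"""Synthetic cohort generation, likelihood-based calling, imputation, sweep."""

from __future__ import annotations

import numpy as np
import pytest

from midpass.callfilter import gq_filter
from midpass.concordance import match_sites, site_metrics
from midpass.core import MISSING
from midpass.simcohort import (
    SimConfig,
    _call_genotypes,
    gq_sweep,
    make_cohort,
    naive_impute,
    simulate_midpass,
)

from conftest import build_matrix


class TestMakeCohort:
    def test_no_recombination_copies_one_founder(self):
        cfg = SimConfig(n_founders=2, n_sites=50, n_samples=10, switch_rate=0.0, seed=3)
        truth = make_cohort(cfg)
        for s in range(cfg.n_samples):
            for h in range(2):
                hap = truth.haplotypes[s, h]
                assert any(
                    np.array_equal(hap, truth.founders[:, f]) for f in range(2)
                )

    def test_truth_has_no_missing_calls(self):
        truth = make_cohort(SimConfig(n_sites=30, n_samples=5, seed=1))
        assert not truth.genotypes.is_missing().any()

    def test_empirical_af_tracks_founder_af(self):
        cfg = SimConfig(n_samples=1000, n_sites=300, seed=5)
        truth = make_cohort(cfg)
        dos = truth.genotypes.allele1 + truth.genotypes.allele2
        emp = dos.sum(axis=1) / (2 * cfg.n_samples)
        f = truth.founder_af
        se = np.sqrt(f * (1 - f) / (2 * cfg.n_samples))
        frac_within = (np.abs(emp - f) <= 3 * se).mean()
        assert frac_within >= 0.985  # ~99.7% expected under normality

    def test_determinism(self):
        cfg = SimConfig(n_sites=40, n_samples=8, seed=9)
        a, b = make_cohort(cfg), make_cohort(cfg)
        assert np.array_equal(a.founders, b.founders)
        assert np.array_equal(a.haplotypes, b.haplotypes)
        assert a.genotypes.equals(b.genotypes)


class TestLikelihoodCalling:
    def test_frozen_oracle_values(self):
        """Independently computed likelihoods: 5 clean ref reads at eps=0.01
        give hom-ref with GQ 15; one ref + one alt read give het with GQ 11."""
        call, gq = _call_genotypes(np.array([5, 2]), np.array([0, 1]), eps=0.01)
        assert call.tolist() == [0, 1]
        assert gq.tolist() == [15, 11]

    def test_zero_error_het_is_certain(self):
        call, gq = _call_genotypes(np.array([4]), np.array([2]), eps=0.0)
        assert call.tolist() == [1]
        assert gq.tolist() == [99]

    def test_zero_depth_is_missing(self):
        truth = make_cohort(SimConfig(n_sites=60, n_samples=10, coverage=0.5, seed=2))
        obs = simulate_midpass(truth)
        zero = obs.dp == 0
        assert zero.any()
        assert (obs.is_missing() == zero).all()

    def test_determinism(self):
        truth = make_cohort(SimConfig(n_sites=40, n_samples=6, seed=4))
        assert simulate_midpass(truth).equals(simulate_midpass(truth))

    def test_gq_calibration_rough(self):
        """Phred semantics: within each GQ stratum the empirical genotype error
        is within a factor of 3 of the likelihood model's own prediction."""
        cfg = SimConfig(n_samples=300, n_sites=1000, seed=6)
        truth = make_cohort(cfg)
        obs = simulate_midpass(truth)
        d_true = truth.genotypes.allele1 + truth.genotypes.allele2
        d_call = obs.allele1 + obs.allele2
        ok = ~obs.is_missing()
        for q in range(3, 30, 3):
            stratum = ok & (obs.gq >= q) & (obs.gq < q + 3)
            if stratum.sum() < 500:
                continue
            emp = (d_call[stratum] != d_true[stratum]).mean()
            pred = np.mean(10.0 ** (-obs.gq[stratum] / 10))
            assert pred / 3 <= max(emp, 1e-6) <= pred * 3, (q, emp, pred)


class TestNaiveImpute:
    def test_unanimous_neighbours(self):
        rows = [["1/1"] * 5 for _ in range(9)]
        rows[4][0] = "./."
        out = naive_impute(build_matrix(rows), window=9, k=3)
        assert out.call(4, 0).alleles == (1, 1)

    def test_identity_without_missing(self):
        m = build_matrix([["0/1", "1/1"], ["0/0", "0/1"]])
        assert naive_impute(m).equals(m)

    def test_no_missing_in_output_and_observed_unchanged(self):
        truth = make_cohort(SimConfig(n_sites=100, n_samples=20, coverage=2, seed=8))
        obs = simulate_midpass(truth)
        imp = naive_impute(obs)
        assert not imp.is_missing().any()
        keep = ~obs.is_missing()
        assert np.array_equal(imp.allele1[keep], obs.allele1[keep])
        assert np.array_equal(imp.allele2[keep], obs.allele2[keep])

    def test_vote_matches_brute_force(self):
        """5-sample, 9-site case: exhaustively score neighbours by window
        agreement and take the k=2 majority vote."""
        rows = [
            ["0/0", "0/0", "1/1", "1/1", "0/1"],
            ["0/1", "0/1", "0/0", "0/0", "1/1"],
            ["0/0", "0/0", "1/1", "1/1", "0/0"],
            ["1/1", "1/1", "0/0", "0/1", "0/1"],
            ["0/1", "./.", "0/0", "0/0", "0/1"],
            ["0/0", "0/0", "1/1", "1/1", "0/1"],
            ["0/1", "0/1", "0/0", "0/0", "0/0"],
            ["1/1", "1/1", "0/1", "0/1", "0/1"],
            ["0/0", "0/0", "1/1", "1/1", "1/1"],
        ]
        m = build_matrix(rows)
        window, k = 9, 2
        out = naive_impute(m, window=window, k=k)

        # brute-force neighbour scoring for the masked call (site 4, sample 1)
        G = m.dosage()
        target, site = 1, 4
        scores = []
        for j in range(5):
            if j == target or G[site, j] < 0:
                scores.append(-1.0)
                continue
            num = den = 0
            for i in range(9):
                if G[i, target] >= 0 and G[i, j] >= 0:
                    den += 1
                    num += G[i, target] == G[i, j]
            scores.append(num / den if den else 0.0)
        top = sorted(range(5), key=lambda j: -scores[j])[:k]
        votes = [G[site, j] for j in top]
        expected = max(set(votes), key=votes.count)
        got = (out.allele1[site, target] + out.allele2[site, target])
        assert got == expected

    def test_invalid_parameters(self):
        m = build_matrix([["0/1"]])
        with pytest.raises(ValueError):
            naive_impute(m, window=4)
        with pytest.raises(ValueError):
            naive_impute(m, k=0)


@pytest.fixture(scope="module")
def small_sim():
    cfg = SimConfig(n_sites=300, n_samples=40, seed=12)
    truth = make_cohort(cfg)
    return truth, simulate_midpass(truth)


class TestGqSweep:

    def test_structural(self, small_sim):
        truth, obs = small_sim
        df = gq_sweep(obs, truth.genotypes, [0, 10, 20])
        assert df["threshold"].tolist() == [0, 10, 20]
        assert df["selected"].sum() == 1

    def test_retained_calls_non_increasing(self, small_sim):
        truth, obs = small_sim
        df = gq_sweep(obs, truth.genotypes, [0, 5, 10, 15, 20])
        assert (np.diff(df["retained_calls"]) <= 0).all()

    def test_failed_imputer_marks_row_and_continues(self, small_sim):
        truth, obs = small_sim

        calls = {"n": 0}

        def flaky(matrix):
            calls["n"] += 1
            if calls["n"] == 1:
                raise RuntimeError("boom")
            return naive_impute(matrix)

        df = gq_sweep(obs, truth.genotypes, [0, 10], imputer=flaky)
        assert df["failed"].tolist() == [True, False]
        assert df.loc[1, "selected"]

    def test_imputation_never_reduces_recall(self, small_sim):
        truth, obs = small_sim
        filtered, _ = gq_filter(obs, 10)
        imputed = naive_impute(filtered)
        pre = site_metrics(match_sites(filtered, truth.genotypes), filtered, truth.genotypes)[0]
        post = site_metrics(match_sites(imputed, truth.genotypes), imputed, truth.genotypes)[0]
        assert post.recall >= pre.recall
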