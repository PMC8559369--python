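"""Site matching, recall/precision, NCR and minor-allele concordance."""

from __future__ import annotations

import math

import numpy as np
import pytest

from midpass.concordance import (
    StratificationSpec,
    genotype_concordance,
    match_sites,
    site_metrics,
    stratified_metrics,
)
from midpass.core import ConfigurationError, RegionSet, SampleCoverage, VariantSite

from conftest import build_matrix, oracle_concordance, oracle_site_metrics, random_matrix


def _sites(*specs):
    return [VariantSite(c, p, r, a) for c, p, r, a in specs]


class TestMatchSites:
    def test_set_semantics(self):
        test = build_matrix([["0/1"]] * 3, sites=_sites(
            ("chr1", 100, "A", ("C",)), ("chr1", 200, "A", ("C",)), ("chr1", 300, "A", ("C",))))
        truth = build_matrix([["0/1"]] * 3, sites=_sites(
            ("chr1", 200, "A", ("C",)), ("chr1", 300, "A", ("C",)), ("chr1", 400, "A", ("C",))))
        m = match_sites(test, truth)
        assert {k[1] for k in m.shared} == {200, 300}
        assert {k[1] for k in m.test_only} == {100}
        assert {k[1] for k in m.truth_only} == {400}

    def test_identical_inputs_all_shared(self, rng):
        m = random_matrix(rng, 8, 2)
        sm = match_sites(m, m)
        assert not sm.test_only and not sm.truth_only
        assert len(sm.shared) == 8

    def test_same_position_different_alts_not_shared(self):
        test = build_matrix([["0/1"]], sites=_sites(("chr1", 100, "A", ("C",))))
        truth = build_matrix([["0/1"]], sites=_sites(("chr1", 100, "A", ("T",))))
        m = match_sites(test, truth)
        assert not m.shared
        assert len(m.test_only) == len(m.truth_only) == 1


class TestSiteMetrics:
    def test_per_sample_derived_example(self):
        # truth variant calls at 3 sites; test at 2 of those + 1 extra
        sites = _sites(*[("chr1", p, "A", ("C",)) for p in (100, 200, 300, 400)])
        truth = build_matrix([["0/1"], ["0/1"], ["1/1"], ["0/0"]], sites=sites)
        test = build_matrix([["0/1"], ["0/1"], ["0/0"], ["0/1"]], sites=sites)
        res = site_metrics(match_sites(test, truth), test, truth)[1]
        assert res.recall == pytest.approx(2 / 3)
        assert res.precision == pytest.approx(2 / 3)

    def test_identity_gives_unity(self, rng):
        m = random_matrix(rng, 10, 3)
        res = site_metrics(match_sites(m, m), m, m)[0]
        assert res.recall == 1.0 and res.precision == 1.0

    def test_empty_test_recall_zero_precision_undefined(self):
        sites = _sites(("chr1", 100, "A", ("C",)))
        truth = build_matrix([["0/1"]], sites=sites)
        test = build_matrix([["./."]], sites=sites)
        res = site_metrics(match_sites(test, truth), test, truth)[1]
        assert res.recall == 0.0
        assert math.isnan(res.precision)


class TestGenotypeConcordance:
    def test_ncr_exclusion_example(self):
        truth = build_matrix([["0/0"], ["0/1"], ["0/1"], ["0/1"]])
        test = build_matrix([["0/0"], ["0/1"], ["1/1"], ["0/1"]])
        res = genotype_concordance(test, truth)
        assert res.excluded_homref_pairs == 1
        assert res.concordance == pytest.approx(2 / 3)

    def test_identity_with_nonref_is_unity(self):
        m = build_matrix([["0/1", "0/0"], ["1/1", "0/1"]])
        assert genotype_concordance(m, m).concordance == 1.0

    def test_minor_allele_flip(self):
        # one site with alt AF 0.8: hom-alt match excluded, hom-ref match counted
        truth = build_matrix([["1/1", "1/1", "1/1", "1/1", "0/0"]])
        test = build_matrix([["1/1", "1/1", "1/1", "1/1", "0/0"]])
        res = genotype_concordance(test, truth, mode="minor-allele")
        assert res.excluded_homref_pairs == 4
        assert res.concordant_nonref == 1  # the (0/0, 0/0) pair
        res_nonref = genotype_concordance(test, truth, mode="non-reference")
        assert res_nonref.excluded_homref_pairs == 1

    def test_minor_equals_nonref_when_af_below_half(self, rng):
        test = random_matrix(rng, 15, 4)
        truth = random_matrix(rng, 15, 4)
        af = {k: 0.3 for k in truth.site_keys()}
        a = genotype_concordance(test, truth, mode="non-reference")
        b = genotype_concordance(test, truth, mode="minor-allele", af_source=af)
        assert (a.concordant_nonref, a.discordant) == (b.concordant_nonref, b.discordant)

    def test_requires_af_for_minor_mode(self):
        t = build_matrix([["0/1"]])
        with pytest.raises(ConfigurationError):
            genotype_concordance(t, t, mode="minor-allele", af_source={})


class TestOracleEquivalence:
    """Naive nested-loop recomputation must agree exactly."""

    def test_random_matrices(self, rng):
        for _ in range(30):
            ns, n = int(rng.integers(1, 20)), int(rng.integers(1, 6))
            test = random_matrix(rng, ns, n)
            truth = random_matrix(rng, ns, n, missing_rate=0.1)
            match = match_sites(test, truth)
            got = site_metrics(match, test, truth)[0]
            exp = oracle_site_metrics(test, truth)
            for attr in ("recall", "precision"):
                g, e = getattr(got, attr), exp[attr]
                assert (math.isnan(g) and math.isnan(e)) or g == e
            for mode in ("non-reference", "minor-allele"):
                gc = genotype_concordance(test, truth, match, mode=mode)
                oc = oracle_concordance(test, truth, mode=mode)
                assert (gc.concordant_nonref, gc.discordant, gc.excluded_homref_pairs) == (
                    oc["concordant"], oc["discordant"], oc["excluded"])

    def test_symmetry(self, rng):
        test = random_matrix(rng, 12, 3)
        truth = random_matrix(rng, 12, 3)
        m_fwd, m_rev = match_sites(test, truth), match_sites(truth, test)
        f = site_metrics(m_fwd, test, truth)[0]
        r = site_metrics(m_rev, truth, test)[0]
        assert f.recall == r.precision and f.precision == r.recall
        # minor-allele flipping depends on which cohort supplies AF, so fix it
        af = {k: 0.2 for k in set(test.site_keys()) | set(truth.site_keys())}
        gf = genotype_concordance(test, truth, m_fwd, af_source=af)
        gr = genotype_concordance(truth, test, m_rev, af_source=af)
        assert gf.concordant_nonref == gr.concordant_nonref

    def test_pooled_is_count_weighted_mean(self):
        truth = build_matrix([["0/1", "0/1"], ["1/1", "./."], ["0/1", "0/0"]])
        test = build_matrix([["0/1", "1/1"], ["0/1", "./."], ["./.", "0/0"]])
        match = match_sites(test, truth)
        rows = genotype_concordance(test, truth, match, per_sample=True)
        pooled, per = rows[0], rows[1:]
        assert pooled.concordant_nonref == sum(r.concordant_nonref for r in per)
        assert pooled.discordant == sum(r.discordant for r in per)


class TestStratified:
    def test_coverage_binning(self):
        m = build_matrix([["0/1", "1/1"]])
        cov = {
            "S0": SampleCoverage("S0", 1.5),
            "S1": SampleCoverage("S1", 4.2),
        }
        spec = StratificationSpec(coverage_bins=(1, 2, 5))
        rows = stratified_metrics(m, m, spec, coverage=cov)
        assert len(rows) == 2
        by_bin = {r.stratum["coverage_bin"]: r for r in rows}
        assert by_bin["[1,2)"].tp_sites == 1  # S0 only
        assert by_bin["[2,5)"].tp_sites == 1  # S1 only

    def test_maf_binning_matches_brute_force(self, rng):
        truth = random_matrix(rng, 20, 5, missing_rate=0.0)
        test = random_matrix(rng, 20, 5)
        spec = StratificationSpec(maf_bins=(0, 0.02, 0.5))
        rows = stratified_metrics(test, truth, spec)
        # brute-force MAF per site from truth allele counts
        def maf(i):
            alt = sum(
                a for j in range(truth.n_samples)
                for a in truth.call(i, j).alleles or ()
            )
            called = sum(not truth.call(i, j).is_missing for j in range(truth.n_samples))
            af = alt / (2 * called)
            return min(af, 1 - af)

        low = [i for i in range(20) if 0 < maf(i) <= 0.02]
        high = [i for i in range(20) if 0.02 < maf(i) <= 0.5]
        by_bin = {r.stratum["maf_bin"]: r for r in rows}
        exp_low = site_metrics(
            match_sites(test.subset(site_idx=low), truth.subset(site_idx=low)),
            test.subset(site_idx=low), truth.subset(site_idx=low))[0]
        assert by_bin["(0,0.02]"].tp_sites == exp_low.tp_sites
        assert by_bin["(0,0.02]"].truth_only_sites == exp_low.truth_only_sites
        assert len(high) + len(low) <= 20

    def test_empty_region_set_gives_empty_rows(self, rng):
        m = random_matrix(rng, 5, 2)
        spec = StratificationSpec(regions=RegionSet())
        rows = stratified_metrics(m, m, spec)
        assert len(rows) == 1
        assert rows[0].tp_sites == 0

    def test_vtype_split(self):
        sites = _sites(("chr1", 100, "A", ("C",)), ("chr1", 200, "AT", ("A",)))
        m = build_matrix([["0/1"], ["0/1"]], sites=sites)
        rows = stratified_metrics(m, m, StratificationSpec(split_vtype=True))
        by_vt = {r.stratum["vtype"]: r for r in rows}
        assert by_vt["SNV"].tp_sites == 1 and by_vt["INDEL"].tp_sites == 1
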