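"""Site matching and genotype-concordance metrics.

Metrics follow the standard small-variant benchmarking definitions:

* **recall** — true-positive variant sites / variant sites in the truth set;
* **precision** — true-positive variant sites / variant sites in the test set;
* **non-reference concordance (NCR)** — the fraction of correctly called
  genotypes among compared pairs, excluding pairs where both calls are
  homozygous reference;
* **minor-allele concordance** — NCR with ref/alt roles swapped at sites whose
  alt-allele frequency exceeds 0.5, so the "reference match" exclusion applies
  to the major allele.

Site matching is allele-aware: the key is (chrom, pos, ref, alt set), so two
records at the same position with different alt sets are distinct sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    ConfigurationError,
    GenotypeMatrix,
    RegionSet,
    SampleCoverage,
    restrict_to_regions,
)

__all__ = [
    "SiteMatch",
    "ConcordanceResult",
    "StratificationSpec",
    "match_sites",
    "site_metrics",
    "genotype_concordance",
    "stratified_metrics",
]


@dataclass
class SiteMatch:
    """Allele-aware classification of site keys into shared/test-only/truth-only."""

    shared: list[tuple]
    test_only: list[tuple]
    truth_only: list[tuple]
    # positional indices of the shared keys in each matrix, aligned pairwise
    test_idx: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    truth_idx: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))


def match_sites(test: GenotypeMatrix, truth: GenotypeMatrix) -> SiteMatch:
    """Classify site keys of two callsets into shared / test-only / truth-only."""
    test_keys = {k: i for i, k in enumerate(test.site_keys())}
    truth_keys = {k: i for i, k in enumerate(truth.site_keys())}
    shared = [k for k in test_keys if k in truth_keys]
    return SiteMatch(
        shared=shared,
        test_only=[k for k in test_keys if k not in truth_keys],
        truth_only=[k for k in truth_keys if k not in test_keys],
        test_idx=np.array([test_keys[k] for k in shared], dtype=int),
        truth_idx=np.array([truth_keys[k] for k in shared], dtype=int),
    )


@dataclass
class ConcordanceResult:
    """Confusion counts and derived metrics, pooled or for one sample/stratum.

    Undefined ratios (zero denominator) are reported as NaN.
    """

    tp_sites: int = 0
    truth_only_sites: int = 0
    test_only_sites: int = 0
    concordant_nonref: int = 0
    discordant: int = 0
    excluded_homref_pairs: int = 0
    sample: str | None = None  # None = pooled
    stratum: dict = field(default_factory=dict)

    @property
    def recall(self) -> float:
        d = self.tp_sites + self.truth_only_sites
        return self.tp_sites / d if d else math.nan

    @property
    def precision(self) -> float:
        d = self.tp_sites + self.test_only_sites
        return self.tp_sites / d if d else math.nan

    @property
    def concordance(self) -> float:
        d = self.concordant_nonref + self.discordant
        return self.concordant_nonref / d if d else math.nan

    def to_dict(self) -> dict:
        return {
            "sample": self.sample if self.sample is not None else "ALL",
            **self.stratum,
            "tp_sites": self.tp_sites,
            "truth_only_sites": self.truth_only_sites,
            "test_only_sites": self.test_only_sites,
            "concordant_nonref": self.concordant_nonref,
            "discordant": self.discordant,
            "excluded_homref_pairs": self.excluded_homref_pairs,
            "recall": self.recall,
            "precision": self.precision,
            "concordance": self.concordance,
        }


def _variant_mask(m: GenotypeMatrix) -> np.ndarray:
    return m.is_variant()


def site_metrics(
    match: SiteMatch,
    test: GenotypeMatrix,
    truth: GenotypeMatrix,
    per_sample: bool = True,
) -> list[ConcordanceResult]:
    """Recall and precision from a site match.

    With ``per_sample`` a site counts for a sample only where that sample's
    call is a non-missing variant call (>= 1 alt allele) in the respective
    callset; the first returned row pools all samples. Without ``per_sample``
    the site-presence classification alone is used (one pooled row).
    """
    if not per_sample:
        tp = len(match.shared)
        return [
            ConcordanceResult(
                tp_sites=tp,
                truth_only_sites=len(match.truth_only),
                test_only_sites=len(match.test_only),
            )
        ]
    if test.samples != truth.samples:
        raise ConfigurationError("per-sample site metrics require identical sample lists")
    v_test = _variant_mask(test)
    v_truth = _variant_mask(truth)
    tp = (v_test[match.test_idx] & v_truth[match.truth_idx]).sum(axis=0)
    test_total = v_test.sum(axis=0)
    truth_total = v_truth.sum(axis=0)
    results = [
        ConcordanceResult(
            tp_sites=int(tp.sum()),
            truth_only_sites=int((truth_total - tp).sum()),
            test_only_sites=int((test_total - tp).sum()),
        )
    ]
    for j, sample in enumerate(test.samples):
        results.append(
            ConcordanceResult(
                tp_sites=int(tp[j]),
                truth_only_sites=int(truth_total[j] - tp[j]),
                test_only_sites=int(test_total[j] - tp[j]),
                sample=sample,
            )
        )
    return results


def _af_lookup(af_source, truth: GenotypeMatrix) -> np.ndarray:
    """Per-truth-site alt-allele frequency.

    ``af_source`` may be None (compute from the truth cohort), a mapping from
    site key to AF, or an AFTable-style DataFrame with chrom/pos/ref/alt/af
    columns (biallelic rows).
    """
    if af_source is None:
        a1, a2 = truth.allele1, truth.allele2
        nonmiss = a1 >= 0
        n_called = nonmiss.sum(axis=1)
        alt = ((a1 > 0).astype(int) + (a2 > 0).astype(int)) * nonmiss
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_called > 0, alt.sum(axis=1) / (2 * n_called), np.nan)
    if isinstance(af_source, pd.DataFrame):
        lut = {
            (r.chrom, int(r.pos), r.ref, frozenset([r.alt])): float(r.af)
            for r in af_source.itertuples(index=False)
        }
    elif isinstance(af_source, Mapping):
        lut = dict(af_source)
    else:
        raise ConfigurationError(f"unsupported af_source: {type(af_source)!r}")
    return np.array([lut.get(k, np.nan) for k in truth.site_keys()], dtype=float)


def genotype_concordance(
    test: GenotypeMatrix,
    truth: GenotypeMatrix,
    match: SiteMatch | None = None,
    mode: str = "non-reference",
    af_source=None,
    per_sample: bool = False,
) -> list[ConcordanceResult] | ConcordanceResult:
    """Genotype concordance over shared sites with calls in both sets.

    ``mode="non-reference"`` excludes equal hom-ref pairs from numerator and
    denominator. ``mode="minor-allele"`` first swaps the hom-ref / hom-alt
    roles at sites whose alt AF > 0.5 (``af_source`` required unless it can be
    computed from the truth cohort), so the exclusion applies to the major
    allele.

    Returns a pooled :class:`ConcordanceResult`, or (with ``per_sample``) the
    pooled row followed by one per sample.
    """
    if mode not in ("non-reference", "minor-allele"):
        raise ConfigurationError(f"unknown mode {mode!r}")
    if test.samples != truth.samples:
        raise ConfigurationError("genotype concordance requires identical sample lists")
    if match is None:
        match = match_sites(test, truth)
    ti, gi = match.test_idx, match.truth_idx
    t1, t2 = test.allele1[ti], test.allele2[ti]
    g1, g2 = truth.allele1[gi], truth.allele2[gi]
    both = (t1 >= 0) & (g1 >= 0)
    equal = (t1 == g1) & (t2 == g2) & both

    if mode == "minor-allele":
        af = _af_lookup(af_source, truth)[gi]
        if (np.isnan(af) & both.any(axis=1)).any():
            raise ConfigurationError("minor-allele mode requires an AF for every compared site")
        flipped = (af > 0.5)[:, None]
        # "major-homozygote" match: at flipped sites both hom-alt (1/1), else both hom-ref
        homref_pair = equal & np.where(
            flipped, (t1 == 1) & (t2 == 1) & (g1 == 1) & (g2 == 1), (t1 == 0) & (t2 == 0)
        )
    else:
        homref_pair = equal & (t1 == 0) & (t2 == 0) & (g1 == 0) & (g2 == 0)

    compared = both & ~homref_pair
    conc = (equal & compared).sum(axis=0)
    disc = (compared & ~equal).sum(axis=0)
    excl = homref_pair.sum(axis=0)
    pooled = ConcordanceResult(
        concordant_nonref=int(conc.sum()),
        discordant=int(disc.sum()),
        excluded_homref_pairs=int(excl.sum()),
    )
    if not per_sample:
        return pooled
    out = [pooled]
    for j, sample in enumerate(test.samples):
        out.append(
            ConcordanceResult(
                concordant_nonref=int(conc[j]),
                discordant=int(disc[j]),
                excluded_homref_pairs=int(excl[j]),
                sample=sample,
            )
        )
    return out


@dataclass
class StratificationSpec:
    """How to slice a concordance evaluation.

    ``maf_bins``/``coverage_bins`` are strictly increasing edge lists defining
    half-open bins (lo, hi]; MAF is min(AF, 1 - AF) from the truth cohort by
    default. ``mode`` selects the allele orientation for concordance. The
    default MAF edge at 0.02 separates low-frequency (MAF <= 2%) variants.
    """

    maf_bins: Sequence[float] | None = None  # e.g. (0, 0.02, 0.5)
    coverage_bins: Sequence[float] | None = None  # e.g. (0, 1.5, 3, 5)
    regions: RegionSet | None = None
    split_vtype: bool = False
    mode: str = "non-reference"

    def __post_init__(self) -> None:
        for edges in (self.maf_bins, self.coverage_bins):
            if edges is not None and not all(a < b for a, b in zip(edges, edges[1:])):
                raise ValueError("bin edges must be strictly increasing")


def _evaluate(test: GenotypeMatrix, truth: GenotypeMatrix, mode: str, af_source) -> ConcordanceResult:
    match = match_sites(test, truth)
    sm = site_metrics(match, test, truth, per_sample=True)[0]
    gc = genotype_concordance(test, truth, match, mode=mode, af_source=af_source)
    sm.concordant_nonref = gc.concordant_nonref
    sm.discordant = gc.discordant
    sm.excluded_homref_pairs = gc.excluded_homref_pairs
    return sm


def stratified_metrics(
    test: GenotypeMatrix,
    truth: GenotypeMatrix,
    spec: StratificationSpec,
    coverage: Mapping[str, SampleCoverage] | None = None,
    af_source=None,
) -> list[ConcordanceResult]:
    """One pooled ConcordanceResult per stratum combination.

    Strata are the cartesian product of the requested dimensions: variant type,
    coverage bin (sample subset), and truth-cohort MAF bin (site subset).
    Region restriction is applied to both callsets before matching. Samples
    without a coverage entry are excluded (recorded in the stratum label of an
    ``excluded_samples`` pseudo-row would be noise; they are simply dropped).
    """
    if spec.regions is not None:
        test = restrict_to_regions(test, spec.regions)
        truth = restrict_to_regions(truth, spec.regions)
    if test.samples != truth.samples:
        raise ConfigurationError("stratified metrics require identical sample lists")

    # sample strata (coverage bins)
    if spec.coverage_bins is not None:
        if coverage is None:
            raise ConfigurationError("coverage bins requested without a coverage table")
        edges = list(spec.coverage_bins)
        sample_strata = []
        missing_cov = [s for s in test.samples if s not in coverage]
        for b in range(len(edges) - 1):
            lo, hi = edges[b], edges[b + 1]
            idx = [
                j
                for j, s in enumerate(test.samples)
                if s in coverage and lo <= coverage[s].mean_depth < hi
            ]
            sample_strata.append(({"coverage_bin": f"[{lo},{hi})"}, idx))
    else:
        sample_strata = [({}, list(range(test.n_samples)))]
        missing_cov = []

    # site strata: vtype x MAF bin (MAF by truth-cohort allele counting)
    truth_af = _af_lookup(af_source, truth)
    truth_maf = np.minimum(truth_af, 1 - truth_af)
    key_maf = dict(zip(truth.site_keys(), truth_maf))
    vtypes = ("SNV", "INDEL") if spec.split_vtype else (None,)
    maf_ranges: list[tuple[float, float] | None]
    if spec.maf_bins is not None:
        e = list(spec.maf_bins)
        maf_ranges = [(e[b], e[b + 1]) for b in range(len(e) - 1)]
    else:
        maf_ranges = [None]

    def site_subset(m: GenotypeMatrix, vt, mr) -> GenotypeMatrix:
        keep = []
        for i, s in enumerate(m.sites):
            if vt is not None and s.vtype != vt:
                continue
            if mr is not None:
                maf = key_maf.get(s.key, np.nan)
                if not (mr[0] < maf <= mr[1]):  # half-open (lo, hi]
                    continue
            keep.append(i)
        return m.subset(site_idx=keep)

    results: list[ConcordanceResult] = []
    for label_s, sample_idx in sample_strata:
        for vt in vtypes:
            for mr in maf_ranges:
                label = dict(label_s)
                if vt is not None:
                    label["vtype"] = vt
                if mr is not None:
                    label["maf_bin"] = f"({mr[0]},{mr[1]}]"
                sub_test = site_subset(test, vt, mr).subset(sample_idx=sample_idx)
                sub_truth = site_subset(truth, vt, mr).subset(sample_idx=sample_idx)
                res = _evaluate(sub_test, sub_truth, spec.mode, af_source)
                res.stratum = label
                results.append(res)
    if missing_cov:
        import warnings

        warnings.warn(
            f"{len(missing_cov)} sample(s) without coverage excluded: {missing_cov[:5]}",
            stacklevel=2,
        )
    return results


def results_to_frame(results: list[ConcordanceResult]) -> pd.DataFrame:
    """Tabulate ConcordanceResults (one row per sample x stratum)."""
    return pd.DataFrame([r.to_dict() for r in results])
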