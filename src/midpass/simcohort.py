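"""Synthetic mid-pass cohort simulation and the GQ-threshold sweep.

The generator produces the three layers a mid-pass benchmarking experiment
needs, with no external data:

1. **Cohort genotypes with LD** — a founder haplotype pool with a neutral-like
   allele-frequency spectrum (P(alt count = i) proportional to 1/i); each
   sample haplotype is a mosaic copied from the founders, switching source
   founder between consecutive sites with probability ``switch_rate``
   (a Li–Stephens-flavoured copying process). Within-cohort imputation relies
   on exactly this haplotype sharing.
2. **Mid-pass sequencing calls** — per (site, sample) read depth is
   Poisson(coverage); each read samples one of the two true alleles uniformly
   and flips to the other allele with probability ``error_rate``; biallelic
   genotype likelihoods with a flat prior give the called GT, and
   GQ = min(99, round(-10 log10(1 - posterior of the call))). Zero depth
   yields a MISSING call.
3. **A naive within-cohort imputer** — k-nearest-neighbour voting over a
   local window of sites, standing in for production imputation software so
   the filter/flag/metric pipeline closes at desk scale. It is test
   scaffolding, not an imputation method.

All operations are pure functions of (inputs, seed); per-sample RNG
sub-streams make outputs independent of iteration order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .callfilter import gq_filter
from .concordance import genotype_concordance, match_sites, site_metrics
from .core import MISSING, GenotypeMatrix, VariantSite

__all__ = [
    "SimConfig",
    "SimTruth",
    "make_cohort",
    "simulate_midpass",
    "naive_impute",
    "gq_sweep",
]


@dataclass(frozen=True)
class SimConfig:
    """All simulator parameters; identical config + seed gives identical output.

    coverage may be a scalar target depth (x-fold) or one value per sample.
    """

    n_founders: int = 8
    n_sites: int = 1000
    n_samples: int = 100
    switch_rate: float = 0.005
    coverage: float | tuple[float, ...] = 4.0
    error_rate: float = 0.01
    seed: int = 0
    chrom: str = "chr1"
    site_spacing: int = 100  # bp between consecutive simulated sites

    def __post_init__(self) -> None:
        if min(self.n_founders, self.n_sites, self.n_samples) < 1:
            raise ValueError("n_founders, n_sites, n_samples must be >= 1")
        if self.n_founders < 2:
            raise ValueError("need >= 2 founders for a polymorphic site")
        if not 0 <= self.switch_rate <= 1:
            raise ValueError("switch_rate must be in [0, 1]")
        if not 0 <= self.error_rate <= 1:
            raise ValueError("error_rate must be in [0, 1]")
        for c in self.coverage_per_sample():
            if c < 0:
                raise ValueError("coverage must be non-negative")

    def coverage_per_sample(self) -> np.ndarray:
        cov = np.broadcast_to(np.asarray(self.coverage, dtype=float), (self.n_samples,))
        return np.array(cov, dtype=float)


@dataclass
class SimTruth:
    """Ground truth of a simulated cohort."""

    config: SimConfig
    founders: np.ndarray  # (n_sites, n_founders) int8 alt-allele indicators
    haplotypes: np.ndarray  # (n_samples, 2, n_sites) int8
    genotypes: GenotypeMatrix  # diploid truth calls, no MISSING

    @property
    def founder_af(self) -> np.ndarray:
        """Per-site alt frequency in the founder pool."""
        return self.founders.mean(axis=1)


def _rng(seed: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), *map(int, stream)])


def _sim_sites(config: SimConfig) -> list[VariantSite]:
    return [
        VariantSite(config.chrom, (i + 1) * config.site_spacing, "A", ("C",))
        for i in range(config.n_sites)
    ]


def make_cohort(config: SimConfig) -> SimTruth:
    """Draw founder haplotypes and build a mosaic-copying diploid cohort."""
    rng = _rng(config.seed, 1)
    nf, ns = config.n_founders, config.n_sites
    # alt allele count i per site: P(i) proportional to 1/i, i = 1..nf-1
    counts = np.arange(1, nf)
    p = (1.0 / counts) / (1.0 / counts).sum()
    alt_counts = rng.choice(counts, size=ns, p=p)
    # assign alts to a uniform random subset of founders of the drawn size
    u = rng.random((ns, nf))
    rank = np.argsort(np.argsort(u, axis=1), axis=1)
    founders = (rank < alt_counts[:, None]).astype(np.int8)

    n_hap = 2 * config.n_samples
    founder_idx = np.empty((n_hap, ns), dtype=np.int32)
    for j in range(config.n_samples):
        hrng = _rng(config.seed, 2, j)
        switch = hrng.random((2, ns)) < config.switch_rate
        switch[:, 0] = True
        draws = hrng.integers(0, nf, size=(2, ns))
        pos = np.where(switch, np.arange(ns)[None, :], 0)
        last = np.maximum.accumulate(pos, axis=1)
        founder_idx[2 * j : 2 * j + 2] = np.take_along_axis(draws, last, axis=1)
    haps = founders[np.arange(ns)[None, :], founder_idx]  # (n_hap, ns)
    haps = haps.reshape(config.n_samples, 2, ns).astype(np.int8)

    dosage = haps.sum(axis=1).T  # (n_sites, n_samples)
    a1 = (dosage >= 2).astype(np.int16)  # 0/0 -> (0,0), 0/1 -> (0,1), 1/1 -> (1,1)
    a2 = (dosage >= 1).astype(np.int16)
    samples = [f"S{j:04d}" for j in range(config.n_samples)]
    gq = np.full(dosage.shape, 99, dtype=np.int16)
    matrix = GenotypeMatrix(_sim_sites(config), samples, a1, a2, gq=gq, _skip_sort=True)
    return SimTruth(config, founders, haps, matrix)


def _call_genotypes(
    depth: np.ndarray, alt_reads: np.ndarray, eps: float
) -> tuple[np.ndarray, np.ndarray]:
    """Likelihood-based biallelic calling for one sample.

    Returns (dosage call in {0,1,2}, GQ); entries with depth 0 are left to the
    caller to mark MISSING. Argmax ties break hom-ref < het < hom-alt.
    """
    d = depth.astype(float)
    a = alt_reads.astype(float)
    r = d - a

    def xlogy(x: np.ndarray, y: float) -> np.ndarray:
        if y > 0:
            return x * np.log(y)
        return np.where(x == 0, 0.0, -np.inf)

    ll = np.stack(
        [
            xlogy(r, 1 - eps) + xlogy(a, eps),  # hom-ref
            d * np.log(0.5),  # het
            xlogy(a, 1 - eps) + xlogy(r, eps),  # hom-alt
        ]
    )
    call = np.argmax(ll, axis=0).astype(np.int16)  # first max wins: RR < het < AA
    m = ll.max(axis=0)
    with np.errstate(invalid="ignore"):
        probs = np.exp(ll - m)
    tot = probs.sum(axis=0)
    err = 1.0 - probs[call, np.arange(call.size)] / tot
    with np.errstate(divide="ignore"):
        gq = np.where(err > 0, np.round(-10.0 * np.log10(np.maximum(err, 1e-300))), 99.0)
    return call, np.minimum(gq, 99).astype(np.int16)


def simulate_midpass(truth: SimTruth, config: SimConfig | None = None) -> GenotypeMatrix:
    """Sequence the truth cohort at mid-pass depth and call genotypes.

    Per (site, sample): depth ~ Poisson(coverage); each read copies one of the
    two true alleles uniformly and flips with probability ``error_rate``; GT,
    GQ from the biallelic likelihoods (flat prior); DP = depth; depth 0 gives
    a MISSING call.
    """
    config = truth.config if config is None else config
    eps = config.error_rate
    cov = config.coverage_per_sample()
    ns, n = config.n_sites, config.n_samples
    dosage_truth = truth.haplotypes.sum(axis=1)  # (n_samples, n_sites)
    a1 = np.full((ns, n), MISSING, dtype=np.int16)
    a2 = np.full((ns, n), MISSING, dtype=np.int16)
    gq = np.full((ns, n), MISSING, dtype=np.int16)
    dp = np.zeros((ns, n), dtype=np.int16)
    for j in range(n):
        rng = _rng(config.seed, 3, j)
        d = rng.poisson(cov[j], size=ns)
        p_alt = eps + (dosage_truth[j] / 2.0) * (1 - 2 * eps)
        alt = rng.binomial(d, p_alt)
        call, q = _call_genotypes(d, alt, eps)
        has = d > 0
        a1[:, j] = np.where(has, (call >= 2).astype(np.int16), MISSING)
        a2[:, j] = np.where(has, (call >= 1).astype(np.int16), MISSING)
        gq[:, j] = np.where(has, q, MISSING)
        dp[:, j] = d
    return GenotypeMatrix(
        list(truth.genotypes.sites),
        list(truth.genotypes.samples),
        a1,
        a2,
        gq=gq,
        dp=dp,
        _skip_sort=True,
    )


def naive_impute(
    observed: GenotypeMatrix, window: int = 81, k: int = 3
) -> GenotypeMatrix:
    """Fill MISSING calls by k-nearest-neighbour voting over a local window.

    For each missing call, the ``k`` samples with the highest genotype
    agreement with the target sample over the ``window`` sites centred on the
    locus vote with their genotype there; the majority genotype is imputed,
    ties broken toward the higher-cohort-frequency genotype (then the lower
    dosage). Observed calls are never changed; the output has no MISSING
    calls. This is desk-scale scaffolding, not a production imputer.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    if k < 1:
        raise ValueError("k must be >= 1")
    G = observed.dosage()  # (n_sites, n_samples), -1 missing
    ns, n = G.shape
    out = observed.copy()
    if ns == 0 or n == 0:
        return out
    valid = G >= 0
    # site-level genotype frequencies for the tie-break and fallbacks
    site_counts = np.stack([((G == g) & valid).sum(axis=1) for g in (0, 1, 2)])  # (3, ns)
    total_counts = np.array([(G == g).sum() for g in (0, 1, 2)])
    overall_modal = int(np.argmax(total_counts)) if valid.any() else 0

    # pairwise agreement cumsums over sites: C[i] = counts over sites < i
    match_c = np.zeros((ns + 1, n, n), dtype=np.int32)
    valid_c = np.zeros((ns + 1, n, n), dtype=np.int32)
    chunk = max(1, int(4e6 // (n * n)) or 1)
    for lo in range(0, ns, chunk):
        hi = min(ns, lo + chunk)
        v = valid[lo:hi]
        both = v[:, :, None] & v[:, None, :]
        eq = (G[lo:hi, :, None] == G[lo:hi, None, :]) & both
        match_c[lo + 1 : hi + 1] = eq.cumsum(axis=0)
        valid_c[lo + 1 : hi + 1] = both.cumsum(axis=0)
        if lo > 0:
            match_c[lo + 1 : hi + 1] += match_c[lo]
            valid_c[lo + 1 : hi + 1] += valid_c[lo]
    half = window // 2

    missing_sites = np.flatnonzero(~valid.all(axis=1))
    for i in missing_sites:
        lo, hi = max(0, i - half), min(ns, i + half + 1)
        targets = np.flatnonzero(~valid[i])
        cand_ok = valid[i]  # voters must have a genotype at site i
        agree = match_c[hi] - match_c[lo]
        seen = valid_c[hi] - valid_c[lo]
        if not cand_ok.any():
            site_mode = (
                int(np.argmax(site_counts[:, i])) if valid[i].any() else overall_modal
            )
            fill = np.full(targets.size, site_mode, dtype=np.int16)
        else:
            sub_agree = agree[targets]  # (m, n_samples)
            sub_seen = seen[targets]
            # unknown agreement (no shared sites in the window) scores 0
            score = np.where(sub_seen > 0, sub_agree / np.maximum(sub_seen, 1), 0.0)
            score[:, ~cand_ok] = -1.0  # also excludes self: targets miss site i
            kk = min(k, int(cand_ok.sum()))
            sel = np.argpartition(-score, kk - 1, axis=1)[:, :kk]
            votes_g = G[i][sel]  # (m, kk)
            sel_ok = np.take_along_axis(score, sel, axis=1) > -0.5
            tallies = np.stack(
                [((votes_g == g) & sel_ok).sum(axis=1) for g in (0, 1, 2)]
            )  # (3, m)
            freq = site_counts[:, i][:, None].astype(float)
            # lexicographic: most votes, then higher cohort frequency, then lower dosage
            key = (
                tallies.astype(np.int64) * 10_000_000
                + (freq * 1000).astype(np.int64) * 10
                + np.array([2, 1, 0])[:, None]
            )
            fill = np.argmax(key, axis=0).astype(np.int16)
        out.allele1[i, targets] = (fill >= 2).astype(np.int16)
        out.allele2[i, targets] = (fill >= 1).astype(np.int16)
    return out


def gq_sweep(
    observed: GenotypeMatrix,
    truth: GenotypeMatrix,
    thresholds: Sequence[int],
    imputer: Callable[[GenotypeMatrix], GenotypeMatrix] | None = None,
    recall_tolerance: float = 0.005,
) -> pd.DataFrame:
    """Filter at each GQ threshold, impute, and score against the truth set.

    Returns one row per threshold with pooled recall, precision and NCR, the
    count of calls retained pre-imputation, and a ``selected`` column marking
    the threshold giving the best balance of the three metrics: the highest
    NCR among thresholds whose recall and precision are each within
    ``recall_tolerance`` of their column maxima, falling back to the highest
    NCR outright when no threshold satisfies both constraints.
    """
    if len(thresholds) == 0:
        raise ValueError("thresholds must be non-empty")
    if imputer is None:
        imputer = naive_impute
    rows = []
    for t in thresholds:
        filtered, report = gq_filter(observed, int(t))
        row = {
            "threshold": int(t),
            "retained_calls": int(report.retained.sum()),
            "failed": False,
            "recall": np.nan,
            "precision": np.nan,
            "ncr": np.nan,
        }
        try:
            imputed = imputer(filtered)
        except Exception:  # a failed imputation run must not abort the sweep
            row["failed"] = True
            rows.append(row)
            continue
        match = match_sites(imputed, truth)
        sm = site_metrics(match, imputed, truth, per_sample=True)[0]
        gc = genotype_concordance(imputed, truth, match)
        row.update(recall=sm.recall, precision=sm.precision, ncr=gc.concordance)
        rows.append(row)
    df = pd.DataFrame(rows)
    ok = ~df["failed"] & df["recall"].notna() & df["ncr"].notna()
    df["selected"] = False
    if ok.any():
        cand = (
            ok
            & (df["recall"] >= df.loc[ok, "recall"].max() - recall_tolerance)
            & (df["precision"] >= df.loc[ok, "precision"].max() - recall_tolerance)
        )
        best = df.loc[cand if cand.any() else ok, "ncr"].idxmax()
        df.loc[best, "selected"] = True
    return df
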