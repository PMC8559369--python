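"""Shared fixtures: tiny matrix builders and brute-force metric oracles.

The oracles deliberately use the scalar ``GenotypeCall`` API and naive nested
loops so they stay independent of the vectorized implementation paths they
check.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from midpass.core import MISSING, GenotypeMatrix, VariantSite


def build_matrix(
    genotypes: list[list[str]],
    samples: list[str] | None = None,
    sites: list[VariantSite] | None = None,
    gq: list[list[int]] | None = None,
    dp: list[list[int]] | None = None,
    filters: list[tuple[str, ...]] | None = None,
    alts: list[tuple[str, ...]] | None = None,
) -> GenotypeMatrix:
    """Build a GenotypeMatrix from genotype strings like "0/1" or "./."."""
    n_sites = len(genotypes)
    n_samples = len(genotypes[0]) if n_sites else 0
    if samples is None:
        samples = [f"S{j}" for j in range(n_samples)]
    if sites is None:
        bases = ("C", "G", "T", "CA")
        sites = [
            VariantSite(
                "chr1",
                100 * (i + 1),
                "A",
                alts[i] if alts else (bases[0],),
                filters[i] if filters else ("PASS",),
            )
            for i in range(n_sites)
        ]
    a1 = np.full((n_sites, n_samples), MISSING, dtype=np.int16)
    a2 = np.full((n_sites, n_samples), MISSING, dtype=np.int16)
    for i, row in enumerate(genotypes):
        for j, g in enumerate(row):
            if "." in g:
                continue
            x, y = (int(p) for p in g.replace("|", "/").split("/"))
            a1[i, j], a2[i, j] = min(x, y), max(x, y)
    gq_arr = np.array(gq, dtype=np.int16) if gq is not None else None
    dp_arr = np.array(dp, dtype=np.int16) if dp is not None else None
    return GenotypeMatrix(sites, samples, a1, a2, gq=gq_arr, dp=dp_arr)


def random_matrix(
    rng: np.random.Generator,
    n_sites: int,
    n_samples: int,
    missing_rate: float = 0.2,
    with_gq: bool = True,
) -> GenotypeMatrix:
    """A random biallelic matrix for oracle-equivalence checks."""
    gts = [["0/0", "0/1", "1/1"][g] for g in range(3)]
    rows = []
    for _ in range(n_sites):
        row = []
        for _ in range(n_samples):
            if rng.random() < missing_rate:
                row.append("./.")
            else:
                row.append(gts[rng.integers(0, 3)])
        rows.append(row)
    gq = rng.integers(0, 60, size=(n_sites, n_samples)).tolist() if with_gq else None
    return build_matrix(rows, gq=gq)


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def oracle_site_metrics(test: GenotypeMatrix, truth: GenotypeMatrix) -> dict:
    """Per-sample and pooled recall/precision by naive per-call enumeration."""
    assert test.samples == truth.samples
    test_keys = {s.key: i for i, s in enumerate(test.sites)}
    truth_keys = {s.key: i for i, s in enumerate(truth.sites)}
    per_sample = {}
    for j, sample in enumerate(test.samples):
        t_set = {k for k, i in test_keys.items() if test.call(i, j).is_variant}
        g_set = {k for k, i in truth_keys.items() if truth.call(i, j).is_variant}
        tp = len(t_set & g_set)
        per_sample[sample] = {
            "tp": tp,
            "truth_only": len(g_set) - tp,
            "test_only": len(t_set) - tp,
            "recall": tp / len(g_set) if g_set else math.nan,
            "precision": tp / len(t_set) if t_set else math.nan,
        }
    tp = sum(v["tp"] for v in per_sample.values())
    tr = sum(v["tp"] + v["truth_only"] for v in per_sample.values())
    te = sum(v["tp"] + v["test_only"] for v in per_sample.values())
    return {
        "per_sample": per_sample,
        "recall": tp / tr if tr else math.nan,
        "precision": tp / te if te else math.nan,
    }


def oracle_concordance(
    test: GenotypeMatrix,
    truth: GenotypeMatrix,
    mode: str = "non-reference",
    af: dict | None = None,
) -> dict:
    """NCR / minor-allele concordance by naive per-call enumeration."""
    assert test.samples == truth.samples
    truth_keys = {s.key: i for i, s in enumerate(truth.sites)}
    if af is None:
        af = {}
        for key, i in truth_keys.items():
            alt = called = 0
            for j in range(truth.n_samples):
                c = truth.call(i, j)
                if c.is_missing:
                    continue
                called += 1
                alt += sum(1 for a in c.alleles if a > 0)
            af[key] = alt / (2 * called) if called else math.nan
    conc = disc = excl = 0
    for s, it in ((s, i) for i, s in enumerate(test.sites)):
        key = s.key
        if key not in truth_keys:
            continue
        ig = truth_keys[key]
        flipped = mode == "minor-allele" and af[key] > 0.5
        for j in range(test.n_samples):
            ct, cg = test.call(it, j), truth.call(ig, j)
            if ct.is_missing or cg.is_missing:
                continue
            equal = ct.alleles == cg.alleles
            major_hom = (1, 1) if flipped else (0, 0)
            if equal and ct.alleles == major_hom:
                excl += 1
            elif equal:
                conc += 1
            else:
                disc += 1
    total = conc + disc
    return {
        "concordant": conc,
        "discordant": disc,
        "excluded": excl,
        "ncr": conc / total if total else math.nan,
    }


IM_ORACLE_BIALLELIC = {
    # (filtered, imputed) -> flag, genotypes as sorted allele pairs or None
    ((0, 0), (0, 0)): 0, ((0, 1), (0, 1)): 0, ((1, 1), (1, 1)): 0,
    ((0, 0), (0, 1)): 1, ((0, 0), (1, 1)): 3,
    ((0, 1), (0, 0)): 2, ((0, 1), (1, 1)): 2,
    ((1, 1), (0, 1)): 1, ((1, 1), (0, 0)): 3,
    (None, (0, 0)): 1, (None, (0, 1)): 1, (None, (1, 1)): 1,
    ((0, 0), None): 0, ((0, 1), None): 0, ((1, 1), None): 0,
}


def oracle_im_flag(filtered: tuple | None, imputed: tuple | None) -> int:
    """Set-rule oracle for IM flags over arbitrary (multi-)allelic pairs."""
    if filtered is None and imputed is None:
        raise ValueError("undefined")
    if imputed is None:
        return 0
    if filtered is None:
        return 1
    if tuple(sorted(filtered)) == tuple(sorted(imputed)):
        return 0
    sf, si = set(filtered), set(imputed)
    if sf <= si:
        return 1
    return 2 if len(set(filtered)) == 2 else 3


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
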