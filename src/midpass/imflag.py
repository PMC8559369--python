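"""Imputation-consistency (IM) flags.

After within-cohort imputation, each imputed genotype is compared with the
GQ-filtered sequencing-based call at the same site and sample:

* **IM0** — not imputed, or imputed and identical to the filtered call;
* **IM1** — not inconsistent: the filtered call was missing, or every
  sequencing-observed allele is still present in the imputed genotype (an
  allele *appeared*, which at low coverage just means we had not observed it);
* **IM2** — inconsistent (an observed allele *disappeared* after imputation)
  and the filtered call was heterozygous;
* **IM3** — inconsistent and the filtered call was homozygous (the imputed
  genotype is homozygous for the opposite allele in the biallelic case).

Allele *sets*, not multisets, drive the rule: 0/1 -> 1/1 loses allele 0 and is
IM2 even though the copy number of allele 1 rose. Phase never affects flags.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from .core import MISSING, ConfigurationError, GenotypeCall, GenotypeMatrix

__all__ = ["IMFlag", "FlaggedMatrix", "assign_flag", "merge_and_flag", "filter_by_flag"]

IM_FORMAT_DESCRIPTION = "Imputation consistency flag"


class IMFlag(IntEnum):
    IM0 = 0
    IM1 = 1
    IM2 = 2
    IM3 = 3


def assign_flag(filtered: GenotypeCall, imputed: GenotypeCall) -> IMFlag:
    """Flag one (filtered, imputed) call pair; see the module docstring.

    Raises if both calls are MISSING (no flag is defined there).
    """
    if filtered.is_missing and imputed.is_missing:
        raise ValueError("assign_flag is undefined when both calls are MISSING")
    if imputed.is_missing:  # site/sample not imputed
        return IMFlag.IM0
    if filtered.is_missing:
        return IMFlag.IM1
    if filtered.alleles == imputed.alleles:
        return IMFlag.IM0
    sf, si = filtered.allele_set, imputed.allele_set
    if sf <= si:  # nothing observed was lost, but genotypes differ
        return IMFlag.IM1
    return IMFlag.IM2 if filtered.is_het else IMFlag.IM3


@dataclass
class FlaggedMatrix:
    """An imputed GenotypeMatrix plus a parallel site x sample IM-flag table."""

    matrix: GenotypeMatrix
    flags: np.ndarray  # int8, same shape as matrix
    skipped_sites: int = 0  # allele-representation mismatches at matched positions
    carried_sites: int = 0  # filtered-only sites carried through unimputed

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, dtype=np.int8)
        if self.flags.shape != self.matrix.shape:
            raise ValueError("flag table dimensions must match the matrix")

    def flag_counts(self) -> dict[IMFlag, int]:
        return {f: int((self.flags == f).sum()) for f in IMFlag}

    def write_vcf(self, path) -> None:
        from .core import write_vcf

        write_vcf(self.matrix, path, extra_format=("IM", self.flags, IM_FORMAT_DESCRIPTION))


def merge_and_flag(filtered: GenotypeMatrix, imputed: GenotypeMatrix) -> FlaggedMatrix:
    """Merge the GQ-filtered and post-imputation callsets and assign IM flags.

    Sites are matched on (chrom, pos, ref, alt set); when alt *order* differs
    the imputed allele indices are remapped onto the filtered site's ordering.
    A matched position whose alt set differs is skipped (counted in
    ``skipped_sites``). Sites present only in the filtered input are carried
    through with flag IM0 ("not imputed"); sites only in the imputed input are
    flagged against an all-MISSING filtered column (IM1 where imputed).
    """
    if set(filtered.samples) != set(imputed.samples):
        raise ConfigurationError("filtered and imputed callsets have different sample sets")
    # align imputed columns onto the filtered sample order
    col = [imputed.samples.index(s) for s in filtered.samples]
    imp = imputed.subset(sample_idx=col)

    filt_by_pos: dict[tuple[str, int, str], int] = {
        (s.chrom, s.pos, s.ref): i for i, s in enumerate(filtered.sites)
    }
    out_sites = []
    out_a1, out_a2, out_gq, out_dp, out_flags = [], [], [], [], []
    skipped = 0
    matched_filtered: set[int] = set()
    n = filtered.n_samples

    for i, site in enumerate(imp.sites):
        j = filt_by_pos.get((site.chrom, site.pos, site.ref))
        a1, a2 = imp.allele1[i].copy(), imp.allele2[i].copy()
        if j is None:
            f1 = np.full(n, MISSING, dtype=np.int16)
            f2 = f1
            fsite = site
        else:
            fsite = filtered.sites[j]
            if set(fsite.alts) != set(site.alts):
                skipped += 1
                matched_filtered.add(j)
                continue
            matched_filtered.add(j)
            if fsite.alts != site.alts:
                # same alt set, different order: remap imputed indices
                remap = np.arange(len(site.alts) + 1, dtype=np.int16)
                for k, alt in enumerate(site.alts, start=1):
                    remap[k] = fsite.alts.index(alt) + 1
                a1 = np.where(a1 >= 0, remap[np.maximum(a1, 0)], a1)
                a2 = np.where(a2 >= 0, remap[np.maximum(a2, 0)], a2)
                lo, hi = np.minimum(a1, a2), np.maximum(a1, a2)
                a1, a2 = lo, hi
            f1, f2 = filtered.allele1[j], filtered.allele2[j]
        i_miss = a1 < 0
        f_miss = f1 < 0
        identical = (f1 == a1) & (f2 == a2)
        in_si = lambda a: (a == a1) | (a == a2)
        lost = ~(in_si(f1) & in_si(f2))
        het = f1 != f2
        flags = np.full(n, IMFlag.IM0, dtype=np.int8)
        flags[~f_miss & ~i_miss & ~identical & ~lost] = IMFlag.IM1
        flags[~f_miss & ~i_miss & lost & het] = IMFlag.IM2
        flags[~f_miss & ~i_miss & lost & ~het] = IMFlag.IM3
        flags[f_miss & ~i_miss] = IMFlag.IM1
        out_sites.append(fsite)
        out_a1.append(a1)
        out_a2.append(a2)
        out_gq.append(imp.gq[i])
        out_dp.append(imp.dp[i])
        out_flags.append(flags)

    carried = 0
    for j, site in enumerate(filtered.sites):
        if j in matched_filtered:
            continue
        # not imputed: carry the filtered calls, flag IM0
        carried += 1
        out_sites.append(site)
        out_a1.append(filtered.allele1[j])
        out_a2.append(filtered.allele2[j])
        out_gq.append(filtered.gq[j])
        out_dp.append(filtered.dp[j])
        out_flags.append(np.full(n, IMFlag.IM0, dtype=np.int8))

    if out_sites:
        a1 = np.array(out_a1, dtype=np.int16)
        a2 = np.array(out_a2, dtype=np.int16)
        gq = np.array(out_gq, dtype=np.int16)
        dp = np.array(out_dp, dtype=np.int16)
        flag_arr = np.array(out_flags, dtype=np.int8)
    else:
        a1 = a2 = gq = dp = np.empty((0, n), dtype=np.int16)
        flag_arr = np.empty((0, n), dtype=np.int8)
    # sort sites (merge may interleave carried sites) and mirror on flags
    order_map = {c: k for k, c in enumerate(filtered.chrom_order)}
    for s in out_sites:
        order_map.setdefault(s.chrom, len(order_map))
    idx = sorted(
        range(len(out_sites)),
        key=lambda t: (
            order_map[out_sites[t].chrom],
            out_sites[t].pos,
            out_sites[t].ref,
            out_sites[t].alts[0],
        ),
    )
    matrix = GenotypeMatrix(
        [out_sites[t] for t in idx],
        list(filtered.samples),
        a1[idx],
        a2[idx],
        gq[idx],
        dp[idx],
        chrom_order=list(order_map),
        _skip_sort=True,
    )
    return FlaggedMatrix(matrix, flag_arr[idx], skipped_sites=skipped, carried_sites=carried)


def filter_by_flag(fm: FlaggedMatrix, drop: set[IMFlag] | frozenset[IMFlag]) -> GenotypeMatrix:
    """Set calls whose flag is in ``drop`` to MISSING; others pass unchanged.

    Only IM2 and IM3 may be dropped (the downstream-filtering recommendation);
    requesting IM0/IM1 raises a configuration error.
    """
    drop = {IMFlag(d) for d in drop}
    if drop - {IMFlag.IM2, IMFlag.IM3}:
        raise ConfigurationError("only IM2 and IM3 calls may be dropped")
    out = fm.matrix.copy()
    if drop:
        mask = np.isin(fm.flags, [int(d) for d in drop])
        out.allele1[mask] = MISSING
        out.allele2[mask] = MISSING
        out.gq[mask] = MISSING
        out.dp[mask] = MISSING
    return out
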