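"""Call-level GQ filtering, truth-set preparation, and call-rate filtering.

GQ filtering sets low-confidence calls to MISSING rather than removing sites,
so site coordinates are preserved for the downstream imputation step (the
imputer consumes sites with missing genotypes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, ConfigurationError, GenotypeMatrix

__all__ = ["FilterReport", "gq_filter", "prepare_truth", "call_rate_filter"]

TRUTH_GQ_THRESHOLD = 20  # truth genotypes must have GQ > 20
DEFAULT_GQ_THRESHOLD = 17  # calls with GQ <= 17 are filtered before imputation
DEFAULT_CALL_RATE = 0.5


@dataclass
class FilterReport:
    """Audit trail of a GQ-filter pass.

    ``set_missing + retained`` equals the per-sample count of non-missing
    input calls.
    """

    threshold: int
    set_missing: pd.Series  # per sample
    retained: pd.Series  # per sample

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"set_missing": self.set_missing, "retained": self.retained}
        ).rename_axis("sample")


def gq_filter(matrix: GenotypeMatrix, threshold: int) -> tuple[GenotypeMatrix, FilterReport]:
    """Set every call with GQ <= ``threshold`` (or GQ absent) to MISSING.

    Calls with GQ > threshold pass through untouched; sites are never removed.
    """
    if threshold < 0:
        raise ValueError(f"threshold must be >= 0, got {threshold}")
    out = matrix.copy()
    nonmissing = ~out.is_missing()
    fail = nonmissing & (out.gq <= threshold)  # absent GQ is -1 <= threshold
    out.allele1[fail] = MISSING
    out.allele2[fail] = MISSING
    out.gq[fail] = MISSING
    out.dp[fail] = MISSING
    report = FilterReport(
        threshold=threshold,
        set_missing=pd.Series(fail.sum(axis=0), index=out.samples),
        retained=pd.Series((nonmissing & ~fail).sum(axis=0), index=out.samples),
    )
    return out, report


def prepare_truth(matrix: GenotypeMatrix, gq_threshold: int = TRUTH_GQ_THRESHOLD) -> GenotypeMatrix:
    """Build a truth set: PASS sites only, genotypes with GQ > 20 only.

    Non-PASS sites are removed outright; retained sites have every call with
    GQ <= ``gq_threshold`` (strict inequality kept) set to MISSING. Idempotent.
    """
    if not matrix.sites:
        return matrix.copy()
    has_gq = (matrix.gq >= 0).any()
    if not has_gq and not matrix.is_missing().all():
        raise ConfigurationError("truth preparation requires per-call GQ")
    keep = [i for i, s in enumerate(matrix.sites) if s.is_pass]
    out = matrix.subset(site_idx=keep)
    filtered, _ = gq_filter(out, gq_threshold)
    return filtered


def call_rate_filter(matrix: GenotypeMatrix, min_rate: float = DEFAULT_CALL_RATE) -> GenotypeMatrix:
    """Keep sites whose call rate (non-missing fraction) is >= ``min_rate``."""
    if not 0 <= min_rate <= 1:
        raise ValueError(f"min_rate must be in [0, 1], got {min_rate}")
    if matrix.n_samples == 0 or matrix.n_sites == 0:
        return matrix.copy()
    rate = (~matrix.is_missing()).sum(axis=1) / matrix.n_samples
    keep = np.flatnonzero(rate >= min_rate)
    return matrix.subset(site_idx=keep)
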