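"""Reference-panel novelty classification and consequence-term mapping.

A cohort variant that is common in the study cohort (MAF > 5%, strict) is
classified against an external panel's allele frequencies as *absent* (not in
the panel), *rare* (panel MAF < 1%, strict) or *common_in_panel*; cohort
variants at or below the 5% gate are *not_evaluated*. Consequence terms
(VEP-style strings) map onto coding / regulatory / other classes through fixed
term lists; for multi-term variants the most severe class wins with precedence
coding > regulatory > other.
"""

from __future__ import annotations

from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import GenotypeMatrix, RegionSet

__all__ = [
    "NoveltyClass",
    "ConsequenceClass",
    "CODING_TERMS",
    "REGULATORY_TERMS",
    "OTHER_TERMS",
    "compute_af",
    "classify_novelty",
    "classify_consequence",
    "novelty_summary",
]


class NoveltyClass(str, Enum):
    ABSENT = "absent"
    RARE = "rare"
    COMMON_IN_PANEL = "common_in_panel"
    NOT_EVALUATED = "not_evaluated"


class ConsequenceClass(str, Enum):
    CODING = "coding"
    REGULATORY = "regulatory"
    OTHER = "other"
    UNCLASSIFIED = "unclassified"


CODING_TERMS = frozenset(
    {
        "frameshift_variant",
        "inframe_deletion",
        "inframe_insertion",
        "missense_variant",
        "start_lost",
        "stop_gained",
        "stop_lost",
        "stop_retained_variant",
        "synonymous_variant",
    }
)
REGULATORY_TERMS = frozenset(
    {
        "5_prime_UTR_variant",
        "3_prime_UTR_variant",
        "mature_miRNA_variant",
        "regulatory_region_variant",
        "splice_acceptor_variant",
        "splice_donor_variant",
        "splice_region_variant",
        "TF_binding_site_variant",
        "TFBS_ablation",
    }
)
OTHER_TERMS = frozenset(
    {
        "downstream_gene_variant",
        "intergenic_variant",
        "intron_variant",
        "non_coding_transcript_exon_variant",
        "upstream_gene_variant",
    }
)
assert not (CODING_TERMS & REGULATORY_TERMS or CODING_TERMS & OTHER_TERMS or REGULATORY_TERMS & OTHER_TERMS)

AF_COLUMNS = ["chrom", "pos", "ref", "alt", "af"]


def compute_af(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Per-alt-allele frequencies and call rates for a cohort.

    One row per (chrom, pos, ref, alt): ``af`` = count of that alt allele over
    2 x non-missing diploid calls; ``call_rate`` over the sample dimension;
    ``maf`` = min(af, 1 - af); ``vtype`` from the owning site. Sites with zero
    non-missing calls are excluded (AF undefined) with a warning.
    """
    rows = []
    undefined = 0
    n = matrix.n_samples
    nonmiss = ~matrix.is_missing()
    for i, site in enumerate(matrix.sites):
        called = int(nonmiss[i].sum())
        if called == 0:
            undefined += 1
            continue
        rate = called / n if n else 0.0
        for k, alt in enumerate(site.alts, start=1):
            count = int((matrix.allele1[i] == k).sum() + (matrix.allele2[i] == k).sum())
            af = count / (2 * called)
            rows.append(
                {
                    "chrom": site.chrom,
                    "pos": site.pos,
                    "ref": site.ref,
                    "alt": alt,
                    "af": af,
                    "maf": min(af, 1 - af),
                    "call_rate": rate,
                    "vtype": site.vtype,
                }
            )
    if undefined:
        import warnings

        warnings.warn(f"{undefined} site(s) with no called genotypes excluded from AF table", stacklevel=2)
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "af", "maf", "call_rate", "vtype"])


def read_panel_af(path) -> pd.DataFrame:
    """Read a panel AF table: TSV with columns chrom, pos, ref, alt, AF."""
    df = pd.read_csv(path, sep="\t", dtype={0: str}, comment="#")
    df.columns = [c.lower() for c in df.columns]
    missing = set(AF_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: panel table lacks column(s) {sorted(missing)}")
    bad = ~df["af"].between(0, 1)
    if bad.any():
        raise ValueError(f"{path}: {int(bad.sum())} AF value(s) outside [0, 1]")
    return df[AF_COLUMNS].copy()


def _key_frame(df: pd.DataFrame) -> pd.Series:
    return df["chrom"].astype(str) + ":" + df["pos"].astype(str) + ":" + df["ref"] + ":" + df["alt"]


def classify_novelty(
    cohort: pd.DataFrame,
    panel: pd.DataFrame,
    cohort_min_maf: float = 0.05,
    panel_rare_max: float = 0.01,
) -> pd.Series:
    """Classify each cohort variant against the panel.

    Strict inequalities as printed: evaluated only where cohort MAF >
    ``cohort_min_maf``; *rare* only where panel MAF < ``panel_rare_max``.
    Variants are matched on (chrom, pos, ref, alt). Returns a Series of
    NoveltyClass values aligned to ``cohort``'s index.
    """
    panel_maf = pd.Series(
        np.minimum(panel["af"].to_numpy(), 1 - panel["af"].to_numpy()),
        index=_key_frame(panel).to_numpy(),
    )
    panel_maf = panel_maf[~panel_maf.index.duplicated()]
    keys = _key_frame(cohort)
    out = []
    cohort_maf = cohort["maf"] if "maf" in cohort else np.minimum(cohort["af"], 1 - cohort["af"])
    for key, maf in zip(keys, cohort_maf):
        if not maf > cohort_min_maf:
            out.append(NoveltyClass.NOT_EVALUATED)
        elif key not in panel_maf.index:
            out.append(NoveltyClass.ABSENT)
        elif panel_maf[key] < panel_rare_max:
            out.append(NoveltyClass.RARE)
        else:
            out.append(NoveltyClass.COMMON_IN_PANEL)
    return pd.Series(out, index=cohort.index, name="novelty")


def classify_consequence(term: str | Iterable[str]) -> ConsequenceClass:
    """Map one consequence term — or several, e.g. ``"intron_variant&missense_variant"``
    or a list — to its class; multi-term precedence coding > regulatory > other.
    Unknown terms are UNCLASSIFIED.
    """
    if isinstance(term, str):
        terms = [t for t in term.replace(",", "&").split("&") if t]
    else:
        terms = list(term)
    classes = set()
    for t in terms:
        t = t.strip()
        if t in CODING_TERMS:
            classes.add(ConsequenceClass.CODING)
        elif t in REGULATORY_TERMS:
            classes.add(ConsequenceClass.REGULATORY)
        elif t in OTHER_TERMS:
            classes.add(ConsequenceClass.OTHER)
    for c in (ConsequenceClass.CODING, ConsequenceClass.REGULATORY, ConsequenceClass.OTHER):
        if c in classes:
            return c
    return ConsequenceClass.UNCLASSIFIED


def novelty_summary(
    cohort: pd.DataFrame,
    novelty: pd.Series,
    consequences: Mapping[str, str] | pd.Series | None = None,
    regions: RegionSet | None = None,
) -> pd.DataFrame:
    """Counts of novel/rare variants by type, class and effect term.

    Only *absent* and *rare* variants are tabulated. Indels outside
    ``regions`` are excluded; SNVs are always retained. ``consequences`` maps
    variant key "chrom:pos:ref:alt" to its (possibly multi-) consequence term
    string. Returns a table with one row per
    (novelty, vtype, consequence class, term) combination plus a ``count``.
    """
    df = cohort.copy()
    df["novelty"] = novelty
    df = df[df["novelty"].isin([NoveltyClass.ABSENT, NoveltyClass.RARE])]
    if regions is not None and len(df):
        in_region = [
            regions.contains(str(r.chrom), int(r.pos)) for r in df.itertuples(index=False)
        ]
        df = df[(df["vtype"] == "SNV").to_numpy() | np.asarray(in_region)]
    if consequences is not None and len(df):
        keys = _key_frame(df)
        terms = [consequences.get(k, "") for k in keys]
        df = df.assign(
            term=terms,
            consequence=[classify_consequence(t).value for t in terms],
        )
    else:
        df = df.assign(term="", consequence=ConsequenceClass.UNCLASSIFIED.value)
    if not len(df):
        return pd.DataFrame(columns=["novelty", "vtype", "consequence", "term", "count"])
    out = (
        df.assign(novelty=df["novelty"].map(lambda x: x.value))
        .groupby(["novelty", "vtype", "consequence", "term"], as_index=False)
        .size()
        .rename(columns={"size": "count"})
        .sort_values(["novelty", "vtype", "consequence", "term"], ignore_index=True)
    )
    return out
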