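"""Domain types and VCF/BED input/output.

Conventions
-----------
* VCF positions are 1-based; BED intervals are 0-based half-open.  A site at
  VCF position ``pos`` lies in BED interval ``(start, end)`` iff
  ``start <= pos - 1 < end``.
* Genotypes are unordered allele pairs; phase is discarded on read.
* Half-calls (e.g. ``./1``) are treated as MISSING.
* Multiallelic records are kept as single sites; alleles are never decomposed.

The in-memory container is :class:`GenotypeMatrix`: a sites x samples table of
calls backed by numpy arrays (allele pair, GQ, DP), with ``-1`` as the sentinel
for missing/absent values.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "MISSING",
    "VariantSite",
    "GenotypeCall",
    "GenotypeMatrix",
    "RegionSet",
    "SampleCoverage",
    "VcfParseError",
    "ConfigurationError",
    "read_vcf",
    "write_vcf",
    "read_bed",
    "restrict_to_regions",
]

#: Sentinel for a missing allele index / absent GQ / absent DP.
MISSING: int = -1


class VcfParseError(ValueError):
    """A VCF header or record could not be parsed."""


class ConfigurationError(ValueError):
    """Inputs are structurally valid but unusable for the requested operation."""


@dataclass(frozen=True)
class VariantSite:
    """One variant locus: coordinates, alleles, type and filter status."""

    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alts: tuple[str, ...]
    filter: tuple[str, ...] = ("PASS",)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref:
            raise ValueError("ref allele must be non-empty")
        if not self.alts or any(not a for a in self.alts):
            raise ValueError("every alt allele must be non-empty")
        alleles = (self.ref,) + self.alts
        if len(set(alleles)) != len(alleles):
            raise ValueError(f"ref and alts must be mutually distinct: {alleles}")

    @property
    def vtype(self) -> str:
        """``"SNV"`` iff ref and all alts are single bases, else ``"INDEL"``."""
        if len(self.ref) == 1 and all(len(a) == 1 for a in self.alts):
            return "SNV"
        return "INDEL"

    @property
    def is_pass(self) -> bool:
        """PASS or unfiltered ('.'); named failing filters return False."""
        return self.filter in (("PASS",), ())

    @property
    def key(self) -> tuple[str, int, str, frozenset[str]]:
        """Allele-aware site key: (chrom, pos, ref, alt set)."""
        return (self.chrom, self.pos, self.ref, frozenset(self.alts))


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's call at one site.

    ``alleles`` is an unordered pair of allele indices (0 = ref, k >= 1 = k-th
    alt) or ``None`` for a missing call; ``gq``/``dp`` are ``None`` when absent.
    """

    alleles: tuple[int, int] | None
    gq: int | None = None
    dp: int | None = None

    def __post_init__(self) -> None:
        if self.alleles is not None:
            a, b = self.alleles
            if a < 0 or b < 0:
                raise ValueError("allele indices must be non-negative; use alleles=None for missing")
            if a > b:
                object.__setattr__(self, "alleles", (b, a))
        if self.gq is not None and not (0 <= self.gq <= 99):
            raise ValueError(f"gq must be in [0, 99], got {self.gq}")
        if self.dp is not None and self.dp < 0:
            raise ValueError(f"dp must be non-negative, got {self.dp}")

    @property
    def is_missing(self) -> bool:
        return self.alleles is None

    @property
    def allele_set(self) -> frozenset[int]:
        if self.alleles is None:
            return frozenset()
        return frozenset(self.alleles)

    @property
    def is_het(self) -> bool:
        return self.alleles is not None and self.alleles[0] != self.alleles[1]

    @property
    def is_variant(self) -> bool:
        """Non-missing and carrying at least one alternate allele."""
        return self.alleles is not None and (self.alleles[0] > 0 or self.alleles[1] > 0)


def _chrom_sort_key(order: dict[str, int]):
    def key(site: VariantSite):
        return (order[site.chrom], site.pos, site.ref, site.alts[0])

    return key


class GenotypeMatrix:
    """A sites x samples table of genotype calls.

    Backing arrays (all shape ``(n_sites, n_samples)``, dtype int16):

    - ``allele1``/``allele2``: sorted allele-index pair, ``-1`` for missing;
    - ``gq``: phred genotype quality, ``-1`` for absent;
    - ``dp``: read depth, ``-1`` for absent.

    Sites are kept sorted by (chromosome order, pos, ref, first alt); the
    chromosome order is taken from the VCF header contig lines when available,
    else first appearance.
    """

    def __init__(
        self,
        sites: Sequence[VariantSite],
        samples: Sequence[str],
        allele1: np.ndarray,
        allele2: np.ndarray,
        gq: np.ndarray | None = None,
        dp: np.ndarray | None = None,
        chrom_order: Sequence[str] | None = None,
        _skip_sort: bool = False,
    ) -> None:
        n_sites, n_samples = len(sites), len(samples)
        shape = (n_sites, n_samples)
        self.sites = list(sites)
        self.samples = list(samples)
        if len(set(self.samples)) != n_samples:
            raise ValueError("duplicate sample identifiers")
        self.allele1 = np.asarray(allele1, dtype=np.int16).reshape(shape)
        self.allele2 = np.asarray(allele2, dtype=np.int16).reshape(shape)
        self.gq = (
            np.full(shape, MISSING, dtype=np.int16)
            if gq is None
            else np.asarray(gq, dtype=np.int16).reshape(shape)
        )
        self.dp = (
            np.full(shape, MISSING, dtype=np.int16)
            if dp is None
            else np.asarray(dp, dtype=np.int16).reshape(shape)
        )
        # normalize: unordered pair stored sorted; half-missing pairs -> missing
        lo = np.minimum(self.allele1, self.allele2)
        hi = np.maximum(self.allele1, self.allele2)
        miss = lo < 0
        lo[miss] = MISSING
        hi[miss] = MISSING
        self.allele1, self.allele2 = lo, hi
        if chrom_order is None:
            seen: dict[str, int] = {}
            for s in self.sites:
                seen.setdefault(s.chrom, len(seen))
            self.chrom_order = list(seen)
        else:
            self.chrom_order = list(chrom_order)
            for s in self.sites:
                if s.chrom not in self.chrom_order:
                    self.chrom_order.append(s.chrom)
        if not _skip_sort:
            self._sort_sites()
        keys = [s.key for s in self.sites]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate site keys (chrom, pos, ref, alt set)")

    def _sort_sites(self) -> None:
        order_map = {c: i for i, c in enumerate(self.chrom_order)}
        idx = sorted(range(len(self.sites)), key=lambda i: _chrom_sort_key(order_map)(self.sites[i]))
        if idx != list(range(len(self.sites))):
            self.sites = [self.sites[i] for i in idx]
            self.allele1 = self.allele1[idx]
            self.allele2 = self.allele2[idx]
            self.gq = self.gq[idx]
            self.dp = self.dp[idx]

    # -- structure ---------------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_sites, self.n_samples)

    def is_missing(self) -> np.ndarray:
        """Boolean (n_sites, n_samples) mask of MISSING calls."""
        return self.allele1 < 0

    def is_variant(self) -> np.ndarray:
        """Non-missing calls carrying >= 1 alt allele."""
        return (self.allele1 > 0) | (self.allele2 > 0)

    def site_keys(self) -> list[tuple]:
        return [s.key for s in self.sites]

    def call(self, i: int, j: int) -> GenotypeCall:
        """The call at site index ``i`` for sample index ``j``."""
        a1 = int(self.allele1[i, j])
        if a1 < 0:
            alleles = None
        else:
            alleles = (a1, int(self.allele2[i, j]))
        gq = int(self.gq[i, j])
        dp = int(self.dp[i, j])
        return GenotypeCall(alleles, gq if gq >= 0 else None, dp if dp >= 0 else None)

    def iter_calls(self) -> Iterator[tuple[int, int, GenotypeCall]]:
        for i in range(self.n_sites):
            for j in range(self.n_samples):
                yield i, j, self.call(i, j)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            list(self.sites),
            list(self.samples),
            self.allele1.copy(),
            self.allele2.copy(),
            self.gq.copy(),
            self.dp.copy(),
            chrom_order=self.chrom_order,
            _skip_sort=True,
        )

    def subset(
        self,
        site_idx: Sequence[int] | np.ndarray | None = None,
        sample_idx: Sequence[int] | np.ndarray | None = None,
    ) -> "GenotypeMatrix":
        """Sub-matrix by positional site/sample indices (order-preserving)."""
        si = np.arange(self.n_sites) if site_idx is None else np.asarray(site_idx, dtype=int)
        sj = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx, dtype=int)
        return GenotypeMatrix(
            [self.sites[i] for i in si],
            [self.samples[j] for j in sj],
            self.allele1[np.ix_(si, sj)],
            self.allele2[np.ix_(si, sj)],
            self.gq[np.ix_(si, sj)],
            self.dp[np.ix_(si, sj)],
            chrom_order=self.chrom_order,
            _skip_sort=True,
        )

    def dosage(self) -> np.ndarray:
        """Biallelic alt-allele dosage in {0, 1, 2}; -1 for missing.

        Raises for multiallelic sites, which have no scalar dosage.
        """
        if any(len(s.alts) > 1 for s in self.sites):
            raise ConfigurationError("dosage is defined for biallelic sites only")
        d = (self.allele1 + self.allele2).astype(np.int16)
        d[self.is_missing()] = MISSING
        return d

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.sites == other.sites
            and self.samples == other.samples
            and np.array_equal(self.allele1, other.allele1)
            and np.array_equal(self.allele2, other.allele2)
            and np.array_equal(self.gq, other.gq)
            and np.array_equal(self.dp, other.dp)
        )

    def __repr__(self) -> str:
        return f"<GenotypeMatrix {self.n_sites} sites x {self.n_samples} samples>"


@dataclass
class RegionSet:
    """Genomic intervals in BED convention (0-based, half-open), normalized.

    ``intervals`` maps chromosome -> (starts, ends) sorted, non-overlapping
    numpy arrays.
    """

    intervals: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    @classmethod
    def from_tuples(cls, tuples: Iterable[tuple[str, int, int]]) -> "RegionSet":
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in tuples:
            if start >= end:
                raise ValueError(f"invalid interval {chrom}:{start}-{end} (start >= end)")
            if start < 0:
                raise ValueError(f"negative start in {chrom}:{start}-{end}")
            by_chrom.setdefault(chrom, []).append((int(start), int(end)))
        out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            merged: list[list[int]] = []
            for s, e in ivs:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            out[chrom] = (
                np.array([m[0] for m in merged], dtype=np.int64),
                np.array([m[1] for m in merged], dtype=np.int64),
            )
        return cls(out)

    def to_tuples(self) -> list[tuple[str, int, int]]:
        out = []
        for chrom in sorted(self.intervals):
            starts, ends = self.intervals[chrom]
            out.extend((chrom, int(s), int(e)) for s, e in zip(starts, ends))
        return out

    def contains(self, chrom: str, pos: int) -> bool:
        """Membership of a 1-based VCF position: (pos - 1) in [start, end)."""
        if chrom not in self.intervals:
            return False
        starts, ends = self.intervals[chrom]
        p = pos - 1
        i = int(np.searchsorted(starts, p, side="right")) - 1
        return i >= 0 and p < ends[i]

    def __len__(self) -> int:
        return sum(len(s) for s, _ in self.intervals.values())


@dataclass(frozen=True)
class SampleCoverage:
    """Per-sample mean deduplicated sequencing depth with an integer bin label.

    The default bin label is the depth rounded to the nearest integer x-fold;
    explicit bin edges (see concordance.StratificationSpec) override it.
    """

    sample: str
    mean_depth: float

    def __post_init__(self) -> None:
        if self.mean_depth < 0:
            raise ValueError("mean depth must be non-negative")

    @property
    def bin(self) -> int:
        return int(np.floor(self.mean_depth + 0.5))


def read_coverage_table(path) -> dict[str, SampleCoverage]:
    """Read a two-column (sample, mean_depth) TSV, with or without header."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise VcfParseError(f"{path}: coverage table needs >= 2 columns")
    try:
        float(df.iloc[0, 1])
    except ValueError:
        df = df.iloc[1:]
    return {
        str(row[0]): SampleCoverage(str(row[0]), float(row[1]))
        for row in df.itertuples(index=False)
    }


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

def read_vcf(
    path,
    required_fields: Iterable[str] = ("GT",),
    drop_non_pass: bool = False,
) -> GenotypeMatrix:
    """Read a multi-sample VCF into a :class:`GenotypeMatrix`.

    Parameters
    ----------
    path
        Plain-text or bgzipped VCF (v4.2 dialect) with a GT FORMAT field.
    required_fields
        Subset of ``{"GT", "GQ", "DP"}``; raising a configuration error if a
        requested field appears on no record.
    drop_non_pass
        Drop sites whose FILTER is neither PASS nor missing at read time.

    Phase is discarded; half-calls become MISSING; multiallelic records are
    kept as single sites.
    """
    required = set(required_fields)
    bad = required - {"GT", "GQ", "DP"}
    if bad:
        raise ConfigurationError(f"unsupported required fields: {sorted(bad)}")
    try:
        vf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise VcfParseError(f"{path}: cannot parse VCF header: {exc}") from exc
    with vf:
        samples = list(vf.header.samples)
        contig_order = list(vf.header.contigs)
        sites: list[VariantSite] = []
        a1_rows, a2_rows, gq_rows, dp_rows = [], [], [], []
        seen_fields: set[str] = set()
        for rec_no, rec in enumerate(vf, start=1):
            try:
                site = _site_from_record(rec)
            except ValueError as exc:
                raise VcfParseError(f"{path}: record {rec_no}: {exc}") from exc
            if drop_non_pass and not site.is_pass:
                continue
            n = len(samples)
            a1 = np.full(n, MISSING, dtype=np.int16)
            a2 = np.full(n, MISSING, dtype=np.int16)
            gq = np.full(n, MISSING, dtype=np.int16)
            dp = np.full(n, MISSING, dtype=np.int16)
            for j, sample in enumerate(samples):
                call = rec.samples[sample]
                alleles = call.get("GT")
                if alleles is not None:
                    seen_fields.add("GT")
                    if (
                        len(alleles) == 2
                        and alleles[0] is not None
                        and alleles[1] is not None
                    ):
                        a1[j], a2[j] = alleles[0], alleles[1]
                v = call.get("GQ")
                if v is not None:
                    seen_fields.add("GQ")
                    gq[j] = min(99, max(0, int(v)))
                v = call.get("DP")
                if v is not None:
                    seen_fields.add("DP")
                    dp[j] = int(v)
            sites.append(site)
            a1_rows.append(a1)
            a2_rows.append(a2)
            gq_rows.append(gq)
            dp_rows.append(dp)
    if sites:
        missing_fields = required - seen_fields
        if missing_fields:
            raise ConfigurationError(
                f"{path}: required FORMAT field(s) {sorted(missing_fields)} "
                "absent from every record"
            )
    n = len(samples)
    stack = lambda rows: (
        np.array(rows, dtype=np.int16) if rows else np.empty((0, n), dtype=np.int16)
    )
    return GenotypeMatrix(
        sites,
        samples,
        stack(a1_rows),
        stack(a2_rows),
        stack(gq_rows),
        stack(dp_rows),
        chrom_order=contig_order if contig_order else None,
    )


def _site_from_record(rec: "pysam.VariantRecord") -> VariantSite:
    if rec.alts is None:
        raise ValueError("record has no ALT allele")
    filters = tuple(rec.filter.keys())
    if not filters:
        filters = ("PASS",)  # '.' treated as unfiltered/PASS-equivalent
    return VariantSite(rec.chrom, rec.pos, rec.ref, tuple(rec.alts), filters)


def write_vcf(
    matrix: GenotypeMatrix,
    path,
    extra_format: tuple[str, np.ndarray, str] | None = None,
) -> None:
    """Write a :class:`GenotypeMatrix` as a VCF v4.2 file.

    ``extra_format`` is an optional ``(tag, values, description)`` triple with
    an integer per-call array of the matrix's shape, emitted as an additional
    FORMAT tag (used for IM consistency flags).
    """
    header = pysam.VariantHeader()
    for chrom in matrix.chrom_order:
        header.contigs.add(chrom)
    named_filters = sorted(
        {f for s in matrix.sites for f in s.filter if f != "PASS"}
    )
    for f in named_filters:
        header.filters.add(f, None, None, "site-level filter")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("GQ", 1, "Integer", "Genotype quality (phred)")
    header.formats.add("DP", 1, "Integer", "Read depth")
    if extra_format is not None:
        tag, values, description = extra_format
        values = np.asarray(values)
        if values.shape != matrix.shape:
            raise ValueError("extra_format values must match the matrix shape")
        header.formats.add(tag, 1, "Integer", description)
    for sample in matrix.samples:
        header.add_sample(sample)
    try:
        out = pysam.VariantFile(str(path), "w", header=header)
    except OSError as exc:
        raise OSError(f"cannot write VCF to {path}: {exc}") from exc
    with out:
        for i, site in enumerate(matrix.sites):
            rec = out.new_record(
                contig=site.chrom,
                start=site.pos - 1,
                alleles=(site.ref,) + site.alts,
            )
            for f in site.filter:
                rec.filter.add(f)
            for j, sample in enumerate(matrix.samples):
                call = rec.samples[sample]
                a1 = int(matrix.allele1[i, j])
                if a1 < 0:
                    call["GT"] = (None, None)
                else:
                    call["GT"] = (a1, int(matrix.allele2[i, j]))
                call.phased = False
                if matrix.gq[i, j] >= 0:
                    call["GQ"] = int(matrix.gq[i, j])
                if matrix.dp[i, j] >= 0:
                    call["DP"] = int(matrix.dp[i, j])
                if extra_format is not None:
                    call[extra_format[0]] = int(np.asarray(extra_format[1])[i, j])
            out.write(rec)


# ---------------------------------------------------------------------------
# BED I/O and region restriction
# ---------------------------------------------------------------------------

def read_bed(path) -> RegionSet:
    """Read a 3+ column BED file into a normalized (sorted, merged) RegionSet."""
    try:
        df = pd.read_csv(
            path,
            sep=r"\s+",
            header=None,
            comment="#",
            usecols=[0, 1, 2],
            names=["chrom", "start", "end"],
            dtype={"chrom": str},
        )
    except pd.errors.EmptyDataError:
        return RegionSet()
    except (ValueError, pd.errors.ParserError) as exc:
        raise VcfParseError(f"{path}: malformed BED: {exc}") from exc
    if df.empty:
        return RegionSet()
    try:
        starts = df["start"].astype(np.int64)
        ends = df["end"].astype(np.int64)
    except (TypeError, ValueError) as exc:
        raise VcfParseError(f"{path}: non-integer BED coordinates: {exc}") from exc
    bad = starts >= ends
    if bad.any():
        i = int(np.argmax(bad.to_numpy()))
        raise VcfParseError(
            f"{path}: line {i + 1}: start >= end "
            f"({df['chrom'].iloc[i]}:{starts.iloc[i]}-{ends.iloc[i]})"
        )
    return RegionSet.from_tuples(zip(df["chrom"], starts, ends))


def restrict_to_regions(matrix: GenotypeMatrix, regions: RegionSet) -> GenotypeMatrix:
    """Keep exactly the sites whose 0-based position lies in ``regions``.

    Sample set is unchanged; the operation is idempotent.
    """
    keep = [
        i for i, s in enumerate(matrix.sites) if regions.contains(s.chrom, s.pos)
    ]
    return matrix.subset(site_idx=keep)
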