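"""SNP calling and major-allele frequencies from pooled counts.

A site in a synchronized pooled pileup is called a SNP when

1. every pool's coverage (four-nucleotide sum; N and deletions never
   count) lies within ``[min_coverage, max_coverage]`` — the coverage
   floor guards frequency precision, the ceiling guards against repeats
   collapsing onto one position; and
2. summing counts across all pools, at least two nucleotides are present
   and the second most frequent one reaches ``min_minor_count`` — a
   minimum minor-allele count absorbs sequencing errors.

The defaults (minor count 4, coverage 20-400) are the thresholds of the
validation study this package re-implements.  The major allele is defined
on the counts of all pools combined, so a single pool's major-allele
frequency can be below 0.5.  Counts and frequencies are kept as exact
integers/rationals until serialization so filter decisions and reported
frequencies are bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .sync import BASES, BASE_INDEX, SyncSite

logger = logging.getLogger(__name__)

#: fixed tie-break order for allele definitions
ALPHABETICAL = ("A", "C", "G", "T")


@dataclass(frozen=True)
class FilterParams:
    """Thresholds for SNP identification on pooled counts.

    ``minor_scope`` controls where the minimum minor-allele count is
    enforced: ``"combined"`` (default) sums counts over all pools;
    ``"per_pool"`` additionally requires the minor allele to reach the
    threshold in every single pool.
    """

    min_minor_count: int = 4
    min_coverage: int = 20
    max_coverage: int = 400
    minor_scope: str = "combined"

    def __post_init__(self) -> None:
        if self.min_minor_count < 1:
            raise ValueError("min_minor_count must be >= 1")
        if not 1 <= self.min_coverage <= self.max_coverage:
            raise ValueError(
                "need 1 <= min_coverage <= max_coverage, got "
                f"{self.min_coverage}..{self.max_coverage}"
            )
        if self.minor_scope not in ("combined", "per_pool"):
            raise ValueError("minor_scope must be 'combined' or 'per_pool'")


def define_major_allele(
    combined_counts: Mapping[str, int] | Sequence[int] | np.ndarray,
) -> tuple[str, str]:
    """Major and minor allele from counts combined across pools.

    Accepts a base->count mapping or a length-4 vector in sync order
    (A, T, C, G).  Major is the argmax, minor the second argmax; ties are
    broken in fixed alphabetical order A < C < G < T.
    """
    if isinstance(combined_counts, Mapping):
        counts = {b: int(combined_counts.get(b, 0)) for b in BASES}
    else:
        vec = np.asarray(combined_counts)
        if vec.shape != (4,):
            raise ValueError("expected four counts in A,T,C,G order")
        counts = {b: int(vec[BASE_INDEX[b]]) for b in BASES}
    if any(c < 0 for c in counts.values()):
        raise ValueError("negative allele counts")
    if all(c == 0 for c in counts.values()):
        raise ValueError("all-zero counts: no allele can be defined")
    ranked = sorted(ALPHABETICAL, key=lambda b: (-counts[b], b))
    return ranked[0], ranked[1]


def pool_frequency(
    counts: Mapping[str, int] | Sequence[int] | np.ndarray,
    major_base: str,
    minor_base: str | None = None,
) -> Fraction:
    """Major-allele frequency in one pool, as an exact rational.

    By default the denominator is the full four-nucleotide coverage.
    When ``minor_base`` is given the site is treated as strictly
    biallelic and any third/fourth-base counts are dropped from the
    denominator.
    """
    if isinstance(counts, Mapping):
        vec = np.array([int(counts.get(b, 0)) for b in BASES], dtype=np.int64)
    else:
        vec = np.asarray(counts, dtype=np.int64)
        if vec.shape != (4,):
            raise ValueError("expected four counts in A,T,C,G order")
    if (vec < 0).any():
        raise ValueError("negative counts")
    if major_base not in BASE_INDEX:
        raise ValueError(f"invalid base {major_base!r}")
    major = int(vec[BASE_INDEX[major_base]])
    if minor_base is None:
        denom = int(vec.sum())
    else:
        if minor_base not in BASE_INDEX or minor_base == major_base:
            raise ValueError(f"invalid minor base {minor_base!r}")
        denom = major + int(vec[BASE_INDEX[minor_base]])
    if denom < 1:
        raise ValueError("zero coverage: frequency undefined")
    return Fraction(major, denom)


@dataclass(frozen=True, eq=False)
class SnpRecord:
    """One called SNP with per-pool counts and frequencies."""

    chrom: str
    pos: int
    ref: str
    major: str
    minor: str
    counts: np.ndarray  # (n_pools, 4) in sync order A,T,C,G

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 2 or counts.shape[1] != 4:
            raise ValueError("counts must be (n_pools, 4)")
        counts.setflags(write=False)
        object.__setattr__(self, "counts", counts)

    @property
    def locus(self) -> str:
        return f"{self.chrom}:{self.pos}"

    @property
    def n_pools(self) -> int:
        return self.counts.shape[0]

    @property
    def coverage(self) -> np.ndarray:
        """Per-pool four-nucleotide coverage."""
        return self.counts.sum(axis=1)

    @property
    def combined_counts(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def is_biallelic(self) -> bool:
        extra = self.combined_counts.sum() - (
            self.combined_counts[BASE_INDEX[self.major]]
            + self.combined_counts[BASE_INDEX[self.minor]]
        )
        return int(extra) == 0

    @property
    def maf(self) -> tuple[Fraction, ...]:
        """Per-pool major-allele frequency (biallelic denominator)."""
        return tuple(
            pool_frequency(row, self.major, self.minor) for row in self.counts
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SnpRecord):
            return NotImplemented
        return (
            (self.chrom, self.pos, self.ref, self.major, self.minor)
            == (other.chrom, other.pos, other.ref, other.major, other.minor)
            and np.array_equal(self.counts, other.counts)
        )


class SnpTable:
    """Called SNPs surviving the filters, in input order."""

    def __init__(self, records: Sequence[SnpRecord]):
        records = list(records)
        if records:
            n = records[0].n_pools
            if any(r.n_pools != n for r in records):
                raise ValueError("records disagree on pool number")
        self.records = records

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SnpRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> SnpRecord:
        return self.records[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SnpTable):
            return NotImplemented
        return self.records == other.records

    @property
    def n_pools(self) -> int:
        return self.records[0].n_pools if self.records else 0

    def loci(self) -> list[str]:
        return [r.locus for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        """Flat table: chrom, pos, alleles, per-pool coverage and MAF."""
        rows = []
        for r in self.records:
            row: dict = {
                "chrom": r.chrom,
                "pos": r.pos,
                "ref": r.ref,
                "major": r.major,
                "minor": r.minor,
            }
            for p in range(r.n_pools):
                row[f"pool{p + 1}_cov"] = int(r.coverage[p])
                row[f"pool{p + 1}_maf"] = float(r.maf[p])
            rows.append(row)
        return pd.DataFrame(rows)

    def write_tsv(self, path: str | Path, header_note: str = "") -> None:
        """Serialize as TSV; per-pool base counts are kept so downstream
        resampling can re-draw reads."""
        with open(path, "wt", encoding="utf-8") as fh:
            if header_note:
                fh.write(f"# {header_note}\n")
            cols = ["chrom", "pos", "ref", "major", "minor"]
            for p in range(self.n_pools):
                cols += [f"pool{p + 1}_{b}" for b in BASES]
                cols += [f"pool{p + 1}_maf"]
            fh.write("\t".join(cols) + "\n")
            for r in self.records:
                fields = [r.chrom, str(r.pos), r.ref, r.major, r.minor]
                for p in range(r.n_pools):
                    fields += [str(int(c)) for c in r.counts[p]]
                    fields.append(repr(float(r.maf[p])))
                fh.write("\t".join(fields) + "\n")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "SnpTable":
        with open(path, "rt", encoding="utf-8") as fh:
            lines = [l for l in fh if l.strip() and not l.startswith("#")]
        if not lines:
            return cls([])
        header = lines[0].rstrip("\n").split("\t")
        n_pools = sum(1 for c in header if c.endswith("_maf"))
        records = []
        for line in lines[1:]:
            f = line.rstrip("\n").split("\t")
            counts = []
            k = 5
            for _ in range(n_pools):
                counts.append([int(x) for x in f[k : k + 4]])
                k += 5  # skip the maf column, recomputed from counts
            records.append(
                SnpRecord(f[0], int(f[1]), f[2], f[3], f[4], np.array(counts))
            )
        return cls(records)


def call_snps(
    sites: Sequence[SyncSite], params: FilterParams = FilterParams()
) -> SnpTable:
    """Apply the SNP-identification filters to synchronized pooled counts.

    Retains a site iff every pool's coverage is within bounds and the
    combined minor-allele count reaches the threshold (see
    :class:`FilterParams`).  Sites where a third or fourth nucleotide
    segregates are retained when the top-two rule passes; the extra
    counts stay in the record but are excluded from the biallelic
    frequency denominator, and a warning is logged.

    An empty input yields an empty table; pools must be consistent across
    sites.
    """
    sites = list(sites)
    if not sites:
        return SnpTable([])
    n_pools = sites[0].n_pools
    for site in sites:
        if site.n_pools != n_pools:
            raise ValueError(
                f"ragged pool counts: {site.locus} has {site.n_pools} "
                f"pools, expected {n_pools}"
            )
    records = []
    for site in sites:
        cov = site.coverage
        if (cov < params.min_coverage).any() or (
            cov > params.max_coverage
        ).any():
            continue
        base_counts = site.counts[:, :4]
        combined = base_counts.sum(axis=0)
        if int((combined > 0).sum()) < 2:
            continue
        major, minor = define_major_allele(combined)
        minor_combined = int(combined[BASE_INDEX[minor]])
        if minor_combined < params.min_minor_count:
            continue
        if params.minor_scope == "per_pool":
            per_pool_minor = base_counts[:, BASE_INDEX[minor]]
            if (per_pool_minor < params.min_minor_count).any():
                continue
        record = SnpRecord(
            site.chrom, site.pos, site.ref, major, minor, base_counts
        )
        if not record.is_biallelic:
            logger.warning(
                "site %s has more than two segregating bases; extra "
                "counts excluded from the biallelic frequency",
                site.locus,
            )
        records.append(record)
    return SnpTable(records)
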