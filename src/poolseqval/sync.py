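"""Reading and writing synchronized pooled pileups (the "sync" format).

A sync file has one line per genomic site: chromosome, 1-based position,
reference base, then one colon-joined ``A:T:C:G:N:del`` count string per
population pool, all tab-separated.  This is the dialect produced by
PoPoolation2's mpileup synchronization step and is the standard exchange
format for pooled allele counts.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

import numpy as np

#: column order of the six count categories in a sync pool string
SYNC_CATEGORIES = ("A", "T", "C", "G", "N", "del")

#: the four nucleotides, in sync column order (not alphabetical)
BASES = ("A", "T", "C", "G")

#: index of each nucleotide within a sync count vector
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

VALID_REF = set("ACGTN")


class SyncParseError(ValueError):
    """Raised when a sync stream violates the format."""


@dataclass(frozen=True, eq=False)
class SyncSite:
    """Pooled pileup counts at one site.

    Parameters
    ----------
    chrom, pos, ref
        Sequence name, 1-based position and reference base (``N`` allowed).
    counts
        Integer array of shape ``(n_pools, 6)`` in :data:`SYNC_CATEGORIES`
        order.  ``N`` and deletion counts are carried through but excluded
        from coverage (the four-nucleotide sum).
    """

    chrom: str
    pos: int
    ref: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 2 or counts.shape[1] != len(SYNC_CATEGORIES):
            raise ValueError(
                f"counts must have shape (n_pools, 6), got {counts.shape}"
            )
        if (counts < 0).any():
            raise ValueError("negative pileup counts")
        if self.pos < 1:
            raise ValueError(f"positions are 1-based, got {self.pos}")
        if self.ref not in VALID_REF:
            raise ValueError(f"invalid reference base {self.ref!r}")
        counts.setflags(write=False)
        object.__setattr__(self, "counts", counts)

    @property
    def n_pools(self) -> int:
        return self.counts.shape[0]

    @property
    def coverage(self) -> np.ndarray:
        """Per-pool coverage: the sum of the four nucleotide counts."""
        return self.counts[:, :4].sum(axis=1)

    @property
    def locus(self) -> str:
        """Canonical locus identifier, ``chrom:pos``."""
        return f"{self.chrom}:{self.pos}"

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SyncSite):
            return NotImplemented
        return (
            self.chrom == other.chrom
            and self.pos == other.pos
            and self.ref == other.ref
            and np.array_equal(self.counts, other.counts)
        )

    def __repr__(self) -> str:  # compact, matches the on-disk line
        return f"SyncSite({format_sync_line(self)!r})"


def _parse_pool(field: str, line_no: int) -> list[int]:
    parts = field.split(":")
    if len(parts) != len(SYNC_CATEGORIES):
        raise SyncParseError(
            f"line {line_no}: pool count string {field!r} has {len(parts)} "
            f"fields, expected {len(SYNC_CATEGORIES)}"
        )
    try:
        values = [int(p) for p in parts]
    except ValueError as exc:
        raise SyncParseError(
            f"line {line_no}: non-integer count in {field!r}"
        ) from exc
    if any(v < 0 for v in values):
        raise SyncParseError(f"line {line_no}: negative count in {field!r}")
    return values


def parse_sync_line(line: str, line_no: int = 1) -> SyncSite:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 4:
        raise SyncParseError(
            f"line {line_no}: expected at least 4 tab-separated fields, "
            f"got {len(fields)}"
        )
    chrom, pos_str, ref = fields[0], fields[1], fields[2]
    try:
        pos = int(pos_str)
    except ValueError as exc:
        raise SyncParseError(
            f"line {line_no}: non-integer position {pos_str!r}"
        ) from exc
    counts = [_parse_pool(f, line_no) for f in fields[3:]]
    try:
        return SyncSite(chrom, pos, ref, np.array(counts, dtype=np.int64))
    except ValueError as exc:
        raise SyncParseError(f"line {line_no}: {exc}") from exc


def format_sync_line(site: SyncSite) -> str:
    pools = "\t".join(
        ":".join(str(int(c)) for c in row) for row in site.counts
    )
    return f"{site.chrom}\t{site.pos}\t{site.ref}\t{pools}"


def read_sync(source: str | Path | IO[str]) -> list[SyncSite]:
    """Parse a sync file (path or open text stream) into sites.

    Raises
    ------
    SyncParseError
        On malformed count strings, non-integer fields, or a pool number
        that changes between lines; messages name the offending line.
    """
    if isinstance(source, (str, Path)):
        with open(source, "rt", encoding="utf-8") as fh:
            return read_sync(fh)
    sites: list[SyncSite] = []
    n_pools: int | None = None
    for line_no, line in enumerate(source, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        site = parse_sync_line(line, line_no)
        if n_pools is None:
            n_pools = site.n_pools
        elif site.n_pools != n_pools:
            raise SyncParseError(
                f"line {line_no}: {site.n_pools} pools, expected {n_pools}"
            )
        sites.append(site)
    return sites


def read_sync_string(text: str) -> list[SyncSite]:
    return read_sync(io.StringIO(text))


def write_sync(sites: Iterable[SyncSite], dest: str | Path | IO[str]) -> None:
    """Write sites in the dialect read by :func:`read_sync` (stable order)."""
    if isinstance(dest, (str, Path)):
        with open(dest, "wt", encoding="utf-8") as fh:
            write_sync(sites, fh)
        return
    for site in sites:
        dest.write(format_sync_line(site) + "\n")


def write_sync_string(sites: Iterable[SyncSite]) -> str:
    buf = io.StringIO()
    write_sync(sites, buf)
    return buf.getvalue()
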