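"""Tabular serialization for genotype matrices, comparison records and
validation reports.

All formats are plain text: tab-separated tables with an optional leading
``#`` comment line carrying the resolved run parameters, and JSON reports
with a ``schema_version`` field.  Floats are written with ``repr`` so a
fixed seed round-trips byte-identically.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np

from .simulate import GenotypeMatrix
from .validate import ComparisonRecord, ValidationReport

DEFAULT_MISSING = "NN"


def write_genotypes(
    genotypes: GenotypeMatrix,
    path: str | Path,
    missing: str = DEFAULT_MISSING,
    header_note: str = "",
) -> None:
    """Genotype table: sample, population, then one column per locus."""
    with open(path, "wt", encoding="utf-8") as fh:
        if header_note:
            fh.write(f"# {header_note}\n")
        fh.write("\t".join(["sample", "population", *genotypes.loci]) + "\n")
        for i, (sample, pop) in enumerate(
            zip(genotypes.samples, genotypes.populations)
        ):
            calls = [
                missing if c is None else c for c in genotypes.calls[i]
            ]
            fh.write("\t".join([sample, pop, *calls]) + "\n")


def read_genotypes(
    path: str | Path, missing: str = DEFAULT_MISSING
) -> GenotypeMatrix:
    with open(path, "rt", encoding="utf-8") as fh:
        lines = [l for l in fh if l.strip() and not l.startswith("#")]
    if not lines:
        raise ValueError(f"{path}: empty genotype table")
    header = lines[0].rstrip("\n").split("\t")
    if header[:2] != ["sample", "population"]:
        raise ValueError(
            f"{path}: genotype tables start with sample and population "
            "columns"
        )
    loci = header[2:]
    samples, populations, rows = [], [], []
    ploidy = None
    for line in lines[1:]:
        fields = line.rstrip("\n").split("\t")
        if len(fields) != len(header):
            raise ValueError(
                f"{path}: row with {len(fields)} fields, expected "
                f"{len(header)}"
            )
        samples.append(fields[0])
        populations.append(fields[1])
        row = [None if c == missing else c for c in fields[2:]]
        for c in row:
            if c is not None:
                ploidy = len(c) if ploidy is None else ploidy
        rows.append(row)
    calls = np.array(rows, dtype=object) if rows else np.empty(
        (0, len(loci)), dtype=object
    )
    return GenotypeMatrix(
        samples, populations, loci, calls, ploidy if ploidy else 2
    )


RECORD_COLUMNS = (
    "snp", "population", "pool_maf", "indiv_maf", "abs_diff",
    "coverage", "complete", "major", "count_A", "count_T", "count_C",
    "count_G",
)


def write_records(
    records: Sequence[ComparisonRecord],
    path: str | Path,
    header_note: str = "",
) -> None:
    """Comparison records as a flat TSV, base counts included so the
    table feeds the coverage-resampling stage directly."""
    with open(path, "wt", encoding="utf-8") as fh:
        if header_note:
            fh.write(f"# {header_note}\n")
        fh.write("\t".join(RECORD_COLUMNS) + "\n")
        for r in records:
            counts = r.counts if r.counts is not None else ("", "", "", "")
            fh.write(
                "\t".join(
                    [
                        r.snp,
                        r.population,
                        repr(r.pool_maf),
                        repr(r.indiv_maf),
                        repr(r.abs_diff),
                        str(r.coverage),
                        "1" if r.complete else "0",
                        r.major,
                        *[str(c) for c in counts],
                    ]
                )
                + "\n"
            )


def read_records(path: str | Path) -> list[ComparisonRecord]:
    records = []
    with open(path, "rt", encoding="utf-8") as fh:
        lines = [l for l in fh if l.strip() and not l.startswith("#")]
    if not lines:
        return records
    header = lines[0].rstrip("\n").split("\t")
    if tuple(header) != RECORD_COLUMNS:
        raise ValueError(f"{path}: unexpected record columns {header}")
    for line in lines[1:]:
        f = dict(zip(header, line.rstrip("\n").split("\t")))
        counts = None
        if f["count_A"]:
            counts = tuple(
                int(f[f"count_{b}"]) for b in ("A", "T", "C", "G")
            )
        records.append(
            ComparisonRecord(
                snp=f["snp"],
                population=f["population"],
                pool_maf=float(f["pool_maf"]),
                indiv_maf=float(f["indiv_maf"]),
                coverage=int(f["coverage"]),
                complete=f["complete"] == "1",
                major=f["major"],
                counts=counts,
            )
        )
    return records


def write_report_json(
    reports: dict[str, ValidationReport], path: str | Path
) -> None:
    payload = {name: rep.to_dict() for name, rep in sorted(reports.items())}
    with open(path, "wt", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
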