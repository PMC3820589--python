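"""Concordance statistics between pooled and individual allele frequencies.

Pairs every called SNP with every population into one comparison record
(pooled major-allele frequency vs the frequency counted from individual
genotypes) and reproduces the validation statistics:

- mean absolute frequency difference with its standard error;
- ordinary least squares on the *untransformed* frequencies for slope,
  intercept and R² (the quantities judged against the ideal 1:1 line);
- the regression p-value and a paired t-test on arcsine-square-root
  transformed frequencies (variance stabilization for proportions);
- Pearson correlation of coverage with the absolute difference, probing
  whether accuracy still depends on coverage in the observed range.

Every statistic is computed twice: over all records, and over the subset
with complete individual genotyping — the difference estimates the impact
of missing calls.  Missing individuals inside a record are handled by
pairwise deletion (the individual frequency is taken over non-missing
calls); record-level exclusion happens only in the complete-only variant.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .poolfreq import SnpTable
from .simulate import GenotypeMatrix
from .sync import BASE_INDEX, BASES

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1


class DegenerateFitError(ValueError):
    """A statistic is undefined because a variable has zero variance."""


@dataclass(frozen=True)
class ComparisonRecord:
    """One SNP x population pairing of the two frequency estimates.

    ``counts`` keeps the pool's four nucleotide counts (sync order
    A,T,C,G) so reads can later be re-drawn at lower coverage;
    ``complete`` is False iff at least one individual call was missing.
    """

    snp: str
    population: str
    pool_maf: float
    indiv_maf: float
    coverage: int
    complete: bool
    major: str = ""
    counts: tuple[int, int, int, int] | None = None

    def __post_init__(self) -> None:
        for name in ("pool_maf", "indiv_maf"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")

    @property
    def abs_diff(self) -> float:
        return abs(self.pool_maf - self.indiv_maf)


def individual_maf(
    calls: Iterable[str | None], major_base: str
) -> Fraction:
    """Major-allele frequency from individual diploid calls at one locus.

    Missing individuals are excluded from numerator and denominator
    (pairwise deletion).  Raises if every call is missing.
    """
    observed = [c for c in calls if c is not None]
    if not observed:
        raise ValueError("all individual calls missing: frequency undefined")
    n_alleles = sum(len(c) for c in observed)
    n_major = sum(c.count(major_base) for c in observed)
    return Fraction(n_major, n_alleles)


def pair_records(
    snp_table: SnpTable, genotypes: GenotypeMatrix
) -> list[ComparisonRecord]:
    """One comparison record per called SNP x population.

    Loci present in only one source are reported via warnings, never
    silently dropped; a population whose calls are all missing at a locus
    yields no record (also warned).  With every locus called in both
    sources the record count is ``n_snps x n_populations``.
    """
    locus_cols = {locus: j for j, locus in enumerate(genotypes.loci)}
    table_loci = set(snp_table.loci())
    only_geno = [l for l in genotypes.loci if l not in table_loci]
    only_table = [l for l in snp_table.loci() if l not in locus_cols]
    if only_geno:
        logger.warning(
            "%d locus/loci only in the genotype table: %s",
            len(only_geno), ", ".join(only_geno),
        )
    if only_table:
        logger.warning(
            "%d locus/loci only in the SNP table: %s",
            len(only_table), ", ".join(only_table),
        )
    if genotypes.n_loci == 0 or genotypes.n_samples == 0:
        logger.warning("empty genotype table: no comparisons possible")
        return []

    pools = genotypes.population_indices()
    if snp_table.n_pools and len(pools) != snp_table.n_pools:
        raise ValueError(
            f"genotype table has {len(pools)} populations but the SNP "
            f"table has {snp_table.n_pools} pools"
        )
    records = []
    for rec in snp_table:
        j = locus_cols.get(rec.locus)
        if j is None:
            continue
        for p, (pop, ix) in enumerate(pools.items()):
            calls = list(genotypes.calls[ix, j])
            n_missing = sum(c is None for c in calls)
            if n_missing == len(calls):
                logger.warning(
                    "SNP %s, population %s: all individual calls missing; "
                    "comparison skipped", rec.locus, pop,
                )
                continue
            records.append(
                ComparisonRecord(
                    snp=rec.locus,
                    population=pop,
                    pool_maf=float(rec.maf[p]),
                    indiv_maf=float(individual_maf(calls, rec.major)),
                    coverage=int(rec.coverage[p]),
                    complete=n_missing == 0,
                    major=rec.major,
                    counts=tuple(int(c) for c in rec.counts[p]),
                )
            )
    return records


def _xy(records: Sequence[ComparisonRecord]) -> tuple[np.ndarray, np.ndarray]:
    x = np.array([r.pool_maf for r in records], dtype=float)
    y = np.array([r.indiv_maf for r in records], dtype=float)
    return x, y


def regression_untransformed(
    records: Sequence[ComparisonRecord],
) -> tuple[float, float, float]:
    """OLS of individual on pooled frequency, untransformed.

    Returns ``(slope, intercept, r_squared)``.  Kept on the raw frequency
    scale because the question is deviation from the ideal 1:1 line.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 records for a regression")
    x, y = _xy(records)
    if np.ptp(x) == 0.0:
        raise DegenerateFitError("zero variance in pooled frequencies")
    fit = stats.linregress(x, y)
    r_squared = 0.0 if np.ptp(y) == 0.0 else float(fit.rvalue) ** 2
    return float(fit.slope), float(fit.intercept), r_squared


def arcsine_transform(freq) -> float | np.ndarray:
    """Variance-stabilizing arcsin(sqrt(p)); maps [0, 1] onto [0, pi/2]."""
    arr = np.asarray(freq, dtype=float)
    if ((arr < 0.0) | (arr > 1.0)).any():
        raise ValueError("frequencies must lie in [0, 1]")
    out = np.arcsin(np.sqrt(arr))
    return float(out) if out.ndim == 0 else out


def regression_p_transformed(records: Sequence[ComparisonRecord]) -> float:
    """Two-sided p-value of the regression slope on transformed scale.

    Both frequencies are arcsine-square-root transformed before the fit;
    the p comes from the slope's t statistic with n - 2 df.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 records for a regression")
    x, y = _xy(records)
    xt, yt = arcsine_transform(x), arcsine_transform(y)
    if np.ptp(xt) == 0.0:
        raise DegenerateFitError("zero variance in pooled frequencies")
    return float(stats.linregress(xt, yt).pvalue)


def paired_t_transformed(
    records: Sequence[ComparisonRecord],
) -> tuple[float, float]:
    """Paired t-test of pooled vs individual frequency, transformed scale.

    Two-sided, n - 1 df.  Identical vectors give ``(0.0, 1.0)``; a
    constant non-zero difference has no within-pair variance, so the
    statistic degenerates to signed infinity with p = 0 (flagged).
    """
    if len(records) < 2:
        raise ValueError("need at least 2 records for a paired t-test")
    x, y = _xy(records)
    d = arcsine_transform(x) - arcsine_transform(y)
    sd = d.std(ddof=1)
    if sd == 0.0:
        if d[0] == 0.0:
            return 0.0, 1.0
        logger.warning(
            "paired t-test degenerate: constant nonzero difference"
        )
        return math.copysign(math.inf, d[0]), 0.0
    res = stats.ttest_rel(arcsine_transform(x), arcsine_transform(y))
    return float(res.statistic), float(res.pvalue)


def mean_abs_diff(
    records: Sequence[ComparisonRecord],
) -> tuple[float, float]:
    """Mean absolute frequency difference and its standard error.

    SE uses the n-1 sample standard deviation over sqrt(n); for a single
    record (or identical differences) the SE is 0.
    """
    if not records:
        raise ValueError("need at least 1 record")
    d = np.array([r.abs_diff for r in records])
    if len(d) == 1:
        return float(d[0]), 0.0
    return float(d.mean()), float(d.std(ddof=1) / math.sqrt(len(d)))


def coverage_effect(
    records: Sequence[ComparisonRecord],
) -> tuple[float, float]:
    """Pearson correlation of coverage with the absolute difference.

    Two-sided p via the t transform with n - 2 df.  Zero variance in
    either variable leaves r undefined (raised as degenerate).
    """
    if len(records) < 3:
        raise ValueError("need at least 3 records")
    cov = np.array([r.coverage for r in records], dtype=float)
    d = np.array([r.abs_diff for r in records])
    if np.ptp(cov) == 0.0 or np.ptp(d) == 0.0:
        raise DegenerateFitError(
            "zero variance: coverage correlation undefined"
        )
    r, p = stats.pearsonr(cov, d)
    return float(r), float(p)


@dataclass(frozen=True)
class ValidationReport:
    """All concordance statistics for one record subset."""

    variant: str  # "all" | "complete_only"
    n: int
    mean_abs_diff: float | None = None
    mean_abs_diff_se: float | None = None
    slope: float | None = None
    intercept: float | None = None
    r_squared: float | None = None
    p_regression: float | None = None
    t_statistic: float | None = None
    p_paired: float | None = None
    pearson_r_coverage: float | None = None
    p_coverage: float | None = None
    note: str | None = None

    def to_dict(self) -> dict:
        def clean(v):
            if v is None or (isinstance(v, float) and not math.isfinite(v)):
                return None
            return v

        return {
            "schema_version": SCHEMA_VERSION,
            "variant": self.variant,
            "n": self.n,
            "mean_abs_diff": clean(self.mean_abs_diff),
            "mean_abs_diff_se": clean(self.mean_abs_diff_se),
            "slope": clean(self.slope),
            "intercept": clean(self.intercept),
            "r_squared": clean(self.r_squared),
            "p_regression": clean(self.p_regression),
            "t_statistic": clean(self.t_statistic),
            "p_paired": clean(self.p_paired),
            "pearson_r_coverage": clean(self.pearson_r_coverage),
            "p_coverage": clean(self.p_coverage),
            "note": self.note,
        }


def build_report(
    records: Sequence[ComparisonRecord], variant: str = "all"
) -> ValidationReport:
    """Run every concordance statistic on the selected record subset.

    ``variant="complete_only"`` keeps records without any missing
    individual call.  Insufficient records produce a report that names
    the gap instead of crashing.
    """
    if variant not in ("all", "complete_only"):
        raise ValueError("variant must be 'all' or 'complete_only'")
    subset = (
        [r for r in records if r.complete]
        if variant == "complete_only"
        else list(records)
    )
    n = len(subset)
    if n < 3:
        return ValidationReport(
            variant=variant,
            n=n,
            note=f"only {n} record(s) after subsetting; statistics require "
            "at least 3",
        )
    mad, se = mean_abs_diff(subset)
    slope, intercept, r2 = regression_untransformed(subset)
    p_reg = regression_p_transformed(subset)
    t_stat, p_t = paired_t_transformed(subset)
    try:
        r_cov, p_cov = coverage_effect(subset)
        note = None
    except DegenerateFitError as exc:
        r_cov = p_cov = None
        note = str(exc)
    return ValidationReport(
        variant=variant,
        n=n,
        mean_abs_diff=mad,
        mean_abs_diff_se=se,
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        p_regression=p_reg,
        t_statistic=t_stat,
        p_paired=p_t,
        pearson_r_coverage=r_cov,
        p_coverage=p_cov,
        note=note,
    )


def build_reports(
    records: Sequence[ComparisonRecord],
) -> dict[str, ValidationReport]:
    """Both reporting variants in one run (all records / complete only)."""
    return {
        "all": build_report(records, "all"),
        "complete_only": build_report(records, "complete_only"),
    }
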