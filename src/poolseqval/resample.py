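"""Coverage titration by read resampling.

Starting from the observed pooled base counts of each SNP x population
comparison, reads are repeatedly re-drawn *without replacement*
(multivariate hypergeometric) at every target coverage in a range, the
pooled major-allele frequency is recomputed from each draw, and two
accuracy summaries are averaged over iterations per coverage level:

- the mean absolute difference to the individual-based frequencies, and
- the R² of the untransformed linear regression against them.

Sampling without replacement is what caps the usable range at the
minimum observed coverage: a pool cannot lend more reads than it has.
The default range (1-55x, 1000 iterations) titrates down from the
smallest per-pool coverage of the emulated study.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .sync import BASE_INDEX
from .validate import ComparisonRecord


@dataclass(frozen=True)
class ResamplingConfig:
    """Coverage range (inclusive), iteration count and master seed."""

    coverage_min: int = 1
    coverage_max: int = 55
    n_iterations: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coverage_min < 1:
            raise ValueError("coverage_min must be >= 1")
        if self.coverage_max < self.coverage_min:
            raise ValueError("coverage_max must be >= coverage_min")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


@dataclass(frozen=True)
class CoverageCurvePoint:
    """Across-iteration summaries at one simulated coverage level."""

    coverage: int
    mean_abs_diff_avg: float
    mean_abs_diff_sd: float
    r_squared_avg: float
    r_squared_sd: float

    def __post_init__(self) -> None:
        if self.mean_abs_diff_sd < 0 or self.r_squared_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if not 0.0 <= self.r_squared_avg <= 1.0:
            raise ValueError("r_squared_avg must lie in [0, 1]")


def downsample_counts(
    counts: Sequence[int] | np.ndarray,
    target: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw ``target`` reads without replacement from observed counts.

    Multivariate hypergeometric: the output always sums to ``target``;
    asking for more reads than exist is an error, never a silent
    with-replacement draw.  ``target`` equal to the total returns the
    counts unchanged.
    """
    vec = np.asarray(counts, dtype=np.int64)
    if (vec < 0).any():
        raise ValueError("negative counts")
    total = int(vec.sum())
    if target < 0:
        raise ValueError("target must be >= 0")
    if target > total:
        raise ValueError(
            f"cannot draw {target} reads from {total} without replacement"
        )
    return rng.multivariate_hypergeometric(vec, target)


def _iteration_stats(
    freqs: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-iteration mean |diff| and R² for a (n_iter, n_records) block.

    R² is the squared Pearson correlation of the resampled frequencies
    with the reference; an iteration whose resampled frequencies are all
    identical (possible at coverage 1) carries no explanatory power and
    scores R² = 0.
    """
    mad = np.abs(freqs - reference[None, :]).mean(axis=1)
    fc = freqs - freqs.mean(axis=1, keepdims=True)
    rc = reference - reference.mean()
    denom_r = float(rc @ rc)
    if denom_r == 0.0:
        return mad, np.zeros(freqs.shape[0])
    num = fc @ rc
    denom_f = (fc**2).sum(axis=1)
    r2 = np.zeros(freqs.shape[0])
    ok = denom_f > 0.0
    r2[ok] = (num[ok] ** 2) / (denom_f[ok] * denom_r)
    return mad, np.minimum(r2, 1.0)


def coverage_curve(
    records: Sequence[ComparisonRecord], config: ResamplingConfig
) -> list[CoverageCurvePoint]:
    """Accuracy-vs-coverage curve over the configured range.

    Records are processed in sorted (snp, population) order and all
    randomness flows from one seeded generator, so a fixed config gives a
    bit-identical curve.  Every record must carry its original base
    counts and have coverage at least ``coverage_max``.
    """
    recs = sorted(records, key=lambda r: (r.snp, r.population))
    if not recs:
        raise ValueError("no records to resample")
    missing = [r.snp for r in recs if r.counts is None or not r.major]
    if missing:
        raise ValueError(
            "records lack base counts or major allele: "
            + ", ".join(sorted(set(missing)))
        )
    shallow = [
        f"{r.snp}/{r.population} ({sum(r.counts)}x)"
        for r in recs
        if sum(r.counts) < config.coverage_max
    ]
    if shallow:
        raise ValueError(
            f"coverage below the requested maximum {config.coverage_max}x "
            "for: " + ", ".join(shallow)
        )
    rng = np.random.default_rng(config.seed)
    reference = np.array([r.indiv_maf for r in recs])
    count_vecs = [np.asarray(r.counts, dtype=np.int64) for r in recs]
    major_ix = [BASE_INDEX[r.major] for r in recs]

    points = []
    n_iter = config.n_iterations
    for c in range(config.coverage_min, config.coverage_max + 1):
        freqs = np.empty((n_iter, len(recs)))
        for k, vec in enumerate(count_vecs):
            draws = rng.multivariate_hypergeometric(vec, c, size=n_iter)
            freqs[:, k] = draws[:, major_ix[k]] / c
        mad, r2 = _iteration_stats(freqs, reference)
        points.append(
            CoverageCurvePoint(
                coverage=c,
                mean_abs_diff_avg=float(mad.mean()),
                mean_abs_diff_sd=_spread(mad),
                r_squared_avg=float(r2.mean()),
                r_squared_sd=_spread(r2),
            )
        )
    return points


def _spread(values: np.ndarray) -> float:
    # identical iterations (e.g. exhaustive draws at full coverage) have
    # exactly zero spread; avoid epsilon-sized rounding residue
    if len(values) < 2 or np.ptp(values) == 0.0:
        return 0.0
    return float(values.std(ddof=1))


NOT_REACHED = None  # sentinel returned when a threshold is never crossed


def coverage_at_threshold(
    curve: Sequence[CoverageCurvePoint],
    metric: str,
    threshold: float,
) -> int | None:
    """Smallest coverage at which the averaged metric crosses a threshold.

    For ``metric="mean_abs_diff"`` the crossing is *below* the threshold;
    for ``metric="r_squared"`` it is at-or-above.  Returns ``None`` when
    the threshold is never crossed.
    """
    if not curve:
        raise ValueError("empty curve")
    if metric == "mean_abs_diff":
        hits = (
            p.coverage for p in curve if p.mean_abs_diff_avg < threshold
        )
    elif metric == "r_squared":
        hits = (p.coverage for p in curve if p.r_squared_avg >= threshold)
    else:
        raise ValueError("metric must be 'mean_abs_diff' or 'r_squared'")
    return min(hits, default=NOT_REACHED)


def curve_summary(curve: Sequence[CoverageCurvePoint]) -> dict:
    """Threshold crossings at the conventional accuracy marks."""
    return {
        "schema_version": 1,
        "coverage_min": curve[0].coverage,
        "coverage_max": curve[-1].coverage,
        "coverage_for_diff_below_5pct": coverage_at_threshold(
            curve, "mean_abs_diff", 0.05
        ),
        "coverage_for_r2_0.95": coverage_at_threshold(
            curve, "r_squared", 0.95
        ),
        "coverage_for_r2_0.99": coverage_at_threshold(
            curve, "r_squared", 0.99
        ),
        "mean_abs_diff_at_max_coverage": curve[-1].mean_abs_diff_avg,
    }


def write_curve_tsv(
    curve: Sequence[CoverageCurvePoint],
    path: str | Path,
    header_note: str = "",
) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        if header_note:
            fh.write(f"# {header_note}\n")
        fh.write(
            "coverage\tmean_abs_diff_avg\tmean_abs_diff_sd\t"
            "r_squared_avg\tr_squared_sd\n"
        )
        for p in curve:
            fh.write(
                f"{p.coverage}\t{p.mean_abs_diff_avg!r}\t"
                f"{p.mean_abs_diff_sd!r}\t{p.r_squared_avg!r}\t"
                f"{p.r_squared_sd!r}\n"
            )


def read_curve_tsv(path: str | Path) -> list[CoverageCurvePoint]:
    points = []
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "coverage")):
                continue
            c, m, ms, r, rs = line.split("\t")
            points.append(
                CoverageCurvePoint(
                    int(c), float(m), float(ms), float(r), float(rs)
                )
            )
    return points


def write_curve_summary(
    curve: Sequence[CoverageCurvePoint], path: str | Path
) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        json.dump(curve_summary(curve), fh, indent=2, sort_keys=True)
        fh.write("\n")
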