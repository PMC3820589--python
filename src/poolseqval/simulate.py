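"""Synthetic pooled-sequencing experiments.

Emulates a Pool-Seq validation design: several natural populations of an
outcrossing diploid, each represented by one equimolar DNA pool of its
sampled individuals, sequenced to moderate-to-high coverage, with the same
individuals also genotyped one by one at a handful of SNPs.  The default
design matches the study layout this package targets: 3 populations x 20
diploid individuals x 9 biallelic SNPs, per-pool coverage uniform on
[55, 284], sequencing error below 1%, and occasional per-individual assay
dropout.

Three stochastic layers are modelled:

1. genotypes — Hardy-Weinberg binomial draws of the major-allele dosage
   per individual, given per-population true frequencies;
2. pooled reads — per-individual DNA contribution weights (gamma, mean 1,
   configurable coefficient of variation; CV 0 means exactly equimolar),
   a coverage sampler, and per-read substitution error spread uniformly
   over the three non-true bases;
3. individual genotyping — each call independently lost with a fixed
   failure probability (the assay is treated as exact when it succeeds).

No read-level artefacts are simulated: no quality scores, no mapping bias,
no indels, no linkage between loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence, Union

import numpy as np

from .sync import BASES, BASE_INDEX, SyncSite

RngLike = Union[int, np.random.Generator]

#: coverage specification: a scalar, a full (n_pools, n_snps) matrix, or
#: ("uniform", lo, hi) for i.i.d. integer coverage on the inclusive range
CoverageSpec = Union[int, np.ndarray, tuple]

DEFAULT_COVERAGE: CoverageSpec = ("uniform", 55, 284)


def _rng(seed: RngLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def singleton_frequency(n_individuals: int, ploidy: int) -> float:
    """Within-pool frequency of an allele present as a single copy.

    One chromosome out of ``n_individuals * ploidy``; for a pool of 20
    diploids this is 1/40 = 2.5%, the detection floor a sequencing-error
    rate must stay safely below for rare alleles to be callable.
    """
    if n_individuals < 1 or ploidy < 1:
        raise ValueError("n_individuals and ploidy must be >= 1")
    return 1.0 / (n_individuals * ploidy)


def minimum_recommended_coverage(n_individuals: int, ploidy: int) -> int:
    """Coverage floor for a pool: the effective pool size.

    Below ``n_individuals * ploidy`` reads, not every chromosome in the
    pool can even in principle be observed, so rare variants are missed by
    construction.
    """
    if n_individuals < 1 or ploidy < 1:
        raise ValueError("n_individuals and ploidy must be >= 1")
    return n_individuals * ploidy


@dataclass(frozen=True)
class PopulationDesign:
    """True allele-frequency layout of the pooled experiment.

    ``true_major_freqs[p, j]`` is the major-allele frequency of SNP ``j``
    in population ``p``; ``major_bases[j]``/``minor_bases[j]`` are the two
    segregating nucleotides.  Loci are placed one per contig (draft-genome
    flavour) with identifiers ``contigNN:pos``.
    """

    true_major_freqs: np.ndarray
    major_bases: tuple[str, ...]
    minor_bases: tuple[str, ...]
    n_individuals_per_pool: int = 20
    ploidy: int = 2
    population_names: tuple[str, ...] = ()
    chroms: tuple[str, ...] = ()
    positions: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        freqs = np.asarray(self.true_major_freqs, dtype=float)
        if freqs.ndim != 2:
            raise ValueError(
                "true_major_freqs must be (n_populations, n_snps), got "
                f"shape {freqs.shape}"
            )
        if ((freqs < 0) | (freqs > 1)).any():
            raise ValueError("frequencies must lie in [0, 1]")
        n_pops, n_snps = freqs.shape
        if n_pops < 1 or n_snps < 1:
            raise ValueError("need at least one population and one SNP")
        if len(self.major_bases) != n_snps or len(self.minor_bases) != n_snps:
            raise ValueError("one major and one minor base per SNP required")
        for j, (ma, mi) in enumerate(zip(self.major_bases, self.minor_bases)):
            if ma not in BASE_INDEX or mi not in BASE_INDEX:
                raise ValueError(f"SNP {j}: bases must be one of {BASES}")
            if ma == mi:
                raise ValueError(f"SNP {j}: major and minor base identical")
        if self.n_individuals_per_pool < 1 or self.ploidy < 1:
            raise ValueError("pool size and ploidy must be >= 1")
        freqs.setflags(write=False)
        object.__setattr__(self, "true_major_freqs", freqs)
        if not self.population_names:
            object.__setattr__(
                self,
                "population_names",
                tuple(f"pop{p + 1}" for p in range(n_pops)),
            )
        elif len(self.population_names) != n_pops:
            raise ValueError("population_names length mismatch")
        if not self.chroms:
            object.__setattr__(
                self,
                "chroms",
                tuple(f"contig{j + 1:02d}" for j in range(n_snps)),
            )
        if not self.positions:
            object.__setattr__(self, "positions", (100,) * n_snps)
        if len(self.chroms) != n_snps or len(self.positions) != n_snps:
            raise ValueError("chroms/positions length mismatch")

    @property
    def n_populations(self) -> int:
        return self.true_major_freqs.shape[0]

    @property
    def n_snps(self) -> int:
        return self.true_major_freqs.shape[1]

    @property
    def effective_pool_size(self) -> int:
        """Chromosomes per pool: individuals x ploidy."""
        return self.n_individuals_per_pool * self.ploidy

    @property
    def loci(self) -> tuple[str, ...]:
        return tuple(
            f"{c}:{p}" for c, p in zip(self.chroms, self.positions)
        )

    @classmethod
    def random(
        cls,
        seed: RngLike,
        n_populations: int = 3,
        n_snps: int = 9,
        n_individuals_per_pool: int = 20,
        ploidy: int = 2,
        freq_low: float = 0.02,
        freq_high: float = 0.98,
    ) -> "PopulationDesign":
        """Draw a design with i.i.d. uniform per-population frequencies.

        Per SNP, the two alleles are a random unordered pair of distinct
        nucleotides and the labels are flipped if needed so that the mean
        frequency across populations is >= 0.5 (major-allele convention:
        within a single population the major-allele frequency may then
        fall below 0.5).
        """
        rng = _rng(seed)
        freqs = rng.uniform(freq_low, freq_high, size=(n_populations, n_snps))
        flip = freqs.mean(axis=0) < 0.5
        freqs[:, flip] = 1.0 - freqs[:, flip]
        majors, minors = [], []
        for _ in range(n_snps):
            a, b = rng.choice(len(BASES), size=2, replace=False)
            majors.append(BASES[a])
            minors.append(BASES[b])
        return cls(
            true_major_freqs=freqs,
            major_bases=tuple(majors),
            minor_bases=tuple(minors),
            n_individuals_per_pool=n_individuals_per_pool,
            ploidy=ploidy,
        )


def default_study_design(seed: RngLike = 0) -> PopulationDesign:
    """The emulated validation layout: 3 pools x 20 diploids x 9 SNPs."""
    return PopulationDesign.random(seed)


@dataclass(frozen=True)
class SequencingModel:
    """Noise model for pooled sequencing of one library per population.

    Parameters
    ----------
    coverage
        Scalar, explicit ``(n_pools, n_snps)`` matrix, or
        ``("uniform", lo, hi)`` for i.i.d. integer coverage.
    error_rate
        Per-base substitution probability; an erroneous read shows one of
        the three non-true bases uniformly.  Must be < 0.25 (above that the
        signal is gone by construction).
    pipetting_cv
        Coefficient of variation of per-individual DNA contribution
        weights (gamma with mean 1).  0 means perfectly equimolar and
        bypasses sampling entirely.
    n_rate, del_rate
        Probability of a read being recorded as ``N`` or as a deletion;
        both default to 0, matching quality-filtered pileups.
    count_mode
        ``"sample"`` draws read counts multinomially; ``"expected"``
        replaces the draw with deterministic largest-remainder rounding of
        the expected counts — useful for exactness checks.
    """

    coverage: CoverageSpec = DEFAULT_COVERAGE
    error_rate: float = 0.0
    pipetting_cv: float = 0.0
    n_rate: float = 0.0
    del_rate: float = 0.0
    count_mode: str = "sample"

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate < 0.25:
            raise ValueError("error_rate must lie in [0, 0.25)")
        if self.pipetting_cv < 0:
            raise ValueError("pipetting_cv must be >= 0")
        if self.n_rate < 0 or self.del_rate < 0 or (
            self.n_rate + self.del_rate
        ) >= 1:
            raise ValueError("n_rate/del_rate must be >= 0 and sum < 1")
        if self.count_mode not in ("sample", "expected"):
            raise ValueError("count_mode must be 'sample' or 'expected'")
        if isinstance(self.coverage, tuple):
            kind, lo, hi = self.coverage
            if kind != "uniform" or lo < 1 or hi < lo:
                raise ValueError(
                    "tuple coverage must be ('uniform', lo, hi) with "
                    "1 <= lo <= hi"
                )
        elif isinstance(self.coverage, (int, np.integer)):
            if self.coverage < 1:
                raise ValueError("coverage must be >= 1")
        else:
            cov = np.asarray(self.coverage, dtype=np.int64)
            if (cov < 1).any():
                raise ValueError("all coverages must be >= 1")
            cov.setflags(write=False)
            object.__setattr__(self, "coverage", cov)

    def sample_coverage(
        self, rng: np.random.Generator, n_pools: int, n_snps: int
    ) -> np.ndarray:
        if isinstance(self.coverage, tuple):
            _, lo, hi = self.coverage
            return rng.integers(lo, hi + 1, size=(n_pools, n_snps))
        if isinstance(self.coverage, (int, np.integer)):
            return np.full((n_pools, n_snps), int(self.coverage), np.int64)
        cov = np.asarray(self.coverage)
        if cov.shape != (n_pools, n_snps):
            raise ValueError(
                f"coverage matrix shape {cov.shape} does not match "
                f"({n_pools}, {n_snps})"
            )
        return cov.astype(np.int64)


@dataclass(eq=False)
class GenotypeMatrix:
    """Per-individual diploid (or higher-ploidy) calls at each locus.

    ``calls[i, j]`` is a sorted string of ``ploidy`` nucleotides (e.g.
    ``"AG"``) or ``None`` for a missing call.  Population labels partition
    the samples into the pools, in order of first appearance.
    """

    samples: list[str]
    populations: list[str]
    loci: list[str]
    calls: np.ndarray
    ploidy: int = 2

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=object)
        n, m = len(self.samples), len(self.loci)
        if len(self.populations) != n:
            raise ValueError("one population label per sample required")
        if self.calls.shape != (n, m):
            raise ValueError(
                f"calls shape {self.calls.shape} != ({n}, {m})"
            )
        for call in self.calls.flat:
            if call is not None and len(call) != self.ploidy:
                raise ValueError(
                    f"call {call!r} does not have ploidy {self.ploidy}"
                )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def population_names(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.populations))

    def population_indices(self) -> dict[str, np.ndarray]:
        """Sample row indices per population, in first-appearance order."""
        out: dict[str, list[int]] = {}
        for i, pop in enumerate(self.populations):
            out.setdefault(pop, []).append(i)
        return {p: np.array(ix) for p, ix in out.items()}

    @property
    def n_missing(self) -> int:
        return sum(c is None for c in self.calls.flat)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            list(self.samples),
            list(self.populations),
            list(self.loci),
            self.calls.copy(),
            self.ploidy,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.samples == other.samples
            and self.populations == other.populations
            and self.loci == other.loci
            and self.ploidy == other.ploidy
            and (self.calls == other.calls).all()
        )

    def dosage(self, base: str) -> np.ndarray:
        """Count of ``base`` per call; -1 marks missing calls."""
        out = np.full(self.calls.shape, -1, dtype=np.int64)
        for ix, call in np.ndenumerate(self.calls):
            if call is not None:
                out[ix] = call.count(base)
        return out


def simulate_genotypes(
    design: PopulationDesign, seed: RngLike
) -> GenotypeMatrix:
    """Draw individual genotypes under Hardy-Weinberg proportions.

    Each individual's major-allele dosage at each SNP is binomial with
    ``ploidy`` trials and the population's true major frequency; loci are
    independent (no linkage).  Fixed seed gives bit-identical output.
    """
    rng = _rng(seed)
    n_ind = design.n_individuals_per_pool
    samples, populations = [], []
    for pop in design.population_names:
        for i in range(n_ind):
            samples.append(f"{pop}_{i + 1:02d}")
            populations.append(pop)
    pop_of_row = np.repeat(np.arange(design.n_populations), n_ind)
    probs = design.true_major_freqs[pop_of_row, :]
    dose = rng.binomial(design.ploidy, probs)
    calls = np.empty(dose.shape, dtype=object)
    for j in range(design.n_snps):
        ma, mi = design.major_bases[j], design.minor_bases[j]
        for i in range(dose.shape[0]):
            d = int(dose[i, j])
            calls[i, j] = "".join(
                sorted(ma * d + mi * (design.ploidy - d))
            )
    return GenotypeMatrix(
        samples, populations, list(design.loci), calls, design.ploidy
    )


def _largest_remainder(total: int, probs: np.ndarray) -> np.ndarray:
    """Deterministic integer apportionment of ``total`` by ``probs``."""
    raw = probs * total
    base = np.floor(raw).astype(np.int64)
    short = total - int(base.sum())
    if short > 0:
        order = np.argsort(-(raw - base), kind="stable")
        base[order[:short]] += 1
    return base


def _split_locus(locus: str) -> tuple[str, int]:
    chrom, _, pos = locus.rpartition(":")
    if chrom and pos.isdigit():
        return chrom, int(pos)
    return locus, 1


def simulate_pool_counts(
    genotypes: GenotypeMatrix,
    model: SequencingModel,
    seed: RngLike,
) -> list[SyncSite]:
    """Sequence one equimolar pool per population and return sync sites.

    Per pool: one gamma contribution weight per individual (CV from the
    model; all exactly 1 at CV 0); per locus the true pool frequency of
    each base is the weight-weighted mean allele dosage divided by ploidy.
    Reads are then drawn at the sampled coverage, each showing the true
    base with probability ``1 - error_rate`` and otherwise one of the
    other three bases uniformly; optional N/deletion categories take their
    configured share.  The six category counts always sum to the coverage.

    Requires fully observed genotypes (missing calls would make the pool
    composition undefined).
    """
    if genotypes.n_missing:
        raise ValueError(
            "pool simulation requires fully observed genotypes "
            f"({genotypes.n_missing} missing calls present)"
        )
    rng = _rng(seed)
    pools = genotypes.population_indices()
    n_pools, n_snps = len(pools), genotypes.n_loci
    ploidy = genotypes.ploidy

    # per-base dosage tensor: (n_samples, n_snps, 4)
    dose = np.stack([genotypes.dosage(b) for b in BASES], axis=-1)

    weights = []
    for pop, ix in pools.items():
        if model.pipetting_cv > 0:
            shape = 1.0 / model.pipetting_cv**2
            weights.append(rng.gamma(shape, 1.0 / shape, size=len(ix)))
        else:
            weights.append(np.ones(len(ix)))
    coverage = model.sample_coverage(rng, n_pools, n_snps)

    e = model.error_rate
    aux = model.n_rate + model.del_rate
    counts = np.zeros((n_snps, n_pools, 6), dtype=np.int64)
    for p, (pop, ix) in enumerate(pools.items()):
        w = weights[p]
        # (n_snps, 4) true base frequencies in this pool
        freqs = np.tensordot(w, dose[ix], axes=(0, 0)) / (ploidy * w.sum())
        observed = freqs * (1.0 - e) + (1.0 - freqs) * (e / 3.0)
        probs = np.empty((n_snps, 6))
        probs[:, :4] = observed * (1.0 - aux)
        probs[:, 4] = model.n_rate
        probs[:, 5] = model.del_rate
        for j in range(n_snps):
            c = int(coverage[p, j])
            if model.count_mode == "expected":
                counts[j, p] = _largest_remainder(c, probs[j])
            else:
                counts[j, p] = rng.multinomial(c, probs[j])

    combined_dose = dose.sum(axis=0)  # (n_snps, 4) true allele counts
    sites = []
    for j, locus in enumerate(genotypes.loci):
        chrom, pos = _split_locus(locus)
        # reference base: the overall most common true allele, ties broken
        # alphabetically (A < C < G < T)
        order = sorted(range(4), key=lambda k: (-combined_dose[j, k], BASES[k]))
        ref = BASES[order[0]]
        sites.append(SyncSite(chrom, pos, ref, counts[j]))
    return sites


def simulate_individual_calls(
    genotypes: GenotypeMatrix, failure_rate: float, seed: RngLike
) -> GenotypeMatrix:
    """Apply random assay dropout to individual genotyping.

    Each (individual, locus) call is independently replaced by missing
    with probability ``failure_rate``; surviving calls are exact (the
    assay introduces no base errors).
    """
    if not 0.0 <= failure_rate < 1.0:
        raise ValueError("failure_rate must lie in [0, 1)")
    rng = _rng(seed)
    out = genotypes.copy()
    if failure_rate > 0.0:
        mask = rng.random(out.calls.shape) < failure_rate
        out.calls[mask] = None
    return out


@dataclass(frozen=True)
class SimulatedExperiment:
    """Bundle of one synthetic run: truth plus both observation channels."""

    design: PopulationDesign
    model: SequencingModel
    failure_rate: float
    genotypes: GenotypeMatrix          # fully observed truth
    observed_genotypes: GenotypeMatrix  # after assay dropout
    sites: list[SyncSite]

    def realized_major_freqs(self) -> np.ndarray:
        """Per-population major-allele frequencies of the drawn genotypes."""
        pools = self.genotypes.population_indices()
        ploidy = self.genotypes.ploidy
        out = np.zeros((len(pools), self.genotypes.n_loci))
        for p, ix in enumerate(pools.values()):
            for j, base in enumerate(self.design.major_bases):
                d = self.genotypes.dosage(base)[ix, j]
                out[p, j] = d.sum() / (ploidy * len(ix))
        return out


def simulate_experiment(
    design: PopulationDesign,
    model: SequencingModel,
    failure_rate: float,
    seed: RngLike,
) -> SimulatedExperiment:
    """Run all three simulators from one master seed.

    Child streams are spawned from a single :class:`numpy.random.SeedSequence`
    so the stages are independent yet jointly reproducible.
    """
    if isinstance(seed, np.random.Generator):
        rngs = [seed, seed, seed]
    else:
        rngs = [
            np.random.default_rng(c)
            for c in np.random.SeedSequence(seed).spawn(3)
        ]
    genotypes = simulate_genotypes(design, rngs[0])
    sites = simulate_pool_counts(genotypes, model, rngs[1])
    observed = simulate_individual_calls(genotypes, failure_rate, rngs[2])
    return SimulatedExperiment(
        design, model, failure_rate, genotypes, observed, sites
    )
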