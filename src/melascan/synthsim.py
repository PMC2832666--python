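"""Seeded synthetic-data generators for every pipeline input.

Every generator is a pure function of its spec plus seed: reruns are
bitwise identical. Generated data satisfy the preconditions of the
downstream analysis modules without adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genodata import (
    MISSING,
    GenotypeMatrix,
    PhenotypeTable,
    PopAlleleCounts,
    SnpRecord,
)
from .wglrh import HaplotypeSet


@dataclass(frozen=True)
class CohortSpec:
    """One-SNP association cohort: HWE genotypes plus a normal phenotype."""

    n: int
    freq: float  # effect-allele (allele_b) frequency
    beta: float = 0.0  # per-allele effect on melanin index
    het_offset: float = 0.0  # dominance deviation added to heterozygotes
    hom_offset: float = 0.0  # deviation added to allele_b homozygotes
    mu: float = 31.0  # phenotype mean (melanin index)
    sigma: float = 3.0  # total phenotype SD
    sex_effect: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.freq < 1:
            raise ValueError("freq must be in (0, 1)")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")


def _genetic_values(spec: CohortSpec) -> np.ndarray:
    g = np.arange(3, dtype=float)
    vals = spec.beta * g
    vals[1] += spec.het_offset
    vals[2] += spec.hom_offset
    return vals


def simulate_cohort(spec: CohortSpec) -> tuple[GenotypeMatrix, PhenotypeTable]:
    """Genotypes in HWE at the stated frequency and melanin index with an
    additive (plus optional dominance) genetic effect and a sex covariate.

    The residual SD is chosen so the total phenotype SD equals ``spec.sigma``;
    an error is raised when the genetic plus sex variance already exceeds
    sigma^2.
    """
    rng = np.random.default_rng(spec.seed)
    p = spec.freq
    geno_probs = np.array([(1 - p) ** 2, 2 * p * (1 - p), p * p])
    gvals = _genetic_values(spec)
    var_g = float(geno_probs @ gvals**2 - (geno_probs @ gvals) ** 2)
    var_sex = 0.25 * spec.sex_effect**2  # sex ~ Bernoulli(1/2)
    resid_var = spec.sigma**2 - var_g - var_sex
    if resid_var <= 0:
        raise ValueError(
            "infeasible variance partition: genetic + sex variance "
            f"({var_g + var_sex:.3f}) >= sigma^2 ({spec.sigma**2:.3f})"
        )
    g = rng.choice(3, size=spec.n, p=geno_probs).astype(np.int8)
    sex = rng.integers(0, 2, size=spec.n)
    centre = spec.mu - float(geno_probs @ gvals) - 0.5 * spec.sex_effect
    m = (
        centre
        + gvals[g]
        + spec.sex_effect * sex
        + rng.normal(0.0, np.sqrt(resid_var), size=spec.n)
    )
    lo, hi = PhenotypeTable.MELANIN_BAND
    m = np.clip(m, lo, hi)
    calls = g.astype(np.int8).reshape(-1, 1)
    if spec.missing_rate > 0:
        drop = rng.random(spec.n) < spec.missing_rate
        calls[drop, 0] = MISSING
    samples = [f"S{i:05d}" for i in range(spec.n)]
    gm = GenotypeMatrix(
        samples=samples,
        snps=[SnpRecord("sim1", "1", 1000, "A", "G", ancestral="A")],
        calls=calls,
    )
    pheno = PhenotypeTable(
        data=pd.DataFrame(
            {"sample_id": samples, "melanin_index": m, "sex": sex}
        )
    )
    return gm, pheno


def simulate_structured_cohort(
    p1: float,
    p2: float,
    n: int,
    mix: float = 0.5,
    seed: int = 0,
) -> GenotypeMatrix:
    """Two-subpopulation Wahlund mixture at a single SNP.

    Each individual belongs to subpopulation 1 with probability ``mix`` and
    draws an HWE genotype at that subpopulation's frequency. When p1 != p2
    the pooled sample shows the classic heterozygote deficit.
    """
    for p in (p1, p2):
        if not 0 < p < 1:
            raise ValueError("subpopulation frequencies must be in (0, 1)")
    rng = np.random.default_rng(seed)
    origin = rng.random(n) < mix
    p_ind = np.where(origin, p1, p2)
    g = rng.binomial(1, p_ind) + rng.binomial(1, p_ind)  # two allele draws
    samples = [f"S{i:05d}" for i in range(n)]
    return GenotypeMatrix(
        samples=samples,
        snps=[SnpRecord("mix1", "1", 1000, "A", "G")],
        calls=g.astype(np.int8).reshape(-1, 1),
    )


@dataclass(frozen=True)
class PanelSpec:
    """Multi-population allele-count panel at controlled differentiation."""

    n_pops: int = 3
    n_chrom: tuple[int, ...] = (200, 200, 200)  # typed chromosomes per pop
    n_snps: int = 5000
    span: int = 50_000_000  # positions uniform over [1, span]
    fst: tuple[float, ...] = (0.0, 0.0, 0.0)  # Balding-Nichols F per pop
    freq_range: tuple[float, float] = (0.05, 0.95)  # ancestral freq distribution
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_chrom) != self.n_pops or len(self.fst) != self.n_pops:
            raise ValueError("n_chrom and fst must have one entry per pop")
        if any(not 0 <= f < 1 for f in self.fst):
            raise ValueError("fst values must be in [0, 1)")
        if self.n_snps <= 0:
            raise ValueError("n_snps must be positive")


def simulate_panel(spec: PanelSpec) -> PopAlleleCounts:
    """Balding-Nichols allele-count panel.

    Each SNP gets an ancestral frequency from Uniform(freq_range); each
    population's frequency is Beta(p(1-F)/F, (1-p)(1-F)/F) around it (or the
    ancestral frequency itself at F = 0), and observed counts are binomial
    at the population's chromosome total.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.freq_range
    p_anc = rng.uniform(lo, hi, size=spec.n_snps)
    positions = np.sort(
        rng.choice(np.arange(1, spec.span + 1), size=spec.n_snps, replace=False)
    )
    count_b = np.empty((spec.n_pops, spec.n_snps), dtype=np.int64)
    n_chrom = np.empty_like(count_b)
    for i in range(spec.n_pops):
        f = spec.fst[i]
        if f == 0:
            p_pop = p_anc
        else:
            p_pop = rng.beta(p_anc * (1 - f) / f, (1 - p_anc) * (1 - f) / f)
        count_b[i] = rng.binomial(spec.n_chrom[i], p_pop)
        n_chrom[i] = spec.n_chrom[i]
    snps = [
        SnpRecord(f"snp{j:06d}", "1", int(pos), "A", "G", ancestral="A")
        for j, pos in enumerate(positions)
    ]
    return PopAlleleCounts(
        snps=snps,
        pops=[f"pop{i + 1}" for i in range(spec.n_pops)],
        count_b=count_b,
        n_chrom=n_chrom,
    )


@dataclass(frozen=True)
class SweepSpec:
    """Forward Wright-Fisher simulation with one selected derived allele."""

    pop_size: int = 500  # haploid chromosomes
    s: float = 0.05  # selection coefficient (fitness 1, 1+s, 1+2s)
    recomb: float = 1e-3  # crossover probability per adjacent-marker interval
    n_markers: int = 41
    marker_spacing: int = 25_000  # bp between adjacent markers
    init_freq: float = 0.05  # starting derived frequency at the focal site
    stop_freq: float = 0.7  # sampling once the derived allele crosses this
    max_generations: int = 5000
    n_sample: int = 100  # haplotypes sampled at the end
    background_freq_range: tuple[float, float] = (0.1, 0.9)
    max_restarts: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.s < 0:
            raise ValueError("selection coefficient must be >= 0")
        if not 0 <= self.recomb <= 1:
            raise ValueError("recombination probability must be in [0, 1]")
        if self.n_sample > self.pop_size:
            raise ValueError("cannot sample more haplotypes than the population")

    @property
    def focal_index(self) -> int:
        return self.n_markers // 2


def _wf_generation(
    pop: np.ndarray, fitness: np.ndarray, recomb: float, rng: np.random.Generator
) -> np.ndarray:
    n, m = pop.shape
    w = fitness / fitness.sum()
    mothers = rng.choice(n, size=n, p=w)
    fathers = rng.choice(n, size=n, p=w)
    child = pop[mothers].copy()
    if recomb > 0 and m > 1:
        cross = rng.random((n, m - 1)) < recomb
        # parity of crossovers before each marker selects the active parent
        take_father = np.cumsum(cross, axis=1) % 2 == 1
        take_father = np.column_stack([np.zeros(n, dtype=bool), take_father])
        child[take_father] = pop[fathers][take_father]
    return child


def simulate_sweep(spec: SweepSpec) -> HaplotypeSet:
    """Binary haplotypes sampled after a partial selective sweep.

    The focal (centre) marker starts at ``init_freq`` derived frequency and
    carriers reproduce with genic selection until it crosses ``stop_freq``;
    runs where the derived allele is lost restart with a fresh stream, up to
    ``max_restarts`` times. Code 1 is the derived allele at every marker.
    """
    root = np.random.SeedSequence(spec.seed)
    for attempt, child_seq in enumerate(root.spawn(spec.max_restarts + 1)):
        rng = np.random.default_rng(child_seq)
        hs = _run_sweep_once(spec, rng)
        if hs is not None:
            return hs
    raise RuntimeError(
        f"derived allele lost in all {spec.max_restarts + 1} attempts; "
        "increase init_freq or selection"
    )


def _run_sweep_once(spec: SweepSpec, rng: np.random.Generator) -> HaplotypeSet | None:
    n, m = spec.pop_size, spec.n_markers
    lo, hi = spec.background_freq_range
    freqs = rng.uniform(lo, hi, size=m)
    pop = (rng.random((n, m)) < freqs).astype(np.uint8)
    focal = spec.focal_index
    # focal derived copies start on a single founder haplotype background
    n_init = max(1, round(spec.init_freq * n))
    founder = pop[rng.integers(n)].copy()
    founder[focal] = 1
    pop[:, focal] = 0
    pop[:n_init] = founder
    for _ in range(spec.max_generations):
        f = pop[:, focal].mean()
        if f == 0:
            return None
        if f >= spec.stop_freq:
            break
        fitness = 1.0 + spec.s * pop[:, focal]
        pop = _wf_generation(pop, fitness, spec.recomb, rng)
    else:
        if spec.s > 0:
            return None  # never reached the stop frequency
    sample_idx = rng.choice(n, size=spec.n_sample, replace=False)
    positions = (np.arange(m) + 1) * spec.marker_spacing
    snps = [
        SnpRecord(f"m{j:04d}", "1", int(positions[j]), "A", "G", ancestral="A")
        for j in range(m)
    ]
    return HaplotypeSet(
        haps=pop[sample_idx],
        positions=positions,
        chrom="1",
        snps=snps,
        derived_is_one=True,
    )
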