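"""Long-range haplotype test: core haplotypes, EHH decay, REHH, gamma null
within core-frequency bins, derived-allele filter, and FDR control.

Distances are physical (base pairs); the EHH of a core haplotype at a marker
is the probability that two random carriers are identical at every SNP from
the core edge out to that marker. The REHH denominator pools all non-target
carriers into a single group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genodata import SnpRecord

DERIVED_FREQ_CUTOFF = 0.60
EHH_FLOOR = 0.05


@dataclass
class HaplotypeSet:
    """Phased binary chromosomes: 1 = derived (or allele_b) at each site."""

    haps: np.ndarray  # uint8, shape (n_haps, n_snps)
    positions: np.ndarray  # 1-based, strictly increasing
    chrom: str = "1"
    snps: list[SnpRecord] | None = None
    derived_is_one: bool = True  # whether code 1 is the derived allele

    def __post_init__(self) -> None:
        self.haps = np.asarray(self.haps, dtype=np.uint8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.haps.ndim != 2 or self.haps.shape[1] != self.positions.size:
            raise ValueError("haps shape inconsistent with positions")
        if not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        if not np.isin(self.haps, (0, 1)).all():
            raise ValueError("haplotypes must be binary")

    @property
    def n_haps(self) -> int:
        return self.haps.shape[0]

    @property
    def n_snps(self) -> int:
        return self.haps.shape[1]

    def derived_freq(self) -> np.ndarray:
        f1 = self.haps.mean(axis=0)
        return f1 if self.derived_is_one else 1.0 - f1


@dataclass(frozen=True)
class CoreSpec:
    """Core SNPs (by index) over which core haplotypes are defined."""

    chrom: str
    snp_indices: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.snp_indices) < 1:
            raise ValueError("need at least one core SNP")


@dataclass
class CoreHaplotypeResult:
    pattern: str  # allele string over the core SNPs
    frequency: float
    carriers: np.ndarray  # haplotype row indices
    core: CoreSpec
    ehh_left: list[tuple[int, float]] = field(default_factory=list)
    ehh_right: list[tuple[int, float]] = field(default_factory=list)
    rehh: float = float("nan")
    rehh_distance: int = 0
    derived_freq_on_core: float = float("nan")
    derived_flag: bool = False
    derived_flag_reason: str = ""
    p_gamma: float = float("nan")
    q_bh: float = float("nan")
    significant: bool = False

    @property
    def n_carriers(self) -> int:
        return len(self.carriers)


def core_haplotypes(
    hs: HaplotypeSet, core: CoreSpec, min_carriers: int = 3
) -> list[CoreHaplotypeResult]:
    """Distinct allele strings over the core SNPs, with carrier sets.

    Patterns with fewer than ``min_carriers`` carriers are dropped, so the
    reported frequencies (over all haplotypes) may sum to less than 1.
    """
    idx = list(core.snp_indices)
    sub = hs.haps[:, idx]
    patterns, inverse = np.unique(sub, axis=0, return_inverse=True)
    out = []
    for k, pat in enumerate(patterns):
        carriers = np.flatnonzero(inverse == k)
        if carriers.size < min_carriers:
            continue
        out.append(
            CoreHaplotypeResult(
                pattern="".join(str(int(a)) for a in pat),
                frequency=carriers.size / hs.n_haps,
                carriers=carriers,
                core=core,
            )
        )
    if not out:
        warnings.warn("all core haplotype patterns below min_carriers", stacklevel=2)
    out.sort(key=lambda r: -r.frequency)
    return out


def _homozygosity(groups: np.ndarray) -> float:
    # sum n_h (n_h - 1) / (n (n - 1)) over distinct extended haplotypes
    _, counts = np.unique(groups, return_counts=True)
    n = counts.sum()
    if n < 2:
        return float("nan")
    return float((counts * (counts - 1)).sum() / (n * (n - 1)))


def ehh_curve(
    hs: HaplotypeSet,
    carriers: np.ndarray,
    core_indices: tuple[int, ...],
    direction: str,
    stop_ehh: float = EHH_FLOOR,
) -> list[tuple[int, float]]:
    """EHH at each marker moving outward from the core in one direction.

    EHH at marker x is the fraction of carrier pairs identical at all SNPs
    between the core edge and x inclusive; computation stops once EHH drops
    below ``stop_ehh`` (the first sub-floor marker is included) or the
    chromosome ends.
    """
    if carriers.size < 2:
        return []
    lo, hi = min(core_indices), max(core_indices)
    if direction == "right":
        scan = range(hi + 1, hs.n_snps)
    elif direction == "left":
        scan = range(lo - 1, -1, -1)
    else:
        raise ValueError("direction must be 'left' or 'right'")
    sub = hs.haps[carriers]
    # group ids for "identical so far"; refined marker by marker
    groups = np.zeros(carriers.size, dtype=np.int64)
    curve: list[tuple[int, float]] = []
    for j in scan:
        groups = groups * 2 + sub[:, j]
        _, groups = np.unique(groups, return_inverse=True)  # re-canonicalize
        e = _homozygosity(groups)
        curve.append((int(hs.positions[j]), e))
        if e < stop_ehh:
            break
    return curve


def ehh_at(
    hs: HaplotypeSet,
    carriers: np.ndarray,
    core_indices: tuple[int, ...],
    marker_index: int,
) -> float:
    """EHH of a carrier group at an arbitrary marker index (either side)."""
    if carriers.size < 2:
        return float("nan")
    lo, hi = min(core_indices), max(core_indices)
    if marker_index > hi:
        cols = slice(hi + 1, marker_index + 1)
    elif marker_index < lo:
        cols = slice(marker_index, lo)
    else:
        return 1.0
    sub = hs.haps[np.asarray(carriers)][:, cols]
    _, groups = np.unique(sub, axis=0, return_inverse=True)
    return _homozygosity(groups)


def rehh_at(
    hs: HaplotypeSet,
    cores: list[CoreHaplotypeResult],
    target: int,
    marker_index: int | None = None,
    ehh_floor: float = EHH_FLOOR,
) -> tuple[float, int]:
    """REHH of ``cores[target]`` against the pooled other-core carriers.

    When ``marker_index`` is None the test distance is the farthest marker
    (searching outward on both sides) at which the pooled EHH is still
    >= ``ehh_floor``. Returns (rehh, marker_index); (nan, -1) when undefined.
    """
    tgt = cores[target]
    others = np.concatenate(
        [c.carriers for i, c in enumerate(cores) if i != target]
    ) if len(cores) > 1 else np.empty(0, dtype=np.int64)
    if others.size < 2 or tgt.carriers.size < 2:
        return float("nan"), -1
    core_idx = tgt.core.snp_indices
    if marker_index is None:
        marker_index = _farthest_marker(hs, others, core_idx, ehh_floor)
        if marker_index < 0:
            return float("nan"), -1
    e_pool = ehh_at(hs, others, core_idx, marker_index)
    if not e_pool or np.isnan(e_pool):
        return float("nan"), -1
    e_tgt = ehh_at(hs, tgt.carriers, core_idx, marker_index)
    return float(e_tgt / e_pool), marker_index


def _farthest_marker(
    hs: HaplotypeSet,
    carriers: np.ndarray,
    core_indices: tuple[int, ...],
    ehh_floor: float,
) -> int:
    lo, hi = min(core_indices), max(core_indices)
    core_pos = (hs.positions[lo] + hs.positions[hi]) / 2
    best, best_dist = -1, -1.0
    for direction, scan in (
        ("right", range(hi + 1, hs.n_snps)),
        ("left", range(lo - 1, -1, -1)),
    ):
        last = -1
        for j in scan:
            if ehh_at(hs, carriers, core_indices, j) >= ehh_floor:
                last = j
            else:
                break
        if last >= 0:
            dist = abs(hs.positions[last] - core_pos)
            if dist > best_dist:
                best, best_dist = last, dist
    return best


@dataclass(frozen=True)
class GammaFit:
    shape: float
    scale: float
    n_obs: int
    loglik: float

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.scale <= 0:
            raise ValueError("gamma parameters must be strictly positive")


def gamma_fit(values: np.ndarray, min_obs: int = 20) -> GammaFit:
    """Maximum-likelihood gamma fit (location fixed at 0) to positive values."""
    vals = np.asarray(values, dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size < min_obs:
        raise ValueError(f"need at least {min_obs} observations, got {vals.size}")
    if np.ptp(vals) == 0:
        raise ValueError("degenerate sample: all values equal")
    if (vals <= 0).any():
        raise ValueError("gamma fit requires strictly positive values")
    shape, _, scale = stats.gamma.fit(vals, floc=0)
    ll = float(stats.gamma.logpdf(vals, shape, scale=scale).sum())
    return GammaFit(shape=float(shape), scale=float(scale), n_obs=vals.size, loglik=ll)


def gamma_upper_p(x: float, fit: GammaFit) -> float:
    """Upper-tail probability of x under a fitted gamma null."""
    return float(stats.gamma.sf(x, fit.shape, scale=fit.scale))


def derived_filter(
    result: CoreHaplotypeResult,
    hs: HaplotypeSet,
    cutoff: float = DERIVED_FREQ_CUTOFF,
) -> CoreHaplotypeResult:
    """Flag cores whose derived core alleles sit above the frequency cutoff.

    The derived frequency of a core pattern is the population frequency of
    the derived allele at the core SNPs where the pattern carries the derived
    state (minimum over such SNPs; strict > cutoff). Patterns carrying no
    derived allele at any core SNP, or sets without ancestral polarization,
    are flagged False with a reason.
    """
    if hs.snps is not None and any(s.ancestral is None for s in hs.snps):
        result.derived_flag = False
        result.derived_flag_reason = "ancestral state unknown"
        return result
    freqs = hs.derived_freq()
    derived_code = 1 if hs.derived_is_one else 0
    carried = [
        freqs[j]
        for j, allele in zip(result.core.snp_indices, result.pattern)
        if int(allele) == derived_code
    ]
    if not carried:
        result.derived_flag = False
        result.derived_flag_reason = "core pattern carries no derived allele"
        return result
    result.derived_freq_on_core = float(min(carried))
    result.derived_flag = result.derived_freq_on_core > cutoff
    if not result.derived_flag:
        result.derived_flag_reason = f"derived frequency <= {cutoff}"
    return result


def bh_fdr(pvals: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: adjusted values and significance flags."""
    p = np.asarray(pvals, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        adj[i] = prev
    return adj, adj <= q


def wglrh_scan(
    hs: HaplotypeSet,
    cores: list[CoreSpec],
    min_carriers: int = 3,
    n_bins: int = 10,
    min_obs: int = 20,
    q: float = 0.05,
    derived_cutoff: float = DERIVED_FREQ_CUTOFF,
    ehh_floor: float = EHH_FLOOR,
    require_derived: bool = True,
) -> pd.DataFrame:
    """Full long-range haplotype scan over a list of core specifications.

    REHH values are binned by core frequency into up to ``n_bins``
    equal-count bins; a gamma null is fitted per bin and each core's REHH is
    tested against its bin's fit, followed by BH FDR control. Cores are
    called significant when q <= ``q`` and (optionally) the derived-allele
    filter passes.
    """
    results: list[CoreHaplotypeResult] = []
    for spec in cores:
        chr_results = core_haplotypes(hs, spec, min_carriers=min_carriers)
        for i, r in enumerate(chr_results):
            r.rehh, r.rehh_distance = rehh_at(hs, chr_results, i, ehh_floor=ehh_floor)
            derived_filter(r, hs, cutoff=derived_cutoff)
        results.extend(chr_results)

    scored = [r for r in results if not np.isnan(r.rehh)]
    if scored:
        freqs = np.array([r.frequency for r in scored])
        rehhs = np.array([r.rehh for r in scored])
        n_bins_eff = max(1, min(n_bins, len(scored) // max(min_obs, 1)))
        # equal-count frequency bins
        ranks = stats.rankdata(freqs, method="ordinal") - 1
        bins = (ranks * n_bins_eff // len(scored)).astype(int)
        for b in np.unique(bins):
            sel = bins == b
            vals = rehhs[sel]
            try:
                fit = gamma_fit(vals, min_obs=min(min_obs, max(2, vals.size)))
            except ValueError:
                continue
            for r, v in zip(np.array(scored, dtype=object)[sel], vals):
                r.p_gamma = gamma_upper_p(v, fit)
        tested = [r for r in scored if not np.isnan(r.p_gamma)]
        if tested:
            adj, flags = bh_fdr(np.array([r.p_gamma for r in tested]), q=q)
            for r, a, f in zip(tested, adj, flags):
                r.q_bh = float(a)
                r.significant = bool(f and (r.derived_flag or not require_derived))

    return pd.DataFrame(
        {
            "chrom": [r.core.chrom for r in results],
            "core_snps": [",".join(map(str, r.core.snp_indices)) for r in results],
            "pattern": [r.pattern for r in results],
            "frequency": [r.frequency for r in results],
            "n_carriers": [r.n_carriers for r in results],
            "rehh": [r.rehh for r in results],
            "derived_freq": [r.derived_freq_on_core for r in results],
            "derived_flag": [r.derived_flag for r in results],
            "p_gamma": [r.p_gamma for r in results],
            "q_bh": [r.q_bh for r in results],
            "significant": [r.significant for r in results],
        }
    )
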