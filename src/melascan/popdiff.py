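"""Per-SNP differentiation (FST, locus-specific branch lengths) and windowed
diversity statistics (S, pi, Tajima's D, lnRH) with genome-wide empirical
p-values and region summaries.

Window coordinates are 0-based half-open and anchored at multiples of the step
from coordinate 0. Statistics computed from array SNPs carry ascertainment
bias; they are computed as defined and calibrated against the empirical
genome-wide distribution rather than corrected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .genodata import PopAlleleCounts, RegionSet

DEFAULT_WINDOW_SIZE = 100_000
DEFAULT_WINDOW_STEP = 25_000


# ---------------------------------------------------------------------------
# per-SNP differentiation


def hudson_fst(p1: float, n1: int, p2: float, n2: int) -> float:
    """Hudson's FST estimator for one SNP from two population frequencies.

    ``n1``/``n2`` are typed chromosome counts. Estimates below 0 are
    returned as-is; NaN when a population has fewer than 2 chromosomes or the
    SNP is monomorphic across both populations.
    """
    if n1 <= 1 or n2 <= 1:
        return float("nan")
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    if den == 0:
        return float("nan")
    return num / den


def wc84_fst(p1: float, n1: int, p2: float, n2: int) -> float:
    """Weir & Cockerham (1984) theta for one SNP from haploid allele counts."""
    if n1 <= 1 or n2 <= 1:
        return float("nan")
    r = 2.0
    n_bar = (n1 + n2) / r
    n_c = (n1 + n2 - (n1**2 + n2**2) / (n1 + n2)) / (r - 1)
    p_bar = (n1 * p1 + n2 * p2) / (n1 + n2)
    s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
    a = (n_bar / n_c) * (
        s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2) / (n_bar - 1)
    )
    b = (n_bar / (n_bar - 1)) * (p_bar * (1 - p_bar) - (r - 1) / r * s2)
    if a + b == 0:
        return float("nan")
    return a / (a + b)


_ESTIMATORS = {"hudson": hudson_fst, "wc84": wc84_fst}


def pairwise_fst(
    pac: PopAlleleCounts,
    pop1: str,
    pop2: str,
    estimator: Literal["hudson", "wc84"] = "hudson",
) -> np.ndarray:
    """Per-SNP FST between two populations of an allele-count panel."""
    try:
        f = _ESTIMATORS[estimator]
    except KeyError:
        raise ValueError(f"unknown estimator {estimator!r}") from None
    i1, i2 = pac.pops.index(pop1), pac.pops.index(pop2)
    p1 = pac.count_b[i1] / pac.n_chrom[i1]
    p2 = pac.count_b[i2] / pac.n_chrom[i2]
    return np.array(
        [
            f(p1[j], int(pac.n_chrom[i1, j]), p2[j], int(pac.n_chrom[i2, j]))
            for j in range(len(pac.snps))
        ]
    )


def hudson_fst_overall(pac: PopAlleleCounts, pop1: str, pop2: str) -> float:
    """Multi-SNP Hudson FST combined as a ratio of averages.

    Summing numerator and denominator over SNPs before dividing avoids the
    downward bias of averaging per-SNP ratios and is the standard way to
    report a panel-wide Hudson estimate.
    """
    i1, i2 = pac.pops.index(pop1), pac.pops.index(pop2)
    p1 = pac.count_b[i1] / pac.n_chrom[i1]
    p2 = pac.count_b[i2] / pac.n_chrom[i2]
    n1, n2 = pac.n_chrom[i1], pac.n_chrom[i2]
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return float(num.sum() / den.sum())


def lsbl(d_ab: float, d_ac: float, d_bc: float) -> tuple[float, float, float]:
    """Locus-specific branch lengths from three pairwise distances.

    Inputs are clamped to [0, 1]; negative branch lengths are reported as
    computed. NaN inputs give NaN branches.
    """
    if any(np.isnan(x) for x in (d_ab, d_ac, d_bc)):
        return (float("nan"),) * 3
    d_ab, d_ac, d_bc = (min(max(d, 0.0), 1.0) for d in (d_ab, d_ac, d_bc))
    return (
        (d_ab + d_ac - d_bc) / 2,
        (d_ab + d_bc - d_ac) / 2,
        (d_ac + d_bc - d_ab) / 2,
    )


def lsbl_table(
    pac: PopAlleleCounts,
    pops: Sequence[str] | None = None,
    estimator: Literal["hudson", "wc84"] = "hudson",
) -> pd.DataFrame:
    """Per-SNP pairwise FST and branch lengths for a three-population panel."""
    a, b, c = pops if pops is not None else pac.pops[:3]
    d_ab = pairwise_fst(pac, a, b, estimator)
    d_ac = pairwise_fst(pac, a, c, estimator)
    d_bc = pairwise_fst(pac, b, c, estimator)
    branches = np.array([lsbl(*t) for t in zip(d_ab, d_ac, d_bc)])
    return pd.DataFrame(
        {
            "snp_id": [s.snp_id for s in pac.snps],
            "chrom": [s.chrom for s in pac.snps],
            "pos": pac.positions,
            f"fst_{a}_{b}": d_ab,
            f"fst_{a}_{c}": d_ac,
            f"fst_{b}_{c}": d_bc,
            f"lsbl_{a}": branches[:, 0],
            f"lsbl_{b}": branches[:, 1],
            f"lsbl_{c}": branches[:, 2],
        }
    )


# ---------------------------------------------------------------------------
# windows


def sliding_windows(
    span_start: int,
    span_end: int,
    size: int = DEFAULT_WINDOW_SIZE,
    step: int = DEFAULT_WINDOW_STEP,
) -> list[tuple[int, int]]:
    """Overlapping windows [k*step, k*step + size) covering the span.

    Anchored at multiples of ``step`` from coordinate 0; every interior
    position falls in exactly size/step windows. The last window is the
    rightmost that still fits inside the span, so a span shorter than
    ``size`` yields a single window starting at the grid point at or below
    the span start.
    """
    if size <= 0 or step <= 0:
        raise ValueError("size and step must be positive")
    if span_end <= span_start:
        return []
    first = max(0, (span_start - size) // step + 1)
    last = max(first, (span_end - size) // step)
    return [(k * step, k * step + size) for k in range(first, last + 1)]


@dataclass
class DiversityWindow:
    """Windowed diversity summary for one population."""

    chrom: str
    start: int
    end: int
    n_snps: int
    S: int
    pi: float
    H_mean: float
    n_chrom: int
    tajima_d: float = float("nan")
    lnrh: float = float("nan")

    @property
    def theta_hat(self) -> float:
        """lnRH diversity estimator [1/(1-H_mean)]^2 - 1."""
        if self.H_mean >= 1.0:
            return float("nan")
        return (1.0 / (1.0 - self.H_mean)) ** 2 - 1.0


def window_diversity(
    pac: PopAlleleCounts,
    pop: str,
    window: tuple[int, int],
    chrom: str | None = None,
    min_snps: int = 10,
) -> DiversityWindow | None:
    """Diversity statistics (S, pi, H_mean) for one window; None below min_snps.

    Per-SNP unbiased expected heterozygosity h = 2n/(2n-1) * 2 p (1-p);
    pi sums h over SNPs; S counts polymorphic SNPs.
    """
    i = pac.pops.index(pop)
    pos = pac.positions
    mask = (pos - 1 >= window[0]) & (pos - 1 < window[1])  # pos is 1-based
    if chrom is not None:
        mask &= np.array([s.chrom == chrom for s in pac.snps])
    idx = np.flatnonzero(mask)
    if idx.size < min_snps:
        return None
    nch = pac.n_chrom[i, idx]
    p = pac.count_b[i, idx] / nch
    h = (nch / (nch - 1)) * 2 * p * (1 - p)
    seg = (p > 0) & (p < 1)
    used_chrom = chrom if chrom is not None else pac.snps[idx[0]].chrom
    return DiversityWindow(
        chrom=used_chrom,
        start=window[0],
        end=window[1],
        n_snps=int(idx.size),
        S=int(seg.sum()),
        pi=float(h.sum()),
        H_mean=float(h.mean()),
        n_chrom=int(nch.min()),
    )


def tajima_constants(n_chrom: int) -> dict[str, float]:
    """The a1..e2 constants of Tajima's D for a sample of n_chrom chromosomes."""
    if n_chrom < 2:
        raise ValueError("need at least 2 chromosomes")
    i = np.arange(1, n_chrom)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n_chrom + 1) / (3.0 * (n_chrom - 1))
    b2 = 2.0 * (n_chrom**2 + n_chrom + 3) / (9.0 * n_chrom * (n_chrom - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n_chrom + 2) / (a1 * n_chrom) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return dict(a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


def tajimas_d(S: int, pi: float, n_chrom: int) -> float:
    """Tajima's D from segregating sites, pairwise diversity, and sample size."""
    if n_chrom < 4:
        raise ValueError("need at least 4 chromosomes")
    if S < 1:
        return float("nan")
    k = tajima_constants(n_chrom)
    var = k["e1"] * S + k["e2"] * S * (S - 1)
    if var <= 0:
        return float("nan")
    return (pi - S / k["a1"]) / np.sqrt(var)


def lnrh(h1: float, h2: float, h_floor: float = 0.001) -> float:
    """Log ratio of heterozygosity-based diversity estimators for two populations.

    theta_k = [1/(1-H_k)]^2 - 1; lnRH = ln(theta_1/theta_2). Any constant
    factor applied to both estimators cancels. NaN when either H is below
    ``h_floor`` or at/above 1.
    """
    if h1 < h_floor or h2 < h_floor or h1 >= 1.0 or h2 >= 1.0:
        return float("nan")
    t1 = (1.0 / (1.0 - h1)) ** 2 - 1.0
    t2 = (1.0 / (1.0 - h2)) ** 2 - 1.0
    return float(np.log(t1 / t2))


def diversity_scan(
    pac: PopAlleleCounts,
    pop: str,
    ref_pop: str | None = None,
    size: int = DEFAULT_WINDOW_SIZE,
    step: int = DEFAULT_WINDOW_STEP,
    min_snps: int = 10,
) -> pd.DataFrame:
    """Sliding-window S/pi/H_mean/Tajima's D (and lnRH vs ``ref_pop``) scan.

    One row per window per chromosome; windows below ``min_snps`` are dropped.
    """
    i_pop = pac.pops.index(pop)
    i_ref = pac.pops.index(ref_pop) if ref_pop is not None else None
    rows = []
    chroms = list(dict.fromkeys(s.chrom for s in pac.snps))
    pos0 = pac.positions - 1  # 0-based
    chrom_arr = np.array([s.chrom for s in pac.snps])

    def _win_stats(i: int, lo: int, hi: int):
        nch = pac.n_chrom[i, lo:hi]
        p = pac.count_b[i, lo:hi] / nch
        h = (nch / (nch - 1)) * 2 * p * (1 - p)
        S = int(((p > 0) & (p < 1)).sum())
        return S, float(h.sum()), float(h.mean()), int(nch.min())

    for chrom in chroms:
        sel = np.flatnonzero(chrom_arr == chrom)
        cpos = pos0[sel]  # sorted within chromosome
        for start, end in sliding_windows(
            int(cpos.min()), int(cpos.max() + 1), size, step
        ):
            lo = sel[0] + int(np.searchsorted(cpos, start, side="left"))
            hi = sel[0] + int(np.searchsorted(cpos, end, side="left"))
            if hi - lo < min_snps:
                continue
            S, pi, h_mean, nch = _win_stats(i_pop, lo, hi)
            d = tajimas_d(S, pi, nch) if (S >= 1 and nch >= 4) else float("nan")
            ln = float("nan")
            if i_ref is not None:
                _, _, h_ref, _ = _win_stats(i_ref, lo, hi)
                ln = lnrh(h_mean, h_ref)
            rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "n_snps": hi - lo,
                    "S": S,
                    "pi": pi,
                    "H_mean": h_mean,
                    "tajima_d": d,
                    "lnrh": ln,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# empirical significance


@dataclass
class EmpiricalDistribution:
    """Sorted genome-wide values of a statistic with a declared tail."""

    name: str
    values: np.ndarray
    tail: Literal["upper", "lower"] = "upper"

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            raise ValueError("empirical distribution must be non-empty")
        self.values = np.sort(vals)

    def empirical_p(self, x: float) -> float:
        """Literal tail proportion: (# values beyond x) / N, strict inequality."""
        n = self.values.size
        if self.tail == "upper":
            return float(n - np.searchsorted(self.values, x, side="right")) / n
        return float(np.searchsorted(self.values, x, side="left")) / n


def empirical_p(x: float, dist: EmpiricalDistribution) -> float:
    return dist.empirical_p(x)


def region_significance_counts(
    table: pd.DataFrame,
    regions: RegionSet,
    value_col: str = "empirical_p",
    thresholds: Sequence[float] = (0.001, 0.01, 0.05),
    mode: Literal["exclusive", "cumulative"] = "exclusive",
) -> pd.DataFrame:
    """Per-region counts of markers/windows below the significance tiers.

    ``table`` needs columns chrom plus either pos (1-based, per-SNP) or
    start/end (window) and ``value_col``. Exclusive mode bins p into
    [0, t1), [t1, t2), [t2, t3); cumulative mode counts p < t for each t.
    """
    t1, t2, t3 = sorted(thresholds)
    rows = []
    has_pos = "pos" in table.columns
    for r in regions:
        if has_pos:
            mask = (table["chrom"] == r.chrom) & (table["pos"] - 1 >= r.start) & (
                table["pos"] - 1 < r.end
            )
        else:
            # windows: count those overlapping the region
            mask = (
                (table["chrom"] == r.chrom)
                & (table["start"] < r.end)
                & (table["end"] > r.start)
            )
        p = table.loc[mask, value_col].dropna().to_numpy()
        if mode == "exclusive":
            counts = (
                int((p < t1).sum()),
                int(((p >= t1) & (p < t2)).sum()),
                int(((p >= t2) & (p < t3)).sum()),
            )
        else:
            counts = (int((p < t1).sum()), int((p < t2).sum()), int((p < t3).sum()))
        rows.append(
            {
                "region": r.name,
                "n_markers": int(mask.sum()),
                f"n_p_lt_{t1}": counts[0],
                f"n_p_lt_{t2}": counts[1],
                f"n_p_lt_{t3}": counts[2],
            }
        )
    return pd.DataFrame(rows)


def attach_empirical_p(
    table: pd.DataFrame,
    value_col: str,
    tail: Literal["upper", "lower"] = "upper",
    out_col: str = "empirical_p",
) -> pd.DataFrame:
    """Add rank-based empirical p-values for ``value_col`` against its own
    genome-wide distribution."""
    dist = EmpiricalDistribution(value_col, table[value_col].to_numpy(), tail)
    out = table.copy()
    out[out_col] = [
        dist.empirical_p(x) if not np.isnan(x) else np.nan
        for x in table[value_col].to_numpy()
    ]
    return out
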