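"""Hardy-Weinberg exact testing and two-locus EM linkage-disequilibrium analysis."""

from __future__ import annotations

from dataclasses import dataclass
from math import lgamma, log
from typing import NamedTuple

import numpy as np
import pandas as pd

from .genodata import MISSING, GenotypeMatrix


class GenotypeCounts(NamedTuple):
    """Observed genotype counts: homozygote A, heterozygote, homozygote B."""

    n_aa: int
    n_ab: int
    n_bb: int

    @property
    def n(self) -> int:
        return self.n_aa + self.n_ab + self.n_bb

    @classmethod
    def from_calls(cls, calls: np.ndarray) -> "GenotypeCounts":
        """Counts from a vector of allele_b copy numbers (missing dropped)."""
        typed = calls[calls != MISSING]
        return cls(
            n_aa=int((typed == 0).sum()),
            n_ab=int((typed == 1).sum()),
            n_bb=int((typed == 2).sum()),
        )


def allele_freq(gc: GenotypeCounts) -> float:
    """Sample frequency of allele A: (2*n_aa + n_ab) / 2n."""
    if gc.n == 0:
        raise ValueError("allele_freq undefined for empty sample")
    return (2 * gc.n_aa + gc.n_ab) / (2 * gc.n)


def hwe_expected(gc: GenotypeCounts) -> tuple[float, float, float]:
    """Expected genotype counts (n p^2, 2npq, n q^2) under Hardy-Weinberg."""
    if gc.n == 0:
        raise ValueError("hwe_expected undefined for empty sample")
    p = allele_freq(gc)
    q = 1.0 - p
    n = gc.n
    return (n * p * p, 2 * n * p * q, n * q * q)


def _log_het_prob(n: int, n_a: int, n_ab: int) -> float:
    # log P(n_ab heterozygotes | n individuals, n_a copies of A), conditional
    # on the allele counts; standard exact-HWE conditional distribution.
    n_aa = (n_a - n_ab) // 2
    n_bb = (2 * n - n_a - n_ab) // 2
    return (
        lgamma(n + 1)
        - lgamma(n_aa + 1)
        - lgamma(n_ab + 1)
        - lgamma(n_bb + 1)
        + n_ab * log(2.0)
        + lgamma(n_a + 1)
        + lgamma(2 * n - n_a + 1)
        - lgamma(2 * n + 1)
    )


def hwe_exact_test(gc: GenotypeCounts) -> float:
    """Two-sided exact Hardy-Weinberg p-value.

    Enumerates every heterozygote count compatible with the observed allele
    counts (same parity) and sums the conditional probabilities of all
    outcomes no more probable than the observed one.
    """
    if gc.n == 0:
        raise ValueError("hwe_exact_test undefined for empty sample")
    n = gc.n
    n_a = 2 * gc.n_aa + gc.n_ab
    n_b = 2 * n - n_a
    if n_a == 0 or n_b == 0:
        return 1.0
    rare = min(n_a, n_b)
    hets = np.arange(rare % 2, rare + 1, 2)
    logps = np.array([_log_het_prob(n, n_a, int(h)) for h in hets])
    probs = np.exp(logps - logps.max())
    probs /= probs.sum()
    p_obs = probs[np.searchsorted(hets, gc.n_ab)]
    # small relative slack guards against float noise in the <= comparison
    p = float(probs[probs <= p_obs * (1.0 + 1e-12)].sum())
    return min(p, 1.0)


@dataclass(frozen=True)
class HapFreqs:
    """Two-locus haplotype frequencies (A/a at locus 1, B/b at locus 2)."""

    f_AB: float
    f_Ab: float
    f_aB: float
    f_ab: float
    loglik: float
    n_iter: int

    def __post_init__(self) -> None:
        freqs = (self.f_AB, self.f_Ab, self.f_aB, self.f_ab)
        if any(f < -1e-12 for f in freqs):
            raise ValueError("haplotype frequencies must be non-negative")
        if abs(sum(freqs) - 1.0) > 1e-9:
            raise ValueError("haplotype frequencies must sum to 1")

    @property
    def p_A(self) -> float:
        return self.f_AB + self.f_Ab

    @property
    def p_B(self) -> float:
        return self.f_AB + self.f_aB


def _hap_loglik(counts: np.ndarray, f: np.ndarray) -> float:
    # counts: 3x3 genotype table (copies of a at locus1, copies of b at locus2)
    # f: [f_AB, f_Ab, f_aB, f_ab]
    f_AB, f_Ab, f_aB, f_ab = f
    ll = 0.0
    # P(genotype) as product of two haplotype draws; double het has two phases
    probs = {
        (0, 0): f_AB**2,
        (0, 1): 2 * f_AB * f_Ab,
        (0, 2): f_Ab**2,
        (1, 0): 2 * f_AB * f_aB,
        (1, 1): 2 * f_AB * f_ab + 2 * f_Ab * f_aB,
        (1, 2): 2 * f_Ab * f_ab,
        (2, 0): f_aB**2,
        (2, 1): 2 * f_aB * f_ab,
        (2, 2): f_ab**2,
    }
    for (i, j), pr in probs.items():
        c = counts[i, j]
        if c > 0:
            if pr <= 0:
                return -np.inf
            ll += c * np.log(pr)
    return ll


def em_hap_freqs(
    g1: np.ndarray,
    g2: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> HapFreqs:
    """EM estimate of two-locus haplotype frequencies from unphased genotypes.

    ``g1``/``g2`` are vectors of allele copy numbers (0/1/2, ``MISSING``
    allowed) at the two loci; individuals missing at either locus are
    excluded. Alleles are labelled so that A/B denote 0-copies alleles
    (i.e. g counts copies of the lowercase allele).

    The EM starts at linkage equilibrium and iterates resolution of the
    double heterozygotes until the log-likelihood change drops below ``tol``.
    """
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    keep = (g1 != MISSING) & (g2 != MISSING)
    g1, g2 = g1[keep], g2[keep]
    n = g1.size
    if n == 0:
        raise ValueError("no individuals typed at both loci")
    counts = np.zeros((3, 3), dtype=np.int64)
    np.add.at(counts, (g1, g2), 1)

    p_a = (2 * counts[2].sum() + counts[1].sum()) / (2 * n)  # freq of allele a
    p_b = (2 * counts[:, 2].sum() + counts[:, 1].sum()) / (2 * n)
    # start at linkage equilibrium (deterministic)
    f = np.array(
        [
            (1 - p_a) * (1 - p_b),
            (1 - p_a) * p_b,
            p_a * (1 - p_b),
            p_a * p_b,
        ]
    )
    n_dh = counts[1, 1]  # double heterozygotes: the only ambiguous class
    # unambiguous haplotype counts contributed by the other 8 cells
    base = np.array(
        [
            2 * counts[0, 0] + counts[0, 1] + counts[1, 0],  # AB
            2 * counts[0, 2] + counts[0, 1] + counts[1, 2],  # Ab
            2 * counts[2, 0] + counts[1, 0] + counts[2, 1],  # aB
            2 * counts[2, 2] + counts[2, 1] + counts[1, 2],  # ab
        ],
        dtype=float,
    )
    ll = _hap_loglik(counts, f)
    it = 0
    for it in range(1, max_iter + 1):
        # E: split double hets between cis (AB/ab) and trans (Ab/aB)
        cis = f[0] * f[3]
        trans = f[1] * f[2]
        denom = cis + trans
        w_cis = 0.5 if denom == 0 else cis / denom
        hap = base.copy()
        hap[0] += n_dh * w_cis
        hap[3] += n_dh * w_cis
        hap[1] += n_dh * (1 - w_cis)
        hap[2] += n_dh * (1 - w_cis)
        # M
        f = hap / (2 * n)
        new_ll = _hap_loglik(counts, f)
        if new_ll - ll < tol and it > 1:
            ll = new_ll
            break
        ll = new_ll
    return HapFreqs(
        f_AB=float(f[0]),
        f_Ab=float(f[1]),
        f_aB=float(f[2]),
        f_ab=float(f[3]),
        loglik=float(ll),
        n_iter=it,
    )


def ld_r2(hf: HapFreqs) -> float:
    """Squared correlation r^2 between two loci from haplotype frequencies.

    Returns NaN when either marginal is monomorphic.
    """
    p_A, p_B = hf.p_A, hf.p_B
    if not (0.0 < p_A < 1.0) or not (0.0 < p_B < 1.0):
        return float("nan")
    d = hf.f_AB - p_A * p_B
    return d * d / (p_A * (1 - p_A) * p_B * (1 - p_B))


def pairwise_r2(gm: GenotypeMatrix, snp_ids: list[str] | None = None) -> pd.DataFrame:
    """Symmetric matrix of EM-based r^2 values over the named SNPs."""
    ids = snp_ids if snp_ids is not None else [s.snp_id for s in gm.snps]
    m = len(ids)
    out = np.full((m, m), np.nan)
    np.fill_diagonal(out, 1.0)
    cols = {sid: gm.column(sid) for sid in ids}
    for i in range(m):
        for j in range(i + 1, m):
            hf = em_hap_freqs(cols[ids[i]], cols[ids[j]])
            out[i, j] = out[j, i] = ld_r2(hf)
    return pd.DataFrame(out, index=ids, columns=ids)


def hwe_table(gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-SNP observed/expected genotype counts, allele frequencies, HWE p."""
    rows = []
    for j, snp in enumerate(gm.snps):
        gc = GenotypeCounts.from_calls(gm.calls[:, j])
        if gc.n == 0:
            continue
        e_aa, e_ab, e_bb = hwe_expected(gc)
        p_a = allele_freq(gc)
        rows.append(
            {
                "snp_id": snp.snp_id,
                "allele_a": snp.allele_a,
                "allele_b": snp.allele_b,
                "obs_aa": gc.n_aa,
                "obs_ab": gc.n_ab,
                "obs_bb": gc.n_bb,
                "exp_aa": round(e_aa, 2),
                "exp_ab": round(e_ab, 2),
                "exp_bb": round(e_bb, 2),
                "freq_a": round(p_a, 3),
                "freq_b": round(1 - p_a, 3),
                "hwe_p": round(hwe_exact_test(gc), 3),
            }
        )
    return pd.DataFrame(rows)
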