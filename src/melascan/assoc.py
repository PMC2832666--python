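"""Quantitative-trait association of SNPs with melanin index.

Each SNP is tested marginally by ordinary least squares with sex as a
covariate, under an additive coding (copies of the effect allele) or an
unconstrained coding (separate heterozygote/homozygote indicators against a
reference homozygote). Missing genotypes are dropped per SNP
(complete-case per test).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genodata import MISSING, GenotypeMatrix, PhenotypeTable
from .hwe_ld import GenotypeCounts, allele_freq, hwe_exact_test, hwe_expected


@dataclass
class AssocResult:
    snp_id: str
    model: str  # "additive" | "unconstrained"
    effect_allele: str
    beta: float | None  # additive slope
    se: float | None
    p: float | None
    beta_het: float | None = None
    se_het: float | None = None
    p_het: float | None = None
    beta_hom: float | None = None
    se_hom: float | None = None
    p_hom: float | None = None
    partial_r2: float | None = None
    n_used: int = 0
    reason: str = ""


def _ols(X: np.ndarray, y: np.ndarray):
    """OLS fit returning (beta, se, t-p-values, SSE). X includes intercept."""
    n, k = X.shape
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sse = float(resid @ resid)
    dof = n - k
    if dof <= 0 or rank < k:
        return beta, np.full(k, np.nan), np.full(k, np.nan), sse
    sigma2 = sse / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta / se
    p = 2 * stats.t.sf(np.abs(tstat), dof)
    return beta, se, p, sse


def _design(
    gm: GenotypeMatrix,
    pheno: PhenotypeTable,
    snp_id: str,
    covariates: tuple[str, ...],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Aligned (genotype, phenotype, covariate matrix) with complete cases."""
    j = gm.snp_index(snp_id)
    ph = pheno.data.drop_duplicates("sample_id").set_index("sample_id")
    ph = ph.reindex(gm.samples)
    y = ph["melanin_index"].to_numpy(dtype=float)
    cov = ph[list(covariates)].to_numpy(dtype=float)
    g = gm.calls[:, j].astype(np.int64)
    keep = (g != MISSING) & ~np.isnan(y)
    if cov.size:
        keep &= ~np.isnan(cov).any(axis=1)
    return g[keep], y[keep], cov[keep], j


def additive_regression(
    gm: GenotypeMatrix,
    pheno: PhenotypeTable,
    snp_id: str,
    effect_allele: str | None = None,
    covariates: tuple[str, ...] = ("sex",),
    min_cases: int = 10,
) -> AssocResult:
    """Additive-model OLS of melanin index on effect-allele copy number.

    ``effect_allele`` defaults to allele_b. Partial R^2 for the genotype term
    is (SSE_reduced - SSE_full) / SSE_total.
    """
    g, y, cov, j = _design(gm, pheno, snp_id, covariates)
    snp = gm.snps[j]
    if effect_allele is None:
        effect_allele = snp.allele_b
    if effect_allele not in (snp.allele_a, snp.allele_b):
        raise ValueError(f"{effect_allele!r} is not an allele of {snp_id}")
    res = AssocResult(
        snp_id=snp_id, model="additive", effect_allele=effect_allele,
        beta=None, se=None, p=None, n_used=g.size,
    )
    if g.size < min_cases:
        res.reason = f"fewer than {min_cases} complete cases"
        return res
    if np.ptp(g) == 0:
        res.reason = "monomorphic SNP"
        return res
    code = g if effect_allele == snp.allele_b else 2 - g
    X_full = np.column_stack([np.ones(g.size), code, cov])
    beta, se, p, sse_full = _ols(X_full, y)
    X_red = np.column_stack([np.ones(g.size), cov])
    _, _, _, sse_red = _ols(X_red, y)
    sse_total = float(((y - y.mean()) ** 2).sum())
    res.beta = float(beta[1])
    res.se = float(se[1])
    res.p = float(p[1])
    res.partial_r2 = (sse_red - sse_full) / sse_total if sse_total > 0 else np.nan
    return res


def unconstrained_regression(
    gm: GenotypeMatrix,
    pheno: PhenotypeTable,
    snp_id: str,
    reference_genotype: int = 0,
    covariates: tuple[str, ...] = ("sex",),
    min_class: int = 2,
) -> AssocResult:
    """Model-free OLS with heterozygote and non-reference-homozygote indicators.

    ``reference_genotype`` is the allele_b copy number (0 or 2) of the
    reference homozygote class; betas are contrasts against it.
    """
    if reference_genotype not in (0, 2):
        raise ValueError("reference genotype must be a homozygote (0 or 2)")
    g, y, cov, j = _design(gm, pheno, snp_id, covariates)
    snp = gm.snps[j]
    effect_allele = snp.allele_b if reference_genotype == 0 else snp.allele_a
    res = AssocResult(
        snp_id=snp_id, model="unconstrained", effect_allele=effect_allele,
        beta=None, se=None, p=None, n_used=g.size,
    )
    classes = [int((g == k).sum()) for k in (0, 1, 2)]
    if min(classes) < min_class:
        res.reason = (
            f"genotype class counts {classes} below minimum {min_class}"
        )
        return res
    other_hom = 2 - reference_genotype
    het = (g == 1).astype(float)
    hom = (g == other_hom).astype(float)
    X = np.column_stack([np.ones(g.size), het, hom, cov])
    beta, se, p, sse_full = _ols(X, y)
    X_red = np.column_stack([np.ones(g.size), cov])
    _, _, _, sse_red = _ols(X_red, y)
    sse_total = float(((y - y.mean()) ** 2).sum())
    res.beta_het, res.se_het, res.p_het = float(beta[1]), float(se[1]), float(p[1])
    res.beta_hom, res.se_hom, res.p_hom = float(beta[2]), float(se[2]), float(p[2])
    res.partial_r2 = (sse_red - sse_full) / sse_total if sse_total > 0 else np.nan
    return res


def assoc_table(
    gm: GenotypeMatrix,
    pheno: PhenotypeTable,
    model: str = "additive",
    covariates: tuple[str, ...] = ("sex",),
) -> pd.DataFrame:
    """Per-SNP association results for every SNP in the matrix."""
    rows = []
    for snp in gm.snps:
        if model == "additive":
            r = additive_regression(gm, pheno, snp.snp_id, covariates=covariates)
            rows.append(
                {
                    "snp_id": r.snp_id,
                    "effect_allele": r.effect_allele,
                    "beta": r.beta,
                    "se": r.se,
                    "p": r.p,
                    "partial_r2": r.partial_r2,
                    "n": r.n_used,
                    "note": r.reason,
                }
            )
        else:
            r = unconstrained_regression(gm, pheno, snp.snp_id, covariates=covariates)
            rows.append(
                {
                    "snp_id": r.snp_id,
                    "effect_allele": r.effect_allele,
                    "beta_het": r.beta_het,
                    "p_het": r.p_het,
                    "beta_hom": r.beta_hom,
                    "p_hom": r.p_hom,
                    "partial_r2": r.partial_r2,
                    "n": r.n_used,
                    "note": r.reason,
                }
            )
    return pd.DataFrame(rows)


def effective_tests(r2: pd.DataFrame | np.ndarray, threshold: float = 0.99) -> int:
    """Effective number of independent tests after collapsing high-LD pairs.

    SNP pairs with r^2 >= ``threshold`` are merged transitively (union-find);
    the effective count is the number of resulting clusters.
    """
    m = np.asarray(r2, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("r2 must be a square matrix")
    k = m.shape[0]
    parent = list(range(k))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(k):
        for j in range(i + 1, k):
            if not np.isnan(m[i, j]) and m[i, j] >= threshold:
                parent[find(i)] = find(j)
    return len({find(i) for i in range(k)})


def bonferroni(p: float, m_effective: int) -> float:
    """Bonferroni-corrected p-value: min(1, p * m)."""
    if m_effective < 1:
        raise ValueError("m_effective must be >= 1")
    return min(1.0, p * m_effective)


def allele_count_comparison(
    gc1: GenotypeCounts, gc2: GenotypeCounts
) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) comparing allele
    counts between two samples.

    Returns (chi2, p). Warns and suggests an exact test when any expected
    cell drops below 1; :func:`allele_count_comparison_exact` provides it.
    """
    import warnings

    table = np.array(
        [
            [2 * gc1.n_aa + gc1.n_ab, 2 * gc1.n_bb + gc1.n_ab],
            [2 * gc2.n_aa + gc2.n_ab, 2 * gc2.n_bb + gc2.n_ab],
        ],
        dtype=float,
    )
    if table.sum(axis=0).min() == 0:
        raise ValueError("both samples must be polymorphic")
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row @ col / table.sum()
    if expected.min() < 1:
        warnings.warn(
            "expected allele count below 1; consider the exact alternative",
            stacklevel=2,
        )
    chi2 = float(((table - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(chi2, df=1))
    return chi2, p


def allele_count_comparison_exact(
    gc1: GenotypeCounts, gc2: GenotypeCounts
) -> float:
    """Fisher exact p for the 2x2 allele-count table (small-count fallback)."""
    table = [
        [2 * gc1.n_aa + gc1.n_ab, 2 * gc1.n_bb + gc1.n_ab],
        [2 * gc2.n_aa + gc2.n_ab, 2 * gc2.n_bb + gc2.n_ab],
    ]
    return float(stats.fisher_exact(table)[1])


def stratification_report(gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-SNP heterozygote excess/deficit summary for stratification checks.

    A pooled sample from differentiated subpopulations shows a systematic
    heterozygote deficit (Wahlund effect); its absence argues against
    stratification confounding.
    """
    rows = []
    for j, snp in enumerate(gm.snps):
        gc = GenotypeCounts.from_calls(gm.calls[:, j])
        if gc.n == 0:
            continue
        _, e_ab, _ = hwe_expected(gc)
        diff = gc.n_ab - e_ab
        rows.append(
            {
                "snp_id": snp.snp_id,
                "obs_het": gc.n_ab,
                "exp_het": e_ab,
                "het_diff": diff,
                "direction": "excess" if diff > 0 else ("deficit" if diff < 0 else "none"),
                "hwe_p": hwe_exact_test(gc),
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["n_deficit"] = int((df["direction"] == "deficit").sum()) if len(df) else 0
    df.attrs["n_excess"] = int((df["direction"] == "excess").sum()) if len(df) else 0
    return df
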