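"""Data model and IO for genotypes, phenotypes, regions, and ancestral-allele tables.

Conventions
-----------
* VCF positions are 1-based; BED intervals are 0-based half-open. All internal
  window arithmetic is 0-based half-open and conversion happens at IO time.
* Genotype calls count copies of ``allele_b`` (the VCF ALT allele) per
  individual: 0, 1, 2, or ``MISSING`` (-1). Operations that care about
  orientation take an explicit effect-allele argument.
* Input is assumed to be on a consistent strand; no strand flipping is done.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING = -1

VALID_BASES = frozenset("ACGT")

#: header columns of the tabular genotype dialect
_TAB_META_COLS = ["snp_id", "chrom", "pos", "allele_a", "allele_b", "ancestral"]


class GenotypeParseError(ValueError):
    """Raised when a genotype file cannot be parsed."""


class SchemaError(ValueError):
    """Raised when a tabular input is missing required columns."""


@dataclass(frozen=True)
class SnpRecord:
    """A biallelic SNP with optional ancestral-state annotation.

    ``ancestral`` is either one of the two observed alleles or ``None`` when
    the ancestral state is unknown.
    """

    snp_id: str
    chrom: str
    pos: int  # 1-based, VCF convention
    allele_a: str
    allele_b: str
    ancestral: str | None = None

    def __post_init__(self) -> None:
        if self.allele_a == self.allele_b:
            raise ValueError(f"{self.snp_id}: alleles must differ")
        if self.pos < 1:
            raise ValueError(f"{self.snp_id}: pos must be >= 1 (got {self.pos})")
        if self.ancestral is not None and self.ancestral not in (
            self.allele_a,
            self.allele_b,
        ):
            raise ValueError(
                f"{self.snp_id}: ancestral {self.ancestral!r} is neither allele"
            )

    @property
    def derived(self) -> str | None:
        """The derived allele, or None when the ancestral state is unknown."""
        if self.ancestral is None:
            return None
        return self.allele_b if self.ancestral == self.allele_a else self.allele_a


@dataclass
class GenotypeMatrix:
    """Diploid calls for samples x SNPs.

    ``calls[i, j]`` is the number of copies of ``snps[j].allele_b`` carried by
    ``samples[i]``, or ``MISSING``.
    """

    samples: list[str]
    snps: list[SnpRecord]
    calls: np.ndarray  # int8, shape (n_samples, n_snps)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.snps)} snps"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError(f"invalid call values: {np.unique(self.calls[bad])}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def snp_index(self, snp_id: str) -> int:
        for j, s in enumerate(self.snps):
            if s.snp_id == snp_id:
                return j
        raise KeyError(snp_id)

    def column(self, snp_id: str) -> np.ndarray:
        return self.calls[:, self.snp_index(snp_id)]

    def allele_b_freq(self, j: int) -> float:
        """Sample frequency of allele_b at SNP index ``j`` (missing dropped)."""
        col = self.calls[:, j]
        typed = col[col != MISSING]
        if typed.size == 0:
            return float("nan")
        return float(typed.sum()) / (2 * typed.size)

    def derived_freq(self, j: int) -> float:
        """Derived-allele frequency at SNP index ``j``; NaN if ancestral unknown."""
        snp = self.snps[j]
        if snp.ancestral is None:
            return float("nan")
        f_b = self.allele_b_freq(j)
        return f_b if snp.ancestral == snp.allele_a else 1.0 - f_b


@dataclass
class PhenotypeTable:
    """Per-sample melanin index (DermaSpectrometer M units), sex, group label."""

    data: pd.DataFrame  # columns: sample_id, melanin_index, sex, [group]

    MELANIN_BAND = (15.0, 110.0)

    def __post_init__(self) -> None:
        required = {"sample_id", "melanin_index", "sex"}
        missing = required - set(self.data.columns)
        if missing:
            raise SchemaError(f"phenotype table missing columns: {sorted(missing)}")
        if self.data["sample_id"].duplicated().any():
            dups = self.data.loc[self.data["sample_id"].duplicated(), "sample_id"]
            raise ValueError(f"duplicate sample ids: {sorted(set(dups))}")
        if not self.data["sex"].isin((0, 1)).all():
            raise ValueError("sex must be coded 0/1")
        lo, hi = self.MELANIN_BAND
        m = self.data["melanin_index"]
        if ((m < lo) | (m > hi)).any():
            raise ValueError(f"melanin index outside plausibility band [{lo}, {hi}]")

    def __len__(self) -> int:
        return len(self.data)

    def aligned_to(self, samples: Sequence[str]) -> pd.DataFrame:
        """Rows reindexed to the given sample order (missing samples dropped)."""
        df = self.data.set_index("sample_id")
        keep = [s for s in samples if s in df.index]
        return df.loc[keep].reset_index()


@dataclass(frozen=True)
class Region:
    name: str
    chrom: str
    start: int  # 0-based
    end: int  # half-open

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"{self.name}: start must be < end")


@dataclass
class RegionSet:
    regions: list[Region]

    def __post_init__(self) -> None:
        names = [r.name for r in self.regions]
        if len(set(names)) != len(names):
            raise ValueError("region names must be unique")

    def __iter__(self):
        return iter(self.regions)

    def __len__(self) -> int:
        return len(self.regions)


@dataclass
class PopAlleleCounts:
    """Per-SNP allele_b counts and typed chromosome totals for several populations."""

    snps: list[SnpRecord]
    pops: list[str]
    count_b: np.ndarray  # int, shape (n_pops, n_snps): copies of allele_b
    n_chrom: np.ndarray  # int, shape (n_pops, n_snps): typed chromosomes (2n)

    def __post_init__(self) -> None:
        self.count_b = np.asarray(self.count_b, dtype=np.int64)
        self.n_chrom = np.asarray(self.n_chrom, dtype=np.int64)
        shape = (len(self.pops), len(self.snps))
        if self.count_b.shape != shape or self.n_chrom.shape != shape:
            raise ValueError("count array shapes inconsistent with pops x snps")
        if (self.n_chrom <= 0).any():
            raise ValueError("typed chromosome totals must be positive")
        if ((self.count_b < 0) | (self.count_b > self.n_chrom)).any():
            raise ValueError("allele counts must lie in [0, 2n]")

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.pos for s in self.snps], dtype=np.int64)

    def freq_b(self, pop: str) -> np.ndarray:
        i = self.pops.index(pop)
        return self.count_b[i] / self.n_chrom[i]


# ---------------------------------------------------------------------------
# readers / writers


def read_genotypes(path: str | Path, dialect: str = "vcf") -> GenotypeMatrix:
    """Read a genotype matrix from a VCF 4.x or tabular file.

    Only biallelic SNPs are accepted; multi-allelic records raise
    :class:`GenotypeParseError`.
    """
    if dialect == "vcf":
        return _read_vcf(path)
    if dialect == "table":
        return _read_table(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_vcf(path: str | Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    snps: list[SnpRecord] = []
    cols: list[np.ndarray] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise GenotypeParseError(
                f"non-biallelic record at {rec.CHROM}:{rec.POS} "
                f"(ALT={rec.ALT}); split or filter upstream"
            )
        snp_id = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        snps.append(
            SnpRecord(
                snp_id=snp_id,
                chrom=rec.CHROM,
                pos=rec.POS,
                allele_a=rec.REF,
                allele_b=rec.ALT[0],
            )
        )
        col = np.empty(len(samples), dtype=np.int8)
        for i, g in enumerate(rec.genotypes):
            a, b = g[0], g[1]
            col[i] = MISSING if (a < 0 or b < 0) else a + b
        cols.append(col)
    calls = (
        np.stack(cols, axis=1) if cols else np.empty((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(samples=samples, snps=snps, calls=calls)


def write_vcf(gm: GenotypeMatrix, path: str | Path, phased: bool = False) -> None:
    """Write a minimal GT-only VCF 4.2 file (plain text)."""
    sep = "|" if phased else "/"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(s.chrom for s in gm.snps):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        gt_strings = {0: f"0{sep}0", 1: f"0{sep}1", 2: f"1{sep}1", MISSING: "./."}
        for j, snp in enumerate(gm.snps):
            gts = "\t".join(gt_strings[int(c)] for c in gm.calls[:, j])
            fh.write(
                f"{snp.chrom}\t{snp.pos}\t{snp.snp_id}\t{snp.allele_a}\t"
                f"{snp.allele_b}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def _read_table(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in _TAB_META_COLS if c not in df.columns]
    if missing:
        raise SchemaError(f"tabular genotype file missing columns: {missing}")
    sample_cols = [c for c in df.columns if c not in _TAB_META_COLS]
    snps = []
    for _, row in df.iterrows():
        anc = row["ancestral"]
        snps.append(
            SnpRecord(
                snp_id=row["snp_id"],
                chrom=row["chrom"],
                pos=int(row["pos"]),
                allele_a=row["allele_a"],
                allele_b=row["allele_b"],
                ancestral=None if anc in (".", "", None) or pd.isna(anc) else anc,
            )
        )
    calls = np.empty((len(sample_cols), len(snps)), dtype=np.int8)
    for j in range(len(snps)):
        for i, c in enumerate(sample_cols):
            v = df.iloc[j][c]
            if v in (".", "NA", "") or pd.isna(v):
                calls[i, j] = MISSING
            elif v in ("0", "1", "2"):
                calls[i, j] = int(v)
            else:
                raise GenotypeParseError(
                    f"bad call {v!r} for sample {c} at line {j + 2}"
                )
    return GenotypeMatrix(samples=sample_cols, snps=snps, calls=calls)


def write_table(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write the tabular dialect: one row per SNP, one column per sample."""
    rows = []
    for j, s in enumerate(gm.snps):
        row = {
            "snp_id": s.snp_id,
            "chrom": s.chrom,
            "pos": s.pos,
            "allele_a": s.allele_a,
            "allele_b": s.allele_b,
            "ancestral": s.ancestral if s.ancestral is not None else ".",
        }
        for i, samp in enumerate(gm.samples):
            c = gm.calls[i, j]
            row[samp] = "." if c == MISSING else str(int(c))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    """Read a TSV phenotype table with columns sample_id, melanin_index, sex[, group].

    Rows whose melanin index is non-numeric or outside the plausibility band
    are dropped with a warning reporting the rejected count.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str}, comment="#")
    required = {"sample_id", "melanin_index", "sex"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"phenotype table missing columns: {sorted(missing)}")
    m = pd.to_numeric(df["melanin_index"], errors="coerce")
    lo, hi = PhenotypeTable.MELANIN_BAND
    ok = m.notna() & (m >= lo) & (m <= hi)
    n_rejected = int((~ok).sum())
    if n_rejected:
        warnings.warn(
            f"rejected {n_rejected} phenotype row(s) with non-numeric or "
            f"out-of-band melanin index",
            stacklevel=2,
        )
    df = df.loc[ok].copy()
    df["melanin_index"] = m[ok].astype(float)
    df["sex"] = pd.to_numeric(df["sex"]).astype(int)
    return PhenotypeTable(data=df.reset_index(drop=True))


def write_phenotypes(pt: PhenotypeTable, path: str | Path) -> None:
    pt.data.to_csv(path, sep="\t", index=False)


def read_regions(path: str | Path) -> RegionSet:
    """Read a BED file (chrom, start, end, name) into a RegionSet."""
    regions = []
    with open(path) as fh:
        for k, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise GenotypeParseError(f"malformed BED line {k}: {line!r}")
            name = parts[3] if len(parts) > 3 else f"region{k}"
            regions.append(
                Region(name=name, chrom=parts[0], start=int(parts[1]), end=int(parts[2]))
            )
    return RegionSet(regions=regions)


def write_regions(rs: RegionSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in rs:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\n")


def read_ancestral_table(path: str | Path) -> dict[str, str]:
    """Read a TSV mapping snp_id -> ancestral allele."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if not {"snp_id", "ancestral"} <= set(df.columns):
        raise SchemaError("ancestral table needs columns snp_id, ancestral")
    table = dict(zip(df["snp_id"], df["ancestral"]))
    for snp_id, allele in table.items():
        if allele not in VALID_BASES:
            raise ValueError(f"{snp_id}: ancestral allele {allele!r} is not a base")
    return table


def attach_ancestral(gm: GenotypeMatrix, table: dict[str, str]) -> GenotypeMatrix:
    """Return a new matrix with ancestral states set from ``table``.

    SNPs absent from the table keep ``ancestral=None``; SNPs whose table
    allele matches neither observed allele get ``None`` plus a warning.
    """
    new_snps = []
    mismatches = []
    for snp in gm.snps:
        anc = table.get(snp.snp_id)
        if anc is None:
            new_snps.append(replace(snp, ancestral=None))
        elif anc in (snp.allele_a, snp.allele_b):
            new_snps.append(replace(snp, ancestral=anc))
        else:
            mismatches.append(snp.snp_id)
            new_snps.append(replace(snp, ancestral=None))
    if mismatches:
        warnings.warn(
            f"ancestral allele matches neither observed allele for "
            f"{len(mismatches)} SNP(s): {mismatches[:10]}",
            stacklevel=2,
        )
    return GenotypeMatrix(samples=list(gm.samples), snps=new_snps, calls=gm.calls.copy())


def read_pop_allele_counts(path: str | Path) -> PopAlleleCounts:
    """Read a TSV of per-population allele counts.

    Expected columns: snp_id, chrom, pos, allele_a, allele_b, then per
    population ``<pop>_count`` (copies of allele_b) and ``<pop>_nchrom``.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    meta = ["snp_id", "chrom", "pos", "allele_a", "allele_b"]
    missing = [c for c in meta if c not in df.columns]
    if missing:
        raise SchemaError(f"allele-count table missing columns: {missing}")
    pops = sorted(
        {c[: -len("_count")] for c in df.columns if c.endswith("_count")}
    )
    if not pops:
        raise SchemaError("no <pop>_count columns found")
    snps = [
        SnpRecord(str(r.snp_id), str(r.chrom), int(r.pos), r.allele_a, r.allele_b)
        for r in df.itertuples()
    ]
    count_b = np.stack([df[f"{p}_count"].to_numpy() for p in pops])
    n_chrom = np.stack([df[f"{p}_nchrom"].to_numpy() for p in pops])
    return PopAlleleCounts(snps=snps, pops=pops, count_b=count_b, n_chrom=n_chrom)


def write_pop_allele_counts(pac: PopAlleleCounts, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "snp_id": [s.snp_id for s in pac.snps],
            "chrom": [s.chrom for s in pac.snps],
            "pos": [s.pos for s in pac.snps],
            "allele_a": [s.allele_a for s in pac.snps],
            "allele_b": [s.allele_b for s in pac.snps],
        }
    )
    for i, p in enumerate(pac.pops):
        df[f"{p}_count"] = pac.count_b[i]
        df[f"{p}_nchrom"] = pac.n_chrom[i]
    df.to_csv(path, sep="\t", index=False)
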