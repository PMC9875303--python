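"""VCF input/output, variant filtering and LD pruning.

Reading goes through :mod:`cyvcf2`; writing emits a minimal GT-only VCFv4.2.
Genotypes are coded as alt-allele dosage (0/1/2) with a distinct MISSING
sentinel; phase is preserved when every genotype in the file is phased.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .cohort import (
    MISSING,
    AlleleCount,
    Cohort,
    CohortError,
    make_samples,
)

__all__ = [
    "read_vcf",
    "write_vcf",
    "filter_variants",
    "segregating_subset",
    "genotype_r2",
    "ld_prune",
    "read_population_map",
    "read_chrom_sizes",
]


class VcfFormatError(ValueError):
    pass


def read_vcf(
    path: str,
    region: str | None = None,
    population_map: dict[str, str] | None = None,
) -> Cohort:
    """Read a diploid VCF into a :class:`Cohort`.

    Multi-allelic records are retained with a comma-joined ALT string so the
    downstream biallelic filter can drop them.  The cohort is flagged phased
    only when every called genotype separator in the file is ``|``.

    Parameters
    ----------
    region
        Optional ``chrom`` or ``chrom:start-end`` restriction (1-based
        inclusive), applied while reading.
    population_map
        sample_id -> population; samples without an entry get population
        ``"unknown"``.
    """
    import cyvcf2

    vcf = cyvcf2.VCF(path, gts012=False)
    sample_ids = list(vcf.samples)
    chrom_sel, lo, hi = _parse_region(region)

    rows: list[tuple] = []
    geno_rows: list[np.ndarray] = []
    hap_rows: list[np.ndarray] = []
    phased = True
    for var in vcf:
        if chrom_sel is not None and var.CHROM != chrom_sel:
            continue
        if lo is not None and not (lo <= var.POS <= hi):
            continue
        gts = var.genotypes  # list of [allele0, allele1, phased]
        if any(len(g) != 3 for g in gts):
            raise VcfFormatError(
                f"non-diploid genotype at {var.CHROM}:{var.POS}; only "
                "diploid GT fields are supported"
            )
        arr = np.array(gts, dtype=np.int64)
        a0, a1, ph = arr[:, 0], arr[:, 1], arr[:, 2]
        called = (a0 >= 0) & (a1 >= 0)
        g = np.where(called, (a0 > 0).astype(int) + (a1 > 0).astype(int), MISSING)
        if called.any() and not ph[called].all():
            phased = False
        rows.append((var.CHROM, var.POS, var.REF, ",".join(var.ALT) or "."))
        geno_rows.append(g.astype(np.int8))
        h = np.empty(2 * len(sample_ids), dtype=np.int8)
        h[::2] = np.where(a0 >= 0, np.minimum(a0, 1), MISSING)
        h[1::2] = np.where(a1 >= 0, np.minimum(a1, 1), MISSING)
        hap_rows.append(h)
    vcf.close()

    variants = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    variants["chrom"] = variants["chrom"].astype(str)
    pops = [
        (population_map or {}).get(s, "unknown") for s in sample_ids
    ]
    n = len(sample_ids)
    genotypes = (
        np.vstack(geno_rows) if geno_rows else np.empty((0, n), dtype=np.int8)
    )
    haplotypes = None
    if phased and n > 0:
        haplotypes = (
            np.vstack(hap_rows) if hap_rows else np.empty((0, 2 * n), dtype=np.int8)
        )
    return Cohort(
        variants=variants,
        samples=make_samples(sample_ids, pops),
        genotypes=genotypes,
        haplotypes=haplotypes,
        phased=phased and n > 0,
    )


def _parse_region(region: str | None):
    if region is None:
        return None, None, None
    if ":" not in region:
        return region, None, None
    chrom, span = region.split(":", 1)
    lo, hi = span.split("-", 1)
    return chrom, int(lo.replace(",", "")), int(hi.replace(",", ""))


def write_vcf(cohort: Cohort, path: str) -> None:
    """Write a cohort as a GT-only VCFv4.2 file (phased separators iff phased)."""
    cohort._check_sorted()
    sep = "|" if cohort.phased else "/"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=herdscan\n")
        for chrom in dict.fromkeys(cohort.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(cohort.samples["sample_id"])
            + "\n"
        )
        hap = cohort.haplotypes
        for i, row in enumerate(cohort.variants.itertuples(index=False)):
            fields = [
                str(row.chrom), str(row.pos), ".", row.ref, row.alt, ".", ".",
                ".", "GT",
            ]
            for s in range(cohort.n_samples):
                g = cohort.genotypes[i, s]
                if g == MISSING:
                    fields.append("./.")
                elif cohort.phased and hap is not None:
                    fields.append(f"{hap[i, 2 * s]}{sep}{hap[i, 2 * s + 1]}")
                else:
                    fields.append({0: "0/0", 1: "0/1", 2: "1/1"}[int(g)])
            fh.write("\t".join(fields) + "\n")


def filter_variants(
    cohort: Cohort,
    min_call_rate: float = 0.95,
    biallelic_only: bool = True,
    autosomes: set[str] | None = None,
) -> Cohort:
    """Keep variants by call rate (inclusive threshold), ALT count and chromosome."""
    keep = cohort.call_rate() >= min_call_rate
    if biallelic_only:
        alt = cohort.variants["alt"].to_numpy()
        keep &= np.array([("," not in a) and a != "." for a in alt])
    if autosomes is not None:
        keep &= cohort.variants["chrom"].isin(set(map(str, autosomes))).to_numpy()
    return cohort.take_variants(keep)


def segregating_subset(cohort: Cohort, populations) -> Cohort:
    """Variants polymorphic in the pool of the named populations."""
    idx = np.concatenate([cohort.sample_indices(p) for p in populations])
    ac = cohort.take_samples(idx).allele_counts()
    keep = (ac.n_alt > 0) & (ac.n_alt < ac.n)
    return cohort.take_variants(keep)


def genotype_r2(g_i: np.ndarray, g_j: np.ndarray) -> float:
    """Squared Pearson correlation of dosages over pairwise-complete calls.

    Returns NaN (the "not estimable" sentinel) when fewer than two complete
    pairs exist or either vector is constant.
    """
    g_i = np.asarray(g_i, dtype=float)
    g_j = np.asarray(g_j, dtype=float)
    ok = (g_i != MISSING) & (g_j != MISSING)
    if ok.sum() < 2:
        return math.nan
    x, y = g_i[ok], g_j[ok]
    vx = x.var()
    vy = y.var()
    if vx == 0 or vy == 0:
        return math.nan
    c = ((x - x.mean()) * (y - y.mean())).mean()
    return float(c * c / (vx * vy))


def _minor_allele_freq(ac: AlleleCount) -> np.ndarray:
    p = ac.p
    return np.minimum(p, 1 - p)


def ld_prune(
    cohort: Cohort,
    window_snps: int = 50,
    step_snps: int = 5,
    r2_max: float = 0.6,
) -> np.ndarray:
    """PLINK-style greedy sliding-window LD pruning.

    Within each window of ``window_snps`` kept variants (advanced by
    ``step_snps``) the most correlated pair above ``r2_max`` is resolved by
    removing the lower-MAF member (ties: the later position).  Returns the
    kept variant indices; the result contains no pair co-occurring in any
    window position with r² > ``r2_max``.
    """
    if not (window_snps > step_snps > 0):
        raise ValueError("require window_snps > step_snps > 0")
    keep = np.ones(cohort.n_variants, dtype=bool)
    maf = _minor_allele_freq(cohort.allele_counts())
    chroms = cohort.variants["chrom"].to_numpy()
    for chrom in dict.fromkeys(chroms):
        idx = np.flatnonzero(chroms == chrom)
        for start in range(0, len(idx), step_snps):
            win = idx[start : start + window_snps]
            if len(win) < 2:
                continue
            _prune_window(cohort, win, keep, maf, r2_max)
            if start + window_snps >= len(idx):
                break
    return np.flatnonzero(keep)


def _prune_window(cohort, win, keep, maf, r2_max):
    active = [int(i) for i in win if keep[i]]
    # cache pairwise r2 among active variants
    r2 = {}
    while True:
        worst = None
        worst_r2 = r2_max
        for a in range(len(active)):
            for b in range(a + 1, len(active)):
                i, j = active[a], active[b]
                key = (i, j)
                if key not in r2:
                    r2[key] = genotype_r2(
                        cohort.genotypes[i], cohort.genotypes[j]
                    )
                val = r2[key]
                if not math.isnan(val) and val > worst_r2:
                    worst_r2 = val
                    worst = key
        if worst is None:
            return
        i, j = worst
        # remove the lower-MAF member; MAF tie -> later position
        if maf[i] < maf[j]:
            drop = i
        elif maf[j] < maf[i]:
            drop = j
        else:
            drop = max(i, j)
        keep[drop] = False
        active.remove(drop)


def read_population_map(path: str) -> dict[str, str]:
    """Two-column TSV (sample_id, population) -> mapping."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["sample_id", "population"],
        dtype=str, comment="#",
    )
    return dict(zip(df["sample_id"], df["population"]))


def read_chrom_sizes(path: str) -> dict[str, int]:
    """Two-column TSV (chromosome, length bp) -> mapping."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "length"], comment="#",
        dtype={"chrom": str},
    )
    return dict(zip(df["chrom"], df["length"].astype(int)))
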