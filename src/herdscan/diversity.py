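"""Nucleotide diversity, heterozygosity and excess-of-homozygosity inbreeding.

Windowed nucleotide diversity (pi) follows the mean-pairwise-difference
definition: per site with n called alleles of which n_alt are alternate,

    pi_site = n_ref * n_alt / C(n, 2) = 2 p q n / (n - 1),

summed over the sites of a fixed-width window, divided by the window width
in bp and multiplied by 100 (all pi values are reported in percent).
Per-individual observed/expected heterozygosity and the method-of-moments
inbreeding coefficient

    F_Hom = (observed hom - expected hom) / (total variants - expected hom)

are computed against a fixed external variant denominator so that breeds
genotyped on a shared variant set remain comparable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import MISSING, AlleleCount, Cohort

__all__ = [
    "site_pairwise_diversity",
    "windowed_pi",
    "pi_summaries",
    "individual_heterozygosity",
    "f_hom",
    "breed_f_hom",
    "het_chisq",
    "tile_windows",
]


def site_pairwise_diversity(ac: AlleleCount) -> np.ndarray:
    """Per-site mean pairwise difference ``n_ref * n_alt / C(n, 2)``.

    Sites with fewer than two called alleles are NaN (excluded from windows).
    """
    n = ac.n.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        pi = ac.n_ref * ac.n_alt / (n * (n - 1) / 2.0)
    return np.where(n >= 2, pi, np.nan)


def tile_windows(
    chrom_sizes: dict[str, int], window_bp: int
) -> pd.DataFrame:
    """Non-overlapping windows tiling each chromosome (1-based inclusive)."""
    rows = []
    for chrom, length in chrom_sizes.items():
        for start in range(1, int(length) + 1, window_bp):
            rows.append((str(chrom), start, min(start + window_bp - 1, int(length))))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _infer_chrom_sizes(cohort: Cohort, window_bp: int) -> dict[str, int]:
    sizes: dict[str, int] = {}
    for chrom, grp in cohort.variants.groupby("chrom", sort=False):
        top = int(grp["pos"].max())
        sizes[str(chrom)] = int(math.ceil(top / window_bp) * window_bp)
    return sizes


def windowed_pi(
    cohort: Cohort,
    population: str,
    window_bp: int = 10_000,
    chrom_sizes: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Nucleotide diversity per tiling window, in percent.

    Returns a window table ``(chrom, start, end, n_snps, value)``; windows
    with no usable site have value 0.  When ``chrom_sizes`` is omitted the
    chromosome extent is inferred from the last variant.
    """
    ac = cohort.allele_counts(population)
    pi = site_pairwise_diversity(ac)
    usable = ~np.isnan(pi)
    sizes = chrom_sizes or _infer_chrom_sizes(cohort, window_bp)
    windows = tile_windows(sizes, window_bp)
    chroms = cohort.variants["chrom"].to_numpy()
    pos = cohort.variants["pos"].to_numpy()

    n_snps = np.zeros(len(windows), dtype=int)
    value = np.zeros(len(windows), dtype=float)
    for chrom in windows["chrom"].unique():
        wmask = (windows["chrom"] == chrom).to_numpy()
        widx = np.flatnonzero(wmask)
        vmask = (chroms == chrom) & usable
        p = pos[vmask]
        v = pi[vmask]
        starts = windows.loc[wmask, "start"].to_numpy()
        ends = windows.loc[wmask, "end"].to_numpy()
        bins = np.searchsorted(starts, p, side="right") - 1
        ok = (bins >= 0) & (p <= ends[np.clip(bins, 0, None)])
        np.add.at(n_snps, widx[bins[ok]], 1)
        np.add.at(value, widx[bins[ok]], v[ok])
    windows["n_snps"] = n_snps
    windows["value"] = value / window_bp * 100.0
    return windows


@dataclass
class PiSummary:
    per_chromosome: pd.DataFrame  # chrom, mean, median (percent)
    tot_mean: float
    tot_median: float


def pi_summaries(windows: pd.DataFrame, include_empty: bool = True) -> PiSummary:
    """Chromosome and genome-wide mean/median of window pi values."""
    if len(windows) == 0:
        raise ValueError("empty window table")
    w = windows if include_empty else windows[windows["n_snps"] > 0]
    per_chrom = (
        w.groupby("chrom", sort=False)["value"]
        .agg(["mean", "median"])
        .reset_index()
    )
    return PiSummary(
        per_chromosome=per_chrom,
        tot_mean=float(w["value"].mean()),
        tot_median=float(w["value"].median()),
    )


def individual_heterozygosity(
    cohort: Cohort,
    population: str,
    denominator: int,
    freq_scope: str = "population",
) -> pd.DataFrame:
    """Per-sample observed/expected heterozygosity and F_Hom.

    Expected homozygosity at each called site is ``1 - 2 p q n / (n - 1)``
    with allele frequencies taken within the focal population
    (``freq_scope="population"``) or over the whole cohort
    (``freq_scope="cohort"``).  ``h_o``/``h_e`` are scaled by the fixed
    external ``denominator`` (e.g. the shared cohort variant count), which
    also serves as the "total number of variants" of F_Hom.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if freq_scope not in ("population", "cohort"):
        raise ValueError("freq_scope must be 'population' or 'cohort'")
    ac = cohort.allele_counts(
        population if freq_scope == "population" else None
    )
    n = ac.n.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        e_het_site = 2 * ac.p * ac.q * n / (n - 1)
    e_het_site = np.where(n >= 2, e_het_site, 0.0)

    rows = []
    for s in cohort.sample_indices(population):
        g = cohort.genotypes[:, s]
        called = g != MISSING
        n_used = int(called.sum())
        o_het = int((g[called] == 1).sum())
        o_hom = n_used - o_het
        e_hom = float(np.sum((1.0 - e_het_site)[called]))
        rows.append(
            {
                "sample_id": cohort.samples["sample_id"].iloc[s],
                "n_used": n_used,
                "o_het": o_het,
                "o_hom": o_hom,
                "e_hom": e_hom,
                "h_o": o_het / denominator,
                "h_e": (n_used - e_hom) / denominator,
                "f_hom": f_hom(o_hom, e_hom, denominator),
            }
        )
    return pd.DataFrame(rows)


def f_hom(o_hom: float, e_hom: float, total_variants: int) -> float:
    """Excess-of-homozygosity inbreeding coefficient (method of moments)."""
    denom = total_variants - e_hom
    if denom <= 0:
        return math.nan
    return (o_hom - e_hom) / denom


def breed_f_hom(stats: pd.DataFrame) -> float:
    """Breed-level F_Hom: unweighted mean over individuals."""
    return float(stats["f_hom"].mean())


def het_chisq(
    o_het: float, e_het: float, o_hom: float, e_hom: float
) -> tuple[float, float]:
    """1-df goodness-of-fit chi-squared between observed and expected
    het/hom counts; returns (statistic, p)."""
    if e_het <= 0 or e_hom <= 0:
        raise ValueError("expected counts must be positive")
    x2 = (o_het - e_het) ** 2 / e_het + (o_hom - e_hom) ** 2 / e_hom
    return float(x2), float(stats.chi2.sf(x2, df=1))
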