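"""Core in-memory containers for multi-population genotype cohorts.

A :class:`Cohort` holds a variant table, a sample table with population
(breed) labels, a genotype matrix in alt-allele dosage coding and, when the
source data were phased, a haplotype matrix.  Every statistic in this
package consumes a Cohort, usually through per-population
:class:`AlleleCount` summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Sentinel genotype / haplotype code for a missing call.  Never imputed.
MISSING: int = -1

VARIANT_COLUMNS = ("chrom", "pos", "ref", "alt")
SAMPLE_COLUMNS = ("sample_id", "population")


class CohortError(ValueError):
    """Raised when a cohort violates its structural invariants."""


@dataclass
class AlleleCount:
    """Per-site reference/alternate allele counts (vectorised over sites).

    ``n_ref`` and ``n_alt`` are integer arrays of called allele counts; the
    derived quantities ``n``, ``p`` (alt frequency) and ``q`` follow.  Sites
    with no called alleles have ``p`` = NaN.
    """

    n_ref: np.ndarray
    n_alt: np.ndarray

    def __post_init__(self) -> None:
        self.n_ref = np.asarray(self.n_ref)
        self.n_alt = np.asarray(self.n_alt)
        if np.any(self.n_ref < 0) or np.any(self.n_alt < 0):
            raise ValueError("allele counts must be non-negative")

    @property
    def n(self) -> np.ndarray:
        return self.n_ref + self.n_alt

    @property
    def p(self) -> np.ndarray:
        n = self.n
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(n > 0, self.n_alt / np.maximum(n, 1), np.nan)

    @property
    def q(self) -> np.ndarray:
        return 1.0 - self.p


@dataclass
class Cohort:
    """Genotype (and optionally haplotype) matrix with coordinates and labels.

    Parameters
    ----------
    variants
        DataFrame with columns ``chrom, pos, ref, alt``; positions 1-based,
        strictly sorted within each chromosome block.
    samples
        DataFrame with columns ``sample_id, population``.
    genotypes
        ``(n_variants, n_samples)`` int8 matrix; 0 hom-ref, 1 het,
        2 hom-alt, :data:`MISSING` for no call.
    haplotypes
        ``(n_variants, 2 * n_samples)`` matrix of allele codes {0, 1} (or
        :data:`MISSING`); present only for phased data.  Sample ``s`` owns
        columns ``2s`` and ``2s + 1``.
    """

    variants: pd.DataFrame
    samples: pd.DataFrame
    genotypes: np.ndarray
    haplotypes: np.ndarray | None = None
    phased: bool = False

    def __post_init__(self) -> None:
        self.variants = self.variants.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.haplotypes is not None:
            self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        self.validate()

    # -- structural checks -------------------------------------------------
    def validate(self) -> None:
        nv, ns = self.n_variants, self.n_samples
        if self.genotypes.shape != (nv, ns):
            raise CohortError(
                f"genotype matrix {self.genotypes.shape} does not match "
                f"{nv} variants x {ns} samples"
            )
        if self.samples["sample_id"].duplicated().any():
            raise CohortError("sample identifiers must be unique")
        if (self.samples["population"].astype(str) == "").any():
            raise CohortError("population labels must be non-empty")
        self._check_sorted()
        if self.haplotypes is not None:
            if self.haplotypes.shape != (nv, 2 * ns):
                raise CohortError("haplotype matrix shape mismatch")
            self._check_hap_consistency()

    def _check_sorted(self) -> None:
        chroms = self.variants["chrom"].to_numpy()
        pos = self.variants["pos"].to_numpy()
        if len(pos) and pos.min() < 1:
            raise CohortError("positions must be >= 1")
        seen: set = set()
        prev_chrom = None
        prev_pos = -1
        for c, p in zip(chroms, pos):
            if c != prev_chrom:
                if c in seen:
                    raise CohortError(f"chromosome {c!r} appears in two blocks")
                seen.add(c)
                prev_chrom, prev_pos = c, p
            else:
                if p <= prev_pos:
                    raise CohortError(
                        f"positions not strictly increasing on {c!r} at {p}"
                    )
                prev_pos = p

    def _check_hap_consistency(self) -> None:
        h = self.haplotypes
        called = (h[:, ::2] != MISSING) & (h[:, 1::2] != MISSING)
        s = h[:, ::2] + h[:, 1::2]
        g = self.genotypes
        ok = np.where(called, s == g, g == MISSING)
        if not np.all(ok):
            raise CohortError("haplotypes inconsistent with genotype codes")

    # -- basic accessors ---------------------------------------------------
    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def populations(self) -> list[str]:
        return list(dict.fromkeys(self.samples["population"]))

    def sample_indices(self, population: str | None = None) -> np.ndarray:
        """Column indices of the samples of one population (or all)."""
        if population is None:
            return np.arange(self.n_samples)
        mask = (self.samples["population"] == population).to_numpy()
        if not mask.any():
            raise KeyError(f"unknown population {population!r}")
        return np.flatnonzero(mask)

    def call_rate(self) -> np.ndarray:
        """Fraction of called genotypes per variant."""
        if self.n_samples == 0:
            return np.ones(self.n_variants)
        return (self.genotypes != MISSING).mean(axis=1)

    def allele_counts(self, population: str | None = None) -> AlleleCount:
        """Per-site called allele counts, optionally within one population."""
        idx = self.sample_indices(population)
        g = self.genotypes[:, idx]
        called = g != MISSING
        n_alt = np.where(called, g, 0).sum(axis=1)
        n = 2 * called.sum(axis=1)
        return AlleleCount(n_ref=n - n_alt, n_alt=n_alt)

    # -- subsetting --------------------------------------------------------
    def take_variants(self, index: np.ndarray) -> "Cohort":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return replace(
            self,
            variants=self.variants.iloc[index],
            genotypes=self.genotypes[index],
            haplotypes=None if self.haplotypes is None else self.haplotypes[index],
        )

    def take_samples(self, index: np.ndarray) -> "Cohort":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        hap = None
        if self.haplotypes is not None:
            cols = np.empty(2 * len(index), dtype=int)
            cols[::2] = 2 * index
            cols[1::2] = 2 * index + 1
            hap = self.haplotypes[:, cols]
        return replace(
            self,
            samples=self.samples.iloc[index],
            genotypes=self.genotypes[:, index],
            haplotypes=hap,
        )

    def haplotype_columns(self, population: str) -> np.ndarray:
        """Haplotype column indices belonging to one population."""
        if self.haplotypes is None:
            raise CohortError("cohort is not phased; no haplotypes available")
        idx = self.sample_indices(population)
        cols = np.empty(2 * len(idx), dtype=int)
        cols[::2] = 2 * idx
        cols[1::2] = 2 * idx + 1
        return cols


def make_variants(
    chrom, pos, ref: str | None = None, alt: str | None = None
) -> pd.DataFrame:
    """Convenience constructor for a variant table."""
    pos = np.asarray(pos)
    n = len(pos)
    chrom = np.full(n, chrom) if np.isscalar(chrom) else np.asarray(chrom)
    return pd.DataFrame(
        {
            "chrom": chrom.astype(str),
            "pos": pos.astype(np.int64),
            "ref": np.full(n, ref if ref is not None else "A"),
            "alt": np.full(n, alt if alt is not None else "C"),
        }
    )


def make_samples(sample_ids, populations) -> pd.DataFrame:
    return pd.DataFrame(
        {"sample_id": list(sample_ids), "population": list(populations)}
    )
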