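"""Synthetic multi-population cohorts with known ground truth.

The generator stands in for restricted whole-genome cattle data.  Population
differentiation follows the Balding-Nichols model: per site an ancestral alt
frequency ``p0`` is drawn uniformly on [maf_min, 1 - maf_min] and each
population k with drift parameter ``F_k`` draws its own frequency

    p_k ~ Beta(p0 (1 - F_k) / F_k, (1 - p0)(1 - F_k) / F_k),

after which 2n haplotype alleles are i.i.d. Bernoulli(p_k).  Hudson's F_ST
between two such populations converges to (F_a + F_b) / 2, so cohorts with a
known target differentiation can be generated directly.  Sites are
independent (no background LD); autozygous tracts and selective sweeps are
planted explicitly where a test needs haplotype structure.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .cohort import MISSING, Cohort, make_samples
from . import vcfio

__all__ = [
    "SimConfig",
    "SimTruth",
    "sim_balding_nichols",
    "cohort_from_pop_freqs",
    "plant_autozygosity",
    "plant_sweep",
    "write_fixture",
    "read_fixture",
]


@dataclass
class SimConfig:
    """World description for :func:`sim_balding_nichols`.

    Defaults emulate a two-breed cattle contrast at desk scale: two
    populations of 30 diploids (the per-breed cap of the study design) on a
    10-Mb chromosome at 1 SNP/kb, with per-population drift F = 0.05 giving
    a pairwise differentiation in the 0.03-0.08 range typical of taurine
    breeds.
    """

    n_pops: int = 2
    n_per_pop: int = 30
    chrom_lengths: dict = field(default_factory=lambda: {"1": 10_000_000})
    density: float = 1e-3  # sites per bp
    maf_min: float = 0.05
    pop_f: tuple = (0.05, 0.05)
    error_rate: float = 0.0
    spacing: str = "uniform"  # "uniform" (random positions) or "grid"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError("site density must be > 0")
        if len(self.pop_f) != self.n_pops:
            raise ValueError("pop_f must have one F per population")
        if any(not (0 <= f < 1) for f in self.pop_f):
            raise ValueError("population F must lie in [0, 1)")
        if self.spacing not in ("uniform", "grid"):
            raise ValueError("spacing must be 'uniform' or 'grid'")


@dataclass
class SimTruth:
    """Ground truth recorded alongside a simulated cohort."""

    pop_fst: dict = field(default_factory=dict)  # "A,B" -> expected F_ST
    autozygous_segments: list = field(default_factory=list)
    sweep: dict | None = None
    seed: int = 0


def _positions(
    rng: np.random.Generator, length: int, density: float, spacing: str = "uniform"
) -> np.ndarray:
    n = int(round(length * density))
    if spacing == "grid":
        step = int(round(1.0 / density))
        return np.arange(1, n + 1, dtype=np.int64) * step - step // 2
    pos = np.unique(rng.integers(1, length + 1, size=n))
    while len(pos) < n:  # top up collisions; rare at test densities
        extra = rng.integers(1, length + 1, size=n - len(pos))
        pos = np.unique(np.concatenate([pos, extra]))
    return pos[:n] if len(pos) > n else pos


def _bn_freqs(rng, p0: np.ndarray, f: float) -> np.ndarray:
    if f == 0:
        return p0.copy()
    a = p0 * (1 - f) / f
    b = (1 - p0) * (1 - f) / f
    return rng.beta(a, b)


def cohort_from_pop_freqs(
    pop_freqs: dict[str, np.ndarray],
    positions_by_chrom: dict[str, np.ndarray],
    n_per_pop: int,
    rng: np.random.Generator,
) -> Cohort:
    """Draw a phased cohort from per-population, per-site alt frequencies.

    ``pop_freqs`` maps population label to a frequency array over all sites
    (chromosomes concatenated in ``positions_by_chrom`` order).
    """
    chroms = []
    pos_all = []
    for chrom, pos in positions_by_chrom.items():
        chroms.append(np.full(len(pos), str(chrom)))
        pos_all.append(np.asarray(pos))
    chrom_col = np.concatenate(chroms) if chroms else np.array([], dtype=str)
    pos_col = (
        np.concatenate(pos_all) if pos_all else np.array([], dtype=np.int64)
    )
    n_sites = len(pos_col)

    hap_blocks = []
    sample_ids = []
    pops = []
    for pop, freqs in pop_freqs.items():
        freqs = np.asarray(freqs, dtype=float)
        if len(freqs) != n_sites:
            raise ValueError("frequency array length mismatch")
        h = (
            rng.random((n_sites, 2 * n_per_pop)) < freqs[:, None]
        ).astype(np.int8)
        hap_blocks.append(h)
        sample_ids += [f"{pop}_{i:03d}" for i in range(n_per_pop)]
        pops += [pop] * n_per_pop
    hap = (
        np.hstack(hap_blocks)
        if hap_blocks
        else np.empty((n_sites, 0), dtype=np.int8)
    )
    geno = (hap[:, ::2] + hap[:, 1::2]).astype(np.int8)
    variants = pd.DataFrame(
        {
            "chrom": chrom_col,
            "pos": pos_col,
            "ref": np.full(n_sites, "A"),
            "alt": np.full(n_sites, "C"),
        }
    )
    return Cohort(
        variants=variants,
        samples=make_samples(sample_ids, pops),
        genotypes=geno,
        haplotypes=hap,
        phased=True,
    )


def sim_balding_nichols(config: SimConfig) -> tuple[Cohort, SimTruth]:
    """Simulate a phased multi-population cohort under Balding-Nichols drift."""
    rng = np.random.default_rng(config.seed)
    positions = {
        str(c): _positions(rng, int(L), config.density, config.spacing)
        for c, L in config.chrom_lengths.items()
    }
    n_sites = sum(len(p) for p in positions.values())
    p0 = rng.uniform(config.maf_min, 1 - config.maf_min, size=n_sites)
    pop_labels = [f"P{k + 1}" for k in range(config.n_pops)]
    pop_freqs = {
        lab: _bn_freqs(rng, p0, f) for lab, f in zip(pop_labels, config.pop_f)
    }
    cohort = cohort_from_pop_freqs(pop_freqs, positions, config.n_per_pop, rng)
    if config.error_rate > 0:
        miss = rng.random(cohort.genotypes.shape) < config.error_rate
        cohort.genotypes[miss] = MISSING
        if cohort.haplotypes is not None:
            cohort.haplotypes[np.repeat(miss, 2, axis=1)] = MISSING
    truth = SimTruth(seed=config.seed)
    for i in range(config.n_pops):
        for j in range(i + 1, config.n_pops):
            truth.pop_fst[f"{pop_labels[i]},{pop_labels[j]}"] = (
                config.pop_f[i] + config.pop_f[j]
            ) / 2
    return cohort, truth


def plant_autozygosity(
    cohort: Cohort,
    sample: str,
    segments: list[tuple[str, int, int]],
    error_rate: float = 0.0,
    seed: int = 0,
    truth: SimTruth | None = None,
) -> tuple[Cohort, SimTruth]:
    """Overwrite one sample's second haplotype with its first inside segments.

    Inside each ``(chrom, start, end)`` interval (1-based inclusive) the
    sample becomes homozygous site by site; each segment genotype is then
    flipped to a heterozygote independently with probability ``error_rate``,
    emulating genotyping error.  Segments of one call must not overlap.
    """
    if cohort.haplotypes is None:
        raise ValueError("plant_autozygosity requires a phased cohort")
    segs = sorted(segments)
    for (c1, s1, e1), (c2, s2, e2) in zip(segs, segs[1:]):
        if c1 == c2 and s2 <= e1:
            raise ValueError("planted segments must not overlap")
    rng = np.random.default_rng(seed)
    s_idx = int(
        np.flatnonzero((cohort.samples["sample_id"] == sample).to_numpy())[0]
    )
    hap = cohort.haplotypes.copy()
    geno = cohort.genotypes.copy()
    chroms = cohort.variants["chrom"].to_numpy()
    pos = cohort.variants["pos"].to_numpy()
    for chrom, start, end in segs:
        in_seg = (chroms == str(chrom)) & (pos >= start) & (pos <= end)
        idx = np.flatnonzero(in_seg)
        hap[idx, 2 * s_idx + 1] = hap[idx, 2 * s_idx]
        geno[idx, s_idx] = 2 * hap[idx, 2 * s_idx]
        flip = idx[rng.random(len(idx)) < error_rate]
        geno[flip, s_idx] = 1
        hap[flip, 2 * s_idx] = 0
        hap[flip, 2 * s_idx + 1] = 1
    out = Cohort(
        variants=cohort.variants,
        samples=cohort.samples,
        genotypes=geno,
        haplotypes=hap,
        phased=cohort.phased,
    )
    truth = truth or SimTruth(seed=seed)
    truth.autozygous_segments += [
        (sample, str(c), int(s), int(e)) for c, s, e in segs
    ]
    return out, truth


def plant_sweep(
    cohort: Cohort,
    population: str,
    core_position: int,
    carrier_fraction: float,
    extent: int,
    chrom: str | None = None,
    seed: int = 0,
) -> tuple[Cohort, SimTruth]:
    """Copy one template haplotype onto a fraction of a population's haplotypes
    over ``[core - extent, core + extent]``, creating an extended shared
    haplotype around the core in that population only."""
    if not (0 < carrier_fraction <= 1):
        raise ValueError("carrier_fraction must lie in (0, 1]")
    if cohort.haplotypes is None:
        raise ValueError("plant_sweep requires a phased cohort")
    chrom = str(chrom) if chrom is not None else str(cohort.variants["chrom"].iloc[0])
    chroms = cohort.variants["chrom"].to_numpy()
    pos = cohort.variants["pos"].to_numpy()
    span = (
        (chroms == chrom)
        & (pos >= core_position - extent)
        & (pos <= core_position + extent)
    )
    idx = np.flatnonzero(span)
    if len(idx) == 0:
        raise ValueError("no variant within `extent` of the sweep core")
    rng = np.random.default_rng(seed)
    cols = cohort.haplotype_columns(population)
    n_carriers = int(len(cols) * carrier_fraction)
    if n_carriers < 1:
        raise ValueError("carrier_fraction selects no haplotypes")
    carriers = rng.choice(cols, size=n_carriers, replace=False)
    template = cohort.haplotypes[np.ix_(idx, [carriers[0]])].copy()
    hap = cohort.haplotypes.copy()
    hap[np.ix_(idx, carriers)] = template
    geno = (hap[:, ::2] + hap[:, 1::2]).astype(np.int8)
    called = (hap[:, ::2] != MISSING) & (hap[:, 1::2] != MISSING)
    geno[~called] = MISSING
    out = Cohort(
        variants=cohort.variants,
        samples=cohort.samples,
        genotypes=geno,
        haplotypes=hap,
        phased=cohort.phased,
    )
    truth = SimTruth(
        sweep={
            "population": population,
            "chrom": chrom,
            "core_position": int(core_position),
            "carrier_fraction": float(carrier_fraction),
            "extent": int(extent),
        },
        seed=seed,
    )
    return out, truth


def write_fixture(cohort: Cohort, truth: SimTruth, directory: str) -> None:
    """Write VCF + population map + truth JSON; re-loadable via :func:`read_fixture`."""
    os.makedirs(directory, exist_ok=True)
    vcfio.write_vcf(cohort, os.path.join(directory, "cohort.vcf"))
    cohort.samples.to_csv(
        os.path.join(directory, "populations.tsv"),
        sep="\t", header=False, index=False,
    )
    with open(os.path.join(directory, "truth.json"), "w") as fh:
        json.dump(asdict(truth), fh, indent=1, sort_keys=True)


def read_fixture(directory: str) -> tuple[Cohort, SimTruth]:
    pop_map = vcfio.read_population_map(os.path.join(directory, "populations.tsv"))
    cohort = vcfio.read_vcf(
        os.path.join(directory, "cohort.vcf"), population_map=pop_map
    )
    with open(os.path.join(directory, "truth.json")) as fh:
        truth = SimTruth(**json.load(fh))
    truth.autozygous_segments = [tuple(s) for s in truth.autozygous_segments]
    return cohort, truth
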