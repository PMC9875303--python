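"""Cross-population extended haplotype homozygosity (XP-EHH) scan.

For a core variant, the site-EHH (EHHS) at an extension x is the probability
that two haplotypes drawn from the population are identical over the span
from the core to x, normalised to 1 at the core:

    hh(x) = sum_k n_k (n_k - 1) / (n (n - 1)),   EHHS(x) = hh(x) / hh(core)

where the n_k are the sizes of the haplotype classes defined by the allele
string from core to x.  iES integrates EHHS over physical distance on both
sides of the core, truncating each side where the curve first drops below a
cutoff (with the linear crossing interpolated).  XP-EHH is the genome-wide
standardised log-ratio ln(iES_A / iES_B); positive scores indicate longer
shared haplotypes - i.e. positive selection - in population A.  Two-sided
normal p-values are Bonferroni-corrected over the scanned cores, and runs
of consecutive significant cores of one sign merge into candidate regions.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import MISSING, Cohort

__all__ = ["ehhs", "ies", "xpehh_scan", "significant_regions"]

log = logging.getLogger(__name__)


def ehhs(
    haplotypes: np.ndarray,
    positions: np.ndarray,
    core: int,
    direction: str,
    stop_below: float = 0.0,
    has_missing: bool | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One half of an EHHS curve from the core outwards.

    Parameters
    ----------
    haplotypes
        (n_sites, n_haplotypes) allele matrix of one population, codes
        {0, 1} with MISSING allowed; haplotypes hitting a missing allele
        drop out of the partition from that extension onward.
    positions
        bp coordinate per site (sorted ascending).
    core
        Row index of the core variant.
    direction
        ``"left"`` or ``"right"``.
    stop_below
        Early-exit once the curve value falls below this (0 disables).

    Returns
    -------
    (distances, values) with the core itself first (distance 0, value 1).
    """
    n_total = haplotypes.shape[1]
    if n_total < 2:
        raise ValueError("need at least 2 haplotypes")
    if direction not in ("left", "right"):
        raise ValueError("direction must be 'left' or 'right'")
    step = 1 if direction == "right" else -1

    if has_missing is None:
        has_missing = bool((haplotypes == MISSING).any())
    core_alleles = haplotypes[core]
    alive = core_alleles != MISSING
    # haplotype classes as index groups; singletons never regain identity,
    # so only groups of size >= 2 are carried along
    groups = [
        np.flatnonzero(alive & (core_alleles == a)) for a in (0, 1)
    ]
    groups = [g for g in groups if len(g) >= 2]
    n = int(alive.sum())
    hh0 = _hh(groups, n)
    if hh0 == 0:
        hh0 = 1.0  # all-singleton core partition; curve is 0 beyond the core
    dists = [0.0]
    vals = [1.0]
    i = core + step
    while 0 <= i < haplotypes.shape[0] and groups:
        a = haplotypes[i]
        if has_missing:
            dead = alive & (a == MISSING)
            if dead.any():
                alive &= ~dead
                n = int(alive.sum())
                if n < 2:
                    break
        nxt = []
        for g in groups:
            ag = a[g]
            if has_missing:
                keep = ag != MISSING
                g = g[keep]
                ag = ag[keep]
            sub = g[ag == 1]
            if len(sub) >= 2:
                nxt.append(sub)
            if len(g) - len(sub) >= 2:
                nxt.append(g[ag == 0])
        groups = nxt
        v = _hh(groups, n) / hh0
        dists.append(abs(float(positions[i] - positions[core])))
        vals.append(v)
        if v == 0.0 or (stop_below > 0 and v < stop_below):
            break
        i += step
    return np.array(dists), np.array(vals)


def _hh(groups: list, n: int) -> float:
    if n < 2:
        return 0.0
    return float(sum(len(g) * (len(g) - 1) for g in groups) / (n * (n - 1)))


def ies(
    left: tuple[np.ndarray, np.ndarray],
    right: tuple[np.ndarray, np.ndarray],
    cutoff: float = 0.05,
) -> float:
    """Integrated EHHS (bp): trapezoid integral of both curve halves, each
    truncated at the interpolated crossing of ``cutoff``."""
    return _ies_half(*left, cutoff) + _ies_half(*right, cutoff)


def _ies_half(dists: np.ndarray, vals: np.ndarray, cutoff: float) -> float:
    total = 0.0
    for k in range(1, len(dists)):
        d0, d1 = dists[k - 1], dists[k]
        v0, v1 = vals[k - 1], vals[k]
        if v1 < cutoff:
            # linear interpolation of the cutoff crossing
            x = d0 + (v0 - cutoff) / (v0 - v1) * (d1 - d0) if v0 > v1 else d0
            total += (v0 + cutoff) / 2.0 * (x - d0)
            return total
        total += (v0 + v1) / 2.0 * (d1 - d0)
    return total


def xpehh_scan(
    cohort: Cohort,
    pop_a: str,
    pop_b: str,
    cutoff: float = 0.05,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """XP-EHH over every variant segregating in either population.

    Returns a table (chrom, pos, ies_a, ies_b, raw, z, p, p_bonf,
    significant); ``raw`` is ln(iES_A / iES_B), ``z`` its genome-wide
    standardisation.  Cores where either integral is zero are skipped with
    a log entry.
    """
    if cohort.haplotypes is None:
        raise ValueError("XP-EHH requires phased haplotypes")
    cols_a = cohort.haplotype_columns(pop_a)
    cols_b = cohort.haplotype_columns(pop_b)
    ac_a = cohort.allele_counts(pop_a)
    ac_b = cohort.allele_counts(pop_b)
    seg = ((ac_a.n_alt > 0) & (ac_a.n_alt < ac_a.n)) | (
        (ac_b.n_alt > 0) & (ac_b.n_alt < ac_b.n)
    )
    chroms = cohort.variants["chrom"].to_numpy()
    pos_all = cohort.variants["pos"].to_numpy()

    rows = []
    for chrom in dict.fromkeys(chroms):
        cmask = chroms == chrom
        idx = np.flatnonzero(cmask & seg)
        if len(idx) == 0:
            continue
        # restrict matrices to this chromosome for locality
        sub = np.flatnonzero(cmask)
        hap_a = cohort.haplotypes[np.ix_(sub, cols_a)]
        hap_b = cohort.haplotypes[np.ix_(sub, cols_b)]
        pos = pos_all[sub]
        local = np.searchsorted(sub, idx)
        miss = (
            bool((hap_a == MISSING).any()),
            bool((hap_b == MISSING).any()),
        )
        for li, gi in zip(local, idx):
            vals = []
            for hap, hm in zip((hap_a, hap_b), miss):
                l = ehhs(hap, pos, li, "left", stop_below=cutoff, has_missing=hm)
                r = ehhs(hap, pos, li, "right", stop_below=cutoff, has_missing=hm)
                vals.append(ies(l, r, cutoff))
            ies_a, ies_b = vals
            if ies_a == 0.0 or ies_b == 0.0:
                log.info(
                    "skipping core %s:%d with zero iES", chrom, pos_all[gi]
                )
                continue
            rows.append(
                {
                    "chrom": chrom,
                    "pos": int(pos_all[gi]),
                    "ies_a": ies_a,
                    "ies_b": ies_b,
                    # difference of logs: exact negation under A/B swap
                    "raw": math.log(ies_a) - math.log(ies_b),
                }
            )
    scan = pd.DataFrame(
        rows, columns=["chrom", "pos", "ies_a", "ies_b", "raw"]
    )
    n = len(scan)
    if n == 0:
        for c in ("z", "p", "p_bonf", "significant"):
            scan[c] = []
        return scan
    raw = scan["raw"].to_numpy()
    sd = raw.std()
    scan["z"] = (raw - raw.mean()) / sd if sd > 0 else 0.0
    scan["p"] = 2.0 * stats.norm.sf(np.abs(scan["z"]))
    scan["p_bonf"] = np.minimum(1.0, scan["p"] * n)
    scan["significant"] = scan["p_bonf"] < alpha
    return scan


def significant_regions(scan: pd.DataFrame) -> pd.DataFrame:
    """Merge consecutive significant cores of one sign into regions.

    Consecutive means adjacent rows of the scan on the same chromosome;
    direction ``"A"`` marks z > 0 (selected in population A).
    """
    rows = []
    cur = None
    for r in scan.itertuples(index=False):
        if not r.significant:
            if cur is not None:
                rows.append(cur)
                cur = None
            continue
        sign = "A" if r.z > 0 else "B"
        if cur is not None and cur["chrom"] == r.chrom and cur["direction"] == sign:
            cur["end"] = r.pos
            cur["n_snps"] += 1
        else:
            if cur is not None:
                rows.append(cur)
            cur = {
                "chrom": r.chrom, "start": r.pos, "end": r.pos,
                "n_snps": 1, "direction": sign,
            }
    if cur is not None:
        rows.append(cur)
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_snps", "direction"]
    )
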