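"""Runs of homozygosity: two-state HMM caller, F_RoH and RoH islands.

The caller decodes a per-animal sequence of hard genotype calls with a
two-state hidden Markov model, states HW (Hardy-Weinberg, outbred) and AZ
(autozygous).  With f the site's alternate-allele frequency and epsilon the
genotype-error rate, emissions are

    HW:  P(het) = 2 f (1 - f),  P(hom-ref) = (1 - f)^2 + f (1 - f) e',
         P(hom-alt) = f^2 + f (1 - f) e'
    AZ:  P(het) = epsilon,      P(hom-ref) = (1 - epsilon)(1 - f),
         P(hom-alt) = (1 - epsilon) f

(e' folds heterozygote miscalls into the HW homozygote classes; 0 by
default).  Between adjacent sites at distance d bp the chain switches with
P(HW->AZ) = 1 - exp(-alpha d) and P(AZ->HW) = 1 - exp(-beta d); beta
defaults to the assumed recombination rate of 1e-8 per bp (1 cM/Mb).
Maximal runs of the Viterbi AZ state become segments.  Genomic inbreeding
F_RoH is the summed segment length over the SNP-covered genome length, per
minimum-length class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import MISSING, AlleleCount, Cohort

__all__ = [
    "RoHModel",
    "LENGTH_CLASSES",
    "L_GENOME_CATTLE",
    "roh_call",
    "roh_call_population",
    "f_roh",
    "roh_snp_freq",
    "roh_islands",
    "viterbi2",
]

#: Default minimum-length classes for F_RoH stratification (bp).
LENGTH_CLASSES: tuple[int, ...] = (50_000, 100_000, 1_000_000, 2_000_000, 4_000_000)

#: SNP-covered autosomal genome length of the cattle reference cohort (bp).
L_GENOME_CATTLE: int = 2_487_849_970

_TINY = 1e-300


@dataclass
class RoHModel:
    """HMM parameters; rates are per bp."""

    az_enter_rate: float = 6.6e-9  # alpha: HW -> AZ
    az_exit_rate: float = 1e-8  # beta: AZ -> HW; 1 cM/Mb recombination
    error_rate: float = 0.01  # epsilon: P(het | AZ)
    het_miscall: float = 0.0  # e' folded into HW homozygote emissions

    def __post_init__(self) -> None:
        if self.az_enter_rate <= 0 or self.az_exit_rate <= 0:
            raise ValueError("transition rates must be positive")
        if not (0 <= self.error_rate < 0.5):
            raise ValueError("error_rate must lie in [0, 0.5)")

    @property
    def stationary(self) -> tuple[float, float]:
        """(P(HW), P(AZ)) of the rate-balance stationary distribution."""
        a, b = self.az_enter_rate, self.az_exit_rate
        return b / (a + b), a / (a + b)


def _emission_matrix(
    genotypes: np.ndarray, f: np.ndarray, model: RoHModel
) -> np.ndarray:
    """(n_sites, 2) emission probabilities for states (HW, AZ).

    Missing genotypes emit 1 in both states.
    """
    e = model.error_rate
    ep = model.het_miscall
    q = 1.0 - f
    hw = np.select(
        [genotypes == 0, genotypes == 1, genotypes == 2],
        [q * q + f * q * ep, 2 * f * q, f * f + f * q * ep],
        default=1.0,
    )
    az = np.select(
        [genotypes == 0, genotypes == 1, genotypes == 2],
        [(1 - e) * q, np.full_like(f, e), (1 - e) * f],
        default=1.0,
    )
    return np.column_stack([hw, az])


def _log_transitions(dist: np.ndarray, model: RoHModel) -> np.ndarray:
    """(n-1, 2, 2) log transition matrices for the gaps between sites."""
    p_enter = -np.expm1(-model.az_enter_rate * dist)  # 1 - exp(-a d)
    p_exit = -np.expm1(-model.az_exit_rate * dist)
    t = np.empty((len(dist), 2, 2))
    t[:, 0, 0] = np.log(np.maximum(1 - p_enter, _TINY))
    t[:, 0, 1] = np.log(np.maximum(p_enter, _TINY))
    t[:, 1, 0] = np.log(np.maximum(p_exit, _TINY))
    t[:, 1, 1] = np.log(np.maximum(1 - p_exit, _TINY))
    return t


def viterbi2(
    log_start: np.ndarray, log_trans: np.ndarray, log_emit: np.ndarray
) -> np.ndarray:
    """Viterbi decoding of a 2-state chain with per-step transition matrices.

    ``log_trans`` has shape (n-1, 2, 2); returns the maximum-probability
    state path (0 = HW, 1 = AZ).  Ties resolve toward state 0.
    """
    n = log_emit.shape[0]
    delta = log_start + log_emit[0]
    back = np.zeros((n, 2), dtype=np.int8)
    for t in range(1, n):
        cand = delta[:, None] + log_trans[t - 1]  # [from, to]
        back[t] = np.argmax(cand, axis=0)
        delta = cand[back[t], [0, 1]] + log_emit[t]
    path = np.empty(n, dtype=np.int8)
    path[-1] = int(np.argmax(delta))
    for t in range(n - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def _posteriors(
    start: np.ndarray, log_trans: np.ndarray, emit: np.ndarray
) -> np.ndarray:
    """Scaled forward-backward; returns per-site P(AZ)."""
    n = emit.shape[0]
    trans = np.exp(log_trans)
    fwd = np.empty((n, 2))
    scale = np.empty(n)
    a = start * emit[0]
    scale[0] = a.sum()
    fwd[0] = a / scale[0]
    for t in range(1, n):
        a = (fwd[t - 1] @ trans[t - 1]) * emit[t]
        scale[t] = a.sum()
        fwd[t] = a / scale[t]
    bwd = np.ones(2)
    post = np.empty(n)
    post[-1] = fwd[-1, 1]
    for t in range(n - 2, -1, -1):
        bwd = trans[t] @ (emit[t + 1] * bwd)
        bwd /= scale[t + 1]
        p = fwd[t] * bwd
        post[t] = p[1] / p.sum()
    return post


def roh_call(
    cohort: Cohort,
    sample: str,
    freqs: AlleleCount | None = None,
    model: RoHModel | None = None,
) -> pd.DataFrame:
    """Call RoH segments for one animal.

    ``freqs`` supplies the per-site allele counts used for the emission
    frequencies (typically the animal's population, or the whole cohort);
    defaults to cohort-wide counts.  Sites with no called allele in
    ``freqs`` are skipped.  Returns a table with columns ``sample_id,
    chrom, start, end, length, n_snps, mean_posterior``.
    """
    model = model or RoHModel()
    ac = freqs if freqs is not None else cohort.allele_counts()
    s_all = cohort.samples["sample_id"]
    hits = np.flatnonzero((s_all == sample).to_numpy())
    if len(hits) == 0:
        raise KeyError(f"unknown sample {sample!r}")
    s = int(hits[0])

    segments = []
    chroms = cohort.variants["chrom"].to_numpy()
    pos_all = cohort.variants["pos"].to_numpy()
    n_ok = ac.n > 0
    p_all = ac.p
    log_start = np.log(np.array(model.stationary))
    for chrom in dict.fromkeys(chroms):
        mask = (chroms == chrom) & n_ok
        idx = np.flatnonzero(mask)
        if len(idx) == 0:
            continue
        pos = pos_all[idx]
        g = cohort.genotypes[idx, s]
        f = np.clip(p_all[idx], 0.0, 1.0)
        emit = _emission_matrix(g, f, model)
        log_emit = np.log(np.maximum(emit, _TINY))
        log_trans = _log_transitions(np.diff(pos).astype(float), model)
        path = viterbi2(log_start, log_trans, log_emit)
        if not path.any():
            continue
        post = _posteriors(np.array(model.stationary), log_trans, emit)
        bounds = np.flatnonzero(np.diff(np.concatenate([[0], path, [0]])))
        for a, b in zip(bounds[::2], bounds[1::2]):  # [a, b) run of AZ
            segments.append(
                {
                    "sample_id": sample,
                    "chrom": chrom,
                    "start": int(pos[a]),
                    "end": int(pos[b - 1]),
                    "length": int(pos[b - 1] - pos[a] + 1),
                    "n_snps": int(b - a),
                    "mean_posterior": float(post[a:b].mean()),
                }
            )
    return pd.DataFrame(
        segments,
        columns=[
            "sample_id", "chrom", "start", "end", "length", "n_snps",
            "mean_posterior",
        ],
    )


def roh_call_population(
    cohort: Cohort,
    population: str,
    model: RoHModel | None = None,
    freq_scope: str = "population",
) -> pd.DataFrame:
    """RoH segments for every animal of a population (concatenated)."""
    ac = cohort.allele_counts(
        population if freq_scope == "population" else None
    )
    idx = cohort.sample_indices(population)
    parts = [
        roh_call(cohort, cohort.samples["sample_id"].iloc[s], ac, model)
        for s in idx
    ]
    parts = [p for p in parts if len(p)]
    if not parts:
        return roh_call(
            cohort, cohort.samples["sample_id"].iloc[idx[0]], ac, model
        ).iloc[:0]
    return pd.concat(parts, ignore_index=True)


def f_roh(
    segments: pd.DataFrame,
    classes: tuple[int, ...] = LENGTH_CLASSES,
    l_genome: int = L_GENOME_CATTLE,
) -> dict[int, float]:
    """F_RoH = sum(L_RoH) / L_genome per minimum-length class."""
    if l_genome <= 0:
        raise ValueError("l_genome must be positive")
    lengths = segments["length"].to_numpy() if len(segments) else np.array([])
    return {
        int(c): float(lengths[lengths >= c].sum() / l_genome) for c in classes
    }


def roh_snp_freq(segments: pd.DataFrame, cohort: Cohort, population: str) -> pd.DataFrame:
    """Per-variant fraction of a population's animals with a RoH covering it."""
    idx = cohort.sample_indices(population)
    n_animals = len(idx)
    chroms = cohort.variants["chrom"].to_numpy()
    pos = cohort.variants["pos"].to_numpy()
    count = np.zeros(cohort.n_variants, dtype=int)
    sample_ids = set(cohort.samples["sample_id"].iloc[idx])
    for sid, grp in segments.groupby("sample_id"):
        if sid not in sample_ids:
            continue
        covered = np.zeros(cohort.n_variants, dtype=bool)
        for seg in grp.itertuples(index=False):
            covered |= (
                (chroms == seg.chrom) & (pos >= seg.start) & (pos <= seg.end)
            )
        count += covered
    return pd.DataFrame(
        {
            "chrom": chroms,
            "pos": pos,
            "frequency": count / n_animals,
        }
    )


def roh_islands(
    freqs: pd.DataFrame,
    top_fraction: float = 0.0005,
    max_gap: int = 100_000,
) -> tuple[float, pd.DataFrame]:
    """Population-level RoH islands from the SNP-in-RoH frequency table.

    The ceil(top_fraction * N) highest frequencies define membership; the
    reported threshold is the smallest member value (ties at the threshold
    are all included).  Consecutive member SNPs on one chromosome separated
    by at most ``max_gap`` bp merge into one island; internal gaps larger
    than the median member spacing are recorded as a count.
    """
    vals = freqs["frequency"].to_numpy()
    n = len(vals)
    if n == 0:
        raise ValueError("empty frequency table")
    m = max(1, math.ceil(top_fraction * n))
    threshold = float(np.sort(vals)[::-1][m - 1])
    if np.all(vals == vals[0]):
        import warnings

        warnings.warn("all SNP-in-RoH frequencies are equal; islands cover all SNPs")
    members = freqs[vals >= threshold].sort_values(["chrom", "pos"])

    rows = []
    for chrom, grp in members.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        fr = grp["frequency"].to_numpy()
        breaks = np.flatnonzero(np.diff(pos) > max_gap)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [len(pos) - 1]])
        for a, b in zip(starts, ends):
            gaps = np.diff(pos[a : b + 1])
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(pos[a]),
                    "end": int(pos[b]),
                    "n_snps": int(b - a + 1),
                    "peak_frequency": float(fr[a : b + 1].max()),
                    "max_internal_gap": int(gaps.max()) if len(gaps) else 0,
                }
            )
    return threshold, pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "n_snps", "peak_frequency",
            "max_internal_gap",
        ],
    )
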