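"""Between-population differentiation, phylogeny, kinship and admixture tests.

Hudson's F_ST estimator is applied per site,

    N = (p1 - p2)^2 - p1 q1 / (n1 - 1) - p2 q2 / (n2 - 1)
    D = p1 (1 - p2) + p2 (1 - p1),

and aggregated as a ratio of averages (sum N / sum D), the form recommended
for unequal sample sizes.  The module also provides Manhattan-distance UPGMA
dendrograms with breed-clade curation, the VanRaden (method 1) genomic
relationship matrix with greedy least-related subset selection, and the f3
admixture statistic with a block jackknife over consecutive variant blocks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import MISSING, AlleleCount, Cohort
from .vcfio import segregating_subset

__all__ = [
    "hudson_site",
    "fst_genomewide",
    "fst_matrix",
    "fst_windows",
    "top_fraction_windows",
    "manhattan_matrix",
    "Node",
    "upgma",
    "to_newick",
    "from_newick",
    "prune_outlier_animals",
    "grm",
    "least_related_subset",
    "f3",
    "F3Result",
]


# --------------------------------------------------------------------------
# Hudson F_ST
# --------------------------------------------------------------------------

def hudson_site(ac1: AlleleCount, ac2: AlleleCount) -> tuple[np.ndarray, np.ndarray]:
    """Per-site Hudson numerator and denominator (vectorised).

    Sites with fewer than two called alleles in either population get
    N = D = 0 and thus drop out of any ratio of sums.
    """
    n1 = ac1.n.astype(float)
    n2 = ac2.n.astype(float)
    usable = (n1 >= 2) & (n2 >= 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        p1, p2 = ac1.p, ac2.p
        num = (
            (p1 - p2) ** 2
            - p1 * (1 - p1) / (n1 - 1)
            - p2 * (1 - p2) / (n2 - 1)
        )
        den = p1 * (1 - p2) + p2 * (1 - p1)
    num = np.where(usable, num, 0.0)
    den = np.where(usable, den, 0.0)
    return num, den


def fst_genomewide(
    cohort: Cohort, pop_a: str, pop_b: str, presubset: bool = True
) -> float:
    """Genome-wide Hudson F_ST between two populations (ratio of averages).

    By default the cohort is first restricted to variants segregating in the
    pool of the two populations.
    """
    if presubset:
        cohort = segregating_subset(cohort, [pop_a, pop_b])
    num, den = hudson_site(
        cohort.allele_counts(pop_a), cohort.allele_counts(pop_b)
    )
    total_d = den.sum()
    if total_d == 0:
        raise ValueError("no usable site for F_ST")
    return float(num.sum() / total_d)


def fst_matrix(cohort: Cohort, focal: str, others: list[str]) -> pd.DataFrame:
    """Pairwise focal-vs-other F_ST table, sorted ascending."""
    rows = [
        {"population": o, "fst": fst_genomewide(cohort, focal, o)}
        for o in others
    ]
    return (
        pd.DataFrame(rows)
        .sort_values("fst", kind="stable")
        .reset_index(drop=True)
    )


def fst_windows(
    cohort: Cohort,
    pop_a: str,
    pop_b: str,
    window_bp: int = 10_000,
    min_snps: int = 5,
    presubset: bool = True,
) -> pd.DataFrame:
    """Windowed Hudson F_ST; windows with fewer than ``min_snps`` usable
    variants are omitted."""
    if presubset:
        cohort = segregating_subset(cohort, [pop_a, pop_b])
    num, den = hudson_site(
        cohort.allele_counts(pop_a), cohort.allele_counts(pop_b)
    )
    usable = (den != 0) | (num != 0)
    chroms = cohort.variants["chrom"].to_numpy()
    pos = cohort.variants["pos"].to_numpy()
    rows = []
    for chrom in dict.fromkeys(chroms):
        mask = (chroms == chrom) & usable
        p = pos[mask]
        if len(p) == 0:
            continue
        win = (p - 1) // window_bp
        for w in np.unique(win):
            sel = win == w
            if sel.sum() < min_snps:
                continue
            d = den[mask][sel].sum()
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(w * window_bp + 1),
                    "end": int((w + 1) * window_bp),
                    "n_snps": int(sel.sum()),
                    "value": float(num[mask][sel].sum() / d) if d else math.nan,
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_snps", "value"])


def top_fraction_windows(
    windows: pd.DataFrame, top_fraction: float = 0.0001
) -> tuple[float, pd.DataFrame]:
    """Top-percentile window selection with adjacent-window merging.

    Selects the ceil(top_fraction * N) highest-value windows; the threshold
    reported is the smallest selected value.  Selected windows that tile
    consecutively on a chromosome merge into one region.
    """
    n = len(windows)
    if n == 0:
        raise ValueError("empty window table")
    m = max(1, math.ceil(top_fraction * n))
    order = np.argsort(windows["value"].to_numpy(), kind="stable")[::-1][:m]
    threshold = float(windows["value"].to_numpy()[order[-1]])
    sel = windows.iloc[np.sort(order)].sort_values(["chrom", "start"])
    rows = []
    cur = None
    for w in sel.itertuples(index=False):
        if cur is not None and w.chrom == cur["chrom"] and w.start == cur["end"] + 1:
            cur["end"] = w.end
            cur["n_windows"] += 1
            cur["max_value"] = max(cur["max_value"], w.value)
        else:
            if cur is not None:
                rows.append(cur)
            cur = {
                "chrom": w.chrom, "start": w.start, "end": w.end,
                "n_windows": 1, "max_value": w.value,
            }
    if cur is not None:
        rows.append(cur)
    return threshold, pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_windows", "max_value"]
    )


# --------------------------------------------------------------------------
# Distances and UPGMA
# --------------------------------------------------------------------------

def manhattan_matrix(cohort: Cohort) -> tuple[np.ndarray, list[str]]:
    """Pairwise Manhattan distances between animals over dosage codes.

    Pairwise-complete sites only; each distance is rescaled by
    (total sites / complete sites) to stay comparable under missingness.
    """
    g = cohort.genotypes.astype(float)
    g[cohort.genotypes == MISSING] = np.nan
    n = cohort.n_samples
    total = cohort.n_variants
    d = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(g[:, i, None] - g[:, i + 1 :])
        complete = (~np.isnan(diff)).sum(axis=0)
        if np.any(complete == 0):
            raise ValueError("a sample pair shares no called site")
        d[i, i + 1 :] = np.nansum(diff, axis=0) * (total / complete)
    return d + d.T, list(cohort.samples["sample_id"])


@dataclass
class Node:
    """Rooted ultrametric dendrogram node; leaves carry labels at height 0."""

    height: float = 0.0
    label: str | None = None
    children: tuple = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]
        out = []
        for c in self.children:
            out += c.leaves()
        return out


def upgma(dist: np.ndarray, labels: list[str]) -> Node:
    """Size-weighted average-linkage (UPGMA) clustering.

    At each step the closest cluster pair merges at height d/2; the distance
    of the merged cluster to any other is the size-weighted mean.  Tied
    minima resolve by the lexicographically smallest pair of cluster
    representative labels (a cluster is represented by its smallest leaf
    label), making the tree deterministic.
    """
    dist = np.asarray(dist, dtype=float)
    if dist.shape != (len(labels), len(labels)) or len(labels) < 2:
        raise ValueError("need a square matrix over >= 2 labels")
    clusters = {i: Node(label=labels[i]) for i in range(len(labels))}
    sizes = {i: 1 for i in range(len(labels))}
    reps = {i: labels[i] for i in range(len(labels))}
    d = {
        (i, j): dist[i, j]
        for i in range(len(labels))
        for j in range(i + 1, len(labels))
    }
    nxt = len(labels)
    while len(clusters) > 1:
        best = min(
            d.items(),
            key=lambda kv: (kv[1], tuple(sorted((reps[kv[0][0]], reps[kv[0][1]])))),
        )
        (i, j), dij = best
        node = Node(height=dij / 2.0, children=(clusters[i], clusters[j]))
        clusters.pop(i), clusters.pop(j)
        for k in list(clusters):
            a = d.pop((min(i, k), max(i, k)))
            b = d.pop((min(j, k), max(j, k)))
            d[(k, nxt)] = (sizes[i] * a + sizes[j] * b) / (sizes[i] + sizes[j])
        d.pop((i, j))
        clusters[nxt] = node
        sizes[nxt] = sizes[i] + sizes[j]
        reps[nxt] = min(reps[i], reps[j])
        nxt += 1
    return next(iter(clusters.values()))


def to_newick(tree: Node) -> str:
    """Newick string with branch lengths = parent height - child height."""

    def fmt(node: Node, parent_height: float) -> str:
        bl = parent_height - node.height
        if node.is_leaf:
            return f"{node.label}:{bl:.17g}"
        inner = ",".join(fmt(c, node.height) for c in node.children)
        return f"({inner}):{bl:.17g}"

    if tree.is_leaf:
        return f"{tree.label};"
    inner = ",".join(fmt(c, tree.height) for c in tree.children)
    return f"({inner});"


class NewickError(ValueError):
    pass


def from_newick(text: str) -> Node:
    """Parse a Newick string back into a dendrogram (heights from root)."""
    text = text.strip()
    if not text.endswith(";"):
        raise NewickError("missing terminating ';'")
    s = text[:-1]
    pos = 0

    def parse() -> tuple:
        nonlocal pos
        if pos < len(s) and s[pos] == "(":
            pos += 1
            children = [parse()]
            while pos < len(s) and s[pos] == ",":
                pos += 1
                children.append(parse())
            if pos >= len(s) or s[pos] != ")":
                raise NewickError(f"unbalanced parenthesis at position {pos}")
            pos += 1
            label, bl = parse_label()
            return ("internal", children, label, bl)
        label, bl = parse_label()
        if label == "" :
            raise NewickError(f"empty leaf label at position {pos}")
        return ("leaf", [], label, bl)

    def parse_label() -> tuple[str, float]:
        nonlocal pos
        start = pos
        while pos < len(s) and s[pos] not in ",():":
            pos += 1
        label = s[start:pos]
        bl = 0.0
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and s[pos] not in ",()":
                pos += 1
            try:
                bl = float(s[start:pos])
            except ValueError as err:
                raise NewickError(f"bad branch length at position {start}") from err
        return label, bl

    ast = parse()
    if pos != len(s):
        raise NewickError(f"trailing characters at position {pos}")

    def depth(node) -> float:
        kind, children, _, _ = node
        if kind == "leaf":
            return 0.0
        return max(c[3] + depth(c) for c in children)

    root_height = depth(ast)

    def build(node, height: float) -> Node:
        kind, children, label, _ = node
        if kind == "leaf":
            return Node(height=0.0, label=label or None)
        return Node(
            height=height,
            children=tuple(build(c, height - c[3]) for c in children),
        )

    return build(ast, root_height)


def prune_outlier_animals(
    tree: Node, breed_of: dict[str, str]
) -> tuple[list[str], list[str], Node]:
    """Keep, per breed, only the largest clade whose leaves are all that breed.

    Animals of a breed falling outside their breed's largest pure clade are
    removed; surviving pure clades collapse to a single leaf carrying the
    breed name.  Returns (kept sample ids, removed sample ids, collapsed
    tree).
    """
    best: dict[str, tuple[int, str, Node]] = {}

    def scan(node: Node) -> str | None:
        """Return the breed if the clade is pure, else None; record maxima."""
        if node.is_leaf:
            breed = breed_of[node.label]
            key = (1, min(node.leaves()))
            _consider(breed, key, node)
            return breed
        child_breeds = [scan(c) for c in node.children]
        if all(b is not None and b == child_breeds[0] for b in child_breeds):
            breed = child_breeds[0]
            leaves = node.leaves()
            _consider(breed, (len(leaves), min(leaves)), node)
            return breed
        return None

    def _consider(breed: str, key, node: Node) -> None:
        # larger clade wins; ties by smallest leaf label for determinism
        size, rep = key
        cur = best.get(breed)
        if cur is None or size > cur[0] or (size == cur[0] and rep < cur[1]):
            best[breed] = (size, rep, node)

    scan(tree)
    kept: list[str] = []
    keep_nodes = {id(v[2]): b for b, v in best.items()}
    for _, _, node in best.values():
        kept += node.leaves()
    removed = [l for l in tree.leaves() if l not in set(kept)]

    def collapse(node: Node) -> Node | None:
        if id(node) in keep_nodes:
            return Node(height=0.0, label=keep_nodes[id(node)])
        if node.is_leaf:
            return None  # outlier leaf
        children = [c for c in (collapse(c) for c in node.children) if c is not None]
        if not children:
            return None
        if len(children) == 1:
            return children[0]
        return Node(height=node.height, children=tuple(children))

    collapsed = collapse(tree)
    return sorted(kept), sorted(removed), collapsed


# --------------------------------------------------------------------------
# GRM and subset selection
# --------------------------------------------------------------------------

def grm(cohort: Cohort) -> tuple[np.ndarray, list[str]]:
    """VanRaden method-1 genomic relationship matrix.

    Dosages are centered by twice the cohort allele frequency and the cross
    product scaled by 2 sum p (1 - p); monomorphic sites are excluded and
    missing dosages contribute zero after centering.
    """
    ac = cohort.allele_counts()
    p = ac.p
    poly = (ac.n > 0) & (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all sites monomorphic; GRM undefined")
    g = cohort.genotypes[poly].astype(float)
    pm = p[poly]
    z = g - 2 * pm[:, None]
    z[g == MISSING] = 0.0
    denom = 2 * np.sum(pm * (1 - pm))
    return (z.T @ z) / denom, list(cohort.samples["sample_id"])


def least_related_subset(
    grm_matrix: np.ndarray, labels: list[str], k: int = 50, seed: int = 0
) -> list[str]:
    """Greedy least-related subset from a GRM.

    Starts at a seeded random animal, then repeatedly adds the animal with
    the smallest mean relationship to the current set (ties by label).
    """
    n = len(labels)
    if k > n:
        raise ValueError("k exceeds the number of animals")
    rng = np.random.default_rng(seed)
    chosen = [int(rng.integers(n))]
    rel_sum = grm_matrix[chosen[0]].astype(float).copy()
    in_set = np.zeros(n, dtype=bool)
    in_set[chosen[0]] = True
    order = np.argsort(np.array(labels), kind="stable")  # label tie-break
    rank = np.empty(n, dtype=int)
    rank[order] = np.arange(n)
    while len(chosen) < k:
        mean_rel = np.where(in_set, np.inf, rel_sum / len(chosen))
        m = mean_rel.min()
        cand = np.flatnonzero(mean_rel == m)
        pick = int(cand[np.argmin(rank[cand])])
        chosen.append(pick)
        in_set[pick] = True
        rel_sum += grm_matrix[pick]
    return [labels[i] for i in chosen]


# --------------------------------------------------------------------------
# f3
# --------------------------------------------------------------------------

@dataclass
class F3Result:
    f3: float
    se: float
    z: float
    n_blocks: int
    block_variants: int
    n_sites: int


def f3(
    cohort: Cohort,
    target: str,
    source_a: str,
    source_b: str,
    block_variants: int = 10_000,
) -> F3Result:
    """f3(target; A, B) with block-jackknife standard error.

    Per usable site the statistic is
    (p_C - p_A)(p_C - p_B) - p_C (1 - p_C) / (n_C - 1)
    (heterozygosity bias correction for the target only); f3 is the mean
    over sites and the SE comes from a leave-one-block-out jackknife over
    consecutive blocks of ``block_variants`` variants.
    """
    ac_c = cohort.allele_counts(target)
    ac_a = cohort.allele_counts(source_a)
    ac_b = cohort.allele_counts(source_b)
    usable = (ac_c.n >= 2) & (ac_a.n >= 1) & (ac_b.n >= 1)
    pc, pa, pb = ac_c.p[usable], ac_a.p[usable], ac_b.p[usable]
    nc = ac_c.n[usable].astype(float)
    terms = (pc - pa) * (pc - pb) - pc * (1 - pc) / (nc - 1)
    n_sites = len(terms)
    n_blocks = math.ceil(n_sites / block_variants)
    if n_blocks < 2:
        raise ValueError("need at least 2 jackknife blocks")
    total = terms.sum()
    est = total / n_sites
    jack = np.empty(n_blocks)
    for j in range(n_blocks):
        sl = slice(j * block_variants, min((j + 1) * block_variants, n_sites))
        m = sl.stop - sl.start
        jack[j] = (total - terms[sl].sum()) / (n_sites - m)
    se = float(np.sqrt((n_blocks - 1) / n_blocks * ((jack - jack.mean()) ** 2).sum()))
    return F3Result(
        f3=float(est),
        se=se,
        z=float(est / se) if se > 0 else math.nan,
        n_blocks=n_blocks,
        block_variants=block_variants,
        n_sites=n_sites,
    )
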