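"""Region post-processing, interval annotation and end-to-end orchestration.

Internal and reported coordinates are 1-based inclusive; BED import/export
converts to/from 0-based half-open in one place (:func:`to_bed` /
:func:`from_bed`).  :func:`run_config` drives the whole pipeline from a YAML
configuration and writes deterministic TSV/Newick/JSON outputs.
"""

from __future__ import annotations

import json
import logging
import os
import warnings

import numpy as np
import pandas as pd
import yaml

from . import diversity, relate, roh as roh_mod, sweep, vcfio
from .cohort import Cohort

__all__ = [
    "flank_regions",
    "annotate_regions",
    "to_bed",
    "from_bed",
    "read_bed",
    "read_gff3_genes",
    "read_qtl_bed",
    "run_config",
    "QTL_TRAIT_CLASSES",
]

log = logging.getLogger(__name__)

#: Trait classes of QTL annotations retained by default.
QTL_TRAIT_CLASSES = frozenset(
    {"production", "exterior", "meat", "milk", "health", "reproduction"}
)

_FLOAT_FMT = "%.8g"


# --------------------------------------------------------------------------
# coordinate conversions (centralised)
# --------------------------------------------------------------------------

def to_bed(regions: pd.DataFrame, path: str, extra: list[str] | None = None) -> None:
    """Write 1-based inclusive regions as 0-based half-open BED."""
    out = regions.copy()
    out["start"] = out["start"].astype(int) - 1
    cols = ["chrom", "start", "end"] + (extra or [])
    out[cols].to_csv(path, sep="\t", header=False, index=False)


def from_bed(path: str) -> pd.DataFrame:
    """Read a BED file into 1-based inclusive coordinates."""
    df = read_bed(path)
    return df


def read_bed(path: str) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"][
            : _n_bed_cols(path)
        ],
        dtype={"chrom": str},
    )
    df["start"] = df["start"].astype(int) + 1  # to 1-based inclusive
    df["end"] = df["end"].astype(int)
    return df


def _n_bed_cols(path: str) -> int:
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                return min(6, len(line.rstrip("\n").split("\t")))
    return 3


def read_gff3_genes(path: str, feature_types: tuple = ("gene",)) -> pd.DataFrame:
    """Extract gene intervals (1-based inclusive) and names from a GFF3 file."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] not in feature_types:
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            rows.append(
                {
                    "chrom": parts[0],
                    "start": int(parts[3]),
                    "end": int(parts[4]),
                    "name": attrs.get("Name", attrs.get("ID", ".")),
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def read_qtl_bed(path: str) -> pd.DataFrame:
    """BED with the QTL trait class in column 4."""
    df = read_bed(path)
    if "name" not in df.columns:
        raise ValueError("QTL BED requires a 4th (trait class) column")
    return df.rename(columns={"name": "trait_class"})


# --------------------------------------------------------------------------
# region flanking and annotation
# --------------------------------------------------------------------------

def flank_regions(
    regions: pd.DataFrame, flank: int = 250_000, chrom_sizes: dict[str, int] | None = None
) -> pd.DataFrame:
    """Extend regions by ``flank`` bp both ways, clamped to [1, L_chrom].

    The original bounds are retained as ``core_start``/``core_end`` for
    inside-vs-flank classification.
    """
    out = regions.copy()
    sizes = {str(k): int(v) for k, v in (chrom_sizes or {}).items()}
    if sizes:
        for r in out.itertuples(index=False):
            if str(r.chrom) not in sizes:
                raise ValueError(f"no chromosome length for {r.chrom!r}")
            if r.end > sizes[str(r.chrom)]:
                raise ValueError(
                    f"region {r.chrom}:{r.start}-{r.end} beyond chromosome end"
                )
    out["core_start"] = out["start"]
    out["core_end"] = out["end"]
    out["start"] = np.maximum(1, out["start"] - flank)
    if sizes:
        out["end"] = [
            min(sizes[str(c)], e + flank)
            for c, e in zip(out["chrom"], out["end"])
        ]
    else:
        out["end"] = out["end"] + flank
    return out


def _overlaps(a_start, a_end, b_start, b_end) -> bool:
    return a_start <= b_end and b_start <= a_end


def annotate_regions(
    regions: pd.DataFrame,
    genes: pd.DataFrame | None = None,
    qtls: pd.DataFrame | None = None,
    qtl_max_len: int = 10_000,
    trait_classes: frozenset = QTL_TRAIT_CLASSES,
) -> pd.DataFrame:
    """Intersect (flanked) regions with gene and QTL intervals.

    Genes are classed ``inside`` when they overlap the unflanked core
    (``core_start``/``core_end``; absent columns fall back to the region
    span) and ``flank`` otherwise.  QTLs must be shorter than
    ``qtl_max_len`` (strict) and carry a recognised trait class; hits with
    unknown classes are dropped with a warning.
    """
    hits = []
    for r in regions.itertuples(index=False):
        core_s = getattr(r, "core_start", r.start)
        core_e = getattr(r, "core_end", r.end)
        if genes is not None:
            sub = genes[genes["chrom"].astype(str) == str(r.chrom)]
            for g in sub.itertuples(index=False):
                if not _overlaps(r.start, r.end, g.start, g.end):
                    continue
                klass = (
                    "inside"
                    if _overlaps(core_s, core_e, g.start, g.end)
                    else "flank"
                )
                hits.append(
                    {
                        "chrom": r.chrom, "region_start": core_s,
                        "region_end": core_e, "feature": g.name,
                        "feature_type": "gene", "overlap": klass,
                        "trait_class": ".",
                    }
                )
        if qtls is not None:
            sub = qtls[qtls["chrom"].astype(str) == str(r.chrom)]
            for q in sub.itertuples(index=False):
                if q.end - q.start + 1 >= qtl_max_len:
                    continue
                if not _overlaps(r.start, r.end, q.start, q.end):
                    continue
                if q.trait_class not in trait_classes:
                    warnings.warn(
                        f"unknown QTL trait class {q.trait_class!r}; hit dropped"
                    )
                    continue
                klass = (
                    "inside"
                    if _overlaps(core_s, core_e, q.start, q.end)
                    else "flank"
                )
                hits.append(
                    {
                        "chrom": r.chrom, "region_start": core_s,
                        "region_end": core_e,
                        "feature": f"{q.chrom}:{q.start}-{q.end}",
                        "feature_type": "qtl", "overlap": klass,
                        "trait_class": q.trait_class,
                    }
                )
    return pd.DataFrame(
        hits,
        columns=[
            "chrom", "region_start", "region_end", "feature", "feature_type",
            "overlap", "trait_class",
        ],
    )


# --------------------------------------------------------------------------
# orchestration
# --------------------------------------------------------------------------

def _write(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def run_config(config: str | dict) -> str:
    """Run the configured stages on a VCF cohort; returns the output directory.

    Stages execute in dependency order: filter -> diversity / fst /
    fst_windows / roh / islands / tree / xpehh -> annotate.  All randomness
    derives from the single configured seed and every table is written with
    a fixed float format, so reruns are byte-identical.
    """
    if isinstance(config, str):
        with open(config) as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = dict(config)

    out_dir = cfg.get("output_dir", "herdscan_out")
    os.makedirs(out_dir, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    stages = list(cfg.get("stages", []))
    params = dict(cfg.get("params", {}))

    inputs = cfg.get("inputs", {})
    for key in ("vcf", "popmap"):
        if key not in inputs:
            raise ValueError(f"stage 'load': missing required input {key!r}")
    pop_map = vcfio.read_population_map(inputs["popmap"])
    cohort = vcfio.read_vcf(inputs["vcf"], population_map=pop_map)
    chrom_sizes = (
        vcfio.read_chrom_sizes(inputs["chrom_sizes"])
        if "chrom_sizes" in inputs
        else None
    )

    run_log: dict = {"seed": seed, "stages": stages, "params": params}
    filt = cfg.get("filter", {})
    cohort = vcfio.filter_variants(
        cohort,
        min_call_rate=float(filt.get("min_call_rate", 0.95)),
        biallelic_only=bool(filt.get("biallelic_only", True)),
        autosomes=filt.get("autosomes"),
    )
    run_log["n_variants_after_filter"] = cohort.n_variants
    run_log["n_samples"] = cohort.n_samples

    focal = params.get("focal_pop", cohort.populations[0])
    others = params.get(
        "other_pops", [p for p in cohort.populations if p != focal]
    )
    contrast = params.get("contrast_pop", others[0] if others else None)
    window_bp = int(params.get("window_bp", 10_000))
    collected_regions: list[pd.DataFrame] = []

    if "prune" in stages:
        pr = cfg.get("prune", {})
        kept = vcfio.ld_prune(
            cohort,
            window_snps=int(pr.get("window_snps", 50)),
            step_snps=int(pr.get("step_snps", 5)),
            r2_max=float(pr.get("r2_max", 0.6)),
        )
        run_log["n_variants_after_prune"] = int(len(kept))
        pruned = cohort.take_variants(kept)
    else:
        pruned = cohort

    if "diversity" in stages:
        denom = int(params.get("denominator", cohort.n_variants))
        rows = []
        pi_tables = []
        for pop in cohort.populations:
            win = diversity.windowed_pi(
                cohort, pop, window_bp, chrom_sizes=chrom_sizes
            )
            summ = diversity.pi_summaries(win)
            het = diversity.individual_heterozygosity(cohort, pop, denom)
            x2, p = diversity.het_chisq(
                het["o_het"].sum(),
                (het["n_used"] - het["e_hom"]).sum(),
                het["o_hom"].sum(),
                het["e_hom"].sum(),
            )
            rows.append(
                {
                    "population": pop,
                    "pi_tot_mean_pct": summ.tot_mean,
                    "pi_tot_median_pct": summ.tot_median,
                    "h_o": het["h_o"].mean(),
                    "h_e": het["h_e"].mean(),
                    "f_hom": diversity.breed_f_hom(het),
                    "het_chisq": x2,
                    "het_p": p,
                }
            )
            win.insert(0, "population", pop)
            pi_tables.append(win)
        _write(pd.DataFrame(rows), os.path.join(out_dir, "diversity_by_breed.tsv"))
        _write(pd.concat(pi_tables), os.path.join(out_dir, "pi_windows.tsv"))

    if "fst" in stages and others:
        table = relate.fst_matrix(cohort, focal, others)
        _write(table, os.path.join(out_dir, "fst_ranking.tsv"))

    if "fst_windows" in stages and contrast:
        win = relate.fst_windows(
            cohort, focal, contrast, window_bp=window_bp,
            min_snps=int(params.get("min_snps", 5)),
        )
        _write(win, os.path.join(out_dir, "fst_windows.tsv"))
        thr, regions = relate.top_fraction_windows(
            win, top_fraction=float(params.get("fst_top_fraction", 1e-4))
        )
        run_log["fst_top_threshold"] = thr
        _write(regions, os.path.join(out_dir, "fst_top_regions.tsv"))
        if len(regions):
            to_bed(regions, os.path.join(out_dir, "fst_top_regions.bed"))
            collected_regions.append(
                regions[["chrom", "start", "end"]].assign(source="fst_top")
            )

    if "roh" in stages or "islands" in stages:
        froh_rows = []
        all_segments = {}
        model = roh_mod.RoHModel(
            az_enter_rate=float(params.get("az_enter_rate", 6.6e-9)),
            az_exit_rate=float(params.get("az_exit_rate", 1e-8)),
            error_rate=float(params.get("roh_error_rate", 0.01)),
        )
        l_genome = int(
            params.get(
                "l_genome",
                sum(chrom_sizes.values()) if chrom_sizes else roh_mod.L_GENOME_CATTLE,
            )
        )
        seg_tables = []
        for pop in cohort.populations:
            segs = roh_mod.roh_call_population(cohort, pop, model)
            all_segments[pop] = segs
            if len(segs):
                seg_tables.append(segs.assign(population=pop))
            for sid, grp in segs.groupby("sample_id"):
                fr = roh_mod.f_roh(grp, l_genome=l_genome)
                froh_rows.append(
                    {"population": pop, "sample_id": sid}
                    | {f"f_roh_ge_{c}": v for c, v in fr.items()}
                )
        if seg_tables:
            _write(
                pd.concat(seg_tables, ignore_index=True),
                os.path.join(out_dir, "roh_segments.tsv"),
            )
        _write(pd.DataFrame(froh_rows), os.path.join(out_dir, "f_roh.tsv"))

        if "islands" in stages:
            isl_tables = []
            for pop, segs in all_segments.items():
                freqs = roh_mod.roh_snp_freq(segs, cohort, pop)
                thr, islands = roh_mod.roh_islands(
                    freqs,
                    top_fraction=float(params.get("island_top_fraction", 5e-4)),
                    max_gap=int(params.get("island_max_gap", 100_000)),
                )
                run_log[f"roh_island_threshold_{pop}"] = thr
                islands.insert(0, "population", pop)
                isl_tables.append(islands)
                if len(islands):
                    collected_regions.append(
                        islands[["chrom", "start", "end"]].assign(
                            source="roh_island"
                        )
                    )
            _write(
                pd.concat(isl_tables, ignore_index=True),
                os.path.join(out_dir, "roh_islands.tsv"),
            )

    if "tree" in stages:
        dist, labels = relate.manhattan_matrix(pruned)
        tree = relate.upgma(dist, labels)
        breed_of = dict(
            zip(cohort.samples["sample_id"], cohort.samples["population"])
        )
        kept, removed, collapsed = relate.prune_outlier_animals(tree, breed_of)
        with open(os.path.join(out_dir, "upgma.nwk"), "w") as fh:
            fh.write(relate.to_newick(tree) + "\n")
        with open(os.path.join(out_dir, "upgma_breeds.nwk"), "w") as fh:
            fh.write(relate.to_newick(collapsed) + "\n")
        run_log["tree_outliers_removed"] = removed

    if "f3" in stages:
        trio = params.get("f3_trio")
        if trio:
            res = relate.f3(
                cohort, trio[0], trio[1], trio[2],
                block_variants=int(params.get("f3_block_variants", 10_000)),
            )
            run_log["f3"] = {
                "target": trio[0], "sources": [trio[1], trio[2]],
                "f3": res.f3, "se": res.se, "z": res.z,
                "n_blocks": res.n_blocks,
            }

    if "xpehh" in stages and contrast:
        if cohort.haplotypes is None:
            raise ValueError(
                "stage 'xpehh' requires phased haplotypes; the input VCF is "
                "not fully phased"
            )
        scan = sweep.xpehh_scan(
            cohort, focal, contrast,
            cutoff=float(params.get("ehhs_cutoff", 0.05)),
            alpha=float(params.get("alpha", 0.05)),
        )
        _write(scan, os.path.join(out_dir, "xpehh_scan.tsv"))
        regions = sweep.significant_regions(scan)
        _write(regions, os.path.join(out_dir, "xpehh_regions.tsv"))
        if len(regions):
            collected_regions.append(
                regions[["chrom", "start", "end"]].assign(source="xpehh")
            )

    if "annotate" in stages and collected_regions:
        regions = pd.concat(collected_regions, ignore_index=True)
        flanked = flank_regions(
            regions,
            flank=int(params.get("flank", 250_000)),
            chrom_sizes=chrom_sizes,
        )
        genes = (
            read_gff3_genes(inputs["genes"])
            if str(inputs.get("genes", "")).endswith((".gff", ".gff3"))
            else (read_bed(inputs["genes"]) if "genes" in inputs else None)
        )
        qtls = read_qtl_bed(inputs["qtls"]) if "qtls" in inputs else None
        hits = annotate_regions(flanked, genes=genes, qtls=qtls)
        _write(hits, os.path.join(out_dir, "annotations.tsv"))

    with open(os.path.join(out_dir, "run_log.json"), "w") as fh:
        json.dump(run_log, fh, indent=1, sort_keys=True)
    return out_dir
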