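"""End-to-end orchestration: simulate/ingest -> group -> DE grid -> consensus -> qPCR.

The pipeline starts at a gene x library count matrix plus a sample
design (library -> genotype, group, replicate); in synthetic mode the
inputs are drawn by :mod:`pooldeg.simdata`.  Stages: optional
metabolite-panel group assignment, TMM normalization and low-expression
filtering, gene-wise dispersion on the full design (genotype as group),
the pooled high-vs-low exact test plus every high x low genotype
pairwise test, D-count consensus classification, and an optional
2^-ddCt direction check.  All randomness flows from one top-level seed
through ``numpy.random.SeedSequence`` spawning; identical config + seed
give identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import consensus as cons
from . import diffexpr as de
from . import metabolites as met
from . import qpcr as qp
from . import simdata as sim
from .diffexpr import InputError

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "read_counts",
           "read_design", "read_metabolites", "read_ct", "write_report",
           "derive_seeds"]

log = logging.getLogger("pooldeg")

FLOAT_FORMAT = "%.6g"


def derive_seeds(seed: int, n: int) -> list[int]:
    """Split one top-level seed into ``n`` independent stage seeds (< 2^31)."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint64)
    return [int(s % (2 ** 31)) for s in state]


@dataclass
class PipelineConfig:
    """Everything a run needs: inputs (paths or a simulation config) and
    stage parameters.  Exactly one of ``sim`` / ``counts_path`` must be
    set."""

    sim: sim.SimConfig | None = None
    counts_path: str | None = None
    design_path: str | None = None
    metabolites_path: str | None = None
    ct_path: str | None = None

    alpha: float = 0.05
    consistency_threshold: float = 1.0
    lfc: float = 1.0
    fdr_max: float = 0.05
    min_cpm: float = 1.0
    min_libraries: int = 2
    min_support: int | None = None  # None -> ceil(7/9 * n_pairs)
    require_direction_consistency: bool = True
    housekeeping_gene: str = "EIF5A"
    calibrator_group: str = "low"

    seed: int = 0
    outdir: str | None = None

    def validate(self) -> None:
        if (self.sim is None) == (self.counts_path is None):
            raise InputError("provide exactly one of a simulation config or a counts path")
        if self.counts_path is not None and self.design_path is None:
            raise InputError("a counts path requires a design path")
        for name, val, lo, hi in (("alpha", self.alpha, 0, 1),
                                  ("consistency_threshold", self.consistency_threshold, 0, 1),
                                  ("fdr_max", self.fdr_max, 0, 1)):
            if not lo <= val <= hi:
                raise InputError(f"{name} must be in [{lo}, {hi}]")
        if self.lfc < 0 or self.min_cpm < 0 or self.min_libraries < 0:
            raise InputError("lfc, min_cpm and min_libraries must be >= 0")


@dataclass
class RunReport:
    """Summary of one pipeline run (serialized to report.json)."""

    groups: dict
    n_genes_input: int
    n_genes_tested: int
    contrasts: dict  # label -> {"n_deg", "n_up", "n_down"}
    pooled: dict  # {"total", "up", "down"}
    d_histogram: dict
    n_true_deg: int
    true_deg_split: dict
    qpcr_agreement: float | None
    provenance: dict

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# strict readers / writers
# ---------------------------------------------------------------------------

def read_counts(path) -> sim.CountMatrix:
    """Read counts.tsv (first column gene_id, one column per library).

    Duplicate gene or library ids, non-integer or negative counts are
    errors, not warnings.
    """
    frame = pd.read_csv(path, sep="\t", dtype={0: str})
    if frame.shape[1] < 3:
        raise InputError(f"{path}: need a gene_id column and >= 2 libraries")
    gene_col = frame.columns[0]
    genes = frame[gene_col].tolist()
    dup = frame[gene_col][frame[gene_col].duplicated()]
    if not dup.empty:
        raise InputError(f"{path}: duplicated gene id {dup.iloc[0]!r}")
    libs = list(frame.columns[1:])
    if len(set(libs)) != len(libs):
        raise InputError(f"{path}: duplicated library column")
    vals = frame[libs].to_numpy()
    as_int = np.asarray(vals, dtype=np.float64)
    if not np.all(np.isfinite(as_int)) or np.any(as_int != np.rint(as_int)):
        bad = np.argwhere(~np.isfinite(as_int) | (as_int != np.rint(as_int)))[0]
        raise InputError(f"{path}: non-integer count at gene {genes[bad[0]]!r}, "
                         f"library {libs[bad[1]]!r}")
    if np.any(as_int < 0):
        bad = np.argwhere(as_int < 0)[0]
        raise InputError(f"{path}: negative count at gene {genes[bad[0]]!r}, "
                         f"library {libs[bad[1]]!r}")
    return sim.CountMatrix(genes, libs, as_int.astype(np.int64))


def read_design(path) -> pd.DataFrame:
    """Read design.tsv (library_id, genotype, group, replicate)."""
    d = pd.read_csv(path, sep="\t", dtype=str)
    needed = {"library_id", "genotype", "group"}
    if not needed.issubset(d.columns):
        raise InputError(f"{path}: design must have columns {sorted(needed)}")
    dup = d["library_id"][d["library_id"].duplicated()]
    if not dup.empty:
        raise InputError(f"{path}: duplicated library id {dup.iloc[0]!r}")
    bad = set(d["group"]) - {"high", "low", "unassigned"}
    if bad:
        raise InputError(f"{path}: unknown group label(s) {sorted(bad)}")
    return d


def check_design_matches(counts: sim.CountMatrix, design: pd.DataFrame) -> None:
    missing = set(design["library_id"]) - set(counts.library_ids)
    if missing:
        raise InputError(f"design lists libraries absent from counts: {sorted(missing)}")
    extra = set(counts.library_ids) - set(design["library_id"])
    if extra:
        raise InputError(f"counts contain libraries absent from design: {sorted(extra)}")


def read_metabolites(path) -> pd.DataFrame:
    panel = pd.read_csv(path)
    needed = {"genotype", "replicate", "metabolite", "concentration"}
    if not needed.issubset(panel.columns):
        raise InputError(f"{path}: metabolite panel must have columns {sorted(needed)}")
    return panel


def read_ct(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    needed = {"sample", "group", "gene", "ct"}
    if not needed.issubset(table.columns):
        raise InputError(f"{path}: Ct table must have columns {sorted(needed)}")
    return table


def write_report(report: RunReport, path) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=2) + "\n")


def _write_tsv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# run
# ---------------------------------------------------------------------------

def _de_table_with_calls(result: de.DEResult, degs: de.DegSet) -> pd.DataFrame:
    t = result.table.copy()
    t["is_deg"] = t["gene_id"].isin(degs.genes)
    t["direction"] = [degs.directions.get(g, "none") for g in t["gene_id"]]
    return t


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run every stage and return the summary report.

    With ``config.outdir`` set, all stage outputs (counts/design in
    synthetic mode, anova.tsv, groups.json, de_<contrast>.tsv,
    consensus.tsv, summary.json, qpcr.tsv, report.json) are written as
    plain TSV/CSV/JSON.
    """
    config.validate()
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    panel = None
    ct_table = None
    truth = None
    if config.sim is not None:
        seeds = derive_seeds(config.seed, 3)
        simcfg = dataclasses.replace(config.sim, seed=seeds[0])
        counts, design, truth = sim.generate_counts(simcfg)
        panel = sim.generate_metabolites(
            genotypes_high=simcfg.genotypes_high,
            genotypes_low=simcfg.genotypes_low, seed=seeds[1])
        # validate a handful of group-effect genes by synthetic qPCR
        qpcr_genes = dict(list(truth.de_genes.items())[:6])
        ct_table = sim.generate_ct_table(
            {g: s * simcfg.de_log2fc for g, s in qpcr_genes.items()},
            noise_sd=0.25, seed=seeds[2],
            housekeeping_gene=config.housekeeping_gene)
        log.info("simulated %d genes x %d libraries (seed %d)",
                 counts.shape[0], counts.shape[1], config.seed)
        if outdir:
            counts.to_frame().rename_axis("gene_id").to_csv(
                outdir / "counts.tsv", sep="\t")
            _write_tsv(design, outdir / "design.tsv")
            (outdir / "truth.json").write_text(truth.to_json() + "\n")
            panel.to_csv(outdir / "metabolites.csv", index=False,
                         float_format=FLOAT_FORMAT)
            ct_table.to_csv(outdir / "ct.csv", index=False,
                            float_format=FLOAT_FORMAT)
    else:
        counts = read_counts(config.counts_path)
        design = read_design(config.design_path)
        check_design_matches(counts, design)
        if config.metabolites_path:
            panel = read_metabolites(config.metabolites_path)
        if config.ct_path:
            ct_table = read_ct(config.ct_path)

    # -- group assignment ----------------------------------------------
    groups_given = set(design["group"]) <= {"high", "low"} and \
        {"high", "low"} <= set(design["group"])
    assignment = None
    if panel is not None and not (groups_given and config.sim is None):
        assignment = met.assign_groups(
            panel, alpha=config.alpha,
            consistency_threshold=config.consistency_threshold)
        if outdir:
            anova = met.anova_table(panel, alpha=config.alpha)
            _write_tsv(pd.DataFrame(
                [{"metabolite": r.metabolite, "F": r.f_statistic,
                  "p": r.p_value, "significant": r.significant}
                 for r in anova]), outdir / "anova.tsv")
            (outdir / "groups.json").write_text(json.dumps({
                "high": sorted(assignment.high_genotypes),
                "low": sorted(assignment.low_genotypes),
                "ambiguous": assignment.ambiguous,
                "scores": assignment.scores,
                "discriminating_metabolites": assignment.discriminating_metabolites,
            }, indent=2) + "\n")
    if not groups_given:
        if assignment is None or assignment.ambiguous:
            raise InputError("group assignment is ambiguous and no groups were "
                             "pre-specified in the design")
        design = design.copy()
        design["group"] = [
            "high" if g in assignment.high_genotypes else
            "low" if g in assignment.low_genotypes else "unassigned"
            for g in design["genotype"]]
        design = design[design["group"] != "unassigned"]
        counts = counts.subset_libraries(design["library_id"].tolist())
    log.info("groups: high=%s low=%s",
             sorted(design.loc[design.group == "high", "genotype"].unique()),
             sorted(design.loc[design.group == "low", "genotype"].unique()))

    # -- normalization, filtering, dispersion --------------------------
    n_input = counts.shape[0]
    factors0 = de.tmm_factors(counts)
    counts = de.filter_low_expression(counts, factors0, config.min_cpm,
                                      config.min_libraries)
    factors = de.tmm_factors(counts)
    geno_of = dict(zip(design["library_id"], design["genotype"]))
    phi = de.estimate_dispersion(counts, factors,
                                 [geno_of[l] for l in counts.library_ids])
    log.info("kept %d/%d genes; median dispersion %.3g",
             counts.shape[0], n_input, float(np.median(phi)))

    # -- DE grid -------------------------------------------------------
    grid = cons.build_contrast_grid(design)
    lib_index = {l: i for i, l in enumerate(counts.library_ids)}

    def run_contrast(contrast: cons.Contrast) -> tuple[de.DEResult, de.DegSet]:
        libs = list(contrast.high_libraries) + list(contrast.low_libraries)
        sub = counts.subset_libraries(libs)
        labels = (["high"] * len(contrast.high_libraries)
                  + ["low"] * len(contrast.low_libraries))
        result = de.nb_exact_test(sub, factors, labels, phi,
                                  contrast=contrast.label)
        return result, de.call_degs(result, lfc=config.lfc,
                                    fdr_max=config.fdr_max)

    pooled_result, pooled_degs = run_contrast(grid.pooled)
    pairwise = []
    contrast_stats = {}
    for pc in grid.pairwise:
        result, degs = run_contrast(pc)
        pairwise.append(degs)
        n_up = sum(d == "up" for d in degs.directions.values())
        contrast_stats[pc.label] = {"n_deg": len(degs), "n_up": n_up,
                                    "n_down": len(degs) - n_up}
        if outdir:
            _write_tsv(_de_table_with_calls(result, degs),
                       outdir / f"de_{pc.label}.tsv")
    if outdir:
        _write_tsv(_de_table_with_calls(pooled_result, pooled_degs),
                   outdir / "de_pooled.tsv")

    n_up_pooled = sum(d == "up" for d in pooled_degs.directions.values())
    pooled_stats = {"total": len(pooled_degs), "up": n_up_pooled,
                    "down": len(pooled_degs) - n_up_pooled}
    contrast_stats["pooled"] = {"n_deg": pooled_stats["total"],
                                "n_up": pooled_stats["up"],
                                "n_down": pooled_stats["down"]}
    log.info("pooled DEGs: %d (%d up / %d down)", pooled_stats["total"],
             pooled_stats["up"], pooled_stats["down"])

    # -- consensus -----------------------------------------------------
    min_support = (config.min_support if config.min_support is not None
                   else cons.default_min_support(grid.n_pairs))
    table = cons.classify_consensus(
        pooled_degs, pairwise, min_support=min_support,
        require_direction_consistency=config.require_direction_consistency)
    summary = cons.consensus_summary(table)
    log.info("true DEGs (D>=%d): %d", min_support, summary["n_true_deg"])
    if outdir:
        _write_tsv(table.table, outdir / "consensus.tsv")
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")

    # -- qPCR check ----------------------------------------------------
    agreement = None
    if ct_table is not None:
        rel = qp.delta_delta_ct(ct_table,
                                housekeeping_gene=config.housekeeping_gene,
                                calibrator_group=config.calibrator_group)
        shared = set(rel.table["gene"]) & set(pooled_result.table["gene_id"])
        if shared:
            agree = qp.direction_agreement(rel, pooled_result)
            agreement = agree.attrs["fraction_agree"]
            if outdir:
                qtab = rel.table.copy()
                agree_map = dict(zip(agree["gene"], agree["agree"]))
                qtab["agrees_with_de"] = [agree_map.get(g) for g in qtab["gene"]]
                _write_tsv(qtab, outdir / "qpcr.tsv")
            log.info("qPCR direction agreement: %.0f%%", 100 * agreement)

    report = RunReport(
        groups={
            "high": sorted(design.loc[design.group == "high", "genotype"].unique()),
            "low": sorted(design.loc[design.group == "low", "genotype"].unique()),
            "from_metabolites": assignment is not None,
        },
        n_genes_input=n_input,
        n_genes_tested=counts.shape[0],
        contrasts=contrast_stats,
        pooled=pooled_stats,
        d_histogram=summary["d_histogram"],
        n_true_deg=summary["n_true_deg"],
        true_deg_split={"up": summary["n_true_up"], "down": summary["n_true_down"]},
        qpcr_agreement=agreement,
        provenance={
            "seed": config.seed,
            "min_support": min_support,
            "lfc": config.lfc,
            "fdr_max": config.fdr_max,
            "alpha": config.alpha,
            "synthetic": config.sim is not None,
        },
    )
    if outdir:
        write_report(report, outdir / "report.json")
    return report
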