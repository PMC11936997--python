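"""Consensus DEG calling across pooled and pairwise genotype contrasts.

The pooled contrast (all high-group libraries vs all low-group
libraries) is cross-validated by every high-genotype x low-genotype
pairwise contrast — nine pairs for a 3 x 3 design.  Each pooled DEG's
D-count is the number of pairwise contrasts in which it is also called,
and "true DEGs" are pooled DEGs supported by at least ``min_support``
pairs (7 of 9 by default) with a consistent direction.  Genes whose
expression shift is confined to one genotype can be pairwise DEGs in at
most 3 of 9 pairs, so the rule rejects exactly the genotype-outlier
false-positive mode that pooling alone admits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffexpr import DegSet, InputError

__all__ = ["Contrast", "ContrastGrid", "ConsensusTable", "build_contrast_grid",
           "d_count", "classify_consensus", "consensus_summary",
           "default_min_support"]


@dataclass(frozen=True)
class Contrast:
    """One two-group comparison: library ids for the high and low side."""

    label: str
    high_libraries: tuple[str, ...]
    low_libraries: tuple[str, ...]


@dataclass(frozen=True)
class ContrastGrid:
    pooled: Contrast
    pairwise: tuple[Contrast, ...]

    @property
    def n_pairs(self) -> int:
        return len(self.pairwise)


@dataclass
class ConsensusTable:
    """Per-gene cross-validation outcome.

    ``table`` columns: gene_id, in_pooled, pooled_direction, d_count,
    consensus_direction (up/down/mixed/none), direction_consistent,
    is_true_deg, plus one boolean column per pairwise contrast.
    """

    table: pd.DataFrame
    pair_labels: list[str]
    min_support: int


def build_contrast_grid(design: pd.DataFrame) -> ContrastGrid:
    """Pooled contrast plus the Cartesian product of high x low genotypes.

    ``design`` has columns library_id, genotype, group.  Pairwise
    contrasts use every library of the two genotypes and are ordered
    lexicographically by (high label, low label).
    """
    for col in ("library_id", "genotype", "group"):
        if col not in design.columns:
            raise InputError(f"design missing column {col!r}")
    high = design[design["group"] == "high"]
    low = design[design["group"] == "low"]
    if high.empty or low.empty:
        raise InputError("both groups must contain at least one genotype")

    def libs(frame, genotype=None):
        if genotype is not None:
            frame = frame[frame["genotype"] == genotype]
        return tuple(frame["library_id"])

    pooled = Contrast("pooled", libs(high), libs(low))
    pairs = []
    for hg in sorted(high["genotype"].unique()):
        for lg in sorted(low["genotype"].unique()):
            pairs.append(Contrast(f"{hg}_vs_{lg}", libs(high, hg), libs(low, lg)))
    return ContrastGrid(pooled, tuple(pairs))


def default_min_support(n_pairs: int) -> int:
    """7-of-9 support rule generalized to other grid sizes: ceil(7/9 * n)."""
    return math.ceil(7 * n_pairs / 9)


def d_count(pairwise_deg_sets: list[DegSet], gene: str,
            require_direction_consistency: bool = True) -> int:
    """Number of pairwise contrasts calling ``gene`` a DEG.

    With direction consistency required, only detections matching the
    gene's majority direction count (a tie counts the larger faction,
    i.e. either).
    """
    dirs = [s.directions[gene] for s in pairwise_deg_sets if gene in s]
    if not dirs or not require_direction_consistency:
        return len(dirs)
    n_up = sum(d == "up" for d in dirs)
    return max(n_up, len(dirs) - n_up)


def _gene_row(gene, pooled, pairwise, min_support, require_direction):
    flags = [gene in s for s in pairwise]
    dirs = [s.directions[gene] for s in pairwise if gene in s]
    n_up = sum(d == "up" for d in dirs)
    n_down = len(dirs) - n_up
    if not dirs:
        consensus_dir = "none"
    elif n_up == n_down:
        consensus_dir = "mixed"
    else:
        consensus_dir = "up" if n_up > n_down else "down"
    dc = max(n_up, n_down) if require_direction else len(dirs)

    in_pooled = gene in pooled
    pooled_dir = pooled.directions.get(gene, "none")
    consistent = bool(dirs) and (n_up == 0 or n_down == 0) and (
        not in_pooled or pooled_dir == dirs[0])
    is_true = in_pooled and dc >= min_support and (
        consistent if require_direction else True)
    return {
        "gene_id": gene,
        "in_pooled": in_pooled,
        "pooled_direction": pooled_dir,
        "d_count": dc,
        "consensus_direction": consensus_dir,
        "direction_consistent": consistent,
        "is_true_deg": is_true,
        **{f"pair_{s.contrast}": f for s, f in zip(pairwise, flags)},
    }


def classify_consensus(pooled: DegSet, pairwise: list[DegSet],
                       min_support: int = 7,
                       require_direction_consistency: bool = True) -> ConsensusTable:
    """Cross-validate pooled DEGs against the pairwise grid.

    Every gene detected in the pooled contrast or any pairwise contrast
    gets a row; a true DEG must be a pooled DEG with D-count >=
    ``min_support`` (and, by default, one consistent direction across
    all of its detections including the pooled one).  Genes detected
    only in the pooled contrast are the D0 class.
    """
    n_pairs = len(pairwise)
    if not 0 <= min_support <= n_pairs:
        raise InputError(f"min_support must be in 0..{n_pairs}")
    universe = set(pooled.genes)
    for s in pairwise:
        universe |= s.genes
    rows = [_gene_row(g, pooled, pairwise, min_support,
                      require_direction_consistency)
            for g in sorted(universe)]
    cols = ["gene_id", "in_pooled", "pooled_direction", "d_count",
            "consensus_direction", "direction_consistent", "is_true_deg"] + [
            f"pair_{s.contrast}" for s in pairwise]
    table = pd.DataFrame(rows, columns=cols) if rows else pd.DataFrame(columns=cols)
    return ConsensusTable(table=table, pair_labels=[s.contrast for s in pairwise],
                          min_support=min_support)


def consensus_summary(consensus: ConsensusTable) -> dict:
    """Summary record: pooled total, D histogram, true-DEG counts and split."""
    t = consensus.table
    n_pairs = len(consensus.pair_labels)
    if t.empty:
        return {"n_pooled": 0,
                "d_histogram": {f"D{d}": 0 for d in range(n_pairs + 1)},
                "n_true_deg": 0, "n_true_up": 0, "n_true_down": 0}
    pooled = t[t["in_pooled"]]
    hist = {f"D{d}": int((pooled["d_count"] == d).sum())
            for d in range(n_pairs + 1)}
    true_degs = t[t["is_true_deg"]]
    n_up = int((true_degs["pooled_direction"] == "up").sum())
    return {
        "n_pooled": int(len(pooled)),
        "d_histogram": hist,
        "n_true_deg": int(len(true_degs)),
        "n_true_up": n_up,
        "n_true_down": int(len(true_degs)) - n_up,
    }
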