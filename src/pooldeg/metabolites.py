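"""Genotype grouping from a replicated metabolite concentration panel.

Each metabolite is tested for genotype effect with a one-way ANOVA at a
significance level alpha (0.05 by default).  Metabolites that reject are
"discriminating"; for each, genotypes are split at the median of their
per-genotype means, and a genotype's consistency score is the fraction
of discriminating metabolites for which it lands in the upper half.
Genotypes consistently in the upper half form the high group, those
consistently in the lower half the low group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import InputError, bh_adjust

__all__ = ["AnovaResult", "GroupAssignment", "one_way_anova", "anova_table",
           "assign_groups"]


@dataclass(frozen=True)
class AnovaResult:
    """One-way ANOVA outcome for a single metabolite."""

    metabolite: str
    f_statistic: float
    p_value: float
    group_means: dict[str, float]
    significant: bool
    degenerate: bool = False  # zero within-group variance with unequal means


@dataclass
class GroupAssignment:
    high_genotypes: frozenset
    low_genotypes: frozenset
    discriminating_metabolites: list[str]
    scores: dict[str, float]
    ambiguous: bool


def one_way_anova(groups: dict[str, np.ndarray], metabolite: str = "",
                  alpha: float = 0.05) -> AnovaResult:
    """Classic one-way F test across genotype replicate vectors.

    F = between-group mean square / within-group mean square, p from the
    F(k-1, N-k) distribution.  Zero within-group variance with unequal
    means returns p = 0 with the degenerate flag set (rather than
    raising), so that near-noiseless panels flow through; identical
    groups give F = 0, p = 1.
    """
    if len(groups) < 2:
        raise InputError("ANOVA needs at least 2 genotypes")
    arrays = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    for g, v in arrays.items():
        if v.size < 2:
            raise InputError(f"genotype {g!r} has fewer than 2 replicates")
        if np.any(~np.isfinite(v)):
            raise InputError(f"non-finite concentration for genotype {g!r}")

    all_vals = np.concatenate(list(arrays.values()))
    grand = all_vals.mean()
    k = len(arrays)
    n_total = all_vals.size
    ss_between = sum(v.size * (v.mean() - grand) ** 2 for v in arrays.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in arrays.values())
    df_b, df_w = k - 1, n_total - k
    means = {g: float(v.mean()) for g, v in arrays.items()}

    if ss_within == 0.0:
        if ss_between == 0.0:
            return AnovaResult(metabolite, 0.0, 1.0, means, False)
        return AnovaResult(metabolite, float("inf"), 0.0, means,
                           significant=0.0 < alpha, degenerate=True)
    f = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(f, df_b, df_w))
    return AnovaResult(metabolite, float(f), p, means, significant=p < alpha)


def anova_table(panel: pd.DataFrame, alpha: float = 0.05,
                bh_correct: bool = False) -> list[AnovaResult]:
    """Per-metabolite one-way ANOVA over a tidy panel.

    ``panel`` has columns genotype, replicate, metabolite, concentration.
    ``bh_correct`` optionally re-derives significance from BH-adjusted
    p-values (off by default: the grouping convention is per-metabolite
    testing at alpha).
    """
    required = {"genotype", "metabolite", "concentration"}
    if not required.issubset(panel.columns):
        raise InputError(f"panel must have columns {sorted(required)}")
    results = []
    for met, sub in panel.groupby("metabolite", sort=False):
        groups = {g: s["concentration"].to_numpy() for g, s in sub.groupby("genotype")}
        results.append(one_way_anova(groups, metabolite=str(met), alpha=alpha))
    if bh_correct and results:
        adj = bh_adjust([r.p_value for r in results])
        results = [
            AnovaResult(r.metabolite, r.f_statistic, r.p_value, r.group_means,
                        significant=q < alpha, degenerate=r.degenerate)
            for r, q in zip(results, adj)
        ]
    return results


def assign_groups(panel: pd.DataFrame, alpha: float = 0.05,
                  consistency_threshold: float = 1.0,
                  bh_correct: bool = False) -> GroupAssignment:
    """Assign genotypes to high/low groups from the metabolite panel.

    For each discriminating metabolite (ANOVA p < alpha) genotypes are
    split at the median of the genotype means; ties at the median break
    toward the lower half.  A genotype's score is its upper-half
    fraction over discriminating metabolites; score >=
    ``consistency_threshold`` puts it in the high group, score <=
    ``1 - consistency_threshold`` in the low group, anything else is
    left unassigned and flags the result ambiguous.  No discriminating
    metabolite yields an empty, ambiguous assignment.
    """
    results = anova_table(panel, alpha=alpha, bh_correct=bh_correct)
    genotypes = list(pd.unique(panel["genotype"]))
    if len(genotypes) < 2:
        raise InputError("need at least 2 genotypes")

    disc = [r for r in results if r.significant]
    if not disc:
        return GroupAssignment(frozenset(), frozenset(), [],
                               {g: 0.0 for g in genotypes}, ambiguous=True)

    upper_counts = {g: 0 for g in genotypes}
    for r in disc:
        means = np.array([r.group_means[g] for g in genotypes])
        med = np.median(means)
        for g, m in zip(genotypes, means):
            if m > med:  # ties at the median fall to the lower half
                upper_counts[g] += 1
    scores = {g: upper_counts[g] / len(disc) for g in genotypes}

    high = frozenset(g for g, s in scores.items() if s >= consistency_threshold)
    low = frozenset(g for g, s in scores.items()
                    if s <= 1.0 - consistency_threshold and g not in high)
    ambiguous = bool(set(genotypes) - set(high) - set(low))
    return GroupAssignment(high, low, [r.metabolite for r in disc], scores,
                           ambiguous)
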