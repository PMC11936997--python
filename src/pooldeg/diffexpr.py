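"""Differential-expression engine for two-group count contrasts.

Implements the classic count-based DE stack end to end: trimmed mean of
M-values (TMM) between-library normalization, counts-per-million,
low-expression filtering, method-of-moments dispersion estimation with
shrinkage toward a common value, an exact-style negative-binomial
two-group test, Benjamini-Hochberg FDR and the |log2FC| >= 1 DEG rule.

The exact test conditions on each gene's total count after equalizing
effective library sizes.  Sums of independent NB(size = n/phi) variables
with a common success probability split beta-binomially given their
total (a Gamma-Poisson argument: the Poisson split is binomial with a
Beta-distributed proportion), so the conditional null distribution of
the high-group sum is BetaBinomial(s, n_high/phi, n_low/phi),
degenerating to Binomial(s, n_high/(n_high+n_low)) as phi -> 0.  The
two-sided p-value sums the probabilities of all outcomes no more likely
than the observed one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .simdata import CountMatrix

__all__ = [
    "InputError",
    "NormFactors",
    "DEResult",
    "DegSet",
    "tmm_factors",
    "cpm",
    "filter_low_expression",
    "estimate_dispersion",
    "nb_exact_test",
    "exact_nb_pvalue",
    "call_degs",
    "bh_adjust",
]


class InputError(ValueError):
    """Raised on malformed or inconsistent inputs."""


@dataclass(frozen=True)
class NormFactors:
    """Per-library TMM scaling factors, geometric mean 1."""

    library_ids: tuple[str, ...]
    factors: np.ndarray
    reference: str

    def __post_init__(self) -> None:
        f = np.asarray(self.factors, dtype=float)
        object.__setattr__(self, "factors", f)
        if f.shape != (len(self.library_ids),):
            raise InputError("factors must align with library ids")
        if np.any(~np.isfinite(f)) or np.any(f <= 0):
            raise InputError("factors must be positive and finite")

    def aligned_to(self, library_ids) -> np.ndarray:
        ids = list(library_ids)
        if set(ids) - set(self.library_ids):
            raise InputError("factors missing for some libraries: "
                             f"{sorted(set(ids) - set(self.library_ids))}")
        pos = {l: i for i, l in enumerate(self.library_ids)}
        return self.factors[[pos[l] for l in ids]]


@dataclass
class DEResult:
    """Per-gene DE statistics for one two-group contrast.

    ``table`` has columns gene_id, log2FC (positive = higher in the
    first/"high" group), logCPM, p_value, fdr.
    """

    contrast: str
    table: pd.DataFrame


@dataclass(frozen=True)
class DegSet:
    """Genes called differentially expressed in one contrast."""

    contrast: str
    directions: dict[str, str]  # gene id -> "up" | "down"

    @property
    def genes(self) -> frozenset:
        return frozenset(self.directions)

    def __contains__(self, gene: str) -> bool:
        return gene in self.directions

    def __len__(self) -> int:
        return len(self.directions)


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------

def _tmm_pair_factor(y: np.ndarray, n_y: float, r: np.ndarray, n_r: float,
                     trim_m: float, trim_a: float, min_genes: int) -> float:
    pos = (y > 0) & (r > 0)
    if int(pos.sum()) < min_genes:
        warnings.warn("fewer than %d genes expressed in both libraries; "
                      "TMM factor set to 1" % min_genes, stacklevel=3)
        return 1.0
    py = y[pos] / n_y
    pr = r[pos] / n_r
    m = np.log2(py / pr)
    a = 0.5 * np.log2(py * pr)
    w = (n_y - y[pos]) / (n_y * y[pos]) + (n_r - r[pos]) / (n_r * r[pos])

    n = m.size
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not np.any(keep) or np.sum(w[keep]) == 0:
        return 1.0
    f = np.sum(w[keep] * m[keep]) / np.sum(w[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0 ** f)


def tmm_factors(counts: CountMatrix, trim_m: float = 0.30, trim_a: float = 0.05,
                min_genes: int = 10) -> NormFactors:
    """Trimmed-mean-of-M-values normalization factors.

    The reference library is the one whose upper-quartile count fraction
    is closest to the mean upper quartile.  For each library, genewise
    log-ratios M and average abundances A are computed against the
    reference over genes expressed in both; values in the top/bottom
    ``trim_m`` tail of M or ``trim_a`` tail of A are discarded and the
    factor is 2 to the precision-weighted mean of the surviving M values
    (weights from the asymptotic binomial variance).  Factors are
    rescaled to geometric mean 1.
    """
    x = counts.counts.astype(float)
    lib = x.sum(axis=0)
    if np.any(lib <= 0):
        bad = [counts.library_ids[i] for i in np.where(lib <= 0)[0]]
        raise InputError(f"libraries with zero total count: {bad}")

    f75 = np.array([np.quantile(x[:, i] / lib[i], 0.75) for i in range(x.shape[1])])
    ref = int(np.argmin(np.abs(f75 - f75.mean())))

    factors = np.ones(x.shape[1])
    for i in range(x.shape[1]):
        if i == ref:
            continue
        factors[i] = _tmm_pair_factor(x[:, i], lib[i], x[:, ref], lib[ref],
                                      trim_m, trim_a, min_genes)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return NormFactors(tuple(counts.library_ids), factors,
                       counts.library_ids[ref])


# ---------------------------------------------------------------------------
# CPM and filtering
# ---------------------------------------------------------------------------

def cpm(counts: CountMatrix, factors: NormFactors) -> pd.DataFrame:
    """Counts per million on the TMM-normalized scale."""
    f = factors.aligned_to(counts.library_ids)
    x = counts.counts.astype(float)
    lib = x.sum(axis=0)
    vals = x / (lib * f)[None, :] * 1e6
    return pd.DataFrame(vals, index=counts.gene_ids, columns=counts.library_ids)


def filter_low_expression(counts: CountMatrix, factors: NormFactors,
                          min_cpm: float = 1.0, min_libraries: int = 2) -> CountMatrix:
    """Keep genes with CPM > ``min_cpm`` in at least ``min_libraries`` libraries."""
    c = cpm(counts, factors).to_numpy()
    keep = (c > min_cpm).sum(axis=1) >= min_libraries
    return CountMatrix([g for g, k in zip(counts.gene_ids, keep) if k],
                       list(counts.library_ids), counts.counts[keep])


# ---------------------------------------------------------------------------
# dispersion
# ---------------------------------------------------------------------------

def _normalized(counts: CountMatrix, factors: NormFactors) -> tuple[np.ndarray, float]:
    """Counts rescaled to a common effective library size (geometric mean)."""
    f = factors.aligned_to(counts.library_ids)
    lib = counts.counts.sum(axis=0).astype(float)
    eff = lib * f
    common = float(np.exp(np.mean(np.log(eff))))
    return counts.counts * (common / eff)[None, :], common


def estimate_dispersion(counts: CountMatrix, factors: NormFactors,
                        groups, n0: float = 10.0, clamp=(1e-6, 10.0),
                        trim: float = 0.1, fallback: float = 0.1) -> np.ndarray:
    """Per-gene NB dispersion (Var = mu + phi mu^2), method of moments.

    Within-group residual variance on the normalized scale gives a raw
    gene-wise estimate ``phi_raw = (s^2 - mu) / mu^2``, clamped to
    ``clamp``, then shrunk toward the trimmed-mean common dispersion
    with weight ``n0 / (n0 + residual df)``.  With no within-group
    replication anywhere a fixed conservative value is returned with a
    warning.
    """
    groups = np.asarray(list(groups))
    if groups.shape != (len(counts.library_ids),):
        raise InputError("group labels must align with libraries")
    z, _ = _normalized(counts, factors)

    labels = pd.unique(groups)
    ss = np.zeros(z.shape[0])
    df = 0
    used = np.zeros(len(groups), dtype=bool)
    for lab in labels:
        idx = groups == lab
        n = int(idx.sum())
        if n >= 2:
            zg = z[:, idx]
            ss += ((zg - zg.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
            df += n - 1
            used |= idx

    if df == 0:
        warnings.warn("no within-group replication; using fallback dispersion "
                      f"{fallback}", stacklevel=2)
        return np.full(z.shape[0], fallback)

    var = ss / df
    mu = z[:, used].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi_raw = (var - mu) / np.square(mu)
    phi_raw = np.where(np.isfinite(phi_raw), phi_raw, clamp[0])
    phi_raw = np.clip(phi_raw, clamp[0], clamp[1])

    common = float(stats.trim_mean(phi_raw, trim))
    w = n0 / (n0 + df)
    return np.clip(w * common + (1 - w) * phi_raw, clamp[0], clamp[1])


# ---------------------------------------------------------------------------
# NB exact test
# ---------------------------------------------------------------------------

def _betabinom_logpmf(k, s, a, b):
    """log pmf of BetaBinomial(s, a, b) via gammaln/betaln (vectorized)."""
    k = np.asarray(k, dtype=float)
    return (special.gammaln(s + 1) - special.gammaln(k + 1)
            - special.gammaln(s - k + 1)
            + special.betaln(k + a, s - k + b) - special.betaln(a, b))


def exact_nb_pvalue(k: int, s: int, n1: int, n2: int, phi: float,
                    max_enumerate: int = 10_000) -> float:
    """Two-sided conditional exact p-value for a high-group sum.

    ``k`` of a total ``s`` equal-size-library counts fell in the group
    of ``n1`` libraries (the other group has ``n2``).  Under the null of
    equal means the conditional law of ``k`` is
    BetaBinomial(s, n1/phi, n2/phi) (Binomial(s, n1/(n1+n2)) at phi=0);
    the p-value sums the probabilities of outcomes no more likely than
    the observed one.  Totals above ``max_enumerate`` use a normal
    approximation with continuity correction.
    """
    if s == 0:
        return 1.0
    if k < 0 or k > s:
        raise InputError("observed sum outside [0, total]")
    p1 = n1 / (n1 + n2)
    if s > max_enumerate:
        if phi <= 1e-8:
            mean, var = s * p1, s * p1 * (1 - p1)
        else:
            a, b = n1 / phi, n2 / phi
            mean = s * a / (a + b)
            var = s * a * b * (a + b + s) / ((a + b) ** 2 * (a + b + 1))
        z = (abs(k - mean) - 0.5) / np.sqrt(var)
        return float(min(1.0, 2.0 * stats.norm.sf(z)))
    ks = np.arange(s + 1)
    if phi <= 1e-8:
        logp = stats.binom.logpmf(ks, s, p1)
    else:
        logp = _betabinom_logpmf(ks, s, n1 / phi, n2 / phi)
    obs = logp[k]
    # relative tolerance guards float ties in the min-likelihood rule
    return float(min(1.0, np.exp(logp[logp <= obs + 1e-10]).sum()))


def nb_exact_test(counts: CountMatrix, factors: NormFactors, groups,
                  dispersion, pseudo_count: float = 0.5,
                  max_enumerate: int = 10_000,
                  contrast: str = "high_vs_low") -> DEResult:
    """Exact-style NB test of the first ("high") group against the second.

    ``groups`` labels each library ``high`` or ``low``; log2FC is
    reported high-over-low (positive = higher in high).  Counts are
    rescaled to a common effective library size, summed within groups
    and rounded; p-values come from :func:`exact_nb_pvalue` with the
    gene's dispersion; BH adjustment across genes gives the FDR column.
    """
    groups = np.asarray(list(groups))
    labels = [l for l in ("high", "low") if l in groups]
    if len(labels) != 2 or set(groups) != {"high", "low"}:
        raise InputError("groups must contain exactly the labels 'high' and 'low'")
    phi = np.asarray(dispersion, dtype=float)
    if phi.ndim == 0:
        phi = np.full(counts.shape[0], float(phi))
    if phi.shape != (counts.shape[0],):
        raise InputError("dispersion must be scalar or per-gene")

    z, _ = _normalized(counts, factors)
    hi = groups == "high"
    lo = groups == "low"
    n1, n2 = int(hi.sum()), int(lo.sum())

    s1 = np.rint(z[:, hi].sum(axis=1)).astype(np.int64)
    s2 = np.rint(z[:, lo].sum(axis=1)).astype(np.int64)
    total = s1 + s2

    m1 = z[:, hi].mean(axis=1)
    m0 = z[:, lo].mean(axis=1)
    lfc = np.log2((m1 + pseudo_count) / (m0 + pseudo_count))
    c = cpm(counts, factors).to_numpy()
    logcpm = np.log2(c.mean(axis=1) + pseudo_count)

    pvals = np.ones(counts.shape[0])
    for g in range(counts.shape[0]):
        if total[g] == 0:
            lfc[g] = 0.0
            continue
        pvals[g] = exact_nb_pvalue(int(s1[g]), int(total[g]), n1, n2,
                                   float(phi[g]), max_enumerate)

    table = pd.DataFrame({
        "gene_id": counts.gene_ids,
        "log2FC": lfc,
        "logCPM": logcpm,
        "p_value": pvals,
        "fdr": bh_adjust(pvals),
    })
    return DEResult(contrast=contrast, table=table)


# ---------------------------------------------------------------------------
# DEG calling and BH
# ---------------------------------------------------------------------------

def call_degs(result: DEResult, lfc: float = 1.0, fdr_max: float = 0.05) -> DegSet:
    """Apply the DEG rule: |log2FC| >= lfc and FDR <= fdr_max (both inclusive)."""
    t = result.table
    sel = (t["log2FC"].abs() >= lfc) & (t["fdr"] <= fdr_max)
    directions = {
        g: ("up" if l > 0 else "down")
        for g, l in zip(t.loc[sel, "gene_id"], t.loc[sel, "log2FC"])
        if l != 0
    }
    return DegSet(contrast=result.contrast, directions=directions)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
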