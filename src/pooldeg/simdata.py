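"""Synthetic data generators with known ground truth.

Emulates a pooled-genotype RNA-seq design: two groups of genotypes
(high / low secondary-metabolite content), a fixed number of sequencing
libraries per genotype, negative-binomial counts with gene-wise
dispersion, plus a replicated metabolite concentration panel and a qPCR
Ct table consistent with the same effect sizes.

Three gene classes are simulated:

* group-effect ("true DE") genes: a log2 shift ``beta`` applied to every
  library of the high group;
* outlier genes: a log2 shift ``gamma`` confined to the libraries of a
  single genotype (the false-positive mode a pairwise consensus filter
  is designed to reject);
* null genes: no effect.

All generators are pure functions of their configuration and seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "GroundTruth",
    "CountMatrix",
    "ConfigurationError",
    "generate_counts",
    "generate_metabolites",
    "generate_ct_table",
    "DEFAULT_METABOLITES",
]


class ConfigurationError(ValueError):
    """Raised when a generator configuration violates its invariants."""


#: The 19 phenolic/flavonoid compounds detected in mungbean sprouts;
#: "S-CHL" is the pre-summed chlorogenic + neo-chlorogenic acid column.
DEFAULT_METABOLITES = (
    "gallic acid", "S-CHL", "genistin", "formononetin", "catechin",
    "syringic acid", "resveratrol", "biochanin A", "caffeic acid",
    "coumestrol", "daidzein", "daidzin", "genistein", "isovitexin",
    "myricetin", "p-coumaric acid", "quercetin", "vitexin", "daidzein-2",
)


@dataclass(frozen=True)
class SimConfig:
    """Configuration of the count simulator.

    Defaults mirror the study design this package targets: six genotypes
    (three high, three low) with two libraries each, ~2,000 genes with
    baseline log2 means spanning [3, 12], NB dispersion ``phi = 0.1``
    (Var = mu + phi mu^2), 100 group-effect genes at ``|beta| = 2`` and
    100 single-genotype outlier genes at ``gamma = 4``.
    """

    n_genes: int = 2000
    genotypes_high: tuple[str, ...] = ("205", "304", "667")
    genotypes_low: tuple[str, ...] = ("SH", "313", "DH")
    libs_per_genotype: int = 2
    baseline_log2_mean_range: tuple[float, float] = (3.0, 12.0)
    lib_size_factors: tuple[float, ...] | None = None
    lib_size_jitter: float = 0.3
    dispersion: float = 0.1
    n_true_de: int = 100
    de_log2fc: float = 2.0
    n_outlier_genes: int = 100
    outlier_log2fc: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "genotypes_high", tuple(self.genotypes_high))
        object.__setattr__(self, "genotypes_low", tuple(self.genotypes_low))
        if self.lib_size_factors is not None:
            object.__setattr__(self, "lib_size_factors", tuple(self.lib_size_factors))

    # -- validation -----------------------------------------------------
    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        if not self.genotypes_high or not self.genotypes_low:
            raise ConfigurationError("genotypes_high and genotypes_low must be non-empty")
        if set(self.genotypes_high) & set(self.genotypes_low):
            raise ConfigurationError("genotypes_high and genotypes_low must be disjoint")
        n_geno = len(self.genotypes_high) + len(self.genotypes_low)
        if len(set(self.genotypes_high)) + len(set(self.genotypes_low)) != n_geno:
            raise ConfigurationError("genotype labels must be unique")
        if self.libs_per_genotype < 1:
            raise ConfigurationError("libs_per_genotype must be >= 1")
        lo, hi = self.baseline_log2_mean_range
        if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
            raise ConfigurationError("baseline_log2_mean_range must be a finite interval")
        if self.dispersion < 0:
            raise ConfigurationError("dispersion must be >= 0")
        if self.n_true_de < 0 or self.n_outlier_genes < 0:
            raise ConfigurationError("n_true_de and n_outlier_genes must be >= 0")
        if self.n_true_de + self.n_outlier_genes > self.n_genes:
            raise ConfigurationError("n_true_de + n_outlier_genes must be <= n_genes")
        if self.lib_size_jitter < 0 or self.lib_size_jitter >= 1:
            raise ConfigurationError("lib_size_jitter must be in [0, 1)")
        n_libs = n_geno * self.libs_per_genotype
        if self.lib_size_factors is not None:
            s = np.asarray(self.lib_size_factors, dtype=float)
            if s.shape != (n_libs,):
                raise ConfigurationError(
                    f"lib_size_factors must have length {n_libs}, got {s.size}"
                )
            if np.any(s <= 0) or not np.all(np.isfinite(s)):
                raise ConfigurationError("lib_size_factors must be positive and finite")

    @property
    def genotypes(self) -> tuple[str, ...]:
        return self.genotypes_high + self.genotypes_low

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class GroundTruth:
    """Which simulated genes carry which effect.

    ``de_genes`` maps gene id -> sign of beta (+1/-1); ``outlier_genes``
    maps gene id -> (genotype, sign of gamma).  The three id sets
    partition the simulated genes.
    """

    de_genes: dict[str, int]
    outlier_genes: dict[str, tuple[str, int]]
    null_genes: frozenset[str]

    def to_json(self) -> str:
        return json.dumps(
            {
                "de_genes": self.de_genes,
                "outlier_genes": {g: list(v) for g, v in self.outlier_genes.items()},
                "null_genes": sorted(self.null_genes),
            },
            indent=2,
        )


@dataclass
class CountMatrix:
    """A nonnegative integer gene x library count matrix."""

    gene_ids: list[str]
    library_ids: list[str]
    counts: np.ndarray  # shape (n_genes, n_libraries), integer dtype

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ConfigurationError("counts must be a 2-D array")
        if self.counts.shape != (len(self.gene_ids), len(self.library_ids)):
            raise ConfigurationError("counts shape does not match gene/library ids")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ConfigurationError("gene ids must be unique")
        if len(set(self.library_ids)) != len(self.library_ids):
            raise ConfigurationError("library ids must be unique")
        if len(self.gene_ids) < 1 or len(self.library_ids) < 2:
            raise ConfigurationError("need at least 1 gene and 2 libraries")
        if np.any(self.counts < 0):
            raise ConfigurationError("counts must be nonnegative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.library_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CountMatrix":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy())

    def subset_libraries(self, library_ids: Sequence[str]) -> "CountMatrix":
        idx = [self.library_ids.index(l) for l in library_ids]
        return CountMatrix(list(self.gene_ids), list(library_ids), self.counts[:, idx])


# ---------------------------------------------------------------------------
# count generation
# ---------------------------------------------------------------------------

def _make_design(config: SimConfig) -> pd.DataFrame:
    rows = []
    for geno in config.genotypes:
        group = "high" if geno in config.genotypes_high else "low"
        for r in range(1, config.libs_per_genotype + 1):
            rows.append({"library_id": f"{geno}_L{r}", "genotype": geno,
                         "group": group, "replicate": r})
    return pd.DataFrame(rows, columns=["library_id", "genotype", "group", "replicate"])


def generate_counts(config: SimConfig) -> tuple[CountMatrix, pd.DataFrame, GroundTruth]:
    """Draw a count matrix, its sample design and the ground truth.

    Counts are NB via a Gamma-Poisson mixture: library *i*, gene *g* has
    mean ``mu_gi = s_i * 2**(b_g + beta_g * x_i + gamma_g * [genotype(i) == o_g])``
    with ``x_i`` the high-group indicator and variance ``mu + phi_g mu^2``;
    ``phi_g = 0`` short-circuits to Poisson.  Group-effect signs alternate
    (+beta, -beta, ...) and outlier genotypes rotate round-robin through
    the genotype list so both groups host outliers.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    design = _make_design(config)

    n_genes = config.n_genes
    gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    lib_ids = design["library_id"].tolist()
    n_libs = len(lib_ids)

    lo, hi = config.baseline_log2_mean_range
    b = rng.uniform(lo, hi, size=n_genes)

    if config.lib_size_factors is not None:
        s = np.asarray(config.lib_size_factors, dtype=float)
    elif config.lib_size_jitter > 0:
        s = rng.uniform(1 - config.lib_size_jitter, 1 + config.lib_size_jitter, size=n_libs)
    else:
        s = np.ones(n_libs)

    beta = np.zeros(n_genes)
    de_genes: dict[str, int] = {}
    for j in range(config.n_true_de):
        sign = 1 if j % 2 == 0 else -1
        beta[j] = sign * config.de_log2fc
        de_genes[gene_ids[j]] = sign

    genotypes = list(config.genotypes)
    gamma = np.zeros(n_genes)
    outlier_geno_idx = np.full(n_genes, -1)
    outlier_genes: dict[str, tuple[str, int]] = {}
    for j in range(config.n_outlier_genes):
        g = config.n_true_de + j
        geno = genotypes[j % len(genotypes)]
        gamma[g] = config.outlier_log2fc
        outlier_geno_idx[g] = j % len(genotypes)
        outlier_genes[gene_ids[g]] = (geno, 1 if config.outlier_log2fc >= 0 else -1)

    x_high = (design["group"] == "high").to_numpy().astype(float)
    geno_idx = np.array([genotypes.index(g) for g in design["genotype"]])

    log2_mu = (
        b[:, None]
        + beta[:, None] * x_high[None, :]
        + gamma[:, None] * (geno_idx[None, :] == outlier_geno_idx[:, None])
    )
    mu = s[None, :] * np.exp2(log2_mu)

    phi = float(config.dispersion)
    if phi == 0:
        counts = rng.poisson(mu)
    else:
        lam = rng.gamma(shape=1.0 / phi, scale=phi * mu)
        counts = rng.poisson(lam)

    truth = GroundTruth(
        de_genes=de_genes,
        outlier_genes=outlier_genes,
        null_genes=frozenset(gene_ids[config.n_true_de + config.n_outlier_genes:]),
    )
    return CountMatrix(gene_ids, lib_ids, counts.astype(np.int64)), design, truth


# ---------------------------------------------------------------------------
# metabolite panel
# ---------------------------------------------------------------------------

def generate_metabolites(
    genotypes_high: Sequence[str] = ("205", "304", "667"),
    genotypes_low: Sequence[str] = ("SH", "313", "DH"),
    n_metabolites: int = 19,
    n_discriminating: int = 7,
    effect_fraction: float = 1.0,
    cv: float = 0.15,
    reps: int = 3,
    seed: int = 0,
    base_range: tuple[float, float] = (1.0, 100.0),
) -> pd.DataFrame:
    """Simulate a replicated metabolite concentration panel (mg/L).

    The first ``n_discriminating`` metabolites have every high-group
    genotype mean scaled by ``1 + effect_fraction``; replicate values are
    Gaussian around the genotype mean with coefficient of variation
    ``cv``, truncated at 0.  Returns tidy records
    (genotype, replicate, metabolite, concentration).
    """
    genotypes_high = list(genotypes_high)
    genotypes_low = list(genotypes_low)
    if not genotypes_high or not genotypes_low:
        raise ConfigurationError("both genotype groups must be non-empty")
    if set(genotypes_high) & set(genotypes_low):
        raise ConfigurationError("genotype groups must be disjoint")
    if n_discriminating > n_metabolites:
        raise ConfigurationError("n_discriminating must be <= n_metabolites")
    if reps < 2:
        raise ConfigurationError("reps must be >= 2 for downstream ANOVA")
    if cv <= 0:
        raise ConfigurationError("cv must be > 0")

    rng = np.random.default_rng(seed)
    if n_metabolites <= len(DEFAULT_METABOLITES):
        names = list(DEFAULT_METABOLITES[:n_metabolites])
    else:
        names = [f"metabolite_{i:02d}" for i in range(n_metabolites)]

    base = np.exp(rng.uniform(np.log(base_range[0]), np.log(base_range[1]),
                              size=n_metabolites))
    rows = []
    for m, name in enumerate(names):
        discriminating = m < n_discriminating
        for geno in genotypes_high + genotypes_low:
            mean = base[m]
            if discriminating and geno in genotypes_high:
                mean = mean * (1.0 + effect_fraction)
            vals = rng.normal(mean, cv * mean, size=reps)
            vals = np.clip(vals, 0.0, None)
            for r, v in enumerate(vals, start=1):
                rows.append({"genotype": geno, "replicate": r,
                             "metabolite": name, "concentration": float(v)})
    return pd.DataFrame(rows, columns=["genotype", "replicate", "metabolite",
                                       "concentration"])


# ---------------------------------------------------------------------------
# qPCR Ct table
# ---------------------------------------------------------------------------

def generate_ct_table(
    gene_log2fc_map: dict[str, float],
    ct_housekeeping: float = 20.0,
    ct_base: float = 28.0,
    noise_sd: float = 0.0,
    reps: int = 3,
    seed: int = 0,
    housekeeping_gene: str = "EIF5A",
) -> pd.DataFrame:
    """Simulate a qPCR Ct table consistent with a set of log2 fold changes.

    For each target gene the high-group Ct is ``ct_base - log2fc`` (one
    PCR cycle per doubling of template) plus Gaussian noise; the
    housekeeping gene sits at ``ct_housekeeping`` in every sample.  With
    ``noise_sd = 0`` the 2^-ddCt readout recovers ``2**log2fc`` exactly.
    """
    if reps < 1:
        raise ConfigurationError("reps must be >= 1")
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for group in ("high", "low"):
        for r in range(1, reps + 1):
            sample = f"{group}_{r}"
            rows.append({
                "sample": sample, "group": group, "gene": housekeeping_gene,
                "ct": float(ct_housekeeping + rng.normal(0, noise_sd) if noise_sd else ct_housekeeping),
                "replicate": r,
            })
            for gene, lfc in gene_log2fc_map.items():
                ct = ct_base - (lfc if group == "high" else 0.0)
                if noise_sd:
                    ct += rng.normal(0, noise_sd)
                rows.append({"sample": sample, "group": group, "gene": gene,
                             "ct": float(ct), "replicate": r})
    return pd.DataFrame(rows, columns=["sample", "group", "gene", "ct", "replicate"])
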