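"""DE engine: TMM oracle equivalence, exact-test oracles, BH, DEG rule."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import pooldeg as pdg
from pooldeg import CountMatrix, DEResult, InputError
from pooldeg.diffexpr import exact_nb_pvalue, _betabinom_logpmf


# ---------------------------------------------------------------------------
# TMM
# ---------------------------------------------------------------------------

def _avg_rank(x):
    """Average ranks (1-based) coded without scipy, for the oracle."""
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x))
    sx = x[order]
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def tmm_oracle(x, trim_m=0.30, trim_a=0.05):
    """Straight-from-the-formula TMM, coded independently of the package."""
    x = np.asarray(x, float)
    lib = x.sum(0)
    f75 = np.array([np.quantile(x[:, i] / lib[i], 0.75) for i in range(x.shape[1])])
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    out = np.ones(x.shape[1])
    for i in range(x.shape[1]):
        if i == ref:
            continue
        y, r = x[:, i], x[:, ref]
        pos = (y > 0) & (r > 0)
        m = np.log2((y[pos] / lib[i]) / (r[pos] / lib[ref]))
        a = 0.5 * np.log2((y[pos] / lib[i]) * (r[pos] / lib[ref]))
        w = (lib[i] - y[pos]) / (lib[i] * y[pos]) + (lib[ref] - r[pos]) / (lib[ref] * r[pos])
        n = m.size
        rm, ra = _avg_rank(m), _avg_rank(a)
        lo_m = np.floor(n * trim_m) + 1
        lo_a = np.floor(n * trim_a) + 1
        keep = ((rm >= lo_m) & (rm <= n + 1 - lo_m)
                & (ra >= lo_a) & (ra <= n + 1 - lo_a))
        out[i] = 2 ** (np.sum(w[keep] * m[keep]) / np.sum(w[keep]))
    return out / np.exp(np.mean(np.log(out)))


def random_counts(rng, n_genes=50, n_libs=4):
    mu = rng.uniform(5, 500, size=(n_genes, 1)) * rng.uniform(0.7, 1.3, size=n_libs)
    x = rng.negative_binomial(5, 5 / (5 + mu))
    x[0] += 1  # keep every library nonzero somewhere
    return CountMatrix([f"g{i}" for i in range(n_genes)],
                       [f"L{j}" for j in range(n_libs)], x)


class TestTMM:
    def test_identical_libraries_give_unit_factors(self):
        col = np.arange(1, 41)
        cm = CountMatrix([f"g{i}" for i in range(40)], list("abcd"),
                         np.tile(col[:, None], (1, 4)))
        assert np.array_equal(pdg.tmm_factors(cm).factors, np.ones(4))

    def test_doubled_library_gives_unit_factors(self):
        rng = np.random.default_rng(0)
        col = rng.integers(1, 200, size=60)
        cm = CountMatrix([f"g{i}" for i in range(60)], ["a", "b"],
                         np.column_stack([col, 2 * col]))
        np.testing.assert_allclose(pdg.tmm_factors(cm).factors, 1.0, atol=1e-12)

    def test_matches_independent_oracle_on_seeded_matrices(self):
        for seed in range(20):
            cm = random_counts(np.random.default_rng(seed))
            got = pdg.tmm_factors(cm).factors
            np.testing.assert_allclose(got, tmm_oracle(cm.counts), rtol=1e-10)

    def test_geometric_mean_one_and_permutation(self):
        cm = random_counts(np.random.default_rng(5), n_libs=6)
        nf = pdg.tmm_factors(cm)
        assert abs(np.mean(np.log(nf.factors))) < 1e-9
        perm = [3, 0, 5, 1, 4, 2]
        cm2 = CountMatrix(cm.gene_ids, [cm.library_ids[i] for i in perm],
                          cm.counts[:, perm])
        nf2 = pdg.tmm_factors(cm2)
        np.testing.assert_allclose(nf2.factors, nf.factors[perm], rtol=1e-10)

    def test_zero_library_raises(self):
        cm = CountMatrix(["g1", "g2"], ["a", "b"], np.array([[1, 0], [2, 0]]))
        with pytest.raises(InputError):
            pdg.tmm_factors(cm)


# ---------------------------------------------------------------------------
# CPM and filtering
# ---------------------------------------------------------------------------

def unit_factors(cm):
    return pdg.NormFactors(tuple(cm.library_ids), np.ones(len(cm.library_ids)),
                           cm.library_ids[0])


class TestCpmFilter:
    def test_cpm_arithmetic(self):
        x = np.zeros((2, 2), dtype=int)
        x[0] = [50, 50]
        x[1] = [2 * 10 ** 6 - 50, 2 * 10 ** 6 - 50]
        cm = CountMatrix(["g1", "g2"], ["a", "b"], x)
        c = pdg.cpm(cm, unit_factors(cm))
        assert c.loc["g1", "a"] == pytest.approx(25.0)

    def test_factor_halves_cpm(self):
        cm = random_counts(np.random.default_rng(1))
        f1 = unit_factors(cm)
        c1 = pdg.cpm(cm, f1)
        f2 = pdg.NormFactors(tuple(cm.library_ids),
                             np.array([2.0, 1, 1, 0.5]), cm.library_ids[0])
        c2 = pdg.cpm(cm, f2)
        np.testing.assert_allclose(c2.iloc[:, 0], c1.iloc[:, 0] / 2)

    def test_filter_rules(self):
        cm = random_counts(np.random.default_rng(2))
        f = unit_factors(cm)
        x = cm.counts.copy()
        x[3] = 0  # all-zero gene
        cm = CountMatrix(cm.gene_ids, cm.library_ids, x)
        kept = pdg.filter_low_expression(cm, f)
        assert "g3" not in kept.gene_ids
        assert pdg.filter_low_expression(cm, f, min_libraries=0).gene_ids == cm.gene_ids

    def test_filter_boundary_inclusive(self):
        # above threshold in exactly min_libraries libraries -> kept
        x = np.ones((30, 4), dtype=int)
        x[0] = [5000, 5000, 0, 0]
        cm = CountMatrix([f"g{i}" for i in range(30)], list("abcd"), x)
        kept = pdg.filter_low_expression(cm, unit_factors(cm), min_cpm=1,
                                         min_libraries=2)
        assert "g0" in kept.gene_ids

    def test_misaligned_factors_raise(self):
        cm = random_counts(np.random.default_rng(3))
        f = pdg.NormFactors(("x", "y", "z", "w"), np.ones(4), "x")
        with pytest.raises(InputError):
            pdg.cpm(cm, f)


# ---------------------------------------------------------------------------
# dispersion
# ---------------------------------------------------------------------------

class TestDispersion:
    @pytest.mark.parametrize("phi,band", [(0.0, (0.0, 0.01)), (0.4, (0.2, 0.6))])
    def test_recovery(self, phi, band):
        cfg = pdg.SimConfig(n_genes=2000, genotypes_high=("A",),
                            genotypes_low=("B",), libs_per_genotype=6,
                            dispersion=phi, n_true_de=0, n_outlier_genes=0,
                            seed=11)
        counts, design, _ = pdg.generate_counts(cfg)
        f = pdg.tmm_factors(counts)
        est = pdg.estimate_dispersion(counts, f, design["genotype"])
        assert band[0] <= np.median(est) <= band[1]

    def test_constant_counts_clamp_to_floor(self):
        x = np.full((5, 4), 100, dtype=int)
        cm = CountMatrix([f"g{i}" for i in range(5)], list("abcd"), x)
        est = pdg.estimate_dispersion(cm, unit_factors(cm), ["u", "u", "v", "v"])
        assert (est <= 1e-3).all()

    def test_no_replication_falls_back(self):
        cm = random_counts(np.random.default_rng(4))
        with pytest.warns(UserWarning):
            est = pdg.estimate_dispersion(cm, unit_factors(cm),
                                          ["a", "b", "c", "d"])
        assert (est == 0.1).all()


# ---------------------------------------------------------------------------
# exact test
# ---------------------------------------------------------------------------

def enumeration_oracle(k, s, n1, n2, phi):
    """Conditional two-sided p by direct NB-product enumeration."""
    ks = np.arange(s + 1)
    r1, r2 = n1 / phi, n2 / phi
    pm = stats.nbinom.pmf(ks, r1, 0.3) * stats.nbinom.pmf(s - ks, r2, 0.3)
    pm = pm / pm.sum()
    return min(1.0, pm[pm <= pm[k] * (1 + 1e-12)].sum())


class TestExactPvalue:
    def test_matches_enumeration_oracle_small_totals(self):
        """Exhaustive agreement with conditional enumeration, totals <= 30."""
        for phi in (0.5, 2.0):
            for s in range(1, 31):
                for k in range(s + 1):
                    got = exact_nb_pvalue(k, s, 1, 1, phi)
                    want = enumeration_oracle(k, s, 1, 1, phi)
                    assert got == pytest.approx(want, rel=1e-10, abs=1e-12)

    def test_betabinom_pmf_against_scipy(self):
        ks = np.arange(26)
        got = _betabinom_logpmf(ks, 25, 4.0, 7.5)
        want = stats.betabinom.logpmf(ks, 25, 4.0, 7.5)
        np.testing.assert_allclose(got, want, rtol=1e-10)

    def test_poisson_limit_is_exact_binomial(self):
        """phi -> 0 with counts (3 | 13): two-sided binomial test of
        3/16 at p = 1/2."""
        want = stats.binomtest(3, 16, 0.5).pvalue
        assert exact_nb_pvalue(3, 16, 1, 1, 0.0) == pytest.approx(want, rel=1e-12)

    def test_zero_total(self):
        assert exact_nb_pvalue(0, 0, 2, 2, 0.1) == 1.0

    def test_large_total_normal_approximation_continuity(self):
        p_enum = exact_nb_pvalue(5400, 10000, 2, 2, 0.1)
        p_norm = exact_nb_pvalue(5400, 10000, 2, 2, 0.1, max_enumerate=5000)
        assert p_norm == pytest.approx(p_enum, rel=0.2)


def two_group_case(rng, n_genes=40):
    cfg = pdg.SimConfig(n_genes=n_genes, n_true_de=5, n_outlier_genes=0,
                        de_log2fc=3.0, seed=int(rng.integers(2 ** 16)))
    counts, design, _ = pdg.generate_counts(cfg)
    f = pdg.tmm_factors(counts)
    return counts, design, f


class TestNbExactTest:
    def test_symmetric_null(self):
        x = np.tile(np.arange(1, 21)[:, None], (1, 4))
        cm = CountMatrix([f"g{i}" for i in range(20)], list("abcd"), x)
        res = pdg.nb_exact_test(cm, unit_factors(cm),
                                ["high", "high", "low", "low"], 0.1)
        assert np.allclose(res.table["log2FC"], 0.0)
        assert np.allclose(res.table["p_value"], 1.0)

    def test_label_swap_antisymmetry(self):
        rng = np.random.default_rng(12)
        counts, design, f = two_group_case(rng)
        phi = 0.1
        labels = design["group"].tolist()
        swapped = ["low" if l == "high" else "high" for l in labels]
        r1 = pdg.nb_exact_test(counts, f, labels, phi)
        r2 = pdg.nb_exact_test(counts, f, swapped, phi)
        np.testing.assert_allclose(r2.table["log2FC"], -r1.table["log2FC"],
                                   rtol=1e-10)
        np.testing.assert_allclose(r2.table["p_value"], r1.table["p_value"],
                                   rtol=1e-10)

    def test_zero_count_gene(self):
        x = np.ones((3, 4), dtype=int) * 50
        x[1] = 0
        cm = CountMatrix(["a", "b", "c"], list("wxyz"), x)
        res = pdg.nb_exact_test(cm, unit_factors(cm),
                                ["high", "high", "low", "low"], 0.1)
        row = res.table.set_index("gene_id").loc["b"]
        assert row["p_value"] == 1.0 and row["log2FC"] == 0.0

    def test_power_monotone_in_effect_size(self):
        """Detection rate of true DE genes is non-decreasing in |beta|."""
        rates = []
        for beta in (0.5, 1.0, 2.0):
            det = 0
            for seed in range(3):
                cfg = pdg.SimConfig(n_genes=500, n_true_de=50,
                                    n_outlier_genes=0, de_log2fc=beta,
                                    seed=100 + seed)
                counts, design, truth = pdg.generate_counts(cfg)
                f = pdg.tmm_factors(counts)
                phi = pdg.estimate_dispersion(counts, f, design["genotype"])
                res = pdg.nb_exact_test(counts, f, design["group"], phi)
                degs = pdg.call_degs(res)
                det += len(degs.genes & set(truth.de_genes))
            rates.append(det / 150)
        assert rates[0] <= rates[1] <= rates[2]

    def test_requires_two_groups(self):
        cm = random_counts(np.random.default_rng(6))
        with pytest.raises(InputError):
            pdg.nb_exact_test(cm, unit_factors(cm), ["high"] * 4, 0.1)


# ---------------------------------------------------------------------------
# DEG rule and BH
# ---------------------------------------------------------------------------

class TestCallDegs:
    @pytest.mark.parametrize("lfc,fdr,included,direction", [
        (1.0, 0.01, True, "up"),      # boundary inclusive on |log2FC| >= 1
        (0.9, 1e-8, False, None),
        (-2.0, 0.2, False, None),     # FDR gate
        (-1.5, 0.05, True, "down"),   # boundary inclusive on FDR
    ])
    def test_rule(self, lfc, fdr, included, direction):
        res = DEResult("c", pd.DataFrame({
            "gene_id": ["g"], "log2FC": [lfc], "logCPM": [5.0],
            "p_value": [fdr], "fdr": [fdr]}))
        degs = pdg.call_degs(res)
        assert ("g" in degs) == included
        if included:
            assert degs.directions["g"] == direction


class TestBH:
    def test_hand_computed_stepup(self):
        np.testing.assert_allclose(pdg.bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_and_degenerate(self):
        assert pdg.bh_adjust([0.3])[0] == pytest.approx(0.3)
        assert (pdg.bh_adjust([1.0, 1.0, 1.0]) == 1.0).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(InputError):
            pdg.bh_adjust([0.5, 1.5])

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30),
           st.randoms(use_true_random=False))
    def test_order_invariance(self, pvals, rnd):
        p = np.array(pvals)
        perm = np.arange(len(p))
        rnd.shuffle(perm)
        adj = pdg.bh_adjust(p)
        adj_perm = pdg.bh_adjust(p[perm])
        np.testing.assert_allclose(adj_perm, adj[perm], rtol=1e-12)
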