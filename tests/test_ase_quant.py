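"""TMM normalization, filters, NB exact test and q-values."""

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from hybridase.ase_quant import (AlleleCountTable, NormalizationError, apply_filters,
                                 ase_test, bh_adjust, estimate_common_dispersion,
                                 estimate_pi0, qvalues, run_ase, tmm_factors)
from hybridase.sim import SimConfig, simulate_study


def brute_tmm(mat, trim_m=0.3, trim_a=0.05):
    """Straightforward loop re-implementation of the pinned TMM definition."""
    lib = mat.sum(axis=0)
    uq = np.array([np.percentile(mat[:, j] / lib[j], 75) for j in range(mat.shape[1])])
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    factors = np.ones(mat.shape[1])
    for j in range(mat.shape[1]):
        if j == ref:
            continue
        m_vals, a_vals, w_vals = [], [], []
        for g in range(mat.shape[0]):
            y, r = mat[g, j], mat[g, ref]
            if y > 0 and r > 0:
                m_vals.append(np.log2((y / lib[j]) / (r / lib[ref])))
                a_vals.append(0.5 * np.log2((y / lib[j]) * (r / lib[ref])))
                w_vals.append((lib[j] - y) / (lib[j] * y) + (lib[ref] - r) / (lib[ref] * r))
        m_vals, a_vals, w_vals = map(np.array, (m_vals, a_vals, w_vals))
        if len(m_vals) == 0 or np.max(np.abs(m_vals)) < 1e-6:
            continue
        n = len(m_vals)
        rm, ra = stats.rankdata(m_vals), stats.rankdata(a_vals)
        keep = ((rm >= np.floor(n * trim_m) + 1) & (rm <= n - np.floor(n * trim_m))
                & (ra >= np.floor(n * trim_a) + 1) & (ra <= n - np.floor(n * trim_a)))
        if keep.any() and w_vals[keep].sum() > 0:
            factors[j] = 2 ** (np.sum(w_vals[keep] * m_vals[keep]) / np.sum(w_vals[keep]))
    return factors / np.exp(np.mean(np.log(factors)))


def make_table(mat, n_rep=3):
    genes = [f"g{i}" for i in range(mat.shape[0])]
    n_col = mat.shape[1]
    assert n_col % (2 * n_rep) == 0
    cols = []
    for h in range(n_col // (2 * n_rep)):
        for a in ("S1", "S2"):
            for r in range(1, n_rep + 1):
                cols.append((f"H{h}", a, r))
    df = pd.DataFrame(mat, index=pd.Index(genes, name="gene"),
                      columns=pd.MultiIndex.from_tuples(cols, names=["hybrid", "allele", "replicate"]))
    return AlleleCountTable(df)


class TestTmm:
    def test_identical_columns_unit_factors(self):
        mat = np.tile(np.arange(1, 21)[:, None], (1, 4))
        np.testing.assert_allclose(tmm_factors(pd.DataFrame(mat)), 1.0)

    def test_pure_scaling_absorbed_by_library_size(self):
        rng = np.random.default_rng(0)
        col = rng.integers(1, 500, size=30)
        mat = np.column_stack([col, 3 * col])
        np.testing.assert_allclose(tmm_factors(pd.DataFrame(mat)), 1.0, atol=1e-12)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            mat = rng.negative_binomial(5, 0.05, size=(20, 6)).astype(float)
            mat[rng.random(mat.shape) < 0.1] = 0
            mat += (mat.sum(axis=1, keepdims=True) == 0)  # avoid all-zero rows
            got = tmm_factors(pd.DataFrame(mat)).to_numpy()
            np.testing.assert_allclose(got, brute_tmm(mat), atol=1e-10)

    def test_geometric_mean_is_one(self):
        rng = np.random.default_rng(2)
        mat = rng.poisson(50, size=(40, 5)).astype(float) + 1
        f = tmm_factors(pd.DataFrame(mat)).to_numpy()
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_column_error_names_column(self):
        mat = pd.DataFrame({"a": [1, 2], "b": [0, 0]})
        with pytest.raises(NormalizationError, match="b"):
            tmm_factors(mat)


class TestFilters:
    def test_uda_boundary(self):
        mat = np.full((1, 12), 10)
        table = make_table(mat)
        assert apply_filters(table).loc["g0", "uda"]

    def test_single_low_replicate_breaks_uda_not_detectable(self):
        mat = np.full((1, 12), 50)
        mat[0, 0] = 9  # one allele below threshold in one replicate of H0
        table = make_table(mat)
        flags = apply_filters(table)
        assert not flags.loc["g0", "uda"]
        assert flags.loc["g0", "detectable_H0"]  # other replicates qualify
        assert flags.loc["g0", "detectable_H1"]

    def test_matches_double_loop_recheck(self):
        rng = np.random.default_rng(3)
        mat = rng.integers(0, 30, size=(25, 12))
        table = make_table(mat)
        flags = apply_filters(table, min_reads=10)
        counts = table.counts
        for g in table.genes:
            uda = True
            for h in table.hybrids:
                a1, a2 = table.alleles(h)
                det = False
                for r in counts[h][a1].columns:
                    c1, c2 = counts[h][a1][r][g], counts[h][a2][r][g]
                    det = det or (c1 >= 10 and c2 >= 10)
                    uda = uda and (c1 >= 10 and c2 >= 10)
                assert flags.loc[g, f"detectable_{h}"] == det
            assert flags.loc[g, "uda"] == uda


def brute_exact_p(s1, s2, n1, n2, phi):
    """Full enumeration of the conditional distribution (independent oracle)."""
    t = s1 + s2
    if t == 0:
        return 1.0
    if phi == 0:
        pmf = np.array([stats.binom.pmf(x, t, n1 / (n1 + n2)) for x in range(t + 1)])
    else:
        mu = t / (n1 + n2)
        r1, r2 = n1 / phi, n2 / phi
        pmf = np.zeros(t + 1)
        for x in range(t + 1):
            la = (special.gammaln(x + r1) - special.gammaln(r1) - special.gammaln(x + 1)
                  + r1 * np.log(r1 / (r1 + n1 * mu)) + x * np.log(n1 * mu / (r1 + n1 * mu)))
            y = t - x
            lb = (special.gammaln(y + r2) - special.gammaln(r2) - special.gammaln(y + 1)
                  + r2 * np.log(r2 / (r2 + n2 * mu)) + y * np.log(n2 * mu / (r2 + n2 * mu)))
            pmf[x] = np.exp(la + lb)
        pmf /= pmf.sum()
    obs = pmf[s1]
    return min(1.0, pmf[pmf <= obs * (1 + 1e-9)].sum())


class TestAseTest:
    def test_symmetric_null_mode(self):
        m, p = ase_test([10, 10, 10], [10, 10, 10], [100.0] * 3, [100.0] * 3, 0.05)
        assert m == 0.0 and p == 1.0

    def test_conditional_binomial_closed_form(self):
        # totals 3 vs 0, single pooled pair, equal sizes, phi = 0
        _, p = ase_test([3], [0], [100.0], [100.0], 0.0)
        assert p == pytest.approx(0.25, abs=1e-12)

    @pytest.mark.parametrize("phi", [0.0, 0.1])
    def test_small_total_fixtures_match_enumeration(self, phi):
        rng = np.random.default_rng(7)
        for _ in range(30):
            c1 = rng.integers(0, 8, size=3)
            c2 = rng.integers(0, 8, size=3)
            _, p = ase_test(c1, c2, [500.0] * 3, [500.0] * 3, phi)
            expected = brute_exact_p(int(c1.sum()), int(c2.sum()), 3, 3, phi)
            assert p == pytest.approx(expected, abs=1e-12)

    def test_allele_swap_negates_m_keeps_p(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            c1, c2 = rng.integers(0, 60, 3), rng.integers(0, 60, 3)
            e = [1000.0] * 3
            m1, p1 = ase_test(c1, c2, e, e, 0.05)
            m2, p2 = ase_test(c2, c1, e, e, 0.05)
            assert m1 == pytest.approx(-m2, abs=1e-12)
            assert p1 == pytest.approx(p2, abs=1e-12)

    def test_zero_library_size_rejected(self):
        with pytest.raises(ValueError):
            ase_test([1], [1], [0.0], [1.0], 0.0)


class TestCommonDispersion:
    @pytest.mark.parametrize("phi_true,lo,hi", [(0.0, 0.0, 0.01), (0.1, 0.07, 0.13)])
    def test_simulation_recovery(self, phi_true, lo, hi):
        cfg = SimConfig(n_genes=2000, n_strains=2, dispersion=phi_true, seed=17)
        study = simulate_study(cfg)
        phi_hat = estimate_common_dispersion(study.table, "S1xS2")
        assert lo <= phi_hat <= hi

    def test_identical_replicates_boundary(self):
        mat = np.array([[40, 40, 40, 20, 20, 20]])
        table = make_table(mat)
        assert estimate_common_dispersion(table, "H0") <= 0.01


class TestQvalues:
    def test_pi0_one_equals_bh(self):
        p = np.array([0.01, 0.2, 0.5, 0.04, 0.9])
        np.testing.assert_allclose(qvalues(p, method="bh"), bh_adjust(p))

    def test_uniform_pi0_near_one(self):
        rng = np.random.default_rng(9)
        p = rng.random(10_000)
        assert 0.9 <= estimate_pi0(p) <= 1.0

    def test_single_p(self):
        np.testing.assert_allclose(qvalues(np.array([0.05]), method="bh"), [0.05])

    def test_q_monotone_in_p_rank(self):
        rng = np.random.default_rng(10)
        p = rng.random(500) ** 2
        q = qvalues(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            qvalues(np.array([0.5, 1.2]))


class TestRunAse:
    def test_recovers_planted_cis_genes(self, small_study):
        res = run_ase(small_study.table)
        truth = small_study.truth.cis
        effect_genes = set(truth.index[(truth != 0).any(axis=1)])
        sig = res[(res.q < 0.05)]
        # discoveries should be heavily enriched in planted genes
        assert len(sig) > 0
        assert sig.gene.isin(effect_genes).mean() > 0.8

    def test_m_sign_follows_truth(self, small_study):
        res = run_ase(small_study.table).set_index(["gene", "hybrid"])
        truth = small_study.truth
        checked = 0
        for g in truth.genes:
            for s1, s2 in small_study.config.hybrids:
                eff = truth.cis_effect(g, s1, s2)
                if abs(eff) < 0.5:
                    continue
                row = res.loc[(g, f"{s1}x{s2}")]
                if row.q < 0.05:
                    assert np.sign(row.M) == np.sign(eff)
                    checked += 1
        assert checked > 20
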