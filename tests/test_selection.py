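"""Truncation/threshold selection, BLUP/GBLUP mixed models, OCS, accuracy."""

import numpy as np
import pytest

from breedsim import (ConfigError, InfeasibleError, Pedigree,
                      estimate_ebv_blup, estimate_ebv_gblup, ocs_select,
                      selection_accuracy, solve_mme, threshold_select,
                      truncation_select)
from breedsim.selection import (ReferencePopulation, SelectionRule,
                                largest_remainder_apportionment)


class TestTruncation:
    def test_population_top_n_with_id_tie_break(self):
        values = np.array([1.0, 3.0, 3.0, 2.0])
        ids = np.array([40, 30, 20, 10])
        sel = truncation_select(values, 2, ids=ids)
        assert sel.tolist() == [1, 2]  # both 3.0s; ids 20 < 30 irrelevant to set
        sel = truncation_select(values, 1, ids=ids)
        assert sel.tolist() == [2]     # tie broken by ascending id

    def test_within_family_counts(self, rng):
        # 50 families x 10 plants, keep the best 5 per family
        fams = np.repeat(np.arange(50), 10)
        values = rng.normal(size=500)
        sel = truncation_select(values, 5, unit="within_family", families=fams)
        assert sel.size == 250
        assert np.all(np.bincount(fams[sel]) == 5)
        # every selected plant beats every unselected plant of its family
        for fam in range(50):
            pos = np.flatnonzero(fams == fam)
            picked = np.intersect1d(pos, sel)
            assert values[picked].min() >= np.delete(values[pos],
                                                     np.searchsorted(pos, picked)).max()

    def test_entire_family_ranks_on_sums(self):
        fams = np.array([0, 0, 1, 1, 2, 2])
        values = np.array([1.0, 1.0, 3.0, -2.0, 0.8, 0.8])
        sel = truncation_select(values, 1, unit="entire_family", families=fams)
        assert fams[sel].tolist() == [0, 0]  # family 0 sums to 2.0, the max

    def test_select_all_is_identity(self, rng):
        v = rng.normal(size=7)
        assert truncation_select(v, 7).tolist() == list(range(7))

    def test_errors(self):
        with pytest.raises(ConfigError):
            truncation_select(np.ones(3), 4)
        with pytest.raises(ConfigError):
            truncation_select(np.ones(3), 1, unit="within_family")
        from breedsim.errors import SimulationError
        with pytest.raises(SimulationError):
            truncation_select(np.array([1.0, np.nan]), 1)


class TestThreshold:
    def test_basic_and_empty(self):
        v = np.array([1.0, 2.0, 3.0])
        assert threshold_select(v, -np.inf).size == 3
        assert threshold_select(v, 2.0).tolist() == [1, 2]
        with pytest.warns(UserWarning):
            assert threshold_select(v, 10.0).size == 0


class TestAccuracy:
    def test_perfect_and_independent(self, rng):
        g = rng.normal(size=5000)
        assert selection_accuracy(g, g) == pytest.approx(1.0)
        assert selection_accuracy(rng.normal(size=5000), g) == pytest.approx(0.0, abs=0.05)

    def test_phenotype_accuracy_is_sqrt_h2(self, rng):
        g = rng.normal(size=40_000)
        y = g + rng.normal(0, np.sqrt(3.0), size=g.size)  # h2 = 0.25
        assert selection_accuracy(y, g) == pytest.approx(0.5, abs=0.02)

    def test_family_sums(self, rng):
        fams = np.repeat(np.arange(100), 4)
        g = rng.normal(size=400)
        acc = selection_accuracy(g, g, families=fams)
        assert acc == pytest.approx(1.0)

    def test_zero_variance_is_nan_with_warning(self):
        with pytest.warns(UserWarning):
            assert np.isnan(selection_accuracy(np.ones(5), np.arange(5.0)))


class TestMixedModels:
    def test_scalar_shrinkage_with_known_mean(self):
        # single phenotyped non-inbred plant, h2 = 0.5, mean fixed at 0:
        # EBV = h2 * y
        ped = Pedigree()
        ped.add_base(False)
        u, _ = estimate_ebv_blup(np.array([2.0]), np.array([0]), ped,
                                 np.array([0]), 1.0, np.array([1.0]),
                                 fit_mean=False)
        assert u[0, 0] == pytest.approx(1.0)

    def test_shrinks_to_zero_as_sigma_g_vanishes(self):
        ped = Pedigree()
        for _ in range(4):
            ped.add_base(False)
        y = np.array([1.0, -2.0, 0.5, 3.0])
        u, _ = estimate_ebv_blup(y, np.arange(4), ped, np.arange(4),
                                 1e-10, np.ones(4))
        assert np.abs(u).max() < 1e-6

    def _random_pedigree_records(self, seed):
        rng = np.random.default_rng(seed)
        ped = Pedigree()
        for i in range(8):
            if i < 3:
                ped.add_base(False)
            elif rng.random() < 0.5:
                ped.add_self(int(rng.integers(i)), 1, 1, i)
            else:
                s, d = rng.integers(i, size=2)
                ped.add_cross(int(s), int(d), 1, 1, i)
        phen = rng.choice(8, size=6, replace=False)
        y = rng.normal(size=6)
        return ped, phen, y

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_blup_matches_gls_oracle(self, seed):
        # direct GLS on V = Z A Z' sg2 + R, u-hat = sg2 A Z' V^-1 (y - X b)
        ped, phen, y = self._random_pedigree_records(seed)
        sg2, se2 = 1.3, 2.0
        ids = np.arange(8)
        u, b = estimate_ebv_blup(y, phen, ped, ids, sg2, np.full(6, se2))
        A = ped.relationship_matrix(ids)
        Z = np.zeros((6, 8))
        Z[np.arange(6), phen] = 1.0
        V = sg2 * Z @ A @ Z.T + se2 * np.eye(6)
        Vi = np.linalg.inv(V)
        X = np.ones((6, 1))
        b_gls = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        u_gls = sg2 * A @ Z.T @ Vi @ (y - X @ b_gls)
        assert b[0] == pytest.approx(b_gls[0], abs=1e-8)
        assert np.allclose(u[:, 0], u_gls, atol=1e-8)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_solution_satisfies_mme_by_substitution(self, seed):
        ped, phen, y = self._random_pedigree_records(seed)
        sg2, se2 = 0.8, 1.5
        A = ped.relationship_matrix(np.arange(8))
        u, b = solve_mme(y, phen, np.zeros(6, dtype=int), A,
                         np.array([[sg2]]), np.full(6, se2))
        Z = np.zeros((6, 8))
        Z[np.arange(6), phen] = 1.0
        X = np.ones((6, 1))
        Ainv = np.linalg.inv(A)
        top = X.T @ X / se2 @ b[:, None] + X.T @ Z / se2 @ u - X.T @ y[:, None] / se2
        bot = (Z.T @ X / se2 @ b[:, None]
               + (Z.T @ Z / se2 + Ainv / sg2) @ u - Z.T @ y[:, None] / se2)
        assert np.abs(top).max() < 1e-8
        assert np.abs(bot).max() < 1e-8

    def test_gblup_equals_blup_when_g_is_a(self):
        ped, phen, y = self._random_pedigree_records(3)
        A = ped.relationship_matrix(np.arange(8))
        u_blup, _ = estimate_ebv_blup(y, phen, ped, np.arange(8), 1.0, np.ones(6))
        u_g, _ = estimate_ebv_gblup(None, None, y, phen, 1.0, np.ones(6), G=A)
        assert np.allclose(u_blup, u_g, atol=1e-10)

    def test_clone_candidate_gets_reference_plants_gebv(self, rng):
        Z = rng.integers(0, 3, (6, 80)).astype(float)
        Z[5] = Z[0]                      # candidate clones reference plant 0
        p = np.full(80, 0.5)
        y = rng.normal(size=5)
        u, _ = estimate_ebv_gblup(Z, p, y, np.arange(5), 1.0, np.ones(5))
        assert u[5, 0] == pytest.approx(u[0, 0], abs=1e-8)

    def test_gblup_accuracy_grows_with_reference_size(self):
        # Monte-Carlo: same simulated trait, three nested reference sizes
        accs = {n: [] for n in (25, 75, 200)}
        for rep in range(20):
            rng = np.random.default_rng(500 + rep)
            m, n_all, n_cand = 120, 200, 40
            p = rng.uniform(0.2, 0.8, m)
            Z = rng.binomial(2, p, size=(n_all + n_cand, m)).astype(float)
            a = rng.normal(0, 1 / np.sqrt(m), m)
            g = (Z - 2 * p) @ a
            g = g / g.std()
            y = g + rng.normal(0, 1.0, g.size)      # h2 = 0.5
            cand = np.arange(n_all, n_all + n_cand)
            for n_ref in accs:
                rows = np.arange(n_ref)
                keep = np.concatenate([rows, cand])
                u, _ = estimate_ebv_gblup(Z[keep], p, y[rows], np.arange(n_ref),
                                          1.0, np.ones(n_ref))
                accs[n_ref].append(np.corrcoef(u[n_ref:, 0], g[cand])[0, 1])
        means = [np.mean(accs[n]) for n in (25, 75, 200)]
        assert means[0] < means[1] < means[2]

    def test_multitrait_correlated_traits_share_information(self, rng):
        # records only on trait 0; high genetic correlation transfers signal
        # to trait 1 EBVs
        n = 30
        G = np.eye(n) + 0.0
        Sg = np.array([[1.0, 0.9], [0.9, 1.0]])
        y = rng.normal(size=n)
        u, _ = solve_mme(y, np.arange(n), np.zeros(n, dtype=int), G, Sg,
                         np.ones(n))
        assert np.corrcoef(u[:, 0], u[:, 1])[0, 1] > 0.99


class TestOCS:
    def test_omega_zero_concentrates_on_best(self):
        ebv = np.array([1.0, 3.0, 2.0])
        c, _ = ocs_select(ebv, np.eye(3), omega=0.0)
        assert np.allclose(c, [0, 1, 0])

    def test_omega_zero_respects_cap(self):
        ebv = np.array([1.0, 3.0, 2.0])
        c, _ = ocs_select(ebv, np.eye(3), omega=0.0, max_contribution=0.5)
        assert np.allclose(c, [0, 0.5, 0.5])

    def test_large_omega_identity_a_gives_uniform(self):
        ebv = np.array([1.0, 2.0, 3.0, 4.0])
        c, _ = ocs_select(ebv, np.eye(4), omega=1e6)
        assert np.allclose(c, 0.25, atol=1e-3)

    def test_penalty_monotone_in_omega(self, rng):
        n = 10
        M = rng.normal(size=(n, n))
        A = M @ M.T / n + np.eye(n)
        ebv = rng.normal(size=n)
        pen_prev = np.inf
        for omega in (0.01, 0.1, 1.0, 10.0, 100.0):
            c, _ = ocs_select(ebv, A, omega=omega)
            pen = c @ A @ c
            assert pen <= pen_prev + 1e-8
            pen_prev = pen

    def test_matches_grid_oracle_n3(self, rng):
        A = np.array([[1.0, 0.5, 0.0], [0.5, 1.0, 0.25], [0.0, 0.25, 1.0]])
        ebv = np.array([0.5, 1.0, 0.8])
        omega = 2.0
        c, _ = ocs_select(ebv, A, omega=omega)

        def u_of(c):
            return c @ ebv - omega * c @ A @ c

        best = -np.inf
        for c1 in np.arange(0, 1.0001, 0.01):
            for c2 in np.arange(0, 1.0001 - c1, 0.01):
                v = u_of(np.array([c1, c2, 1 - c1 - c2]))
                best = max(best, v)
        assert u_of(c) >= best - 1e-4

    def test_mating_apportionment(self):
        counts = largest_remainder_apportionment(np.array([0.5, 0.3, 0.2]), 10)
        assert counts.tolist() == [5, 3, 2]
        counts = largest_remainder_apportionment(np.array([1, 1, 1.0]), 10)
        assert counts.sum() == 10 and counts.max() - counts.min() <= 1

    def test_ocs_returns_matings(self):
        c, m = ocs_select(np.array([1.0, 2.0]), np.eye(2), omega=1.0,
                          n_matings=20)
        assert m.sum() == 20

    def test_invalid_inputs(self):
        with pytest.raises(ConfigError):
            ocs_select(np.array([1.0]), np.eye(1), omega=1.0)
        with pytest.raises(ConfigError):
            ocs_select(np.array([1.0, 2.0]), np.eye(2), omega=-1.0)
        with pytest.raises(InfeasibleError):
            ocs_select(np.array([1.0, 2.0]), np.eye(2), omega=0.0,
                       max_contribution=0.3)


class TestSelectionRuleAndReference:
    def test_rule_validation(self):
        with pytest.raises(ConfigError):
            SelectionRule(unit="within_family")       # family missing
        with pytest.raises(ConfigError):
            SelectionRule(unit="per_plant")

    def test_reference_population_append_only(self):
        ref = ReferencePopulation()
        ref.add_genotype(7, np.array([0, 1, 2]))
        ref.add_genotype(7, np.array([9, 9, 9]))      # idempotent
        assert ref.n_genotyped == 1
        assert ref.dosage_matrix()[0].tolist() == [0, 1, 2]
        ref.add_record("YP", 7, 1.5, 0.5)
        assert ref.records["YP"] == [(7, 1.5, 0.5)]
        from breedsim.errors import SimulationError
        with pytest.raises(SimulationError):
            ref.add_record("YP", 99, 1.0, 1.0)
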