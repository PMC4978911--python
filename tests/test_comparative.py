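"""Burden regressions, independent contrasts, and antimutator thresholds."""

import dendropy
import numpy as np
import pytest

from driftbarrier import (
    antimutator_threshold,
    loglog_regression,
    mutational_burden,
    origin_regression,
    pic_contrasts,
    reproduce_paper,
    subset_regression,
)
from driftbarrier.comparative_analysis import UNICELLULAR_GROUPS
from tests.conftest import random_bifurcating_newick


def ols_normal_equations(x, y):
    """Closed-form OLS oracle via the normal equations."""
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    sigma2 = resid @ resid / (len(x) - 2)
    cov = sigma2 * np.linalg.inv(X.T @ X)
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 1 - (resid @ resid) / ss_tot
    return beta[1], beta[0], np.sqrt(cov[1, 1]), np.sqrt(cov[0, 0]), r2


def brownian_covariance(tree: dendropy.Tree) -> tuple[list, np.ndarray]:
    """V[i,j] = root-to-MRCA path length under Brownian motion."""
    depth = {}
    for nd in tree.preorder_node_iter():
        parent = nd.parent_node
        edge = nd.edge.length or 0.0
        depth[nd] = (depth[parent] if parent else 0.0) + (edge if parent else 0.0)
    leaves = list(tree.leaf_node_iter())
    labels = [lf.taxon.label for lf in leaves]
    n = len(leaves)
    V = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                V[i, j] = depth[leaves[i]]
            else:
                mrca = dendropy.Tree.mrca(
                    tree, taxa=[leaves[i].taxon, leaves[j].taxon]
                )
                V[i, j] = depth[mrca]
    return labels, V


def gls_slope(V, x, y):
    """GLS slope of y on x (with intercept) under covariance V."""
    Vi = np.linalg.inv(V)
    one = np.ones(len(x))
    sxx = x @ Vi @ x - (one @ Vi @ x) ** 2 / (one @ Vi @ one)
    sxy = x @ Vi @ y - (one @ Vi @ x) * (one @ Vi @ y) / (one @ Vi @ one)
    return sxy / sxx


class TestMutationalBurden:
    def test_bacterial_burden_arithmetic(self, species_records):
        agt = next(r for r in species_records if r.label == "Agt")
        assert mutational_burden(agt) == pytest.approx(
            0.30e-10 * 0.50e7, rel=1e-9
        )
        assert mutational_burden(agt) == pytest.approx(1.5e-4)

    def test_log_identity(self, species_records):
        for r in species_records:
            assert np.log10(mutational_burden(r)) == pytest.approx(
                np.log10(r.u_id) + np.log10(r.Ge)
            )

    def test_unknown_genome_choice_rejected(self, species_records):
        with pytest.raises(ValueError):
            mutational_burden(species_records[0], "whole_genome")


class TestLogLogRegression:
    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            n = int(rng.integers(3, 30))
            x = rng.uniform(0.1, 100, n)
            y = 10 ** (rng.normal(0, 1) + rng.normal(0, 1) * np.log10(x)
                       + rng.normal(0, 0.3, n))
            fit = loglog_regression(x, y)
            slope, icpt, se_s, se_i, r2 = ols_normal_equations(
                np.log10(x), np.log10(y)
            )
            assert fit.slope == pytest.approx(slope, rel=1e-10)
            assert fit.intercept == pytest.approx(icpt, rel=1e-10)
            assert fit.se_slope == pytest.approx(se_s, rel=1e-10)
            assert fit.se_intercept == pytest.approx(se_i, rel=1e-10)
            assert fit.r2 == pytest.approx(r2, rel=1e-10)

    def test_collinear_points_give_r2_one(self):
        fit = loglog_regression([1, 10, 100], [2, 20, 200])
        assert fit.r2 == pytest.approx(1.0)
        assert fit.slope == pytest.approx(1.0)

    def test_nonpositive_values_rejected(self):
        with pytest.raises(ValueError):
            loglog_regression([1, 2, -3], [1, 2, 3])

    def test_p_value_decreases_with_residual_variance(self):
        rng = np.random.default_rng(7)
        x = np.linspace(1, 10, 12)
        noise = rng.normal(0, 1, 12)
        p_values = []
        for scale in (1.0, 0.5, 0.1, 0.01):
            y = 10 ** (1 - 0.5 * np.log10(x) + noise * scale)
            p_values.append(loglog_regression(x, y).p_value)
        assert all(a > b for a, b in zip(p_values, p_values[1:]))


class TestSubsetRegression:
    def test_all_filter_equals_full_regression(self, species_records):
        full = subset_regression(species_records, None, "burden_ge")
        expl = subset_regression(species_records, lambda r: True, "burden_ge")
        assert full == expl

    def test_unicellular_subset_has_df_8(self, species_records):
        fit = subset_regression(species_records, UNICELLULAR_GROUPS, "burden_ge")
        assert fit.n == 10 and fit.df == 8

    def test_too_small_subset_rejected(self, species_records):
        with pytest.raises(ValueError):
            subset_regression(species_records, lambda r: r.label == "Ec")


class TestPicContrasts:
    def test_two_leaf_closed_form(self):
        tree = dendropy.Tree.get(data="(A:1,B:1);", schema="newick", rooting="force-rooted")
        cs = pic_contrasts(tree, {"A": 3.0, "B": 1.0})
        assert len(cs.contrasts) == 1
        assert cs.values()[0] == pytest.approx((3.0 - 1.0) / np.sqrt(2))

    def test_contrast_count_is_n_minus_one(self, species_records, species_tree):
        trait = {r.label: np.log10(r.Ne) for r in species_records}
        cs = pic_contrasts(species_tree, trait)
        assert len(cs.contrasts) == len(species_records) - 1

    def test_missing_trait_rejected(self, species_tree):
        with pytest.raises(ValueError, match="missing trait"):
            pic_contrasts(species_tree, {"Agt": 1.0})

    def test_polytomy_rejected(self):
        tree = dendropy.Tree.get(data="(A:1,B:1,C:1);", schema="newick", rooting="force-rooted")
        with pytest.raises(ValueError, match="bifurcating"):
            pic_contrasts(tree, {"A": 1, "B": 2, "C": 3})

    def test_brownian_simulation_standardizes_variance(self):
        # contrasts of a Brownian trait are iid N(0, sigma^2)
        tree = dendropy.Tree.get(
            data=random_bifurcating_newick(np.random.default_rng(8), 8),
            schema="newick", rooting="force-rooted",
        )
        labels, V = brownian_covariance(tree)
        rng = np.random.default_rng(9)
        chol = np.linalg.cholesky(V)
        all_contrasts = []
        for _ in range(1000):
            traits = dict(zip(labels, chol @ rng.normal(size=len(labels))))
            all_contrasts.extend(pic_contrasts(tree, traits).values())
        sd = np.std(all_contrasts)
        assert sd == pytest.approx(1.0, abs=0.05)

    def test_origin_slope_equals_gls_slope_on_random_trees(self):
        rng = np.random.default_rng(10)
        for rep in range(30):
            n = int(rng.integers(4, 9))
            tree = dendropy.Tree.get(
                data=random_bifurcating_newick(rng, n), schema="newick",
                rooting="force-rooted"
            )
            labels, V = brownian_covariance(tree)
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            cx = pic_contrasts(tree, dict(zip(labels, x)))
            cy = pic_contrasts(tree, dict(zip(labels, y)))
            fit = origin_regression(cx, cy)
            assert fit.slope == pytest.approx(gls_slope(V, x, y), rel=1e-9)


class TestOriginRegression:
    def test_exact_proportionality(self):
        cx = np.array([1.0, -2.0, 3.0])
        fit = origin_regression(cx, 2 * cx)
        assert fit.slope == pytest.approx(2.0)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.df == 2

    def test_orientation_invariance(self):
        rng = np.random.default_rng(11)
        cx = rng.normal(size=10)
        cy = rng.normal(size=10)
        base = origin_regression(cx, cy)
        for i in range(10):
            flipped_x, flipped_y = cx.copy(), cy.copy()
            flipped_x[i] *= -1
            flipped_y[i] *= -1
            flipped = origin_regression(flipped_x, flipped_y)
            assert flipped.slope == pytest.approx(base.slope)
            assert flipped.r2 == pytest.approx(base.r2)
            assert flipped.p_value == pytest.approx(base.p_value)

    def test_zero_contrast_kept_in_df(self):
        cx = np.array([1.0, 0.0, 2.0])
        cy = np.array([1.0, 5.0, 2.0])
        fit = origin_regression(cx, cy)
        assert fit.df == 2


class TestAntimutatorThreshold:
    def test_enteric_bacterium_threshold(self, species_records):
        ec = next(r for r in species_records if r.label == "Ec")
        est = antimutator_threshold(ec, s_coeff=0.01, t_link=2.0)
        expected = 1.0 / (ec.Ne * 0.01 * 2.0 * ec.Ge)
        assert est.delta_u_id == pytest.approx(expected)
        assert est.delta_u_id == pytest.approx(7.1e-14, rel=0.02)
        assert 0.001 <= est.fraction_of_u_id <= 0.01  # ~0.19%

    def test_doubling_ne_halves_threshold(self, species_records):
        ec = next(r for r in species_records if r.label == "Ec")
        import dataclasses

        doubled = dataclasses.replace(ec, Ne=2 * ec.Ne)
        a = antimutator_threshold(ec).delta_u_id
        b = antimutator_threshold(doubled).delta_u_id
        assert a == pytest.approx(2 * b)

    def test_diploid_uses_half_drift_power(self, species_records):
        hs = next(r for r in species_records if r.label == "Hs")
        est = antimutator_threshold(hs)
        assert est.delta_u_id == pytest.approx(
            1.0 / (2 * hs.Ne * 0.01 * 2.0 * hs.Ge)
        )

    def test_fraction_invariant_to_joint_rescaling(self, species_records):
        import dataclasses

        ec = next(r for r in species_records if r.label == "Ec")
        est = antimutator_threshold(ec)
        # rescaling u_id rescales delta/u_id denominator only; the ratio of a
        # jointly rescaled (delta, u_id) pair is unchanged
        scaled = dataclasses.replace(ec, u_id=10 * ec.u_id)
        est2 = antimutator_threshold(scaled)
        assert est2.delta_u_id == pytest.approx(est.delta_u_id)
        assert (est2.delta_u_id * 10) / (scaled.u_id) == pytest.approx(
            est.fraction_of_u_id
        )


class TestReproducePaper:
    def test_dropping_one_species_reduces_df(self, species_records, species_tree):
        full = reproduce_paper(species_records, species_tree)
        pruned_records = [r for r in species_records if r.label != "Sc"]
        pruned_tree = species_tree.clone(depth=1)
        pruned_tree.prune_taxa_with_labels(["Sc"])
        pruned_tree.purge_taxon_namespace()
        pruned = reproduce_paper(pruned_records, pruned_tree)
        for name in ("fig1a", "fig1b", "fig3", "pic"):
            assert pruned["fits"][name].df == full["fits"][name].df - 1

    def test_report_is_stable_under_fixed_input(self, species_records, species_tree):
        a = reproduce_paper(species_records, species_tree)
        b = reproduce_paper(species_records, species_tree)
        assert a["fits_table"].to_csv() == b["fits_table"].to_csv()
        assert a["barrier_table"].to_csv() == b["barrier_table"].to_csv()

    def test_label_mismatch_names_offenders(self, species_records, species_tree):
        with pytest.raises(ValueError, match="Sc"):
            reproduce_paper(
                [r for r in species_records if r.label != "Sc"], species_tree
            )
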