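import itertools
import math
import warnings

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from metacomm import (
    CountTable,
    assign_metacommunity,
    dm_loglik,
    fit_dmm,
    laplace_evidence,
    rarefy,
    select_k,
)
from metacomm.dmm import DMMModel
from metacomm.simulate import CohortSpec, generate_cohort


class TestDMLoglik:
    def test_hand_value_with_coefficient(self):
        # counts (2,1) under DM(alpha=(1,1)): probability 0.25
        ll = dm_loglik(np.array([2, 1]), np.array([1.0, 1.0]), log_coef=True)
        assert ll == pytest.approx(math.log(0.25), abs=1e-9)

    @pytest.mark.parametrize("n,m", [(n, m) for n in range(1, 5) for m in (2, 3)])
    def test_pmf_normalizes_by_enumeration(self, n, m):
        """Summed over every composition of n reads into m taxa the DM pmf
        must integrate to one."""
        rng = np.random.default_rng(n * 10 + m)
        alpha = rng.uniform(0.2, 5.0, size=m)
        total = 0.0
        for cells in itertools.product(range(n + 1), repeat=m - 1):
            if sum(cells) > n:
                continue
            x = np.array(list(cells) + [n - sum(cells)])
            total += math.exp(dm_loglik(x, alpha, log_coef=True))
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_multinomial_limit(self):
        """alpha -> infinity proportional to p recovers the multinomial."""
        p = np.array([0.6, 0.3, 0.1])
        x = np.array([3, 2, 1])
        ll_dm = dm_loglik(x, 1e6 * p, log_coef=True)
        ll_mult = (math.lgamma(7) - sum(math.lgamma(v + 1) for v in x)
                   + float(np.sum(x * np.log(p))))
        assert ll_dm == pytest.approx(ll_mult, abs=1e-3)

    def test_single_taxon_probability_one(self):
        assert dm_loglik(np.array([5]), np.array([2.0]), log_coef=True) == pytest.approx(0.0)

    def test_nonpositive_alpha_rejected(self):
        with pytest.raises(ValueError):
            dm_loglik(np.array([1, 2]), np.array([1.0, 0.0]))


@pytest.fixture(scope="module")
def fitted_small(small_rarefied_module):
    table, _ = small_rarefied_module
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = fit_dmm(table, 3, seed=0, n_restarts=2, tol=1e-6)
    return table, model


@pytest.fixture(scope="module")
def small_rarefied_module():
    spec = CohortSpec(
        n_taxa=50, K=3, n_controls=24, n_adenoma_pairs=12, n_carcinoma_pairs=12,
        depth_mean=3000, seed=11,
    )
    table, records, truth = generate_cohort(spec)
    rt, _ = rarefy(table, 500, seed=1)
    return rt, truth


class TestFitDMM:
    def test_k1_responsibilities_all_one(self, small_rarefied_module):
        table, _ = small_rarefied_module
        model = fit_dmm(table, 1, seed=0, n_restarts=1)
        assert np.allclose(model.responsibilities, 1.0)

    def test_duplicated_samples_share_responsibilities(self):
        rng = np.random.default_rng(0)
        base = rng.integers(0, 60, size=(20, 6))
        counts = np.column_stack([base, base[:, :3]])  # duplicate 3 columns
        t = CountTable([f"t{i}" for i in range(20)],
                       [f"s{j}" for j in range(9)], counts)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = fit_dmm(t, 2, seed=0, n_restarts=1, max_iter=50)
        assert np.allclose(model.responsibilities[:3],
                           model.responsibilities[6:9], atol=1e-6)

    def test_objective_trace_monotone(self, fitted_small):
        _, model = fitted_small
        trace = np.array(model.fit_log["objective_trace"])
        assert np.all(np.diff(trace) >= -1e-6 * (np.abs(trace[:-1]) + 1))

    def test_recovers_planted_components(self, fitted_small, small_rarefied_module):
        table, truth = small_rarefied_module
        _, model = fitted_small
        true_labels = [truth.component_labels[s] for s in table.sample_ids]
        assert adjusted_rand_score(true_labels, model.hard_labels()) >= 0.9

    def test_k_exceeding_samples_rejected(self, tiny_table):
        with pytest.raises(ValueError):
            fit_dmm(tiny_table, 5, seed=0)


class TestLaplaceEvidence:
    def test_label_permutation_invariance(self, fitted_small):
        table, model = fitted_small
        perm = [2, 0, 1]
        permuted = DMMModel(
            K=3,
            weights=model.weights[perm],
            alphas=model.alphas[perm],
            responsibilities=model.responsibilities[:, perm],
            taxon_ids=model.taxon_ids,
            sample_ids=model.sample_ids,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ev_a = laplace_evidence(model, table)
            ev_b = laplace_evidence(permuted, table)
        # finite-difference weight-block Hessian leaves ~1e-5 relative noise
        assert ev_a == pytest.approx(ev_b, rel=1e-6, abs=0.01)

    def test_duplicate_component_pays_occam_penalty(self, fitted_small):
        table, model = fitted_small
        dup = DMMModel(
            K=4,
            weights=np.concatenate([model.weights * [1, 1, 0.5], [model.weights[2] * 0.5]]),
            alphas=np.vstack([model.alphas, model.alphas[2] * 1.000001]),
            responsibilities=np.column_stack(
                [model.responsibilities[:, :2],
                 model.responsibilities[:, 2] / 2,
                 model.responsibilities[:, 2] / 2]),
            taxon_ids=model.taxon_ids,
            sample_ids=model.sample_ids,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert laplace_evidence(dup, table) < laplace_evidence(model, table)

    def test_true_k_beats_k1_on_structured_data(self, small_rarefied_module):
        table, _ = small_rarefied_module
        wins = 0
        for seed in range(5):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m1 = fit_dmm(table, 1, seed=seed, n_restarts=1)
                m3 = fit_dmm(table, 3, seed=seed, n_restarts=1)
                wins += laplace_evidence(m3, table) > laplace_evidence(m1, table)
        assert wins >= 4


class TestSelectK:
    def test_singleton_range(self, small_rarefied_module):
        table, _ = small_rarefied_module
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sel = select_k(table, [2], seed=0, n_restarts=1)
        assert sel.best_K == 2

    def test_single_component_data_prefers_k1(self):
        spec = CohortSpec(n_taxa=40, K=1, n_controls=40, n_adenoma_pairs=0,
                          n_carcinoma_pairs=0, depth_mean=2000, seed=5)
        table, _, _ = generate_cohort(spec)
        rt, _ = rarefy(table, 500, seed=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sel = select_k(rt, range(1, 4), seed=0, n_restarts=1)
        assert sel.best_K == 1

    def test_recovers_k3(self, small_rarefied_module):
        table, truth = small_rarefied_module
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sel = select_k(table, range(1, 6), seed=3, n_restarts=1)
        assert sel.best_K == 3
        true_labels = [truth.component_labels[s] for s in table.sample_ids]
        assert adjusted_rand_score(
            true_labels, sel.best_model.hard_labels()) >= 0.9


class TestAssignment:
    def test_training_table_reproduces_responsibilities(self, fitted_small):
        table, model = fitted_small
        assign = assign_metacommunity(model, table)
        order = np.argsort(-model.weights, kind="stable")
        assert np.allclose(assign.posteriors, model.responsibilities, atol=1e-6)
        # letters follow descending mixture weight
        assert assign.component_letters[order[0]] == "A"

    def test_new_sample_from_component_assigned_confidently(
            self, fitted_small, small_rarefied_module):
        table, model = fitted_small
        rng = np.random.default_rng(0)
        comp = 1
        p = rng.dirichlet(model.alphas[comp])
        x = rng.multinomial(500, p)
        new = CountTable(model.taxon_ids, ["new"], x[:, np.newaxis])
        assign = assign_metacommunity(model, new)
        j = int(np.argmax(assign.posteriors[0]))
        assert j == comp
        assert assign.posteriors[0, j] > 0.9

    def test_missing_taxa_filled_with_zeros(self, fitted_small):
        table, model = fitted_small
        sub = CountTable(table.taxon_ids[:-5], ["s"],
                         table.counts[:-5, :1] + 1)
        with pytest.warns(UserWarning, match="absent"):
            assign = assign_metacommunity(model, sub)
        assert len(assign.labels) == 1

    def test_no_overlap_rejected(self, fitted_small):
        _, model = fitted_small
        alien = CountTable(["x1", "x2"], ["s"], np.array([[1], [2]]))
        with pytest.raises(ValueError):
            assign_metacommunity(model, alien)

    def test_posterior_tie_broken_to_lowest_index(self):
        model = DMMModel(
            K=2,
            weights=np.array([0.5, 0.5]),
            alphas=np.array([[1.0, 1.0], [1.0, 1.0]]),
            responsibilities=np.zeros((0, 2)),
            taxon_ids=["a", "b"],
            sample_ids=[],
        )
        new = CountTable(["a", "b"], ["s"], np.array([[3], [4]]))
        assign = assign_metacommunity(model, new)
        # identical components -> exact tie -> first component, letter 'A'
        assert assign.labels[0] == "A"
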