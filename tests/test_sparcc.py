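import numpy as np
import pandas as pd
import pytest

from metacomm import (
    CountTable,
    build_network,
    compare_networks,
    paired_site_correlations,
    sparcc_estimate,
    sparcc_pvalues,
)
from metacomm.data_model import SampleRecord
from metacomm.simulate import generate_correlated_basis

pytestmark = pytest.mark.filterwarnings("ignore::UserWarning")

PLANTED = ((0, 1, 0.7), (2, 3, 0.7), (4, 5, 0.7))


@pytest.fixture(scope="module")
def planted():
    table, true_corr, _ = generate_correlated_basis(seed=1)
    est = sparcc_estimate(table, seed=0)
    return table, true_corr, est


class TestSparccEstimate:
    def test_unit_diagonal_and_symmetry(self, planted):
        _, _, est = planted
        assert np.allclose(np.diag(est.rho), 1.0)
        assert np.allclose(est.rho, est.rho.T)
        assert np.all(np.abs(est.rho) <= 1.0)

    def test_planted_pairs_recovered(self, planted):
        _, _, est = planted
        for i, j, r in PLANTED:
            assert est.rho[i, j] == pytest.approx(r, abs=0.15)

    def test_null_pairs_stay_weak(self, planted):
        _, _, est = planted
        mask = np.ones_like(est.rho, dtype=bool)
        np.fill_diagonal(mask, False)
        for i, j, _ in PLANTED:
            mask[i, j] = mask[j, i] = False
        assert np.mean(np.abs(est.rho[mask]) > 0.3) <= 0.05

    def test_independent_basis_centred_at_zero(self):
        table, _, _ = generate_correlated_basis(planted_pairs=(), seed=3)
        est = sparcc_estimate(table, seed=0)
        off = est.offdiag()
        assert abs(np.mean(off)) < 0.05
        assert np.max(np.abs(off)) < 0.45

    def test_compositional_invariance_to_depth_rescaling(self):
        """Multiplying per-sample depths leaves the estimate nearly
        unchanged: SparCC sees only relative information."""
        table, _, _ = generate_correlated_basis(n_taxa=20, n_samples=80,
                                             planted_pairs=((0, 1, 0.7),), seed=4)
        rng = np.random.default_rng(0)
        factors = rng.integers(2, 6, size=table.n_samples)
        scaled = CountTable(table.taxon_ids, table.sample_ids,
                            table.counts * factors[np.newaxis, :])
        a = sparcc_estimate(table, seed=9)
        b = sparcc_estimate(scaled, seed=9)
        assert np.allclose(a.rho, b.rho, atol=0.1)
        assert b.rho[0, 1] == pytest.approx(a.rho[0, 1], abs=0.05)

    def test_log_basis_pearson_oracle(self):
        """On high-diversity data at large depth, SparCC approaches the
        Pearson correlation of the drawn log-basis abundances."""
        table, _, log_basis = generate_correlated_basis(
            mean_log_spread=0.4, depth=20_000, seed=6)
        est = sparcc_estimate(table, seed=0)
        pearson = np.corrcoef(log_basis, rowvar=False)
        iu = np.triu_indices(len(est.taxon_ids), 1)
        assert np.max(np.abs(est.rho[iu] - pearson[iu])) <= 0.1

    def test_too_few_taxa_rejected(self):
        t = CountTable(["a", "b", "c"], ["s1", "s2"],
                       np.arange(6).reshape(3, 2) + 1)
        with pytest.raises(ValueError):
            sparcc_estimate(t)

    def test_seed_determinism(self):
        table, _, _ = generate_correlated_basis(n_taxa=10, n_samples=40, seed=5,
                                             planted_pairs=())
        a = sparcc_estimate(table, n_inference=3, seed=11)
        b = sparcc_estimate(table, n_inference=3, seed=11)
        assert np.array_equal(a.rho, b.rho)


class TestSparccPvalues:
    @pytest.fixture(scope="class")
    def pvals(self, planted):
        table, _, est = planted
        p = sparcc_pvalues(table, est, n_sim=100, seed=0, n_inference=3)
        return p

    def test_bounds_and_floor(self, pvals):
        off = pvals[np.triu_indices(50, 1)]
        assert np.all(off > 0)
        assert np.all(off <= 1)
        assert off.min() >= 1 / 101

    def test_planted_pairs_at_floor(self, pvals):
        for i, j, _ in PLANTED:
            assert pvals[i, j] == pytest.approx(1 / 101)

    def test_null_pvalues_roughly_uniform(self, pvals):
        from scipy.stats import kstest

        mask = np.zeros((50, 50), dtype=bool)
        mask[np.triu_indices(50, 1)] = True
        for i, j, _ in PLANTED:
            mask[i, j] = mask[j, i] = False
        null_p = pvals[mask]
        assert kstest(null_p, "uniform").pvalue > 0.01

    def test_bad_n_sim(self, planted):
        table, _, est = planted
        with pytest.raises(ValueError):
            sparcc_pvalues(table, est, n_sim=0)


class TestBuildNetwork:
    def test_planted_pairs_only_edges(self):
        """On a 20-taxon calibration simulation the filtered network holds
        exactly the planted pairs: enough permutations that the p-value
        floor (1/2501) clears the BH threshold across the 190 tested pairs."""
        pairs = ((0, 1, 0.7), (4, 5, 0.7))
        table, _, _ = generate_correlated_basis(
            n_taxa=20, n_samples=150, planted_pairs=pairs, seed=2)
        est = sparcc_estimate(table, seed=0)
        p = sparcc_pvalues(table, est, n_sim=2500, seed=0, n_inference=2)
        net = build_network(est, p, strength_min=0.3, fdr_max=0.05, state="test")
        edges = {tuple(sorted((a, b)))
                 for a, b in zip(net.edges.taxon_a, net.edges.taxon_b)}
        expected = {tuple(sorted((est.taxon_ids[i], est.taxon_ids[j])))
                    for i, j, _ in pairs}
        assert edges == expected

    def test_lowering_threshold_is_monotone(self, planted):
        table, _, est = planted
        p = sparcc_pvalues(table, est, n_sim=50, seed=1, n_inference=2)
        strict = build_network(est, p, strength_min=0.5, fdr_max=0.05)
        loose = build_network(est, p, strength_min=0.2, fdr_max=0.05)
        strict_edges = set(zip(strict.edges.taxon_a, strict.edges.taxon_b))
        loose_edges = set(zip(loose.edges.taxon_a, loose.edges.taxon_b))
        assert strict_edges <= loose_edges

    def test_empty_network_is_valid(self, planted):
        _, _, est = planted
        p = np.ones_like(est.rho)
        net = build_network(est, p, strength_min=0.3, fdr_max=0.05)
        assert net.n_edges == 0


class TestPairedSiteCorrelations:
    @staticmethod
    def _paired_table(identical: bool, n_pairs=40, seed=0):
        rng = np.random.default_rng(seed)
        T = 12
        ids, cols, meta = [], [], []
        for i in range(n_pairs):
            logw = rng.normal(0, 1, size=T)
            les = rng.multinomial(3000, np.exp(logw) / np.exp(logw).sum())
            if identical:
                adj = les.copy()
            else:
                logw2 = rng.normal(0, 1, size=T)
                adj = rng.multinomial(3000, np.exp(logw2) / np.exp(logw2).sum())
            for site, col in (("lesion", les), ("adjacent", adj)):
                sid = f"p{i}_{site}"
                ids.append(sid)
                cols.append(col)
                meta.append(SampleRecord(sid, f"s{i}", "carcinoma", site,
                                         "ECRC", f"pair{i}"))
        table = CountTable([f"t{k}" for k in range(T)], ids,
                           np.column_stack(cols))
        return table, meta

    def test_identical_compositions_cross_self_correlation_high(self):
        table, meta = self._paired_table(identical=True)
        res = paired_site_correlations(table, meta, n_inference=5, seed=0)
        assert np.mean(np.diag(res.cross_rho)) > 0.8

    def test_independent_sites_cross_block_near_zero(self):
        table, meta = self._paired_table(identical=False, seed=1)
        res = paired_site_correlations(table, meta, n_inference=5, seed=0)
        assert abs(np.mean(res.cross_rho)) < 0.1
        assert np.mean(np.abs(res.cross_rho) > 0.5) < 0.05

    def test_within_blocks_are_single_site_estimates(self):
        table, meta = self._paired_table(identical=False, seed=2)
        res = paired_site_correlations(table, meta, n_inference=3, seed=5)
        # replicate the documented child-seed derivation
        children = np.random.SeedSequence(5).spawn(3)
        s_les = int(children[0].generate_state(1)[0] % 2**31)
        lesion_ids = [r.sample_id for r in meta if r.site == "lesion"]
        direct = sparcc_estimate(table.select_samples(lesion_ids),
                                 n_inference=3, seed=s_les)
        assert res.within_lesion.taxon_ids == direct.taxon_ids
        assert np.array_equal(res.within_lesion.rho, direct.rho)


class TestCompareNetworks:
    def test_identical_networks(self, planted):
        _, _, est = planted
        edges = pd.DataFrame({"taxon_a": ["taxon_000"], "taxon_b": ["taxon_001"],
                              "rho": [0.7]})
        cmp_ = compare_networks(est, est, edges, edges)
        assert cmp_.ks.statistic == pytest.approx(0.0)
        assert cmp_.sign_concordance == pytest.approx(1.0)
        assert cmp_.strong_positive_a == cmp_.strong_positive_b

    def test_negated_network_discordant(self, planted):
        _, _, est = planted
        from metacomm.sparcc import BasisCorrelation

        neg = BasisCorrelation(
            taxon_ids=est.taxon_ids,
            rho=np.where(np.eye(len(est.taxon_ids), dtype=bool), 1.0, -est.rho),
            omega=est.omega,
            t_matrix=est.t_matrix,
        )
        pairs = [("taxon_000", "taxon_001"), ("taxon_002", "taxon_003")]
        ea = pd.DataFrame({"taxon_a": [a for a, _ in pairs],
                           "taxon_b": [b for _, b in pairs],
                           "rho": [0.7, 0.7]})
        eb = ea.assign(rho=[-0.7, -0.7])
        cmp_ = compare_networks(est, neg, ea, eb)
        assert cmp_.sign_concordance == pytest.approx(0.0)

    def test_shifted_distributions_rejected_by_ks(self):
        ta, _, _ = generate_correlated_basis(n_taxa=40, n_samples=150,
                                          planted_pairs=(), seed=7)
        est_a = sparcc_estimate(ta, n_inference=5, seed=0)
        from metacomm.sparcc import BasisCorrelation

        shifted = np.clip(est_a.rho + 0.2, -1, 1)
        np.fill_diagonal(shifted, 1.0)
        est_b = BasisCorrelation(est_a.taxon_ids, (shifted + shifted.T) / 2,
                                 est_a.omega, est_a.t_matrix)
        cmp_ = compare_networks(est_a, est_b)
        assert cmp_.ks.p_value < 0.01

    def test_disjoint_taxa_rejected(self, planted):
        _, _, est = planted
        from metacomm.sparcc import BasisCorrelation

        other = BasisCorrelation(["zz1", "zz2"], np.eye(2), np.ones(2),
                                 np.zeros((2, 2)))
        with pytest.raises(ValueError):
            compare_networks(est, other)
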