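"""Compositionality-robust correlation inference (SparCC) and networks.

Read counts only carry relative information, so naive correlations of
proportions are distorted.  SparCC estimates the correlations of the
underlying ("basis") abundances from the variances of pairwise
log-ratios, t_ij = var log(x_i/x_j), under a sparsity assumption: with
most pairs uncorrelated, basis variances omega solve the linear system
sum_j t_ij = (T-2) omega_i + sum_j omega_j, and

    rho_ij = (omega_i + omega_j - t_ij) / (2 sqrt(omega_i omega_j)).

Strongly correlated pairs violating the assumption are excluded
iteratively and the system re-solved; the whole procedure is averaged
over posterior draws of the underlying fractions.  Significance comes
from a permutation null (independent per-taxon shuffles across
samples), and networks keep the edges passing both a correlation
strength and a BH-FDR filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data_model import CountTable, SampleRecord
from .stats import TestResult, bh_adjust, ks_two_sample

__all__ = [
    "BasisCorrelation",
    "CorrelationNetwork",
    "PairedSiteCorrelation",
    "NetworkComparison",
    "sparcc_estimate",
    "sparcc_pvalues",
    "build_network",
    "paired_site_correlations",
    "compare_networks",
]


@dataclass
class BasisCorrelation:
    """Averaged SparCC estimate over inference iterations."""

    taxon_ids: list[str]
    rho: np.ndarray  # symmetric, unit diagonal, clipped to [-1, 1]
    omega: np.ndarray  # basis variances
    t_matrix: np.ndarray  # mean log-ratio variance matrix
    excluded_taxa: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        T = len(self.taxon_ids)
        if self.rho.shape != (T, T) or self.t_matrix.shape != (T, T):
            raise ValueError("matrix shape mismatch")
        if not np.allclose(self.rho, self.rho.T, atol=1e-9):
            raise ValueError("rho must be symmetric")
        if not np.allclose(np.diag(self.rho), 1.0, atol=1e-9):
            raise ValueError("rho must have unit diagonal")

    def offdiag(self) -> np.ndarray:
        iu = np.triu_indices(len(self.taxon_ids), 1)
        return self.rho[iu]


def _log_ratio_variance(logF: np.ndarray) -> np.ndarray:
    """t_ij = var over samples of log(f_i / f_j); zero diagonal."""
    cov = np.cov(logF, rowvar=False)
    v = np.diag(cov)
    t = v[:, np.newaxis] + v[np.newaxis, :] - 2.0 * cov
    np.fill_diagonal(t, 0.0)
    return t


def _solve_basis(t: np.ndarray, excluded: set[tuple[int, int]]) -> np.ndarray:
    T = t.shape[0]
    M = np.ones((T, T)) + np.eye(T) * (T - 2)
    b = t.sum(axis=1).astype(float)
    for i, j in excluded:
        M[i, i] -= 1
        M[j, j] -= 1
        M[i, j] -= 1
        M[j, i] -= 1
        b[i] -= t[i, j]
        b[j] -= t[i, j]
    try:
        omega = np.linalg.solve(M, b)
    except np.linalg.LinAlgError:
        omega = np.linalg.lstsq(M, b, rcond=None)[0]
    return np.maximum(omega, 1e-12)


def _rho_from(t: np.ndarray, omega: np.ndarray) -> np.ndarray:
    denom = 2.0 * np.sqrt(np.outer(omega, omega))
    rho = (omega[:, np.newaxis] + omega[np.newaxis, :] - t) / denom
    rho = np.clip(rho, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return (rho + rho.T) / 2.0


def _one_inference(t: np.ndarray, n_exclusion: int, threshold: float):
    """Solve, then iteratively exclude the strongest pair above threshold."""
    T = t.shape[0]
    excluded: set[tuple[int, int]] = set()
    omega = _solve_basis(t, excluded)
    rho = _rho_from(t, omega)
    mask = np.zeros_like(rho, dtype=bool)
    np.fill_diagonal(mask, True)
    max_pairs = T * (T - 1) // 2
    exc_count = np.zeros(T, dtype=int)
    for _ in range(min(n_exclusion, max_pairs)):
        r = np.where(mask, 0.0, np.abs(rho))
        i, j = np.unravel_index(np.argmax(r), r.shape)
        if r[i, j] <= threshold:
            break
        mask[i, j] = mask[j, i] = True
        # cap per-taxon exclusions so the linear system stays determined
        if exc_count[i] >= T - 4 or exc_count[j] >= T - 4:
            continue
        excluded.add((min(i, j), max(i, j)))
        exc_count[i] += 1
        exc_count[j] += 1
        omega = _solve_basis(t, excluded)
        rho = _rho_from(t, omega)
    return rho, omega


def sparcc_estimate(
    table: CountTable,
    n_inference: int = 20,
    n_exclusion: int = 100,
    exclusion_threshold: float = 0.1,
    seed: int | None = None,
) -> BasisCorrelation:
    """SparCC basis correlations of a count table.

    Each inference iteration draws per-sample fractions from a
    Dirichlet posterior with unit pseudocounts, computes log-ratio
    variances, solves for basis variances with all correlations assumed
    zero, and refines by excluding up to ``n_exclusion`` strong pairs
    (|rho| above ``exclusion_threshold``).  The returned rho is the
    element-wise mean over the inference iterations.
    """
    if n_inference < 1:
        raise ValueError("n_inference must be >= 1")
    counts = table.counts
    var_zero = np.all(counts == counts[:, :1], axis=1) & (counts.sum(axis=1) == 0)
    excluded_taxa = [t for t, z in zip(table.taxon_ids, var_zero) if z]
    if excluded_taxa:
        warnings.warn(f"excluding {len(excluded_taxa)} all-zero taxa: {excluded_taxa[:5]}...")
        keep = ~var_zero
        counts = counts[keep]
        taxon_ids = [t for t, z in zip(table.taxon_ids, var_zero) if not z]
    else:
        taxon_ids = list(table.taxon_ids)
    T = len(taxon_ids)
    if T < 4:
        raise ValueError("SparCC needs at least 4 taxa")
    rng = np.random.default_rng(seed)
    rho_sum = np.zeros((T, T))
    omega_sum = np.zeros(T)
    t_sum = np.zeros((T, T))
    for _ in range(n_inference):
        G = rng.gamma(counts.T + 1.0)  # (samples, taxa) Dirichlet(counts+1) draw
        F = G / G.sum(axis=1, keepdims=True)
        t = _log_ratio_variance(np.log(F))
        rho, omega = _one_inference(t, n_exclusion, exclusion_threshold)
        rho_sum += rho
        omega_sum += omega
        t_sum += t
    rho = rho_sum / n_inference
    np.fill_diagonal(rho, 1.0)
    return BasisCorrelation(
        taxon_ids=taxon_ids,
        rho=np.clip((rho + rho.T) / 2.0, -1.0, 1.0),
        omega=omega_sum / n_inference,
        t_matrix=t_sum / n_inference,
        excluded_taxa=excluded_taxa,
    )


def sparcc_pvalues(
    table: CountTable,
    observed: BasisCorrelation,
    n_sim: int = 500,
    seed: int | None = None,
    **estimate_kwargs,
) -> np.ndarray:
    """Two-sided empirical permutation p-values for SparCC correlations.

    Each simulated dataset shuffles every taxon's counts independently
    across samples (destroying correlations, preserving per-taxon
    margins) and re-estimates SparCC with the same settings;
    p_ij = (1 + #{|rho_sim| >= |rho_obs|}) / (1 + n_sim).
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    rng = np.random.default_rng(seed)
    idx = [table.taxon_ids.index(t) for t in observed.taxon_ids]
    counts = table.counts[idx]
    T, S = counts.shape
    hits = np.zeros((T, T))
    abs_obs = np.abs(observed.rho)
    for _ in range(n_sim):
        perm = np.empty_like(counts)
        for i in range(T):
            perm[i] = counts[i, rng.permutation(S)]
        sim_table = CountTable(list(observed.taxon_ids), list(table.sample_ids), perm)
        sim = sparcc_estimate(sim_table, seed=int(rng.integers(2**31)),
                              **estimate_kwargs)
        hits += np.abs(sim.rho) >= abs_obs
    p = (1.0 + hits) / (1.0 + n_sim)
    np.fill_diagonal(p, 1.0)
    return np.minimum(p, 1.0)


@dataclass
class CorrelationNetwork:
    """FDR- and strength-filtered taxon co-occurrence network."""

    state: str
    nodes: pd.DataFrame  # taxon_id, mean_abundance, is_marker
    edges: pd.DataFrame  # taxon_a, taxon_b, rho, p, q
    strength_min: float
    fdr_max: float

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph(state=self.state)
        for row in self.nodes.itertuples(index=False):
            g.add_node(row.taxon_id, mean_abundance=float(row.mean_abundance),
                       is_marker=bool(row.is_marker))
        for row in self.edges.itertuples(index=False):
            g.add_edge(row.taxon_a, row.taxon_b, rho=float(row.rho),
                       p=float(row.p), q=float(row.q))
        return g

    def write_edges_tsv(self, path) -> None:
        out = self.edges.copy()
        out["state"] = self.state
        out.to_csv(path, sep="\t", index=False)


def build_network(
    corr: BasisCorrelation,
    p_matrix: np.ndarray,
    strength_min: float = 0.3,
    fdr_max: float = 0.05,
    node_info: pd.DataFrame | None = None,
    state: str = "",
) -> CorrelationNetwork:
    """Keep taxon pairs with |rho| >= strength_min and BH q <= fdr_max.

    BH adjustment is applied across all tested pairs within this state.
    ``node_info`` may supply per-taxon mean abundance and marker flags;
    otherwise zeros/False are used.
    """
    T = len(corr.taxon_ids)
    iu = np.triu_indices(T, 1)
    p_flat = np.asarray(p_matrix)[iu]
    q_flat = bh_adjust(p_flat)
    rho_flat = corr.rho[iu]
    keep = (np.abs(rho_flat) >= strength_min) & (q_flat <= fdr_max)
    edges = pd.DataFrame(
        {
            "taxon_a": [corr.taxon_ids[i] for i in iu[0][keep]],
            "taxon_b": [corr.taxon_ids[j] for j in iu[1][keep]],
            "rho": rho_flat[keep],
            "p": p_flat[keep],
            "q": q_flat[keep],
        }
    )
    if node_info is None:
        nodes = pd.DataFrame(
            {"taxon_id": corr.taxon_ids,
             "mean_abundance": np.zeros(T),
             "is_marker": np.zeros(T, dtype=bool)}
        )
    else:
        nodes = node_info.set_index("taxon_id").reindex(corr.taxon_ids)
        nodes["mean_abundance"] = nodes.get("mean_abundance", 0.0)
        nodes["is_marker"] = nodes.get("is_marker", False).fillna(False).astype(bool)
        nodes = nodes.reset_index()[["taxon_id", "mean_abundance", "is_marker"]]
    return CorrelationNetwork(state=state, nodes=nodes, edges=edges,
                              strength_min=strength_min, fdr_max=fdr_max)


@dataclass
class PairedSiteCorrelation:
    """Within- and between-site basis correlations on matched pairs.

    Variables are taxa at the lesion and taxa at the adjacent mucosa;
    each lesion/adjacent pair contributes one joint observation.  The
    within-site blocks are the plain single-site SparCC estimates on
    the paired samples; the cross-site block combines cross-site
    log-ratio variances with the within-site basis variances.
    """

    taxon_ids: list[str]
    within_lesion: BasisCorrelation
    within_adjacent: BasisCorrelation
    cross_rho: np.ndarray  # [i, j] = corr(lesion taxon i, adjacent taxon j)


def paired_site_correlations(
    table: CountTable,
    metadata: list[SampleRecord],
    n_inference: int = 20,
    n_exclusion: int = 100,
    exclusion_threshold: float = 0.1,
    seed: int | None = None,
) -> PairedSiteCorrelation:
    """SparCC within and between paired lesion/adjacent sampling sites."""
    pairs: dict[str, dict[str, str]] = {}
    for r in metadata:
        if r.pair_id and r.sample_id in table.sample_ids:
            pairs.setdefault(r.pair_id, {})[r.site] = r.sample_id
    complete = [p for p in pairs.values() if "lesion" in p and "adjacent" in p]
    if len(complete) < 10:
        warnings.warn(f"only {len(complete)} complete pairs; estimates unstable")
    if not complete:
        raise ValueError("no complete lesion/adjacent pairs")
    lesion_ids = [p["lesion"] for p in complete]
    adjacent_ids = [p["adjacent"] for p in complete]
    ss = np.random.SeedSequence(seed)
    s_les, s_adj, s_cross = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(3))
    kw = dict(n_inference=n_inference, n_exclusion=n_exclusion,
              exclusion_threshold=exclusion_threshold)
    les = sparcc_estimate(table.select_samples(lesion_ids), seed=s_les, **kw)
    adj = sparcc_estimate(table.select_samples(adjacent_ids), seed=s_adj, **kw)
    common = [t for t in les.taxon_ids if t in set(adj.taxon_ids)]
    li = [les.taxon_ids.index(t) for t in common]
    ai = [adj.taxon_ids.index(t) for t in common]
    row = {t: i for i, t in enumerate(table.taxon_ids)}
    CL = table.counts[[row[t] for t in common]][:, [table.sample_ids.index(s) for s in lesion_ids]]
    CA = table.counts[[row[t] for t in common]][:, [table.sample_ids.index(s) for s in adjacent_ids]]
    rng = np.random.default_rng(s_cross)
    Tn = len(common)
    cross_sum = np.zeros((Tn, Tn))
    omega_l = les.omega[li]
    omega_a = adj.omega[ai]
    for _ in range(n_inference):
        GL = rng.gamma(CL.T + 1.0)
        FL = np.log(GL / GL.sum(axis=1, keepdims=True))
        GA = rng.gamma(CA.T + 1.0)
        FA = np.log(GA / GA.sum(axis=1, keepdims=True))
        # t_cross[i, j] = var over pairs of log(fL_i / fA_j)
        vl = FL.var(axis=0, ddof=1)
        va = FA.var(axis=0, ddof=1)
        nobs = FL.shape[0]
        cov = (FL - FL.mean(axis=0)).T @ (FA - FA.mean(axis=0)) / (nobs - 1)
        t_cross = vl[:, np.newaxis] + va[np.newaxis, :] - 2.0 * cov
        denom = 2.0 * np.sqrt(np.outer(omega_l, omega_a))
        cross_sum += np.clip(
            (omega_l[:, np.newaxis] + omega_a[np.newaxis, :] - t_cross) / denom,
            -1.0, 1.0,
        )
    return PairedSiteCorrelation(
        taxon_ids=common,
        within_lesion=les,
        within_adjacent=adj,
        cross_rho=cross_sum / n_inference,
    )


@dataclass
class NetworkComparison:
    ks: TestResult  # KS test on the off-diagonal correlation distributions
    sign_table: np.ndarray | None  # 2x2 (a +/-) x (b +/-) on shared significant pairs
    sign_fisher_p: float | None
    sign_concordance: float | None  # fraction of shared pairs with matching sign
    strong_positive_a: int  # pairs with rho >= 0.5 in state a
    strong_positive_b: int
    n_shared_significant: int = 0


def compare_networks(
    corr_a: BasisCorrelation,
    corr_b: BasisCorrelation,
    edges_a: pd.DataFrame | None = None,
    edges_b: pd.DataFrame | None = None,
    strong_threshold: float = 0.5,
) -> NetworkComparison:
    """Compare two disease states' correlation structures.

    (1) KS two-sample test on off-diagonal correlation distributions;
    (2) on pairs significant in both states, a 2x2 sign-concordance
    table with Fisher's exact test; (3) counts of strong positive
    correlations (rho >= ``strong_threshold``) per state.
    """
    shared = [t for t in corr_a.taxon_ids if t in set(corr_b.taxon_ids)]
    if not shared:
        raise ValueError("no shared taxa between the two states")
    ks = ks_two_sample(corr_a.offdiag(), corr_b.offdiag())
    strong_a = int(np.sum(corr_a.offdiag() >= strong_threshold))
    strong_b = int(np.sum(corr_b.offdiag() >= strong_threshold))

    sign_table = sign_p = concord = None
    n_shared = 0
    if edges_a is not None and edges_b is not None:
        key = lambda df: {tuple(sorted((a, b))): r  # noqa: E731
                          for a, b, r in zip(df["taxon_a"], df["taxon_b"], df["rho"])}
        ka, kb = key(edges_a), key(edges_b)
        both = sorted(set(ka) & set(kb))
        n_shared = len(both)
        if both:
            sign_table = np.zeros((2, 2), dtype=np.int64)
            for pair in both:
                sign_table[0 if ka[pair] > 0 else 1, 0 if kb[pair] > 0 else 1] += 1
            concord = float((sign_table[0, 0] + sign_table[1, 1]) / n_shared)
            if np.all(sign_table.sum(axis=0) > 0) and np.all(sign_table.sum(axis=1) > 0):
                sign_p = float(sps.fisher_exact(sign_table)[1])
    return NetworkComparison(
        ks=ks,
        sign_table=sign_table,
        sign_fisher_p=sign_p,
        sign_concordance=concord,
        strong_positive_a=strong_a,
        strong_positive_b=strong_b,
        n_shared_significant=n_shared,
    )
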