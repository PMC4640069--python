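"""Ground-truth synthetic cohorts emulating a paired mucosal-biopsy study.

The generator draws each sample from a mixture of K Dirichlet-
multinomial components (the "metacommunities"), builds paired
lesion/adjacent samples whose components agree with a tunable
concordance probability, plants phenotype-specific marker taxa with
known fold changes, and varies sequencing depth negative-binomially.
Every random choice is recorded in a :class:`SyntheticTruth` so each
downstream method can be checked against the generating process.

The default :class:`CohortSpec` mirrors the study design this package
targets: 61 healthy controls, 47 adenoma and 52 carcinoma
lesion/adjacent pairs (259 biopsies), five metacommunities, per-sample
depths averaging ~8,000 reads before rarefaction to 1,000.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .data_model import CountTable, SampleRecord, validate_records

__all__ = [
    "PlantedMarker",
    "CohortSpec",
    "SyntheticTruth",
    "generate_cohort",
    "default_paper_like_spec",
    "generate_correlated_basis",
]


@dataclass(frozen=True)
class PlantedMarker:
    """A taxon whose abundance is shifted in one phenotype's samples."""

    taxon_index: int
    phenotype: str  # "adenoma" or "carcinoma"
    fold_change: float  # applied to the lesion; adjacent gets sqrt(fold_change)
    apply_to_adjacent: bool = True

    def __post_init__(self) -> None:
        if self.fold_change <= 0:
            raise ValueError("fold change must be positive")
        if self.phenotype not in ("adenoma", "carcinoma"):
            raise ValueError(f"markers attach to lesion phenotypes, got {self.phenotype!r}")


@dataclass
class CohortSpec:
    """Generating parameters of a synthetic paired cohort."""

    n_taxa: int = 100
    K: int = 5
    weights: tuple[float, ...] | None = None  # None -> uniform
    #: Dirichlet concentration of each component; lower = more
    #: within-metacommunity heterogeneity (overdispersion)
    theta: float = 50.0
    base_log_sd: float = 1.5  # spread of the shared log-abundance profile
    n_signature: int = 12  # taxa boosted per component
    signature_shift: float = 2.5  # log-scale boost of signature taxa
    n_controls: int = 61
    n_adenoma_pairs: int = 47
    n_carcinoma_pairs: int = 52
    concordance_adenoma: float = 0.64
    concordance_carcinoma: float = 0.61
    transition_kernel: str = "uniform"  # or "e_attractor"
    attractor_component: int | None = None  # used by "e_attractor"
    markers: tuple[PlantedMarker, ...] | None = None  # None -> auto panel
    n_auto_markers: int = 8  # per phenotype and direction
    marker_fold_change: float = 3.0
    depth_mean: float = 8000.0
    depth_dispersion: float = 3.2  # negative-binomial size parameter
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.n_taxa < 2:
            raise ValueError("need at least 2 taxa")
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if w.size != self.K or np.any(w < 0) or abs(w.sum() - 1) > 1e-9:
                raise ValueError("weights must be a length-K simplex vector")
        for c in (self.concordance_adenoma, self.concordance_carcinoma):
            if not (0.0 <= c <= 1.0):
                raise ValueError("concordance probabilities must lie in [0, 1]")
        if self.transition_kernel not in ("uniform", "e_attractor"):
            raise ValueError(f"unknown transition kernel {self.transition_kernel!r}")
        if self.depth_mean < 1:
            raise ValueError("depth_mean must be >= 1")

    @property
    def n_samples(self) -> int:
        return self.n_controls + 2 * (self.n_adenoma_pairs + self.n_carcinoma_pairs)

    def mixture_weights(self) -> np.ndarray:
        if self.weights is None:
            return np.full(self.K, 1.0 / self.K)
        return np.asarray(self.weights, dtype=float)

    # -- (de)serialization ------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        if d["markers"] is not None:
            d["markers"] = [asdict(m) for m in self.markers]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        d = dict(d)
        if d.get("markers") is not None:
            d["markers"] = tuple(PlantedMarker(**m) for m in d["markers"])
        if d.get("weights") is not None:
            d["weights"] = tuple(d["weights"])
        return cls(**d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "CohortSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class SyntheticTruth:
    """Everything the generator decided, keyed for later checking."""

    component_labels: dict[str, int]  # sample_id -> true component index
    pair_concordant: dict[str, bool]  # pair_id -> lesion comp == adjacent comp
    markers: list[PlantedMarker]
    alphas: np.ndarray  # (K, n_taxa) component Dirichlet parameters
    weights: np.ndarray
    spec: CohortSpec


def default_paper_like_spec(seed: int = 0) -> CohortSpec:
    """The study-sized default cohort: 259 samples, K=5 metacommunities."""
    return CohortSpec(seed=seed)


def _auto_markers(spec: CohortSpec, alphas: np.ndarray, rng) -> list[PlantedMarker]:
    """Plant markers on abundant (but not dominant) taxa.

    Disease-marker taxa in mucosal cohorts are typically abundant
    community members, and a fold change on a taxon whose proportion
    noise exceeds the shift is undetectable by any method; the band is
    the 60th-95th percentile of mean abundance.
    """
    mean_alpha = alphas.mean(axis=0)
    order = np.argsort(mean_alpha)
    band = order[int(spec.n_taxa * 0.60): int(spec.n_taxa * 0.95)]
    need = 4 * spec.n_auto_markers
    chosen = rng.choice(band, size=min(need, band.size), replace=False)
    markers = []
    idx = 0
    for phenotype in ("carcinoma", "adenoma"):
        for fc in (spec.marker_fold_change, 1.0 / spec.marker_fold_change):
            for _ in range(spec.n_auto_markers):
                if idx >= chosen.size:
                    break
                markers.append(PlantedMarker(int(chosen[idx]), phenotype, fc))
                idx += 1
    return markers


def _marker_multiplier(markers, phenotype, site, n_taxa) -> np.ndarray:
    mult = np.ones(n_taxa)
    for m in markers:
        if m.phenotype != phenotype:
            continue
        if site == "lesion":
            mult[m.taxon_index] *= m.fold_change
        elif site == "adjacent" and m.apply_to_adjacent:
            mult[m.taxon_index] *= np.sqrt(m.fold_change)
    return mult


def generate_cohort(spec: CohortSpec) -> tuple[CountTable, list[SampleRecord], SyntheticTruth]:
    """Draw a full synthetic cohort; bit-reproducible under ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    K, T = spec.K, spec.n_taxa

    # component Dirichlet parameters: shared log-normal base profile with
    # component-specific sparse signature boosts, scaled to concentration theta
    base = rng.normal(0.0, spec.base_log_sd, size=T)
    alphas = np.empty((K, T))
    for k in range(K):
        shift = np.zeros(T)
        sig = rng.choice(T, size=min(spec.n_signature, T), replace=False)
        shift[sig] = spec.signature_shift
        a = np.exp(base + shift)
        alphas[k] = a / a.sum() * spec.theta
    weights = spec.mixture_weights()

    markers = (list(spec.markers) if spec.markers is not None
               else _auto_markers(spec, alphas, rng))
    for m in markers:
        if not (0 <= m.taxon_index < T):
            raise ValueError(f"marker taxon index {m.taxon_index} out of range")

    taxon_ids = [f"taxon_{i:03d}" for i in range(T)]
    records: list[SampleRecord] = []
    columns: list[np.ndarray] = []
    labels: dict[str, int] = {}
    concordant: dict[str, bool] = {}

    def draw_sample(component: int, phenotype: str, site: str) -> np.ndarray:
        mult = _marker_multiplier(markers, phenotype, site, T)
        alpha = alphas[component] * mult
        depth = max(1, int(rng.negative_binomial(
            spec.depth_dispersion,
            spec.depth_dispersion / (spec.depth_dispersion + spec.depth_mean),
        )))
        p = rng.dirichlet(alpha)
        return rng.multinomial(depth, p)

    def redraw(adjacent_comp: int) -> int:
        if K == 1:
            return adjacent_comp
        if spec.transition_kernel == "e_attractor":
            attractor = (spec.attractor_component
                         if spec.attractor_component is not None else K - 1)
            if adjacent_comp != attractor:
                return attractor
        others = [k for k in range(K) if k != adjacent_comp]
        return int(rng.choice(others))

    for i in range(spec.n_controls):
        comp = int(rng.choice(K, p=weights))
        sid = f"ctrl_{i:03d}"
        records.append(SampleRecord(sid, f"subjN{i:03d}", "normal", "control"))
        labels[sid] = comp
        columns.append(draw_sample(comp, "normal", "control"))

    pair_plan = (
        [("adenoma", spec.n_adenoma_pairs, spec.concordance_adenoma,
          ("LGDP", "HGDP"), 39 / 52)],
        [("carcinoma", spec.n_carcinoma_pairs, spec.concordance_carcinoma,
          ("ECRC", "LCRC"), 0.5)],
    )
    for group in pair_plan:
        for phenotype, n_pairs, conc, stages, frac_first in group:
            short = phenotype[0]
            for i in range(n_pairs):
                adj_comp = int(rng.choice(K, p=weights))
                is_conc = bool(rng.random() < conc)
                les_comp = adj_comp if is_conc else redraw(adj_comp)
                stage = stages[0] if rng.random() < frac_first else stages[1]
                subj = f"subj{short.upper()}{i:03d}"
                pid = f"{phenotype}_pair_{i:03d}"
                for site, comp in (("lesion", les_comp), ("adjacent", adj_comp)):
                    sid = f"{short}{i:03d}_{site[:3]}"
                    records.append(SampleRecord(sid, subj, phenotype, site, stage, pid))
                    labels[sid] = comp
                    columns.append(draw_sample(comp, phenotype, site))
                concordant[pid] = is_conc

    validate_records(records)
    table = CountTable(
        taxon_ids, [r.sample_id for r in records],
        np.column_stack(columns).astype(np.int64),
    )
    truth = SyntheticTruth(
        component_labels=labels,
        pair_concordant=concordant,
        markers=markers,
        alphas=alphas,
        weights=weights,
        spec=spec,
    )
    return table, records, truth


def generate_correlated_basis(
    n_taxa: int = 50,
    n_samples: int = 200,
    planted_pairs: tuple[tuple[int, int, float], ...] = ((0, 1, 0.7), (2, 3, 0.7), (4, 5, 0.7)),
    log_sd: float = 1.0,
    mean_log_spread: float = 1.0,
    depth: int = 5000,
    seed: int = 0,
) -> tuple[CountTable, np.ndarray, np.ndarray]:
    """Compositional counts from a log-normal basis with planted correlations.

    The log basis abundances are multivariate normal with independent
    coordinates except for ``planted_pairs`` (i, j, correlation); each
    sample's counts are multinomial draws from the closed (normalized)
    basis.  Returns the count table, the population log-basis
    correlation matrix, and the drawn (samples x taxa) log-basis values
    themselves -- the oracles for compositionality-robust correlation
    estimators.
    """
    rng = np.random.default_rng(seed)
    corr = np.eye(n_taxa)
    for i, j, r in planted_pairs:
        if not (0 <= i < n_taxa and 0 <= j < n_taxa and i != j):
            raise ValueError(f"bad planted pair ({i}, {j})")
        if not (-1 < r < 1):
            raise ValueError("planted correlation must lie in (-1, 1)")
        corr[i, j] = corr[j, i] = r
    cov = corr * log_sd**2
    mu = rng.normal(0.0, mean_log_spread, size=n_taxa)
    # anchor planted taxa at typical abundance: at the rare tail their
    # read-sampling noise swamps the basis signal, at the dominant end
    # the sparsity approximation degrades
    for i, j, _ in planted_pairs:
        mu[i] = mu[j] = 0.0
    logw = rng.multivariate_normal(mu, cov, size=n_samples, method="cholesky")
    w = np.exp(logw)
    fracs = w / w.sum(axis=1, keepdims=True)
    counts = np.vstack([rng.multinomial(depth, f) for f in fracs]).T
    table = CountTable(
        [f"taxon_{i:03d}" for i in range(n_taxa)],
        [f"s{j:03d}" for j in range(n_samples)],
        counts,
    )
    return table, corr, logw
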