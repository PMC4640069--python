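"""Direction-labelled marker taxa and the Microbial Community Polarization Index.

Markers are taxa whose mean relative abundance in one of the four
lesion-related groups — carcinoma (C), carcinoma-adjacent (C'), adenoma
(A), adenoma-adjacent (A') — differs from the normal-control mean by at
least a 1.5-fold change.  The MCPI of a sample is a composite of two
Microbial-Dysbiosis-Index-style log-ratios built from those markers:

    MCPI_j = log10[(sum TI_C + eps) / (sum TD_C + eps)]
           - log10[(sum TI_A + eps) / (sum TD_A + eps)]

where TI/TD are the abundances of taxa increased/decreased on the
carcinoma side (C or C') and the adenoma side (A or A') respectively.
Positive scores indicate carcinoma-characteristic shifts, negative
scores adenoma-characteristic shifts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import RelAbundanceTable, SampleRecord
from .stats import bh_adjust, wilcoxon_signed_rank

__all__ = [
    "MarkerEntry",
    "MarkerPanel",
    "MCPIResult",
    "GROUPS",
    "select_markers",
    "mcpi",
    "marker_fold_change_by_stage",
    "DEFAULT_EPSILON",
]

#: contrast groups: (group symbol, phenotype, site)
GROUPS = (
    ("C", "carcinoma", "lesion"),
    ("C'", "carcinoma", "adjacent"),
    ("A", "adenoma", "lesion"),
    ("A'", "adenoma", "adjacent"),
)

#: pseudocount on the relative-abundance scale; well below the 1e-3
#: resolution of depth-1000 rarefaction, so it only guards zeros
DEFAULT_EPSILON = 1e-6

_MIN_FC = 1.5


@dataclass(frozen=True)
class MarkerEntry:
    taxon_id: str
    group: str  # one of C, C', A, A'
    direction: str  # "increased" or "decreased"
    fold_change: float  # group mean / control mean (pseudocounted)

    def __post_init__(self) -> None:
        if self.group not in {g for g, _, _ in GROUPS}:
            raise ValueError(f"unknown contrast group {self.group!r}")
        if self.direction not in ("increased", "decreased"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.fold_change <= 0:
            raise ValueError("fold change must be positive")


@dataclass
class MarkerPanel:
    """Marker entries with uniqueness and threshold invariants enforced."""

    entries: list[MarkerEntry]
    min_fold_change: float = _MIN_FC

    def __post_init__(self) -> None:
        seen = set()
        for e in self.entries:
            key = (e.taxon_id, e.group)
            if key in seen:
                raise ValueError(f"duplicate marker {key}")
            seen.add(key)
            if e.direction == "increased" and e.fold_change < self.min_fold_change:
                raise ValueError(
                    f"{e.taxon_id} ({e.group}): increased marker below threshold"
                )
            if e.direction == "decreased" and e.fold_change > 1 / self.min_fold_change:
                raise ValueError(
                    f"{e.taxon_id} ({e.group}): decreased marker above threshold"
                )

    def __len__(self) -> int:
        return len(self.entries)

    def taxa(self, side: str, direction: str) -> list[str]:
        """Marker taxa on one side of the index.

        ``side='C'`` pools groups C and C', ``side='A'`` pools A and A'.
        """
        groups = {"C": ("C", "C'"), "A": ("A", "A'")}[side]
        out: list[str] = []
        for e in self.entries:
            if e.group in groups and e.direction == direction and e.taxon_id not in out:
                out.append(e.taxon_id)
        return out

    def swap_sides(self) -> "MarkerPanel":
        """Exchange the carcinoma-side and adenoma-side groups (C<->A, C'<->A')."""
        swap = {"C": "A", "A": "C", "C'": "A'", "A'": "C'"}
        return MarkerPanel(
            [MarkerEntry(e.taxon_id, swap[e.group], e.direction, e.fold_change)
             for e in self.entries],
            self.min_fold_change,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.taxon_id, e.group, e.direction, e.fold_change) for e in self.entries],
            columns=["taxon_id", "group", "direction", "fold_change"],
        )

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def _group_masks(metadata: list[SampleRecord]):
    by_id = {r.sample_id: r for r in metadata}
    return by_id


def select_markers(
    rel_table: RelAbundanceTable,
    metadata: list[SampleRecord],
    min_fold_change: float = _MIN_FC,
    epsilon: float = DEFAULT_EPSILON,
) -> MarkerPanel:
    """Select direction-labelled marker taxa by fold change vs normal controls.

    For each contrast group the fold change of a taxon is
    (group mean + eps) / (control mean + eps) of relative abundances;
    taxa at or above ``min_fold_change`` are labelled increased, at or
    below its reciprocal decreased, everything else is excluded.
    """
    if min_fold_change <= 1:
        raise ValueError("min_fold_change must exceed 1")
    by_id = _group_masks(metadata)
    ids = rel_table.sample_ids
    known = [s for s in ids if s in by_id]
    ctrl_idx = [i for i, s in enumerate(ids) if s in by_id and by_id[s].phenotype == "normal"]
    if not ctrl_idx:
        raise ValueError("no normal controls in metadata/table overlap")
    V = rel_table.values
    ctrl_mean = V[:, ctrl_idx].mean(axis=1)
    entries: list[MarkerEntry] = []
    for group, phenotype, site in GROUPS:
        idx = [i for i, s in enumerate(ids)
               if s in by_id and by_id[s].phenotype == phenotype and by_id[s].site == site]
        if not idx:
            continue
        if len(idx) < 3:
            warnings.warn(f"contrast group {group} has only {len(idx)} sample(s)")
        fc = (V[:, idx].mean(axis=1) + epsilon) / (ctrl_mean + epsilon)
        for t, f in zip(rel_table.taxon_ids, fc):
            if f >= min_fold_change:
                entries.append(MarkerEntry(t, group, "increased", float(f)))
            elif f <= 1.0 / min_fold_change:
                entries.append(MarkerEntry(t, group, "decreased", float(f)))
    return MarkerPanel(entries, min_fold_change)


@dataclass
class MCPIResult:
    sample_ids: list[str]
    scores: np.ndarray
    c_terms: np.ndarray  # carcinoma-side log-ratio component
    a_terms: np.ndarray  # adenoma-side log-ratio component

    def __post_init__(self) -> None:
        if not np.allclose(self.scores, self.c_terms - self.a_terms, atol=1e-12):
            raise ValueError("score must equal carcinoma term minus adenoma term")

    def score_of(self, sample_id: str) -> float:
        return float(self.scores[self.sample_ids.index(sample_id)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_ids, "score": self.scores,
             "c_term": self.c_terms, "a_term": self.a_terms}
        )


def mcpi(
    rel_table: RelAbundanceTable,
    panel: MarkerPanel,
    epsilon: float = DEFAULT_EPSILON,
) -> MCPIResult:
    """Microbial Community Polarization Index of every sample.

    Composite of two MDI-style log10 ratios over the pooled
    carcinoma-side and adenoma-side marker abundances; exactly
    antisymmetric under exchanging the two sides.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if len(panel) == 0:
        raise ValueError("empty marker panel")
    row = {t: i for i, t in enumerate(rel_table.taxon_ids)}
    V = rel_table.values

    def pooled(side: str, direction: str) -> np.ndarray:
        idx = [row[t] for t in panel.taxa(side, direction) if t in row]
        if not idx:
            return np.zeros(rel_table.n_samples)
        return V[idx, :].sum(axis=0)

    c_term = np.log10(pooled("C", "increased") + epsilon) - np.log10(
        pooled("C", "decreased") + epsilon
    )
    a_term = np.log10(pooled("A", "increased") + epsilon) - np.log10(
        pooled("A", "decreased") + epsilon
    )
    return MCPIResult(list(rel_table.sample_ids), c_term - a_term, c_term, a_term)


def marker_fold_change_by_stage(
    rel_table: RelAbundanceTable,
    metadata: list[SampleRecord],
    panel: MarkerPanel,
    epsilon: float = DEFAULT_EPSILON,
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Within-pair lesion/adjacent fold change of each marker taxon per stage.

    For every marker taxon and clinicopathologic stage: the median of
    (lesion + eps)/(adjacent + eps) across pairs in that stage, with a
    Wilcoxon signed-rank test on the log fold changes and BH correction
    across taxa within each stage.  Stages with fewer than ``min_pairs``
    pairs are flagged and left untested (p = q = NaN).
    """
    by_id = {r.sample_id: r for r in metadata}
    col = {s: j for j, s in enumerate(rel_table.sample_ids)}
    pairs: dict[str, dict[str, SampleRecord]] = {}
    for r in metadata:
        if r.pair_id and r.sample_id in col:
            pairs.setdefault(r.pair_id, {})[r.site] = r
    stage_pairs: dict[str, list[tuple[int, int]]] = {}
    for pid, members in pairs.items():
        if "lesion" in members and "adjacent" in members:
            stage = members["lesion"].stage
            stage_pairs.setdefault(stage, []).append(
                (col[members["lesion"].sample_id], col[members["adjacent"].sample_id])
            )
    marker_taxa = sorted({e.taxon_id for e in panel.entries})
    row = {t: i for i, t in enumerate(rel_table.taxon_ids)}
    V = rel_table.values
    records = []
    for stage, idx_pairs in sorted(stage_pairs.items()):
        n_pairs = len(idx_pairs)
        testable = n_pairs >= min_pairs
        if not testable:
            warnings.warn(f"stage {stage}: only {n_pairs} pair(s); tests skipped")
        les = np.array([i for i, _ in idx_pairs])
        adj = np.array([j for _, j in idx_pairs])
        p_list, med_list = [], []
        for t in marker_taxa:
            if t not in row:
                med_list.append(np.nan)
                p_list.append(np.nan)
                continue
            fc = (V[row[t], les] + epsilon) / (V[row[t], adj] + epsilon)
            med_list.append(float(np.median(fc)))
            logfc = np.log(fc)
            if testable and np.any(logfc != 0):
                p_list.append(wilcoxon_signed_rank(logfc).p_value)
            else:
                p_list.append(np.nan)
        p_arr = np.asarray(p_list)
        q_arr = np.full_like(p_arr, np.nan)
        tested = ~np.isnan(p_arr)
        if tested.any():
            q_arr[tested] = bh_adjust(p_arr[tested])
        for t, med, p, q in zip(marker_taxa, med_list, p_arr, q_arr):
            records.append((t, stage, n_pairs, med, p, q))
    return pd.DataFrame(
        records,
        columns=["taxon_id", "stage", "n_pairs", "median_fold_change", "p", "q"],
    )
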