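"""Lesion vs lesion-adjacent concordance of metacommunities and paired tests.

A lesion/adjacent pair is concordant when both biopsies receive the same
metacommunity label.  The transition table counts
(adjacent label -> lesion label) pairs, optionally stratified by
clinicopathologic stage, and the accompanying tests ask whether
discordance is associated with a grouping (e.g. phenotype or the
adjacent metacommunity) and whether within-pair diversity shifts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import SampleRecord
from .dmm import MetacommunityAssignment
from .stats import TestResult, fisher_exact_mc, wilcoxon_signed_rank

__all__ = [
    "TransitionTable",
    "concordance_table",
    "test_discordance_association",
    "paired_diversity_test",
]


@dataclass
class TransitionTable:
    """K x K counts of (adjacent-label -> lesion-label) pairs."""

    labels: list[str]  # metacommunity letters, row/col order
    counts: np.ndarray  # rows: adjacent label, cols: lesion label
    by_stage: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        K = len(self.labels)
        if self.counts.shape != (K, K):
            raise ValueError("transition matrix shape mismatch")
        for stage, m in self.by_stage.items():
            if np.asarray(m).shape != (K, K):
                raise ValueError(f"stage {stage}: matrix shape mismatch")

    @property
    def n_pairs(self) -> int:
        return int(self.counts.sum())

    @property
    def concordance_rate(self) -> float:
        return float(np.trace(self.counts) / self.counts.sum())

    @property
    def discordance_rate(self) -> float:
        return 1.0 - self.concordance_rate

    def percentages(self, stage: str | None = None) -> np.ndarray:
        """Row-normalized percentages: of pairs with a given adjacent
        label, the percentage transitioning to each lesion label."""
        m = self.counts if stage is None else np.asarray(self.by_stage[stage])
        rows = m.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(rows > 0, 100.0 * m / rows, np.nan)
        return out

    def conditional_concordance(self) -> dict[str, float]:
        """Per adjacent label: fraction of its pairs keeping the label
        at the lesion (e.g. the '92% of E-adjacent pairs have E lesions'
        style statistic)."""
        out = {}
        for i, lab in enumerate(self.labels):
            total = self.counts[i].sum()
            out[lab] = float(self.counts[i, i] / total) if total else np.nan
        return out

    def to_dataframe(self, stage: str | None = None) -> pd.DataFrame:
        m = self.counts if stage is None else np.asarray(self.by_stage[stage])
        return pd.DataFrame(m, index=self.labels, columns=self.labels)


def _collect_pairs(metadata: list[SampleRecord]):
    pairs: dict[str, dict[str, SampleRecord]] = {}
    for r in metadata:
        if r.pair_id:
            pairs.setdefault(r.pair_id, {})[r.site] = r
    return pairs


def concordance_table(
    assignment: MetacommunityAssignment,
    metadata: list[SampleRecord],
    stratify_by_stage: bool = True,
) -> TransitionTable:
    """Tally metacommunity transitions from adjacent mucosae to lesions."""
    letters = sorted(set(assignment.component_letters))
    index = {lab: i for i, lab in enumerate(letters)}
    assigned = assignment.as_dict()
    K = len(letters)
    counts = np.zeros((K, K), dtype=np.int64)
    by_stage: dict[str, np.ndarray] = {}
    for pid, members in _collect_pairs(metadata).items():
        if "lesion" not in members or "adjacent" not in members:
            raise ValueError(f"pair {pid!r} lacks a lesion or adjacent sample")
        for site in ("lesion", "adjacent"):
            if members[site].sample_id not in assigned:
                raise ValueError(
                    f"pair {pid!r}: sample {members[site].sample_id!r} has no label"
                )
        i = index[assigned[members["adjacent"].sample_id]]
        j = index[assigned[members["lesion"].sample_id]]
        counts[i, j] += 1
        if stratify_by_stage:
            stage = members["lesion"].stage
            by_stage.setdefault(stage, np.zeros((K, K), dtype=np.int64))[i, j] += 1
    return TransitionTable(labels=letters, counts=counts, by_stage=by_stage)


def test_discordance_association(
    concordant: list[bool],
    groups: list[str],
    *,
    n_replicates: int = 10_000,
    n_repeats: int = 1_000,
    seed: int | None = None,
) -> TestResult:
    """Monte-Carlo Fisher test of (concordant/discordant) x group.

    ``concordant`` and ``groups`` are parallel per-pair vectors; the
    contingency table is built here and tested with the fixed-margin
    Monte-Carlo Fisher test, reported as mean p over repeats with its
    Monte-Carlo spread.
    """
    if len(concordant) != len(groups):
        raise ValueError("concordant and groups must have equal length")
    levels = sorted(set(groups))
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    table = np.zeros((2, len(levels)), dtype=np.int64)
    for c, g in zip(concordant, groups):
        table[0 if c else 1, levels.index(g)] += 1
    return fisher_exact_mc(table, n_replicates=n_replicates,
                           n_repeats=n_repeats, seed=seed)


def paired_diversity_test(
    values_lesion,
    values_adjacent,
    *,
    subset: list[bool] | None = None,
    min_pairs: int = 3,
) -> TestResult | None:
    """Wilcoxon signed-rank test on within-pair differences.

    Typically applied to inverse Simpson diversity or MCPI, optionally
    restricted (``subset``) to pairs concordant for one metacommunity.
    Returns None (with a warning) when fewer than ``min_pairs`` usable
    pairs remain or all differences vanish.
    """
    x = np.asarray(values_lesion, dtype=float)
    y = np.asarray(values_adjacent, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    if subset is not None:
        mask = np.asarray(subset, dtype=bool)
        x, y = x[mask], y[mask]
    if x.size < min_pairs:
        warnings.warn(f"only {x.size} pair(s) after filtering; no test")
        return None
    d = x - y
    if np.all(d == 0):
        warnings.warn("all within-pair differences are zero; no test")
        return None
    return wilcoxon_signed_rank(d)
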