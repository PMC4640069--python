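"""Count tables, sample metadata and the basic abundance transforms.

The universal substrate of the pipeline is a phylotype count table
(taxa x samples, non-negative integers) together with per-sample
clinical annotations (phenotype, biopsy site, clinicopathologic stage,
and lesion/adjacent pair linkage).  On disk both live as plain TSV:
taxa as rows and samples as columns for the counts (the usual
amplicon-community convention), one row per sample for the metadata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountTable",
    "RelAbundanceTable",
    "SampleRecord",
    "FormatError",
    "ValidationError",
    "read_count_table",
    "write_count_table",
    "read_metadata",
    "write_metadata",
    "validate_records",
    "rarefy",
    "RarefactionResult",
    "to_relative",
    "bin_rare_taxa",
    "RARE_BIN",
]

PHENOTYPES = ("normal", "adenoma", "carcinoma")
SITES = ("control", "lesion", "adjacent")
STAGES = ("LGDP", "HGDP", "ECRC", "LCRC", "none")

#: pseudo-taxon receiving the pooled counts of rare phylotypes
RARE_BIN = "RARE_BIN"


class FormatError(ValueError):
    """Malformed on-disk table (bad cell, duplicated identifier...)."""


class ValidationError(ValueError):
    """Metadata violating the cohort schema (pairing, stage rules...)."""


def _check_unique(ids: Sequence[str], kind: str) -> None:
    seen: set[str] = set()
    dups = [i for i in ids if i in seen or seen.add(i)]  # type: ignore[func-returns-value]
    if dups:
        raise FormatError(f"duplicate {kind} identifier(s): {sorted(set(dups))}")


@dataclass
class CountTable:
    """Taxa x samples matrix of non-negative integer read counts."""

    taxon_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray  # shape (n_taxa, n_samples), integer dtype

    def __post_init__(self) -> None:
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        _check_unique(self.taxon_ids, "taxon")
        _check_unique(self.sample_ids, "sample")
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.taxon_ids), len(self.sample_ids)):
            raise FormatError(
                f"count matrix shape {counts.shape} does not match "
                f"{len(self.taxon_ids)} taxa x {len(self.sample_ids)} samples"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(counts, 1), 0)):
                bad = np.argwhere(np.mod(counts, 1) != 0)[0]
                raise FormatError(
                    f"non-integer count at ({self.taxon_ids[bad[0]]}, "
                    f"{self.sample_ids[bad[1]]})"
                )
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            bad = np.argwhere(counts < 0)[0]
            raise FormatError(
                f"negative count at ({self.taxon_ids[bad[0]]}, "
                f"{self.sample_ids[bad[1]]})"
            )
        self.counts = counts.astype(np.int64)

    # -- convenience -------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def depths(self) -> np.ndarray:
        """Per-sample read totals (column sums)."""
        return self.counts.sum(axis=0)

    def sample_index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)

    def select_samples(self, sample_ids: Sequence[str]) -> "CountTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CountTable(list(self.taxon_ids), list(sample_ids), self.counts[:, idx])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.taxon_ids, columns=self.sample_ids)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountTable):
            return NotImplemented
        return (
            self.taxon_ids == other.taxon_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.counts, other.counts)
        )


@dataclass
class RelAbundanceTable:
    """Per-sample proportions (or a monotone display transform of them).

    With ``transform='none'`` every column sums to one.  The
    arcsine-square-root variant applies ``asin(sqrt(p))`` element-wise
    and is meant for display / marker heat-matrices only, never as
    input to count models.
    """

    taxon_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # (n_taxa, n_samples) floats
    transform: str = "none"

    def __post_init__(self) -> None:
        _check_unique(self.taxon_ids, "taxon")
        _check_unique(self.sample_ids, "sample")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.taxon_ids), len(self.sample_ids)):
            raise FormatError("value matrix shape mismatch")
        if self.transform == "none":
            sums = self.values.sum(axis=0)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise FormatError("per-sample proportions must sum to 1")
            if np.any(self.values < 0) or np.any(self.values > 1):
                raise FormatError("proportions must lie in [0, 1]")

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.taxon_ids, columns=self.sample_ids)


@dataclass(frozen=True)
class SampleRecord:
    """Clinical annotation of a single biopsy sample.

    ``pair_id`` links a lesion biopsy to the adjacent-mucosa biopsy
    taken from the same subject; controls are unpaired by definition.
    """

    sample_id: str
    subject_id: str
    phenotype: str
    site: str
    stage: str = "none"
    pair_id: str | None = None

    def __post_init__(self) -> None:
        if self.phenotype not in PHENOTYPES:
            raise ValidationError(f"unknown phenotype {self.phenotype!r}")
        if self.site not in SITES:
            raise ValidationError(f"unknown site {self.site!r}")
        if self.stage not in STAGES:
            raise ValidationError(f"unknown stage {self.stage!r}")
        if self.phenotype == "normal":
            if self.site != "control" or self.pair_id is not None:
                raise ValidationError(
                    f"sample {self.sample_id}: normal phenotype requires "
                    "site=control and no pair_id"
                )
        else:
            if self.site == "control":
                raise ValidationError(
                    f"sample {self.sample_id}: site=control implies phenotype=normal"
                )
        if self.stage in ("LGDP", "HGDP") and self.phenotype != "adenoma":
            raise ValidationError(
                f"sample {self.sample_id}: stage {self.stage} requires adenoma"
            )
        if self.stage in ("ECRC", "LCRC") and self.phenotype != "carcinoma":
            raise ValidationError(
                f"sample {self.sample_id}: stage {self.stage} requires carcinoma"
            )


def validate_records(records: Sequence[SampleRecord]) -> None:
    """Cross-sample checks: unique ids, well-formed lesion/adjacent pairs."""
    _check_unique([r.sample_id for r in records], "sample")
    pairs: dict[str, list[SampleRecord]] = {}
    for r in records:
        if r.pair_id is not None:
            pairs.setdefault(r.pair_id, []).append(r)
    for pid, members in pairs.items():
        if len(members) != 2:
            raise ValidationError(
                f"pair_id {pid!r} has {len(members)} member(s), expected 2"
            )
        sites = sorted(m.site for m in members)
        if sites != ["adjacent", "lesion"]:
            raise ValidationError(
                f"pair_id {pid!r} must link one lesion and one adjacent sample"
            )
        if members[0].subject_id != members[1].subject_id:
            raise ValidationError(f"pair_id {pid!r} spans two subjects")
        if members[0].phenotype != members[1].phenotype:
            raise ValidationError(f"pair_id {pid!r} spans two phenotypes")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_count_table(path) -> CountTable:
    """Read a taxa-x-samples TSV (header = sample ids, column 1 = taxon id)."""
    df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    taxon_ids = [str(t) for t in df.index]
    sample_ids = [str(s) for s in df.columns]
    _check_unique(taxon_ids, "taxon")
    _check_unique(sample_ids, "sample")
    counts = np.empty(df.shape, dtype=np.int64)
    raw = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            cell = raw[i, j]
            try:
                val = float(cell)
            except (TypeError, ValueError):
                raise FormatError(
                    f"non-numeric count {cell!r} at ({taxon_ids[i]}, {sample_ids[j]})"
                ) from None
            if val < 0 or not float(val).is_integer():
                raise FormatError(
                    f"invalid count {cell!r} at ({taxon_ids[i]}, {sample_ids[j]}): "
                    "counts must be non-negative integers"
                )
            counts[i, j] = int(val)
    return CountTable(taxon_ids, sample_ids, counts)


def write_count_table(table: CountTable, path) -> None:
    table.to_dataframe().to_csv(path, sep="\t", index_label="taxon_id")


_META_COLUMNS = ("sample_id", "subject_id", "phenotype", "site")


def read_metadata(path) -> list[SampleRecord]:
    """Read and validate the sample metadata TSV.

    Required columns: sample_id, subject_id, phenotype, site.  Optional:
    stage, pair_id.  Enum values are case-insensitive on read.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"metadata missing required column(s): {missing}")
    records = []
    for row in df.itertuples(index=False):
        stage = str(getattr(row, "stage", "") or "none")
        stage = stage.upper() if stage.lower() != "none" else "none"
        pair = str(getattr(row, "pair_id", "") or "") or None
        records.append(
            SampleRecord(
                sample_id=str(row.sample_id),
                subject_id=str(row.subject_id),
                phenotype=str(row.phenotype).lower(),
                site=str(row.site).lower(),
                stage=stage,
                pair_id=pair,
            )
        )
    validate_records(records)
    return records


def write_metadata(records: Sequence[SampleRecord], path) -> None:
    df = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "subject_id": [r.subject_id for r in records],
            "phenotype": [r.phenotype for r in records],
            "site": [r.site for r in records],
            "stage": [r.stage for r in records],
            "pair_id": [r.pair_id or "" for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

class RarefactionResult(NamedTuple):
    table: CountTable
    dropped: list[str]  # sample ids with fewer reads than the target depth


def rarefy(table: CountTable, depth: int = 1000, *, seed: int | None = None) -> RarefactionResult:
    """Subsample every sample to a fixed depth without replacement.

    Each retained sample's reads are drawn by multivariate hypergeometric
    sampling, so each cell never exceeds its original count and every
    retained column sums exactly to ``depth``.  Samples with fewer than
    ``depth`` total reads are dropped and reported.
    """
    if depth < 1:
        raise ValueError(f"rarefaction depth must be >= 1, got {depth}")
    rng = np.random.default_rng(seed)
    totals = table.depths()
    keep_cols = []
    dropped = []
    new_cols = []
    for j, sid in enumerate(table.sample_ids):
        if totals[j] < depth:
            dropped.append(sid)
            continue
        col = rng.multivariate_hypergeometric(table.counts[:, j], depth)
        keep_cols.append(sid)
        new_cols.append(col)
    counts = (
        np.column_stack(new_cols) if new_cols else np.zeros((table.n_taxa, 0), dtype=np.int64)
    )
    return RarefactionResult(CountTable(list(table.taxon_ids), keep_cols, counts), dropped)


def to_relative(table: CountTable, transform: str = "none") -> RelAbundanceTable:
    """Convert counts to per-sample proportions.

    ``transform='arcsine_sqrt'`` additionally applies asin(sqrt(p))
    element-wise — a variance-stabilising display transform.
    """
    if transform not in ("none", "arcsine_sqrt"):
        raise ValueError(f"unknown transform {transform!r}")
    depths = table.depths()
    if np.any(depths == 0):
        zero = [s for s, d in zip(table.sample_ids, depths) if d == 0]
        raise ValueError(f"zero-depth sample(s): {zero}")
    props = table.counts / depths[np.newaxis, :]
    if transform == "arcsine_sqrt":
        props = np.arcsin(np.sqrt(props))
    return RelAbundanceTable(
        list(table.taxon_ids), list(table.sample_ids), props, transform=transform
    )


def bin_rare_taxa(table: CountTable, cutoff: float) -> CountTable:
    """Pool rare phylotypes into a single ``RARE_BIN`` pseudo-taxon.

    Rarity is measured on total relative abundance: a taxon is rare when
    its reads summed over all samples fall below ``cutoff`` of the grand
    total.  Column sums are preserved exactly; the bin row is always
    present (zero if nothing was binned) so downstream dimensionality is
    stable across cutoff sweeps.
    """
    if not (0 <= cutoff < 1):
        raise ValueError(f"cutoff must lie in [0, 1), got {cutoff}")
    grand = table.counts.sum()
    if grand == 0:
        raise ValueError("empty table")
    shares = table.counts.sum(axis=1) / grand
    rare = shares < cutoff
    kept_ids = [t for t, r in zip(table.taxon_ids, rare) if not r]
    if RARE_BIN in kept_ids:
        raise FormatError(f"taxon id {RARE_BIN!r} is reserved")
    kept = table.counts[~rare, :]
    binned = table.counts[rare, :].sum(axis=0, keepdims=True)
    return CountTable(
        kept_ids + [RARE_BIN],
        list(table.sample_ids),
        np.vstack([kept, binned]),
    )
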