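"""Rarity-cutoff sweep: do the model-based and medoid-based cluster
counts agree once rare phylotypes are pooled?

For each cutoff on total relative abundance the table is re-binned and
(1) a DMM is fitted over a K range with the evidence-optimal K
recorded, (2) PAM is run on Bray-Curtis distances with the
Calinski-Harabasz-optimal k recorded, and (3) the NMDS ordination is
compared by Procrustes to the unbinned (cutoff-0) ordination.  The
recommended cutoff is the smallest one at which the two methods agree
on the largest jointly supported cluster number.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import CountTable, bin_rare_taxa, to_relative
from .dmm import select_k
from .ordination import bray_curtis, calinski_harabasz, nmds, pam_cluster, procrustes_r

__all__ = ["RaritySweepReport", "rarity_sweep", "DEFAULT_CUTOFFS"]

DEFAULT_CUTOFFS = (0.0, 0.0005, 0.001, 0.005, 0.01)


@dataclass
class CutoffRecord:
    cutoff: float
    n_taxa_retained: int  # excluding the rare bin
    dmm_best_K: int
    pam_best_k: int
    ch_profile: dict[int, float]
    procrustes_R_vs_baseline: float
    evidence: dict[int, float]


@dataclass
class RaritySweepReport:
    records: list[CutoffRecord]
    recommended_cutoff: float | None
    errors: dict[float, str] = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (r.cutoff, r.n_taxa_retained, r.dmm_best_K, r.pam_best_k,
                 r.procrustes_R_vs_baseline)
                for r in self.records
            ],
            columns=["cutoff", "n_taxa_retained", "dmm_best_K", "pam_best_k",
                     "procrustes_R_vs_baseline"],
        )


def rarity_sweep(
    table: CountTable,
    cutoffs=DEFAULT_CUTOFFS,
    k_range=range(1, 8),
    *,
    seed: int | None = None,
    n_restarts: int = 1,
    nmds_dims: int = 2,
) -> RaritySweepReport:
    """Sweep rarity cutoffs, cross-checking DMM against PAM/CH and NMDS."""
    cutoffs = sorted(set(float(c) for c in cutoffs))
    k_list = [k for k in k_range]
    rng = np.random.default_rng(seed)
    records: list[CutoffRecord] = []
    errors: dict[float, str] = {}
    baseline_coords = None
    prev_retained = None
    for cutoff in cutoffs:
        try:
            binned = bin_rare_taxa(table, cutoff) if cutoff > 0 else table
            n_retained = binned.n_taxa - (1 if cutoff > 0 else 0)
            if prev_retained is not None and n_retained > prev_retained:
                raise RuntimeError("retained taxa increased with cutoff")
            prev_retained = n_retained
            rel = to_relative(binned)
            dist = bray_curtis(rel)
            sub = int(rng.integers(2**31))
            sel = select_k(binned, k_list, seed=sub, n_restarts=n_restarts)
            ord_ = nmds(dist, n_dims=nmds_dims, seed=sub)
            ch: dict[int, float] = {}
            for k in k_list:
                if k < 2 or k > binned.n_samples - 1:
                    continue
                labels = pam_cluster(dist, k, seed=sub).labels
                if len(np.unique(labels)) < 2:
                    continue
                ch[k] = calinski_harabasz(ord_.coordinates, labels)
            pam_best = max(ch, key=ch.get) if ch else 1
            if baseline_coords is None:
                baseline_coords = ord_.coordinates
                R = 1.0
            else:
                R = procrustes_r(baseline_coords, ord_.coordinates)
            records.append(
                CutoffRecord(
                    cutoff=cutoff,
                    n_taxa_retained=n_retained,
                    dmm_best_K=sel.best_K,
                    pam_best_k=pam_best,
                    ch_profile=ch,
                    procrustes_R_vs_baseline=R,
                    evidence=sel.evidence,
                )
            )
        except Exception as exc:  # skip-and-flag per cutoff
            errors[cutoff] = str(exc)
            warnings.warn(f"cutoff {cutoff}: {exc}")
    agreeing = [r for r in records if r.dmm_best_K == r.pam_best_k]
    recommended = None
    if agreeing:
        max_k = max(r.dmm_best_K for r in agreeing)
        recommended = min(r.cutoff for r in agreeing if r.dmm_best_K == max_k)
    return RaritySweepReport(records=records, recommended_cutoff=recommended,
                             errors=errors)
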