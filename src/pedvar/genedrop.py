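"""Monte-Carlo gene drop: founder-allele retention and founder genome surviving.

Each replicate labels every root genome source with two globally unique
alleles and transmits one allele per parent, uniformly at random, down the
topologically ordered pedigree.  Root sources are (a) founders with both
parents unknown, which carry their own two alleles, and (b) one phantom per
unknown parent slot of a partially known founder.  Retention r_f of a root is
the expected fraction of its two alleles present in the scored cohort;
founder genome surviving is FGS = sum_f r_f.  Retention ignores how evenly
surviving alleles are represented, so FGS is an upper companion to the
kinship-based founder genome equivalents.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .pedigree import Pedigree, PedigreeError

__all__ = ["GeneDropConfig", "GeneDropResult", "run_gene_drop", "allele_retention_curve"]


@dataclass
class GeneDropConfig:
    """Replicate count, scored cohort (default: every named animal) and seed."""

    replicates: int = 10_000
    cohort: Sequence[str] | None = None
    seed: int = 0
    named_founders_only: bool = False   # restrict scoring to named (non-phantom) roots

    def __post_init__(self):
        if self.replicates < 1:
            raise PedigreeError("replicate count must be >= 1")


@dataclass
class GeneDropResult:
    """Per-root retention, founder genome surviving, and Monte-Carlo errors."""

    founder_ids: list[str]            # scored roots (phantoms suffixed ".phantom")
    is_phantom: np.ndarray
    retention: np.ndarray             # r_f per scored root
    retention_se: np.ndarray
    fgs: float                        # sum of retention
    fgs_se: float
    surviving_alleles: np.ndarray     # per-replicate surviving allele count
    config: GeneDropConfig = field(repr=False, default=None)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"founder": self.founder_ids,
                             "phantom": self.is_phantom,
                             "retention": self.retention,
                             "se": self.retention_se})


def run_gene_drop(ped: Pedigree, cfg: GeneDropConfig) -> GeneDropResult:
    """Drop uniquely labelled founder alleles through the pedigree.

    Deterministic for a given seed and configuration.
    """
    n = len(ped)
    cohort = cfg.cohort if cfg.cohort is not None else ped.ids
    if len(cohort) == 0:
        raise PedigreeError("empty gene-drop cohort")
    cohort_idx = np.array([ped.index_of(a) for a in cohort], dtype=np.int64)

    # enumerate roots: both-unknown founders, plus one phantom per unknown slot
    root_ids: list[str] = []
    phantom: list[bool] = []
    own_root = np.full(n, -1, dtype=np.int64)          # both-unknown founder -> root
    sire_phantom = np.full(n, -1, dtype=np.int64)      # unknown-sire slot -> root
    dam_phantom = np.full(n, -1, dtype=np.int64)
    for i, r in enumerate(ped.records):
        if r.both_parents_unknown:
            own_root[i] = len(root_ids)
            root_ids.append(r.id)
            phantom.append(False)
        else:
            if ped.sire[i] < 0:
                sire_phantom[i] = len(root_ids)
                root_ids.append(f"{r.id}.sire.phantom")
                phantom.append(True)
            if ped.dam[i] < 0:
                dam_phantom[i] = len(root_ids)
                root_ids.append(f"{r.id}.dam.phantom")
                phantom.append(True)
    n_roots = len(root_ids)
    reps = cfg.replicates
    rng = np.random.default_rng(cfg.seed)

    # allele labels: root r owns labels 2r and 2r+1
    al = np.empty((reps, n, 2), dtype=np.int32)
    for i in ped.topo:
        if own_root[i] >= 0:
            al[:, i, 0] = 2 * own_root[i]
            al[:, i, 1] = 2 * own_root[i] + 1
            continue
        for slot, (pidx, ph) in enumerate(((ped.sire[i], sire_phantom[i]),
                                           (ped.dam[i], dam_phantom[i]))):
            pick = rng.integers(0, 2, size=reps)
            if pidx >= 0:
                al[:, i, slot] = al[np.arange(reps), pidx, pick]
            else:
                al[:, i, slot] = 2 * ph + pick

    # presence of each allele label in the cohort, per replicate
    flat = al[:, cohort_idx, :].reshape(reps, -1)
    present = np.zeros((reps, 2 * n_roots), dtype=bool)
    rows = np.repeat(np.arange(reps), flat.shape[1])
    present[rows, flat.ravel()] = True

    is_phantom = np.asarray(phantom)
    keep = ~is_phantom if cfg.named_founders_only else np.ones(n_roots, dtype=bool)
    keep_roots = np.flatnonzero(keep)
    # per-replicate retention of each scored root (0, 0.5 or 1)
    per_rep = (present[:, 2 * keep_roots].astype(np.float64)
               + present[:, 2 * keep_roots + 1]) / 2.0
    retention = per_rep.mean(axis=0)
    retention_se = per_rep.std(axis=0, ddof=1) / np.sqrt(reps) if reps > 1 else np.zeros_like(retention)
    fgs_rep = per_rep.sum(axis=1)
    surviving = (2.0 * fgs_rep).astype(np.int64)
    fgs_se = float(fgs_rep.std(ddof=1) / np.sqrt(reps)) if reps > 1 else 0.0
    return GeneDropResult(
        founder_ids=[root_ids[i] for i in keep_roots],
        is_phantom=is_phantom[keep_roots],
        retention=retention,
        retention_se=retention_se,
        fgs=float(fgs_rep.mean()),
        fgs_se=fgs_se,
        surviving_alleles=surviving,
        config=cfg,
    )


def allele_retention_curve(result: GeneDropResult) -> pd.DataFrame:
    """Distribution of per-replicate surviving founder-allele counts."""
    counts = np.bincount(result.surviving_alleles)
    support = np.flatnonzero(counts)
    return pd.DataFrame({"surviving_alleles": support,
                         "replicates": counts[support],
                         "fraction": counts[support] / len(result.surviving_alleles)})
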