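"""Coancestry, inbreeding, mean kinship, gene diversity and effective size.

The kinship matrix f(i,j) is built by the tabular recursion over a
topologically ordered pedigree: with a(i,j) = 2 f(i,j) the additive
relationship,

    a(i,i) = 1 + F_i = 1 + a(sire_i, dam_i) / 2
    a(i,j) = (a(sire_i, j) + a(dam_i, j)) / 2        (j earlier than i)

and an unknown parent contributes 0 (a distinct, unrelated, non-inbred
phantom).  All values are dyadic rationals, so double precision is exact.

From f the module derives the conservation-genetics summaries: individual
inbreeding F_i = f(sire_i, dam_i), average relatedness AR_i, cohort mean
kinship MK, gene diversity GD = 1 - MK, founder genome equivalents
fge = 1 / (2 MK), the per-generation rate of inbreeding dF from the
individual-increase formulation, and realized effective population size
Ne = 1 / (2 dF).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .pedigree import Pedigree, PedigreeError, completeness

__all__ = [
    "KinshipMatrix",
    "InbreedingSummary",
    "DiversitySummary",
    "kinship_matrix",
    "inbreeding_coefficients",
    "average_relatedness",
    "mean_kinship_summary",
    "delta_F_and_Ne",
    "demographic_ne",
    "inbreeding_by_year",
]


@dataclass
class KinshipMatrix:
    """Symmetric pairwise coancestry f(i,j); diagonal 0.5 * (1 + F_i)."""

    ids: list[str]
    f: np.ndarray

    def __post_init__(self):
        self._index = {a: i for i, a in enumerate(self.ids)}

    def value(self, a: str, b: str) -> float:
        return float(self.f[self._index[a], self._index[b]])

    def subset(self, cohort: Sequence[str]) -> "KinshipMatrix":
        try:
            idx = [self._index[a] for a in cohort]
        except KeyError as e:
            raise PedigreeError(f"cohort id {e.args[0]!r} not in kinship matrix") from None
        return KinshipMatrix(list(cohort), self.f[np.ix_(idx, idx)])

    @property
    def inbreeding(self) -> np.ndarray:
        """F_i recovered from the diagonal: 2 f(i,i) - 1."""
        return 2.0 * np.diag(self.f) - 1.0


def _relationship_matrix(ped: Pedigree) -> np.ndarray:
    n = len(ped)
    a = np.zeros((n, n), dtype=np.float64)
    sire, dam = ped.sire, ped.dam
    for i in ped.topo:
        s, d = sire[i], dam[i]
        row = np.zeros(n)
        if s >= 0:
            row += 0.5 * a[s]
        if d >= 0:
            row += 0.5 * a[d]
        a[i, :] = row
        a[:, i] = row
        a[i, i] = 1.0 + (0.5 * a[s, d] if (s >= 0 and d >= 0) else 0.0)
    return a


def kinship_matrix(ped: Pedigree, cohort: Sequence[str] | None = None) -> KinshipMatrix:
    """Tabular-method kinship over the full pedigree, optionally subset.

    The matrix is always computed on the complete pedigree and then restricted
    to ``cohort``: truncating the pedigree first would change F.
    """
    k = KinshipMatrix(ped.ids, _relationship_matrix(ped) / 2.0)
    if cohort is not None:
        k = k.subset(cohort)
    return k


@dataclass
class InbreedingSummary:
    """Per-animal inbreeding coefficients with the headline counts."""

    values: pd.Series           # id -> F
    mean: float
    sd: float
    n_inbred: int               # F > 0
    n_above_20pct: int
    n_above_25pct: int


def inbreeding_coefficients(ped: Pedigree, kin: KinshipMatrix | None = None) -> InbreedingSummary:
    """F_i = f(sire_i, dam_i); zero when either parent is unknown."""
    if kin is None:
        kin = kinship_matrix(ped)
    f = kin.f
    n = len(ped)
    F = np.zeros(n)
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        if s >= 0 and d >= 0:
            F[i] = f[s, d]
    values = pd.Series(F, index=ped.ids, name="F")
    return InbreedingSummary(
        values=values,
        mean=float(F.mean()),
        sd=float(F.std(ddof=1)) if n > 1 else 0.0,
        n_inbred=int((F > 0).sum()),
        n_above_20pct=int((F > 0.20).sum()),
        n_above_25pct=int((F > 0.25).sum()),
    )


def average_relatedness(ped: Pedigree, kin: KinshipMatrix | None = None) -> dict:
    """AR_i: mean additive relationship 2 f(i,j) of i with every animal, itself included."""
    if kin is None:
        kin = kinship_matrix(ped)
    ar = (2.0 * kin.f).mean(axis=1)
    values = pd.Series(ar, index=kin.ids, name="AR")
    return {"values": values, "mean": float(ar.mean()),
            "n_above_25pct": int((ar > 0.25).sum())}


def mean_kinship_summary(kin: KinshipMatrix, cohort: Sequence[str] | None = None,
                         include_diagonal: bool = True) -> dict:
    """Cohort mean kinship MK, gene diversity GD = 1 - MK, fge = 1/(2 MK).

    ``include_diagonal`` keeps the self-kinship terms in the average (the
    mean-kinship-matrix convention of pedigree-management software); the
    alternative averages off-diagonal pairs only.
    """
    if cohort is not None:
        kin = kin.subset(cohort)
    n = len(kin.ids)
    if n == 0:
        raise PedigreeError("empty cohort")
    f = kin.f
    if include_diagonal:
        mk = float(f.mean())
    else:
        if n < 2:
            raise PedigreeError("off-diagonal mean kinship needs >= 2 animals")
        mk = float((f.sum() - np.trace(f)) / (n * (n - 1)))
    return {"MK": mk, "GD": 1.0 - mk,
            "fge": float("inf") if mk == 0 else 1.0 / (2.0 * mk),
            "n": n, "include_diagonal": include_diagonal}


@dataclass
class DiversitySummary:
    """Population-level diversity summary assembled by the report layer."""

    mean_F: float
    sd_F: float
    n_inbred: int
    mean_AR: float
    MK: float
    GD: float
    fge: float
    delta_F: float
    Ne: float
    Ne_demographic: float
    census_n: int | None = None
    extras: dict = field(default_factory=dict)

    @property
    def ne_over_n(self) -> float | None:
        return None if not self.census_n else self.Ne / self.census_n


def delta_F_and_Ne(ped: Pedigree, census_n: int | None = None,
                   kin: KinshipMatrix | None = None) -> dict:
    """Rate of inbreeding and effective population size.

    Individual increase in inbreeding dF_i = 1 - (1 - F_i)^(1/(t_i - 1)) with
    t_i the equivalent complete generations (the animal's own generation is
    discounted); realized Ne = 1/(2 mean dF).  The demographic alternative
    Ne_dem = 4 Nm Nf / (Nm + Nf) uses the counts of sires and dams actually
    used in breeding.
    """
    if kin is None:
        kin = kinship_matrix(ped)
    F = inbreeding_coefficients(ped, kin).values.to_numpy()
    t = completeness(ped).equivalent_complete_generations
    eligible = t > 1.0
    if not eligible.any():
        raise PedigreeError("pedigree too shallow: no animal with t > 1")
    dF = 1.0 - (1.0 - F[eligible]) ** (1.0 / (t[eligible] - 1.0))
    mean_dF = float(dF.mean())
    ne = float("inf") if mean_dF <= 0 else 1.0 / (2.0 * mean_dF)

    sires = {ped.sire[i] for i in range(len(ped)) if ped.sire[i] >= 0}
    dams = {ped.dam[i] for i in range(len(ped)) if ped.dam[i] >= 0}
    nm, nf = len(sires), len(dams)
    ne_dem = 4.0 * nm * nf / (nm + nf) if (nm + nf) > 0 else float("nan")
    out = {"delta_F": mean_dF, "Ne": ne, "Ne_demographic": ne_dem,
           "n_eligible": int(eligible.sum()), "n_sires": nm, "n_dams": nf}
    if census_n:
        out["Ne_over_N"] = ne / census_n
    return out


def demographic_ne(n_males: int, n_females: int) -> float:
    """Sex-ratio effective size 4 Nm Nf / (Nm + Nf) from breeder counts."""
    if n_males + n_females == 0:
        return float("nan")
    return 4.0 * n_males * n_females / (n_males + n_females)


def inbreeding_by_year(ped: Pedigree, kin: KinshipMatrix | None = None) -> pd.DataFrame:
    """Birth-year cohorts: animal count and mean F (years with no births absent)."""
    F = inbreeding_coefficients(ped, kin).values
    years = pd.Series([r.birth_year for r in ped.records], index=ped.ids, dtype="Int64")
    df = pd.DataFrame({"birth_year": years, "F": F}).dropna(subset=["birth_year"])
    if df.empty:
        return pd.DataFrame(columns=["birth_year", "n", "mean_F"])
    out = (df.groupby("birth_year")["F"].agg(n="size", mean_F="mean")
             .reset_index())
    out["birth_year"] = out["birth_year"].astype(int)
    return out
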