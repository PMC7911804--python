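"""Per-locus STR diversity statistics and the panel summary table.

For a locus with allele frequencies p_a estimated from the typed genotypes:

    He  = 1 - sum p_a^2                     (expected heterozygosity)
    PIC = He - sum_{a<b} 2 p_a^2 p_b^2      (polymorphic information content)
    Ho  = heterozygote fraction among typed individuals
    FIS = 1 - Ho / He                       (within-population fixation index)

The plain He estimator is the default; the small-sample unbiased variant
2n/(2n-1) * He is available by flag.  Panel means are unweighted arithmetic
means over loci.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypeTable, GenotypeError
from . import hwe as _hwe

__all__ = ["LocusSummary", "PanelSummary", "allele_frequencies", "pic",
           "expected_heterozygosity", "heterozygosity", "fis",
           "locus_summary", "panel_summary"]


@dataclass
class LocusSummary:
    """One row of the per-locus summary table."""

    locus: str
    n_typed: int
    frequencies: dict[int, float]
    pic: float
    ho: float
    he: float
    fis: float
    hwe_p: float | None = None
    hwe_se: float | None = None

    @property
    def n_alleles(self) -> int:
        return len(self.frequencies)


@dataclass
class PanelSummary:
    """Per-locus rows plus unweighted cross-locus means and total allele count."""

    loci: list[LocusSummary]

    def as_frame(self) -> pd.DataFrame:
        rows = [{"locus": s.locus, "n": s.n_typed, "n_alleles": s.n_alleles,
                 "PIC": s.pic, "Ho": s.ho, "He": s.he, "FIS": s.fis,
                 "hwe_p": s.hwe_p, "hwe_se": s.hwe_se} for s in self.loci]
        return pd.DataFrame(rows).set_index("locus")

    @property
    def total_alleles(self) -> int:
        return sum(s.n_alleles for s in self.loci)

    def mean(self, stat: str) -> float:
        vals = [getattr(s, stat) for s in self.loci]
        vals = [v for v in vals if v is not None and np.isfinite(v)]
        return float(np.mean(vals))


def allele_frequencies(table: GenotypeTable, locus: str) -> tuple[dict[int, float], int]:
    """Allele frequency map and typed-individual count for one locus."""
    calls = table.locus_calls(locus)
    if len(calls) == 0:
        raise GenotypeError(f"no typed genotypes at locus {locus!r}")
    alleles, counts = np.unique(calls, return_counts=True)
    freqs = {int(a): float(c) / (2 * len(calls)) for a, c in zip(alleles, counts)}
    return freqs, len(calls)


def _check_freqs(freqs: dict | np.ndarray, renormalise_tol: float = 1e-6) -> np.ndarray:
    p = np.asarray(list(freqs.values()) if isinstance(freqs, dict) else freqs, dtype=float)
    if (p < 0).any():
        raise GenotypeError("negative allele frequency")
    total = p.sum()
    if abs(total - 1.0) > renormalise_tol:
        warnings.warn(f"allele frequencies sum to {total:.6f}; renormalising",
                      stacklevel=3)
        p = p / total
    return p


def pic(freqs: dict[int, float] | np.ndarray) -> float:
    """Polymorphic information content of a frequency vector."""
    p = _check_freqs(freqs)
    s2 = float(np.sum(p ** 2))
    s4 = float(np.sum(p ** 4))
    return 1.0 - s2 - (s2 ** 2 - s4)


def expected_heterozygosity(freqs: dict[int, float] | np.ndarray,
                            n: int | None = None,
                            estimator: str = "plain") -> float:
    """He = 1 - sum p^2; ``unbiased`` applies the 2n/(2n-1) correction."""
    p = _check_freqs(freqs)
    he = 1.0 - float(np.sum(p ** 2))
    if estimator == "unbiased":
        if not n:
            raise GenotypeError("unbiased He needs the typed sample size n")
        he *= 2 * n / (2 * n - 1)
    elif estimator != "plain":
        raise GenotypeError(f"unknown He estimator {estimator!r}")
    return he


def heterozygosity(table: GenotypeTable, locus: str,
                   estimator: str = "plain") -> tuple[float, float]:
    """Observed and expected heterozygosity (Ho, He) at one locus."""
    calls = table.locus_calls(locus)
    if len(calls) == 0:
        raise GenotypeError(f"no typed genotypes at locus {locus!r}")
    ho = float((calls[:, 0] != calls[:, 1]).mean())
    freqs, n = allele_frequencies(table, locus)
    return ho, expected_heterozygosity(freqs, n, estimator)


def fis(ho: float, he: float) -> float:
    """FIS = 1 - Ho/He; undefined (NaN, with a warning) when He = 0."""
    if he == 0:
        warnings.warn("He = 0: FIS undefined at a monomorphic locus", stacklevel=2)
        return float("nan")
    return 1.0 - ho / he


def locus_summary(table: GenotypeTable, locus: str,
                  he_estimator: str = "plain",
                  hwe: dict | None = None) -> LocusSummary:
    """Full per-locus summary; ``hwe`` passes settings to the MCMC exact test
    (e.g. ``{"batches": 100, "dememorization": 10_000, "seed": 1}``) or is
    ``None`` to skip the test."""
    freqs, n = allele_frequencies(table, locus)
    ho, he = heterozygosity(table, locus, he_estimator)
    p = se = None
    if hwe is not None:
        counts = _hwe.GenotypeCounts.from_table(table, locus)
        res = _hwe.hwe_mcmc(counts, **hwe)
        p, se = res.p, res.se
    return LocusSummary(locus=locus, n_typed=n, frequencies=freqs,
                        pic=pic(freqs), ho=ho, he=he, fis=fis(ho, he),
                        hwe_p=p, hwe_se=se)


def panel_summary(table: GenotypeTable, he_estimator: str = "plain",
                  hwe: dict | None = None) -> PanelSummary:
    """Summary rows for every locus in the table."""
    if not table.loci:
        raise GenotypeError("genotype table has no loci")
    hwe_settings = dict(hwe) if hwe is not None else None
    rows = []
    for j, locus in enumerate(table.loci):
        settings = hwe_settings
        if settings is not None and "seed" in settings:
            settings = {**settings, "seed": settings["seed"] + j}
        rows.append(locus_summary(table, locus, he_estimator, settings))
    return PanelSummary(rows)
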