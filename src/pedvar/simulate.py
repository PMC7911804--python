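"""Synthetic pedigrees and STR genotypes with the structure the analyses assume.

The pedigree generator emulates a small closed studbook population with
overlapping generations: founders of unknown origin enter over the early
years (a configurable fraction with both parents unknown, the rest with one
recorded parent), litters of 2-16 pups (target mean about 6) are produced by
parents sampled inside an integer breeding-age window, and close matings
(full-sib, half-sib, parent-offspring) can be planted deliberately by
reassigning the parents of an existing litter, so litter counts are
preserved and planted counts are exactly recoverable.

The genotype generator drops Mendelian alleles down any pedigree from
founder alleles drawn at configured locus frequencies (defaults: the
21-locus reference panel), with optional missing calls.
"""

from __future__ import annotations

import json
import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import panels
from .genotypes import GenotypeTable, write_genepop
from .pedigree import (Pedigree, PedigreeRecord, PedigreeError, UNKNOWN,
                       classify_matings, identify_founders, litter_statistics,
                       write_pedigree)

__all__ = ["PedigreeSimConfig", "GenotypeSimConfig", "simulate_pedigree",
           "simulate_genotypes", "simulate_discrete_generations",
           "polish_greyhound_config", "fixture_bundle"]


def _substream(seed: int, name: str) -> np.random.Generator:
    """Named, independent random sub-stream derived from one integer seed."""
    digest = hashlib.sha256(f"{seed}:{name}".encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "little"))


@dataclass
class PedigreeSimConfig:
    """Study-population structure knobs for the pedigree generator."""

    n_total: int = 912
    n_founders_both_unknown: int = 27
    n_founders_one_unknown: int = 56
    years: int = 35
    founder_year_span: int = 9          # both-unknown founders enter years 0..span-1
    first_litter_year: int = 10
    litter_min: int = 2
    litter_max: int = 16
    litter_mean: float = 6.0
    breeding_age_min: int = 2           # integer-year floor of the 1.5-year rule
    breeding_age_max: int = 10
    mean_parent_age: float = 5.0
    mating_policy: str = "avoid_close_kin"   # or "random"
    planted: tuple = ()                 # (kind, year) pairs
    sex_ratio: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not (1 <= self.litter_min <= self.litter_max <= 20):
            raise PedigreeError("litter size range must lie within [1, 20]")
        if self.breeding_age_min < 1 or self.breeding_age_max <= self.breeding_age_min:
            raise PedigreeError("breeding-age window must be positive")
        if self.mating_policy not in ("random", "avoid_close_kin"):
            raise PedigreeError(f"unknown mating policy {self.mating_policy!r}")


@dataclass
class GenotypeSimConfig:
    """Locus frequency sets, missing-call rate and sample for the gene dropper."""

    loci: dict[str, dict[int, float]] = field(
        default_factory=lambda: {l: panels.locus_frequencies(l, renormalise=True)
                                 for l in panels.panel_loci()})
    missing_rate: float = 0.0
    sample_ids: list[str] | None = None   # subset of pedigree ids to genotype
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.missing_rate < 1.0):
            raise PedigreeError("missing rate must be in [0, 1)")
        norm = {}
        for locus, freqs in self.loci.items():
            total = sum(freqs.values())
            norm[locus] = {a: p / total for a, p in freqs.items()}
        self.loci = norm


def polish_greyhound_config(seed: int = 0) -> PedigreeSimConfig:
    """Preset mirroring the studied studbook: 912 records, 83 founders
    (27 with both parents unknown), litters 2-16 averaging ~6, and planted
    close matings (2 full-sib, 21 half-sib, 2 parent-offspring)."""
    plants = ([("full_sib", 24), ("full_sib", 30)]
              + [("half_sib", y) for y in
                 (18, 19, 20, 21, 22, 23, 24, 25, 26, 27, 28, 29, 30, 31, 32,
                  33, 33, 34, 34, 34, 34)]
              + [("parent_offspring", 26), ("parent_offspring", 31)])
    return PedigreeSimConfig(planted=tuple(plants), seed=seed)


# ---------------------------------------------------------------------------
# Pedigree simulation

def _age_weights(ages: np.ndarray, mean_age: float, lo: int, hi: int) -> np.ndarray:
    """Unnormalised parent-age weights: a discretised bell centred on the
    target mean, truncated symmetrically so the expected age equals it."""
    half = min(mean_age - lo, hi - mean_age)
    w = np.exp(-0.5 * ((ages - mean_age) / 1.5) ** 2)
    w[(ages < mean_age - half) | (ages > mean_age + half)] = 0.0
    return w


class _SimState:
    """Mutable record store used while building a synthetic pedigree."""

    def __init__(self):
        self.id: list[str] = []
        self.sire: list[int] = []     # -1 unknown
        self.dam: list[int] = []
        self.sex: list[str] = []
        self.year: list[int] = []
        self.founder: list[bool] = []
        self.blocked: set[int] = set()   # never used as parents (plant litters)

    def add(self, sire: int, dam: int, sex: str, year: int, founder: bool) -> int:
        i = len(self.id)
        self.id.append(f"PG{i + 1:04d}")
        self.sire.append(sire)
        self.dam.append(dam)
        self.sex.append(sex)
        self.year.append(year)
        self.founder.append(founder)
        return i

    def eligible(self, year: int, sex: str, lo: int, hi: int) -> np.ndarray:
        yr = np.asarray(self.year)
        sx = np.asarray(self.sex)
        age = year - yr
        ok = (sx == sex) & (age >= lo) & (age <= hi)
        if self.blocked:
            ok[list(self.blocked)] = False
        return np.flatnonzero(ok)

    def close_kin(self, a: int, b: int) -> bool:
        """Parent-offspring, full-sib or half-sib relation between a and b."""
        if self.sire[b] == a or self.dam[b] == a or self.sire[a] == b or self.dam[a] == b:
            return True
        shares = ((self.sire[a] >= 0 and self.sire[a] == self.sire[b])
                  or (self.dam[a] >= 0 and self.dam[a] == self.dam[b]))
        return shares

    def to_pedigree(self) -> Pedigree:
        recs = []
        for i in range(len(self.id)):
            recs.append(PedigreeRecord(
                id=self.id[i],
                sire_id=self.id[self.sire[i]] if self.sire[i] >= 0 else None,
                dam_id=self.id[self.dam[i]] if self.dam[i] >= 0 else None,
                sex=self.sex[i],
                birth_year=self.year[i],
                status="stud" if any(p == i for p in self.sire + self.dam) else "non-stud",
            ))
        return Pedigree(recs)


def _draw_litter_sizes(rng: np.random.Generator, cfg: PedigreeSimConfig,
                       n_offspring: int) -> list[int]:
    """Litter sizes in [min, max] with the target mean, summing to n_offspring.

    Beta-binomial over the range: real litter-size records are overdispersed
    relative to a binomial, and both range extremes do occur in studbooks.
    """
    span = cfg.litter_max - cfg.litter_min
    mu = (cfg.litter_mean - cfg.litter_min) / span if span else 0.0
    conc = 3.5                          # concentration: sd ~ 3 pups at mean 6
    sizes: list[int] = []
    while sum(sizes) < n_offspring:
        p = rng.beta(mu * conc, (1 - mu) * conc) if span else 0.0
        sizes.append(cfg.litter_min + int(rng.binomial(span, p)))
    excess = sum(sizes) - n_offspring
    # shave the overshoot off the last litters, never below the minimum
    for idx in range(len(sizes) - 1, -1, -1):
        if excess == 0:
            break
        take = min(excess, sizes[idx] - cfg.litter_min)
        sizes[idx] -= take
        excess -= take
    if excess > 0:
        # every litter is at the minimum: drop litters and top others back up
        while excess > 0 and sizes:
            excess -= sizes.pop()
        deficit = -excess
        for idx in range(len(sizes)):
            if deficit == 0:
                break
            add = min(deficit, cfg.litter_max - sizes[idx])
            sizes[idx] += add
            deficit -= add
        if deficit > 0:
            raise PedigreeError("litter-size constraints cannot reach the target count")
    return sizes


def _pick_parent(state: _SimState, rng: np.random.Generator, cfg: PedigreeSimConfig,
                 year: int, sex: str) -> int:
    pool = state.eligible(year, sex, cfg.breeding_age_min, cfg.breeding_age_max)
    if len(pool) == 0:
        raise PedigreeError(f"no eligible {sex} parent in year {year}")
    ages = year - np.asarray(state.year)[pool]
    w = _age_weights(ages.astype(float), cfg.mean_parent_age,
                     cfg.breeding_age_min, cfg.breeding_age_max)
    if w.sum() == 0:
        w = np.ones_like(w)
    return int(rng.choice(pool, p=w / w.sum()))


def simulate_pedigree(cfg: PedigreeSimConfig, seed: int | None = None) -> Pedigree:
    """Generate a pedigree under ``cfg``; deterministic for a given seed."""
    seed = cfg.seed if seed is None else seed
    rng = _substream(seed, "pedigree")
    state = _SimState()

    # both-unknown founders spread over the opening years; sexes alternate so
    # even tiny founder cohorts contain both sexes
    for i in range(cfg.n_founders_both_unknown):
        year = int(i * cfg.founder_year_span / max(cfg.n_founders_both_unknown, 1))
        state.add(-1, -1, "M" if i % 2 == 0 else "F", year, founder=True)

    # one-unknown founders: one recorded parent drawn from the existing stock
    one_years = np.sort(rng.integers(cfg.founder_year_span,
                                     cfg.years - 2, size=cfg.n_founders_one_unknown))
    n_births = cfg.n_total - cfg.n_founders_both_unknown - cfg.n_founders_one_unknown
    litter_sizes = _draw_litter_sizes(rng, cfg, n_births)
    breeding_years = np.arange(cfg.first_litter_year, cfg.years + 1)
    litter_years = [int(breeding_years[i % len(breeding_years)])
                    for i in range(len(litter_sizes))]
    litter_years.sort()

    events = ([("one_unknown", int(y), 0) for y in one_years]
              + [("litter", y, s) for y, s in zip(litter_years, litter_sizes)])
    events.sort(key=lambda e: e[1])

    # litters to reserve per year for planted matings: their pups never breed,
    # so the later parent reassignment cannot ripple through the pedigree
    plants_needed: dict[int, int] = {}
    for _kind, year in cfg.planted:
        plants_needed[year] = plants_needed.get(year, 0) + 1

    litters: list[dict] = []
    pairs_by_year: dict[int, set[tuple[int, int]]] = {}
    for kind, year, size in events:
        if kind == "one_unknown":
            parent_sex = "M" if rng.random() < 0.5 else "F"
            try:
                parent = _pick_parent(state, rng, cfg, year, parent_sex)
            except PedigreeError:
                parent_sex = "M" if parent_sex == "F" else "F"
                parent = _pick_parent(state, rng, cfg, year, parent_sex)
            sex = "M" if rng.random() < cfg.sex_ratio else "F"
            state.add(parent if parent_sex == "M" else -1,
                      parent if parent_sex == "F" else -1,
                      sex, year, founder=True)
            continue
        # a litter: pick a sire and dam honouring the mating policy
        taken = pairs_by_year.setdefault(year, set())
        for _attempt in range(200):
            sire = _pick_parent(state, rng, cfg, year, "M")
            dam = _pick_parent(state, rng, cfg, year, "F")
            if (sire, dam) in taken:    # one litter per pair and year
                continue
            if cfg.mating_policy == "random" or not state.close_kin(sire, dam):
                break
        else:
            raise PedigreeError(f"could not find an eligible mating in year {year}")
        taken.add((sire, dam))
        pups = [state.add(sire, dam, "M" if rng.random() < cfg.sex_ratio else "F",
                          year, founder=False) for _ in range(size)]
        reserved = plants_needed.get(year, 0) > 0
        if reserved:
            plants_needed[year] -= 1
            state.blocked.update(pups)
        litters.append({"sire": sire, "dam": dam, "year": year,
                        "pups": pups, "reserved": reserved})

    short = {y: k for y, k in plants_needed.items() if k > 0}
    if short:
        raise PedigreeError(f"infeasible planted matings: no litter in years {sorted(short)}")
    _plant_matings(state, litters, rng, cfg)
    return state.to_pedigree()


def _plant_matings(state: _SimState, litters: list[dict],
                   rng: np.random.Generator, cfg: PedigreeSimConfig) -> None:
    """Reassign the parents of existing litters to create the planted close
    matings; restricted to litters whose pups have no progeny so the swap
    cannot create accidental close matings elsewhere."""
    if not cfg.planted:
        return
    used_pairs: set[tuple[int, int]] = {(l["sire"], l["dam"]) for l in litters}
    reassigned: set[int] = set()

    def candidates(kind: str, year: int) -> list[tuple[int, int]]:
        lo, hi = cfg.breeding_age_min, cfg.breeding_age_max
        out = []
        n = len(state.id)
        males = [i for i in range(n) if state.sex[i] == "M" and i not in state.blocked
                 and lo <= year - state.year[i] <= hi]
        females = [i for i in range(n) if state.sex[i] == "F" and i not in state.blocked
                   and lo <= year - state.year[i] <= hi]
        for m in males:
            for f in females:
                if (m, f) in used_pairs:
                    continue
                if kind == "parent_offspring":
                    ok = (state.sire[f] == m or state.dam[f] == m
                          or state.sire[m] == f or state.dam[m] == f)
                elif kind == "full_sib":
                    ok = (state.sire[m] >= 0 and state.sire[m] == state.sire[f]
                          and state.dam[m] >= 0 and state.dam[m] == state.dam[f])
                else:  # half_sib: share exactly one parent
                    shared = (int(state.sire[m] >= 0 and state.sire[m] == state.sire[f])
                              + int(state.dam[m] >= 0 and state.dam[m] == state.dam[f]))
                    ok = shared == 1
                if ok:
                    out.append((m, f))
        return out

    for kind, year in cfg.planted:
        pool = [li for li, l in enumerate(litters)
                if l["year"] == year and l["reserved"] and li not in reassigned]
        pairs = candidates(kind, year)
        if not pool or not pairs:
            raise PedigreeError(
                f"infeasible planted mating: {kind} in year {year}")
        li = pool[int(rng.integers(len(pool)))]
        m, f = pairs[int(rng.integers(len(pairs)))]
        lit = litters[li]
        for pup in lit["pups"]:
            state.sire[pup] = m
            state.dam[pup] = f
        used_pairs.add((m, f))
        reassigned.add(li)
        lit["sire"], lit["dam"] = m, f


# ---------------------------------------------------------------------------
# Idealised discrete-generation population (known rate of inbreeding)

def simulate_discrete_generations(n_males: int = 10, n_females: int = 10,
                                  n_generations: int = 12,
                                  offspring_per_generation: int = 48,
                                  seed: int = 0) -> Pedigree:
    """Closed population with discrete generations and a fixed number of
    breeders per sex, so the expected rate of inbreeding is
    dF = 1/(8 Nm) + 1/(8 Nf) and Ne = 4 Nm Nf / (Nm + Nf)."""
    rng = _substream(seed, "discrete")
    state = _SimState()
    males = [state.add(-1, -1, "M", 0, True) for _ in range(n_males)]
    females = [state.add(-1, -1, "F", 0, True) for _ in range(n_females)]
    for g in range(1, n_generations + 1):
        new_m, new_f = [], []
        for c in range(offspring_per_generation):
            sire = males[int(rng.integers(len(males)))]
            dam = females[int(rng.integers(len(females)))]
            sex = "M" if c % 2 == 0 else "F"
            idx = state.add(sire, dam, sex, g, False)
            (new_m if sex == "M" else new_f).append(idx)
        males = list(rng.choice(new_m, size=n_males, replace=False))
        females = list(rng.choice(new_f, size=n_females, replace=False))
    return state.to_pedigree()


# ---------------------------------------------------------------------------
# Genotype simulation

def simulate_genotypes(ped: Pedigree, cfg: GenotypeSimConfig,
                       seed: int | None = None) -> GenotypeTable:
    """Mendelian gene drop of labelled allele sizes down the pedigree.

    Founders (and unknown parent slots) draw alleles independently from the
    configured locus frequencies; every descendant inherits one allele from
    each parent uniformly at random.
    """
    seed = cfg.seed if seed is None else seed
    rng = _substream(seed, "genotypes")
    n = len(ped)
    loci = list(cfg.loci)
    calls = np.zeros((n, len(loci), 2), dtype=np.int32)
    for j, locus in enumerate(loci):
        alleles = np.array(list(cfg.loci[locus]), dtype=np.int32)
        p = np.array(list(cfg.loci[locus].values()))
        founder_draw = rng.choice(alleles, size=(n, 2), p=p)
        if (ped.sire < 0).all() and (ped.dam < 0).all():
            calls[:, j, :] = founder_draw      # founder-only: pure HWE draw
            continue
        col = np.zeros((n, 2), dtype=np.int32)
        for i in ped.topo:
            s, d = ped.sire[i], ped.dam[i]
            col[i, 0] = col[s, rng.integers(2)] if s >= 0 else founder_draw[i, 0]
            col[i, 1] = col[d, rng.integers(2)] if d >= 0 else founder_draw[i, 1]
        calls[:, j, :] = col
    if cfg.missing_rate > 0:
        miss = rng.random((n, len(loci))) < cfg.missing_rate
        calls[miss] = 0
    table = GenotypeTable(ped.ids, loci, calls)
    if cfg.sample_ids is not None:
        keep = [table.ids.index(a) for a in cfg.sample_ids]
        table = GenotypeTable(list(cfg.sample_ids), loci, calls[keep])
    return table


# ---------------------------------------------------------------------------
# Fixture bundle

def fixture_bundle(outdir, seed: int = 0, n_genotyped: int = 174) -> dict:
    """Write a matched pedigree CSV + GenePop file + summary JSON.

    The summary holds the generator's self-reported structure recomputed by
    the analysis modules, so test suites can assert self-consistency.
    Byte-stable for a fixed seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ped_cfg = polish_greyhound_config(seed=seed)
    ped = simulate_pedigree(ped_cfg)
    sample_rng = _substream(seed, "sample")
    sample = [ped.ids[i] for i in
              np.sort(sample_rng.choice(len(ped), size=n_genotyped, replace=False))]
    geno = simulate_genotypes(ped, GenotypeSimConfig(sample_ids=sample, seed=seed))

    write_pedigree(ped, outdir / "pedigree.csv")
    write_genepop(geno, outdir / "genotypes.gen", title="pedvar fixture bundle")

    founders = identify_founders(ped)
    matings = classify_matings(ped)
    litter = litter_statistics(ped)
    summary = {
        "seed": seed,
        "n_records": len(ped),
        "n_founders_any_unknown": founders.n_any_unknown,
        "n_founders_both_unknown": founders.n_both_unknown,
        "matings": matings.as_dict(),
        "litter": litter.litter_stats,
        "n_genotyped": len(sample),
        "loci": geno.loci,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
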