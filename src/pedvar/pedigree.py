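"""Pedigree data model, parsing, validation and descriptive breeding statistics.

A pedigree is a directed acyclic family structure: one record per animal with
optional sire/dam links.  Animals with at least one unknown parent are the
*founders* through which all genetic variation enters the population; the
stricter both-parents-unknown subset is always reported alongside.  Unknown
parents are written ``NN`` on disk (the studbook notation for animals of
unknown origin) and modelled as missing links here; the kinship machinery
treats each unknown slot as a distinct unrelated, non-inbred phantom.
"""

from __future__ import annotations

import io
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "UNKNOWN",
    "PedigreeError",
    "PedigreeRecord",
    "Pedigree",
    "FounderReport",
    "CompletenessReport",
    "MatingReport",
    "LitterReport",
    "ProgenyReport",
    "read_pedigree",
    "write_pedigree",
    "identify_founders",
    "completeness",
    "generation_interval",
    "classify_matings",
    "litter_statistics",
    "progeny_statistics",
]

#: Canonical token written to files for an unknown parent.
UNKNOWN = "NN"

# tokens normalised to "unknown parent" on input (case-insensitive)
_UNKNOWN_TOKENS = {"", "nn", "0", "unknown", "na", "nan", "none"}

_SEX_TOKENS = {"m": "M", "male": "M", "f": "F", "female": "F", "u": "U",
               "unknown": "U", "": "U", "nan": "U"}


class PedigreeError(ValueError):
    """Raised when a pedigree violates a structural invariant."""


def _norm_parent(token) -> str | None:
    s = str(token).strip()
    return None if s.lower() in _UNKNOWN_TOKENS else s


def _norm_sex(token) -> str:
    s = str(token).strip().lower()
    if s not in _SEX_TOKENS:
        raise PedigreeError(f"unrecognised sex code {token!r}")
    return _SEX_TOKENS[s]


@dataclass(frozen=True)
class PedigreeRecord:
    """One animal: identifier, parent links, sex, birth year, breeding status."""

    id: str
    sire_id: str | None = None
    dam_id: str | None = None
    sex: str = "U"              # M / F / U
    birth_year: int | None = None
    status: str = "unknown"     # stud / non-stud / unknown

    def __post_init__(self):
        if not self.id or str(self.id).strip() == "":
            raise PedigreeError("empty animal identifier")
        if self.sire_id == self.id or self.dam_id == self.id:
            raise PedigreeError(f"self-parent: animal {self.id!r} listed as its own parent")

    @property
    def has_unknown_parent(self) -> bool:
        return self.sire_id is None or self.dam_id is None

    @property
    def both_parents_unknown(self) -> bool:
        return self.sire_id is None and self.dam_id is None


class Pedigree:
    """Validated, topologically ordered collection of :class:`PedigreeRecord`.

    Parameters
    ----------
    records
        Animal records in any order.
    on_missing_parent
        ``"error"`` rejects a named parent without its own record;
        ``"create"`` auto-creates a founder record for it.
    """

    def __init__(self, records: Iterable[PedigreeRecord],
                 on_missing_parent: Literal["error", "create"] = "error"):
        records = list(records)
        ids = [r.id for r in records]
        seen = set()
        for i in ids:
            if i in seen:
                raise PedigreeError(f"duplicate animal id {i!r}")
            seen.add(i)

        # resolve named-but-absent parents
        known = set(ids)
        extra: list[PedigreeRecord] = []
        for r in records:
            for pid, psex in ((r.sire_id, "M"), (r.dam_id, "F")):
                if pid is not None and pid not in known:
                    if on_missing_parent == "create":
                        extra.append(PedigreeRecord(id=pid, sex=psex))
                        known.add(pid)
                    else:
                        raise PedigreeError(
                            f"parent {pid!r} of animal {r.id!r} has no record")
        records = extra + records

        self.records: list[PedigreeRecord] = records
        self._index = {r.id: i for i, r in enumerate(records)}
        n = len(records)
        self.sire = np.full(n, -1, dtype=np.int64)
        self.dam = np.full(n, -1, dtype=np.int64)
        for i, r in enumerate(records):
            if r.sire_id is not None:
                self.sire[i] = self._index[r.sire_id]
            if r.dam_id is not None:
                self.dam[i] = self._index[r.dam_id]

        self._validate_links()
        self.topo = self._topological_order()

    # -- construction helpers ------------------------------------------------

    @classmethod
    def from_frame(cls, df: pd.DataFrame,
                   on_missing_parent: Literal["error", "create"] = "error") -> "Pedigree":
        cols = {c.lower(): c for c in df.columns}
        for required in ("id", "sire", "dam"):
            if required not in cols:
                raise PedigreeError(f"pedigree table lacks column {required!r}")
        recs = []
        for _, row in df.iterrows():
            year = row[cols["birth_year"]] if "birth_year" in cols else None
            if year is not None and (pd.isna(year) or str(year).strip() == ""):
                year = None
            recs.append(PedigreeRecord(
                id=str(row[cols["id"]]).strip(),
                sire_id=_norm_parent(row[cols["sire"]]),
                dam_id=_norm_parent(row[cols["dam"]]),
                sex=_norm_sex(row[cols["sex"]]) if "sex" in cols else "U",
                birth_year=None if year is None else int(float(year)),
                status=str(row[cols["status"]]).strip() if "status" in cols else "unknown",
            ))
        return cls(recs, on_missing_parent=on_missing_parent)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "id": [r.id for r in self.records],
            "sire": [r.sire_id if r.sire_id is not None else UNKNOWN for r in self.records],
            "dam": [r.dam_id if r.dam_id is not None else UNKNOWN for r in self.records],
            "sex": [r.sex for r in self.records],
            "birth_year": [r.birth_year for r in self.records],
            "status": [r.status for r in self.records],
        })

    # -- basic accessors -----------------------------------------------------

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, animal_id: str) -> bool:
        return animal_id in self._index

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def index_of(self, animal_id: str) -> int:
        try:
            return self._index[animal_id]
        except KeyError:
            raise PedigreeError(f"unknown animal id {animal_id!r}") from None

    def record(self, animal_id: str) -> PedigreeRecord:
        return self.records[self.index_of(animal_id)]

    # -- validation ----------------------------------------------------------

    def _validate_links(self) -> None:
        for i, r in enumerate(self.records):
            for pidx, role, want in ((self.sire[i], "sire", "M"), (self.dam[i], "dam", "F")):
                if pidx < 0:
                    continue
                p = self.records[pidx]
                if p.sex not in ("U", want):
                    raise PedigreeError(
                        f"{role} {p.id!r} of {r.id!r} has sex {p.sex}, expected {want}")
                if (p.birth_year is not None and r.birth_year is not None
                        and p.birth_year >= r.birth_year):
                    raise PedigreeError(
                        f"{role} {p.id!r} (born {p.birth_year}) not older than "
                        f"offspring {r.id!r} (born {r.birth_year})")

    def _topological_order(self) -> np.ndarray:
        g = nx.DiGraph()
        g.add_nodes_from(range(len(self.records)))
        for i in range(len(self.records)):
            if self.sire[i] >= 0:
                g.add_edge(self.sire[i], i)
            if self.dam[i] >= 0:
                g.add_edge(self.dam[i], i)
        if not nx.is_directed_acyclic_graph(g):
            cyc = nx.find_cycle(g)
            member = self.records[cyc[0][0]].id
            raise PedigreeError(f"pedigree contains a cycle through animal {member!r}")
        return np.fromiter(nx.topological_sort(g), dtype=np.int64)


# ---------------------------------------------------------------------------
# I/O

def read_pedigree(path, on_missing_parent: Literal["error", "create"] = "error") -> Pedigree:
    """Read a pedigree CSV (``id,sire,dam[,sex,birth_year,status]``).

    Unknown-parent tokens ``""``, ``"NN"``, ``"0"`` and ``"UNKNOWN"`` are
    normalised; the file is validated and topologically ordered on load.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return Pedigree.from_frame(df, on_missing_parent=on_missing_parent)


def write_pedigree(ped: Pedigree, path) -> None:
    """Write the canonical pedigree CSV with ``NN`` for unknown parents."""
    df = ped.to_frame()
    df["birth_year"] = df["birth_year"].map(lambda y: "" if y is None else str(y))
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Founders

@dataclass
class FounderReport:
    """Founder census under both definitions, with breeding-use accounting."""

    definition: str
    founders_any_unknown: set[str]
    founders_both_unknown: set[str]
    progeny_counts: dict[str, int]            # per founder (any-unknown set)
    founder_males: int = 0
    founder_females: int = 0
    progeny_of_founder_males: int = 0
    progeny_of_founder_females: int = 0
    founders_without_progeny: int = 0
    breeding_use_fraction: float = 0.0

    @property
    def founders(self) -> set[str]:
        """Founder set selected by ``definition``."""
        return (self.founders_both_unknown if self.definition == "both_unknown"
                else self.founders_any_unknown)

    @property
    def n_any_unknown(self) -> int:
        return len(self.founders_any_unknown)

    @property
    def n_both_unknown(self) -> int:
        return len(self.founders_both_unknown)


def _progeny_map(ped: Pedigree) -> dict[str, int]:
    counts: dict[str, int] = defaultdict(int)
    for i in range(len(ped)):
        if ped.sire[i] >= 0:
            counts[ped.records[ped.sire[i]].id] += 1
        if ped.dam[i] >= 0:
            counts[ped.records[ped.dam[i]].id] += 1
    return counts


def identify_founders(ped: Pedigree,
                      definition: Literal["any_unknown", "both_unknown"] = "any_unknown",
                      ) -> FounderReport:
    """Identify founders (>=1 unknown parent) and the both-unknown subset."""
    if definition not in ("any_unknown", "both_unknown"):
        raise PedigreeError(f"unknown founder definition {definition!r}")
    any_unknown = {r.id for r in ped.records if r.has_unknown_parent}
    both_unknown = {r.id for r in ped.records if r.both_parents_unknown}
    progeny = _progeny_map(ped)
    fp = {f: progeny.get(f, 0) for f in any_unknown}

    used_males = [f for f in any_unknown if ped.record(f).sex == "M" and fp[f] > 0]
    used_females = [f for f in any_unknown if ped.record(f).sex == "F" and fp[f] > 0]
    without = sum(1 for f in any_unknown if fp[f] == 0)
    return FounderReport(
        definition=definition,
        founders_any_unknown=any_unknown,
        founders_both_unknown=both_unknown,
        progeny_counts=fp,
        founder_males=len(used_males),
        founder_females=len(used_females),
        progeny_of_founder_males=sum(fp[f] for f in used_males),
        progeny_of_founder_females=sum(fp[f] for f in used_females),
        founders_without_progeny=without,
        breeding_use_fraction=(len(any_unknown) - without) / len(any_unknown)
        if any_unknown else 0.0,
    )


# ---------------------------------------------------------------------------
# Pedigree completeness

@dataclass
class CompletenessReport:
    """Per-animal pedigree depth metrics and their population means.

    ``max_generations`` is the longest known ancestor path;
    ``complete_generations`` the deepest fully known ancestor generation;
    ``t`` the equivalent complete generations, sum of (1/2)^g over all known
    ancestor positions.
    """

    ids: list[str]
    max_generations: np.ndarray
    complete_generations: np.ndarray
    equivalent_complete_generations: np.ndarray

    @property
    def mean_max_generations(self) -> float:
        return float(self.max_generations.mean())

    @property
    def mean_complete_generations(self) -> float:
        return float(self.complete_generations.mean())

    @property
    def mean_equivalent_complete_generations(self) -> float:
        return float(self.equivalent_complete_generations.mean())

    def t_of(self, animal_id: str, ids_index: dict | None = None) -> float:
        return float(self.equivalent_complete_generations[self.ids.index(animal_id)])


def completeness(ped: Pedigree) -> CompletenessReport:
    n = len(ped)
    maxg = np.zeros(n, dtype=np.int64)
    compg = np.zeros(n, dtype=np.int64)
    t = np.zeros(n, dtype=np.float64)
    for i in ped.topo:
        s, d = ped.sire[i], ped.dam[i]
        parents = [p for p in (s, d) if p >= 0]
        if parents:
            maxg[i] = 1 + max(maxg[p] for p in parents)
            t[i] = sum(0.5 * (1.0 + t[p]) for p in parents)
        if s >= 0 and d >= 0:
            compg[i] = 1 + min(compg[s], compg[d])
    return CompletenessReport(ped.ids, maxg, compg, t)


# ---------------------------------------------------------------------------
# Generation interval

def generation_interval(ped: Pedigree) -> dict:
    """Mean parent age (years) at offspring birth, with its standard error.

    Averages over all (parent, offspring) pairs with both birth years known;
    pairs with a missing year are skipped and counted.
    """
    ages = []
    skipped = 0
    for i, r in enumerate(ped.records):
        for pidx in (ped.sire[i], ped.dam[i]):
            if pidx < 0:
                continue
            p = ped.records[pidx]
            if r.birth_year is None or p.birth_year is None:
                skipped += 1
                continue
            ages.append(r.birth_year - p.birth_year)
    if not ages:
        raise PedigreeError("no dated parent-offspring pairs")
    arr = np.asarray(ages, dtype=float)
    se = float(arr.std(ddof=1) / np.sqrt(len(arr))) if len(arr) > 1 else 0.0
    return {"mean": float(arr.mean()), "se": se, "n_pairs": len(arr),
            "n_skipped": skipped, "degenerate": len(arr) == 1}


# ---------------------------------------------------------------------------
# Close-mating classification

@dataclass
class MatingReport:
    """Counts of close matings, as distinct parent pairs and as offspring.

    The percentage for each category is 100 * (distinct parent pairs) /
    (total records), the convention under which 2 full-sib matings in a
    912-animal studbook read 0.22%.
    """

    n_records: int
    pairs: dict[str, set[tuple[str, str]]] = field(default_factory=dict)
    offspring: dict[str, int] = field(default_factory=dict)

    def count(self, category: str) -> int:
        return len(self.pairs.get(category, ()))

    def percentage(self, category: str) -> float:
        return 100.0 * self.count(category) / self.n_records if self.n_records else 0.0

    def as_dict(self) -> dict:
        return {cat: {"matings": self.count(cat),
                      "offspring": self.offspring.get(cat, 0),
                      "percentage": self.percentage(cat)}
                for cat in ("parent_offspring", "full_sib", "half_sib")}


def _relation(ped: Pedigree, a: int, b: int) -> str | None:
    """Relation between two animals: parent_offspring > full_sib > half_sib."""
    if ped.sire[b] == a or ped.dam[b] == a or ped.sire[a] == b or ped.dam[a] == b:
        return "parent_offspring"
    shared = 0
    if ped.sire[a] >= 0 and ped.sire[a] == ped.sire[b]:
        shared += 1
    if ped.dam[a] >= 0 and ped.dam[a] == ped.dam[b]:
        shared += 1
    if shared == 2:
        return "full_sib"
    if shared == 1:
        return "half_sib"
    return None


def classify_matings(ped: Pedigree) -> MatingReport:
    report = MatingReport(n_records=len(ped),
                          pairs={c: set() for c in ("parent_offspring", "full_sib", "half_sib")},
                          offspring={c: 0 for c in ("parent_offspring", "full_sib", "half_sib")})
    for i in range(len(ped)):
        s, d = ped.sire[i], ped.dam[i]
        if s < 0 or d < 0:
            continue
        rel = _relation(ped, s, d)
        if rel is not None:
            report.pairs[rel].add((ped.records[s].id, ped.records[d].id))
            report.offspring[rel] += 1
    return report


# ---------------------------------------------------------------------------
# Litters and full-sib groups

@dataclass
class LitterReport:
    """Full-sib group (same sire+dam) and litter (same sire+dam+year) sizes.

    Statistics are over groups of size >= 2; singletons are counted apart.
    """

    full_sib_group_sizes: list[int]     # size >= 2 groups
    litter_sizes: list[int]             # size >= 2 litters
    n_singleton_groups: int
    n_singleton_litters: int

    @property
    def n_full_sib_groups(self) -> int:
        return len(self.full_sib_group_sizes)

    @property
    def n_individuals_in_full_sib_groups(self) -> int:
        return sum(self.full_sib_group_sizes)

    def _stats(self, sizes: Sequence[int]) -> dict:
        if not sizes:
            return {"min": None, "max": None, "mean": None, "n": 0}
        return {"min": int(min(sizes)), "max": int(max(sizes)),
                "mean": float(np.mean(sizes)), "n": len(sizes)}

    @property
    def litter_stats(self) -> dict:
        return self._stats(self.litter_sizes)

    @property
    def full_sib_group_stats(self) -> dict:
        return self._stats(self.full_sib_group_sizes)


def litter_statistics(ped: Pedigree) -> LitterReport:
    groups: dict[tuple, int] = defaultdict(int)
    litters: dict[tuple, int] = defaultdict(int)
    for i, r in enumerate(ped.records):
        s, d = ped.sire[i], ped.dam[i]
        if s < 0 or d < 0:
            continue
        groups[(s, d)] += 1
        if r.birth_year is not None:
            litters[(s, d, r.birth_year)] += 1
    gsizes = sorted(v for v in groups.values() if v >= 2)
    lsizes = sorted(v for v in litters.values() if v >= 2)
    return LitterReport(
        full_sib_group_sizes=gsizes,
        litter_sizes=lsizes,
        n_singleton_groups=sum(1 for v in groups.values() if v == 1),
        n_singleton_litters=sum(1 for v in litters.values() if v == 1),
    )


# ---------------------------------------------------------------------------
# Breeding-use statistics

@dataclass
class ProgenyReport:
    """Breeders and non-breeders by sex, split by founder status."""

    table: pd.DataFrame      # rows: founder/non_founder/all x male/female
    n_breeders: int
    n_breeder_males: int
    n_breeder_females: int
    n_zero_progeny: int
    progeny_of_males: int
    progeny_of_females: int

    @property
    def breeder_fraction(self) -> float:
        total = int(self.table.loc[("all", "all"), "n_animals"])
        return self.n_breeders / total if total else 0.0


def progeny_statistics(ped: Pedigree, founder_report: FounderReport | None = None) -> ProgenyReport:
    if founder_report is None:
        founder_report = identify_founders(ped)
    progeny = _progeny_map(ped)
    rows = []
    founders = founder_report.founders_any_unknown
    for r in ped.records:
        rows.append({
            "founder": "founder" if r.id in founders else "non_founder",
            "sex": {"M": "male", "F": "female"}.get(r.sex, "unknown"),
            "progeny": progeny.get(r.id, 0),
        })
    df = pd.DataFrame(rows)
    out = []
    for fclass in ("founder", "non_founder", "all"):
        sub_f = df if fclass == "all" else df[df["founder"] == fclass]
        for sex in ("male", "female", "all"):
            sub = sub_f if sex == "all" else sub_f[sub_f["sex"] == sex]
            out.append({
                "founder": fclass, "sex": sex,
                "n_animals": len(sub),
                "n_with_progeny": int((sub["progeny"] > 0).sum()),
                "n_zero_progeny": int((sub["progeny"] == 0).sum()),
                "total_progeny": int(sub["progeny"].sum()),
            })
    table = pd.DataFrame(out).set_index(["founder", "sex"])
    males = df[df["sex"] == "male"]
    females = df[df["sex"] == "female"]
    return ProgenyReport(
        table=table,
        n_breeders=int((df["progeny"] > 0).sum()),
        n_breeder_males=int((males["progeny"] > 0).sum()),
        n_breeder_females=int((females["progeny"] > 0).sum()),
        n_zero_progeny=int((df["progeny"] == 0).sum()),
        progeny_of_males=int(males["progeny"].sum()),
        progeny_of_females=int(females["progeny"].sum()),
    )
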