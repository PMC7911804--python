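"""Diploid STR genotype table with GenePop and long-CSV input/output.

Alleles are integer fragment lengths (bp); a genotype is an unordered pair,
stored sorted; 0 encodes a missing call.  GenePop files use the 3-digit
allele coding with ``000000`` for missing.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["GenotypeTable", "GenotypeError", "read_genotypes", "write_genepop", "write_long_csv"]

MISSING = 0


class GenotypeError(ValueError):
    """Raised on malformed genotype input."""


@dataclass
class GenotypeTable:
    """Individuals x loci diploid calls; shape (n, L, 2), 0 = missing."""

    ids: list[str]
    loci: list[str]
    calls: np.ndarray

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int32)
        if self.calls.shape != (len(self.ids), len(self.loci), 2):
            raise GenotypeError("calls array shape does not match ids x loci")
        if (self.calls < 0).any():
            raise GenotypeError("allele labels must be non-negative integers")
        # canonical order within the pair, missing never alone
        self.calls = np.sort(self.calls, axis=2)
        half = (self.calls == MISSING).sum(axis=2) == 1
        if half.any():
            raise GenotypeError("half-missing genotype call")

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    def locus_index(self, locus: str) -> int:
        try:
            return self.loci.index(locus)
        except ValueError:
            raise GenotypeError(f"unknown locus {locus!r}") from None

    def typed_mask(self, locus: str) -> np.ndarray:
        return self.calls[:, self.locus_index(locus), 0] != MISSING

    def locus_calls(self, locus: str) -> np.ndarray:
        """Typed genotype pairs (m, 2) at one locus."""
        j = self.locus_index(locus)
        mask = self.calls[:, j, 0] != MISSING
        return self.calls[mask, j, :]

    def __eq__(self, other) -> bool:
        return (isinstance(other, GenotypeTable) and self.ids == other.ids
                and self.loci == other.loci and np.array_equal(self.calls, other.calls))

    # -- long-format frame ---------------------------------------------------

    @classmethod
    def from_long_frame(cls, df: pd.DataFrame) -> "GenotypeTable":
        cols = {c.lower(): c for c in df.columns}
        for c in ("id", "locus", "allele1", "allele2"):
            if c not in cols:
                raise GenotypeError(f"long genotype table lacks column {c!r}")
        ids = list(dict.fromkeys(df[cols["id"]].astype(str)))
        loci = list(dict.fromkeys(df[cols["locus"]].astype(str)))
        idx = {a: i for i, a in enumerate(ids)}
        ldx = {l: j for j, l in enumerate(loci)}
        calls = np.zeros((len(ids), len(loci), 2), dtype=np.int32)
        for _, row in df.iterrows():
            def norm(v):
                s = str(v).strip()
                return 0 if s in ("", "0", "nan", "NA") else int(float(s))
            a1, a2 = norm(row[cols["allele1"]]), norm(row[cols["allele2"]])
            if (a1 == 0) != (a2 == 0):
                raise GenotypeError(f"half-missing genotype for {row[cols['id']]!r}")
            calls[idx[str(row[cols["id"]])], ldx[str(row[cols["locus"]])]] = (a1, a2)
        return cls(ids, loci, calls)

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for i, ind in enumerate(self.ids):
            for j, locus in enumerate(self.loci):
                a1, a2 = self.calls[i, j]
                rows.append({"id": ind, "locus": locus, "allele1": int(a1), "allele2": int(a2)})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Readers / writers

def _read_genepop(path) -> GenotypeTable:
    lines = Path(path).read_text().splitlines()
    if len(lines) < 3:
        raise GenotypeError("truncated GenePop file")
    body = lines[1:]
    loci: list[str] = []
    i = 0
    while i < len(body) and body[i].strip().lower() != "pop":
        # locus names: one per line, or comma-separated on one line
        loci.extend(x.strip() for x in body[i].split(",") if x.strip())
        i += 1
    if i == len(body):
        raise GenotypeError("GenePop file has no 'Pop' line")
    ids, rows = [], []
    for lineno, line in enumerate(body[i + 1:], start=i + 3):
        if not line.strip():
            continue
        if line.strip().lower() == "pop":
            continue    # further populations read into the same table
        if "," not in line:
            raise GenotypeError(f"line {lineno}: missing ',' after individual id")
        ind, geno = line.split(",", 1)
        tokens = geno.split()
        if len(tokens) != len(loci):
            raise GenotypeError(
                f"line {lineno}: {len(tokens)} genotypes for {len(loci)} loci")
        pairs = []
        for tok in tokens:
            if len(tok) not in (4, 6) or not tok.isdigit():
                raise GenotypeError(f"line {lineno}: malformed genotype {tok!r}")
            w = len(tok) // 2
            pairs.append((int(tok[:w]), int(tok[w:])))
        ids.append(ind.strip())
        rows.append(pairs)
    calls = np.asarray(rows, dtype=np.int32).reshape(len(ids), len(loci), 2)
    # GenePop codes missing as 00/000 on either side; normalise to fully missing
    half = (calls == 0).any(axis=2)
    calls[half] = 0
    return GenotypeTable(ids, loci, calls)


def read_genotypes(path, format: str = "long_csv") -> GenotypeTable:
    """Read genotypes from ``genepop`` or ``long_csv`` (id,locus,allele1,allele2)."""
    if format == "genepop":
        return _read_genepop(path)
    if format == "long_csv":
        return GenotypeTable.from_long_frame(pd.read_csv(path, dtype=str, keep_default_na=False))
    raise GenotypeError(f"unknown genotype format {format!r}")


def write_genepop(table: GenotypeTable, path, title: str = "pedvar export") -> None:
    out = [title]
    out.extend(table.loci)
    out.append("Pop")
    for i, ind in enumerate(table.ids):
        toks = [f"{a1:03d}{a2:03d}" for a1, a2 in table.calls[i]]
        out.append(f"{ind} , " + " ".join(toks))
    Path(path).write_text("\n".join(out) + "\n")


def write_long_csv(table: GenotypeTable, path) -> None:
    table.to_long_frame().to_csv(path, index=False)
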