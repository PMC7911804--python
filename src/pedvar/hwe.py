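"""Exact test of Hardy-Weinberg proportions conditional on allele counts.

Under HWE, conditional on the allele counts m_1..m_k of a sample of n
diploids, the probability of a genotype array {n_ab} is

    P({n_ab} | m) = n! 2^h prod_a m_a! / ( (2n)! prod_{a<=b} n_ab! )

with h the number of heterozygous individuals.  The exact p-value is the
total probability of arrays no more probable than the observed one (ties
included in the tail, the standard convention).

Two engines are provided: exhaustive enumeration of the fiber (the oracle,
feasible for small k and n) and a Metropolis chain over arrays using the
two-genotype switch proposal, with dememorization (burn-in) and batching for
a Monte-Carlo standard error.  The chain inner loop is numba-compiled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .genotypes import GenotypeTable, GenotypeError

__all__ = ["GenotypeCounts", "HweResult", "conditional_log_probability",
           "hwe_exhaustive", "hwe_mcmc"]

_LN2 = math.log(2.0)
_TIE_TOL = 1e-9


@dataclass
class GenotypeCounts:
    """Genotype count matrix of one locus: the test's sufficient statistics.

    ``counts[a, b]`` (a <= b) holds the count of genotype (a, b) over the
    allele index 0..k-1; the lower triangle is zero.
    """

    locus: str
    alleles: list[int]
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.alleles)
        if self.counts.shape != (k, k):
            raise GenotypeError("genotype count matrix shape mismatch")
        if (self.counts < 0).any() or np.tril(self.counts, -1).any():
            raise GenotypeError("genotype counts must be a non-negative upper triangle")

    @property
    def k(self) -> int:
        return len(self.alleles)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def allele_counts(self) -> np.ndarray:
        """m_a = 2 n_aa + sum_{b != a} n_ab."""
        sym = self.counts + self.counts.T      # diagonal doubles to 2 n_aa
        return sym.sum(axis=1)

    @classmethod
    def from_table(cls, table: GenotypeTable, locus: str) -> "GenotypeCounts":
        calls = table.locus_calls(locus)
        if len(calls) == 0:
            raise GenotypeError(f"no typed genotypes at locus {locus!r}")
        alleles = sorted(set(calls.ravel().tolist()))
        idx = {a: i for i, a in enumerate(alleles)}
        k = len(alleles)
        counts = np.zeros((k, k), dtype=np.int64)
        for a1, a2 in calls:
            i, j = sorted((idx[int(a1)], idx[int(a2)]))
            counts[i, j] += 1
        return cls(locus, alleles, counts)


@dataclass
class HweResult:
    """Exact-test p-value with its Monte-Carlo standard error (0 if exhaustive)."""

    p: float
    se: float
    method: str                 # "exhaustive" or "mcmc"
    settings: dict

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p < alpha


def _log_factorials(limit: int) -> np.ndarray:
    return np.concatenate(([0.0], np.cumsum(np.log(np.arange(1, limit + 1)))))


def conditional_log_probability(counts: GenotypeCounts) -> float:
    """Log of P({n_ab} | allele counts) under HWE."""
    n = counts.n
    m = counts.allele_counts
    lf = _log_factorials(2 * n)
    h = int(counts.counts.sum() - np.trace(counts.counts))
    return (lf[n] + h * _LN2 + lf[m].sum() - lf[2 * n]
            - lf[counts.counts[np.triu_indices(counts.k)]].sum())


def conditional_probability(counts: GenotypeCounts) -> float:
    return math.exp(conditional_log_probability(counts))


# ---------------------------------------------------------------------------
# Exhaustive enumeration

def _enumerate_fiber(m: np.ndarray, max_states: int):
    """Yield every genotype count matrix with allele counts ``m``."""
    k = len(m)
    cells = [(a, b) for a in range(k) for b in range(a, k)]
    mat = np.zeros((k, k), dtype=np.int64)
    rem = m.astype(np.int64).copy()
    states = 0

    def rec(ci: int):
        nonlocal states
        if ci == len(cells):
            if rem.sum() == 0:
                states += 1
                if states > max_states:
                    raise GenotypeError(
                        f"fiber exceeds {max_states} arrays; use the MCMC test")
                yield mat.copy()
            return
        a, b = cells[ci]
        if a == b:
            top = rem[a] // 2
        else:
            top = min(rem[a], rem[b])
        for c in range(top + 1):
            use = 2 * c if a == b else c
            mat[a, b] = c
            rem[a] -= 2 * c if a == b else c
            if a != b:
                rem[b] -= c
            # once all cells containing allele a are placed, m_a must be spent
            ok = True
            if b == k - 1 and rem[a] != 0:
                ok = False
            if ok:
                yield from rec(ci + 1)
            rem[a] += 2 * c if a == b else c
            if a != b:
                rem[b] += c
            mat[a, b] = 0

    yield from rec(0)


def hwe_exhaustive(counts: GenotypeCounts, max_states: int = 5_000_000) -> HweResult:
    """Exact p-value by full enumeration of the conditional distribution."""
    m = counts.allele_counts
    if counts.k == 1:
        return HweResult(1.0, 0.0, "exhaustive", {"states": 1})
    obs_lp = conditional_log_probability(counts)
    n = counts.n
    lf = _log_factorials(2 * n)
    const = lf[n] + lf[m].sum() - lf[2 * n]
    iu = np.triu_indices(counts.k)
    total = 0.0
    tail = 0.0
    states = 0
    for mat in _enumerate_fiber(m, max_states):
        h = int(mat.sum() - np.trace(mat))
        lp = const + h * _LN2 - lf[mat[iu]].sum()
        pr = math.exp(lp)
        total += pr
        if lp <= obs_lp + _TIE_TOL:
            tail += pr
        states += 1
    # enumeration identity: probabilities over the fiber sum to 1
    if abs(total - 1.0) > 1e-8:
        raise GenotypeError(f"fiber probabilities sum to {total!r}, not 1")
    return HweResult(min(tail, 1.0), 0.0, "exhaustive", {"states": states})


# ---------------------------------------------------------------------------
# Markov-chain Monte-Carlo exact test

@njit(cache=True, inline="always")
def _channel(p1a, p1b, p2a, p2b, ch):  # pragma: no cover
    """Result (pair_i, pair_j), sorted within pair, of proposal channel ch.

    Channels: (order ij / ji) x (pairing option 0 / 1) applied to the pairs
    currently at i (p1) and j (p2).
    """
    if ch == 0:
        i1, i2, j1, j2 = p1a, p2a, p1b, p2b
    elif ch == 1:
        i1, i2, j1, j2 = p1a, p2b, p1b, p2a
    elif ch == 2:
        j1, j2, i1, i2 = p2a, p1a, p2b, p1b
    else:
        j1, j2, i1, i2 = p2a, p1b, p2b, p1a
    if i1 > i2:
        i1, i2 = i2, i1
    if j1 > j2:
        j1, j2 = j2, j1
    return i1, i2, j1, j2


@njit(cache=True)
def _gt_chain(ga, gb, cnt, het, s_obs,
              dememorization, batches, iters_per_batch, seed):  # pragma: no cover
    # Metropolis-Hastings on individual genotype assignments with stationary
    # weight 2^h; the induced marginal over count arrays is the conditional
    # HWE distribution.  The Hastings factor is the ratio of the number of
    # proposal channels producing the reverse and forward moves.
    np.random.seed(seed)
    n = ga.shape[0]
    hits = np.zeros(batches, dtype=np.float64)
    total_steps = dememorization + batches * iters_per_batch
    h = het
    s = 0.0
    # array score s = h ln2 - sum log n_ab!, tracked incrementally for the
    # tail comparison against the observed array's score
    k = cnt.shape[0]
    for a in range(k):
        for b in range(a, k):
            c = cnt[a, b]
            acc = 0.0
            for t in range(2, int(c) + 1):
                acc += np.log(t)
            s -= acc
    s += h * 0.6931471805599453
    ln2 = 0.6931471805599453

    for step in range(total_steps):
        i = np.random.randint(n)
        j = np.random.randint(n - 1)
        if j >= i:
            j += 1
        p1a, p1b = ga[i], gb[i]
        p2a, p2b = ga[j], gb[j]
        ch = np.random.randint(4)
        n1a, n1b, n2a, n2b = _channel(p1a, p1b, p2a, p2b, ch)

        if not (n1a == p1a and n1b == p1b and n2a == p2a and n2b == p2b):
            # forward channels producing (n1, n2); reverse producing (p1, p2)
            n_fwd = 0
            n_rev = 0
            for c4 in range(4):
                f1, f2, f3, f4 = _channel(p1a, p1b, p2a, p2b, c4)
                if f1 == n1a and f2 == n1b and f3 == n2a and f4 == n2b:
                    n_fwd += 1
                r1, r2, r3, r4 = _channel(n1a, n1b, n2a, n2b, c4)
                if r1 == p1a and r2 == p1b and r3 == p2a and r4 == p2b:
                    n_rev += 1
            h_new = h
            if p1a != p1b:
                h_new -= 1
            if p2a != p2b:
                h_new -= 1
            if n1a != n1b:
                h_new += 1
            if n2a != n2b:
                h_new += 1
            log_ratio = (h_new - h) * ln2 + np.log(n_rev / n_fwd)
            if np.log(np.random.random()) < log_ratio:
                # accept: update assignment, counts and array score
                s_new = s + (h_new - h) * ln2
                c = cnt[p1a, p1b]; s_new += np.log(c); cnt[p1a, p1b] = c - 1
                c = cnt[p2a, p2b]; s_new += np.log(c); cnt[p2a, p2b] = c - 1
                c = cnt[n1a, n1b]; s_new -= np.log(c + 1.0); cnt[n1a, n1b] = c + 1
                c = cnt[n2a, n2b]; s_new -= np.log(c + 1.0); cnt[n2a, n2b] = c + 1
                ga[i] = n1a; gb[i] = n1b
                ga[j] = n2a; gb[j] = n2b
                s = s_new
                h = h_new
        if step >= dememorization:
            if s <= s_obs + 1e-9:
                b = (step - dememorization) // iters_per_batch
                hits[b] += 1.0
    return hits


def _expand_individuals(counts: GenotypeCounts) -> tuple[np.ndarray, np.ndarray]:
    ga, gb = [], []
    k = counts.k
    for a in range(k):
        for b in range(a, k):
            for _ in range(int(counts.counts[a, b])):
                ga.append(a)
                gb.append(b)
    return np.asarray(ga, dtype=np.int64), np.asarray(gb, dtype=np.int64)


def _array_score(counts: GenotypeCounts) -> float:
    """Fiber-relative log score: h ln2 - sum log n_ab!  (constants dropped)."""
    lf = _log_factorials(counts.n)
    h = int(counts.counts.sum() - np.trace(counts.counts))
    iu = np.triu_indices(counts.k)
    return h * _LN2 - float(lf[counts.counts[iu]].sum())


def hwe_mcmc(counts: GenotypeCounts, batches: int = 100,
             dememorization: int = 10_000, iters_per_batch: int = 5_000,
             seed: int = 0) -> HweResult:
    """MCMC exact test: p = fraction of sampled arrays no more probable than
    the observed one; standard error from the between-batch variance."""
    if batches < 2:
        raise GenotypeError("need at least 2 batches for a standard error")
    if dememorization < 0 or iters_per_batch < 1:
        raise GenotypeError("invalid chain settings")
    settings = {"batches": batches, "dememorization": dememorization,
                "iters_per_batch": iters_per_batch, "seed": seed}
    if counts.k == 1 or counts.n == 0:
        return HweResult(1.0, 0.0, "mcmc", settings)
    ga, gb = _expand_individuals(counts)
    if len(ga) < 2:
        return HweResult(1.0, 0.0, "mcmc", settings)
    s_obs = _array_score(counts)
    cnt = counts.counts.astype(np.float64).copy()
    hits = _gt_chain(ga.copy(), gb.copy(), cnt,
                     int(counts.counts.sum() - np.trace(counts.counts)),
                     s_obs, dememorization, batches, iters_per_batch,
                     seed & 0x7FFFFFFF)
    batch_p = hits / iters_per_batch
    p = float(batch_p.mean())
    se = float(batch_p.std(ddof=1) / math.sqrt(batches))
    return HweResult(p, se, "mcmc", settings)
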