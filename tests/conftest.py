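import numpy as np
import pytest

from pedvar.pedigree import Pedigree, PedigreeRecord


@pytest.fixture
def trio() -> Pedigree:
    """Smallest valid family: two founders and one offspring."""
    return Pedigree([
        PedigreeRecord("A", sex="M", birth_year=2000),
        PedigreeRecord("B", sex="F", birth_year=2002),
        PedigreeRecord("C", "A", "B", sex="F", birth_year=2006),
    ])


@pytest.fixture
def full_sib_family() -> Pedigree:
    """Two founders, four full sibs, and an inbred full-sib-mating pup."""
    return Pedigree([
        PedigreeRecord("S", sex="M"), PedigreeRecord("D", sex="F"),
        PedigreeRecord("K1", "S", "D", sex="M"),
        PedigreeRecord("K2", "S", "D", sex="F"),
        PedigreeRecord("K3", "S", "D", sex="M"),
        PedigreeRecord("K4", "S", "D", sex="F"),
        PedigreeRecord("P", "K1", "K2", sex="U"),
    ])


def full_sib_line(n_matings: int) -> Pedigree:
    """Repeated brother-sister matings from unrelated founders."""
    recs = [PedigreeRecord("M0", sex="M"), PedigreeRecord("F0", sex="F")]
    prev = ("M0", "F0")
    for g in range(1, n_matings + 1):
        recs.append(PedigreeRecord(f"M{g}", prev[0], prev[1], sex="M"))
        recs.append(PedigreeRecord(f"F{g}", prev[0], prev[1], sex="F"))
        prev = (f"M{g}", f"F{g}")
    return Pedigree(recs)


def random_small_pedigree(seed: int, n_max: int = 50) -> Pedigree:
    """Random overlapping-generation pedigree of at most ``n_max`` animals,
    random mating (close matings allowed), for oracle cross-checks."""
    import pedvar as pv

    rng = np.random.default_rng(seed)
    n_total = int(rng.integers(12, n_max + 1))
    n_both = int(rng.integers(4, 9))
    n_one = int(rng.integers(0, 4))
    cfg = pv.PedigreeSimConfig(
        n_total=n_total, n_founders_both_unknown=n_both,
        n_founders_one_unknown=n_one, years=16, founder_year_span=4,
        first_litter_year=5, litter_min=1, litter_max=6,
        litter_mean=float(rng.uniform(2.5, 4.0)), mating_policy="random",
        seed=seed)
    return pv.simulate_pedigree(cfg)
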