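import numpy as np
import pytest

from natfert.haplotypes import Haplotype
from natfert.pedigree import kinship_matrix, validate_pedigree
from natfert.simulate import PedigreeSimConfig, simulate_pedigree

# The seven CFTR (TG)m-polyT-Met470Val haplotype classes observed in the
# study population, at their reported frequencies.
CFTR_HAPLOTYPE_FREQS = {
    Haplotype(10, 7, "Met"): 0.45,
    Haplotype(11, 7, "Met"): 0.15,
    Haplotype(12, 7, "Met"): 0.03,
    Haplotype(10, 9, "Met"): 0.08,
    Haplotype(11, 9, "Met"): 0.01,
    Haplotype(11, 7, "Val"): 0.26,
    Haplotype(12, 7, "Val"): 0.02,
}


@pytest.fixture(scope="session")
def isolate():
    """A 13-generation, 62-founder simulated isolate with its kinship matrix.

    Session-scoped: the pedigree is the shared substrate for the
    association, variance-component and calibration suites.
    """
    simped = simulate_pedigree(PedigreeSimConfig(seed=11))
    kin = kinship_matrix(simped.pedigree)
    return simped, kin


@pytest.fixture
def trio():
    return validate_pedigree(
        [("F", 0, 0, "M"), ("M", 0, 0, "F"), ("C", "F", "M", "M")]
    )


@pytest.fixture
def fullsib_ped():
    """Two founders, two full sibs, and a full-sib-mating child (f = 1/4)."""
    return validate_pedigree(
        [
            ("A", 0, 0, "M"),
            ("B", 0, 0, "F"),
            ("S1", "A", "B", "M"),
            ("S2", "A", "B", "F"),
            ("K", "S1", "S2", "M"),
        ]
    )


@pytest.fixture
def cousin_ped():
    """First-cousin mating; the child has f = 1/16."""
    recs = [
        ("GF", 0, 0, "M"),
        ("GM", 0, 0, "F"),
        ("P1", "GF", "GM", "M"),
        ("P2", "GF", "GM", "F"),
        ("S1", 0, 0, "F"),
        ("S2", 0, 0, "M"),
        ("C1", "P1", "S1", "M"),
        ("C2", "S2", "P2", "F"),
        ("K", "C1", "C2", "M"),
    ]
    return validate_pedigree(recs)


def ibd_gene_drop(ped, n_rep, seed):
    """Test-side IBD oracle: drop *unique* founder allele labels, then
    estimate phi(i,j) as the probability that one allele sampled from i
    and one from j carry the same label (with replacement on the diagonal).
    Independent of the package's kinship recursion."""
    rng = np.random.default_rng(seed)
    n = len(ped)
    lab = np.empty((n_rep, n, 2), dtype=np.int32)
    next_label = 0
    for k, iid in enumerate(ped.order):
        ind = ped[iid]
        if ind.is_founder:
            lab[:, k, 0] = next_label
            lab[:, k, 1] = next_label + 1
            next_label += 2
        else:
            fi, mi = ped.index[ind.father], ped.index[ind.mother]
            pick = rng.integers(0, 2, size=(n_rep, 2))
            rows = np.arange(n_rep)
            lab[:, k, 0] = lab[rows, fi, pick[:, 0]]
            lab[:, k, 1] = lab[rows, mi, pick[:, 1]]
    # sample one allele per individual per replicate, twice independently
    pick1 = rng.integers(0, 2, size=(n_rep, n))
    pick2 = rng.integers(0, 2, size=(n_rep, n))
    rows = np.arange(n_rep)[:, None]
    cols = np.arange(n)[None, :]
    draw1 = lab[rows, cols, pick1]
    draw2 = lab[rows, cols, pick2]
    phi_hat = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            phi_hat[i, j] = (draw1[:, i] == draw2[:, j]).mean()
    return phi_hat
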