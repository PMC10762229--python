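import numpy as np
import pytest
from scipy.sparse import coo_matrix

from microdomain import BinnedGenome, ContactMatrix, balance_ice
from microdomain.benchmarks import (
    boundary_benchmark,
    perturbation_benchmark,
    se_benchmark,
)


def make_matrix(dense: np.ndarray, bin_size: int = 200, chrom: str = "chrT") -> ContactMatrix:
    """Wrap a dense symmetric array as a ContactMatrix (upper triangle)."""
    dense = np.asarray(dense, float)
    n = dense.shape[0]
    genome = BinnedGenome((chrom,), (n * bin_size,), bin_size)
    iu = np.triu_indices(n)
    return ContactMatrix(genome, {chrom: coo_matrix((dense[iu], iu), shape=(n, n))})


def random_dense(n: int, seed: int = 0, base: float = 5.0) -> np.ndarray:
    """Strictly positive random symmetric matrix (every diagonal defined)."""
    rng = np.random.default_rng(seed)
    A = rng.gamma(2.0, 1.0, (n, n)) + base
    return (A + A.T) / 2


@pytest.fixture
def tiny_genome():
    return BinnedGenome(("chrA", "chrB"), (10_000, 6_000), 200)


@pytest.fixture
def uniform_matrix():
    m = make_matrix(np.ones((60, 60)))
    return balance_ice(m, tol=1e-12)


@pytest.fixture(scope="session")
def bench():
    """The default boundary/decay/looping benchmark map (balanced)."""
    return boundary_benchmark(1)


@pytest.fixture(scope="session")
def se_bench():
    return se_benchmark(1)


def _perturb_result(coupling: float) -> dict:
    """Full selection + scoring + regression; keeps only the result tables
    so the four deep maps are not held in memory simultaneously."""
    from microdomain.model import (
        gene_contact_scores,
        perturbation_regression,
        select_perturbed_genes,
    )

    b = perturbation_benchmark(1, coupling=coupling)
    sel = select_perturbed_genes(b["truth"].genes, b["occ_wt"], b["occ_mut"])
    affected = set(b["truth"].genes.df.iloc[b["affected"]]["name"])
    scores = gene_contact_scores(b["wt"], b["mut"], sel, b["occ_wt"], b["occ_mut"])
    reg = perturbation_regression(scores)
    return {
        "regression": reg,
        "scores": scores,
        "n_selected": len(sel),
        "n_affected_recovered": len(affected & set(sel.df["name"])),
        "attenuation": b["truth"].attenuation,
    }


@pytest.fixture(scope="session")
def perturb_result_coupled():
    return _perturb_result(0.5)


@pytest.fixture(scope="session")
def perturb_result_null():
    return _perturb_result(0.0)
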