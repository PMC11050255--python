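import numpy as np
import pytest

from hutchgs import (ModelSpec, build_design, simulate_genotypes,
                     simulate_phenotypes, vanraden_grm)
from hutchgs.presets import bivariate_architecture, tiny_design


@pytest.fixture(scope="session")
def tiny_population():
    """60 half-sib offspring x 500 markers (shared, read-only)."""
    geno, pedigree = simulate_genotypes(tiny_design(seed=42))
    return geno, pedigree


@pytest.fixture(scope="session")
def tiny_bivariate(tiny_population):
    """Bivariate phenotypes + GRM + model data on the tiny population."""
    geno, _ = tiny_population
    arch = bivariate_architecture("W49", "W70", n_qtl=50)
    pheno, truth = simulate_phenotypes(geno, arch, seed=7)
    grm = vanraden_grm(geno)
    spec = ModelSpec(traits=("W49", "W70"), fixed_factors=("sex",))
    data = build_design(pheno, spec, grm)
    return {"geno": geno, "arch": arch, "pheno": pheno, "truth": truth,
            "grm": grm, "spec": spec, "data": data}


def dense_restricted_loglik(M, R, data):
    """Independent dense evaluation of the multivariate restricted
    log-likelihood (direct V construction, no rotation tricks)."""
    import scipy.linalg

    G = data.grm.matrix
    q = G.shape[0]
    y = np.concatenate([td.y for td in data.traits])
    X = scipy.linalg.block_diag(*[td.X for td in data.traits])
    cells = np.concatenate([i * q + td.idx for i, td in enumerate(data.traits)])
    Ktot = np.kron(np.atleast_2d(M), G) + np.kron(np.atleast_2d(R), np.eye(q))
    V = Ktot[np.ix_(cells, cells)]
    N, p = X.shape
    Vinv = np.linalg.inv(V)
    B = X.T @ Vinv @ X
    beta = np.linalg.solve(B, X.T @ Vinv @ y)
    r = y - X @ beta
    return -0.5 * (np.linalg.slogdet(V)[1] + np.linalg.slogdet(B)[1]
                   + r @ Vinv @ r + (N - p) * np.log(2 * np.pi))
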