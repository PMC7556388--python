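import numpy as np
import pytest

from pasl.genesets import MembershipMatrix


def random_membership(rng, p, g, min_size=2, max_size=None):
    """Random binary membership matrix with g genesets over p features."""
    max_size = max_size or max(3, p // 2)
    rows = []
    for _ in range(g):
        s = int(rng.integers(min_size, max_size + 1))
        row = np.zeros(p, dtype=np.int8)
        row[rng.choice(p, size=s, replace=False)] = 1
        rows.append(row)
    return MembershipMatrix(
        np.vstack(rows), [f"G{i}" for i in range(g)], [f"f{j}" for j in range(p)]
    )


def planted_matrix(rng, G, n, n_atoms, noise_sd=0.1, scale=2.0):
    """n×p matrix with n_atoms rank-1 components planted inside genesets."""
    p = G.n_features
    X = rng.standard_normal((n, p)) * noise_sd
    picks = rng.choice(G.n_genesets, size=n_atoms, replace=False)
    atoms = []
    for gi in picks:
        sup = G.support(gi)
        d = rng.standard_normal(sup.size)
        d /= np.linalg.norm(d)
        full = np.zeros(p)
        full[sup] = d
        X += np.outer(rng.standard_normal(n) * scale, full)
        atoms.append((int(gi), full))
    return X, atoms


@pytest.fixture
def rng():
    return np.random.default_rng(20240117)
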