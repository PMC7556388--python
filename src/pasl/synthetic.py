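"""Geneset-structured synthetic expression data with planted dictionaries.

The generator emulates the simulation design used to calibrate the
size normalization: a membership matrix of equally distributed genesets
with sizes {30, 50, 100, 200} over p = 500 features, a planted
dictionary built from randomly selected genesets (equally many per size
class), standard-normal activity scores and isotropic Gaussian noise,
with n = 400 samples by default.  A recovery report scores a fitted
model against the planted truth by absolute cosine matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genesets import GenesetCollection, MembershipMatrix
from .model import PaslModel

__all__ = ["SimTruth", "make_geneset_prior", "simulate", "recovery_report", "to_collection"]

DEFAULT_SIZES = (30, 50, 100, 200)


@dataclass
class SimTruth:
    """Ground truth of one simulation run."""

    G_true: MembershipMatrix
    D_true: np.ndarray  # n_atoms × p, unit-norm rows
    L_true: np.ndarray  # n × n_atoms
    atom_geneset_indices: list[int]
    noise_sd: float
    size_classes: tuple[int, ...]
    seed: int | None

    @property
    def atom_sizes(self) -> np.ndarray:
        return self.G_true.sizes[self.atom_geneset_indices]


def make_geneset_prior(
    p: int = 500,
    sizes: tuple[int, ...] = DEFAULT_SIZES,
    per_size: int = 10,
    overlap_fraction: float = 1.0,
    seed: int | None = None,
) -> MembershipMatrix:
    """Random membership matrix with ``per_size`` genesets per size class.

    Members are sampled uniformly without replacement from the ``p``
    features.  ``overlap_fraction`` blends between fully independent
    sampling (1.0, genesets share features freely) and disjoint
    round-robin allocation (0.0, error if the features do not suffice).
    Intermediate values draw that fraction of each geneset's members
    from the whole feature pool and the rest from its private block.
    """
    if per_size < 1 or not sizes:
        raise ValueError("need at least one geneset")
    if max(sizes) > p:
        raise ValueError("geneset size exceeds the number of features")
    if not (0.0 <= overlap_fraction <= 1.0):
        raise ValueError("overlap_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    all_sizes = [s for s in sizes for _ in range(per_size)]
    private_sizes = [int(round((1.0 - overlap_fraction) * s)) for s in all_sizes]
    if sum(private_sizes) > p:
        raise ValueError(
            f"disjoint allocation infeasible: {sum(private_sizes)} private "
            f"features requested but only {p} available; raise overlap_fraction"
        )
    # round-robin: private blocks are carved from a single permutation
    perm = rng.permutation(p)
    rows, names = [], []
    cursor = 0
    for k, (s, s_priv) in enumerate(zip(all_sizes, private_sizes)):
        members = set(perm[cursor : cursor + s_priv].tolist())
        cursor += s_priv
        pool = np.setdiff1d(np.arange(p), np.fromiter(members, dtype=int, count=len(members)))
        extra = rng.choice(pool, size=s - len(members), replace=False)
        members |= set(extra.tolist())
        row = np.zeros(p, dtype=np.int8)
        row[list(members)] = 1
        rows.append(row)
        names.append(f"SIM_SET_{s}_{k % per_size + 1}" if per_size > 1 else f"SIM_SET_{s}")
    feature_ids = [f"g{j+1}" for j in range(p)]
    return MembershipMatrix(np.vstack(rows), names, feature_ids)


def simulate(
    G: MembershipMatrix,
    n: int = 400,
    n_atoms: int = 40,
    noise_sd: float = 0.5,
    score_sd: float = 1.0,
    seed: int | None = None,
) -> tuple[pd.DataFrame, SimTruth]:
    """Draw ``X = L_true · D_true + E`` with atoms planted in genesets.

    ``n_atoms`` genesets are selected equally across size classes (an
    error if ``n_atoms`` is not achievable without reusing a geneset);
    each planted atom is a random unit vector supported on its geneset,
    scores are i.i.d. ``N(0, score_sd²)`` and the noise is isotropic
    Gaussian with standard deviation ``noise_sd``.
    """
    if n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    rng = np.random.default_rng(seed)
    sizes = G.sizes
    classes = sorted(set(sizes.tolist()))
    per_class, rem = divmod(n_atoms, len(classes))
    chosen: list[int] = []
    for ci, c in enumerate(classes):
        members = np.flatnonzero(sizes == c)
        want = per_class + (1 if ci < rem else 0)
        if want > members.size:
            raise ValueError(
                f"cannot plant {want} atoms in the {members.size} genesets of size {c}"
            )
        chosen.extend(rng.choice(members, size=want, replace=False).tolist())

    p = G.n_features
    D = np.zeros((n_atoms, p))
    for k, gi in enumerate(chosen):
        support = G.support(gi)
        v = rng.standard_normal(support.size)
        v /= np.linalg.norm(v)
        D[k, support] = v
    L = rng.standard_normal((n, n_atoms)) * score_sd
    X = L @ D + rng.standard_normal((n, p)) * noise_sd

    frame = pd.DataFrame(
        X, index=[f"s{i+1}" for i in range(n)], columns=list(G.feature_ids)
    )
    truth = SimTruth(
        G_true=G,
        D_true=D,
        L_true=L,
        atom_geneset_indices=chosen,
        noise_sd=noise_sd,
        size_classes=tuple(classes),
        seed=seed,
    )
    return frame, truth


def to_collection(G: MembershipMatrix, description: str = "simulated") -> GenesetCollection:
    """View a membership matrix as a geneset collection (for GMT export)."""
    entries = []
    for i, name in enumerate(G.geneset_names):
        members = {G.feature_ids[j] for j in G.support(i)}
        entries.append((name, description, members))
    return GenesetCollection(entries)


@dataclass
class RecoveryReport:
    """How well a fitted model recovered the planted dictionary."""

    size_histogram: dict[int, int]
    matches: pd.DataFrame  # planted_atom, learned_atom, |cosine|
    recovered_fraction: float
    threshold: float
    selection_frequencies: dict[int, float] = field(default_factory=dict)


def recovery_report(
    model: PaslModel, truth: SimTruth, threshold: float = 0.9
) -> RecoveryReport:
    """Match learned atoms to planted atoms by absolute cosine similarity.

    Learned atoms live in the standardized feature space; planted atoms
    in the raw space.  Each learned loading is therefore mapped back
    (multiplied by the training standard deviations and renormalized)
    before the cosines are computed.  Matching is greedy one-to-one on
    the |cosine| matrix; the report includes the per-size-class
    histogram of selected inference atoms and the fraction of planted
    atoms recovered above ``threshold``.
    """
    d1 = [a for a in model.atoms if a.phase == "inference"]
    sizes = truth.G_true.sizes
    hist: dict[int, int] = {int(c): 0 for c in truth.size_classes}
    for a in d1:
        hist[int(sizes[a.geneset_index])] += 1
    total = sum(hist.values())
    freqs = {c: (v / total if total else 0.0) for c, v in hist.items()}

    rows = []
    if d1 and truth.D_true.size:
        Dl = np.vstack([a.loading for a in d1]) * model.standardizer.stds
        norms = np.linalg.norm(Dl, axis=1, keepdims=True)
        Dl /= np.where(norms > 0, norms, 1.0)
        Dt = truth.D_true / np.linalg.norm(truth.D_true, axis=1, keepdims=True)
        C = np.abs(Dl @ Dt.T)  # learned × planted
        n_match = min(C.shape)
        for _ in range(n_match):
            li, pi = np.unravel_index(np.argmax(C), C.shape)
            rows.append((int(pi), d1[li].name, float(C[li, pi])))
            C[li, :] = -1.0
            C[:, pi] = -1.0
    matches = pd.DataFrame(rows, columns=["planted_atom", "learned_atom", "cosine"])
    n_planted = truth.D_true.shape[0]
    recovered = int((matches["cosine"] > threshold).sum()) if len(matches) else 0
    return RecoveryReport(
        size_histogram=hist,
        matches=matches.sort_values("planted_atom").reset_index(drop=True),
        recovered_fraction=recovered / n_planted if n_planted else 0.0,
        threshold=threshold,
        selection_frequencies=freqs,
    )
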