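"""Inference phase: greedy extraction of geneset-constrained PC atoms.

The greedy loop maintains an ordering of genesets by the Box-Cox
normalized variance of their first principal component on the current
residual.  At each step the top entry is popped; its first PC is
recomputed on the current residual and accepted if the realized
normalized variance is at least ``t`` times the expected (precomputed)
one — otherwise the full ordering is recomputed.  ``t = 1`` therefore
reproduces the dynamic approach (re-solve over all genesets at every
iteration) and ``t = 0`` the static approach (order once, never again).
Accepted atoms are deflated from the residual; the loop stops at
``max_atoms`` or when the relative reconstruction error no longer
decreases by more than ``stop_tol``.

Variance normalization divides the raw first-PC variance by the Box-Cox
transform of the geneset size, compensating for the tendency of large
genesets to carry more variance purely by having more features.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "boxcox",
    "normalized_variance",
    "restricted_first_pc",
    "order_genesets",
    "deflate",
    "infer_dictionary",
    "OrderingEntry",
    "InferenceTrace",
    "Atom",
]


def boxcox(y: float, lam: float) -> float:
    """Box-Cox power transform ``(y**lam - 1)/lam`` (``log y`` at lam = 0).

    Continuous in ``lam`` at 0; requires ``y > 0``.
    """
    if y <= 0:
        raise ValueError(f"Box-Cox transform requires y > 0, got {y}")
    if lam == 0:
        return math.log(y)
    return (y**lam - 1.0) / lam


def normalized_variance(raw_variance: float, geneset_size: int, lam: float | None) -> float:
    """Size-normalized variance score: ``raw / boxcox(size, lam)``.

    ``lam=None`` disables normalization (score equals the raw variance).
    Since ``boxcox(1, lam) = 0`` for every ``lam``, singleton genesets use
    the size-2 divisor instead of dividing by zero.
    """
    if raw_variance < 0:
        raise ValueError("raw_variance must be >= 0")
    if geneset_size < 1:
        raise ValueError("geneset_size must be >= 1")
    if lam is None:
        return raw_variance
    divisor = boxcox(max(geneset_size, 2), lam)
    return raw_variance / divisor


def restricted_first_pc(X: np.ndarray, support: np.ndarray) -> tuple[np.ndarray, float]:
    """First principal component of ``X`` restricted to ``support`` columns.

    Returns the top right-singular direction embedded into length ``p``
    (zeros outside the support) and its variance ``σ₁²/(n−1)``.  The
    residual is not re-centered: deflation destroys column means, so the
    second-moment bookkeeping stays exact on the raw residual.  Sign
    convention: the largest-magnitude loading coefficient is positive.
    An all-zero restricted block yields a zero loading and variance 0.
    """
    support = np.asarray(support, dtype=np.intp)
    if support.size == 0:
        raise ValueError("support must be non-empty")
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least 2 samples")
    A = X[:, support]
    loading = np.zeros(p)
    if not A.any():
        return loading, 0.0
    # top singular pair via the smaller Gram matrix (deterministic)
    if n <= support.size:
        M = A @ A.T
        w, U = np.linalg.eigh(M)
        s2 = max(w[-1], 0.0)
        u = U[:, -1]
        v = A.T @ u
        nv = np.linalg.norm(v)
        if nv == 0.0:
            return loading, 0.0
        v /= nv
    else:
        M = A.T @ A
        w, V = np.linalg.eigh(M)
        s2 = max(w[-1], 0.0)
        v = V[:, -1]
    j = np.argmax(np.abs(v))
    if v[j] < 0:
        v = -v
    loading[support] = v
    return loading, s2 / (n - 1)


def deflate(X: np.ndarray, loading: np.ndarray) -> np.ndarray:
    """Remove an atom's contribution: ``X' = X − (X·d)·dᵀ``.

    Afterwards the projection of ``X'`` on ``d`` is zero.  A non-unit
    loading is normalized internally (with a warning).
    """
    norm = np.linalg.norm(loading)
    if not np.isclose(norm, 1.0, atol=1e-8):
        import warnings

        warnings.warn("deflate: loading not unit-norm, normalizing", stacklevel=2)
        loading = loading / norm
    scores = X @ loading
    return X - np.outer(scores, loading)


@dataclass
class OrderingEntry:
    """One geneset's first-PC summary on a given residual."""

    geneset_index: int
    raw_variance: float
    normalized_variance: float
    loading: np.ndarray
    size: int
    version: int = 0  # residual epoch the entry was computed on

    @property
    def sort_key(self) -> tuple:
        # descending normalized variance; ties: smaller geneset, lower index
        return (-self.normalized_variance, self.size, self.geneset_index)


@dataclass
class Atom:
    """One dictionary atom: a unit-norm loading with provenance."""

    loading: np.ndarray
    name: str
    phase: str  # "inference" or "discovery"
    geneset_index: int | None = None
    geneset_name: str | None = None
    occurrence: int = 1
    explained_variance: float = 0.0

    @property
    def support(self) -> np.ndarray:
        return np.flatnonzero(self.loading)


@dataclass
class InferenceTrace:
    """Per-iteration record of the greedy inference loop.

    ``records`` rows: (iteration, geneset_name, realized raw variance,
    expected normalized variance, realized normalized variance,
    relative reconstruction error after deflation, cumulative explained
    variance fraction, reorder flag).  The reorder flag is true at
    iteration 0 (the initial ordering).  ``initial_ordering`` keeps the
    ranked ``(name, normalized_variance)`` pairs computed before any atom
    was accepted.
    """

    t: float
    lam: float | None
    max_atoms: int
    stop_tol: float
    initial_ordering: list[tuple[str, float]] = field(default_factory=list)
    records: list[dict] = field(default_factory=list)
    n_reorders: int = 0
    notes: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        cols = [
            "iteration",
            "geneset",
            "realized_variance",
            "expected_normalized_variance",
            "realized_normalized_variance",
            "relative_reconstruction_error",
            "cumulative_explained_variance",
            "reorder",
        ]
        return pd.DataFrame(self.records, columns=cols)


def order_genesets(X: np.ndarray, G, lam: float | None) -> list[OrderingEntry]:
    """Rank all genesets by normalized first-PC variance on ``X``.

    Sorted by normalized variance descending; ties broken by smaller
    geneset size, then lower geneset index, so runs are deterministic
    regardless of sort stability.
    """
    if G.n_genesets == 0:
        raise ValueError("membership matrix has no genesets")
    sizes = G.sizes
    entries = []
    for i in range(G.n_genesets):
        loading, var = restricted_first_pc(X, G.support(i))
        nv = normalized_variance(var, int(sizes[i]), lam)
        entries.append(OrderingEntry(i, var, nv, loading, int(sizes[i])))
    entries.sort(key=lambda e: e.sort_key)
    return entries


def infer_dictionary(
    X: np.ndarray,
    G,
    t: float = 0.9,
    lam: float | None = 1.0 / 3.0,
    max_atoms: int = 500,
    stop_tol: float = 1e-3,
) -> tuple[list[Atom], InferenceTrace]:
    """Greedy geneset-constrained dictionary extraction (the inference phase).

    Parameters
    ----------
    X : standardized ``n × p`` matrix (it is not modified).
    G : MembershipMatrix aligned to the columns of ``X``.
    t : reorder threshold in [0, 1].  A popped geneset is accepted when
        its realized normalized variance is at least ``t`` times the
        expected one; otherwise the full ordering is recomputed.
    lam : Box-Cox exponent for size normalization; ``None`` disables it.
    max_atoms : upper bound on the number of atoms (a₁).
    stop_tol : stop when the relative reconstruction error decreases by
        less than this between consecutive accepted atoms.

    Returns the ordered atom list and the fit trace.  The same geneset
    may contribute several atoms (successive PCs of its residual block).
    """
    if not (0.0 <= t <= 1.0):
        raise ValueError(f"t must be in [0, 1], got {t}")
    if max_atoms < 0:
        raise ValueError("max_atoms must be >= 0")
    if G.n_genesets == 0:
        raise ValueError("membership matrix has no genesets")

    X = np.asarray(X, dtype=np.float64)
    R = X.copy()
    total = float(np.sum(X * X))
    trace = InferenceTrace(t=t, lam=lam, max_atoms=max_atoms, stop_tol=stop_tol)
    names = G.geneset_names
    sizes = G.sizes

    epoch = 0  # bumped at every deflation; entries carry the epoch they saw
    queue = order_genesets(R, G, lam)
    for e in queue:
        e.version = epoch
    trace.initial_ordering = [(names[e.geneset_index], e.normalized_variance) for e in queue]
    trace.n_reorders += 1  # the initial ordering counts as iteration-0 reorder

    atoms: list[Atom] = []
    occurrences: dict[int, int] = {}
    if total == 0.0:
        trace.notes.append("zero input matrix")
        return atoms, trace
    rel_err = 1.0
    iteration = 0

    while len(atoms) < max_atoms and queue:
        entry = queue.pop(0)
        gi = entry.geneset_index
        if entry.version == epoch:
            # computed on the current residual: expected == realized,
            # the acceptance test is a tautology
            loading, var = entry.loading, entry.raw_variance
            nv = entry.normalized_variance
        else:
            loading, var = restricted_first_pc(R, G.support(gi))
            nv = normalized_variance(var, int(sizes[gi]), lam)
            # at t=1 the ordering is recomputed at every iteration: a stale
            # entry whose restricted variance *grew* under deflation (possible
            # when genesets overlap the deflated atom) must not short-circuit
            # the full re-ranking
            if t >= 1.0 or nv < t * entry.normalized_variance:
                # stale ordering: recompute it on the current residual
                queue = order_genesets(R, G, lam)
                for e in queue:
                    e.version = epoch
                trace.n_reorders += 1
                trace.records.append(
                    {
                        "iteration": iteration,
                        "geneset": names[gi],
                        "realized_variance": var,
                        "expected_normalized_variance": entry.normalized_variance,
                        "realized_normalized_variance": nv,
                        "relative_reconstruction_error": rel_err,
                        "cumulative_explained_variance": 1.0 - rel_err,
                        "reorder": True,
                    }
                )
                iteration += 1
                continue
        if var <= 0.0 or nv <= 0.0:
            # nothing left in this geneset's block: drop it from the queue
            trace.notes.append(f"dropped geneset {names[gi]!r}: no variance left")
            continue

        # accept: deflate and record
        R -= np.outer(R @ loading, loading)
        epoch += 1
        occurrences[gi] = occurrences.get(gi, 0) + 1
        atoms.append(
            Atom(
                loading=loading,
                name=f"{names[gi]}.{occurrences[gi]}",
                phase="inference",
                geneset_index=gi,
                geneset_name=names[gi],
                occurrence=occurrences[gi],
                explained_variance=var,
            )
        )
        new_rel = float(np.sum(R * R)) / total
        trace.records.append(
            {
                "iteration": iteration,
                "geneset": names[gi],
                "realized_variance": var,
                "expected_normalized_variance": entry.normalized_variance,
                "realized_normalized_variance": nv,
                "relative_reconstruction_error": new_rel,
                "cumulative_explained_variance": 1.0 - new_rel,
                "reorder": False,
            }
        )
        iteration += 1
        decrease = rel_err - new_rel
        rel_err = new_rel
        if decrease < stop_tol:
            trace.notes.append("stopped: reconstruction error no longer decreasing")
            break
        if t >= 1.0:
            # dynamic mode: the full ordering is recomputed every iteration
            queue = order_genesets(R, G, lam)
            for e in queue:
                e.version = epoch
            trace.n_reorders += 1
        else:
            # the accepted geneset may contribute its next PC: reinsert it
            # with its variance recomputed on the deflated residual
            nloading, nvar = restricted_first_pc(R, G.support(gi))
            nnv = normalized_variance(nvar, int(sizes[gi]), lam)
            nentry = OrderingEntry(gi, nvar, nnv, nloading, int(sizes[gi]), version=epoch)
            keys = [e.sort_key for e in queue]
            queue.insert(bisect.bisect_left(keys, nentry.sort_key), nentry)

    return atoms, trace
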